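"""Population gene-tree congruence between two genes.

Haplotype tables are collapsed to k pseudo-haplotypes (average-linkage
clustering of Hamming distances), embedded in 3D by classical metric MDS,
and each population is represented as an isotropic Gaussian mixture whose
weights are pseudo-haplotype frequencies. Congruence between two such
mixtures is measured by dG, the squared L2 distance between the mixture
densities after the best rigid superposition (rotation, translation and
mirror reflection; no scaling), and assessed by permuting frequencies.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import cdist, squareform
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .errors import InputError
from .geometry import apply_rigid, kabsch

DEFAULT_K = 15
DEFAULT_N_PERM = 1000
DEFAULT_K_NN = 5


# ---------------------------------------------------------------------------
# Pseudo-haplotypes
# ---------------------------------------------------------------------------

@dataclass
class PseudoHaplotypeSet:
    """k representative sequences with pooled frequencies and a member map
    from original haplotype row to pseudo-haplotype index."""

    sequences: list[str]
    frequencies: np.ndarray
    members: dict[int, int]

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.frequencies < 0) or abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise InputError("pseudo-haplotype frequencies must be >= 0 and sum to 1")

    @property
    def k(self) -> int:
        return len(self.sequences)

    def distance_matrix(self) -> np.ndarray:
        return hamming_matrix(self.sequences)


def hamming_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise Hamming distance (mismatch count) between equal-length strings."""
    if len({len(s) for s in seqs}) != 1:
        raise InputError("sequences must have equal length")
    arr = np.array([list(s) for s in seqs])
    d = np.zeros((len(seqs), len(seqs)))
    for i in range(len(seqs)):
        d[i] = (arr != arr[i]).sum(axis=1)
    return d


def collapse_pseudohaplotypes(haps: pd.DataFrame, k: int = DEFAULT_K) -> PseudoHaplotypeSet:
    """Collapse a haplotype table (columns sequence/count/frequency) to k
    pseudo-haplotypes by average-linkage clustering of Hamming distances.

    The representative of each cluster is its highest-count member (ties by
    table order); the frequency is the summed member frequency.
    """
    n = len(haps)
    if n < k:
        raise InputError(f"only {n} haplotypes; choose k <= {n}")
    if k < 1:
        raise InputError("k must be >= 1")
    seqs = list(haps["sequence"])
    if n == k:
        labels = np.arange(n)
    else:
        d = hamming_matrix(seqs)
        z = linkage(squareform(d, checks=False), method="average")
        # cut_tree yields exactly k clusters even with tied merge heights
        labels = cut_tree(z, n_clusters=k).ravel()
    counts = np.asarray(haps["count"], dtype=float)
    freqs = counts / counts.sum()
    reps: list[str] = []
    pooled: list[float] = []
    members: dict[int, int] = {}
    for ci, lab in enumerate(sorted(set(labels.tolist()))):
        idx = np.flatnonzero(labels == lab)
        rep = idx[np.argmax(counts[idx])]
        reps.append(seqs[rep])
        pooled.append(float(freqs[idx].sum()))
        for j in idx:
            members[int(j)] = ci
    return PseudoHaplotypeSet(reps, np.array(pooled), members)


# ---------------------------------------------------------------------------
# 3D embedding and Gaussian mixtures
# ---------------------------------------------------------------------------

def embed_3d(dist: np.ndarray) -> np.ndarray:
    """Classical metric MDS into 3 dimensions.

    Axes are the three leading eigenvectors of the double-centered squared
    distance matrix, scaled by sqrt(eigenvalue); missing or non-positive
    axes are zero-padded. Sign convention: the first nonzero loading of
    each axis is positive.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(d, d.T) or np.any(np.abs(np.diag(d)) > 1e-12):
        raise InputError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    coords = np.zeros((n, 3))
    for axis, idx in enumerate(order[:3]):
        if evals[idx] <= 1e-12:
            break
        v = evecs[:, idx] * np.sqrt(evals[idx])
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
        coords[:, axis] = v
    return coords


@dataclass
class PopulationGMM:
    """Isotropic Gaussian mixture: k component means in 3D, one shared
    variance sigma2, weights = pseudo-haplotype frequencies."""

    means: np.ndarray
    weights: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.means.shape[0],):
            raise InputError("one weight per component required")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise InputError("weights must be >= 0 and sum to 1")
        if not self.sigma2 > 0:
            raise InputError("sigma2 must be positive")

    @property
    def k(self) -> int:
        return self.means.shape[0]

    def density(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        d2 = cdist(pts, self.means, "sqeuclidean")
        norm = (2.0 * np.pi * self.sigma2) ** -1.5
        return (np.exp(-d2 / (2.0 * self.sigma2)) * norm) @ self.weights

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PopulationGMM":
        return PopulationGMM(apply_rigid(self.means, rotation, translation),
                             self.weights.copy(), self.sigma2)

    def with_weights(self, weights: np.ndarray) -> "PopulationGMM":
        return PopulationGMM(self.means.copy(), weights, self.sigma2)


def gmm_from_pseudohaplotypes(
    pseudo: PseudoHaplotypeSet,
    sigma2: float | None = None,
    sigma_scale: float = 0.1,
) -> PopulationGMM:
    """Embed the pseudo-haplotype Hamming distances in 3D and wrap them in a
    mixture. Default sigma is ``sigma_scale`` times the mean inter-component
    distance."""
    coords = embed_3d(pseudo.distance_matrix())
    return make_gmm(coords, pseudo.frequencies, sigma2=sigma2, sigma_scale=sigma_scale)


def make_gmm(
    means: np.ndarray,
    weights: np.ndarray,
    sigma2: float | None = None,
    sigma_scale: float = 0.1,
) -> PopulationGMM:
    means = np.asarray(means, dtype=float).reshape(-1, 3)
    if sigma2 is None:
        d = cdist(means, means)
        k = means.shape[0]
        off = d[~np.eye(k, dtype=bool)]
        mean_sep = float(off.mean()) if off.size else 1.0
        if mean_sep <= 0:
            mean_sep = 1.0
        sigma2 = (sigma_scale * mean_sep) ** 2
    return PopulationGMM(means, weights, float(sigma2))


# ---------------------------------------------------------------------------
# dG and Procrustes superposition
# ---------------------------------------------------------------------------

def _cross_term(g1: PopulationGMM, g2: PopulationGMM) -> float:
    """integral of f1*f2 for two isotropic mixtures, in closed form."""
    s = g1.sigma2 + g2.sigma2
    d2 = cdist(g1.means, g2.means, "sqeuclidean")
    kern = (2.0 * np.pi * s) ** -1.5 * np.exp(-d2 / (2.0 * s))
    return float(g1.weights @ kern @ g2.weights)


def delta_g(g1: PopulationGMM, g2: PopulationGMM) -> float:
    """Squared L2 distance between the two mixture densities,
    integral of (f1 - f2)^2 over R^3, in closed form."""
    val = _cross_term(g1, g1) - 2.0 * _cross_term(g1, g2) + _cross_term(g2, g2)
    return max(val, 0.0)


@dataclass(frozen=True)
class ProcrustesResult:
    """Best rigid (possibly mirrored) superposition of g2 onto g1."""

    rotation: np.ndarray
    translation: np.ndarray
    delta_g: float
    mirrored: bool
    p_value: float | None = None


def procrustes_superimpose(g1: PopulationGMM, g2: PopulationGMM) -> ProcrustesResult:
    """Minimize dG over rotations, translations and mirror reflections.

    Components correspond by index; the Kabsch fit is weighted by the mean
    of the two components' frequencies, translation aligns the weighted
    centroids, and both the proper and the mirrored optimum are evaluated,
    keeping whichever gives the smaller dG. No scaling is applied.
    """
    if g1.k != g2.k:
        raise InputError("mixtures must have the same number of components")
    w = 0.5 * (g1.weights + g2.weights)
    best: ProcrustesResult | None = None
    for mirror in (False, True):
        r, t = kabsch(g2.means, g1.means, weights=w, allow_mirror=mirror)
        if mirror and np.linalg.det(r) > 0:
            continue  # unconstrained optimum was already proper
        moved = g2.transformed(r, t)
        dg = delta_g(g1, moved)
        if best is None or dg < best.delta_g:
            best = ProcrustesResult(r, t, dg, mirrored=bool(np.linalg.det(r) < 0))
    assert best is not None
    return best


def permutation_test(
    g1: PopulationGMM,
    g2: PopulationGMM,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
    shuffle: str = "both",
) -> ProcrustesResult:
    """Frequency-shuffling null for the Procrustes dG.

    The observed dG is the superposition optimum; each of ``n_perm`` null
    draws permutes the component frequencies (of both mixtures by default,
    or of one with ``shuffle='g1'``/``'g2'``) and recomputes the optimum.
    p = (1 + #{dG_null <= dG_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    if shuffle not in ("both", "g1", "g2"):
        raise InputError("shuffle must be 'both', 'g1' or 'g2'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = procrustes_superimpose(g1, g2)
    hits = 0
    for _ in range(n_perm):
        a = g1.with_weights(rng.permutation(g1.weights)) if shuffle in ("both", "g1") else g1
        b = g2.with_weights(rng.permutation(g2.weights)) if shuffle in ("both", "g2") else g2
        null = procrustes_superimpose(a, b)
        if null.delta_g <= obs.delta_g + 1e-15:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return ProcrustesResult(obs.rotation, obs.translation, obs.delta_g, obs.mirrored, p)


# ---------------------------------------------------------------------------
# Trees and tanglegram
# ---------------------------------------------------------------------------

def nj_tree(dist: np.ndarray, ids: list[str] | None = None) -> str:
    """Neighbor-joining tree of a distance matrix, returned as Newick."""
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("distance matrix must be square")
    k = d.shape[0]
    if k < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    if ids is None:
        ids = [f"h{i}" for i in range(k)]
    tree = _skbio_nj(DistanceMatrix(d, ids))
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tanglegram_edges(
    coords1: np.ndarray,
    coords2: np.ndarray,
    k_nn: int = DEFAULT_K_NN,
) -> list[tuple[int, int]]:
    """Mutual k-nearest-neighbour edges between two embedded leaf sets in a
    common (post-Procrustes) frame; distance ties broken by lower index."""
    c1 = np.asarray(coords1, dtype=float).reshape(-1, 3)
    c2 = np.asarray(coords2, dtype=float).reshape(-1, 3)
    d = cdist(c1, c2)
    k1 = min(k_nn, c2.shape[0])
    k2 = min(k_nn, c1.shape[0])
    # stable argsort => ties broken by lower index
    nn_of_1 = np.argsort(d, axis=1, kind="stable")[:, :k1]
    nn_of_2 = np.argsort(d.T, axis=1, kind="stable")[:, :k2]
    set2 = [set(row.tolist()) for row in nn_of_2]
    edges = []
    for i in range(c1.shape[0]):
        for j in nn_of_1[i]:
            if i in set2[j]:
                edges.append((i, int(j)))
    return edges
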