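"""Ternary complex assembly from binary docking poses.

Two binary poses sharing subunit A (receptor-ligand and receptor-receptor)
are merged by Kabsch superposition on the shared subunit; the resulting
ternary poses are screened with two inclusive constraints — at most
``max_overlap`` ligand atoms overlapping subunit B at the 1 A threshold and
a mean ligand-to-B distance of at most 5 A — then clustered by subunit-B
orientation (single linkage on RMSD) with the lowest-energy member as each
cluster's representative.

The module also builds the residue co-occurrence matrix over predicted
binding sites of a model collection and biclusters it into candidate sites.

The three geometric metrics (all in A, atoms as point sets):

    d(L, R)  = mean_i min_j |L_i - R_j|        (asymmetric by design)
    dm(L, R) = min_ij |L_i - R_j|              (symmetric)
    N_o      = #{i : min_j |L_i - R_j| < t_o}  (strict inequality)
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from sklearn.cluster import SpectralClustering

from .errors import InputError
from .geometry import apply_rigid, kabsch, superposition_rmsd
from .io import Structure

DEFAULT_OVERLAP_THRESHOLD = 1.0   # t_o, Angstrom
DEFAULT_MAX_OVERLAP = 10          # max allowed N_o
DEFAULT_MAX_MEAN_DIST = 5.0       # max allowed d(ligand, B), Angstrom
DEFAULT_RMSD_THRESHOLD = 5.0      # pose clustering cut, Angstrom


# ---------------------------------------------------------------------------
# Distance and overlap metrics
# ---------------------------------------------------------------------------

def _coords(x) -> np.ndarray:
    c = x.coords if isinstance(x, Structure) else np.asarray(x, dtype=float)
    c = c.reshape(-1, 3)
    if c.size == 0:
        raise InputError("empty atom set")
    return c


def mean_distance(ligand, receptor) -> float:
    """Mean over ligand atoms of the distance to the nearest receptor atom."""
    lc, rc = _coords(ligand), _coords(receptor)
    mins, _ = cKDTree(rc).query(lc)
    return float(np.mean(mins))


def min_distance(ligand, receptor) -> float:
    """Smallest atom-atom distance between the two sets (symmetric)."""
    lc, rc = _coords(ligand), _coords(receptor)
    mins, _ = cKDTree(rc).query(lc)
    return float(np.min(mins))


def overlap_count(ligand, receptor, t_o: float = DEFAULT_OVERLAP_THRESHOLD) -> int:
    """Number of ligand atoms whose nearest receptor atom is closer than
    ``t_o`` (strict)."""
    if t_o <= 0:
        raise InputError("overlap threshold must be positive")
    lc, rc = _coords(ligand), _coords(receptor)
    mins, _ = cKDTree(rc).query(lc)
    return int(np.sum(mins < t_o))


# ---------------------------------------------------------------------------
# Ternary poses
# ---------------------------------------------------------------------------

@dataclass
class TernaryPose:
    """A ligand and subunit B brought into subunit A's frame.

    A is the superposition anchor: its coordinates are shared by every
    ternary pose built from the same A-ligand pose.
    """

    pose_id: str
    a: Structure
    b: Structure
    ligand: Structure
    source: tuple[str, str] = ("", "")
    energy: float | None = None
    superposition_rmsd: float = 0.0
    metrics: dict = field(default_factory=dict)

    def compute_metrics(self, t_o: float = DEFAULT_OVERLAP_THRESHOLD) -> dict:
        self.metrics.update(
            n_overlap=overlap_count(self.ligand, self.b, t_o),
            mean_dist=mean_distance(self.ligand, self.b),
            min_dist=min_distance(self.ligand, self.b),
        )
        return self.metrics


def _atom_key_map(s: Structure) -> dict[tuple[str, str, str], int]:
    out = {}
    for res in s.residues:
        for i in res.atom_ids:
            out[(res.chain, res.index, s.atom_names[i])] = i
    return out


def merge_ternary(
    pose_al: tuple[Structure, Structure],
    pose_ab: tuple[Structure, Structure],
    pose_id: str = "",
    source: tuple[str, str] = ("", ""),
    energy: float | None = None,
    rmsd_warn: float = 1.0,
) -> TernaryPose:
    """Merge an A-ligand pose and an A-B pose into one ternary pose.

    The two copies of A are matched atom-by-atom on (chain, residue index,
    atom name); the Kabsch transform fitting pose_ab's A onto pose_al's A is
    applied to B. A superposition RMSD above ``rmsd_warn`` signals different
    A conformers and only raises a warning.
    """
    a_ref, ligand = pose_al
    a_mov, b = pose_ab
    keys_ref = _atom_key_map(a_ref)
    keys_mov = _atom_key_map(a_mov)
    common = [k for k in keys_ref if k in keys_mov]
    if len(common) < 3:
        raise InputError(
            f"shared subunit has only {len(common)} matched atoms; "
            "incompatible A sequences?"
        )
    x = a_mov.coords[[keys_mov[k] for k in common]]
    y = a_ref.coords[[keys_ref[k] for k in common]]
    rot, t = kabsch(x, y)
    rmsd = superposition_rmsd(apply_rigid(x, rot, t), y)
    if rmsd > rmsd_warn:
        warnings.warn(
            f"pose {pose_id or '?'}: A-subunit superposition RMSD {rmsd:.2f} A "
            "exceeds 1 A — different A conformers"
        )
    return TernaryPose(
        pose_id=pose_id, a=a_ref, b=b.transformed(rot, t), ligand=ligand,
        source=source, energy=energy, superposition_rmsd=rmsd,
    )


def filter_ternary(
    poses: list[TernaryPose],
    max_overlap: int = DEFAULT_MAX_OVERLAP,
    t_o: float = DEFAULT_OVERLAP_THRESHOLD,
    max_mean_dist: float = DEFAULT_MAX_MEAN_DIST,
) -> list[TernaryPose]:
    """Keep poses with N_o(ligand, B) <= max_overlap and d(ligand, B) <=
    max_mean_dist (both bounds inclusive). Each pose's metrics and verdict
    are recorded in ``pose.metrics``."""
    kept = []
    for pose in poses:
        m = pose.compute_metrics(t_o=t_o)
        ok = m["n_overlap"] <= max_overlap and m["mean_dist"] <= max_mean_dist
        pose.metrics["kept"] = bool(ok)
        if ok:
            kept.append(pose)
    return kept


@dataclass
class PoseCluster:
    members: list[str]
    representative: str


def cluster_poses(
    poses: list[TernaryPose],
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD,
) -> list[PoseCluster]:
    """Single-linkage clustering of poses on B-subunit RMSD.

    Poses are already in A-anchored frames, so equal heterodimer
    orientation means small B RMSD. Representatives are the lowest-energy
    members (ties by pose id); without energies, the lexicographically
    first pose id is used with a warning.
    """
    if not poses:
        raise InputError("no poses to cluster")
    n = len(poses)
    shapes = {p.b.coords.shape for p in poses}
    if len(shapes) != 1:
        raise InputError("poses must share subunit-B atom correspondence")
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = superposition_rmsd(poses[i].b.coords, poses[j].b.coords)
        if rmsd_threshold <= 0:
            labels = np.arange(n)
        else:
            z = linkage(squareform(dm, checks=False), method="single")
            labels = fcluster(z, t=rmsd_threshold, criterion="distance") - 1
    have_energy = all(p.energy is not None for p in poses)
    if not have_energy:
        warnings.warn("missing energies; representatives chosen by pose id")
    clusters = []
    for lab in sorted(set(labels.tolist())):
        idx = [i for i in range(n) if labels[i] == lab]
        members = [poses[i].pose_id for i in idx]
        if have_energy:
            rep = min(idx, key=lambda i: (poses[i].energy, poses[i].pose_id))
        else:
            rep = min(idx, key=lambda i: poses[i].pose_id)
        clusters.append(PoseCluster(members=members, representative=poses[rep].pose_id))
    return clusters


# ---------------------------------------------------------------------------
# Active-site co-occurrence
# ---------------------------------------------------------------------------

@dataclass
class SiteCoMatrix:
    """Residue-residue co-membership frequencies over a model collection:

        M_ij = sum_m f_m sum_s I_ms(i) I_ms(j)

    with f_m the model (haplotype) frequency and I_ms the indicator of
    residue membership in site s of model m.
    """

    residues: list[int]
    matrix: np.ndarray
    n_models: int

    def index_of(self, residue: int) -> int:
        return self.residues.index(residue)


def site_cooccurrence(models: list[tuple[float, list[set[int]]]]) -> SiteCoMatrix:
    """Build the co-occurrence matrix from (frequency, sites) per model,
    sites being residue-index sets (alignment columns)."""
    if not models:
        raise InputError("empty model list")
    for f, _sites in models:
        if f < 0:
            raise InputError("model frequencies must be nonnegative")
    universe = sorted({r for _, sites in models for s in sites for r in s})
    if not universe:
        raise InputError("no residues in any site")
    pos = {r: i for i, r in enumerate(universe)}
    m = np.zeros((len(universe), len(universe)))
    for f, sites in models:
        for s in sites:
            idx = [pos[r] for r in s]
            for i in idx:
                for j in idx:
                    m[i, j] += f
    return SiteCoMatrix(residues=universe, matrix=m, n_models=len(models))


def bicluster_sites(co: SiteCoMatrix, k: int, seed: int = 0) -> list[list[int]]:
    """Spectral clustering of the co-occurrence matrix (as an affinity)
    into k residue groups, ordered by descending summed within-group
    affinity. Residues with all-zero rows are left out."""
    active = np.flatnonzero(co.matrix.sum(axis=1) > 0)
    if active.size == 0:
        raise InputError("co-occurrence matrix is all zero")
    if k > active.size:
        raise InputError(f"k={k} exceeds the {active.size} residues with signal")
    sub = co.matrix[np.ix_(active, active)]
    if k == 1:
        groups_idx = [active.tolist()]
    else:
        sc = SpectralClustering(n_clusters=k, affinity="precomputed", random_state=seed,
                                assign_labels="discretize")
        with warnings.catch_warnings():
            # block-diagonal affinities (disconnected graphs) are expected here
            warnings.filterwarnings("ignore", message="Graph is not fully connected")
            labels = sc.fit_predict(sub)
        groups_idx = [active[labels == lab].tolist() for lab in sorted(set(labels.tolist()))]
    def affinity(g):
        idx = [int(np.flatnonzero(active == i)[0]) for i in g]
        return float(sub[np.ix_(idx, idx)].sum())
    groups_idx.sort(key=lambda g: (-affinity(g), g))
    return [[co.residues[i] for i in g] for g in groups_idx]
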