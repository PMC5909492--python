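"""Synthetic fixtures with planted ground truth.

Everything downstream is testable offline from three generators:

* toy dimers — two residue-lattice slabs facing each other across a known
  planar interface at z = 0, with jittered atom positions and residue names
  taken from the population's major haplotype so structures map onto their
  alignments;
* pooled population alignments — a major haplotype plus derived haplotypes
  carrying substitutions only inside planted patches (codon-consistent nt
  and aa rows), with Zipf-skewed clone counts summing to the pool size.
  Both the amino-acid-level and the nucleotide-level haplotype counts are
  plantable, emulating a pooled clone library of ~100 Sanger reads per gene;
* congruent / decoupled distance-matrix pairs driving the tree-congruence
  permutation test, and hand-placed docking pose batches with known
  overlap / distance metrics for the ternary filter.

Identical spec + seed reproduce identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import seq3

from .errors import InputError
from .geometry import random_rotation
from .io import CODON_TABLE, PopulationAlignment, Residue, Structure

SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPatch:
    """A residue-range patch of planted polymorphism (0-based, end exclusive)."""

    start: int
    end: int
    rate: float = 0.5          # per-site substitution probability per derived haplotype
    syn_fraction: float = 0.0  # probability a substitution is synonymous

    def columns(self) -> np.ndarray:
        return np.arange(self.start, self.end)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition defaults for all generators.

    The population emulates a pooled clone library: ``n_seq`` Sanger reads
    per gene collapsing to tens of haplotypes with Zipf-skewed frequencies.
    The dimer is a pair of ``res_grid`` residue lattices (``pitch`` A apart,
    ``atoms_per_residue`` jittered atoms each) separated by ``z_separation``
    A across the interface plane z = 0.
    """

    seed: int = 0
    n_seq: int = 100
    n_aa_hap: int = 20
    n_nt_hap: int = 30
    zipf_exponent: float = 1.0
    patches: tuple[PlantedPatch, ...] = ()
    res_grid: tuple[int, int] = (14, 14)
    pitch: float = 2.0
    atoms_per_residue: int = 4
    z_separation: float = 4.0
    slab_thickness: float = 1.5
    jitter: float = 0.15
    k_pseudo: int = 15


# ---------------------------------------------------------------------------
# Population alignments
# ---------------------------------------------------------------------------

def _syn_variants(codon: str) -> list[str]:
    aa = CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            m = codon[:pos] + alt + codon[pos + 1:]
            if CODON_TABLE[m] == aa:
                out.append(m)
    return out


def _nonsyn_variants(codon: str) -> list[str]:
    aa = CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            m = codon[:pos] + alt + codon[pos + 1:]
            if CODON_TABLE[m] not in (aa, "*"):
                out.append(m)
    return out


def _zipf_counts(n_items: int, total: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Integer counts summing to ``total``, Zipf-decaying over rank, each >= 1."""
    if n_items > total:
        raise InputError("more haplotypes than sequences")
    w = 1.0 / np.arange(1, n_items + 1) ** exponent
    w /= w.sum()
    raw = w * (total - n_items)
    counts = np.ones(n_items, dtype=int) + np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    for i in range(rem):
        counts[order[i % n_items]] += 1
    return counts


def make_population(
    spec: SyntheticSpec,
    n_columns: int,
    patches: tuple[PlantedPatch, ...] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PopulationAlignment, dict]:
    """Generate a pooled population alignment with planted patches.

    A random gap-free major haplotype (sense codons picked so every patch
    codon has both synonymous and non-synonymous single-nucleotide
    variants) is diversified into exactly ``spec.n_aa_hap`` amino-acid
    haplotypes; extra synonymous-only variants bring the nucleotide-level
    count to ``spec.n_nt_hap``. Substitutions occur only inside patches.
    Returns the alignment plus a ground-truth dict.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if patches is None:
        patches = spec.patches
    for p in patches:
        if not (0 <= p.start < p.end <= n_columns):
            raise InputError(f"patch {p} outside the {n_columns}-column alignment")
        if not 0.0 <= p.rate <= 1.0 or not 0.0 <= p.syn_fraction <= 1.0:
            raise InputError("patch rates must lie in [0, 1]")
    versatile = [c for c in SENSE_CODONS if _syn_variants(c) and _nonsyn_variants(c)]
    patch_cols = sorted({int(c) for p in patches for c in p.columns()})
    major = [str(rng.choice(SENSE_CODONS)) for _ in range(n_columns)]
    for c in patch_cols:
        major[c] = str(rng.choice(versatile))

    def mutate(base: list[str]) -> list[str]:
        out = list(base)
        for p in patches:
            for c in p.columns():
                if rng.random() >= p.rate:
                    continue
                syn = rng.random() < p.syn_fraction
                pool = _syn_variants(out[c]) if syn else _nonsyn_variants(out[c])
                if not pool:
                    pool = _nonsyn_variants(out[c]) or _syn_variants(out[c])
                out[c] = str(pool[rng.integers(len(pool))])
        return out

    def translate(codons: list[str]) -> str:
        return "".join(CODON_TABLE[c] for c in codons)

    nt_haps: list[list[str]] = [major]
    aa_seen = {translate(major)}
    nt_seen = {"".join(major)}
    guard = 0
    while len(aa_seen) < spec.n_aa_hap:
        cand = mutate(major)
        guard += 1
        if guard > 200 * spec.n_aa_hap:
            raise InputError(
                "cannot plant the requested aa haplotype count; "
                "increase patch size or rate"
            )
        if translate(cand) in aa_seen or "".join(cand) in nt_seen:
            continue
        nt_haps.append(cand)
        aa_seen.add(translate(cand))
        nt_seen.add("".join(cand))
    base_i = 0
    guard = 0
    while len(nt_haps) < spec.n_nt_hap:
        guard += 1
        if guard > 500 * spec.n_nt_hap:
            raise InputError("cannot plant the requested nt haplotype count")
        base = nt_haps[base_i % len(nt_haps)]
        base_i += 1
        cand = list(base)
        syn_cols = [c for c in patch_cols if _syn_variants(cand[c])]
        if not syn_cols:
            raise InputError("no patch codon admits a synonymous variant")
        c = int(syn_cols[rng.integers(len(syn_cols))])
        pool = _syn_variants(cand[c])
        cand[c] = str(pool[rng.integers(len(pool))])
        if "".join(cand) in nt_seen:
            continue
        nt_haps.append(cand)
        nt_seen.add("".join(cand))
    counts = _zipf_counts(len(nt_haps), spec.n_seq, spec.zipf_exponent, rng)
    aa = np.array([list(translate(hap)) for hap in nt_haps], dtype="<U1")
    nt = np.array([list("".join(hap)) for hap in nt_haps], dtype="<U1")
    aln = PopulationAlignment(
        aa=aa, nt=nt, counts=counts,
        ids=[f"hap{i}_n{int(c)}" for i, c in enumerate(counts)],
    )
    truth = {
        "major": "".join(major),
        "patch_columns": patch_cols,
        "n_aa_hap": len(aa_seen),
        "n_nt_hap": len(nt_haps),
    }
    return aln, truth


# ---------------------------------------------------------------------------
# Toy dimers and ligands
# ---------------------------------------------------------------------------

def _lattice_xy(spec: SyntheticSpec) -> np.ndarray:
    nx, ny = spec.res_grid
    xs = spec.pitch * (np.arange(nx) - (nx - 1) / 2.0)
    ys = spec.pitch * (np.arange(ny) - (ny - 1) / 2.0)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def residue_lattice_xy(spec: SyntheticSpec, residue_index: int) -> np.ndarray:
    """Planted lateral position of a residue (row-major over the lattice)."""
    return _lattice_xy(spec)[residue_index]


def _slab(
    spec: SyntheticSpec,
    sequence: str,
    z_surface: float,
    inward: float,
    chain: str,
    rng: np.random.Generator,
    label: str,
) -> Structure:
    xy = _lattice_xy(spec)
    if len(sequence) != xy.shape[0]:
        raise InputError("sequence length must equal the residue lattice size")
    local = np.array([[-0.4, -0.4], [0.4, -0.4], [-0.4, 0.4], [0.4, 0.4]])
    coords, names, elements, residues = [], [], [], []
    apr = spec.atoms_per_residue
    for ridx, aa in enumerate(sequence):
        ids = []
        for k in range(apr):
            off = local[k % 4] * (1 + k // 4)
            depth = z_surface + (inward * spec.slab_thickness if k >= apr / 2 else 0.0)
            pos = np.array([xy[ridx, 0] + off[0], xy[ridx, 1] + off[1], depth])
            pos = pos + rng.normal(scale=spec.jitter, size=3)
            ids.append(len(coords))
            coords.append(pos)
            names.append(f"C{k + 1}")
            elements.append("C")
        residues.append(Residue(str(ridx + 1), seq3(aa).upper(), chain, tuple(ids)))
    return Structure(np.array(coords), names, elements, residues, label=label)


def make_dimer(
    spec: SyntheticSpec,
    seq_a: str,
    seq_b: str,
    rng: np.random.Generator | None = None,
) -> tuple[Structure, Structure, dict]:
    """Two facing residue-lattice slabs with a known planar interface.

    Subunit A's surface layer sits at z = -z_separation/2 and B's at
    +z_separation/2, so the true contact surface is the plane z = 0. Residue
    k of each slab sits at the lattice position ``residue_lattice_xy(spec, k)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    half = spec.z_separation / 2.0
    a = _slab(spec, seq_a, -half, -1.0, "A", rng, label="subunitA")
    b = _slab(spec, seq_b, +half, +1.0, "B", rng, label="subunitB")
    truth = {"plane_z": 0.0, "separation": spec.z_separation}
    return a, b, truth


def make_ligand(
    spec: SyntheticSpec,
    path_xy: np.ndarray | None = None,
    n_atoms: int = 6,
    rng: np.random.Generator | None = None,
) -> Structure:
    """A small linear ligand lying in the interface plane (z = 0).

    Default: ``n_atoms`` atoms spaced 1.5 A along +X from the origin;
    ``path_xy`` overrides the lateral path.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    if path_xy is None:
        path_xy = np.column_stack([1.5 * np.arange(n_atoms), np.zeros(n_atoms)])
    path_xy = np.asarray(path_xy, dtype=float).reshape(-1, 2)
    coords = np.column_stack([path_xy, np.zeros(len(path_xy))])
    coords = coords + rng.normal(scale=spec.jitter / 2, size=coords.shape)
    residues = [Residue("1", "LIG", "L", tuple(range(len(coords))))]
    return Structure(coords, [f"C{i + 1}" for i in range(len(coords))],
                     ["C"] * len(coords), residues, label="ligand")


# ---------------------------------------------------------------------------
# Congruence fixtures
# ---------------------------------------------------------------------------

@dataclass
class CongruencePair:
    """Two matched population embeddings plus a decoupled control.

    ``dist1``/``freq1`` and ``dist2``/``freq2`` share tree structure and
    correlated frequencies; ``dist_ctrl``/``freq_ctrl`` are independent.
    """

    dist1: np.ndarray
    freq1: np.ndarray
    dist2: np.ndarray
    freq2: np.ndarray
    dist_ctrl: np.ndarray
    freq_ctrl: np.ndarray


def make_congruent_pair(
    spec: SyntheticSpec,
    k: int | None = None,
    noise: float = 0.05,
    rng: np.random.Generator | None = None,
) -> CongruencePair:
    """Distance matrices of two populations with matched topology and
    frequencies, plus a decoupled control.

    Set 1 is k random points in 3D; set 2 is a rigidly moved, lightly
    jittered copy (so pairwise distances nearly coincide) with identical
    Zipf frequencies. The control has independent geometry and
    independently shuffled frequencies.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if k is None:
        k = spec.k_pseudo
    if k < 3:
        raise InputError("need k >= 3 pseudo-haplotypes")
    pts1 = rng.normal(scale=3.0, size=(k, 3))
    rot = random_rotation(rng)
    pts2 = pts1 @ rot.T + rng.normal(scale=noise, size=(k, 3))
    pts_ctrl = rng.normal(scale=3.0, size=(k, 3))

    def dists(p):
        d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
        np.fill_diagonal(d, 0.0)
        return d

    freq = 1.0 / np.arange(1, k + 1) ** spec.zipf_exponent
    freq /= freq.sum()
    freq_ctrl = rng.permutation(freq)
    return CongruencePair(
        dist1=dists(pts1), freq1=freq.copy(),
        dist2=dists(pts2), freq2=freq.copy(),
        dist_ctrl=dists(pts_ctrl), freq_ctrl=freq_ctrl,
    )


# ---------------------------------------------------------------------------
# Pose fixtures
# ---------------------------------------------------------------------------

def _point_structure(coords: np.ndarray, chain: str, label: str) -> Structure:
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    residues = [Residue(str(i + 1), "GLY", chain, (i,)) for i in range(len(coords))]
    return Structure(coords, ["CA"] * len(coords), ["C"] * len(coords),
                     residues, label=label)


def make_filter_fixture() -> tuple[list, list[bool]]:
    """Eight hand-placed ternary poses with exactly known filter metrics.

    The ligand is 12 atoms spaced 20 A apart along X at z = 0; each pose's
    subunit B copies the ligand shifted per-atom along Z by ``t_i``, so the
    nearest-B distance of ligand atom i is exactly |t_i|: N_o counts
    |t_i| < 1 and the mean distance is mean |t_i|. Returns the poses and the
    expected keep verdicts (3 keepers, incl. both boundary cases N_o = 10
    and d = 5.0).
    """
    from .assembly import TernaryPose  # local import to avoid a cycle

    n = 12
    lig_coords = np.column_stack([20.0 * np.arange(n), np.zeros(n), np.zeros(n)])
    ligand = _point_structure(lig_coords, "L", "ligand")
    anchor = _point_structure(np.array([[0.0, 50.0, 0.0], [10.0, 50.0, 0.0],
                                        [20.0, 50.0, 0.0]]), "A", "anchorA")
    cases = [
        ("clear_keep", [0.0] * 4 + [2.0] * 8, True),        # N_o=4, d=1.33
        ("boundary_overlap", [0.0] * 10 + [2.5] * 2, True),  # N_o=10, d=0.42
        ("boundary_distance", [5.0] * 12, True),             # N_o=0, d=5.0
        ("over_overlap", [0.0] * 11 + [2.0], False),         # N_o=11
        ("over_distance", [5.5] * 12, False),                # d=5.5
        ("both_bad", [0.0] * 11 + [60.0], False),            # N_o=11, d=5.0
        ("all_overlap", [0.5] * 12, False),                  # N_o=12
        ("far_away", [7.0] * 12, False),                     # d=7.0
    ]
    poses, expected = [], []
    for name, shifts, keep in cases:
        b_coords = lig_coords + np.column_stack(
            [np.zeros(n), np.zeros(n), np.array(shifts)])
        poses.append(TernaryPose(
            pose_id=name, a=anchor, b=_point_structure(b_coords, "B", f"B_{name}"),
            ligand=ligand, energy=None,
        ))
        expected.append(keep)
    return poses, expected


def make_cluster_fixture(
    spec: SyntheticSpec,
    n_groups: int = 3,
    per_group: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[list, list[int]]:
    """Ternary poses in well-separated orientation groups.

    Each group shares one rigid placement of subunit B (jittered by 0.1 A
    per pose); across groups B is rotated far apart. Energies increase with
    pose order so the first pose of each group is its lowest-energy
    representative. Returns poses and their group labels.
    """
    from .assembly import TernaryPose

    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    base = rng.normal(scale=4.0, size=(20, 3)) + np.array([0.0, 0.0, 30.0])
    ligand = _point_structure(rng.normal(scale=2.0, size=(6, 3)), "L", "ligand")
    anchor = _point_structure(np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0],
                                        [0.0, 5.0, 0.0]]), "A", "anchorA")
    poses, labels = [], []
    for g in range(n_groups):
        rot = random_rotation(rng)
        shift = rng.normal(scale=25.0, size=3)
        placed = base @ rot.T + shift
        for p in range(per_group):
            jitter = rng.normal(scale=0.1, size=placed.shape)
            pid = f"g{g}p{p}"
            poses.append(TernaryPose(
                pose_id=pid, a=anchor,
                b=_point_structure(placed + jitter, "B", f"B_{pid}"),
                ligand=ligand, energy=float(10 * g + p),
            ))
            labels.append(g)
    return poses, labels
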