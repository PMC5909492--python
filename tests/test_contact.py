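"""Complex orientation, contact surface, sliding cylinder, diversity maps."""
import numpy as np
import pytest

import cylmap as cm
from cylmap.errors import EmptyResultError, InputError
from cylmap.geometry import random_rotation


def slab_structure(z, nx=6, ny=6, pitch=2.0, chain="A", label="slab", jitter=0.0, seed=0):
    """Flat residue lattice at height z; 1 atom per residue unless jittered."""
    rng = np.random.default_rng(seed)
    coords, names, elements, residues = [], [], [], []
    idx = 0
    for i in range(nx):
        for j in range(ny):
            pos = np.array([pitch * (i - (nx - 1) / 2), pitch * (j - (ny - 1) / 2), z])
            if jitter:
                pos = pos + rng.normal(scale=jitter, size=3)
            coords.append(pos)
            names.append("CA")
            elements.append("C")
            residues.append(cm.Residue(str(idx + 1), "GLY", chain, (idx,)))
            idx += 1
    return cm.Structure(np.array(coords), names, elements, residues, label=label)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def test_orientation_puts_centroid_axis_on_z():
    a = slab_structure(-3.0, jitter=0.3, seed=1)
    b = slab_structure(+3.0, jitter=0.3, seed=2, chain="B")
    a2, b2 = cm.orient_complex(a, b)
    ca, cb = a2.centroid(), b2.centroid()
    assert np.allclose(ca[:2], cb[:2], atol=1e-9)
    assert cb[2] > ca[2]
    assert np.allclose(0.5 * (ca + cb), 0.0, atol=1e-9)
    # rigid motion preserves the centroid separation
    assert np.linalg.norm(cb - ca) == pytest.approx(
        np.linalg.norm(b.centroid() - a.centroid()))


def test_orientation_is_invariant_to_rigid_pretransform():
    a = slab_structure(-3.0, jitter=0.3, seed=3)
    b = slab_structure(+3.0, jitter=0.3, seed=4, chain="B")
    ref_a, ref_b = cm.orient_complex(a, b)
    rng = np.random.default_rng(5)
    for _ in range(5):
        rot = random_rotation(rng)
        shift = rng.normal(scale=30.0, size=3)
        a2, b2 = cm.orient_complex(a.transformed(rot, shift), b.transformed(rot, shift))
        assert np.allclose(a2.coords, ref_a.coords, atol=1e-6)
        assert np.allclose(b2.coords, ref_b.coords, atol=1e-6)


def test_orientation_rejects_coincident_centroids():
    a = slab_structure(0.0)
    with pytest.raises(InputError):
        cm.orient_complex(a, a)


# ---------------------------------------------------------------------------
# Contact surface
# ---------------------------------------------------------------------------

def test_flat_slabs_give_midplane_surface():
    a = slab_structure(-2.0)
    b = slab_structure(+2.0, chain="B")
    surf = cm.build_surface(a, b, step=1.0, gap_threshold=8.0)
    assert surf.n_defined > 0
    assert np.allclose(surf.z[surf.defined], 0.0, atol=1e-12)
    assert np.allclose(surf.gap[surf.defined], 4.0, atol=1e-12)


def test_gap_threshold_excludes_distant_slabs():
    a = slab_structure(-2.0)
    b = slab_structure(+2.0, chain="B")
    with pytest.raises(EmptyResultError):
        cm.build_surface(a, b, gap_threshold=3.0)  # gap 4 > 3


def test_tilted_slab_midpoint_follows_the_analytic_plane():
    # upper slab: z = 3 + 0.2 x; lower flat at -3 -> midpoint 0.5*(0.2x)
    nx, ny, pitch = 9, 9, 2.0
    a = slab_structure(-3.0, nx=nx, ny=ny, pitch=pitch)
    b = slab_structure(0.0, nx=nx, ny=ny, pitch=pitch, chain="B")
    coords = b.coords.copy()
    coords[:, 2] = 3.0 + 0.2 * coords[:, 0]
    b = cm.Structure(coords, b.atom_names, b.elements, b.residues, label="tilted")
    surf = cm.build_surface(a, b, step=1.0, gap_threshold=10.0)
    xs, _ = surf.grid_xy()
    for i, j in surf.defined_nodes():
        x_near_atoms = coords[np.abs(coords[:, 0] - xs[i]) <= 0.8, 0]
        if x_near_atoms.size == 0:
            continue
        expected = 0.5 * (-3.0 + 3.0 + 0.2 * x_near_atoms.min())
        assert surf.z[i, j] == pytest.approx(expected, abs=0.25)


def test_surface_midpoint_property():
    a = slab_structure(-2.5, jitter=0.2, seed=6)
    b = slab_structure(+2.5, jitter=0.2, seed=7, chain="B")
    a, b = cm.orient_complex(a, b)
    surf = cm.build_surface(a, b)
    # z - lower == upper - z at every defined node
    capture = surf.step * np.sqrt(2) / 2
    for i, j in surf.defined_nodes():
        xy = surf.node_xy(i, j)
        for s, side in ((a, "below"), (b, "above")):
            lat = np.linalg.norm(s.coords[:, :2] - xy, axis=1)
            zs = s.coords[lat <= capture, 2]
            bound = zs.max() if side == "below" else zs.min()
            assert abs(abs(surf.z[i, j] - bound) - surf.gap[i, j] / 2) < 1e-9


# ---------------------------------------------------------------------------
# Cylinder neighborhood
# ---------------------------------------------------------------------------

def four_atom_residue(center, spread=0.5, chain="A"):
    offs = np.array([[-1, -1, 0], [1, -1, 0], [-1, 1, 0], [1, 1, 0]]) * spread
    coords = np.asarray(center) + offs
    return cm.Structure(
        coords, [f"C{i}" for i in range(4)], ["C"] * 4,
        [cm.Residue("1", "GLY", chain, (0, 1, 2, 3))],
    )


def test_single_residue_fully_inside_has_unit_weight():
    s = four_atom_residue([0.0, 0.0, -2.0])
    nb = cm.cylinder_neighborhood(s, np.zeros(3), r=4.0, h=1.0)
    assert nb.f[0] == 1.0
    assert nb.w[0] == pytest.approx(1.0)  # d = min d -> exponent 0


def test_partial_membership_fraction():
    # 2 of 4 atoms inside r: atoms at x = +-2.0, radius cuts at 1.0
    offs = np.array([[-2.0, 0, 0], [-1.8, 0, 0], [2.0, 0, 0], [1.8, 0, 0]])
    s = cm.Structure(offs, [f"C{i}" for i in range(4)], ["C"] * 4,
                     [cm.Residue("1", "GLY", "A", (0, 1, 2, 3))])
    nb = cm.cylinder_neighborhood(s, np.array([-2.0, 0.0, 0.0]), r=1.0, h=1.0)
    assert nb.f[0] == pytest.approx(0.5)


def test_weight_ratio_follows_gauss_decay():
    h = 3.0
    r1 = four_atom_residue([0.0, 0.0, -2.0])
    r2 = four_atom_residue([0.0, 0.0, -3.5])
    merged = cm.Structure(
        np.vstack([r1.coords, r2.coords]),
        r1.atom_names + r2.atom_names, ["C"] * 8,
        [cm.Residue("1", "GLY", "A", (0, 1, 2, 3)),
         cm.Residue("2", "GLY", "A", (4, 5, 6, 7))],
    )
    nb = cm.cylinder_neighborhood(merged, np.zeros(3), r=5.0, h=h)
    delta = nb.d[1] - nb.d[0]
    assert nb.w[0] == pytest.approx(1.0)
    assert nb.w[1] / nb.w[0] == pytest.approx(np.exp(-delta ** 2 / h))
    # monotone: w non-increasing in d at fixed f
    order = np.argsort(nb.d)
    assert all(np.diff(nb.w[order]) <= 1e-12)


def test_empty_cylinder_returns_empty_neighborhood():
    s = four_atom_residue([50.0, 50.0, 0.0])
    nb = cm.cylinder_neighborhood(s, np.zeros(3), r=2.0)
    assert nb.empty


# ---------------------------------------------------------------------------
# Diversity maps
# ---------------------------------------------------------------------------

def test_monomorphic_alignment_gives_all_zero_pi_map(patch_spec, oriented_dimer):
    a, b, _ = oriented_dimer
    n_res = patch_spec.res_grid[0] * patch_spec.res_grid[1]
    mono = cm.SyntheticSpec(seed=2, n_aa_hap=1, n_nt_hap=1)
    aln, _ = cm.make_population(mono, n_res)
    aln = cm.PopulationAlignment(
        aa=np.array([list(a.sequence())] * 2), counts=np.array([50, 50]))
    surf = cm.build_surface(a, b)
    m = cm.diversity_map(surf, a, aln, cm.map_structure_to_alignment(a, aln))
    assert np.nanmax(m.values) == 0.0


def test_pi_map_peaks_at_planted_patch(patch_spec, population, oriented_dimer):
    aln, truth = population
    a, b, _ = oriented_dimer
    surf = cm.build_surface(a, b)
    m = cm.diversity_map(surf, a, aln, cm.map_structure_to_alignment(a, aln))
    # planted truth: lateral positions of the patch residues after orientation
    patch_xy = np.array([a.residue_coords(c).mean(axis=0)[:2]
                         for c in truth["patch_columns"]])
    peak = np.unravel_index(np.nanargmax(m.values), m.values.shape)
    peak_xy = surf.node_xy(*peak)
    dist = np.linalg.norm(patch_xy - peak_xy, axis=1).min()
    assert dist <= patch_spec.pitch + 4.0  # peak sits on/near the planted strip


def test_wide_cylinder_flat_bandwidth_reduces_to_global_pi(patch_spec, population,
                                                           oriented_dimer):
    aln, _ = population
    a, b, _ = oriented_dimer
    surf = cm.build_surface(a, b, step=4.0)
    colmap = cm.map_structure_to_alignment(a, aln)
    # radius beyond the lateral extent, near-infinite bandwidth: every node
    # sees all residues with f = 1, w = 1 -> global unweighted pi
    m = cm.diversity_map(surf, a, aln, colmap, r=1e3, h=1e12)
    expected = cm.pi_sites(aln)
    vals = m.values[~np.isnan(m.values)]
    assert np.allclose(vals, expected, atol=1e-9)


def test_diversity_map_rigid_invariance(patch_spec, population):
    aln, _ = population
    seq = "".join(aln.aa[0])
    small = cm.SyntheticSpec(seed=21, res_grid=(8, 8), patches=patch_spec.patches)
    a0, b0, _ = cm.make_dimer(small, seq[:64], seq[:64])
    rng = np.random.default_rng(17)

    def pipeline(a, b):
        a, b = cm.orient_complex(a, b)
        surf = cm.build_surface(a, b)
        colmap = cm.map_structure_to_alignment(a, aln)
        return cm.diversity_map(surf, a, aln, colmap).values

    ref = pipeline(a0, b0)
    for _ in range(3):
        rot = random_rotation(rng)
        shift = rng.normal(scale=20.0, size=3)
        moved = pipeline(a0.transformed(rot, shift), b0.transformed(rot, shift))
        assert moved.shape == ref.shape
        assert np.allclose(np.nan_to_num(moved, nan=-1),
                           np.nan_to_num(ref, nan=-1), atol=1e-9)


def test_grid_refinement_keeps_map_stable(patch_spec, population, oriented_dimer):
    aln, _ = population
    a, b, _ = oriented_dimer
    colmap = cm.map_structure_to_alignment(a, aln)
    coarse = cm.diversity_map(cm.build_surface(a, b, step=2.0), a, aln, colmap)
    fine = cm.diversity_map(cm.build_surface(a, b, step=1.0), a, aln, colmap)
    # compare nodes at shared (x, y) positions
    cx, cy = coarse.surface.grid_xy()
    fx, fy = fine.surface.grid_xy()
    checked = 0
    for i, j in coarse.surface.defined_nodes():
        fi = np.flatnonzero(np.abs(fx - cx[i]) < 1e-9)
        fj = np.flatnonzero(np.abs(fy - cy[j]) < 1e-9)
        if fi.size and fj.size and not np.isnan(fine.values[fi[0], fj[0]]):
            assert fine.values[fi[0], fj[0]] == pytest.approx(
                coarse.values[i, j], abs=0.05 * max(coarse.finite_max(), 1e-9))
            checked += 1
    assert checked > 10
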