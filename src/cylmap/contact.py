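"""Contact-zone construction and sliding-cylinder diversity maps.

The two docked subunits are first brought into a canonical frame: the axis
through their centroids becomes +Z (subunit ``a`` below, ``b`` above) with
the origin at the centroid midpoint, and the in-plane orientation is fixed
by the leading principal axis of the union. On an XY grid, each node's z is
the midpoint between the two subunits along the vertical through that node;
nodes where either side is absent or the vertical gap exceeds a threshold
are undefined. The defined nodes form the contact surface.

A vertical cylinder of radius r slid across the grid then collects, per
node, the nearby residues of one subunit with Gauss-decay weights

    w_i = f_i * exp(-(d_i - min_j d_j)^2 / h)

where f_i is the fraction of the residue's atoms inside the cylinder, d_i
the mean 3D distance of its atoms to the node, and h a bandwidth defaulting
to s^2/2 with s the subunit's mean atom-to-centroid distance. Population
diversity (pi or dN/dS) over the collected residues, weighted by w_i, gives
one map value per node.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyResultError, InputError
from .io import PopulationAlignment, ResidueColumnMap, Structure
from .popdiv import (
    NO_VARIATION,
    UNDEFINED_HIGH,
    codon_column_counts,
    dnds_from_counts,
    pi_sites,
)

DEFAULT_RADIUS = 4.0       # cylinder radius r, Angstrom
DEFAULT_STEP = 1.0         # grid step, Angstrom
DEFAULT_GAP_THRESHOLD = 8.0  # max vertical protein-protein gap, Angstrom


# ---------------------------------------------------------------------------
# Canonical orientation
# ---------------------------------------------------------------------------

def orientation_frame(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and pre-translation of the canonical complex frame.

    Returns ``(M, m)`` such that oriented coordinates are ``(x - m) @ M``:
    column 3 of M is the unit centroid axis a->b, columns 1/2 span the
    orthogonal plane with the leading principal axis of the union projected
    onto +X. The principal-axis sign is fixed by the third central moment
    along it, which makes the frame equivariant under rigid motions of the
    input (up to exactly symmetric degenerate inputs).
    """
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise InputError("both subunits must be nonempty")
    ca, cb = a.centroid(), b.centroid()
    axis = cb - ca
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise InputError("subunit centroids coincide; cannot define the complex axis")
    e3 = axis / norm
    m = 0.5 * (ca + cb)
    union = np.vstack([a.coords, b.coords]) - m
    cov = union.T @ union / union.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    u = v - (v @ e3) * e3
    if np.linalg.norm(u) < 1e-8:  # principal axis parallel to Z: try next axis
        v = evecs[:, np.argsort(evals)[-2]]
        u = v - (v @ e3) * e3
        if np.linalg.norm(u) < 1e-8:
            u = np.array([1.0, 0.0, 0.0]) - e3[0] * e3
    u /= np.linalg.norm(u)
    skew = float(np.sum((union @ u) ** 3))
    if skew < 0:
        u = -u
    e1 = u
    e2 = np.cross(e3, e1)
    return np.column_stack([e1, e2, e3]), m


def orient_complex(a: Structure, b: Structure, *extra: Structure) -> tuple[Structure, ...]:
    """Rigidly move the complex into the canonical frame.

    ``a`` ends below the XY plane and ``b`` above, centroid midpoint at the
    origin. Any ``extra`` structures (e.g. a ligand) receive the same
    transform.
    """
    frame, m = orientation_frame(a, b)
    rot = frame.T                      # x' = R (x - m)
    shift = -rot @ m
    return tuple(s.transformed(rot, shift) for s in (a, b, *extra))


# ---------------------------------------------------------------------------
# Contact surface
# ---------------------------------------------------------------------------

@dataclass
class ContactSurface:
    """Gridded midpoint surface between the two oriented subunits.

    ``z`` is an (nx, ny) array, NaN where undefined; node (i, j) sits at
    ``origin + step * (i, j)``. ``gap`` stores the vertical protein-protein
    distance per node.
    """

    origin: np.ndarray       # (2,) x0, y0
    step: float
    z: np.ndarray            # (nx, ny), NaN = undefined
    gap: np.ndarray          # (nx, ny), NaN = undefined
    gap_threshold: float
    above_label: str = ""
    below_label: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.z)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())

    def node_xy(self, i: int, j: int) -> np.ndarray:
        return self.origin + self.step * np.array([i, j], dtype=float)

    def node_xyz(self, i: int, j: int) -> np.ndarray:
        x, y = self.node_xy(i, j)
        return np.array([x, y, self.z[i, j]])

    def defined_nodes(self) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.defined)]

    def grid_xy(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.z.shape
        xs = self.origin[0] + self.step * np.arange(nx)
        ys = self.origin[1] + self.step * np.arange(ny)
        return xs, ys

    def same_grid(self, other: "ContactSurface") -> bool:
        return (
            self.z.shape == other.z.shape
            and abs(self.step - other.step) < 1e-9
            and np.allclose(self.origin, other.origin)
        )


def build_surface(
    a: Structure,
    b: Structure,
    step: float = DEFAULT_STEP,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    capture: float | None = None,
) -> ContactSurface:
    """Build the gridded contact surface of an oriented complex.

    Per column, the lower bound is the max z of below-subunit atoms within
    the lateral capture radius (default step * sqrt(2)/2) and the upper
    bound the min z of above-subunit atoms; the node's z is their midpoint.
    Nodes with either side empty or a gap above ``gap_threshold`` are
    undefined.
    """
    if step <= 0:
        raise InputError("step must be positive")
    if capture is None:
        capture = step * math.sqrt(2.0) / 2.0
    below, above = (a, b) if a.centroid()[2] <= b.centroid()[2] else (b, a)
    allxy = np.vstack([a.coords[:, :2], b.coords[:, :2]])
    lo = np.floor(allxy.min(axis=0) / step) * step
    hi = np.ceil(allxy.max(axis=0) / step) * step
    nx = int(round((hi[0] - lo[0]) / step)) + 1
    ny = int(round((hi[1] - lo[1]) / step)) + 1
    z = np.full((nx, ny), np.nan)
    gap = np.full((nx, ny), np.nan)
    tree_lo = cKDTree(below.coords[:, :2])
    tree_hi = cKDTree(above.coords[:, :2])
    xs = lo[0] + step * np.arange(nx)
    ys = lo[1] + step * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    hits_lo = tree_lo.query_ball_point(nodes, capture)
    hits_hi = tree_hi.query_ball_point(nodes, capture)
    for flat, (il, ih) in enumerate(zip(hits_lo, hits_hi)):
        if not il or not ih:
            continue
        zlow = below.coords[il, 2].max()
        zup = above.coords[ih, 2].min()
        g = zup - zlow
        if g > gap_threshold:
            continue
        i, j = divmod(flat, ny)
        z[i, j] = 0.5 * (zlow + zup)
        gap[i, j] = g
    if not np.any(~np.isnan(z)):
        raise EmptyResultError(
            "no defined surface nodes: subunits not in contact at this gap threshold"
        )
    return ContactSurface(
        origin=lo, step=step, z=z, gap=gap, gap_threshold=gap_threshold,
        above_label=above.label, below_label=below.label,
    )


# ---------------------------------------------------------------------------
# Sliding cylinder
# ---------------------------------------------------------------------------

@dataclass
class CylinderNeighborhood:
    """Residues of one subunit inside the cylinder at a surface node.

    Per residue: f (atom fraction inside), d (mean 3D atom distance to the
    node), w (Gauss-decay weight, maximal for the closest residue).
    """

    center: np.ndarray
    radius: float
    bandwidth: float
    residue_ids: np.ndarray   # indices into Structure.residues
    f: np.ndarray
    d: np.ndarray
    w: np.ndarray

    @property
    def empty(self) -> bool:
        return self.residue_ids.size == 0


def cylinder_neighborhood(
    s: Structure,
    center: np.ndarray,
    r: float = DEFAULT_RADIUS,
    h: float | None = None,
) -> CylinderNeighborhood:
    """Collect the residues of subunit ``s`` inside the infinite vertical
    cylinder of radius ``r`` centred at the 3D surface node ``center``.

    Membership is lateral (XY distance <= r); f/d/w follow the Gauss-decay
    weighting. ``h`` defaults to s^2/2 with s the subunit's mean
    atom-to-centroid distance. An empty cylinder returns an empty
    neighborhood; the caller decides how to treat it.
    """
    if r <= 0:
        raise InputError("cylinder radius must be positive")
    center = np.asarray(center, dtype=float).reshape(3)
    if h is None:
        h = s.mean_size() ** 2 / 2.0
    if h <= 0:
        raise InputError("bandwidth h must be positive")
    lat = np.linalg.norm(s.coords[:, :2] - center[:2], axis=1)
    inside = lat <= r
    rid, f, d = [], [], []
    for i, res in enumerate(s.residues):
        ids = list(res.atom_ids)
        n_in = int(inside[ids].sum())
        if n_in == 0:
            continue
        rid.append(i)
        f.append(n_in / len(ids))
        d.append(float(np.linalg.norm(s.coords[ids] - center, axis=1).mean()))
    if not rid:
        return CylinderNeighborhood(center, r, h, np.empty(0, int),
                                    np.empty(0), np.empty(0), np.empty(0))
    f_arr = np.array(f)
    d_arr = np.array(d)
    w_arr = f_arr * np.exp(-((d_arr - d_arr.min()) ** 2) / h)
    return CylinderNeighborhood(center, r, h, np.array(rid), f_arr, d_arr, w_arr)


@dataclass
class DiversityMap:
    """Per-node scalar field over a contact surface for one subunit.

    ``values`` mirrors the surface grid: NaN = undefined node or empty
    cylinder; +inf encodes the dN/dS "undefined-high" sentinel (only
    non-synonymous variation) and 0.0 the "no-variation" sentinel.
    """

    surface: ContactSurface
    values: np.ndarray
    subunit: str
    measure: str

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def finite_max(self) -> float:
        finite = self.values[np.isfinite(self.values)]
        return float(finite.max()) if finite.size else 0.0


def diversity_map(
    surface: ContactSurface,
    s: Structure,
    aln: PopulationAlignment,
    colmap: ResidueColumnMap,
    measure: str = "pi",
    r: float = DEFAULT_RADIUS,
    h: float | None = None,
) -> DiversityMap:
    """Slide the cylinder across the defined surface nodes and score the
    population diversity of subunit ``s`` at each node.

    ``measure`` is 'pi' (weighted amino-acid diversity) or 'dnds'
    (weighted Nei-Gojobori ratio with sentinel encoding). Residues without
    an alignment column are dropped with a warning.
    """
    if measure not in ("pi", "dnds"):
        raise InputError("measure must be 'pi' or 'dnds'")
    if h is None:
        h = s.mean_size() ** 2 / 2.0
    chain_res = s.chain_residues(colmap.chain)
    chain_pos = {id(res): pos for pos, res in enumerate(chain_res)}
    col_of = colmap.as_dict()
    res_to_col: dict[int, int] = {}
    unmapped = 0
    for i, res in enumerate(s.residues):
        pos = chain_pos.get(id(res))
        if pos is None:
            continue
        col = col_of.get(pos)
        if col is None:
            unmapped += 1
            continue
        res_to_col[i] = col
    if unmapped:
        warnings.warn(f"{unmapped} residues of {s.label!r} have no alignment column; dropped")
    col_counts = (
        {col: codon_column_counts(aln, col) for col in sorted(set(res_to_col.values()))}
        if measure == "dnds"
        else {}
    )
    values = np.full(surface.shape, np.nan)
    for i, j in surface.defined_nodes():
        nb = cylinder_neighborhood(s, surface.node_xyz(i, j), r=r, h=h)
        if nb.empty:
            continue
        cols, wts = [], []
        for rid, w in zip(nb.residue_ids, nb.w):
            col = res_to_col.get(int(rid))
            if col is not None:
                cols.append(col)
                wts.append(w)
        if not cols:
            continue
        if measure == "pi":
            values[i, j] = pi_sites(aln, np.array(cols), np.array(wts))
        else:
            v = dnds_from_counts([col_counts[c] for c in cols], np.array(wts))
            if v == NO_VARIATION:
                values[i, j] = 0.0
            elif v == UNDEFINED_HIGH:
                values[i, j] = np.inf
            else:
                values[i, j] = float(v)
    if not np.any(~np.isnan(values)):
        raise EmptyResultError("no surface node obtained a diversity value")
    return DiversityMap(surface, values, subunit=s.label, measure=measure)
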