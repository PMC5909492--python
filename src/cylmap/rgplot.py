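"""Red-Green plots: combine two diversity maps and classify the contact zone.

The two subunits' maps become the red and green channels of one image over
the shared surface grid, each normalized by its own maximum. A precedence
filter partitions the defined nodes:

* black  - mutual conservatism: both intensities below ``black_frac`` (20%);
* green  - green channel more than ``ratio`` (2x) the red;
* red    - red channel more than ``ratio`` the green;
* yellow - the remainder: comparable polymorphism on both sides.

A ligand lying in the oriented frame can be projected onto the grid and its
co-localization with the four classes measured.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .contact import ContactSurface, DiversityMap
from .errors import InputError

DEFAULT_BLACK_FRAC = 0.2
DEFAULT_RATIO = 2.0
LABELS = ("black", "yellow", "red", "green")


def normalize_channels(map_r: DiversityMap, map_g: DiversityMap) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel max normalization of two maps on the same surface.

    Each channel is divided by its own maximum over defined finite nodes;
    an all-zero channel stays zero. The dN/dS sentinel +inf (non-synonymous
    variation only) maps to intensity 1.
    """
    if not map_r.surface.same_grid(map_g.surface):
        raise InputError("maps live on different surfaces")

    def norm(m: DiversityMap) -> np.ndarray:
        mx = m.finite_max()
        out = np.full(m.values.shape, np.nan)
        defined = m.defined
        if mx > 0:
            out[defined] = np.clip(m.values[defined] / mx, 0.0, 1.0)
        else:
            out[defined] = 0.0
        out[np.isposinf(m.values)] = 1.0
        return out

    return norm(map_r), norm(map_g)


@dataclass
class RGClassification:
    """Per-node four-way label over the defined nodes of a surface."""

    surface: ContactSurface
    r: np.ndarray
    g: np.ndarray
    labels: np.ndarray       # (nx, ny) of '' | black | yellow | red | green
    black_frac: float
    ratio: float

    @property
    def defined(self) -> np.ndarray:
        return self.labels != ""


def classify(
    r: np.ndarray,
    g: np.ndarray,
    surface: ContactSurface,
    black_frac: float = DEFAULT_BLACK_FRAC,
    ratio: float = DEFAULT_RATIO,
) -> RGClassification:
    """Apply the four-way precedence filter to normalized intensities.

    Precedence: black first (both channels < black_frac), then green
    (G > ratio * R), then red (R > ratio * G), yellow as the remainder —
    which guarantees a partition of the defined nodes.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    if r.shape != g.shape or r.shape != surface.shape:
        raise InputError("intensity fields must match the surface grid")
    finite = ~np.isnan(r) & ~np.isnan(g)
    if np.any((r[finite] < 0) | (r[finite] > 1) | (g[finite] < 0) | (g[finite] > 1)):
        raise InputError("intensities must lie in [0, 1]")
    labels = np.full(r.shape, "", dtype="<U6")
    black = finite & (r < black_frac) & (g < black_frac)
    green = finite & ~black & (g > ratio * r)
    red = finite & ~black & ~green & (r > ratio * g)
    yellow = finite & ~black & ~green & ~red
    labels[black] = "black"
    labels[green] = "green"
    labels[red] = "red"
    labels[yellow] = "yellow"
    return RGClassification(surface, r, g, labels, black_frac, ratio)


def area_fractions(c: RGClassification) -> dict[str, float]:
    """Percentage of defined nodes per label, plus the mutual black+yellow
    total. Percentages sum to 100 within rounding."""
    n = int(c.defined.sum())
    if n == 0:
        raise InputError("classification has no defined nodes")
    out = {lab: 100.0 * float((c.labels == lab).sum()) / n for lab in LABELS}
    out["black_yellow"] = out["black"] + out["yellow"]
    return out


def project_ligand(ligand, surface: ContactSurface, capture: float | None = None) -> set[tuple[int, int]]:
    """Grid nodes laterally within ``capture`` (default: one grid step) of
    any ligand atom. The ligand must already be in the oriented frame."""
    if capture is None:
        capture = surface.step
    xs, ys = surface.grid_xy()
    nodes: set[tuple[int, int]] = set()
    for atom in np.asarray(ligand.coords, dtype=float):
        di = np.abs(xs - atom[0])
        dj = np.abs(ys - atom[1])
        for i in np.flatnonzero(di <= capture):
            for j in np.flatnonzero(dj <= capture):
                if di[i] ** 2 + dj[j] ** 2 <= capture ** 2:
                    nodes.add((int(i), int(j)))
    if not nodes:
        warnings.warn("ligand projects onto no grid node")
    return nodes


def colocalization(c: RGClassification, nodes: set[tuple[int, int]]) -> dict[str, float]:
    """Fraction of the projected nodes falling in each label class.

    Nodes outside the defined surface are dropped with a warning; the
    remaining fractions sum to 1.
    """
    if not nodes:
        raise InputError("empty node set")
    kept = [(i, j) for i, j in nodes if c.labels[i, j] != ""]
    if len(kept) < len(nodes):
        warnings.warn(f"{len(nodes) - len(kept)} projected nodes are undefined; dropped")
    if not kept:
        raise InputError("no projected node lies on the defined surface")
    out = {lab: 0.0 for lab in LABELS}
    for i, j in kept:
        out[str(c.labels[i, j])] += 1.0
    for lab in LABELS:
        out[lab] /= len(kept)
    return out


def render_rgplot(c: RGClassification, path: str, ligand_nodes: set[tuple[int, int]] | None = None,
                  filtered: bool = True) -> None:
    """Write the RG image (raw channels or the filtered four-class view) as
    PNG, with an optional ligand-projection outline."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nx, ny = c.surface.shape
    img = np.zeros((ny, nx, 3))
    if filtered:
        palette = {"black": (0.0, 0.0, 0.0), "yellow": (1.0, 1.0, 0.0),
                   "red": (1.0, 0.0, 0.0), "green": (0.0, 1.0, 0.0)}
        for lab, rgb in palette.items():
            for i, j in zip(*np.nonzero(c.labels == lab)):
                img[j, i] = rgb
    else:
        defined = c.defined
        for i, j in zip(*np.nonzero(defined)):
            img[j, i] = (c.r[i, j], c.g[i, j], 0.0)
    undefined = ~c.defined
    for i, j in zip(*np.nonzero(undefined)):
        img[j, i] = (0.25, 0.25, 0.3)
    fig, ax = plt.subplots(figsize=(6, 6))
    x0, y0 = c.surface.origin
    s = c.surface.step
    ax.imshow(img, origin="lower",
              extent=(x0 - s / 2, x0 + s * (nx - 0.5), y0 - s / 2, y0 + s * (ny - 0.5)))
    if ligand_nodes:
        lx = [c.surface.node_xy(i, j)[0] for i, j in ligand_nodes]
        ly = [c.surface.node_xy(i, j)[1] for i, j in ligand_nodes]
        ax.scatter(lx, ly, s=12, facecolors="none", edgecolors="white", linewidths=0.8)
    ax.set_xlabel("x (A)")
    ax.set_ylabel("y (A)")
    ax.set_title("RG-plot (filtered)" if filtered else "RG-plot (raw)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
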