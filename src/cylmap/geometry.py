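"""Rigid-body geometry helpers: Kabsch superposition and random rotations.

All rotations are proper or improper 3x3 orthogonal matrices acting on
row-vector coordinate arrays as ``coords @ R.T + t``.
"""
from __future__ import annotations

import numpy as np

from .errors import InputError


def kabsch(
    moving: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
    allow_mirror: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``moving`` onto ``target``.

    Returns ``(R, t)`` such that ``moving @ R.T + t`` minimizes the
    (weighted) squared deviation from ``target``. With
    ``allow_mirror=False`` the rotation is proper (det +1); with
    ``allow_mirror=True`` the unconstrained orthogonal optimum is
    returned, which may be a reflection (det -1).
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise InputError("kabsch requires two equally shaped (n, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise InputError("kabsch requires at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise InputError("weights must be nonnegative with positive sum")
        w = w / w.sum()
    cm = w @ moving
    ct = w @ target
    x = moving - cm
    y = target - ct
    h = (x * w[:, None]).T @ y
    u, _, vt = np.linalg.svd(h)
    r = vt.T @ u.T
    if not allow_mirror and np.linalg.det(r) < 0:
        vt2 = vt.copy()
        vt2[-1] *= -1.0
        r = vt2.T @ u.T
    t = ct - r @ cm
    return r, t


def apply_rigid(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply ``x -> R x + t`` to an (n, 3) coordinate array."""
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + np.asarray(translation)


def superposition_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two matched (n, 3) arrays."""
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def random_rotation(rng: np.random.Generator, mirror: bool = False) -> np.ndarray:
    """Uniform random rotation matrix; optionally composed with a reflection."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    if mirror:
        q = q @ np.diag([1.0, 1.0, -1.0])
    return q
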