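"""Small geometry helpers shared across the analysis modules.

All distances are in Å.  When orthorhombic box lengths are supplied,
pairwise displacements are wrapped with the minimum-image convention;
otherwise raw Euclidean distances are used.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "min_image_displacement",
    "pairwise_distances",
    "min_dist_to_set",
    "nearest_in_set",
    "fibonacci_sphere",
]


def min_image_displacement(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the primary image of an orthorhombic box."""
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def pairwise_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> np.ndarray:
    """(n, m) distance matrix between point sets ``a`` (n,3) and ``b`` (m,3)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    d = a[:, None, :] - b[None, :, :]
    if box is not None:
        d = min_image_displacement(d, box)
    return np.linalg.norm(d, axis=-1)


def min_dist_to_set(points: np.ndarray, ref: np.ndarray, box: np.ndarray | None = None) -> np.ndarray:
    """Minimum distance from each of ``points`` (k,3) to the point set ``ref`` (m,3)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ref = np.asarray(ref, dtype=float)
    if ref.size == 0:
        raise ValueError("reference point set is empty")
    if box is None and len(ref) > 64:
        tree = cKDTree(ref)
        d, _ = tree.query(points)
        return np.asarray(d, dtype=float)
    return pairwise_distances(points, ref, box).min(axis=1)


def nearest_in_set(points: np.ndarray, ref: np.ndarray, box: np.ndarray | None = None):
    """Distance to and index of the nearest point of ``ref`` for each of ``points``."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ref = np.asarray(ref, dtype=float)
    if ref.size == 0:
        raise ValueError("reference point set is empty")
    if box is None and len(ref) > 64:
        tree = cKDTree(ref)
        d, i = tree.query(points)
        return np.asarray(d, dtype=float), np.asarray(i, dtype=int)
    dm = pairwise_distances(points, ref, box)
    i = dm.argmin(axis=1)
    return dm[np.arange(len(points)), i], i


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` approximately uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
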