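"""Multi-level distance label maps.

A binary tumor mask is converted into a categorical per-pixel field with five
levels: 0 = background, 1 = tumor, and 2/3/4 = concentric "high-risk" shells at
increasing normalized distance from the tumor. The shells act as auxiliary
supervision (an attention target) for the high-risk segmentation branch of the
network: pixels near a lesion carry information about its margin and matrix
even when the lesion itself is tiny after down-scaling.

Distances are measured from the tumor *pixel set* (not its bounding box), so
the construction is well defined for arbitrary shapes and multi-component
masks. The default metric is Chebyshev, which produces the rectangular shells
seen around compact lesions; Euclidean shells are available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "MultiLevelDistanceMap",
    "make_distance_map",
    "distance_map_to_mask",
    "one_hot_encode",
    "N_DISTANCE_LEVELS",
]

#: number of categorical levels: background, tumor, three shells
N_DISTANCE_LEVELS = 5

_METRICS = ("chebyshev", "euclidean")
_NORMALIZERS = ("max", "min", "diag")


@dataclass(frozen=True)
class MultiLevelDistanceMap:
    """Categorical H×W field with values in {0..4} plus its provenance.

    Attributes
    ----------
    grid : np.ndarray
        uint8 array of shape (H, W) with values 0..4.
    thresholds : tuple of float
        The three normalized-distance cut points (t1, t2, t3).
    metric : str
        "chebyshev" or "euclidean".
    normalizer : float
        The length (in px) that normalized the raw pixel distances.
    """

    grid: np.ndarray
    thresholds: tuple
    metric: str
    normalizer: float

    @property
    def shape(self) -> tuple:
        return self.grid.shape


def _validate_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask must be strictly binary {{0,1}}, found values {vals[:10]}")
    return mask.astype(bool)


def _resolve_normalizer(normalizer, shape) -> float:
    h, w = shape
    if normalizer is None or normalizer == "max":
        return float(max(h, w))
    if normalizer == "min":
        return float(min(h, w))
    if normalizer == "diag":
        return float(np.hypot(h, w))
    norm = float(normalizer)
    if norm <= 0:
        raise ValueError(f"normalizer must be positive, got {normalizer}")
    return norm


def make_distance_map(
    mask: np.ndarray,
    thresholds: Sequence[float] = (0.25, 0.5, 0.75),
    metric: str = "chebyshev",
    normalizer=None,
) -> MultiLevelDistanceMap:
    """Build the 5-level distance map from a binary tumor mask.

    For every background pixel p, d(p) is the distance to the nearest tumor
    pixel, divided by ``normalizer`` (default: max(H, W)). Labels:

    ==========  =======================
    label       condition
    ==========  =======================
    1           mask(p) = 1
    2           0 < d(p) <= t1
    3           t1 < d(p) <= t2
    4           t2 < d(p) <= t3
    0           d(p) > t3
    ==========  =======================

    Shell intervals are half-open (lo, hi], so a pixel exactly at a threshold
    belongs to the nearer shell. An empty mask yields an all-zero map (there
    is no tumor to measure distance from).
    """
    m = _validate_binary(mask)
    t1, t2, t3 = (float(t) for t in thresholds)
    if not (0.0 < t1 < t2 < t3 <= 1.0):
        raise ValueError(f"thresholds must satisfy 0 < t1 < t2 < t3 <= 1, got {(t1, t2, t3)}")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    norm = _resolve_normalizer(normalizer, m.shape)

    grid = np.zeros(m.shape, dtype=np.uint8)
    if m.any():
        if metric == "euclidean":
            d = ndimage.distance_transform_edt(~m)
        else:
            d = ndimage.distance_transform_cdt(~m, metric="chessboard").astype(float)
        dn = d / norm
        grid[(dn > 0) & (dn <= t1)] = 2
        grid[(dn > t1) & (dn <= t2)] = 3
        grid[(dn > t2) & (dn <= t3)] = 4
        grid[m] = 1
    return MultiLevelDistanceMap(grid=grid, thresholds=(t1, t2, t3), metric=metric, normalizer=norm)


def distance_map_to_mask(dmap: MultiLevelDistanceMap | np.ndarray) -> np.ndarray:
    """Recover the binary tumor mask: level-1 pixels are exactly the foreground."""
    grid = dmap.grid if isinstance(dmap, MultiLevelDistanceMap) else np.asarray(dmap)
    return (grid == 1).astype(np.uint8)


def one_hot_encode(labelmap: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot encode an integer label field to shape (..., n_classes)."""
    lab = np.asarray(labelmap)
    if not np.issubdtype(lab.dtype, np.integer):
        if not np.array_equal(lab, lab.astype(int)):
            raise ValueError("labelmap must contain integers")
        lab = lab.astype(int)
    if lab.size and (lab.min() < 0 or lab.max() >= n_classes):
        raise ValueError(
            f"labels must lie in [0, {n_classes}), found range [{lab.min()}, {lab.max()}]"
        )
    return np.eye(n_classes, dtype=np.float32)[lab]
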