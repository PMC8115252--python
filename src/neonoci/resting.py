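"""Resting-state network timeseries and amplitudes.

Network timeseries come from the spatial stage of dual regression: each
frame's in-mask voxel vector is regressed on the K network template maps
(plus a per-frame intercept, so the global signal level cannot leak into
the network coefficients).  Amplitudes summarise a network timeseries by
the median absolute deviation from the median (MAD), which is robust to the
large spikes that motion leaves in neonatal data; the MAD is unscaled by
default (no 1.4826 Gaussian-consistency factor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .images import Bold4D, VoxelMap

__all__ = [
    "NetworkTimeseries",
    "spatial_regression_timeseries",
    "mad_amplitude",
    "outlier_fraction",
    "match_templates",
]


@dataclass
class NetworkTimeseries:
    """K networks x T frames of spatial-regression coefficients."""

    series: np.ndarray
    labels: list
    tr: float

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be K x T")
        if self.series.shape[0] < 1 or self.series.shape[1] < 2:
            raise ValueError("need K >= 1 networks and T >= 2 frames")
        if not np.isfinite(self.series).all():
            raise ValueError("non-finite timeseries values")
        if len(self.labels) != self.series.shape[0]:
            raise ValueError("one label per network required")

    @property
    def n_networks(self) -> int:
        return self.series.shape[0]

    @property
    def n_frames(self) -> int:
        return self.series.shape[1]


def spatial_regression_timeseries(bold: Bold4D, templates: Sequence[VoxelMap],
                                  mask: Optional[np.ndarray] = None,
                                  labels: Optional[Sequence[str]] = None) -> NetworkTimeseries:
    """Per-frame multiple regression of the data on template maps.

    For each frame t, the in-mask voxel vector y_t is fit by OLS on the K
    template vectors plus an intercept; the K regression coefficients form
    the networks' values at frame t.
    """
    if len(templates) < 1:
        raise ValueError("need at least one template")
    mask = bold.mask if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    G = np.column_stack([t.data[mask] for t in templates] + [np.ones(int(mask.sum()))])
    if np.linalg.matrix_rank(G) < G.shape[1]:
        raise ValueError("templates are collinear within the mask")
    Y = bold.data[mask]                      # (V, T)
    coefs, _, _, _ = np.linalg.lstsq(G, Y, rcond=None)   # (K+1, T)
    if labels is None:
        labels = [f"net{k:02d}" for k in range(len(templates))]
    return NetworkTimeseries(coefs[:-1], list(labels), bold.tr)


def mad_amplitude(series: Sequence[float], scale: float = 1.0) -> float:
    """Median absolute deviation from the median.

    Unscaled by default; pass ``scale=1.4826`` for the Gaussian-consistent
    estimator (for a Gaussian series the raw MAD is 0.6745 times the sd).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 frames")
    return float(np.median(np.abs(x - np.median(x))) * scale)


def outlier_fraction(series: Sequence[float], k: float = 5.0) -> float:
    """Fraction of frames further than k robust spreads from the median.

    The spread is the MAD; if the MAD is zero the standard deviation is used
    instead, and if both are zero the series is constant and the fraction
    is 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 frames")
    med = np.median(x)
    spread = float(np.median(np.abs(x - med)))
    if spread == 0:
        spread = float(x.std())
    if spread == 0:
        return 0.0
    return float(np.mean(np.abs(x - med) > k * spread))


def match_templates(set_a: Sequence[VoxelMap], set_b: Sequence[VoxelMap],
                    min_abs_r: float = 0.3) -> dict:
    """Greedy one-to-one pairing of two template sets by spatial correlation.

    Pairs are assigned in descending absolute spatial Pearson correlation
    (computed over the intersection of the first set's mask); pairs whose
    |r| falls below ``min_abs_r`` are left unmatched.  Greedy assignment is
    an explicit numeric stand-in for correlation-plus-visual-confirmation
    matching.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("template sets must be nonempty")
    mask = set_a[0].mask
    A = np.stack([m.data[mask] for m in set_a])
    B = np.stack([m.data[mask] for m in set_b])
    if np.any(A.std(axis=1) == 0) or np.any(B.std(axis=1) == 0):
        raise ValueError("constant template map")
    Az = (A - A.mean(axis=1, keepdims=True))
    Az /= np.linalg.norm(Az, axis=1, keepdims=True)
    Bz = (B - B.mean(axis=1, keepdims=True))
    Bz /= np.linalg.norm(Bz, axis=1, keepdims=True)
    R = Az @ Bz.T
    pairs = []
    used_a: set = set()
    used_b: set = set()
    order = np.dstack(np.unravel_index(np.argsort(-np.abs(R), axis=None), R.shape))[0]
    for i, j in order:
        i, j = int(i), int(j)
        if i in used_a or j in used_b:
            continue
        if abs(R[i, j]) < min_abs_r:
            break
        pairs.append({"a": i, "b": j, "r": float(R[i, j])})
        used_a.add(i)
        used_b.add(j)
    return {
        "pairs": pairs,
        "unmatched_a": sorted(set(range(len(set_a))) - used_a),
        "unmatched_b": sorted(set(range(len(set_b))) - used_b),
        "correlation_matrix": R,
    }
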