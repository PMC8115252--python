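"""Imaging confounds for evoked and resting-state analyses.

Per-run confounds: mean framewise displacement (head motion), the multiple
correlation between the predicted BOLD response and a 24-column head-motion
expansion (stimulus-correlated motion), and signal amplitudes in CSF and
white-matter reference regions (residual cardiac pulsatility and global
amplitude respectively).

Framewise displacement follows the sum-of-absolute-backward-differences
convention, with rotations converted to arc length on a 50 mm sphere by
default (the radius is configurable; formulas in the literature differ only
in this mapping).
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .images import Bold4D, VoxelMap
from .resting import mad_amplitude
from .tables import motion_to_frame

__all__ = [
    "framewise_displacement",
    "motion_expansion",
    "stimulus_correlated_motion",
    "roi_amplitude",
]


def framewise_displacement(motion, radius_mm: float = 50.0) -> dict:
    """Per-frame framewise displacement and its mean.

    FD(t) = sum_i |d translation_i| + radius * sum_i |d rotation_i| over
    backward differences; FD of the first frame is 0 and the mean is taken
    over frames 2..T.
    """
    arr = motion_to_frame(motion)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    diffs = np.abs(np.diff(arr, axis=0))
    fd = diffs[:, :3].sum(axis=1) + radius_mm * diffs[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd])
    return {"fd": fd, "mean_fd": float(fd[1:].mean())}


def motion_expansion(motion) -> np.ndarray:
    """24-column motion expansion: params, derivatives, and both squared.

    Columns 0-5 are the six rigid parameters, 6-11 their backward-difference
    derivatives (first row 0), and 12-23 the elementwise squares of the
    first twelve.
    """
    arr = motion_to_frame(motion)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 frames")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(arr, axis=0)])
    first12 = np.hstack([arr, deriv])
    return np.hstack([first12, first12 ** 2])


def stimulus_correlated_motion(predicted_response: np.ndarray,
                               motion24: np.ndarray) -> float:
    """Multiple correlation R between the predicted response and motion.

    R = sqrt(R^2) from OLS of the predicted BOLD response (stimulus
    timeseries convolved with the HRF) on the 24 motion columns plus an
    intercept.  Always in [0, 1].
    """
    y = np.asarray(predicted_response, dtype=float)
    X = np.asarray(motion24, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("row count mismatch between response and motion")
    if y.std() == 0:
        raise ValueError("constant predicted response")
    design = np.column_stack([X, np.ones(y.size)])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot
    return float(np.sqrt(np.clip(r2, 0.0, 1.0)))


def roi_amplitude(source: Union[VoxelMap, Bold4D], roi_mask: np.ndarray,
                  mode: str = "mean_beta") -> float:
    """Signal amplitude within a reference region.

    ``mean_beta`` (for 3D beta maps): mean of the map over ROI voxels.
    ``mad_timeseries`` (for 4D runs): the ROI is averaged voxelwise first,
    then the MAD of the resulting single timeseries is taken.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if mode == "mean_beta":
        if not isinstance(source, VoxelMap):
            raise ValueError("mean_beta mode requires a 3D map")
        return float(source.data[roi].mean())
    if mode == "mad_timeseries":
        if not isinstance(source, Bold4D):
            raise ValueError("mad_timeseries mode requires a 4D run")
        series = source.data[roi].mean(axis=0)
        return mad_amplitude(series)
    raise ValueError(f"unknown mode {mode!r}")
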