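"""Functional-imaging statistics: dF/F0 traces, activity maps, response SNR.

All quantities are ratios to a resting baseline F0, so they are invariant to
the unknown global scale of the reconstructed strength movie.  Response SNR
follows the standard definition: peak dF/F0 in the response window divided
by the SD of dF/F0 in the rest window.  The peak is the signed extremum of
largest magnitude, so suppressed responses (decreases) get negative peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AcquisitionConfig

__all__ = [
    "ROITrace",
    "ResponseStats",
    "compute_f0",
    "delta_f_over_f",
    "activity_map",
    "clip_mask",
    "response_stats",
    "extract_roi_traces",
    "cohort_summary",
]

REST_GUARD_S = 0.5   # gap between the rest window and stimulus onset


@dataclass
class ROITrace:
    """Fluorescence time series of one ROI with its analysis windows."""

    roi_id: int
    t: np.ndarray
    F: np.ndarray
    F0: float
    dff: np.ndarray
    rest_window: tuple[float, float]
    response_window: tuple[float, float]


@dataclass
class ResponseStats:
    """Per-ROI response summary."""

    roi_id: int
    peak_dff: float     # signed extremum of dF/F0 in the response window
    rest_sd: float
    snr: float          # peak_dff / rest_sd (signed); inf flagged if sd == 0
    sign: str           # "increase" / "decrease"
    snr_infinite: bool = False


def _window_mask(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi < lo:
        raise ValueError("window end precedes start")
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError("window extends past the recording")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not mask.any():
        raise ValueError("window contains no frames")
    return mask


def compute_f0(trace, t, rest_window: tuple[float, float]) -> float:
    """Baseline F0 = mean fluorescence over the rest window."""
    trace = np.asarray(trace, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    F0 = float(trace[_window_mask(t, rest_window)].mean())
    if F0 <= 0:
        raise ValueError("F0 <= 0: trace unusable for dF/F0")
    return F0


def delta_f_over_f(trace, F0: float) -> np.ndarray:
    """Elementwise (F - F0)/F0; decreases give negative values."""
    if F0 <= 0:
        raise ValueError("F0 must be > 0")
    return (np.asarray(trace, dtype=np.float64) - F0) / F0


def activity_map(
    movie,
    dt: float,
    stim_onset: float,
    window_s: float = 5.0,
    rest_window: tuple[float, float] | None = None,
):
    """Per-pixel mean dF/F0 over ``[stim_onset, stim_onset + window_s]``.

    ``movie`` is (n_frames, H, W).  F0 is the per-pixel mean over the rest
    window (everything before onset minus a 0.5 s guard by default); pixels
    with F0 <= 0 are masked (NaN).
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3:
        raise ValueError("movie must be (n_frames, H, W)")
    t = np.arange(movie.shape[0]) * dt
    if rest_window is None:
        rest_window = (0.0, max(stim_onset - REST_GUARD_S, dt))
    rest = _window_mask(t, rest_window)
    resp = _window_mask(t, (stim_onset, stim_onset + window_s))
    F0 = movie[rest].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        amap = (movie[resp].mean(axis=0) - F0) / F0
    amap[F0 <= 0] = np.nan
    return amap


def clip_mask(clip_movie) -> np.ndarray:
    """Pixels clipped in at least one frame of a digitized movie.

    Accepts either a (n_frames, H, W) boolean clip stack or a stack of
    per-frame ``FrameRecord`` objects.
    """
    if hasattr(clip_movie, "__len__") and len(clip_movie) and \
            hasattr(clip_movie[0], "clip_map"):
        clip_movie = np.stack([fr.clip_map for fr in clip_movie])
    clip_movie = np.asarray(clip_movie, dtype=bool)
    if clip_movie.ndim == 2:
        return clip_movie.copy()
    return clip_movie.any(axis=0)


def extract_roi_traces(
    movie,
    roi_ids,
    dt: float,
    stim_onset: float,
    response_window_s: float = 5.0,
) -> list[ROITrace]:
    """Mean-over-ROI fluorescence traces with default analysis windows.

    ROI membership comes from the generator's ground-truth ROI map; no
    segmentation is attempted.  The rest window is everything before
    stimulus onset minus a 0.5 s guard.
    """
    movie = np.asarray(movie, dtype=np.float64)
    roi_ids = np.asarray(roi_ids)
    t = np.arange(movie.shape[0]) * dt
    rest = (0.0, max(stim_onset - REST_GUARD_S, dt))
    resp = (stim_onset, min(stim_onset + response_window_s, t[-1]))
    traces = []
    for rid in np.unique(roi_ids):
        if rid == 0:
            continue
        mask = roi_ids == rid
        F = movie[:, mask].mean(axis=1)
        F0 = compute_f0(F, t, rest)
        traces.append(ROITrace(
            roi_id=int(rid), t=t, F=F, F0=F0, dff=delta_f_over_f(F, F0),
            rest_window=rest, response_window=resp))
    return traces


def response_stats(trace: ROITrace) -> ResponseStats:
    """Peak dF/F0, resting SD, and their ratio (response SNR) for one ROI."""
    rest = _window_mask(trace.t, trace.rest_window)
    resp = _window_mask(trace.t, trace.response_window)
    dff_resp = trace.dff[resp]
    peak = float(dff_resp[np.argmax(np.abs(dff_resp))])
    rest_sd = float(np.std(trace.dff[rest], ddof=1))
    if rest_sd == 0.0:
        return ResponseStats(trace.roi_id, peak, 0.0, math.inf,
                             "increase" if peak >= 0 else "decrease",
                             snr_infinite=True)
    return ResponseStats(trace.roi_id, peak, rest_sd, peak / rest_sd,
                         "increase" if peak >= 0 else "decrease")


def cohort_summary(stats: list[ResponseStats]) -> pd.DataFrame:
    """Aggregate per-ROI statistics into a tidy table."""
    return pd.DataFrame([{
        "roi_id": s.roi_id,
        "peak_dff": s.peak_dff,
        "rest_sd": s.rest_sd,
        "snr": s.snr,
        "sign": s.sign,
    } for s in stats])
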