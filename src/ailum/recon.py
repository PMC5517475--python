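"""Post-hoc linear reconstruction and dynamic-range accounting.

The microscope stores the re-digitized log map ``L_hh``; linear sample
strength is recovered, to within an unimportant global factor, as

    X  ∝  2 ** (L_hh / (G_L * G_M)).

Constant offsets (the encoder offset ``C``, the power-normalization
convention) only multiply all pixels by the same factor, which is carried as
metadata and never silently normalized away.

``occupied_bits`` operationalizes reading a dynamic range off a log
histogram: bin the ``log2`` values in 0.5-bit bins and report the span
between the lowest and highest bin holding at least ``min_count`` pixels
(the count threshold suppresses single-pixel noise tails).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import AcquisitionConfig

__all__ = [
    "ReconstructedImage",
    "HistogramComparison",
    "reconstruct_linear",
    "occupied_bits",
    "compare_histograms",
    "quantization_budget",
]


@dataclass
class ReconstructedImage:
    """Linear strength map in relative units (unknown global factor)."""

    X_map: np.ndarray
    log2X_map: np.ndarray
    scale_note: str = ("values are proportional to sample strength; the "
                       "global factor (offset C, power normalization, G_S) "
                       "is unknown")


def reconstruct_linear(L_hh_map, G_L: float, G_M: float) -> ReconstructedImage:
    """Linearize a re-digitized log map: ``X = 2**(L_hh/(G_L*G_M))``."""
    if G_L <= 0 or G_M <= 0:
        raise ValueError("G_L and G_M must be > 0")
    L_hh = np.asarray(L_hh_map, dtype=np.float64)
    log2X = L_hh / (G_L * G_M)
    return ReconstructedImage(X_map=2.0**log2X, log2X_map=log2X)


def occupied_bits(
    image,
    min_count: int = 10,
    bin_width: float = 0.5,
    log_input: bool = False,
) -> float:
    """Occupied dynamic range of an image, in bits.

    Histogram the ``log2`` of the positive pixel values (``log_input=True``
    if the image is already a log2 map) in ``bin_width``-bit bins and return
    the center-to-center span between the extreme bins holding at least
    ``min_count`` pixels.  A constant image occupies 0 bits.
    """
    vals = np.asarray(image, dtype=np.float64).ravel()
    if log_input:
        vals = vals[np.isfinite(vals)]
    else:
        vals = vals[vals > 0]
        if vals.size == 0:
            raise ValueError("image has no positive values")
        vals = np.log2(vals)
    lo = math.floor(vals.min() / bin_width) * bin_width
    hi = math.ceil(vals.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    occupied = np.nonzero(counts >= min_count)[0]
    if occupied.size == 0:
        raise ValueError(f"no histogram bin holds >= {min_count} pixels")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(centers[occupied[-1]] - centers[occupied[0]])


@dataclass
class HistogramComparison:
    """Bin-wise agreement of two linear histograms over their overlap."""

    bin_edges: np.ndarray
    density_a: np.ndarray
    density_b: np.ndarray
    overlap_range: tuple[float, float] | None
    max_rel_dev: float
    mean_rel_dev: float
    no_overlap: bool


def compare_histograms(
    ai_image,
    conventional_image,
    conventional_clip_mask=None,
    n_bins: int = 32,
    noise_floor_count: int = 5,
) -> HistogramComparison:
    """Compare linear-domain histograms of co-registered AI and conventional
    images over the range where the conventional image is neither clipped nor
    noise-dominated.

    Both images are normalized to their median over the overlap before
    binning (the AI reconstruction carries an unknown global factor).
    Bins where the conventional histogram holds fewer than
    ``noise_floor_count`` pixels are excluded from the deviation metrics.
    """
    a = np.asarray(ai_image, dtype=np.float64).ravel()
    b = np.asarray(conventional_image, dtype=np.float64).ravel()
    if conventional_clip_mask is not None:
        keep = ~np.asarray(conventional_clip_mask, dtype=bool).ravel()
        a = a[keep]
        b = b[keep]
    pos = (a > 0) & (b > 0)
    a, b = a[pos], b[pos]
    if a.size == 0:
        return HistogramComparison(np.empty(0), np.empty(0), np.empty(0),
                                   None, math.nan, math.nan, True)
    # remove the unknown global scale of the reconstruction
    a = a * (np.median(b) / np.median(a))
    lo = max(a.min(), b.min())
    hi = min(a.max(), b.max())
    if not hi > lo:
        return HistogramComparison(np.empty(0), np.empty(0), np.empty(0),
                                   None, math.nan, math.nan, True)
    edges = np.geomspace(lo, hi, n_bins + 1)
    ca, _ = np.histogram(a, bins=edges)
    cb, _ = np.histogram(b, bins=edges)
    da = ca / max(ca.sum(), 1)
    db = cb / max(cb.sum(), 1)
    valid = cb >= noise_floor_count
    if not valid.any():
        return HistogramComparison(edges, da, db, (lo, hi), math.nan,
                                   math.nan, True)
    rel = np.abs(da[valid] - db[valid]) / np.maximum(db[valid], 1e-300)
    return HistogramComparison(
        bin_edges=edges, density_a=da, density_b=db, overlap_range=(lo, hi),
        max_rel_dev=float(rel.max()), mean_rel_dev=float(rel.mean()),
        no_overlap=False)


def quantization_budget(
    cfg: AcquisitionConfig,
    S_hat=None,
    P_hat=None,
    n_redigitizations: int = 1,
) -> float:
    """Worst-case ``log2 X`` error (bits) of the encode/re-digitize path.

    Sums the LUT grids (half a step each for signal and, times ``alpha``,
    power), the re-digitization rounding (half an LSB of ``L_hh`` per pass),
    and — when code maps are given — the ADC rounding of the codes
    themselves (half an LSB relative, largest for the smallest code present).
    """
    from .encoder import default_luts

    lut_S, lut_P = default_luts(cfg)
    budget = 0.5 * lut_S.step + cfg.alpha * 0.5 * lut_P.step
    budget += n_redigitizations * 0.5 / (cfg.G_L * cfg.G_M)
    inv_ln2 = 1.0 / math.log(2.0)
    if S_hat is not None:
        s_min = float(np.min(np.maximum(np.asarray(S_hat), 1)))
        budget += 0.5 / s_min * inv_ln2
    if P_hat is not None:
        p_min = float(np.min(np.maximum(np.asarray(P_hat), 1)))
        budget += cfg.alpha * 0.5 / p_min * inv_ln2
    return budget
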