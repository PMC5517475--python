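"""FPGA-side log2 encoding of the sample strength.

The unit converts the signal and power codes to ``log2`` via ``B_L``-bit
lookup tables and outputs

    L_X = G_L * (log2(S_hat) - alpha * log2(P_hat / 2**B_P)) + C

with ``G_L = 2**B_L / B_S`` and offset ``C = 2**B_L``.  The power log is
taken of the code normalized to full scale, so its contribution is
non-negative and ``L_X >= C`` for all valid codes — the offset's stated
purpose (the downstream electronics may not accept negative levels).

``L_X`` leaves the unit through a DAC and is re-digitized at ``B`` bits by
the microscope acquisition electronics with gain ``G_M`` chosen to fill the
``B``-bit range at the largest possible ``L_X``; what the microscope stores
is ``L_hh = round(G_M * L_X)``.

LUT entries are quantized on a fixed-point grid whose step is the smallest
power-of-two full scale covering ``log2(domain)`` divided by ``2**B_L``;
this grid contains the integers, so entries at power-of-two codes are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import AcquisitionConfig
from .feedback import FrameRecord

__all__ = ["LogLUT", "EncodedFrame", "build_log_lut", "log_encode",
           "encode_frame", "redigitize"]


@dataclass
class LogLUT:
    """``B_L``-bit quantized ``log2`` table over integer codes."""

    entries: np.ndarray     # float64, entries[k] ~= log2(k), entries[0] = 0
    bit_depth: int
    domain_size: int
    step: float             # quantization step of the value grid

    def __getitem__(self, code):
        return self.entries[code]


def build_log_lut(domain_size: int, B_L: int) -> LogLUT:
    """Pre-calculate the ``log2`` lookup table.

    ``entries[k] = log2(k)`` rounded to the ``B_L``-bit grid; code 0 maps to
    the entry for code 1 (floor rule), so the table is monotone
    non-decreasing starting at 0.
    """
    if B_L < 1:
        raise ValueError("B_L must be >= 1")
    if domain_size < 2:
        raise ValueError("domain_size must be >= 2")
    codes = np.arange(domain_size, dtype=np.float64)
    codes[0] = 1.0
    exact = np.log2(codes)
    # full scale = smallest power of two covering the value range
    full_scale = 2.0 ** math.ceil(math.log2(max(exact[-1], 1.0)))
    step = full_scale / 2.0**B_L
    entries = np.rint(exact / step) * step
    return LogLUT(entries=entries, bit_depth=B_L, domain_size=domain_size,
                  step=step)


def log_encode(
    S_hat,
    P_hat,
    cfg: AcquisitionConfig,
    luts: tuple[LogLUT, LogLUT] | None = None,
):
    """Log-encoded sample strength ``L_X`` for code pairs (scalar or array).

    Requires ``S_hat >= 1`` and ``P_hat >= 1`` (codes are floored upstream);
    zero codes violate the contract and are rejected.
    """
    S_hat = np.asarray(S_hat)
    P_hat = np.asarray(P_hat)
    if np.any(S_hat < 1) or np.any(P_hat < 1):
        raise ValueError("codes must be >= 1 (floored upstream)")
    if luts is None:
        luts = default_luts(cfg)
    lut_S, lut_P = luts
    log_S = lut_S.entries[S_hat]
    log_P_norm = lut_P.entries[P_hat] - cfg.B_P   # log2 of P_hat / 2**B_P <= 0
    L = cfg.G_L * (log_S - cfg.alpha * log_P_norm) + cfg.C
    if L.ndim == 0:
        return float(L)
    return L


def default_luts(cfg: AcquisitionConfig) -> tuple[LogLUT, LogLUT]:
    """Signal and power LUTs sized to their converters (shared builder)."""
    return (build_log_lut(2**cfg.B_S, cfg.B_L),
            build_log_lut(2**cfg.B_P + 1, cfg.B_L))


def redigitize(L_map, cfg: AcquisitionConfig):
    """Re-digitization by the microscope electronics at ``B`` bits.

    ``G_M`` is computed from the configured bit depths (the theoretical
    ``L_X`` maximum), not from the data, so reconstruction needs no per-frame
    calibration.  Returns ``(L_hh_map, G_M_used)``.
    """
    L_map = np.asarray(L_map, dtype=np.float64)
    if np.any(L_map < 0):
        raise ValueError("log output must be >= 0")
    G_M = cfg.G_M
    code_max = 2**cfg.B - 1
    L_hh = np.clip(np.rint(G_M * L_map), 0, code_max).astype(np.int64)
    if L_hh.ndim == 0:
        return int(L_hh), G_M
    return L_hh, G_M


@dataclass
class EncodedFrame:
    """Log output of one frame, before and after re-digitization."""

    L_hat_map: np.ndarray       # float, G_L*log2(X_code) + C
    L_hh_map: np.ndarray        # int codes in [0, 2**B - 1]
    G_M_used: float
    G_L: float
    C: float
    alpha: int

    def sidecar(self) -> dict:
        """Metadata needed for post-hoc linearization."""
        return {"G_M": self.G_M_used, "G_L": self.G_L, "C": self.C,
                "alpha": self.alpha}


def encode_frame(
    record: FrameRecord,
    cfg: AcquisitionConfig,
    luts: tuple[LogLUT, LogLUT] | None = None,
) -> EncodedFrame:
    """Encode a scanned frame; signal codes of 0 are floored to 1.

    Fills ``record.L_hat_map`` as a side effect and returns the encoded
    frame with its re-digitized ``B``-bit map.
    """
    if record.scan_mode != "ai":
        raise ValueError("only AI frames carry the (S_hat, P_hat) code pairs "
                         "required for log encoding")
    S_hat = np.maximum(record.S_hat_map, 1)
    P_hat = np.maximum(record.P_hat_map, 1)
    L = log_encode(S_hat, P_hat, cfg, luts)
    L_hh, G_M = redigitize(L, cfg)
    record.L_hat_map = L
    return EncodedFrame(L_hat_map=L, L_hh_map=L_hh, G_M_used=G_M,
                        G_L=cfg.G_L, C=cfg.C, alpha=cfg.alpha)
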