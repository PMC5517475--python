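"""Physical chain: multiphoton excitation, detection, digitization, EOM.

Detected fluorescence follows the multiphoton law ``S = X * P**alpha`` with
``X`` the sample strength (all factors of local emissivity lumped together)
and ``alpha`` the excitation order.  ``S`` is expressed in detected
photoelectrons per pixel dwell so that Poisson shot-noise statistics are
literal; the detector saturates (clips) at ``S_sat``.

The power actuator is an electro-optic modulator (EOM) modeled as a
first-order lag with an optional weak quadratic distortion at low command
levels; the power monitor is a photodiode with additive Gaussian noise,
digitized at ``B_P`` bits and floored at one LSB so its logarithm is always
defined.
"""

from __future__ import annotations

import math

import numpy as np

from .config import AcquisitionConfig, NoiseModel

__all__ = [
    "excite_and_detect",
    "quantize_signal",
    "quantize_signal_conventional",
    "apply_eom",
    "measure_power",
]


def excite_and_detect(
    X,
    P_actual,
    cfg: AcquisitionConfig,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
):
    """Detected signal (photoelectrons) for strength ``X`` at power ``P_actual``.

    Returns ``(S, clipped)`` where ``S`` has mean ``X * P**alpha + dark_rate``
    (a Poisson draw when ``noise.shot_noise``), clipped at ``cfg.S_sat``;
    ``clipped`` flags pixels where the detector saturated.  Accepts scalars or
    arrays (broadcast).
    """
    noise = noise or NoiseModel()
    X = np.asarray(X, dtype=float)
    P = np.asarray(P_actual, dtype=float)
    if np.any(X < 0):
        raise ValueError("sample strength X must be >= 0")
    if np.any(P < 0):
        raise ValueError("power must be >= 0")
    mean = X * P**cfg.alpha + noise.dark_rate
    if noise.shot_noise:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        # Poisson(lam) at lam >> S_sat clips with certainty; skip the draw to
        # keep huge out-of-control transients cheap.
        lam = np.minimum(mean, 20.0 * cfg.S_sat)
        S = rng.poisson(lam).astype(float)
    else:
        S = mean
    clipped = S >= cfg.S_sat
    S = np.minimum(S, cfg.S_sat)
    if S.ndim == 0:
        return float(S), bool(clipped)
    return S, clipped


def quantize_signal(S, cfg: AcquisitionConfig):
    """Digitize signal at the AI unit's ``B_S``-bit ADC.

    Returns ``(S_hat, clipped_high)`` with ``S_hat = round(G_S*S)`` clipped to
    ``[0, 2**B_S - 1]``.  Clipping is a flagged, valid outcome.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("signal must be >= 0")
    code_max = 2**cfg.B_S - 1
    raw = np.rint(cfg.G_S * S)
    clipped = raw > code_max
    S_hat = np.clip(raw, 0, code_max).astype(np.int64)
    if S_hat.ndim == 0:
        return int(S_hat), bool(clipped)
    return S_hat, clipped


def quantize_signal_conventional(S, cfg: AcquisitionConfig):
    """Digitize signal at the microscope's own ``B``-bit electronics.

    Conventional acquisition routes the PMT straight to the ``B``-bit ADC
    whose gain fills the detector saturation: code = round(S * 2**B / S_sat).
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("signal must be >= 0")
    code_max = 2**cfg.B - 1
    raw = np.rint(S * (2.0**cfg.B) / cfg.S_sat)
    clipped = raw > code_max
    S_hat = np.clip(raw, 0, code_max).astype(np.int64)
    if S_hat.ndim == 0:
        return int(S_hat), bool(clipped)
    return S_hat, clipped


def apply_eom(
    P_command: float,
    P_prev_actual: float,
    dt: float,
    noise: NoiseModel | None = None,
) -> float:
    """Power delivered by the EOM one time step after ``P_command`` is applied.

    First-order relaxation toward the (optionally distorted) command:
    below ``eom_quad_threshold`` the effective target acquires a weak
    quadratic term, mimicking the nonlinear EOM response at small drive.
    ``eom_tau = 0`` means an instantaneous, ideal actuator.
    """
    noise = noise or NoiseModel()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if P_command < 0:
        raise ValueError("commanded power must be >= 0")
    target = P_command
    if noise.eom_quad > 0.0 and P_command < noise.eom_quad_threshold:
        target = P_command + noise.eom_quad * (P_command - noise.eom_quad_threshold) ** 2
    if noise.eom_tau == 0.0:
        return float(target)
    return float(target + (P_prev_actual - target) * math.exp(-dt / noise.eom_tau))


def measure_power(
    P_actual,
    cfg: AcquisitionConfig,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
):
    """Photodiode measurement of the delivered power, as a ``B_P``-bit code.

    ``P_hat = round((P + eps)/G_P)`` with ``eps ~ N(0, pd_sigma)``, clipped to
    ``[1, 2**B_P]``.  The floor of one LSB keeps ``log2(P_hat)`` defined for
    arbitrarily small powers.
    """
    noise = noise or NoiseModel()
    P = np.asarray(P_actual, dtype=float)
    if np.any(P < 0):
        raise ValueError("power must be >= 0")
    if noise.pd_sigma > 0.0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        P = P + rng.normal(0.0, noise.pd_sigma, size=P.shape)
    P_hat = np.clip(np.rint(P / cfg.G_P), 1, 2**cfg.B_P).astype(np.int64)
    if P_hat.ndim == 0:
        return int(P_hat)
    return P_hat
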