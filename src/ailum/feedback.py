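"""Per-pixel negative-feedback power regulation and frame scanning.

A PID controller acts on the digitized error ``S0_hat - S_hat`` (signal-ADC
LSB) and commands the power DAC so that the detected fluorescence is held at
the set point ``S0``.  When more than ``P_max`` would be needed the command
pins at the maximum code and the pixel is in *power-limited* mode; otherwise
it is in *feedback-active* mode.  The mode transition sits at
``X_t = S0 / P_max**alpha``.

The loop gain of the plant ``S = X P**alpha`` scales as ``alpha*S/P``, i.e.
inversely with power near the set point.  By default the controller
increments are therefore scheduled proportionally to the current power code
(floored at ``2**(B_P-8)``), which renders the closed-loop dynamics uniform
over the full strength range; see ``docs/methods.md``.  Gains act unscaled
when ``cfg.gain_schedule`` is off or ``gain_scale=1`` is passed explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .config import AcquisitionConfig, ConfigError, NoiseModel

__all__ = [
    "MODE_FEEDBACK_ACTIVE",
    "MODE_POWER_LIMITED",
    "PIDState",
    "PixelTrace",
    "FrameRecord",
    "pid_step",
    "run_pixel_dwell",
    "scan_frame",
    "transition_strength",
]

MODE_FEEDBACK_ACTIVE = "feedback_active"
MODE_POWER_LIMITED = "power_limited"


@dataclass
class PIDState:
    """Controller memory: integrator, previous error, and loop carry."""

    integral: float = 0.0
    prev_error: float = 0.0
    u: float = 0.0          # last commanded DAC code (the integrator's bias)
    P_actual: float = 0.0   # power currently delivered by the EOM

    def validate(self) -> None:
        for v in (self.integral, self.prev_error, self.u, self.P_actual):
            if not math.isfinite(v):
                raise ValueError("non-finite PID state")


@dataclass
class PixelTrace:
    """Sub-step history of one pixel dwell."""

    t: np.ndarray
    S_series: np.ndarray
    P_command_series: np.ndarray
    P_actual_series: np.ndarray
    mode: str
    S_hat: int
    P_hat: int
    clip_flag: bool
    state: PIDState = field(default_factory=PIDState)


@dataclass
class FrameRecord:
    """Digitized per-pixel outputs of one frame scan."""

    S_hat_map: np.ndarray      # int64 codes (B_S bits in AI, B bits conventional)
    P_hat_map: np.ndarray      # int64 power codes in [1, 2**B_P]
    mode_map: np.ndarray       # uint8: 0 feedback_active, 1 power_limited
    clip_map: np.ndarray       # bool: final sample saturated
    scan_mode: str             # "ai" or "conventional"
    L_hat_map: np.ndarray | None = None   # filled by the encoder

    @property
    def shape(self) -> tuple[int, int]:
        return self.S_hat_map.shape

    @property
    def clip_fraction(self) -> float:
        return float(np.mean(self.clip_map))

    @property
    def power_limited_fraction(self) -> float:
        return float(np.mean(self.mode_map == 1))


def pid_step(
    error: float,
    state: PIDState,
    cfg: AcquisitionConfig,
    gain_scale: float = 1.0,
) -> tuple[float, PIDState]:
    """One PID update on the LSB error; returns (commanded DAC code, state).

    ``command = clamp(Kp*e + Ki*I + Kd*de/dt, 0, 2**B_P)`` with the
    integrator frozen (conditional integration anti-windup) while the output
    is clamped and the error keeps pushing into the clamp.  ``gain_scale``
    multiplies the integral and derivative increments (used by the dwell loop
    for power-proportional scheduling; the default of 1 is a plain PID).
    """
    if not (math.isfinite(error) and math.isfinite(gain_scale)):
        raise ValueError("non-finite PID input")
    state.validate()
    dt = cfg.dt_substep
    u_max = float(2**cfg.B_P)
    I_new = state.integral + gain_scale * error * dt
    u_raw = (cfg.Kp * error + cfg.Ki * I_new
             + cfg.Kd * gain_scale * (error - state.prev_error) / dt)
    if u_raw >= u_max:
        u = u_max
        integral = I_new if error <= 0 else state.integral
    elif u_raw <= 0.0:
        u = 0.0
        integral = I_new if error >= 0 else state.integral
    else:
        u = u_raw
        integral = I_new
    new_state = PIDState(integral=integral, prev_error=error, u=u,
                         P_actual=state.P_actual)
    return u, new_state


def transition_strength(cfg: AcquisitionConfig) -> float:
    """Strength ``X_t = S0 / P_max**alpha`` at the mode boundary."""
    return cfg.S0 / cfg.P_max**cfg.alpha


def run_pixel_dwell(
    X: float,
    cfg: AcquisitionConfig,
    noise: NoiseModel | None = None,
    carry_in: PIDState | None = None,
    seed: int | None = None,
) -> PixelTrace:
    """Simulate one pixel dwell: ``n_substeps`` iterations of
    {EOM -> excite/detect -> quantize -> PID}.

    ``carry_in`` is the previous pixel's loop state (defaults to a cold
    start from zero power).  With noise off, ``X > X_t`` settles to
    ``S = S0`` within tolerance and ``X < X_t`` rails at ``P_max``.
    """
    if X < 0:
        raise ValueError("sample strength X must be >= 0")
    if cfg.n_substeps < 2:
        raise ConfigError("n_substeps: must be >= 2")
    noise = noise or NoiseModel()
    if carry_in is None:
        carry_in = PIDState()
    carry_in.validate()
    params = _kernels.pack_params(cfg, noise)
    if seed is None:
        seed = cfg.seed
    out, S_series, Pc_series, Pa_series = _kernels.dwell_trace(
        float(X), carry_in.u, carry_in.integral, carry_in.prev_error,
        carry_in.P_actual, params, seed)
    S_hat, P_hat, mode, clip, S, u, integral, e_prev, P_act = out
    t = (np.arange(cfg.n_substeps) + 1) * cfg.dt_substep
    return PixelTrace(
        t=t,
        S_series=S_series,
        P_command_series=Pc_series,
        P_actual_series=Pa_series,
        mode=MODE_POWER_LIMITED if mode == 1 else MODE_FEEDBACK_ACTIVE,
        S_hat=int(S_hat),
        P_hat=int(P_hat),
        clip_flag=bool(clip),
        state=PIDState(integral=integral, prev_error=e_prev, u=u,
                       P_actual=P_act),
    )


def scan_frame(
    scene,
    cfg: AcquisitionConfig,
    noise: NoiseModel | None = None,
    mode: str = "ai",
    seed: int | None = None,
) -> FrameRecord:
    """Raster-scan a scene (row-major) and return the digitized frame.

    ``mode="ai"`` runs the feedback loop per pixel, with PID state and power
    carried across adjacent pixels when ``cfg.carry_over``.  In
    ``mode="conventional"`` the feedback is bypassed: the power is held at
    ``P0`` everywhere and the signal is digitized at ``B`` bits by the
    microscope's own electronics.
    """
    strength = np.asarray(getattr(scene, "strength", scene), dtype=np.float64)
    if strength.ndim != 2:
        raise ValueError("scene strength must be a 2-D grid")
    if np.any(strength < 0):
        raise ValueError("sample strengths must be >= 0")
    noise = noise or NoiseModel()
    if seed is None:
        seed = cfg.seed
    if mode == "ai":
        params = _kernels.pack_params(cfg, noise)
        S_hat, P_hat, mode_map, clip_map = _kernels.scan_ai(
            strength, params, seed, cfg.carry_over)
        return FrameRecord(S_hat, P_hat, mode_map, clip_map, scan_mode="ai")
    if mode == "conventional":
        rng = np.random.default_rng(seed)
        P = cfg.P0
        mean = strength * P**cfg.alpha + noise.dark_rate
        if noise.shot_noise:
            lam = np.minimum(mean, 20.0 * cfg.S_sat)
            S = rng.poisson(lam).astype(np.float64)
        else:
            S = mean
        det_clip = S >= cfg.S_sat
        S = np.minimum(S, cfg.S_sat)
        code_max = 2**cfg.B - 1
        raw = np.rint(S * (2.0**cfg.B) / cfg.S_sat)
        clip_map = det_clip | (raw > code_max)
        S_hat = np.clip(raw, 0, code_max).astype(np.int64)
        P_meas = P
        if noise.pd_sigma > 0.0:
            P_meas = P + rng.normal(0.0, noise.pd_sigma)
        P_code = int(np.clip(round(P_meas / cfg.G_P), 1, 2**cfg.B_P))
        P_hat = np.full(strength.shape, P_code, dtype=np.int64)
        mode_map = np.zeros(strength.shape, dtype=np.uint8)
        return FrameRecord(S_hat, P_hat, mode_map, clip_map,
                           scan_mode="conventional")
    raise ValueError(f"unknown scan mode {mode!r} (expected 'ai' or 'conventional')")
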