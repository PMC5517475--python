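"""Acquisition constants and noise parameters.

All system constants of the active-illumination (AI) chain live in
:class:`AcquisitionConfig`: the excitation order ``alpha`` (2 for two-photon),
the bit depths of the signal ADC (``B_S``), power DAC/ADC (``B_P``), log
lookup tables (``B_L``) and the host microscope acquisition electronics
(``B``), the detector saturation ``S_sat`` (detected photoelectrons per pixel
dwell), the feedback set point as a fraction of saturation, the power limits,
and the PID controller gains.  Derived gains follow the hardware conventions

* ``G_S = 2**B_S / S_sat``      -- signal ADC gain (codes per photoelectron),
* ``G_P = P_max / 2**B_P``      -- power DAC gain (power units per code),
* ``G_L = 2**B_L / B_S``        -- log-encoder output scale,
* ``C   = 2**B_L``              -- additive log offset (keeps L_X >= 0),
* ``G_M = (2**B - 1) / max(L_X)`` -- re-digitization gain of the microscope,

and are recomputed from the bit depths unless explicitly overridden.

Power is expressed in normalized units where the conventional-imaging power
``P0`` and the allowed maximum ``P_max`` both default to 1.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

__all__ = ["AcquisitionConfig", "NoiseModel", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


def _require(cond: bool, key: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{key}: {message}")


@dataclass
class AcquisitionConfig:
    """Constants of the acquisition chain.

    Parameters left at ``None`` among the derived gains (``G_S``, ``G_P``,
    ``G_L``, ``C``, ``G_M``) are recomputed from the bit depths in
    ``__post_init__``; pass explicit values to override.
    """

    alpha: int = 2              # excitation order (2 two-photon, 3 three-photon)
    B: int = 12                 # microscope acquisition bit depth
    B_S: int = 13               # signal ADC effective bit depth
    B_P: int = 14               # power DAC/ADC bit depth
    B_L: int = 13               # log LUT bit depth
    S_sat: float = 250.0        # detector saturation, photoelectrons per dwell
    S0_frac: float = 0.5        # set point as fraction of S_sat
    P_max: float = 1.0          # maximum allowed power, normalized
    P0: float = 1.0             # conventional-imaging power, normalized

    # derived gains; None -> computed from bit depths
    G_S: float | None = None
    G_P: float | None = None
    G_L: float | None = None
    C: float | None = None
    G_M: float | None = None

    # PID controller (error measured in signal-ADC LSB)
    Kp: float = 0.0
    Ki: float = 1.5e7           # 1/s; Ki*dt_substep = 1.5 at the defaults below
    Kd: float = 0.0
    gain_schedule: bool = True  # scale loop increments by P-code / 2**B_P
    schedule_floor: int | None = None   # min code in the schedule; None -> 2**(B_P-8)
    carry_over: bool = True     # carry power & PID state across raster pixels

    n_substeps: int = 32        # feedback updates per pixel dwell
    dwell_time: float = 3.2e-6  # s
    seed: int = 0

    def __post_init__(self) -> None:
        for key in ("alpha", "B", "B_S", "B_P", "B_L"):
            v = getattr(self, key)
            _require(isinstance(v, (int,)) and v >= 1, key, "must be an integer >= 1")
        _require(self.S_sat > 0, "S_sat", "must be > 0")
        _require(0 < self.S0_frac <= 1, "S0_frac", "must be in (0, 1]")
        _require(self.P_max > 0, "P_max", "must be > 0")
        _require(self.P0 > 0, "P0", "must be > 0")
        _require(self.n_substeps >= 2, "n_substeps", "must be >= 2")
        _require(self.dwell_time > 0, "dwell_time", "must be > 0")
        if self.G_S is None:
            self.G_S = 2.0**self.B_S / self.S_sat
        if self.G_P is None:
            self.G_P = self.P_max / 2.0**self.B_P
        if self.G_L is None:
            self.G_L = 2.0**self.B_L / self.B_S
        if self.C is None:
            self.C = 2.0**self.B_L
        if self.G_M is None:
            self.G_M = (2.0**self.B - 1.0) / self.L_max
        if self.schedule_floor is None:
            self.schedule_floor = 2 ** max(self.B_P - 8, 0)
        for key in ("G_S", "G_P", "G_L", "C", "G_M"):
            _require(getattr(self, key) > 0, key, "must be > 0")

    # -- derived quantities -------------------------------------------------

    @property
    def S0(self) -> float:
        """Set point in photoelectrons per dwell."""
        return self.S0_frac * self.S_sat

    @property
    def S0_hat(self) -> int:
        """Digitized set point in signal-ADC LSB."""
        return int(round(self.G_S * self.S0))

    @property
    def P_max_hat(self) -> int:
        """Maximum power DAC code."""
        return 2**self.B_P

    @property
    def L_max(self) -> float:
        """Largest possible log output ``G_L*(B_S + alpha*B_P) + C``.

        Computed from the configured bit depths (not from data) so the
        re-digitization gain is calibration-free across frames.
        """
        g_l = self.G_L if self.G_L is not None else 2.0**self.B_L / self.B_S
        c = self.C if self.C is not None else 2.0**self.B_L
        return g_l * (self.B_S + self.alpha * self.B_P) + c

    @property
    def dt_substep(self) -> float:
        return self.dwell_time / self.n_substeps

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AcquisitionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown acquisition key(s): {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw: Any) -> "AcquisitionConfig":
        """Copy with some fields changed; derived gains are recomputed unless
        they are among ``kw``."""
        d = self.to_dict()
        recompute = {"G_S", "G_P", "G_L", "C", "G_M", "schedule_floor"} - set(kw)
        for key in recompute:
            d[key] = None
        d.update(kw)
        return AcquisitionConfig.from_dict(d)


@dataclass
class NoiseModel:
    """Stochastic and dynamic imperfections of the physical chain.

    With everything at the defaults the chain is fully deterministic: no shot
    noise, an ideal photodiode, and an instantaneous, linear EOM.
    """

    shot_noise: bool = False    # Poisson photon statistics on the detector
    pd_sigma: float = 0.0       # photodiode additive noise SD, normalized power
    eom_tau: float = 0.0        # EOM first-order time constant, s (0 = instant)
    eom_quad: float = 0.0       # quadratic EOM distortion coefficient
    eom_quad_threshold: float = 0.05  # command level below which distortion acts
    dark_rate: float = 0.0      # detector dark counts per dwell substep chain

    def __post_init__(self) -> None:
        for key in ("pd_sigma", "eom_tau", "eom_quad", "eom_quad_threshold",
                    "dark_rate"):
            _require(getattr(self, key) >= 0, key, "must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "NoiseModel":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown noise key(s): {sorted(unknown)}")
        return cls(**d)

    @property
    def deterministic(self) -> bool:
        return not self.shot_noise and self.pd_sigma == 0.0
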