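"""Numba kernels for the per-pixel feedback loop.

The dwell loop is inherently sequential (the PID state and EOM output evolve
sub-step by sub-step, and by default carry over between adjacent raster
pixels), so whole-frame scans are compiled with numba rather than vectorized.

State variables threaded through the loop:

``u``       commanded power DAC code (float, clamped to [0, 2**B_P])
``I``       PID integrator (error-seconds)
``e_prev``  previous error in signal-ADC LSB
``P_act``   power currently delivered by the EOM (normalized units)

Parameters are packed in a flat float64 vector (see ``pack_params``) because
the kernels are shared by single-dwell, frame-scan and Monte-Carlo entry
points.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import AcquisitionConfig, NoiseModel

# parameter vector layout
P_ALPHA = 0
P_SSAT = 1
P_GS = 2
P_GP = 3
P_S0HAT = 4
P_SCODEMAX = 5
P_PHATMAX = 6
P_KP = 7
P_KI = 8
P_KD = 9
P_DT = 10
P_NSUB = 11
P_SCHED = 12
P_SCHEDFLOOR = 13
P_SHOT = 14
P_PDSIGMA = 15
P_EOMTAU = 16
P_EOMQUAD = 17
P_EOMTHR = 18
P_DARK = 19
N_PARAMS = 20


def pack_params(cfg: AcquisitionConfig, noise: NoiseModel) -> np.ndarray:
    p = np.zeros(N_PARAMS, dtype=np.float64)
    p[P_ALPHA] = cfg.alpha
    p[P_SSAT] = cfg.S_sat
    p[P_GS] = cfg.G_S
    p[P_GP] = cfg.G_P
    p[P_S0HAT] = cfg.S0_hat
    p[P_SCODEMAX] = 2**cfg.B_S - 1
    p[P_PHATMAX] = 2**cfg.B_P
    p[P_KP] = cfg.Kp
    p[P_KI] = cfg.Ki
    p[P_KD] = cfg.Kd
    p[P_DT] = cfg.dt_substep
    p[P_NSUB] = cfg.n_substeps
    p[P_SCHED] = 1.0 if cfg.gain_schedule else 0.0
    p[P_SCHEDFLOOR] = cfg.schedule_floor
    p[P_SHOT] = 1.0 if noise.shot_noise else 0.0
    p[P_PDSIGMA] = noise.pd_sigma
    p[P_EOMTAU] = noise.eom_tau
    p[P_EOMQUAD] = noise.eom_quad
    p[P_EOMTHR] = noise.eom_quad_threshold
    p[P_DARK] = noise.dark_rate
    return p


@njit(cache=True)
def _dwell_core(X, u, I, e_prev, P_act, params, S_series, Pc_series, Pa_series,
                record):
    """One pixel dwell: n_substeps of {EOM -> detect -> quantize -> PID}.

    Returns (S_hat, P_hat, mode, clip, S, u, I, e_prev, P_act).
    mode: 0 = feedback_active, 1 = power_limited (final command pinned at max).
    clip: final sample saturated the detector / signal ADC.
    """
    alpha = params[P_ALPHA]
    S_sat = params[P_SSAT]
    G_S = params[P_GS]
    G_P = params[P_GP]
    S0_hat = params[P_S0HAT]
    S_code_max = params[P_SCODEMAX]
    P_hat_max = params[P_PHATMAX]
    Kp = params[P_KP]
    Ki = params[P_KI]
    Kd = params[P_KD]
    dt = params[P_DT]
    n_sub = int(params[P_NSUB])
    sched = params[P_SCHED] > 0.5
    sched_floor = params[P_SCHEDFLOOR]
    shot = params[P_SHOT] > 0.5
    pd_sigma = params[P_PDSIGMA]
    eom_tau = params[P_EOMTAU]
    eom_quad = params[P_EOMQUAD]
    eom_thr = params[P_EOMTHR]
    dark = params[P_DARK]

    S = 0.0
    S_hat = 0.0
    clip = False
    for k in range(n_sub):
        # DAC output and EOM response
        u_code = np.rint(u)
        P_cmd = u_code * G_P
        target = P_cmd
        if eom_quad > 0.0 and P_cmd < eom_thr:
            target = P_cmd + eom_quad * (P_cmd - eom_thr) ** 2
        if eom_tau == 0.0:
            P_act = target
        else:
            P_act = target + (P_act - target) * np.exp(-dt / eom_tau)

        # excitation and detection
        mean = X * P_act**alpha + dark
        if shot:
            lam = mean
            if lam > 20.0 * S_sat:
                lam = 20.0 * S_sat
            S = float(np.random.poisson(lam))
        else:
            S = mean
        clip = S >= S_sat
        if clip:
            S = S_sat

        # signal ADC
        raw = np.rint(G_S * S)
        if raw > S_code_max:
            raw = S_code_max
            clip = True
        S_hat = raw

        # PID on the LSB error, with optional power-proportional gain
        # schedule (cancels the 1/P plant-gain variation of S = X P^alpha)
        e = S0_hat - S_hat
        g = 1.0
        if sched:
            gc = u_code
            if gc < sched_floor:
                gc = sched_floor
            g = gc / P_hat_max
        I_new = I + g * e * dt
        u_raw = Kp * e + Ki * I_new + Kd * g * (e - e_prev) / dt
        if u_raw >= P_hat_max:
            u = P_hat_max
            if e <= 0.0:          # error no longer pushes into the clamp
                I = I_new
        elif u_raw <= 0.0:
            u = 0.0
            if e >= 0.0:
                I = I_new
        else:
            u = u_raw
            I = I_new
        e_prev = e

        if record:
            S_series[k] = S
            Pc_series[k] = P_cmd
            Pa_series[k] = P_act

    # final power measurement (photodiode + B_P-bit ADC, floored at 1 LSB)
    P_meas = P_act
    if pd_sigma > 0.0:
        P_meas = P_act + pd_sigma * np.random.normal()
    P_hat = np.rint(P_meas / G_P)
    if P_hat < 1.0:
        P_hat = 1.0
    if P_hat > P_hat_max:
        P_hat = P_hat_max

    mode = 1 if np.rint(u) >= P_hat_max else 0
    return S_hat, P_hat, mode, clip, S, u, I, e_prev, P_act


@njit(cache=True)
def dwell_trace(X, u, I, e_prev, P_act, params, seed):
    """Single pixel dwell with per-sub-step recording (seeded)."""
    np.random.seed(seed)
    n_sub = int(params[P_NSUB])
    S_series = np.zeros(n_sub)
    Pc_series = np.zeros(n_sub)
    Pa_series = np.zeros(n_sub)
    out = _dwell_core(X, u, I, e_prev, P_act, params,
                      S_series, Pc_series, Pa_series, True)
    return out, S_series, Pc_series, Pa_series


@njit(cache=True)
def scan_ai(strength, params, seed, carry_over):
    """Raster-scan a 2-D strength map in active-illumination mode.

    Row-major order; PID state and EOM power carry across adjacent pixels
    when ``carry_over`` (hardware-like continuity), otherwise each pixel
    starts from zero power.
    """
    np.random.seed(seed)
    H, W = strength.shape
    S_hat_map = np.zeros((H, W), dtype=np.int64)
    P_hat_map = np.zeros((H, W), dtype=np.int64)
    mode_map = np.zeros((H, W), dtype=np.uint8)
    clip_map = np.zeros((H, W), dtype=np.bool_)
    scratch = np.zeros(1)
    u = 0.0
    I = 0.0
    e_prev = 0.0
    P_act = 0.0
    for i in range(H):
        for j in range(W):
            if not carry_over:
                u = 0.0
                I = 0.0
                e_prev = 0.0
                P_act = 0.0
            (S_hat, P_hat, mode, clip, S, u, I, e_prev, P_act) = _dwell_core(
                strength[i, j], u, I, e_prev, P_act, params,
                scratch, scratch, scratch, False)
            S_hat_map[i, j] = int(S_hat)
            P_hat_map[i, j] = int(P_hat)
            mode_map[i, j] = mode
            clip_map[i, j] = clip
    return S_hat_map, P_hat_map, mode_map, clip_map


@njit(cache=True)
def mc_dwells(X, params, n_reps, seed):
    """Independent repeated dwells at one strength (fresh state each rep)."""
    np.random.seed(seed)
    S_hats = np.zeros(n_reps, dtype=np.int64)
    P_hats = np.zeros(n_reps, dtype=np.int64)
    modes = np.zeros(n_reps, dtype=np.uint8)
    clips = np.zeros(n_reps, dtype=np.bool_)
    scratch = np.zeros(1)
    for r in range(n_reps):
        (S_hat, P_hat, mode, clip, S, u, I, e_prev, P_act) = _dwell_core(
            X, 0.0, 0.0, 0.0, 0.0, params, scratch, scratch, scratch, False)
        S_hats[r] = int(S_hat)
        P_hats[r] = int(P_hat)
        modes[r] = mode
        clips[r] = clip
    return S_hats, P_hats, modes, clips
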