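# Methods

This note documents the model implemented by `ailum`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Physical model

**Excitation and detection.** The detected fluorescence per pixel dwell is
`S = X·P^α + dark` photoelectrons, with `X` the sample strength (all local
emissivity factors lumped into one nonnegative number), `P` the delivered
laser power in normalized units (conventional imaging power `P₀ = 1` by
default), and `α` the excitation order. `S` is expressed in detected
photoelectrons so that shot noise is literally Poisson: each detector
sample is a Poisson draw with the instantaneous mean. The detector
saturates (hard clip, flagged) at `S_sat`, 250 photoelectrons per dwell by
default; that value is configurable and is interpreted as photoelectrons so
that the shot-noise-limited SNR at saturation is `√250 ≈ 15.8`. No PMT
multiplicative gain noise, afterpulsing, or pre-amp shaping is modeled.

**Power actuation (EOM).** The commanded power passes through a first-order
lag with time constant `eom_tau` (0 = ideal) and, optionally, a weak
quadratic distortion below a low-command threshold, standing in for the
nonlinear EOM response at small drive levels. The command itself is
quantized by the `B_P`-bit DAC (gain `G_P = P_max/2^B_P`).

**Power measurement.** A photodiode with additive Gaussian noise of SD
`pd_sigma` (normalized power units) monitors the delivered power; its
output is digitized at `B_P` bits and floored at one LSB so the logarithm
is always defined. The floor is a deliberate deviation from plain
quantization: it gives the encoder a total contract (`P̂ ≥ 1`) at the cost
of a bounded bias only for powers below half an LSB, which are unmeasurable
anyway. One lumped `pd_sigma` stands in for everything the roll-off
analysis attributes to imprecise power control and detection (digitization,
EOM control noise, photodiode electronics); no separate per-source model is
attempted.

## Feedback loop

Per pixel dwell the loop iterates `n_substeps` times (default 32,
`dwell_time` 3.2 µs): EOM → excite/detect → `B_S`-bit signal ADC
(`G_S = 2^B_S/S_sat`) → PID. The PID acts on the error `Ŝ₀ − Ŝ` in ADC
LSB; its output is clamped to the DAC range `[0, 2^B_P]` with conditional
integration (the integrator freezes while the output is clamped and the
error keeps pushing into the clamp). Mode is *power-limited* when the final
command is pinned at the maximum code, *feedback-active* otherwise; the
boundary sits at `X_t = S₀/P_max^α` (125 at the defaults).

**Gain scheduling.** The plant gain `dŜ/dP̂ ∝ α·S/P` varies inversely with
power: a fixed-gain linear loop stable at the dimmest operating point would
need hundreds of sub-steps to slew across a bright transition, and one fast
at the top would limit-cycle violently at the bottom. The integral and
derivative increments are therefore scaled by the current power code
(floored at `2^(B_P−8)` so a cold start can lift off zero), which exactly
cancels the `1/P` variation for the power-law plant and makes the
closed-loop contraction rate uniform — the discrete-time equivalent of
doing the control in the log-power domain. With the default
`Ki·Δt = 1.5` the noise-free loop settles within half a dwell from a cold
start or across an 8-decade strength step; the schedule can be disabled
(`gain_schedule=False`), returning a plain PID. Default gains are
integral-only (`Kp = Kd = 0`): proportional action on the LSB error is
deliberately avoided because during detector clipping the error saturates
at a constant and a large `Kp` only produces rail-to-rail oscillation.

**Carry-over.** Power and controller state carry across adjacent raster
pixels (hardware-like continuity; row-major order, no serpentine). A
`carry_over=False` option resets each pixel to zero power, which
approaches every pixel from below — slower on bright scenes but never
overshooting. Settling tolerance for "holds S₀" is ±2 % of `S₀`, noise
off; within-dwell transients may clip the detector harmlessly, so only the
final sample's saturation is flagged per pixel.

**Why imperfect regulation is acceptable.** The reconstruction uses the
*measured* pair `(Ŝ, P̂)` from the final sub-step, so the ratio
`Ŝ/(P̂/2^B_P)^α` is correct whether or not the loop converged — the
failure modes that matter are only (a) a clipped final sample and (b)
codes driven below one LSB. The test suite exercises this deliberately
with detuned gains, EOM lag and truncated dwells.

## Log encoder and reconstruction

`log₂Ŝ` and `log₂P̂` come from `B_L`-bit lookup tables. Entries are
quantized on a fixed-point grid whose step is the smallest power-of-two
full scale covering the table's log₂ range divided by `2^B_L`
(`2^−9 ≈ 0.002` for `B_L = 13` over a 16-range); this grid contains the
integers, so entries at power-of-two codes are exact and the table is
monotone. Code 0 maps to the entry of code 1.

The encoder output is `L̂_X = G_L·(log₂Ŝ − α·log₂(P̂/2^B_P)) + C` with
`G_L = 2^B_L/B_S` and `C = 2^B_L`. The power log is taken of the code
normalized to full scale — a negative quantity, so the `−α·log₂` term is
nonnegative and `L̂_X ≥ C` always. Taken of raw codes instead, the stated
offset `C` could not prevent negative outputs for large `P̂`; the
normalized convention is the single normative interpretation this package
fixes, and it honors the offset's stated purpose (acquisition electronics
that reject negative inputs).

Re-digitization by the microscope at `B` bits uses
`G_M = (2^B − 1)/L̂_max`, where `L̂_max = G_L·(B_S + α·B_P) + C` comes from
the configured bit depths, never from the data — reconstruction is
therefore calibration-free across frames. The hardware's intermediate
DAC→ADC hop is collapsed into this single quantization; it is a pure gain
link and a second rounding would add nothing testable. Reconstruction is
`X ∝ 2^(L̂̂/(G_L·G_M))`; the unknown global factor (from `C`, the power
normalization and `G_S`) is carried as metadata and never silently
normalized away. The worst-case log₂ error of the encode/re-digitize path
is budgeted as half a LUT step for the signal plus `α` halves for the
power plus half an `L̂̂` LSB — about 0.01 bits at the defaults — plus the
code-rounding terms `0.5/Ŝ + α·0.5/P̂` (in nats) when comparing acquired
frames; `ailum.recon.quantization_budget` computes it.

## SNR model

Propagating Poisson noise on `S` and an effective power-measurement noise
`σ_P` through `X = S/P^α` gives

`SNR_X = [1/S + α²·σ_P²/P²]^(−1/2)` ,

evaluated on the steady state of each branch: `P = P_max`, `S = X·P_max^α`
below `X_t`; `S = S₀`, `P = (S₀/X)^(1/α)` above. `σ_P` combines `pd_sigma`
with the power-ADC quantization noise `G_P/√12` in quadrature. The
conventional curve is `S/√(S + σ_q²)` with `σ_q` the `B`-bit quantization
noise in photoelectrons, defined up to `X_sat = S_sat/P₀^α`. This
error-propagation form is adopted as the canonical model; the roll-off
landmark `X_r` is operationalized as the 3 dB point where the two noise
terms are equal, `P_r = α·σ_P·√S₀`, `X_r = S₀/P_r^α` (10⁴ for `S₀ = 125`,
`σ_P = 0.005`; infinite when `σ_P = 0`). Monte-Carlo validation runs the
full pipeline (feedback → encode → re-digitize → reconstruct) from a cold
start per repetition and agrees with the closed form within 5 % at 10⁴
repetitions over four decades of strength.

## Synthetic scenes

**Structural.** Somas are flat disks at the scene maximum, dendrites
2-px-wide persistent random walks with log-uniform strengths, spines 1–2 px
puncta adjacent to dendrites at the scene minimum; the dimmest structure is
pinned to the exact minimum so a requested max/min ratio is met exactly
(contract: within 1 % for ratios in [1, 10¹⁰]). Morphologies are schematic:
the emulated feature is the brightness *statistics* (compact bright and dim
structures on empty background), not anatomy, and no 3-D optics are
modeled. The default absolute scale puts the brightest structures at
`X = 10⁷` so that at a 10⁸:1 span the feedback-active power code stays
≈ 58 ≫ 1 (resolvable against `pd_sigma ≤ 10⁻³`) while the dimmest
structures sit near 0.1 detected photoelectron — dim enough to be
shot-noise starved, as in real tissue.

**Functional.** ROIs are disks with log-uniform baselines (default
50–5000); each ROI's ΔF/F₀ time course is zero before stimulus onset, then
a difference-of-exponentials kernel (rise 0.1 s, decay 1.0 s — a
GCaMP3-like choice, configurable) normalized to unit peak *over the sampled
frames* and scaled by a per-ROI amplitude drawn uniformly in [−0.3, 2.0]
by default, so response decreases occur and the recorded amplitude is
exactly the trace's peak ΔF/F₀. Amplitudes below −1 are rejected
(strength cannot go negative). Defaults: 0.2 s frame interval, 50 frames,
onset at 3 s, leaving the full 5 s post-stimulus analysis window.

## Functional analysis

F₀ is the mean over a rest window (everything before onset minus a 0.5 s
guard); activity maps average ΔF/F₀ over the 5 s post-onset window with
F₀ ≤ 0 pixels masked; clip masks flag pixels saturated in ≥ 1 frame. The
response peak is the signed extremum of largest magnitude, so suppressed
cells get negative peaks and negative SNR = peak/SD(rest) — a convention
this package fixes since either sign choice is defensible. ROI membership
comes from the generator's ground-truth map; segmentation, motion
correction and neuropil subtraction are out of scope.

What the paired AI-vs-conventional benchmark shows: when the conventional
power must be lowered so the brightest response never clips, dim ROIs
become shot-noise starved; AI at full ceiling holds every sufficiently
bright ROI at `S₀`, so resting ΔF/F₀ noise is lower and the response-SNR
distribution shifts right. This reproduces the *direction* of the benefit;
the magnitude depends entirely on the scene's brightness distribution, so
no particular percentage is claimed.

## Numerical choices and limitations

- All randomness flows from integer seeds (`numpy` Generator at the API
  level; the numba kernels seed their own stream), and identical seeds give
  bit-identical outputs, including TIFF checksums.
- Poisson draws with mean far above `20·S_sat` are short-circuited to the
  (certain) clipped value to keep out-of-control transients cheap.
- The scan kernels are JIT-compiled (numba) because the loop state is
  sequential across sub-steps and pixels; a 256×256 AI frame at 32
  sub-steps runs in well under a second after compilation.
- Problem sizes used in the shipped benchmarks — 256×256 structural
  frames, 48–64 px functional movies of ~50 frames, 10⁴ Monte-Carlo
  repetitions per strength — were chosen as the smallest sizes at which
  the measured quantities are stable to well inside their tolerances.
- The PID tuning of the real instrument is not public; the loop dynamics
  here are representative (uniform contraction by design), not a replica,
  and the controller defaults are stated in the config, not hard-coded.
- Conventional-vs-AI histogram comparison assumes co-registered inputs
  (same scene and seed); no image registration is provided.
- Z-stacks are independent planes; no resonant-scanner timing,
  bidirectional-scan artifacts, or video-rate engineering.
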