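# ailum — active-illumination multiphoton microscopy simulator

Multiphoton microscopes have limited dynamic range: a 12-bit acquisition
chain can distinguish at best 4096:1, while brightness in labeled brain
tissue — dim dendritic spines next to bright somas, or calcium indicators
bursting during activity — can span many orders of magnitude more. *Active
illumination* (AI) solves this with a per-pixel feedback loop: the detected
fluorescence `S = X·P^α` (where `X` is the local sample strength, `P` the
laser power and `α` the excitation order, 2 for two-photon) is held at a set
point `S₀` by modulating `P` up to a ceiling `P_max`, and the quantity of
interest is recovered from the simultaneous measurement of both signals,

```
log₂ X = log₂ S − α·log₂ P ,
```

log-encoded into the microscope's standard electronics so that no
information is lost to coarse sampling at high signal levels. The maximum
dynamic-range gain over conventional acquisition is `2^(αB−1)` for `B`-bit
electronics — almost 10⁷ for two-photon at `B = 12`.

`ailum` is a desk-scale software model of this acquisition chain for people
who want to study, tune, or extend the method without hardware: it
simulates the physics (multiphoton excitation, Poisson shot noise, detector
saturation, EOM actuator dynamics, photodiode power measurement, every ADC/
DAC quantization), the per-pixel PID feedback with automatic switching
between feedback-active and power-limited modes, the `B_L`-bit lookup-table
log encoder, post-hoc linear reconstruction, the closed-form SNR theory
with Monte-Carlo validation, and ΔF/F₀ functional-imaging statistics on
reconstructed calcium movies. Synthetic scenes (structural, with brightness
spanning up to 10¹⁰:1, and functional movies with response increases *and*
decreases) are generated by the package itself; no external data is needed.

## Worked example

```python
import numpy as np
from ailum import (AcquisitionConfig, NoiseModel, make_structural_scene,
                   acquire_frame, occupied_bits, landmarks, dynamic_range_gain)

cfg = AcquisitionConfig()                      # alpha=2, B=12, S_sat=250, S0=125
noise = NoiseModel(shot_noise=True, pd_sigma=0.001)

gain, conv_range = dynamic_range_gain(cfg.alpha, cfg.B)
x_sat, x_t, x_r = landmarks(cfg, NoiseModel(pd_sigma=0.005))
print(f"conventional range {conv_range}:1, max AI gain x{gain}")
print(f"landmarks: X_sat={x_sat:.0f}  X_t={x_t:.0f}  X_r={x_r:.0f}")

scene = make_structural_scene((256, 256), range_ratio=1e8, seed=7)
ai = acquire_frame(scene, cfg, noise, mode="ai", seed=7)
conv = acquire_frame(scene, cfg, noise, mode="conventional", seed=7)
print(f"AI:   occupied {occupied_bits(ai.recon.X_map):.1f} bits, "
      f"clipped fraction {ai.record.clip_fraction:.3f}")
print(f"conv: occupied {occupied_bits(conv.recon.X_map[conv.recon.X_map > 0]):.1f} bits, "
      f"clipped fraction {conv.record.clip_fraction:.3f}")
```

prints

```
conventional range 4096:1, max AI gain x8388608
landmarks: X_sat=250  X_t=125  X_r=10000
AI:   occupied 30.5 bits, clipped fraction 0.000
conv: occupied 7.5 bits, clipped fraction 0.078
```

Reading: a synthetic scene whose ground-truth strengths span 10⁸:1 is
captured by the AI loop in one pass — the log₂ histogram of the
reconstructed strength occupies ~30 bits, no pixel ever saturates — whereas
conventional acquisition at fixed power clips 8% of the pixels against the
detector ceiling and the unclipped remainder occupies well under its 12-bit
bound. `X_sat` is the strength that saturates a conventional scan, `X_t`
the strength where the AI loop switches from feedback-active to
power-limited mode, and `X_r` the 3 dB roll-off of the AI SNR plateau set
by power-measurement noise.

The same pipelines are scriptable from the shell:

```
ailum simulate-structural --shape 256x256 --range 1e8 --seed 7 --out run/
ailum reconstruct --input run/ai_L_hh.tif --out run/recon/
ailum snr-curve --out snr.csv --plot snr.png
ailum simulate-functional --n-rois 12 --seed 3 --out fun/
ailum analyze-functional --movie fun/ai_movie.tif --rois fun/scene_rois.tif --out fun/analysis/
```

Every command writes a manifest (config snapshot, seed, SHA-256 of each
output), so any figure-style artifact is regenerable from the manifest
alone.

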