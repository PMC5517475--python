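"""Convenience pipelines: scene -> scan -> encode -> reconstruct."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AcquisitionConfig, NoiseModel
from .encoder import EncodedFrame, default_luts, encode_frame
from .feedback import FrameRecord, scan_frame
from .recon import ReconstructedImage, reconstruct_linear
from .scenes import FunctionalScene, SceneMap

__all__ = ["AcquisitionResult", "acquire_frame", "acquire_movie"]


@dataclass
class AcquisitionResult:
    """One acquired frame with its encoded and linearized products.

    For conventional scans the ``B``-bit codes are already linear in the
    detected signal, so ``recon.X_map`` simply holds the codes (zero stays
    zero) and ``encoded`` is ``None``.
    """

    record: FrameRecord
    encoded: EncodedFrame | None
    recon: ReconstructedImage


def acquire_frame(
    scene,
    cfg: AcquisitionConfig,
    noise: NoiseModel | None = None,
    mode: str = "ai",
    seed: int | None = None,
) -> AcquisitionResult:
    """Scan one frame and linearize it."""
    record = scan_frame(scene, cfg, noise, mode=mode, seed=seed)
    if mode == "ai":
        enc = encode_frame(record, cfg)
        rec = reconstruct_linear(enc.L_hh_map, enc.G_L, enc.G_M_used)
        return AcquisitionResult(record=record, encoded=enc, recon=rec)
    codes = record.S_hat_map.astype(np.float64)
    with np.errstate(divide="ignore"):
        log2x = np.where(codes > 0, np.log2(np.maximum(codes, 1)), -np.inf)
    rec = ReconstructedImage(
        X_map=codes, log2X_map=log2x,
        scale_note="conventional B-bit codes; linear in detected signal")
    return AcquisitionResult(record=record, encoded=None, recon=rec)


def acquire_movie(
    fscene: FunctionalScene,
    cfg: AcquisitionConfig,
    noise: NoiseModel | None = None,
    mode: str = "ai",
    seed: int | None = None,
):
    """Acquire every frame of a functional scene.

    Returns ``(movie, clip_stack)``: the reconstructed (AI) or raw-code
    (conventional) linear movie as float (n_frames, H, W), and the per-frame
    boolean clip maps.  Frame ``f`` uses seed ``seed + f``.
    """
    if seed is None:
        seed = cfg.seed
    luts = default_luts(cfg)
    H, W = fscene.baseline.shape
    movie = np.zeros((fscene.n_frames, H, W))
    clips = np.zeros((fscene.n_frames, H, W), dtype=bool)
    for f in range(fscene.n_frames):
        frame_scene = fscene.frame(f)
        record = scan_frame(frame_scene, cfg, noise, mode=mode, seed=seed + f)
        clips[f] = record.clip_map
        if mode == "ai":
            enc = encode_frame(record, cfg, luts)
            movie[f] = 2.0 ** (enc.L_hh_map / (enc.G_L * enc.G_M_used))
        else:
            movie[f] = record.S_hat_map
    return movie, clips
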