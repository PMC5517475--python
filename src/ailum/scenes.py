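"""Seeded synthetic scenes: structural maps and functional movies.

Structural scenes emulate the brightness statistics of fluorescently labeled
neural tissue: a few large bright somas (disks), thinner dendrites of
intermediate brightness (random-walk paths), and small dim spines adjacent
to the dendrites.  Somas carry the scene maximum and spines the scene
minimum, so a requested max/min brightness ratio (up to 1e10:1) is realized
exactly by compact structures; dendrite strengths are drawn log-uniformly in
between.  Morphologies are schematic — the goal is the strength statistics,
not anatomy.

Functional movies modulate a baseline scene of circular ROIs with
calcium-transient time courses: flat before stimulus onset, then a
difference-of-exponentials kernel (default 0.1 s rise, 1.0 s decay,
GCaMP3-like) scaled by a per-ROI peak dF/F0 that may be negative (response
decreases).  The kernel is normalized to unit peak over the sampled frames,
so the recorded amplitude is exactly the peak dF/F0 of the trace.

All generation is driven by one integer seed; identical seeds give
bit-identical scenes.  Pixel coordinates are 0-based, row-major, (row, col).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

__all__ = [
    "SceneMap",
    "FunctionalScene",
    "CLASS_NAMES",
    "make_structural_scene",
    "make_functional_scene",
    "ground_truth_summary",
]

LABEL_BACKGROUND = 0
LABEL_SOMA = 1
LABEL_DENDRITE = 2
LABEL_SPINE = 3
CLASS_NAMES = {LABEL_BACKGROUND: "background", LABEL_SOMA: "soma",
               LABEL_DENDRITE: "dendrite", LABEL_SPINE: "spine"}


@dataclass
class SceneMap:
    """Ground-truth sample strength ``X`` per pixel."""

    strength: np.ndarray        # float64, >= 0
    labels: np.ndarray          # int8 class grid
    seed: int
    structure_ids: np.ndarray = None   # int32, 0 = none, k>0 per structure
    range_ratio: float = 1.0
    peak_strength: float = 1.0

    def __post_init__(self):
        if self.structure_ids is None:
            self.structure_ids = (self.labels > 0).astype(np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.strength.shape

    @property
    def min_positive(self) -> float:
        pos = self.strength[self.strength > 0]
        return float(pos.min()) if pos.size else 0.0

    @property
    def achieved_ratio(self) -> float:
        mp = self.min_positive
        return float(self.strength.max() / mp) if mp > 0 else 1.0


@dataclass
class FunctionalScene:
    """Baseline scene plus per-ROI calcium-transient dynamics."""

    baseline: SceneMap
    dt: float
    n_frames: int
    roi_ids: np.ndarray                 # int32 grid, 0 background, 1..n ROIs
    response_amplitudes: np.ndarray     # per-ROI peak dF/F0 (signed)
    kernel_params: tuple[float, float]  # (rise_s, decay_s)
    stim_onset: float
    seed: int
    dff_traces: np.ndarray = field(default=None)  # (n_rois, n_frames)

    @property
    def n_rois(self) -> int:
        return len(self.response_amplitudes)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def frame(self, f: int) -> np.ndarray:
        """Strength map at frame ``f``: baseline * (1 + dF/F0)."""
        mod = np.ones(self.baseline.shape)
        for r in range(self.n_rois):
            mod[self.roi_ids == r + 1] = 1.0 + self.dff_traces[r, f]
        return self.baseline.strength * mod

    def frames(self) -> np.ndarray:
        """Full (n_frames, H, W) ground-truth strength movie."""
        gain = np.ones((self.n_frames,) + self.baseline.shape)
        for r in range(self.n_rois):
            mask = self.roi_ids == r + 1
            gain[:, mask] = 1.0 + self.dff_traces[r][:, None]
        return self.baseline.strength[None, :, :] * gain


def _default_counts(shape: tuple[int, int]) -> dict[str, int]:
    area = shape[0] * shape[1]
    return {
        "soma": max(1, area // 16384),
        "dendrite": max(2, area // 8192),
        "spine": max(8, area // 1024),
    }


def _place_disks(rng, shape, n, radius, occupied, margin=1, max_tries=2000):
    """Non-overlapping disk placement; returns list of (rr, cc) index pairs."""
    H, W = shape
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"counts exceed grid capacity: cannot place {n} disks of "
                f"radius {radius} on a {H}x{W} grid")
        r = rng.integers(radius + margin, H - radius - margin)
        c = rng.integers(radius + margin, W - radius - margin)
        rr, cc = _disk((r, c), radius, shape=shape)
        if occupied[rr, cc].any():
            continue
        occupied[rr, cc] = True
        out.append((rr, cc))
    return out


def _walk_path(rng, shape, length):
    """Persistent 8-connected random walk; returns (rows, cols) arrays."""
    H, W = shape
    r = float(rng.integers(2, H - 2))
    c = float(rng.integers(2, W - 2))
    theta = rng.uniform(0, 2 * np.pi)
    rows, cols = [], []
    for _ in range(length):
        theta += rng.normal(0.0, 0.3)
        r = min(max(r + np.sin(theta), 1.0), H - 2.0)
        c = min(max(c + np.cos(theta), 1.0), W - 2.0)
        rows.append(int(round(r)))
        cols.append(int(round(c)))
    return np.array(rows), np.array(cols)


def make_structural_scene(
    shape: tuple[int, int] = (256, 256),
    range_ratio: float = 1e8,
    counts: dict[str, int] | None = None,
    seed: int = 0,
    peak_strength: float = 1e7,
    soma_radius: int | None = None,
) -> SceneMap:
    """Generate a structural scene whose brightness spans ``range_ratio``:1.

    Somas sit exactly at ``peak_strength`` and spines exactly at
    ``peak_strength / range_ratio``; the achieved max / min-positive ratio
    equals the request (well within the 1% contract).  Identical seeds give
    bit-identical scenes.
    """
    if range_ratio < 1:
        raise ValueError("range_ratio must be >= 1")
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError("shape must be at least 32x32")
    if peak_strength <= 0:
        raise ValueError("peak_strength must be > 0")
    counts = dict(_default_counts(shape) if counts is None else counts)
    for k in counts:
        if k not in ("soma", "dendrite", "spine"):
            raise ValueError(f"unknown structure class {k!r}")
    n_soma = int(counts.get("soma", 0))
    n_dend = int(counts.get("dendrite", 0))
    n_spine = int(counts.get("spine", 0))
    if n_soma + n_dend + n_spine < 1:
        raise ValueError("scene needs at least one structure")
    if soma_radius is None:
        soma_radius = max(4, min(10, min(shape) // 8))
    if n_soma * np.pi * soma_radius**2 > 0.5 * shape[0] * shape[1]:
        raise ValueError("counts exceed grid capacity: somas would cover "
                         "more than half the grid")

    rng = np.random.default_rng(seed)
    strength = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int8)
    structure_ids = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    min_strength = peak_strength / range_ratio
    sid = 0

    for rr, cc in _place_disks(rng, shape, n_soma, soma_radius, occupied):
        sid += 1
        strength[rr, cc] = peak_strength
        labels[rr, cc] = LABEL_SOMA
        structure_ids[rr, cc] = sid

    dendrite_mask = np.zeros(shape, dtype=bool)
    length = int(min(shape) * 1.5)
    for _ in range(n_dend):
        sid += 1
        if min_strength == peak_strength:
            level = peak_strength
        else:
            level = float(np.exp(rng.uniform(np.log(min_strength),
                                             np.log(peak_strength))))
        rows, cols = _walk_path(rng, shape, length)
        for r, c in zip(rows, cols):
            rr, cc = _disk((r, c), 1.5, shape=shape)   # ~2 px wide
            free = ~occupied[rr, cc] | dendrite_mask[rr, cc]
            rr, cc = rr[free], cc[free]
            strength[rr, cc] = level
            labels[rr, cc] = LABEL_DENDRITE
            structure_ids[rr, cc] = sid
            dendrite_mask[rr, cc] = True
        occupied |= dendrite_mask

    # spines: 1-2 px puncta on background pixels adjacent to a dendrite
    if n_spine > 0:
        if dendrite_mask.any():
            from scipy.ndimage import binary_dilation
            halo = binary_dilation(dendrite_mask, iterations=2) & ~occupied
        else:
            halo = ~occupied
        cand = np.argwhere(halo)
        if len(cand) < n_spine:
            raise ValueError("counts exceed grid capacity: not enough free "
                             "pixels adjacent to dendrites for the spines")
        pick = rng.choice(len(cand), size=n_spine, replace=False)
        for r, c in cand[pick]:
            sid += 1
            strength[r, c] = min_strength
            labels[r, c] = LABEL_SPINE
            structure_ids[r, c] = sid
            occupied[r, c] = True
            if rng.random() < 0.5:      # second pixel for some spines
                for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                    r2, c2 = r + dr, c + dc
                    if (0 <= r2 < shape[0] and 0 <= c2 < shape[1]
                            and not occupied[r2, c2]):
                        strength[r2, c2] = min_strength
                        labels[r2, c2] = LABEL_SPINE
                        structure_ids[r2, c2] = sid
                        occupied[r2, c2] = True
                        break

    # pin the extremes so the requested ratio is met exactly whatever the
    # structure mix: dimmest structure -> scene minimum
    pos = strength > 0
    if pos.any() and range_ratio > 1:
        cur_min = strength[pos].min()
        if cur_min > min_strength:
            dimmest = structure_ids[pos][np.argmin(strength[pos])]
            strength[structure_ids == dimmest] = min_strength
    return SceneMap(strength=strength, labels=labels, seed=seed,
                    structure_ids=structure_ids, range_ratio=range_ratio,
                    peak_strength=peak_strength)


def make_functional_scene(
    shape: tuple[int, int] = (64, 64),
    n_rois: int = 12,
    amp_spec=None,
    dt: float = 0.2,
    n_frames: int = 50,
    stim_onset: float = 3.0,
    seed: int = 0,
    baseline_range: tuple[float, float] = (50.0, 5000.0),
    roi_radius: int = 3,
    kernel_params: tuple[float, float] = (0.1, 1.0),
) -> FunctionalScene:
    """Generate a functional movie scene with calcium-like transients.

    ``amp_spec`` is either a sequence of per-ROI peak dF/F0 values or a
    ``{"low": a, "high": b}`` uniform range (default −0.3 to 2.0, so both
    response increases and decreases occur).  Amplitudes below −1 would
    drive strength negative and are rejected.  The recording must extend at
    least 5 s past ``stim_onset``.
    """
    total = n_frames * dt
    if total < stim_onset + 5.0:
        raise ValueError("recording must span stim_onset + 5 s "
                         f"(have {total:.2f} s, need {stim_onset + 5.0:.2f} s)")
    rng = np.random.default_rng(seed)
    if amp_spec is None:
        amp_spec = {"low": -0.3, "high": 2.0}
    if isinstance(amp_spec, dict):
        lo, hi = float(amp_spec["low"]), float(amp_spec["high"])
        if lo < -1.0:
            raise ValueError("amplitude < -1 would force negative strength")
        amps = rng.uniform(lo, hi, size=n_rois)
    else:
        amps = np.asarray(amp_spec, dtype=np.float64)
        if len(amps) != n_rois:
            raise ValueError("amp_spec length must equal n_rois")
    if np.any(amps < -1.0):
        raise ValueError("amplitude < -1 would force negative strength")

    occupied = np.zeros(shape, dtype=bool)
    strength = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int8)
    roi_ids = np.zeros(shape, dtype=np.int32)
    disks = _place_disks(rng, shape, n_rois, roi_radius, occupied, margin=1)
    lo_b, hi_b = baseline_range
    for i, (rr, cc) in enumerate(disks):
        level = float(np.exp(rng.uniform(np.log(lo_b), np.log(hi_b))))
        strength[rr, cc] = level
        labels[rr, cc] = LABEL_SOMA
        roi_ids[rr, cc] = i + 1
    baseline = SceneMap(strength=strength, labels=labels, seed=seed,
                        structure_ids=roi_ids.astype(np.int32),
                        range_ratio=hi_b / lo_b, peak_strength=hi_b)

    t = np.arange(n_frames) * dt
    tau_r, tau_d = kernel_params
    rel = t - stim_onset
    kern = np.where(rel >= 0,
                    np.exp(-np.maximum(rel, 0) / tau_d)
                    - np.exp(-np.maximum(rel, 0) / tau_r), 0.0)
    peak = kern.max()
    if peak > 0:
        kern = kern / peak     # unit peak over the sampled frames
    dff = amps[:, None] * kern[None, :]
    return FunctionalScene(baseline=baseline, dt=dt, n_frames=n_frames,
                           roi_ids=roi_ids, response_amplitudes=amps,
                           kernel_params=(tau_r, tau_d),
                           stim_onset=stim_onset, seed=seed, dff_traces=dff)


def ground_truth_summary(scene) -> pd.DataFrame:
    """Per-structure (or per-ROI) table of class, size and mean strength."""
    if isinstance(scene, FunctionalScene):
        rows = []
        for r in range(scene.n_rois):
            mask = scene.roi_ids == r + 1
            rows.append({
                "roi_id": r + 1,
                "n_pixels": int(mask.sum()),
                "mean_strength": float(scene.baseline.strength[mask].mean()),
                "amplitude": float(scene.response_amplitudes[r]),
            })
        return pd.DataFrame(rows)
    rows = []
    for sid in np.unique(scene.structure_ids):
        if sid == 0:
            continue
        mask = scene.structure_ids == sid
        label = int(scene.labels[mask][0])
        rows.append({
            "structure_id": int(sid),
            "class": CLASS_NAMES.get(label, str(label)),
            "n_pixels": int(mask.sum()),
            "mean_strength": float(scene.strength[mask].mean()),
        })
    return pd.DataFrame(rows)
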