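"""File I/O: TIFF stacks, CSV tables, JSON/YAML configs, run manifests.

Image kinds carry an explicit dtype contract so round-trips are lossless:
``strength32f`` (32-bit float), ``codes16u`` (16-bit unsigned integer
codes), ``mask8u`` (8-bit masks).  Movies are written as multi-page TIFF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from . import __version__
from .config import AcquisitionConfig, ConfigError, NoiseModel
from .scenes import FunctionalScene, SceneMap, ground_truth_summary

__all__ = [
    "KINDS",
    "write_stack",
    "read_stack",
    "write_scene",
    "save_config",
    "load_config",
    "RunManifest",
    "sha256_of",
]

KINDS = {
    "strength32f": np.float32,
    "codes16u": np.uint16,
    "mask8u": np.uint8,
}


def _check_kind(data: np.ndarray, kind: str) -> np.ndarray:
    if kind not in KINDS:
        raise ValueError(f"unknown stack kind {kind!r}; expected one of "
                         f"{sorted(KINDS)}")
    dtype = KINDS[kind]
    if np.issubdtype(dtype, np.integer):
        if not np.issubdtype(data.dtype, np.integer) and data.dtype != bool:
            raise ValueError(f"kind {kind!r} requires integer data, got "
                             f"{data.dtype}")
        info = np.iinfo(dtype)
        if data.min() < info.min or data.max() > info.max:
            raise ValueError(f"data out of range for {kind!r}")
    return np.asarray(data).astype(dtype)


def write_stack(path, data, kind: str) -> Path:
    """Write a 2-D image or 3-D movie as (multi-page) TIFF."""
    path = Path(path)
    arr = _check_kind(np.asarray(data), kind)
    if arr.ndim not in (2, 3):
        raise ValueError("data must be 2-D (image) or 3-D (movie)")
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


def read_stack(path, kind: str) -> np.ndarray:
    """Read a stack written by :func:`write_stack`; checks the dtype."""
    if kind not in KINDS:
        raise ValueError(f"unknown stack kind {kind!r}")
    arr = tifffile.imread(path)
    if arr.dtype != KINDS[kind]:
        raise ValueError(f"{path}: dtype {arr.dtype} does not match kind "
                         f"{kind!r} ({np.dtype(KINDS[kind])})")
    return arr


def write_scene(outdir, scene, stem: str = "scene") -> dict[str, Path]:
    """Write a scene as 32-bit float TIFF + ground-truth CSV + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    if isinstance(scene, FunctionalScene):
        files["movie"] = write_stack(outdir / f"{stem}.tif", scene.frames(),
                                     "strength32f")
        files["roi_ids"] = write_stack(outdir / f"{stem}_rois.tif",
                                       scene.roi_ids.astype(np.uint16),
                                       "codes16u")
        params = {
            "kind": "functional", "seed": scene.seed, "dt": scene.dt,
            "n_frames": scene.n_frames, "stim_onset": scene.stim_onset,
            "kernel_params": list(scene.kernel_params),
            "amplitudes": [float(a) for a in scene.response_amplitudes],
        }
    elif isinstance(scene, SceneMap):
        files["image"] = write_stack(outdir / f"{stem}.tif", scene.strength,
                                     "strength32f")
        files["labels"] = write_stack(outdir / f"{stem}_labels.tif",
                                      scene.labels.astype(np.uint8), "mask8u")
        params = {
            "kind": "structural", "seed": scene.seed,
            "range_ratio": scene.range_ratio,
            "peak_strength": scene.peak_strength,
        }
    else:
        raise TypeError("scene must be a SceneMap or FunctionalScene")
    csv_path = outdir / f"{stem}_ground_truth.csv"
    ground_truth_summary(scene).to_csv(csv_path, index=False)
    files["ground_truth"] = csv_path
    sidecar = outdir / f"{stem}.json"
    sidecar.write_text(json.dumps(params, indent=2))
    files["sidecar"] = sidecar
    return files


def save_config(path, cfg: AcquisitionConfig,
                noise: NoiseModel | None = None) -> Path:
    """Write acquisition + noise parameters as JSON or YAML (by extension)."""
    path = Path(path)
    doc = {"acquisition": cfg.to_dict(),
           "noise": (noise or NoiseModel()).to_dict()}
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))
    return path


def load_config(path) -> tuple[AcquisitionConfig, NoiseModel]:
    """Load a config file; derived gains are recomputed from bit depths
    unless the file overrides them explicitly."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix in (".yml", ".yaml"):
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    cfg = AcquisitionConfig.from_dict(doc.get("acquisition", {}))
    noise = NoiseModel.from_dict(doc.get("noise", {}))
    return cfg, noise


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Record of one pipeline run: config snapshot, seeds, outputs."""

    command: str
    seed: int
    config: dict[str, Any]
    noise: dict[str, Any]
    files: dict[str, str] = dataclasses.field(default_factory=dict)
    stats: dict[str, Any] = dataclasses.field(default_factory=dict)
    version: str = __version__

    def add_file(self, key: str, path) -> None:
        self.files[str(key)] = f"{Path(path).name}:sha256:{sha256_of(path)}"

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path

    @property
    def config_hash(self) -> str:
        blob = json.dumps({"config": self.config, "noise": self.noise},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
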