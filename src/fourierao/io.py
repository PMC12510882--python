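"""Volume I/O and run configuration.

Volumes travel as multi-page TIFF with the voxel pitch recorded in the
image description (JSON), so a written volume round-trips losslessly
with its sampling metadata. Run configuration is a flat INI-style text
file with ``[optics]``, ``[preprocess]`` and ``[run]`` sections,
schema-validated at load.
"""

from __future__ import annotations

import configparser
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .embedding import PreprocessConfig
from .optics import OpticalConfig

__all__ = ["read_volume", "write_volume", "write_otf", "RunConfig",
           "load_config"]

DEFAULT_PITCH = (125.0, 125.0, 200.0)


def write_volume(grid: np.ndarray, path,
                 voxel_pitch=DEFAULT_PITCH) -> None:
    """Write a 3D grid as multi-page TIFF with pitch metadata (nm)."""
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError("expected a 3D volume (z, y, x)")
    desc = json.dumps({"voxel_pitch_nm": list(map(float, voxel_pitch))})
    tifffile.imwrite(path, grid, description=desc,
                     photometric="minisblack")


def read_volume(path):
    """Read a multi-page TIFF; returns ``(volume, voxel_pitch_nm)``.

    Missing pitch metadata falls back to the package defaults with a
    warning.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            volume = tf.asarray()
            desc = tf.pages[0].description or ""
    except Exception as exc:
        raise IOError(f"cannot read TIFF volume {path!r}: {exc}") from exc
    if volume.ndim == 2:
        volume = volume[None]
    pitch = None
    try:
        meta = json.loads(desc)
        pitch = tuple(float(p) for p in meta["voxel_pitch_nm"])
    except Exception:
        pass
    if pitch is None:
        warnings.warn(f"{path}: no voxel-pitch metadata; assuming "
                      f"{DEFAULT_PITCH} nm", stacklevel=2)
        pitch = DEFAULT_PITCH
    return volume, pitch


def write_otf(otf, amp_path, phase_path,
              voxel_pitch=DEFAULT_PITCH) -> None:
    """Write an OTF as paired amplitude/phase multi-page TIFFs."""
    values = np.asarray(otf.values if hasattr(otf, "values") else otf)
    write_volume(np.abs(values).astype(np.float32), amp_path, voxel_pitch)
    write_volume(np.angle(values).astype(np.float32), phase_path,
                 voxel_pitch)


@dataclass
class RunConfig:
    """Everything one end-to-end correction run needs."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model_path: Optional[Path] = None
    iterations: int = 1
    output_dir: Path = Path("fourierao_out")
    seed: int = 0


_OPTICS_KEYS = {"na_detection": float, "wavelength": float,
                "refractive_index": float}
_PRE_KEYS = {"highpass_sigma": float, "lowpass_sigma": float,
             "tukey_alpha": float, "percentile_lo": float,
             "percentile_hi": float}
_RUN_KEYS = {"model_path": str, "iterations": int, "output_dir": str,
             "seed": int}


def load_config(path) -> RunConfig:
    """Parse and validate a flat INI configuration file."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise IOError(f"cannot read config file {path!r}")

    def section(name, schema):
        out = {}
        if parser.has_section(name):
            for key, raw in parser.items(name):
                if key not in schema:
                    raise ValueError(f"unknown key {key!r} in [{name}]")
                out[key] = schema[key](raw)
        return out

    opt = section("optics", _OPTICS_KEYS)
    if "voxel_pitch" in (parser.options("optics")
                         if parser.has_section("optics") else []):
        raise ValueError("set pitches via dx/dy/dz keys")
    pre = section("preprocess", _PRE_KEYS)
    run = section("run", _RUN_KEYS)
    cfg = RunConfig(optics=OpticalConfig(**opt),
                    preprocess=PreprocessConfig(**pre))
    if "model_path" in run:
        cfg.model_path = Path(run["model_path"])
    if "iterations" in run:
        cfg.iterations = run["iterations"]
    if "output_dir" in run:
        cfg.output_dir = Path(run["output_dir"])
    if "seed" in run:
        cfg.seed = run["seed"]
    return cfg
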