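"""Reading and writing scene rasters, masks, point sets and configs.

Rasters are stored as TIFF (3-band float in [0, 1] for scenes, single-band
uint8 {0, 1} for masks) via :mod:`tifffile`, with the quadrat-local
georeferencing (resolution in m/pixel, SW-corner origin, x east / y north)
carried in a JSON ImageDescription tag.  Point sets and tile tables are
plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classify import PixelMask
from .scene import RGBScene, SceneParams

__all__ = [
    "write_scene",
    "read_scene",
    "write_mask",
    "read_mask",
    "write_points",
    "read_points",
    "load_scene_params",
    "dump_scene_params",
    "load_dryad_deposit",
]


def _meta(resolution: float, origin: tuple[float, float]) -> str:
    return json.dumps(
        {"resolution_m": resolution, "origin_sw": list(origin), "axes": "x east, y north, row 0 north"}
    )


def write_scene(scene: RGBScene, path: str | Path) -> None:
    tifffile.imwrite(
        Path(path),
        scene.pixels.astype(np.float32),
        photometric="rgb",
        description=_meta(scene.resolution, scene.origin),
    )


def read_scene(path: str | Path) -> RGBScene:
    with tifffile.TiffFile(Path(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {"resolution_m": 0.01, "origin_sw": [0.0, 0.0]}
    if arr.dtype == np.uint8:  # 8-bit input: rescale to reflectance
        arr = arr.astype(np.float32) / 255.0
    return RGBScene(
        pixels=np.asarray(arr, dtype=np.float32),
        resolution=float(meta["resolution_m"]),
        origin=tuple(meta.get("origin_sw", (0.0, 0.0))),
    )


def write_mask(mask: PixelMask, path: str | Path) -> None:
    tifffile.imwrite(
        Path(path),
        mask.values.astype(np.uint8),
        description=json.dumps({"label": mask.label, "resolution_m": mask.resolution}),
    )


def read_mask(path: str | Path) -> PixelMask:
    with tifffile.TiffFile(Path(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {"label": "unknown", "resolution_m": 0.01}
    return PixelMask(arr.astype(bool), meta["label"], float(meta["resolution_m"]))


def write_points(points: pd.DataFrame, path: str | Path) -> None:
    points.to_csv(Path(path), index=False)


def read_points(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def dump_scene_params(params: SceneParams, path: str | Path) -> None:
    import dataclasses

    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=False)


def load_scene_params(path: str | Path) -> SceneParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("mounds_per_colony", "mound_radius_range", "colonization_beta", "reuse_beta",
                "background_rgb", "flower_rgb", "mound_rgb"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SceneParams(**raw)


def load_dryad_deposit(path: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Load the deposited field dataset (tile tables and subplot point sets).

    The field coefficients reported for the study meadows can only be
    reproduced from the archived deposit (doi:10.5061/dryad.8w9ghx3xs),
    which must be downloaded separately and passed as ``path``.  This
    package's default validation relies on synthetic scenes instead.
    """
    if path is None:
        raise FileNotFoundError(
            "the field dataset is not bundled: download the archived deposit "
            "(doi:10.5061/dryad.8w9ghx3xs) and pass its directory as `path`"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"deposit directory {path} does not exist")
    tables = {p.stem: pd.read_csv(p) for p in sorted(path.glob("*.csv"))}
    if not tables:
        raise FileNotFoundError(f"no CSV tables found under {path}")
    return tables
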