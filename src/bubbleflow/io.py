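"""Reading and writing of the on-disk formats: frame stacks (multi-page
TIFF for real data, NPZ for complex), JSON sidecar metadata, TIC CSVs,
fit records and detection tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import (
    BubbleDetections,
    DopplerImage,
    FrameStack,
    GammaVariateFit,
    TimeIntensityCurve,
)
from .errors import InvalidInputError

__all__ = [
    "save_stack", "load_stack",
    "save_tic", "load_tic",
    "save_fit", "load_fit",
    "save_doppler_image",
    "save_detections", "load_detections",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF (real) or NPZ (complex) with a
    JSON sidecar carrying frame rate and pixel size."""
    path = Path(path)
    if stack.is_complex:
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        np.savez(path, data=stack.data)
    else:
        if path.suffix not in (".tif", ".tiff"):
            path = path.with_suffix(".tif")
        tifffile.imwrite(path, stack.data)
    meta = {"frame_rate_hz": stack.frame_rate, "pixel_size_um": stack.pixel_size}
    _sidecar(path).write_text(json.dumps(meta))
    return path


def load_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such stack file: {path}")
    meta = json.loads(_sidecar(path).read_text())
    if path.suffix == ".npz":
        data = np.load(path)["data"]
    else:
        data = tifffile.imread(path)
    return FrameStack(data, meta["frame_rate_hz"], meta.get("pixel_size_um"))


def save_tic(tic: TimeIntensityCurve, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": tic.times, "intensity": tic.intensities})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def load_tic(path: str | Path) -> TimeIntensityCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    return TimeIntensityCurve(df["time_s"].to_numpy(), df["intensity"].to_numpy())


def save_fit(fit: GammaVariateFit, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(fit), indent=2))
    return path


def load_fit(path: str | Path) -> GammaVariateFit:
    return GammaVariateFit(**json.loads(Path(path).read_text()))


def save_doppler_image(image: DopplerImage, path: str | Path) -> Path:
    """Doppler/ASAP map as single-page TIFF; complex maps are stored as
    their magnitude with the phase discarded (sign retained for real)."""
    path = Path(path)
    data = image.data
    if np.iscomplexobj(data):
        data = np.abs(data)
    tifffile.imwrite(path, data.astype(np.float32))
    return path


def save_detections(detections: list[BubbleDetections] | BubbleDetections,
                    path: str | Path) -> Path:
    if isinstance(detections, BubbleDetections):
        detections = [detections]
    rows = []
    for det in detections:
        for (r, c), d in zip(det.centers, det.diameters):
            rows.append({"fov_id": det.fov_id, "row": r, "col": c, "diameter_um": d})
    pd.DataFrame(rows, columns=["fov_id", "row", "col", "diameter_um"]).to_csv(
        Path(path), index=False, float_format=_FLOAT_FMT
    )
    return Path(path)


def load_detections(path: str | Path) -> list[BubbleDetections]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for fov_id, grp in df.groupby("fov_id", sort=False):
        out.append(BubbleDetections(
            centers=grp[["row", "col"]].to_numpy(),
            diameters=grp["diameter_um"].to_numpy(),
            fov_id=str(fov_id),
        ))
    return out
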