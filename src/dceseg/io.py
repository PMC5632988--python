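"""NIfTI and JSON file I/O.

Dynamic series are 4D NIfTI (``.nii``/``.nii.gz``) with time as the 4th
dimension; acquisition metadata (``n_pre``, ``frame_interval_s``) travels in
a JSON sidecar named like the image (``series.nii.gz`` -> ``series.json``).
ROIs are JSON arrays of 0-based half-open rectangles; masks are uint8 NIfTI.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .dataset import RoiRect
from .tic import DEFAULT_N_PRE, DynamicSeries

__all__ = [
    "read_series",
    "write_series",
    "read_rois",
    "write_rois",
    "read_mask",
    "write_mask",
]


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_series(
    path, n_pre: int | None = None, frame_interval_s: float | None = None
) -> DynamicSeries:
    """Load a 4D dynamic series; sidecar JSON supplies metadata unless
    overridden by the arguments."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"{path} is not a 4D dynamic series (shape {data.shape}); "
            "the time axis must be dimension 4"
        )
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return DynamicSeries(
        intensities=data,
        n_pre=n_pre if n_pre is not None else int(meta.get("n_pre", DEFAULT_N_PRE)),
        frame_interval_s=(
            frame_interval_s
            if frame_interval_s is not None
            else float(meta.get("frame_interval_s", 5.9))
        ),
    )


def write_series(series: DynamicSeries, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(series.intensities, affine=np.eye(4)), str(path))
    _sidecar(path).write_text(
        json.dumps(
            {"n_pre": series.n_pre, "frame_interval_s": series.frame_interval_s},
            indent=2,
        )
    )


def read_rois(path) -> list[RoiRect]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):  # single ROI object
        data = [data]
    return [RoiRect.from_dict(d) for d in data]


def write_rois(rois, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps([r.to_dict() for r in rois], indent=2))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def write_mask(mask: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine=np.eye(4)), str(path)
    )
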