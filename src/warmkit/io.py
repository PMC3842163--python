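"""Readers and writers: 4D NIfTI dynamic images with JSON timing sidecars,
TSV time–activity and arterial-input tables, and parametric-map output.

NIfTI-1 has no standard slot for per-frame timing, so frame starts/ends
travel in a JSON sidecar next to the image (``<image>.json`` for
``<image>.nii[.gz]``) with the schema::

    {"frame_start_s": [...], "frame_end_s": [...]}

TAC tables are tab-separated with header ``frame_start_s  frame_end_s
value``; arterial input tables use ``sample_time_s  concentration``.
Lines starting with ``#`` are comments.  All times are seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import WarmkitError
from .tac import ArterialInput, TimeActivityCurve

__all__ = [
    "DynamicImage",
    "read_dynamic_image",
    "write_dynamic_image",
    "read_tac_table",
    "write_tac_table",
    "read_arterial_input",
    "write_arterial_input",
    "read_mask",
    "write_parametric_map",
    "read_parametric_map",
]

SIDECAR_SCHEMA = '{"frame_start_s": [...], "frame_end_s": [...]}'


@dataclass(frozen=True)
class DynamicImage:
    """A 4D dynamic image (one volume per frame) with its frame schedule."""

    data: np.ndarray
    affine: np.ndarray
    frame_starts: np.ndarray
    frame_ends: np.ndarray

    @property
    def frame_mid_times(self) -> np.ndarray:
        return (self.frame_starts + self.frame_ends) / 2.0

    @property
    def frame_durations(self) -> np.ndarray:
        return self.frame_ends - self.frame_starts

    def mean_tac(self, mask: np.ndarray, label: str = "") -> TimeActivityCurve:
        """Mean TAC over the voxels of a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.data.shape[:3]:
            raise WarmkitError("mask shape does not match the image grid")
        if not np.any(mask):
            raise WarmkitError("empty mask")
        return TimeActivityCurve.from_frames(
            self.frame_starts, self.frame_ends, self.data[mask].mean(axis=0), label=label
        )


def _sidecar_path(image_path: Path) -> Path:
    name = image_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return image_path.with_name(name[: -len(suffix)] + ".json")
    return image_path.with_suffix(".json")


def read_dynamic_image(path) -> DynamicImage:
    """Load a 4D NIfTI image and its JSON frame-timing sidecar."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise WarmkitError(f"expected a 4-D image, got {data.ndim}-D")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise WarmkitError(
            f"missing frame-timing sidecar {sidecar.name}; expected JSON {SIDECAR_SCHEMA}"
        )
    meta = json.loads(sidecar.read_text())
    try:
        starts = np.asarray(meta["frame_start_s"], dtype=float)
        ends = np.asarray(meta["frame_end_s"], dtype=float)
    except KeyError as exc:
        raise WarmkitError(f"sidecar missing key {exc}; expected {SIDECAR_SCHEMA}") from exc
    if len(starts) != data.shape[3] or len(ends) != data.shape[3]:
        raise WarmkitError(
            f"sidecar lists {len(starts)} frames but the image has {data.shape[3]}"
        )
    if np.any(ends <= starts) or np.any(np.diff(starts) <= 0):
        raise WarmkitError("frame times must be positive-duration and increasing")
    return DynamicImage(data=data, affine=img.affine, frame_starts=starts, frame_ends=ends)


def write_dynamic_image(image: DynamicImage, path, extra_metadata: dict | None = None) -> None:
    """Write a 4D image plus its timing sidecar (float32 on disk)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), image.affine), str(path))
    meta = {
        "frame_start_s": list(map(float, image.frame_starts)),
        "frame_end_s": list(map(float, image.frame_ends)),
    }
    if extra_metadata:
        meta.update(extra_metadata)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_tac_table(path) -> TimeActivityCurve:
    """Read a TSV TAC table (frame_start_s, frame_end_s, value)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise WarmkitError(f"empty TAC table {path}") from exc
    required = {"frame_start_s", "frame_end_s", "value"}
    if not required <= set(df.columns):
        raise WarmkitError(f"TAC table must have columns {sorted(required)}")
    if df.empty:
        raise WarmkitError(f"TAC table {path} has no rows")
    return TimeActivityCurve.from_frames(
        df["frame_start_s"].to_numpy(),
        df["frame_end_s"].to_numpy(),
        df["value"].to_numpy(),
        label=path.stem,
    )


def write_tac_table(tac: TimeActivityCurve, path) -> None:
    pd.DataFrame(
        {
            "frame_start_s": tac.frame_starts,
            "frame_end_s": tac.frame_ends,
            "value": tac.values,
        }
    ).to_csv(path, sep="\t", index=False)


def read_arterial_input(path) -> ArterialInput:
    """Read a TSV arterial-input table (sample_time_s, concentration)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise WarmkitError(f"empty arterial input table {path}") from exc
    required = {"sample_time_s", "concentration"}
    if not required <= set(df.columns):
        raise WarmkitError(f"arterial input table must have columns {sorted(required)}")
    return ArterialInput(df["sample_time_s"].to_numpy(), df["concentration"].to_numpy())


def write_arterial_input(aif: ArterialInput, path) -> None:
    pd.DataFrame(
        {"sample_time_s": aif.sample_times, "concentration": aif.concentrations}
    ).to_csv(path, sep="\t", index=False)


def read_mask(path, grid_shape: tuple | None = None) -> np.ndarray:
    """Read a binary NIfTI mask (any nonzero voxel is in)."""
    mask = np.asarray(nib.load(str(path)).dataobj) != 0
    if mask.ndim != 3:
        raise WarmkitError("mask must be a 3-D image")
    if grid_shape is not None and mask.shape != tuple(grid_shape):
        raise WarmkitError(f"mask shape {mask.shape} does not match image grid {grid_shape}")
    return mask


def write_parametric_map(
    parametric_map: np.ndarray,
    path,
    affine: np.ndarray | None = None,
    sidecar_metadata: dict | None = None,
) -> None:
    """Write a float32 parametric map plus a JSON sidecar.

    The sidecar records method, configuration and exclusion counts
    (whatever the caller passes) so every map is self-describing.
    NaN encodes voxels where the estimator failed.
    """
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(parametric_map, dtype=np.float32), affine), str(path))
    if sidecar_metadata is not None:
        _sidecar_path(path).write_text(json.dumps(sidecar_metadata, indent=2, sort_keys=True))


def read_parametric_map(path) -> tuple:
    """Read back a parametric map and its sidecar (``{}`` if absent)."""
    path = Path(path)
    img = nib.load(str(path))
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return np.asarray(img.dataobj, dtype=float), meta
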