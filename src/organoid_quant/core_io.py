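"""Calibrated data containers and readers/writers for the pipeline inputs.

Images are handled as floating point in [0, 1] internally; integer TIFFs are
normalized by the dtype maximum on read and the original dtype is remembered
so that write-after-read round-trips bit-exactly. Calibration (pixel/voxel
size, frame rate) comes from an optional YAML sidecar (``<image>.yaml``) or
from explicit arguments; explicit arguments win.

Coordinate conventions: 0-based indices, axis order ``(z|t, y, x)``,
half-open crop intervals.
"""

from __future__ import annotations

import contextlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("organoid_quant")

#: pixel size (µm) of the camera at the two objectives used for acquisition
PIXEL_SIZE_100X_UM = 0.065
PIXEL_SIZE_60X_UM = 0.108
#: default z-step (µm) of the confocal stacks
Z_STEP_UM = 0.2
#: default calcium-movie sampling rate (Hz)
FRAME_RATE_HZ = 4.0


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _dtype_max(dtype: np.dtype) -> float | None:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return None


def _as_normalized_float(arr: np.ndarray) -> tuple[np.ndarray, float | None]:
    """Return (float array in [0,1], original integer dtype max or None)."""
    arr = np.asarray(arr)
    dmax = _dtype_max(arr.dtype)
    if dmax is not None:
        return arr.astype(np.float64) / dmax, dmax
    out = arr.astype(np.float64)
    return out, None


@dataclass
class Image2D:
    """A single-channel (or channel-stacked) 2D fluorescence image.

    Parameters
    ----------
    pixels : (Y, X) ndarray
        Non-negative intensities, normalized to [0, 1] for pipeline input.
    pixel_size_um : float
        Lateral pixel size in µm (0.065 for the 100× setup, 0.108 for 60×).
    channel_names : list of str
        Optional channel labels for bookkeeping.
    """

    pixels: np.ndarray
    pixel_size_um: float = PIXEL_SIZE_100X_UM
    channel_names: list[str] = field(default_factory=list)
    dtype_max: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(f"Image2D needs a 2D array, got {self.pixels.ndim}D")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if np.any(self.pixels < 0) or not np.all(np.isfinite(self.pixels)):
            raise ValidationError("intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass
class ImageStack3D:
    """A calibrated 3D fluorescence z-stack with axis order (Z, Y, X)."""

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (Z_STEP_UM, PIXEL_SIZE_100X_UM, PIXEL_SIZE_100X_UM)
    channel_names: list[str] = field(default_factory=list)
    dtype_max: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValidationError(f"ImageStack3D needs a 3D array, got {self.voxels.ndim}D")
        if self.voxels.shape[0] < 1:
            raise ValidationError("stack must contain at least one plane")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)  # type: ignore[assignment]
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValidationError("voxel_size_um must be three positive reals (dz, dy, dx)")
        if np.any(self.voxels < 0) or not np.all(np.isfinite(self.voxels)):
            raise ValidationError("intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


@dataclass
class Movie:
    """A time-lapse movie with axis order (T, Y, X). Default 4 Hz sampling."""

    frames: np.ndarray
    frame_rate_hz: float = FRAME_RATE_HZ
    pixel_size_um: float = PIXEL_SIZE_100X_UM
    dtype_max: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValidationError(f"Movie needs a (T, Y, X) array, got {self.frames.ndim}D")
        if self.frames.shape[0] < 2:
            raise ValidationError("a movie needs at least two frames")
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")
        if np.any(self.frames < 0) or not np.all(np.isfinite(self.frames)):
            raise ValidationError("intensities must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.frames.shape[0] / self.frame_rate_hz


GROUP_ROW = "__group__"


@dataclass
class CountMatrix:
    """Gene × sample count matrix with group labels and housekeeping genes.

    ``counts`` is a DataFrame indexed by gene id with one column per sample.
    ``group_of_sample`` maps each sample label to its group (e.g. CTRL/MUT).
    """

    counts: pd.DataFrame
    group_of_sample: dict[str, str]
    housekeeping_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = [g for g in self.housekeeping_ids if g not in self.counts.index]
        if missing:
            raise ValidationError(f"housekeeping genes missing from matrix: {missing}")
        unknown = [s for s in self.group_of_sample if s not in self.counts.columns]
        if unknown:
            raise ValidationError(f"group labels for unknown samples: {unknown}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_labels(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_labels if self.group_of_sample.get(s) == group]

    def subset_group(self, group: str) -> "CountMatrix":
        cols = self.samples_in_group(group)
        return CountMatrix(
            counts=self.counts[cols].copy(),
            group_of_sample={s: group for s in cols},
            housekeeping_ids=list(self.housekeeping_ids),
        )


@dataclass
class CtTable:
    """Long-form qPCR Ct table: rows of (sample_label, gene_id, ct_value)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_label", "gene_id", "ct_value"}
        if not required.issubset(self.rows.columns):
            raise ValidationError(f"CtTable needs columns {sorted(required)}")
        if not np.all(np.isfinite(self.rows["ct_value"].to_numpy(dtype=float))):
            raise ValidationError("ct_value must be finite")

    def ct(self, sample: str, gene: str) -> float:
        sel = self.rows[(self.rows.sample_label == sample) & (self.rows.gene_id == gene)]
        if sel.empty:
            raise KeyError(f"no Ct for sample={sample!r}, gene={gene!r}")
        return float(sel.ct_value.iloc[0])


# ---------------------------------------------------------------------------
# image I/O


def _sidecar_calibration(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"calibration sidecar {sidecar} must be a mapping")
        return data
    return {}


def read_image(
    path: str | Path,
    *,
    kind: str = "auto",
    pixel_size_um: float | None = None,
    voxel_size_um: Sequence[float] | None = None,
    frame_rate_hz: float | None = None,
) -> Image2D | ImageStack3D | Movie:
    """Read a TIFF (single page, multi-page stack, or time series).

    ``kind`` is one of ``auto``, ``image``, ``stack``, ``movie``. With
    ``auto``, a 2D array becomes an :class:`Image2D`; a 3D array becomes a
    :class:`Movie` when a frame rate is available (argument or sidecar) and
    an :class:`ImageStack3D` otherwise. Calibration from a YAML sidecar
    (``<image>.yaml``) is overridden by explicit arguments.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc

    side = _sidecar_calibration(path)
    pixel_size_um = pixel_size_um if pixel_size_um is not None else side.get("pixel_size_um")
    voxel_size_um = voxel_size_um if voxel_size_um is not None else side.get("voxel_size_um")
    frame_rate_hz = frame_rate_hz if frame_rate_hz is not None else side.get("frame_rate_hz")
    for name, val in (("pixel_size_um", pixel_size_um), ("frame_rate_hz", frame_rate_hz)):
        if val is not None and val <= 0:
            raise ValidationError(f"{name} must be positive, got {val}")
    if voxel_size_um is not None and any(v <= 0 for v in voxel_size_um):
        raise ValidationError("voxel sizes must be positive")

    data, dmax = _as_normalized_float(arr)
    if arr.ndim == 2:
        if kind not in ("auto", "image"):
            raise ValidationError(f"2D data cannot be read as kind={kind!r}")
        return Image2D(data, pixel_size_um=pixel_size_um or PIXEL_SIZE_100X_UM, dtype_max=dmax)
    if arr.ndim != 3:
        raise ValidationError(f"unsupported TIFF dimensionality: {arr.ndim}")

    if kind == "auto":
        kind = "movie" if frame_rate_hz is not None else "stack"
    if kind == "movie":
        return Movie(
            data,
            frame_rate_hz=frame_rate_hz or FRAME_RATE_HZ,
            pixel_size_um=pixel_size_um or PIXEL_SIZE_100X_UM,
            dtype_max=dmax,
        )
    if kind == "stack":
        if voxel_size_um is None:
            px = pixel_size_um or PIXEL_SIZE_100X_UM
            voxel_size_um = (Z_STEP_UM, px, px)
        return ImageStack3D(data, voxel_size_um=tuple(voxel_size_um), dtype_max=dmax)
    raise ValidationError(f"unknown kind {kind!r}")


def write_image(path: str | Path, obj: Image2D | ImageStack3D | Movie) -> None:
    """Write a container back to TIFF plus a YAML calibration sidecar.

    Integer-origin data (``dtype_max`` set) is rescaled and rounded back to
    the original integer range so read→write round-trips are bit-exact;
    float-origin data is written as float32.
    """
    path = Path(path)
    arr = obj.pixels if isinstance(obj, Image2D) else (
        obj.voxels if isinstance(obj, ImageStack3D) else obj.frames
    )
    if obj.dtype_max is not None:
        dmax = obj.dtype_max
        dtype = np.uint8 if dmax <= 255 else (np.uint16 if dmax <= 65535 else np.uint32)
        out = np.rint(arr * dmax).astype(dtype)
    else:
        out = arr.astype(np.float32)
    tifffile.imwrite(path, out, photometric="minisblack")

    side: dict = {}
    if isinstance(obj, Image2D):
        side["pixel_size_um"] = obj.pixel_size_um
    elif isinstance(obj, ImageStack3D):
        side["voxel_size_um"] = list(obj.voxel_size_um)
    else:
        side["frame_rate_hz"] = obj.frame_rate_hz
        side["pixel_size_um"] = obj.pixel_size_um
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(side, fh)


# ---------------------------------------------------------------------------
# count-matrix and Ct-table I/O


def read_counts(
    path: str | Path,
    housekeeping_ids: Sequence[str],
    groups: str | Path | Mapping[str, str] | None = None,
) -> CountMatrix:
    """Read a gene × sample CSV into a :class:`CountMatrix`.

    The CSV has gene ids in the first column and one column per sample. Group
    labels come either from a row with id ``__group__`` inside the CSV or
    from ``groups`` (a mapping, or the path of a two-column sample,group CSV).
    """
    df = pd.read_csv(path, index_col=0)
    group_map: dict[str, str] = {}
    if GROUP_ROW in df.index:
        group_map = {s: str(v) for s, v in df.loc[GROUP_ROW].items()}
        df = df.drop(index=GROUP_ROW)
    if isinstance(groups, (str, Path)):
        gdf = pd.read_csv(groups)
        group_map = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    elif isinstance(groups, Mapping):
        group_map = dict(groups)
    return CountMatrix(
        counts=df.astype(float),
        group_of_sample=group_map,
        housekeeping_ids=list(housekeeping_ids),
    )


def write_counts(path: str | Path, cm: CountMatrix) -> None:
    """Write a CountMatrix to CSV with an embedded ``__group__`` row."""
    df = cm.counts.copy()
    if cm.group_of_sample:
        grp = pd.DataFrame(
            [[cm.group_of_sample.get(s, "") for s in df.columns]],
            index=[GROUP_ROW],
            columns=df.columns,
        )
        df = pd.concat([grp, df])
    df.to_csv(path)


def read_ct_table(path: str | Path) -> CtTable:
    return CtTable(pd.read_csv(path))


def write_ct_table(path: str | Path, table: CtTable) -> None:
    table.rows.to_csv(path, index=False)


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# structured stage logging


@contextlib.contextmanager
def log_stage(stage: str, **params) -> Iterator[dict]:
    """Log one structured record per pipeline stage.

    Yields a dict the stage may fill with an output summary; on exit a single
    record with stage name, parameters, elapsed seconds and the summary is
    emitted at INFO level.
    """
    summary: dict = {}
    t0 = time.perf_counter()
    try:
        yield summary
    finally:
        elapsed = time.perf_counter() - t0
        logger.info(
            "stage=%s elapsed_s=%.3f params=%s summary=%s",
            stage,
            elapsed,
            json.dumps(params, default=_json_default),
            json.dumps(summary, default=_json_default),
        )
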