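"""Reading and writing segmentation rasters and parameter tables.

A measurement input is a triple of binary masks (artery, vein, optic
disc) on a common pixel grid plus the physical pixel spacing. Masks may
arrive as three single-channel rasters or as one RGB composite with the
conventional coloring (arteries red, veins blue, disc yellow).

Measurement output is one :class:`MorphometryRecord` per eye, written as
CSV with a fixed column order; missing values are blank cells.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SegmentationMap",
    "MorphometryRecord",
    "RECORD_FIELDS",
    "read_segmentation",
    "write_segmentation",
    "write_records_csv",
    "read_records_csv",
    "validate_quality",
    "DimensionMismatchError",
]

#: Parameter columns of a morphometry record, in canonical CSV order.
RECORD_FIELDS = (
    "avr",
    "crae",
    "crve",
    "d0_a",
    "d1_a",
    "d2_a",
    "sl_a",
    "d0_v",
    "d1_v",
    "d2_v",
    "sl_v",
    "length_avg_a",
    "length_avg_v",
    "curvature_avg_a",
    "curvature_avg_v",
    "angle_avg_a",
    "angle_avg_v",
    "asymmetry_avg_a",
    "asymmetry_avg_v",
    "branch_avg_a",
    "branch_avg_v",
    "vessel_length_density",
    "vessel_density",
)


class DimensionMismatchError(ValueError):
    """Raised when the mask channels do not share one pixel grid."""

    def __init__(self, channel: str, shape, expected):
        self.channel = channel
        super().__init__(
            f"channel '{channel}' has shape {shape}, expected {expected}"
        )


@dataclass
class SegmentationMap:
    """Artery/vein/disc binary masks on one pixel grid with calibration."""

    artery_mask: np.ndarray
    vein_mask: np.ndarray
    disc_mask: np.ndarray
    pixel_spacing: float  # µm per pixel
    source_id: str = ""

    def __post_init__(self) -> None:
        self.artery_mask = np.asarray(self.artery_mask, dtype=bool)
        shape = self.artery_mask.shape
        for name in ("vein_mask", "disc_mask"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.shape != shape:
                raise DimensionMismatchError(name.replace("_mask", ""), arr.shape, shape)
            setattr(self, name, arr)
        if not (self.pixel_spacing > 0):
            raise ValueError("pixel_spacing must be positive")
        self.pixel_spacing = float(self.pixel_spacing)

    @property
    def height(self) -> int:
        return self.artery_mask.shape[0]

    @property
    def width(self) -> int:
        return self.artery_mask.shape[1]

    @property
    def vessel_mask(self) -> np.ndarray:
        """Union of artery and vein foreground."""
        return self.artery_mask | self.vein_mask


@dataclass
class MorphometryRecord:
    """Per-eye parameter vector; ``None`` marks a value left blank."""

    source_id: str = ""
    avr: Optional[float] = None
    crae: Optional[float] = None
    crve: Optional[float] = None
    d0_a: Optional[float] = None
    d1_a: Optional[float] = None
    d2_a: Optional[float] = None
    sl_a: Optional[float] = None
    d0_v: Optional[float] = None
    d1_v: Optional[float] = None
    d2_v: Optional[float] = None
    sl_v: Optional[float] = None
    length_avg_a: Optional[float] = None
    length_avg_v: Optional[float] = None
    curvature_avg_a: Optional[float] = None
    curvature_avg_v: Optional[float] = None
    angle_avg_a: Optional[float] = None
    angle_avg_v: Optional[float] = None
    asymmetry_avg_a: Optional[float] = None
    asymmetry_avg_v: Optional[float] = None
    branch_avg_a: Optional[float] = None
    branch_avg_v: Optional[float] = None
    vessel_length_density: Optional[float] = None
    vessel_density: Optional[float] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def ok(v):  # treat None/NaN as missing
            return v is not None and not (isinstance(v, float) and math.isnan(v))

        for name in ("vessel_length_density", "vessel_density"):
            v = getattr(self, name)
            if ok(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("curvature_avg_a", "curvature_avg_v"):
            v = getattr(self, name)
            if ok(v) and v < 1.0 - 1e-9:
                raise ValueError(f"{name}={v} below 1 (arc/chord ratio)")
        for name in ("angle_avg_a", "angle_avg_v"):
            v = getattr(self, name)
            if ok(v) and not (0.0 < v < 180.0):
                raise ValueError(f"{name}={v} outside (0, 180) degrees")
        for name in ("branch_avg_a", "branch_avg_v"):
            v = getattr(self, name)
            if ok(v) and v < 0:
                raise ValueError(f"{name}={v} negative")
        if ok(self.avr) and ok(self.crae) and ok(self.crve):
            if abs(self.avr - self.crae / self.crve) > 1e-6 * max(1.0, self.avr):
                raise ValueError("avr inconsistent with crae/crve")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_raster(path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot decode raster {path}: {exc}") from exc


def _rgb_split(rgb: np.ndarray, tolerance: int) -> tuple:
    """Split an RGB composite into artery/vein/disc masks.

    Pure-color convention: red -> artery, blue -> vein, yellow -> disc.
    A pixel belongs to a class when its Chebyshev distance to the pure
    color is at most ``tolerance``.
    """
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("RGB dialect requires a 3-channel raster")
    rgb = rgb[..., :3].astype(np.int16)
    targets = {
        "artery": (255, 0, 0),
        "vein": (0, 0, 255),
        "disc": (255, 255, 0),
    }
    masks = {}
    for name, color in targets.items():
        dist = np.max(np.abs(rgb - np.asarray(color)), axis=-1)
        masks[name] = dist <= tolerance
    return masks["artery"], masks["vein"], masks["disc"]


def read_segmentation(
    paths_or_multichannel: Union[Sequence, str, Path],
    pixel_spacing: float,
    rgb_tolerance: int = 100,
    source_id: Optional[str] = None,
) -> SegmentationMap:
    """Load a segmentation map from rasters on disk.

    Parameters
    ----------
    paths_or_multichannel:
        Either a sequence of three single-channel raster paths in the
        order (artery, vein, disc) — any nonzero value is foreground —
        or a single path to an RGB composite (red=artery, blue=vein,
        yellow=disc).
    pixel_spacing:
        Pixel size in µm.
    """
    if isinstance(paths_or_multichannel, (str, Path)):
        rgb = _load_raster(paths_or_multichannel)
        artery, vein, disc = _rgb_split(rgb, rgb_tolerance)
        sid = source_id or Path(paths_or_multichannel).stem
    else:
        paths = list(paths_or_multichannel)
        if len(paths) != 3:
            raise ValueError("expected three channel paths (artery, vein, disc)")
        channels = []
        shapes = {}
        for name, p in zip(("artery", "vein", "disc"), paths):
            arr = _load_raster(p)
            if arr.ndim == 3:  # collapse any color content to intensity
                arr = arr[..., :3].max(axis=-1)
            shapes[name] = arr.shape
            channels.append(arr != 0)
        ref = channels[0].shape
        for name, ch in zip(("artery", "vein", "disc"), channels):
            if ch.shape != ref:
                raise DimensionMismatchError(name, shapes[name], ref)
        artery, vein, disc = channels
        sid = source_id or Path(paths[0]).stem
    return SegmentationMap(artery, vein, disc, pixel_spacing, source_id=sid)


def write_segmentation(segmap: SegmentationMap, directory, prefix: str = "") -> List[Path]:
    """Write the three masks as 8-bit PNGs; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name, mask in (
        ("artery", segmap.artery_mask),
        ("vein", segmap.vein_mask),
        ("disc", segmap.disc_mask),
    ):
        path = directory / f"{prefix}{name}.png"
        Image.fromarray((mask.astype(np.uint8)) * 255).save(path)
        out.append(path)
    return out


def records_to_frame(records: Sequence[MorphometryRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        d = rec.to_dict()
        rows.append({"source_id": d["source_id"], **{k: d[k] for k in RECORD_FIELDS}})
    return pd.DataFrame(rows, columns=("source_id",) + RECORD_FIELDS)


def write_records_csv(records: Sequence[MorphometryRecord], path) -> Path:
    """Write records as CSV; column order fixed, missing cells blank."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    frame = records_to_frame(records)
    path = Path(path)
    # shortest-round-trip float rendering: a read-back reproduces every
    # numeric cell bit-exactly
    frame.to_csv(path, index=False, na_rep="", float_format=lambda v: repr(float(v)))
    return path


def read_records_csv(path) -> List[MorphometryRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(("source_id",) + RECORD_FIELDS) - set(frame.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        kwargs = {"source_id": "" if pd.isna(row["source_id"]) else str(row["source_id"])}
        for name in RECORD_FIELDS:
            v = row[name]
            kwargs[name] = None if pd.isna(v) else float(v)
        out.append(MorphometryRecord(**kwargs))
    return out


def validate_quality(
    segmap: SegmentationMap, min_vessel_fraction: float = 0.01
) -> List[str]:
    """Advisory quality checks; returns human-readable warnings.

    Mirrors the acquisition requirement that the large majority of the
    vasculature be identifiable: an empty or border-clipped disc, or a
    suspiciously sparse vessel mask, usually signals a bad segmentation.
    """
    warnings = []
    disc = segmap.disc_mask
    if not disc.any():
        warnings.append("no optic disc: disc mask is empty")
    else:
        if (
            disc[0, :].any()
            or disc[-1, :].any()
            or disc[:, 0].any()
            or disc[:, -1].any()
        ):
            warnings.append("optic disc touches the image border")
    frac = segmap.vessel_mask.mean()
    if frac < min_vessel_fraction:
        warnings.append(
            f"vessel foreground fraction {frac:.4f} below floor {min_vessel_fraction}"
        )
    return warnings
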