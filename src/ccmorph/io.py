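"""Calibrated image and study-table I/O.

Corneal confocal microscopy (CCM) frames are small 8-bit grayscale rasters
covering a fixed physical field of the sub-basal nerve plexus.  Everything
downstream is reported per mm² of corneal surface, so the calibration —
µm per pixel edge and the field size in pixels — travels with every image
and every derived quantity.

The default geometry follows the HRT III convention: 384 × 384 px over a
400 × 400 µm field (pixel pitch 400/384 ≈ 1.042 µm).  The device manual is
the source of the convention; the geometry is configurable throughout.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "Calibration",
    "CCMImage",
    "CCMVariables",
    "SubjectRecord",
    "CalibrationMismatchError",
    "DEFAULT_CALIBRATION",
    "VARIABLE_NAMES",
    "load_image",
    "save_mask_png",
    "read_subject_table",
    "aggregate_subject",
]


class CalibrationMismatchError(ValueError):
    """Raster shape does not match the calibration's field dimensions."""


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a CCM frame.

    Parameters
    ----------
    pixel_pitch_um
        Edge length of one pixel in µm. Must be positive.
    field_width_px, field_height_px
        Field size in pixels.
    """

    pixel_pitch_um: float = 400.0 / 384.0
    field_width_px: int = 384
    field_height_px: int = 384

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be > 0")
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ValueError("field dimensions must be > 0")

    @property
    def field_area_mm2(self) -> float:
        """Imaged corneal surface area in mm²."""
        w_um = self.field_width_px * self.pixel_pitch_um
        h_um = self.field_height_px * self.pixel_pitch_um
        return (w_um * h_um) / 1e6

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_pitch_um**2

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) = (height, width)."""
        return (self.field_height_px, self.field_width_px)


DEFAULT_CALIBRATION = Calibration()


@dataclass
class CCMImage:
    """A calibrated grayscale CCM frame.

    ``intensities`` is a 2-D uint8 array, row-major, origin top-left.
    """

    intensities: np.ndarray
    calibration: Calibration = DEFAULT_CALIBRATION
    subject_id: str = ""
    eye: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2:
            raise ValueError("intensities must be a 2-D array")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensity values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        if arr.shape != self.calibration.shape:
            raise CalibrationMismatchError(
                f"image shape {arr.shape} != calibration field "
                f"{self.calibration.shape}"
            )
        self.intensities = arr


#: Canonical order of the five morphometric endpoints plus mean bundle width.
VARIABLE_NAMES = ("nfd", "nbd", "nfl", "nfa_wxl", "nfa_fiji", "mean_width_um")


@dataclass
class CCMVariables:
    """Per-image (or per-subject averaged) CCM endpoints.

    nfd
        Main nerve fiber (bundle) density, fibers/mm².
    nbd
        Branch density, branches/mm².
    nfl
        Nerve fiber length, mm of skeleton per mm².
    nfa_wxl
        Nerve fiber area as width integrated along the skeleton, µm²/mm².
    nfa_fiji
        Nerve fiber area as segmented-mask pixel area, µm²/mm².
    mean_width_um
        Length-weighted mean bundle width, µm (= nfa_wxl / (1000 · nfl)).
    """

    nfd: float = 0.0
    nbd: float = 0.0
    nfl: float = 0.0
    nfa_wxl: float = 0.0
    nfa_fiji: float = 0.0
    mean_width_um: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "CCMVariables":
        return cls(**{k: float(m[k]) for k in VARIABLE_NAMES if k in m})


@dataclass
class SubjectRecord:
    """One study row: a subject (or subject/eye/visit cell) and its endpoints."""

    subject_id: str
    group_label: str
    variables: CCMVariables
    nds: int | None = None
    eye: str = ""
    visit: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.group_label:
            raise ValueError("group_label must be non-empty")
        if self.nds is not None and not (0 <= self.nds <= 10):
            raise ValueError("nds must be within 0–10 when present")


def load_image(path: str | Path, calibration: Calibration = DEFAULT_CALIBRATION,
               *, subject_id: str = "", eye: str = "", visit: str = "") -> CCMImage:
    """Read a grayscale TIFF/PNG/BMP raster and attach the calibration.

    Raises
    ------
    OSError
        If the file is missing or not a decodable raster.
    CalibrationMismatchError
        If the raster shape differs from the calibration's field dimensions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse an RGB(A) encoding of a gray image
        arr = arr[..., :3].mean(axis=-1).round().astype(np.uint8)
    return CCMImage(np.asarray(arr, dtype=np.uint8), calibration,
                    subject_id=subject_id, eye=eye, visit=visit)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground = 255)."""
    out = np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), out)


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read a study table CSV.

    Expected columns: ``subject_id, group`` and optionally
    ``nds, eye, visit, image_path`` or per-variable value columns.
    """
    df = pd.read_csv(path)
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    return df


def _mean_variables(items: Sequence[CCMVariables]) -> CCMVariables:
    vals = {k: float(np.mean([getattr(v, k) for v in items]))
            for k in VARIABLE_NAMES}
    return CCMVariables(**vals)


def aggregate_subject(
    records: Iterable[tuple[str, CCMVariables]],
    mode: str = "both_eyes",
) -> tuple[CCMVariables, list[str]]:
    """Average per-image endpoints into one per-subject row.

    Parameters
    ----------
    records
        Iterable of ``(eye_label, CCMVariables)`` for a single subject; in
        ``single_eye`` mode eye labels are ignored.
    mode
        ``"single_eye"`` — arithmetic mean over all images (also the
        "pooled" sensitivity variant for two-eye data);
        ``"both_eyes"`` — mean over images within each eye, then mean of
        the eye-means. With only one eye present the available eye's mean
        is returned and flagged.

    Returns
    -------
    (variables, flags)
        The averaged endpoints and a list of warnings (e.g. ``missing_eye``).
    """
    recs = list(records)
    if not recs:
        raise ValueError("no records to aggregate")
    if mode not in ("single_eye", "both_eyes", "pooled"):
        raise ValueError(f"unknown aggregation mode {mode!r}")

    flags: list[str] = []
    if mode in ("single_eye", "pooled"):
        return _mean_variables([v for _, v in recs]), flags

    by_eye: dict[str, list[CCMVariables]] = {}
    for eye, v in recs:
        by_eye.setdefault(eye, []).append(v)
    eye_means = [_mean_variables(vs) for vs in by_eye.values()]
    if len(eye_means) == 1:
        flags.append("missing_eye")
    return _mean_variables(eye_means), flags
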