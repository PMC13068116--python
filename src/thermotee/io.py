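"""Reading and writing thermal frames, label masks, metadata and result reports.

Thermal frames are per-pixel absolute surface temperature matrices in degrees
Celsius, as produced by a radiometric long-wave infrared camera operated in
T-linear mode (pixel values map affinely to absolute temperature).  Two on-disk
dialects are supported:

``csv_celsius``
    H rows of W comma-separated floats, one value per pixel, in deg C, no header.
``tiff_centikelvin``
    Single-page 16-bit grayscale TIFF holding unsigned centi-kelvin counts
    ``v``; temperature is recovered as ``v * 0.01 - 273.15`` deg C.

An optional sidecar file ``<frame>.meta`` of ``key=value`` lines carries
acquisition metadata (``ambient_c``, ``frame_id``, ``acquired_at``).

Label masks are 8-bit single-channel PNGs with class codes
{0=background, 1=patient, 2=tube, 3=screen}.  Result reports are CSV or XLSX
tables with a fixed column set (see :func:`write_report`).

Temperatures are kept in deg C throughout I/O; the conversion to kelvin happens
only inside the radiative-physics layer.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy import ndimage

__all__ = [
    "ThermalFrame",
    "PatientRecord",
    "LabelMask",
    "EnergyReport",
    "BACKGROUND",
    "PATIENT",
    "TUBE",
    "SCREEN",
    "CLASS_NAMES",
    "REPORT_COLUMNS",
    "read_frame",
    "write_frame",
    "read_mask",
    "write_mask",
    "write_report",
    "read_report",
    "reports_to_frame",
]

# Label codes shared by every stage of the pipeline.
BACKGROUND, PATIENT, TUBE, SCREEN = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", PATIENT: "patient", TUBE: "tube", SCREEN: "screen"}

#: Sensor-plausibility bound for any stored temperature, deg C.
TEMP_MIN_C, TEMP_MAX_C = -40.0, 120.0

#: Maximum tolerated fraction of NaN (dead-pixel) entries in a frame.
MAX_NAN_FRACTION = 0.10

REPORT_COLUMNS = [
    "frame_id",
    "age_years",
    "sex",
    "weight_kg",
    "mean_skin_c",
    "radiative_power_area",
    "radiative_power_total",
    "bsa_m2",
    "tee_area",
    "tee_total",
    "expected_tee_area",
    "deviation_pct",
    "zone",
]


class FrameValidationError(ValueError):
    """A frame violates a structural or physical invariant."""


class FrameParseError(ValueError):
    """A frame file cannot be parsed under the requested dialect."""


class MaskValidationError(ValueError):
    """A label mask contains out-of-set values or has a bad shape."""


@dataclasses.dataclass
class ThermalFrame:
    """A radiometric thermal frame: per-pixel temperature in deg C plus metadata.

    Parameters
    ----------
    temps
        ``(H, W)`` float array of absolute surface temperatures in deg C.
        The native sensor resolution is 120 rows by 160 columns, but any
        ``H >= 8`` and ``W >= 8`` is accepted.  NaN entries mark dead pixels
        and must stay below 10% of the frame.
    ambient_c
        Room temperature in deg C, if the acquisition recorded one.
    frame_id
        Opaque identifier, carried through to reports.
    acquired_at
        Optional ISO-8601 timestamp string.
    """

    temps: np.ndarray
    ambient_c: float | None = None
    frame_id: str = ""
    acquired_at: str | None = None

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        if self.temps.ndim != 2:
            raise FrameValidationError(f"temps must be 2-D, got ndim={self.temps.ndim}")
        h, w = self.temps.shape
        if h < 8 or w < 8:
            raise FrameValidationError(f"frame too small: {h}x{w}, need at least 8x8")
        nan_frac = float(np.isnan(self.temps).mean())
        if nan_frac >= MAX_NAN_FRACTION:
            raise FrameValidationError(
                f"dead-pixel fraction {nan_frac:.3f} exceeds {MAX_NAN_FRACTION:.0%}"
            )
        finite = self.temps[np.isfinite(self.temps)]
        if finite.size:
            bad = (finite < TEMP_MIN_C) | (finite > TEMP_MAX_C)
            if bad.any():
                rows, cols = np.where(
                    np.nan_to_num(self.temps, nan=20.0) != np.clip(
                        np.nan_to_num(self.temps, nan=20.0), TEMP_MIN_C, TEMP_MAX_C
                    )
                )
                raise FrameValidationError(
                    f"temperature out of [{TEMP_MIN_C}, {TEMP_MAX_C}] deg C at "
                    f"pixel (row={rows[0]}, col={cols[0]}): {self.temps[rows[0], cols[0]]:.2f}"
                )
        if not np.isfinite(self.temps).any():
            raise FrameValidationError("frame has no finite pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.temps.shape  # type: ignore[return-value]

    def filled(self) -> "ThermalFrame":
        """Return a copy with NaN dead pixels replaced by the 3x3 median of
        finite neighbours (applied before any downstream physics)."""
        if not np.isnan(self.temps).any():
            return self
        t = self.temps.copy()
        nan = np.isnan(t)
        med = ndimage.generic_filter(
            np.where(nan, np.nan, t), np.nanmedian, size=3, mode="mirror"
        )
        t[nan] = med[nan]
        # isolated NaN islands larger than the window: fall back to global median
        still = np.isnan(t)
        if still.any():
            t[still] = np.nanmedian(self.temps)
        return dataclasses.replace(self, temps=t)

    def border_ambient(self) -> float:
        """Median temperature of the 1-pixel border ring.

        Used as the ambient-temperature fallback when the acquisition carries
        no ambient channel; the border of a bedside frame is background-
        dominated.
        """
        t = self.temps
        ring = np.concatenate([t[0, :], t[-1, :], t[1:-1, 0], t[1:-1, -1]])
        return float(np.nanmedian(ring))

    def ambient_or_fallback(self) -> tuple[float, bool]:
        """Return ``(ambient_c, used_fallback)``."""
        if self.ambient_c is not None:
            return float(self.ambient_c), False
        return self.border_ambient(), True


@dataclasses.dataclass
class PatientRecord:
    """Per-patient metadata required to turn radiative power into TEE."""

    weight_kg: float
    age_years: float
    sex: Literal["female", "male", "unspecified"] = "unspecified"

    def __post_init__(self) -> None:
        if not 0 < self.weight_kg <= 150:
            raise ValueError(f"weight_kg={self.weight_kg} outside (0, 150]")
        if not 0 <= self.age_years <= 21:
            raise ValueError(f"age_years={self.age_years} outside [0, 21]")
        if self.sex not in ("female", "male", "unspecified"):
            raise ValueError(f"sex={self.sex!r} not in {{female, male, unspecified}}")


@dataclasses.dataclass
class LabelMask:
    """Per-pixel semantic labels {0=background, 1=patient, 2=tube, 3=screen}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise MaskValidationError("labels must be 2-D")
        bad = np.setdiff1d(np.unique(self.labels), [BACKGROUND, PATIENT, TUBE, SCREEN])
        if bad.size:
            raise MaskValidationError(f"labels contain out-of-set values {bad.tolist()}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def class_mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclasses.dataclass
class EnergyReport:
    """Product of the pipeline for one frame/patient.

    All ``*_area`` quantities are per square metre of body surface area;
    ``*_total`` quantities are the per-area value scaled by the BSA of Eq.-style
    pediatric weight formula (see :mod:`thermotee.energetics`).
    """

    mean_skin_c: float
    radiative_power_area: float  # W/m^2
    radiative_power_total: float  # W
    bsa_m2: float
    tee_area: float  # kcal/m^2/day
    tee_total: float  # kcal/day
    expected_tee_area: float | None = None
    deviation_pct: float | None = None
    zone: str | None = None
    frame_id: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for total, per_area, name in (
            (self.radiative_power_total, self.radiative_power_area, "radiative_power"),
            (self.tee_total, self.tee_area, "tee"),
        ):
            expect = per_area * self.bsa_m2
            if not math.isclose(total, expect, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    f"{name}_total={total} inconsistent with per-area x BSA = {expect}"
                )


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

Dialect = Literal["csv_celsius", "tiff_centikelvin"]


def _read_sidecar(path: Path) -> dict[str, str]:
    meta = Path(str(path) + ".meta")
    out: dict[str, str] = {}
    if meta.exists():
        for line in meta.read_text().splitlines():
            line = line.strip()
            if line and "=" in line:
                k, v = line.split("=", 1)
                out[k.strip()] = v.strip()
    return out


def read_frame(path: str | Path, dialect: Dialect = "csv_celsius") -> ThermalFrame:
    """Load a thermal frame from disk.

    Raises
    ------
    FrameParseError
        Ragged CSV rows (the offending row is named) or an unreadable TIFF.
    FrameValidationError
        Temperatures outside the sensor-plausibility bound (the offending
        pixel coordinate is named) or a structurally invalid frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv_celsius":
        rows: list[list[float]] = []
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.reader(fh)):
                if not row:
                    continue
                try:
                    rows.append([float(x) for x in row])
                except ValueError as exc:
                    raise FrameParseError(f"row {i}: non-numeric cell ({exc})") from exc
                if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                    raise FrameParseError(
                        f"row {i}: ragged grid ({len(rows[-1])} cells, expected {len(rows[0])})"
                    )
        if not rows:
            raise FrameParseError("empty CSV frame")
        temps = np.asarray(rows, dtype=float)
    elif dialect == "tiff_centikelvin":
        raw = tifffile.imread(path)
        if raw.ndim != 2:
            raise FrameParseError(f"expected single-page grayscale TIFF, got shape {raw.shape}")
        temps = raw.astype(np.float64) * 0.01 - 273.15
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    meta = _read_sidecar(path)
    ambient = float(meta["ambient_c"]) if "ambient_c" in meta else None
    return ThermalFrame(
        temps=temps,
        ambient_c=ambient,
        frame_id=meta.get("frame_id", path.stem),
        acquired_at=meta.get("acquired_at"),
    )


def write_frame(frame: ThermalFrame, path: str | Path, dialect: Dialect = "csv_celsius") -> Path:
    """Write a frame in the given dialect plus a ``.meta`` sidecar.

    The centi-kelvin dialect quantizes to the sensor's 0.01 deg C grid; frames
    already on that grid round-trip exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "csv_celsius":
        np.savetxt(path, frame.temps, delimiter=",", fmt="%.6f")
    elif dialect == "tiff_centikelvin":
        counts = np.round((frame.temps + 273.15) * 100.0)
        if np.nanmin(counts) < 0 or np.nanmax(counts) > 65535:
            raise FrameValidationError("temperature outside the 16-bit centi-kelvin range")
        tifffile.imwrite(path, np.nan_to_num(counts).astype(np.uint16))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = []
    if frame.ambient_c is not None:
        lines.append(f"ambient_c={frame.ambient_c}")
    if frame.frame_id:
        lines.append(f"frame_id={frame.frame_id}")
    if frame.acquired_at:
        lines.append(f"acquired_at={frame.acquired_at}")
    if lines:
        Path(str(path) + ".meta").write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def read_mask(path: str | Path) -> LabelMask:
    """Read an 8-bit single-channel PNG label mask (codes {0,1,2,3})."""
    img = Image.open(path)
    if img.mode != "L":
        img = img.convert("L")
    arr = np.asarray(img)
    return LabelMask(labels=arr)


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask.labels, mode="L").save(path, format="PNG")
    return path


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def reports_to_frame(
    reports: Sequence[tuple[EnergyReport, PatientRecord]],
) -> pd.DataFrame:
    """Tabulate (report, patient) pairs with the fixed report column set."""
    rows = []
    for rep, pat in reports:
        rows.append(
            {
                "frame_id": rep.frame_id,
                "age_years": pat.age_years,
                "sex": pat.sex,
                "weight_kg": pat.weight_kg,
                "mean_skin_c": rep.mean_skin_c,
                "radiative_power_area": rep.radiative_power_area,
                "radiative_power_total": rep.radiative_power_total,
                "bsa_m2": rep.bsa_m2,
                "tee_area": rep.tee_area,
                "tee_total": rep.tee_total,
                "expected_tee_area": rep.expected_tee_area,
                "deviation_pct": rep.deviation_pct,
                "zone": rep.zone,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(
    reports: Sequence[tuple[EnergyReport, PatientRecord]],
    path: str | Path,
    format: Literal["csv", "xlsx"] = "csv",
) -> Path:
    """Write one row per patient with the fixed report column set."""
    if not reports:
        raise ValueError("empty report list")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = reports_to_frame(reports)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path: str | Path, format: Literal["csv", "xlsx"] | None = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() == ".xlsx" else "csv"
    if format == "csv":
        return pd.read_csv(path)
    return pd.read_excel(path)
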