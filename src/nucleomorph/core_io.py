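"""Data model, readers/writers, and pixel-to-micron calibration.

Conventions used throughout the package:

* pixel indices are 0-based, ``x`` is the column and ``y`` the row;
* polygons live in continuous pixel coordinates with pixel centers at
  integer positions (a flag on :func:`rasterize` shifts centers to
  ``integer + 0.5`` for data exported under that convention);
* a pixel belongs to a polygon if its center lies strictly inside the
  (cleaned-up) polygon ring.

The default calibration of 0.25 µm/pixel corresponds to a 400x whole-slide
scan; an ROI of 0.1185 mm² (half a standard high-power field, aspect 4:3)
is then 1 896 000 pixels.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.validation import make_valid

__all__ = [
    "Calibration",
    "LabelMask",
    "NucleusPolygon",
    "ROISpec",
    "CaseRecord",
    "read_label_mask",
    "write_label_mask",
    "read_polygons",
    "write_polygons",
    "rasterize",
    "area_um2",
    "read_case_table",
    "write_case_table",
]

#: Causes of death / censoring recognised in outcome tables.
CAUSES = ("tumor_related_death", "unrelated_death", "alive_or_lost")


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration of an image: physical edge length of one pixel."""

    microns_per_pixel: float = 0.25

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be strictly positive")

    @property
    def area_scale(self) -> float:
        """µm² covered by one pixel."""
        return self.microns_per_pixel**2


def area_um2(pixel_count: float, calibration: Calibration) -> float:
    """Convert a pixel count into an area in µm².

    The nuclear area is defined as the number of pixels within the
    segmented nucleus times the squared pixel edge length.
    """
    if pixel_count < 0:
        raise ValueError(f"pixel_count must be >= 0, got {pixel_count}")
    return float(pixel_count) * calibration.area_scale


@dataclass
class LabelMask:
    """An instance label image: 0 = background, k > 0 = nucleus instance k.

    Label ids need not be contiguous but must be unique per instance.
    ``unlabeled`` flags binary masks whose foreground has not yet been
    separated into instances (see :func:`nucleomorph.segmentation.label_components`).
    """

    labels: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)
    unlabeled: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.labels.shape[0] < 1 or self.labels.shape[1] < 1:
            raise ValueError("mask must have positive height and width")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def height(self) -> int:
        return int(self.labels.shape[0])

    @property
    def width(self) -> int:
        return int(self.labels.shape[1])

    @property
    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_instances(self) -> int:
        return int(self.instance_ids.size)

    def instance_areas_um2(self) -> dict[int, float]:
        """Calibrated area of every instance, keyed by label id."""
        ids, counts = np.unique(self.labels, return_counts=True)
        keep = ids > 0
        return {
            int(i): area_um2(int(c), self.calibration)
            for i, c in zip(ids[keep], counts[keep])
        }


@dataclass
class NucleusPolygon:
    """A closed polygon outline of one nucleus, in pixel coordinates."""

    vertices: np.ndarray
    id: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        # drop an explicitly repeated closing vertex
        if v.shape[0] > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("a polygon needs at least 3 distinct vertices")
        self.vertices = v

    def to_shapely(self) -> ShapelyPolygon:
        """Cleaned-up shapely ring (self-intersections resolved)."""
        poly = ShapelyPolygon(self.vertices)
        if not poly.is_valid:
            poly = make_valid(poly)
        return poly


@dataclass(frozen=True)
class ROISpec:
    """Geometry of a region of interest cropped from a whole-slide image."""

    area_mm2: float = 0.1185
    aspect_ratio: float = 4.0 / 3.0

    def __post_init__(self) -> None:
        if not self.area_mm2 > 0:
            raise ValueError("area_mm2 must be positive")

    def shape_px(self, calibration: Calibration) -> tuple[int, int]:
        """(height, width) in pixels of an ROI with this area and aspect."""
        area_px = self.area_mm2 * 1e6 / calibration.area_scale
        height = math.sqrt(area_px / self.aspect_ratio)
        width = self.aspect_ratio * height
        return int(round(height)), int(round(width))


@dataclass
class CaseRecord:
    """One tumor case: per-ROI morphometry plus outcome and benchmarks.

    ``roi_measurements`` holds one parameter dict per ROI (3-5 per case in
    the study design), in the order the ROIs were selected.  ``cause`` is
    one of ``tumor_related_death``, ``unrelated_death`` or ``alive_or_lost``.
    """

    case_id: str
    roi_measurements: list[dict[str, float]]
    survival_time_months: float
    cause: str
    followup_months: float | None = None
    mc: int | None = None
    grade: str | None = None
    estimates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cause not in CAUSES:
            raise ValueError(f"cause must be one of {CAUSES}, got {self.cause!r}")
        if self.survival_time_months < 0:
            raise ValueError("survival_time_months must be >= 0")
        if self.followup_months is None:
            self.followup_months = self.survival_time_months

    def roi_values(self, parameter: str) -> list[float]:
        """Per-ROI values of one parameter, in ROI-selection order."""
        return [float(m[parameter]) for m in self.roi_measurements]

    def case_value(self, parameter: str) -> float:
        """Unweighted mean of one parameter across the case's ROIs."""
        return float(np.mean(self.roi_values(parameter)))


# ---------------------------------------------------------------------------
# mask I/O


def read_label_mask(path: str | Path, calibration: Calibration | None = None) -> LabelMask:
    """Read an 8/16-bit single-channel PNG or TIFF instance/binary mask.

    Binary inputs (values in {0, v}) are flagged ``unlabeled``: their
    foreground still has to be separated into instances.
    """
    calibration = calibration or Calibration()
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel mask, got shape {arr.shape}"
        )
    arr = arr.astype(np.int64)
    nonzero = np.unique(arr[arr > 0])
    unlabeled = nonzero.size == 1 and np.count_nonzero(arr) > 1
    return LabelMask(arr, calibration, unlabeled=unlabeled)


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as 16-bit PNG or TIFF (by extension)."""
    path = Path(path)
    if mask.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances; use TIFF int32 export")
    arr = mask.labels.astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# polygon I/O

def read_polygons(path: str | Path) -> list[NucleusPolygon]:
    """Read nucleus polygons from JSON.

    The dialect is a top-level list of objects
    ``{"id": int, "label": str, "points": [[x, y], ...]}`` with points in
    pixel coordinates.  Record order and ids are preserved.  A record with
    fewer than 3 vertices raises an error naming the record index.
    """
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError("polygon JSON must be a top-level list of records")
    out: list[NucleusPolygon] = []
    for i, rec in enumerate(data):
        try:
            pts = rec["points"]
        except (TypeError, KeyError) as exc:
            raise ValueError(f"record {i}: missing 'points'") from exc
        try:
            poly = NucleusPolygon(
                np.asarray(pts, dtype=float),
                id=rec.get("id", i),
                label=rec.get("label"),
            )
        except ValueError as exc:
            raise ValueError(f"record {i}: {exc}") from exc
        out.append(poly)
    return out


def write_polygons(polygons: Iterable[NucleusPolygon], path: str | Path) -> None:
    records = [
        {
            "id": int(p.id) if p.id is not None else i,
            "label": p.label or "nucleus",
            "points": np.asarray(p.vertices, dtype=float).tolist(),
        }
        for i, p in enumerate(polygons)
    ]
    with open(path, "w") as fh:
        json.dump(records, fh)


def rasterize(
    polygons: Sequence[NucleusPolygon],
    width: int,
    height: int,
    calibration: Calibration | None = None,
    *,
    half_pixel_centers: bool = False,
) -> LabelMask:
    """Paint polygons into a label mask, one unique label per polygon.

    A pixel is painted when its center lies strictly inside the polygon
    (even-odd interior after validity cleanup).  Later polygons overwrite
    earlier ones where they overlap.  Polygons that cover no pixel center
    after clipping to the image bounds are skipped with a warning.
    """
    calibration = calibration or Calibration()
    labels = np.zeros((height, width), dtype=np.int32)
    offset = 0.5 if half_pixel_centers else 0.0
    for k, poly in enumerate(polygons, start=1):
        geom = poly.to_shapely()
        minx, miny, maxx, maxy = geom.bounds
        x0 = max(0, math.floor(minx - offset))
        x1 = min(width - 1, math.ceil(maxx - offset))
        y0 = max(0, math.floor(miny - offset))
        y1 = min(height - 1, math.ceil(maxy - offset))
        if x1 < x0 or y1 < y0:
            warnings.warn(f"polygon {k} lies outside the image bounds; skipped")
            continue
        xs = np.arange(x0, x1 + 1) + offset
        ys = np.arange(y0, y1 + 1) + offset
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)
        if not inside.any():
            warnings.warn(f"polygon {k} covers no pixel center; skipped")
            continue
        sub = labels[y0 : y1 + 1, x0 : x1 + 1]
        sub[inside] = k
    return LabelMask(labels, calibration)


# ---------------------------------------------------------------------------
# case tables

_CASE_COLUMNS = ["case_id", "roi_id", "survival_time_months", "cause", "followup_months"]


def write_case_table(cases: Sequence[CaseRecord], path: str | Path) -> None:
    """Write cases as a flat CSV: one row per ROI, case columns repeated."""
    rows = []
    for case in cases:
        for roi_idx, meas in enumerate(case.roi_measurements):
            row: dict[str, object] = {
                "case_id": case.case_id,
                "roi_id": roi_idx,
                "survival_time_months": case.survival_time_months,
                "cause": case.cause,
                "followup_months": case.followup_months,
            }
            if case.mc is not None:
                row["mc"] = case.mc
            if case.grade is not None:
                row["grade"] = case.grade
            for key, val in case.estimates.items():
                row[f"estimate_{key}"] = val
            row.update(meas)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_case_table(path: str | Path) -> list[CaseRecord]:
    """Read the flat per-ROI CSV written by :func:`write_case_table`."""
    df = pd.read_csv(path)
    missing = [c for c in _CASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"case table missing columns: {missing}")
    param_cols = [
        c
        for c in df.columns
        if c not in _CASE_COLUMNS
        and c not in {"mc", "grade"}
        and not c.startswith("estimate_")
    ]
    cases = []
    for case_id, grp in df.groupby("case_id", sort=False):
        grp = grp.sort_values("roi_id")
        first = grp.iloc[0]
        mc = first.get("mc")
        grade = first.get("grade")
        estimates = {
            c[len("estimate_") :]: first[c]
            for c in df.columns
            if c.startswith("estimate_") and pd.notna(first[c])
        }
        cases.append(
            CaseRecord(
                case_id=str(case_id),
                roi_measurements=[
                    {c: float(row[c]) for c in param_cols if pd.notna(row[c])}
                    for _, row in grp.iterrows()
                ],
                survival_time_months=float(first["survival_time_months"]),
                cause=str(first["cause"]),
                followup_months=float(first["followup_months"]),
                mc=None if pd.isna(mc) else int(mc),
                grade=None if (grade is None or pd.isna(grade)) else str(grade),
                estimates=estimates,
            )
        )
    return cases
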