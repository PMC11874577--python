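"""Per-nucleus shape descriptors and the per-ROI / per-case parameter suite.

Size is quantified by the calibrated nuclear area; shape by eccentricity
(focal distance of the region's moment-equivalent ellipse over its major
axis length: 0 = circular, ->1 = elongated) and solidity (pixel area over
convex-hull area: values below 1 indicate indented, "bizarre" nuclear
contours).  Per ROI, the suite comprises for area: mean, median, SD, 90th
percentile, 90th percentile/median, mean of the largest 10%, percentage of
large (karyomegalic) nuclei above fixed reference sizes, and skewness; for
eccentricity: mean, SD, skewness; for solidity: mean, SD, skewness and the
percentage of indented nuclei below fixed solidity percentile thresholds.

Conventions (the field is not uniform here, so they are fixed and
documented): sample SD (ddof=1, needs n >= 2), linear-interpolation
percentiles, adjusted Fisher-Pearson skewness (needs n >= 3 and SD > 0),
top-10% count = ceil(0.1 n).  Undefined statistics are reported as missing
(None), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from nucleomorph.core_io import Calibration, LabelMask

__all__ = [
    "NucleusFeatures",
    "MorphometryConfig",
    "ROIMorphometry",
    "nucleus_features",
    "mask_features",
    "roi_morphometry",
    "invert_mean_solidity",
    "case_morphometry",
    "parameter_correlations",
]

#: Reference sizes for karyomegalic ("large") nuclei, in µm².  50.3 is twice
#: the median nuclear area of the reference annotation corpus, 37.8 its 90th
#: percentile; both are case-independent on purpose.
LARGE_NUCLEUS_THRESHOLDS_UM2 = (37.8, 50.3)

#: Solidity cutoffs below which a nucleus counts as indented; the 2nd, 5th
#: and 10th percentiles of the reference annotation corpus.
INDENTATION_THRESHOLDS = (0.913, 0.936, 0.943)


@dataclass(frozen=True)
class NucleusFeatures:
    """Descriptors of one segmented nucleus."""

    area: float  # µm²
    eccentricity: float
    solidity: float
    centroid: tuple[float, float]  # (x, y) px
    id: int | None = None


@dataclass(frozen=True)
class MorphometryConfig:
    large_nucleus_thresholds_um2: tuple[float, ...] = LARGE_NUCLEUS_THRESHOLDS_UM2
    indentation_thresholds: tuple[float, ...] = INDENTATION_THRESHOLDS
    top_fraction: float = 0.10

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.large_nucleus_thresholds_um2):
            raise ValueError("large-nucleus thresholds must be positive")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")


@dataclass
class ROIMorphometry:
    """The parameter vector computed over one ROI's nuclei."""

    n_nuclei: int
    area_mean: float
    area_median: float
    area_sd: float | None
    area_p90: float
    area_p90_over_median: float | None
    area_mean_top10: float
    pct_large: dict[float, float]
    area_skewness: float | None
    ecc_mean: float
    ecc_sd: float | None
    ecc_skewness: float | None
    sol_mean: float
    sol_sd: float | None
    sol_skewness: float | None
    pct_indented: dict[float, float]

    def as_dict(self) -> dict[str, float | None]:
        """Flat parameter dict; threshold keys become column suffixes."""
        out: dict[str, float | None] = {
            "n_nuclei": self.n_nuclei,
            "area_mean": self.area_mean,
            "area_median": self.area_median,
            "area_sd": self.area_sd,
            "area_p90": self.area_p90,
            "area_p90_over_median": self.area_p90_over_median,
            "area_mean_top10": self.area_mean_top10,
            "area_skewness": self.area_skewness,
            "ecc_mean": self.ecc_mean,
            "ecc_sd": self.ecc_sd,
            "ecc_skewness": self.ecc_skewness,
            "sol_mean": self.sol_mean,
            "sol_sd": self.sol_sd,
            "sol_skewness": self.sol_skewness,
        }
        for t, v in self.pct_large.items():
            out[f"pct_large_{t:g}"] = v
        for t, v in self.pct_indented.items():
            out[f"pct_indented_{t:g}"] = v
        return out


def nucleus_features(
    instance_pixels: np.ndarray, calibration: Calibration | None = None,
    *, id: int | None = None,
) -> NucleusFeatures:
    """Measure one nucleus given as a binary pixel array.

    Area is the calibrated pixel count; eccentricity comes from the
    ellipse with the same second central moments as the region; solidity
    is the ratio of the pixel count to the convex-hull pixel count.  A
    1-pixel instance degenerates to eccentricity 0 and solidity 1.
    """
    calibration = calibration or Calibration()
    arr = np.asarray(instance_pixels).astype(np.uint8)
    if arr.sum() == 0:
        raise ValueError("empty pixel set")
    props = measure.regionprops(measure.label(arr > 0, connectivity=2))
    if len(props) != 1:
        # merge: treat all foreground as one instance
        props = measure.regionprops((arr > 0).astype(np.uint8))
    p = props[0]
    cy, cx = p.centroid
    return NucleusFeatures(
        area=float(p.area) * calibration.area_scale,
        eccentricity=float(p.eccentricity),
        solidity=float(p.solidity),
        centroid=(float(cx), float(cy)),
        id=id,
    )


def mask_features(mask: LabelMask) -> list[NucleusFeatures]:
    """Measure every instance of a label mask."""
    out = []
    for p in measure.regionprops(mask.labels):
        cy, cx = p.centroid
        out.append(
            NucleusFeatures(
                area=float(p.area) * mask.calibration.area_scale,
                eccentricity=float(p.eccentricity),
                solidity=float(p.solidity),
                centroid=(float(cx), float(cy)),
                id=int(p.label),
            )
        )
    return out


def _sd(x: np.ndarray) -> float | None:
    return float(np.std(x, ddof=1)) if x.size >= 2 else None


def _skew(x: np.ndarray) -> float | None:
    if x.size < 3 or np.std(x, ddof=1) == 0:
        return None
    import warnings

    with warnings.catch_warnings():
        # scipy warns about near-identical data; the zero-SD case is
        # already reported as missing above
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.skew(x, bias=False))


def roi_morphometry(
    features: Sequence[NucleusFeatures] | Iterable[NucleusFeatures],
    config: MorphometryConfig | None = None,
) -> ROIMorphometry:
    """Aggregate per-nucleus features into the ROI parameter vector.

    ``pct_large`` counts nuclei with area strictly above each reference
    threshold, over all (post-filter) nuclei; ``pct_indented`` counts
    solidity strictly below each cutoff.  ``area_mean_top10`` averages the
    ``ceil(top_fraction * n)`` largest areas.
    """
    config = config or MorphometryConfig()
    features = list(features)
    if not features:
        raise ValueError("roi_morphometry requires at least one nucleus")
    area = np.array([f.area for f in features])
    ecc = np.array([f.eccentricity for f in features])
    sol = np.array([f.solidity for f in features])
    n = area.size

    median = float(np.median(area))
    p90 = float(np.percentile(area, 90))  # linear interpolation
    k_top = int(np.ceil(config.top_fraction * n))
    top = np.sort(area)[-k_top:]
    return ROIMorphometry(
        n_nuclei=n,
        area_mean=float(area.mean()),
        area_median=median,
        area_sd=_sd(area),
        area_p90=p90,
        area_p90_over_median=(p90 / median) if median > 0 else None,
        area_mean_top10=float(top.mean()),
        pct_large={
            t: float(100.0 * (area > t).sum() / n)
            for t in config.large_nucleus_thresholds_um2
        },
        area_skewness=_skew(area),
        ecc_mean=float(ecc.mean()),
        ecc_sd=_sd(ecc),
        ecc_skewness=_skew(ecc),
        sol_mean=float(sol.mean()),
        sol_sd=_sd(sol),
        sol_skewness=_skew(sol),
        pct_indented={
            t: float(100.0 * (sol < t).sum() / n)
            for t in config.indentation_thresholds
        },
    )


def invert_mean_solidity(roi_list: Sequence[ROIMorphometry | Mapping[str, float]]) -> float:
    """Case-level indentation score: 1 minus the mean of per-ROI mean solidity.

    Inverts the direction of solidity so that, like the other parameters,
    larger values indicate more abnormal (more indented) nuclei.
    """
    vals = []
    for roi in roi_list:
        v = roi.sol_mean if isinstance(roi, ROIMorphometry) else roi["sol_mean"]
        if v is not None:
            vals.append(float(v))
    if not vals:
        raise ValueError("no ROI with a defined mean solidity")
    return 1.0 - float(np.mean(vals))


def case_morphometry(
    roi_list: Sequence[ROIMorphometry | Mapping[str, float | None]],
) -> dict[str, float | None]:
    """Average each ROI-level parameter across a case's ROIs (unweighted).

    All ROIs must report the same parameter set; a parameter that is
    missing in any ROI is missing at case level too.
    """
    if not roi_list:
        raise ValueError("case_morphometry requires at least one ROI")
    dicts = [
        r.as_dict() if isinstance(r, ROIMorphometry) else dict(r) for r in roi_list
    ]
    keys = set(dicts[0])
    for d in dicts[1:]:
        if set(d) != keys:
            raise ValueError("mismatched parameter sets across ROIs")
    out: dict[str, float | None] = {}
    for key in dicts[0]:
        vals = [d[key] for d in dicts]
        out[key] = None if any(v is None for v in vals) else float(np.mean(vals))
    return out


def parameter_correlations(case_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of case-level parameters.

    Zero-variance columns yield missing correlations (NaN).
    """
    if len(case_table) < 3:
        raise ValueError("need at least 3 cases for correlations")
    return case_table.corr(method="pearson")
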