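"""Intratumoral heterogeneity of morphometric measurements across a case's
3-5 ROIs, and heterogeneity itself as a prognostic test.

Variation between tumor regions is summarized by the coefficient of
variation (SD/mean) and by the raw SD across ROIs; the "hotspot" view
counts the proportion of ROIs whose measurement meets or exceeds the
sensitive prognostic threshold (threshold 1).
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from nucleomorph.core_io import CaseRecord
from nucleomorph.prognostics import label_outcomes, roc_auc

__all__ = [
    "roi_cv",
    "roi_sd_score",
    "hotspot_proportion",
    "death_probability_table",
    "auc_vs_n_rois",
]


def roi_cv(values_per_roi: Sequence[float]) -> float:
    """Coefficient of variation (sample SD / mean) across a case's ROIs."""
    v = np.asarray(values_per_roi, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 ROIs")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined: mean is 0")
    return float(np.std(v, ddof=1) / mean)


def roi_sd_score(values_per_roi: Sequence[float]) -> float:
    """Sample SD of a parameter across a case's ROIs (prognostic score)."""
    v = np.asarray(values_per_roi, dtype=float)
    if v.size < 2:
        raise ValueError("SD score needs at least 2 ROIs")
    return float(np.std(v, ddof=1))


def hotspot_proportion(values_per_roi: Sequence[float], threshold1: float) -> float:
    """Fraction of ROIs at or above the sensitive threshold ("hotspots")."""
    v = np.asarray(values_per_roi, dtype=float)
    if v.size == 0:
        raise ValueError("needs at least 1 ROI")
    return float((v >= threshold1).sum() / v.size)


def death_probability_table(
    cases: Sequence[CaseRecord],
    parameter: str,
    threshold1: float,
    metric: str = "tumor_related_death_anytime",
) -> pd.DataFrame:
    """Outcome distribution by exact hotspot-ROI proportion.

    Cases are binned by the exact fraction of hotspot ROIs (e.g. 2/5 and
    2/4 are distinct bins, as encountered in the cohort); each bin reports
    the tumor-related-mortality (TRM) and other-case counts and the death
    probability TRM/(TRM+other), rounded to a whole percent.  Empty bins
    are omitted.  Counts always sum to the cohort size.
    """
    outcome = label_outcomes(cases, metric)
    rows: dict[Fraction, dict[str, int]] = {}
    for case, pos in zip(cases, outcome.labels):
        values = case.roi_values(parameter)
        frac = Fraction(int(sum(v >= threshold1 for v in values)), len(values))
        cell = rows.setdefault(frac, {"trm": 0, "other": 0})
        cell["trm" if pos else "other"] += 1
    records = []
    for frac in sorted(rows):
        trm, other = rows[frac]["trm"], rows[frac]["other"]
        records.append(
            {
                "proportion": float(frac),
                "bin": str(frac),
                "trm": trm,
                "other": other,
                "death_probability_pct": int(round(100 * trm / (trm + other))),
            }
        )
    return pd.DataFrame(records)


def auc_vs_n_rois(
    cases: Sequence[CaseRecord],
    parameter: str,
    metric: str = "tumor_related_death_anytime",
    max_rois: int = 5,
) -> dict[int, float]:
    """AUC of the cumulative ROI mean for k = 1..max_rois ROIs.

    For each k the case score is the mean of its first min(k, available)
    ROI measurements, in ROI-selection order; cases with fewer ROIs use all
    they have.  At the full count this equals the case-level (all-ROI
    average) AUC.
    """
    outcome = label_outcomes(cases, metric)
    out: dict[int, float] = {}
    for k in range(1, max_rois + 1):
        scores = [
            float(np.mean(case.roi_values(parameter)[:k])) for case in cases
        ]
        auc, _ = roc_auc(scores, outcome.labels)
        out[k] = auc
    return out
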