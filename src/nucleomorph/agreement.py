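"""Rater-reproducibility statistics.

Categorical estimates (2-tier karyomegaly, 3-tier anisokaryosis) are
compared with Cohen's kappa (optionally linearly or quadratically weighted
for ordered tiers) and, across more than two raters, with Light's kappa
(the mean of all pairwise Cohen's kappas).  Numeric measurements use the
intraclass correlation coefficient, two-way random-effects model with
absolute agreement on single measures (ICC(2,1)).  Band labels follow the
conventional interpretation scales for kappa (slight/fair/moderate/
substantial/almost perfect) and ICC (poor/fair/good/excellent).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "cohens_kappa",
    "lights_kappa",
    "icc_2way_single",
    "interpret_agreement",
    "consensus_count",
]

_WEIGHTS = {"none": None, "linear": "linear", "quadratic": "quadratic"}


def cohens_kappa(r1, r2, weighting: str = "none") -> float:
    """Weighted Cohen's kappa between two raters' categorical vectors.

    Chance-corrected agreement 1 - observed/expected weighted disagreement.
    When a degenerate table makes the expected disagreement zero (e.g. both
    raters constant), the statistic is undefined and NaN is returned with a
    warning.
    """
    if weighting not in _WEIGHTS:
        raise ValueError(f"weighting must be one of {sorted(_WEIGHTS)}")
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape:
        raise ValueError("rating vectors must have equal length")
    if np.unique(r1).size == 1 and np.unique(r2).size == 1:
        if np.array_equal(r1, r2):
            warnings.warn("both raters constant and identical: kappa undefined")
            return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k = cohen_kappa_score(r1, r2, weights=_WEIGHTS[weighting])
    if np.isnan(k):
        warnings.warn("degenerate rating table: kappa undefined")
    return float(k)


def lights_kappa(table: pd.DataFrame | np.ndarray, weighting: str = "none") -> float:
    """Light's kappa: mean pairwise Cohen's kappa over all rater pairs.

    ``table`` is cases x raters.  With exactly 2 raters this reduces to
    Cohen's kappa.  Undefined pairwise kappas propagate as NaN.
    """
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a cases x raters table with >= 2 raters")
    kappas = [
        cohens_kappa(arr[:, i], arr[:, j], weighting)
        for i, j in itertools.combinations(range(arr.shape[1]), 2)
    ]
    return float(np.mean(kappas))


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_raters: int


def icc_2way_single(table: pd.DataFrame | np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``table`` is cases x raters with numeric entries; rows containing
    missing values are dropped listwise (the count kept is reported in the
    result).  The 95% CI is the conventional F-distribution interval.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 cases and >= 2 raters")
    keep = ~np.isnan(arr).any(axis=1)
    arr = arr[keep]
    if arr.shape[0] < 2:
        raise ValueError("fewer than 2 complete cases after listwise deletion")
    n, k = arr.shape

    import pingouin as pg

    long = pd.DataFrame(
        {
            "case": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "value": arr.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc_table = pg.intraclass_corr(
            data=long, targets="case", raters="rater", ratings="value"
        ).set_index("Type")
    # two-way random, absolute agreement, single measures: ICC(2,1),
    # labelled ICC(A,1) in the McGraw & Wong naming pingouin uses
    key = "ICC2" if "ICC2" in icc_table.index else "ICC(A,1)"
    row = icc_table.loc[key]
    ci_col = "CI95%" if "CI95%" in icc_table.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(
        icc=float(row["ICC"]),
        ci_low=float(lo),
        ci_high=float(hi),
        n_cases=n,
        n_raters=k,
    )


def interpret_agreement(value: float, scale: str = "kappa") -> str:
    """Band label for a kappa or ICC value.

    Kappa: poor (<= 0), slight (0.01-0.20), fair (0.21-0.40), moderate
    (0.41-0.60), substantial (0.61-0.80), almost perfect (0.81-1.00).
    ICC: poor (< 0.40), fair (0.40-0.59), good (0.60-0.74),
    excellent (0.75-1.00).
    """
    if not -1 <= value <= 1:
        raise ValueError("agreement values lie in [-1, 1]")
    if scale == "kappa":
        if value <= 0:
            return "poor"
        for hi, name in [(0.20, "slight"), (0.40, "fair"), (0.60, "moderate"), (0.80, "substantial")]:
            if value <= hi:
                return name
        return "almost perfect"
    if scale == "icc":
        if value < 0.40:
            return "poor"
        if value < 0.60:
            return "fair"
        if value < 0.75:
            return "good"
        return "excellent"
    raise ValueError("scale must be 'kappa' or 'icc'")


def consensus_count(table: pd.DataFrame | np.ndarray, min_agree: int) -> int:
    """Number of cases on which at least ``min_agree`` raters agree.

    Agreement means assigning the same category; the most frequent category
    per case must reach multiplicity ``min_agree``.
    """
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise ValueError("need a cases x raters table")
    count = 0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        if counts.max() >= min_agree:
            count += 1
    return count
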