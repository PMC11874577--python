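"""Prognostic-value statistics: outcome labeling, ROC/AUC with bootstrap
CIs, sensitivity-matched threshold selection on a 200-interval grid,
confusion metrics, Kaplan-Meier curves and univariate Cox hazard ratios.

Outcome conventions: the primary endpoints are tumor-related mortality at
any time of follow-up and tumor-specific survival time.  Patients who died
of unrelated causes are grouped with survivors for ROC/confusion analyses
and censored at their death time for survival analyses; survivors are
censored at the end of follow-up.  The 12-month variants restrict events to
the first 12 months (the overall variant counting death of any cause).

A test is positive when the measurement is greater than or equal to the
cutoff; parameters whose direction is inverted a priori (solidity) are
entered via their inverted score instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from lifelines import CoxPHFitter, KaplanMeierFitter
from sklearn.metrics import roc_auc_score

from nucleomorph.core_io import CaseRecord

__all__ = [
    "OutcomeData",
    "ThresholdResult",
    "SurvivalFit",
    "OUTCOME_METRICS",
    "label_outcomes",
    "roc_auc",
    "threshold_grid",
    "select_threshold",
    "confusion_metrics",
    "kaplan_meier",
    "cox_hr",
]

OUTCOME_METRICS = ("tumor_related_death_anytime", "tumor_specific_12mo", "overall_12mo")


@dataclass
class OutcomeData:
    """Binary labels for ROC/confusion plus (time, event) for survival."""

    labels: np.ndarray  # 1 = positive outcome (death per the metric)
    times: np.ndarray  # survival / censoring time in months
    events: np.ndarray  # 1 = tumor-related death observed
    metric: str


@dataclass
class ConfusionRates:
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    false_omission_rate: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "false_omission_rate": self.false_omission_rate,
        }


@dataclass
class ThresholdResult:
    """A dichotomization of a numeric test: positive iff value >= cutoff."""

    cutoff: float
    tp: int
    fp: int
    fn: int
    tn: int
    rates: ConfusionRates


@dataclass
class SurvivalFit:
    """Kaplan-Meier curves per group and the univariate Cox summary."""

    km_times: dict[int, np.ndarray]
    km_survival: dict[int, np.ndarray]
    median_survival: dict[int, float | None]
    hazard_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    unstable: bool = False


def label_outcomes(cases: Sequence[CaseRecord], metric: str = "tumor_related_death_anytime") -> OutcomeData:
    """Derive outcome labels and survival data from case records.

    ROC/confusion label: positive iff tumor-related death (restricted to
    the first 12 months for ``tumor_specific_12mo``; any-cause death within
    12 months for ``overall_12mo``).  Survival data: event = tumor-related
    death at the death time; unrelated deaths censored at death, survivors
    censored at end of follow-up.
    """
    if metric not in OUTCOME_METRICS:
        raise ValueError(f"metric must be one of {OUTCOME_METRICS}")
    labels, times, events = [], [], []
    for case in cases:
        if case.cause is None or case.survival_time_months is None:
            raise ValueError(f"case {case.case_id}: missing cause or time")
        tumor_death = case.cause == "tumor_related_death"
        any_death = case.cause in ("tumor_related_death", "unrelated_death")
        t_event = case.survival_time_months if any_death else case.followup_months
        if metric == "tumor_related_death_anytime":
            pos = tumor_death
        elif metric == "tumor_specific_12mo":
            pos = tumor_death and case.survival_time_months <= 12.0
        else:  # overall_12mo: death regardless of cause
            pos = any_death and case.survival_time_months <= 12.0
        labels.append(int(pos))
        times.append(float(t_event))
        events.append(int(tumor_death))
    return OutcomeData(
        labels=np.array(labels), times=np.array(times), events=np.array(events),
        metric=metric,
    )


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 0,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float] | None]:
    """AUC of the ROC curve, optionally with a percentile bootstrap 95% CI.

    The AUC is the trapezoid area over all distinct cutoffs, equal to the
    tie-corrected Mann-Whitney probability that a positive case scores
    above a negative one.  The bootstrap resamples cases with replacement
    (``n_boot`` draws, seeded); degenerate resamples with one class absent
    are discarded.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    auc = float(roc_auc_score(labels, scores))
    if n_boot <= 0:
        return auc, None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = scores.size
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) < 2:
            continue
        boots.append(roc_auc_score(labels[idx], scores[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


def threshold_grid(scores: Sequence[float], n_intervals: int = 200) -> np.ndarray:
    """Candidate cutoffs dividing the score range into equal intervals.

    Returns ``n_intervals + 1`` cutoffs ``min + k (max-min)/n``,
    k = 0..n (0.5% steps of the range for the default 200).
    """
    scores = np.asarray(scores, dtype=float)
    lo, hi = float(scores.min()), float(scores.max())
    if lo == hi:
        raise ValueError("scores are constant; no threshold grid exists")
    return lo + np.arange(n_intervals + 1) * (hi - lo) / n_intervals


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> ConfusionRates:
    """Sensitivity, specificity, precision and false-omission rate.

    The false-omission rate FN/(FN+TN) is the event rate among
    test-negative cases.  A rate with a zero denominator is reported as
    missing (None) rather than 0.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn + tn == 0:
        raise ValueError("all counts are zero")

    def rate(num: int, den: int) -> float | None:
        return num / den if den else None

    return ConfusionRates(
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        precision=rate(tp, tp + fp),
        false_omission_rate=rate(fn, fn + tn),
    )


def _confusion_at(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> tuple[int, int, int, int]:
    pos = scores >= cutoff
    tp = int((pos & (labels == 1)).sum())
    fp = int((pos & (labels == 0)).sum())
    fn = int((~pos & (labels == 1)).sum())
    tn = int((~pos & (labels == 0)).sum())
    return tp, fp, fn, tn


def select_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    target_sensitivity: Fraction | tuple[int, int] | float,
    n_intervals: int = 200,
) -> ThresholdResult:
    """Pick the highest grid cutoff achieving an exact target sensitivity.

    The score range is divided into ``n_intervals`` equal steps; among all
    grid cutoffs whose sensitivity (positive iff score >= cutoff) equals
    the target exactly, the highest is returned with its full confusion
    metrics.  The target is matched as a rational count — e.g. 10/13 —
    never as a rounded percentage.  If no grid cutoff achieves it, the
    error lists the achievable sensitivities.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("no positive cases")
    if isinstance(target_sensitivity, tuple):
        target = Fraction(*target_sensitivity)
    elif isinstance(target_sensitivity, Fraction):
        target = target_sensitivity
    else:
        target = Fraction(target_sensitivity).limit_denominator(n_pos)
    grid = threshold_grid(scores, n_intervals)
    best: ThresholdResult | None = None
    achieved: set[Fraction] = set()
    for cutoff in grid:
        tp, fp, fn, tn = _confusion_at(scores, labels, float(cutoff))
        sens = Fraction(tp, n_pos)
        achieved.add(sens)
        if sens == target:
            best = ThresholdResult(
                cutoff=float(cutoff), tp=tp, fp=fp, fn=fn, tn=tn,
                rates=confusion_metrics(tp, fp, fn, tn),
            )  # keep overwriting: grid ascends, so the last hit is the highest
    if best is None:
        opts = ", ".join(str(a) for a in sorted(achieved))
        raise ValueError(
            f"target sensitivity {target} not achievable on the grid; "
            f"achievable: {opts}"
        )
    return best


def kaplan_meier(
    times: Sequence[float], events: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Product-limit survival estimate.

    Returns (event/censoring timeline, S(t) step values, median survival).
    The median is the first time at which S drops to 0.5 or below; missing
    if the curve never reaches it.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    t = kmf.survival_function_.index.to_numpy(dtype=float)
    s = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    below = np.nonzero(s <= 0.5)[0]
    median = float(t[below[0]]) if below.size else None
    return t, s, median


def cox_hr(
    group: Sequence[int], times: Sequence[float], events: Sequence[int]
) -> SurvivalFit:
    """Univariate Cox regression of survival on a binary group indicator.

    Returns the hazard ratio (group 1 vs 0) with Wald 95% CI and p-value,
    plus Kaplan-Meier curves per group.  When one group has no events the
    partial likelihood is monotone and the estimate diverges; the fit is
    flagged ``unstable`` and the (near-boundary) penalized estimate is
    reported for orientation only.
    """
    import pandas as pd

    group = np.asarray(group, dtype=int)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if set(np.unique(group)) - {0, 1}:
        raise ValueError("group must be binary 0/1")
    if events.sum() == 0:
        raise ValueError("no events at all")

    fit = SurvivalFit(km_times={}, km_survival={}, median_survival={})
    for g in (0, 1):
        sel = group == g
        if sel.any():
            t, s, med = kaplan_meier(times[sel], events[sel])
            fit.km_times[g], fit.km_survival[g], fit.median_survival[g] = t, s, med

    events_per_group = {g: int(events[group == g].sum()) for g in (0, 1)}
    unstable = min(events_per_group.values()) == 0
    df = pd.DataFrame({"t": times, "e": events, "g": group})
    cph = CoxPHFitter(penalizer=1e-6 if not unstable else 0.1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="t", event_col="e")
    coef = float(cph.params_["g"])
    se = float(cph.standard_errors_["g"])
    fit.hazard_ratio = float(np.exp(coef))
    fit.ci_low = float(np.exp(coef - 1.96 * se))
    fit.ci_high = float(np.exp(coef + 1.96 * se))
    fit.p_value = float(cph.summary.loc["g", "p"])
    fit.unstable = bool(unstable)
    return fit
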