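"""Prognostic value of the SD of nuclear area on a simulated cohort.

Generates 96 cases whose tumor-related death hazard rises with
anisokaryosis, then runs the full prognostic machinery: ROC/AUC with a
bootstrap CI, sensitivity-matched threshold selection on the 200-interval
grid, and Kaplan-Meier / Cox analysis of the dichotomized test.
"""

from fractions import Fraction

import numpy as np

from nucleomorph.prognostics import cox_hr, label_outcomes, roc_auc, select_threshold
from nucleomorph.synthetic import CohortSpec, generate_cohort

cases, truth = generate_cohort(CohortSpec(), seed=1)
outcome = label_outcomes(cases, "tumor_related_death_anytime")
scores = np.array([c.case_value("area_sd") for c in cases])
print(f"{len(cases)} cases, {outcome.labels.sum()} tumor-related deaths, "
      f"{sum(c.cause == 'unrelated_death' for c in cases)} unrelated deaths")

auc, ci = roc_auc(scores, outcome.labels, n_boot=2000, seed=1)
print(f"AUC (tumor-related mortality): {auc:.3f} (95% CI {ci[0]:.3f}-{ci[1]:.3f})")

n_pos = int(outcome.labels.sum())
target = Fraction(round(10 / 13 * n_pos), n_pos)
thr = select_threshold(scores, outcome.labels, target)
print(f"threshold 1 (sensitivity {float(target):.1%}): >= {thr.cutoff:.1f} µm² "
      f"-> specificity {thr.rates.specificity:.1%}, precision {thr.rates.precision:.1%}, "
      f"false omission {thr.rates.false_omission_rate:.1%}")

fit = cox_hr((scores >= thr.cutoff).astype(int), outcome.times, outcome.events)
print(f"hazard ratio above vs below threshold: {fit.hazard_ratio:.1f} "
      f"(95% CI {fit.ci_low:.1f}-{fit.ci_high:.1f}, p = {fit.p_value:.2g})")
# A high AUC with a large hazard ratio at the sensitivity-matched cutoff is
# the signature of a prognostically useful morphometric parameter.
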