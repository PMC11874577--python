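# Methods

This note documents the measurement conventions, statistical models,
defaults, and design choices of `nucleomorph`, and what the synthetic
generators do and do not emulate.

## Measurement model

A region of interest (ROI) is a fixed-area crop from a whole-slide image:
0.1185 mm² (half a standard high-power field) with 4:3 aspect, which at the
default calibration of 0.25 µm/pixel is 1 896 000 pixels. Nuclear area is
the instance pixel count times `mpp²`. Eccentricity and solidity are taken
from `skimage.measure.regionprops`: eccentricity is the focal distance of
the moment-equivalent ellipse divided by its major axis length, solidity
the pixel count over the convex-hull pixel count. A 1-pixel instance
degenerates to eccentricity 0 and solidity 1 by definition.

Conventions the field leaves open, fixed here once and used everywhere:

- **SD** is the sample SD (`ddof=1`); needs n ≥ 2, else reported missing.
- **Percentiles** use linear interpolation between order statistics.
- **Skewness** is the adjusted Fisher–Pearson coefficient; defined only
  for n ≥ 3 and SD > 0, else missing. Missing never silently becomes 0.
- **Top-10% mean** averages the `ceil(0.1 n)` largest areas (12 nuclei → 2).
- **Large-nucleus percentages** use strict `>` against the case-independent
  reference sizes 37.8 and 50.3 µm² (the 90th percentile and twice the
  median of a large reference annotation corpus); the denominator is the
  post-filter nucleus set. **Indented percentages** use strict `<` against
  solidity 0.913/0.936/0.943 (2nd/5th/10th percentiles of the same corpus).
- **Coordinates**: 0-based, x = column, y = row; polygons in continuous
  pixel coordinates with integer pixel centers (a flag shifts to
  half-integer centers). A pixel belongs to a polygon iff its center lies
  strictly inside the cleaned ring; centers exactly on the boundary are
  excluded, which keeps rasterization deterministic.

## Segmentation post-processing

Binary model output → connected components → size filter. Defaults:
8-neighbor connectivity (4-neighbor splits thin diagonal boundaries),
strict `< 7.0 µm²` removal (a fragment smaller than that is not a complete
nucleus), border-touching instances kept (the border-exclusion rule belongs
to the manual grid protocol, not the algorithmic path); all three are
configurable. The bundled `baseline_segment` (Otsu threshold, hole filling,
distance-transform watershed with peak markers no closer than the radius of
a minimum-area nucleus) is a classical front end for demonstrations and
synthetic images; it is deterministic and is not a substitute for a trained
model on real histology.

## Sampling protocols

*Grid protocol (≥ 100 nuclei).* A 5 × 6 grid is walked center-out: fields
are ranked by Chebyshev ring around the grid center (for six columns, the
two middle columns are ring 0), serpentine within each ring, outer ring
last; the walk is frozen and documented because the protocol's "uniform
meander from the center" admits several orders. Every instance intersecting
the current field counts (grid-line touching included), instances touching
the outer image border never count, instances spanning fields count once;
collection stops after the field that reaches 100.

*Stratified 12-nucleus protocol.* Nuclei sorted by area split at ranks
`⌊n/3⌋` and `⌊2n/3⌋` (ties broken by instance id); 4 drawn uniformly per
tercile with a seeded generator. Humans choose "representative" nuclei
non-uniformly, so the rater simulator adds an explicit tilt — selection
probability ∝ `area^t` within each tercile — plus multiplicative lognormal
measurement noise; both default to 0.

## Prognostic statistics

Outcome conventions: positive = tumor-related death (any time, or within
12 months for the tumor-specific 12-month variant; the overall 12-month
variant counts death of any cause). Unrelated deaths are grouped with
survivors for ROC/confusion analyses and censored at death time for
survival analyses; survivors are censored at end of follow-up.

A test is positive when the measurement ≥ cutoff. Threshold selection
divides the score range into 200 equal intervals (201 cutoffs) and, among
cutoffs achieving the target sensitivity *exactly as a count* (e.g. 10 of
13 — never a rounded percentage), returns the highest. AUC is the
tie-corrected Mann–Whitney statistic; its CI is a percentile bootstrap over
cases (default 2 000 resamples, seeded; degenerate one-class resamples are
discarded). Kaplan–Meier and Cox fits are delegated to `lifelines`; the
Cox model is univariate on the binary group, Wald CI and p, with
`lifelines`' Efron tie approximation (ties are rare at continuous survival
times; a tiny ridge penalty stabilizes the no-event-group boundary case,
which is additionally flagged `unstable`). The hotspot rule uses ≥ at the
threshold, consistent with the positivity rule.

## Agreement statistics

Cohen's kappa (unweighted/linear/quadratic; linear is the default for the
ordered 3-tier estimates, unweighted for binary karyomegaly), Light's kappa
as the unweighted mean over rater pairs, and ICC(2,1) — two-way random
effects, absolute agreement, single measures — with the F-based CI, via
`pingouin`. Missing rater entries are dropped listwise per analysis and the
retained case count is reported. Band labels: kappa poor ≤ 0 < slight ≤
0.20 < fair ≤ 0.40 < moderate ≤ 0.60 < substantial ≤ 0.80 < almost
perfect; ICC poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent.

## Synthetic generators

*ROI generator.* Non-overlapping deformed ellipses placed by seeded
dart-throwing with an 8-connectivity 1-pixel clearance (instances can never
merge under component labeling). Areas are lognormal (default mean 26 µm²,
SD 8 µm², the scale of an unremarkable ccMCT region; gamma available behind
a flag), eccentricity is `0.92 · Beta(4, 2.5)` (mean ≈ 0.57), orientation
uniform. Indentations are circular bites subtracted at a random boundary
point (probability 0.1, bite radius 0.35 of the minor semi-axis); bite
depth maps monotonically to solidity. Placement tries 200 darts per
nucleus, then skips with a warning — never silent padding. The manifest
records area/eccentricity/solidity measured from the *drawn pixel set*, so
manifest truth and mask morphometry agree exactly by construction; what is
validated against the spec is distributional recovery (mean within ~1%, SD
within a few % of the requested lognormal at n = 400 over seeds). The
optional RGB render (dark nuclei, textured light background, granule
speckle) supports end-to-end segmentation demos only; it does not emulate
H&E stain variation, overlapping nuclei, cutting artifacts, or
out-of-focus regions — so segmentation scores on synthetic images bound
nothing about real histology.

*Cohort generator.* Latent severity `s ~ N(0,1)` per case; case-level area
mean `24 + 3 s` µm² and area SD `8 · exp(0.30 s)` µm²; per ROI, Gaussian
between-ROI noise (SD 1.5 and 1.0 µm² respectively) plus finite-sample
error from measuring n = 455 sampled nuclei (the median per-ROI nucleus
count in real material). ROI count per case is 5 with probability 91/96, 4
with 4/96, 3 with 1/96, mirroring the study design. Survival: tumor-related
death is exponential with log-hazard `−8.4 + 0.35 · (case area SD)` per
month, unrelated death an independent exponential (hazard 0.0042/month),
administrative censoring U(12, 45) months; the defaults give ≈ 13%
tumor-related and ≈ 11% unrelated mortality, matching the outcome mix of a
surgical ccMCT population, with typical AUCs around 0.75–0.85. The truth
ledger carries the latent severity, true case parameters, and hazards, so
recovery tests compare pipeline output to the generating model rather than
to itself. What passing these tests shows is that the *statistics* behave
correctly under the assumed generative structure — not that real tumors
follow it.

*Rater generator.* All raters observe the same latent case severity; each
applies common tier thresholds shifted by a personal Gaussian offset
(SD 1.5 µm²) to a noisy perception (lognormal, SD 0.15). The offsets are
what push inter-rater kappa below intra-rater kappa. Numeric raters report
the latent value under multiplicative lognormal noise (SD 0.2), giving
ICCs near 0.65 at the defaults.

## Numerical and scale choices

All statistics are deterministic given seeds; the pipeline serializes
floats at 6 decimals so reruns are byte-identical. Test and acceptance
problem sizes (e.g. 20 ROI seeds, 50 null-cohort replicates, n = 2 000 for
Cox recovery, 8 seeds in the distribution-recovery unit test) were chosen
as the smallest sizes at which the Monte-Carlo standard error is comfortably
inside the asserted tolerance.

## Known limitations

- The deep segmentation model itself is out of scope; real-image Dice/F1
  depend on it and are only bounded by the classical baseline here.
- The exact meander order and within-tercile nucleus choice of human
  annotators are unknowable; both are parameterized, frozen defaults.
- The Cox implementation flags, but cannot rescue, cohorts with no events
  in one group (the partial likelihood is monotone there).
- Polygon rasterization treats boundary-grazing pixel centers as outside;
  against continuous-geometry areas this is a sub-percent effect for
  nuclei ≥ 50 px but grows for very small instances.
- `death_probability_table` rounds probabilities to whole percent by
  design, as the corresponding outcome tables print them.
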