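# Methods

This note records the conventions, defaults and design choices behind
dustqi, and what the synthetic-data tests do and do not demonstrate
about real surveys.

## Data model

Concentrations are a strictly positive, finite site × element matrix in
mg/kg dry weight. Element symbols are case-sensitive and matched exactly
between the concentration and background tables; there is no alias
resolution, so a symbol or unit mismatch fails loudly instead of
producing a silently wrong ratio. No unit conversion is performed
(detection limits are often quoted in µg/kg; converting is the caller's
job). Values below a detection limit are not imputed — the package
requires positive inputs and deliberately implements no MDL/2-style
substitution, since any censoring rule changes every ratio index and
should be an explicit, documented upstream decision. CSV (comma, dot
decimal, UTF-8) is the only tabular dialect; floats are written at 17
significant digits and read back with round-trip parsing, so
write→read is bit-exact.

## Index conventions

- **PLI** is computed as `exp(mean(log PI))`. PIs in a mixed panel span
  several orders of magnitude and a direct product over ~17 terms risks
  under/overflow; the log form is exact and stable.
- **PLI_d** drops PIs below a threshold (default 0.03) rather than a
  hard-coded element list: which elements fall below depends on the
  background set, so the rule, not a frozen list, is what transfers
  between surveys. The dropped elements are reported with the value.
- **Removal variants** (default: without Ca) remove the configured
  elements *first* and apply the PLI_d threshold to the reduced panel
  afterwards, so the variant is a genuine reanalysis of the smaller
  panel.
- **EF** uses Al as the default reference (Ca and Fe selectable); the
  reference used is recorded in the result. `EF_j = PI_j / PI_ref` is
  asserted as an identity in the tests.
- **Grade boundaries.** Published grade tables are ambiguous at the
  boundaries ("1–2" vs "2–3"; a gap between 25 and 26 on the AQI
  scale). Each scheme here is a total, monotone step function:
  boundary values belong to the class above them by default (so a
  Nemerow value of exactly 0.7 grades "warning level", matching the
  strict "less than 0.7" wording of the lowest class), with
  per-boundary overrides where the published wording is strict the
  other way: PI > 5, EF > 40 and Nemerow/CPI > 3 are strict (the
  boundary value stays in the class below), AQI keeps 25/50/75/100 in
  the lower class with the gap values grading upward, and Igeo ≤ 0 is
  class 0 with every later boundary inclusive upward. CPI reuses the
  Nemerow scale and labels verbatim.
- Igeo uses log base 2 with the conventional 1.5 background-fluctuation
  buffer.

## Statistics

Standard deviation is the sample (n−1) estimator throughout, CV =
sd/mean, skewness is the adjusted Fisher–Pearson sample coefficient and
kurtosis is sample excess kurtosis — the conventions under which a flat
series shows negative kurtosis, as survey summary tables do. Pearson
p-values use the exact t transform `t = r·sqrt((n−2)/(1−r²))` on n−2
df, two-sided, and are reported unadjusted (an optional Holm adjustment
exists but defaults off, matching how survey correlation tables are
usually printed). The method detection limit is `MDL = X̄ + t·SD` over
blank replicates, with t the one-sided Student quantile at the chosen
confidence (default 99%) on n−1 df — 2.896 for nine replicates — and an
override to reproduce any fixed published multiplier.

## Multivariate workflow

Normalization defaults to per-element z-scores (min–max optional).
k-means uses Lloyd iterations from 25 random seeded initializations,
keeping the best by within-cluster sum of squares; the scikit-learn
backend relocates any emptied centroid to the farthest points, which
serves as the empty-cluster policy. k is chosen as the silhouette
argmax over 2..k_max (ties to the smaller k); the elbow (WSS) curve is
returned for inspection but never auto-thresholded, since the "elbow"
is a visual judgement. Hierarchical clustering runs on Euclidean
distances with candidate linkages average, complete, ward and median;
ward follows the ward.D2 convention (plain distances in). The winning
linkage maximises the cophenetic correlation between merge heights and
input distances, with exact ties broken deterministically in the order
average > complete > ward > median.

Cluster stability follows the clusterwise bootstrap design: resample
sites with replacement B times (default 100), recluster each resample
with the same recipe, and score every original cluster by its best
Jaccard match against the resample clusters, computed on the set of
original sites present in the resample (duplicates collapse). Reported
per cluster: the mean Jaccard (> 0.85 highly stable, 0.60–0.85 stable)
and the dissolution rate — the share of replicates recovered below 0.5
— as the matching instability figure. Degenerate resamples (fewer
distinct sites than clusters) are skipped and counted.

PCA is a singular-value decomposition of the centered input; feed
z-scored data for correlation-matrix PCA or raw data for covariance
PCA (both modes are deliberately exposed). Component standard
deviations are singular values divided by sqrt(n−1); all p components
are always reported, with zero variance past the rank, so variance
proportions sum to 1 even when sites < variables. Loadings are
unit-norm eigenvectors, each component oriented so its
largest-magnitude loading is positive (a deterministic sign
convention). Variable cos2 is the squared-coordinate share per variable
(rows sum to 1); contributions are the squared-coordinate share per
component × 100 (columns sum to 100). Partition agreement uses the
adjusted Rand index with the full contingency table.

## Synthetic surveys

The generator emulates a 20-site, 17-element urban indoor-dust survey
from an arid region: per-element target means and CVs at levels typical
of such surveys (Ca ≈ 14 000 mg/kg at CV 0.22 down to Co ≈ 1.9 mg/kg;
trace-metal CVs up to ≈ 1.5). Marginals are lognormal, moment-matched
exactly via `sigma² = ln(1+CV²)`, `mu = ln(mean) − sigma²/2` — chosen
because concentration series are positive and right-skewed; no
distributional form is implied by the summary moments themselves.
Group structure is multiplicative (a per-element shift factor per
group), matching the ratio scale of every index; site-group counts are
allocated deterministically by largest remainder. Elements are drawn
independently by default — observed inter-element correlation is a
feature of real data, not of this model — with an optional common
lognormal site factor to induce positive correlation when the
correlation pipeline itself is under test. Blanks are independent
normals (they can be negative, as real blanks are).

Limitations of the emulation: skewness and kurtosis are whatever the
two-parameter lognormal implies, not matched to survey tables; there is
no spatial structure, no temporal component and no measurement-error
model beyond blanks. Consequently, passing pipeline tests shows the
algorithms recover structure that is present and report instability
when it is not — it does not validate any distributional claim about a
particular real survey.

## Backgrounds

Every index magnitude is conditional on the background set. The package
ships one documented default — upper-continental-crust averages for the
17 panel elements — and otherwise treats backgrounds as user input. With
crustal backgrounds, Cd (CB = 0.09 mg/kg) tends to dominate Nemerow and
AQI on the synthetic panel; with regional soil baselines the dominant
element is typically Ca. This is the intended behaviour of the indices,
and the removal-sensitivity variants exist precisely to quantify it.

## Problem sizes and determinism

Defaults are sized for survey-scale data: 20 sites, 17 elements,
bootstrap B = 100, k-means restarts 25, moment-recovery checks at
n = 100 000 draws. Every stochastic operation takes an explicit seed and
is bit-reproducible under it; the acceptance script derives all of its
randomness from a single `--seed`.
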