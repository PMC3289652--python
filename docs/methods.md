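# Methods

## Statistical model and procedure

The unit of analysis is the within-sample Ct difference
ΔCt(a,b) = Ct(a) − Ct(b) over all unordered miRNA pairs of a panel.
Because qPCR Ct is (approximately) −log2 of template abundance plus a
per-sample constant, ΔCt is a log2 abundance ratio and any per-sample
additive offset — serum volume, extraction yield, RT efficiency —
cancels identically. This is the entire normalization strategy: no
reference gene, no global mean-centering. The price is a quadratic
feature space (m miRNAs → m(m−1)/2 features) and strong feature
correlation, which the design addresses not by multiplicity correction
but by an independent-cohort validation with locked rules.

Per diffpair, on the training split only:

* **Welch t-test** (unequal variances, Welch–Satterthwaite fractional
  degrees of freedom, two-sided p). Reported, never used for gating.
* **ROC AUC** by the Mann–Whitney identity
  AUC = P(case > control) + ½P(tie), reported on the ≥ 0.5 side with the
  orientation absorbed into the rule's direction flag.
* **Cutoff selection** maximizing sensitivity + specificity (Youden)
  over both directions. The threshold grid is the set of midpoints
  between adjacent *distinct* sorted training values, plus ±∞ sentinels,
  which makes the chosen cutoff well-defined between samples and
  reproducible from the data alone. A value exactly at the cutoff
  classifies as control; with midpoint cutoffs no training sample ever
  sits on the boundary. Ties in sensitivity + specificity are broken by
  (1) larger min(sens, spec) — preferring balanced rules, because both
  downstream gates are symmetric — then (2) smaller |cutoff|, then
  (3) the cancer-above direction. All tie-break comparisons are done on
  integer confusion counts, so they are exact.
* **Candidate gate**: training sensitivity ≥ 80% and specificity ≥ 80%,
  both inclusive. The reported training metrics are resubstitution
  values (the cutoff is evaluated on the data that chose it); the
  inflation this causes is exactly what the locked validation exposes.

Validation applies each rule (pair, cutoff, direction) unchanged to the
test split; `apply_rule` takes no labels, so test-set re-optimization is
impossible by construction. Sensitivity, specificity, PPV and NPV come
from the test confusion table; undefined ratios (no positive or no
negative predictions) are reported as missing, never coerced to 0 or 1.
The test gate is sensitivity and specificity ≥ 75%, inclusive.

**Binomial intervals** are exact Clopper–Pearson, from beta-distribution
quantiles: lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k), with
the conventional endpoints at k = 0 and k = n. Exact intervals are the
conservative default for small validation cohorts; for a 55/55
sensitivity the lower 95% bound is 0.9351. We note one reporting
discrepancy we do not attempt to reverse-engineer: for a 63/75
specificity the exact interval is (0.7372, 0.9145), which rounds to
0.74–0.91 at two decimals, while 0.73–0.91 has appeared in print for
these counts; no standard interval (exact or Wilson) reproduces the 0.73.

**Fisher exact test** (cohort balance): two-sided p = Σ P(T) over all
2×2 tables T with the observed margins whose hypergeometric point
probability does not exceed the observed table's (with a 1e-7 relative
slack so equal-probability tables are included despite log-scale
round-off). This point-probability definition — not the doubled
one-tail — is the one that reproduces the reference cohort p-values
(0.015 for 9/20 vs 24/30 smokers; 0.005 for 65/75 vs 55/55). Point
probabilities are accumulated as log-factorials (`gammaln`) and summed
by log-sum-exp. Table 1-style percentages are converted back to counts
by rounding half away from zero, with a consistency warning when the
back-computed percentage drifts more than 0.5 from the printed one.

## Censoring and replicates

Targets undetected within the cycle limit (default 40 cycles) are stored
*at* the limit with a censoring flag, not as missing. Rationale: the
screening design drops only miRNAs undetected in every sample; for
partial censoring the clamp keeps every ΔCt computable and is the
conservative qPCR convention (the true Ct is ≥ 40, so the clamp
understates abundance differences rather than inventing them). The
`any_censored` flag is propagated per pair so downstream users can audit
which ΔCt values involve clamped members. Replicate RT/qPCR runs are
combined as the mean of detected replicate Ct values; a cell is censored
only when all replicates are censored.

## Synthetic cohort generator

The generator draws

Ct(sample, miRNA, replicate) = baseline(miRNA) + shift(sample)
                               + effect(miRNA)·1[cancer] + noise,

then censors values above the cycle limit. Defaults (all in cycles):
baseline means uniform on 22–36 (the usable dynamic range of serum
panels) jittered with sd 0.8; per-sample global shift N(0, 1.5²) — the
nuisance diffpairs cancel, on by default so the design rationale is
always exercised; per-replicate measurement noise N(0, 0.5²), with a
heavier-tailed Student-t(5) option for robustness checks; two
replicates; disease effects additive on Ct in cancer samples (a k-cycle
shift ≈ 2^k fold-change — the natural qPCR scale). A configurable
fraction of null miRNAs is placed far above the limit to emulate the
never-amplifying targets the global-undetected filter removes; these are
recorded in the truth manifest. Demographics (age, sex, smoking, stage,
histology) are drawn with group-dependent smoking rates matching the
reference cohorts, so the Fisher-test stage has realistic input.

`paper_shaped_cohort` presets the reference geometry — 181 miRNAs,
training 30 cancers / 20 controls, test 55 / 75, two replicates, one
3-cycle planted effect. Identical config + seed gives byte-identical
output (single `numpy.random.default_rng` stream).

What the generator does **not** model: amplification-efficiency
differences between assays, hemolysis and other pre-analytic artifacts,
correlated miRNA co-regulation, and non-additive (Ct-dependent) disease
effects. Passing tests therefore demonstrate that the pipeline's
statistics and bookkeeping are correct under the stated noise model, not
that real serum cohorts will yield transferable biomarkers.

## Numerical choices and problem sizes

* Screening is fully vectorized: the cutoff search sorts each ΔCt column
  once and scans cumulative class counts, O(n·p) memory for n samples
  and p pairs; a 130 × 16,290 cohort screens in about one second.
* Welch p-values for zero-variance-in-both-groups columns (possible with
  heavily censored pairs) fall back to t = 0, p = 1.
* Test-suite simulation sizes are scaled to keep the whole suite under a
  minute: parameter-recovery uses 30 seeded cohorts at a 10-miRNA panel
  (the planted-pair AUC statistic does not depend on panel width), null
  calibration uses 5 cohorts at 20 miRNAs, and one session-scoped
  181-miRNA cohort exercises the full 16,290-pair geometry.
* The acceptance script reruns the full reference-geometry cycle
  (181 miRNAs, 16,290 pairs, 180 samples, 2 replicates) at the supplied
  seed; it completes in a few seconds.

## Known limitations

* Resubstitution training metrics (assumed, as is conventional when only
  a single train/test split is specified) overstate training accuracy;
  interpret only the locked test-set metrics.
* No multiplicity correction is applied, by design fidelity; the
  optional Benjamini–Hochberg column is reporting-only.
* PPV/NPV are prevalence-dependent and are not projected to screening
  populations.
* The ±∞ sentinel cutoffs can be selected on degenerate (constant)
  columns; such rules classify everything into one class and never pass
  either gate.
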