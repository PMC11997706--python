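# Methods

## Model and assumptions

The package develops binary diagnostic classifiers (malignant vs. benign
breast lesion) from serum miRNA microarray profiles. Log2-transformed
signal intensities are treated as approximately normal per miRNA, with an
additive per-specimen technical offset (RNA input amount, extraction and
labeling efficiency) shared by all miRNAs of a specimen. The explanatory
variable is the within-subject difference of log2 signals of two miRNAs —
a log2 fold change — which removes the per-specimen offset exactly and so
requires no reference miRNA or global normalization. If the two members of
a pair are up- and down-regulated by δ log2 units in the malignant class,
the paired feature separates the classes by 2δ.

Validity of the ratio rests on the two miRNAs responding identically to
input concentration. This is screened empirically: each miRNA's dilution
series (serial 2× dilutions, each measured in triplicate) is regressed by
OLS — log2 signal on log2 relative concentration, the undiluted sample at
0 — and a miRNA qualifies when R² ≥ 0.975. Two qualified miRNAs may be
paired when their slopes differ by at most 0.05 (inclusive; a 1e-12
absolute slack keeps the boundary robust to float representation). The
regression uses all replicate points individually rather than replicate
means: the triplicate design prescribes no pooling rule, and per-point
regression is the stricter, more
data-efficient choice. On the log2/log2 axes a perfectly proportional
probe has slope 1, making slopes comparable across miRNAs.

The classifier is a logistic regression on at most five paired features.
Five is a deliberate cap: it limits overfitting, keeps the model auditable
for diagnostic use, and bounds the subset search. The subject-level score
("index") is the fitted probability; a score at or above the cutoff calls
the subject malignant, below it "neither cancer nor a pre-cancerous
diagnosis". The intended use is rule-out, so NPV and sensitivity are the
headline metrics.

## Fitting and subset selection

Logistic fits use iteratively reweighted least squares (Newton–Raphson on
the log-likelihood), converging when the largest absolute coefficient
update is below 1e-8, capped at 100 iterations. Complete separation —
a monotone likelihood with diverging coefficients — is reported through a
`converged` flag and message rather than raised, because subset search
must tolerate degenerate candidate subsets; the linear predictor is
clipped at ±30 to keep the working weights finite. Constant feature
columns are flagged and handled through a pseudo-inverse solve. The
implementation is cross-checked against `statsmodels.Logit` in the test
suite (coefficients to 1e-6, log-likelihood to 1e-8).

Subset selection minimizes AIC = 2k − 2 log L with k counting the
intercept (the standard convention). Two strategies:

- **exhaustive** — every subset of size 0..max_pairs; the empty subset is
  the intercept-only model, so a pair is only kept when it genuinely beats
  no-information. Used automatically for pools of ≤ 15 candidates.
- **heuristic** — forward selection to max_pairs keeping the best subset
  seen, then single-drop and single-swap local refinement until AIC stops
  improving. This plays the role of an active-set search on pools (study
  scale: thousands of candidate pairs) where enumeration is infeasible.
  Agreement with exhaustive search on small pools is a tested property
  (≥ 18 of 20 seeded instances).

Ties break toward the smaller subset, then lexicographic pair order, so
selection is deterministic. Pair orientation is canonicalized
lexicographically during enumeration; the coefficient's sign absorbs
direction. The published model's printed orientations already satisfy the
canonical order and are stored verbatim.

The cutoff is chosen on training scores: candidate thresholds are the
midpoints between consecutive distinct scores plus one value below the
minimum (which classifies everyone positive, so the sensitivity floor of
0.90 is always satisfiable); among candidates with sensitivity ≥ 0.90 the
one maximizing specificity wins, largest cutoff on ties. Midpoints make
the boundary independent of which observed score defines it. When the
below-minimum candidate wins it is mapped to half the minimum score so the
stored cutoff stays inside (0, 1). The classification rule is inclusive:
index exactly at the cutoff is a malignant call.

## Evaluation

Proportion intervals use the Wilson score method
(`statsmodels.proportion_confint`). AUC is the Mann–Whitney probability
with ties counted ½ (midranks), identical to the trapezoidal area under
the ROC built from all distinct thresholds. The DeLong interval uses
placement-value variances with a normal approximation, clipped to [0, 1];
its point estimate is computed by the same midrank formula as the ROC AUC
so the two agree exactly, including at perfect separation (degenerate
zero-width interval, reported rather than raised). Group comparisons use
Welch's two-tailed t-test by default — the safer choice under unequal
class variances — with a pooled-variance flag. Chi-squared tests on composition tables use no
continuity correction. The covariate screen uses Pearson correlation with
the t-test on the regression slope for numeric covariates and one-way
ANOVA for categorical ones, dropping levels with fewer than two subjects.
Display rounding is half-up to one decimal in percent; internal values
keep full precision.

## Synthetic data: what it emulates, and what it does not

`generate_cohort` draws per-miRNA baselines N(baseline_mean, baseline_sd),
adds a per-subject global offset N(0, subject_offset_sd) modelling RNA
input, per-cell noise N(0, noise_sd), and, for malignant subjects, ±effect
on the members of each planted pair. Detection is an explicit boolean per
cell (the microarray's detection call is vendor-defined and not modelled);
undetected cells carry NaN. Cells drop out independently at
`detection_dropout_rate`, except designated low-signal specimens, which
are forced below the detection-count threshold, and all other specimens,
which are topped up to at least the threshold so the designated set is
exactly the set failing the downstream filter. Defaults mirror the study
conditions: 140 benign / 34 malignant, ±0.2 planted effects (class
difference 0.4), a 250-signal detection threshold, nine sites, four 2×
dilutions in triplicate, and five donors × six biweekly draws. The
dropout default of 0.002/cell is calibrated so roughly 70% of miRNAs
survive universal detection over ~174 training specimens, matching the
study's screen; the pipeline's dilution-slope spread (sd 0.12) makes
roughly a quarter of pairs slope-matched at tolerance 0.05, matching the
study's 3623-of-15,931 pass fraction. Noise terms are independent and
Gaussian in log2 space.

Randomness is hierarchical (`numpy.random.SeedSequence`): one stream for
cohort-level draws, one spawned stream per subject, so enlarging a cohort
leaves existing subjects bit-identical. Sites are assigned cyclically by
subject index; clinical covariates (age, BI-RADS, breast composition,
race/ethnicity) are drawn independently of class and signal, so covariate
screens are null by construction.

Not modelled: probe cross-hybridization, hemolysis biochemistry (hemolysis
is a metadata flag only), scanner artifacts, correlated miRNA co-regulation,
non-Gaussian heavy tails, or site-specific batch effects beyond the
partition structure. Passing tests on this generator therefore demonstrate
the pipeline's correctness and its invariances (offset cancellation,
determinism, threshold boundaries), not real-serum performance; the
real-data AUC cannot be recomputed because the study's serum data are not
deposited.

## Pipeline order and the train/test split

The exclusion cascade runs: metadata exclusion (hemolysis, no pathology
consensus, "Other (in situ)" or "Suspicious/atypical" category) → the
fewer-than-250-detected-signals filter (exactly 250 is retained) → the
site-level split → miRNA eligibility. The linearity screen and the
universal-detection screen are computed independently and intersected,
which makes the result invariant to their order.
Universal detection uses training specimens only, so no test-set
information leaks into feature eligibility. Held-out subjects in which a
model miRNA is undetected cannot be scored and are dropped from
evaluation with a logged count.

The split assigns whole sites to one partition ("site-level"), measuring
cross-institution transportability. Sites can be listed explicitly or
assigned by a seeded shuffle choosing the prefix whose subject share is
closest to the requested test fraction (default 0.34, the study's 91/265).

## Numerical and interface choices

- TSV with header row is the canonical tabular format (missing = empty
  cell); CSV is accepted on read. Model files are JSON with pairs,
  coefficients, intercept, cutoff, and metadata.
- All pipeline randomness derives from one seed via `SeedSequence`;
  artifacts are byte-identical across reruns (timestamps only in the log).
- The intercept-only model is a legal selection outcome (zero pairs) when
  no pair improves AIC.
- The acceptance script reconstructs the study's confusion counts from its
  printed class sizes and one-decimal rates; the test suite verifies by
  enumeration that those integer counts are unique.
- The planted-pair recovery benchmark uses miRNA-disjoint candidate pairs:
  when two pairs are planted, a cross pair (up of one with down of the
  other) carries an identical class effect, so exact recovery is only
  identifiable among disjoint candidates.

## Problem sizes

The test suite and acceptance script run cohorts of up to 425 subjects ×
300 miRNAs, candidate pools of up to ~4000 pairs for heuristic selection
and ≤ 15 for exhaustive benchmarks, and 50–100 seeded replicates for
stochastic properties — sizes chosen to match the study's dimensions where
they matter (174/91 split, 250-signal threshold) and to keep Monte-Carlo
error well inside the asserted margins.

## Known limitations

- The published model is applied, never refit: its training serum data are
  unavailable, so only closed-form quantities (printed rates, intervals,
  the index equation) are reproduced exactly.
- The SPDAS-style heuristic is a forward-plus-swap search; it guarantees a
  local AIC optimum, not the global one, on large pools.
- The generator's independence assumptions make synthetic test-set
  performance optimistic relative to real multi-site serum data.
- No multiple-testing correction is applied in the covariate screen; each
  covariate association is reported as a single unadjusted test.
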