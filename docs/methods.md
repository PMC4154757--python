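# Methods

## Problem and model

`sarcoscreen` screens expression probes for genes that are simultaneously
*diagnostic* — discriminating histological subtypes of soft tissue sarcoma
(STS) — and *prognostic* — associated with overall survival.  Two
p-values are computed per probe:

* **p₁** — one-way fixed-effects ANOVA of the log₂-transformed signal
  across the four discrimination subtypes (UPS, MFS, MLS, SS; 72 of 88
  patients under the default cohort composition);
* **p₂** — two-group logrank test of overall survival, the groups being
  the patients above vs. at-or-below the probe's median signal, with all
  follow-up beyond 50 months treated as censored.

The screening score is the integrated statistic **p′ = p₁ · p₂**.  Because
both tests are computed on overlapping patients, p′ is not a p-value:
its null distribution is unknown and stochastically smaller than the
product of independent uniforms.  The screen therefore converts p′ into a
family-wise-error-controlled **adjusted p** with a permutation minP
(Westfall–Young single-step) construction:

1. permute whole clinical rows (subtype, survival time, event, grade,
   metastasis move together) against the fixed expression columns;
2. re-derive the four-subtype discrimination subset from the permuted
   labels, recompute every probe's p′, and record the minimum over probes;
3. repeat R times; the adjusted p of a probe is the fraction of the R
   minima at or below its observed p′.

Permuting entire rows preserves the joint dependence of subtype, survival
and covariates, which is exactly the dependence that makes p′
non-uniform; the permutation null therefore absorbs both the multiplicity
over probes and the p₁–p₂ correlation.  When no null minimum reaches the
observed p′ the adjusted value is reported as `<1/R` (`reported_lt` in
the result table), matching the conventional display `<1.00E-05` at
R = 100 000.

Expression-side quantities (log signals, median splits) are fixed across
permutations — only the clinical labels move — so each permutation is a
relabeling and the engine vectorizes it: group sums for the ANOVA are
gathered per subtype, and the logrank risk-set structure (sorted times,
tie segments, event counts, at-risk totals) is computed once because the
multiset of (time, event) pairs is permutation-invariant.  R = 1 000 on a
300-probe × 88-patient dataset takes well under a second on one core;
R = 100 000 remains tractable.

## Prefilter cascade

Probes pass, in fixed order: (1) removal of control and cross-hybridizing
probes (annotation flags); (2) removal of probes whose fraction of MAS5
Absent calls reaches 50% (≥ 44 of 88 by default; the strict `>` reading
is a switch, and Marginal calls count as present); (3) removal of probes
whose 95th-minus-5th signal percentile is below 2000 MAS5 units
(linear-interpolation percentiles at index (n−1)·p/100; nearest-rank
selectable); (4) restriction to probes in the disease-knowledge map
(OMIM-style MIM→probe pairs supplied as a file — no live retrieval).
Each stage is a pure subset operation, so stage counts always sum to the
total removed.  Log transform is log₂(x+1) — the +1 keeps zero signals
finite and is order-preserving; ANOVA p-values are invariant to the log
base.  Median binarization sends values equal to the median to the low
group; the even-n median is the mean of the two middle order statistics.

## Statistics layer

All statistics are implemented directly from their defining formulas and
cross-validated in the test suite against independent oracles (hand
tabulations, grid-search likelihood maximization, eigendecomposition,
and reference libraries):

* one-way ANOVA from group sums; a zero-variance grid returns F = 0,
  p = 1 with a flag rather than an error, so genome-wide scans never
  abort;
* k-sample logrank with hypergeometric covariance and tie handling; the
  two-sample case reduces to (O−E)²/V; zero events returns p = 1 flagged;
* Welch t with Welch–Satterthwaite df;
* Spearman rho as the Pearson correlation of mid-ranks, p from the
  two-sided t approximation t = ρ√((n−2)/(1−ρ²)) (exact permutation is
  pointless at n = 88);
* Benjamini–Hochberg step-up q-values;
* Kaplan–Meier product-limit curves stepped at event times;
* Cox proportional hazards for a binary covariate by Newton iteration on
  the Breslow partial likelihood (ties are Breslow; with continuous
  simulated times Breslow and Efron coincide).  A monotone likelihood
  (all events in one group) is clipped at |log HR| = 15 and flagged
  non-converged;
* PCA of the standardized data (correlation-matrix PCA) by symmetric
  eigendecomposition, sign-fixed so each component's largest-magnitude
  loading is positive; covariance PCA is a switch.  Correlation PCA is
  the default because MAS5 signals span orders of magnitude;
* complete-linkage agglomerative clustering on Euclidean distances with
  a lexicographic tie-break on cluster-id pairs for cross-platform
  determinism;
* row scaling to mean 0, SD 1 (ddof = 1, the R `scale` convention used
  by heatmap tools).

## UPS threshold scan

Within a single-subtype cohort (UPS by default) each probe is split at
the 30th–80th signal percentiles; `p_best` is the minimum logrank p over
thresholds.  The permutation null permutes the cohort's clinical rows
and records, per repetition, the minimum p over the *whole* probe ×
threshold grid (the joint reading of a "6 thresholds × k probes"
correction); a per-probe null is available as `mode="per_probe"`.
Thresholds that give an empty group are skipped; a probe with every
threshold degenerate is flagged and excluded.

## Synthetic cohort generator

The generator emulates the structure of the motivating 88-patient STS
cohort and is the package's test bed:

* subtype counts 20 UPS / 20 MLS / 17 SS / 15 MFS / 6 LMS / 5 FS /
  5 MPNST (configurable);
* survival: exponential event times with rate
  `base_hazard[subtype] · exp(β·z)`, where z ∈ {0,1} is a latent
  per-patient risk class (fair coin) and β = `hazard_log_hr` (default
  1.5).  Baseline hazards are ordered MFS 0.004 < MLS 0.010 ≈ SS 0.011
  < … < UPS 0.028 events/month so subtype prognosis is ordered (MFS
  best, UPS worst).  Administrative censoring at 60 months; the analysis
  itself re-censors at the 50-month horizon.  Because the hazard is
  log-linear in z, the Cox/logrank stages have a correctly specified
  target and parameter recovery is meaningful;
* grade from subtype-specific multinomials monotone in malignancy;
  metastasis Bernoulli with probability increasing in grade (0.15 /
  0.40 / 0.65) — this gives the Spearman stage a signed target;
* expression: signals are 2^v with v = per-probe baseline + planted
  shifts + N(0, 0.7) noise on the log₂ scale.  Baselines are
  U(5, 12.5) — median signal near the MAS5 target scaling of 1000.
  Planted probes draw baselines from the well-expressed range (≥ 2¹⁰) so
  the detection/range prefilters act only on null probes; a real screen
  has no such guarantee (see Limitations);
* planted effects: `diagnostic` probes shift one designated
  discrimination subtype's mean by 1.5 log₂ units (rotating across UPS,
  MFS, MLS, SS); `prognostic` probes add 1.5·z; `both` probes carry both
  effects.  Default fractions are 5% of probes per class on 300 probes;
* Absent calls are logistic in v (midpoint log₂ = 6, slope 1.5) — low
  signal → Absent, mimicking MAS5 detection without probe-level data;
  Marginal calls occur at 3%;
* the knowledge map contains every planted probe plus 80% of null
  unflagged probes, encoding the premise of knowledge-based screening
  that disease genes are annotated in the knowledge source.

All randomness derives from one master seed through named substreams
(cohort, latent, survival, expression, calls, assignment, knowledge), so
any stage can be regenerated independently and reruns are bit-identical.

### What the generator does not emulate

Batch effects, probe-level PM/MM structure, competing risks,
subtype-specific expression programs beyond single-probe shifts, and
annotation errors (every probe is correctly annotated, and planted
probes are guaranteed to be in the knowledge map and well expressed).
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under its own assumptions, not robustness to the
failure modes of real microarray data.

## Numerical choices

* Percentiles: linear interpolation between order statistics (the common
  statistical-software default); nearest-rank is a switch.
* Adjusted p estimator: plain exceedance k/R with `<1/R` display at
  k = 0; the conservative (k+1)/(R+1) variant is deliberately not the
  default because the display convention is the reported one.
* The logrank arm of the screen defaults to all 88 patients
  (`survival_cohort="all"`); restricting to the 72 discrimination-subtype
  patients is `survival_cohort="discrimination"`.  Both views appear in
  descriptions of this design; the figure-level description (all
  patients) is the default.
* Engine p-values use `scipy.special` distribution tails (`fdtrc`,
  `chdtrc`); the scalar statistics layer agrees with the vectorized
  engine to ≈1e-10 (different summation orders).
* Degenerate probes (constant signal, or a median split with one empty
  group) are flagged and excluded from the screen and from the null
  minima, consistently between observed and permuted computations.

## Problem sizes used in the test suite

Simulation-based checks run at 300 probes × 88 patients with R = 1 000
permutations (200 datasets for the family-wise error calibration, 50 for
planted-effect recovery), chosen so the full suite completes on a single
core in a few minutes while leaving the binomial noise of the estimated
rates well inside the asserted bands.

## Known limitations

* The minP adjustment is single-step, not step-down; it is conservative
  for all but the best probe.
* The Cox stage estimates a single binary covariate only (no
  stratification or multivariable adjustment), which is all the pipeline
  needs for high/low expression hazard ratios.
* At n ≈ 20 with strong effects (log HR ≈ 2) the binary-covariate Cox
  estimate is information-limited — late risk sets contain only the
  low-hazard group — so roughly a quarter of estimates fall more than
  0.75 log-units from the truth; the recovery test documents this rate.
* Percentile-threshold scans at small n are power-limited: with a
  log HR of 1.5 at n = 20 the planted probe wins the joint-minP scan
  barely more than half the time; recovery becomes reliable (≈ 86%)
  near log HR 2.
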