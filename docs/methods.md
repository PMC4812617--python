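# Methods

## Model and estimation

The prediction model is a two-block ridge regression treated as a mixed
model: `y = 1β₀ + Fu + Mv + e` with `uⱼ ~ N(0, σ²_f)`,
`vⱼ ~ N(0, σ²_m)`, `eᵢ ~ N(0, σ²_e)`.  The intercept is the only fixed
effect.  The model assigns one average effect per predictor and parent
pool; it captures additive gene action plus the part of dominance that
divergent pool allele frequencies convert into average effects, and it
omits specific combining ability (SCA) entirely — SCA and field error
are confounded in the residual.

**REML.** The restricted likelihood is defined as the Gaussian
log-density of `A'y`, where `A` is an orthonormal basis of the
orthogonal complement of the intercept column.  This form is
basis-invariant and fixes the additive constant, which the test suite
exploits by checking the implementation against an explicitly
constructed contrast basis.  Internally the likelihood is evaluated
through `H = I + γ_f FF' + γ_m MM'` with variance ratios
`γ = σ²/σ²_e`; `σ²_e` and `β₀` are profiled out analytically, so the
optimization is two-dimensional.  The optimizer is deterministic: a
coarse grid over `log₁₀ γ ∈ {-4, -2, 0, 2, 4}²` followed by Nelder-Mead
refinement (objective tolerance 1e-8) with ratios clipped to
`[1e-6, 1e6]`.  A ratio that ends on the lower boundary is reported as
an exactly zero component and its effect block is dropped from the MME
rather than inverting a near-singular system.  The restricted
likelihood of degenerate designs can be multimodal; the grid start
makes the search reproducible and robust at the problem sizes this
package targets (n ≤ a few hundred).

**BLUP.** Two algebraically equivalent solvers are kept: the explicit
`(1+2p)`-dimensional Henderson system with ridge penalties
`λ_f = σ²_e/σ²_f`, `λ_m = σ²_e/σ²_m`, and an n-dimensional route
`û = γ_f F'H⁻¹(y − 1β̂₀)` (the Woodbury form).  `auto` selects the
explicit system when `2p + 1 ≤ n` and the n-route otherwise; tests
assert agreement of both routes with a brute-force dense assembly to
1e-8.  Cross-validation always uses the n-route and accepts precomputed
`FF'`/`MM'` kernels, which makes 1000 refits on a 98-hybrid factorial a
matter of seconds even with ~10⁴ predictors.

**Prediction.** `ŷ* = β₀ + F*û + M*v̂`; predicted general combining
abilities are the two block terms.  `F*`/`M*` for new lines are built
with the normalization constants stored in the fitted model, never
recomputed from the new lines.

## Predictor preparation

* **Markers** (dominant presence/absence): columns are removed when the
  missing fraction exceeds 0.10 or the gene diversity `2p(1−p)` falls
  below 0.2 (defaults; both thresholds exposed).  Remaining missing
  calls are imputed by the within-pool band frequency — unbiased for
  observed column means; fractional imputed values are permitted in the
  design.  Marker columns are not normalized: their maximum is already
  1, so the max-normalization would be vacuous.
* **Transcripts**: the differential-expression screen keeps genes that
  (a) vary across lines by a per-gene one-way F-test with
  Benjamini-Hochberg control at FDR 0.01, (b) show a maximal pairwise
  line-mean fold change ≥ 1.3 on the log2 scale, and (c) have mean log2
  intensity ≥ 8.  The screen is a plain F-test by design — empirical-
  Bayes variance moderation is out of scope here — and the retained
  gene list is an explicit input everywhere downstream, so an
  externally computed screen can be substituted.  Fold/intensity
  criteria operate on log2 values; the design-matrix normalization
  operates on linear intensities (`f_ij = o_ij / max_k o_kj`, maxima
  over the pool's parental lines).
* **Normalization scope**: maxima are computed once from all lines of a
  pool, matching the formula as written.  Computing them from an
  estimation set only (the information-leakage-free variant) is
  available through `build_design(..., norm_lines=...)`.  At factorial
  scale the difference is negligible because every pool line appears in
  almost every estimation set.

## Cross-validation

* **Type 2**: sample 3 female and 5 male lines; the 15 crosses among
  them are the validation set, the other 83 crosses the estimation set.
  Both parents of every validation hybrid then have testcross data — 
  the defining type-2 condition.  The scheme flag `type2_literal_text`
  swaps the two sets, exposing an alternative reading of the scheme's
  verbal description under which the sampled block trains the model;
  that variant violates the type-2 condition and is off by default.
* **Type 0**: sample 5 female and 10 male estimation lines; estimation
  = the 50 crosses among them, validation = the 8 crosses among the
  remaining 2 × 4 lines; the 40 mixed crosses are used in neither set.
* Runs are seeded `base_seed + run_index`, so any run can be reproduced
  in isolation.  The per-run mRNAr1k gene sample draws from a separate
  stream keyed by `(base_seed, run_index, tag)`; resampling per run is
  the default (fixing one sample is a one-line change via `genes=`).
* Accuracy is the Pearson `r(y, ŷ)` and the mean absolute error per
  run; summaries are medians and means over runs.  A run whose
  validation response or prediction is constant has undefined `r`: it
  is recorded as missing, counted, and excluded from the summaries
  rather than aborting — consistent with keeping every run when the
  distribution includes extreme values.

## Synthetic data generator

The generator's defaults are the study conditions: a 7 × 14 factorial
(98 hybrids), 970 dominant markers, 10,810 transcripts, broad-sense
heritability 0.80 and SCA:GCA variance ratio 1.12 on a grain-yield-like
scale (mean 11.7).  Phenotypes follow
`y_fm = μ + g_f + g_m + s_fm + e_fm`:

* **GCAs** are sums of Gaussian per-pool effects at `n_causal` shared
  causal markers (default 50 — an oligo-/polygenic middle ground for a
  yield-like trait), centered and rescaled so their sample variance
  equals the configured `var_gca_f`/`var_gca_m` exactly.  Pools share
  the causal positions but have independent band frequencies and
  effects, mirroring divergent heterotic pools.
* **SCA and error** are independent draws per cross (`var_sca`,
  `var_error`).  SCA is deliberately not predictor-linked: the fitted
  model omits it, so in the generator it plays its real role of
  structured noise.
* **Markers**: pool-specific band frequencies uniform on (0.1, 0.9);
  missing calls at rate 0.02 (typical for a curated dominant-marker
  panel; the real panel was pre-filtered, so a low rate is realistic).
* **Transcripts**: per-gene baselines `N(9.5, 1)` on the log2 scale,
  chosen so a realistic fraction of genes clears the intensity-8
  screen.  Each causal marker perturbs a random 5% of genes
  (`N(0, 0.6)` log2 loadings), so transcripts tag the same signal as
  markers — the empirical marker/transcript parity becomes a testable
  property.  Replicates (default 3 per line) add `N(0, 0.25)` log2
  noise; intensities are exponentiated, hence strictly positive.
* **Per-se values and heterosis**: inbred performance is
  `μ − 2.5 + 1·g + noise`.  The GCA coefficient of 1 (rather than the
  2 a purely additive model would give) leaves half of each GCA inside
  the mid-parent heterosis `MPH = y_fm − (P_f + P_m)/2`, the standard
  definition adopted here; that is the generator's stand-in for
  dominance-driven, predictor-linked heterosis and makes MPH a
  non-trivially predictable response.

What the generator does **not** emulate: linkage and recombination
(markers are exchangeable given their frequencies), multi-location
trial structure and GCA×environment interaction, incomplete factorials,
microarray normalization artifacts, and correlated missingness.
Passing tests therefore demonstrate correctness and the method's
statistical behaviour under the modelled structure, not field-data
performance; with SCA:GCA = 1.12 and h² = 0.8 the synthetic factorial
is *harder* than the real data appear to be (the realized type-2
medians here sit near the theoretical ceiling
`√(σ²_GCA/σ²_total) ≈ 0.6` imposed by unpredictable SCA + error).

## Numerical and design choices

* Problem sizes in tests and the acceptance script are the study's
  (n = 98; marker p = 970) with transcript panels of 1000–10,810
  depending on the experiment; run counts are 1000 where the run count
  itself is the point and 50–200 for ordering experiments, where
  medians stabilize quickly.
* All randomness flows through `numpy.random.default_rng`; datasets are
  bitwise reproducible from their config, CV runs from
  `base_seed + run_index`.
* Model files store effects at 17 significant digits and are re-read
  with round-trip float parsing, so a reloaded model predicts
  identically.
* The CLI is deliberately thin (`simulate`, `cv`, `run-all`); filters,
  design assembly, fitting and prediction are library calls
  (`examples/` shows each).  A thread-count knob was considered and
  dropped: at these problem sizes a single core is fast and identical
  results across thread counts are then trivially guaranteed.
* Degenerate inputs: all-missing marker columns, pool-wide missing
  blocks, non-positive intensities, unknown parent ids and mismatched
  dimensions raise typed errors (`DataError`/`ConfigError`) naming the
  offender; zero variance components are handled by dropping blocks.

## Known limitations

* The REML optimizer is tuned for two variance components; it does not
  generalize to more random-effect blocks without widening the search.
* `run_cv` assumes a complete factorial; incomplete factorials are
  rejected rather than handled.
* The per-gene F-test screen ignores the correlation structure a
  loop-design microarray experiment induces; with few replicates it is
  less powerful than a moderated test.
* Mid-parent heterosis prediction refits the same model with MPH as the
  response; no model change is attempted.
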