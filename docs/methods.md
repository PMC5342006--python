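# Methods

## The screening model

The pipeline treats a candidate synthetic-lethal (SL) pair as a
*tumor-dependent* pair: one whose joint differential expression tumor tissue
appears to require. Three data layers feed four stages.

### Co-differential-expression sifting

Input is a patient × gene table of log₂(tumor/matched-normal) expression
ratios. All ratios are stored in log base 2, so a fold cutoff c enters as
±log₂ c; "1.5-fold" means |log₂ ratio| ≥ log₂ 1.5 ≈ 0.585, with inclusive
boundaries throughout (matching the "≥" conventions of the IHC criteria).
The open band (1/c, c) belongs to no pattern, so the four pattern fractions
of a pair sum to at most 1.

The permutation null exchanges each patient's tumor/normal labels
independently with probability ½; an exchange negates that patient's
log-ratios for **both** genes jointly. Joint flipping is the only scheme
consistent with exchanging tissue labels — flipping genes independently
would break the within-patient pairing the statistic depends on. The
reported p-value uses the add-one convention (1 + #{≥ observed})/(1 + N),
which is a valid p-value (never 0) and reproduces the 0.0001 reporting floor
at N = 10,000 after four-decimal rounding; the raw proportion is available
via `add_one=False`. When 2ⁿ ≤ N the implementation switches silently to
exhaustive enumeration of all 2ⁿ label assignments and the p-value is exact
over that set. Patients missing either gene's value are dropped pairwise.

q-values use Storey's estimator: π₀(λ) = #{p > λ}/(m(1−λ)) on the grid
λ = 0.05, 0.10, …, 0.95, smoothed by a cubic polynomial and read off at
λ = 0.95, clipped to (0, 1]; q_i = π₀ · min_{p_j ≥ p_i} (m p_j / rank_j).
`method="bh"` fixes π₀ = 1. The default family is all tested
(pair, pattern) hypotheses in the expression screen and the per-feature
family in the synergy screen (`fdr_family="global"` merges the latter).

### IHC synergy screen

IHC observations live on the ordinal scale 0 < ± < 1+ < 2+ < 3+ or as a
percent stained; each marker's criterion is a direction (≥ or <) and a
threshold, and the bundled 23-marker default panel reproduces the published
criteria of the 131-patient lung-adenocarcinoma study the package ships as
reference data. Pair enumeration excludes same-protein, multi-location
pairs by protein symbol (not antibody), giving C(23,2) − 3 = 250 pairs for
the default panel.

Fisher's exact test uses the probability-ordering two-sided convention (sum
of hypergeometric probabilities, at fixed margins, no more probable than the
observed table, with relative tie tolerance 1e−7); mid-p and doubling
conventions differ in the third decimal and are not offered. A zero margin
returns p = 1 — no association is testable. The five clinical features are
dichotomized as: death before 36 months (patients censored alive before 36
months are excluded from that feature's table; including them as
non-adverse is an explicit flag), poorly differentiated grade, metastasis,
N1–2 nodal disease, stage III–IV.

Classification: *synergistic* requires pair p < α with both single-marker
p ≥ α; *putative* requires pair p < α and strictly smaller than both
singles. The strict inequalities mean a printed-precision tie between the
pair and a single p-value classifies as neither — deliberate, since the
putative rule is defined by the pair being *more* significant.

### Survival markers and risk transfer

Cox models use Efron tie handling (the default of the survival software
ecosystem this field uses). Stepwise selection is bidirectional from the
full candidate model, greedily applying the single add/drop move that most
reduces AIC (= −2 log partial likelihood + 2k) until no move improves it;
the empty model's AIC uses the null partial likelihood. VIF_j =
1/(1 − R²_j) from an intercepted least-squares regression of indicator j on
the rest; perfectly collinear columns report +∞.

Fold-change marker rules flag a subject only when *every* gene passes its
directional cutoff (↑: ≥ c× reference; ↓: ≤ reference/c, boundaries
inclusive), with per-gene cutoff overrides. For cohorts without matched
normals the reference is the per-gene cohort median, a configurable choice —
the right reference for such cohorts is genuinely open, and median-centering
is the least-assumption default.

Risk scores are the fitted linear predictor Σβx; the hazard ratio of a
transferred score is reported per unit of linear predictor. Concordance is
the Gönen–Heller estimator (the only established "concordance probability
estimate" by that name), computed from scores alone and hence immune to
validation-set censoring; Harrell's C is deliberately not substituted.
Kaplan–Meier display groups split at the median score with ties to the low
group. Constant transferred scores (a marker absent from a validation
cohort) mark the evaluation not-applicable rather than failing.

## The synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes, at
the study's stated scale: 83 expression-profiled patients, 131 IHC/clinical
patients, a 23-marker panel with the published per-marker abnormality rates
as default marginals.

* **Expression.** Baseline entries are N(0, σ²) log₂-ratios with σ = 1.0 by
  default — the typical spread of microarray tumor/normal log-ratios, which
  puts chance (up,up) co-occurrence at the few-percent level seen in real
  unrelated pairs. A planted pair overwrites a Bernoulli(penetrance) subset
  of patients with ±log₂(fold) on both genes, signs set by the pattern. At
  σ = 1.0 the observed fraction estimates penetrance *plus* the chance
  background; recovery checks that target the penetrance itself use
  σ = 0.1, where the background is negligible.
* **IHC/clinical.** Marker abnormality is Bernoulli at its marginal rate and
  mapped back to an ordinal grade drawn uniformly from the grades consistent
  with the call (uniform percent within the consistent range for
  percent-criterion markers). Pair×feature synergy is planted as a
  **centered pure-epistasis interaction** on the feature's log-odds:
  η = logit p₀ + log(OR)·(a−q_a)(b−q_b)/((1−q_a)(1−q_b)) for marker
  indicators a, b with marginal rates q_a, q_b. The both-abnormal cell's
  odds are multiplied by exactly OR, while the centering cancels each
  marker's marginal main effect (exactly at balanced rates, to first order
  otherwise) — this is what "pair associated, singles not" requires; the
  naive alternative (elevate only the both-abnormal cell, leave other cells
  at baseline) leaks a strong marginal association into both single-marker
  tests and cannot produce the synergistic signature. A corollary worth
  knowing: with a strong OR the both-normal cell's rate also rises, which is
  the unavoidable price of zero marginal effects in a 2×2 of Bernoulli
  margins. Feature flags are rendered as categorical clinical fields, and
  the survival-time column is drawn to agree with the death-before-36-months
  flag.
* **Survival.** Event times are exponential with hazard h₀·exp(Σβx)
  (default h₀ = ln 2 / 48 per month, a 4-year baseline median typical of a
  resected-adenocarcinoma cohort), censored by an independent
  Uniform(0, 120 months) time. This is the simplest generative model
  consistent with proportional hazards.
* **Determinism.** One seed per study; each component (expression, IHC,
  clinical, survival) draws from its own child stream keyed by a fixed CRC32
  label, so adding markers never perturbs expression draws. Identical specs
  give bit-identical studies.
* **What it does not emulate:** probe intensities or normalization, RNA-seq
  counts, correlation between the expression and IHC layers (independent
  unless coupled by the caller), non-proportional hazards, informative
  censoring. Passing tests therefore certify the *inference machinery*, not
  robustness to those real-data features.

## Numerical and design choices

* Expected screen tables carry a `rank` from the lexicographic sort on
  (f_uu, f_ud, f_du, f_dd), residual ties broken by gene symbol.
* `fisher_exact_2x2` delegates to the scipy implementation of the
  probability-ordering convention; the test suite verifies it against
  independent hypergeometric enumeration on every 2×2 table up to total
  count 40.
* The exact permutation test on a discrete pattern count is conservative
  when the achievable-p grid is coarse: at 83 patients its type-I error at
  α = 0.05 is ≈ 0.03. This is granularity, not miscalibration — the test is
  exact over the exchange distribution, as the exhaustive-enumeration
  agreement checks certify. The null-calibration suite therefore measures
  the 5%-level rejection rate at 200 patients, where the grid is fine near
  0.05.
* Degenerate inputs: all-censored survival data, constant covariates, empty
  expression matrices and zero margins raise informative errors (or p = 1
  where a convention exists) rather than propagating NaNs.

## Known limitations

* Storey's π₀ smoother is a cubic polynomial on the λ-grid rather than a
  spline; on small families (m < ~100) π₀ is noisy and the BH mode is the
  safer choice.
* Stepwise-AIC selection inherits the usual instability of greedy model
  search; the selection trace is returned so runs can be audited.
* The 2-hop expansion is purely combinatorial — it proposes, it does not
  test; proposed pairs should re-enter the synergy screen.
* At the study's own cohort sizes (83/131 patients) single-seed estimates
  are noisy (wide Cox CIs, occasional sign flips for weak effects); the
  guarantees in the test suite are formulated over repeated seeds and, for
  hazard-ratio recovery, at n = 1000.
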