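# slsift

Screening for candidate **synthetic-lethal (SL) gene pairs** from tumor
cohort data. Two genes are synthetic lethal when losing both kills a cell
but losing either alone does not; SL partners of genes already mutated in a
tumor are attractive drug targets because hitting them spares normal cells.
`slsift` implements an integrated screening pipeline for this problem —
built for cancer biostatisticians who have paired tumor/normal expression,
immunohistochemistry (IHC) and clinical outcome tables and want to go from a
literature list of candidate pairs to ranked, survival-annotated SL
predictions — together with a synthetic-cohort generator so that every stage
is testable end-to-end without any external download.

## What it computes

**1. Co-differential-expression sifting** (`slsift.expression`). For a gene
pair (g₁, g₂) and per-patient log₂(tumor/normal) ratios, a patient is *up*
for a gene when the ratio ≥ log₂ c and *down* when ≤ −log₂ c (fold cutoff
c = 1.5). Each pair gets four pattern fractions f₍uu₎, f₍ud₎, f₍du₎, f₍dd₎ —
the proportions of patients with both genes in each up/down configuration
(patients in neither zone count toward none, so the fractions need not sum
to 1). Significance is a label-exchange permutation test: each of 10,000
permutations flips, per patient with probability ½, the tumor/normal labels,
negating that patient's ratios for both genes jointly; p = (1 + #{permuted
fraction ≥ observed})/(1 + 10,000), with exhaustive enumeration of all 2ⁿ
flips replacing Monte Carlo when 2ⁿ ≤ n_perm. FDR over the tested family is
controlled by Storey q-values (π₀ estimated on a λ-grid with a cubic
smoother; Benjamini–Hochberg available as `method="bh"`). Pairs with any
fraction above 1% are ranked lexicographically by (f₍uu₎, f₍ud₎, f₍du₎, f₍dd₎).

**2. IHC synergy screen** (`slsift.synergy`). Markers are dichotomized by
per-marker criteria on the ordinal staining scale 0 < ± < 1+ < 2+ < 3+ (or a
percent-stained cutoff); the bundled default panel has 23 markers over 20
proteins and enumerates 250 pairs (same-protein, different-location pairs
excluded). Each pair is tested by two-sided Fisher's exact test against five
dichotomized clinical features (death < 3 years, poor grade, metastasis,
N1–2 nodal disease, stage III–IV). A pair is **synergistic** when the
both-abnormal indicator associates with the feature (p < 0.05) while neither
single marker does, and **putative** when the pair's p-value is significant
and strictly smaller than both single-marker p-values. Either label
nominates the pair; candidates are expanded by the 2-hop rule (A–B and B–C
known ⇒ propose A–C).

**3. Survival markers** (`slsift.survival`). Kaplan–Meier curves,
Mantel–Haenszel log-rank tests, univariate Cox proportional-hazards fits
(Efron ties), bidirectional stepwise model selection under AIC, variance
inflation factors for collinear indicator sets, and directional fold-change
rules (e.g. *RAD54B*↑ at 2-fold, per-gene overrides) for expression-based
cohorts.

**4. Predictive risk models** (`slsift.risk`). Cox risk models over marker
indicators (± age/stage covariates) fitted on a training cohort transfer to
validation cohorts as linear-predictor risk scores, evaluated by the hazard
ratio of the score and the Gönen–Heller concordance probability estimate

    K = 2/(n(n−1)) Σ_{i<j} [ I(sᵢ ≥ sⱼ)/(1+exp(sⱼ−sᵢ)) + I(sⱼ > sᵢ)/(1+exp(sᵢ−sⱼ)) ],

a model-based concordance measure (0.5 = no discrimination) unaffected by
censoring in the validation outcomes.

**5. Synthetic cohorts** (`slsift.cohort`). Generates the three coupled
tables the pipeline consumes with planted truths: co-expression patterns at
a chosen penetrance and fold, pure-epistasis pair×feature interactions
(both-abnormal odds × OR, single-marker margins null), and exponential
survival with proportional marker hazards under uniform censoring.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study and
write their tables under `results/`:

```sh
python analysis/01_simulate_cohorts.py     # 83-patient expression + 131-patient IHC cohorts
python analysis/02_expression_screen.py    # pattern fractions, permutation p, q-values
python analysis/03_ihc_synergy_screen.py   # 250 pairs x 5 features, labels, 2-hop
python analysis/04_survival_markers.py     # KM/log-rank, Cox, stepwise AIC, VIF
python analysis/05_predictive_risk.py      # risk-model transfer, HR of score, CPE
```

With the default seed, script 02 prints

```
4 pairs screened; 4 pass the 1% rule
top-ranked pair: FEN1-RAD54B with (up,up) fraction 0.34
planted FEN1-RAD54B (up,up): fraction 0.34, permutation p = 0.0001, q = 0.0016
```

— the pair planted at penetrance 0.31 tops the ranking with the floor
p-value (1/10,001 rounds to 0.0001), while the three unplanted literature
pairs show near-chance fractions. Script 03 prints

```
1250 pair x feature tests; 26 labelled records
25 distinct predicted SL pairs; 47 2-hop expansions
planted FEN1(N)-RAD54B(N) x metastasis: pair p = 0.0026 (singles 0.691 / 1.000) -> synergistic
```

— the planted interaction is recovered as a synergistic correlation (pair
significant, both singles null); the remaining labelled records are the
expected false-positive background of 1,250 tests at α = 0.05, which the
attached q-values flag as such. Script 05 shows risk-score transfer, e.g.

```
            model  HR_of_score  ci_lower  ci_upper   CPE
      marker_only         2.26      1.44      3.54 0.536
marker+covariates         2.09      1.73      2.51 0.658
  covariates_only         2.27      1.78      2.88 0.627
```

— the covariate-augmented marker model discriminates best, and the CPE
ordering (marker+covariates ≥ covariates-only) mirrors what one expects when
the marker carries real signal.

A `slsift` command-line interface wraps the same stages
(`slsift simulate`, `slsift screen-expression`, `slsift screen-synergy`,
`slsift run-all --config config.yaml`).

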