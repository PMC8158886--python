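# Methods

This note records the statistical model implemented by `metabometa`, the
design of the synthetic-study generator used to validate it, the default
parameter values and why they were chosen, and the known limitations of
both.

## 1. Analysis pipeline

### 1.1 Outcome and outlier exclusion

The outcome is the percent change in the homeostatic model assessment of
insulin resistance,

    %ΔHOMA-IR = 100 · (HOMA-IR_followup − HOMA-IR_baseline) / HOMA-IR_baseline,

with HOMA-IR = glucose · insulin / 405 for glucose in mg/dL (the molar
convention, glucose · insulin / 22.5, is also supported). Before any
modeling, each cohort excludes subjects whose outcome lies more than
`k = 5` sample standard deviations (ddof = 1) from the cohort mean. The
rule is applied in a **single pass**: mean and SD are computed once, on
the full cohort, and every subject beyond the threshold is removed
simultaneously. There is no re-iteration after removal, so the excluded
set is a deterministic function of the raw outcome vector. When the SD is
zero no one is excluded. A consequence of the single-pass rule worth
knowing: one displaced point among n others contributes at most about √n
standardized deviations, so a 5-SD rule cannot fire at all in cohorts of
fewer than ~27 subjects.

### 1.2 Per-cohort regression

Raw LC-MS peak areas are natural-log transformed; zeros are treated as
missing (and tracked separately as "zeroness"). For each metabolite j in
cohort c, two ordinary-least-squares models are fit on complete cases:

* **univariate**: `%ΔHOMA-IR ~ 1 + log x_j`
* **full**: `%ΔHOMA-IR ~ 1 + log x_j + age + sex + race + baseline
  triglycerides + %Δweight`

Categorical covariates are dummy-coded with the largest level as
reference; single-level factors are dropped. Designs are checked for full
column rank via pivoted QR, and rank-deficient fits raise an error naming
the collinear columns. Fits with fewer than 3 complete cases or with a
zero-variance predictor are skipped (the metabolite simply contributes no
estimate from that cohort). Inference on the metabolite coefficient is
the classical t test; the per-cohort outputs are (β̂_jc, SE_jc, n_jc,
p_jc).

### 1.3 Inverse-variance meta-analysis

Per metabolite, the k available cohort estimates are pooled two ways.

**Fixed effects** with weights w_c = 1/SE_c²:

    β̂_F = Σ w_c β̂_c / Σ w_c,   SE_F = (Σ w_c)^{-1/2}.

**Heterogeneity** via Cochran's statistic

    Q = Σ w_c (β̂_c − β̂_F)²,  df = k − 1,  p_Q = P(χ²_df ≥ Q),

with H = √(Q/df) and I² = max(0, (Q − df)/Q). For k = 1 we set Q = 0,
df = 0, and p_Q undefined (NA).

**DerSimonian–Laird random effects** with

    τ̂² = max(0, (Q − (k−1)) / (Σ w − Σ w²/Σ w)),  w*_c = 1/(SE_c² + τ̂²),

pooled as above with w*. All pooled p-values use the normal (z)
approximation. By construction SE_random ≥ SE_fixed.

**Filtering.** A metabolite enters the meta table only if its pooled
missing fraction — missingness-weighted by cohort size, with a metabolite
entirely absent from a cohort counted as fully missing there — is
**strictly below 0.25** and the metabolite has a known identity.
Association p-values (fixed and random) are Benjamini–Hochberg adjusted
across the retained metabolites; heterogeneity p-values are reported
nominally, as the heterogeneity analysis is treated as
hypothesis-generating.

### 1.4 Metabolite-set enrichment

Metabolites are ranked in descending order (ties broken lexicographically
by identifier) by either the random-effects z statistic (`signed_z`,
association) or Cochran's Q (`q_stat`, heterogeneity; metabolites
measured in fewer than 2 cohorts are dropped since Q is undefined). Each
chemical-taxonomy subclass with at least `min_size = 5` retained members
is scored by a weighted Kolmogorov–Smirnov running sum: walking down the
ranked list of N metabolites with n set members, a hit adds
|s_i|^w / Σ_hits |s|^w and a miss subtracts 1/(N − n); the enrichment
score ES is the signed extremum of the walk (the walk always terminates
at zero). The weight exponent defaults to w = 1. If the total hit mass is
zero (all member statistics exactly zero) the hit increments fall back to
equal mass 1/n.

**Null distribution.** The null is generated by **membership
permutation**: uniformly random size-matched subsets of the ranked list.
Nulls are shared across all sets of the same size and seeded by
`default_rng([seed, size])`, so results are invariant to the order in
which sets appear in the database. An exhaustive mode enumerates all
C(N, n) memberships for small problems and is used to validate the
sampler. The permutation p-value is one-sided among same-sign null
scores, with add-one smoothing:

    p = (nMoreExtreme + 1) / (n_same_sign + 1).

NES divides ES by the mean |null ES| of the same sign; if no same-sign
null scores exist, p = 1 and NES is undefined (NA, with a warning).
Set-level p-values are BH-adjusted across tested sets.

## 2. Synthetic-study generator

The generator exists so that the full pipeline can be exercised, and its
operating characteristics measured, without patient data. Everything is
driven by a single integer seed through `numpy`'s `default_rng` with
spawn-style seed lists (`[seed, 0]` for the shared annotation,
`[seed, 10+i]` for cohort i), so studies are reproducible and cohorts are
independent given the seed.

**Metabolome.** `n_metabolites` features partitioned into taxonomy
subclasses (by default a 22-subclass composition totaling 765, with
subclass sizes shrunk proportionally for smaller panels). Each metabolite
gets an identifier, an HMDB-style accession, one of 4 LC-MS method
labels, a coefficient of variation drawn from U(0.02, 0.5], and a log
abundance mean from N(15, 2).

**Abundances.** Log abundances within a subclass are exchangeable with
correlation ρ (`within_subclass_correlation = 0.5` by default),
implemented by a shared subclass factor. Lipid subclasses (keyword-matched
on the subclass name) are additionally coupled to the subject's
standardized baseline-triglyceride z score with loading
`tg_coupling = 0.5`, mimicking the strong lipid–clinical-lipid
correlations seen in real plasma metabolomics. Raw abundances are
exponentiated and masked missing completely at random
(`missingness_rate = 0.05`).

**Outcome.** The outcome is additive on the percent-change scale:
cohort-specific mean and SD (defaults emulate a behavioral, an exercise,
and a surgical cohort with n = 443/163/125 and %ΔHOMA-IR ≈ −16 ± 105,
−16 ± 42, −71 ± 21), a weight-change contribution
(`weight_effect = 0.5`), plus any planted metabolite effects. Glucose and
insulin at baseline/followup are back-computed to be consistent with the
HOMA-IR values.

**Planted effects** (`default_config`): a *homogeneous* effect of
−0.15 cohort-outcome-SD per standardized log abundance in 30
triacylglycerol-like members (same sign in every cohort), and a
*heterogeneous* effect of ±0.3 SD in 14 amino-acid-like members whose
sign flips in the surgical-like cohort. The magnitudes were chosen a
priori to be detectable at the set level at the default cohort sizes
without being trivially large at the metabolite level; they were not
adjusted after observing test outcomes.

**Planted outcome outliers.** Each cohort displaces
`n_outcome_outliers = 2` randomly chosen subjects' outcomes. The
displacement starts at 6 post-hoc SDs and grows geometrically (×1.4)
until the single-pass 5-SD rule flags exactly the planted subjects — a
fixed displacement cannot guarantee this because the displaced points
themselves inflate the SD used by the rule.

**Null configuration** (`null_config`): no planted effects, no TG
coupling, and ρ = 0. The zero correlation is deliberate: the membership
permutation null assumes exchangeability of metabolites across set
boundaries, so calibration of its p-values is only expected (and only
tested) under that assumption. This was a theory-driven choice made
before measuring calibration, not a tuning response.

## 3. Default parameters at a glance

| Parameter | Default | Rationale |
|---|---|---|
| Outlier rule `k` | 5 SD, single pass | conservative; removes only gross outcome errors |
| Missingness cut | pooled fraction < 0.25, strict | balances coverage vs. complete-case instability |
| Minimum set size | 5 | below this, the running-sum extremum is dominated by single members |
| Weight exponent `w` | 1 | standard weighted-KS choice; `w = 0` recovers the classical KS walk |
| `n_perm` | 10 000 | p-value floor ≈ 1e-4; BH across ≈ 22 sets resolves well above the floor. Raise (e.g. to 1e6) when reporting individual set p-values near the floor |
| `within_subclass_correlation` | 0.5 | typical of co-regulated lipid panels |
| `tg_coupling`, `weight_effect` | 0.5 | strong but not dominant clinical coupling |
| Planted effect sizes | 0.15 / 0.3 SD | set-level detectable, metabolite-level modest |

## 4. Validation summary

The test suite checks, among other things: every meta-analysis field
against an independent normal-equations/erfc/gammaincc oracle on 1000
random triples (rel. 1e-10) and a hand-worked case (1e-12); BH against a
literal step-up implementation; ES and permutation p against exhaustive
enumeration of all memberships on small lists (1e-12); null calibration
(uniform meta p-values by KS test in ≥ 45/50 null studies; set-level
false-positive rate within a 99% binomial band of 0.05 over ~50 × 20
tests); recovery of both planted effects in ≥ 18/20 replicate studies at
200 metabolites; the filtering rules on constructed fixtures including
the exact 0.25 boundary; and byte-identical reruns of the full 765-
metabolite pipeline.

## 5. Limitations

* **DerSimonian–Laird with k = 3** is known to be mildly conservative:
  τ̂² is truncated at zero and estimated noisily from two degrees of
  freedom, and z-based intervals ignore that uncertainty
  (Hartung–Knapp-type adjustments are not implemented). Random-effects
  p-values under the null are slightly right-shifted, which the
  calibration test tolerates.
* **The membership-permutation null assumes exchangeability.** With
  strong within-set correlation the effective number of independent
  members is smaller than the set size and permutation p-values become
  anti-conservative for correlated sets. This is a property of the
  method, not the implementation; competitive sample-permutation nulls
  would address it but require subject-level data at enrichment time.
* **Indirect associations are real associations.** Because lipid
  subclasses share a triglyceride factor, planting an effect in one lipid
  set makes other lipid sets genuinely (indirectly) associated; the
  generator's truth therefore asserts that the planted set attains the
  *most extreme* NES, not that it is the only significant one.
* **The generator is a caricature.** MCAR missingness, Gaussian
  log abundances, exchangeable blocks, and an additive percent-change
  outcome are deliberate simplifications; results on synthetic studies
  demonstrate correctness and power of the *pipeline*, not effect sizes
  to be expected in real cohorts.
* **Numerics.** All tables are written with `%.10g`, `NA` for missing,
  and `#`-prefixed headers carrying the seed, a configuration hash, and
  the package version; no timestamps, so identical configurations produce
  byte-identical outputs.
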