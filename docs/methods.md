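# Methods

This note records the statistical model, the estimation machinery, the
design of the synthetic-herd generator, and the numerical choices behind
`lactaqg`. It is a description of what the code computes, not a report of
empirical results.

## Data model

The unit of analysis is the test-day record: one cow on one recording day,
with daily milk yield (kg), its three milking-shift components, fat and
protein percentages, body weight, parity, calendar season, and days in milk
(DIM). Records pass through a fixed-order cleaning protocol (see
`lactaqg.qc`) before any modelling:

1. drop records missing the ear tag or a parseable test date;
2. drop records whose parity/season is missing and not inferable (season
   from the test-date month; parity from a calving-sequence table);
3. drop records with more than 30 % of the seven core traits missing;
4. deduplicate on ear tag + test date, keeping the most complete record;
5. mean-impute continuous traits with under 5 % column missingness using
   parity-by-season cell means;
6. flag statistical outliers (|Z| > 3 or beyond 1.5 IQR within
   parity-by-season cells) and delete physiologically impossible daily
   yields (outside 2–60 kg) — extreme-but-possible values are kept with an
   audit flag;
7. restrict DIM to lactation weeks 3–44 (15–308 days).

Every stage logs exact in/removed/out counts; the protocol is idempotent.

## The repeatability animal model

For trait vector *y* (one entry per record),

```
y = Xb + Z_a a + Z_m m + Z_pe p + e
a ~ N(0, Σ_a ⊗ A)      additive genetic, over the whole pedigree
m ~ N(0, Σ_m ⊗ A_m)    maternal genetic, indexed by the dam of the cow
p ~ N(0, Σ_pe ⊗ I)     permanent environment, one level per cow
e ~ N(0, Σ_e ⊗ I)      residual
```

- **Fixed effects** `b`: parity class (1, 2, 3, 4, ≥5), calendar season,
  lactation stage (early ≤ 100 d, mid 101–200 d, late ≥ 201 d), and
  body-weight class (six classes with edges 500/550/600/650/700 kg), all
  treatment-coded with an intercept.
- **A** is the numerator relationship matrix; its sparse inverse is built
  directly by Henderson's rules with inbreeding (Mendelian-sampling
  variance `d_i = 0.5 − 0.25 (F_s + F_d)`, unknown parents contributing
  F = −1). Inbreeding coefficients use the Meuwissen–Luo algorithm, which
  never forms A.
- **Maternal term**: records whose cow has an unknown dam receive a
  phantom, unrelated dam level (block-diagonal identity extension of
  A⁻¹). The direct–maternal genetic covariance is fixed at zero; it is not
  identifiable at the data scales the package targets.
- In multi-trait mode every term carries a free trait-by-trait covariance
  matrix (Σ_a, Σ_m, Σ_pe, Σ_e).

Derived parameters, per trait: heritability
`h² = σ²_a / (σ²_a + σ²_m + σ²_pe + σ²_e)` (maternal variance in the
denominator), repeatability `r = (σ²_a + σ²_pe) / total`, genetic
correlations from Σ_a and phenotypic correlations from the summed
covariance.

## Restricted-likelihood evaluation

The restricted log-likelihood is evaluated through the sparse mixed-model
equations (MME):

```
−2 l_R = log|R| + log|G| + log|C| + y'Py  (+ constant)
```

with `C` the MME coefficient matrix assembled as
`kron(Σ_e⁻¹, W'W) + Σ_terms kron(Σ_term⁻¹, padded prior)`, `log|C|` from a
sparse LU factorization, and `y'Py = y'R⁻¹y − solution'·rhs`. The
`log|G|` term includes `q·log|Σ_term| + k·log|A|`, with `log|A|` computed
once as `−log|A⁻¹|`. The test suite verifies this MME-based evaluation
against the dense textbook form `log|V| + log|X'V⁻¹X| + y'Py`.

## Estimation

- **Single trait.** The residual variance is profiled out analytically:
  with variance ratios γ_x = σ²_x/σ²_e fixed, the restricted-likelihood
  maximizer is `σ̂²_e = y'Py/(n − p)`. The profiled −2 l_R is minimized by
  Nelder–Mead over log variance ratios, clipped to [−14, 8] with a
  quadratic penalty (the clip corresponds to ratios between ~8·10⁻⁷ and
  ~3·10³, i.e. effectively boundary estimates remain representable).
- **Multiple traits.** Each covariance matrix is parameterized by its
  Cholesky factor (log diagonal, free off-diagonals), guaranteeing positive
  semidefiniteness, and the joint −2 l_R is minimized by L-BFGS-B with
  finite-difference gradients. Initial values come from univariate fits
  for the diagonals plus half the phenotypic correlation for the additive
  and residual off-diagonals.
- **Uncertainty.** Standard errors come from the observed-information
  matrix: a central finite-difference Hessian of −2 l_R in the variance
  components; half of it estimates the information, and its pseudo-inverse
  the sampling covariance. SEs of heritability and genetic correlations
  use the delta method on that covariance.

A deliberate deviation from the classical EM-warm-start + average-
information REML recipe: AI-REML needs traces of selected inverse blocks of
C, which require a supernodal sparse Cholesky with a Takahashi-type
selected inverse; no such primitive is available in the scientific Python
stack used here. Direct maximization of the same restricted likelihood
reaches the same optimum (the likelihood, not the algorithm, defines the
estimator) at the cost of more likelihood evaluations, each of which is a
single sparse factorization. The observed-information SEs play the role of
the AI-matrix SEs.

## Synthetic-herd generator

The generator exists to provide ground truth for calibration, not to be a
demographic model of a real population:

- **Pedigree**: discrete generations; each generation has a fixed number
  of males and females; every non-founder has a sire (drawn from a limited
  pool, giving paternal half-sib families) and a dam mated to a single
  sire. Females of the most recent generations carry records, so
  dam–daughter record pairs exist and the maternal and permanent-
  environment terms are identified.
- **Breeding values** are gene-dropped: founders N(0, Σ_a); descendants
  mid-parent average plus Mendelian sampling with covariance
  `0.5(1 − (F_s + F_d)/2) Σ_a`, so the vector has covariance `A ⊗ Σ_a`
  exactly (verified against the tabular A in the tests).
- **Records**: per-cow test days are unique DIM values in 15–308 days with
  real calendar dates from a per-cow calving date; fixed-effect profiles
  (parity, season, stage, body-weight class) are expressed in units of the
  trait's phenotypic SD; milking-shift yields are a Dirichlet split of the
  daily total, closing exactly. Optional corruption (missingness,
  impossible outliers, duplicated rows) is tracked row-by-row so QC
  bookkeeping can be audited.

Known realism limits: generations are discrete and non-overlapping; parity
is assigned per cow, not per lactation-year; all records of a cow fall in
one lactation; selection is absent (parents are drawn at random), so
genetic trend is zero by construction and genetic drift across the small
sire pool is the only source of between-generation mean movement; herd
management effects (contemporary groups) beyond season are absent.

## Calibration evidence

`lactaqg.recovery` (used by both the test suite and
`scripts/acceptance.py`) simulates herds at the package's default
generative components — heritabilities 0.382 / 0.292 / 0.360 and genetic
correlations up to |0.809| — and re-estimates them with the REML pipeline:
univariate heritability recovery over 10 seeded replicates of a
1,000-recorded-cow herd, bivariate genetic-correlation recovery over 5
seeded replicates. Replicate seeds are spawned deterministically from a
single base seed. Herd sizes are a Monte-Carlo precision choice, balancing
replicate sampling error against runtime on one CPU.

## Numerical choices

- Sparse LU via SuperLU with `MMD_AT_PLUS_A` ordering and symmetric mode:
  on MME matrices this ordering is an order of magnitude faster than the
  default column ordering.
- Dense A construction (tabular method) is guarded to pedigrees of at most
  2,000 animals; everything larger uses only the sparse A⁻¹.
- `log|C|` from the LU U-factor diagonal; covariance log-determinants via
  `slogdet` with an explicit positive-definiteness failure.
- Nelder–Mead tolerances (`xatol 1e-3` on log ratios, `fatol 1e-4` on
  −2 l_R) resolve variance ratios to ~0.1 %, far below their sampling
  error; tightening them further changes estimates in the fourth decimal
  at roughly double the evaluation count.

## Limitations

- No selected-inverse machinery: per-effect prediction-error variances
  (reliabilities) are not reported, only the full-model SEs.
- The maternal term is weakly identified without many dam–daughter pairs;
  on small data its estimate can sit at the zero boundary, where SEs from
  the observed information are unreliable.
- Finite-difference Hessians cost `O(n_par²)` likelihood evaluations;
  `compute_se=False` skips them for simulation studies.
- Single-records-per-cow data leave the permanent-environment variance
  unidentified (the model warns below 2 records per cow on average).
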