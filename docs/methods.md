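# Methods

## The evaluation model

`coldeval` scores germplasm varieties for stress tolerance from a varieties ×
indices table. The method assumes the observed indices are noisy, correlated
manifestations of a common underlying tolerance level, plus index-specific
variation; it makes no distributional assumption beyond finite variance per
column.

**Standardization and PCA.** Indices are measured in incommensurable units
(ordinal damage degrees, ratios, concentrations), so each column is z-scored
with the sample standard deviation (n − 1) and the principal components are
taken from the correlation matrix. Eigenvalues therefore sum to the number of
indices and the contribution rate of component *i* is p_i = 100·λ_i/Σλ.
Components are retained up to a cumulative contribution threshold, default
**85 %** — the conventional cutoff in this literature, and the value at which
the canonical two-arm example retains 2 of 5 morphological and 3 of 9
physiological components.

**Coefficient convention.** Reported coefficients are component *score*
coefficients (eigenvector entry / √λ), so CI scores are standardized linear
combinations with unit sample variance; raw eigenvectors and loadings
(eigenvector·√λ) are exposed as alternates. The choice is immaterial
downstream: the min–max membership step is invariant to any positive
rescaling of a CI column, so D does not depend on the convention.

**Sign orientation.** Eigenvectors are sign-ambiguous. Each component is
oriented so that its score correlates non-negatively with the
polarity-adjusted row mean of the standardized matrix (lower-is-better
columns negated); an exact-zero correlation is resolved by making the
largest-magnitude coefficient positive. This makes "larger CI ⇒ more
tolerant" hold wherever the data permit, which in turn gives withering-degree
indices negative coefficients on the first component, as expected.

**Membership, weights, D.** μ(x_i) = (x_i − x_min)/(x_max − x_min) per
retained component; w_i = p_i normalized over the *retained* set (confirmed
arithmetically: 54.545/86.555 = 0.630 and 46.789/93.839 = 0.499, matching
the published weights); D = Σ μ·w. Because μ ∈ [0, 1] and Σw = 1, D ∈ [0, 1];
a variety that is best on every component scores exactly 1.

**Classification and ranking.** Thresholds 0.2 / 0.5 / 0.8 partition D into
weak / moderate / strong / very-strong. The published rule uses strict
inequalities on both sides, leaving the boundary points unassigned; here
boundaries go to the **higher** class (D ≥ 0.8 is very strong). Ranking is by
descending D with competition ranking ("1, 1, 3") for ties — any fixed
convention would do; this one is stable and easy to test.

**Indicator selection.** Per-index Pearson r against D with a two-sided
t-test (df = n − 2, α = 0.05). Stepwise regression is p-value-based
bidirectional stepping (forward entry of the smallest entry p-value below
α_enter = 0.05, then removal of any included predictor above
α_stay = 0.05, to a fixpoint), the default behaviour of the legacy
statistics packages this method is usually run in; pure-forward and
pure-backward variants are available. Predictors enter raw so coefficients
are on the measured scale; standardized betas are reported alongside. The
final model is a plain OLS refit, so its coefficients match an independent
OLS fit of the selected columns to machine precision.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `cumulative_threshold` | 85 (%) | component retention cutoff |
| `class_boundaries` | 0.2, 0.5, 0.8 | D-class thresholds |
| `alpha`, `alpha_enter`, `alpha_stay` | 0.05 | significance levels |
| `precision` | 3 | decimal places in published-style tables |
| LWD scale | 1/4, 1/2 interval edges | ordinal damage degrees, below |

**Leaf-withering scale.** Fractions of withered leaf area map to ordinal
degrees: 0 → 1; (0, ¼] → 3; (¼, ½] → 5; (½, 1) → 7; 1 (or an explicit
whole-plant flag) → 9. The field's verbal scale leaves (½, ⅔] unassigned
(degree 7 is described as "more than ⅔"); assigning the whole of (½, 1) to
degree 7 keeps the map monotone and total. Intervals are left-open/
right-closed to match the "up to" phrasing.

## The synthetic-data generator

`generate` draws a latent tolerance t per variety (uniform(0,1) by default,
standard normal optionally) and produces each index as
`baseline + sign(polarity)·loading·t + ε` with ε ~ N(0, noise_sd²). The
default panel mirrors the original screening design: **133 varieties × 5
morphological indices** — two lower-is-better withering degrees spanning the
ordinal 1–9 range (baseline 9, loading 8) and three higher-is-better
recovery ratios rising from a stressed floor toward 1 (SR: 0.1 + 0.9t;
CRI/NRI: 0.3 + 0.7t) — with noise_sd set to 5 % of each loading, a
measurement-error level typical of averaged meter readings.
`generate_raw_trial` emulates the paired control/treated greenhouse design:
30 grains sown per variety, binomial survival with treated success
probability `control_prob·(floor + (1 − floor)·t)`, meter readings depressed
by `0.6·(1 − t)`, and withered fractions equal to 1 − t (80 % of that after
recovery growth). A deterministic mode (no meter noise, expected counts)
supports exact endpoint checks.

What the simulator does **not** emulate: genuine multi-factor biology
(a single latent trait drives every index), heteroscedastic or non-Gaussian
assay error, censoring/missingness, block or bench effects, and
between-season variation. Passing rank-recovery tests therefore show the
pipeline is a faithful implementation of the scoring chain, not that the
chain is a validated measure of field cold tolerance.

## Numerical choices

- Eigendecomposition via `scipy.linalg.eigh`; eigenvalues clipped at 0 and
  sorted descending. Components whose neighbouring eigenvalue gap is below
  1e−10 are flagged unstable (their coefficients are arbitrary within the
  shared eigenspace); tests compare such eigenvectors only up to the span.
- Zero-variance columns are rejected by name rather than silently dropped;
  missing cells are rejected unless per-index mean imputation is explicitly
  requested.
- Constant CI columns abort the membership step (a constant comprehensive
  index cannot discriminate varieties).
- All internal arithmetic is full double precision; rounding (half-even, 3
  decimals by default) is applied only to published-style report tables.
- Stepwise entry ties are broken by column order and every add/drop is
  recorded, so selection is deterministic given data and thresholds.
  Candidates whose addition would make the design singular are skipped at
  entry; a singular design in a direct fit raises a collinearity error
  naming the offending columns.

## Known limitations

- The six-variety worked example is reproduced from comprehensive-index
  values printed at 3 decimal places, so recomputed membership values can
  differ from the printed ones by one unit in the last digit; the bundled
  dataset documents the two cells where this occurs. The printed per-variety
  composite column of that table is itself inconsistent with the method's
  own weighted-sum definition (some printed values exceed 1); this package
  follows the definition and does not attempt to match that column.
- With fewer varieties than indices the correlation matrix is rank-deficient;
  the fit proceeds with a warning but trailing components are meaningless.
- The stepwise procedure inherits the known inferential caveats of p-based
  selection (post-selection p-values are optimistic); it is provided for
  indicator screening, not confirmatory inference.
- Acceptance-scale runs use 133 simulated varieties, 50-observation
  regression panels and 50-seed null replications — sizes chosen to match
  the original design while keeping the suite quick on a laptop.
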