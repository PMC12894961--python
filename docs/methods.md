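# Methods

## The modelling problem

A leaf's reflectance spectrum R(λ) on a dense grid (400–2400 nm at 1 nm,
p = 2001 wavelengths) carries overlapping signatures of pigments, water,
nitrogen-bearing compounds and structure. Traits are predicted by linear
models because the predictors are numerous and strongly collinear:
PLSR compresses X into K latent components maximizing covariance with the
response, linear SVR fits an ε-insensitive linear function under an
L2 penalty. Both reduce to an affine map ŷ = **β**ᵀx + b; their difference
lies in how complexity is controlled (NoC vs C).

## PLSR: algorithm and numerical choices

The implementation is NIPALS for a single response, with mean-centering of
X and y (unit-variance scaling of X is available but off by default:
reflectance columns share units, and scaling would inflate noisy
low-variance bands). Per component k:

    w_k ∝ X_kᵀ y_k   (unit norm)
    t_k = X_k w_k
    p_k = X_kᵀ t_k / t_kᵀ t_k,  q_k = y_kᵀ t_k / t_kᵀ t_k
    X_{k+1} = X_k − t_k p_kᵀ,   y_{k+1} = y_k − q_k t_k

Coefficients for any truncation K come from the rotation
r_k = w_k − Σ_{j<k}(p_jᵀw_k) r_j, β_K = Σ_{k≤K} r_k q_k, so one fit serves a
whole NoC grid — predictions for every K at once are a cumulative sum over
component contributions.

Numerical choices:

* extraction stops when the deflated ‖X‖_F falls below 1e-12 of its initial
  value (or the weight vector degenerates); requesting more components than
  the effective rank silently reuses the last valid coefficient vector, so
  NoC grids up to 40 are safe on small folds;
* a constant response yields a zero-coefficient model with intercept
  mean(y) rather than an error;
* at K = rank(centered X) the fit equals the minimum-norm least-squares
  solution; this is the oracle check in the test suite (pseudoinverse,
  agreement to 1e-8);
* score vectors are mutually orthogonal to 1e-8 relative tolerance by
  construction, asserted in tests.

## Linear SVR

The convex optimisation is delegated to scikit-learn's libsvm binding
(`SVR(kernel="linear")`) behind the `fit_linear_svr` contract; predictors
are standardized to unit variance internally and the response is
standardized so that ε (default 0.1) has a scale-free meaning — only C is
tuned, over a default grid of 9 log-spaced values 1e-3…1e3. Coefficients
are reported on the original scales. Solver tolerance is 1e-8 with a
200 000-iteration cap; the cap bounds effort on near-degenerate folds
(tiny C) where the fit is already flat.

## NoC selection

* `repeated_cv` (default 20 × 5-fold): per repetition
  NoC_MSE(opt) = argmin mean validation MSE; consensus NoC_MSE = mode of
  the optima. Tie-breaking everywhere is to the smallest candidate
  (parsimony; also preserves the observed tendency of PRESS to pick
  slightly smaller NoC).
* `single_cv` (default 3-fold): one CV pass; the fold count for "a single
  CV iteration" is a free design choice here, 3 mirrors the inner repeated
  scheme and is configurable.
* `press` (default 100 sub-samples, 80/20): PRESS(k) summed over held-out
  splits; global minimum, no one-standard-error rule.

Candidates infeasible for the smallest training fold
(k > min(n_train − 1, p)) are dropped up front; an empty feasible grid is
an error that names the feasible maximum. Error curves are stored for the
full grid, including past the optimum, so the qualitative NoC-response
shape of a trait (plateau, overfitting decline, flat-null) can be plotted.

Randomness: one master seed; every repetition/sub-sample derives a child
generator through `numpy.random.SeedSequence.spawn` (counter-based), so
results are bit-reproducible and repetitions are independent.

## Nested cross-validation and scenarios

Aggregation (raw → plot → genotype averaging), the trait's wavelength
window, and optional per-season trait scaling are applied *before* fold
construction. Each outer fold runs the inner hyperparameter search on
calibration rows only, refits on the full calibration set, and scores the
validation rows. Under genotype grouping the inner folds are also
genotype-exclusive. An audit verifies, per repetition: validation folds
are disjoint and partition the eligible rows; calibration and validation
share no sample; under grouping, no genotype (or season) appears on both
sides. A corrupted plan raises `LeakageError` — this is itself a test.

Scenario construction:

* `random`: per repetition, a shuffled k-fold split.
* `unseen_genotype`: genotypes are shuffled and dealt into k folds (sizes
  differ by at most one); all rows of a genotype follow its fold.
* `unseen_season`: a single calibration set (all rows of the training
  seasons) and a single validation set (the test season). The inner loop
  uses random splits within the multi-season calibration set.
* `unseen_genotype_unseen_season`: the test season's genotypes are split
  into k validation folds; calibration is the other seasons (or an
  explicitly restricted set of training seasons, behind the
  `train_seasons` argument) minus the validation genotypes.

Metrics: R² (1 − SS_res/SS_tot about the validation fold's observed mean,
possibly negative) and RMSE% for the within-season scenarios; squared
Pearson for season transfer, where trait levels shift and the trend is the
target. Squared Pearson is additionally recorded for all scenarios so the
four can be compared on one metric. RMSE% is defined as 100·RMSE/mean(obs)
per validation fold — normalization by the mean is the common chemometrics
convention; range normalization is available and is used automatically for
per-season-scaled traits, whose mean is ≈ 0. Fold metrics are summarized
by median and IQR, never pooled across folds.

## Season-comparison statistics

Coefficient of variation (100·SD/mean per trait and season), Spearman rank
correlation of genotype-mean trait values between seasons, per-genotype
Pearson correlation of mean spectra within a wavelength region (defaults:
visible 350–700, near-infrared 700–1300, shortwave-infrared 1300–2500 nm),
and a Mantel permutation test comparing the genotype × genotype covariance
matrices of mean spectra from two seasons. The "correlation of averaged
spectra per genotype" statistic is ambiguous between correlating across
wavelengths within a genotype and across genotypes within a wavelength;
the per-genotype-across-wavelengths reading is the default and the
alternative is exposed via `mode="per_wavelength"`.

Mantel details: r is the Pearson correlation of strictly-upper-triangle
entries; the p-value permutes B's rows and columns simultaneously
(genotype labels), one-sided upper, with the (count+1)/(n_perm+1)
estimator and identity draws excluded; `exact=True` enumerates all n!
permutations (n ≤ 8) and is verified against a brute-force oracle in the
tests.

## The synthetic-data generator

The generator emulates the statistical structure of a replicated
multi-genotype, multi-season field trial. Defaults mirror the target
design: 320 genotypes × 3 seasons × 2 plots × 3 replicates, 400–2400 nm at
1 nm. Latent scores per sample i and factor f decompose as

    t_if = g_f(genotype) + s_f(season) + gx_f(genotype, season)
           + p_f(plot) + e_if

with default variances σ²_G = 1.0, σ²_S = 0.5, σ²_GxE = 0.4, σ²_P = 0.1,
σ²_E = 0.3 — genotype-dominated, with substantial season and interaction
components, the regime in which cross-season transfer is hard but not
hopeless. Reflectance is a vegetation-like baseline (dark visible region,
NIR plateau ≈ 0.45, declining SWIR) plus the scores mapped through six
Gaussian-bump basis functions (amplitude 0.02 reflectance units per unit
score) plus smooth spectral noise, clipped to [0, 1] with a warning if
clipping exceeds 5%. One season's baseline carries an elevated 750–1500 nm
plateau (default +0.04 in the second season), reproducing the kind of
seasonal spectral anomaly that breaks transfer.

Traits are linear in the latent scores plus optional per-season mean
shifts, leaf-level noise, and missingness at a configurable rate. Three
further structures are deliberate design choices, because without them a
stationary X→y map would make cross-season transfer trivially perfect and
all evaluation schemes equivalent:

* **trait-side G×E** — a genotype×season trait deviation with SD
  `gxe_sensitivity · sqrt(σ²_GxE)`, the part of the interaction that
  reflectance does not carry. This is what makes increasing σ²_GxE
  strictly degrade season transfer. Structural traits get low sensitivity
  (0.6), the physiological trait high (1.2), mirroring the relative
  environmental sensitivity of such trait classes;
* **stable genotype structure** — a smooth per-genotype spectral signature
  (SD 0.012 reflectance units, ≈ 1% reflectance) paired with a stable
  per-genotype trait deviation. Models evaluated on *seen* genotypes (in
  any season) can exploit this pairing; genotype-exclusive evaluation
  cannot — the channel that separates the strict
  unseen-genotype-in-unseen-season scenario from plain season transfer;
* **genotype×season spectral signatures** (SD 0.004) — the idiosyncratic
  within-season structure that replicate-sharing random CV can memorize.

What the generator does *not* emulate: real leaf optics (no
radiative-transfer model — Gaussian bumps suffice for the statistical
properties under test), spatial field effects of the planting design,
instrument artefacts, or skewed/heteroscedastic trait distributions.
Passing tests therefore demonstrate that the *pipeline machinery* behaves
correctly under the assumed variance structure, not that any particular
field dataset will reach a given accuracy.

## Problem sizes used in tests and the acceptance script

Simulations are scaled down from the default field design so the whole
suite runs in well under a minute of compute per block: typically 40
genotypes, 3 seasons, 2 plots × 1–3 replicates, and a 10 nm wavelength
grid (p = 201) for nested-CV properties; the exact low-rank/NoC-recovery
checks use the 5 nm grid (p = 401, n = 120) with all noise terms disabled;
the full 2001-wavelength grid is exercised for bookkeeping and generator
structure. NoC grids span 1–30 (1–40 where the recovery property is the
point). These sizes preserve every qualitative property of the full-scale
design (n/p ratios, group structure, variance hierarchy).

## Known limitations

* PLSR is single-response; multi-trait modelling requires one model per
  trait.
* The season-transfer scenarios assume at least two seasons of data and at
  least three shared genotypes for the descriptive statistics.
* The Wilcoxon comparison of scenario distributions is a reporting-time
  annotation, not an inferential claim about field data.
* The generator's Gaussian, homoscedastic structure understates the tail
  behaviour of real physiological traits.
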