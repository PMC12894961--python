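# leafspec

Leaf-trait prediction from hyperspectral reflectance (HSR) for multi-season
field phenotyping: partial least squares regression (PLSR) and linear
support vector regression (SVR), principled selection of the PLSR number of
components (NoC), a nested cross-validation engine that distinguishes
*generalizability* (predicting new samples from the seen distribution) from
*transferability* (predicting unseen genotypes, unseen seasons, or both),
and the descriptive statistics used to compare seasons before modelling.

## Who this is for

Plant phenomics groups that measure leaf reflectance on a dense wavelength
grid (here 400–2400 nm at 1 nm) across many genotypes, replicated plots and
several growing seasons, and want to predict structural, biochemical or
physiological traits (SLA, %N, C:N, photosynthetic and chlorophyll
fluorescence traits) from the spectra — while quantifying honestly how far
those models carry: to new leaves, to new genotypes, or to a new season.

## The models and the calibration problem

PLSR regresses the trait *y* onto *K* mutually orthogonal latent components
**t**₁ … **t**_K, each a linear combination of the *p* wavelengths chosen to
covary with the response — the standard answer to *p* ≫ *n* and heavy
collinearity in reflectance data. The single complexity hyperparameter is
the number of components (NoC). Three selection strategies are implemented:

* **repeated CV** — 20 repetitions of 5-fold CV; each repetition picks
  NoC_MSE(opt) = argmin of the mean validation MSE; the consensus NoC_MSE is
  the mode of the per-repetition optima;
* **single CV** — one k-fold CV (default 3-fold), argmin of the MSE curve;
* **PRESS** — 100 random 80/20 sub-samples; PRESS(k) = Σ squared held-out
  prediction errors; NoC_PRESS = argmin PRESS.

All ties break to the smallest hyperparameter. Linear-kernel SVR
(ε-insensitive loss) is the comparison model, tuned over a log-spaced grid
of its regularization constant C.

## Prediction scenarios

The nested CV engine evaluates four scenarios with a built-in leakage
audit (any shared sample — or shared genotype, under grouping — between
calibration and validation raises an error):

| scenario | outer folds | metric |
|---|---|---|
| random | 20 × random 5-fold | R², RMSE% |
| unseen genotype | genotype-exclusive 5-fold (outer *and* inner) | R², RMSE% |
| unseen season | train on whole season(s), test the held-out season | squared Pearson |
| unseen genotype × unseen season | validation genotypes excluded from multi-season training | squared Pearson |

Squared Pearson is used for season transfer because trait *levels* shift
between seasons; the trend is the meaningful target. Data can be averaged
to plot or genotype level before modelling, traits can be restricted to a
spectral window (e.g. 1500–2400 nm for nitrogen traits), and trait values
can be centred/scaled within each season before pooling seasons.

A synthetic-data module generates multi-season datasets with genotype,
season, G×E, plot and residual variance components driving both smooth
spectra and traits, so every claim the pipeline makes is testable against
known ground truth without downloading field data.

## Worked example

```python
from leafspec import (SyntheticConfig, generate_dataset, ModelSpec,
                      run_nested_cv, select_noc_repeated_cv)

cfg = SyntheticConfig(n_genotypes=40, n_seasons=3, plots_per_genotype=2,
                      reps_per_plot=2, wavelength_step=10.0)
ds, tt, truth = generate_dataset(cfg, seed=1)

cal = select_noc_repeated_cv(ds.reflectance, tt.values["photo_rate"],
                             range(1, 31), reps=20, k_folds=5, seed=1)
ms = ModelSpec(noc_grid=tuple(range(1, 31)))
res = run_nested_cv(ds, tt, "photo_rate", ms, scenario="random",
                    k_folds=5, reps=20, seed=1)
```

Output (printed by the script version of this example):

```
dataset: 480 samples x 201 wavelengths, traits: ['sla', 'nitrogen_pct', 'photo_rate']
repeated-CV consensus NoC = 11 (per-repetition optima: [10, 11, 12])
scenario i  (random 5-fold x 20): median R2 = 0.476, IQR = 0.109, folds = 100
scenario ii (unseen genotype):    median R2 = 0.305, IQR = 0.181
scenario iii (unseen season S3):  squared Pearson = 0.470
```

Reading the numbers: NoC selection is stable across repetitions (optima
10–12, consensus 11). The 20×5 outer loop yields exactly 100 validation
folds. Accuracy drops from random splits (median R² 0.48) to unseen
genotypes (0.31) because genotype-exclusive folds remove the information
that replicate sharing leaks, and season transfer is evaluated on the
trend metric.

A command-line interface mirrors the library:

```bash
leafspec simulate --seed 1 --out data/
leafspec describe --spectra data/spectra.csv --traits data/traits.csv \
    --metadata data/metadata.csv --out describe/
leafspec evaluate --config experiment.yaml
leafspec report --results-dir out/
```

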