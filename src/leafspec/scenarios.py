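"""Prediction scenarios, nested cross-validation, and validation metrics.

Four scenarios probe increasingly hard generalisation questions:

* ``random`` — repeated random k-fold CV within the data at hand: can the
  model predict new leaves drawn from the same genotypes and season(s)?
* ``unseen_genotype`` — genotype-exclusive k-fold CV (outer *and* inner
  folds share no genotype): does the model transfer to new genotypes?
* ``unseen_season`` — train on whole season(s), validate on a held-out
  season: does the model transfer across growing environments?
* ``unseen_genotype_unseen_season`` — the strict variant: validation
  genotypes in the target season are excluded from the multi-season
  training data, so both the genotype and the environment are new.

Each outer fold runs an inner hyperparameter search (NoC for PLSR, C for
SVR) on its calibration rows only, refits on the full calibration set, and
scores the validation rows.  Per-fold metrics are R² and RMSE% for the
within-season scenarios and squared Pearson correlation for the season
transfer scenarios, where the trend rather than absolute agreement is the
question.  A built-in audit rejects any fold plan that leaks samples — or,
under genotype grouping, genotypes — across the calibration/validation
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration as calib
from ._folds import child_rngs, group_kfold_indices, kfold_indices
from .data import SpectralDataset, TraitTable, aggregate, center_scale_by_season, restrict_wavelengths
from .models import fit_linear_svr, fit_plsr

SCENARIOS = (
    "random",
    "unseen_genotype",
    "unseen_season",
    "unseen_genotype_unseen_season",
)


class LeakageError(RuntimeError):
    """A fold plan shares samples (or grouped units) across the split."""


# ---------------------------------------------------------------------------
# Metrics


def r_squared(obs, pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the validation
    fold's observed mean; may be negative."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant observations: R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse_percent(obs, pred, normalizer: str = "mean") -> float:
    """RMSE expressed as a percentage of the observed mean (or range)."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if normalizer == "mean":
        denom = float(np.mean(obs))
        if denom == 0:
            raise ValueError("zero observed mean: RMSE% undefined")
    elif normalizer == "range":
        denom = float(np.ptp(obs))
        if denom == 0:
            raise ValueError("zero observed range: RMSE% undefined")
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    return 100.0 * rmse / denom


def squared_pearson(obs, pred) -> float:
    """Squared Pearson correlation; invariant to affine rescaling of the
    predictions, so it scores the predicted trend only."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# Fold plans


@dataclass
class FoldPlan:
    """Scenario-specific calibration/validation index sets.

    ``repetitions`` is a list of repetitions, each a list of
    (calibration indices, validation indices) pairs.
    """

    scenario: str
    grouping: str | None
    repetitions: list[list[tuple[np.ndarray, np.ndarray]]]
    seed: int
    eligible: np.ndarray | None = None  # rows the validation folds must cover

    @property
    def n_folds(self) -> int:
        return sum(len(rep) for rep in self.repetitions)


def build_fold_plan(
    samples: pd.DataFrame,
    scenario: str,
    k_folds: int = 5,
    reps: int = 20,
    train_seasons=None,
    test_season=None,
    seed: int = 0,
) -> FoldPlan:
    """Construct the outer-loop folds for one scenario.

    ``unseen_season`` uses whole seasons (one calibration/validation pair);
    the strict variant splits the target season's genotypes into ``k_folds``
    validation folds and trains on the other seasons minus those genotypes
    (optionally restricted to ``train_seasons``).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    n = len(samples)
    genotype = samples["genotype_id"].to_numpy()
    season = samples["season"].astype(str).to_numpy()
    all_idx = np.arange(n)

    if scenario in ("unseen_season", "unseen_genotype_unseen_season"):
        if test_season is None:
            raise ValueError(f"{scenario} requires test_season")
        test_season = str(test_season)
        if test_season not in set(season):
            raise ValueError(f"test season {test_season!r} absent from data")

    if scenario == "random":
        rngs = child_rngs(seed, reps)
        repetitions = []
        for rng in rngs:
            folds = kfold_indices(n, k_folds, rng)
            repetitions.append(
                [(np.setdiff1d(all_idx, v), v) for v in folds]
            )
        return FoldPlan("random", None, repetitions, seed, eligible=all_idx)

    if scenario == "unseen_genotype":
        rngs = child_rngs(seed, reps)
        repetitions = []
        for rng in rngs:
            folds = group_kfold_indices(genotype, k_folds, rng)
            repetitions.append(
                [(np.setdiff1d(all_idx, v), v) for v in folds]
            )
        return FoldPlan(
            "unseen_genotype", "genotype_id", repetitions, seed, eligible=all_idx
        )

    if scenario == "unseen_season":
        if train_seasons is None:
            train_seasons = sorted(set(season) - {test_season})
        train_seasons = [str(s) for s in train_seasons]
        if test_season in train_seasons:
            raise ValueError("test season cannot appear among training seasons")
        missing = [s for s in train_seasons if s not in set(season)]
        if missing:
            raise ValueError(f"training season(s) absent from data: {missing}")
        cal = np.flatnonzero(np.isin(season, train_seasons))
        val = np.flatnonzero(season == test_season)
        return FoldPlan(
            "unseen_season", "season", [[(cal, val)]], seed, eligible=val
        )

    # strict variant: unseen genotypes in an unseen season
    if train_seasons is None:
        train_seasons = sorted(set(season) - {test_season})
    train_seasons = [str(s) for s in train_seasons]
    if test_season in train_seasons:
        raise ValueError("test season cannot appear among training seasons")
    test_rows = np.flatnonzero(season == test_season)
    train_rows = np.flatnonzero(np.isin(season, train_seasons))
    test_genotypes = samples["genotype_id"].iloc[test_rows].to_numpy()
    rngs = child_rngs(seed, reps)
    repetitions = []
    for rng in rngs:
        val_folds = group_kfold_indices(test_genotypes, k_folds, rng)
        rep = []
        for local_val in val_folds:
            val = test_rows[local_val]
            held_genotypes = set(genotype[val])
            cal = train_rows[
                ~np.isin(genotype[train_rows], sorted(held_genotypes))
            ]
            rep.append((cal, val))
        repetitions.append(rep)
    return FoldPlan(
        "unseen_genotype_unseen_season",
        "genotype_id",
        repetitions,
        seed,
        eligible=test_rows,
    )


def audit_fold_plan(plan: FoldPlan, samples: pd.DataFrame) -> None:
    """Verify the plan's exclusivity guarantees; raise LeakageError on any
    violation.  Checks, per repetition: validation folds are disjoint and
    cover the eligible rows; calibration and validation never share a
    sample; under genotype grouping, never share a genotype."""
    genotype = samples["genotype_id"].to_numpy()
    for r, rep in enumerate(plan.repetitions):
        seen: set[int] = set()
        for f, (cal, val) in enumerate(rep):
            cal_set, val_set = set(cal.tolist()), set(val.tolist())
            if cal_set & val_set:
                raise LeakageError(
                    f"repetition {r} fold {f}: calibration and validation share "
                    f"{len(cal_set & val_set)} sample(s)"
                )
            if seen & val_set:
                raise LeakageError(
                    f"repetition {r}: validation folds overlap at fold {f}"
                )
            seen |= val_set
            if plan.grouping == "genotype_id":
                shared = set(genotype[cal]) & set(genotype[val])
                if shared:
                    raise LeakageError(
                        f"repetition {r} fold {f}: genotype(s) on both sides: "
                        f"{sorted(shared)[:5]}"
                    )
            elif plan.grouping == "season":
                season = samples["season"].astype(str).to_numpy()
                shared = set(season[cal]) & set(season[val])
                if shared:
                    raise LeakageError(
                        f"repetition {r} fold {f}: season(s) on both sides: "
                        f"{sorted(shared)}"
                    )
        if plan.eligible is not None and seen != set(plan.eligible.tolist()):
            raise LeakageError(
                f"repetition {r}: validation folds do not partition the "
                f"eligible samples"
            )


# ---------------------------------------------------------------------------
# Nested CV engine


@dataclass
class ModelSpec:
    """Which model to fit and its hyperparameter grid."""

    model: str = "plsr"  # "plsr" | "svr"
    noc_grid: tuple = calib.DEFAULT_NOC_GRID
    c_grid: tuple = calib.DEFAULT_C_GRID
    epsilon: float = 0.1


@dataclass
class NestedCVConfig:
    """Inner-loop design and metric options."""

    inner_strategy: str = "single_cv"  # single_cv | repeated_cv | press
    inner_k_folds: int = 3
    inner_reps: int = 10
    inner_subsamples: int = 100
    inner_train_fraction: float = 0.8
    rmse_normalizer: str = "mean"
    scale_by_season: bool | None = None  # None: follow the trait registry


@dataclass
class EvaluationResult:
    """Per-fold metrics plus median/IQR summaries for one configuration."""

    per_fold: pd.DataFrame
    summaries: dict[str, dict[str, float]]
    config: dict = field(default_factory=dict)

    def median(self, metric: str) -> float:
        return self.summaries[metric]["median"]


def _summaries(per_fold: pd.DataFrame, metrics: list[str]) -> dict:
    out = {}
    for m in metrics:
        vals = per_fold[m].to_numpy(dtype=float)
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        out[m] = {"median": float(q50), "iqr": float(q75 - q25), "q25": float(q25), "q75": float(q75)}
    return out


def _select_hyperparameter(
    model_spec: ModelSpec,
    cv_config: NestedCVConfig,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    groups: np.ndarray | None,
    seed: int,
):
    if model_spec.model == "svr":
        return calib.select_svr_c(
            X_cal, y_cal, model_spec.c_grid,
            k_folds=cv_config.inner_k_folds, seed=seed, groups=groups,
            epsilon=model_spec.epsilon,
        )
    if cv_config.inner_strategy == "single_cv":
        return calib.select_noc_single_cv(
            X_cal, y_cal, model_spec.noc_grid,
            k_folds=cv_config.inner_k_folds, seed=seed, groups=groups,
        )
    if cv_config.inner_strategy == "repeated_cv":
        return calib.select_noc_repeated_cv(
            X_cal, y_cal, model_spec.noc_grid,
            reps=cv_config.inner_reps, k_folds=cv_config.inner_k_folds,
            seed=seed, groups=groups,
        )
    if cv_config.inner_strategy == "press":
        return calib.select_noc_press(
            X_cal, y_cal, model_spec.noc_grid,
            n_subsamples=cv_config.inner_subsamples,
            train_fraction=cv_config.inner_train_fraction,
            seed=seed, groups=groups,
        )
    raise ValueError(f"unknown inner strategy {cv_config.inner_strategy!r}")


def run_nested_cv(
    ds: SpectralDataset,
    tt: TraitTable,
    trait: str,
    model_spec: ModelSpec | None = None,
    aggregation: str = "raw",
    scenario: str = "random",
    k_folds: int = 5,
    reps: int = 20,
    train_seasons=None,
    test_season=None,
    cv_config: NestedCVConfig | None = None,
    fold_plan: FoldPlan | None = None,
    seed: int = 0,
) -> EvaluationResult:
    """Run the full nested CV for one trait × model × scenario configuration.

    Aggregation, the trait's wavelength window, and (optionally) per-season
    trait scaling are applied before fold construction.  The inner loop sees
    calibration rows only, and honours genotype exclusivity whenever the
    outer scenario does.  Rows with a missing trait value are dropped
    per-fold; spectra rows are never dropped globally.
    """
    if model_spec is None:
        model_spec = ModelSpec()
    if cv_config is None:
        cv_config = NestedCVConfig()
    if trait not in tt.values:
        raise KeyError(f"unknown trait {trait!r}")

    ds, tt = aggregate(ds, tt, aggregation)
    trait_spec = tt.spec_for(trait)
    if trait_spec.wavelength_window is not None:
        ds = restrict_wavelengths(ds, *trait_spec.wavelength_window)
    scale_flag = (
        trait_spec.scale_by_season
        if cv_config.scale_by_season is None
        else cv_config.scale_by_season
    )
    season_params = None
    if scale_flag:
        tt, season_params = center_scale_by_season(tt, trait)

    if fold_plan is None:
        fold_plan = build_fold_plan(
            ds.samples, scenario, k_folds=k_folds, reps=reps,
            train_seasons=train_seasons, test_season=test_season, seed=seed,
        )
    else:
        scenario = fold_plan.scenario
    audit_fold_plan(fold_plan, ds.samples)

    X = ds.reflectance
    y = tt.values[trait]
    genotype = ds.samples["genotype_id"].to_numpy()
    group_exclusive = fold_plan.grouping == "genotype_id"
    season_transfer = scenario in ("unseen_season", "unseen_genotype_unseen_season")
    # R^2 is the headline metric within seasons, squared Pearson for season
    # transfer; sq_pearson is recorded everywhere so scenarios can be
    # compared on a single trend metric.
    metrics = (
        ["sq_pearson", "rmse_pct"]
        if season_transfer
        else ["r2", "sq_pearson", "rmse_pct"]
    )

    inner_seeds = child_rngs(seed + 1, fold_plan.n_folds)
    records = []
    fold_counter = 0
    for r, rep in enumerate(fold_plan.repetitions):
        for f, (cal, val) in enumerate(rep):
            cal = cal[~np.isnan(y[cal])]
            val = val[~np.isnan(y[val])]
            if len(cal) < 3 or len(val) < 2:
                raise ValueError(
                    f"repetition {r} fold {f}: too few non-missing trait values"
                )
            inner_seed = int(
                inner_seeds[fold_counter].integers(0, 2**31 - 1)
            )
            fold_counter += 1
            groups = genotype[cal] if group_exclusive else None
            sel = _select_hyperparameter(
                model_spec, cv_config, X[cal], y[cal], groups, inner_seed
            )
            chosen = sel.consensus
            if model_spec.model == "svr":
                model = fit_linear_svr(
                    X[cal], y[cal], C=float(chosen), epsilon=model_spec.epsilon
                )
                pred = model.predict(X[val])
            else:
                k = int(chosen)
                model = fit_plsr(X[cal], y[cal], max_noc=k)
                pred = model.predict(X[val], k)
            rec = {
                "repetition": r,
                "fold": f,
                "n_calibration": len(cal),
                "n_validation": len(val),
                "selected": float(chosen),
            }
            if season_transfer:
                rec["sq_pearson"] = squared_pearson(y[val], pred)
            else:
                rec["r2"] = r_squared(y[val], pred)
                rec["sq_pearson"] = squared_pearson(y[val], pred)
            rec["rmse_pct"] = (
                rmse_percent(y[val], pred, cv_config.rmse_normalizer)
                if not scale_flag
                else rmse_percent(y[val], pred, "range")
            )
            records.append(rec)

    per_fold = pd.DataFrame.from_records(records)
    config_echo = {
        "trait": trait,
        "model": model_spec.model,
        "aggregation": aggregation,
        "scenario": scenario,
        "calibration_strategy": (
            "svr_c" if model_spec.model == "svr" else cv_config.inner_strategy
        ),
        "k_folds": k_folds,
        "reps": reps,
        "seed": seed,
        "scale_by_season": bool(scale_flag),
        "train_seasons": None if train_seasons is None else [str(s) for s in train_seasons],
        "test_season": None if test_season is None else str(test_season),
    }
    if season_params is not None:
        config_echo["season_scaling_params"] = {
            s: [m, sd] for s, (m, sd) in season_params.items()
        }
    return EvaluationResult(per_fold, _summaries(per_fold, metrics), config_echo)
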