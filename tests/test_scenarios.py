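"""Fold plans, the leakage audit, metrics, and the nested CV engine."""

import numpy as np
import pandas as pd
import pytest

from leafspec import (
    LeakageError,
    ModelSpec,
    NestedCVConfig,
    audit_fold_plan,
    build_fold_plan,
    generate_dataset,
    r_squared,
    rmse_percent,
    run_nested_cv,
    squared_pearson,
)
from leafspec.simulate import SyntheticConfig, TraitDef

from conftest import make_samples, noiseless_config, small_noisy_config


class TestMetrics:
    def test_r_squared_reference_points(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(obs, obs) == pytest.approx(1.0)
        assert r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)
        assert r_squared(obs, np.full(4, 2.0)) == pytest.approx(-0.2)
        with pytest.raises(ValueError):
            r_squared(np.ones(4), obs)

    def test_rmse_percent_reference_points(self):
        assert rmse_percent([1.0, 3.0], [1.0, 3.0]) == pytest.approx(0.0)
        assert rmse_percent([1.0, 3.0], [2.0, 2.0]) == pytest.approx(50.0)
        obs, pred = np.array([1.0, 3.0]), np.array([2.0, 2.5])
        assert rmse_percent(3 * obs, 3 * pred) == pytest.approx(
            rmse_percent(obs, pred)
        )
        with pytest.raises(ValueError):
            rmse_percent([-1.0, 1.0], [0.0, 0.0])

    def test_squared_pearson_reference_points(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert squared_pearson(obs, 2 * obs + 5) == pytest.approx(1.0)
        assert squared_pearson(obs, [1.0, 3.0, 2.0]) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            squared_pearson(obs, np.ones(3))


class TestFoldPlans:
    def samples_10x6(self):
        return make_samples(
            [
                (f"g{g}r{r}", f"G{g}", "S1", f"P{r % 2}", f"R{r}")
                for g in range(10)
                for r in range(6)
            ]
        )

    def test_unseen_genotype_folds_hold_whole_genotypes(self):
        samples = self.samples_10x6()
        plan = build_fold_plan(samples, "unseen_genotype", k_folds=5, reps=3, seed=0)
        genotype = samples["genotype_id"].to_numpy()
        for rep in plan.repetitions:
            for cal, val in rep:
                assert len(val) == 12  # 2 genotypes x 6 rows
                assert len(set(genotype[val])) == 2
                assert not set(genotype[cal]) & set(genotype[val])
        audit_fold_plan(plan, samples)

    def test_leave_one_genotype_out(self):
        samples = self.samples_10x6()
        plan = build_fold_plan(samples, "unseen_genotype", k_folds=10, reps=1, seed=0)
        genotype = samples["genotype_id"].to_numpy()
        for cal, val in plan.repetitions[0]:
            assert len(set(genotype[val])) == 1

    def test_unseen_season_excludes_test_rows_from_calibration(self):
        samples = make_samples(
            [
                (f"{s}g{g}", f"G{g}", s, "P1", "R1")
                for s in ("A", "B", "C")
                for g in range(6)
            ]
        )
        plan = build_fold_plan(
            samples, "unseen_season", train_seasons=["A", "B"], test_season="C", seed=0
        )
        (cal, val), = plan.repetitions[0]
        season = samples["season"].to_numpy()
        assert set(season[cal]) == {"A", "B"}
        assert set(season[val]) == {"C"}
        audit_fold_plan(plan, samples)

    def test_strict_variant_excludes_validation_genotypes_from_training(self):
        samples = make_samples(
            [
                (f"{s}g{g}r{r}", f"G{g}", s, "P1", f"R{r}")
                for s in ("A", "B", "C")
                for g in range(10)
                for r in range(2)
            ]
        )
        plan = build_fold_plan(
            samples, "unseen_genotype_unseen_season",
            k_folds=5, reps=2, test_season="C", seed=3,
        )
        genotype = samples["genotype_id"].to_numpy()
        season = samples["season"].to_numpy()
        for rep in plan.repetitions:
            covered = set()
            for cal, val in rep:
                assert set(season[val]) == {"C"}
                assert "C" not in set(season[cal])
                assert not set(genotype[cal]) & set(genotype[val])
                covered |= set(val.tolist())
            assert covered == set(np.flatnonzero(season == "C").tolist())
        audit_fold_plan(plan, samples)

    def test_missing_test_season_and_too_many_folds_error(self):
        samples = self.samples_10x6()
        with pytest.raises(ValueError, match="absent"):
            build_fold_plan(samples, "unseen_season", test_season="S9")
        with pytest.raises(ValueError, match="exceeds"):
            build_fold_plan(samples, "unseen_genotype", k_folds=11, reps=1)

    def test_corrupted_plan_rejected_by_audit(self):
        samples = self.samples_10x6()
        plan = build_fold_plan(samples, "unseen_genotype", k_folds=5, reps=1, seed=0)
        cal, val = plan.repetitions[0][0]
        # move one row of a validation genotype into calibration: the rest of
        # that genotype stays in validation, so the genotype leaks
        plan.repetitions[0][0] = (np.append(cal, val[0]), val[1:])
        with pytest.raises(LeakageError, match="genotype"):
            audit_fold_plan(plan, samples)

    def test_overlapping_validation_folds_rejected(self):
        samples = self.samples_10x6()
        plan = build_fold_plan(samples, "random", k_folds=5, reps=1, seed=0)
        cal0, val0 = plan.repetitions[0][0]
        cal1, val1 = plan.repetitions[0][1]
        plan.repetitions[0][1] = (cal1, np.union1d(val1, val0[:1]))
        with pytest.raises(LeakageError):
            audit_fold_plan(plan, samples)


class TestNestedCV:
    def test_20x5_yields_100_fold_records(self):
        ds, tt, _ = generate_dataset(noiseless_config(), seed=1)
        res = run_nested_cv(
            ds, tt, "t", ModelSpec(noc_grid=tuple(range(1, 6))),
            scenario="random", k_folds=5, reps=20, seed=0,
        )
        assert len(res.per_fold) == 100
        assert res.per_fold["repetition"].nunique() == 20

    def test_noiseless_data_gives_near_perfect_r2(self):
        ds, tt, _ = generate_dataset(noiseless_config(), seed=2)
        res = run_nested_cv(
            ds, tt, "t", ModelSpec(noc_grid=tuple(range(1, 6))),
            scenario="random", k_folds=5, reps=3, seed=0,
        )
        assert res.median("r2") >= 0.99

    def test_null_trait_gives_near_zero_r2(self):
        cfg = noiseless_config(n_genotypes=50).with_(
            traits={
                "null": TraitDef((0.0, 0.0, 0.0), noise_sd=1.0,
                                 genotype_dev_sd=0.0, gxe_sensitivity=0.0)
            }
        )
        ds, tt, _ = generate_dataset(cfg, seed=3)
        res = run_nested_cv(
            ds, tt, "null", ModelSpec(noc_grid=tuple(range(1, 6))),
            scenario="random", k_folds=5, reps=4, seed=0,
        )
        assert abs(res.median("r2")) <= 0.05

    def test_missing_trait_rows_dropped_per_fold(self):
        cfg = small_noisy_config(n_genotypes=20, n_seasons=1)
        cfg = cfg.with_(
            traits={
                "m": TraitDef((1.0, 0.5, 0, 0, 0, 0), noise_sd=0.5,
                              missing_rate=0.2)
            }
        )
        ds, tt, _ = generate_dataset(cfg, seed=4)
        n_missing = int(np.isnan(tt.values["m"]).sum())
        assert n_missing > 0
        res = run_nested_cv(
            ds, tt, "m", ModelSpec(noc_grid=tuple(range(1, 8))),
            scenario="random", k_folds=5, reps=2, seed=0,
        )
        per_rep = res.per_fold.groupby("repetition")[
            ["n_calibration", "n_validation"]
        ].sum()
        # every repetition sees each non-missing sample k-1 times in
        # calibration and once in validation
        expected = 5 * (ds.n_samples - n_missing)
        assert (per_rep.sum(axis=1) == expected).all()

    def test_trait_window_restricts_predictors(self):
        cfg = small_noisy_config(n_genotypes=15, n_seasons=1)
        ds, tt, _ = generate_dataset(cfg, seed=5)
        res = run_nested_cv(
            ds, tt, "nitrogen_pct", ModelSpec(noc_grid=tuple(range(1, 8))),
            scenario="random", k_folds=5, reps=2, seed=0,
        )
        assert res.config["trait"] == "nitrogen_pct"
        assert len(res.per_fold) == 10

    def test_svr_model_runs_and_selects_c(self):
        cfg = small_noisy_config(n_genotypes=15, n_seasons=1)
        ds, tt, _ = generate_dataset(cfg, seed=6)
        res = run_nested_cv(
            ds, tt, "photo_rate",
            ModelSpec(model="svr", c_grid=(0.1, 1.0, 10.0)),
            scenario="random", k_folds=5, reps=2, seed=0,
        )
        assert set(res.per_fold["selected"]).issubset({0.1, 1.0, 10.0})
        assert res.median("r2") > 0.2

    def test_rerun_same_seed_is_identical(self):
        cfg = small_noisy_config(n_genotypes=15, n_seasons=1)
        ds, tt, _ = generate_dataset(cfg, seed=7)
        kw = dict(
            model_spec=ModelSpec(noc_grid=tuple(range(1, 8))),
            scenario="random", k_folds=5, reps=2, seed=3,
        )
        a = run_nested_cv(ds, tt, "sla", **kw)
        b = run_nested_cv(ds, tt, "sla", **kw)
        pd.testing.assert_frame_equal(a.per_fold, b.per_fold)


class TestScenarioProperties:
    def test_random_beats_unseen_genotype(self):
        """Replicate sharing inflates random-split accuracy relative to
        genotype-exclusive folds."""
        meds = {"random": [], "unseen_genotype": []}
        ms = ModelSpec(noc_grid=tuple(range(1, 16)))
        for seed in range(3):
            ds, tt, _ = generate_dataset(small_noisy_config(n_seasons=1, reps_per_plot=3), seed=seed)
            for scen in meds:
                res = run_nested_cv(
                    ds, tt, "photo_rate", ms, scenario=scen,
                    k_folds=5, reps=3, seed=seed,
                )
                meds[scen].append(res.median("r2"))
        assert np.mean(meds["random"]) >= np.mean(meds["unseen_genotype"])

    def test_season_scaling_improves_cross_season_transfer(self):
        """A pure between-season trait mean shift is corrected by per-season
        centering/scaling, raising cross-season squared Pearson."""
        gains = []
        ms = ModelSpec(noc_grid=tuple(range(1, 16)))
        for seed in range(3):
            ds, tt, _ = generate_dataset(
                small_noisy_config(reps_per_plot=1), seed=seed
            )
            kw = dict(
                model_spec=ms, scenario="unseen_season",
                train_seasons=["S1", "S2"], test_season="S3", seed=seed,
            )
            off = run_nested_cv(
                ds, tt, "sla", cv_config=NestedCVConfig(scale_by_season=False), **kw
            )
            on = run_nested_cv(
                ds, tt, "sla", cv_config=NestedCVConfig(scale_by_season=True), **kw
            )
            gains.append(
                on.median("sq_pearson") - off.median("sq_pearson")
            )
        assert np.mean(gains) > 0

    def test_aggregation_recovers_signal_under_replicate_noise(self):
        """With replicate-level trait noise well above the signal SD,
        genotype averaging beats raw data."""
        tr = {
            "t": TraitDef((1.0, 0.7, 0.4, 0, 0, 0), noise_sd=3.0,
                          genotype_dev_sd=0.0, gxe_sensitivity=0.0)
        }
        cfg = small_noisy_config(
            n_genotypes=50, n_seasons=1, reps_per_plot=3, traits=tr
        )
        ds, tt, _ = generate_dataset(cfg, seed=0)
        ms = ModelSpec(noc_grid=tuple(range(1, 16)))
        raw = run_nested_cv(ds, tt, "t", ms, aggregation="raw",
                            scenario="random", reps=3, seed=0)
        gen = run_nested_cv(ds, tt, "t", ms, aggregation="genotype",
                            scenario="random", reps=3, seed=0)
        assert gen.median("r2") > raw.median("r2")
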