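"""Config-driven orchestration: describe -> calibrate -> evaluate -> report.

An experiment is a flat YAML/dict config naming either a synthetic-data
configuration or three dataset CSV paths, plus a list of evaluation runs
(trait × model × aggregation × scenario).  Every run writes tidy per-fold
CSVs and a JSON summary into the output directory together with a frozen
copy of the resolved config, so every reported number is recomputable from
the artifacts alone.  A failing run is logged and surfaced at the end
without aborting the other runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import SpectralDataset, TraitSpec, TraitTable, load_dataset, subsample_wavelengths, write_dataset
from .descriptive import SeasonSummary, season_summary
from .scenarios import EvaluationResult, ModelSpec, NestedCVConfig, run_nested_cv
from .simulate import SyntheticConfig, TraitDef, generate_dataset

logger = logging.getLogger("leafspec")


@dataclass
class RunSpec:
    """One evaluation run: trait × model × aggregation × scenario."""

    trait: str
    model: str = "plsr"
    aggregation: str = "raw"
    scenario: str = "random"
    k_folds: int = 5
    reps: int = 20
    train_seasons: list | None = None
    test_season: str | None = None
    scale_by_season: bool | None = None

    def label(self) -> str:
        return f"{self.trait}__{self.model}__{self.aggregation}__{self.scenario}"


@dataclass
class ExperimentConfig:
    """Resolved experiment configuration."""

    seed: int = 0
    output_dir: str = "leafspec_out"
    synthetic: SyntheticConfig | None = None
    dataset_paths: dict | None = None  # {"spectra":..., "traits":..., "metadata":...}
    subsample_step: int = 1
    describe: bool = False
    mantel_permutations: int = 199
    calibration: NestedCVConfig = field(default_factory=NestedCVConfig)
    noc_grid: tuple = tuple(range(1, 21))
    c_grid: tuple = tuple(np.logspace(-3, 3, 9))
    runs: list[RunSpec] = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        synthetic = None
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw.pop("synthetic"))
            if "traits" in syn and syn["traits"] is not None:
                syn["traits"] = {
                    name: TraitDef(
                        loadings=tuple(td["loadings"]),
                        noise_sd=float(td.get("noise_sd", 0.5)),
                        season_shift=dict(td.get("season_shift", {})),
                        wavelength_window=tuple(td["wavelength_window"])
                        if td.get("wavelength_window")
                        else None,
                        scale_by_season=bool(td.get("scale_by_season", False)),
                        missing_rate=float(td.get("missing_rate", 0.0)),
                    )
                    for name, td in syn["traits"].items()
                }
            synthetic = SyntheticConfig(**syn)
        dataset_paths = raw.pop("dataset", None)
        calibration = NestedCVConfig(**raw.pop("calibration", {}))
        runs = [RunSpec(**r) for r in raw.pop("runs", [])]
        noc_grid = tuple(raw.pop("noc_grid", tuple(range(1, 21))))
        c_grid = tuple(raw.pop("c_grid", tuple(np.logspace(-3, 3, 9))))
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(
            synthetic=synthetic,
            dataset_paths=dataset_paths,
            calibration=calibration,
            runs=runs,
            noc_grid=noc_grid,
            c_grid=c_grid,
            **{k: v for k, v in raw.items() if k in known},
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noc_grid"] = [int(v) for v in self.noc_grid]
        d["c_grid"] = [float(v) for v in self.c_grid]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_inputs(config: ExperimentConfig) -> tuple[SpectralDataset, TraitTable]:
    if config.synthetic is not None:
        ds, tt, _ = generate_dataset(config.synthetic, seed=config.seed)
    elif config.dataset_paths is not None:
        ds, tt = load_dataset(
            config.dataset_paths["spectra"],
            config.dataset_paths["traits"],
            config.dataset_paths["metadata"],
        )
    else:
        raise ValueError("config needs either a 'synthetic' or a 'dataset' section")
    if config.subsample_step > 1:
        ds = subsample_wavelengths(ds, config.subsample_step)
    return ds, tt


@dataclass
class ExperimentOutput:
    results: dict[str, EvaluationResult]
    season: SeasonSummary | None
    failures: dict[str, str]
    output_dir: Path


def run_experiment(config: ExperimentConfig) -> ExperimentOutput:
    """Execute an experiment config end to end, writing all artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    logger.info("experiment seed=%d hash=%s", config.seed, config.config_hash())
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    ds, tt = _load_inputs(config)
    for run in config.runs:
        if run.trait not in tt.values:
            raise ValueError(
                f"config references unknown trait {run.trait!r}; "
                f"available: {tt.trait_names}"
            )
        if run.scenario not in (
            "random", "unseen_genotype", "unseen_season",
            "unseen_genotype_unseen_season",
        ):
            raise ValueError(f"unknown scenario {run.scenario!r}")

    season = None
    if config.describe:
        season = season_summary(
            ds, tt, n_perm=config.mantel_permutations, seed=config.seed
        )
        for name, frame in season.to_frames().items():
            frame.to_csv(out / f"describe_{name}.csv", index=False)

    results: dict[str, EvaluationResult] = {}
    failures: dict[str, str] = {}
    for run in config.runs:
        label = run.label()
        model_spec = ModelSpec(
            model=run.model, noc_grid=config.noc_grid, c_grid=config.c_grid
        )
        cv_config = dataclasses.replace(
            config.calibration, scale_by_season=run.scale_by_season
        )
        try:
            res = run_nested_cv(
                ds, tt, run.trait,
                model_spec=model_spec,
                aggregation=run.aggregation,
                scenario=run.scenario,
                k_folds=run.k_folds,
                reps=run.reps,
                train_seasons=run.train_seasons,
                test_season=run.test_season,
                cv_config=cv_config,
                seed=config.seed,
            )
        except Exception as exc:  # keep other runs alive
            logger.error("run %s failed: %s", label, exc)
            failures[label] = str(exc)
            continue
        results[label] = res
        res.per_fold.to_csv(out / f"{label}__folds.csv", index=False)
        logger.info(
            "run %s: %s", label,
            {m: round(s["median"], 4) for m, s in res.summaries.items()},
        )

    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "runs": {
            label: {"summaries": res.summaries, "config": res.config}
            for label, res in results.items()
        },
        "failures": failures,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return ExperimentOutput(results, season, failures, out)


def significance_stars(p: float) -> str:
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p <= thresh:
            return stars
    return "ns"


def compare_scenarios(
    a: EvaluationResult, b: EvaluationResult, metric: str = "r2"
) -> dict:
    """Paired Wilcoxon signed-rank test between two evaluations of the same
    data, pairing per-repetition medians of the metric.  Reporting-time
    annotation only."""
    from scipy import stats

    ma = a.per_fold.groupby("repetition")[metric].median()
    mb = b.per_fold.groupby("repetition")[metric].median()
    if len(ma) != len(mb):
        raise ValueError("evaluations have different repetition counts")
    if np.allclose(ma.to_numpy(), mb.to_numpy()):
        return {"statistic": 0.0, "p_value": 1.0, "stars": "ns"}
    stat, p = stats.wilcoxon(ma.to_numpy(), mb.to_numpy())
    return {"statistic": float(stat), "p_value": float(p),
            "stars": significance_stars(float(p))}


def summarize(results: dict[str, EvaluationResult]) -> pd.DataFrame:
    """Report table: one row per configuration × metric with median and IQR."""
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for label, res in results.items():
        for metric, s in res.summaries.items():
            rows.append(
                {
                    "run": label,
                    "trait": res.config.get("trait"),
                    "model": res.config.get("model"),
                    "aggregation": res.config.get("aggregation"),
                    "scenario": res.config.get("scenario"),
                    "metric": metric,
                    "median": s["median"],
                    "iqr": s["iqr"],
                    "n_folds": len(res.per_fold),
                }
            )
    return pd.DataFrame(rows)


def simulate_to_files(
    config: SyntheticConfig, seed: int, out_dir
) -> dict[str, Path]:
    """Generate a synthetic dataset and write the three CSVs plus the
    ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, tt, truth = generate_dataset(config, seed=seed)
    paths = {
        "spectra": out / "spectra.csv",
        "traits": out / "traits.csv",
        "metadata": out / "metadata.csv",
        "truth": out / "ground_truth.json",
    }
    write_dataset(ds, tt, paths["spectra"], paths["traits"], paths["metadata"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "trait_loadings": {
                    k: v.tolist() for k, v in truth.trait_loadings.items()
                },
                "realized_variances": truth.realized_variances,
                "config": dataclasses.asdict(config),
            },
            fh,
            indent=2,
            default=str,
        )
    return paths
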