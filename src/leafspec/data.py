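"""Aligned spectra / trait / metadata containers and preprocessing rules.

A dataset is a triple of files sharing one ``sample_id`` key:

* spectra — wide CSV, first column ``sample_id``, remaining headers numeric
  wavelengths in nm (strictly increasing);
* traits — CSV with ``sample_id`` plus one column per trait, empty cell =
  missing;
* metadata — CSV with ``sample_id, genotype_id, season, plot_id,
  replicate_id`` describing the field hierarchy (genotypes grown in
  replicated plots within seasons).

In memory they become a :class:`SpectralDataset` and a :class:`TraitTable`
sharing one sample order.  Preprocessing mirrors common practice for
leaf-level reflectance: wavelength sub-sampling, restriction of a trait to a
spectral window (e.g. 1500–2400 nm for nitrogen-related traits), averaging
replicates up to plot or genotype level, and per-season centering/scaling of
trait values before seasons are pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = ["sample_id", "genotype_id", "season", "plot_id", "replicate_id"]

#: sentinel for hierarchy levels collapsed by aggregation
COLLAPSED = "*"

REFLECTANCE_RANGE = (-0.01, 1.5)


class DataValidationError(ValueError):
    """Raised when input tables violate the dataset contract."""


@dataclass(frozen=True)
class SampleKey:
    """Identity of one leaf-level observation within the field hierarchy."""

    sample_id: str
    genotype_id: str
    season: str
    plot_id: str
    replicate_id: str


@dataclass(frozen=True)
class TraitSpec:
    """Per-trait modelling options.

    wavelength_window
        Closed nm interval of predictors used for this trait, or ``None``
        for the full grid.
    scale_by_season
        Whether trait values are centred/scaled within each season before
        seasons are pooled for training.
    """

    wavelength_window: tuple[float, float] | None = None
    scale_by_season: bool = False


def _check_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in samples.columns]
    if missing:
        raise DataValidationError(f"metadata missing columns: {missing}")
    samples = samples[METADATA_COLUMNS].astype(str).reset_index(drop=True)
    dup = samples["sample_id"][samples["sample_id"].duplicated()]
    if len(dup):
        raise DataValidationError(f"duplicate sample_id: {sorted(set(dup))}")
    key_cols = ["genotype_id", "season", "plot_id", "replicate_id"]
    if samples.duplicated(key_cols).any():
        bad = samples[samples.duplicated(key_cols, keep=False)]
        raise DataValidationError(
            "duplicate (genotype, season, plot, replicate) keys:\n" + bad.to_string()
        )
    return samples


@dataclass
class SpectralDataset:
    """n×p reflectance matrix with its wavelength grid and sample metadata."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.samples = _check_samples(self.samples)
        if self.wavelengths.ndim != 1 or np.any(np.diff(self.wavelengths) <= 0):
            raise DataValidationError("wavelengths must be strictly increasing")
        if self.reflectance.shape != (len(self.samples), len(self.wavelengths)):
            raise DataValidationError(
                f"reflectance shape {self.reflectance.shape} does not match "
                f"{len(self.samples)} samples x {len(self.wavelengths)} wavelengths"
            )
        if np.isnan(self.reflectance).any():
            raise DataValidationError("reflectance contains NaN")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]

    def sample_keys(self) -> list[SampleKey]:
        return [SampleKey(*row) for row in self.samples.itertuples(index=False)]


@dataclass
class TraitTable:
    """Per-sample trait values (NaN = missing), aligned to a SpectralDataset."""

    samples: pd.DataFrame
    values: dict[str, np.ndarray]
    registry: dict[str, TraitSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = _check_samples(self.samples)
        n = len(self.samples)
        clean: dict[str, np.ndarray] = {}
        for name, vec in self.values.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise DataValidationError(
                    f"trait {name!r} has length {vec.shape}, expected ({n},)"
                )
            clean[name] = vec
        self.values = clean

    @property
    def trait_names(self) -> list[str]:
        return list(self.values)

    def spec_for(self, trait: str) -> TraitSpec:
        return self.registry.get(trait, TraitSpec())


def _check_aligned(ds: SpectralDataset, tt: TraitTable) -> None:
    if not ds.samples["sample_id"].equals(tt.samples["sample_id"]):
        raise DataValidationError("spectra and traits are not aligned by sample_id")


# ---------------------------------------------------------------------------
# IO


def load_dataset(
    spectra_path,
    traits_path,
    metadata_path,
    registry: dict[str, TraitSpec] | None = None,
) -> tuple[SpectralDataset, TraitTable]:
    """Load and align the three CSV files into dataset objects.

    The spectra file's sample order defines the shared order.  Samples
    missing from the trait file are retained with all traits missing and
    reported via a warning; samples missing from the metadata file are a
    hard error.
    """
    spectra = pd.read_csv(spectra_path, float_precision="round_trip")
    if spectra.columns[0] != "sample_id":
        raise DataValidationError("spectra file must start with a sample_id column")
    try:
        wavelengths = np.array([float(c) for c in spectra.columns[1:]])
    except ValueError as exc:
        raise DataValidationError(f"non-numeric wavelength header: {exc}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise DataValidationError("wavelength header is not strictly increasing")
    sample_ids = spectra["sample_id"].astype(str)
    dup = sample_ids[sample_ids.duplicated()]
    if len(dup):
        raise DataValidationError(f"duplicate sample_id in spectra: {sorted(set(dup))}")
    reflectance = spectra.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(reflectance).any():
        raise DataValidationError("reflectance contains missing values")
    lo, hi = REFLECTANCE_RANGE
    n_out = int(np.sum((reflectance < lo) | (reflectance > hi)))
    if n_out:
        warnings.warn(
            f"{n_out} reflectance values outside [{lo}, {hi}]", stacklevel=2
        )

    meta = pd.read_csv(metadata_path, dtype=str)
    meta = _check_samples(meta)
    meta_ids = set(meta["sample_id"])
    absent = [s for s in sample_ids if s not in meta_ids]
    if absent:
        raise DataValidationError(f"metadata missing sample_id(s): {absent}")
    meta = meta.set_index("sample_id").loc[sample_ids].reset_index()

    traits = pd.read_csv(traits_path, float_precision="round_trip")
    traits["sample_id"] = traits["sample_id"].astype(str)
    trait_names = [c for c in traits.columns if c != "sample_id"]
    missing_in_traits = [s for s in sample_ids if s not in set(traits["sample_id"])]
    if missing_in_traits:
        warnings.warn(
            f"{len(missing_in_traits)} sample(s) absent from trait file, traits "
            f"set to missing: {missing_in_traits[:5]}",
            stacklevel=2,
        )
    traits = traits.set_index("sample_id").reindex(sample_ids)
    values = {name: traits[name].to_numpy(dtype=float) for name in trait_names}

    ds = SpectralDataset(wavelengths, reflectance, meta)
    tt = TraitTable(meta.copy(), values, dict(registry or {}))
    _validate_registry(ds, tt)
    return ds, tt


def _validate_registry(ds: SpectralDataset, tt: TraitTable) -> None:
    wl_lo, wl_hi = ds.wavelengths[0], ds.wavelengths[-1]
    for name, spec in tt.registry.items():
        if spec.wavelength_window is not None:
            lo, hi = spec.wavelength_window
            if lo < wl_lo or hi > wl_hi:
                raise DataValidationError(
                    f"window {spec.wavelength_window} for trait {name!r} lies "
                    f"outside the grid [{wl_lo}, {wl_hi}]"
                )


def write_dataset(ds: SpectralDataset, tt: TraitTable, spectra_path, traits_path, metadata_path) -> None:
    """Write the three CSVs; mirrors :func:`load_dataset` bit-exactly."""
    _check_aligned(ds, tt)
    spectra = pd.DataFrame(
        ds.reflectance, columns=[repr(float(w)) for w in ds.wavelengths]
    )
    spectra.insert(0, "sample_id", ds.samples["sample_id"].to_numpy())
    spectra.to_csv(spectra_path, index=False)
    traits = pd.DataFrame({"sample_id": tt.samples["sample_id"].to_numpy(), **tt.values})
    traits.to_csv(traits_path, index=False)
    ds.samples.to_csv(metadata_path, index=False)


# ---------------------------------------------------------------------------
# Transformations


def subsample_wavelengths(ds: SpectralDataset, step: int) -> SpectralDataset:
    """Keep every ``step``-th wavelength starting at the first one.

    Used as a cheap dimension reduction: a 2001-wavelength 1 nm grid with
    ``step=5`` keeps 401 wavelengths with near-identical downstream model
    accuracy.
    """
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    idx = np.arange(0, ds.n_wavelengths, step)
    return SpectralDataset(
        ds.wavelengths[idx], ds.reflectance[:, idx], ds.samples.copy()
    )


def restrict_wavelengths(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep wavelengths w with lo <= w <= hi (closed interval)."""
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (ds.wavelengths >= lo) & (ds.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"no wavelengths in window [{lo}, {hi}]")
    return SpectralDataset(
        ds.wavelengths[mask], ds.reflectance[:, mask], ds.samples.copy()
    )


_AGG_LEVELS = ("raw", "plot", "genotype")


def aggregate(
    ds: SpectralDataset, tt: TraitTable, level: str
) -> tuple[SpectralDataset, TraitTable]:
    """Average replicate rows up to plot or genotype level.

    ``plot`` keeps one row per (genotype, season, plot); ``genotype`` keeps
    one row per (genotype, season).  Reflectance is averaged wavelength by
    wavelength; traits are averaged ignoring missing cells (a group with no
    observed value stays missing).  Collapsed hierarchy levels get the "*"
    sentinel.
    """
    _check_aligned(ds, tt)
    if level not in _AGG_LEVELS:
        raise ValueError(f"level must be one of {_AGG_LEVELS}, got {level!r}")
    if level == "raw":
        return ds, tt

    keys = ["genotype_id", "season"] + (["plot_id"] if level == "plot" else [])
    groups = ds.samples.groupby(keys, sort=False)
    rows: list[dict[str, str]] = []
    refl = np.empty((groups.ngroups, ds.n_wavelengths))
    vals = {name: np.empty(groups.ngroups) for name in tt.values}
    for i, (key, sub) in enumerate(groups):
        key = (key,) if isinstance(key, str) else key
        idx = sub.index.to_numpy()
        refl[i] = ds.reflectance[idx].mean(axis=0)
        for name, vec in tt.values.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vals[name][i] = np.nanmean(vec[idx])
        rec = dict(zip(keys, key))
        rec.setdefault("plot_id", COLLAPSED)
        rec["replicate_id"] = COLLAPSED
        rec["sample_id"] = "|".join(
            [rec["genotype_id"], rec["season"]]
            + ([rec["plot_id"]] if level == "plot" else [])
        )
        rows.append(rec)
    samples = pd.DataFrame(rows)[METADATA_COLUMNS]
    ds_out = SpectralDataset(ds.wavelengths.copy(), refl, samples)
    tt_out = TraitTable(samples.copy(), vals, dict(tt.registry))
    return ds_out, tt_out


def center_scale_by_season(
    tt: TraitTable, trait: str
) -> tuple[TraitTable, dict[str, tuple[float, float]]]:
    """Z-score one trait within each season (sample SD, ddof=1).

    Returns the transformed table and per-season (mean, SD) so predictions
    can be mapped back to the original scale when needed.  Squared Pearson
    correlation, the metric used for cross-season transfer, is invariant to
    the affine back-transform.
    """
    if trait not in tt.values:
        raise KeyError(f"unknown trait {trait!r}")
    vec = tt.values[trait].copy()
    params: dict[str, tuple[float, float]] = {}
    for season in tt.samples["season"].unique():
        mask = (tt.samples["season"] == season).to_numpy() & ~np.isnan(vec)
        if mask.sum() < 2:
            raise ValueError(
                f"season {season!r} has {int(mask.sum())} non-missing value(s) "
                f"for trait {trait!r}; need at least 2"
            )
        mu = float(vec[mask].mean())
        sd = float(vec[mask].std(ddof=1))
        if sd == 0:
            raise ValueError(f"zero within-season SD for trait {trait!r} in {season!r}")
        vec[mask] = (vec[mask] - mu) / sd
        params[str(season)] = (mu, sd)
    values = dict(tt.values)
    values[trait] = vec
    return TraitTable(tt.samples.copy(), values, dict(tt.registry)), params
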