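"""Season-comparison statistics for multi-season trait/spectra panels.

Before any modelling, four descriptive views quantify how much seasons
differ and therefore how hard cross-season transfer is likely to be:

* per-trait coefficient of variation within each season;
* Spearman rank correlation of genotype-mean trait values between seasons
  (are genotype rankings stable across environments?);
* per-genotype Pearson correlation of mean spectra between seasons inside a
  wavelength region (visible, near-infrared, shortwave-infrared);
* a Mantel permutation test comparing the genotype × genotype covariance
  matrices of mean spectra from two seasons (is the covariance *structure*
  preserved even when levels shift?).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .data import SpectralDataset, TraitTable, restrict_wavelengths

#: default spectral regions (nm): visible, near-infrared, shortwave-infrared
DEFAULT_REGIONS = {
    "visible": (350.0, 700.0),
    "nir": (700.0, 1300.0),
    "swir": (1300.0, 2500.0),
}


def coefficient_of_variation(tt: TraitTable, trait: str, season: str) -> float:
    """CV% = 100 * sample SD / mean of the trait within one season."""
    if trait not in tt.values:
        raise KeyError(f"unknown trait {trait!r}")
    mask = (tt.samples["season"].astype(str) == str(season)).to_numpy()
    vals = tt.values[trait][mask]
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError(f"fewer than 2 non-missing values in season {season!r}")
    mean = float(vals.mean())
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return 100.0 * float(vals.std(ddof=1)) / mean


def _genotype_means(
    tt: TraitTable, trait: str, season: str
) -> pd.Series:
    mask = (tt.samples["season"].astype(str) == str(season)).to_numpy()
    df = pd.DataFrame(
        {
            "genotype_id": tt.samples["genotype_id"].to_numpy()[mask],
            "value": tt.values[trait][mask],
        }
    )
    return df.groupby("genotype_id")["value"].mean().dropna()


def between_season_spearman(
    tt: TraitTable, trait: str, season_a: str, season_b: str
) -> float:
    """Spearman rank correlation of genotype-mean trait values between two
    seasons, over the genotypes present in both."""
    a = _genotype_means(tt, trait, season_a)
    b = _genotype_means(tt, trait, season_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} genotype(s) shared between seasons; need >= 3"
        )
    rho, _ = stats.spearmanr(a.loc[shared], b.loc[shared])
    return float(rho)


def _genotype_mean_spectra(ds: SpectralDataset, season: str) -> pd.DataFrame:
    mask = (ds.samples["season"].astype(str) == str(season)).to_numpy()
    if not mask.any():
        raise ValueError(f"season {season!r} absent from data")
    df = pd.DataFrame(ds.reflectance[mask])
    df["genotype_id"] = ds.samples["genotype_id"].to_numpy()[mask]
    return df.groupby("genotype_id").mean()


def cross_season_spectral_correlation(
    ds: SpectralDataset,
    region: tuple[float, float],
    season_a: str,
    season_b: str,
    mode: str = "per_genotype",
) -> float:
    """Mean correlation of genotype-mean spectra between two seasons inside
    one wavelength region.

    ``per_genotype`` (default) correlates each shared genotype's two mean
    spectra across the region's wavelengths and averages over genotypes;
    ``per_wavelength`` correlates genotype values across genotypes at each
    wavelength and averages over wavelengths.
    """
    ds = restrict_wavelengths(ds, *region)
    a = _genotype_mean_spectra(ds, season_a)
    b = _genotype_mean_spectra(ds, season_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} genotype(s) shared between seasons; need >= 3"
        )
    A = a.loc[shared].to_numpy()
    B = b.loc[shared].to_numpy()
    if mode == "per_genotype":
        corrs = [
            float(np.corrcoef(A[i], B[i])[0, 1]) for i in range(len(shared))
        ]
    elif mode == "per_wavelength":
        corrs = [
            float(np.corrcoef(A[:, j], B[:, j])[0, 1]) for j in range(A.shape[1])
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.mean(corrs))


def season_covariance(
    ds: SpectralDataset, season: str, genotypes=None
) -> np.ndarray:
    """Genotype × genotype covariance matrix of mean spectra for one season,
    computed across wavelengths; the Mantel-test input."""
    means = _genotype_mean_spectra(ds, season)
    if genotypes is not None:
        means = means.loc[list(genotypes)]
    return np.cov(means.to_numpy())


def mantel_test(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 999,
    seed: int | None = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """Mantel test between two symmetric matrices.

    The statistic r is the Pearson correlation of the strictly-upper-
    triangle entries.  The p-value permutes B's rows and columns
    simultaneously: random permutations (identity excluded) with the
    (count + 1)/(n_perm + 1) estimator, one-sided upper; or, with
    ``exact=True``, full enumeration of all n! permutations with
    p = count(r_perm >= r)/n! (feasible for small matrices only).
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A and B must be square matrices of equal size")
    if not np.allclose(A, A.T) or not np.allclose(B, B.T):
        raise ValueError("inputs must be symmetric")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A[iu]

    def corr_with(Bp: np.ndarray) -> float:
        return float(np.corrcoef(a, Bp[iu])[0, 1])

    r = corr_with(B)
    eps = 1e-12
    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        total = math.factorial(n)
        count = 0
        for perm in permutations(range(n)):
            perm = np.asarray(perm)
            if corr_with(B[np.ix_(perm, perm)]) >= r - eps:
                count += 1
        return r, count / total
    rng = np.random.default_rng(seed)
    identity = np.arange(n)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        while np.array_equal(perm, identity):
            perm = rng.permutation(n)
        if corr_with(B[np.ix_(perm, perm)]) >= r - eps:
            count += 1
    return r, (count + 1) / (n_perm + 1)


@dataclass
class SeasonSummary:
    """Collected season-comparison statistics for one dataset."""

    trait_cv: pd.DataFrame          # trait x season CV%
    trait_spearman: pd.DataFrame    # trait x season-pair Spearman rho
    spectral_correlation: pd.DataFrame  # region x season-pair mean correlation
    mantel: pd.DataFrame            # season-pair Mantel r and p

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "trait_cv": self.trait_cv,
            "trait_spearman": self.trait_spearman,
            "spectral_correlation": self.spectral_correlation,
            "mantel": self.mantel,
        }


def season_summary(
    ds: SpectralDataset,
    tt: TraitTable,
    regions: dict[str, tuple[float, float]] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> SeasonSummary:
    """Compute all descriptive statistics for every trait and season pair."""
    if regions is None:
        lo, hi = ds.wavelengths[0], ds.wavelengths[-1]
        regions = {
            name: (max(rlo, lo), min(rhi, hi))
            for name, (rlo, rhi) in DEFAULT_REGIONS.items()
            if rlo < hi and rhi > lo
        }
    seasons = list(dict.fromkeys(ds.samples["season"].astype(str)))
    pairs = [
        (seasons[i], seasons[j])
        for i in range(len(seasons))
        for j in range(i + 1, len(seasons))
    ]

    cv_rows = []
    for trait in tt.trait_names:
        for s in seasons:
            try:
                cv = coefficient_of_variation(tt, trait, s)
            except ValueError:
                cv = np.nan
            cv_rows.append({"trait": trait, "season": s, "cv_pct": cv})
    sp_rows = []
    for trait in tt.trait_names:
        for sa, sb in pairs:
            try:
                rho = between_season_spearman(tt, trait, sa, sb)
            except ValueError:
                rho = np.nan
            sp_rows.append(
                {"trait": trait, "season_a": sa, "season_b": sb, "spearman": rho}
            )
    sc_rows = []
    for name, region in regions.items():
        for sa, sb in pairs:
            sc_rows.append(
                {
                    "region": name,
                    "season_a": sa,
                    "season_b": sb,
                    "mean_correlation": cross_season_spectral_correlation(
                        ds, region, sa, sb
                    ),
                }
            )
    mantel_rows = []
    shared_by_pair = {}
    for sa, sb in pairs:
        ga = set(ds.samples.loc[ds.samples["season"].astype(str) == sa, "genotype_id"])
        gb = set(ds.samples.loc[ds.samples["season"].astype(str) == sb, "genotype_id"])
        shared_by_pair[(sa, sb)] = sorted(ga & gb)
    for (sa, sb), shared in shared_by_pair.items():
        cov_a = season_covariance(ds, sa, shared)
        cov_b = season_covariance(ds, sb, shared)
        r, p = mantel_test(cov_a, cov_b, n_perm=n_perm, seed=seed)
        mantel_rows.append(
            {"season_a": sa, "season_b": sb, "mantel_r": r, "p_value": p}
        )
    return SeasonSummary(
        pd.DataFrame(cv_rows),
        pd.DataFrame(sp_rows),
        pd.DataFrame(sc_rows),
        pd.DataFrame(mantel_rows),
    )
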