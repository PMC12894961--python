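"""Synthetic multi-season leaf spectra and traits with known ground truth.

The generator emulates the statistical structure of a multi-season field
phenotyping trial — many genotypes grown in replicated plots over several
seasons — without modelling leaf optics.  Each sample carries a small
vector of latent scores decomposed into genotype, season, genotype×season
(G×E), plot, and residual effects, all Gaussian with configurable
variances:

    t_if = g_f(genotype) + s_f(season) + gx_f(genotype, season)
           + p_f(plot) + e_if.

Reflectance is a smooth season baseline (low visible reflectance, a
near-infrared plateau, declining shortwave-infrared) plus the latent scores
mapped through Gaussian-bump basis functions, plus smooth spectral noise,
clipped to [0, 1].  One season's baseline can carry an elevated 750–1500 nm
plateau, mimicking the kind of seasonal anomaly that breaks cross-season
model transfer.  Traits are linear in the same latent scores plus optional
per-season mean shifts and observation noise, so the spectra→trait map is
exactly low-rank and every pipeline property (NoC recovery, scenario
ordering, G×E monotonicity, aggregation and scaling effects) is testable
against known truth.

Defaults mirror the field design the pipeline targets: 320 genotypes ×
3 seasons × 2 plots × 3 replicates, reflectance on a 400–2400 nm grid at
1 nm steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import METADATA_COLUMNS, SpectralDataset, TraitSpec, TraitTable


@dataclass(frozen=True)
class TraitDef:
    """One simulated trait: loadings on the latent scores, noise, shifts.

    ``noise_sd`` is independent per leaf-level observation.
    ``genotype_dev_sd`` is a deviation fixed per genotype across all
    seasons (idiosyncratic but genetically stable).  ``gxe_sensitivity``
    scales a genotype×season trait deviation drawn with SD
    ``gxe_sensitivity · sqrt(var_gxe)``: the part of the trait's G×E
    response that reflectance does not carry, which is what makes
    cross-season transfer degrade as G×E variance grows.  Together with the
    matching spectral signatures these create the information that
    replicate- or genotype-sharing validation schemes can exploit but
    genotype-exclusive / cross-season ones cannot.
    """

    loadings: tuple
    noise_sd: float = 0.5
    genotype_dev_sd: float = 0.0
    gxe_sensitivity: float = 1.0
    season_shift: dict = field(default_factory=dict)  # season label -> shift
    wavelength_window: tuple[float, float] | None = None
    scale_by_season: bool = False
    missing_rate: float = 0.0


def _default_traits(n_latent: int) -> dict[str, TraitDef]:
    def pad(v):
        return tuple((list(v) + [0.0] * n_latent)[:n_latent])

    return {
        # structural trait with a strong first-season mean shift, the
        # situation per-season centering/scaling is designed to fix
        # structural traits carry little G×E, hence low sensitivity
        "sla": TraitDef(pad([1.2, 0.8, 0.5]), noise_sd=0.5,
                        genotype_dev_sd=0.5, gxe_sensitivity=0.6,
                        season_shift={"S1": 3.0}),
        # nitrogen-like trait restricted to the shortwave-infrared window
        "nitrogen_pct": TraitDef(pad([0.0, 1.0, 0.6, 0.4]), noise_sd=0.5,
                                 genotype_dev_sd=0.5, gxe_sensitivity=0.6,
                                 wavelength_window=(1500.0, 2400.0)),
        # noisier, environmentally sensitive physiological trait
        "photo_rate": TraitDef(pad([0.5, 0.3, 0.2, 0.8, 0.4]), noise_sd=1.0,
                               genotype_dev_sd=0.6, gxe_sensitivity=1.2),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults emulate the target field design."""

    n_genotypes: int = 320
    n_seasons: int = 3
    plots_per_genotype: int = 2
    reps_per_plot: int = 3
    wavelength_start: float = 400.0
    wavelength_stop: float = 2400.0
    wavelength_step: float = 1.0
    n_latent: int = 6
    var_genotype: float = 1.0
    var_season: float = 0.5
    var_gxe: float = 0.4
    var_plot: float = 0.1
    var_resid: float = 0.3
    basis_amplitude: float = 0.02
    smooth_noise_sd: float = 0.003
    #: smooth spectral signature fixed per genotype across seasons
    #: (idiosyncratic but stable, outside the latent basis)
    genotype_signature_sd: float = 0.012
    #: smooth spectral signature shared by all replicates of a genotype
    #: within a season (idiosyncratic, outside the latent basis)
    group_noise_sd: float = 0.004
    #: season label -> amplitude of an extra 750-1500 nm plateau in the baseline
    season_baseline_shift: dict = field(
        default_factory=lambda: {"S2": 0.04}
    )
    traits: dict[str, TraitDef] | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("var_genotype", "var_season", "var_gxe", "var_plot", "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")

    def resolved_traits(self) -> dict[str, TraitDef]:
        traits = self.traits if self.traits is not None else _default_traits(self.n_latent)
        for name, td in traits.items():
            if len(td.loadings) != self.n_latent:
                raise ValueError(
                    f"trait {name!r} has {len(td.loadings)} loadings, "
                    f"expected n_latent={self.n_latent}"
                )
        return traits

    def wavelengths(self) -> np.ndarray:
        return np.arange(
            self.wavelength_start,
            self.wavelength_stop + 0.5 * self.wavelength_step,
            self.wavelength_step,
        )

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """What the generator actually drew, for oracle-style tests."""

    latent_scores: np.ndarray          # n x n_latent
    basis: np.ndarray                  # n_latent x p
    trait_loadings: dict[str, np.ndarray]
    genotype_effects: np.ndarray       # G x F
    season_effects: np.ndarray         # S x F
    gxe_effects: np.ndarray            # G x S x F
    realized_variances: dict[str, float]
    config: SyntheticConfig
    seed: int


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _baseline(wl: np.ndarray) -> np.ndarray:
    """Vegetation-like reflectance curve: dark visible region, NIR plateau
    near 0.45, declining shortwave infrared."""
    return (
        0.05
        + 0.40 * _sigmoid((wl - 710.0) / 25.0)
        - 0.18 * _sigmoid((wl - 1400.0) / 120.0)
        - 0.12 * _sigmoid((wl - 1900.0) / 80.0)
    )


def _plateau_bump(wl: np.ndarray, lo: float = 750.0, hi: float = 1500.0) -> np.ndarray:
    return _sigmoid((wl - lo) / 30.0) * _sigmoid((hi - wl) / 30.0)


def _basis(wl: np.ndarray, n_latent: int) -> np.ndarray:
    """Gaussian bumps with distinct centers and widths, unit peak."""
    lo, hi = wl[0], wl[-1]
    centers = np.linspace(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo), n_latent)
    widths = np.linspace(80.0, 220.0, n_latent)
    return np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / widths[:, None]) ** 2)


def _smooth_noise(rng, n: int, wl: np.ndarray, sd: float) -> np.ndarray:
    """Spectrally smooth noise: white noise on a coarse 50-node grid,
    linearly interpolated to the wavelength grid."""
    if sd == 0:
        return np.zeros((n, wl.size))
    n_nodes = 50
    nodes = np.linspace(wl[0], wl[-1], n_nodes)
    coarse = rng.normal(0.0, sd, size=(n, n_nodes))
    return np.array([np.interp(wl, nodes, row) for row in coarse])


def generate_dataset(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[SpectralDataset, TraitTable, GroundTruth]:
    """Draw one synthetic dataset; bit-reproducible from (config, seed)."""
    if config is None:
        config = SyntheticConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    G, S = config.n_genotypes, config.n_seasons
    P, R = config.plots_per_genotype, config.reps_per_plot
    F = config.n_latent
    wl = config.wavelengths()
    p = wl.size
    if F > p:
        raise ValueError("n_latent exceeds the number of wavelengths")
    traits = config.resolved_traits()

    genotypes = [f"G{i + 1:04d}" for i in range(G)]
    seasons = [f"S{j + 1}" for j in range(S)]

    g_eff = rng.normal(0.0, np.sqrt(config.var_genotype), size=(G, F))
    s_eff = rng.normal(0.0, np.sqrt(config.var_season), size=(S, F))
    gx_eff = rng.normal(0.0, np.sqrt(config.var_gxe), size=(G, S, F))
    p_eff = rng.normal(0.0, np.sqrt(config.var_plot), size=(G, S, P, F))

    rows = []
    for j, season in enumerate(seasons):
        for i, genotype in enumerate(genotypes):
            for q in range(P):
                for r in range(R):
                    rows.append((i, j, q, r, genotype, season, f"P{q + 1}", f"R{r + 1}"))
    n = len(rows)
    gi = np.array([r[0] for r in rows])
    sj = np.array([r[1] for r in rows])
    pq = np.array([r[2] for r in rows])

    e_eff = rng.normal(0.0, np.sqrt(config.var_resid), size=(n, F))
    scores = g_eff[gi] + s_eff[sj] + gx_eff[gi, sj] + p_eff[gi, sj, pq] + e_eff

    basis = _basis(wl, F)
    base = _baseline(wl)
    baselines = np.tile(base, (S, 1))
    bump = _plateau_bump(wl)
    for season, amp in config.season_baseline_shift.items():
        if season in seasons:
            baselines[seasons.index(season)] += amp * bump

    reflectance = baselines[sj] + config.basis_amplitude * (scores @ basis)
    if config.genotype_signature_sd > 0:
        geno_sig = _smooth_noise(rng, G, wl, config.genotype_signature_sd)
        reflectance += geno_sig[gi]
    if config.group_noise_sd > 0:
        group_sig = _smooth_noise(rng, G * S, wl, config.group_noise_sd)
        reflectance += group_sig[gi * S + sj]
    reflectance += _smooth_noise(rng, n, wl, config.smooth_noise_sd)
    n_clipped = int(np.sum((reflectance < 0) | (reflectance > 1)))
    if n_clipped > 0.05 * reflectance.size:
        warnings.warn(
            f"{100 * n_clipped / reflectance.size:.1f}% of reflectance values "
            "clipped to [0, 1]; consider reducing basis_amplitude",
            stacklevel=2,
        )
    reflectance = np.clip(reflectance, 0.0, 1.0)

    samples = pd.DataFrame(
        {
            "sample_id": [
                f"{r[4]}|{r[5]}|{r[6]}|{r[7]}" for r in rows
            ],
            "genotype_id": [r[4] for r in rows],
            "season": [r[5] for r in rows],
            "plot_id": [r[6] for r in rows],
            "replicate_id": [r[7] for r in rows],
        }
    )[METADATA_COLUMNS]

    values: dict[str, np.ndarray] = {}
    registry: dict[str, TraitSpec] = {}
    loadings_out: dict[str, np.ndarray] = {}
    for name, td in traits.items():
        lam = np.asarray(td.loadings, float)
        y = scores @ lam
        for season, shift in td.season_shift.items():
            if season in seasons:
                y = y + shift * (sj == seasons.index(season))
        if td.genotype_dev_sd > 0:
            geno_dev = rng.normal(0.0, td.genotype_dev_sd, size=G)
            y = y + geno_dev[gi]
        gxe_sd = td.gxe_sensitivity * np.sqrt(config.var_gxe)
        if gxe_sd > 0:
            gxe_dev = rng.normal(0.0, gxe_sd, size=G * S)
            y = y + gxe_dev[gi * S + sj]
        y = y + rng.normal(0.0, td.noise_sd, size=n)
        if td.missing_rate > 0:
            miss = rng.random(n) < td.missing_rate
            y = y.astype(float)
            y[miss] = np.nan
        values[name] = y
        loadings_out[name] = lam
        registry[name] = TraitSpec(
            wavelength_window=td.wavelength_window,
            scale_by_season=td.scale_by_season,
        )

    ds = SpectralDataset(wl, reflectance, samples)
    tt = TraitTable(samples.copy(), values, registry)
    truth = GroundTruth(
        latent_scores=scores,
        basis=basis,
        trait_loadings=loadings_out,
        genotype_effects=g_eff,
        season_effects=s_eff,
        gxe_effects=gx_eff,
        realized_variances={
            "genotype": float(g_eff.var()),
            "season": float(s_eff.var()),
            "gxe": float(gx_eff.var()),
            "plot": float(p_eff.var()),
            "resid": float(e_eff.var()),
        },
        config=config,
        seed=seed,
    )
    return ds, tt, truth
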