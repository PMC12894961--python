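"""Shared fixtures: small programmatically generated datasets."""

import numpy as np
import pandas as pd
import pytest

from leafspec import SpectralDataset, SyntheticConfig, TraitDef, TraitTable, generate_dataset


def make_samples(records):
    """records: list of (sample_id, genotype, season, plot, replicate)."""
    return pd.DataFrame(
        records,
        columns=["sample_id", "genotype_id", "season", "plot_id", "replicate_id"],
    )


@pytest.fixture
def tiny_dataset():
    """One genotype, one season, 2 plots x 3 replicates, 3 wavelengths."""
    records = [
        (f"s{i}", "G1", "S1", f"P{p}", f"R{r}")
        for i, (p, r) in enumerate(
            [(1, 1), (1, 2), (1, 3), (2, 1), (2, 2), (2, 3)]
        )
    ]
    samples = make_samples(records)
    wavelengths = np.array([400.0, 401.0, 402.0])
    # one wavelength carries the values 1..6 used in aggregation examples
    reflectance = np.column_stack(
        [np.linspace(0.1, 0.6, 6), np.full(6, 0.5), np.arange(1, 7) / 10.0]
    )
    ds = SpectralDataset(wavelengths, reflectance, samples)
    tt = TraitTable(
        samples.copy(),
        {"trait_a": np.array([1.0, np.nan, 3.0, 4.0, 5.0, 6.0])},
    )
    return ds, tt


def noiseless_config(n_genotypes=20, n_latent=3, **kw):
    """All randomness off except the latent genotype effects; exactly
    low-rank spectra and an exactly linear trait."""
    defaults = dict(
        n_genotypes=n_genotypes,
        n_seasons=1,
        plots_per_genotype=2,
        reps_per_plot=3,
        wavelength_step=5.0,
        n_latent=n_latent,
        var_season=0.0,
        var_gxe=0.0,
        var_plot=0.0,
        var_resid=0.0,
        basis_amplitude=0.008,
        smooth_noise_sd=0.0,
        genotype_signature_sd=0.0,
        group_noise_sd=0.0,
        season_baseline_shift={},
        traits={
            "t": TraitDef(
                tuple([1.0, 0.7, 0.4][:n_latent]),
                noise_sd=0.0,
                genotype_dev_sd=0.0,
                gxe_sensitivity=0.0,
            )
        },
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


@pytest.fixture
def noiseless_3latent():
    """n=120, p=401 exactly rank-3 dataset with a noiseless linear trait."""
    ds, tt, truth = generate_dataset(noiseless_config(), seed=11)
    return ds, tt, truth


def small_noisy_config(**kw):
    """Scaled-down version of the default multi-season design (coarser
    wavelength grid, fewer genotypes) for nested-CV tests."""
    defaults = dict(
        n_genotypes=40,
        n_seasons=3,
        plots_per_genotype=2,
        reps_per_plot=2,
        wavelength_step=10.0,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)
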