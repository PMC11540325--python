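"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def simulate_rcbd(seed, n_genotypes=36, n_replicates=5, sigma2_g=1.0, sigma2_e=1.0,
                  rep_sd=0.3):
    """One balanced RCBD single-trait data set as a tidy frame."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, np.sqrt(sigma2_g), n_genotypes)
    b = rng.normal(0.0, rep_sd, n_replicates)
    e = rng.normal(0.0, np.sqrt(sigma2_e), (n_genotypes, n_replicates))
    y = b[None, :] + g[:, None] + e
    return pd.DataFrame(
        {
            "genotype": np.repeat([f"g{j:02d}" for j in range(n_genotypes)], n_replicates),
            "replicate": np.tile(np.arange(1, n_replicates + 1), n_genotypes),
            "y": y.ravel(),
        }
    ), g


def simulate_paired_traits(seed, n_genotypes=36, n_replicates=5, h2=0.4, r_g=0.8,
                           r_e=0.6):
    """Two traits on the same plots with known genetic/residual correlations."""
    rng = np.random.default_rng(seed)
    sg, se = h2, 1.0 - h2
    Sg = sg * np.array([[1.0, r_g], [r_g, 1.0]])
    Re = se * np.array([[1.0, r_e], [r_e, 1.0]])
    g = rng.multivariate_normal(np.zeros(2), Sg, n_genotypes)
    b = rng.normal(0.0, 0.2, (n_replicates, 2))
    e = rng.multivariate_normal(np.zeros(2), Re, (n_genotypes, n_replicates))
    y = b[None, :, :] + g[:, None, :] + e
    return pd.DataFrame(
        {
            "genotype": np.repeat([f"g{j:02d}" for j in range(n_genotypes)], n_replicates),
            "replicate": np.tile(np.arange(1, n_replicates + 1), n_genotypes),
            "t1": y[:, :, 0].ravel(),
            "t2": y[:, :, 1].ravel(),
        }
    )


@pytest.fixture(scope="session")
def small_trial():
    """A small simulated multi-harvest trial with terminal yield rows."""
    from foragegrowth.synthetic import (
        GroundTruthSpec,
        TrialDesign,
        simulate_trial,
        simulate_yield_from_curve,
    )

    design = TrialDesign(
        n_genotypes=12, n_replicates=3, n_harvests=2, flights_per_harvest=6, seed=424242
    )
    records, truth = simulate_trial(design, GroundTruthSpec())
    records = simulate_yield_from_curve(records, truth)
    return records, truth


@pytest.fixture(scope="session")
def rr_fit_medium():
    """One converged RR fit (with yield) on a mid-size trial, reused across tests."""
    from foragegrowth.random_regression import RRSpec, fit_rr
    from foragegrowth.synthetic import (
        GroundTruthSpec,
        TrialDesign,
        simulate_trial,
        simulate_yield_from_curve,
    )

    design = TrialDesign(
        n_genotypes=24, n_replicates=4, n_harvests=1, flights_per_harvest=8, seed=90210
    )
    records, truth = simulate_trial(design, GroundTruthSpec())
    records = simulate_yield_from_curve(records, truth)
    fit = fit_rr(RRSpec(data=records, trait="ndvi", include_yield=True))
    return fit, truth
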