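"""Selection efficiency and stability: RSE, GGE biplot, growth-curve SDs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from foragegrowth.random_regression import RRSpec, fit_rr
from foragegrowth.stability import (
    GEMatrix,
    gge_biplot,
    growth_stability,
    mean_vs_stability_report,
    rse,
)
from foragegrowth.synthetic import (
    GroundTruthSpec,
    TrialDesign,
    simulate_ge_yield,
    simulate_trial,
)


class TestRSE:
    def test_low_heritability_flight_worked_example(self):
        # h2_vi=0.22, h2_fy=0.32, r_g=0.24 -> sqrt(0.6875)*0.24 = 0.199
        assert rse(0.22, 0.32, 0.24) == pytest.approx(0.199, abs=5e-4)
        assert round(rse(0.22, 0.32, 0.24), 2) == 0.20

    def test_equal_heritabilities_perfect_correlation(self):
        assert rse(0.4, 0.4, 1.0) == pytest.approx(1.0)

    def test_zero_genetic_correlation(self):
        assert rse(0.5, 0.3, 0.0) == 0.0

    def test_zero_yield_heritability_undefined(self):
        assert np.isnan(rse(0.4, 0.0, 0.5))

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            rse(1.4, 0.3, 0.5)
        with pytest.raises(ValueError):
            rse(0.4, 0.3, 1.5)

    @given(
        h2=st.floats(0.05, 1.0),
        scale=st.floats(0.1, 0.9),
        r_g=st.floats(-1.0, 1.0),
    )
    def test_depends_only_on_heritability_ratio(self, h2, scale, r_g):
        assert rse(h2 * scale, h2, r_g) == pytest.approx(
            rse(h2 * scale / 2, h2 / 2, r_g), rel=1e-9
        )


def toy_ge():
    return pd.DataFrame(
        [[2.0, 0.0], [0.0, 2.0], [-2.0, -2.0]],
        index=pd.Index(["g1", "g2", "g3"], name="genotype"),
        columns=["e1", "e2"],
    )


class TestGGEBiplot:
    def test_matches_direct_svd_oracle_on_toy_matrix(self):
        Y = toy_ge().to_numpy()
        centered = Y - Y.mean(axis=0, keepdims=True)
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        bp = gge_biplot(toy_ge())
        assert np.allclose(np.sort(bp.singular_values)[::-1], s[:2], atol=1e-12)
        # scores equal the scaled SVD factors up to the fixed sign convention
        recon = bp.genotype_scores.to_numpy() @ bp.environment_scores.to_numpy().T
        assert np.allclose(recon, centered, atol=1e-12)  # rank-2 exact here

    def test_rank2_reconstruction_error_equals_trailing_singular_values(self):
        ge, _ = simulate_ge_yield(10, 6, stability_profile=0.5, seed=3)
        Y = ge.to_numpy()
        centered = Y - Y.mean(axis=0, keepdims=True)
        s = np.linalg.svd(centered, compute_uv=False)
        bp = gge_biplot(ge)
        err = np.sum((centered - bp.reconstruction_rank2()) ** 2)
        assert err == pytest.approx(np.sum(s[2:] ** 2), rel=1e-10)

    def test_frobenius_identity_and_explained_fraction(self):
        ge, _ = simulate_ge_yield(9, 5, stability_profile=0.4, seed=11)
        Y = ge.to_numpy()
        centered = Y - Y.mean(axis=0, keepdims=True)
        s = np.linalg.svd(centered, compute_uv=False)
        assert np.sum(s**2) == pytest.approx(np.sum(centered**2), rel=1e-12)
        bp = gge_biplot(ge)
        assert 0.0 <= bp.explained_fraction <= 1.0
        assert bp.explained_fraction == pytest.approx(np.sum(s[:2] ** 2) / np.sum(s**2))

    def test_additive_data_have_zero_stability_projection(self):
        ge, _ = simulate_ge_yield(8, 5, stability_profile=0.0, seed=5)
        bp = gge_biplot(ge)
        assert np.abs(bp.aea_stability.to_numpy()).max() < 1e-10

    def test_aea_points_toward_higher_mean_yield(self):
        ge, _ = simulate_ge_yield(12, 6, stability_profile=0.3, seed=9)
        bp = gge_biplot(ge)
        genotype_means = ge.mean(axis=1)
        r = np.corrcoef(bp.aea_mean.to_numpy(), genotype_means.to_numpy())[0, 1]
        assert r > 0.95

    def test_invariant_to_environment_relabeling(self):
        ge, _ = simulate_ge_yield(8, 5, stability_profile=0.5, seed=21)
        bp1 = gge_biplot(ge)
        shuffled = ge[list(np.random.default_rng(0).permutation(ge.columns))]
        bp2 = gge_biplot(shuffled)
        assert np.allclose(
            np.abs(bp1.aea_stability.to_numpy()), np.abs(bp2.aea_stability.to_numpy()),
            atol=1e-9,
        )
        assert np.allclose(bp1.aea_mean.to_numpy(), bp2.aea_mean.to_numpy(), atol=1e-9)

    def test_incomplete_or_tiny_matrices_rejected(self):
        bad = toy_ge().copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing cells"):
            GEMatrix(values=bad)
        with pytest.raises(ValueError, match="3 genotypes"):
            GEMatrix(values=toy_ge().iloc[:2])


def _fit_cuttings(seed, instability, n_genotypes=24, n_replicates=4, n_harvests=5,
                  flights=6):
    from foragegrowth.synthetic import simulate_yield_from_curve
    from foragegrowth.varcomp import fit_st_blup

    design = TrialDesign(
        n_genotypes=n_genotypes, n_replicates=n_replicates, n_harvests=n_harvests,
        flights_per_harvest=flights, seed=seed,
    )
    rec, truth = simulate_trial(design, GroundTruthSpec(instability_sd=instability))
    rec = simulate_yield_from_curve(rec, truth)
    fits, yblups = [], {}
    for h in truth.design.harvests:
        grp = rec[rec["harvest"] == h]
        fits.append(fit_rr(RRSpec(data=grp, trait="ndvi"), tol=1e-7, max_iter=200))
        yblups[h] = fit_st_blup(grp[grp["is_yield"]], "ndvi").blups
    return fits, yblups, truth


class TestGrowthStability:
    def test_identical_effects_across_cuttings_give_zero_sd(self):
        class FakeFit:
            def __init__(self, u, basis):
                self.u_hat = u
                self.basis = basis

            @property
            def genotypes(self):
                return list(self.u_hat.index)

        from foragegrowth.features import legendre_basis

        basis = legendre_basis([0.0, 1.0], order=3)
        rng = np.random.default_rng(0)
        u = pd.DataFrame(rng.standard_normal((6, 4)), index=[f"g{i}" for i in range(6)])
        fits = [FakeFit(u.copy(), basis) for _ in range(4)]
        prof = growth_stability(fits)
        assert np.abs(prof.growth_sd.to_numpy()).max() < 1e-12

    def test_invariant_to_affine_rescaling_of_trait_units(self):
        class FakeFit:
            def __init__(self, u, basis):
                self.u_hat = u
                self.basis = basis

            @property
            def genotypes(self):
                return list(self.u_hat.index)

        from foragegrowth.features import legendre_basis

        basis = legendre_basis([0.0, 1.0], order=3)
        rng = np.random.default_rng(3)
        us = [pd.DataFrame(rng.standard_normal((6, 4)), index=[f"g{i}" for i in range(6)])
              for _ in range(4)]
        prof1 = growth_stability([FakeFit(u, basis) for u in us])
        prof2 = growth_stability([FakeFit(u * 7.3, basis) for u in us])
        assert np.allclose(prof1.growth_sd.to_numpy(), prof2.growth_sd.to_numpy(), atol=1e-10)

    def test_growth_sd_detects_true_instability(self):
        """Stable (SD 0) vs unstable (SD 1) genotype sets: the growth-curve SD
        ranks the truth (rank correlation > 0.7); small-scale version of the
        full Monte-Carlo check."""
        inst = np.array([0.0] * 12 + [1.0] * 12)
        rhos = []
        for seed in range(5):
            fits, yblups, truth = _fit_cuttings(3000 + seed, inst)
            prof = growth_stability(fits, yield_blups=yblups)
            rhos.append(
                spearmanr(prof.growth_sd_mean.to_numpy(), truth.instability_sd).statistic
            )
        assert np.mean(rhos) > 0.7

    def test_growth_and_yield_instability_positively_associated(self):
        inst = np.array([0.0] * 12 + [1.0] * 12)
        fits, yblups, _ = _fit_cuttings(3009, inst)
        prof = growth_stability(fits, yield_blups=yblups)
        rho = spearmanr(prof.growth_sd_mean.to_numpy(), prof.yield_sd.to_numpy()).statistic
        assert rho > 0.0

    def test_genotype_missing_from_a_cutting_excluded(self):
        inst = 0.3
        fits, yblups, _ = _fit_cuttings(3001, inst, n_genotypes=6, n_harvests=2, flights=6)
        fits[0].u_hat = fits[0].u_hat.iloc[1:]
        prof = growth_stability(fits, yield_blups=None)
        assert fits[1].u_hat.index[0] in prof.excluded
        assert len(prof.growth_sd) == 5


class TestMeanVsStabilityReport:
    def test_additive_simulation_all_stable(self):
        ge, _ = simulate_ge_yield(8, 5, stability_profile=0.0, seed=2)
        report = mean_vs_stability_report(gge_biplot(ge))
        assert (report["stability_class"] == "stable").all()

    def test_max_aea_projection_labeled_high_yielding(self):
        ge, _ = simulate_ge_yield(9, 5, stability_profile=0.3, seed=4)
        report = mean_vs_stability_report(gge_biplot(ge))
        top = report["aea_mean"].idxmax()
        assert report.loc[top, "mean_class"] == "high"

    def test_classification_invariant_to_environment_relabeling(self):
        ge, _ = simulate_ge_yield(10, 5, stability_profile=0.5, seed=6)
        r1 = mean_vs_stability_report(gge_biplot(ge))
        shuffled = ge[list(np.random.default_rng(1).permutation(ge.columns))]
        r2 = mean_vs_stability_report(gge_biplot(shuffled))
        assert (r1["mean_class"] == r2["mean_class"]).all()
        assert (r1["stability_class"] == r2["stability_class"]).all()

    def test_profile_columns_joined(self):
        inst = np.array([0.0] * 3 + [1.0] * 3)
        fits, yblups, _ = _fit_cuttings(3002, inst, n_genotypes=6, n_harvests=2, flights=6)
        prof = growth_stability(fits, yield_blups=yblups)
        ge, _ = simulate_ge_yield(6, 4, stability_profile=0.2, seed=8)
        ge.index = prof.growth_sd.index
        report = mean_vs_stability_report(gge_biplot(ge), prof)
        assert {"growth_sd", "yield_sd"} <= set(report.columns)
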