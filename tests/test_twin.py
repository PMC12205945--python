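"""Twin-model engine checks: implied covariance algebra, FIML oracle,
nesting, selection, constraint tests, decomposition, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinlocal.synthetic import (
    SimulationConfig,
    simulate_twin_cohort,
    truth_from_proportions,
)
from twinlocal.twin import (
    CholeskyParams,
    TwinData,
    cross_trait_cholesky,
    decompose_variance,
    fiml_neg2ll,
    fit_cholesky,
    implied_covariance,
    profile_ci,
    quantity_value,
    select_model,
    test_amplification as lrt_amplification,
    test_new_influence as lrt_new_influence,
)
from twinlocal.saturated import (
    fit_saturated,
    test_assumptions as lrt_assumptions,
    test_covariate as lrt_covariate,
    twin_correlations,
)


def _simulate(truth, n=1000, seed=0, **kw):
    cfg = SimulationConfig(
        n_mz_pairs=n, n_dz_pairs=n, cholesky_truth=truth,
        beta_age=0.0, beta_sex=0.0, beta_fd=0.0,
        p_missing_wave2=0.0, p_unpaired=0.0, seed=seed, **kw,
    )
    df, _ = simulate_twin_cohort(cfg)
    return TwinData.from_long(df)


class TestImpliedCovariance:
    def test_pure_e_gives_identity_within_and_zero_cross(self):
        p = CholeskyParams(e11=1.0, e22=1.0)
        sig = implied_covariance(p, "MZ")
        assert np.allclose(sig, np.eye(4))

    def test_pure_a_mz_cross_twin_unity(self):
        p = CholeskyParams(a11=1.0, e11=1e-6, e22=1.0)
        sig = implied_covariance(p, "MZ")
        assert sig[0, 2] == pytest.approx(1.0)
        sig_dz = implied_covariance(p, "DZ")
        assert sig_dz[0, 2] == pytest.approx(0.5)

    def test_dz_cells_match_hand_expanded_path_algebra(self):
        a11, a21, c11, e11 = 0.5, 0.3, 0.4, 0.7
        p = CholeskyParams(a11=a11, a21=a21, c11=c11, e11=e11, e22=0.9)
        sig = implied_covariance(p, "DZ")
        # independent expansion of the path-model covariance algebra
        assert sig[0, 0] == pytest.approx(a11**2 + c11**2 + e11**2)
        assert sig[0, 1] == pytest.approx(a11 * a21 + 0.0 + 0.0)
        assert sig[0, 2] == pytest.approx(0.5 * a11**2 + c11**2)
        assert sig[0, 3] == pytest.approx(0.5 * a11 * a21 + 0.0)
        assert sig[1, 1] == pytest.approx(a21**2 + 0.9**2)
        assert sig[1, 3] == pytest.approx(0.5 * a21**2)
        # symmetry and PSD
        assert np.allclose(sig, sig.T)
        assert np.linalg.eigvalsh(sig).min() >= -1e-12


class TestFimlLikelihood:
    def test_complete_data_matches_direct_density_oracle(self, rng):
        p = truth_from_proportions(0.4, 0.2, mu1=1.0, mu2=2.0)
        zyg = np.array(["MZ"] * 5 + ["DZ"] * 5)
        y = rng.normal(size=(10, 4))
        data = TwinData.from_arrays(zyg, y)
        got = fiml_neg2ll(p, data)
        expect = 0.0
        for i, z in enumerate(zyg):
            d = stats.multivariate_normal(p.mu(), implied_covariance(p, z))
            expect += -2.0 * d.logpdf(y[i])
        assert got == pytest.approx(expect, abs=1e-8)

    def test_missing_twin_contributes_marginal_density(self, rng):
        p = truth_from_proportions(0.4, 0.2)
        y = rng.normal(size=(1, 4))
        y[0, 2:] = np.nan  # twin 2 fully missing
        data = TwinData.from_arrays(np.array(["MZ"]), y)
        got = fiml_neg2ll(p, data)
        sig = implied_covariance(p, "MZ")[:2, :2]
        d = stats.multivariate_normal(p.mu()[:2], sig)
        assert got == pytest.approx(-2.0 * d.logpdf(y[0, :2]), abs=1e-8)

    def test_duplicating_data_doubles_neg2ll(self, rng):
        p = truth_from_proportions(0.4, 0.2)
        zyg = np.array(["MZ"] * 4 + ["DZ"] * 4)
        y = rng.normal(size=(8, 4))
        single = fiml_neg2ll(p, TwinData.from_arrays(zyg, y))
        doubled = fiml_neg2ll(
            p, TwinData.from_arrays(np.r_[zyg, zyg], np.vstack([y, y]))
        )
        assert doubled == pytest.approx(2 * single, rel=1e-12)


class TestSaturated:
    def test_mle_covariance_matches_divide_by_n_moments(self, rng):
        zyg = np.array(["MZ"] * 400 + ["DZ"] * 400)
        rs = np.random.default_rng(3)
        y = rs.multivariate_normal(
            [0, 0, 0, 0],
            implied_covariance(truth_from_proportions(0.5, 0.1), "MZ"),
            size=800,
        )
        data = TwinData.from_arrays(zyg, y)
        fit = fit_saturated(data)
        for z, sel in (("MZ", slice(0, 400)), ("DZ", slice(400, 800))):
            sub = y[sel]
            mean_ml = sub.mean(axis=0)
            cov_ml = (sub - mean_ml).T @ (sub - mean_ml) / sub.shape[0]
            assert np.allclose(fit.means[z], mean_ml, atol=1e-4)
            assert np.max(np.abs(fit.sigmas[z] - cov_ml)) < 1e-4 * np.abs(cov_ml).max() + 1e-6

    def test_saturated_never_fits_worse_than_constrained(self, medium_data):
        sat = fit_saturated(medium_data)
        ace = fit_cholesky(medium_data, "ACE", n_starts=2)
        ae = fit_cholesky(medium_data, "AE", n_starts=2)
        e = fit_cholesky(medium_data, "E", n_starts=2)
        assert sat.minus2ll <= ace.minus2ll + 1e-6
        assert ace.minus2ll <= ae.minus2ll + 1e-6
        assert ae.minus2ll <= e.minus2ll + 1e-6

    def test_assumption_tests_have_power_against_mean_shift(self):
        data = _simulate(truth_from_proportions(0.4, 0.2), n=500, seed=9)
        # shift twin 2's values by +1 SD
        for g in data.groups:
            for j, e in enumerate(g.idx):
                if e >= 2:
                    g.Y[:, j] += 1.0
            g.__post_init__()
        res = lrt_assumptions(data)
        row = res[res.test == "means_birth_order"].iloc[0]
        assert row["p"] < 1e-6
        assert row["df"] == 4

    def test_assumption_tests_null_calibrated(self):
        rejections = []
        for rep in range(40):
            data = _simulate(truth_from_proportions(0.4, 0.2), n=150, seed=500 + rep)
            res = lrt_assumptions(data)
            rejections.append(
                (res[res.test == "means_birth_order"]["p"].iloc[0] < 0.05)
            )
        assert np.mean(rejections) <= 0.15

    def test_covariate_effect_recovered_and_constant_rejected(self):
        cfg = SimulationConfig(
            n_mz_pairs=500, n_dz_pairs=500,
            cholesky_truth=truth_from_proportions(0.4, 0.2),
            beta_age=0.0, beta_sex=0.5, beta_fd=0.0,
            p_missing_wave2=0.0, p_unpaired=0.0, seed=21,
        )
        df, _ = simulate_twin_cohort(cfg)
        data = TwinData.from_long(df)
        row = lrt_covariate(data, "sex")
        assert row["p"] < 1e-4
        assert row["beta_w1"] == pytest.approx(0.5, abs=0.15)
        df0 = df.copy()
        df0["age_years"] = 11.0
        with pytest.raises(ValueError, match="constant"):
            lrt_covariate(TwinData.from_long(df0), "age")

    def test_twin_correlations_match_direct_pearson(self, medium_cohort):
        df, _ = medium_cohort
        data = TwinData.from_long(df)
        tc = twin_correlations(data).set_index("correlation")
        wide = df[(df.zygosity == "MZ") & (df.wave == 1)].pivot(
            index="family_id", columns="birth_order", values="value"
        )
        direct = np.corrcoef(wide[1], wide[2])[0, 1]
        assert tc.loc["rMZ_w1", "r"] == pytest.approx(direct, abs=0.01)
        # AE-style algebra: rMZ ~ h2 + c2 = 0.7, rDZ ~ 0.5 h2 + c2 = 0.45
        assert tc.loc["rMZ_w1", "r"] == pytest.approx(0.7, abs=0.05)
        assert tc.loc["rDZ_w1", "r"] == pytest.approx(0.45, abs=0.05)


class TestCholeskyFits:
    def test_ae_truth_recovered_by_ace_fit(self):
        truth = truth_from_proportions(0.6, 1e-9)
        data = _simulate(truth, n=2500, seed=31)
        fit = fit_cholesky(data, "ACE", n_starts=2)
        dec = decompose_variance(fit)
        assert dec["std"]["A"]["w1"] == pytest.approx(0.6, abs=0.05)
        assert dec["std"]["C"]["w1"] < 0.05

    def test_twin_order_permutation_leaves_optimum_unchanged(self, medium_data):
        fit = fit_cholesky(medium_data, "ACE", n_starts=2)
        swapped_groups = []
        for g in medium_data.groups:
            perm = [{0: 2, 1: 3, 2: 0, 3: 1}[e] for e in g.idx]
            order = np.argsort(perm)
            from twinlocal.twin import _Group

            swapped_groups.append(
                _Group(g.zygosity, np.array(sorted(perm)),
                       g.Y[:, order], g.X[:, order])
            )
        swapped = TwinData(swapped_groups)
        assert fiml_neg2ll(fit.params, swapped) == pytest.approx(
            fit.minus2ll, rel=1e-10
        )

    def test_scale_equivariance(self, medium_cohort):
        """Multiplying phenotypes by s scales raw components by s^2 exactly
        (likelihood identity) and leaves re-optimized proportions unchanged
        up to optimizer tolerance."""
        import dataclasses

        df, _ = medium_cohort
        data = TwinData.from_long(df)
        fit1 = fit_cholesky(data, "ACE", n_starts=1)
        s = 3.0
        df2 = df.copy()
        df2["value"] = df2["value"] * s
        data2 = TwinData.from_long(df2)
        # exact identity: scaling every path and mean by s shifts -2lnL by
        # 2 N log s, so the scaled optimum is the optimum of the scaled data
        p1 = fit1.params
        scaled = dataclasses.replace(
            p1, **{k: getattr(p1, k) * s
                   for k in ("a11", "a21", "a22", "c11", "c21", "c22",
                             "e11", "e21", "e22", "mu1", "mu2")}
        )
        expect = fit1.minus2ll + 2.0 * data.n_obs * np.log(s)
        assert fiml_neg2ll(scaled, data2) == pytest.approx(expect, rel=1e-12)
        # re-optimized standardized proportions agree to optimizer tolerance
        fit2 = fit_cholesky(data2, "ACE", n_starts=1)
        d1, d2 = decompose_variance(fit1), decompose_variance(fit2)
        for comp in "ACE":
            assert d2["raw"][comp]["w1"] == pytest.approx(
                s**2 * d1["raw"][comp]["w1"], rel=1e-3, abs=1e-8
            )
            assert d2["std"][comp]["w1"] == pytest.approx(
                d1["std"][comp]["w1"], abs=1e-4
            )

    def test_mz_dz_swap_invariance_under_ce_truth(self):
        truth = truth_from_proportions(h2=1e-9, c2=0.5)
        data = _simulate(truth, n=1500, seed=77)
        fit = fit_cholesky(data, "CE", n_starts=2)
        for g in data.groups:
            g.zygosity = {"MZ": "DZ", "DZ": "MZ"}[g.zygosity]
        swapped_fit = fit_cholesky(data, "CE", n_starts=2)
        d1 = decompose_variance(fit)["std"]["C"]["w1"]
        d2 = decompose_variance(swapped_fit)["std"]["C"]["w1"]
        assert d1 == pytest.approx(d2, abs=0.05)
        assert d1 == pytest.approx(0.5, abs=0.05)


class TestConstraintTests:
    def test_chi2_nonnegative_and_df_one(self, medium_data):
        fit = fit_cholesky(medium_data, "ACE", n_starts=2)
        for comp in ("A", "C"):
            row = lrt_new_influence(fit, comp)
            assert row["chi2"] >= 0.0
            assert row["df"] == 1
        amp = lrt_amplification(fit, "A")
        assert amp["chi2"] >= 0.0
        # generator truth has a21 = 0.6 a11 -> weakening continuing influence
        assert amp["direction"] == "deamplification"

    def test_equal_paths_truth_keeps_amplification_chi2_small(self):
        # a21 = a11 truth with genuine wave-2-specific variance in every source
        truth = CholeskyParams(
            a11=0.6, a21=0.6, a22=0.3, c11=0.4, c21=0.4, c22=0.2,
            e11=0.69, e21=0.3, e22=0.62,
        )
        chis = []
        for rep in range(10):
            data = _simulate(truth, n=800, seed=900 + rep)
            fit = fit_cholesky(data, "ACE", n_starts=2)
            chis.append(lrt_amplification(fit, "A")["chi2"])
        # chi2(1) median is 0.455; well below that threshold on average
        assert np.median(chis) < 4.0

    def test_requesting_absent_component_rejected(self, medium_data):
        fit = fit_cholesky(medium_data, "AE", n_starts=1)
        with pytest.raises(ValueError, match="not in fitted model"):
            lrt_new_influence(fit, "C")


class TestSelection:
    def _fake(self, aic, n_free, label):
        return type(
            "F", (), {"aic": aic, "n_free": n_free, "convergence": True,
                      "label": label},
        )()

    def test_min_aic_with_ambiguity_flag(self):
        fits = [self._fake(100.0, 8, "AE"), self._fake(101.5, 8, "CE"),
                self._fake(110.0, 11, "ACE")]
        best, amb = select_model(fits)
        assert best.label == "AE" and amb

    def test_clear_winner_no_flag(self):
        fits = [self._fake(100.0, 8, "AE"), self._fake(104.0, 8, "CE")]
        best, amb = select_model(fits)
        assert best.label == "AE" and not amb

    def test_tie_broken_toward_fewer_parameters(self):
        fits = [self._fake(100.0, 11, "ACE"), self._fake(100.0, 5, "E")]
        best, _ = select_model(fits)
        assert best.label == "E"


class TestDecomposition:
    def test_hand_arithmetic(self):
        p = CholeskyParams(a11=0.6, c11=0.0, e11=0.8, e22=1.0)
        fit = type("F", (), {"params": p})()
        dec = decompose_variance(fit)
        assert dec["total"]["w1"] == pytest.approx(1.0)
        assert dec["std"]["A"]["w1"] == pytest.approx(0.36)

    def test_proportions_sum_to_one(self, medium_data):
        fit = fit_cholesky(medium_data, "ACE", n_starts=1)
        dec = decompose_variance(fit)
        for w in ("w1", "w2"):
            total = sum(dec["std"][c][w] for c in "ACE")
            assert total == pytest.approx(1.0, abs=1e-8)
        w2split = sum(
            dec["w2_split"][c][k] for c in "ACE" for k in ("continuing", "new")
        )
        assert w2split == pytest.approx(1.0, abs=1e-8)

    def test_matches_monte_carlo_latent_variance(self):
        truth = truth_from_proportions(0.5, 0.2, overlap=0.6)
        cfg = SimulationConfig(
            n_mz_pairs=50_000, n_dz_pairs=0, cholesky_truth=truth,
            beta_age=0.0, beta_sex=0.0, beta_fd=0.0,
            p_missing_wave2=0.0, p_unpaired=0.0, seed=5,
        )
        _, rec = simulate_twin_cohort(cfg)
        mc_a1 = np.var(rec["contrib"]["A"][:, :, 0])
        assert mc_a1 == pytest.approx(0.5, abs=0.02)


class TestProfileCI:
    def test_brackets_estimate_and_floors_at_zero(self, medium_data):
        fit = fit_cholesky(medium_data, "ACE", n_starts=2)
        lo, hi = profile_ci(fit, "std_a1")
        qhat = quantity_value(fit.params, "std_a1")
        assert lo <= qhat <= hi
        assert lo >= 0.0 and hi <= 1.0

    def test_large_n_matches_wald_half_width(self, medium_data):
        from twinlocal.twin import _wald_ci

        fit = fit_cholesky(medium_data, "ACE", n_starts=2)
        lo, hi = profile_ci(fit, "std_e1")
        wlo, whi = _wald_ci(fit, "std_e1", 0.95)
        half, whalf = (hi - lo) / 2, (whi - wlo) / 2
        assert half == pytest.approx(whalf, rel=0.10)


class TestCrossTrait:
    def test_single_shared_factor_gives_unit_genetic_correlation(self):
        p = CholeskyParams(a11=0.7, a21=0.5, a22=0.0, e11=0.5, e22=0.5)
        assert quantity_value(p, "r_a") == pytest.approx(1.0)

    def test_independent_genetics_gives_zero(self):
        p = CholeskyParams(a11=0.7, a21=0.0, a22=0.5, e11=0.5, e22=0.5)
        assert quantity_value(p, "r_a") == pytest.approx(0.0)

    def test_simulated_genetic_correlation_recovered(self):
        truth = truth_from_proportions(h2=0.5, c2=0.2, overlap=0.6)
        data = _simulate(truth, n=2500, seed=101)
        corr, fit = cross_trait_cholesky(data, n_starts=2)
        assert corr.r_a == pytest.approx(0.6, abs=0.07)
        assert fit.convergence
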