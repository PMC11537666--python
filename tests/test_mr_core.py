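"""MR estimators against independent oracles and generative models."""
import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate.errors import InsufficientInstrumentsError
from mrmediate.gwas_io import HarmonizedPair
from mrmediate.mr_core import (egger, ivw, mode_estimators, run_methods,
                               wald_ratio, weighted_median,
                               weighted_percentile)

from conftest import simulate_pairs


def pairs_from_arrays(bx, by, sx, sy):
    return [
        HarmonizedPair(variant_id=f"snp_{i}", effect_allele="A",
                       beta_exp=bx[i], se_exp=sx[i], eaf_exp=0.3,
                       beta_out=by[i], se_out=sy[i], eaf_out=0.3, action="kept")
        for i in range(len(bx))
    ]


class TestIVW:
    def test_exact_proportionality_recovers_slope_with_zero_q(self):
        bx = np.array([0.1, 0.2, -0.15])
        by = 0.7 * bx
        res = ivw((bx, by, np.full(3, 0.01), np.full(3, 0.02)))
        assert res.beta == pytest.approx(0.7, abs=1e-12)
        assert res.info["Q"] == pytest.approx(0.0, abs=1e-12)

    def test_printed_three_pair_instance_matches_wls_oracle(self):
        bx = np.array([0.1, 0.2, 0.15])
        by = np.array([0.05, 0.09, 0.08])
        sy = np.array([0.02, 0.03, 0.025])
        oracle = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        res = ivw((bx, by, np.full(3, 0.01), sy))
        assert res.beta == pytest.approx(oracle.params[0], abs=1e-12)

    def test_scaling_outcome_se_leaves_beta_doubles_se(self):
        bx, by, sx, sy = simulate_pairs(0)
        a = ivw((bx, by, sx, sy))
        b = ivw((bx, by, sx, 2 * sy))
        assert b.beta == pytest.approx(a.beta, rel=1e-12)
        assert b.se == pytest.approx(2 * a.se, rel=1e-12)

    def test_random_effects_inflates_only_under_heterogeneity(self):
        bx, by, sx, sy = simulate_pairs(1, theta=0.3)
        fixed = ivw((bx, by, sx, sy), "fixed")
        random = ivw((bx, by, sx, sy), "random")
        assert random.beta == fixed.beta
        assert random.se >= fixed.se

    def test_single_snp_raises_and_routes_to_wald(self):
        bx, by, sx, sy = (np.array([0.1]), np.array([0.05]),
                          np.array([0.01]), np.array([0.02]))
        with pytest.raises(InsufficientInstrumentsError):
            ivw((bx, by, sx, sy))
        res = wald_ratio((bx, by, sx, sy))
        assert res.method == "Wald_ratio"
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.2)

    def test_or_ci_consistent_with_beta_ci(self):
        bx, by, sx, sy = simulate_pairs(2)
        res = ivw((bx, by, sx, sy))
        assert res.odds_ratio == pytest.approx(np.exp(res.beta))
        assert res.or_ci_low == pytest.approx(np.exp(res.ci_low))
        assert res.or_ci_high == pytest.approx(np.exp(res.ci_high))
        assert res.ci_low < res.ci_high


class TestEgger:
    def test_generative_identity(self):
        rng = np.random.default_rng(5)
        J = 200
        b = rng.uniform(0.05, 0.3, J)
        sy = np.full(J, 0.01)
        by = 0.4 * b + rng.normal(0, sy)
        res, intercept, ise = egger((b, by, np.full(J, 1e-4), sy))
        assert res.beta == pytest.approx(0.4, abs=0.02)
        assert abs(intercept) < 3 * ise

    def test_constant_offset_moves_intercept_not_slope(self):
        bx, by, sx, sy = simulate_pairs(3, theta=0.3)
        bx = np.abs(bx)  # single orientation so the offset is truly constant
        r0, i0, _ = egger((bx, by, sx, sy))
        r1, i1, _ = egger((bx, by + 0.05, sx, sy))
        assert i1 - i0 == pytest.approx(0.05, abs=1e-10)
        assert r1.beta == pytest.approx(r0.beta, abs=1e-10)

    def test_matches_statsmodels_wls_oracle(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.05, 0.3, 5)
        by = rng.normal(0, 0.1, 5)
        sy = rng.uniform(0.01, 0.05, 5)
        res, intercept, ise = egger((bx, by, np.full(5, 0.01), sy))
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
        assert intercept == pytest.approx(fit.params[0], abs=1e-12)
        assert res.beta == pytest.approx(fit.params[1], abs=1e-12)
        # statsmodels scales by Q/(J-2) without flooring at 1
        q = res.info["Q"]
        floor = max(1.0, q / 3)
        assert res.se == pytest.approx(fit.bse[1] * np.sqrt(floor / (q / 3)), rel=1e-9)

    def test_orientation_invariance(self):
        bx, by, sx, sy = simulate_pairs(11, theta=0.25)
        flip = np.sign(np.random.default_rng(0).standard_normal(bx.size))
        r1, i1, _ = egger((bx, by, sx, sy))
        r2, i2, _ = egger((bx * flip, by * flip, sx, sy))
        assert r2.beta == pytest.approx(r1.beta, rel=1e-12)
        assert i2 == pytest.approx(i1, rel=1e-10)

    def test_needs_three(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger((np.array([0.1, 0.2]), np.array([0.0, 0.1]),
                   np.array([0.01, 0.01]), np.array([0.02, 0.02])))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        bx = np.ones(3)
        by = np.array([1.0, 2.0, 3.0])
        sy = np.ones(3)
        res = weighted_median((bx, by, np.full(3, 1e-6), sy), n_boot=50, seed=0)
        assert res.beta == pytest.approx(2.0)

    def test_dominant_weight_pulls_to_its_ratio(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([1.0, 2.0, 3.0])
        sy = np.array([10.0, 0.001, 10.0])  # middle ratio has ~all the weight
        res = weighted_median((bx, by, np.full(3, 1e-6), sy), n_boot=50, seed=0)
        assert res.beta == pytest.approx(2.0, abs=1e-6)

    def test_matches_percentile_oracle(self):
        rng = np.random.default_rng(13)
        bx = rng.uniform(0.05, 0.3, 7)
        by = rng.normal(0.2 * bx, 0.02)
        sy = rng.uniform(0.01, 0.05, 7)
        ratios = by / bx
        w = bx**2 / sy**2
        # oracle: explicit cumulative-weight interpolation
        order = np.argsort(ratios)
        rr, ww = ratios[order], w[order] / w.sum()
        cum = np.cumsum(ww) - 0.5 * ww
        below = np.searchsorted(cum, 0.5) - 1
        frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
        expected = rr[below] + frac * (rr[below + 1] - rr[below])
        res = weighted_median((bx, by, np.full(7, 0.01), sy), n_boot=50, seed=0)
        assert res.beta == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_se_deterministic_under_seed(self):
        bx, by, sx, sy = simulate_pairs(17)
        a = weighted_median((bx, by, sx, sy), n_boot=100, seed=42)
        b = weighted_median((bx, by, sx, sy), n_boot=100, seed=42)
        assert a.se == b.se

    def test_zero_exposure_beta_excluded_with_warning(self):
        bx = np.array([0.0, 0.1, 0.2, 0.15])
        by = np.array([0.5, 0.02, 0.04, 0.03])
        with pytest.warns(UserWarning, match="beta_exp = 0"):
            res = weighted_median((bx, by, np.full(4, 0.01), np.full(4, 0.02)),
                                  n_boot=20, seed=0)
        assert res.n_snp == 3


class TestModeEstimators:
    def test_identical_ratios_return_point_mass(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 1.3 * bx
        for kind in ("simple", "weighted"):
            res = mode_estimators((bx, by, np.full(3, 0.01), np.full(3, 0.02)),
                                  kind, n_boot=10, seed=0)
            assert res.beta == pytest.approx(1.3)

    def test_bimodal_mass_wins_over_mean(self):
        # 7 ratios at ~1.0, 3 at ~3.0: mode must sit near 1, far from mean 1.6
        bx = np.ones(10)
        by = np.array([1.0, 0.99, 1.01, 1.0, 0.98, 1.02, 1.0, 3.0, 2.99, 3.01])
        res = mode_estimators((bx, by, np.full(10, 1e-4), np.full(10, 0.02)),
                              "simple", n_boot=10, seed=0)
        assert abs(res.beta - 1.0) < 0.2
        # grid-density oracle agrees on the argmax neighbourhood
        from mrmediate.mr_core import _density_mode, _silverman_bandwidth
        h = _silverman_bandwidth(by, 1.0)
        grid = np.linspace(by.min() - 3 * h, by.max() + 3 * h, 4001)
        dens = np.exp(-0.5 * ((grid[:, None] - by[None, :]) / h) ** 2).sum(axis=1)
        assert abs(res.beta - grid[np.argmax(dens)]) < 0.05

    def test_equal_weights_match_simple(self):
        bx = np.array([0.1, 0.12, 0.11, 0.13])
        by = np.array([0.05, 0.055, 0.06, 0.05])
        sy = np.full(4, 0.02)
        bx_eq = np.full(4, 0.1)  # equal bx and sy -> equal weights
        ratios_kwargs = dict(n_boot=10, seed=0)
        simple = mode_estimators((bx_eq, by, np.full(4, 0.01), sy), "simple", **ratios_kwargs)
        weighted = mode_estimators((bx_eq, by, np.full(4, 0.01), sy), "weighted", **ratios_kwargs)
        assert simple.beta == pytest.approx(weighted.beta, abs=1e-12)


class TestEnsembleProperties:
    def test_order_invariance_of_all_estimators(self):
        bx, by, sx, sy = simulate_pairs(23)
        perm = np.random.default_rng(1).permutation(bx.size)
        for fn in (lambda p: ivw(p).beta,
                   lambda p: egger(p)[0].beta,
                   lambda p: weighted_median(p, n_boot=10, seed=0).beta):
            assert fn((bx[perm], by[perm], sx[perm], sy[perm])) == \
                pytest.approx(fn((bx, by, sx, sy)), rel=1e-9)

    def test_unbiased_under_valid_instruments(self):
        # 50 instruments, true effect 0.3, no pleiotropy: every estimator's
        # mean over 200 draws within 3 MC SEs of truth
        estimates = {"ivw": [], "egger": [], "wmedian": [], "smode": [], "wmode": []}
        for s in range(200):
            pairs = simulate_pairs(1000 + s, J=50, theta=0.3)
            estimates["ivw"].append(ivw(pairs).beta)
            estimates["egger"].append(egger(pairs)[0].beta)
            estimates["wmedian"].append(weighted_median(pairs, n_boot=8, seed=s).beta)
            estimates["smode"].append(mode_estimators(pairs, "simple", n_boot=8, seed=s).beta)
            estimates["wmode"].append(mode_estimators(pairs, "weighted", n_boot=8, seed=s).beta)
        for name, est in estimates.items():
            mean = np.mean(est)
            mcse = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(mean - 0.3) < 3 * mcse + 0.01, f"{name}: {mean:.4f} +- {mcse:.4f}"

    def test_weighted_median_robust_where_ivw_is_not(self):
        # 40% of instruments share directional pleiotropy: IVW drifts, the
        # weighted median stays near truth
        ivw_est, wm_est = [], []
        for s in range(60):
            rng = np.random.default_rng(3000 + s)
            J = 30
            b = rng.uniform(0.2, 0.5, J)  # positively oriented instruments
            sx, sy = np.full(J, 0.002), np.full(J, 0.005)
            pleio = np.zeros(J)
            pleio[: int(0.4 * J)] = 0.1
            bx = b + rng.normal(0, sx)
            by = 0.3 * b + pleio + rng.normal(0, sy)
            ivw_est.append(ivw((bx, by, sx, sy)).beta)
            wm_est.append(weighted_median((bx, by, sx, sy), n_boot=8, seed=s).beta)
        wm_bias = abs(np.mean(wm_est) - 0.3)
        ivw_bias = abs(np.mean(ivw_est) - 0.3)
        # IVW is materially biased; the weighted median stays within 5% of truth
        assert ivw_bias > 3 * np.std(ivw_est, ddof=1) / np.sqrt(60)
        assert ivw_bias > 0.05
        assert wm_bias < ivw_bias / 5
        assert wm_bias < 0.015


def test_run_methods_battery_and_single_snp_fallback():
    pairs = simulate_pairs(29, J=10)
    results = run_methods(pairs, n_boot=10, seed=0)
    names = {r.method for r in results}
    assert {"IVW_fixed", "IVW_random", "Egger", "weighted_median",
            "simple_mode", "weighted_mode"} <= names
    bx, by, sx, sy = simulate_pairs(29, J=1)
    single = run_methods((bx, by, sx, sy))
    assert [r.method for r in single] == ["Wald_ratio"]
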