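"""Causal estimators against independent brute-force oracles."""

import numpy as np
import pytest

from conftest import make_instruments, random_instruments
from mrpipe.estimators import (
    DegenerateInstrumentError,
    EstimatorConfig,
    InsufficientInstrumentsError,
    METHOD_ORDER,
    _weighted_median,
    egger,
    ivw,
    maximum_likelihood,
    median_estimator,
    mode_estimator,
    run_all_methods,
    wald_ratio,
)
from mrpipe.harmonization import HarmonizedInstrument


def _inst(bx, sx, by, sy, rsid="rs000001"):
    return HarmonizedInstrument(rsid, bx, sx, by, sy)


class TestWaldRatio:
    def test_direct_formula(self):
        res = wald_ratio(_inst(0.1, 0.01, 0.05, 0.02))
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.2)
        assert res.n_snp == 1

    def test_sign_follows_exposure_effect(self):
        assert wald_ratio(_inst(-0.1, 0.01, 0.05, 0.02)).beta == \
            pytest.approx(-0.5)

    def test_matches_scalar_division_oracle(self, rng):
        for _ in range(20):
            bx, by = rng.normal(0.1, 0.05), rng.normal(0.03, 0.02)
            sy = rng.uniform(0.005, 0.05)
            if bx == 0:
                continue
            res = wald_ratio(_inst(bx, 0.01, by, sy))
            assert res.beta == pytest.approx(by / bx, rel=1e-12)
            assert res.se == pytest.approx(sy / abs(bx), rel=1e-12)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(_inst(0.0, 0.01, 0.05, 0.02))


def _wls_through_origin(bx, by, sy):
    """Brute-force WLS fit of outcome on exposure effects, weights 1/sy²."""
    w = 1.0 / np.asarray(sy) ** 2
    x, y = np.asarray(bx), np.asarray(by)
    beta = np.sum(w * x * y) / np.sum(w * x * x)
    se = np.sqrt(1.0 / np.sum(w * x * x))
    return beta, se


class TestIvw:
    def test_single_instrument_equals_wald(self):
        inst = _inst(0.1, 0.01, 0.05, 0.02)
        for model in ("fixed", "random"):
            res = ivw([inst], model)
            wald = wald_ratio(inst)
            assert res.beta == pytest.approx(wald.beta)
            assert res.se == pytest.approx(wald.se)

    def test_homogeneous_ratios(self):
        insts = make_instruments([0.1, 0.2, 0.05], [0.01] * 3,
                                 [0.03, 0.06, 0.015], [0.02] * 3)
        fixed, random = ivw(insts, "fixed"), ivw(insts, "random")
        assert fixed.beta == pytest.approx(0.3)
        assert random.extra["q"] == pytest.approx(0.0, abs=1e-20)
        assert random.se == pytest.approx(fixed.se)

    def test_matches_wls_oracle(self, rng):
        for _ in range(100):
            insts = random_instruments(rng, j=10)
            bx = [i.beta_exp for i in insts]
            by = [i.beta_out for i in insts]
            sy = [i.se_out for i in insts]
            beta, se = _wls_through_origin(bx, by, sy)
            res = ivw(insts, "fixed")
            assert res.beta == pytest.approx(beta, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)

    def test_point_estimate_identical_across_models(self, rng):
        insts = random_instruments(rng)
        assert ivw(insts, "fixed").beta == ivw(insts, "random").beta

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(50):
            insts = random_instruments(rng, j=rng.integers(2, 15))
            assert ivw(insts, "random").se >= ivw(insts, "fixed").se

    def test_untruncated_dispersion_can_shrink_se(self):
        insts = make_instruments([0.1, 0.2, 0.05], [0.01] * 3,
                                 [0.03, 0.06, 0.015], [0.02] * 3)
        res = ivw(insts, "random", truncate_underdispersion=False)
        assert res.se < ivw(insts, "fixed").se  # Q = 0 here

    def test_order_and_sign_flip_invariance(self, rng):
        insts = random_instruments(rng)
        shuffled = list(insts)
        rng.shuffle(shuffled)
        flipped = [
            HarmonizedInstrument(i.rsid, -i.beta_exp, i.se_exp,
                                 -i.beta_out, i.se_out)
            for i in insts
        ]
        base = ivw(insts).beta
        assert ivw(shuffled).beta == pytest.approx(base, rel=1e-12)
        assert ivw(flipped).beta == pytest.approx(base, rel=1e-12)

    def test_empty_input(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw([])


class TestMaximumLikelihood:
    def test_no_exposure_error_reduces_to_fixed_ivw(self, rng):
        insts = random_instruments(rng, j=8)
        tiny = [
            HarmonizedInstrument(i.rsid, i.beta_exp, 1e-10, i.beta_out,
                                 i.se_out)
            for i in insts
        ]
        assert maximum_likelihood(tiny).beta == pytest.approx(
            ivw(tiny, "fixed").beta, abs=1e-6)

    def test_homogeneous_ratios_recovered(self):
        insts = make_instruments([0.1, 0.2, 0.15], [1e-4] * 3,
                                 [0.03, 0.06, 0.045], [1e-4] * 3)
        assert maximum_likelihood(insts).beta == pytest.approx(0.3, abs=1e-6)

    def test_two_instrument_grid_oracle(self):
        """Dense grid over (gamma_1, gamma_2, beta) brackets the optimum."""
        insts = make_instruments([0.10, 0.16], [0.02, 0.03],
                                 [0.04, 0.03], [0.015, 0.02])
        res = maximum_likelihood(insts)

        bx = np.array([0.10, 0.16]); sx = np.array([0.02, 0.03])
        by = np.array([0.04, 0.03]); sy = np.array([0.015, 0.02])
        betas = np.linspace(res.beta - 0.5, res.beta + 0.5, 801)
        g1 = np.linspace(bx[0] - 4 * sx[0], bx[0] + 4 * sx[0], 161)
        g2 = np.linspace(bx[1] - 4 * sx[1], bx[1] + 4 * sx[1], 161)
        best = (np.inf, None)
        for b in betas:
            o1 = ((bx[0] - g1) ** 2 / sx[0] ** 2
                  + (by[0] - b * g1) ** 2 / sy[0] ** 2).min()
            o2 = ((bx[1] - g2) ** 2 / sx[1] ** 2
                  + (by[1] - b * g2) ** 2 / sy[1] ** 2).min()
            if o1 + o2 < best[0]:
                best = (o1 + o2, b)
        assert res.beta == pytest.approx(best[1], abs=2e-3)

    def test_requires_two_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            maximum_likelihood([_inst(0.1, 0.01, 0.05, 0.02)])


def _wls_with_intercept(x, y, w):
    """Brute-force weighted normal-equations solve with an intercept."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    params = np.linalg.solve(xtwx, X.T @ W @ y)
    resid = y - X @ params
    scale = float(resid @ W @ resid) / (len(x) - 2)
    cov = np.linalg.inv(xtwx)
    base_se = np.sqrt(np.diag(cov))
    return params, base_se, scale


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.3 * bx + 0.1
        insts = make_instruments(bx, [0.01] * 4, by, [0.02] * 4)
        res = egger(insts)
        assert res.beta == pytest.approx(0.3, abs=1e-10)
        assert res.extra["intercept"] == pytest.approx(0.1, abs=1e-10)

    def test_zero_intercept_data_tracks_ivw(self, rng):
        bx = rng.uniform(0.05, 0.2, 10)
        by = 0.3 * bx
        insts = make_instruments(bx, [0.01] * 10, by, [0.02] * 10)
        res = egger(insts)
        assert res.extra["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert res.beta == pytest.approx(ivw(insts, "fixed").beta, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            insts = random_instruments(rng, j=10)
            bx = np.array([i.beta_exp for i in insts])
            by = np.array([i.beta_out for i in insts])
            sy = np.array([i.se_out for i in insts])
            sign = np.where(bx < 0, -1, 1)
            x, y, w = bx * sign, by * sign, 1.0 / sy**2
            params, base_se, scale = _wls_with_intercept(x, y, w)
            res = egger(insts)
            assert res.beta == pytest.approx(params[1], abs=1e-10)
            assert res.extra["intercept"] == pytest.approx(params[0],
                                                           abs=1e-10)
            mult = max(1.0, np.sqrt(scale))
            assert res.se == pytest.approx(base_se[1] * mult, abs=1e-10)
            assert res.extra["intercept_se"] == pytest.approx(
                base_se[0] * mult, abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_instruments([0.1, 0.2], [0.01] * 2,
                                   [0.03, 0.06], [0.02] * 2))


class TestMedian:
    def test_odd_count_midpoint(self):
        insts = make_instruments([0.1] * 3, [0.01] * 3,
                                 [0.01, 0.03, 0.05], [0.02] * 3)
        res = median_estimator(insts, "simple", n_boot=0)
        assert res.beta == pytest.approx(0.3)

    def test_even_count_interpolates(self):
        assert _weighted_median(np.array([0.1, 0.5]),
                                np.array([0.5, 0.5])) == pytest.approx(0.3)

    def test_matches_cumulative_weight_oracle(self, rng):
        def oracle(ratios, weights):
            order = np.argsort(ratios)
            r, w = ratios[order], weights[order] / weights.sum()
            s, prev_s, prev_r = 0.0, None, None
            for wi, ri in zip(w, r):
                si = s + wi / 2.0
                if si >= 0.5:
                    if prev_s is None:
                        return ri
                    return prev_r + (ri - prev_r) * (0.5 - prev_s) / (si - prev_s)
                s += wi
                prev_s, prev_r = si, ri
            return r[-1]

        for _ in range(50):
            insts = random_instruments(rng, j=7)
            for weighting in ("simple", "weighted"):
                res = median_estimator(insts, weighting, n_boot=0)
                bx = np.array([i.beta_exp for i in insts])
                by = np.array([i.beta_out for i in insts])
                sy = np.array([i.se_out for i in insts])
                ratios = by / bx
                sr = sy / np.abs(bx)
                weights = (np.ones_like(ratios) if weighting == "simple"
                           else 1.0 / sr**2)
                assert res.beta == pytest.approx(
                    oracle(ratios, weights), abs=1e-12)

    def test_bootstrap_se_reproducible(self, rng):
        insts = random_instruments(rng, j=7)
        a = median_estimator(insts, "weighted", n_boot=200, seed=11)
        b = median_estimator(insts, "weighted", n_boot=200, seed=11)
        c = median_estimator(insts, "weighted", n_boot=200, seed=12)
        assert a.se == b.se
        assert a.se != c.se
        assert a.se > 0

    def test_robust_to_minority_outliers(self, rng):
        bx = np.full(7, 0.1)
        by = 0.3 * bx
        by[:2] = 0.3 * bx[:2] + 0.2  # two invalid instruments
        insts = make_instruments(bx, [0.01] * 7, by, [0.02] * 7)
        res = median_estimator(insts, "weighted", n_boot=0)
        assert res.beta == pytest.approx(0.3, abs=1e-9)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            median_estimator(make_instruments([0.1] * 2, [0.01] * 2,
                                              [0.03] * 2, [0.02] * 2))


class TestMode:
    def test_degenerate_cluster_returns_common_ratio(self):
        insts = make_instruments([0.1] * 4, [0.01] * 4,
                                 [0.04] * 4, [0.02] * 4)
        res = mode_estimator(insts, "simple", n_boot=0)
        assert res.beta == pytest.approx(0.4)

    def test_mode_ignores_minority_outlier(self):
        bx = np.full(7, 0.1)
        by = np.array([0.03] * 6 + [0.2])
        insts = make_instruments(bx, [0.01] * 7, by, [0.02] * 7)
        res = mode_estimator(insts, "simple", n_boot=0)
        assert res.beta == pytest.approx(0.3, abs=0.05)

    def test_grid_refinement_stable(self, rng):
        """A 10x finer grid moves the density argmax only within one cell."""
        insts = random_instruments(rng, j=9)
        coarse = mode_estimator(insts, "weighted", n_boot=0)
        fine = mode_estimator(insts, "weighted", n_boot=0, n_grid=5120)
        h = coarse.extra["bandwidth"]
        ratios = [i.beta_out / i.beta_exp for i in insts]
        cell = (np.ptp(ratios) + 6 * h) / 511
        assert abs(coarse.beta - fine.beta) <= cell

    def test_bandwidth_factor_changes_only_h(self, rng):
        insts = random_instruments(rng, j=9)
        res1 = mode_estimator(insts, "weighted", bandwidth_factor=1.0,
                              n_boot=0)
        res2 = mode_estimator(insts, "weighted", bandwidth_factor=2.0,
                              n_boot=0)
        assert res2.extra["bandwidth"] == pytest.approx(
            2 * res1.extra["bandwidth"])


class TestRunAllMethods:
    def test_full_battery_order_and_count(self, rng):
        insts = random_instruments(rng, j=13)
        results = run_all_methods(insts, EstimatorConfig(n_boot=50, seed=3))
        assert [r.method for r in results] == list(METHOD_ORDER)
        assert all(not r.skipped for r in results)

    def test_insufficient_instruments_marked_skipped(self, rng):
        insts = random_instruments(rng, j=2)
        results = run_all_methods(insts, EstimatorConfig(n_boot=10, seed=3))
        skipped = {r.method for r in results if r.skipped}
        assert skipped == {"egger", "simple_median", "weighted_median",
                           "simple_mode", "weighted_mode"}

    def test_seeded_bootstrap_reproducible(self, rng):
        insts = random_instruments(rng, j=13)
        cfg = EstimatorConfig(n_boot=100, seed=42)
        a = run_all_methods(insts, cfg)
        b = run_all_methods(insts, cfg)
        assert [r.se for r in a] == [r.se for r in b]
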