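import numpy as np
import pytest
from scipy.stats import chi2, gamma as gamma_dist

from bbmeta import (
    ExactMomentsEth,
    MetaDataset,
    NullEth,
    Study2x2,
    admissible_rho_range,
    ci_gamma_profile,
    ci_q_profile,
    cochran_q,
    expected_q_odm,
    gamma_approx_params,
    rho_corrected_mp,
    rho_mandel_paule,
    rho_moment,
    study_effects,
)
from bbmeta.qstat import DegenerateDenominatorError

from conftest import brute_force_q


def grid_root(f, lo, hi, step):
    """Independent sign-change scan of f on [lo, hi] with the given step."""
    xs = np.arange(lo, hi, step)
    vals = np.array([f(x) for x in xs])
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    assert len(idx) >= 1, "grid oracle found no sign change"
    i = idx[0]
    return 0.5 * (xs[i] + xs[i + 1])


class TestCochranQ:
    def test_identical_studies_give_zero(self, identical):
        assert cochran_q(study_effects(identical)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self, k3_effects):
        for rho in (0.0, 0.05, 0.2):
            w = k3_effects.weights_fem / (1 + k3_effects.a * rho)
            expect = brute_force_q(k3_effects.theta, w)
            assert cochran_q(k3_effects, rho) == pytest.approx(expect, rel=1e-12)

    def test_corrected_q_at_zero_equals_plain_q(self, toys):
        for ds in toys.values():
            eff = study_effects(ds)
            assert cochran_q(eff, 0.0) == cochran_q(eff)

    def test_monotone_nonincreasing_on_fixtures(self, toys):
        for ds in toys.values():
            eff = study_effects(ds)
            lo, hi = admissible_rho_range(eff)
            grid = np.linspace(lo + 1e-6, hi - 1e-6, 200)
            vals = np.array([cochran_q(eff, r) for r in grid])
            assert (np.diff(vals) <= 1e-12).all()


class TestExpectedQ:
    def test_rho_zero_is_dof(self, k3_effects):
        assert expected_q_odm(k3_effects, 0.0) == k3_effects.K - 1

    def test_two_equal_studies_hand_algebra(self):
        # equal studies: a1 = a2 = a, w1 = w2, so E(Q) = 1 + a rho
        ds = MetaDataset([Study2x2("a", 4, 12, 6, 12), Study2x2("b", 4, 12, 6, 12)])
        eff = study_effects(ds)
        a = eff.a[0]
        assert expected_q_odm(eff, 0.07) == pytest.approx(1 + a * 0.07, rel=1e-12)

    def test_matches_direct_sums(self, k3_effects):
        K = k3_effects.K
        w, a = k3_effects.weights_fem, k3_effects.a
        rho = 0.13
        expect = (K - 1) + (K * a.mean() - (w * a).sum() / w.sum()) * rho
        assert expected_q_odm(k3_effects, rho) == pytest.approx(expect, rel=1e-12)


class TestRhoMoment:
    def test_formula_fixed_point(self, k3_effects):
        res = rho_moment(k3_effects)
        K, w, a = k3_effects.K, k3_effects.weights_fem, k3_effects.a
        q = cochran_q(k3_effects)
        expect = (q - (K - 1)) / (K * a.mean() - (w * a).sum() / w.sum())
        assert res.rho == pytest.approx(max(expect, -1 / a.max()), rel=1e-12)

    def test_homogeneous_data_hits_floor(self, identical):
        # Q = 0 << K-1 and all a_j equal: raw estimate equals -1/max(a)
        eff = study_effects(identical)
        res = rho_moment(eff)
        assert res.rho == pytest.approx(-1 / eff.a.max())

    def test_negative_estimate_above_floor(self):
        # near-identical large studies: Q < K-1 but floor -1/a is far below
        ds = MetaDataset(
            [
                Study2x2("a", 50, 200, 50, 200),
                Study2x2("b", 49, 200, 50, 200),
                Study2x2("c", 50, 200, 51, 200),
            ]
        )
        eff = study_effects(ds)
        assert cochran_q(eff) < eff.K - 1
        res = rho_moment(eff)
        assert -1 / eff.a.max() < res.rho < 0
        assert not res.at_boundary

    def test_truncation_flag(self, identical):
        res = rho_moment(study_effects(identical), truncate_at_zero=True)
        assert res.rho == 0.0 and res.at_boundary

    def test_degenerate_denominator(self, k3_effects):
        # K*abar - abar_w <= 0 only when every a_j is zero (all-minimal
        # studies); exercise the guard on a synthetic effect table
        from dataclasses import replace

        eff = replace(k3_effects, a=np.zeros(k3_effects.K))
        with pytest.raises(DegenerateDenominatorError):
            rho_moment(eff)


class TestMandelPaule:
    def test_estimating_equation_residual(self, k3_effects, unbalanced):
        for eff in (k3_effects, study_effects(unbalanced)):
            res = rho_mandel_paule(eff)
            if not res.at_boundary:
                assert abs(cochran_q(eff, res.rho) - (eff.K - 1)) < 1e-8

    def test_agrees_with_grid_search(self, k3_effects):
        res = rho_mandel_paule(k3_effects)
        lo, hi = admissible_rho_range(k3_effects)
        if res.at_boundary:
            pytest.skip("boundary solution on this fixture")
        f = lambda r: cochran_q(k3_effects, r) - (k3_effects.K - 1)
        approx = grid_root(f, max(lo + 1e-6, res.rho - 0.01), min(1, res.rho + 0.01), 1e-6)
        assert res.rho == pytest.approx(approx, abs=1e-5)

    def test_boundary_when_homogeneous(self, identical):
        eff = study_effects(identical)
        res = rho_mandel_paule(eff)
        lo, _ = admissible_rho_range(eff)
        assert res.at_boundary and res.rho == lo


class TestGammaApprox:
    def test_null_provider_fixed_point(self, k3_effects):
        params = gamma_approx_params(k3_effects, provider=NullEth())
        assert params.mean_q == pytest.approx(k3_effects.K - 1)

    def test_variance_quadratic_hand_value(self):
        # K=10, E(Q)=9: 4.74*9 - 12.17*9 + 9.42*81/9 = 17.91
        mean_q = 9.0
        K = 10
        var = 4.74 * (K - 1) - 12.17 * mean_q + 9.42 * mean_q**2 / (K - 1)
        assert var == pytest.approx(17.91)

    def test_gamma_moment_identities(self, k3_effects):
        params = gamma_approx_params(k3_effects)
        assert params.shape * params.scale == pytest.approx(params.mean_q, rel=1e-12)
        assert params.shape * params.scale**2 == pytest.approx(params.var_q, rel=1e-12)

    def test_exact_moments_provider_tracks_simulated_mean_q(self):
        """The theoretical E(Q) provider is validated against simulation."""
        rng = np.random.default_rng(20240915)
        K, n, p2, theta = 8, 25, 0.15, 0.0
        p1 = p2 * np.exp(theta) / (1 - p2 + p2 * np.exp(theta))
        qs = []
        reps = 3000
        for _ in range(reps):
            x1 = rng.binomial(n, p1, K)
            x2 = rng.binomial(n, p2, K)
            # guard against degenerate margins
            x1 = np.clip(x1, 0, n)
            ds = MetaDataset(
                Study2x2(f"s{j}", int(a), n, int(b), n)
                for j, (a, b) in enumerate(zip(x1, x2))
            )
            qs.append(cochran_q(study_effects(ds)))
        sim_mean = np.mean(qs)
        sim_se = np.std(qs) / np.sqrt(reps)
        ds0 = MetaDataset(
            Study2x2(f"s{j}", int(round(n * p1)), n, int(round(n * p2)), n)
            for j in range(K)
        )
        eth = ExactMomentsEth()(study_effects(ds0))
        assert abs(eth - sim_mean) < max(3 * sim_se, 0.1)


class TestCorrectedMP:
    def test_coincides_with_mp_under_null_provider(self, k3_effects):
        # E(Q) = K-1 makes the cMP estimating equation identical to MP's
        a = rho_corrected_mp(k3_effects, provider=NullEth())
        b = rho_mandel_paule(k3_effects)
        assert a.rho == pytest.approx(b.rho, abs=1e-10)

    def test_estimating_equation_residual(self, k3_effects):
        res = rho_corrected_mp(k3_effects)
        if not res.at_boundary:
            target = res.meta["gamma_params"].mean_q
            assert abs(cochran_q(k3_effects, res.rho) - target) < 1e-8

    def test_agrees_with_grid_search(self, unbalanced):
        eff = study_effects(unbalanced)
        res = rho_corrected_mp(eff)
        if res.at_boundary:
            pytest.skip("boundary solution on this fixture")
        target = res.meta["gamma_params"].mean_q
        f = lambda r: cochran_q(eff, r) - target
        approx = grid_root(f, res.rho - 0.01, res.rho + 0.01, 1e-6)
        assert res.rho == pytest.approx(approx, abs=1e-5)


class TestQProfileCI:
    def test_endpoints_agree_with_fine_grid(self, unbalanced):
        eff = study_effects(unbalanced)
        ci = ci_q_profile(eff, 0.95)
        K = eff.K
        lo_q = chi2.ppf(0.025, K - 1)
        hi_q = chi2.ppf(0.975, K - 1)
        lo_adm, _ = admissible_rho_range(eff)
        grid = np.linspace(lo_adm + 1e-7, 1 - 1e-7, 40001)
        inside = np.array([lo_q <= cochran_q(eff, r) <= hi_q for r in grid])
        assert inside.any()
        g_lo, g_hi = grid[inside][0], grid[inside][-1]
        step = grid[1] - grid[0]
        if not ci.low_truncated:
            assert abs(ci.low - g_lo) < 2 * step
        if not ci.high_truncated:
            assert abs(ci.high - g_hi) < 2 * step

    def test_level_to_zero_collapses_to_point(self, k3_effects):
        # as level -> 0 both quantiles approach the chi-square median and the
        # interval collapses to the single rho solving Q*(rho) = median
        ci = ci_q_profile(k3_effects, 1e-6)
        assert not ci.empty
        assert ci.high - ci.low < 1e-4
        med = chi2.ppf(0.5, k3_effects.K - 1)
        assert cochran_q(k3_effects, 0.5 * (ci.low + ci.high)) == pytest.approx(
            med, abs=1e-3
        )

    def test_homogeneous_data_empty_interval(self, identical):
        # Q*(rho) == 0 everywhere: below the lower chi-square quantile
        ci = ci_q_profile(study_effects(identical), 0.95)
        assert ci.empty

    def test_bad_level_rejected(self, k3_effects):
        with pytest.raises(ValueError):
            ci_q_profile(k3_effects, 1.5)


class TestGammaProfileCI:
    def test_endpoints_agree_with_fine_grid(self, unbalanced):
        eff = study_effects(unbalanced)
        ci = ci_gamma_profile(eff, 0.95)
        params = ci.meta["gamma_params"]
        lo_q = gamma_dist.ppf(0.025, params.shape, scale=params.scale)
        hi_q = gamma_dist.ppf(0.975, params.shape, scale=params.scale)
        lo_adm, _ = admissible_rho_range(eff)
        grid = np.linspace(lo_adm + 1e-7, 1 - 1e-7, 40001)
        inside = np.array([lo_q <= cochran_q(eff, r) <= hi_q for r in grid])
        assert inside.any()
        g_lo, g_hi = grid[inside][0], grid[inside][-1]
        step = grid[1] - grid[0]
        if not ci.low_truncated:
            assert abs(ci.low - g_lo) < 2 * step
        if not ci.high_truncated:
            assert abs(ci.high - g_hi) < 2 * step

    def test_null_gamma_close_to_chi_square_band(self, unbalanced):
        # gamma moments matched to chi-square(K-1): endpoints nearly coincide
        eff = study_effects(unbalanced)
        # mean matched exactly; variance 1.99(K-1) vs chi-square's 2(K-1),
        # so endpoints approach but do not exactly equal the chi-square band
        ci_g = ci_gamma_profile(eff, 0.95, provider=NullEth())
        ci_q = ci_q_profile(eff, 0.95)
        assert ci_g.low == pytest.approx(ci_q.low, abs=2e-2)
        assert ci_g.high == pytest.approx(ci_q.high, abs=2e-2)


def test_moment_estimator_unbiased_under_homogeneity():
    """Mean of the moment estimator over binomial (rho=0) replicates is ~0."""
    rng = np.random.default_rng(77)
    K, n, p2, theta = 80, 250, 0.4, 0.0
    reps = 2000
    vals = np.empty(reps)
    for i in range(reps):
        x1 = rng.binomial(n, p2, K)
        x2 = rng.binomial(n, p2, K)
        ds = MetaDataset(
            Study2x2(f"s{j}", int(a), n, int(b), n)
            for j, (a, b) in enumerate(zip(x1, x2))
        )
        vals[i] = rho_moment(study_effects(ds)).rho
    se = vals.std(ddof=1) / np.sqrt(reps)
    assert abs(vals.mean()) < 3 * se
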