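"""Likelihood scan: SAD(1) covariance, bivariate likelihood, marker tests,
genetic effect curves."""

import numpy as np
import pytest
from scipy import stats

from crinet._kernels import sad1_paths
from crinet.errors import DegenerateMarkerError, InvalidInputError
from crinet.growth import CRIParams
from crinet.mapping import (GLSContext, MarkerGenotypes,
                            SADParams, bivariate_loglik, estimate_sad_params,
                            fit_alternative, fit_null, genetic_effect_curves,
                            lrt_scan, sad1_covariance, subhypothesis_tests)
from crinet.simulate import (SimConfig, simulate_genotypes,
                             simulate_phenotypes)


class TestSAD1Covariance:
    def test_white_noise_limit(self):
        psi = SADParams(0.0, 0.0, 2.0, 3.0, 0.0)
        S = sad1_covariance(psi, 4)
        expected = np.diag([4.0] * 4 + [9.0] * 4)
        assert np.allclose(S, expected)

    def test_contemporaneous_cross_correlation(self):
        psi = SADParams(0.0, 0.0, 2.0, 3.0, 0.5)
        S = sad1_covariance(psi, 4)
        assert np.allclose(S[:4, 4:], 0.5 * 2.0 * 3.0 * np.eye(4))

    def test_matches_monte_carlo(self, sad_params):
        """Entrywise agreement with the empirical covariance of simulated
        SAD(1) paths."""
        T, n = 5, 400_000
        rng = np.random.default_rng(0)
        z = rng.standard_normal((n, T, 2))
        paths = sad1_paths(sad_params.phi_h, sad_params.phi_d,
                           sad_params.nu_h, sad_params.nu_d, sad_params.rho,
                           n, T, z)
        emp = np.cov(paths.T)
        S = sad1_covariance(sad_params, T)
        # MC standard error of each covariance entry
        se = np.sqrt((np.outer(np.diag(S), np.diag(S)) + S ** 2) / n)
        assert np.all(np.abs(emp - S) < 5 * se)

    @pytest.mark.parametrize("phi_h,phi_d,rho", [
        (0.0, 0.0, 0.0), (0.5, -0.3, 0.6), (0.9, 0.9, -0.8), (-0.7, 0.95, 0.2),
        (0.99999999, 0.5, 0.3),  # phi -> 1 continuity limit
    ])
    def test_symmetric_positive_definite(self, phi_h, phi_d, rho):
        psi = SADParams(phi_h, phi_d, 1.0, 2.0, rho)
        S = sad1_covariance(psi, 6)
        assert np.allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() > 0

    def test_invalid_rho_rejected(self):
        with pytest.raises(InvalidInputError):
            SADParams(0.5, 0.5, 1.0, 1.0, 1.0)


class TestBivariateLoglik:
    def test_closed_form_at_mean(self):
        """Data exactly at the mean with unit variances: the density reduces
        to the normalizing constant."""
        T = 3
        psi = SADParams(0.0, 0.0, 1.0, 1.0, 0.0)
        mu = np.arange(2 * T, dtype=float)
        ll = bivariate_loglik(mu[None, :], mu, psi)
        assert ll == pytest.approx(-T * np.log(2 * np.pi), rel=1e-12)

    def test_scaling_nu_changes_loglik_as_normal_density(self):
        T = 3
        rng = np.random.default_rng(1)
        y = rng.standard_normal((1, 2 * T))
        mu = np.zeros(2 * T)
        ll1 = bivariate_loglik(y, mu, SADParams(0.0, 0.0, 1.0, 1.0, 0.0))
        ll2 = bivariate_loglik(y, mu, SADParams(0.0, 0.0, 2.0, 2.0, 0.0))
        # doubling all sds: -2T log 2 on the constant, quadratic term / 4
        quad = float(np.sum(y ** 2))
        assert ll2 - ll1 == pytest.approx(-2 * T * np.log(2) + quad / 2 - quad / 8)

    def test_matches_direct_inverse_oracle(self, sad_params):
        T, n = 4, 7
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((n, 2 * T))
        mu = rng.standard_normal(2 * T)
        S = sad1_covariance(sad_params, T)
        Sinv = np.linalg.inv(S)
        _, logdet = np.linalg.slogdet(S)
        direct = sum(-0.5 * (2 * T * np.log(2 * np.pi) + logdet
                             + (y - mu) @ Sinv @ (y - mu)) for y in Y)
        assert bivariate_loglik(Y, mu, sad_params) == pytest.approx(direct, abs=1e-8)


def _simulated(n=60, h2=0.05, p=20, seed=5, **kw):
    cfg = SimConfig(n=n, h2=h2, p=p, seed=seed, **kw)
    rng = np.random.default_rng(seed)
    markers = simulate_genotypes(cfg, rng)
    phen = simulate_phenotypes(markers, cfg, rng)
    return cfg, markers, phen


class TestFits:
    def test_sad_estimation_recovers_truth(self, sad_params):
        T, n = 8, 3000
        rng = np.random.default_rng(3)
        z = rng.standard_normal((n, T, 2))
        R = sad1_paths(sad_params.phi_h, sad_params.phi_d, sad_params.nu_h,
                       sad_params.nu_d, sad_params.rho, n, T, z)
        est = estimate_sad_params(R, T)
        assert est.phi_h == pytest.approx(sad_params.phi_h, abs=0.05)
        assert est.nu_d == pytest.approx(sad_params.nu_d, rel=0.05)
        assert est.rho == pytest.approx(sad_params.rho, abs=0.05)

    def test_marker_with_identical_params_gives_small_lrt(self):
        """A marker independent of the phenotypes (global null) yields an
        LRT in the bulk of its chi-square reference."""
        _, markers, phen = _simulated(n=80, h2=0.0, p=1, seed=9)
        res = lrt_scan(phen, markers, step=0.1)
        assert res[0].lrt < stats.chi2.ppf(0.999, res[0].df)

    def test_class_sizes_bookkeeping(self):
        _, markers, phen = _simulated(n=60, h2=0.0, p=3, seed=11)
        null = fit_null(phen, step=0.1)
        ctx = GLSContext(null.psi, phen.T)
        alt = fit_alternative(phen, markers[1], ctx, null.theta.to_array(),
                              step=0.1)
        assert sum(alt.class_sizes.values()) == phen.n - np.sum(
            markers[1].codes == -1)

    def test_missing_genotypes_dropped(self):
        _, markers, phen = _simulated(n=60, h2=0.0, p=1, seed=13)
        m = markers[0]
        codes = m.codes.copy()
        codes[:5] = -1
        m2 = MarkerGenotypes(m.marker_id, m.segregation, codes)
        null = fit_null(phen, step=0.1)
        ctx = GLSContext(null.psi, phen.T)
        alt = fit_alternative(phen, m2, ctx, null.theta.to_array(), step=0.1)
        assert int(alt.included.sum()) == 55

    def test_degenerate_marker_raises(self):
        _, markers, phen = _simulated(n=60, h2=0.0, p=1, seed=15)
        m = markers[0]
        codes = np.zeros_like(m.codes)
        codes[0] = 1  # a single individual in class 1 -> dropped
        m2 = MarkerGenotypes(m.marker_id, m.segregation, codes)
        null = fit_null(phen, step=0.1)
        ctx = GLSContext(null.psi, phen.T)
        with pytest.raises(DegenerateMarkerError):
            fit_alternative(phen, m2, ctx, null.theta.to_array(), step=0.1)


class TestScan:
    def test_empty_marker_list(self):
        _, _, phen = _simulated(n=20, h2=0.0, p=1, seed=17)
        assert lrt_scan(phen, []) == []

    def test_fdr_monotone_in_raw_p(self):
        _, markers, phen = _simulated(n=60, h2=0.05, p=25, seed=19)
        res = lrt_scan(phen, markers, step=0.1)
        ok = sorted((r for r in res if not r.failed), key=lambda r: r.p_value)
        fdr = [r.p_fdr for r in ok]
        assert all(a <= b + 1e-12 for a, b in zip(fdr, fdr[1:]))

    def test_lrt_nonnegative(self):
        _, markers, phen = _simulated(n=60, h2=0.05, p=25, seed=19)
        res = lrt_scan(phen, markers, step=0.1)
        assert all(r.lrt >= 0 for r in res if not r.failed)

    def test_null_p_values_approximately_uniform(self):
        """Global null: raw chi-square p-values across 200 markers pass a
        Kolmogorov-Smirnov uniformity check."""
        _, markers, phen = _simulated(n=66, h2=0.0, p=200, seed=11)
        res = lrt_scan(phen, markers, step=0.1)
        p = np.array([r.p_value for r in res if not r.failed])
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_causal_marker_detected(self):
        _, markers, phen = _simulated(n=100, h2=0.1, p=20, seed=23)
        res = lrt_scan(phen, markers, step=0.1)
        by_id = {r.marker_id: r for r in res}
        causal = by_id["snp0"]
        assert causal.p_value < 0.05 / 20


class TestSubhypotheses:
    def test_constrained_never_beats_free_and_nulls_recover(self):
        cfg, markers, phen = _simulated(n=80, h2=0.08, p=2, seed=29)
        null = fit_null(phen, step=0.1)
        ind, inter = subhypothesis_tests(phen, markers[0], null, step=0.1)
        assert ind.lrt >= 0 and inter.lrt >= 0
        assert 0 <= ind.p_value <= 1 and 0 <= inter.p_value <= 1
        assert ind.df == 4 * 1 and inter.df == 2 * 1  # testcross J=2

    def test_asymptote_effect_hits_independent_subtest(self):
        """The simulated causal effect shifts asymptotes (independence
        parameters), so the independence sub-test should carry the signal."""
        cfg, markers, phen = _simulated(n=150, h2=0.2, p=1, seed=31)
        null = fit_null(phen, step=0.1)
        ind, inter = subhypothesis_tests(phen, markers[0], null, step=0.1)
        assert ind.p_value < 0.01


class TestEffectCurves:
    def _thetas(self):
        a = CRIParams(0.6, 24.0, -0.01, 0.45, 30.0, 0.004)
        b = CRIParams(0.6, 26.0, -0.01, 0.45, 33.0, 0.004)
        return {0: a, 1: b}

    def test_identical_params_zero_curves(self, annual_times, init_state):
        th = self._thetas()
        pair = genetic_effect_curves({0: th[0], 1: th[0]}, [0.5, 0.5],
                                     annual_times, init_state)
        assert np.allclose(pair.g1, 0) and np.allclose(pair.g2, 0)

    def test_two_point_weighted_sd(self, annual_times, init_state):
        """Two equally weighted classes: g(t) = |mu_1(t) - mu_2(t)| / 2."""
        from crinet.growth import integrate_cri
        th = self._thetas()
        pair = genetic_effect_curves(th, [0.5, 0.5], annual_times, init_state)
        t1 = integrate_cri(th[0], init_state, annual_times)
        t2 = integrate_cri(th[1], init_state, annual_times)
        assert np.allclose(pair.g1, np.abs(t1.height - t2.height) / 2)
        assert np.allclose(pair.g2, np.abs(t1.diameter - t2.diameter) / 2)

    def test_matches_brute_force_enumeration(self, annual_times, init_state):
        from crinet.growth import integrate_cri
        th = {0: CRIParams(0.5, 22.0, -0.02, 0.4, 28.0, 0.01),
              1: CRIParams(0.65, 25.0, 0.0, 0.5, 31.0, 0.002),
              2: CRIParams(0.55, 24.0, 0.01, 0.45, 30.0, -0.005)}
        w = np.array([0.25, 0.5, 0.25])
        pair = genetic_effect_curves(th, w, annual_times, init_state)
        M1 = np.array([integrate_cri(th[j], init_state, annual_times).height
                       for j in range(3)])
        mbar = w @ M1
        brute = np.sqrt(w @ (M1 - mbar) ** 2)
        assert np.allclose(pair.g1, brute)
        assert np.all(pair.g1 >= 0) and np.all(pair.g2 >= 0)
        assert np.all(np.abs(pair.dynamic_correlation) <= 1 + 1e-12)

    def test_invariant_to_class_relabeling(self, annual_times, init_state):
        th = self._thetas()
        a = genetic_effect_curves(th, [0.3, 0.7], annual_times, init_state)
        b = genetic_effect_curves({0: th[1], 1: th[0]}, [0.7, 0.3],
                                  annual_times, init_state)
        assert np.allclose(a.g1, b.g1) and np.allclose(a.g2, b.g2)

    def test_frequencies_must_sum_to_one(self, annual_times, init_state):
        with pytest.raises(InvalidInputError):
            genetic_effect_curves(self._thetas(), [0.5, 0.6], annual_times,
                                  init_state)


class TestPermutationThreshold:
    def test_threshold_positive_and_controls_null(self):
        """Label-permutation threshold: positive, and above the typical
        single null marker's LRT (it tracks the max over markers)."""
        from crinet.mapping import permutation_threshold
        _, markers, phen = _simulated(n=40, h2=0.0, p=5, seed=37)
        thr = permutation_threshold(phen, markers, n_perm=8, alpha=0.2,
                                    seed=1, step=0.1)
        res = lrt_scan(phen, markers, step=0.1, lrt_threshold=thr)
        assert thr > 0
        med = np.median([r.lrt for r in res if not r.failed])
        assert thr > med


class TestPsiReestimation:
    def test_flag_refits_covariance_and_keeps_classes(self):
        _, markers, phen = _simulated(n=60, h2=0.1, p=1, seed=41)
        null = fit_null(phen, step=0.1)
        ctx = GLSContext(null.psi, phen.T)
        base = fit_alternative(phen, markers[0], ctx, null.theta.to_array(),
                               step=0.1)
        re = fit_alternative(phen, markers[0], ctx, null.theta.to_array(),
                             step=0.1, reestimate_psi=True)
        assert set(re.theta_by_genotype) == set(base.theta_by_genotype)
        assert re.psi_used.to_dict() != null.psi.to_dict()
        assert np.isfinite(re.loglik)
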