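import math

import numpy as np
import pytest
from scipy.special import iv

from ringwander.circular_stats import (
    BivariateCosineModel,
    VonMises,
    bessel_ratio,
    bivariate_log_normalization,
    bivariate_marginal,
    bivariate_moments,
    bivariate_normalization,
    bivariate_pdf,
    circular_moment,
    firing_rate_variance,
    gaussian_approx,
    modality,
    model_a_tuning_stats,
    model_b_center_stats,
    tuning_mean,
    tuning_variance,
    von_mises_pdf,
)

TWO_PI = 2.0 * math.pi


def _quad_grid(n=2048):
    return -np.pi + TWO_PI / n * np.arange(n)


class TestVonMisesPdf:
    def test_uniform_at_zero_concentration(self):
        vm = VonMises(concentration=0.0)
        beta = np.linspace(-np.pi, np.pi, 7)
        assert np.allclose(von_mises_pdf(beta, vm), 1.0 / TWO_PI)

    @pytest.mark.parametrize("kappa", [0.5, 2.0, 10.0])
    def test_normalized(self, kappa):
        b = _quad_grid()
        total = von_mises_pdf(b, VonMises(concentration=kappa)).sum() * TWO_PI / len(b)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_large_kappa_gaussian_limit(self):
        kappa = 400.0
        vm = VonMises(concentration=kappa)
        sigma2 = 1.0 / kappa
        beta = np.linspace(-0.1, 0.1, 21)
        gauss = np.exp(-(beta**2) / (2 * sigma2)) / math.sqrt(TWO_PI * sigma2)
        assert np.allclose(von_mises_pdf(beta, vm), gauss, rtol=2e-3)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            VonMises(concentration=-1.0)


class TestCircularMoments:
    def test_zeroth_is_one(self):
        assert circular_moment(0, VonMises(concentration=3.0)) == 1.0

    def test_first_moment_quadrature_oracle(self):
        vm = VonMises(concentration=2.0)
        b = _quad_grid()
        direct = (np.exp(1j * b) * von_mises_pdf(b, vm)).sum() * TWO_PI / len(b)
        assert circular_moment(1, vm) == pytest.approx(direct, abs=1e-12)
        assert circular_moment(1, vm).real == pytest.approx(iv(1, 2.0) / iv(0, 2.0))

    def test_uniform_moments_vanish(self):
        vm = VonMises(concentration=0.0)
        for n in (1, 2, 5):
            assert abs(circular_moment(n, vm)) == pytest.approx(0.0, abs=1e-15)

    def test_modulus_bounded(self):
        for kappa in (0.1, 1.0, 30.0, 200.0):
            for n in (1, 2, 3):
                assert 0.0 <= abs(circular_moment(n, VonMises(concentration=kappa))) <= 1.0

    def test_centered_moment_phase(self):
        vm = VonMises(concentration=2.0, center=0.7)
        assert np.angle(circular_moment(1, vm)) == pytest.approx(0.7)


class TestTuningCurves:
    def test_mean_vanishes_without_stimulus(self):
        theta = np.linspace(-np.pi, np.pi, 9)
        assert np.allclose(tuning_mean(theta, 1.85, VonMises(concentration=0.0)), 0.0)

    def test_mean_saturates_at_high_concentration(self):
        theta = np.linspace(-np.pi, np.pi, 9)
        out = tuning_mean(theta, 1.85, VonMises(concentration=1e6))
        assert np.allclose(out, 1.85 * np.cos(theta), rtol=1e-5)

    def test_mean_amplitude_monotone(self):
        kappas = np.linspace(0.0, 20.0, 81)
        amps = np.array([bessel_ratio(1, k) for k in kappas])
        assert np.all(np.diff(amps) > 0)

    def test_variance_flat_at_zero_concentration(self):
        theta = np.linspace(-np.pi, np.pi, 9)
        v = tuning_variance(theta, 1.85, VonMises(concentration=0.0))
        assert np.allclose(v, 1.85**2 / 2)

    def test_variance_m_shape(self):
        vm = VonMises(concentration=2.0)
        assert tuning_variance(np.pi / 2, 1.0, vm) > tuning_variance(0.0, 1.0, vm)
        theta = np.linspace(-np.pi, np.pi, 361)
        v = tuning_variance(theta, 1.0, vm)
        assert theta[np.argmax(v)] == pytest.approx(-np.pi / 2, abs=0.02) or theta[
            np.argmax(v)
        ] == pytest.approx(np.pi / 2, abs=0.02)

    def test_variance_monte_carlo_oracle(self, rng):
        # sample beta ~ VM(kappa=2), variance of A cos(theta + beta), 1e6 draws
        kappa, amp = 2.0, 1.85
        beta = rng.vonmises(0.0, kappa, size=1_000_000)
        vm = VonMises(concentration=kappa)
        for theta in (0.0, np.pi / 4, np.pi / 2):
            samples = amp * np.cos(theta + beta)
            est = samples.var()
            se = np.sqrt(((samples - samples.mean()) ** 2).var() / samples.size)
            assert abs(est - tuning_variance(theta, amp, vm)) < 3 * se

    def test_variance_pi_periodic(self):
        vm = VonMises(concentration=3.0)
        theta = np.linspace(-np.pi, 0, 50)
        assert np.allclose(
            tuning_variance(theta, 1.0, vm), tuning_variance(theta + np.pi, 1.0, vm)
        )


class TestFiringRateVariance:
    def test_flat_at_zero_concentration(self, params):
        theta = np.linspace(-np.pi, np.pi, 13)
        v = firing_rate_variance(theta, 1.85, VonMises(concentration=0.0), params)
        assert np.allclose(v, v[0])
        assert np.all(v >= 0)

    def test_sampling_oracle(self, params, rng):
        from ringwander.model_core import firing_rate

        kappa, amp = 2.0, 1.85
        beta = rng.vonmises(0.0, kappa, size=500_000)
        vm = VonMises(concentration=kappa)
        for theta in (0.0, np.pi / 2):
            samples = firing_rate(amp * np.cos(theta + beta), params)
            est = samples.var()
            se = np.sqrt(((samples - samples.mean()) ** 2).var() / samples.size)
            pred = float(firing_rate_variance(theta, amp, vm, params)[0])
            assert abs(est - pred) < 3 * se

    def test_bimodal_in_marginal_regime(self, params):
        theta = np.linspace(-np.pi, np.pi, 181)
        v = firing_rate_variance(theta, 1.85, VonMises(concentration=2.0), params)
        assert v[np.argmin(np.abs(theta - np.pi / 2))] > v[np.argmin(np.abs(theta))]


class TestBivariateNormalization:
    def test_chi_zero_closed_form(self):
        n = bivariate_normalization(1.0, 2.0, 0.0)
        assert n == pytest.approx(TWO_PI**2 * iv(0, 1.0) * iv(0, 2.0), rel=1e-12)

    def test_all_zero_uniform(self):
        assert bivariate_normalization(0.0, 0.0, 0.0) == pytest.approx(TWO_PI**2, rel=1e-12)

    def test_series_vs_quadrature_single(self):
        n = 400
        b = _quad_grid(n)
        b1, b2 = np.meshgrid(b, b, indexing="ij")
        quad = np.exp(np.cos(b1) + 2 * np.cos(b2) + 5 * np.cos(b1 - b2)).sum() * (TWO_PI / n) ** 2
        assert bivariate_normalization(1.0, 2.0, 5.0) == pytest.approx(quad, rel=1e-8)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            bivariate_normalization(-1.0, 1.0, 0.0)

    def test_large_argument_scaled_path(self):
        # log-normalization stays finite and matches quadrature at kappa=64
        logn = bivariate_log_normalization(64.0, 64.0, 1.0)
        n = 600
        b = _quad_grid(n)
        b1, b2 = np.meshgrid(b, b, indexing="ij")
        expo = 64 * np.cos(b1) + 64 * np.cos(b2) + np.cos(b1 - b2)
        peak = expo.max()
        quad_log = peak + np.log(np.exp(expo - peak).sum() * (TWO_PI / n) ** 2)
        assert logn == pytest.approx(quad_log, abs=1e-8)


@pytest.fixture(scope="module")
def model():
    return BivariateCosineModel(kappa1=1.0, kappa2=2.0, chi=5.0)


class TestBivariateDensity:

    def test_joint_integrates_to_one(self, model):
        n = 400
        b = _quad_grid(n)
        b1, b2 = np.meshgrid(b, b, indexing="ij")
        total = bivariate_pdf(b1, b2, model).sum() * (TWO_PI / n) ** 2
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_marginal_integrates_to_one(self, model):
        b = _quad_grid(2048)
        total = bivariate_marginal(b, model).sum() * TWO_PI / len(b)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_marginal_even(self, model):
        b = np.linspace(0, np.pi, 50)
        assert np.allclose(bivariate_marginal(b, model), bivariate_marginal(-b, model))

    def test_marginal_matches_direct_quadrature(self, model):
        # validates the index assignment in the closed form
        n = 2048
        b2 = _quad_grid(n)
        for b1 in (-2.0, -0.5, 0.0, 1.0, 2.5):
            direct = bivariate_pdf(b1, b2, model).sum() * TWO_PI / n
            assert bivariate_marginal(b1, model) == pytest.approx(direct, rel=1e-10)

    def test_marginal_chi_zero_reduces_to_von_mises(self):
        model = BivariateCosineModel(kappa1=1.5, kappa2=0.7, chi=0.0)
        b = np.linspace(-np.pi, np.pi, 33)
        vm = VonMises(concentration=1.5)
        assert np.allclose(bivariate_marginal(b, model), von_mises_pdf(b, vm), rtol=1e-10)


class TestModality:
    def test_weak_negative_coupling_unimodal(self):
        assert modality(2.0, 2.0, -0.5) == "unimodal"

    def test_strong_negative_coupling_bimodal(self):
        assert modality(3.0, 3.0, -2.0) == "bimodal"

    @pytest.mark.parametrize("chi", [0.0, 0.3, 5.0])
    def test_nonnegative_coupling_unimodal(self, chi):
        assert modality(1.0, 4.0, chi) == "unimodal"

    def test_boundary(self):
        assert modality(2.0, 2.0, -1.0) == "boundary"

    def test_requires_positive_kappas(self):
        with pytest.raises(ValueError):
            modality(0.0, 1.0, 1.0)


class TestGaussianApprox:
    def test_chi_zero_diagonal(self):
        g = gaussian_approx(2.0, 4.0, 0.0)
        assert np.allclose(g.covariance, np.diag([0.5, 0.25]))

    def test_symmetric_variance_value(self):
        g = gaussian_approx(1.0, 1.0, 5.0)
        assert g.covariance[0, 0] == pytest.approx(6.0 / 11.0)
        assert g.covariance[0, 0] < 1.0  # coupling shrinks below 1/kappa

    def test_inverse_consistency(self):
        k1, k2, chi = 3.0, 2.0, 1.5
        g = gaussian_approx(k1, k2, chi)
        prec = np.array([[k1 + chi, -chi], [-chi, k2 + chi]])
        assert np.allclose(g.covariance @ prec, np.eye(2), atol=1e-12)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            gaussian_approx(1.0, 1.0, -0.6)

    def test_tv_to_exact_decreases_with_concentration(self):
        # total-variation distance on [-pi,pi]^2 shrinks along kappa = 4, 16, 64
        n = 240
        b = _quad_grid(n)
        b1, b2 = np.meshgrid(b, b, indexing="ij")
        cell = (TWO_PI / n) ** 2
        tvs = []
        for kappa in (4.0, 16.0, 64.0):
            model = BivariateCosineModel(kappa1=kappa, kappa2=kappa, chi=1.0)
            exact = bivariate_pdf(b1, b2, model)
            gauss = gaussian_approx(kappa, kappa, 1.0).pdf(b1, b2)
            tvs.append(0.5 * np.abs(exact - gauss).sum() * cell)
        assert tvs[0] > tvs[1] > tvs[2]


class TestModelATuning:
    def test_chi_zero_reduces_to_univariate(self, rng):
        amp = 1.85
        theta = np.linspace(-np.pi, np.pi, 25)
        model = BivariateCosineModel(kappa1=2.0, kappa2=2.0, chi=0.0)
        stats = model_a_tuning_stats(theta, amp, model, n_quad=720)
        vm = VonMises(concentration=2.0)
        assert np.allclose(stats.mean, tuning_mean(theta, amp, vm), atol=1e-8)
        assert np.allclose(stats.variance, tuning_variance(theta, amp, vm), atol=1e-8)
        assert np.allclose(stats.correlation, 0.0, atol=1e-8)

    def test_variance_suppressed_by_coupling(self):
        theta = np.array([np.pi / 2])
        out = []
        for chi in (0.0, 1.0, 5.0):
            model = BivariateCosineModel(kappa1=2.0, kappa2=2.0, chi=chi)
            out.append(model_a_tuning_stats(theta, 1.0, model).variance[0])
        assert out[0] > out[1] > out[2]

    def test_phase_variance_suppressed_by_coupling(self):
        # var(beta1) from exact 2-D quadrature decreases as chi grows
        variances = []
        for chi in (0.0, 1.0, 5.0):
            n = 720
            b = _quad_grid(n)
            model = BivariateCosineModel(kappa1=2.0, kappa2=2.0, chi=chi)
            marg = bivariate_marginal(b, model)
            var = (b**2 * marg).sum() * TWO_PI / n
            variances.append(var)
        assert variances[0] > variances[1] > variances[2]

    def test_moments_match_gibbs_sampling(self, rng):
        # conditional distributions of the cosine model are von Mises, so a
        # vectorized Gibbs sampler is an independent route to the moments
        kappa, chi = 2.0, 5.0
        n_chains, n_sweeps, keep = 4000, 150, 50
        b1 = rng.uniform(-np.pi, np.pi, n_chains)
        b2 = rng.uniform(-np.pi, np.pi, n_chains)
        sums = np.zeros((n_chains, 3))
        for sweep in range(n_sweeps):
            z = kappa + chi * np.exp(1j * b2)
            b1 = rng.vonmises(np.angle(z), np.abs(z))
            z = kappa + chi * np.exp(1j * b1)
            b2 = rng.vonmises(np.angle(z), np.abs(z))
            if sweep >= n_sweeps - keep:
                sums += np.stack(
                    [np.cos(b1), np.cos(b1) * np.cos(b2), np.sin(b1) * np.sin(b2)], axis=1
                )
        chain_means = sums / keep
        est = chain_means.mean(axis=0)
        se = chain_means.std(axis=0) / math.sqrt(n_chains)
        m = bivariate_moments(kappa, kappa, chi)
        for value, target, err in zip(est, (m.cos1, m.cos1cos2, m.sin1sin2), se):
            assert abs(value - target) < 4 * err

    def test_quadrature_resolution_stable(self):
        model = BivariateCosineModel(kappa1=2.0, kappa2=2.0, chi=5.0)
        theta = np.array([0.0, np.pi / 2])
        a = model_a_tuning_stats(theta, 1.0, model, n_quad=360)
        b = model_a_tuning_stats(theta, 1.0, model, n_quad=720)
        assert np.allclose(a.variance, b.variance, atol=1e-10)
        assert np.allclose(a.correlation, b.correlation, atol=1e-10)

    def test_normalization_cross_check(self):
        m = bivariate_moments(1.0, 2.0, 5.0, n_quad=400)
        assert m.norm == pytest.approx(bivariate_normalization(1.0, 2.0, 5.0), rel=1e-8)


@pytest.fixture(scope="module")
def phi(bump, grid):
    from ringwander.model_core import CouplingParams
    from ringwander.phase_reduction import coupling_fn_model_b

    table = coupling_fn_model_b(
        CouplingParams(model="B", modulated_amplitude=1.0), bump, grid=grid
    )
    return table.phi


class TestModelBSurround:

    def test_chi_zero_flat(self, phi):
        biases = np.linspace(-np.pi, np.pi, 9)
        stats = model_b_center_stats(biases, 1.0, 0.0, phi)
        assert np.allclose(stats.mean, stats.mean[0], atol=1e-12)
        assert np.allclose(stats.variance, stats.variance[0], atol=1e-12)

    def test_facilitation_suppression_crossover(self, phi):
        biases = np.array([0.0, np.pi])
        neg = model_b_center_stats(biases, 1.0, -1.0, phi)
        pos = model_b_center_stats(biases, 1.0, 1.0, phi)
        # inhibitory coupling: variance higher for aligned stimuli
        assert neg.variance[0] > neg.variance[1]
        # excitatory coupling: reversed
        assert pos.variance[0] < pos.variance[1]

    def test_mean_and_variance_move_oppositely(self, phi):
        biases = np.linspace(-np.pi, np.pi, 25)
        for chi in (-1.0, 1.0):
            stats = model_b_center_stats(biases, 1.0, chi, phi)
            dm = np.diff(stats.mean)
            dv = np.diff(stats.variance)
            moving = np.abs(dm) > 1e-6
            assert np.all(np.sign(dm[moving]) == -np.sign(dv[moving]))
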