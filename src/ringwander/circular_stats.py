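"""Analytic steady-state circular statistics of wandering bump phases.

Univariate: the stationary phase density of a stimulus-pinned wandering bump
is von Mises, ``M(beta; center, kappa) = exp(kappa cos(beta - center)) /
(2 pi I0(kappa))``, with ``kappa = contrast / (eps * A * D)``.  Averaging the
rigidly shifted profile ``A cos(theta + beta)`` over this density gives
cosine-shaped mean tuning and an M-shaped (bimodal) variance tuning curve.

Bivariate: a coupled symmetric pair has the stationary joint density of the
"cosine model" bivariate von Mises,

    p(b1, b2) ~ exp(kappa1 cos b1 + kappa2 cos b2 + chi cos(b1 - b2)),

whose normalization admits a rapidly converging alternating Bessel series.
A generalized variant replaces ``chi cos(b1 - b2)`` by ``chi phi(b1 - b2)``
with a tabulated even potential ``phi`` (delta-kernel coupling), for which
all statistics are obtained by 2-D quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.special import ive

from .model_core import RingParams, firing_rate, wrap_angle

__all__ = [
    "VonMises",
    "BivariateCosineModel",
    "ModelBDensity",
    "GaussianApprox",
    "von_mises_pdf",
    "circular_moment",
    "bessel_ratio",
    "tuning_mean",
    "tuning_variance",
    "firing_rate_variance",
    "bivariate_normalization",
    "bivariate_log_normalization",
    "bivariate_pdf",
    "bivariate_marginal",
    "bivariate_moments",
    "modality",
    "gaussian_approx",
    "model_a_tuning_stats",
    "model_b_center_stats",
]

TWO_PI = 2.0 * math.pi

#: default tensor-quadrature resolution per axis (periodic rectangle rule)
N_QUAD_2D = 361

_SERIES_RTOL = 1e-14
_SERIES_MAX_TERMS = 500
_SERIES_STREAK = 3


@dataclass(frozen=True)
class VonMises:
    """Von Mises distribution with concentration ``kappa >= 0`` and center angle."""

    concentration: float
    center: float = 0.0

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        object.__setattr__(self, "center", float(wrap_angle(self.center)))


def bessel_ratio(n: int, kappa: float) -> float:
    """Overflow-safe modified Bessel ratio ``I_n(kappa) / I_0(kappa)``."""
    return float(ive(n, kappa) / ive(0, kappa))


def von_mises_pdf(beta, vm: VonMises):
    """Normalized density; ``kappa = 0`` gives the uniform density ``1/(2 pi)``."""
    beta = np.asarray(beta, dtype=float)
    k = vm.concentration
    # exponentially scaled I0 keeps the ratio finite for large kappa
    return np.exp(k * (np.cos(beta - vm.center) - 1.0)) / (TWO_PI * ive(0, k))


def circular_moment(n: int, vm: VonMises) -> complex:
    """nth circular moment ``<e^{i n beta}> = (I_n / I_0)(kappa) e^{i n center}``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return complex(1.0)
    return bessel_ratio(n, vm.concentration) * np.exp(1j * n * vm.center)


def tuning_mean(theta, amplitude: float, vm: VonMises):
    """Trial-averaged tuning curve ``<U>(theta) = A (I1/I0)(kappa) cos(theta)``.

    Requires the stimulus-aligned frame (``center == 0``).  The mean amplitude
    grows monotonically with ``kappa`` and vanishes for ``kappa = 0`` where the
    bump position is uniform on the ring.
    """
    _require_centered(vm)
    return amplitude * bessel_ratio(1, vm.concentration) * np.cos(np.asarray(theta, dtype=float))


def tuning_variance(theta, amplitude: float, vm: VonMises):
    """Variance tuning of ``A cos(theta + beta)`` under the von Mises phase.

    var(U) = (A^2/2) { 1 - r1^2 - [r1^2 - r2] cos(2 theta) },  r_n = I_n/I_0.

    Flat at ``A^2/2`` for ``kappa = 0``; M-shaped for ``kappa > 0`` with maxima
    at ``theta = +/- pi/2`` and a minimum at the pinned direction.
    """
    _require_centered(vm)
    theta = np.asarray(theta, dtype=float)
    r1 = bessel_ratio(1, vm.concentration)
    r2 = bessel_ratio(2, vm.concentration)
    return 0.5 * amplitude**2 * (1.0 - r1**2 - (r1**2 - r2) * np.cos(2.0 * theta))


def firing_rate_variance(
    theta, amplitude: float, vm: VonMises, params: RingParams, n_quad: int = 2048
):
    """Variance of the firing rate ``f(A cos(theta + beta))`` by quadrature in beta."""
    _require_centered(vm)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    beta = -np.pi + TWO_PI / n_quad * np.arange(n_quad)
    w = von_mises_pdf(beta, vm) * TWO_PI / n_quad
    rates = firing_rate(amplitude * np.cos(theta[:, None] + beta[None, :]), params)
    mean = rates @ w
    second = (rates**2) @ w
    return np.clip(second - mean**2, 0.0, None)


def _require_centered(vm: VonMises) -> None:
    if vm.center != 0.0:
        raise ValueError("tuning statistics assume the stimulus-aligned frame (center = 0)")


# ---------------------------------------------------------------------------
# bivariate cosine model


def _series_sum_scaled(kappa1: float, kappa2: float, chi: float) -> float:
    """Bessel product series with each factor exponentially scaled.

    For the density ``exp(k1 cos b1 + k2 cos b2 + chi cos(b1 - b2))`` the
    cosine-addition expansion gives ``N/(2 pi)^2 = sum_s eps_s I_s(k1) I_s(k2)
    I_s(chi)`` with positive coefficients (``eps_0 = 1``, ``eps_s = 2``); an
    alternating form applies only to the sign convention with a negative
    interaction term, since ``I_s(-chi) = (-1)^s I_s(chi)``.
    """
    total = float(ive(0, kappa1) * ive(0, kappa2) * ive(0, chi))
    streak = 0
    for s in range(1, _SERIES_MAX_TERMS + 1):
        term = 2.0 * float(ive(s, kappa1) * ive(s, kappa2) * ive(s, chi))
        total += term
        if abs(term) < _SERIES_RTOL * abs(total):
            streak += 1
            if streak >= _SERIES_STREAK:
                return total
        else:
            streak = 0
    raise RuntimeError("bivariate normalization series did not converge")


def bivariate_log_normalization(kappa1: float, kappa2: float, chi: float) -> float:
    """``log N`` with ``N = iint exp(k1 cos b1 + k2 cos b2 + chi cos(b1-b2)) db1 db2``."""
    if kappa1 < 0 or kappa2 < 0:
        raise ValueError("kappa parameters must be >= 0")
    scaled = _series_sum_scaled(kappa1, kappa2, chi)
    return math.log(scaled) + kappa1 + kappa2 + abs(chi) + 2.0 * math.log(TWO_PI)


def bivariate_normalization(kappa1: float, kappa2: float, chi: float) -> float:
    """Normalization constant via the adaptive Bessel product series.

    Equals ``(2 pi)^2 [I0(k1) I0(k2) I0(chi) + 2 sum_s I_s(k1) I_s(k2)
    I_s(chi)]`` (signed Bessel values carry any negative ``chi``) and agrees
    with 2-D periodic quadrature of the unnormalized density to high relative
    accuracy.
    """
    return math.exp(bivariate_log_normalization(kappa1, kappa2, chi))


@dataclass(frozen=True)
class BivariateCosineModel:
    """Cosine-model bivariate von Mises with precomputed log-normalization."""

    kappa1: float
    kappa2: float
    chi: float
    log_normalization: float = field(init=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self,
            "log_normalization",
            bivariate_log_normalization(self.kappa1, self.kappa2, self.chi),
        )

    @property
    def normalization(self) -> float:
        return math.exp(self.log_normalization)


def bivariate_pdf(beta1, beta2, model: BivariateCosineModel):
    """Joint stationary phase density on the torus."""
    b1 = np.asarray(beta1, dtype=float)
    b2 = np.asarray(beta2, dtype=float)
    expo = (
        model.kappa1 * np.cos(b1)
        + model.kappa2 * np.cos(b2)
        + model.chi * np.cos(b1 - b2)
        - model.log_normalization
    )
    return np.exp(expo)


def bivariate_marginal(beta1, model: BivariateCosineModel):
    """Marginal density of ``beta1``: ``2 pi e^{k1 cos b1} I0(R(b1)) / N``.

    Integrating the ``beta2``-dependent exponent ``k2 cos b2 + chi cos(b1 - b2)``
    gives a Bessel factor with resultant ``R(b1)^2 = k2^2 + chi^2 +
    2 k2 chi cos(b1)``; the remaining exponential carries ``kappa1``.  (Note
    the index pairing: the Bessel resultant takes the concentration of the
    integrated-out variable.  The tests validate this closed form against
    direct quadrature of the joint density.)
    """
    b1 = np.asarray(beta1, dtype=float)
    resultant = np.sqrt(
        model.kappa2**2 + model.chi**2 + 2.0 * model.kappa2 * model.chi * np.cos(b1)
    )
    log_p = (
        math.log(TWO_PI)
        + model.kappa1 * np.cos(b1)
        + resultant
        + np.log(ive(0, resultant))
        - model.log_normalization
    )
    return np.exp(log_p)


def modality(kappa1: float, kappa2: float, chi: float, tol: float = 1e-12) -> str:
    """Classify the joint density: 'unimodal', 'bimodal' or 'boundary'.

    Unimodal iff ``-chi < kappa1 kappa2 / (kappa1 + kappa2)`` (in particular
    for any ``chi >= 0``); bimodal when the reverse strict inequality holds
    together with ``kappa1, kappa2 > -chi``.
    """
    if kappa1 <= 0 or kappa2 <= 0:
        raise ValueError("modality requires kappa1, kappa2 > 0")
    harmonic = kappa1 * kappa2 / (kappa1 + kappa2)
    if abs(-chi - harmonic) <= tol:
        return "boundary"
    if -chi < harmonic:
        return "unimodal"
    if kappa1 > -chi and kappa2 > -chi:
        return "bimodal"
    return "unimodal"


@dataclass(frozen=True)
class GaussianApprox:
    """Large-concentration Gaussian approximation ``(b1, b2) ~ N2(0, Sigma)``."""

    covariance: np.ndarray

    def pdf(self, beta1, beta2):
        b1 = np.asarray(beta1, dtype=float)
        b2 = np.asarray(beta2, dtype=float)
        prec = np.linalg.inv(self.covariance)
        det = np.linalg.det(self.covariance)
        quad = (
            prec[0, 0] * b1**2 + 2.0 * prec[0, 1] * b1 * b2 + prec[1, 1] * b2**2
        )
        return np.exp(-0.5 * quad) / (TWO_PI * math.sqrt(det))


def gaussian_approx(kappa1: float, kappa2: float, chi: float) -> GaussianApprox:
    """Covariance of the Gaussian limit.

    ``Sigma = [[k2 + chi, chi], [chi, k1 + chi]] / (k1 k2 + chi (k1 + k2))``,
    the inverse of the precision ``[[k1 + chi, -chi], [-chi, k2 + chi]]``.
    For ``chi = 0`` this is ``diag(1/k1, 1/k2)``; positive coupling shrinks
    the per-network variance below ``1/kappa``.
    """
    denom = kappa1 * kappa2 + chi * (kappa1 + kappa2)
    if denom <= 0:
        raise ValueError("Gaussian approximation requires a positive-definite covariance")
    sigma = np.array([[kappa2 + chi, chi], [chi, kappa1 + chi]]) / denom
    if sigma[0, 0] <= 0 or np.linalg.det(sigma) <= 0:
        raise ValueError("Gaussian approximation requires a positive-definite covariance")
    return GaussianApprox(covariance=sigma)


# ---------------------------------------------------------------------------
# 2-D quadrature machinery


def _torus_grid(n: int) -> np.ndarray:
    """Endpoint-free uniform grid on [-pi, pi); rectangle rule is spectrally
    accurate for smooth periodic integrands."""
    return -np.pi + TWO_PI / n * np.arange(n)


class BivariateMoments(NamedTuple):
    cos1: float
    sin1: float
    cos2_1: float  # <cos 2 beta1>
    cos1cos2: float
    sin1sin2: float
    norm: float  # quadrature estimate of the normalization


def bivariate_moments(
    kappa1: float,
    kappa2: float,
    chi: float,
    phi: Callable | None = None,
    bias2: float = 0.0,
    n_quad: int = N_QUAD_2D,
) -> BivariateMoments:
    """Moments of ``exp(k1 cos b1 + k2 cos(b2 + bias2) + chi * c(b1 - b2))``.

    ``c`` is ``cos`` by default or a supplied even potential ``phi``.  All
    moments are computed by tensor quadrature on an ``n_quad x n_quad``
    periodic grid; ``norm`` is returned so callers can cross-check it against
    the Bessel series.
    """
    b = _torus_grid(n_quad)
    diff = b[:, None] - b[None, :]
    pot = np.cos(diff) if phi is None else np.asarray(phi(diff), dtype=float)
    # peel the peak off the exponent to avoid overflow at large concentrations
    expo = kappa1 * np.cos(b)[:, None] + kappa2 * np.cos(b + bias2)[None, :] + chi * pot
    peak = expo.max()
    w = np.exp(expo - peak)
    z = w.sum()
    cos1 = float((np.cos(b)[:, None] * w).sum() / z)
    sin1 = float((np.sin(b)[:, None] * w).sum() / z)
    cos2_1 = float((np.cos(2.0 * b)[:, None] * w).sum() / z)
    cos1cos2 = float(((np.cos(b)[:, None] * np.cos(b)[None, :]) * w).sum() / z)
    sin1sin2 = float(((np.sin(b)[:, None] * np.sin(b)[None, :]) * w).sum() / z)
    norm = float(z * (TWO_PI / n_quad) ** 2 * math.exp(min(peak, 700.0)))
    return BivariateMoments(cos1, sin1, cos2_1, cos1cos2, sin1sin2, norm)


class TuningStats(NamedTuple):
    theta: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    correlation: np.ndarray


def model_a_tuning_stats(
    theta,
    amplitude: float,
    model: BivariateCosineModel,
    n_quad: int = N_QUAD_2D,
) -> TuningStats:
    """Mean, variance and inter-network correlation tuning for a symmetric pair.

    Assembled from 2-D quadrature moments of the joint density:

        <U1>(th)  = A <cos b1> cos(th)
        var(U1)   = (A^2/2) [1 - <cos b1>^2 - (<cos b1>^2 - <cos 2 b1>) cos 2th]
        cov(th)   = (A^2/2) [<s1 s2> + <c1 c2> - <c1><c2>]
                    - (A^2/2) [<s1 s2> - (<c1 c2> - <c1><c2>)] cos 2th
        corr(th)  = cov(th) / var(U1)            (symmetric case)

    At ``chi = 0`` the mean/variance reduce exactly to the single-ring forms
    and the correlation vanishes identically.
    """
    if model.kappa1 != model.kappa2:
        raise ValueError("model A tuning statistics assume the symmetric case kappa1 = kappa2")
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    m = bivariate_moments(model.kappa1, model.kappa2, model.chi, n_quad=n_quad)
    mean = amplitude * m.cos1 * np.cos(theta)
    cos2t = np.cos(2.0 * theta)
    half_a2 = 0.5 * amplitude**2
    variance = half_a2 * (1.0 - m.cos1**2 - (m.cos1**2 - m.cos2_1) * cos2t)
    cov_c = m.cos1cos2 - m.cos1**2
    covariance = half_a2 * (m.sin1sin2 + cov_c) - half_a2 * (m.sin1sin2 - cov_c) * cos2t
    with np.errstate(invalid="ignore", divide="ignore"):
        correlation = np.where(variance > 0, covariance / variance, 0.0)
    return TuningStats(theta=theta, mean=mean, variance=variance, correlation=correlation)


@dataclass(frozen=True)
class ModelBDensity:
    """Generalized stationary density ``exp(kappa cos(b1 + bias1) + kappa
    cos(b2 + bias2) + chi phi(b1 - b2)) / M`` with tabulated potential."""

    kappa: float
    chi: float
    bias1: float
    bias2: float
    phi: Callable
    normalization: float

    def pdf(self, beta1, beta2):
        b1 = np.asarray(beta1, dtype=float)
        b2 = np.asarray(beta2, dtype=float)
        expo = (
            self.kappa * np.cos(b1 + self.bias1)
            + self.kappa * np.cos(b2 + self.bias2)
            + self.chi * np.asarray(self.phi(b1 - b2), dtype=float)
        )
        return np.exp(expo) / self.normalization


class SurroundStats(NamedTuple):
    surround_bias: np.ndarray
    mean: np.ndarray  # normalized center mean <cos beta1>
    variance: np.ndarray  # normalized center variance var(U1)/A^2 at theta = pi/2


def model_b_center_stats(
    surround_bias,
    kappa: float,
    chi: float,
    phi: Callable,
    n_quad: int = 240,
) -> SurroundStats:
    """Center-network statistics versus the surround stimulus bias.

    Network 1 (center) is pinned at bias 0; network 2 (surround) at each
    requested bias.  For every bias the density ``exp(kappa cos b1 +
    kappa cos(b2 + bias) + chi phi(b1 - b2))`` is normalized by 2-D quadrature
    and the normalized mean ``<cos b1>`` and peak normalized variance
    ``var(U1)/A^2 = (1 - <cos 2 b1>)/2`` (at ``theta = pi/2``) are assembled.

    Facilitation/suppression crossover: relative to the decoupled baseline,
    ``chi < 0`` raises the center variance for aligned stimuli and lowers it
    for opposed stimuli; ``chi > 0`` reverses the pattern, moving opposite to
    the mean in both cases.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    biases = np.atleast_1d(np.asarray(surround_bias, dtype=float))
    b = _torus_grid(n_quad)
    diff = b[:, None] - b[None, :]
    left = np.exp(kappa * np.cos(b))[:, None] * np.exp(
        chi * np.asarray(phi(diff), dtype=float) - abs(chi) * _phi_scale(phi)
    )
    cos1 = np.cos(b)
    cos2_1 = np.cos(2.0 * b)
    means = np.empty_like(biases)
    variances = np.empty_like(biases)
    for i, tb in enumerate(biases):
        right = np.exp(kappa * np.cos(b + tb))
        col = left @ right
        z = col.sum()
        m1 = float(cos1 @ col / z)
        m2 = float(cos2_1 @ col / z)
        means[i] = m1
        variances[i] = 0.5 * (1.0 - m2)
    return SurroundStats(surround_bias=biases, mean=means, variance=variances)


def _phi_scale(phi: Callable) -> float:
    """Rough magnitude of the potential, used only to keep exponents bounded."""
    probe = np.linspace(-np.pi, np.pi, 64)
    return float(np.max(np.abs(np.asarray(phi(probe), dtype=float))))
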