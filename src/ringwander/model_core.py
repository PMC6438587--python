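"""Ring-network model core: parameter types, sigmoidal rate, stationary bumps.

A ring network is a population of rate neurons indexed by a preferred angle
``theta`` on ``[-pi, pi)`` with rotation-symmetric cosine recurrent weights
``J(theta) = J_bar * cos(theta)``.  In the marginal regime the network
supports a stationary "bump" ``U(theta) = A cos(theta)`` whose amplitude
solves the scalar self-consistency condition

    A = J_bar * g(A),      g(A) = int_{-pi}^{pi} cos(theta) f(A cos(theta)) dtheta.

This module solves that condition, classifies linear stability of each root
and exposes the discretized linearized operator used for cross-validation of
the analytic eigenvalues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "NoBumpError",
    "RingParams",
    "StimulusParams",
    "NoiseParams",
    "CouplingParams",
    "RingGrid",
    "BumpSolution",
    "wrap_angle",
    "firing_rate",
    "firing_rate_deriv",
    "bump_overlap",
    "solve_bump",
    "stable_bump",
    "stability_eigenvalues",
    "discretized_linear_operator",
]

TWO_PI = 2.0 * math.pi

#: lambda_even within this band of zero is reported as marginal, not stable
MARGINAL_TOL = 1e-8

#: roots of the self-consistency condition closer than this are merged
ROOT_MERGE_TOL = 1e-6


class NoBumpError(RuntimeError):
    """Raised when an operation requires a nonzero bump and none exists."""


def wrap_angle(x):
    """Wrap angle(s) to the half-open interval ``[-pi, pi)``."""
    return np.mod(np.asarray(x) + np.pi, TWO_PI) - np.pi


@dataclass(frozen=True)
class RingParams:
    """Intrinsic parameters of a single ring network.

    Attributes
    ----------
    weight_amplitude : float
        Amplitude ``J_bar`` of the cosine recurrent kernel (>= 0).
    gain, threshold, max_rate : float
        Sigmoid rate parameters: ``f(u) = max_rate / (1 + exp(-gain*(u - threshold)))``.
        The analysis-facing convention is ``max_rate = 1`` (dimensionless rate);
        a physical spikes/sec scale is a display-only rescaling.
    time_constant : float
        Membrane/population time constant in milliseconds.  Dynamics are
        integrated in units of the time constant, so it only enters when
        labelling outputs in physical time.
    """

    weight_amplitude: float = 1.0
    gain: float = 4.0
    threshold: float = 0.5
    max_rate: float = 1.0
    time_constant: float = 10.0

    def __post_init__(self) -> None:
        if self.weight_amplitude < 0:
            raise ValueError("weight_amplitude must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.max_rate <= 0:
            raise ValueError("max_rate must be > 0")
        if self.time_constant <= 0:
            raise ValueError("time_constant must be > 0")


@dataclass(frozen=True)
class StimulusParams:
    """External input ``h(theta) = contrast * cos(theta - bias)``."""

    contrast: float = 0.0
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")
        object.__setattr__(self, "bias", float(wrap_angle(self.bias)))


@dataclass(frozen=True)
class NoiseParams:
    """Spatially structured additive noise.

    The noise increment has spatial correlation
    ``C(theta) = white_weight * delta(theta) + cosine_weight * cos(theta)``
    and the field equations scale both the noise and the weak inputs by
    ``epsilon``.

    ``white_convention`` fixes the discretization of the delta part on a grid
    with spacing ``dtheta``:

    - ``"per_point"`` (default): independent per-grid-point increments of
      variance ``white_weight * dt``, i.e. an effective continuum correlation
      weight ``white_weight * dtheta``.  This is the reading under which the
      worked wandering-bump simulations stay in the weak-fluctuation regime.
    - ``"dirac"``: variance ``white_weight * dt / dtheta``, the literal
      continuum delta.  Note the delta-correlated part makes the field
      spatially discontinuous, so per-point fluctuations grow without bound
      as the grid is refined; use small weights with this convention.
    """

    epsilon: float = 0.05
    white_weight: float = 0.0
    cosine_weight: float = 0.0
    white_convention: str = "per_point"

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.white_weight < 0 or self.cosine_weight < 0:
            raise ValueError("noise weights must be >= 0 (PSD covariance)")
        if self.white_convention not in ("per_point", "dirac"):
            raise ValueError("white_convention must be 'per_point' or 'dirac'")

    def effective_white_weight(self, spacing: float) -> float:
        """Continuum delta-correlation weight implied on a grid of given spacing."""
        if self.white_convention == "per_point":
            return self.white_weight * spacing
        return self.white_weight


@dataclass(frozen=True)
class CouplingParams:
    """Inter-network coupling kernel.

    ``model='A'``: vertical/inter-laminar kernel ``E + K_bar cos(theta)``.
    ``model='B'``: horizontal like-to-like delta kernel ``K_bar delta(theta)``.
    ``model='none'``: both components are zeroed.
    """

    model: str = "none"
    uniform_component: float = 0.0
    modulated_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("A", "B", "none"):
            raise ValueError("coupling model must be 'A', 'B' or 'none'")
        if self.model == "none":
            object.__setattr__(self, "uniform_component", 0.0)
            object.__setattr__(self, "modulated_amplitude", 0.0)


@dataclass(frozen=True)
class RingGrid:
    """Equispaced periodic grid ``theta_i = -pi + i * spacing`` on ``[-pi, pi)``.

    The default ``n_points = 200`` corresponds to an angular step of
    ``0.01 * pi``.  On this grid the composite trapezoidal rule for periodic
    integrands collapses to ``spacing * sum(...)`` and is spectrally accurate.
    """

    n_points: int = 200

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")

    @property
    def spacing(self) -> float:
        return TWO_PI / self.n_points

    @property
    def angles(self) -> np.ndarray:
        return -np.pi + self.spacing * np.arange(self.n_points)

    def quad(self, values: np.ndarray, axis: int = -1) -> np.ndarray:
        """Periodic trapezoidal quadrature over the ring."""
        return np.sum(values, axis=axis) * self.spacing


def firing_rate(u, params: RingParams):
    """Sigmoid firing rate ``f(u) = f0 / (1 + exp(-gain*(u - threshold)))``."""
    return params.max_rate * expit(params.gain * (np.asarray(u, dtype=float) - params.threshold))


def firing_rate_deriv(u, params: RingParams):
    """Derivative ``f'(u)`` of the sigmoid rate."""
    s = expit(params.gain * (np.asarray(u, dtype=float) - params.threshold))
    return params.max_rate * params.gain * s * (1.0 - s)


def bump_overlap(amplitude: float, params: RingParams, grid: RingGrid | None = None) -> float:
    """First cosine moment ``g(A) = int cos(theta) f(A cos(theta)) dtheta``."""
    grid = grid or RingGrid()
    th = grid.angles
    return float(grid.quad(np.cos(th) * firing_rate(amplitude * np.cos(th), params)))


@dataclass(frozen=True)
class BumpSolution:
    """A root of the bump self-consistency condition with its stability data.

    Attributes
    ----------
    amplitude : float
        Bump amplitude ``A`` (0 for the spatially uniform solution).
    params : RingParams
        Network the bump was solved for (needed by ``profile``/``adjoint_null``).
    gamma_norm : float
        Normalization ``Gamma = -A * int f'(U) sin^2(theta) dtheta`` of the
        phase projection (strictly negative for a nonzero bump; analytically
        equal to ``-A / J_bar``).
    lambda_zero, lambda_even : float
        Leading eigenvalues of the linearization: the marginal translation
        mode (exactly 0 for a nonzero bump) and the even expansion mode.
        For the zero solution both entries hold the degenerate first-harmonic
        eigenvalue of the uniform state.
    is_stable : bool
        ``lambda_even < 0`` beyond the marginal tolerance.
    """

    amplitude: float
    params: RingParams
    gamma_norm: float
    lambda_zero: float
    lambda_even: float
    is_stable: bool
    residual: float = field(default=0.0, compare=False)

    @property
    def is_zero(self) -> bool:
        return self.amplitude == 0.0

    def profile(self, theta) -> np.ndarray:
        """Stationary profile ``U(theta) = A cos(theta)``."""
        return self.amplitude * np.cos(np.asarray(theta, dtype=float))

    def adjoint_null(self, theta) -> np.ndarray:
        """Adjoint null vector ``V(theta) = f'(U(theta)) sin(theta)``."""
        theta = np.asarray(theta, dtype=float)
        return firing_rate_deriv(self.profile(theta), self.params) * np.sin(theta)

    def as_record(self) -> dict:
        """Flat key-value export (one CSV row / JSON object)."""
        return {
            "amplitude": self.amplitude,
            "weight_amplitude": self.params.weight_amplitude,
            "gain": self.params.gain,
            "threshold": self.params.threshold,
            "max_rate": self.params.max_rate,
            "gamma_norm": self.gamma_norm,
            "lambda_zero": self.lambda_zero,
            "lambda_even": self.lambda_even,
            "is_stable": self.is_stable,
            "residual": self.residual,
        }


def stability_eigenvalues(
    bump: "BumpSolution | float",
    params: RingParams,
    n_quad: int = 4001,
) -> tuple[float, float]:
    """Leading eigenvalues ``(lambda_zero, lambda_even)`` of the linearization.

    For a nonzero bump the translation eigenvalue is zero by construction and
    the even (expansion) eigenvalue is

        lambda_even = 2 * [ J_bar * int_0^pi f'(U(theta)) dtheta - 1 ].

    For the zero state the two first-harmonic modes are degenerate with
    eigenvalue ``pi * J_bar * f'(0) - 1``, returned in both slots.
    """
    amplitude = bump.amplitude if isinstance(bump, BumpSolution) else float(bump)
    jbar = params.weight_amplitude
    if amplitude == 0.0:
        lam = math.pi * jbar * float(firing_rate_deriv(0.0, params)) - 1.0
        return lam, lam
    th = np.linspace(0.0, math.pi, n_quad)
    integral = np.trapezoid(firing_rate_deriv(amplitude * np.cos(th), params), th)
    lam_e = 2.0 * (jbar * float(integral) - 1.0)
    return 0.0, lam_e


def _classify(amplitude: float, params: RingParams, grid: RingGrid, residual: float) -> BumpSolution:
    lam0, lam_e = stability_eigenvalues(amplitude, params)
    if amplitude == 0.0:
        gamma = 0.0
        stable = lam_e < -MARGINAL_TOL
    else:
        th = grid.angles
        gamma = -amplitude * float(
            grid.quad(firing_rate_deriv(amplitude * np.cos(th), params) * np.sin(th) ** 2)
        )
        stable = lam_e < -MARGINAL_TOL
    return BumpSolution(
        amplitude=amplitude,
        params=params,
        gamma_norm=gamma,
        lambda_zero=lam0,
        lambda_even=lam_e,
        is_stable=stable,
        residual=residual,
    )


def solve_bump(
    params: RingParams,
    tol: float = 1e-10,
    scan_max: float = 10.0,
    grid: RingGrid | None = None,
    n_brackets: int = 400,
) -> list[BumpSolution]:
    """Find all stationary bump amplitudes of a single ring network.

    Roots of ``F(A) = A - J_bar * g(A)`` on ``(0, scan_max]`` are located by a
    uniform sign-change scan with ``n_brackets`` brackets and refined by
    Brent's method to ``|F(A)| < tol``.  The trivial ``A = 0`` solution is
    always included first (``is_zero`` flag) with its own stability
    classification.  Near-duplicate roots are merged.

    Returns
    -------
    list of BumpSolution
        Zero solution first, then nonzero roots in ascending amplitude.
    """
    if scan_max <= 0:
        raise ValueError("scan_max must be > 0")
    grid = grid or RingGrid()

    def residual_fn(a: float) -> float:
        return a - params.weight_amplitude * bump_overlap(a, params, grid)

    solutions = [_classify(0.0, params, grid, residual=0.0)]
    if params.weight_amplitude == 0.0:
        return solutions

    edges = np.linspace(0.0, scan_max, n_brackets + 1)
    # skip the exact zero at A=0: start the scan just inside the first bracket
    edges[0] = scan_max / n_brackets * 1e-6
    values = np.array([residual_fn(a) for a in edges])
    roots: list[float] = []
    for lo, hi, flo, fhi in zip(edges[:-1], edges[1:], values[:-1], values[1:]):
        if flo == 0.0:
            roots.append(float(lo))
        elif flo * fhi < 0.0:
            roots.append(float(brentq(residual_fn, lo, hi, xtol=tol, rtol=8.9e-16)))
    merged: list[float] = []
    for r in sorted(roots):
        if not merged or abs(r - merged[-1]) > ROOT_MERGE_TOL:
            merged.append(r)
    for r in merged:
        solutions.append(_classify(r, params, grid, residual=abs(residual_fn(r))))
    return solutions


def stable_bump(params: RingParams, grid: RingGrid | None = None, **kwargs) -> BumpSolution:
    """Largest stable nonzero bump, raising :class:`NoBumpError` if absent."""
    candidates = [
        s for s in solve_bump(params, grid=grid, **kwargs) if not s.is_zero and s.is_stable
    ]
    if not candidates:
        raise NoBumpError(
            "no nonzero stable bump (weight amplitude too small for this gain/threshold?)"
        )
    return max(candidates, key=lambda s: s.amplitude)


def discretized_linear_operator(
    bump: BumpSolution,
    params: RingParams,
    grid: RingGrid | None = None,
) -> np.ndarray:
    """Matrix of the linearized dynamics about a bump on a periodic grid.

    Discretizes ``(M psi)(theta) = -psi(theta) + int J(theta - theta')
    f'(U(theta')) psi(theta') dtheta'`` with trapezoidal weights.  Its two
    leading eigenvalues approximate ``(lambda_zero, lambda_even)``; all
    remaining eigenvalues sit at -1 (the essential spectrum).
    """
    grid = grid or RingGrid()
    th = grid.angles
    kernel = params.weight_amplitude * np.cos(th[:, None] - th[None, :])
    fprime = firing_rate_deriv(bump.profile(th), params)
    return -np.eye(grid.n_points) + kernel * fprime[None, :] * grid.spacing
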