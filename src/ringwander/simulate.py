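"""Stochastic simulation of the field equations and the reduced phase SDEs.

The field integrator is Euler-Maruyama in time (default step 0.001 in units
of the network time constant) with periodic trapezoidal quadrature for the
ring convolutions, matching the analytic conventions of the other modules:

    du = [-u + J * f(u) + eps K * f(u_other) + eps h] dt + sqrt(2 eps) dW

The spatially structured noise increment ``dW`` with correlation
``a delta(theta) + b cos(theta)`` is sampled exactly as independent white
terms plus a rank-2 shared cosine/sine pair.  Phases are read out from the
first circular harmonic of each snapshot.

Reproducibility: every run derives its generator from a single master seed
via ``numpy.random.SeedSequence(seed)``; vectorized ensembles draw all
realizations from that one stream, so identical seeds give bitwise-identical
trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_core import (
    CouplingParams,
    NoBumpError,
    NoiseParams,
    RingGrid,
    RingParams,
    StimulusParams,
    firing_rate,
    stable_bump,
    wrap_angle,
)
from .phase_reduction import PhaseReduction
from .circular_stats import VonMises, von_mises_pdf

__all__ = [
    "FieldTrajectory",
    "FieldEnsemble",
    "PhaseTrajectory",
    "EnsembleStats",
    "sample_noise_increment",
    "simulate_field",
    "simulate_field_ensemble",
    "extract_phase",
    "simulate_phase_sde",
    "ensemble_stats",
    "unwrap_increments",
    "tv_to_von_mises",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class FieldTrajectory:
    """Single-realization field simulation output.

    ``activity`` has shape ``(n_networks, n_records, n_points)`` and
    ``phases`` shape ``(n_networks, n_records)``; times are in units of the
    network time constant and uniformly spaced by the recording interval.
    """

    grid: RingGrid
    times: np.ndarray
    activity: np.ndarray
    phases: np.ndarray
    seed: int
    config: dict


@dataclass(frozen=True)
class FieldEnsemble:
    """Vectorized multi-realization field run with per-angle pooled statistics.

    ``phases`` has shape ``(n_realizations, n_networks, n_records)``.  The
    per-angle mean/variance of ``u`` and ``f(u)`` pool recorded snapshots of
    all realizations after the burn-in.
    """

    grid: RingGrid
    times: np.ndarray
    phases: np.ndarray
    u_mean: np.ndarray
    u_var: np.ndarray
    rate_mean: np.ndarray
    rate_var: np.ndarray
    n_pooled: int
    seed: int
    config: dict


@dataclass(frozen=True)
class PhaseTrajectory:
    """Reduced-SDE simulation output; phases wrapped to ``[-pi, pi)``."""

    times: np.ndarray
    phases: np.ndarray  # (n_realizations, n_networks, n_records)
    seed: int
    config: dict


@dataclass(frozen=True)
class EnsembleStats:
    """Pooled circular summary of a set of phase samples."""

    n_realizations: int
    n_pooled: int
    first_moment: complex
    resultant_length: float
    circular_mean: float
    bin_edges: np.ndarray
    hist_density: np.ndarray


def sample_noise_increment(
    grid: RingGrid,
    noise: NoiseParams,
    dt: float,
    rng: np.random.Generator,
    size: tuple | None = None,
) -> np.ndarray:
    """Sample ``dW`` over the grid: white per-point terms plus a rank-2 cosine part.

    The covariance is ``(a_eff/dtheta) delta_ij dt + b cos(th_i - th_j) dt``
    where ``a_eff = noise.effective_white_weight(dtheta)`` (so under the
    ``"dirac"`` convention the per-point variance is ``a dt / dtheta``, the
    grid discretization of a Dirac delta, and under ``"per_point"`` it is
    ``a dt``).  The cosine part is realized exactly as ``sqrt(b dt)
    (xi_c cos theta + xi_s sin theta)`` with two shared standard normals,
    the low-rank decomposition of the cosine kernel.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    shape = (grid.n_points,) if size is None else tuple(size) + (grid.n_points,)
    th = grid.angles
    out = np.zeros(shape)
    if noise.white_weight > 0:
        var = noise.effective_white_weight(grid.spacing) * dt / grid.spacing
        out += math.sqrt(var) * rng.standard_normal(shape)
    if noise.cosine_weight > 0:
        amp_shape = shape[:-1] + (1,)
        xi_c = rng.standard_normal(amp_shape)
        xi_s = rng.standard_normal(amp_shape)
        out += math.sqrt(noise.cosine_weight * dt) * (xi_c * np.cos(th) + xi_s * np.sin(th))
    return out


def extract_phase(snapshot, grid: RingGrid | None = None, min_amplitude: float = 1e-8):
    """Bump phase from the first circular harmonic of a field snapshot.

    ``beta_hat = -arg( sum_i u(theta_i) e^{i theta_i} dtheta )``; exact (to
    machine precision) for ``u = A cos(theta + beta)`` and insensitive to
    higher harmonics by orthogonality.  Raises :class:`NoBumpError` when the
    first-harmonic amplitude falls below ``min_amplitude``.
    """
    grid = grid or RingGrid()
    u = np.asarray(snapshot, dtype=float)
    z = (u * np.exp(1j * grid.angles)).sum(axis=-1) * grid.spacing
    if np.any(np.abs(z) < min_amplitude):
        raise NoBumpError("no bump: first-harmonic amplitude below threshold")
    return -np.angle(z)


def _as_list(x, cls):
    return [x] if isinstance(x, cls) else list(x)


def _sigmoid_rates(u: np.ndarray, rings: list[RingParams]) -> np.ndarray:
    """Sigmoid rate of the full state, inlined for the hot loop (``u`` is
    (n_nets, R, N); parameters may differ per network)."""
    out = np.empty_like(u)
    with np.errstate(over="ignore"):  # exp overflow saturates the sigmoid at 0
        for j, r in enumerate(rings):
            np.exp(-r.gain * (u[j] - r.threshold), out=out[j])
            out[j] += 1.0
            np.divide(r.max_rate, out[j], out=out[j])
    return out


def _field_drift_factory(
    rings: list[RingParams],
    stimuli: list[StimulusParams],
    coupling: CouplingParams,
    epsilon: float,
    grid: RingGrid,
):
    """Build the deterministic RHS acting on state ``u`` of shape (n_nets, R, N)."""
    th = grid.angles
    cos_t, sin_t = np.cos(th), np.sin(th)
    n_nets = len(rings)
    inputs = [epsilon * s.contrast * np.cos(th - s.bias) for s in stimuli]

    def drift(u: np.ndarray) -> np.ndarray:
        rates = _sigmoid_rates(u, rings)
        out = np.empty_like(u)
        for j in range(n_nets):
            r = rates[j]
            mc = (r @ cos_t) * (rings[j].weight_amplitude * grid.spacing)
            ms = (r @ sin_t) * (rings[j].weight_amplitude * grid.spacing)
            out[j] = mc[:, None] * cos_t
            out[j] += ms[:, None] * sin_t
            out[j] -= u[j]
            out[j] += inputs[j]
            if n_nets == 2 and coupling.model != "none":
                ro = rates[1 - j]
                if coupling.model == "A":
                    oc = (ro @ cos_t) * grid.spacing
                    os_ = (ro @ sin_t) * grid.spacing
                    total = ro.sum(axis=-1) * grid.spacing
                    cross = coupling.uniform_component * total[:, None] + (
                        coupling.modulated_amplitude * (oc[:, None] * cos_t + os_[:, None] * sin_t)
                    )
                else:  # delta kernel acts pointwise: K_bar * f(u_other(theta))
                    cross = coupling.modulated_amplitude * ro
                out[j] += epsilon * cross
        return out

    return drift


def _integrate_field(
    rings: list[RingParams],
    stimuli: list[StimulusParams],
    noise: NoiseParams | None,
    epsilon: float,
    duration: float,
    dt: float,
    seed: int,
    grid: RingGrid,
    coupling: CouplingParams,
    n_realizations: int,
    initial_phase: float,
    record_every: float,
    burn_in: float,
    record_activity: bool,
):
    if dt > 0.01:
        raise ValueError("field integration requires dt <= 0.01 (units of the time constant)")
    n_nets = len(rings)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bumps = [stable_bump(r, grid=grid) for r in rings]
    th = grid.angles
    u = np.stack(
        [
            np.broadcast_to(b.profile(th + initial_phase), (n_realizations, grid.n_points)).copy()
            for b in bumps
        ]
    )
    drift = _field_drift_factory(rings, stimuli, coupling, epsilon, grid)
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(record_every / dt)))
    n_rec = n_steps // stride
    times = dt * stride * (1 + np.arange(n_rec))
    phases = np.empty((n_realizations, n_nets, n_rec))
    activity = (
        np.empty((n_nets, n_rec, grid.n_points)) if record_activity else None
    )
    acc_u = np.zeros((n_nets, grid.n_points))
    acc_u2 = np.zeros((n_nets, grid.n_points))
    acc_r = np.zeros((n_nets, grid.n_points))
    acc_r2 = np.zeros((n_nets, grid.n_points))
    n_pooled = 0
    # noise amplitudes including the sqrt(2 eps) field prefactor
    sig_white = sig_cos = 0.0
    if noise is not None and epsilon > 0:
        var_white = noise.effective_white_weight(grid.spacing) * dt / grid.spacing
        sig_white = math.sqrt(2.0 * epsilon * var_white)
        sig_cos = math.sqrt(2.0 * epsilon * noise.cosine_weight * dt)
    cos_t, sin_t = np.cos(th), np.sin(th)
    exp_i_th = np.exp(1j * th)
    rec = 0
    for step in range(1, n_steps + 1):
        du = drift(u)
        du *= dt
        u += du
        if sig_white > 0.0:
            white = rng.standard_normal(u.shape)
            white *= sig_white
            u += white
        if sig_cos > 0.0:
            amps = rng.standard_normal((n_nets, n_realizations, 2))
            u += sig_cos * (amps[..., :1] * cos_t + amps[..., 1:] * sin_t)
        if step % stride == 0:
            if not np.all(np.isfinite(u)):
                raise FloatingPointError(f"field blew up at t = {step * dt:g}")
            z = (u @ exp_i_th) * grid.spacing  # (n_nets, R)
            phases[:, :, rec] = -np.angle(z).T
            if record_activity:
                activity[:, rec, :] = u[:, 0, :]
            if step * dt > burn_in:
                acc_u += u.sum(axis=1)
                acc_u2 += (u**2).sum(axis=1)
                r = np.stack([firing_rate(u[j], rings[j]) for j in range(n_nets)])
                acc_r += r.sum(axis=1)
                acc_r2 += (r**2).sum(axis=1)
                n_pooled += n_realizations
            rec += 1
    if n_pooled > 0:
        u_mean = acc_u / n_pooled
        u_var = np.clip(acc_u2 / n_pooled - u_mean**2, 0.0, None)
        r_mean = acc_r / n_pooled
        r_var = np.clip(acc_r2 / n_pooled - r_mean**2, 0.0, None)
    else:
        u_mean = u_var = r_mean = r_var = np.full((n_nets, grid.n_points), np.nan)
    config = {
        "rings": [vars(r).copy() for r in rings],
        "stimuli": [vars(s).copy() for s in stimuli],
        "noise": vars(noise).copy() if noise is not None else None,
        "coupling": vars(coupling).copy(),
        "epsilon": epsilon,
        "duration": duration,
        "dt": dt,
        "seed": seed,
        "n_realizations": n_realizations,
        "record_every": record_every,
        "burn_in": burn_in,
        "initial_phase": initial_phase,
        "n_points": grid.n_points,
    }
    return times, phases, activity, (u_mean, u_var, r_mean, r_var), n_pooled, config


def simulate_field(
    rings: RingParams | Sequence[RingParams],
    stimuli: StimulusParams | Sequence[StimulusParams],
    noise: NoiseParams | None = None,
    epsilon: float | None = None,
    duration: float = 100.0,
    dt: float = 0.001,
    seed: int = 0,
    grid: RingGrid | None = None,
    coupling: CouplingParams | None = None,
    initial_phase: float = 0.0,
    record_every: float = 0.5,
) -> FieldTrajectory:
    """Single-realization Euler-Maruyama run of one or two coupled rings.

    ``duration``/``dt``/``record_every`` are in units of the time constant.
    ``epsilon`` defaults to ``noise.epsilon``; pass ``epsilon=0`` with
    ``noise=None`` for the deterministic flow (the solved bump is then a
    fixed point to quadrature accuracy).
    """
    grid = grid or RingGrid()
    ring_list = _as_list(rings, RingParams)
    stim_list = _as_list(stimuli, StimulusParams)
    if epsilon is None:
        if noise is None:
            raise ValueError("epsilon must be given when noise is None")
        epsilon = noise.epsilon
    times, phases, activity, _, _, config = _integrate_field(
        ring_list,
        stim_list,
        noise,
        epsilon,
        duration,
        dt,
        seed,
        grid,
        coupling or CouplingParams(),
        n_realizations=1,
        initial_phase=initial_phase,
        record_every=record_every,
        burn_in=duration,
        record_activity=True,
    )
    return FieldTrajectory(
        grid=grid,
        times=times,
        activity=activity,
        phases=phases[0],
        seed=seed,
        config=config,
    )


def simulate_field_ensemble(
    rings: RingParams | Sequence[RingParams],
    stimuli: StimulusParams | Sequence[StimulusParams],
    noise: NoiseParams,
    n_realizations: int,
    duration: float = 500.0,
    dt: float = 0.001,
    seed: int = 0,
    grid: RingGrid | None = None,
    coupling: CouplingParams | None = None,
    initial_phase: float = 0.0,
    record_every: float = 0.5,
    burn_in: float = 100.0,
) -> FieldEnsemble:
    """Vectorized multi-realization field run with pooled per-angle statistics."""
    grid = grid or RingGrid()
    times, phases, _, stats, n_pooled, config = _integrate_field(
        _as_list(rings, RingParams),
        _as_list(stimuli, StimulusParams),
        noise,
        noise.epsilon,
        duration,
        dt,
        seed,
        grid,
        coupling or CouplingParams(),
        n_realizations=n_realizations,
        initial_phase=initial_phase,
        record_every=record_every,
        burn_in=burn_in,
        record_activity=False,
    )
    u_mean, u_var, r_mean, r_var = stats
    return FieldEnsemble(
        grid=grid,
        times=times,
        phases=phases,
        u_mean=u_mean,
        u_var=u_var,
        rate_mean=r_mean,
        rate_var=r_var,
        n_pooled=n_pooled,
        seed=seed,
        config=config,
    )


def simulate_phase_sde(
    reductions: PhaseReduction | Sequence[PhaseReduction],
    duration: float,
    dt: float = 0.01,
    seed: int = 0,
    n_realizations: int = 1,
    initial_phases: float | Sequence[float] = 0.0,
    record_every: float = 0.5,
) -> PhaseTrajectory:
    """Euler-Maruyama integration of the reduced phase SDE(s) on the circle.

    Drift of network ``j``: ``-eps Lambda_j sin(beta_j + bias_j) -
    eps K_j(beta_j - beta_other)``; noise ``sqrt(2 eps D_j dt)`` per step.
    Phases are wrapped to ``[-pi, pi)`` after every step.
    """
    red_list = _as_list(reductions, PhaseReduction)
    n_nets = len(red_list)
    if n_nets not in (1, 2):
        raise ValueError("one or two phase reductions required")
    eps = red_list[0].epsilon
    if any(abs(r.epsilon - eps) > 1e-15 for r in red_list):
        raise ValueError("all reductions must share the same epsilon")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lam = np.array([r.drift_amplitude for r in red_list])
    bias = np.array([r.bias for r in red_list])
    sigma = np.array([math.sqrt(2.0 * eps * r.diffusion * dt) for r in red_list])
    beta = np.empty((n_nets, n_realizations))
    init = np.broadcast_to(np.atleast_1d(np.asarray(initial_phases, dtype=float)), (n_nets,))
    for j in range(n_nets):
        beta[j] = init[j]
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(record_every / dt)))
    n_rec = n_steps // stride
    times = dt * stride * (1 + np.arange(n_rec))
    phases = np.empty((n_realizations, n_nets, n_rec))
    rec = 0
    for step in range(1, n_steps + 1):
        drift = -eps * lam[:, None] * np.sin(beta + bias[:, None])
        if n_nets == 2:
            for j in (0, 1):
                kj = red_list[j].coupling_fn(wrap_angle(beta[j] - beta[1 - j]))
                drift[j] -= eps * np.asarray(kj, dtype=float)
        beta = beta + drift * dt + sigma[:, None] * rng.standard_normal(beta.shape)
        beta = wrap_angle(beta)
        if step % stride == 0:
            phases[:, :, rec] = beta.T
            rec += 1
    config = {
        "epsilon": eps,
        "drift_amplitudes": lam.tolist(),
        "diffusions": [r.diffusion for r in red_list],
        "coupling_models": [r.coupling_model for r in red_list],
        "coupling_strengths": [r.coupling_strength for r in red_list],
        "duration": duration,
        "dt": dt,
        "seed": seed,
        "n_realizations": n_realizations,
        "record_every": record_every,
    }
    return PhaseTrajectory(times=times, phases=phases, seed=seed, config=config)


def unwrap_increments(phases: np.ndarray, axis: int = -1) -> np.ndarray:
    """Unwrap a wrapped phase series: map successive increments to
    ``(-pi, pi]`` and cumulate, so diffusion estimates are wrap-free."""
    phases = np.asarray(phases, dtype=float)
    inc = np.diff(phases, axis=axis)
    inc = -wrap_angle(-inc)  # increments in (-pi, pi]
    first = np.take(phases, [0], axis=axis)
    return np.concatenate([first, first + np.cumsum(inc, axis=axis)], axis=axis)


def ensemble_stats(
    phases: np.ndarray,
    times: np.ndarray | None = None,
    burn_in: float = 0.0,
    bins: int = 36,
) -> EnsembleStats:
    """Pooled circular statistics of phase samples of shape ``(n_real, n_rec)``."""
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    if times is not None:
        keep = np.asarray(times) > burn_in
        if not np.any(keep):
            raise ValueError("empty post-burn-in window")
        phases = phases[..., keep]
    pooled = phases.reshape(-1)
    z = np.exp(1j * pooled).mean()
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    density, _ = np.histogram(pooled, bins=edges, density=True)
    return EnsembleStats(
        n_realizations=phases.shape[0],
        n_pooled=pooled.size,
        first_moment=complex(z),
        resultant_length=float(np.abs(z)),
        circular_mean=float(np.angle(z)),
        bin_edges=edges,
        hist_density=density,
    )


def tv_to_von_mises(stats: EnsembleStats, vm: VonMises, n_sub: int = 32) -> float:
    """Total-variation distance between a pooled histogram and a von Mises law.

    Analytic bin masses are computed by trapezoidal sub-quadrature of the
    density inside each bin; TV = 0.5 * sum_k |p_hat_k - p_k|.
    """
    edges = stats.bin_edges
    widths = np.diff(edges)
    emp = stats.hist_density * widths
    masses = np.empty_like(emp)
    for k in range(len(widths)):
        x = np.linspace(edges[k], edges[k + 1], n_sub + 1)
        masses[k] = np.trapezoid(von_mises_pdf(x, vm), x)
    masses /= masses.sum()
    return 0.5 * float(np.abs(emp - masses).sum())
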