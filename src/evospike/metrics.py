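"""Spike-train similarity measures.

The van Rossum distance is the L2 distance between spike trains after causal
exponential filtering; its timescale ``tau`` tunes sensitivity from
rate-level (long tau) to spike-timing-level (short tau).  With the unit-norm
kernel of :mod:`evospike.spike_trains` the squared distance has the closed
form

    d^2(u, v) = sum_ij e^{-|u_i-u_j|/tau} + sum_ij e^{-|v_i-v_j|/tau}
                - 2 sum_ij e^{-|u_i-v_j|/tau}

which is evaluated either by the O(nm) double sum (`method='brute'`) or by an
O(n+m) sorted-merge recursion (`method='efficient'`, the default).

The coincidence factor Gamma is the chance-corrected fraction of spikes
matched one-to-one within a window delta between a model and a target train;
Gamma = 1 is a perfect match at that resolution and 0 is chance level for a
homogeneous Poisson model at the target rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spike_trains import (FilteredFunction, SampledTrace, SpikeTrain,
                           TrialSet, filter_train)

__all__ = [
    "CoincidenceResult",
    "ReliabilityResult",
    "van_rossum_distance",
    "van_rossum_to_function",
    "coincidence_factor",
    "intrinsic_reliability",
    "expected_coincidence_poisson",
    "expected_van_rossum_poisson",
    "rate_filtered_on_grid",
    "train_filtered_on_grid",
]


# --------------------------------------------------------------------------
# van Rossum distance


def _self_sum_efficient(t: np.ndarray, tau: float) -> float:
    """sum_ij exp(-|t_i - t_j|/tau) for sorted t, by forward recursion."""
    n = t.size
    if n == 0:
        return 0.0
    # m_k = sum_{i<k} exp(-(t_k - t_i)/tau); m_k = (m_{k-1}+1) e^{-dt/tau}
    decay = np.exp(-np.diff(t) / tau)
    m = 0.0
    acc = 0.0
    for d in decay:
        m = (m + 1.0) * d
        acc += m
    return n + 2.0 * acc


def _cross_sum_efficient(u: np.ndarray, v: np.ndarray, tau: float) -> float:
    """sum_ij exp(-|u_i - v_j|/tau) for sorted u, v, by two-sided merge."""
    if u.size == 0 or v.size == 0:
        return 0.0
    total = 0.0
    # contribution of u_i <= v_j: carry a running exponential sum along u
    i = 0
    run = 0.0
    last = None
    for vj in v:
        while i < u.size and u[i] <= vj:
            if last is None:
                run = 1.0
            else:
                run = run * math.exp(-(u[i] - last) / tau) + 1.0
            last = u[i]
            i += 1
        if last is not None:
            total += run * math.exp(-(vj - last) / tau)
    # contribution of u_i > v_j: symmetric backward pass
    i = u.size - 1
    run = 0.0
    last = None
    for vj in v[::-1]:
        while i >= 0 and u[i] > vj:
            if last is None:
                run = 1.0
            else:
                run = run * math.exp(-(last - u[i]) / tau) + 1.0
            last = u[i]
            i -= 1
        if last is not None:
            total += run * math.exp(-(last - vj) / tau)
    return total


def _self_sum_brute(t: np.ndarray, tau: float) -> float:
    if t.size == 0:
        return 0.0
    return float(np.exp(-np.abs(t[:, None] - t[None, :]) / tau).sum())


def _cross_sum_brute(u: np.ndarray, v: np.ndarray, tau: float) -> float:
    if u.size == 0 or v.size == 0:
        return 0.0
    return float(np.exp(-np.abs(u[:, None] - v[None, :]) / tau).sum())


def van_rossum_distance(u: SpikeTrain, v: SpikeTrain, tau: float,
                        method: str = "efficient") -> float:
    """van Rossum distance between two spike trains at timescale ``tau`` (ms).

    ``method`` selects the O(n+m) merge recursion (``'efficient'``) or the
    direct double sum (``'brute'``); the two agree to floating-point accuracy
    and the brute-force path exists as an independent cross-check.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    a, b = u.times, v.times
    if method == "efficient":
        d2 = (_self_sum_efficient(a, tau) + _self_sum_efficient(b, tau)
              - 2.0 * _cross_sum_efficient(a, b, tau))
    elif method == "brute":
        d2 = (_self_sum_brute(a, tau) + _self_sum_brute(b, tau)
              - 2.0 * _cross_sum_brute(a, b, tau))
    else:
        raise ValueError("method must be 'efficient' or 'brute'")
    return math.sqrt(max(d2, 0.0))


def van_rossum_to_function(u: SpikeTrain, g: FilteredFunction) -> float:
    """L2 distance between ``filter(u)`` (at g's timescale) and ``g``.

    Used when the target is an average function over trials rather than a
    single train; computed exactly from the exponential-sum representation.
    """
    f = filter_train(u, g.tau, kappa=g.kappa)
    return f.distance(g)


# --------------------------------------------------------------------------
# coincidence factor


@dataclass(frozen=True)
class CoincidenceResult:
    """Coincidence factor Gamma with its bookkeeping counts."""

    gamma: float
    n_coinc: int
    n_exp: int
    n_model: int
    delta: float
    rate: float

    def __float__(self):
        return self.gamma


@dataclass(frozen=True)
class ReliabilityResult:
    """Intrinsic reliability Gamma_i and mean inter-trial van Rossum distance."""

    gamma_i: float
    cluster_size: float
    n_trials: int

    def performance_factor(self, gamma: float) -> float:
        """Gamma_A = Gamma / Gamma_i."""
        return gamma / self.gamma_i


def count_coincidences(model: np.ndarray, target: np.ndarray, delta: float) -> int:
    """Greedy earliest-first one-to-one matching within ``|dt| <= delta``."""
    i = j = n = 0
    while i < model.size and j < target.size:
        d = model[i] - target[j]
        if abs(d) <= delta:
            n += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return n


def coincidence_factor(model: SpikeTrain, target: SpikeTrain, delta: float) -> CoincidenceResult:
    """Coincidence factor between a model train and an experimental target.

    Gamma = 2/(1-2*delta*f) * (N_c - 2*delta*f*N_e) / (N_e + N_m), with f the
    target's mean rate.  Requires ``2*f*delta < 1``; raises otherwise.  Two
    empty trains count as a perfect (degenerate) match.
    """
    n_e, n_m = target.n_spikes, model.n_spikes
    if target.duration <= 0:
        raise ValueError("target duration must be positive")
    f = n_e / target.duration
    if n_e + n_m == 0:
        return CoincidenceResult(1.0, 0, 0, 0, delta, f)
    if n_e == 0:
        raise ValueError("coincidence factor undefined for an empty target train")
    if 2.0 * f * delta >= 1.0:
        raise ValueError("coincidence factor requires 2*f*delta < 1")
    n_c = count_coincidences(model.times, target.times, delta)
    gamma = (2.0 / (1.0 - 2.0 * delta * f)) * (n_c - 2.0 * delta * f * n_e) / (n_e + n_m)
    return CoincidenceResult(gamma, n_c, n_e, n_m, delta, f)


def intrinsic_reliability(trials: TrialSet, delta: float,
                          tau: float | None = None) -> ReliabilityResult:
    """Mean inter-trial coincidence factor and cluster size of a trial set.

    Gamma is asymmetric in which train supplies the rate f, so each unordered
    pair contributes the mean of both directed values.  ``cluster_size`` is
    the mean pairwise van Rossum distance (at ``tau``, default 10 ms).
    """
    if len(trials) < 2:
        raise ValueError("intrinsic reliability requires at least 2 trials")
    tau = 10.0 if tau is None else tau
    gammas, dists = [], []
    for i in range(len(trials)):
        for j in range(i + 1, len(trials)):
            a, b = trials[i], trials[j]
            g = 0.5 * (coincidence_factor(a, b, delta).gamma
                       + coincidence_factor(b, a, delta).gamma)
            gammas.append(g)
            dists.append(van_rossum_distance(a, b, tau))
    return ReliabilityResult(float(np.mean(gammas)), float(np.mean(dists)), len(trials))


# --------------------------------------------------------------------------
# expected values against inhomogeneous Poisson rate models


def expected_coincidence_poisson(rate: SampledTrace, target: SpikeTrain, delta: float,
                                 n_mc: int = 100, seed: int | None = None) -> float:
    """Expected coincidence factor of a Poisson model with rate r(t) (spikes/ms).

    <N_m> is the integral of the rate; <N_c> is a Monte-Carlo mean over
    ``n_mc`` thinning-sampled Poisson trains.
    """
    from .synthetic import generate_poisson_train

    if np.any(rate.values < 0):
        raise ValueError("rate must be non-negative")
    if target.n_spikes == 0:
        raise ValueError("expected coincidence undefined for an empty target")
    f = target.n_spikes / target.duration
    if 2.0 * f * delta >= 1.0:
        raise ValueError("requires 2*f*delta < 1")
    n_e = target.n_spikes
    n_m_mean = float(np.trapezoid(rate.values, dx=rate.dt))
    rng = np.random.default_rng(seed)
    n_c = 0.0
    for _ in range(n_mc):
        train = generate_poisson_train(rate, rng)
        n_c += count_coincidences(train.times, target.times, delta)
    n_c /= n_mc
    return ((n_c - 2.0 * f * delta * n_e) / (0.5 * (n_e + n_m_mean))
            / (1.0 - 2.0 * f * delta))


def train_filtered_on_grid(u: SpikeTrain, times: np.ndarray, tau: float,
                           kappa: float | None = None) -> np.ndarray:
    """Evaluate filter(u) exactly at sorted grid points by decay recursion."""
    from .spike_trains import default_kernel_constant

    k = default_kernel_constant(tau) if kappa is None else kappa
    out = np.zeros(times.size)
    val = 0.0
    prev_t = times[0]
    spikes = u.times
    si = 0
    for n, t in enumerate(times):
        val *= math.exp(-(t - prev_t) / tau)
        while si < spikes.size and spikes[si] <= t:
            val += k * math.exp(-(t - spikes[si]) / tau)
            si += 1
        out[n] = val
        prev_t = t
    return out


def rate_filtered_on_grid(rate: SampledTrace, tau: float,
                          kappa: float | None = None) -> np.ndarray:
    """Convolution (r * h) on the rate's own grid.

    The rate is treated as piecewise linear between samples and the
    exponential kernel integral over each step is taken in closed form, so
    the recursion is exact for piecewise-linear rates.
    """
    from .spike_trains import default_kernel_constant

    k = default_kernel_constant(tau) if kappa is None else kappa
    r = rate.values
    dt = rate.dt
    lam = math.exp(-dt / tau)
    # integral_0^dt (r0 + (r1-r0) s/dt) * exp(-(dt-s)/tau) ds = c0*r0 + c1*r1
    c0 = tau * tau * (1 - lam) / dt - lam * tau
    c1 = tau * (1 - lam) - c0
    out = np.empty_like(r)
    out[0] = 0.0
    for n in range(1, r.size):
        out[n] = out[n - 1] * lam + k * (c0 * r[n - 1] + c1 * r[n])
    return out


def expected_van_rossum_poisson(rate: SampledTrace, u: SpikeTrain, tau: float) -> float:
    """Distance between the expected Poisson function and a train's function.

    Computed as the L2 distance, on the rate's grid with trapezoidal
    integration, between filter(u) and the rate convolved with the same
    kernel.  This is the distance between expected filtered functions, not
    the expectation of the distance, so it lower-bounds the Monte-Carlo mean
    distance (Jensen plus the Poisson variance term).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if np.any(rate.values < 0):
        raise ValueError("rate must be non-negative")
    # pad the grid past the data so the exponential tails are integrated
    tail = 10.0 * tau
    n_tail = int(math.ceil(tail / rate.dt))
    values = np.concatenate([rate.values, np.zeros(n_tail)])
    padded = SampledTrace(values, dt=rate.dt, t0=rate.t0)
    times = padded.times
    f_u = train_filtered_on_grid(u, times, tau)
    f_r = rate_filtered_on_grid(padded, tau)
    diff2 = (f_u - f_r) ** 2
    return math.sqrt(float(np.trapezoid(diff2, dx=rate.dt)))
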