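"""Spike trains, sampled traces and exponentially filtered functions.

All times are in milliseconds, voltages in mV.  A spike train is an ordered
set of event times on ``[0, T]``; filtering a train with a causal exponential
kernel maps it to a square-integrable function, the basic object behind the
van Rossum distance.  The kernel is

    h(t) = kappa * exp(-t / tau)   for t >= 0,  0 otherwise,

with ``kappa = sqrt(2 / tau)`` by default so that ``integral h^2 dt = 1`` and
the distance between a one-spike train and the empty train is exactly 1 at
every timescale.  The constant is configurable for users who prefer other
conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "SampledTrace",
    "TrialSet",
    "FilteredFunction",
    "default_kernel_constant",
    "filter_train",
    "average_function",
    "mean_isi_and_rate",
    "extract_spikes_from_voltage",
    "read_spike_trains",
    "write_spike_trains",
    "read_trace",
    "write_trace",
]

#: tolerance below which two spike times count as duplicates (ms)
DUPLICATE_TOL = 1e-9


def default_kernel_constant(tau: float) -> float:
    """Normalization constant ``sqrt(2/tau)`` of the causal exponential kernel."""
    return math.sqrt(2.0 / tau)


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered set of spike times on ``[0, T]``.

    Parameters
    ----------
    times : array-like
        Strictly increasing spike times in ms.
    duration : float
        Recording duration T in ms; all times must lie in ``[0, T]``.
    """

    times: np.ndarray
    duration: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        object.__setattr__(self, "times", t)
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if t.size:
            if np.any(np.diff(t) <= DUPLICATE_TOL):
                raise ValueError("spike times must be strictly increasing "
                                 f"(tolerance {DUPLICATE_TOL} ms)")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def shift(self, dt_ms: float, duration: float | None = None) -> "SpikeTrain":
        """Return a copy with all times shifted by ``dt_ms`` (clipped to range)."""
        t = self.times + dt_ms
        T = self.duration if duration is None else duration
        return SpikeTrain(t[(t >= 0) & (t <= T)], T)


@dataclass
class SampledTrace:
    """A regularly sampled signal: voltage, current or firing rate.

    ``values[i]`` is the sample at time ``t0 + i * dt`` (ms).
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    unit: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.size < 2:
            raise ValueError("a trace needs at least two samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class TrialSet:
    """Repeated spike-train responses to one stimulus, sharing a duration."""

    trials: list
    stimulus_id: str = ""

    def __post_init__(self):
        if not all(isinstance(u, SpikeTrain) for u in self.trials):
            raise TypeError("TrialSet holds SpikeTrain objects")
        if self.trials:
            T = self.trials[0].duration
            if any(abs(u.duration - T) > 1e-9 for u in self.trials):
                raise ValueError("all trials must share one duration")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    @property
    def duration(self) -> float:
        if not self.trials:
            raise ValueError("empty TrialSet has no duration")
        return self.trials[0].duration


class FilteredFunction:
    """A weighted sum of exponentially filtered spike trains.

    Represents ``f(t) = sum_k w_k sum_i h(t - u_{k,i})`` with the causal
    kernel ``h(t) = kappa exp(-t/tau)``.  Because the components are pure
    exponential sums, evaluation, L2 norms and inner products are all exact;
    no grid is involved.
    """

    def __init__(self, components: Sequence[tuple[float, np.ndarray]], tau: float,
                 kappa: float | None = None):
        if tau <= 0:
            raise ValueError("tau must be positive")
        self.tau = float(tau)
        self.kappa = default_kernel_constant(tau) if kappa is None else float(kappa)
        self.components = [(float(w), np.asarray(t, dtype=float).ravel())
                           for w, t in components]

    @classmethod
    def from_train(cls, u: SpikeTrain, tau: float, kappa: float | None = None):
        return cls([(1.0, u.times)], tau, kappa)

    @classmethod
    def average(cls, trials: TrialSet, tau: float, mode: str = "mean",
                kappa: float | None = None):
        if len(trials) == 0:
            raise ValueError("cannot average an empty TrialSet")
        if mode == "mean":
            w = 1.0 / len(trials)
        elif mode == "sum":
            w = 1.0
        else:
            raise ValueError("mode must be 'mean' or 'sum'")
        return cls([(w, u.times) for u in trials], tau, kappa)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for w, times in self.components:
            if times.size == 0:
                continue
            dt = t[..., None] - times
            mask = dt >= 0
            out += w * np.sum(np.where(mask, np.exp(np.where(mask, -dt / self.tau, 0.0)), 0.0),
                              axis=-1) * self.kappa
        return out

    # --- exact L2 geometry -------------------------------------------------

    def _cross_sum(self, a: np.ndarray, b: np.ndarray) -> float:
        """sum_ij exp(-|a_i - b_j|/tau), exact, O(n m) broadcast."""
        if a.size == 0 or b.size == 0:
            return 0.0
        return float(np.exp(-np.abs(a[:, None] - b[None, :]) / self.tau).sum())

    def inner(self, other: "FilteredFunction") -> float:
        """Exact L2 inner product ``integral f g dt`` over the whole line."""
        if abs(other.tau - self.tau) > 1e-12:
            raise ValueError("inner product requires matching kernel timescales")
        # integral h(t-a) h(t-b) dt = kappa^2 * tau/2 * exp(-|a-b|/tau)
        c = self.kappa * other.kappa * self.tau / 2.0
        total = 0.0
        for w1, t1 in self.components:
            for w2, t2 in other.components:
                total += w1 * w2 * self._cross_sum(t1, t2)
        return c * total

    def norm_sq(self) -> float:
        return self.inner(self)

    def distance(self, other: "FilteredFunction") -> float:
        d2 = self.norm_sq() - 2.0 * self.inner(other) + other.norm_sq()
        return math.sqrt(max(d2, 0.0))


def filter_train(u: SpikeTrain, tau: float, kappa: float | None = None) -> FilteredFunction:
    """Map a spike train to its exponentially filtered function."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return FilteredFunction.from_train(u, tau, kappa)


def average_function(trials: TrialSet, tau: float, mode: str = "mean",
                     kappa: float | None = None) -> FilteredFunction:
    """Average (or summed) filtered function over a set of trials.

    The default is the pointwise mean of the per-trial filtered functions;
    ``mode='sum'`` gives the unnormalized sum.
    """
    return FilteredFunction.average(trials, tau, mode=mode, kappa=kappa)


def mean_isi_and_rate(u: SpikeTrain) -> tuple[float | None, float]:
    """Mean inter-spike interval (ms; None for <2 spikes) and rate (spikes/ms)."""
    isi = float(np.mean(np.diff(u.times))) if u.n_spikes >= 2 else None
    if u.duration <= 0:
        raise ValueError("rate requires positive duration")
    return isi, u.n_spikes / u.duration


def extract_spikes_from_voltage(v: SampledTrace, threshold: float = 0.0,
                                refractory: float = 1.0) -> SpikeTrain:
    """Spike times from a voltage trace by threshold crossing.

    Each upward crossing of ``threshold`` yields one spike, timed by linear
    interpolation between the bracketing samples.  Crossings closer than
    ``refractory`` ms to the previous accepted spike are merged into it (one
    spike per action potential).
    """
    x = v.values
    above = x >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    for i in idx:
        frac = (threshold - x[i]) / (x[i + 1] - x[i])
        t = v.t0 + (i + frac) * v.dt
        if times and t - times[-1] < refractory:
            continue
        times.append(t)
    T = v.t0 + v.duration
    return SpikeTrain(np.asarray(times), T)


# --- text I/O ---------------------------------------------------------------
# Spike trains: '#'-comment lines, a header '# T_ms=<float>', one train per
# line (whitespace-separated times in ms; an empty line is an empty train).
# Traces: two-column CSV 't_ms,value' with a header row.


def write_spike_trains(path, trials: TrialSet | Iterable[SpikeTrain]) -> None:
    trains = list(trials)
    T = max((u.duration for u in trains), default=0.0)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# T_ms={float(T)!r}\n")
        for u in trains:
            fh.write(" ".join(repr(float(t)) for t in u.times) + "\n")


def read_spike_trains(path) -> TrialSet:
    """Read a trial set from the plain-text spike-train format."""
    T = None
    rows: list[np.ndarray] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if s.startswith("#"):
                body = s[1:].strip()
                if body.startswith("T_ms="):
                    T = float(body[len("T_ms="):])
                continue
            try:
                t = np.asarray([float(x) for x in s.split()], dtype=float)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad spike time ({exc})") from None
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"{path}: line {lineno}: times not strictly increasing")
            if t.size and t[0] < 0:
                raise ValueError(f"{path}: line {lineno}: negative spike time")
            rows.append(t)
    if T is None:
        T = float(np.ceil(max((r[-1] for r in rows if r.size), default=0.0)))
    return TrialSet([SpikeTrain(r, T) for r in rows])


def write_trace(path, trace: SampledTrace) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("t_ms,value\n")
        for t, x in zip(trace.times, trace.values):
            fh.write(f"{float(t)!r},{float(x)!r}\n")


def read_trace(path, unit: str = "") -> SampledTrace:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns t_ms,value")
    t, x = data[:, 0], data[:, 1]
    dt = float(np.median(np.diff(t)))
    if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: trace is not regularly sampled")
    return SampledTrace(x, dt=dt, t0=float(t[0]), unit=unit)
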