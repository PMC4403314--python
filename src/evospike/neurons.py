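"""Deterministic simulation of two- and three-variable spiking neuron models.

The family shares the generic form

    dv/dt = f(v) - w + R*I,      dw/dt = a*(b*v - w),

with a hard reset when the voltage reaches a cutoff ``v_c``: ``v -> v_r``,
``w -> w + alpha``.  The members differ in ``f(v)``:

* ``IF``    -- leaky integrate-and-fire, no adaptation (a = b = 0).
* ``aIF``   -- leaky IF with an adaptation current (b = 0).
* ``atIF``  -- leaky IF whose cutoff voltage adapts instead of carrying a
  current: ``tau_t dv_c/dt = b*v - v_c`` and ``v_c -> v_c + alpha`` at reset.
* ``aEIF``  -- adaptive exponential IF: ``f(v)`` has an exponential
  spike-initiation term with slope ``Delta_T`` around threshold ``V_T``.
* ``a2EIF`` -- three-variable extension of the aEIF in which the exponential
  threshold itself adapts: ``tau_t dv_t/dt = V_t0 - v_t`` and
  ``v_t -> v_t + beta`` at reset.  Its voltage equation divides the whole
  right-hand side (including w and R*I) by ``tau_m``.
* ``aQIF``  -- Izhikevich quadratic model, ``f(v) = 0.04 v^2 + 5 v + 140``
  with a fixed 30 mV cutoff.

Integration is classical RK4 at a fixed step ``dt`` (default 0.1 ms) with the
input current held constant within each of its own sampling intervals.  Spike
times are located by linear interpolation of the within-step cutoff crossing.
The exponential argument is clipped at 40 before exponentiation; the clipped
region is only visited during the spike upswing, which the reset discards.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .spike_trains import SampledTrace, SpikeTrain

__all__ = [
    "ModelKind",
    "ParameterSet",
    "SimulationResult",
    "FREE_PARAMETERS",
    "derivative",
    "simulate",
    "fast_exp",
]


class ModelKind(enum.IntEnum):
    IF = 0
    aIF = 1
    atIF = 2
    aEIF = 3
    a2EIF = 4
    aQIF = 5


#: free (gene) parameters of each model; everything else is fixed
FREE_PARAMETERS: dict[ModelKind, tuple[str, ...]] = {
    ModelKind.IF: ("tau_m", "R"),
    ModelKind.aIF: ("tau_m", "tau_w", "alpha", "R"),
    ModelKind.atIF: ("tau_m", "tau_t", "alpha", "b", "R"),
    ModelKind.aEIF: ("tau_m", "tau_w", "E_L", "Delta_T", "V_T", "b", "alpha",
                     "V_r", "R"),
    ModelKind.a2EIF: ("tau_m", "tau_w", "tau_t", "E_L", "Delta_T", "b",
                      "alpha", "beta", "V_r", "V_t0", "R"),
    ModelKind.aQIF: ("izh_a", "izh_b", "V_r", "alpha", "R"),
}

_EXP_CLIP = 40.0


@dataclass(frozen=True)
class ParameterSet:
    """A model-tagged vector of neuron parameters (the GA gene).

    Time constants in ms, voltages in mV; the current scale ``R`` absorbs the
    units of the injected signal.  For the Izhikevich model ``izh_a`` and
    ``izh_b`` are its a and b, ``V_r`` its c and ``alpha`` its d.
    """

    model: ModelKind = ModelKind.aEIF
    tau_m: float = 10.0       # membrane time constant (ms)
    tau_w: float = 144.0      # adaptation-current time constant (ms)
    tau_t: float = 100.0      # threshold-adaptation time constant (ms)
    E_L: float = -70.0        # resting potential (mV)
    Delta_T: float = 2.0      # exponential slope factor (mV)
    V_T: float = -50.0        # exponential threshold (mV)
    V_t0: float = -50.0       # baseline threshold of the a2EIF (mV)
    b: float = 0.001          # subthreshold adaptation coupling
    alpha: float = 1.0        # adaptation increment at reset
    beta: float = 2.0         # threshold increment at reset (mV)
    V_r: float = -70.0        # reset voltage (mV)
    V_c: float = 0.0          # spike cutoff voltage (mV; 30 fixed for aQIF)
    R: float = 1.0            # input current scale
    izh_a: float = 0.02       # Izhikevich recovery rate (1/ms)
    izh_b: float = 0.2        # Izhikevich recovery coupling

    def __post_init__(self):
        if self.tau_m <= 0 or self.tau_w <= 0 or self.tau_t <= 0:
            raise ValueError("time constants must be positive")
        if self.model in (ModelKind.aEIF, ModelKind.a2EIF) and self.Delta_T <= 0:
            raise ValueError("Delta_T must be positive for exponential models")
        cutoff = self.cutoff
        if self.V_r >= cutoff:
            raise ValueError("V_r must lie below the cutoff voltage")

    @property
    def cutoff(self) -> float:
        """Spike cutoff voltage; fixed at 30 mV for the Izhikevich model."""
        return 30.0 if self.model == ModelKind.aQIF else self.V_c

    @property
    def free_names(self) -> tuple[str, ...]:
        return FREE_PARAMETERS[self.model]

    def to_gene(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        names = self.free_names if names is None else names
        return np.asarray([getattr(self, n) for n in names], dtype=float)

    def with_gene(self, gene: np.ndarray, names: tuple[str, ...] | None = None) -> "ParameterSet":
        names = self.free_names if names is None else names
        if len(gene) != len(names):
            raise ValueError("gene length does not match free parameter count")
        return replace(self, **dict(zip(names, map(float, gene))))

    def _packed(self) -> np.ndarray:
        return np.asarray([
            self.tau_m, self.tau_w, self.tau_t, self.E_L, self.Delta_T,
            self.V_T, self.V_t0, self.b, self.alpha, self.beta, self.V_r,
            self.cutoff, self.R, self.izh_a, self.izh_b,
        ], dtype=float)


@dataclass
class SimulationResult:
    spikes: SpikeTrain
    voltage: SampledTrace | None = None
    adaptation: SampledTrace | None = None
    threshold: SampledTrace | None = None


# --------------------------------------------------------------------------
# fast exponential

_LOG2E = 1.4426950408889634
_LN2 = 0.6931471805599453


@njit(cache=True, inline="always")
def _fast_exp_scalar(x: float) -> float:
    n = int(math.floor(x * _LOG2E + 0.5))
    r = x - n * _LN2
    return math.ldexp(1.0 + r * (1.0 + 0.5 * r), n)


@njit(cache=True)
def _fast_exp_arr(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    for k in range(x.size):
        out[k] = _fast_exp_scalar(x[k])
    return out


def fast_exp(x):
    """Low-order approximation of ``exp(x)`` (relative error < 1% on [-20, 20]).

    Range reduction ``x = n*ln2 + r`` with ``|r| <= ln2/2`` followed by a
    quadratic in ``r`` and an exponent shift (``ldexp``): far fewer floating
    point operations than a correctly rounded library exponential.  Intended
    for model right-hand sides only; never used inside the spike metrics.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        return float(_fast_exp_arr(x.ravel())[0])
    return _fast_exp_arr(x.ravel()).reshape(x.shape)


# --------------------------------------------------------------------------
# right-hand sides


def derivative(params: ParameterSet, state, I: float) -> tuple[float, float, float]:
    """Model right-hand side d(v, w, v_thr)/dt at a given state and current.

    ``v_thr`` is the dynamic cutoff for the atIF model and the dynamic
    exponential threshold for the a2EIF; it is inert for the other models.
    This is a readable reference implementation; the simulator uses a
    numba-compiled equivalent.
    """
    v, w, vthr = state
    p = params
    kind = p.model
    if kind == ModelKind.IF:
        dv = -(v - p.E_L) / p.tau_m + p.R * I
        return dv, 0.0, 0.0
    if kind == ModelKind.aIF:
        dv = -(v - p.E_L) / p.tau_m - w + p.R * I
        dw = -w / p.tau_w
        return dv, dw, 0.0
    if kind == ModelKind.atIF:
        dv = -(v - p.E_L) / p.tau_m + p.R * I
        dthr = (p.b * v - vthr) / p.tau_t
        return dv, 0.0, dthr
    if kind == ModelKind.aEIF:
        arg = min((v - p.V_T) / p.Delta_T, _EXP_CLIP)
        dv = ((p.E_L - v) + p.Delta_T * math.exp(arg)) / p.tau_m - w + p.R * I
        dw = (p.b * v - w) / p.tau_w
        return dv, dw, 0.0
    if kind == ModelKind.a2EIF:
        arg = min((v - vthr) / p.Delta_T, _EXP_CLIP)
        dv = (p.E_L - v + p.Delta_T * math.exp(arg) - w + p.R * I) / p.tau_m
        dw = (p.b * v - w) / p.tau_w
        dthr = (p.V_t0 - vthr) / p.tau_t
        return dv, dw, dthr
    if kind == ModelKind.aQIF:
        dv = 0.04 * v * v + 5.0 * v + 140.0 - w + p.R * I
        dw = p.izh_a * (p.izh_b * v - w)
        return dv, dw, 0.0
    raise ValueError(f"unknown model kind {kind}")


@njit(cache=True, inline="always", fastmath=True)
def _rhs(kind, pp, v, w, vthr, I, use_fast):
    """Numba right-hand side; returns (dv, dw, dvthr)."""
    tau_m, tau_w, tau_t = pp[0], pp[1], pp[2]
    E_L, Delta_T, V_T, V_t0 = pp[3], pp[4], pp[5], pp[6]
    b, R = pp[7], pp[12]
    if kind == 0:  # IF
        return -(v - E_L) / tau_m + R * I, 0.0, 0.0
    if kind == 1:  # aIF
        return -(v - E_L) / tau_m - w + R * I, -w / tau_w, 0.0
    if kind == 2:  # atIF
        return -(v - E_L) / tau_m + R * I, 0.0, (b * v - vthr) / tau_t
    if kind == 3:  # aEIF
        arg = (v - V_T) / Delta_T
        if arg > _EXP_CLIP:
            arg = _EXP_CLIP
        # below arg=-10 the exponential term is under ~1e-5 mV/ms (sub-
        # thousandth-of-a-spike-time effect over seconds); skip the call
        if arg < -10.0:
            e = 0.0
        elif use_fast:
            e = _fast_exp_scalar(arg)
        else:
            e = math.exp(arg)
        return (((E_L - v) + Delta_T * e) / tau_m - w + R * I,
                (b * v - w) / tau_w, 0.0)
    if kind == 4:  # a2EIF
        arg = (v - vthr) / Delta_T
        if arg > _EXP_CLIP:
            arg = _EXP_CLIP
        if arg < -10.0:
            e = 0.0
        elif use_fast:
            e = _fast_exp_scalar(arg)
        else:
            e = math.exp(arg)
        return ((E_L - v + Delta_T * e - w + R * I) / tau_m,
                (b * v - w) / tau_w, (V_t0 - vthr) / tau_t)
    # aQIF
    izh_a, izh_b = pp[13], pp[14]
    return (0.04 * v * v + 5.0 * v + 140.0 - w + R * I,
            izh_a * (izh_b * v - w), 0.0)


@njit(cache=True, fastmath=True)
def _simulate_core(kind, pp, current, n_sub, dt, v0, w0, vthr0, use_fast,
                   record, max_spikes):
    """Fixed-step RK4 with reset handling.

    ``current`` is sampled every ``n_sub`` integration steps (zero-order
    hold).  Returns (spike_times, n_spikes, v_trace, w_trace, thr_trace);
    traces have length n_steps+1 when ``record``, else length 1.
    """
    alpha, beta = pp[8], pp[9]
    v_r, v_c = pp[10], pp[11]
    n_steps = current.size * n_sub
    spikes = np.empty(max_spikes)
    n_spk = 0
    if record:
        v_tr = np.empty(n_steps + 1)
        w_tr = np.empty(n_steps + 1)
        th_tr = np.empty(n_steps + 1)
    else:
        v_tr = np.empty(1)
        w_tr = np.empty(1)
        th_tr = np.empty(1)
    v, w, vthr = v0, w0, vthr0
    if record:
        v_tr[0] = v
        w_tr[0] = w
        th_tr[0] = vthr
    # voltage ceiling for RK4 stage evaluations: above the cutoff the
    # trajectory is discarded by the reset, so capping stage voltages there
    # costs nothing and keeps the stage derivatives finite and positive
    # during the spike upswing
    v_cap = v_c + 40.0
    for step in range(n_steps):
        I = current[step // n_sub]
        k1v, k1w, k1t = _rhs(kind, pp, min(v, v_cap), w, vthr, I, use_fast)
        k2v, k2w, k2t = _rhs(kind, pp, min(v + 0.5 * dt * k1v, v_cap),
                             w + 0.5 * dt * k1w,
                             vthr + 0.5 * dt * k1t, I, use_fast)
        k3v, k3w, k3t = _rhs(kind, pp, min(v + 0.5 * dt * k2v, v_cap),
                             w + 0.5 * dt * k2w,
                             vthr + 0.5 * dt * k2t, I, use_fast)
        k4v, k4w, k4t = _rhs(kind, pp, min(v + dt * k3v, v_cap),
                             w + dt * k3w,
                             vthr + dt * k3t, I, use_fast)
        v_new = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        w_new = w + dt / 6.0 * (k1w + 2.0 * k2w + 2.0 * k3w + k4w)
        t_new = vthr + dt / 6.0 * (k1t + 2.0 * k2t + 2.0 * k3t + k4t)
        cutoff = t_new if kind == 2 else v_c
        v_rec = v_new
        if v_new >= cutoff:
            v_rec = cutoff  # record the clipped spike peak, not the reset
            # linear interpolation of the crossing inside the step
            frac = 0.0
            if v_new > v:
                frac = (cutoff - v) / (v_new - v)
                if frac < 0.0:
                    frac = 0.0
                elif frac > 1.0:
                    frac = 1.0
            if n_spk < max_spikes:
                spikes[n_spk] = (step + frac) * dt
            n_spk += 1
            v_new = v_r
            if kind == 2:    # atIF: cutoff jumps up by alpha, w untouched
                t_new = t_new + alpha
            elif kind == 4:  # a2EIF: exponential threshold jumps by beta
                w_new = w_new + alpha
                t_new = t_new + beta
            else:
                w_new = w_new + alpha
        v, w, vthr = v_new, w_new, t_new
        if record:
            v_tr[step + 1] = v_rec
            w_tr[step + 1] = w
            th_tr[step + 1] = vthr
    return spikes, n_spk, v_tr, w_tr, th_tr, v, w, vthr


@njit(cache=True, fastmath=True)
def _simulate_aeif(pp, current, n_sub, dt, max_spikes):
    """Branch-lean aEIF-only integrator (the hot model in both benchmarks).

    Numerically identical to :func:`_simulate_core` with ``kind == 3``; kept
    separate so the inner loop carries no model dispatch.
    """
    tau_m, tau_w = pp[0], pp[1]
    E_L, Delta_T, V_T = pp[3], pp[4], pp[5]
    b, R = pp[7], pp[12]
    alpha, v_r, v_c = pp[8], pp[10], pp[11]
    inv_tm, inv_tw, inv_dT = 1.0 / tau_m, 1.0 / tau_w, 1.0 / Delta_T
    v_cap = v_c + 40.0
    n_steps = current.size * n_sub
    spikes = np.empty(max_spikes)
    n_spk = 0
    v, w = E_L, 0.0
    for step in range(n_steps):
        I = current[step // n_sub]
        drive = R * I

        vv = min(v, v_cap)
        arg = (vv - V_T) * inv_dT
        if arg > _EXP_CLIP:
            arg = _EXP_CLIP
        e = math.exp(arg) if arg >= -10.0 else 0.0
        k1v = ((E_L - vv) + Delta_T * e) * inv_tm - w + drive
        k1w = (b * vv - w) * inv_tw

        vv = min(v + 0.5 * dt * k1v, v_cap)
        w2 = w + 0.5 * dt * k1w
        arg = (vv - V_T) * inv_dT
        if arg > _EXP_CLIP:
            arg = _EXP_CLIP
        e = math.exp(arg) if arg >= -10.0 else 0.0
        k2v = ((E_L - vv) + Delta_T * e) * inv_tm - w2 + drive
        k2w = (b * vv - w2) * inv_tw

        vv = min(v + 0.5 * dt * k2v, v_cap)
        w3 = w + 0.5 * dt * k2w
        arg = (vv - V_T) * inv_dT
        if arg > _EXP_CLIP:
            arg = _EXP_CLIP
        e = math.exp(arg) if arg >= -10.0 else 0.0
        k3v = ((E_L - vv) + Delta_T * e) * inv_tm - w3 + drive
        k3w = (b * vv - w3) * inv_tw

        vv = min(v + dt * k3v, v_cap)
        w4 = w + dt * k3w
        arg = (vv - V_T) * inv_dT
        if arg > _EXP_CLIP:
            arg = _EXP_CLIP
        e = math.exp(arg) if arg >= -10.0 else 0.0
        k4v = ((E_L - vv) + Delta_T * e) * inv_tm - w4 + drive
        k4w = (b * vv - w4) * inv_tw

        v_new = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        w_new = w + dt / 6.0 * (k1w + 2.0 * k2w + 2.0 * k3w + k4w)
        if v_new >= v_c:
            frac = 0.0
            if v_new > v:
                frac = (v_c - v) / (v_new - v)
                if frac < 0.0:
                    frac = 0.0
                elif frac > 1.0:
                    frac = 1.0
            if n_spk < max_spikes:
                spikes[n_spk] = (step + frac) * dt
            n_spk += 1
            v_new = v_r
            w_new = w_new + alpha
        v, w = v_new, w_new
    return spikes, n_spk


#: packed parameter-vector layout used by the compiled simulator core
PACKED_INDEX = {
    "tau_m": 0, "tau_w": 1, "tau_t": 2, "E_L": 3, "Delta_T": 4, "V_T": 5,
    "V_t0": 6, "b": 7, "alpha": 8, "beta": 9, "V_r": 10, "V_c": 11, "R": 12,
    "izh_a": 13, "izh_b": 14,
}


def initial_threshold(kind: int, pp: np.ndarray) -> float:
    """Initial value of the auxiliary threshold state for a packed vector."""
    if kind == int(ModelKind.atIF):
        return float(pp[PACKED_INDEX["V_c"]])
    if kind == int(ModelKind.a2EIF):
        return float(pp[PACKED_INDEX["V_t0"]])
    return 0.0


def simulate_packed(kind: int, pp: np.ndarray, current_values: np.ndarray,
                    current_dt: float, dt: float = 0.1,
                    use_fast_exp: bool = False) -> np.ndarray:
    """Spike times from a packed parameter vector (hot path for the GA).

    Skips the dataclass bookkeeping of :func:`simulate`; identical numerics.
    The caller guarantees a valid vector (bounds come from the feasible
    region) and a ``dt`` that divides ``current_dt``.
    """
    n_sub = int(round(current_dt / dt))
    duration = current_values.size * current_dt
    max_spikes = 2 * int(duration) + 64
    if kind == int(ModelKind.aEIF) and not use_fast_exp:
        spikes, n_spk = _simulate_aeif(pp, current_values, n_sub, dt,
                                       max_spikes)
    else:
        spikes, n_spk, _, _, _, _, _, _ = _simulate_core(
            kind, pp, current_values, n_sub, dt, pp[PACKED_INDEX["E_L"]],
            0.0, initial_threshold(kind, pp), use_fast_exp, False,
            max_spikes)
    n_spk = min(n_spk, max_spikes)
    t = spikes[:n_spk]
    if t.size:
        t = t[np.concatenate([[True], np.diff(t) > 1e-9])]
    return t


def simulate(params: ParameterSet, current: SampledTrace, dt: float = 0.1,
             record_voltage: bool = False, use_fast_exp: bool = False,
             v0: float | None = None, w0: float = 0.0,
             settle_ms: float = 0.0) -> SimulationResult:
    """Integrate a spiking model driven by an injected current.

    ``dt`` must divide the current's sampling step (the current is held
    constant within its own intervals).  Initial conditions are
    ``v = E_L`` (or ``v0``), ``w = w0`` and, for threshold-adaptive models,
    the baseline threshold.  ``settle_ms`` prepends that much simulation at
    the first current value before t = 0 to wash out the initial condition.
    Deterministic: identical inputs give identical outputs.
    """
    if not np.all(np.isfinite(current.values)):
        raise ValueError("current contains non-finite values")
    if dt <= 0 or dt > current.dt + 1e-12:
        raise ValueError("dt must be positive and at most the current's step")
    n_sub = int(round(current.dt / dt))
    if abs(n_sub * dt - current.dt) > 1e-9:
        raise ValueError("current.dt must be an integer multiple of dt")
    p = params
    v_init = p.E_L if v0 is None else v0
    if p.model == ModelKind.atIF:
        vthr0 = p.cutoff
    elif p.model == ModelKind.a2EIF:
        vthr0 = p.V_t0
    else:
        vthr0 = 0.0
    pp = p._packed()
    kind = int(p.model)
    if settle_ms > 0:
        n_pre = int(round(settle_ms / current.dt))
        pre = np.full(n_pre, current.values[0])
        out = _simulate_core(kind, pp, pre, n_sub, dt, v_init, w0, vthr0,
                             use_fast_exp, False, 8)
        v_init, w0, vthr0 = out[5], out[6], out[7]
    duration = current.values.size * current.dt
    max_spikes = 2 * int(duration) + 64  # cap ~2 kHz; plenty for these models
    spikes, n_spk, v_tr, w_tr, th_tr, _, _, _ = _simulate_core(
        kind, pp, current.values, n_sub, dt, v_init, w0, vthr0,
        use_fast_exp, record_voltage, max_spikes)
    n_spk = min(n_spk, max_spikes)
    t_spk = spikes[:n_spk]
    if t_spk.size:  # guard against coincident step-boundary crossings
        keep = np.concatenate([[True], np.diff(t_spk) > 1e-9])
        t_spk = t_spk[keep]
    train = SpikeTrain(t_spk, duration)
    res = SimulationResult(spikes=train)
    if record_voltage:
        res.voltage = SampledTrace(v_tr, dt=dt, t0=current.t0, unit="mV")
        res.adaptation = SampledTrace(w_tr, dt=dt, t0=current.t0)
        res.threshold = SampledTrace(th_tr, dt=dt, t0=current.t0, unit="mV")
    return res
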