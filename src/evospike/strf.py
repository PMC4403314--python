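"""Spectro-temporal receptive field estimation by normalized reverse correlation.

A spectro-temporal receptive field (STRF) is a linear kernel ``h(lag, band)``
whose convolution with a stimulus spectrogram predicts a neuron's firing
rate:

    r_hat(t) = sum_{i<N_lag} sum_{k<M} h(i, k) * s(t - i, k).

Stacking the lagged stimulus into a design matrix S turns estimation into
least squares; the normal-equation solution ``h = (S^T S)^{-1} S^T r``
amplifies noise along the low-variance stimulus dimensions of natural
sounds, so the autocorrelation matrix is inverted through a truncated-SVD
pseudo-inverse.  A single hyper-parameter ``lam`` in (0, 1] gives the
cumulative singular-value fraction to retain and is chosen by
cross-validation on held-out predictive correlation.

Vectorization order is lag-major: flat coordinate ``j = i*M + k`` holds lag
``i``, band ``k``.  Stimulus history before t = 0 is zero-padded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spike_trains import SampledTrace, TrialSet

__all__ = [
    "Spectrogram",
    "STRF",
    "RegularizationConfig",
    "compute_psth",
    "build_design_matrix",
    "regularized_pseudoinverse",
    "estimate_strf",
    "estimate_strf_pooled",
    "cross_validate_lambda",
    "predict_rate",
    "normalize_l1",
    "read_matrix",
    "write_matrix",
]


@dataclass
class Spectrogram:
    """Stimulus matrix ``values[t, k]``: time bins by M frequency bands."""

    values: np.ndarray
    dt: float = 1.0                      # bin width, ms
    band_edges: np.ndarray | None = None  # M+1 edges, Hz

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram contains non-finite values")
        if self.band_edges is None:
            self.band_edges = np.linspace(0.0, 8000.0, self.n_bands + 1)
        else:
            self.band_edges = np.asarray(self.band_edges, dtype=float)

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times * self.dt


@dataclass
class STRF:
    """Kernel ``kernel[k, i]``: M frequency bands by N_lag time lags."""

    kernel: np.ndarray
    lag_dt: float = 1.0   # lag bin width, ms

    def __post_init__(self):
        self.kernel = np.atleast_2d(np.asarray(self.kernel, dtype=float))
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel contains non-finite values")

    @property
    def n_bands(self) -> int:
        return self.kernel.shape[0]

    @property
    def n_lags(self) -> int:
        return self.kernel.shape[1]

    @property
    def temporal_width(self) -> float:
        return self.n_lags * self.lag_dt

    def vec(self) -> np.ndarray:
        """Lag-major flattening: element i*M + k is (lag i, band k)."""
        return self.kernel.T.ravel()

    @classmethod
    def from_vec(cls, h: np.ndarray, n_bands: int, lag_dt: float = 1.0) -> "STRF":
        h = np.asarray(h, dtype=float)
        if h.size % n_bands:
            raise ValueError("vector length is not a multiple of the band count")
        return cls(h.reshape(-1, n_bands).T, lag_dt=lag_dt)

    def l1_norm(self) -> float:
        return float(np.abs(self.kernel).sum())


@dataclass(frozen=True)
class RegularizationConfig:
    """Truncated-SVD tolerance and cross-validation folds."""

    lam: float = 1.0
    folds: int = 4

    def __post_init__(self):
        if not (0.0 < self.lam <= 1.0):
            raise ValueError("lam must lie in (0, 1]")


def compute_psth(trials: TrialSet, bin_ms: float = 1.0) -> SampledTrace:
    """Trial-averaged binned firing rate in spikes/ms.

    Bin b covers ``[b*bin, (b+1)*bin)``; the value is the mean spike count
    per trial in the bin divided by the bin width.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    if len(trials) == 0:
        raise ValueError("PSTH of an empty TrialSet is undefined")
    T = trials.duration
    n_bins = max(int(math.ceil(T / bin_ms)), 2)
    counts = np.zeros(n_bins)
    for u in trials:
        idx = np.minimum((u.times / bin_ms).astype(int), n_bins - 1)
        np.add.at(counts, idx, 1.0)
    rate = counts / (len(trials) * bin_ms)
    return SampledTrace(rate, dt=bin_ms, unit="spikes/ms")


def build_design_matrix(s: Spectrogram, n_lag: int) -> np.ndarray:
    """Design matrix: row t holds ``s(t-i, k)`` at column ``i*M + k``.

    Entries with ``t - i < 0`` are zero (no stimulus history before onset).
    """
    if n_lag < 1:
        raise ValueError("need at least one lag")
    T, M = s.values.shape
    D = np.zeros((T, n_lag * M))
    for i in range(n_lag):
        D[i:, i * M:(i + 1) * M] = s.values[:T - i]
    return D


def regularized_pseudoinverse(A: np.ndarray, lam: float) -> np.ndarray:
    """Truncated-SVD pseudo-inverse of a symmetric PSD matrix.

    Keeps the largest ``m`` singular values whose cumulative fraction of the
    total stays strictly below ``lam`` (at least one is always kept);
    ``lam = 1`` keeps every nonzero direction, recovering the plain
    pseudo-inverse.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("expected a square matrix")
    U, sig, Vt = np.linalg.svd(A, hermitian=True)
    total = sig.sum()
    if total <= 0:
        return np.zeros_like(A)
    if lam >= 1.0:
        m = int(np.sum(sig > sig[0] * 1e-12))
    else:
        frac = np.cumsum(sig) / total
        m = int(np.sum(frac < lam))
    m = max(m, 1)
    inv = np.zeros_like(sig)
    inv[:m] = 1.0 / sig[:m]
    return (Vt.T * inv) @ U.T


def estimate_strf(s: Spectrogram, r: SampledTrace, n_lag: int = 40,
                  reg: RegularizationConfig | None = None) -> STRF:
    """Normalized reverse correlation: ``h = pinv_lam(S^T S) S^T r``."""
    reg = reg or RegularizationConfig()
    if abs(r.dt - s.dt) > 1e-9:
        raise ValueError("rate and spectrogram must share a time grid")
    rv = r.values
    if rv.size < s.n_times:
        raise ValueError("rate is shorter than the stimulus")
    rv = rv[:s.n_times]
    D = build_design_matrix(s, n_lag)
    A = D.T @ D
    c = D.T @ rv
    h = regularized_pseudoinverse(A, reg.lam) @ c
    return STRF.from_vec(h, s.n_bands, lag_dt=s.dt)


def estimate_strf_pooled(stimuli, rates, n_lag: int = 40,
                         reg: RegularizationConfig | None = None) -> STRF:
    """Reverse correlation pooled over several stimulus/response pairs.

    Accumulates the normal equations ``sum_s S_s^T S_s`` and
    ``sum_s S_s^T r_s`` across recordings before the regularized inversion;
    with few spikes per stimulus this is markedly more stable than averaging
    per-stimulus estimates.
    """
    reg = reg or RegularizationConfig()
    stimuli, rates = list(stimuli), list(rates)
    if not stimuli or len(stimuli) != len(rates):
        raise ValueError("need matching, non-empty stimulus and rate lists")
    M = stimuli[0].n_bands
    A = np.zeros((n_lag * M, n_lag * M))
    c = np.zeros(n_lag * M)
    for s, r in zip(stimuli, rates):
        if s.n_bands != M:
            raise ValueError("stimuli must share a band count")
        D = build_design_matrix(s, n_lag)
        A += D.T @ D
        c += D.T @ r.values[:s.n_times]
    h = regularized_pseudoinverse(A, reg.lam) @ c
    return STRF.from_vec(h, M, lag_dt=stimuli[0].dt)


def predict_rate(h: STRF, s: Spectrogram) -> SampledTrace:
    """Discrete convolution of the kernel with the stimulus (zero-padded)."""
    if h.n_bands != s.n_bands:
        raise ValueError("kernel and stimulus band counts differ")
    T = s.n_times
    out = np.zeros(T)
    for i in range(h.n_lags):
        w = h.kernel[:, i]
        out[i:] += s.values[:T - i] @ w
    return SampledTrace(out, dt=s.dt, unit="rate")


def cross_validate_lambda(s: Spectrogram, trials: TrialSet, n_lag: int,
                          lam_grid, folds: int = 4,
                          psth_bin: float | None = None) -> float:
    """Pick the SVD tolerance maximizing held-out predictive correlation.

    The recording is cut into ``folds`` contiguous time blocks; for each
    candidate ``lam`` the STRF estimated on the remaining blocks predicts
    the held-out PSTH, and the mean Pearson correlation across folds is the
    score.  Returns the best grid element.
    """
    lam_grid = list(lam_grid)
    if not lam_grid:
        raise ValueError("empty lambda grid")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    psth = compute_psth(trials, s.dt if psth_bin is None else psth_bin)
    rv = psth.values[:s.n_times]
    T = s.n_times
    edges = np.linspace(0, T, folds + 1).astype(int)
    if np.any(np.diff(edges) < n_lag):
        raise ValueError("folds too short for the requested lag count")
    D = build_design_matrix(s, n_lag)
    scores = np.zeros(len(lam_grid))
    for f in range(folds):
        lo, hi = edges[f], edges[f + 1]
        mask = np.ones(T, dtype=bool)
        mask[lo:hi] = False
        D_tr, r_tr = D[mask], rv[mask]
        D_te, r_te = D[lo:hi], rv[lo:hi]
        A = D_tr.T @ D_tr
        c = D_tr.T @ r_tr
        U, sig, Vt = np.linalg.svd(A, hermitian=True)
        total = sig.sum()
        frac = np.cumsum(sig) / total if total > 0 else np.ones_like(sig)
        for li, lam in enumerate(lam_grid):
            if lam >= 1.0:
                m = int(np.sum(sig > sig[0] * 1e-12))
            else:
                m = int(np.sum(frac < lam))
            m = max(m, 1)
            inv = np.zeros_like(sig)
            inv[:m] = 1.0 / sig[:m]
            h = (Vt.T * inv) @ (U.T @ c)
            pred = D_te @ h
            if np.std(pred) > 0 and np.std(r_te) > 0:
                scores[li] += float(np.corrcoef(pred, r_te)[0, 1])
    return float(lam_grid[int(np.argmax(scores))])


def normalize_l1(h: STRF) -> tuple[STRF, float]:
    """Split a kernel into its unit-L1 shape and a separate scale.

    ``predict_rate(h, s) == scale * predict_rate(h_unit, s)``; the scale is
    what the genetic algorithm optimizes alongside the neuron parameters.
    """
    scale = h.l1_norm()
    if scale <= 0:
        raise ValueError("cannot normalize an identically zero kernel")
    return STRF(h.kernel / scale, lag_dt=h.lag_dt), scale


# --------------------------------------------------------------------------
# delimited-text matrix I/O (rows = frequency bands low->high, columns =
# time/lag bins with lag 0 first; '#' header carries the bin width)


def write_matrix(path, values: np.ndarray, dt: float,
                 band_edges: np.ndarray | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# dt_ms={float(dt)!r}\n")
        if band_edges is not None:
            fh.write("# band_edges_hz=" + ",".join(repr(float(e)) for e in band_edges) + "\n")
        np.savetxt(fh, values, delimiter="\t")


def read_matrix(path) -> tuple[np.ndarray, float, np.ndarray | None]:
    dt = 1.0
    edges = None
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        s = line.strip()
        if s.startswith("#"):
            b = s[1:].strip()
            if b.startswith("dt_ms="):
                dt = float(b[len("dt_ms="):])
            elif b.startswith("band_edges_hz="):
                edges = np.asarray([float(x) for x in
                                    b[len("band_edges_hz="):].split(",")])
        elif s:
            body.append([float(x) for x in s.split()])
    return np.asarray(body), dt, edges
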