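"""STRF -> spiking-neuron cascade model and its tandem evolution.

The in-vivo model is a two-stage cascade: a spectro-temporal receptive
field, constrained to unit L1 norm, convolves the stimulus spectrogram into
an estimated input current ``I(t) = C * (h * s)(t)`` (the overall scale C is
a separate gene), which drives a deterministic aEIF neuron.  Because neither
stage can be fit in closed form against spike trains, both are evolved: two
populations — aEIF parameter sets (including C) and unit-norm kernels —
take turns evolving for ``phase_length`` generations each, every member
being scored against the current best member of the other population.  The
fitness is the summed van Rossum distance, per training stimulus, between
the candidate's spike train and the average filtered function of that
stimulus's trials, at a timescale annealing from half the stimulus length to
the trials' mean inter-spike interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evolution import (GAConfig, ParameterRange, default_ranges,
                        epsilon_schedule, select_roulette, tau_schedule)
from .metrics import (coincidence_factor, expected_coincidence_poisson,
                      expected_van_rossum_poisson, van_rossum_distance,
                      van_rossum_to_function)
from .neurons import FREE_PARAMETERS, ModelKind, ParameterSet, simulate
from .spike_trains import (SampledTrace, SpikeTrain, TrialSet,
                           average_function, mean_isi_and_rate)
from .strf import STRF, Spectrogram, normalize_l1, predict_rate

__all__ = [
    "CascadeGenome",
    "TandemConfig",
    "drive_current",
    "simulate_cascade",
    "mutate_strf",
    "crossover_strf",
    "tandem_fit",
    "benchmark_vs_poisson",
    "calibrate_rate",
    "select_reliable_cells",
]

#: neuron-side gene of the cascade: aEIF free parameters without the current
#: scale R (redundant with C), plus the cascade scale C as the last entry
CASCADE_NEURON_GENES = ("tau_m", "tau_w", "E_L", "Delta_T", "V_T", "b",
                        "alpha", "V_r")


@dataclass
class CascadeGenome:
    """A complete in-vivo model: unit-L1 STRF, scale C, aEIF parameters."""

    strf: STRF
    scale: float
    neuron: ParameterSet

    def __post_init__(self):
        if self.neuron.model != ModelKind.aEIF:
            raise ValueError("the cascade uses an aEIF neuron")
        if abs(self.strf.l1_norm() - 1.0) > 1e-6:
            raise ValueError("cascade STRF must be L1-normalized")


@dataclass
class TandemConfig:
    """Tandem-evolution knobs: one GA per population plus the alternation."""

    neuron_ga: GAConfig = field(default_factory=lambda: GAConfig(
        population_size=60, elite_count=3, max_generations=600))
    strf_population: int = 60
    strf_elite: int = 3
    strf_mutation_scale: float = 0.5
    strf_mutation_prob: float = 0.8
    phase_length: int = 50
    max_iterations: int = 600
    c_range: tuple[float, float] = (5.0, 100.0)
    seed: int = 0

    def __post_init__(self):
        if self.phase_length < 1:
            raise ValueError("phase_length must be at least 1")


def drive_current(genome: CascadeGenome, s: Spectrogram) -> SampledTrace:
    """Estimated input current ``C * (h * s)(t)`` on the stimulus grid."""
    rate = predict_rate(genome.strf, s)
    return SampledTrace(genome.scale * rate.values, dt=rate.dt, unit="current")


def simulate_cascade(genome: CascadeGenome, s: Spectrogram,
                     dt: float = 0.1) -> SpikeTrain:
    """Deterministic cascade response to one stimulus."""
    return simulate(genome.neuron, drive_current(genome, s), dt=dt).spikes


def mutate_strf(h: STRF, scale: float, rng: np.random.Generator) -> STRF:
    """Perturb a random rectangular patch (up to 4x4 bins) and re-normalize.

    The perturbation is zero-mean Gaussian with sd ``scale * mean|h|``; the
    output is always unit L1.  The operator is local in (band, lag) so
    mutations refine one region of the kernel at a time.
    """
    if scale <= 0:
        raise ValueError("mutation scale must be positive")
    k = h.kernel.copy()
    M, N = k.shape
    hb = int(rng.integers(1, min(4, M) + 1))
    wl = int(rng.integers(1, min(4, N) + 1))
    b0 = int(rng.integers(0, M - hb + 1))
    l0 = int(rng.integers(0, N - wl + 1))
    sd = scale * float(np.abs(k).mean())
    k[b0:b0 + hb, l0:l0 + wl] += rng.normal(0.0, sd, size=(hb, wl))
    total = np.abs(k).sum()
    if total <= 0:
        return h
    return STRF(k / total, lag_dt=h.lag_dt)


def crossover_strf(h1: STRF, h2: STRF, rng: np.random.Generator) -> STRF:
    """Per-coefficient uniform mix of two kernels, re-normalized to unit L1."""
    pick = rng.random(h1.kernel.shape) < 0.5
    k = np.where(pick, h1.kernel, h2.kernel)
    total = np.abs(k).sum()
    if total <= 0:
        k = h1.kernel.copy()
        total = np.abs(k).sum()
    return STRF(k / total, lag_dt=h1.lag_dt)


# --------------------------------------------------------------------------
# tandem fitting


class _CascadeContext:
    """Precomputed per-stimulus design matrices and annealed targets."""

    def __init__(self, stimuli, responses, average_mode="mean", dt=0.1):
        from .strf import build_design_matrix

        if len(stimuli) == 0 or len(stimuli) != len(responses):
            raise ValueError("need matching, non-empty stimulus and response lists")
        self.stimuli = list(stimuli)
        self.responses = list(responses)
        self.dt = dt
        self.average_mode = average_mode
        self.n_lags = None
        self.designs = None
        self.tau_starts = []
        self.tau_ends = []
        for s, trials in zip(self.stimuli, self.responses):
            T = s.duration
            pooled = [u for u in trials if u.n_spikes >= 2]
            isis = [mean_isi_and_rate(u)[0] for u in pooled]
            tau_end = float(np.mean(isis)) if isis else T / 2.0
            self.tau_starts.append(T / 2.0)
            self.tau_ends.append(min(tau_end, T / 2.0))

    def prepare_designs(self, n_lags: int):
        from .strf import build_design_matrix

        self.n_lags = n_lags
        self.designs = [build_design_matrix(s, n_lags) for s in self.stimuli]

    def taus(self, i: int, n: int) -> list[float]:
        return [tau_schedule(i, n, a, b)
                for a, b in zip(self.tau_starts, self.tau_ends)]

    def drive(self, stim_idx: int, h_vec: np.ndarray, c: float) -> SampledTrace:
        values = c * (self.designs[stim_idx] @ h_vec)
        return SampledTrace(values, dt=self.stimuli[stim_idx].dt, unit="current")

    def target(self, idx: int, tau: float):
        """Average filtered function of one stimulus's trials, with its
        squared norm, cached per (stimulus, timescale)."""
        if not hasattr(self, "_target_cache"):
            self._target_cache = {}
        key = (idx, round(tau, 9))
        if key not in self._target_cache:
            g = average_function(self.responses[idx], tau,
                                 mode=self.average_mode)
            self._target_cache[key] = (g, g.norm_sq())
            if len(self._target_cache) > 64:  # drop stale timescales
                for old in list(self._target_cache)[:32]:
                    del self._target_cache[old]
        return self._target_cache[key]

    def fitness(self, h_vec: np.ndarray, c: float, neuron: ParameterSet,
                taus: list[float]) -> float:
        from .spike_trains import filter_train

        total = 0.0
        for idx, tau in enumerate(taus):
            train = simulate(neuron, self.drive(idx, h_vec, c), dt=self.dt).spikes
            g, g_norm_sq = self.target(idx, tau)
            f = filter_train(train, tau)
            d2 = f.norm_sq() - 2.0 * f.inner(g) + g_norm_sq
            total += math.sqrt(max(d2, 0.0))
        return total


def tandem_fit(stimuli, responses, init_strf: STRF,
               config: TandemConfig | None = None,
               validation_stimuli=None, validation_responses=None,
               delta: float = 2.0, dt: float = 0.1,
               average_mode: str = "mean"):
    """Alternating evolution of the neuron and STRF populations.

    ``init_strf`` (typically the normalized-reverse-correlation estimate)
    seeds the kernel population: the first member is its unit-L1 shape, the
    rest are mutations of it.  The neuron population (aEIF genes plus the
    scale C) starts uniform in its feasible box.  Populations alternate
    every ``phase_length`` iterations; each is always scored against the
    frozen current-best member of the other.

    Returns ``(CascadeGenome, history)`` where history has one row per
    iteration: ``iteration, phase, best_f, mean_f, best_f_tau_end,
    mean_gamma_validation``.
    """
    config = config or TandemConfig()
    rng = np.random.default_rng(config.seed)
    ctx = _CascadeContext(stimuli, responses, average_mode, dt)
    ctx.prepare_designs(init_strf.n_lags)
    vctx = None
    if validation_stimuli:
        vctx = _CascadeContext(validation_stimuli, validation_responses,
                               average_mode, dt)
        vctx.prepare_designs(init_strf.n_lags)

    ncfg = config.neuron_ga
    n_total = config.max_iterations

    # neuron population: aEIF genes + C
    base = ParameterSet(model=ModelKind.aEIF, R=1.0)
    nrange = default_ranges(ModelKind.aEIF, base)
    keep = [nrange.names.index(n) for n in CASCADE_NEURON_GENES]
    lows = np.append(nrange.low[keep], config.c_range[0])
    highs = np.append(nrange.high[keep], config.c_range[1])
    gene_range = ParameterRange(CASCADE_NEURON_GENES + ("C",), lows, highs)
    n_pop = ncfg.population_size
    neuron_genes = gene_range.sample(rng, n_pop)

    def neuron_of(gene):
        return base.with_gene(gene[:-1], CASCADE_NEURON_GENES)

    # STRF population: the estimate plus mutations of it
    unit, _ = normalize_l1(init_strf)
    strfs = [unit]
    for _ in range(config.strf_population - 1):
        strfs.append(mutate_strf(unit, config.strf_mutation_scale, rng))

    def eval_neurons(genes, h_vec, taus):
        return np.asarray([ctx.fitness(h_vec, g[-1], neuron_of(g), taus)
                           for g in genes])

    def eval_strfs(pop, gene, taus):
        c, neuron = gene[-1], neuron_of(gene)
        return np.asarray([ctx.fitness(h.vec(), c, neuron, taus) for h in pop])

    taus0 = ctx.taus(0, n_total)
    best_strf_idx = 0
    h_best = strfs[best_strf_idx].vec()
    n_fits = eval_neurons(neuron_genes, h_best, taus0)
    best_gene = neuron_genes[int(np.argmin(n_fits))].copy()
    s_fits = eval_strfs(strfs, best_gene, taus0)

    best_combined = None
    best_combined_f = math.inf
    history = []

    def strf_step(fits, pop, i):
        order = np.argsort(fits, kind="stable")
        new = [pop[j] for j in order[:config.strf_elite]]
        scale_i = config.strf_mutation_scale * (0.1 ** (i / n_total))
        while len(new) < config.strf_population:
            a = pop[select_roulette(fits, rng)]
            b = pop[select_roulette(fits, rng)]
            child = crossover_strf(a, b, rng)
            if rng.random() < config.strf_mutation_prob:
                child = mutate_strf(child, scale_i, rng)
            new.append(child)
        return new

    def neuron_step(fits, genes, i):
        order = np.argsort(fits, kind="stable")
        new = np.empty_like(genes)
        k = ncfg.elite_count
        new[:k] = genes[order[:k]]
        eps = epsilon_schedule(i, n_total, ncfg.eps_m0, ncfg.eps_m_min)
        for m in range(k, genes.shape[0]):
            i1, i2 = select_roulette(fits, rng), select_roulette(fits, rng)
            pick = rng.random(genes.shape[1]) < 0.5
            child = np.where(pick, genes[i1], genes[i2])
            if rng.random() < ncfg.mutation_prob:
                j = int(rng.integers(child.size))
                child = child.copy()
                child[j] *= 1.0 + rng.normal(0.0, math.sqrt(eps))
            new[m] = gene_range.clip(child)
        return new

    for i in range(1, n_total + 1):
        taus = ctx.taus(i, n_total)
        phase = (i - 1) // config.phase_length
        evolving_neurons = (phase % 2 == 0)
        if evolving_neurons:
            neuron_genes = neuron_step(n_fits, neuron_genes, i)
            n_fits = eval_neurons(neuron_genes, h_best, taus)
            j = int(np.argmin(n_fits))
            best_gene = neuron_genes[j].copy()
            best_f, mean_f = float(n_fits[j]), float(np.mean(n_fits))
        else:
            strfs = strf_step(s_fits, strfs, i)
            s_fits = eval_strfs(strfs, best_gene, taus)
            j = int(np.argmin(s_fits))
            h_best = strfs[j].vec()
            best_strf_idx = j
            best_f, mean_f = float(s_fits[j]), float(np.mean(s_fits))
        # at phase boundaries the partner population is re-scored against
        # the newly frozen best of the evolving one
        if i % config.phase_length == 0:
            if evolving_neurons:
                s_fits = eval_strfs(strfs, best_gene, taus)
                j = int(np.argmin(s_fits))
                h_best = strfs[j].vec()
            else:
                n_fits = eval_neurons(neuron_genes, h_best, taus)
                best_gene = neuron_genes[int(np.argmin(n_fits))].copy()

        f_end = _CascadeContext.fitness(
            ctx, h_best, best_gene[-1], neuron_of(best_gene),
            ctx.tau_ends)
        if f_end < best_combined_f:
            best_combined_f = f_end
            best_combined = (h_best.copy(), best_gene.copy())
        gamma = math.nan
        if vctx is not None:
            gammas = []
            for idx, trials in enumerate(vctx.responses):
                train = simulate(neuron_of(best_gene),
                                 vctx.drive(idx, h_best, best_gene[-1]),
                                 dt=dt).spikes
                for u in trials:
                    try:
                        gammas.append(coincidence_factor(train, u, delta).gamma)
                    except ValueError:
                        pass
            if gammas:
                gamma = float(np.mean(gammas))
        history.append((i, "neuron" if evolving_neurons else "strf",
                        best_f, mean_f, f_end, gamma))

    h_vec, gene = best_combined
    genome = CascadeGenome(
        strf=STRF.from_vec(h_vec, stimuli[0].n_bands, lag_dt=init_strf.lag_dt),
        scale=float(gene[-1]),
        neuron=neuron_of(gene),
    )
    hist = pd.DataFrame(history, columns=[
        "iteration", "phase", "best_f", "mean_f", "best_f_tau_end",
        "mean_gamma_validation"])
    return genome, hist


# --------------------------------------------------------------------------
# benchmarking against Poisson rate models


def calibrate_rate(rate: SampledTrace, target_mean_rate: float) -> SampledTrace:
    """Floor a predicted rate at zero and rescale to a target mean (spikes/ms)."""
    v = np.clip(rate.values, 0.0, None)
    m = v.mean()
    if m > 0:
        v = v * (target_mean_rate / m)
    return SampledTrace(v, dt=rate.dt, unit="spikes/ms")


@dataclass
class BenchmarkReport:
    per_stimulus: pd.DataFrame
    cascade_gamma_mean: float
    poisson_gamma_mean: float
    cascade_d_mean: float
    poisson_d_mean: float
    gamma_win_fraction: float
    d_win_fraction: float


def benchmark_vs_poisson(genome: CascadeGenome, stimuli, rates, validation,
                         delta: float = 2.0, tau: float = 10.0,
                         n_mc: int = 100, seed: int = 0,
                         dt: float = 0.1) -> BenchmarkReport:
    """Deterministic cascade vs. Poisson rate model on validation stimuli.

    ``rates`` are the calibrated (nonnegative, mean-matched) STRF rate
    predictions, one per validation stimulus.  For each stimulus the cascade
    spike train's mean coincidence factor and van Rossum distance across
    trials are compared with the Poisson model's expected values.
    """
    rows = []
    for idx, (stim, rate, trials) in enumerate(zip(stimuli, rates, validation)):
        train = simulate_cascade(genome, stim, dt=dt)
        gammas, dists = [], []
        pg, pd_ = [], []
        for k, u in enumerate(trials):
            try:
                gammas.append(coincidence_factor(train, u, delta).gamma)
                pg.append(expected_coincidence_poisson(
                    rate, u, delta, n_mc=n_mc, seed=seed + 1000 * idx + k))
            except ValueError:
                pass
            dists.append(van_rossum_distance(train, u, tau))
            pd_.append(expected_van_rossum_poisson(rate, u, tau))
        rows.append((idx, float(np.mean(gammas)) if gammas else math.nan,
                     float(np.mean(pg)) if pg else math.nan,
                     float(np.mean(dists)), float(np.mean(pd_))))
    df = pd.DataFrame(rows, columns=["stimulus", "cascade_gamma",
                                     "poisson_gamma", "cascade_d", "poisson_d"])
    return BenchmarkReport(
        per_stimulus=df,
        cascade_gamma_mean=float(df.cascade_gamma.mean()),
        poisson_gamma_mean=float(df.poisson_gamma.mean()),
        cascade_d_mean=float(df.cascade_d.mean()),
        poisson_d_mean=float(df.poisson_d.mean()),
        gamma_win_fraction=float((df.cascade_gamma > df.poisson_gamma).mean()),
        d_win_fraction=float((df.cascade_d < df.poisson_d).mean()),
    )


def select_reliable_cells(trial_sets_by_cell: dict, delta: float = 2.0,
                          threshold: float = 0.1) -> list:
    """Utility filter: keep cells whose mean intrinsic reliability across
    stimuli exceeds ``threshold`` (chance level is 0)."""
    from .metrics import intrinsic_reliability

    keep = []
    for cell, trial_sets in trial_sets_by_cell.items():
        vals = [intrinsic_reliability(ts, delta).gamma_i for ts in trial_sets
                if len(ts) >= 2]
        if vals and float(np.mean(vals)) > threshold:
            keep.append(cell)
    return keep
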