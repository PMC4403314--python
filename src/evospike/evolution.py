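"""Hybrid genetic algorithm for spiking-neuron parameter estimation.

Real-valued genes, elitism, roulette selection, per-coordinate uniform
crossover and a non-uniform (decaying) multiplicative Gaussian mutation.  The
fitness is the van Rossum distance between the candidate's spike train and
the target, evaluated at a timescale that anneals geometrically across
generations from ``tau_start`` (of order half the data length) down to
``tau_end`` (of order the target's mean inter-spike interval): early
generations match firing rates, late generations match spike times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import coincidence_factor, van_rossum_distance, van_rossum_to_function
from .neurons import FREE_PARAMETERS, ModelKind, ParameterSet, simulate
from .spike_trains import (FilteredFunction, SampledTrace, SpikeTrain,
                           TrialSet, average_function, mean_isi_and_rate)

__all__ = [
    "ParameterRange",
    "GAConfig",
    "Population",
    "tau_schedule",
    "epsilon_schedule",
    "select_roulette",
    "crossover",
    "mutate",
    "evolve_generation",
    "fit_neuron",
    "default_ranges",
]


@dataclass(frozen=True)
class ParameterRange:
    """Axis-aligned feasible region S: per-gene [low, high] bounds."""

    names: tuple[str, ...]
    low: np.ndarray
    high: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.low, dtype=float)
        hi = np.asarray(self.high, dtype=float)
        object.__setattr__(self, "low", lo)
        object.__setattr__(self, "high", hi)
        if lo.shape != hi.shape or lo.size != len(self.names):
            raise ValueError("bounds must match the number of named parameters")
        if np.any(lo >= hi):
            raise ValueError("each low bound must be below its high bound")

    @property
    def n_params(self) -> int:
        return len(self.names)

    @classmethod
    def from_dict(cls, bounds: dict[str, tuple[float, float]]) -> "ParameterRange":
        names = tuple(bounds)
        lo = [bounds[n][0] for n in names]
        hi = [bounds[n][1] for n in names]
        return cls(names, np.asarray(lo), np.asarray(hi))

    @classmethod
    def around(cls, center: dict[str, float], lo_frac: float = 0.3,
               hi_frac: float = 1.7) -> "ParameterRange":
        """Bounds at ``[lo_frac, hi_frac]`` times a canonical value per axis.

        Negative canonical values get the mirrored interval so the bounds
        stay ordered.
        """
        bounds = {}
        for n, c in center.items():
            a, b = lo_frac * c, hi_frac * c
            bounds[n] = (min(a, b), max(a, b))
        return cls.from_dict(bounds)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=(n, self.n_params))

    def clip(self, gene: np.ndarray) -> np.ndarray:
        return np.clip(gene, self.low, self.high)


def default_ranges(model: ModelKind, base: ParameterSet | None = None,
                   lo_frac: float = 0.3, hi_frac: float = 1.7) -> ParameterRange:
    """Feasible region spanning ``[0.3x, 1.7x]`` of canonical parameter values."""
    base = ParameterSet(model=model) if base is None else base
    names = FREE_PARAMETERS[model]
    return ParameterRange.around({n: getattr(base, n) for n in names},
                                 lo_frac, hi_frac)


@dataclass
class GAConfig:
    """Run-time knobs of the genetic algorithm.

    ``eps_m0`` is the *variance* of the multiplicative Gaussian mutation at
    generation 0 (0.2 is a good general-purpose start); it decays
    geometrically to ``eps_m_min`` over the run.  ``tau_start``/``tau_end``
    (ms) bound the annealed fitness timescale; either may be None to use
    data-driven defaults (half the record length and the target mean ISI).
    ``stop_eps`` halts early once the tracked distance falls below it.
    """

    population_size: int = 240
    elite_count: int = 12
    mutation_prob: float = 0.05
    eps_m0: float = 0.2
    eps_m_min: float = 0.01
    max_generations: int = 200
    stop_eps: float | None = None
    tau_start: float | None = None
    tau_end: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.elite_count < self.population_size):
            raise ValueError("need 1 <= elite_count < population_size")
        if not (0.0 < self.mutation_prob < 1.0):
            raise ValueError("mutation_prob must lie in (0, 1)")


@dataclass
class Population:
    """One GA generation: genes (N x d), their fitnesses, and the index."""

    genes: np.ndarray
    fitnesses: np.ndarray
    generation: int = 0

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitnesses))

    @property
    def best_fitness(self) -> float:
        return float(self.fitnesses[self.best_index])


def tau_schedule(i: int, n_gen: int, tau_start: float, tau_end: float) -> float:
    """Geometric interpolation from ``tau_start`` (i=0) to ``tau_end`` (i=N)."""
    if not (tau_start >= tau_end > 0):
        raise ValueError("need tau_start >= tau_end > 0")
    if n_gen <= 0:
        return tau_end
    return tau_start * (tau_end / tau_start) ** (i / n_gen)


def epsilon_schedule(i: int, n_gen: int, eps_m0: float = 0.2,
                     eps_min: float = 0.01) -> float:
    """Geometric decay of the mutation variance from eps_m0 to eps_min."""
    if n_gen <= 0:
        return eps_min
    return eps_m0 * (eps_min / eps_m0) ** (i / n_gen)


def select_roulette(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Roulette-wheel pick with probability decreasing in the distance.

    Fitness here is a distance (smaller is better) while roulette selection
    presumes a quantity to maximize, so genes are weighted by
    ``(max - fit) + eta`` with a small floor ``eta`` proportional to the
    fitness spread; an all-equal population degrades to uniform selection.
    """
    f = np.asarray(fitnesses, dtype=float)
    spread = float(f.max() - f.min())
    if spread <= 0:
        return int(rng.integers(f.size))
    w = (f.max() - f) + 1e-6 * spread
    return int(rng.choice(f.size, p=w / w.sum()))


def crossover(x1: np.ndarray, x2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-coordinate uniform mix: each child gene copied from either parent."""
    if x1.shape != x2.shape:
        raise ValueError("parents must share a gene layout")
    pick = rng.random(x1.shape) < 0.5
    return np.where(pick, x1, x2)


def mutate(x: np.ndarray, eps_m: float, rng: np.random.Generator,
           ranges: ParameterRange | None = None) -> np.ndarray:
    """Rescale one uniformly chosen coordinate by ``1 + r``, r ~ N(0, eps_m).

    ``eps_m`` is the variance of r; the result is clipped to the feasible
    region when ``ranges`` is given.
    """
    if eps_m <= 0:
        raise ValueError("eps_m must be positive")
    y = x.copy()
    j = int(rng.integers(x.size))
    y[j] = y[j] * (1.0 + rng.normal(0.0, math.sqrt(eps_m)))
    return ranges.clip(y) if ranges is not None else y


def evolve_generation(pop: Population, eval_fn, config: GAConfig,
                      rng: np.random.Generator,
                      ranges: ParameterRange | None = None) -> Population:
    """Produce and evaluate the next generation.

    The ``elite_count`` fittest genes (ties broken by gene index) are copied
    unchanged and protected from mutation; the remaining slots are filled by
    roulette-selected parents recombined by uniform crossover, each child
    then mutated with probability ``mutation_prob``.  ``eval_fn(genes)``
    returns the fitness array; every member is (re-)evaluated once, so the
    per-generation evaluation count equals the population size.
    """
    n, d = pop.genes.shape
    k = config.elite_count
    order = np.argsort(pop.fitnesses, kind="stable")
    new = np.empty_like(pop.genes)
    new[:k] = pop.genes[order[:k]]
    for m in range(k, n):
        i1 = select_roulette(pop.fitnesses, rng)
        i2 = select_roulette(pop.fitnesses, rng)
        child = crossover(pop.genes[i1], pop.genes[i2], rng)
        if ranges is not None:
            child = ranges.clip(child)
        if rng.random() < config.mutation_prob:
            eps = epsilon_schedule(pop.generation, config.max_generations,
                                   config.eps_m0, config.eps_m_min)
            child = mutate(child, eps, rng, ranges)
        new[m] = child
    fits = np.asarray(eval_fn(new), dtype=float)
    return Population(new, fits, pop.generation + 1)


# --------------------------------------------------------------------------
# end-to-end neuron fitting


class _NeuronFitness:
    """Evaluates neuron genes: simulate on the current, distance to target."""

    def __init__(self, target, current: SampledTrace, base: ParameterSet,
                 names: tuple[str, ...], dt: float, map_fn,
                 average_mode: str = "mean", use_fast_exp: bool = False,
                 tie_params: dict[str, str] | None = None):
        self.current = current
        self.base = base
        self.names = names
        self.dt = dt
        self.map_fn = map_fn
        self.average_mode = average_mode
        self.use_fast_exp = use_fast_exp
        self.tie_params = tie_params or {}
        # hot path: packed parameter vectors straight into the compiled core
        from .neurons import PACKED_INDEX
        self._packed_base = base._packed()
        self._kind = int(base.model)
        self._gene_idx = np.asarray([PACKED_INDEX[n] for n in names],
                                    dtype=np.intp)
        self._tie_idx = [(PACKED_INDEX[d], PACKED_INDEX[s])
                         for d, s in self.tie_params.items()]
        if isinstance(target, SpikeTrain):
            self.target_train = target
            self.trials = None
        elif isinstance(target, TrialSet):
            self.target_train = None
            self.trials = target
        else:
            raise TypeError("target must be a SpikeTrain or TrialSet")

    def params_of(self, gene: np.ndarray) -> ParameterSet:
        p = self.base.with_gene(gene, self.names)
        if self.tie_params:
            p = replace(p, **{dst: getattr(p, src)
                              for dst, src in self.tie_params.items()})
        return p

    def simulate_gene(self, gene: np.ndarray) -> SpikeTrain:
        from .neurons import simulate_packed

        pp = self._packed_base.copy()
        pp[self._gene_idx] = gene
        for d, s in self._tie_idx:
            pp[d] = pp[s]
        t = simulate_packed(self._kind, pp, self.current.values,
                            self.current.dt, self.dt, self.use_fast_exp)
        return SpikeTrain(t, self.current.values.size * self.current.dt)

    def trains(self, genes: np.ndarray) -> list[SpikeTrain]:
        return list(self.map_fn(self.simulate_gene, list(genes)))

    def distance(self, train: SpikeTrain, tau: float) -> float:
        if self.target_train is not None:
            return van_rossum_distance(train, self.target_train, tau)
        g = average_function(self.trials, tau, mode=self.average_mode)
        return van_rossum_to_function(train, g)

    def distances(self, trains: list[SpikeTrain], tau: float) -> np.ndarray:
        if self.target_train is None:
            g = average_function(self.trials, tau, mode=self.average_mode)
            return np.asarray([van_rossum_to_function(t, g) for t in trains])
        return np.asarray([van_rossum_distance(t, self.target_train, tau)
                           for t in trains])


def _default_tau_bounds(target, current: SampledTrace,
                        config: GAConfig) -> tuple[float, float]:
    T = current.duration
    tau_start = config.tau_start if config.tau_start is not None else T / 2.0
    tau_end = config.tau_end
    if tau_end is None:
        train = target if isinstance(target, SpikeTrain) else max(
            target, key=lambda u: u.n_spikes)
        isi, rate = mean_isi_and_rate(train)
        tau_end = isi if isi is not None else tau_start
    tau_end = min(tau_end, tau_start)
    return tau_start, tau_end


def fit_neuron(target, current: SampledTrace,
               model: ModelKind = ModelKind.aEIF,
               ranges: ParameterRange | None = None,
               config: GAConfig | None = None,
               base_params: ParameterSet | None = None,
               validation_target: SpikeTrain | None = None,
               validation_current: SampledTrace | None = None,
               delta: float = 2.0, dt: float = 0.1,
               average_mode: str = "mean", use_fast_exp: bool = False,
               map_fn=map, initial_genes: np.ndarray | None = None,
               fixed_tau: bool = False,
               tie_params: dict[str, str] | None = None):
    """Fit a spiking neuron model to a target spike train by evolution.

    Parameters
    ----------
    target : SpikeTrain or TrialSet
        Training target.  A TrialSet is matched through its average filtered
        function (rebuilt at each generation's timescale).
    current : SampledTrace
        Injected current driving every candidate model.
    model, ranges, config, base_params
        Model kind, feasible region (defaults to the canonical +-70% box),
        GA configuration, and the carrier for the fixed (non-gene)
        parameters.
    validation_target, validation_current, delta
        Optional held-out data; the generation-best coincidence factor at
        window ``delta`` (ms) is tracked per generation but never optimized.
    map_fn
        Pluggable map over gene simulations (e.g. a multiprocessing map);
        the sequential builtin is the deterministic default.
    initial_genes
        Optional seed genes replacing the head of the random initial
        population (e.g. a previously found solution).
    fixed_tau : bool
        If True the fitness timescale stays at ``tau_start`` for the whole
        run instead of annealing (used for schedule comparisons).
    tie_params : dict, optional
        Non-gene parameters slaved to gene parameters, e.g.
        ``{"V_r": "E_L"}`` makes the reset voltage follow the resting
        potential (the usual constraint in recovery benchmarks).

    Returns
    -------
    (ParameterSet, pandas.DataFrame)
        The best-ever parameter set (by distance at the final timescale) and
        the per-generation history: ``generation, tau_ms, eps_m, best_d,
        mean_d, best_d_tau_end, best_gamma_validation``.
    """
    config = config or GAConfig()
    base = ParameterSet(model=model) if base_params is None else base_params
    if base.model != model:
        base = replace(base, model=model)
    if ranges is None:
        ranges = default_ranges(model, base)
    names = ranges.names
    rng = np.random.default_rng(config.seed)
    tau_start, tau_end = _default_tau_bounds(target, current, config)
    n_gen = config.max_generations

    ctx = _NeuronFitness(target, current, base, names, dt, map_fn,
                         average_mode, use_fast_exp, tie_params)
    genes = ranges.sample(rng, config.population_size)
    if initial_genes is not None:
        initial_genes = np.atleast_2d(np.asarray(initial_genes, dtype=float))
        genes[:initial_genes.shape[0]] = initial_genes

    best_gene = None
    best_d_end = math.inf
    history = []

    def tau_at(i):
        return tau_start if fixed_tau else tau_schedule(i, n_gen, tau_start, tau_end)

    pop = None
    for i in range(n_gen + 1):
        tau_i = tau_at(i)
        if i == 0:
            trains = ctx.trains(genes)
            fits = ctx.distances(trains, tau_i)
            pop = Population(genes, fits, 0)
        else:
            holder = {}

            def eval_fn(g, _tau=tau_i, _holder=holder):
                tr = ctx.trains(g)
                _holder["trains"] = tr
                return ctx.distances(tr, _tau)

            pop = evolve_generation(pop, eval_fn, config, rng, ranges)
            trains = holder["trains"]
        j = pop.best_index
        d_end = ctx.distance(trains[j], tau_end)
        if d_end < best_d_end:
            best_d_end = d_end
            best_gene = pop.genes[j].copy()
        gamma = math.nan
        if validation_target is not None:
            vcur = validation_current if validation_current is not None else current
            vres = simulate(ctx.params_of(pop.genes[j]), vcur, dt=dt,
                            use_fast_exp=use_fast_exp)
            try:
                gamma = coincidence_factor(vres.spikes, validation_target, delta).gamma
            except ValueError:
                gamma = math.nan
        eps_i = epsilon_schedule(i, n_gen, config.eps_m0, config.eps_m_min)
        history.append((i, tau_i, eps_i, pop.best_fitness,
                        float(np.mean(pop.fitnesses)), d_end, gamma))
        if config.stop_eps is not None and d_end < config.stop_eps:
            break

    hist = pd.DataFrame(history, columns=[
        "generation", "tau_ms", "eps_m", "best_d", "mean_d",
        "best_d_tau_end", "best_gamma_validation"])
    return ctx.params_of(best_gene), hist
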