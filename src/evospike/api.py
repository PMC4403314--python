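"""Model/Results front end.

Each estimation problem is wrapped statsmodels-style: a model object is
built from data, its ``fit()`` runs the estimation and returns a results
object carrying the estimates, their spread across repeated runs where
applicable, the convergence history and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cascade import CascadeGenome, TandemConfig, simulate_cascade, tandem_fit
from .evolution import GAConfig, ParameterRange, default_ranges, fit_neuron
from .metrics import coincidence_factor, van_rossum_distance
from .neurons import FREE_PARAMETERS, ModelKind, ParameterSet, simulate
from .spike_trains import SampledTrace, SpikeTrain, TrialSet
from .strf import (STRF, RegularizationConfig, Spectrogram, compute_psth,
                   cross_validate_lambda, estimate_strf, predict_rate)

__all__ = [
    "NeuronFit",
    "NeuronFitResults",
    "STRFModel",
    "STRFResults",
    "CascadeFit",
    "CascadeResults",
]


class NeuronFit:
    """Evolutionary fit of a spiking neuron model to a target spike train.

    Parameters
    ----------
    target : SpikeTrain or TrialSet
        Training spikes (a TrialSet is matched via its average function).
    current : SampledTrace
        The injected current.
    kind : ModelKind
        Which model family to fit.
    ranges : ParameterRange, optional
        Feasible region; defaults to a +-70% box around canonical values.
    validation_target, validation_current : optional held-out data for
        tracking the coincidence factor during the run.

    Examples
    --------
    >>> model = NeuronFit(train_spikes, current, kind=ModelKind.aEIF)
    >>> res = model.fit(GAConfig(population_size=100, max_generations=250),
    ...                 n_runs=5)
    >>> print(res.summary())
    """

    def __init__(self, target, current: SampledTrace,
                 kind: ModelKind = ModelKind.aEIF,
                 ranges: ParameterRange | None = None,
                 base_params: ParameterSet | None = None,
                 validation_target: SpikeTrain | None = None,
                 validation_current: SampledTrace | None = None,
                 delta: float = 2.0, dt: float = 0.1):
        self.target = target
        self.current = current
        self.kind = kind
        self.ranges = ranges if ranges is not None else default_ranges(
            kind, base_params)
        self.base_params = base_params
        self.validation_target = validation_target
        self.validation_current = validation_current
        self.delta = delta
        self.dt = dt

    def fit(self, config: GAConfig | None = None, n_runs: int = 1,
            use_fast_exp: bool = False, map_fn=map,
            fixed_tau: bool = False) -> "NeuronFitResults":
        """Run the genetic algorithm ``n_runs`` times (seeds offset by run).

        With ``n_runs > 1`` the results object reports the mean and standard
        deviation of each recovered parameter across runs, the standard way
        to quote the stochastic-search uncertainty.
        """
        config = config or GAConfig()
        runs, histories = [], []
        for r in range(n_runs):
            cfg = replace(config, seed=config.seed + r)
            params, hist = fit_neuron(
                self.target, self.current, model=self.kind,
                ranges=self.ranges, config=cfg, base_params=self.base_params,
                validation_target=self.validation_target,
                validation_current=self.validation_current,
                delta=self.delta, dt=self.dt, use_fast_exp=use_fast_exp,
                map_fn=map_fn, fixed_tau=fixed_tau)
            runs.append(params)
            histories.append(hist)
        return NeuronFitResults(self, runs, histories, config)


class NeuronFitResults:
    """Best-fit parameters, per-run spread, and convergence history."""

    def __init__(self, model: NeuronFit, runs, histories, config):
        self.model = model
        self.runs = runs
        self.histories = histories
        self.config = config
        self.names = model.ranges.names
        self._genes = np.array([p.to_gene(self.names) for p in runs])

    @property
    def params(self) -> ParameterSet:
        """The parameter set of the best run (lowest final distance)."""
        finals = [h.best_d_tau_end.iloc[-1] for h in self.histories]
        return self.runs[int(np.argmin(finals))]

    @property
    def params_mean(self) -> dict:
        return dict(zip(self.names, self._genes.mean(axis=0)))

    @property
    def params_sd(self) -> dict:
        return dict(zip(self.names, self._genes.std(axis=0, ddof=1)
                        if len(self.runs) > 1 else np.zeros(len(self.names))))

    @property
    def history(self) -> pd.DataFrame:
        return self.histories[0]

    @property
    def final_distance(self) -> float:
        return float(min(h.best_d_tau_end.iloc[-1] for h in self.histories))

    def predicted_spikes(self, current: SampledTrace | None = None) -> SpikeTrain:
        cur = current if current is not None else self.model.current
        return simulate(self.params, cur, dt=self.model.dt).spikes

    def validation_gamma(self) -> float:
        """Coincidence factor of the best fit on the held-out data."""
        if self.model.validation_target is None:
            raise ValueError("no validation data attached to the model")
        train = self.predicted_spikes(self.model.validation_current)
        return coincidence_factor(train, self.model.validation_target,
                                  self.model.delta).gamma

    def summary(self) -> str:
        lines = [
            "Evolutionary neuron fit",
            "=" * 55,
            f"model: {self.model.kind.name}    runs: {len(self.runs)}    "
            f"generations: {self.config.max_generations}",
            f"population: {self.config.population_size}    "
            f"final van Rossum distance: {self.final_distance:.4g}",
            "-" * 55,
            f"{'parameter':>10} {'mean':>12} {'sd':>10} {'low':>10} {'high':>10}",
        ]
        mu, sd = self.params_mean, self.params_sd
        for j, n in enumerate(self.names):
            lines.append(f"{n:>10} {mu[n]:>12.5g} {sd[n]:>10.3g} "
                         f"{self.model.ranges.low[j]:>10.4g} "
                         f"{self.model.ranges.high[j]:>10.4g}")
        return "\n".join(lines)


class STRFModel:
    """Linear receptive-field estimation from a spectrogram and spike trials.

    ``fit()`` runs normalized reverse correlation; when a grid of SVD
    tolerances is given, the tolerance is chosen by cross-validated held-out
    correlation first.
    """

    def __init__(self, stimulus: Spectrogram, response, n_lags: int = 40,
                 psth_bin: float | None = None):
        self.stimulus = stimulus
        if isinstance(response, TrialSet):
            self.trials = response
            self.rate = compute_psth(response,
                                     psth_bin if psth_bin else stimulus.dt)
        elif isinstance(response, SampledTrace):
            self.trials = None
            self.rate = response
        else:
            raise TypeError("response must be a TrialSet or SampledTrace")
        self.n_lags = n_lags

    def fit(self, lam: float = 1.0, lam_grid=None, folds: int = 4) -> "STRFResults":
        if lam_grid is not None:
            if self.trials is None:
                raise ValueError("cross-validation needs spike trials")
            lam = cross_validate_lambda(self.stimulus, self.trials,
                                        self.n_lags, lam_grid, folds)
        strf = estimate_strf(self.stimulus, self.rate, self.n_lags,
                             RegularizationConfig(lam=lam, folds=folds))
        return STRFResults(self, strf, lam)


class STRFResults:
    def __init__(self, model: STRFModel, strf: STRF, lam: float):
        self.model = model
        self.strf = strf
        self.lam = lam

    def predicted_rate(self, stimulus: Spectrogram | None = None) -> SampledTrace:
        s = stimulus if stimulus is not None else self.model.stimulus
        return predict_rate(self.strf, s)

    def prediction_correlation(self) -> float:
        pred = self.predicted_rate().values
        obs = self.model.rate.values[:pred.size]
        if np.std(pred) == 0 or np.std(obs) == 0:
            return math.nan
        return float(np.corrcoef(pred, obs)[0, 1])

    def summary(self) -> str:
        k = self.strf.kernel
        return "\n".join([
            "Normalized reverse-correlation STRF",
            "=" * 45,
            f"bands: {self.strf.n_bands}    lags: {self.strf.n_lags}    "
            f"width: {self.strf.temporal_width:g} ms",
            f"SVD tolerance lambda: {self.lam:g}",
            f"kernel L1 norm: {np.abs(k).sum():.4g}    "
            f"peak |h|: {np.abs(k).max():.4g}",
            f"training prediction correlation: "
            f"{self.prediction_correlation():.3f}",
        ])


class CascadeFit:
    """Tandem evolution of an STRF -> aEIF cascade against multi-trial data.

    The initial kernel defaults to the reverse-correlation estimate pooled
    over the training stimuli (estimated per stimulus and averaged).
    """

    def __init__(self, stimuli, responses, init_strf: STRF | None = None,
                 n_lags: int = 40, validation_stimuli=None,
                 validation_responses=None, delta: float = 2.0,
                 init_lam: float = 0.99, psth_smooth_ms: float = 2.0):
        from scipy.ndimage import gaussian_filter1d

        from .strf import RegularizationConfig, estimate_strf_pooled

        self.stimuli = list(stimuli)
        self.responses = list(responses)
        self.validation_stimuli = validation_stimuli
        self.validation_responses = validation_responses
        self.delta = delta
        if init_strf is None:
            # pooled reverse correlation over the training stimuli, with a
            # lightly smoothed PSTH: spikes are sparse relative to the kernel
            # dimension, so pooling and smoothing stabilize the seed kernel
            rates = []
            for s, trials in zip(self.stimuli, self.responses):
                psth = compute_psth(trials, s.dt)
                v = gaussian_filter1d(psth.values, psth_smooth_ms / s.dt)
                rates.append(SampledTrace(v, dt=s.dt))
            init_strf = estimate_strf_pooled(
                self.stimuli, rates, n_lags,
                RegularizationConfig(lam=init_lam))
        self.init_strf = init_strf

    def fit(self, config: TandemConfig | None = None) -> "CascadeResults":
        genome, hist = tandem_fit(
            self.stimuli, self.responses, self.init_strf, config,
            validation_stimuli=self.validation_stimuli,
            validation_responses=self.validation_responses,
            delta=self.delta)
        return CascadeResults(self, genome, hist)


class CascadeResults:
    def __init__(self, model: CascadeFit, genome: CascadeGenome,
                 history: pd.DataFrame):
        self.model = model
        self.genome = genome
        self.history = history

    def predicted_spikes(self, stimulus: Spectrogram) -> SpikeTrain:
        return simulate_cascade(self.genome, stimulus)

    def validation_gamma(self) -> float:
        if not self.model.validation_stimuli:
            raise ValueError("no validation data attached")
        gammas = []
        for s, trials in zip(self.model.validation_stimuli,
                             self.model.validation_responses):
            train = self.predicted_spikes(s)
            for u in trials:
                gammas.append(coincidence_factor(train, u,
                                                 self.model.delta).gamma)
        return float(np.mean(gammas))

    def summary(self) -> str:
        n = self.genome.neuron
        lines = [
            "STRF -> aEIF cascade fit (tandem evolution)",
            "=" * 50,
            f"iterations: {len(self.history)}    final training fitness: "
            f"{self.history.best_f_tau_end.iloc[-1]:.4g}",
            f"scale C: {self.genome.scale:.4g}    STRF L1 norm: "
            f"{self.genome.strf.l1_norm():.4g}",
            f"aEIF: tau_m={n.tau_m:.3g} ms  tau_w={n.tau_w:.4g} ms  "
            f"E_L={n.E_L:.4g} mV  V_T={n.V_T:.4g} mV",
            f"      Delta_T={n.Delta_T:.3g} mV  b={n.b:.3g}  "
            f"alpha={n.alpha:.3g}  V_r={n.V_r:.4g} mV",
        ]
        g = self.history.mean_gamma_validation.dropna()
        if len(g):
            lines.append(f"final mean validation coincidence factor: "
                         f"{g.iloc[-1]:.3f}")
        return "\n".join(lines)
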