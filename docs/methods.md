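# Methods

`evospike` estimates parameters of spiking neuron models from spike-train
data with a hybrid genetic algorithm, and extends the estimation to an
STRF → neuron cascade for sensory recordings.  This note documents the
models, the fitness machinery, the algorithmic choices that were genuinely
open, the synthetic benchmarks, and the package's known limitations.

## Spiking neuron models

All models share the two-variable template

    dv/dt = f(v) − w + R·I(t),        dw/dt = a·(b·v − w),

with a hard reset on reaching a cutoff voltage `v_c`: `v → v_r`,
`w → w + α`.  The family members differ in `f(v)` and in which variable
adapts:

| model | f(v) | adaptation | free (gene) parameters |
|-------|------|------------|------------------------|
| IF    | −(v−E_L)/τ_m | none | τ_m, R |
| aIF   | −(v−E_L)/τ_m | current w | τ_m, τ_w, α, R |
| atIF  | −(v−E_L)/τ_m | cutoff: τ_t dv_c/dt = b·v − v_c, v_c → v_c+α | τ_m, τ_t, α, b, R |
| aEIF  | [(E_L−v) + Δ_T·e^{(v−V_T)/Δ_T}]/τ_m | current w | τ_m, τ_w, E_L, Δ_T, V_T, b, α, V_r, R |
| a²EIF | as aEIF but the whole RHS (incl. w, R·I) is divided by τ_m and the exponential threshold v_t adapts: τ_t dv_t/dt = V_t0 − v_t, v_t → v_t+β | both | + τ_t, β, V_t0 |
| aQIF  | 0.04v² + 5v + 140 (Izhikevich) | current w | a, b, c(=V_r), d(=α), R |

Conventions and numerical choices:

* Times in ms, voltages in mV; the injected current's units are absorbed by
  the scale `R` (scaling invariances of these models are deliberately not
  factored out; the search ranges do that work).
* Integration is classical RK4 at fixed `dt` (default 0.1 ms), with the
  input held constant within each of its own sampling intervals (`dt` must
  divide the current's step).  Halving `dt` moves spike times by well under
  0.1 ms away from threshold-grazing events.
* Spike time = linear interpolation of the cutoff crossing inside the step.
* The exponential argument is clipped at 40; additionally the voltage fed
  into the right-hand side during RK4 stages is capped at `v_c + 40` mV.
  Both only affect the spike upswing, which the reset discards; the cap is
  what keeps the stage derivatives finite and positive during the upswing
  (without it, an intermediate stage can overshoot so far that the leak
  term dominates with the opposite sign).
* Initial conditions: `v = E_L`, `w = 0`, and the baseline threshold for
  threshold-adaptive models; a settle-in period can be prepended.
* In recorded voltage traces, the sample at a crossing holds the clipped
  spike peak (`v_c`) and integration resumes from `v_r`; this makes traces
  round-trip through threshold-based spike extraction (one upward crossing
  per reset).  Extraction itself merges crossings closer than 1 ms (one
  spike per action potential) and times the crossing by linear
  interpolation.
* The Izhikevich cutoff is fixed at +30 mV regardless of the gene.
* `fast_exp` (range reduction plus a quadratic, < 1 % relative error on
  [−20, 20]) is available for model right-hand sides only — never inside
  metrics.  On this build it is not faster than the library exponential, so
  it is off by default.

## Spike-train metrics

A train is filtered with the causal kernel `h(t) = √(2/τ)·e^{−t/τ}` (unit
L² norm, so a one-spike train is at distance exactly 1 from the empty
train at every timescale; the constant is configurable).  The van Rossum
distance is the L² distance between filtered trains, computed either by
the closed-form double sum or by an O(n+m) sorted-merge recursion; the two
implementations agree to 1e−10 and serve as mutual checks.  Distances to
average functions (pointwise means of per-trial filtered functions; a
summed variant is available) are evaluated exactly through the
exponential-sum representation.

The coincidence factor uses greedy earliest-first one-to-one matching
within |Δt| ≤ δ — each spike can be matched at most once, which prevents
coincidence-count inflation.  Γ of two empty trains is defined as 1
(degenerate perfect match).  Intrinsic reliability Γ_i averages both
directed Γ values per trial pair, since the statistic is asymmetric in
which train supplies the rate.  The expected Poisson benchmarks follow
their definitions: ⟨N_m⟩ is the integral of the rate, ⟨N_c⟩ a Monte-Carlo
mean over thinning-sampled trains; the expected van Rossum value is the
distance between *expected* filtered functions (rate convolved with the
kernel by an exact piecewise-linear recursion), which lower-bounds the
Monte-Carlo mean distance by Jensen's inequality — the tests assert the
inequality, not equality.  A limit worth knowing: a Poisson model with
narrow rate bumps at the target spikes cannot push the expected Γ to 1;
with m expected spikes per bump the ceiling is 2(1−e^{−m})/(1+m) ≈ 0.65
near m ≈ 1.25, because Poisson count dispersion inflates ⟨N_m⟩.

## The genetic algorithm

Real-valued genes, bounded by a per-parameter feasible box (defaults:
[0.3×, 1.7×] the canonical value).  Per generation: the k fittest genes are
copied unchanged (elitism, ties broken by index; elites are protected from
mutation), the rest are bred by roulette selection plus per-coordinate
uniform crossover, and each child is mutated with some probability
(`GAConfig` default 5 %).  Mutation rescales one uniformly chosen
coordinate by (1+r), r ~ N(0, ε_m) with ε_m the *variance*, decaying
geometrically from 0.2 to 0.01 over the run (`eps_m_min` configurable).

The benchmark experiments pass a mutation probability of 0.4 and a
variance floor of 0.001 instead of the defaults.  The reasoning: once the
population homogenizes — which happens within a few dozen generations
under elitist roulette selection — crossover produces copies, and the
number of genuinely new candidates per generation equals the mutation
count.  At 5 % that is ~11 new points per generation for a population of
240, far too few to zig-zag through correlated-parameter valleys within a
few hundred generations; at 40 % the same total evaluation budget reaches
a clearly lower training distance (0.25 vs 0.34 in matched probes).  A
thousand-generation run — the protocol these models are usually fitted
with — does not need the higher rate; the desk-scale experiments here do.  Roulette weights are `(max_fit − fit) + η` with a small
floor η — selection needs a maximized quantity while the fitness is a
distance; this transform is simple and rank-respecting, and degrades to
uniform selection on an all-equal population.

The fitness timescale anneals geometrically from `τ_start` (default half
the record length) to `τ_end` (default the target's mean inter-spike
interval): early generations match firing rates, late ones spike timing.
All members, elites included, are re-evaluated at each generation's τ so
fitness ordering is consistent within a generation (exactly N evaluations
per generation).  The best-ever gene is tracked by its distance at
`τ_end`, so the returned solution is comparable across the whole run.  The
validation coincidence factor is tracked per generation but never enters
the fitness.

## The cascade model and tandem evolution

For sensory data the drive is `I(t) = C·(h ⋆ s)(t)`: a spectro-temporal
receptive field `h` (20 bands × 40 lags by default), constrained to unit
L¹ norm, convolved with the stimulus spectrogram and scaled by `C`, feeding
an aEIF neuron.  The scale `C` is optimized with the neuron genes, which
separates the kernel's shape from its magnitude.  `R` is fixed at 1 in the
cascade (it is redundant with `C`).

The initial kernel comes from normalized reverse correlation: the
truncated-SVD pseudo-inverse of the stimulus autocorrelation applied to
the stimulus–response cross-correlation.  The SVD tolerance λ keeps the
largest singular values whose cumulative fraction stays strictly below λ
(at least one always kept; λ = 1 keeps every nonzero direction), and can
be cross-validated on held-out predictive correlation over contiguous
time folds.  With few spikes relative to the ~800 kernel coefficients,
the seed kernel is estimated by *pooling* the normal equations across
stimuli and lightly smoothing the PSTH (2 ms); per-stimulus estimates at
realistic spike counts are noise-dominated.

Tandem evolution alternates every `phase_length` (default 50) iterations
between evolving the neuron population and the kernel population, each
member scored against the frozen current best of the other population; at
each phase boundary the resting population is re-scored against the newly
frozen partner.  Kernel variation operators (nowhere defined in the
underlying method, so package design choices): crossover is a
per-coefficient uniform mix re-normalized to unit L¹; mutation perturbs a
random rectangular patch of up to 4×4 bins with zero-mean Gaussian noise
(sd = scale × mean|h|, the scale decaying tenfold over the run) and
re-normalizes.  The training fitness is the sum over training stimuli of
the van Rossum distance to that stimulus's average function, each
stimulus's timescale annealing from T/2 to its trials' mean ISI.

## Synthetic benchmarks

* **Injected currents** are Ornstein–Uhlenbeck processes
  (I(t+dt) = I + (μ−I)dt/τ_c + σ√(2dt/τ_c)·z).  Defaults μ = 2.4,
  σ = 1.5, τ_c = 10 ms drive the recovery-target aEIF at ≈ 11 Hz —
  inside the intended 5–15 Hz band for the current-injection benchmark.
* **The parameter-recovery benchmark**: ground-truth aEIF (τ_m = 10 ms,
  τ_w = 144 ms, b = 0.001, V_T = −50 mV, V_r = E_L = −70 mV, α = 1 mV,
  Δ_T = 2 mV; R = 1 and v_c = 0 fixed), 4 s of OU current, first 2 s
  training / last 2 s validation.  The search gene is the seven-parameter
  set above with V_r tied to E_L; initial ranges: τ_m ∈ [3,17],
  τ_w ∈ [36,204], b ∈ [3e−4,1.7e−3], V_T ∈ [−70,−20], E_L ∈ [−120,−50],
  α ∈ [0.3,1.7], Δ_T ∈ [0.5,3].
* **The auditory benchmark**: band-limited random spectrograms (Gaussian
  noise, 5 ms temporal and ~1-band spectral smoothing, shifted and clipped
  to be nonnegative), a Gabor-shaped unit-L¹ kernel, scale C = 40 (≈ 50 Hz
  responses, realistic for auditory midbrain neurons driven by song), and
  the canonical aEIF.  Trials are the deterministic cascade spikes with
  optional Gaussian jitter and a small deletion probability — a
  variability model adequate for testing reliability statistics and the
  benchmark pipeline, *not* a model of real trial-to-trial dynamics.

What passing these benchmarks does and does not show: recovery of a model
from data generated by the same model class demonstrates the estimator's
correctness and the information content of the protocol, but says nothing
about model mismatch, slow ion-channel dynamics, bursting, or the
non-Poisson variability of real neurons — none of which the generators
emulate.

## Benchmark experiment scales

`evospike.benchmarks` freezes the standard experiments:

* **Parameter recovery** — five GA runs, population 240, 400 generations,
  each on its own 4 s current realization (2 s train / 2 s validation);
  the headline numbers are the per-parameter means over runs.  About 13
  minutes on one CPU.
* **Timescale comparison** — ten paired seeds, population 40, 150
  generations; both schedules race to 90 % of the annealed run's best
  validation Γ, scored by the first generation from which a run stays at
  or above that level.  About 3 minutes.
* **Cascade recovery** — ten 2 s stimuli (5 train / 5 validation), five
  trials each, populations of 48, 400 tandem iterations alternating every
  50.  About 5 minutes.

## Identifiability at desk scale

The recovery benchmark has a soft degeneracy: jointly shifting
(E_L, V_T, V_r) changes spike times only through the brief upswing to the
fixed cutoff and the weak b·v coupling, so the absolute voltage level is
weakly identified; b, τ_w and Δ_T partially compensate along the same
valley.  One run in the standard experiment found an excellent fit
(distance 0.12 at the final timescale) with the entire voltage level
shifted by +15 mV — the level only becomes identifiable once the residual
distance falls to the size of the b·v coupling's footprint (~0.01), which
is cluster-scale convergence (the original protocol is population 240 ×
1000 generations × 20 runs).  At the package's desk scale the
time-constant, coupling and increment parameters recover to within a few
percent; the absolute voltage level carries a few-mV spread.

The cascade benchmark has an analogous search-budget wall.  The pipeline
itself is sound (the generating genome scores Γ = 1 against its own
data), and fitting only the neuron stage against the *true* kernel
reaches Γ ≈ 0.88 — but the reverse-correlation seed kernel, estimated
through the spiking nonlinearity, reaches a cosine of only ~0.8 to the
true kernel, which caps neuron-only fits near Γ ≈ 0.5, and patch-mutation
search over the 800-coefficient kernel improves it only slowly: tandem
runs up to a thousand iterations plateau at validation Γ ≈ 0.55–0.60
while the reconstructed driving current already correlates ≥ 0.83 with
the true one.  With only two training stimuli the kernel population
*overfits* (training fitness improves while the kernel drifts away from
truth); ten stimuli remove the overfitting but not the search-budget
limit.  Tight spike-for-spike recovery of the cascade is therefore a
cluster-scale result; the desk-scale experiment demonstrates drive
reconstruction, not 2 ms spike alignment.

## Known limitations

* The MAT model and cochleagram front ends are out of scope; spectrogram
  input is assumed already computed.
* Event-driven (exact) integration is not provided; RK4 with reset is.
* The Γ normalization assumes 2fδ < 1; dense targets at wide windows are
  rejected rather than extrapolated.
* The tandem fit's best-partner pairing is a design choice; co-evolution
  with other pairings (e.g. bipartite tournaments) is not implemented.
* Parallel fitness evaluation is exposed as a pluggable `map`; the default
  is sequential and deterministic.
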