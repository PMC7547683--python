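# Methods

## Model

Agents are continuous-time recurrent neural networks (CTRNNs) of N = 3
interneurons.  Internal states evolve as

    τ_i dy_i/dt = −y_i + Σ_j w_ij o_j + w_i^in I,     o_j = σ(y_j + θ_j),

with σ the logistic sigmoid, and the scalar network output is
O = 2σ(Σ_i w_i^o o_i) − 1 ∈ (−1, 1).  Integration is explicit Euler with
dt = 0.02 time units (configurable); the state update uses the neuron
outputs of the incoming step, and outputs are recomputed from the updated
states.  Optional additive Gaussian state noise (default std 0, i.e. off)
can be injected into the increment of y for robustness studies.

Three open-loop agent–environment settings are modelled:

* **CPG** — the network receives no input (I ≡ 0); its output drives a
  leaky environment τ_env ds/dt = −s + O with τ_env = 0.5.  Trials start
  from a regular lattice of initial neuron outputs over (0.05, 0.95)^N
  (for 100 conditions in 3 dimensions, a 5×5×4 grid) and, when recording
  ensembles, from evenly spaced environment initial states in (−1, 1), so
  each trial starts the coupled system in a distinct condition.
* **Passive perceiver (PP)** — a network (by default a uniformly random
  genotype, decoded) is driven by a pre-recorded environmental signal
  (here: the signals the CPGs generated, one distinct recorded trial per
  PP trial); the env column of the trace equals the drive exactly.
* **Relational categorization** — a cue stimulus in [3, 11] is presented
  for t ∈ [0, 5), no stimulus for t ∈ [5, 15), a probe for t ∈ [15, 20];
  the correct output during the probe stage is +1 if probe > cue else −1.
  The 2-probe battery uses 35 cues evenly spaced in [4, 10] (so cue ± 1
  stays presentable), each with probes cue − 1 and cue + 1 (70 trials,
  35 per class).  The 9-probe battery pairs the same cues with the nine
  integer probes 3..11, dropping ties (the interval [3, 11] contains
  exactly nine integers).  Initial internal state for relational trials is
  y = 0; the stage boundaries make the input column exactly piecewise
  constant.

## Scores

* **Oscillation fitness** (CPG): per trial, the sum over time of the
  absolute consecutive-step change of every neuron output plus that of the
  network output; fitness is the mean over the 100 lattice trials of a
  10-time-unit simulation.  The aggregation (sum of total variation,
  averaged over trials) is this package's choice: oscillators that swing
  most neurons across their range score well above the evolutionary
  success threshold of 30, while any network settling to a fixed point
  scores near 0 (transients only).
* **Relational performance**: d = mean over probe-stage samples and trials
  of |O(t) − target| / 2, performance = 1 − d ∈ [0, 1].  Dividing by 2
  maps the worst case (output saturated at the wrong extreme) to 0 and a
  perfect output to 1; an output pinned at 0 scores 0.5.  A trial's
  *classification* is the sign of its probe-stage mean output.

## Evolutionary optimization

Genotypes are vectors in [0, 1]^21 (N² + 4N genes) decoded linearly per
group: weights, input weights, output weights, biases ∈ [−16, 16];
time constants ∈ [0.5, 10] (conventional CTRNN ranges, stable at
dt = 0.02; the original ranges are not published, so results that depend
on them — notably the exact best task score — can shift).  Each
generation: evaluate all 100 individuals; copy the top max(1, round(1%))
unchanged; fill the rest by fitness-proportionate selection of two parents
(fitness shifted by its population minimum; uniform fallback for flat
populations), uniform crossover (each gene from either parent with
probability 1/2 — the recombination operator is this package's choice),
and additive Gaussian mutation (std 0.01) clipped to [0, 1].  Elitism
makes the best fitness non-decreasing.  A generic `stop_at_fitness` target
halts a run once reached; the CPG task uses its own success rule
(fitness ≥ 30 within 50 generations) as the default stopping target, and
failed CPG runs are retried with fresh seeds until the requested ensemble
size is reached.  Relational optimization defaults to 500 generations; the
analysis ensemble consists of networks that successfully perform the task,
so the relational pipeline likewise retries runs falling below a
configurable performance threshold (every attempt is recorded, so
evolvability statistics remain available un-gated).

## Density estimation

Continuous variables are histogrammed on a fixed grid of 100 bins per
dimension, repeated for 7 shifted binnings whose edges are offset by
shift/7 of a bin width (average shifted histograms); samples falling
outside the shifted edges clamp into the terminal bins, and samples more
than one bin width outside the declared bounds are rejected.  Joints are
stored sparsely (occupied bins only), so memory scales with the sample
count, never with bins^dims.  Bin bounds are computed once per analysis
over *all* time points and trials, keeping distributions at different time
points comparable — the framework requires one fixed reference
distribution across time.  Averaging across shifts happens at the level of
the *information estimate* (each measure computed once per shifted binning,
then averaged), which keeps every distribution at the stated 100-bin
resolution; averaging the densities themselves onto a finer common grid
would change the state space.  Trial labels (cue, probe) are exact
categorical values and bypass binning.  Robustness of the resulting time
series to 5/11 shifts and 50/200 bins is asserted by a test (pairwise
Pearson r > 0.9 on a CPG ensemble).

## Information measures

Specific information of a source A about a target outcome y is
I(Y=y; A) = Σ_a p(a|y) [log2 p(y|a) − log2 p(y)].  The I_min redundancy of
source collections A₁..A_k is Σ_y p(y) min_i I(Y=y; A_i); a collection of
several variables is their concatenation.  Two-source PID atoms follow as
R = I_min(Y;{A}{B}), unique_A = I(Y;A) − R, unique_B = I(Y;B) − R,
synergy = I(Y;[A,B]) − I(Y;A) − I(Y;B) + R; with I_min all atoms are
non-negative (specific information is monotone under source refinement).
The three transfer terms are the differences of I_min redundancies quoted
in the README.  A note on naming: the surrounding literature is
inconsistent about which of the letters A/B denotes the neural source in
the transfer-term notation, so the public API names the terms by *role*
(`transfer_from_neural`, `transfer_from_env`) and never exposes bare
letters.

"Neural activity" for estimation is the N-vector of neuron outputs o(t) by
default (the quantities the network communicates); the scalar network
output O(t) is available as an alternative.  The prediction lag δt
defaults to one Euler step (0.02 time units) and is configurable.

The time-unrolled decomposition builds, at each time point t, the
across-trial sample of (Y, A = N(t−δt), B = S(t−δt), X = N(t)) — Y being
S(t+δt) or a per-trial label — estimates the joint per shifted binning,
computes the transfer terms, and averages over shifts.  Pooled predictive
information instead pools (N(t), S(t+δt)) pairs over all t and trials
into one sample.  Total predictive information "averaged over the task" is
the time-average of the per-time-point I(label; N(t)) series.

## Noise floors and statistical design

Every claim of the form "this term is ≈ 0" is tested against shuffle
surrogates: the target is permuted across trials (20 permutations,
seed-controlled), destroying the coupling while preserving marginals, and
the same estimator is run on each permutation.  Two floors are reported:

* a per-time-point floor: the 95th percentile across permutations of the
  surrogate value at each analyzed time point (the correct null for a
  comparison at a single pre-registered time point, such as the end of the
  delay stage);
* a pooled floor: the 95th percentile of surrogate values pooled over
  permutations and time points;
* a familywise floor: the 95th percentile across permutations of each
  permutation's *maximum* over time, for claims that a term "never exceeds
  the floor at any time point" — comparing a max against a marginal
  percentile would be guaranteed to fail at scale.

For label targets the pooled floor is dominated by time points where the
deterministic trajectories have fully separated at the binning resolution:
there, *any* permuted labeling is perfectly explained by the fragmented
neural state, and the surrogate saturates near the label entropy.  Pooling
such time points into a floor for a different time point would make the
floor uninformative, which is why single-time-point claims always use the
per-time-point floor.

Because each network's max-vs-floor comparison is itself a 5%-level test,
condition-level "never a unique source" claims over an ensemble of
networks are accepted when the count of per-network exceedances stays
within the binomial 95% critical count under the null (2 of 10); demanding
zero exceedances would reject the claim with probability ≈ 0.4 even when
it is true.  Group "similarity" claims (e.g. cue-stage probe information
in optimized vs random networks) are operationalized as an equivalence
margin: the medians differ by at most 20% of the pooled median.  The
"significantly less information under 9 probes" claim uses the paired
per-network drop with a two-sided sign test.

## Problem sizes

The full study conditions are 100 networks per condition and 500 trials
per network (CPG/PP), 100 evolutionary runs of 500 generations
(relational).  The bundled studies and tests run scaled versions chosen as
this package's default scaled-study sizes: 10 networks × 100 trials for CPG/PP
source recovery, 5 relational runs of up to 200 generations (halting a run
once performance reaches 0.90), surrogate series evaluated every 5th–10th
time point before pooling.  All qualitative orderings asserted by the
tests are preserved at these sizes; exact magnitudes (e.g. the best task
score) depend on ensemble size and the unpublished parameter ranges.

## Synthetic data and its limits

All inputs are generated internally by deterministic simulation; there is
no measurement noise, and trials differ only through initial conditions
and stimulus parameters.  Passing tests therefore demonstrate that the
estimator recovers *structural* ground truth (which subsystem can, by
construction, be a source) in noise-free, low-dimensional, strongly
oscillatory or staged regimes.  They do not establish performance on
noisy, high-dimensional, or closed-loop recordings: in particular, with
deterministic dynamics the per-time-point estimates saturate near the
binned target entropy once trajectories separate, and finite-sample
binning collisions create small positive artifacts in every term — which
is exactly why all near-zero claims are made relative to shuffle-surrogate
floors rather than absolute zero.  Closed-loop agent–environment coupling,
where neither marginal distribution is fixed over time, is out of scope.

## Numerical choices

Tiny negative values (> −1e-9) arising from floating-point cancellation in
atoms and transfer terms are clipped to 0; larger negatives are never
produced by I_min (asserted by fuzz tests against an independent
brute-force oracle).  Constant dimensions get a unit-width bin range.
Degenerate inputs (zero-entropy targets, identical trials) yield exact
zeros.  The Euler scheme and kernel batching are bit-for-bit equivalent
between the numba and NumPy paths (asserted by a test); all randomness
(evolution, surrogates, shuffles) flows through seeded generators, making
every pipeline bit-reproducible from its config.
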