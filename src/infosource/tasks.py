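"""Agent-environment task settings.

Three settings are modelled, each an open-loop coupling between a CTRNN and
a one-dimensional environment:

* **CPG** (central pattern generator): the network receives no input and its
  output drives a leaky environment state ``tau_env * ds/dt = -s + O``.
* **Passive perceiver (PP)**: the network is driven by a pre-recorded
  environmental signal that it cannot influence.
* **Relational categorization**: the network receives a cue stimulus
  (t in [0, 5)), a silent delay (t in [5, 15)), then a probe (t in [15, 20]),
  and must output +1 if the probe exceeds the cue and -1 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import _fast
from .ctrnn import DEFAULT_DT, NetworkParams, initial_state, state_from_outputs
from .trace import Trace, TrialEnsemble

TAU_ENV = 0.5

CUE_ONSET = 0.0
DELAY_ONSET = 5.0
PROBE_ONSET = 15.0
TRIAL_END = 20.0

CUE_RANGE = (3.0, 11.0)


@dataclass(frozen=True)
class RelationalTrial:
    """One cue/probe pair; ``target`` is ``sign(probe - cue)``."""

    cue: float
    probe: float

    def __post_init__(self):
        if not (CUE_RANGE[0] <= self.cue <= CUE_RANGE[1]):
            raise ValueError("cue outside [3, 11]")
        if not (CUE_RANGE[0] <= self.probe <= CUE_RANGE[1]):
            raise ValueError("probe outside [3, 11]")
        if self.probe == self.cue:
            raise ValueError("probe must differ from cue")

    @property
    def target(self) -> int:
        return 1 if self.probe > self.cue else -1


def cpg_env_step(s: float, O: float, dt: float = DEFAULT_DT, tau_env: float = TAU_ENV) -> float:
    """Euler step of the environment ``tau_env * ds/dt = -s + O``."""
    if dt <= 0 or tau_env <= 0:
        raise ValueError("dt and tau_env must be positive")
    return s + (dt / tau_env) * (-s + O)


def _env_filter(out_traj: np.ndarray, env_init: np.ndarray, dt: float, tau_env: float) -> np.ndarray:
    """Batch-integrate the environment driven by network outputs.

    ``s[k+1] = s[k] + (dt/tau_env) (-s[k] + O[k])``, using the output of the
    incoming step (same explicit scheme as the network update).
    """
    from scipy.signal import lfilter

    n_trials, n_time = out_traj.shape
    a = 1.0 - dt / tau_env
    b = dt / tau_env
    env_init = np.broadcast_to(env_init, (n_trials,)).astype(float)
    # s[k+1] = a s[k] + b O[k] is a first-order IIR filter of the output
    z, _ = lfilter([b], [1.0, -a], out_traj[:, :-1], axis=1, zi=(a * env_init)[:, None])
    return np.concatenate([env_init[:, None], z], axis=1)


def _batch_traces(params, y0, inputs, dt, env=None) -> List[Trace]:
    o_traj, out_traj = _fast.integrate_batch(
        params.weights,
        params.input_weights,
        params.output_weights,
        params.taus,
        params.biases,
        y0,
        inputs[:, :-1],
        dt,
    )
    if not np.all(np.isfinite(out_traj)):
        raise FloatingPointError("non-finite values during integration")
    time = np.arange(inputs.shape[1]) * dt
    return [
        Trace(
            dt=dt,
            time=time,
            input=inputs[b],
            neuron_outputs=o_traj[b],
            output=out_traj[b],
            env_state=None if env is None else env[b],
        )
        for b in range(inputs.shape[0])
    ]


# ---------------------------------------------------------------------------
# CPG


def output_lattice(n_points: int, n_neurons: int, low: float = 0.05, high: float = 0.95) -> np.ndarray:
    """Regular lattice of ``n_points`` initial-output vectors in (0, 1)^N.

    Per-dimension counts start at ``floor(n_points**(1/N))`` and are
    incremented cyclically until their product reaches ``n_points``; the
    lattice is enumerated lexicographically and truncated to ``n_points``
    (for 100 points in 3 dimensions this is the full 5 x 5 x 4 grid).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    counts = [max(1, int(np.floor(n_points ** (1.0 / n_neurons) + 1e-9)))] * n_neurons
    d = 0
    while int(np.prod(counts)) < n_points:
        counts[d] += 1
        d = (d + 1) % n_neurons
    axes = [np.linspace(low, high, c) for c in counts]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, n_neurons)
    return grid[:n_points]


def simulate_cpg(
    params: NetworkParams,
    init_outputs: Sequence[float],
    env_init: float = 0.0,
    duration: float = 10.0,
    dt: float = DEFAULT_DT,
) -> Trace:
    """One CPG trial: zero input, environment driven by the network output."""
    init = state_from_outputs(params, np.asarray(init_outputs, dtype=float))
    n_steps = int(np.floor(duration / dt + 1e-12))
    inputs = np.zeros((1, n_steps + 1))
    o_traj, out_traj = _fast.integrate_batch(
        params.weights,
        params.input_weights,
        params.output_weights,
        params.taus,
        params.biases,
        init.y[None, :],
        inputs[:, :-1],
        dt,
    )
    env = _env_filter(out_traj, np.array([env_init]), dt, TAU_ENV)
    time = np.arange(n_steps + 1) * dt
    return Trace(dt=dt, time=time, input=inputs[0], neuron_outputs=o_traj[0], output=out_traj[0], env_state=env[0])


def record_cpg_ensemble(
    params: NetworkParams,
    n_trials: int,
    duration: float = 10.0,
    dt: float = DEFAULT_DT,
    env_inits: Optional[np.ndarray] = None,
) -> TrialEnsemble:
    """Record ``n_trials`` CPG trials.

    Neuron initial outputs are placed on a regular lattice over (0, 1)^N and
    the environment initial condition is varied across trials (evenly spaced
    in (-1, 1) by default), so that every trial starts the coupled system in
    a different condition.
    """
    lattice = output_lattice(n_trials, params.n_neurons)
    if env_inits is None:
        env_inits = np.linspace(-0.95, 0.95, n_trials)
    env_inits = np.asarray(env_inits, dtype=float)
    n_steps = int(np.floor(duration / dt + 1e-12))
    inputs = np.zeros((n_trials, n_steps + 1))
    y0 = np.stack([state_from_outputs(params, lattice[b]).y for b in range(n_trials)])
    o_traj, out_traj = _fast.integrate_batch(
        params.weights, params.input_weights, params.output_weights,
        params.taus, params.biases, y0, inputs[:, :-1], dt,
    )
    env = _env_filter(out_traj, env_inits, dt, TAU_ENV)
    time = np.arange(n_steps + 1) * dt
    traces = [
        Trace(dt=dt, time=time, input=inputs[b], neuron_outputs=o_traj[b], output=out_traj[b], env_state=env[b])
        for b in range(n_trials)
    ]
    labels = pd.DataFrame({"trial_id": np.arange(n_trials), "init_id": np.arange(n_trials), "env_init": env_inits})
    return TrialEnsemble(traces=traces, labels=labels)


def cpg_fitness(
    params: NetworkParams,
    n_init_conditions: int = 100,
    duration: float = 10.0,
    dt: float = DEFAULT_DT,
) -> float:
    """Oscillation fitness of a network.

    Each trial starts from one lattice point of initial neuron outputs and
    runs for ``duration`` time units; the trial score sums the absolute
    consecutive-step change of every neuron output and of the network output
    over all time points, and fitness is the mean score across trials.  A
    network at a fixed point scores ~0; healthy oscillators score well above
    the evolutionary success threshold of 30.
    """
    lattice = output_lattice(n_init_conditions, params.n_neurons)
    y0 = np.log(np.clip(lattice, 1e-6, 1 - 1e-6) / (1 - np.clip(lattice, 1e-6, 1 - 1e-6))) - params.biases
    n_steps = int(np.floor(duration / dt + 1e-12))
    inputs = np.zeros((n_init_conditions, n_steps))
    o_traj, out_traj = _fast.integrate_batch(
        params.weights, params.input_weights, params.output_weights,
        params.taus, params.biases, y0, inputs, dt,
    )
    return float(np.mean(trial_oscillation_scores(o_traj, out_traj)))


def trial_oscillation_scores(o_traj: np.ndarray, out_traj: np.ndarray) -> np.ndarray:
    """Per-trial oscillation score from (B, T, N) outputs and (B, T) network output."""
    neuron_term = np.abs(np.diff(o_traj, axis=1)).sum(axis=(1, 2))
    output_term = np.abs(np.diff(out_traj, axis=1)).sum(axis=1)
    return neuron_term + output_term


# ---------------------------------------------------------------------------
# Passive perceiver


def simulate_pp(params: NetworkParams, env_signal: np.ndarray, dt: float = DEFAULT_DT) -> Trace:
    """One PP trial: network driven by ``env_signal``; the environment column
    equals the supplied signal exactly (the network cannot influence it)."""
    env_signal = np.asarray(env_signal, dtype=float).ravel()
    if not np.all(np.isfinite(env_signal)):
        raise ValueError("env_signal must be finite")
    inputs = env_signal[None, :]
    init = initial_state(params)
    traces = _batch_traces(params, init.y[None, :], inputs, dt, env=inputs)
    return traces[0]


def record_pp_ensemble(params: NetworkParams, drive_signals: np.ndarray, dt: float = DEFAULT_DT) -> TrialEnsemble:
    """Record PP trials, one per row of ``drive_signals`` (n_trials, T)."""
    drive = np.atleast_2d(np.asarray(drive_signals, dtype=float))
    y0 = np.zeros((drive.shape[0], params.n_neurons))
    traces = _batch_traces(params, y0, drive, dt, env=drive)
    labels = pd.DataFrame({"trial_id": np.arange(drive.shape[0])})
    return TrialEnsemble(traces=traces, labels=labels)


# ---------------------------------------------------------------------------
# Relational categorization


def make_relational_trials(task_variant: str = "2probe", n_cues: int = 35) -> List[RelationalTrial]:
    """Build the trial battery for one task variant.

    ``2probe``: ``n_cues`` cues evenly spaced in [4, 10] (so cue +/- 1 stays
    inside the presentable range [3, 11]), each paired with probes
    ``cue - 1`` and ``cue + 1``.  ``9probe``: the same cues, each paired with
    the nine integer probe values 3..11, dropping pairs where the probe
    coincides with the cue.
    """
    if n_cues < 1:
        raise ValueError("n_cues must be >= 1")
    cues = np.linspace(4.0, 10.0, n_cues) if n_cues > 1 else np.array([7.0])
    trials: List[RelationalTrial] = []
    if task_variant == "2probe":
        for cue in cues:
            trials.append(RelationalTrial(cue=float(cue), probe=float(cue - 1)))
            trials.append(RelationalTrial(cue=float(cue), probe=float(cue + 1)))
    elif task_variant == "9probe":
        probes = np.arange(3.0, 12.0)
        for cue in cues:
            for probe in probes:
                if abs(probe - cue) < 1e-9:
                    continue
                trials.append(RelationalTrial(cue=float(cue), probe=float(probe)))
    else:
        raise ValueError(f"unknown task variant {task_variant!r}")
    return trials


def relational_input(trial: RelationalTrial, t: float) -> float:
    """Stimulus at time ``t``: cue in [0, 5), 0 in [5, 15), probe in [15, 20]."""
    if t < CUE_ONSET or t > TRIAL_END:
        raise ValueError("t outside the trial window [0, 20]")
    if t < DELAY_ONSET:
        return trial.cue
    if t < PROBE_ONSET:
        return 0.0
    return trial.probe


def simulate_relational(
    params: NetworkParams,
    trials: Sequence[RelationalTrial],
    dt: float = DEFAULT_DT,
    y0: Optional[np.ndarray] = None,
) -> TrialEnsemble:
    """Simulate the trial battery (duration 20, initial internal state 0)."""
    trials = list(trials)
    if not trials:
        raise ValueError("trial list must be non-empty")
    n_steps = int(np.floor(TRIAL_END / dt + 1e-12))
    time = np.arange(n_steps + 1) * dt
    cue_mask = time < DELAY_ONSET
    probe_mask = time >= PROBE_ONSET
    inputs = np.zeros((len(trials), n_steps + 1))
    for b, tr in enumerate(trials):
        inputs[b, cue_mask] = tr.cue
        inputs[b, probe_mask] = tr.probe
    if y0 is None:
        y0 = np.zeros((len(trials), params.n_neurons))
    else:
        y0 = np.broadcast_to(np.asarray(y0, dtype=float), (len(trials), params.n_neurons)).copy()
    traces = _batch_traces(params, y0, inputs, dt)
    labels = pd.DataFrame(
        {
            "trial_id": np.arange(len(trials)),
            "cue": [tr.cue for tr in trials],
            "probe": [tr.probe for tr in trials],
            "target": [tr.target for tr in trials],
        }
    )
    return TrialEnsemble(traces=traces, labels=labels)


def _probe_mask(ensemble: TrialEnsemble) -> np.ndarray:
    mask = ensemble.traces[0].time >= PROBE_ONSET
    if not mask.any():
        raise ValueError("ensemble has no probe-stage samples")
    return mask


def relational_performance(ensemble: TrialEnsemble) -> float:
    """Task score in [0, 1].

    The deviation ``d`` is the mean over probe-stage time points and trials
    of ``|O(t) - target| / 2`` (the division by 2 maps the worst case, output
    at the opposite extreme, to 1); the score is ``1 - d``.
    """
    mask = _probe_mask(ensemble)
    out = ensemble.stack("output")[:, mask]
    targets = ensemble.labels["target"].to_numpy()[:, None]
    d = float(np.mean(np.abs(out - targets)) / 2.0)
    return 1.0 - d


def relational_input_matrix(trials: Sequence[RelationalTrial], dt: float = DEFAULT_DT):
    """Precomputed (inputs, targets, probe_mask) arrays for a trial battery."""
    n_steps = int(np.floor(TRIAL_END / dt + 1e-12))
    time = np.arange(n_steps + 1) * dt
    cue_mask = time < DELAY_ONSET
    probe_mask = time >= PROBE_ONSET
    inputs = np.zeros((len(trials), n_steps + 1))
    for b, tr in enumerate(trials):
        inputs[b, cue_mask] = tr.cue
        inputs[b, probe_mask] = tr.probe
    targets = np.array([tr.target for tr in trials], dtype=float)
    return inputs, targets, probe_mask


def relational_fitness(
    params: NetworkParams,
    inputs: np.ndarray,
    targets: np.ndarray,
    probe_mask: np.ndarray,
    dt: float = DEFAULT_DT,
) -> float:
    """Task score without materialising traces (optimizer inner loop).

    Identical to :func:`relational_performance` on the ensemble that
    :func:`simulate_relational` would record for the same battery.
    """
    probe_start = int(np.argmax(probe_mask))
    d = _fast.probe_deviation(
        params.weights, params.input_weights, params.output_weights,
        params.taus, params.biases,
        np.zeros((inputs.shape[0], params.n_neurons)), inputs[:, :-1],
        targets, probe_start, dt,
    ) / 2.0
    return float(1.0 - d)


def relational_classifications(ensemble: TrialEnsemble) -> np.ndarray:
    """Predicted class per trial: sign of the mean output over the probe stage."""
    mask = _probe_mask(ensemble)
    out = ensemble.stack("output")[:, mask]
    return np.where(out.mean(axis=1) >= 0, 1, -1)
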