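"""Continuous-time recurrent neural network (CTRNN) model.

The network is a layer of :math:`N` leaky-integrator interneurons with
sigmoidal outputs.  Internal states evolve as

.. math::

    \\tau_i \\dot{y}_i = -y_i + \\sum_j w_{ij} o_j + w_i^{in} I, \\qquad
    o_j = \\sigma(y_j + \\theta_j),

driven by a single scalar stimulus :math:`I`, and the network communicates a
scalar output :math:`O = 2\\sigma(\\sum_i w_i^o o_i) - 1 \\in (-1, 1)`.
Integration is explicit Euler with a default step of ``dt = 0.02``; the
update of :math:`y` uses the neuron outputs of the incoming state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _fast
from .trace import Trace

DEFAULT_DT = 0.02

_EPS_OUT = 1e-6


def sigmoid(x):
    with np.errstate(over="ignore"):  # exp overflow saturates cleanly to 0/1
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class NetworkParams:
    """CTRNN parameters.

    ``weights[i, j]`` is the connection strength from neuron ``j`` to neuron
    ``i``; ``taus`` are per-neuron time constants (must be positive);
    ``biases`` shift the sigmoid of each neuron.
    """

    weights: np.ndarray
    input_weights: np.ndarray
    output_weights: np.ndarray
    taus: np.ndarray
    biases: np.ndarray

    def __post_init__(self):
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.input_weights = np.asarray(self.input_weights, dtype=float).ravel()
        self.output_weights = np.asarray(self.output_weights, dtype=float).ravel()
        self.taus = np.asarray(self.taus, dtype=float).ravel()
        self.biases = np.asarray(self.biases, dtype=float).ravel()
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be a square matrix")
        for name in ("input_weights", "output_weights", "taus", "biases"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if not np.all(self.taus > 0):
            raise ValueError("all time constants must be positive")
        for name in ("weights", "input_weights", "output_weights", "taus", "biases"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]


@dataclass
class NetworkState:
    """Instantaneous network state: internal states ``y`` and outputs ``o``."""

    y: np.ndarray
    o: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.o = np.asarray(self.o, dtype=float).ravel()
        if self.y.shape != self.o.shape:
            raise ValueError("y and o must have the same length")


def initial_state(params: NetworkParams, y0: Optional[np.ndarray] = None) -> NetworkState:
    """State with given internal states (default 0) and consistent outputs."""
    y = np.zeros(params.n_neurons) if y0 is None else np.asarray(y0, dtype=float).ravel()
    if y.shape != (params.n_neurons,):
        raise ValueError("y0 length must match network size")
    return NetworkState(y=y, o=sigmoid(y + params.biases))


def state_from_outputs(params: NetworkParams, outputs: np.ndarray) -> NetworkState:
    """State whose neuron outputs equal ``outputs`` (clipped into (0, 1)).

    Inverts the sigmoid: ``y = logit(o) - theta``.  Used by tasks that set
    initial neuron *outputs* rather than internal states.
    """
    o = np.clip(np.asarray(outputs, dtype=float).ravel(), _EPS_OUT, 1.0 - _EPS_OUT)
    if o.shape != (params.n_neurons,):
        raise ValueError("outputs length must match network size")
    y = np.log(o / (1.0 - o)) - params.biases
    return NetworkState(y=y, o=sigmoid(y + params.biases))


def step(
    state: NetworkState,
    params: NetworkParams,
    input: float,
    dt: float = DEFAULT_DT,
    noise_std: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> NetworkState:
    """One explicit Euler step of the interneuron dynamics.

    Uses the neuron outputs of the *incoming* state on the right-hand side,
    then recomputes outputs from the updated internal states.  Optional
    additive Gaussian state noise (std ``noise_std``) is injected into the
    increment of ``y``; it is off by default.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(input):
        raise ValueError("input must be finite")
    if state.y.shape != (params.n_neurons,):
        raise ValueError("state does not match network size")
    drive = -state.y + params.weights @ state.o + params.input_weights * float(input)
    dy = (dt / params.taus) * drive
    if noise_std > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        dy = dy + rng.normal(0.0, noise_std, size=dy.shape)
    y_new = state.y + dy
    return NetworkState(y=y_new, o=sigmoid(y_new + params.biases))


def network_output(state: NetworkState, params: NetworkParams) -> float:
    """Scalar network output ``O = 2 sigma(sum_i w_i^o o_i) - 1`` in (-1, 1)."""
    if state.o.shape != (params.n_neurons,):
        raise ValueError("state does not match network size")
    return float(2.0 * sigmoid(params.output_weights @ state.o) - 1.0)


def simulate(
    params: NetworkParams,
    input_fn: Callable[[float], float],
    duration: float,
    dt: float = DEFAULT_DT,
    init: Optional[NetworkState] = None,
    noise_std: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Trace:
    """Integrate the network for ``duration`` time units, recording a Trace.

    The trace has ``floor(duration/dt) + 1`` rows; the first row is the
    initial condition before any update.  ``input_fn(t)`` supplies the
    stimulus applied during the step starting at time ``t``; the recorded
    input column holds ``input_fn(t_k)`` for every recorded time.
    """
    if duration < dt:
        raise ValueError("duration must be at least dt")
    state = initial_state(params) if init is None else init
    n_steps = int(np.floor(duration / dt + 1e-12))
    time = np.arange(n_steps + 1) * dt
    inputs = np.array([float(input_fn(t)) for t in time])
    if not np.all(np.isfinite(inputs)):
        raise ValueError("input_fn produced non-finite values")
    if noise_std > 0.0:
        # Noise breaks the shared-parameter batching; integrate step by step.
        if rng is None:
            rng = np.random.default_rng()
        n = params.n_neurons
        o_traj = np.empty((n_steps + 1, n))
        out_traj = np.empty(n_steps + 1)
        o_traj[0] = state.o
        out_traj[0] = network_output(state, params)
        for k in range(n_steps):
            state = step(state, params, inputs[k], dt, noise_std=noise_std, rng=rng)
            o_traj[k + 1] = state.o
            out_traj[k + 1] = network_output(state, params)
    else:
        o_batch, out_batch = _fast.integrate_batch(
            params.weights,
            params.input_weights,
            params.output_weights,
            params.taus,
            params.biases,
            state.y[None, :],
            inputs[None, :-1],
            dt,
        )
        o_traj, out_traj = o_batch[0], out_batch[0]
    if not (np.all(np.isfinite(o_traj)) and np.all(np.isfinite(out_traj))):
        bad = np.argmax(~np.isfinite(out_traj))
        raise FloatingPointError(f"non-finite state at time index {bad}")
    return Trace(dt=dt, time=time, input=inputs, neuron_outputs=o_traj, output=out_traj)


def shuffle_params(params: NetworkParams, rng_seed: int) -> NetworkParams:
    """Permute each parameter group within itself (never across groups).

    The time constants, input weights, flattened recurrent weights, output
    weights and biases are each independently permuted, so every group keeps
    its exact multiset of values while the neuron/connection assignments are
    randomised.  Deterministic given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    n = params.n_neurons
    flat_w = params.weights.ravel()
    return NetworkParams(
        weights=rng.permutation(flat_w).reshape(n, n),
        input_weights=rng.permutation(params.input_weights),
        output_weights=rng.permutation(params.output_weights),
        taus=rng.permutation(params.taus),
        biases=rng.permutation(params.biases),
    )
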