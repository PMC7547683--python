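"""Batched CTRNN integration kernels.

Compiled with numba when it is importable; otherwise a NumPy implementation
with identical semantics is used.  Both paths implement the same explicit
Euler scheme as :func:`infosource.ctrnn.step` (a cross-check test enforces
agreement), vectorised over a batch of trials that share one parameter set.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def _integrate_nb(weights, input_weights, output_weights, taus, biases, y0, inputs, dt):
    n_trials, n_steps = inputs.shape
    n = weights.shape[0]
    n_time = n_steps + 1
    o_traj = np.empty((n_trials, n_time, n))
    out_traj = np.empty((n_trials, n_time))
    for b in range(n_trials):
        y = y0[b].copy()
        for i in range(n):
            o_traj[b, 0, i] = 1.0 / (1.0 + np.exp(-(y[i] + biases[i])))
        acc = 0.0
        for i in range(n):
            acc += output_weights[i] * o_traj[b, 0, i]
        out_traj[b, 0] = 2.0 / (1.0 + np.exp(-acc)) - 1.0
        for k in range(n_steps):
            stim = inputs[b, k]
            for i in range(n):
                drive = -y[i] + input_weights[i] * stim
                for j in range(n):
                    drive += weights[i, j] * o_traj[b, k, j]
                y[i] = y[i] + (dt / taus[i]) * drive
            acc = 0.0
            for i in range(n):
                o_traj[b, k + 1, i] = 1.0 / (1.0 + np.exp(-(y[i] + biases[i])))
                acc += output_weights[i] * o_traj[b, k + 1, i]
            out_traj[b, k + 1] = 2.0 / (1.0 + np.exp(-acc)) - 1.0
    return o_traj, out_traj


def _integrate_np(weights, input_weights, output_weights, taus, biases, y0, inputs, dt):
    n_trials, n_steps = inputs.shape
    n = weights.shape[0]
    o_traj = np.empty((n_trials, n_steps + 1, n))
    out_traj = np.empty((n_trials, n_steps + 1))
    y = y0.copy()
    o = 1.0 / (1.0 + np.exp(-(y + biases)))
    o_traj[:, 0, :] = o
    out_traj[:, 0] = 2.0 / (1.0 + np.exp(-(o @ output_weights))) - 1.0
    rate = dt / taus
    for k in range(n_steps):
        drive = -y + o @ weights.T + inputs[:, k, None] * input_weights
        y = y + rate * drive
        o = 1.0 / (1.0 + np.exp(-(y + biases)))
        o_traj[:, k + 1, :] = o
        out_traj[:, k + 1] = 2.0 / (1.0 + np.exp(-(o @ output_weights))) - 1.0
    return o_traj, out_traj


@njit(cache=True, fastmath=True)
def _probe_deviation_nb(weights, input_weights, output_weights, taus, biases,
                        y0, inputs, targets, probe_start, dt):
    n_trials, n_steps = inputs.shape
    n = weights.shape[0]
    total = 0.0
    o = np.empty(n)
    o_new = np.empty(n)
    for b in range(n_trials):
        y = y0[b].copy()
        for i in range(n):
            o[i] = 1.0 / (1.0 + np.exp(-(y[i] + biases[i])))
        if probe_start == 0:
            acc = 0.0
            for i in range(n):
                acc += output_weights[i] * o[i]
            total += abs(2.0 / (1.0 + np.exp(-acc)) - 1.0 - targets[b])
        for k in range(n_steps):
            stim = inputs[b, k]
            for i in range(n):
                drive = -y[i] + input_weights[i] * stim
                for j in range(n):
                    drive += weights[i, j] * o[j]
                y[i] = y[i] + (dt / taus[i]) * drive
            acc = 0.0
            for i in range(n):
                o_new[i] = 1.0 / (1.0 + np.exp(-(y[i] + biases[i])))
                acc += output_weights[i] * o_new[i]
            for i in range(n):
                o[i] = o_new[i]
            if k + 1 >= probe_start:
                total += abs(2.0 / (1.0 + np.exp(-acc)) - 1.0 - targets[b])
    n_probe = n_steps + 1 - probe_start
    return total / (n_trials * n_probe)


def probe_deviation(weights, input_weights, output_weights, taus, biases,
                    y0, inputs, targets, probe_start, dt):
    """Mean probe-stage |O(t) - target| without storing trajectories.

    The optimizer inner loop for the relational task; falls back to the
    trajectory-recording path when numba is unavailable.
    """
    if HAVE_NUMBA:
        return _probe_deviation_nb(
            np.ascontiguousarray(weights, dtype=np.float64),
            np.ascontiguousarray(input_weights, dtype=np.float64),
            np.ascontiguousarray(output_weights, dtype=np.float64),
            np.ascontiguousarray(taus, dtype=np.float64),
            np.ascontiguousarray(biases, dtype=np.float64),
            np.ascontiguousarray(y0, dtype=np.float64),
            np.ascontiguousarray(inputs, dtype=np.float64),
            np.ascontiguousarray(targets, dtype=np.float64),
            int(probe_start),
            float(dt),
        )
    _, out = _integrate_np(weights, input_weights, output_weights, taus, biases,
                           y0, inputs, dt)
    return float(np.mean(np.abs(out[:, probe_start:] - targets[:, None])))


def integrate_batch(weights, input_weights, output_weights, taus, biases, y0, inputs, dt):
    """Integrate a batch of trials of one network.

    Parameters
    ----------
    y0 : (n_trials, N) initial internal states.
    inputs : (n_trials, n_steps) stimulus value applied at each Euler step.

    Returns
    -------
    o_traj : (n_trials, n_steps + 1, N) neuron outputs, first row = initial state.
    out_traj : (n_trials, n_steps + 1) network output.
    """
    args = (
        np.ascontiguousarray(weights, dtype=np.float64),
        np.ascontiguousarray(input_weights, dtype=np.float64),
        np.ascontiguousarray(output_weights, dtype=np.float64),
        np.ascontiguousarray(taus, dtype=np.float64),
        np.ascontiguousarray(biases, dtype=np.float64),
        np.ascontiguousarray(y0, dtype=np.float64),
        np.ascontiguousarray(inputs, dtype=np.float64),
        float(dt),
    )
    if HAVE_NUMBA:
        return _integrate_nb(*args)
    return _integrate_np(*args)
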