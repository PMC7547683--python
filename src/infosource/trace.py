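"""Trial time-series containers.

A :class:`Trace` holds one trial: time, stimulus input, neuron outputs,
network output, and (for agent-environment tasks) the environment state.
A :class:`TrialEnsemble` stacks traces of identical length and time step
across trials, together with a per-trial label table; the across-trial
stacking is what per-time-point information estimation operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd


@dataclass
class Trace:
    dt: float
    time: np.ndarray
    input: np.ndarray
    neuron_outputs: np.ndarray  # (T, N)
    output: np.ndarray
    env_state: Optional[np.ndarray] = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.input = np.asarray(self.input, dtype=float).ravel()
        self.neuron_outputs = np.atleast_2d(np.asarray(self.neuron_outputs, dtype=float))
        self.output = np.asarray(self.output, dtype=float).ravel()
        if self.env_state is not None:
            self.env_state = np.asarray(self.env_state, dtype=float).ravel()
        t = len(self.time)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("input", "output"):
            if len(getattr(self, name)) != t:
                raise ValueError(f"{name} length does not match time")
        if self.neuron_outputs.shape[0] != t:
            raise ValueError("neuron_outputs length does not match time")
        if self.env_state is not None and len(self.env_state) != t:
            raise ValueError("env_state length does not match time")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_neurons(self) -> int:
        return self.neuron_outputs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.time, "input": self.input}
        for i in range(self.n_neurons):
            cols[f"o_{i + 1}"] = self.neuron_outputs[:, i]
        cols["output"] = self.output
        if self.env_state is not None:
            cols["env_state"] = self.env_state
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Trace":
        df = pd.read_csv(path, sep="\t")
        o_cols = [c for c in df.columns if c.startswith("o_")]
        time = df["time"].to_numpy()
        dt = float(time[1] - time[0]) if len(time) > 1 else 1.0
        return cls(
            dt=dt,
            time=time,
            input=df["input"].to_numpy(),
            neuron_outputs=df[o_cols].to_numpy(),
            output=df["output"].to_numpy(),
            env_state=df["env_state"].to_numpy() if "env_state" in df else None,
        )


@dataclass
class TrialEnsemble:
    """Traces of equal length/dt plus a per-trial label table."""

    traces: List[Trace]
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if len(self.traces) < 1:
            raise ValueError("ensemble requires at least one trace")
        t0, dt0 = len(self.traces[0]), self.traces[0].dt
        for tr in self.traces:
            if len(tr) != t0 or abs(tr.dt - dt0) > 1e-12:
                raise ValueError("all traces must share length and dt")
        if len(self.labels) == 0:
            self.labels = pd.DataFrame({"trial_id": np.arange(len(self.traces))})

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def n_time(self) -> int:
        return len(self.traces[0])

    @property
    def dt(self) -> float:
        return self.traces[0].dt

    @property
    def n_neurons(self) -> int:
        return self.traces[0].n_neurons

    def stack(self, column: str) -> np.ndarray:
        """Stack one column across trials.

        ``column`` is one of ``input``, ``output``, ``env_state`` (returning
        an (n_trials, T) array) or ``neuron_outputs`` ((n_trials, T, N)).
        """
        arrays = [getattr(tr, column) for tr in self.traces]
        if any(a is None for a in arrays):
            raise ValueError(f"column {column!r} absent from some traces")
        return np.stack(arrays)

    def save(self, path) -> None:
        """Write the ensemble to an HDF5 container (trial-major arrays)."""
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            f.attrs["dt"] = self.dt
            f.create_dataset("time", data=self.traces[0].time)
            f.create_dataset("input", data=self.stack("input"))
            f.create_dataset("neuron_outputs", data=self.stack("neuron_outputs"))
            f.create_dataset("output", data=self.stack("output"))
            if self.traces[0].env_state is not None:
                f.create_dataset("env_state", data=self.stack("env_state"))
            grp = f.create_group("labels")
            grp.attrs["columns"] = list(self.labels.columns)
            for col in self.labels.columns:
                vals = self.labels[col].to_numpy()
                if vals.dtype.kind in "OU":
                    vals = vals.astype("S")
                grp.create_dataset(col, data=vals)

    @classmethod
    def load(cls, path) -> "TrialEnsemble":
        import h5py

        with h5py.File(path, "r") as f:
            dt = float(f.attrs["dt"])
            time = f["time"][:]
            inputs = f["input"][:]
            outputs = f["neuron_outputs"][:]
            net_out = f["output"][:]
            env = f["env_state"][:] if "env_state" in f else None
            labels = {}
            order = [str(c) for c in f["labels"].attrs.get("columns", list(f["labels"]))]
            for col in order:
                vals = f["labels"][col][:]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                labels[col] = vals
        traces = [
            Trace(
                dt=dt,
                time=time,
                input=inputs[b],
                neuron_outputs=outputs[b],
                output=net_out[b],
                env_state=None if env is None else env[b],
            )
            for b in range(inputs.shape[0])
        ]
        return cls(traces=traces, labels=pd.DataFrame(labels))
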