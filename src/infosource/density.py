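"""Average-shifted-histogram (ASH) estimation of discrete joint distributions.

Continuous samples are histogrammed on a fixed per-dimension grid (default
100 bins), repeated for ``n_shifts`` binnings (default 7) whose bin edges
are offset by ``shift_index / n_shifts`` of a bin width.  Each shifted
binning yields one sparse :class:`DiscreteJoint`; downstream information
measures are computed once per shift and averaged.  Bin bounds are meant to
be fixed once per analysis (over all time points and trials) so that
distributions estimated at different time points are comparable.

Dimensions flagged as *discrete* (trial labels such as the cue value)
bypass binning: their integer codes are used directly and are unaffected by
the shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

DEFAULT_N_BINS = 100
DEFAULT_N_SHIFTS = 7

_PAD = 1e-9


@dataclass
class BinSpec:
    """Per-dimension binning: bounds, bin counts, and one shift offset."""

    lower: np.ndarray
    upper: np.ndarray
    n_bins: np.ndarray
    shift_index: int = 0
    n_shifts: int = 1
    discrete: Optional[np.ndarray] = None  # boolean mask; discrete dims ignore shifts

    def __post_init__(self):
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        self.n_bins = np.atleast_1d(np.asarray(self.n_bins, dtype=int))
        if self.discrete is None:
            self.discrete = np.zeros(len(self.lower), dtype=bool)
        else:
            self.discrete = np.atleast_1d(np.asarray(self.discrete, dtype=bool))
        if not (len(self.lower) == len(self.upper) == len(self.n_bins) == len(self.discrete)):
            raise ValueError("per-dimension arrays must share length")
        if np.any(self.upper <= self.lower):
            raise ValueError("upper bounds must exceed lower bounds")
        if np.any(self.n_bins < 2) and not np.all(self.discrete[self.n_bins < 2]):
            raise ValueError("n_bins must be >= 2 for continuous dimensions")
        if not (0 <= self.shift_index < max(self.n_shifts, 1)):
            raise ValueError("shift_index must lie in [0, n_shifts)")

    @property
    def ndim(self) -> int:
        return len(self.lower)

    @property
    def binwidth(self) -> np.ndarray:
        return (self.upper - self.lower) / self.n_bins


@dataclass
class DiscreteJoint:
    """Sparse discrete joint distribution over binned variables.

    ``indices`` is a (K, d) array of occupied bin-index tuples and ``probs``
    the matching probabilities (summing to 1).  Memory is proportional to
    the number of occupied bins, never to ``n_bins ** d``.
    """

    indices: np.ndarray
    probs: np.ndarray
    n_bins: np.ndarray

    def __post_init__(self):
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=np.int64))
        self.probs = np.asarray(self.probs, dtype=float).ravel()
        self.n_bins = np.atleast_1d(np.asarray(self.n_bins, dtype=np.int64))
        if self.indices.shape[0] != len(self.probs):
            raise ValueError("indices and probs must have matching length")
        if self.indices.shape[1] != len(self.n_bins):
            raise ValueError("n_bins must give one size per dimension")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        if np.any(self.indices < 0) or np.any(self.indices >= self.n_bins):
            raise ValueError("bin indices out of range")

    @property
    def ndim(self) -> int:
        return self.indices.shape[1]

    @classmethod
    def from_codes(cls, codes: np.ndarray, n_bins: np.ndarray) -> "DiscreteJoint":
        """Aggregate per-sample integer codes (M, d) into a joint distribution."""
        codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
        uniq, counts = _unique_rows(codes, np.asarray(n_bins, dtype=np.int64))
        return cls(indices=uniq, probs=counts / counts.sum(), n_bins=n_bins)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.indices, columns=[f"dim_{i}" for i in range(self.ndim)])
        df["probability"] = self.probs
        return df


def _unique_rows(codes: np.ndarray, radices: np.ndarray):
    """Unique rows + counts via mixed-radix encoding to a single int64 key."""
    strides = np.concatenate([np.cumprod(radices[::-1])[-2::-1], [1]]).astype(np.int64)
    keys = codes @ strides
    uniq_keys, counts = np.unique(keys, return_counts=True)
    rows = np.empty((len(uniq_keys), len(radices)), dtype=np.int64)
    rem = uniq_keys
    for d in range(len(radices)):
        rows[:, d] = rem // strides[d]
        rem = rem % strides[d]
    return rows, counts


def assign_bins(samples: np.ndarray, spec: BinSpec) -> np.ndarray:
    """Bin index of each sample under half-open intervals (last bin closed).

    Shifted edges are ``lower + (k + shift_index/n_shifts) * binwidth``;
    samples below the first shifted edge clamp into bin 0 and above the last
    into bin ``n_bins - 1``.  Samples further than one bin width outside the
    declared bounds violate the bounds policy and are rejected.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[1] != spec.ndim:
        raise ValueError("sample dimensionality does not match BinSpec")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    w = spec.binwidth
    cont = ~spec.discrete
    if np.any(samples[:, cont] < (spec.lower - w)[cont]) or np.any(
        samples[:, cont] > (spec.upper + w)[cont]
    ):
        raise ValueError("sample outside declared bounds by more than one bin width")
    frac = spec.shift_index / spec.n_shifts if spec.n_shifts > 1 else 0.0
    codes = np.empty(samples.shape, dtype=np.int64)
    codes[:, cont] = np.floor((samples[:, cont] - spec.lower[cont]) / w[cont] - frac).astype(np.int64)
    if spec.discrete.any():
        codes[:, spec.discrete] = np.round(samples[:, spec.discrete]).astype(np.int64)
    np.clip(codes, 0, spec.n_bins - 1, out=codes)
    return codes


def bin_data(samples: np.ndarray, spec: BinSpec) -> DiscreteJoint:
    """Histogram samples under one (possibly shifted) binning."""
    codes = assign_bins(samples, spec)
    return DiscreteJoint.from_codes(codes, spec.n_bins)


def auto_bounds(samples: np.ndarray) -> tuple:
    """Per-dimension (min - pad, max + pad) bounds over the whole dataset."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    lo = samples.min(axis=0) - _PAD
    hi = samples.max(axis=0) + _PAD
    flat = hi - lo <= 2 * _PAD  # constant dimension: give it unit width
    hi[flat] = lo[flat] + 1.0
    return lo, hi


def make_specs(
    bounds,
    n_bins: int = DEFAULT_N_BINS,
    n_shifts: int = DEFAULT_N_SHIFTS,
    discrete: Optional[np.ndarray] = None,
    discrete_sizes: Optional[np.ndarray] = None,
) -> List[BinSpec]:
    """One BinSpec per shift index for fixed bounds.

    ``discrete_sizes`` gives the category count of discrete dimensions
    (their ``n_bins``); continuous dimensions all use ``n_bins``.
    """
    lo, hi = bounds
    lo = np.atleast_1d(np.asarray(lo, dtype=float))
    hi = np.atleast_1d(np.asarray(hi, dtype=float))
    d = len(lo)
    nb = np.full(d, n_bins, dtype=int)
    if discrete is not None and np.any(discrete):
        if discrete_sizes is None:
            raise ValueError("discrete dimensions need discrete_sizes")
        nb[discrete] = np.asarray(discrete_sizes, dtype=int)[discrete]
    return [
        BinSpec(lower=lo, upper=hi, n_bins=nb, shift_index=s, n_shifts=n_shifts, discrete=discrete)
        for s in range(n_shifts)
    ]


def ash_estimates(
    samples: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    n_shifts: int = DEFAULT_N_SHIFTS,
    bounds="auto",
    discrete: Optional[np.ndarray] = None,
    discrete_sizes: Optional[np.ndarray] = None,
) -> List[DiscreteJoint]:
    """One DiscreteJoint per shifted binning of the sample matrix.

    ``bounds="auto"`` computes padded min/max bounds from the supplied
    samples; pass explicit ``(lower, upper)`` arrays to keep bounds fixed
    across repeated calls within one analysis.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 1:
        raise ValueError("at least one sample required")
    if isinstance(bounds, str) and bounds == "auto":
        bounds = auto_bounds(samples)
    specs = make_specs(bounds, n_bins=n_bins, n_shifts=n_shifts, discrete=discrete, discrete_sizes=discrete_sizes)
    return [bin_data(samples, spec) for spec in specs]


def ash_density(
    samples: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    n_shifts: int = DEFAULT_N_SHIFTS,
    bounds="auto",
) -> DiscreteJoint:
    """Classic shift-averaged histogram on the refined common grid.

    The alternative to estimate-averaging: the ``n_shifts`` shifted
    histograms are averaged as *densities* on the grid of
    ``n_bins * n_shifts`` cells per dimension (each coarse bin spreads its
    mass uniformly over its fine cells).  Because every occupied coarse
    bin expands into ``n_shifts ** d`` fine cells, this is practical only
    for low-dimensional diagnostics; the information pipelines use
    estimate-averaging, which keeps the state space at the coarse
    resolution.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    d = samples.shape[1]
    if isinstance(bounds, str) and bounds == "auto":
        bounds = auto_bounds(samples)
    specs = make_specs(bounds, n_bins=n_bins, n_shifts=n_shifts)
    if n_shifts**d * samples.shape[0] > 5_000_000:
        raise ValueError("refined-grid ASH is only supported for low-dimensional data")
    fine_bins = np.full(d, n_bins * n_shifts, dtype=np.int64)
    # offsets of a coarse cell's fine-cell block, one axis per dimension
    block = np.stack(
        np.meshgrid(*[np.arange(n_shifts)] * d, indexing="ij"), axis=-1
    ).reshape(-1, d)
    parts = []
    weights = []
    for spec in specs:
        joint = bin_data(samples, spec)
        # coarse cell k of shift s covers fine cells k*n_shifts + s ... + s + n_shifts - 1,
        # clipped at the domain edges
        base = joint.indices * n_shifts + spec.shift_index
        fine = (base[:, None, :] + block[None, :, :]).reshape(-1, d)
        np.clip(fine, 0, fine_bins - 1, out=fine)
        parts.append(fine)
        weights.append(np.repeat(joint.probs / n_shifts**d, len(block)))
    fine_all = np.vstack(parts)
    w_all = np.concatenate(weights)
    strides = np.concatenate([np.cumprod(fine_bins[::-1])[-2::-1], [1]]).astype(np.int64)
    keys = fine_all @ strides
    uniq, inv = np.unique(keys, return_inverse=True)
    probs = np.bincount(inv.ravel(), weights=w_all, minlength=len(uniq))
    probs = probs / probs.sum()  # each shift contributes total mass 1; renormalize the average
    rows = np.empty((len(uniq), d), dtype=np.int64)
    rem = uniq
    for k in range(d):
        rows[:, k] = rem // strides[k]
        rem = rem % strides[k]
    return DiscreteJoint(indices=rows, probs=probs, n_bins=fine_bins)


def marginalize(joint: DiscreteJoint, keep_dims: Sequence[int]) -> DiscreteJoint:
    """Sum mass over all dimensions not in ``keep_dims``."""
    keep = list(keep_dims)
    if len(keep) == 0:
        raise ValueError("keep_dims must be non-empty")
    sub = joint.indices[:, keep]
    radices = joint.n_bins[keep]
    strides = np.concatenate([np.cumprod(radices[::-1])[-2::-1], [1]]).astype(np.int64)
    keys = sub @ strides
    uniq, inv = np.unique(keys, return_inverse=True)
    probs = np.bincount(inv, weights=joint.probs, minlength=len(uniq))
    rows = np.empty((len(uniq), len(keep)), dtype=np.int64)
    rem = uniq
    for d in range(len(keep)):
        rows[:, d] = rem // strides[d]
        rem = rem % strides[d]
    return DiscreteJoint(indices=rows, probs=probs, n_bins=radices)
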