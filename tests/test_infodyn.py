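import numpy as np
import pandas as pd
import pytest

from infosource import infodyn
from infosource.density import DiscreteJoint
from infosource.infodyn import (
    entropy,
    i_min,
    mutual_info,
    pid_two_sources,
    predictive_info_pooled,
    predictive_info_surrogates,
    specific_info,
    transfer_terms,
    unrolled_decomposition,
)
from infosource.trace import Trace, TrialEnsemble

import _oracle
from conftest import joint_from_dict

AND_GATE = {(0, 0, 0): 0.25, (0, 0, 1): 0.25, (0, 1, 0): 0.25, (1, 1, 1): 0.25}
XOR_GATE = {(0, 0, 0): 0.25, (1, 0, 1): 0.25, (1, 1, 0): 0.25, (0, 1, 1): 0.25}


class TestEntropy:
    def test_uniform_four_bins(self):
        j = DiscreteJoint(indices=[[0], [1], [2], [3]], probs=[0.25] * 4, n_bins=[4])
        assert entropy(j) == pytest.approx(2.0)

    def test_point_mass(self):
        j = DiscreteJoint(indices=[[0]], probs=[1.0], n_bins=[1])
        assert entropy(j) == 0.0

    def test_hand_evaluated(self):
        j = DiscreteJoint(indices=[[0], [1], [2]], probs=[0.5, 0.25, 0.25], n_bins=[3])
        assert entropy(j) == pytest.approx(1.5)


class TestMutualInfo:
    def test_independent_joint_zero(self):
        d = {(x, y): 0.25 for x in range(2) for y in range(2)}
        assert mutual_info(joint_from_dict(d, [2, 2]), [0], [1]) == pytest.approx(0.0)

    def test_deterministic_copy_one_bit(self):
        j = joint_from_dict({(0, 0): 0.5, (1, 1): 0.5}, [2, 2])
        assert mutual_info(j, [0], [1]) == pytest.approx(1.0)

    def test_hand_evaluated(self):
        j = joint_from_dict({(0, 0): 0.4, (0, 1): 0.1, (1, 0): 0.1, (1, 1): 0.4}, [2, 2])
        assert mutual_info(j, [0], [1]) == pytest.approx(0.278072, abs=1e-6)

    def test_equals_entropy_identity(self):
        rng = np.random.default_rng(0)
        d = _oracle.random_joint(rng, [3, 3])
        j = joint_from_dict(d, [3, 3])
        from infosource.density import marginalize

        hx = entropy(marginalize(j, [0]))
        hy = entropy(marginalize(j, [1]))
        hxy = entropy(j)
        assert mutual_info(j, [0], [1]) == pytest.approx(hx + hy - hxy, abs=1e-12)


class TestSpecificInfo:
    def test_perfect_copy(self):
        j = joint_from_dict({(0, 0): 0.5, (1, 1): 0.5}, [2, 2])
        assert specific_info(j, [0], [1], [0]) == pytest.approx(1.0)

    def test_independent_source_zero_for_every_outcome(self):
        d = {(y, a): 0.25 for y in range(2) for a in range(2)}
        j = joint_from_dict(d, [2, 2])
        for y in (0, 1):
            assert specific_info(j, [0], [1], [y]) == pytest.approx(0.0, abs=1e-12)

    def test_and_gate_values(self):
        j = joint_from_dict(AND_GATE, [2, 2, 2])
        assert specific_info(j, [0], [1], [1]) == pytest.approx(1.0)
        assert specific_info(j, [0], [1], [0]) == pytest.approx(0.081704, abs=1e-6)

    def test_rejects_zero_probability_outcome(self):
        j = joint_from_dict({(0, 0): 1.0}, [2, 2])
        with pytest.raises(ValueError):
            specific_info(j, [0], [1], [1])


class TestIMin:
    def test_single_source_equals_mutual_info(self):
        rng = np.random.default_rng(1)
        d = _oracle.random_joint(rng, [3, 3])
        j = joint_from_dict(d, [3, 3])
        assert i_min(j, [0], [[1]]) == pytest.approx(mutual_info(j, [1], [0]), abs=1e-12)

    def test_xor_redundancy_zero(self):
        j = joint_from_dict(XOR_GATE, [2, 2, 2])
        assert i_min(j, [0], [[1], [2]]) == pytest.approx(0.0, abs=1e-12)

    def test_and_redundancy(self):
        j = joint_from_dict(AND_GATE, [2, 2, 2])
        assert i_min(j, [0], [[1], [2]]) == pytest.approx(0.311278, abs=1e-6)


class TestPidTwoSources:
    def test_and_gate_atoms(self):
        atoms = pid_two_sources(joint_from_dict(AND_GATE, [2, 2, 2]), [0], [1], [2])
        assert atoms.redundancy == pytest.approx(0.311278, abs=1e-6)
        assert atoms.unique_a == pytest.approx(0.0, abs=1e-9)
        assert atoms.unique_b == pytest.approx(0.0, abs=1e-9)
        assert atoms.synergy == pytest.approx(0.5, abs=1e-9)

    def test_xor_gate_atoms(self):
        atoms = pid_two_sources(joint_from_dict(XOR_GATE, [2, 2, 2]), [0], [1], [2])
        assert atoms.redundancy == pytest.approx(0.0, abs=1e-12)
        assert atoms.synergy == pytest.approx(1.0, abs=1e-12)

    def test_copy_with_independent_distractor(self):
        d = {(y, y, b): 0.25 for y in range(2) for b in range(2)}
        atoms = pid_two_sources(joint_from_dict(d, [2, 2, 2]), [0], [1], [2])
        assert atoms.unique_a == pytest.approx(1.0)
        assert atoms.redundancy == pytest.approx(0.0, abs=1e-12)
        assert atoms.synergy == pytest.approx(0.0, abs=1e-9)


class TestTransferTerms:
    def test_env_copy_chain(self):
        d = {(y, a, y, y): 0.25 for y in range(2) for a in range(2)}
        td = transfer_terms(joint_from_dict(d, [2, 2, 2, 2]), [0], [1], [2], [3])
        assert td.transfer_from_env == pytest.approx(1.0)
        assert td.transfer_from_neural == pytest.approx(0.0, abs=1e-12)
        assert td.transfer_redundant == pytest.approx(0.0, abs=1e-12)

    def test_neural_copy_chain(self):
        d = {(y, y, b, y): 0.25 for y in range(2) for b in range(2)}
        td = transfer_terms(joint_from_dict(d, [2, 2, 2, 2]), [0], [1], [2], [3])
        assert td.transfer_from_neural == pytest.approx(1.0)
        assert td.transfer_from_env == pytest.approx(0.0, abs=1e-12)

    def test_fully_synchronized_is_all_redundant(self):
        d = {(y, y, y, y): 0.5 for y in range(2)}
        td = transfer_terms(joint_from_dict(d, [2, 2, 2, 2]), [0], [1], [2], [3])
        assert td.transfer_redundant == pytest.approx(1.0)
        assert td.transfer_from_neural == pytest.approx(0.0, abs=1e-12)
        assert td.transfer_from_env == pytest.approx(0.0, abs=1e-12)
        assert td.total_in_x == pytest.approx(1.0)


class TestOracleEquivalence:
    """Vectorised measures vs the independent brute-force oracle."""

    @pytest.mark.parametrize("seed", range(40))
    def test_pid_and_transfer_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 5, size=4)
        d = _oracle.random_joint(rng, sizes)
        j = joint_from_dict(d, sizes)
        atoms = pid_two_sources(j, [0], [1], [2])
        ref = _oracle.pid_two_sources(d, [0], [1], [2])
        for key in ("total", "redundancy", "unique_a", "unique_b", "synergy"):
            assert getattr(atoms, key) == pytest.approx(ref[key], abs=1e-9)
        td = transfer_terms(j, [0], [1], [2], [3])
        ref_t = _oracle.transfer_terms(d, [0], [1], [2], [3])
        for key in ("transfer_from_neural", "transfer_from_env", "transfer_redundant", "total_in_x"):
            assert getattr(td, key) == pytest.approx(ref_t[key], abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_atoms_and_terms_nonnegative(self, seed):
        rng = np.random.default_rng(1000 + seed)
        sizes = rng.integers(2, 5, size=4)
        d = _oracle.random_joint(rng, sizes)
        j = joint_from_dict(d, sizes)
        atoms = pid_two_sources(j, [0], [1], [2])
        td = transfer_terms(j, [0], [1], [2], [3])
        for v in (atoms.redundancy, atoms.unique_a, atoms.unique_b, atoms.synergy,
                  td.transfer_from_neural, td.transfer_from_env, td.transfer_redundant):
            assert v >= -1e-9
        assert td.transfer_from_neural <= td.total_in_x + 1e-9
        assert td.transfer_from_env <= td.total_in_x + 1e-9


def _copy_channel_ensemble(n_trials=64, n_time=40, n_levels=8):
    """Y(t+1) = X(t) exactly, X uniform over n_levels distinct values."""
    rng = np.random.default_rng(0)
    traces = []
    for _ in range(n_trials):
        x = rng.integers(0, n_levels, size=n_time) / (n_levels - 1)
        stim = np.concatenate([[0.0], x[:-1]])  # S(t+1) = X(t)
        traces.append(
            Trace(dt=1.0, time=np.arange(n_time, dtype=float), input=stim,
                  neuron_outputs=x[:, None], output=x, env_state=stim)
        )
    return TrialEnsemble(traces=traces)


class TestPooledPredictiveInfo:
    def test_copy_channel_recovers_log2_levels(self):
        ens = _copy_channel_ensemble()
        pi = predictive_info_pooled(ens, dt_steps=1, n_bins=100, n_shifts=7)
        assert abs(pi - 3.0) < 0.05

    def test_independent_streams_below_surrogate_band(self):
        rng = np.random.default_rng(5)
        traces = [
            Trace(dt=1.0, time=np.arange(50.0), input=rng.random(50),
                  neuron_outputs=rng.random((50, 1)), output=rng.random(50))
            for _ in range(30)
        ]
        ens = TrialEnsemble(traces=traces)
        pi = predictive_info_pooled(ens, n_bins=20)
        floor = np.percentile(predictive_info_surrogates(ens, 20, seed=1, n_bins=20), 95)
        assert pi < floor * 1.1

    def test_invariant_under_trial_permutation(self):
        ens = _copy_channel_ensemble(n_trials=16)
        perm = np.random.default_rng(2).permutation(len(ens))
        ens_perm = TrialEnsemble(traces=[ens.traces[i] for i in perm])
        a = predictive_info_pooled(ens)
        b = predictive_info_pooled(ens_perm)
        assert a == pytest.approx(b, abs=1e-12)


def _staged_label_ensemble():
    """Ground-truth ensemble: the stimulus encodes a binary label up to
    t=10; one neuron encodes it from t=8 onward.

    Expected source pattern for the label: env is the unique source at the
    first time the neuron encodes (t=8), redundant while both carry it
    (t in (8, 10]), and the network is the unique source after stimulus
    offset (t > 11)."""
    n_time = 20
    time = np.arange(n_time, dtype=float)
    traces, labels = [], []
    rng = np.random.default_rng(9)
    for trial in range(24):
        label = trial % 2
        jitter = 0.01 * rng.standard_normal(n_time)
        stim = np.where(time < 10, 0.2 + 0.6 * label, 0.0) + jitter
        o = np.where(time >= 8, 0.2 + 0.6 * label, 0.5) + 0.01 * rng.standard_normal(n_time)
        traces.append(
            Trace(dt=1.0, time=time, input=stim, neuron_outputs=o[:, None], output=o)
        )
        labels.append(label)
    return TrialEnsemble(
        traces=traces, labels=pd.DataFrame({"trial_id": range(24), "label": labels})
    )


class TestUnrolledDecomposition:
    def test_identical_trials_give_zero_everywhere(self):
        time = np.arange(30.0)
        x = np.sin(time * 0.3) * 0.4 + 0.5
        traces = [
            Trace(dt=1.0, time=time, input=x, neuron_outputs=x[:, None], output=x, env_state=x)
            for _ in range(10)
        ]
        ts = unrolled_decomposition(TrialEnsemble(traces=traces), n_bins=20)
        assert np.allclose(ts.total_in_x, 0.0, atol=1e-12)
        assert np.allclose(ts.transfer_from_neural, 0.0, atol=1e-12)

    def test_staged_label_source_pattern(self):
        ens = _staged_label_ensemble()
        ts = unrolled_decomposition(ens, target="label", n_bins=30)
        t = ts.time
        onset = ts.transfer_from_env[t == 8][0]
        mid = ts.transfer_redundant[t == 9][0]
        late = ts.transfer_from_neural[t == 14][0]
        assert onset > 0.9  # env uniquely provides the label when N first encodes it
        assert mid > 0.9  # both sources carry it while the stimulus is on
        assert late > 0.9  # network is the unique source after offset
        assert ts.transfer_from_env[t == 14][0] < 0.05
        assert ts.transfer_from_neural[t == 8][0] < 0.05

    def test_unequal_trial_lengths_rejected(self):
        a = Trace(dt=1.0, time=np.arange(5.0), input=np.zeros(5),
                  neuron_outputs=np.zeros((5, 1)), output=np.zeros(5))
        b = Trace(dt=1.0, time=np.arange(6.0), input=np.zeros(6),
                  neuron_outputs=np.zeros((6, 1)), output=np.zeros(6))
        with pytest.raises(ValueError):
            TrialEnsemble(traces=[a, b])

    def test_shift_averaging_deterministic(self):
        ens = _staged_label_ensemble()
        a = unrolled_decomposition(ens, target="label", n_bins=30)
        b = unrolled_decomposition(ens, target="label", n_bins=30)
        np.testing.assert_array_equal(a.total_in_x, b.total_in_x)
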