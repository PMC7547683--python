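import numpy as np
import pandas as pd
import pytest

from infosource import tasks
from infosource.ctrnn import NetworkParams, sigmoid
from infosource.tasks import (
    RelationalTrial,
    cpg_env_step,
    cpg_fitness,
    make_relational_trials,
    output_lattice,
    record_cpg_ensemble,
    record_pp_ensemble,
    relational_classifications,
    relational_input,
    relational_performance,
    simulate_cpg,
    simulate_pp,
    simulate_relational,
    trial_oscillation_scores,
)
from infosource.trace import Trace, TrialEnsemble


def constant_output_params(level=4.0):
    """Network whose neurons saturate to a constant output."""
    return NetworkParams(
        weights=np.zeros((3, 3)), input_weights=np.zeros(3),
        output_weights=[level, 0.0, 0.0], taus=np.ones(3), biases=np.zeros(3),
    )


class TestEnvStep:
    @pytest.mark.parametrize(
        "s,O,expected",
        [(0.0, 1.0, 0.04), (0.5, 0.5, 0.5), (1.0, 0.0, 0.96)],
    )
    def test_hand_evaluated(self, s, O, expected):
        assert cpg_env_step(s, O, dt=0.02, tau_env=0.5) == pytest.approx(expected)

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            cpg_env_step(0.0, 0.0, dt=0.0)


class TestSimulateCpg:
    def test_input_identically_zero(self, random_params):
        tr = simulate_cpg(random_params, [0.5, 0.5, 0.5], duration=2.0)
        assert np.all(tr.input == 0.0)

    def test_neural_trajectory_independent_of_environment(self, random_params):
        tr1 = simulate_cpg(random_params, [0.5, 0.5, 0.5], env_init=0.0, duration=2.0)
        tr2 = simulate_cpg(random_params, [0.5, 0.5, 0.5], env_init=0.9, duration=2.0)
        np.testing.assert_array_equal(tr1.neuron_outputs, tr2.neuron_outputs)

    def test_environment_tracks_constant_output(self):
        p = constant_output_params()
        tr = simulate_cpg(p, [0.5, 0.5, 0.5], env_init=-0.5, duration=10.0)
        assert abs(tr.env_state[-1] - tr.output[-1]) < 1e-3

    def test_ensemble_lattice_initial_conditions(self, random_params):
        ens = record_cpg_ensemble(random_params, 10, duration=0.5)
        assert len(ens) == 10
        firsts = ens.stack("neuron_outputs")[:, 0, :]
        assert len(np.unique(firsts.round(8), axis=0)) == 10


class TestSimulatePp:
    def test_env_column_equals_supplied_signal(self, random_params):
        sig = np.sin(np.arange(101) * 0.1)
        tr = simulate_pp(random_params, sig)
        np.testing.assert_array_equal(tr.env_state, sig)

    def test_zero_input_weights_decouple_network(self, random_params):
        p = NetworkParams(
            weights=random_params.weights, input_weights=np.zeros(3),
            output_weights=random_params.output_weights,
            taus=random_params.taus, biases=random_params.biases,
        )
        tr1 = simulate_pp(p, np.sin(np.arange(101) * 0.1))
        tr2 = simulate_pp(p, np.cos(np.arange(101) * 0.3))
        np.testing.assert_array_equal(tr1.neuron_outputs, tr2.neuron_outputs)

    def test_constant_signal_fixed_point(self, single_neuron):
        tr = simulate_pp(single_neuron, np.full(1501, 0.8))
        assert abs(tr.neuron_outputs[-1, 0] - sigmoid(0.8)) < 1e-3


class TestRelationalTrials:
    def test_2probe_battery_counts(self):
        trials = make_relational_trials("2probe", n_cues=35)
        assert len(trials) == 70
        targets = np.array([t.target for t in trials])
        assert (targets == 1).sum() == 35
        assert (targets == -1).sum() == 35

    def test_single_cue_2probe(self):
        trials = make_relational_trials("2probe", n_cues=1)
        assert len(trials) == 2
        assert {t.probe - t.cue for t in trials} == {-1.0, 1.0}

    def test_9probe_drops_tied_probe(self):
        trials = make_relational_trials("9probe", n_cues=35)
        cues = np.linspace(4, 10, 35)
        integer_cues = [c for c in cues if abs(c - round(c)) < 1e-9]
        assert len(trials) == 35 * 9 - len(integer_cues)
        assert all(t.probe != t.cue for t in trials)

    def test_all_values_in_presentable_range(self):
        for variant in ("2probe", "9probe"):
            for t in make_relational_trials(variant):
                assert 3.0 <= t.cue <= 11.0
                assert 3.0 <= t.probe <= 11.0

    def test_rejects_zero_cues(self):
        with pytest.raises(ValueError):
            make_relational_trials("2probe", n_cues=0)

    def test_trial_rejects_equal_cue_probe(self):
        with pytest.raises(ValueError):
            RelationalTrial(cue=5.0, probe=5.0)


class TestRelationalInput:
    @pytest.mark.parametrize(
        "t,expected", [(2.0, 6.0), (0.0, 6.0), (10.0, 0.0), (5.0, 0.0), (17.0, 5.0), (20.0, 5.0)]
    )
    def test_stage_lookup(self, t, expected):
        trial = RelationalTrial(cue=6.0, probe=5.0)
        assert relational_input(trial, t) == expected

    def test_rejects_out_of_window(self):
        trial = RelationalTrial(cue=6.0, probe=7.0)
        with pytest.raises(ValueError):
            relational_input(trial, 21.0)

    def test_simulated_input_column_is_piecewise_constant(self, random_params):
        trials = make_relational_trials("2probe", n_cues=2)
        ens = simulate_relational(random_params, trials)
        tr = ens.traces[0]
        cue_stage = tr.time < 5
        delay = (tr.time >= 5) & (tr.time < 15)
        probe_stage = tr.time >= 15
        assert np.all(tr.input[cue_stage] == trials[0].cue)
        assert np.all(tr.input[delay] == 0.0)
        assert np.all(tr.input[probe_stage] == trials[0].probe)


class TestSimulateRelational:
    def test_ensemble_shape_and_labels(self, random_params):
        trials = make_relational_trials("2probe", n_cues=35)
        ens = simulate_relational(random_params, trials, dt=0.02)
        assert len(ens) == 70
        assert ens.n_time == 1001
        assert set(ens.labels.columns) >= {"cue", "probe", "target"}

    def test_deterministic(self, random_params):
        trials = make_relational_trials("2probe", n_cues=3)
        a = simulate_relational(random_params, trials)
        b = simulate_relational(random_params, trials)
        np.testing.assert_array_equal(a.stack("output"), b.stack("output"))

    def test_labels_round_trip_serialization(self, random_params, tmp_path):
        trials = make_relational_trials("2probe", n_cues=3)
        ens = simulate_relational(random_params, trials)
        ens.save(tmp_path / "ens.h5")
        back = TrialEnsemble.load(tmp_path / "ens.h5")
        pd.testing.assert_frame_equal(
            ens.labels, back.labels, check_dtype=False, check_exact=False
        )
        np.testing.assert_allclose(ens.stack("output"), back.stack("output"))


def synthetic_relational_ensemble(output_value_fn, trials):
    """Ensemble with prescribed output values, bypassing any dynamics."""
    time = np.arange(0, 20.0 + 1e-9, 0.1)
    traces = []
    for tr in trials:
        out = np.array([output_value_fn(tr, t) for t in time])
        traces.append(
            Trace(dt=0.1, time=time, input=np.zeros_like(time),
                  neuron_outputs=np.zeros((len(time), 1)), output=out)
        )
    labels = pd.DataFrame(
        {"trial_id": range(len(trials)), "cue": [t.cue for t in trials],
         "probe": [t.probe for t in trials], "target": [t.target for t in trials]}
    )
    return TrialEnsemble(traces=traces, labels=labels)


class TestRelationalPerformance:
    trials = make_relational_trials("2probe", n_cues=5)

    def test_perfect_output_scores_one(self):
        ens = synthetic_relational_ensemble(lambda tr, t: float(tr.target), self.trials)
        assert relational_performance(ens) == pytest.approx(1.0)

    def test_zero_output_scores_half(self):
        ens = synthetic_relational_ensemble(lambda tr, t: 0.0, self.trials)
        assert relational_performance(ens) == pytest.approx(0.5)

    def test_opposite_output_scores_zero(self):
        ens = synthetic_relational_ensemble(lambda tr, t: -float(tr.target), self.trials)
        assert relational_performance(ens) == pytest.approx(0.0)

    def test_strictly_decreasing_in_perturbation(self):
        perfs = [
            relational_performance(
                synthetic_relational_ensemble(lambda tr, t, e=eps: tr.target * (1 - e), self.trials)
            )
            for eps in (0.0, 0.2, 0.5)
        ]
        assert perfs[0] > perfs[1] > perfs[2]

    def test_classifications_follow_output_sign(self):
        ens = synthetic_relational_ensemble(lambda tr, t: 0.3 * tr.target, self.trials)
        np.testing.assert_array_equal(
            relational_classifications(ens), ens.labels["target"].to_numpy()
        )


class TestCpgFitness:
    def test_alternating_synthetic_trace_score(self):
        # one neuron alternates 0.4/0.6 each step over 500 steps: per-step
        # change 0.2, so the neuron term alone contributes 500 * 0.2 = 100
        o = np.zeros((1, 501, 1))
        o[0, :, 0] = np.where(np.arange(501) % 2 == 0, 0.4, 0.6)
        out = np.zeros((1, 501))
        scores = trial_oscillation_scores(o, out)
        assert scores[0] == pytest.approx(500 * 0.2)

    def test_constant_network_scores_near_zero(self):
        p = constant_output_params()
        assert cpg_fitness(p, n_init_conditions=10, duration=5.0) < 5.0

    def test_invariant_to_trial_order(self):
        o = np.random.default_rng(0).random((4, 50, 2))
        out = np.random.default_rng(1).random((4, 50))
        total = trial_oscillation_scores(o, out).mean()
        perm = [2, 0, 3, 1]
        total_perm = trial_oscillation_scores(o[perm], out[perm]).mean()
        assert total == pytest.approx(total_perm)


class TestOutputLattice:
    def test_100_points_in_3d_is_5x5x4_grid(self):
        grid = output_lattice(100, 3)
        assert grid.shape == (100, 3)
        assert len(np.unique(grid[:, 0])) == 5
        assert len(np.unique(grid[:, 1])) == 5
        assert len(np.unique(grid[:, 2])) == 4
        assert grid.min() >= 0.05 and grid.max() <= 0.95

    def test_points_unique_and_count_respected(self):
        for n in (1, 7, 10, 27):
            grid = output_lattice(n, 3)
            assert grid.shape == (n, 3)
            assert len(np.unique(grid.round(9), axis=0)) == n
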