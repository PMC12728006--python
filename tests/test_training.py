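"""Accuracy evaluation and simulated-annealing training."""

import math

import numpy as np
import pytest

from netmoa.network import (ModelSolution, PropagationConfig, Stimulus,
                            build_network)
from netmoa.synthetic import SyntheticSpec, generate_system
from netmoa.training import (AnnealConfig, TrainingError, TrainingRule,
                             TrainingSet, anneal_solution, evaluate_accuracy,
                             load_ensemble, load_training_set, save_ensemble,
                             save_training_set, train_ensemble)


def short_config(**overrides) -> AnnealConfig:
    """Reduced schedule for fast unit tests (not the recovery benchmark)."""
    base = dict(initial_temperature=0.02, min_temperature=1e-4,
                cooling_rate=0.85, steps_per_temperature=60)
    base.update(overrides)
    return AnnealConfig(**base)


@pytest.fixture
def two_node():
    net = build_network([("A", "B")])
    rules = TrainingSet([TrainingRule(Stimulus({"A": 1.0}), {"B": 1})])
    return net, rules


class TestEvaluateAccuracy:
    def test_positive_weight_satisfies_positive_rule(self, two_node):
        net, rules = two_node
        good = ModelSolution(net, np.array([1.0]))
        bad = ModelSolution(net, np.array([-1.0]))
        assert evaluate_accuracy(net, good, rules) == 1.0
        assert evaluate_accuracy(net, bad, rules) == 0.0

    def test_zero_weights_fail_every_expectation(self, two_node):
        net, rules = two_node
        zero = ModelSolution(net, np.zeros(1))
        assert evaluate_accuracy(net, zero, rules) == 0.0

    def test_threshold_gates_weak_compliance(self, two_node):
        net, rules = two_node
        # weight chosen so tanh(w) sits between 0.05 and 0.1
        weak = ModelSolution(net, np.array([0.07]))
        assert math.tanh(0.07) < 0.1
        assert evaluate_accuracy(net, weak, rules, activity_threshold=0.1) \
            == 0.0
        assert evaluate_accuracy(net, weak, rules,
                                 activity_threshold=0.05) == 1.0

    def test_counts_per_expectation_not_per_rule(self):
        net = build_network([("A", "B"), ("A", "C")])
        rules = TrainingSet([TrainingRule(Stimulus({"A": 1.0}),
                                          {"B": 1, "C": -1})])
        half = ModelSolution(net, np.array([1.0, 1.0]))
        assert evaluate_accuracy(net, half, rules) == 0.5

    def test_empty_training_set_rejected(self):
        with pytest.raises(TrainingError):
            TrainingSet([])
        with pytest.raises(TrainingError):
            TrainingRule(Stimulus({"A": 1.0}), {})


class TestAnnealSolution:
    def test_one_edge_toy_learns_the_rule(self, two_node):
        net, rules = two_node
        sol = anneal_solution(net, rules, short_config(), seed=1)
        assert sol.accuracy == 1.0
        assert sol.weight_vector[0] > 0

    def test_deterministic_given_seed(self, two_node):
        net, rules = two_node
        cfg = short_config()
        s1 = anneal_solution(net, rules, cfg, seed=3)
        s2 = anneal_solution(net, rules, cfg, seed=3)
        assert np.array_equal(s1.weight_vector, s2.weight_vector)
        assert s1.accuracy == s2.accuracy

    def test_weights_respect_bound(self, two_node):
        net, rules = two_node
        sol = anneal_solution(net, rules, short_config(), seed=5)
        assert np.all(np.abs(sol.weight_vector) <= 1.0)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(TrainingError):
            AnnealConfig(cooling_rate=1.5)
        with pytest.raises(TrainingError):
            AnnealConfig(initial_temperature=-1)

    def test_more_steps_do_not_hurt_objective(self):
        """Paired-seed check: doubling the step budget does not degrade the
        trained accuracy on average."""
        system = generate_system(
            SyntheticSpec.desk_scale(seed=2, n_nodes=40,
                                     motive_sizes=(4, 3, 3, 4),
                                     n_rules=8))
        accs = {}
        for steps in (30, 60):
            cfg = short_config(steps_per_temperature=steps)
            accs[steps] = np.mean([
                anneal_solution(system.network, system.training_set, cfg,
                                seed=s).accuracy for s in range(6)])
        assert accs[60] >= accs[30] - 0.05


class TestTrainEnsemble:
    def test_satisfiable_toy_yields_gated_members(self, two_node):
        net, rules = two_node
        ens = train_ensemble(net, rules,
                             short_config(n_solutions=3, base_seed=0))
        assert len(ens.solutions) == 3
        assert all(s.accuracy > 0.9 for s in ens.solutions)
        accs = [s.accuracy for s in ens.solutions]
        assert accs == sorted(accs, reverse=True)

    def test_contradictory_rules_cap_accuracy_at_half(self):
        net = build_network([("A", "B")])
        rules = TrainingSet([
            TrainingRule(Stimulus({"A": 1.0}), {"B": 1}),
            TrainingRule(Stimulus({"A": 1.0}), {"B": -1}),
        ])
        sol = anneal_solution(net, rules, short_config(), seed=0)
        assert sol.accuracy <= 0.5
        with pytest.raises(TrainingError, match="best accuracy"):
            train_ensemble(net, rules,
                           short_config(n_solutions=1, retry_factor=2))

    def test_seed_determinism_of_full_training(self, two_node):
        net, rules = two_node
        cfg = short_config(n_solutions=2, base_seed=11)
        e1 = train_ensemble(net, rules, cfg)
        e2 = train_ensemble(net, rules, cfg)
        for s1, s2 in zip(e1.solutions, e2.solutions):
            assert np.array_equal(s1.weight_vector, s2.weight_vector)

    def test_desk_scale_reaches_gate(self):
        """Default schedule clears the 0.90 gate on the planted benchmark."""
        system = generate_system(SyntheticSpec.desk_scale(seed=0))
        sol = anneal_solution(system.network, system.training_set,
                              AnnealConfig(), seed=0)
        assert sol.accuracy > 0.9


class TestIO:
    def test_training_set_round_trip(self, tmp_path, two_node):
        _, rules = two_node
        save_training_set(rules, tmp_path / "rules.json")
        back = load_training_set(tmp_path / "rules.json")
        assert [(r.stimulus.inputs, r.expected) for r in back.rules] == \
            [(r.stimulus.inputs, r.expected) for r in rules.rules]

    def test_ensemble_archive_round_trip(self, tmp_path, two_node):
        net, rules = two_node
        cfg = short_config(n_solutions=2)
        ens = train_ensemble(net, rules, cfg)
        save_ensemble(ens, tmp_path / "ens", cfg)
        back = load_ensemble(tmp_path / "ens", net)
        assert back.accuracy_gate == ens.accuracy_gate
        for s1, s2 in zip(ens.solutions, back.solutions):
            assert np.allclose(s1.weight_vector, s2.weight_vector,
                               atol=1e-10)
            assert s1.accuracy == s2.accuracy
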