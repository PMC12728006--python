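"""Propagation core: construction, fixed points, invariants, reachability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netmoa.characterization import (DiseaseCharacterization,
                                     EffectorAssignment)
from netmoa.network import (InteractionNetwork, ModelSolution, NetworkError,
                            PropagationConfig, Stimulus, build_network,
                            combine_stimuli, ensemble_activity, Ensemble,
                            motive_reachability, propagate, read_edge_list,
                            stimulus_from_drug, write_edge_list)
from netmoa.characterization import DrugProfile

from conftest import random_small_network, random_solution


def brute_force_fixed_point(network, weights, clamp, config):
    """Independent dict-based implementation of the damped update rule."""
    a = {n: 0.0 for n in network.nodes}
    a.update(clamp)
    for it in range(config.max_iter):
        new = {}
        for v in network.nodes:
            if v in clamp and config.clamp_inputs:
                new[v] = clamp[v]
                continue
            total = sum(weights[(u, v)] * a[u]
                        for u in network.graph.predecessors(v))
            new[v] = math.tanh(config.gain * total)
        stepped = {v: (1 - config.damping) * a[v] + config.damping * new[v]
                   for v in network.nodes}
        delta = max(abs(stepped[v] - a[v]) for v in network.nodes)
        a = stepped
        if delta < config.tol:
            return a
    return a


class TestBuildNetwork:
    def test_two_rows_three_nodes(self):
        net = build_network([("A", "B"), ("B", "C")])
        assert net.n_nodes == 3 and net.n_edges == 2
        assert list(net.graph.predecessors("B")) == ["A"]
        assert list(net.graph.successors("B")) == ["C"]

    def test_self_loop_rejected_by_default(self):
        with pytest.raises(NetworkError, match="self-loop"):
            build_network([("A", "A")])
        net = build_network([("A", "A")], allow_self_loops=True)
        assert net.n_edges == 1

    def test_edge_list_round_trip(self, tmp_path):
        net = build_network([("A", "B", 1), ("B", "C", -1), ("C", "A", None)])
        write_edge_list(net, tmp_path / "net.tsv")
        back = read_edge_list(tmp_path / "net.tsv")
        assert back.edges == net.edges
        assert back.sign_prior == net.sign_prior

    def test_synthetic_graph_edge_count_matches_recount(self):
        rng = np.random.default_rng(7)
        net = random_small_network(rng, 12, edge_prob=0.3)
        assert net.n_edges == len(set(net.graph.edges()))
        assert net.n_edges == len(net.edge_index)


class TestStimuli:
    def test_stimulus_from_drug_clamps_all_targets(self, chain_network):
        net = build_network([("ITGA4", "X"), ("ITGB7", "X"), ("MADCAM1", "X")])
        vdz = DrugProfile("VDZ", {"ITGA4": -1, "ITGB7": -1},
                          {"MADCAM1": -1})
        stim = stimulus_from_drug(vdz, net, magnitude=1.0)
        assert stim.inputs == {"ITGA4": -1, "ITGB7": -1, "MADCAM1": -1}
        half = stimulus_from_drug(vdz, net, magnitude=0.5)
        assert half.inputs == {p: v * 0.5 for p, v in stim.inputs.items()}

    def test_missing_target_lists_proteins(self, chain_network):
        drug = DrugProfile("X", {"ZZZ": -1})
        with pytest.raises(NetworkError, match="ZZZ"):
            stimulus_from_drug(drug, chain_network)

    def test_combine_disjoint_is_union(self):
        s = combine_stimuli(Stimulus({"A": -1.0}), Stimulus({"B": 0.5}))
        assert s.inputs == {"A": -1.0, "B": 0.5}

    def test_combine_clips_at_bounds(self):
        s = combine_stimuli(Stimulus({"A": -1.0}), Stimulus({"A": -1.0}))
        assert s.inputs == {"A": -1.0}

    def test_all_zero_stimulus_rejected(self):
        with pytest.raises(NetworkError):
            Stimulus({"A": 0.0})


class TestPropagate:
    def test_zero_weight_kills_signal(self, chain_network):
        sol = ModelSolution(chain_network, np.zeros(2))
        prof = propagate(chain_network, sol, Stimulus({"A": 1.0}))
        assert prof.activity["B"] == 0.0 and prof.activity["C"] == 0.0

    def test_unit_weight_chain_gives_tanh(self, chain_network):
        sol = ModelSolution(chain_network,
                            np.ones(2))
        prof = propagate(chain_network, sol, Stimulus({"A": 1.0}),
                         PropagationConfig(tol=1e-12, max_iter=500))
        assert prof.activity["B"] == pytest.approx(math.tanh(1.0), abs=1e-6)
        assert prof.activity["C"] == pytest.approx(math.tanh(math.tanh(1.0)),
                                                   abs=1e-6)

    def test_clamped_node_retains_exact_value(self, chain_network):
        sol = ModelSolution(chain_network, np.array([0.7, -0.3]))
        prof = propagate(chain_network, sol, Stimulus({"A": -0.4}))
        assert prof.activity["A"] == -0.4

    def test_determinism_bitwise(self):
        rng = np.random.default_rng(3)
        net = random_small_network(rng, 8)
        sol = random_solution(net, rng)
        stim = Stimulus({net.nodes[0]: 1.0})
        p1 = propagate(net, sol, stim)
        p2 = propagate(net, sol, stim)
        assert p1.activity == p2.activity
        assert (p1.converged, p1.iterations) == (p2.converged, p2.iterations)

    def test_nonpositive_tol_rejected(self):
        with pytest.raises(NetworkError):
            PropagationConfig(tol=0.0)

    def test_nonfinite_weight_rejected(self, chain_network):
        with pytest.raises(NetworkError, match="non-finite"):
            ModelSolution(chain_network, np.array([np.nan, 1.0]))

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_small_networks(self, seed):
        """propagate matches an independent brute-force implementation."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        net = random_small_network(rng, n, edge_prob=0.5)
        sol = random_solution(net, rng)
        clamp = {net.nodes[0]: float(rng.uniform(-1, 1)) or 0.5}
        config = PropagationConfig(tol=1e-10, max_iter=2000)
        prof = propagate(net, sol, Stimulus(clamp), config)
        oracle = brute_force_fixed_point(net, sol.weights, clamp, config)
        for node in net.nodes:
            assert prof.activity[node] == pytest.approx(oracle[node],
                                                        abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_boundedness_property(self, seed):
        rng = np.random.default_rng(seed)
        net = random_small_network(rng, int(rng.integers(3, 10)))
        sol = random_solution(net, rng)
        stim = Stimulus({net.nodes[0]: -1.0, net.nodes[-1]: 1.0})
        prof = propagate(net, sol, stim)
        assert all(-1 <= v <= 1 for v in prof.activity.values())
        assert prof.activity[net.nodes[0]] == -1.0

    def test_damping_does_not_change_acyclic_fixed_point(self):
        rng = np.random.default_rng(11)
        net = random_small_network(rng, 7, acyclic=True)
        sol = random_solution(net, rng)
        stim = Stimulus({net.nodes[0]: 1.0})
        profiles = [propagate(net, sol, stim,
                              PropagationConfig(tol=1e-11, max_iter=5000,
                                                damping=d))
                    for d in (0.2, 0.5, 1.0)]
        for other in profiles[1:]:
            for node in net.nodes:
                assert profiles[0].activity[node] == pytest.approx(
                    other.activity[node], abs=1e-8)


class TestEnsembleActivity:
    def test_single_solution_matches_propagate(self, chain_network):
        sol = ModelSolution(chain_network, np.array([0.5, 0.5]),
                            accuracy=1.0)
        ens = Ensemble([sol], accuracy_gate=0.9)
        stim = Stimulus({"A": 1.0})
        mean, sd = ensemble_activity(ens, chain_network, stim)
        direct = propagate(chain_network, sol, stim)
        assert mean.activity == direct.activity
        assert all(v == 0.0 for v in sd.values())

    def test_symmetric_solutions_average_to_zero(self, chain_network):
        a = ModelSolution(chain_network, np.array([0.8, 0.0]), accuracy=1.0)
        b = ModelSolution(chain_network, np.array([-0.8, 0.0]), accuracy=1.0)
        ens = Ensemble([a, b], accuracy_gate=0.9)
        mean, sd = ensemble_activity(ens, chain_network, Stimulus({"A": 1.0}))
        assert mean.activity["B"] == pytest.approx(0.0, abs=1e-12)
        assert sd["B"] > 0

    def test_gate_invariant_enforced(self, chain_network):
        bad = ModelSolution(chain_network, np.zeros(2), accuracy=0.5)
        with pytest.raises(NetworkError):
            Ensemble([bad], accuracy_gate=0.9)


class TestMotiveReachability:
    def test_downstream_motive_fully_reachable(self):
        net = build_network([("T", "X"), ("X", "E1"), ("X", "E2")])
        chars = DiseaseCharacterization(assignments=[
            EffectorAssignment("E1", 1, 1), EffectorAssignment("E2", 1, -1)])
        frac = motive_reachability(net, Stimulus({"T": -1.0}), chars, 1)
        assert frac == 1.0

    def test_disconnected_motive_unreached(self):
        net = build_network([("T", "X"), ("E1", "E2")])
        chars = DiseaseCharacterization(assignments=[
            EffectorAssignment("E1", 2, 1), EffectorAssignment("E2", 2, 1)])
        assert motive_reachability(net, Stimulus({"T": -1.0}), chars, 2) == 0.0

    def test_unknown_motive_raises(self, chain_network, toy_characterization):
        from netmoa.characterization import CharacterizationError
        with pytest.raises(CharacterizationError):
            motive_reachability(chain_network, Stimulus({"A": 1.0}),
                                toy_characterization, 9)
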