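import numpy as np
import pytest

from netmoa.characterization import (DiseaseCharacterization,
                                     EffectorAssignment)
from netmoa.network import (InteractionNetwork, ModelSolution,
                            PropagationConfig, Stimulus, build_network)


@pytest.fixture
def chain_network():
    """A -> B -> C chain."""
    return build_network([("A", "B"), ("B", "C")])


@pytest.fixture
def toy_characterization():
    return DiseaseCharacterization(assignments=[
        EffectorAssignment("B", 1, +1),
        EffectorAssignment("C", 1, -1),
        EffectorAssignment("C", 2, +1),
    ])


def random_small_network(rng: np.random.Generator, n_nodes: int,
                         edge_prob: float = 0.4,
                         acyclic: bool = False) -> InteractionNetwork:
    """Random directed graph on <= n_nodes labelled nodes."""
    names = [f"N{i}" for i in range(n_nodes)]
    rows = []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i == j:
                continue
            if acyclic and i > j:
                continue
            if rng.random() < edge_prob:
                rows.append((names[i], names[j]))
    if not rows:
        rows = [(names[0], names[-1])]
    return build_network(rows)


def random_solution(network: InteractionNetwork,
                    rng: np.random.Generator) -> ModelSolution:
    return ModelSolution(network=network,
                         weight_vector=rng.uniform(-1, 1, network.n_edges))
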