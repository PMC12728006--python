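"""Directed protein network and the signal-propagation core.

The model is a signed, weighted, directed protein-interaction graph. A drug is
represented as a *stimulus*: clamp values in [-1, 1] applied at its target
(and pseudotarget) proteins. Signal propagates by iterating

    a_v  <-  sigma( sum_{u -> v} w_{u->v} * a_u )

for every non-clamped node v, where sigma is a sigmoid onto [-1, 1]
(hyperbolic tangent with configurable gain). Clamped nodes keep their
stimulus value throughout. On acyclic graphs this reduces to feed-forward
evaluation; on cyclic graphs a damped synchronous fixed-point iteration is
used and convergence is reported explicitly (``converged`` / ``iterations``).

The learned parameters are the per-edge weights w (one real in
[-w_max, +w_max] per edge); a :class:`ModelSolution` is one such weight
assignment, and an :class:`Ensemble` is the set of solutions that passed the
training accuracy gate, interpreted as plausible molecular variants of the
same system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .characterization import (DiseaseCharacterization, DrugProfile,
                               normalize_symbol)


class NetworkError(ValueError):
    """Structural problem in a network, stimulus or solution."""


@dataclass
class PropagationConfig:
    """Numerical settings for fixed-point propagation.

    tol: max-abs-change convergence tolerance (must be > 0).
    max_iter: iteration cap; hitting it sets ``converged=False``.
    damping: fraction of the new iterate mixed in each step, in (0, 1].
        Damping changes the path to the fixed point, not the fixed point.
    gain: sigmoid slope at the origin (tanh(gain * x)).
    clamp_inputs: if True (default) stimulus nodes are held at their clamp
        value every iteration; if False the stimulus is applied only as the
        initial state (one-shot pulse) and may decay.
    """
    tol: float = 1e-6
    max_iter: int = 200
    damping: float = 0.5
    gain: float = 1.0
    clamp_inputs: bool = True

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise NetworkError(f"tol must be positive, got {self.tol}")
        if not (0 < self.damping <= 1):
            raise NetworkError(f"damping must be in (0,1], got {self.damping}")
        if self.max_iter < 1:
            raise NetworkError("max_iter must be >= 1")


class InteractionNetwork:
    """Directed protein graph with optional per-edge priors.

    ``sign_prior`` records curated interaction types (+1 activation / -1
    inhibition); ``strength_prior`` records evidence-derived interaction
    strengths in (0, 1]. Both are soft guidance for training, not hard
    constraints. Wraps a :class:`networkx.DiGraph` and maintains stable
    node/edge orderings so weight vectors and sparse matrices line up
    across the training and analysis code.
    """

    def __init__(self, graph: nx.DiGraph,
                 sign_prior: Mapping[tuple[str, str], int] | None = None,
                 strength_prior: Mapping[tuple[str, str], float] | None = None,
                 allow_self_loops: bool = False):
        for u, v in graph.edges():
            if u == v and not allow_self_loops:
                raise NetworkError(f"self-loop {u}->{u} not allowed")
        self.graph = graph
        self.nodes: list[str] = sorted(graph.nodes())
        self.node_index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        self.edges: list[tuple[str, str]] = sorted(graph.edges())
        self.edge_index: dict[tuple[str, str], int] = {
            e: i for i, e in enumerate(self.edges)}
        self.sign_prior: dict[tuple[str, str], int] = {}
        for e, s in (sign_prior or {}).items():
            if e not in self.edge_index:
                raise NetworkError(f"sign prior on unknown edge {e}")
            if s not in (-1, 1):
                raise NetworkError(f"sign prior must be +1/-1 on {e}")
            self.sign_prior[e] = s
        self.strength_prior: dict[tuple[str, str], float] = {}
        for e, s in (strength_prior or {}).items():
            if e not in self.edge_index:
                raise NetworkError(f"strength prior on unknown edge {e}")
            if not 0 < s <= 1:
                raise NetworkError(f"strength prior on {e} must be in (0,1]")
            self.strength_prior[e] = float(s)
        # Row/col index arrays for building the propagation matrix: entry k
        # corresponds to self.edges[k] = (u, v), contributing w_k at (v, u).
        n = len(self.nodes)
        self._rows = np.array([self.node_index[v] for _, v in self.edges])
        self._cols = np.array([self.node_index[u] for u, _ in self.edges])
        self._shape = (n, n)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, protein: str) -> bool:
        return protein in self.node_index

    def adjacency_matrix(self, weights: np.ndarray) -> sp.csr_matrix:
        """(n, n) sparse matrix M with M[v, u] = w(u->v); M @ a = node inputs."""
        if len(weights) != self.n_edges:
            raise NetworkError("weight vector length != edge count")
        return sp.csr_matrix((weights, (self._rows, self._cols)),
                             shape=self._shape)

    def sign_prior_vector(self) -> np.ndarray:
        """Per-edge prior in {-1, 0, +1}; 0 = no prior."""
        vec = np.zeros(self.n_edges)
        for e, s in self.sign_prior.items():
            vec[self.edge_index[e]] = s
        return vec

    def strength_prior_vector(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, has_prior mask) per edge, aligned with ``edges``."""
        vals = np.zeros(self.n_edges)
        mask = np.zeros(self.n_edges, dtype=bool)
        for e, s in self.strength_prior.items():
            vals[self.edge_index[e]] = s
            mask[self.edge_index[e]] = True
        return vals, mask


def build_network(edge_rows: Iterable[tuple[str, str] | tuple[str, str, int | None]],
                  allow_self_loops: bool = False) -> InteractionNetwork:
    """Build a network from (source, target[, sign_prior]) rows."""
    graph = nx.DiGraph()
    priors: dict[tuple[str, str], int] = {}
    for row in edge_rows:
        u, v = normalize_symbol(row[0]), normalize_symbol(row[1])
        if not u or not v:
            raise NetworkError(f"dangling endpoint in edge row {row!r}")
        if u == v and not allow_self_loops:
            raise NetworkError(f"self-loop {u}->{u} not allowed")
        graph.add_edge(u, v)
        if len(row) > 2 and row[2] not in (None, 0):
            priors[(u, v)] = int(row[2])
    return InteractionNetwork(graph, sign_prior=priors,
                              allow_self_loops=allow_self_loops)


def read_edge_list(path: str | Path,
                   allow_self_loops: bool = False) -> InteractionNetwork:
    """Read an edge-list TSV.

    Columns: ``source  target  sign_prior(+1/-1/blank)
    strength_prior(float/blank)``; the prior columns are optional. Lines
    starting with ``#`` are comments; a header line is optional.
    """
    rows: list[tuple[str, str, int | None]] = []
    strengths: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "source":
                continue
            prior = None
            if len(parts) > 2 and parts[2].strip():
                prior = int(parts[2])
            if len(parts) > 3 and parts[3].strip():
                strengths[(normalize_symbol(parts[0]),
                           normalize_symbol(parts[1]))] = float(parts[3])
            rows.append((parts[0], parts[1], prior))
    net = build_network(rows, allow_self_loops=allow_self_loops)
    for e, s in strengths.items():
        if not 0 < s <= 1:
            raise NetworkError(f"strength prior on {e} must be in (0,1]")
        net.strength_prior[e] = s
    return net


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tsign_prior\tstrength_prior\n")
        for u, v in network.edges:
            prior = network.sign_prior.get((u, v), "")
            strength = network.strength_prior.get((u, v), "")
            if strength != "":
                strength = f"{strength:.6g}"
            fh.write(f"{u}\t{v}\t{prior}\t{strength}\n")


@dataclass
class ModelSolution:
    """One learned weight assignment over the network's edges.

    ``weight_vector`` is aligned with ``network.edges``; the ``weights``
    mapping view is derived on demand. ``accuracy`` is set after evaluation
    against a training set.
    """
    network: InteractionNetwork
    weight_vector: np.ndarray
    accuracy: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.weight_vector = np.asarray(self.weight_vector, dtype=float)
        if len(self.weight_vector) != self.network.n_edges:
            raise NetworkError("solution does not cover all edges")
        if not np.all(np.isfinite(self.weight_vector)):
            raise NetworkError("non-finite weight in solution")

    @property
    def weights(self) -> dict[tuple[str, str], float]:
        return {e: float(w) for e, w in zip(self.network.edges,
                                            self.weight_vector)}


@dataclass
class Ensemble:
    """Valid solutions (accuracy above the gate), sorted best-first."""
    solutions: list[ModelSolution]
    accuracy_gate: float = 0.90

    def __post_init__(self) -> None:
        if not self.solutions:
            raise NetworkError("ensemble must be non-empty")
        for s in self.solutions:
            if s.accuracy is None or s.accuracy <= self.accuracy_gate:
                raise NetworkError(
                    f"ensemble member accuracy {s.accuracy} does not exceed "
                    f"gate {self.accuracy_gate}")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([s.accuracy for s in self.solutions]))


@dataclass
class Stimulus:
    """Clamp values in [-1, 1] applied at stimulated proteins."""
    inputs: dict[str, float]

    def __post_init__(self) -> None:
        if not self.inputs or all(v == 0 for v in self.inputs.values()):
            raise NetworkError("stimulus must have at least one nonzero input")
        for p, v in self.inputs.items():
            if not -1 <= v <= 1:
                raise NetworkError(f"clamp value {v} for {p} outside [-1,1]")


def stimulus_from_drug(profile: DrugProfile, network: InteractionNetwork,
                       magnitude: float = 1.0) -> Stimulus:
    """Stimulus clamping each target and pseudotarget at sign * magnitude."""
    if not 0 < magnitude <= 1:
        raise NetworkError(f"magnitude must be in (0,1], got {magnitude}")
    missing = [p for p in profile.all_targets if p not in network]
    if missing:
        raise NetworkError(
            f"drug {profile.name} targets absent from network: {sorted(missing)}")
    return Stimulus({p: s * magnitude for p, s in profile.all_targets.items()})


def combine_stimuli(a: Stimulus, b: Stimulus) -> Stimulus:
    """Per-protein sum of clamp values, clipped to [-1, +1]."""
    combined = dict(a.inputs)
    for p, v in b.inputs.items():
        combined[p] = float(np.clip(combined.get(p, 0.0) + v, -1.0, 1.0))
    return Stimulus(combined)


@dataclass
class ActivityProfile:
    """Predicted protein activity in [-1, 1] for every node."""
    activity: dict[str, float]
    converged: bool
    iterations: int
    clamped: frozenset[str] = field(default_factory=frozenset)

    def __getitem__(self, protein: str) -> float:
        return self.activity[protein]

    def vector(self, network: InteractionNetwork) -> np.ndarray:
        return np.array([self.activity[n] for n in network.nodes])


def _propagate_batch(matrix: sp.csr_matrix, clamp_idx: np.ndarray,
                     clamp_vals: np.ndarray, config: PropagationConfig,
                     n_nodes: int, init: np.ndarray | None = None
                     ) -> tuple[np.ndarray, bool, int]:
    """Damped fixed-point iteration for a batch of stimuli.

    ``clamp_vals`` has shape (len(clamp_idx), m) for m stimuli sharing the
    same clamped node set; returns (activities (n, m), converged, iterations).
    """
    m = clamp_vals.shape[1]
    a = np.zeros((n_nodes, m)) if init is None else init.copy()
    a[clamp_idx, :] = clamp_vals
    d = config.damping
    for it in range(1, config.max_iter + 1):
        new = np.tanh(config.gain * (matrix @ a))
        if config.clamp_inputs:
            new[clamp_idx, :] = clamp_vals
        stepped = (1 - d) * a + d * new
        delta = float(np.max(np.abs(stepped - a))) if stepped.size else 0.0
        a = stepped
        if delta < config.tol:
            return a, True, it
    return a, False, config.max_iter


def propagate(network: InteractionNetwork, solution: ModelSolution,
              stimulus: Stimulus,
              config: PropagationConfig | None = None) -> ActivityProfile:
    """Propagate a stimulus through one weight solution.

    Deterministic given (network, solution, stimulus, config). Clamped nodes
    retain their stimulus value exactly; all activities lie in [-1, 1].
    """
    config = config or PropagationConfig()
    for p in stimulus.inputs:
        if p not in network:
            raise NetworkError(f"stimulated protein {p} not in network")
    matrix = network.adjacency_matrix(solution.weight_vector)
    clamp_idx = np.array([network.node_index[p] for p in stimulus.inputs],
                         dtype=int)
    clamp_vals = np.array([[v] for v in stimulus.inputs.values()])
    a, converged, iters = _propagate_batch(matrix, clamp_idx, clamp_vals,
                                           config, network.n_nodes)
    activity = {n: float(a[i, 0]) for n, i in network.node_index.items()}
    return ActivityProfile(activity=activity, converged=converged,
                           iterations=iters,
                           clamped=frozenset(stimulus.inputs))


def ensemble_activity(ensemble: Ensemble, network: InteractionNetwork,
                      stimulus: Stimulus,
                      config: PropagationConfig | None = None
                      ) -> tuple[ActivityProfile, dict[str, float]]:
    """Mean activity profile across ensemble members, plus per-protein SD.

    The per-protein standard deviation is the model's proxy for interpatient
    molecular variability: distinct valid solutions may route the same
    stimulus differently.
    """
    profiles = [propagate(network, s, stimulus, config)
                for s in ensemble.solutions]
    stacked = np.stack([p.vector(network) for p in profiles])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    activity = {n: float(mean[i]) for n, i in network.node_index.items()}
    dispersion = {n: float(sd[i]) for n, i in network.node_index.items()}
    mean_profile = ActivityProfile(
        activity=activity,
        converged=all(p.converged for p in profiles),
        iterations=max(p.iterations for p in profiles),
        clamped=frozenset(stimulus.inputs))
    return mean_profile, dispersion


def motive_reachability(network: InteractionNetwork, stimulus: Stimulus,
                        chars: DiseaseCharacterization, motive: int) -> float:
    """Fraction of a motive's effectors reachable from any stimulated node.

    A purely structural (unweighted) check used to justify excluding a motive
    from modelling when no signal can reach it.
    """
    effectors = {a.protein for a in chars.motive_assignments(motive)}
    if not effectors:
        return 0.0
    reachable: set[str] = set()
    for p in stimulus.inputs:
        if p in network:
            reachable |= {p} | nx.descendants(network.graph, p)
    return len(effectors & reachable) / len(effectors)


def write_activity_profile(profile: ActivityProfile, path: str | Path,
                           metadata: dict | None = None) -> None:
    """Write ``protein  activity  clamped`` TSV plus a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\tactivity\tclamped\n")
        for p in sorted(profile.activity):
            fh.write(f"{p}\t{profile.activity[p]:.10g}\t"
                     f"{str(p in profile.clamped).lower()}\n")
    meta = {"converged": profile.converged, "iterations": profile.iterations}
    meta.update(metadata or {})
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True))
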