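"""Synthetic benchmark systems with planted ground truth.

The real inputs this pipeline was designed around — a proprietary curated
human protein-interaction network and a curated drug/condition training
corpus — are not publicly deposited, so every stage of the pipeline is
exercised on generated systems instead: a sparse directed network
(scale-free, small-world or DAG topology), overlapping effector motives,
drug target profiles, a planted ground-truth weight solution, and training
rules produced by propagating stimuli through that ground truth. Rules
record only expectations whose ground-truth activity magnitude reaches the
0.1 threshold, so at zero noise the planted solution scores accuracy 1.0 by
construction.

``generate_planted_synergy`` additionally plants disjoint single-drug
mechanisms plus a shared convergent block, and records the intended
exclusive/convergent effector sets so the combination decomposition can be
checked against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .characterization import (DiseaseCharacterization, DrugProfile,
                               EffectorAssignment, save_characterization,
                               save_drug_profile)
from .network import (InteractionNetwork, ModelSolution, PropagationConfig,
                      Stimulus, propagate, write_edge_list)
from .training import TrainingRule, TrainingSet, save_training_set


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of a generated benchmark system.

    Defaults are literature-scale: a ~1000-node sparse network, four motives of
    sizes 50/24/45/59 overlapping to 148 unique effectors (overlap_fraction
    30/178), two drugs. ``desk_scale()`` returns the small configuration
    used for routine test runs.
    """
    n_nodes: int = 1000
    topology: str = "scale_free"
    mean_degree: float = 3.0
    motive_sizes: tuple[int, ...] = (50, 24, 45, 59)
    overlap_fraction: float = 30 / 178
    n_drugs: int = 2
    targets_per_drug: int = 3
    n_rules: int = 25
    max_expectations_per_rule: int = 5
    rule_noise: float = 0.0
    detach_motive: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("scale_free", "small_world", "dag"):
            raise SyntheticError(f"unknown topology {self.topology!r}")
        if not 0 <= self.overlap_fraction < 1:
            raise SyntheticError("overlap_fraction must be in [0,1)")
        if max(self.motive_sizes) > self.n_nodes:
            raise SyntheticError("motive size exceeds node count")
        if self.unique_effectors > self.n_nodes:
            raise SyntheticError("unique effector total exceeds node count")
        if self.detach_motive is not None and not (
                1 <= self.detach_motive <= len(self.motive_sizes)):
            raise SyntheticError(f"detach_motive {self.detach_motive} unknown")

    @property
    def unique_effectors(self) -> int:
        """Unique effector total implied by sizes and overlap."""
        total = sum(self.motive_sizes)
        return max(max(self.motive_sizes),
                   int(round(total * (1 - self.overlap_fraction))))

    @classmethod
    def desk_scale(cls, **overrides) -> "SyntheticSpec":
        """Small benchmark for routine runs: 120 nodes, 25 rules.

        Acyclic topology by default so propagation is a feed-forward
        evaluation with a unique fixed point — the well-posed regime for
        judging training recovery; cyclic topologies are exercised by the
        propagation tests.
        """
        base = dict(n_nodes=120, topology="dag", mean_degree=3.0,
                    motive_sizes=(12, 6, 10, 14), overlap_fraction=0.15,
                    n_drugs=2, targets_per_drug=3, n_rules=25)
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticSystem:
    """Everything one run of the generator produced."""
    spec: SyntheticSpec
    network: InteractionNetwork
    characterization: DiseaseCharacterization
    drugs: list[DrugProfile]
    ground_truth: ModelSolution
    training_set: TrainingSet
    planted: dict[str, set[str]] = field(default_factory=dict)


def _node_name(i: int) -> str:
    return f"G{i:04d}"


def _topology_edges(spec: SyntheticSpec,
                    rng: np.random.Generator) -> set[tuple[int, int]]:
    n, k = spec.n_nodes, spec.mean_degree
    edges: set[tuple[int, int]] = set()
    if spec.topology == "dag":
        p = min(1.0, 2 * k / max(1, n - 1))
        for j in range(1, n):
            for i in range(j):
                if rng.random() < p:
                    edges.add((i, j))
    elif spec.topology == "small_world":
        kk = max(2, int(round(k)) * 2)
        ring = nx.watts_strogatz_graph(n, kk, 0.1,
                                       seed=int(rng.integers(2**31)))
        for u, v in ring.edges():
            if rng.random() < 0.5:
                u, v = v, u
            if u != v:
                edges.add((u, v))
    else:  # scale_free: preferential attachment with random edge orientation
        m = max(1, int(round(k)))
        degree = np.ones(n)
        for j in range(1, n):
            pool = np.arange(j)
            prob = degree[:j] / degree[:j].sum()
            chosen = rng.choice(pool, size=min(m, j), replace=False, p=prob)
            for c in chosen:
                u, v = (int(c), j) if rng.random() < 0.7 else (j, int(c))
                edges.add((u, v))
                degree[c] += 1
                degree[j] += 1
    return {(u, v) for u, v in edges if u != v}


def _allocate_motives(sizes: list[int], pool: list[str], detached: int | None,
                      rng: np.random.Generator) -> dict[int, list[str]]:
    """Assign pool members to motives so the union covers the pool exactly.

    Phase 1 gives every pool member one motive (probability proportional to
    remaining capacity); phase 2 fills each motive's remaining capacity with
    duplicates, creating the overlap. A detached motive gets dedicated
    members and never overlaps the others (its members must stay
    structurally separable from the rest).
    """
    n_motives = len(sizes)
    members: dict[int, list[str]] = {m: [] for m in range(1, n_motives + 1)}
    pool = list(pool)
    if detached is not None:
        det_size = sizes[detached - 1]
        det_members, pool = pool[:det_size], pool[det_size:]
        members[detached] = det_members
    open_motives = [m for m in range(1, n_motives + 1) if m != detached]
    capacity = {m: sizes[m - 1] for m in open_motives}
    if not open_motives:
        return members
    if max(capacity.values()) > len(pool) or sum(capacity.values()) < len(pool):
        raise SyntheticError(
            f"infeasible overlap: {len(pool)} unique effectors vs motive "
            f"sizes {sizes} (need max<=unique<=sum over open motives)")
    remaining = dict(capacity)
    for member in pool:
        probs = np.array([remaining[m] for m in open_motives], dtype=float)
        m = open_motives[int(rng.choice(len(open_motives),
                                        p=probs / probs.sum()))]
        members[m].append(member)
        remaining[m] -= 1
    for m in open_motives:
        others = [x for x in pool if x not in set(members[m])]
        extra = rng.choice(len(others), size=remaining[m], replace=False)
        members[m].extend(others[i] for i in sorted(extra))
    return members


def _attach_priors(network: InteractionNetwork, weights: np.ndarray,
                   rng: np.random.Generator) -> None:
    """Derive per-edge priors from the planted weights, as curated evidence
    would: the interaction type (sign) exactly, the interaction strength as
    the true magnitude blurred by observation noise."""
    network.sign_prior = {e: (1 if w >= 0 else -1)
                          for e, w in zip(network.edges, weights)}
    strengths = np.clip(np.abs(weights) + rng.normal(0.0, 0.1, len(weights)),
                        0.05, 1.0)
    network.strength_prior = {e: float(s)
                              for e, s in zip(network.edges, strengths)}


def _rules_from_ground_truth(network: InteractionNetwork,
                             ground_truth: ModelSolution,
                             effectors: set[str],
                             drug_stimuli: list[Stimulus],
                             n_rules: int, rule_noise: float,
                             rng: np.random.Generator,
                             prop: PropagationConfig,
                             max_expectations: int = 5) -> TrainingSet:
    """Propagate stimuli through the ground truth and record effector signs.

    Only expectations with ground-truth |activity| >= 0.1 are emitted, so at
    zero noise the planted solution satisfies every rule exactly. At most
    ``max_expectations`` effectors are recorded per rule (sampled without
    replacement) so the training set stays smaller than the number of free
    weights — the under-determination that makes an ensemble of distinct
    valid solutions possible in the first place.
    """
    sources = [n for n in network.nodes
               if network.graph.out_degree(n) > 0]
    rules: list[TrainingRule] = []
    candidates = list(drug_stimuli)
    attempts = 0
    while len(rules) < n_rules and attempts < 50 * n_rules:
        attempts += 1
        if candidates:
            stim = candidates.pop(0)
        else:
            k = int(rng.integers(1, 4))
            picked = rng.choice(len(sources), size=min(k, len(sources)),
                                replace=False)
            inputs = {sources[i]: float(rng.choice([-1.0, 1.0]))
                      for i in sorted(picked)}
            stim = Stimulus(inputs)
        profile = propagate(network, ground_truth, stim, prop)
        eligible = [p for p in sorted(effectors)
                    if abs(profile.activity.get(p, 0.0)) >= 0.1
                    and p not in stim.inputs]
        if len(eligible) > max_expectations:
            picked = rng.choice(len(eligible), size=max_expectations,
                                replace=False)
            eligible = [eligible[i] for i in sorted(picked)]
        expected = {}
        for p in eligible:
            sign = int(np.sign(profile.activity[p]))
            if rule_noise > 0 and rng.random() < rule_noise:
                sign = -sign
            expected[p] = sign
        if expected:
            rules.append(TrainingRule(stimulus=stim, expected=expected))
    if len(rules) < n_rules:
        raise SyntheticError(
            f"could only generate {len(rules)}/{n_rules} non-empty rules; "
            "network too disconnected for the requested rule count")
    return TrainingSet(rules=rules)


def generate_system(spec: SyntheticSpec) -> SyntheticSystem:
    """Generate a full benchmark system; bit-for-bit reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    edge_ids = sorted(_topology_edges(spec, rng))
    graph = nx.DiGraph()
    graph.add_nodes_from(_node_name(i) for i in range(spec.n_nodes))
    graph.add_edges_from((_node_name(u), _node_name(v)) for u, v in edge_ids)

    # Drug targets: prefer well-connected sources so stimuli actually move.
    out_deg = dict(graph.out_degree())
    ranked = sorted(graph.nodes, key=lambda n: (-out_deg[n], n))
    n_targets = spec.n_drugs * spec.targets_per_drug
    top = ranked[:max(n_targets * 4, n_targets)]
    picked = rng.choice(len(top), size=n_targets, replace=False)
    target_names = [top[i] for i in sorted(picked)]
    drugs = [DrugProfile(
        name=f"drug{chr(ord('A') + d)}",
        targets={target_names[d * spec.targets_per_drug + t]: -1
                 for t in range(spec.targets_per_drug)})
        for d in range(spec.n_drugs)]

    reachable: set[str] = set()
    for t in target_names:
        reachable |= {t} | nx.descendants(graph, t)

    # Effector pool: detached-motive members come from outside the reachable
    # set when possible; the rest from reachable non-target nodes.
    u = spec.unique_effectors
    det_size = (spec.motive_sizes[spec.detach_motive - 1]
                if spec.detach_motive else 0)
    unreachable = sorted(set(graph.nodes) - reachable - set(target_names))
    reach_pool = sorted(reachable - set(target_names))
    if det_size > len(unreachable) + len(reach_pool):
        raise SyntheticError("not enough nodes for the detached motive")
    det_nodes = [unreachable[i] for i in sorted(
        rng.choice(len(unreachable), size=min(det_size, len(unreachable)),
                   replace=False))]
    while len(det_nodes) < det_size:  # fall back: will be severed below
        extra = [n for n in reach_pool if n not in det_nodes]
        det_nodes.append(extra[int(rng.integers(len(extra)))])
    open_needed = u - det_size
    pool_source = [n for n in reach_pool if n not in set(det_nodes)]
    if open_needed > len(pool_source):
        filler = [n for n in unreachable if n not in set(det_nodes)]
        pool_source = pool_source + filler
    if open_needed > len(pool_source):
        raise SyntheticError("not enough reachable nodes for effector pool")
    idx = rng.choice(len(pool_source), size=open_needed, replace=False)
    open_nodes = [pool_source[i] for i in sorted(idx)]
    pool = det_nodes + open_nodes

    members = _allocate_motives(list(spec.motive_sizes), pool,
                                spec.detach_motive, rng)
    assignments = []
    for m in sorted(members):
        for p in members[m]:
            assignments.append(EffectorAssignment(
                protein=p, motive=m,
                disease_sign=int(rng.choice([-1, 1]))))
    chars = DiseaseCharacterization(assignments=assignments)

    # Sever every path from the stimulated region into the detached motive.
    if spec.detach_motive is not None:
        det_set = set(members[spec.detach_motive])
        for e in sorted(det_set):
            for pred in sorted(graph.predecessors(e)):
                if pred in reachable:
                    graph.remove_edge(pred, e)

    network = InteractionNetwork(graph)
    weights = rng.uniform(-1.0, 1.0, size=network.n_edges)
    _attach_priors(network, weights, rng)
    ground_truth = ModelSolution(network=network, weight_vector=weights,
                                 seed=spec.seed)

    prop = PropagationConfig()
    drug_stimuli = [Stimulus({p: float(s) for p, s in d.all_targets.items()})
                    for d in drugs]
    training_set = _rules_from_ground_truth(
        network, ground_truth, chars.proteins, drug_stimuli,
        spec.n_rules, spec.rule_noise, rng, prop,
        spec.max_expectations_per_rule)
    ground_truth.accuracy = None  # set by evaluate_accuracy downstream
    return SyntheticSystem(spec=spec, network=network, characterization=chars,
                           drugs=drugs, ground_truth=ground_truth,
                           training_set=training_set)


def generate_planted_synergy(spec: SyntheticSpec, n_exclusive_a: int = 5,
                             n_exclusive_b: int = 4,
                             n_convergent: int = 3) -> SyntheticSystem:
    """Two-drug system with planted exclusive and convergent effector blocks.

    Drug A's targets feed its exclusive block and the convergent block;
    drug B's feed its own exclusive block and the convergent block; planted
    effectors receive no other incoming edges and emit none, so the
    decomposition computed on the ground-truth model recovers the planted
    sets exactly. Remaining motive capacity is filled with background nodes
    unreachable from the drug targets.
    """
    if spec.n_drugs != 2:
        raise SyntheticError("planted synergy requires exactly 2 drugs")
    n_planted = n_exclusive_a + n_exclusive_b + n_convergent
    if n_planted > spec.unique_effectors:
        raise SyntheticError("planted blocks exceed the unique effector total")
    if n_planted > sum(spec.motive_sizes):
        raise SyntheticError("planted blocks exceed total motive capacity")
    rng = np.random.default_rng(spec.seed)

    edge_ids = sorted(_topology_edges(spec, rng))
    graph = nx.DiGraph()
    graph.add_nodes_from(_node_name(i) for i in range(spec.n_nodes))
    graph.add_edges_from((_node_name(u), _node_name(v)) for u, v in edge_ids)

    ta = [f"TRGA{t}" for t in range(spec.targets_per_drug)]
    tb = [f"TRGB{t}" for t in range(spec.targets_per_drug)]
    block_a = [f"EXA{i:02d}" for i in range(n_exclusive_a)]
    block_b = [f"EXB{i:02d}" for i in range(n_exclusive_b)]
    block_c = [f"CNV{i:02d}" for i in range(n_convergent)]
    graph.add_nodes_from(ta + tb + block_a + block_b + block_c)

    planted_edges: dict[tuple[str, str], float] = {}

    def wire(targets: list[str], effector: str) -> float:
        """Edge from one target; returns the effector's single-drug activity."""
        t = targets[int(rng.integers(len(targets)))]
        w = float(rng.choice([-1, 1])) * rng.uniform(0.6, 1.0)
        graph.add_edge(t, effector)
        planted_edges[(t, effector)] = w
        return float(np.tanh(-w))  # target clamped at -1 (inhibitor)

    activity_a = {e: wire(ta, e) for e in block_a}
    activity_b = {e: wire(tb, e) for e in block_b}
    activity_c: dict[str, float] = {}
    for e in block_c:
        tA = ta[int(rng.integers(len(ta)))]
        tB = tb[int(rng.integers(len(tb)))]
        sign = float(rng.choice([-1, 1]))
        wA = sign * rng.uniform(0.6, 1.0)
        wB = sign * rng.uniform(0.6, 1.0)
        graph.add_edge(tA, e)
        graph.add_edge(tB, e)
        planted_edges[(tA, e)] = wA
        planted_edges[(tB, e)] = wB
        activity_c[e] = float(np.tanh(-wA - wB))

    # A target the random wiring skipped would be an isolated node and
    # vanish in the edge-list round trip; give it an inert sink edge.
    for t in ta + tb:
        if graph.out_degree(t) == 0:
            sink = f"SNK_{t}"
            graph.add_edge(t, sink)
            planted_edges[(t, sink)] = 0.05

    drugs = [DrugProfile(name="drugA", targets={t: -1 for t in ta}),
             DrugProfile(name="drugB", targets={t: -1 for t in tb})]

    planted_set = set(block_a + block_b + block_c)
    # Planted effectors are leaves fed only by their wired targets.
    for e in sorted(planted_set):
        for pred in sorted(graph.predecessors(e)):
            if (pred, e) not in planted_edges:
                graph.remove_edge(pred, e)
        for succ in sorted(graph.successors(e)):
            graph.remove_edge(e, succ)

    # Motive membership: planted effectors round-robin across motives, then
    # background filler unreachable from the targets.
    n_motives = len(spec.motive_sizes)
    capacity = list(spec.motive_sizes)
    single_activity = {**activity_a, **activity_b, **activity_c}
    assignments = []
    order = sorted(capacity_i for capacity_i in range(n_motives))
    mi = 0
    membership: dict[str, list[int]] = {}
    for e in block_a + block_b + block_c:
        for _ in range(n_motives):
            m = order[mi % n_motives] + 1
            mi += 1
            if capacity[m - 1] > 0:
                capacity[m - 1] -= 1
                membership[e] = [m]
                break
    for e, motives in membership.items():
        sign = -int(np.sign(single_activity[e]))
        for m in motives:
            assignments.append(EffectorAssignment(e, m, sign))

    filler_pool = sorted(set(graph.nodes) - planted_set - set(ta + tb))
    filler_needed = min(sum(capacity),
                        spec.unique_effectors - len(planted_set))
    idx = rng.choice(len(filler_pool), size=filler_needed, replace=False)
    fillers = [filler_pool[i] for i in sorted(idx)]
    fi = 0
    for m in range(1, n_motives + 1):
        take = min(capacity[m - 1], len(fillers) - fi)
        for _ in range(take):
            assignments.append(EffectorAssignment(
                fillers[fi], m, int(rng.choice([-1, 1]))))
            fi += 1
    chars = DiseaseCharacterization(assignments=assignments)

    network = InteractionNetwork(graph)
    weights = rng.uniform(-1.0, 1.0, size=network.n_edges)
    for e, w in planted_edges.items():
        weights[network.edge_index[e]] = w
    _attach_priors(network, weights, rng)
    ground_truth = ModelSolution(network=network, weight_vector=weights,
                                 seed=spec.seed)

    prop = PropagationConfig()
    drug_stimuli = [Stimulus({p: float(s) for p, s in d.all_targets.items()})
                    for d in drugs]
    training_set = _rules_from_ground_truth(
        network, ground_truth, chars.proteins, drug_stimuli,
        spec.n_rules, spec.rule_noise, rng, prop,
        spec.max_expectations_per_rule)
    return SyntheticSystem(
        spec=spec, network=network, characterization=chars, drugs=drugs,
        ground_truth=ground_truth, training_set=training_set,
        planted={"exclusive_a": set(block_a), "exclusive_b": set(block_b),
                 "convergent": set(block_c)})


def write_system(system: SyntheticSystem, directory: str | Path) -> None:
    """Write the full tuple in the package's TSV/JSON dialects + manifest."""
    import json
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_edge_list(system.network, directory / "network.tsv")
    save_characterization(system.characterization,
                          directory / "characterization.tsv")
    for drug in system.drugs:
        save_drug_profile(drug, directory / f"profile_{drug.name}.tsv")
    with open(directory / "ground_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for (u, v), w in zip(system.network.edges,
                             system.ground_truth.weight_vector):
            fh.write(f"{u}\t{v}\t{w:.12g}\n")
    save_training_set(system.training_set, directory / "training_set.json")
    manifest = {"spec": {**vars(system.spec),
                         "motive_sizes": list(system.spec.motive_sizes)},
                "planted": {k: sorted(v) for k, v in system.planted.items()}}
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
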