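"""Mechanism-of-action analytics over propagated activity profiles.

Given predicted protein activities under a treatment, this module computes:

* **fSignal** — the average signal arriving at the disease effectors, either
  raw (literal mean activity) or disease-oriented (mean of
  ``-disease_sign * activity``, so that positive values mean net reversion of
  the disease state).
* **Reverted effectors** — effectors driven to the sign opposite their
  disease sign with magnitude >= the reversion threshold (0.1, inclusive).
* **Combination decomposition** — for a two-drug combination, the partition
  of reverted effectors into convergent (reverted by each drug alone and at
  least as strongly by the combination), exclusive to either drug, emergent
  (reverted only by the combination), and attenuated (reverted by both drugs
  alone but more weakly in combination).
* **Bioflag corroboration** — whether literature-reported downstream protein
  changes are reproduced by the model.
* **Sobol sensitivity** — variance-based attribution of the fSignal output
  to perturbations of the individual stimulus clamp values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .characterization import (Bioflag, ComplementaryTableRow,
                               DiseaseCharacterization)
from .network import (ActivityProfile, Ensemble, InteractionNetwork,
                      PropagationConfig, Stimulus, _propagate_batch,
                      ensemble_activity)
from .sobol import sobol_indices_from_evals, saltelli_sample


class AnalysisError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Settings for the analytic layer.

    reversion_threshold: minimum |activity| for an effector to count as
        reverted (inclusive boundary).
    fsignal_orientation: ``disease_oriented`` (default; positive = net
        reversion) or ``raw`` (literal mean activity at the effectors).
    sobol_samples: Saltelli base sample size N (N * (d + 2) evaluations).
    sobol_delta: half-width of the uniform perturbation box around each
        nominal clamp value, truncated to [-1, 1].
    """
    reversion_threshold: float = 0.1
    fsignal_orientation: str = "disease_oriented"
    sobol_samples: int = 1024
    sobol_delta: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reversion_threshold < 0:
            raise AnalysisError("reversion_threshold must be >= 0")
        if self.fsignal_orientation not in ("raw", "disease_oriented"):
            raise AnalysisError(
                f"unknown fsignal orientation {self.fsignal_orientation!r}")


@dataclass
class MoAResult:
    """Per-treatment summary: fSignal, reverted effectors, percentages."""
    fsignal: float
    fsignal_by_motive: dict[int, float]
    reverted: set[tuple[str, int]]
    percent_reversed_by_motive: dict[int, float]
    percent_reversed_overall: float
    non_convergent_flags: set[str] = field(default_factory=set)


@dataclass
class CombinationComparison:
    """Decomposition of the combination's reverted effectors.

    The five sets partition the unique proteins reverted by the combination
    together with those reverted by both single drugs: ``convergent`` (both
    drugs alone, combination at least as strong), ``exclusive_a`` /
    ``exclusive_b`` (one drug alone, maintained in combination),
    ``emergent`` (combination only), and ``attenuated`` (both drugs alone
    but the combination is weaker than the stronger single drug).
    """
    convergent: set[str]
    exclusive_a: set[str]
    exclusive_b: set[str]
    emergent: set[str]
    attenuated: set[str]
    per_motive_breakdown: dict[int, dict[str, set[str]]]
    complementary_table: list[ComplementaryTableRow]

    @property
    def all_classified(self) -> set[str]:
        return (self.convergent | self.exclusive_a | self.exclusive_b
                | self.emergent | self.attenuated)


@dataclass
class BioflagReport:
    n_evaluated: int
    n_corroborated: int
    n_antagonised: int
    n_below_threshold: int
    per_protein_status: dict[str, str]
    absent: set[str] = field(default_factory=set)


@dataclass
class SensitivityRanking:
    first_order: dict[str, float]
    total_order: dict[str, float]
    ranking: list[str]


def _oriented(activity: float, disease_sign: int, orientation: str) -> float:
    if orientation == "raw":
        return activity
    return -disease_sign * activity


def fsignal(profile: ActivityProfile, chars: DiseaseCharacterization,
            motive: int | None = None,
            config: AnalysisConfig | None = None) -> float:
    """Average signal arriving at the effectors.

    Within a motive the mean runs over (protein, motive) assignments; over
    the whole characterization it runs over unique proteins, each protein
    contributing the mean of its per-motive oriented values (in raw mode the
    per-motive values coincide, so this equals the plain protein mean).
    """
    config = config or AnalysisConfig()
    orientation = config.fsignal_orientation
    if motive is not None:
        assigns = chars.motive_assignments(motive)
        if not assigns:
            raise AnalysisError(f"motive {motive} has no effectors")
        vals = [_oriented(profile.activity.get(a.protein, 0.0),
                          a.disease_sign, orientation) for a in assigns]
        return float(np.mean(vals))
    if not chars.assignments:
        raise AnalysisError("characterization is empty")
    per_protein: dict[str, list[float]] = {}
    for a in chars.assignments:
        per_protein.setdefault(a.protein, []).append(
            _oriented(profile.activity.get(a.protein, 0.0), a.disease_sign,
                      orientation))
    return float(np.mean([np.mean(v) for v in per_protein.values()]))


def reverted_effectors(profile: ActivityProfile,
                       chars: DiseaseCharacterization,
                       config: AnalysisConfig | None = None
                       ) -> set[tuple[str, int]]:
    """(protein, motive) pairs driven opposite their disease sign.

    Inclusion requires sign(activity) == -disease_sign and |activity| >=
    the reversion threshold (boundary inclusive).
    """
    config = config or AnalysisConfig()
    thr = config.reversion_threshold
    out = set()
    for a in chars.assignments:
        act = profile.activity.get(a.protein, 0.0)
        if abs(act) >= thr and np.sign(act) == -a.disease_sign:
            out.add((a.protein, a.motive))
    return out


def percent_reversed(profile: ActivityProfile,
                     chars: DiseaseCharacterization,
                     motive: int | None = None,
                     config: AnalysisConfig | None = None) -> float:
    """100 * unique reverted proteins / unique effector proteins in scope."""
    config = config or AnalysisConfig()
    if motive is not None:
        scope = {a.protein for a in chars.motive_assignments(motive)}
    else:
        scope = chars.proteins
    if not scope:
        raise AnalysisError("no effectors in scope")
    reverted = {p for p, m in reverted_effectors(profile, chars, config)
                if motive is None or m == motive}
    return 100.0 * len(reverted) / len(scope)


def analyze_moa(profile: ActivityProfile, chars: DiseaseCharacterization,
                config: AnalysisConfig | None = None) -> MoAResult:
    """Full per-treatment summary for one activity profile."""
    config = config or AnalysisConfig()
    reverted = reverted_effectors(profile, chars, config)
    by_motive = {m: percent_reversed(profile, chars, m, config)
                 for m in sorted(chars.motives)}
    fs_by_motive = {m: fsignal(profile, chars, m, config)
                    for m in sorted(chars.motives)}
    flags = set() if profile.converged else set(profile.activity)
    return MoAResult(
        fsignal=fsignal(profile, chars, None, config),
        fsignal_by_motive=fs_by_motive,
        reverted=reverted,
        percent_reversed_by_motive=by_motive,
        percent_reversed_overall=percent_reversed(profile, chars, None, config),
        non_convergent_flags=flags)


def _mod_symbol(activity: float, thr: float) -> int:
    if activity >= thr:
        return 1
    if activity <= -thr:
        return -1
    return 0


def compare_combination(profile_a: ActivityProfile,
                        profile_b: ActivityProfile,
                        profile_ab: ActivityProfile,
                        chars: DiseaseCharacterization,
                        config: AnalysisConfig | None = None
                        ) -> CombinationComparison:
    """Decompose the combination's reverted effectors by drug contribution.

    Convergence requires reversion by each drug alone plus the "at least as
    strongly reversed" condition |a_ab| >= max(|a_a|, |a_b|) in the
    combination.
    """
    config = config or AnalysisConfig()
    if not (set(profile_a.activity) == set(profile_b.activity)
            == set(profile_ab.activity)):
        raise AnalysisError("profiles are defined over different proteins")

    rev_a = reverted_effectors(profile_a, chars, config)
    rev_b = reverted_effectors(profile_b, chars, config)
    rev_ab = reverted_effectors(profile_ab, chars, config)
    prot_a = {p for p, _ in rev_a}
    prot_b = {p for p, _ in rev_b}
    prot_ab = {p for p, _ in rev_ab}

    convergent, exclusive_a, exclusive_b = set(), set(), set()
    emergent, attenuated = set(), set()
    for p in sorted(prot_ab | (prot_a & prot_b)):
        in_a, in_b = p in prot_a, p in prot_b
        strong = abs(profile_ab.activity[p]) >= max(
            abs(profile_a.activity[p]), abs(profile_b.activity[p]))
        if in_a and in_b:
            (convergent if (p in prot_ab and strong) else attenuated).add(p)
        elif in_a and p in prot_ab:
            exclusive_a.add(p)
        elif in_b and p in prot_ab:
            exclusive_b.add(p)
        elif p in prot_ab:
            emergent.add(p)

    per_motive: dict[int, dict[str, set[str]]] = {}
    for m in sorted(chars.motives):
        in_motive = {p for p, mm in rev_ab if mm == m}
        per_motive[m] = {
            "convergent": convergent & in_motive,
            "exclusive_a": exclusive_a & in_motive,
            "exclusive_b": exclusive_b & in_motive,
            "emergent": emergent & in_motive,
        }

    thr = config.reversion_threshold
    table = []
    for p in sorted(exclusive_a | exclusive_b):
        motives = sorted(m for pp, m in
                         ((a.protein, a.motive) for a in chars.assignments)
                         if pp == p)
        signs = [chars.sign(p, m) for m in motives]
        table.append(ComplementaryTableRow(
            protein=p, motives=motives, disease_signs=signs,
            mod_a=_mod_symbol(profile_a.activity[p], thr),
            mod_b=_mod_symbol(profile_b.activity[p], thr),
            mod_combo=_mod_symbol(profile_ab.activity[p], thr)))

    return CombinationComparison(
        convergent=convergent, exclusive_a=exclusive_a,
        exclusive_b=exclusive_b, emergent=emergent, attenuated=attenuated,
        per_motive_breakdown=per_motive, complementary_table=table)


def corroborate_bioflags(profile: ActivityProfile, bioflags: list[Bioflag],
                         config: AnalysisConfig | None = None
                         ) -> BioflagReport:
    """Check reported drug-induced protein changes against the model.

    corroborated: sign matches with |activity| >= threshold; antagonised:
    sign opposes with |activity| >= threshold; below_threshold otherwise
    (including exact zeros). Bioflag proteins absent from the profile are
    reported separately and excluded from ``n_evaluated``.
    """
    config = config or AnalysisConfig()
    if not bioflags:
        raise AnalysisError("no bioflags to evaluate")
    thr = config.reversion_threshold
    status: dict[str, str] = {}
    absent: set[str] = set()
    for bf in bioflags:
        if bf.protein not in profile.activity:
            absent.add(bf.protein)
            continue
        act = profile.activity[bf.protein]
        if abs(act) >= thr and np.sign(act) == bf.expected_sign:
            status[bf.protein] = "corroborated"
        elif abs(act) >= thr:
            status[bf.protein] = "antagonised"
        else:
            status[bf.protein] = "below_threshold"
    counts = {s: sum(1 for v in status.values() if v == s)
              for s in ("corroborated", "antagonised", "below_threshold")}
    return BioflagReport(
        n_evaluated=len(status),
        n_corroborated=counts["corroborated"],
        n_antagonised=counts["antagonised"],
        n_below_threshold=counts["below_threshold"],
        per_protein_status=status, absent=absent)


def sobol_sensitivity(network: InteractionNetwork, ensemble: Ensemble,
                      stimulus: Stimulus, chars: DiseaseCharacterization,
                      config: AnalysisConfig | None = None,
                      propagation: PropagationConfig | None = None
                      ) -> SensitivityRanking:
    """Sobol attribution of fSignal to the stimulus clamp values.

    Each stimulated protein's clamp value is perturbed uniformly within
    +/- ``sobol_delta`` of its nominal value (truncated to [-1, 1]); the
    output is the fSignal over the characterization. Indices are averaged
    over ensemble members; ranking is by total-order index descending, ties
    broken lexicographically. Deterministic given ``config.seed``.
    """
    config = config or AnalysisConfig()
    propagation = propagation or PropagationConfig()
    params = sorted(stimulus.inputs)
    d = len(params)
    if d < 2:
        raise AnalysisError("need >= 2 stimulated proteins for Sobol analysis")
    if config.sobol_samples < 64:
        raise AnalysisError("sobol_samples must be >= 64")

    bounds = []
    for p in params:
        nominal = stimulus.inputs[p]
        bounds.append((max(-1.0, nominal - config.sobol_delta),
                       min(1.0, nominal + config.sobol_delta)))
    rng = np.random.default_rng(config.seed)
    sample = saltelli_sample(bounds, config.sobol_samples, rng)

    clamp_idx = np.array([network.node_index[p] for p in params], dtype=int)
    eff_assign = [(network.node_index[a.protein], a.disease_sign)
                  for a in chars.assignments if a.protein in network]
    if not eff_assign:
        raise AnalysisError("no characterization effector is in the network")
    eff_idx = np.array([i for i, _ in eff_assign])
    eff_sign = np.array([s for _, s in eff_assign], dtype=float)

    n = config.sobol_samples
    first = np.zeros(d)
    total = np.zeros(d)
    for sol in ensemble.solutions:
        matrix = network.adjacency_matrix(sol.weight_vector)
        acts, _, _ = _propagate_batch(matrix, clamp_idx, sample.T, propagation,
                                      network.n_nodes)
        eff = acts[eff_idx, :]
        if config.fsignal_orientation == "disease_oriented":
            eff = -eff_sign[:, None] * eff
        outputs = eff.mean(axis=0)
        res = sobol_indices_from_evals(outputs, d, n)
        first += res.first_order
        total += res.total_order
    first /= len(ensemble.solutions)
    total /= len(ensemble.solutions)
    ranking = sorted(params, key=lambda p: (-total[params.index(p)], p))
    return SensitivityRanking(
        first_order={p: float(first[i]) for i, p in enumerate(params)},
        total_order={p: float(total[i]) for i, p in enumerate(params)},
        ranking=ranking)


def extract_moa_subnetwork(network: InteractionNetwork, ensemble: Ensemble,
                           stimulus: Stimulus,
                           chars: DiseaseCharacterization,
                           config: AnalysisConfig | None = None,
                           propagation: PropagationConfig | None = None
                           ) -> nx.DiGraph:
    """Subgraph carrying the mechanism: targets, reverted effectors, and the
    intermediate nodes on directed paths between them with |mean activity|
    >= the reversion threshold.

    Node attributes: ``role`` in {target, effector, intermediate},
    ``activity``, ``convergent`` flag placeholder (set by callers that know
    the decomposition). Edge attribute ``interaction``: activation if the
    ensemble-mean weight times the upstream mean activity is positive,
    inhibition if negative.
    """
    config = config or AnalysisConfig()
    mean_profile, _ = ensemble_activity(ensemble, network, stimulus,
                                        propagation)
    reverted = {p for p, _ in
                reverted_effectors(mean_profile, chars, config)}
    sub = nx.DiGraph()
    if not reverted:
        return sub
    thr = config.reversion_threshold
    targets = set(stimulus.inputs)
    candidates = {n for n, a in mean_profile.activity.items()
                  if abs(a) >= thr} | targets | reverted
    cand_graph = network.graph.subgraph(candidates)
    downstream: set[str] = set()
    for t in targets & set(cand_graph.nodes):
        downstream |= {t} | nx.descendants(cand_graph, t)
    upstream: set[str] = set()
    rev_graph = cand_graph.reverse(copy=False)
    for e in reverted & set(cand_graph.nodes):
        upstream |= {e} | nx.descendants(rev_graph, e)
    keep = downstream & upstream
    if not keep:
        return sub

    mean_weights = np.mean([s.weight_vector for s in ensemble.solutions],
                           axis=0)
    for node in keep:
        role = ("target" if node in targets
                else "effector" if node in reverted else "intermediate")
        sub.add_node(node, role=role,
                     activity=mean_profile.activity[node])
    for (u, v), w in zip(network.edges, mean_weights):
        if u in keep and v in keep:
            influence = w * mean_profile.activity[u]
            sub.add_edge(u, v, weight=float(w),
                         interaction="activation" if influence >= 0
                         else "inhibition")
    return sub


def subnetwork_to_dot(sub: nx.DiGraph,
                      convergent: set[str] | None = None) -> str:
    """Render a mechanism subgraph as DOT.

    Green edges = activation, red = inhibition; diamonds = drug targets;
    filled circles = convergent effectors.
    """
    convergent = convergent or set()
    lines = ["digraph MoA {", "  rankdir=LR;"]
    for node in sorted(sub.nodes):
        attrs = sub.nodes[node]
        shape = "diamond" if attrs.get("role") == "target" else "ellipse"
        style = "filled" if node in convergent else "solid"
        fill = ', fillcolor="lightblue"' if node in convergent else ""
        lines.append(f'  "{node}" [shape={shape}, style="{style}"{fill}, '
                     f'label="{node}\\n{attrs.get("activity", 0):+.2f}"];')
    for u, v in sorted(sub.edges):
        color = ("green" if sub.edges[u, v]["interaction"] == "activation"
                 else "red")
        lines.append(f'  "{u}" -> "{v}" [color={color}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def profile_from_modulation(rows: list[ComplementaryTableRow], column: str,
                            magnitude: float = 0.5) -> ActivityProfile:
    """Replay a printed modulation column as a symbolic activity profile.

    The +/-``magnitude`` mapping (down -> -0.5, up -> +0.5, none -> 0 by
    default) is a fixture convention: classifications depend only on signs
    and the 0.1 reversion threshold, not on the chosen magnitude.
    """
    activity = {}
    for r in rows:
        mod = getattr(r, column)
        activity[r.protein] = mod * magnitude
    return ActivityProfile(activity=activity, converged=True, iterations=0)
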