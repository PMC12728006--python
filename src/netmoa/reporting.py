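"""Pipeline orchestration, report writers, and the table-replay regression.

``run_pipeline`` ties the stages together: train an ensemble against the
training rules, propagate each drug and the combination, decompose the
combination's reverted effectors, corroborate bioflags, run the Sobol
sensitivity analysis, and write a deterministic JSON report plus DOT and
TSV exports. Every artefact embeds the configuration hash and seeds so any
output is regenerable from config + seed alone.

``replay_tables`` re-derives the published table-level tallies from the
packaged fixtures through the pipeline's own classification logic — a
regression guard that the classification rules (reversion threshold,
exclusivity, convergence, corroboration) reproduce the transcribed tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import characterization as ch
from .moa import (AnalysisConfig, analyze_moa, compare_combination,
                  corroborate_bioflags, extract_moa_subnetwork,
                  profile_from_modulation, sobol_sensitivity,
                  subnetwork_to_dot)
from .network import (ActivityProfile, PropagationConfig, combine_stimuli,
                      ensemble_activity, read_edge_list, stimulus_from_drug)
from .training import (AnnealConfig, config_hash, load_training_set,
                       save_ensemble, train_ensemble)

log = logging.getLogger("netmoa")

# Published table-level tallies the fixtures must replay (unique proteins):
# drug-A-exclusive reversions (and the motive-1 subset), drug-B-exclusive
# (and the motive-4 subset), convergent effectors, and corroborated
# bioflags under the combination.
REPLAY_EXPECTATIONS = {
    "exclusive_a": 13,
    "exclusive_a_m1": 6,
    "exclusive_b": 11,
    "exclusive_b_m4": 7,
    "convergent": 10,
    "bioflags_corroborated_combo": 20,
}

_STATUS_ACTIVITY = {"corroborated": 0.5, "antagonised": -0.5,
                    "below_threshold": 0.05}


def bioflag_profile_from_statuses(rows: list[ch.BioflagTableRow],
                                  column: str) -> ActivityProfile:
    """Symbolic activity profile replaying a corroboration status column."""
    activity = {}
    for r in rows:
        status = getattr(r, column)
        if status == "blank":
            continue  # protein absent from the evaluated models
        activity[r.protein] = _STATUS_ACTIVITY[status] * r.bioflag_sign
    return ActivityProfile(activity=activity, converged=True, iterations=0)


def replay_tables(fixture_dir: str | Path | None = None) -> dict:
    """Recompute the published table counts from fixtures; report mismatches.

    Returns a report dict with ``passed`` plus per-count actual/expected and
    the offending proteins on any mismatch.
    """
    if fixture_dir is None:
        comp = ch.load_complementary_table(
            ch.fixture_path("table1_complementary"))
        conv = ch.load_complementary_table(ch.fixture_path("table2_convergent"))
        bio = ch.load_bioflag_table(ch.fixture_path("table3a_bioflags_vdz"))
    else:
        fixture_dir = Path(fixture_dir)
        comp = ch.load_complementary_table(
            fixture_dir / "table1_complementary.tsv")
        conv = ch.load_complementary_table(fixture_dir / "table2_convergent.tsv")
        bio = ch.load_bioflag_table(fixture_dir / "table3a_bioflags_vdz.tsv")

    rows = comp + conv
    chars = ch.characterization_from_table(rows)
    profile_a = profile_from_modulation(rows, "mod_a")
    profile_b = profile_from_modulation(rows, "mod_b")
    profile_ab = profile_from_modulation(rows, "mod_combo")
    comparison = compare_combination(profile_a, profile_b, profile_ab, chars)
    combo_bio = bioflag_profile_from_statuses(bio, "status_combo")
    bioflags = [ch.Bioflag(r.protein, r.bioflag_sign) for r in bio
                if getattr(r, "status_combo") != "blank"]
    bioreport = corroborate_bioflags(combo_bio, bioflags)

    actual = {
        "exclusive_a": len(comparison.exclusive_a),
        "exclusive_a_m1": len(
            comparison.per_motive_breakdown[1]["exclusive_a"]),
        "exclusive_b": len(comparison.exclusive_b),
        "exclusive_b_m4": len(
            comparison.per_motive_breakdown[4]["exclusive_b"]),
        "convergent": len(comparison.convergent),
        "bioflags_corroborated_combo": bioreport.n_corroborated,
    }
    members = {
        "exclusive_a": sorted(comparison.exclusive_a),
        "exclusive_b": sorted(comparison.exclusive_b),
        "convergent": sorted(comparison.convergent),
    }
    mismatches = {}
    for key, expected in REPLAY_EXPECTATIONS.items():
        if actual[key] != expected:
            mismatches[key] = {
                "expected": expected, "actual": actual[key],
                "proteins": members.get(key, []),
            }
    return {"passed": not mismatches, "counts": actual,
            "expected": dict(REPLAY_EXPECTATIONS), "members": members,
            "mismatches": mismatches}


@dataclass
class RunConfig:
    """File-driven pipeline configuration.

    All randomness flows from ``anneal.base_seed`` and ``analysis.seed``.
    """
    network_path: str | Path
    characterization_path: str | Path
    drug_a_path: str | Path
    drug_b_path: str | Path
    training_set_path: str | Path
    output_dir: str | Path
    bioflags_path: str | Path | None = None
    anneal: AnnealConfig = field(default_factory=AnnealConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    log_level: str = "INFO"

    def validate(self) -> None:
        paths = [self.network_path, self.characterization_path,
                 self.drug_a_path, self.drug_b_path, self.training_set_path]
        if self.bioflags_path is not None:
            paths.append(self.bioflags_path)
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _moa_section(result) -> dict:
    return {
        "fsignal": result.fsignal,
        "fsignal_by_motive": {str(m): v
                              for m, v in result.fsignal_by_motive.items()},
        "percent_reversed_overall": result.percent_reversed_overall,
        "percent_reversed_by_motive": {
            str(m): v for m, v in result.percent_reversed_by_motive.items()},
        "n_reverted_unique": len({p for p, _ in result.reverted}),
        "n_reverted_pairs": len(result.reverted),
        "non_convergent_propagation": sorted(result.non_convergent_flags)[:10],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute train -> per-drug MoA -> combination -> decomposition ->
    bioflags -> Sobol -> exports. Returns the report dict (also written to
    ``report.json`` in the output directory)."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stages: dict[str, float] = {}

    def stage(name):
        start = time.perf_counter()

        def done():
            stages[name] = round(time.perf_counter() - start, 3)
            log.info("stage %s done in %.2fs", name, stages[name])
        return done

    try:
        done = stage("load")
        network = read_edge_list(config.network_path)
        chars = ch.load_characterization(config.characterization_path)
        drug_a = ch.load_drug_profile(config.drug_a_path)
        drug_b = ch.load_drug_profile(config.drug_b_path)
        training_set = load_training_set(config.training_set_path)
        bioflags = (ch.load_bioflags(config.bioflags_path)
                    if config.bioflags_path else [])
        done()

        done = stage("train")
        ensemble = train_ensemble(network, training_set, config.anneal)
        save_ensemble(ensemble, out / "ensemble", config.anneal)
        done()

        done = stage("moa")
        stim_a = stimulus_from_drug(drug_a, network)
        stim_b = stimulus_from_drug(drug_b, network)
        stim_ab = combine_stimuli(stim_a, stim_b)
        profiles = {}
        moa = {}
        for label, stim in (("drug_a", stim_a), ("drug_b", stim_b),
                            ("combination", stim_ab)):
            profile, _ = ensemble_activity(ensemble, network, stim,
                                           config.propagation)
            profiles[label] = (stim, profile)
            moa[label] = analyze_moa(profile, chars, config.analysis)
        done()

        done = stage("decomposition")
        comparison = compare_combination(
            profiles["drug_a"][1], profiles["drug_b"][1],
            profiles["combination"][1], chars, config.analysis)
        done()

        bioflag_section = None
        if bioflags:
            done = stage("bioflags")
            reports = {
                label: corroborate_bioflags(profile, bioflags, config.analysis)
                for label, (_, profile) in profiles.items()}
            bioflag_section = {
                label: {"n_evaluated": r.n_evaluated,
                        "n_corroborated": r.n_corroborated,
                        "n_antagonised": r.n_antagonised,
                        "n_below_threshold": r.n_below_threshold,
                        "absent": sorted(r.absent)}
                for label, r in reports.items()}
            done()

        done = stage("sobol")
        sens = sobol_sensitivity(network, ensemble, stim_ab, chars,
                                 config.analysis, config.propagation)
        done()

        done = stage("export")
        sub = extract_moa_subnetwork(network, ensemble, stim_ab, chars,
                                     config.analysis, config.propagation)
        (out / "moa_subnetwork.dot").write_text(
            subnetwork_to_dot(sub, convergent=comparison.convergent))
        with open(out / "moa_subnetwork_edges.tsv", "w") as fh:
            fh.write("source\ttarget\tinteraction\tweight\n")
            for u, v in sorted(sub.edges):
                e = sub.edges[u, v]
                fh.write(f"{u}\t{v}\t{e['interaction']}\t{e['weight']:.6g}\n")
        done()

        report = {
            "config_hash": config_hash(config.anneal),
            "seeds": {"anneal_base_seed": config.anneal.base_seed,
                      "analysis_seed": config.analysis.seed},
            "training": {
                "n_solutions": len(ensemble.solutions),
                "accuracy_gate": ensemble.accuracy_gate,
                "mean_accuracy": round(ensemble.mean_accuracy, 4),
                "mean_accuracy_pct": f"{100 * ensemble.mean_accuracy:.2f}%",
                "accuracies": [round(s.accuracy, 4)
                               for s in ensemble.solutions],
                "n_rules": len(training_set.rules),
                "n_expectations": training_set.n_expectations,
            },
            "moa": {label: _moa_section(r) for label, r in moa.items()},
            "decomposition": {
                "convergent": sorted(comparison.convergent),
                "exclusive_a": sorted(comparison.exclusive_a),
                "exclusive_b": sorted(comparison.exclusive_b),
                "emergent": sorted(comparison.emergent),
                "attenuated": sorted(comparison.attenuated),
                "per_motive": {
                    str(m): {k: sorted(v) for k, v in sets.items()}
                    for m, sets in comparison.per_motive_breakdown.items()},
            },
            "bioflags": bioflag_section,
            "sobol": {
                "first_order": {p: round(v, 4)
                                for p, v in sens.first_order.items()},
                "total_order": {p: round(v, 4)
                                for p, v in sens.total_order.items()},
                "ranking": sens.ranking,
            },
            "stage_seconds": stages,
        }
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {list(stages)[-1] if stages else 'load'} "
            f"failed: {exc}") from exc

    stable = {k: v for k, v in report.items() if k != "stage_seconds"}
    (out / "report.json").write_text(json.dumps(stable, indent=1,
                                                sort_keys=True))
    _write_decomposition_csv(comparison, chars, out / "decomposition.csv")
    return report


def _write_decomposition_csv(comparison, chars, path: Path) -> None:
    """Table-style CSV mirroring the complementary-mechanism layout."""
    sym = {1: "up", -1: "down", 0: "none"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein,motives,disease_signs,mod_a,mod_b,mod_combo,class\n")
        classes = {p: "exclusive_a" for p in comparison.exclusive_a}
        classes.update({p: "exclusive_b" for p in comparison.exclusive_b})
        for row in comparison.complementary_table:
            fh.write(",".join([
                row.protein,
                ";".join(str(m) for m in row.motives),
                ";".join(sym[s] for s in row.disease_signs),
                sym[row.mod_a], sym[row.mod_b], sym[row.mod_combo],
                classes.get(row.protein, "?")]) + "\n")
        for p in sorted(comparison.convergent):
            motives = sorted(a.motive for a in chars.assignments
                             if a.protein == p)
            signs = [chars.sign(p, m) for m in motives]
            fh.write(",".join([
                p, ";".join(map(str, motives)),
                ";".join(sym[s] for s in signs),
                "-", "-", "-", "convergent"]) + "\n")
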