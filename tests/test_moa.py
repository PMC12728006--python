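"""fSignal, reversion classification, combination decomposition, bioflags."""

import numpy as np
import pytest

from netmoa import characterization as ch
from netmoa.characterization import (Bioflag, DiseaseCharacterization,
                                     EffectorAssignment)
from netmoa.moa import (AnalysisConfig, AnalysisError, analyze_moa,
                        compare_combination, corroborate_bioflags, fsignal,
                        percent_reversed, profile_from_modulation,
                        reverted_effectors)
from netmoa.network import ActivityProfile


def profile(**activities) -> ActivityProfile:
    return ActivityProfile(activity=dict(activities), converged=True,
                           iterations=1)


@pytest.fixture(scope="module")
def table_fixture():
    rows = (ch.load_complementary_table(ch.fixture_path("table1_complementary"))
            + ch.load_complementary_table(ch.fixture_path("table2_convergent")))
    chars = ch.characterization_from_table(rows)
    return {
        "rows": rows,
        "chars": chars,
        "a": profile_from_modulation(rows, "mod_a"),
        "b": profile_from_modulation(rows, "mod_b"),
        "ab": profile_from_modulation(rows, "mod_combo"),
    }


class TestFsignal:
    def test_zero_profile_is_zero_in_both_modes(self, toy_characterization):
        prof = profile(A=0.0, B=0.0, C=0.0)
        for mode in ("raw", "disease_oriented"):
            cfg = AnalysisConfig(fsignal_orientation=mode)
            assert fsignal(prof, toy_characterization, config=cfg) == 0.0

    def test_disease_oriented_sign_convention(self):
        chars = DiseaseCharacterization(
            assignments=[EffectorAssignment("X", 1, +1)])
        prof = profile(X=-0.8)
        assert fsignal(prof, chars) == pytest.approx(0.8)
        raw = AnalysisConfig(fsignal_orientation="raw")
        assert fsignal(prof, chars, config=raw) == pytest.approx(-0.8)

    def test_matches_independent_mean(self, table_fixture):
        """Motive-restricted fSignal equals a spreadsheet-style recomputation."""
        chars, prof = table_fixture["chars"], table_fixture["a"]
        for motive in (1, 3, 4):
            expected = np.mean([
                -a.disease_sign * prof.activity[a.protein]
                for a in chars.assignments if a.motive == motive])
            assert fsignal(prof, chars, motive) == pytest.approx(expected)

    def test_empty_motive_raises(self, toy_characterization):
        with pytest.raises(Exception):
            fsignal(profile(A=0.1), toy_characterization, motive=9)


class TestRevertedEffectors:
    def test_boundary_inclusive_at_threshold(self):
        chars = DiseaseCharacterization(
            assignments=[EffectorAssignment("X", 1, -1)])
        assert reverted_effectors(profile(X=0.1), chars) == {("X", 1)}

    def test_below_threshold_excluded(self):
        chars = DiseaseCharacterization(
            assignments=[EffectorAssignment("X", 1, +1)])
        assert reverted_effectors(profile(X=-0.09), chars) == set()

    def test_same_direction_not_reverted(self):
        chars = DiseaseCharacterization(
            assignments=[EffectorAssignment("X", 1, +1)])
        assert reverted_effectors(profile(X=0.9), chars) == set()

    def test_vdz_column_reverts_13_unique_proteins(self, table_fixture):
        reverted = reverted_effectors(table_fixture["a"],
                                      table_fixture["chars"])
        assert len({p for p, _ in reverted}) == 13 + 10  # exclusive + convergent

    def test_threshold_monotonicity(self, table_fixture):
        rng = np.random.default_rng(5)
        chars = table_fixture["chars"]
        prof = ActivityProfile(
            activity={p: float(rng.uniform(-1, 1))
                      for p in chars.proteins},
            converged=True, iterations=1)
        sets = [reverted_effectors(prof, chars, AnalysisConfig(
                    reversion_threshold=t))
                for t in (0.05, 0.1, 0.3, 0.6)]
        for smaller_t, larger_t in zip(sets, sets[1:]):
            assert larger_t <= smaller_t


class TestPercentReversed:
    def test_extremes(self):
        chars = DiseaseCharacterization(assignments=[
            EffectorAssignment("X", 1, +1), EffectorAssignment("Y", 1, +1)])
        assert percent_reversed(profile(X=0.5, Y=0.5), chars) == 0.0
        assert percent_reversed(profile(X=-0.5, Y=-0.5), chars) == 100.0

    def test_fractional_count(self):
        assigns = [EffectorAssignment(f"P{i}", 1, +1) for i in range(10)]
        chars = DiseaseCharacterization(assignments=assigns)
        acts = {f"P{i}": (-0.5 if i < 4 else 0.0) for i in range(10)}
        prof = ActivityProfile(activity=acts, converged=True, iterations=1)
        assert percent_reversed(prof, chars) == pytest.approx(40.0)

    def test_empty_scope_raises(self):
        chars = DiseaseCharacterization(assignments=[])
        with pytest.raises(AnalysisError):
            percent_reversed(profile(X=0.1), chars)


class TestCompareCombination:
    def test_table_counts_replayed(self, table_fixture):
        comparison = compare_combination(
            table_fixture["a"], table_fixture["b"], table_fixture["ab"],
            table_fixture["chars"])
        assert len(comparison.exclusive_a) == 13
        assert len(comparison.exclusive_b) == 11
        assert len(comparison.convergent) == 10
        assert comparison.emergent == set()
        assert comparison.attenuated == set()
        assert len(comparison.per_motive_breakdown[1]["exclusive_a"]) == 6
        assert len(comparison.per_motive_breakdown[4]["exclusive_b"]) == 7

    def test_partition_disjoint_and_total(self, table_fixture):
        comparison = compare_combination(
            table_fixture["a"], table_fixture["b"], table_fixture["ab"],
            table_fixture["chars"])
        sets = [comparison.convergent, comparison.exclusive_a,
                comparison.exclusive_b, comparison.emergent,
                comparison.attenuated]
        for i, s1 in enumerate(sets):
            for s2 in sets[i + 1:]:
                assert not (s1 & s2)
        reverted_ab = {p for p, _ in reverted_effectors(
            table_fixture["ab"], table_fixture["chars"])}
        assert reverted_ab <= comparison.all_classified

    def test_identical_single_profiles_all_convergent(self):
        chars = DiseaseCharacterization(assignments=[
            EffectorAssignment("X", 1, +1), EffectorAssignment("Y", 1, +1)])
        single = profile(X=-0.5, Y=-0.5)
        combo = profile(X=-0.6, Y=-0.5)
        comparison = compare_combination(single, single, combo, chars)
        assert comparison.convergent == {"X", "Y"}
        assert not comparison.exclusive_a and not comparison.exclusive_b

    def test_attenuated_when_combo_weaker(self):
        chars = DiseaseCharacterization(
            assignments=[EffectorAssignment("X", 1, +1)])
        comparison = compare_combination(
            profile(X=-0.5), profile(X=-0.5), profile(X=-0.3), chars)
        assert comparison.attenuated == {"X"}
        assert comparison.convergent == set()

    def test_emergent_combination_only(self):
        chars = DiseaseCharacterization(
            assignments=[EffectorAssignment("X", 1, +1)])
        comparison = compare_combination(
            profile(X=-0.05), profile(X=-0.05), profile(X=-0.4), chars)
        assert comparison.emergent == {"X"}

    def test_mismatched_universes_rejected(self):
        chars = DiseaseCharacterization(
            assignments=[EffectorAssignment("X", 1, +1)])
        with pytest.raises(AnalysisError):
            compare_combination(profile(X=-0.5), profile(Y=-0.5),
                                profile(X=-0.5), chars)


class TestBioflags:
    def test_directions(self):
        flags = [Bioflag("UP", +1), Bioflag("DOWN", -1), Bioflag("WEAK", -1),
                 Bioflag("GONE", -1)]
        prof = profile(UP=0.6, DOWN=0.4, WEAK=-0.05)
        report = corroborate_bioflags(prof, flags)
        assert report.per_protein_status == {
            "UP": "corroborated", "DOWN": "antagonised",
            "WEAK": "below_threshold"}
        assert report.absent == {"GONE"}
        assert report.n_evaluated == 3
        assert (report.n_corroborated + report.n_antagonised
                + report.n_below_threshold) == report.n_evaluated

    def test_all_zero_profile_all_below_threshold(self):
        flags = [Bioflag("A", 1), Bioflag("B", -1)]
        report = corroborate_bioflags(profile(A=0.0, B=0.0), flags)
        assert report.n_below_threshold == 2

    def test_combined_treatment_fixture_corroborates_20(self):
        from netmoa.reporting import bioflag_profile_from_statuses
        rows = ch.load_bioflag_table(ch.fixture_path("table3a_bioflags_vdz"))
        prof = bioflag_profile_from_statuses(rows, "status_combo")
        flags = [Bioflag(r.protein, r.bioflag_sign) for r in rows
                 if r.status_combo != "blank"]
        report = corroborate_bioflags(prof, flags)
        assert report.n_corroborated == 20
        assert report.n_antagonised == 1

    def test_empty_bioflags_rejected(self):
        with pytest.raises(AnalysisError):
            corroborate_bioflags(profile(A=0.1), [])


class TestAnalyzeMoa:
    def test_percentages_within_bounds(self, table_fixture):
        result = analyze_moa(table_fixture["ab"], table_fixture["chars"])
        assert 0 <= result.percent_reversed_overall <= 100
        for v in result.percent_reversed_by_motive.values():
            assert 0 <= v <= 100
        assert result.reverted <= {
            (a.protein, a.motive)
            for a in table_fixture["chars"].assignments}
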