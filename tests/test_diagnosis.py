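import pytest

from mitoveritas.align import IndelReport
from mitoveritas.chimera import ChimeraReport, ChimeraSegment
from mitoveritas.config import DEFAULT_CONFIG
from mitoveritas.diagnosis import (
    Diagnosis,
    compare_strata,
    detect_symptoms,
    diagnose,
    percent,
    summarize_cohort,
)
from mitoveritas.io_metadata import LabelComparison
from mitoveritas.trees import PlacementSummary


def placement(marker, species="Aviana alpha", inside=True, nearest="Aviana alpha",
              nearest_d=0.002, con_d=0.002, het_sp="Aviana bravo", het_d=0.09,
              term=0.002, med=0.002, tree_med=0.002, sister=0.002,
              resolved=True):
    return PlacementSummary(
        query_label=f"{species.replace(' ', '_')}|QX",
        marker_name=marker,
        inside_conspecific_clade=inside,
        nearest_species=nearest,
        nearest_distance=nearest_d,
        nearest_conspecific_distance=con_d,
        nearest_hetero_species=het_sp,
        nearest_hetero_distance=het_d,
        terminal_branch=term,
        conspecific_median_terminal=med,
        tree_median_terminal=tree_med,
        sister_branch=sister,
        reference_resolved=resolved,
        single_reference=False,
    )


def no_indels(marker):
    return IndelReport("QX", marker)


def labels_ok():
    return LabelComparison("QX", True, "aviana alpha", "aviana alpha")


ALL = ("COI", "CYTB", "ND2")


class TestDetectSymptoms:
    def test_clean_query_fires_nothing(self):
        s = detect_symptoms({m: placement(m) for m in ALL},
                            {m: no_indels(m) for m in ALL})
        assert not s.any_symptom and s.fired() == []

    def test_multiple_indels_fire_s1(self):
        indels = {m: no_indels(m) for m in ALL}
        indels["ND2"] = IndelReport("QX", "ND2", indel_events=2,
                                    total_gap_columns=2, frameshift=True)
        s = detect_symptoms({m: placement(m) for m in ALL}, indels)
        assert s.per_marker["ND2"].s1_indels
        assert not s.per_marker["COI"].s1_indels

    def test_single_indel_never_fires_s1(self):
        indels = {m: no_indels(m) for m in ALL}
        indels["ND2"] = IndelReport("QX", "ND2", indel_events=1,
                                    total_gap_columns=3)
        s = detect_symptoms({m: placement(m) for m in ALL}, indels)
        assert not s.per_marker["ND2"].s1_indels

    def test_close_match_outside_fires_s2(self):
        p = {m: placement(m, inside=False, nearest="Aviana bravo",
                          nearest_d=0.005, con_d=0.09, het_d=0.005)
             for m in ALL}
        s = detect_symptoms(p, {m: no_indels(m) for m in ALL})
        assert all(s.per_marker[m].s2_close_match_outside for m in ALL)
        assert not s.s3_tree_mismatch  # same wrong species everywhere

    def test_gene_tree_mismatch_fires_s3(self):
        p = {m: placement(m) for m in ALL}
        p["COI"] = placement("COI", inside=False, nearest="Aviana bravo",
                             nearest_d=0.001, het_d=0.001)
        p["CYTB"] = placement("CYTB", inside=False, nearest="Aviana carina",
                              nearest_d=0.001, het_sp="Aviana carina",
                              het_d=0.001)
        s = detect_symptoms(p, {m: no_indels(m) for m in ALL})
        assert s.s3_tree_mismatch

    def test_long_branch_inside_clade_fires_s4(self):
        p = {m: placement(m) for m in ALL}
        p["CYTB"] = placement("CYTB", term=0.08, med=0.002)
        s = detect_symptoms(p, {m: no_indels(m) for m in ALL})
        assert s.per_marker["CYTB"].s4_long_branch_in_clade
        assert not s.per_marker["COI"].s4_long_branch_in_clade

    def test_deep_divergence_outside_fires_s5(self):
        p = {m: placement(m, inside=False, con_d=0.08, nearest_d=0.08,
                          het_d=0.09) for m in ALL}
        s = detect_symptoms(p, {m: no_indels(m) for m in ALL})
        assert all(s.per_marker[m].s5_deep_divergence_outside for m in ALL)

    def test_distant_no_close_match_fires_s6(self):
        p = {m: placement(m, inside=False, nearest_d=0.15, con_d=0.15,
                          het_d=0.16) for m in ALL}
        s = detect_symptoms(p, {m: no_indels(m) for m in ALL})
        assert all(s.per_marker[m].s6_distant_no_close_match for m in ALL)

    def test_sister_on_long_branch_fires_s7(self):
        p = {"COI": placement("COI", inside=False, con_d=0.04, het_d=0.05,
                              sister=0.08, tree_med=0.002)}
        s = detect_symptoms(p, {"COI": no_indels("COI")})
        assert s.per_marker["COI"].s7_sister_on_long_branch

    def test_requires_a_usable_marker(self):
        with pytest.raises(ValueError):
            detect_symptoms({}, {})


def run_diagnose(placements, indels=None, chimera=None, labels=None,
                 resolutions=None, duplications=None, hybrid_pairs=None):
    indels = indels or {m: no_indels(m) for m in placements}
    symptoms = detect_symptoms(placements, indels)
    return diagnose(symptoms, chimera, labels or labels_ok(),
                    resolutions or {m: True for m in placements},
                    hybrid_pairs=hybrid_pairs, duplications=duplications)


def chimera_report(segments, labeled="Aviana alpha"):
    return ChimeraReport("QX", labeled, segments)


class TestDiagnose:
    def test_clean_record_is_authentic(self):
        d = run_diagnose({m: placement(m) for m in ALL})
        assert d.verdict == "authentic"

    def test_same_wrong_species_everywhere_is_misidentification(self):
        p = {m: placement(m, inside=False, nearest="Aviana bravo",
                          nearest_d=0.004, con_d=0.09, het_d=0.004)
             for m in ALL}
        d = run_diagnose(p)
        assert d.verdict == "misidentification"
        assert not d.hybrid_note

    def test_hybridizing_pair_is_noted(self):
        p = {m: placement(m, inside=False, nearest="Aviana bravo",
                          nearest_d=0.004, con_d=0.09, het_d=0.004)
             for m in ALL}
        pairs = {frozenset({"aviana alpha", "aviana bravo"})}
        d = run_diagnose(p, hybrid_pairs=pairs)
        assert d.verdict == "misidentification" and d.hybrid_note

    def test_region_specific_close_matches_are_chimera(self):
        p = {m: placement(m) for m in ALL}
        p["CYTB"] = placement("CYTB", inside=False, nearest="Aviana delta",
                              nearest_d=0.005, het_sp="Aviana delta",
                              het_d=0.005, con_d=0.12)
        rep = chimera_report([
            ChimeraSegment(0, 9000, "Aviana alpha", False,
                           mean_window_distance=0.004, n_windows=60),
            ChimeraSegment(9000, 12000, "Aviana delta", True,
                           divergence_from_authentic=0.12,
                           mean_window_distance=0.006, n_windows=20),
            ChimeraSegment(12000, 16000, "Aviana alpha", False,
                           mean_window_distance=0.004, n_windows=30),
        ])
        d = run_diagnose(p, chimera=rep)
        assert d.verdict == "chimera"
        assert d.chimera_report.n_heterospecific_fragments == 1

    def test_distant_winner_segments_are_not_chimera_evidence(self):
        """An error/numt-divergent region that 'wins' another species only
        at 15% distance must not be called a donor fragment."""
        p = {m: placement(m) for m in ALL}
        p["CYTB"] = placement("CYTB", inside=False, nearest="Aviana alpha",
                              nearest_d=0.15, con_d=0.15, het_d=0.18)
        rep = chimera_report([
            ChimeraSegment(0, 9000, "Aviana alpha", False,
                           mean_window_distance=0.004, n_windows=60),
            ChimeraSegment(9000, 10000, "Aviana delta", True,
                           mean_window_distance=0.16, n_windows=7),
            ChimeraSegment(10000, 16000, "Aviana alpha", False,
                           mean_window_distance=0.004, n_windows=40),
        ])
        d = run_diagnose(p, chimera=rep)
        assert d.verdict == "seq_errors_numts"

    def test_multiple_indels_are_errors_numts(self):
        indels = {m: no_indels(m) for m in ALL}
        indels["ND2"] = IndelReport("QX", "ND2", indel_events=2,
                                    total_gap_columns=2, frameshift=True)
        d = run_diagnose({m: placement(m) for m in ALL}, indels=indels)
        assert d.verdict == "seq_errors_numts"
        assert any("S1@ND2" in c for c in d.fired_symptoms)

    def test_duplication_is_incorrect_assembly(self):
        p = {m: placement(m) for m in ALL}
        p["CYTB"] = placement("CYTB", term=0.05)  # long branch
        d = run_diagnose(p, duplications={"CYTB": (14_500, 15_000)})
        assert d.verdict == "incorrect_assembly"

    def test_label_mismatch_resolved_toward_paper(self):
        p = {m: placement(m, species="Aviana bravo", inside=False,
                          nearest="Aviana alpha", nearest_d=0.003,
                          con_d=0.09, het_sp="Aviana alpha", het_d=0.003)
             for m in ALL}
        labels = LabelComparison("QX", False, "aviana bravo", "aviana alpha")
        d = run_diagnose(p, labels=labels)
        assert d.verdict == "mislabeled_on_genbank"

    def test_label_mismatch_resolved_toward_record(self):
        p = {m: placement(m) for m in ALL}
        labels = LabelComparison("QX", False, "aviana alpha", "aviana bravo")
        d = run_diagnose(p, labels=labels)
        assert d.verdict == "mislabeled_in_paper"

    def test_unresolved_references_cannot_be_verified(self):
        d = run_diagnose({m: placement(m, resolved=False) for m in ALL},
                         resolutions={m: False for m in ALL})
        assert d.verdict == "could_not_be_verified"

    def test_symptoms_without_applicable_rule_go_to_manual_review(self):
        p = {"COI": placement("COI", inside=False, con_d=0.06, nearest_d=0.06,
                              het_d=0.07)}
        d = run_diagnose(p, indels={"COI": no_indels("COI")})
        assert d.verdict == "could_not_be_verified"
        assert any("manual review" in r for r in d.rationale)

    def test_mismatched_chimera_accession_is_an_error(self):
        p = {m: placement(m) for m in ALL}
        rep = ChimeraReport("OTHER", "Aviana alpha", [])
        with pytest.raises(ValueError):
            run_diagnose(p, chimera=rep)

    def test_exactly_one_verdict_and_rationale_nonempty_unless_authentic(self):
        p = {m: placement(m, inside=False, nearest="Aviana bravo",
                          nearest_d=0.004, con_d=0.09, het_d=0.004)
             for m in ALL}
        d = run_diagnose(p)
        assert d.verdict in {"misidentification"}
        assert d.rationale


class TestSummaries:
    @staticmethod
    def make(verdict, acc, sp="aviana alpha"):
        return Diagnosis(accession=acc, verdict=verdict, species_on_record=sp,
                         rationale=["x"] if verdict != "authentic" else [])

    def test_percent_problematic(self):
        diags = [self.make("misidentification", f"P{i}", f"sp{i}") for i in range(5)]
        diags += [self.make("authentic", f"A{i}") for i in range(95)]
        s = summarize_cohort(diags)
        assert s.percent_problematic == 5.0
        assert s.n_problematic == 5 and s.n_problem_species == 5

    def test_all_unverifiable_has_no_rate(self):
        diags = [self.make("could_not_be_verified", f"U{i}") for i in range(4)]
        s = summarize_cohort(diags)
        assert s.percent_problematic is None and s.n_verifiable == 0

    def test_verdict_counts_conserve_cohort_size(self):
        diags = [self.make(v, f"X{i}") for i, v in enumerate(
            ["authentic", "chimera", "misidentification", "authentic",
             "could_not_be_verified"])]
        s = summarize_cohort(diags)
        assert sum(s.verdict_counts.values()) == len(diags)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_cohort([])

    def test_percent_helper_rounds_like_print(self):
        assert percent(1, 3) == 33.3
        assert percent(1, 3, 0) == 33
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)

    def test_strata_chi_squared_is_plain_pearson(self):
        stat, p = compare_strata(10, 100, 10, 100)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        stat, _ = compare_strata(30, 100, 10, 100)
        assert stat > 10
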