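"""Symptom detection and per-record diagnosis.

A flagged mitogenome shows at least one of seven symptoms:

S1  multiple insertions/deletions in a protein-coding marker alignment;
S2  a close match with another species, outside the conspecific clade;
S3  a mismatch between gene trees (different nearest species per marker);
S4  a long terminal branch inside the conspecific clade;
S5  a deep divergence, outside the conspecific clade;
S6  a distant position without a close match to any species;
S7  a position outside the conspecific clade with the sister lineage on a
    long branch.

Symptoms map many-to-many onto causes, so the diagnosis applies an ordered
rule list and keeps every fired symptom in the rationale: label mismatches
are metadata-only and checked first; region-specific heterospecific matches
(chimeras) outrank whole-sequence signals; self-duplication outranks the
error/numt call; a consistent close match to one wrong species with no long
branch is a misidentification.  Records whose references are not reciprocally
monophyletic, or whose symptoms fit no rule, cannot be verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import chi2_contingency

from .align import IndelReport
from .chimera import ChimeraReport, ChimeraSegment, chimera_stats
from .config import DEFAULT_CONFIG, MARKER_NAMES, ScreenConfig
from .io_metadata import LabelComparison, normalize_binomial
from .markers import MarkerFragment
from .trees import PlacementSummary

VERDICTS = (
    "authentic",
    "misidentification",
    "chimera",
    "seq_errors_numts",
    "incorrect_assembly",
    "mislabeled_in_paper",
    "mislabeled_on_genbank",
    "could_not_be_verified",
)

PROBLEM_VERDICTS = frozenset(VERDICTS[1:-1])


@dataclass
class MarkerSymptoms:
    marker_name: str
    s1_indels: bool = False
    s2_close_match_outside: bool = False
    s4_long_branch_in_clade: bool = False
    s5_deep_divergence_outside: bool = False
    s6_distant_no_close_match: bool = False
    s7_sister_on_long_branch: bool = False
    quantities: dict = field(default_factory=dict)

    def fired(self) -> list[str]:
        codes = []
        for code, val in (("S1", self.s1_indels), ("S2", self.s2_close_match_outside),
                          ("S4", self.s4_long_branch_in_clade),
                          ("S5", self.s5_deep_divergence_outside),
                          ("S6", self.s6_distant_no_close_match),
                          ("S7", self.s7_sister_on_long_branch)):
            if val:
                codes.append(code)
        return codes


@dataclass
class SymptomSet:
    """All symptoms of one query, per marker plus the cross-marker S3."""

    accession: str
    per_marker: dict[str, MarkerSymptoms]
    s3_tree_mismatch: bool = False
    s3_detail: dict = field(default_factory=dict)
    placements: dict[str, PlacementSummary] = field(default_factory=dict)

    @property
    def any_symptom(self) -> bool:
        return self.s3_tree_mismatch or any(
            ms.fired() for ms in self.per_marker.values()
        )

    def fired(self) -> list[str]:
        codes = [f"{c}@{m}" for m, ms in sorted(self.per_marker.items())
                 for c in ms.fired()]
        if self.s3_tree_mismatch:
            codes.append("S3")
        return codes


@dataclass
class Diagnosis:
    accession: str
    verdict: str
    rationale: list[str] = field(default_factory=list)
    fired_symptoms: list[str] = field(default_factory=list)
    hybrid_note: bool = False
    chimera_report: ChimeraReport | None = None
    confidence_notes: list[str] = field(default_factory=list)
    species_on_record: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def detect_symptoms(
    placements: Mapping[str, PlacementSummary],
    indels: Mapping[str, IndelReport],
    config: ScreenConfig = DEFAULT_CONFIG,
    synonym_map: Mapping[str, str] | None = None,
) -> SymptomSet:
    """Evaluate S1-S7 for one query from its per-marker evidence."""
    if not placements:
        raise ValueError("need at least one usable marker")
    qlabel = next(iter(placements.values())).query_label
    accession = qlabel.split("|", 1)[1] if "|" in qlabel else qlabel
    per_marker: dict[str, MarkerSymptoms] = {}
    for marker, p in placements.items():
        ms = MarkerSymptoms(marker_name=marker)
        rep = indels.get(marker)
        if rep is not None and rep.evaluable:
            ms.s1_indels = rep.indel_events >= config.multiple_indel_min
            if ms.s1_indels:
                ms.quantities["indel_events"] = rep.indel_events
                ms.quantities["frameshift"] = rep.frameshift
        outside = p.inside_conspecific_clade is False
        if outside and p.nearest_hetero_distance is not None:
            ms.s2_close_match_outside = p.nearest_hetero_distance <= config.tau_close
            if ms.s2_close_match_outside:
                ms.quantities["close_match"] = (p.nearest_hetero_species,
                                                p.nearest_hetero_distance)
        if (p.inside_conspecific_clade and p.conspecific_median_terminal is not None):
            threshold = config.theta_lb * max(p.conspecific_median_terminal,
                                              config.lb_floor)
            ms.s4_long_branch_in_clade = p.terminal_branch > threshold
            if ms.s4_long_branch_in_clade:
                ms.quantities["terminal_branch"] = p.terminal_branch
                ms.quantities["long_branch_threshold"] = threshold
        if outside and p.nearest_conspecific_distance is not None:
            hetero_close = (p.nearest_hetero_distance is not None
                            and p.nearest_hetero_distance <= config.tau_close)
            ms.s5_deep_divergence_outside = (
                p.nearest_conspecific_distance > config.tau_deep and not hetero_close
            )
            if ms.s5_deep_divergence_outside:
                ms.quantities["conspecific_distance"] = p.nearest_conspecific_distance
        ms.s6_distant_no_close_match = p.nearest_distance > config.tau_noid
        if ms.s6_distant_no_close_match:
            ms.quantities["nearest_distance"] = p.nearest_distance
        if outside:
            ms.s7_sister_on_long_branch = (
                p.sister_branch > config.theta_lb
                * max(p.tree_median_terminal, config.lb_floor)
            )
            if ms.s7_sister_on_long_branch:
                ms.quantities["sister_branch"] = p.sister_branch
        per_marker[marker] = ms

    symptoms = SymptomSet(accession=accession, per_marker=per_marker,
                          placements=dict(placements))
    if len(placements) >= 2:
        nearest = {
            m: normalize_binomial(p.nearest_species, synonym_map)
            for m, p in placements.items()
        }
        if len(set(nearest.values())) > 1:
            symptoms.s3_tree_mismatch = True
            symptoms.s3_detail = nearest
    return symptoms


def _trees_support(
    placements: Mapping[str, PlacementSummary],
    name_norm: str,
    config: ScreenConfig,
    synonym_map: Mapping[str, str] | None,
) -> bool:
    """All usable markers put the query closest to ``name_norm``, closely."""
    return all(
        normalize_binomial(p.nearest_species, synonym_map) == name_norm
        and p.nearest_distance <= config.tau_close
        for p in placements.values()
    )


def diagnose(
    symptoms: SymptomSet,
    chimera: ChimeraReport | None,
    labels: LabelComparison,
    resolutions: Mapping[str, bool],
    hybrid_pairs: set[frozenset[str]] | None = None,
    config: ScreenConfig = DEFAULT_CONFIG,
    duplications: Mapping[str, tuple[int, int]] | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> Diagnosis:
    """Combine all evidence for one accession into a single verdict.

    The first matching rule wins; every fired symptom stays in the
    rationale so mixed cases keep their secondary evidence visible.
    """
    if chimera is not None and chimera.accession != symptoms.accession:
        raise ValueError(
            f"chimera report is for {chimera.accession!r}, "
            f"not {symptoms.accession!r}"
        )
    placements = symptoms.placements
    fired = symptoms.fired()
    labeled_norm = normalize_binomial(
        next(iter(placements.values())).query_label.split("|", 1)[0].replace("_", " "),
        synonym_map,
    )

    def result(verdict: str, why: str, **kwargs) -> Diagnosis:
        return Diagnosis(
            accession=symptoms.accession,
            verdict=verdict,
            rationale=[why] + [f"symptom {c}" for c in fired],
            fired_symptoms=fired,
            species_on_record=labels.normalized_on_record,
            **kwargs,
        )

    # (1) unresolvable references, nothing suspicious
    usable = list(placements)
    all_unresolved = usable and all(not resolutions.get(m, True) for m in usable)
    if all_unresolved and not symptoms.any_symptom:
        return result("could_not_be_verified",
                      "reference sequences unresolved in every usable marker")

    # (2) record/paper label mismatch, adjudicated by the trees
    if not labels.names_agree and not labels.no_paper_label:
        if _trees_support(placements, labels.normalized_in_paper, config, synonym_map):
            return result("mislabeled_on_genbank",
                          "names differ and gene trees support the name in the paper")
        if _trees_support(placements, labels.normalized_on_record, config, synonym_map):
            return result("mislabeled_in_paper",
                          "names differ and gene trees support the name on the record")

    # (3) different species closely match different regions: chimera.
    # Closeness matters: a donor fragment matches its true species at the
    # intraspecific scale, whereas an error/numt-divergent region "wins"
    # some species only at a large distance and must not count.
    close_het = []
    native_winners: set[str] = set()
    dup_spans = list((duplications or {}).values())

    def _explained_by_duplication(seg) -> bool:
        # apparent foreign windows inside a self-duplicated span are the
        # duplicate aligning against other species' copies of the same gene
        return any(min(seg.end, e) - max(seg.start, s) > 0.5 * seg.length
                   for s, e in dup_spans)

    if chimera is not None:
        close_het = [s for s in chimera.segments
                     if s.is_heterospecific
                     and s.mean_window_distance <= config.tau_close
                     and not _explained_by_duplication(s)]
        native_winners = {normalize_binomial(s.assigned_species)
                          for s in chimera.segments if not s.is_heterospecific}
    region_winners = native_winners | {normalize_binomial(s.assigned_species)
                                       for s in close_het}
    if chimera is not None and close_het and len(region_winners) >= 2:
        note = []
        if chimera.possible_misidentified_source:
            note = ["possible misidentified source specimen"]
        return Diagnosis(
            accession=symptoms.accession,
            verdict="chimera",
            rationale=["different fragments closely match different species"]
            + [f"symptom {c}" for c in fired],
            fired_symptoms=fired,
            chimera_report=chimera,
            confidence_notes=note,
            species_on_record=labels.normalized_on_record,
        )

    # (4) self-duplicated / displaced fragment: incorrect assembly
    if duplications:
        spans = ", ".join(f"{m}:{s}-{e}" for m, (s, e) in sorted(duplications.items()))
        return result("incorrect_assembly",
                      f"partial duplication detected by self-comparison ({spans})")

    # (5) multiple indels, or divergent sequence matching no species
    s1_markers = [m for m, ms in symptoms.per_marker.items() if ms.s1_indels]
    s6_markers = [m for m, ms in symptoms.per_marker.items()
                  if ms.s6_distant_no_close_match]
    if s1_markers:
        return result("seq_errors_numts",
                      f"multiple indel events in {', '.join(sorted(s1_markers))}")
    if s6_markers:
        return result("seq_errors_numts",
                      "divergent sequence without a close match to any species "
                      f"({', '.join(sorted(s6_markers))})")

    # (6) same wrong species in every usable marker, no long branch
    nearest = {m: normalize_binomial(p.nearest_species, synonym_map)
               for m, p in placements.items()}
    same_wrong = (
        len(set(nearest.values())) == 1
        and next(iter(nearest.values())) != labeled_norm
        and all(p.nearest_distance <= config.tau_close for p in placements.values())
        and not any(ms.s4_long_branch_in_clade for ms in symptoms.per_marker.values())
    )
    if same_wrong:
        matched = next(iter(nearest.values()))
        hybrid = bool(hybrid_pairs) and frozenset({labeled_norm, matched}) in hybrid_pairs
        return result(
            "misidentification",
            f"same incorrect position ({matched}) in all gene trees, no long branch",
            hybrid_note=hybrid,
        )

    # (7) nothing fired: authentic; otherwise leave for manual review
    if not symptoms.any_symptom:
        return Diagnosis(accession=symptoms.accession, verdict="authentic",
                         species_on_record=labels.normalized_on_record)
    return result("could_not_be_verified",
                  "symptoms fired but no diagnosis rule applied; manual review")


# ---------------------------------------------------------------------------
# cohort summaries


def percent(n: float, d: float, digits: int = 1) -> float:
    """Printed-style percentage of n/d rounded to ``digits`` decimals."""
    if d == 0:
        raise ZeroDivisionError("empty denominator")
    return round(100.0 * n / d, digits)


@dataclass
class CohortSummary:
    n: int
    verdict_counts: dict[str, int]
    symptom_counts: dict[str, int]
    n_verifiable: int
    n_problematic: int
    percent_problematic: float | None
    n_problem_species: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v, self.verdict_counts.get(v, 0)) for v in VERDICTS],
            columns=["verdict", "count"],
        )


def summarize_cohort(diagnoses: Iterable[Diagnosis]) -> CohortSummary:
    """Verdict/symptom tallies and the problematic rate among verifiable records."""
    diagnoses = list(diagnoses)
    if not diagnoses:
        raise ValueError("no diagnoses to summarize")
    verdicts: dict[str, int] = {}
    symptoms: dict[str, int] = {}
    species: set[str] = set()
    for d in diagnoses:
        verdicts[d.verdict] = verdicts.get(d.verdict, 0) + 1
        for code in d.fired_symptoms:
            base = code.split("@")[0]
            symptoms[base] = symptoms.get(base, 0) + 1
        if d.verdict in PROBLEM_VERDICTS:
            species.add(d.species_on_record)
    n = len(diagnoses)
    n_verifiable = n - verdicts.get("could_not_be_verified", 0)
    n_problem = sum(c for v, c in verdicts.items() if v in PROBLEM_VERDICTS)
    pct = percent(n_problem, n_verifiable) if n_verifiable else None
    return CohortSummary(
        n=n,
        verdict_counts=verdicts,
        symptom_counts=symptoms,
        n_verifiable=n_verifiable,
        n_problematic=n_problem,
        percent_problematic=pct,
        n_problem_species=len(species),
    )


def compare_strata(
    problematic_a: int, total_a: int, problematic_b: int, total_b: int
) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 table of
    problematic vs fine counts in two strata.  Returns (statistic, p)."""
    table = [
        [problematic_a, total_a - problematic_a],
        [problematic_b, total_b - problematic_b],
    ]
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# single-marker counterfactual


@dataclass
class RecordEvidence:
    """Everything the diagnosis needs for one accession, kept per marker so
    the single-marker counterfactual can re-diagnose from partial evidence."""

    accession: str
    labels: LabelComparison
    placements: dict[str, PlacementSummary]
    indels: dict[str, IndelReport]
    resolutions: dict[str, bool]
    fragments: dict[str, MarkerFragment]
    chimera: ChimeraReport | None = None
    duplications: dict[str, tuple[int, int]] | None = None


def diagnose_record(
    ev: RecordEvidence,
    config: ScreenConfig = DEFAULT_CONFIG,
    hybrid_pairs: set[frozenset[str]] | None = None,
    synonym_map: Mapping[str, str] | None = None,
    restrict_to_marker: str | None = None,
) -> Diagnosis:
    """Diagnose one record, optionally using a single marker's evidence only.

    In single-marker mode the chimera evidence is clipped to that marker's
    span on the query: a chimera whose breakpoints all lie outside the
    marker collapses to a single-species region and cannot be recognized as
    a chimera from that marker alone — exactly the failure mode that makes
    single-marker screening miss most chimeras.
    """
    placements, indels, resolutions = ev.placements, ev.indels, ev.resolutions
    chimera, duplications = ev.chimera, ev.duplications
    if restrict_to_marker is not None:
        m = restrict_to_marker
        if m not in placements:
            raise KeyError(f"marker {m} not usable for {ev.accession}")
        placements = {m: placements[m]}
        indels = {k: v for k, v in indels.items() if k == m}
        resolutions = {k: v for k, v in resolutions.items() if k == m}
        duplications = {k: v for k, v in (duplications or {}).items() if k == m} or None
        chimera = _clip_chimera(chimera, ev.fragments.get(m)) if chimera else None
    symptoms = detect_symptoms(placements, indels, config, synonym_map)
    return diagnose(symptoms, chimera, ev.labels, resolutions,
                    hybrid_pairs=hybrid_pairs, config=config,
                    duplications=duplications, synonym_map=synonym_map)


def _clip_chimera(report: ChimeraReport, fragment: MarkerFragment | None) -> ChimeraReport | None:
    if fragment is None:
        return None
    lo, hi = fragment.start, fragment.end
    clipped = []
    for seg in report.segments:
        s, e = max(seg.start, lo), min(seg.end, hi)
        if e > s:
            clipped.append(ChimeraSegment(
                start=s, end=e,
                assigned_species=seg.assigned_species,
                is_heterospecific=seg.is_heterospecific,
                divergence_from_authentic=seg.divergence_from_authentic,
                mean_window_distance=seg.mean_window_distance,
                n_windows=seg.n_windows,
            ))
    merged: list[ChimeraSegment] = []
    for seg in clipped:
        if merged and merged[-1].assigned_species == seg.assigned_species:
            prev = merged[-1]
            w = prev.length + seg.length
            prev.mean_window_distance = (
                prev.mean_window_distance * prev.length
                + seg.mean_window_distance * seg.length
            ) / max(w, 1)
            prev.end = seg.end
        else:
            merged.append(seg)
    out = ChimeraReport(accession=report.accession,
                        labeled_species=report.labeled_species, segments=merged)
    if merged and all(s.is_heterospecific for s in merged):
        out.possible_misidentified_source = True
    return out


def single_marker_detectability(
    evidence: Iterable[RecordEvidence],
    reference_diagnoses: Mapping[str, str],
    config: ScreenConfig = DEFAULT_CONFIG,
    hybrid_pairs: set[frozenset[str]] | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """How many problems each marker would detect on its own.

    ``reference_diagnoses`` maps accession to the class assigned with all
    markers (or the ground truth).  Returns one row per (marker, class):
    ``detected_count`` of records of that class whose single-marker verdict
    matches it, the class ``total``, and ``called_misidentification`` — the
    number of that class's records the single marker would miscall as a
    misidentification.
    """
    evidence = list(evidence)
    rows = []
    classes = sorted(set(reference_diagnoses.values()) & PROBLEM_VERDICTS)
    for marker in MARKER_NAMES:
        for cls in classes:
            members = [ev for ev in evidence
                       if reference_diagnoses.get(ev.accession) == cls]
            detected = miscalled = 0
            total = 0
            for ev in members:
                if marker not in ev.placements:
                    continue
                total += 1
                verdict = diagnose_record(ev, config, hybrid_pairs, synonym_map,
                                          restrict_to_marker=marker).verdict
                if verdict == cls:
                    detected += 1
                elif verdict == "misidentification":
                    miscalled += 1
            rows.append({"marker": marker, "class": cls,
                         "detected_count": detected, "total": total,
                         "called_misidentification": miscalled})
    return pd.DataFrame(rows)
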