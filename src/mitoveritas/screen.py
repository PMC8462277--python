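"""End-to-end authentication screen: model and results objects.

:class:`MitogenomeScreen` is built from query records plus a reference
panel; :meth:`MitogenomeScreen.fit` runs the full pipeline — candidate
filtering, marker extraction, per-marker alignment, per-query
neighbor-joining placement, indel and self-duplication scans, chimera
localization for flagged records, and the diagnosis rules — and returns a
:class:`ScreenResults` carrying per-record diagnoses, the evidence behind
them, and cohort summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .align import MarkerAlignment, align_marker, detect_indels, pdist_matrix
from .chimera import analyze_chimera
from .config import DEFAULT_CONFIG, MARKER_NAMES, ScreenConfig
from .diagnosis import (
    Diagnosis,
    RecordEvidence,
    CohortSummary,
    diagnose_record,
    single_marker_detectability,
    summarize_cohort,
)
from .io_metadata import (
    FilterReport,
    MitogenomeRecord,
    compare_labels,
    filter_candidates,
    load_hybrid_pairs,
    load_records,
    load_synonym_map,
    normalize_binomial,
)
from .markers import MarkerFragment, MarkerProfile, extract_all, find_duplicated_span, load_marker_panel
from .trees import GeneTree, make_label, nj_tree, place_query, species_of

log = logging.getLogger(__name__)


class MitogenomeScreen:
    """Authentication screen over a set of query mitogenomes.

    Parameters
    ----------
    records
        Query mitogenomes with metadata.
    marker_profiles
        Reference marker panel, one profile per marker.
    genome_panel
        Whole reference mitogenomes ``(species, sequence)`` used for
        chimera localization.
    synonym_map, hybrid_pairs
        Optional taxonomy helpers: old-name to canonical-name map, and
        species pairs known to hybridize (annotates, never changes, a
        misidentification verdict).
    config
        Decision thresholds; see :class:`~mitoveritas.config.ScreenConfig`.
    """

    def __init__(
        self,
        records: list[MitogenomeRecord],
        marker_profiles: dict[str, MarkerProfile],
        genome_panel: list[tuple[str, str]],
        synonym_map: Mapping[str, str] | None = None,
        hybrid_pairs: set[frozenset[str]] | None = None,
        config: ScreenConfig = DEFAULT_CONFIG,
    ) -> None:
        self.records = records
        self.marker_profiles = marker_profiles
        self.genome_panel = genome_panel
        self.synonym_map = dict(synonym_map) if synonym_map else None
        self.hybrid_pairs = hybrid_pairs or set()
        self.config = config

    @classmethod
    def from_files(
        cls,
        queries: str | Path,
        metadata: str | Path,
        marker_panel: str | Path,
        genome_panel: str | Path,
        synonyms: str | Path | None = None,
        hybrids: str | Path | None = None,
        config: ScreenConfig = DEFAULT_CONFIG,
    ) -> "MitogenomeScreen":
        from Bio import SeqIO

        records = load_records(queries, metadata)
        profiles = load_marker_panel(str(marker_panel))
        genomes = []
        for rec in SeqIO.parse(str(genome_panel), "fasta"):
            species = rec.id.split("|")[0].replace("_", " ")
            genomes.append((species, str(rec.seq).upper()))
        return cls(
            records,
            profiles,
            genomes,
            synonym_map=load_synonym_map(synonyms) if synonyms else None,
            hybrid_pairs=load_hybrid_pairs(hybrids) if hybrids else None,
            config=config,
        )

    @classmethod
    def from_cohort(cls, cohort, config: ScreenConfig = DEFAULT_CONFIG) -> "MitogenomeScreen":
        """Build a screen directly from a simulated cohort."""
        return cls(
            cohort.records,
            cohort.panel.marker_profiles(),
            cohort.panel.genome_panel(),
            hybrid_pairs=cohort.hybrid_pairs,
            config=config,
        )

    # ------------------------------------------------------------------

    def fit(self) -> "ScreenResults":
        cfg = self.config
        filter_report = filter_candidates(self.records, cfg.min_len, cfg.max_len)
        retained = {a for a in filter_report.retained}
        screened = [r for r in self.records if r.accession in retained]

        # reference rows per marker, aligned once; queries are appended rows
        ref_rows: dict[str, list[tuple[str, str]]] = {}
        for marker, profile in self.marker_profiles.items():
            ref_rows[marker] = [
                (make_label(sp, f"ref{i}"), seq)
                for i, (sp, seq) in enumerate(profile.reference_seqs)
            ]

        fragments: dict[str, dict[str, MarkerFragment]] = {}
        not_assessed: list[str] = []
        query_rows: dict[str, list[tuple[str, str]]] = {m: [] for m in self.marker_profiles}
        labels_by_acc: dict[str, str] = {}
        for rec in screened:
            found = extract_all(rec, self.marker_profiles, cfg.min_identity)
            usable = {m: f for m, f in found.items() if f is not None and f.usable}
            fragments[rec.accession] = usable
            if not usable:
                not_assessed.append(rec.accession)
                continue
            qlabel = make_label(rec.species_on_record, rec.accession)
            labels_by_acc[rec.accession] = qlabel
            for m, frag in usable.items():
                query_rows[m].append((qlabel, frag.extracted_seq))

        alignments: dict[str, MarkerAlignment] = {}
        ref_dists: dict[str, np.ndarray] = {}
        for marker in self.marker_profiles:
            rows = ref_rows[marker] + query_rows[marker]
            if len(rows) < 2:
                continue
            alignments[marker] = align_marker(rows, marker_name=marker)
            n_ref = len(ref_rows[marker])
            all_dists = pdist_matrix([s for _, s in alignments[marker].rows])
            ref_dists[marker] = all_dists

        evidence: list[RecordEvidence] = []
        diagnoses: list[Diagnosis] = []
        for rec in screened:
            if rec.accession in not_assessed:
                continue
            qlabel = labels_by_acc[rec.accession]
            placements = {}
            indels = {}
            resolutions = {}
            for marker, frag in fragments[rec.accession].items():
                aln = alignments[marker]
                labels = aln.labels
                n_ref = len(ref_rows[marker])
                qi = labels.index(qlabel)
                idx = list(range(n_ref)) + [qi]
                sub = ref_dists[marker][np.ix_(idx, idx)]
                if np.isnan(sub).any():
                    log.warning("%s/%s: incomparable rows, marker skipped",
                                rec.accession, marker)
                    continue
                tree = nj_tree(sub, [labels[i] for i in idx], marker_name=marker)
                placement = place_query(tree, aln, qlabel)
                placements[marker] = placement
                resolutions[marker] = placement.reference_resolved
                conspecific = [
                    lbl for lbl, _ in ref_rows[marker]
                    if normalize_binomial(species_of(lbl))
                    == normalize_binomial(rec.species_on_record)
                ]
                fallback = False
                if not conspecific:
                    genus = normalize_binomial(rec.species_on_record).split()[0]
                    conspecific = [
                        lbl for lbl, _ in ref_rows[marker]
                        if normalize_binomial(species_of(lbl)).split()[0] == genus
                    ]
                    fallback = True
                indels[marker] = detect_indels(aln, qlabel, conspecific,
                                               used_fallback_rows=fallback)
            if not placements:
                not_assessed.append(rec.accession)
                continue

            duplications: dict[str, tuple[int, int]] = {}
            for marker, frag in fragments[rec.accession].items():
                span = find_duplicated_span(
                    rec.sequence, frag, probe=cfg.dup_window,
                    max_dist=cfg.dup_max_dist, min_hits=cfg.dup_min_hits)
                if span is not None:
                    duplications[marker] = span

            label_cmp = compare_labels(rec, self.synonym_map)
            ev = RecordEvidence(
                accession=rec.accession,
                labels=label_cmp,
                placements=placements,
                indels=indels,
                resolutions=resolutions,
                fragments=fragments[rec.accession],
                duplications=duplications or None,
            )
            from .diagnosis import detect_symptoms

            symptoms = detect_symptoms(placements, indels, cfg, self.synonym_map)
            needs_chimera_scan = (
                symptoms.any_symptom or not label_cmp.names_agree or duplications
            )
            if needs_chimera_scan:
                ev.chimera = analyze_chimera(
                    rec, self.genome_panel, window=cfg.window, step=cfg.step,
                    min_run=cfg.min_run)
            diagnoses.append(diagnose_record(ev, cfg, self.hybrid_pairs,
                                             self.synonym_map))
            evidence.append(ev)

        # one cohort-wide tree per marker (references + every usable query)
        cohort_trees: dict[str, GeneTree] = {}
        for marker, aln in alignments.items():
            if len(aln.rows) >= 3 and not np.isnan(ref_dists[marker]).any():
                cohort_trees[marker] = nj_tree(ref_dists[marker], aln.labels,
                                               marker_name=marker)

        return ScreenResults(
            model=self,
            filter_report=filter_report,
            diagnoses=diagnoses,
            evidence=evidence,
            not_assessed=not_assessed,
            alignments=alignments,
            cohort_trees=cohort_trees,
        )


@dataclass
class ScreenResults:
    """Fitted screen: per-record diagnoses plus the evidence behind them."""

    model: MitogenomeScreen
    filter_report: FilterReport
    diagnoses: list[Diagnosis]
    evidence: list[RecordEvidence]
    not_assessed: list[str]
    alignments: dict[str, MarkerAlignment] = field(default_factory=dict)
    cohort_trees: dict[str, GeneTree] = field(default_factory=dict)

    def placements_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.evidence:
            for marker, p in ev.placements.items():
                rows.append({
                    "accession": ev.accession,
                    "marker": marker,
                    "inside_conspecific_clade": p.inside_conspecific_clade,
                    "nearest_species": p.nearest_species,
                    "nearest_distance": round(p.nearest_distance, 6),
                    "terminal_branch": round(p.terminal_branch, 6),
                    "conspecific_median_terminal": (
                        None if p.conspecific_median_terminal is None
                        else round(p.conspecific_median_terminal, 6)),
                    "sister_branch": round(p.sister_branch, 6),
                    "reference_resolved": p.reference_resolved,
                })
        return pd.DataFrame(rows)

    def fragments_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.evidence:
            for marker, f in sorted(ev.fragments.items()):
                rows.append({
                    "accession": ev.accession, "marker": marker,
                    "start": f.start, "end": f.end, "strand": f.strand,
                    "identity": round(f.identity_to_locator, 4),
                    "usable": f.usable,
                })
        return pd.DataFrame(rows)

    @property
    def cohort_summary(self) -> CohortSummary:
        return summarize_cohort(self.diagnoses)

    def verdicts(self) -> dict[str, str]:
        return {d.accession: d.verdict for d in self.diagnoses}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.diagnoses:
            rows.append({
                "accession": d.accession,
                "species": d.species_on_record,
                "verdict": d.verdict,
                "symptoms": ";".join(d.fired_symptoms),
                "hybrid_note": d.hybrid_note,
                "rationale": " | ".join(d.rationale),
            })
        return pd.DataFrame(rows, columns=["accession", "species", "verdict",
                                           "symptoms", "hybrid_note", "rationale"])

    def single_marker_detectability(
        self, reference: Mapping[str, str] | None = None
    ) -> pd.DataFrame:
        """Per-marker counterfactual detection counts.

        ``reference`` maps accession to class; defaults to this screen's
        own all-marker verdicts.
        """
        ref = dict(reference) if reference is not None else self.verdicts()
        return single_marker_detectability(
            self.evidence, ref, self.model.config,
            self.model.hybrid_pairs, self.model.synonym_map)

    def summary(self) -> str:
        s = self.cohort_summary
        lines = [
            "Mitogenome authentication screen",
            "=" * 40,
            f"queries screened      : {s.n}",
            f"not assessed          : {len(self.not_assessed)}",
            f"excluded by filters   : {len(self.filter_report.excluded)}",
            f"verifiable            : {s.n_verifiable}",
            f"problematic           : {s.n_problematic}"
            + (f" ({s.percent_problematic}% of verifiable)"
               if s.percent_problematic is not None else ""),
            f"species with problems : {s.n_problem_species}",
            "",
            "verdict counts",
            "-" * 40,
        ]
        for verdict, count in sorted(s.verdict_counts.items(),
                                     key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"  {verdict:<24s}{count:>5d}")
        if s.symptom_counts:
            lines += ["", "symptom counts (flagged records)", "-" * 40]
            for code, count in sorted(s.symptom_counts.items()):
                lines.append(f"  {code:<24s}{count:>5d}")
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "diagnoses.tsv", sep="\t", index=False)
        self.filter_report.write_tsv(outdir / "filter_report.tsv")
        self.placements_frame().to_csv(outdir / "placements.tsv", sep="\t",
                                       index=False)
        self.fragments_frame().to_csv(outdir / "fragments.tsv", sep="\t",
                                      index=False)
        for marker, tree in self.cohort_trees.items():
            (outdir / f"gene_tree_{marker}.nwk").write_text(tree.newick + "\n")
        chimera_rows = []
        per_record = {}
        for d in self.diagnoses:
            entry = {
                "verdict": d.verdict,
                "rationale": d.rationale,
                "fired_symptoms": d.fired_symptoms,
                "hybrid_note": d.hybrid_note,
                "confidence_notes": d.confidence_notes,
            }
            if d.chimera_report is not None:
                entry["chimera"] = d.chimera_report.to_rows()
                chimera_rows.extend(d.chimera_report.to_rows())
            per_record[d.accession] = entry
        with open(outdir / "diagnoses.json", "w") as fh:
            json.dump(per_record, fh, indent=2, sort_keys=True)
        if chimera_rows:
            pd.DataFrame(chimera_rows).to_csv(outdir / "chimera_segments.tsv",
                                              sep="\t", index=False)
        (outdir / "summary.txt").write_text(self.summary() + "\n")
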