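"""Marker alignments, p-distances and indel detection.

Marker fragments are aligned with a deterministic anchored-star strategy:
every row is pairwise-aligned to the first sequence (the anchor) under an
affine gap penalty (match +1, mismatch -1, gap open -5, extend -2, end gaps
free), and insertion columns relative to the anchor are merged across rows.
The stiff gap penalty matters: a plain edit-distance alignment happily
trades two substitutions for an insertion-deletion pair at equal cost,
planting phantom indels in divergent but colinear sequences.  For
protein-coding mitochondrial markers — nearly colinear, indel-poor — the
star alignment reproduces what a progressive aligner finds,
deterministically.

Distances are uncorrected p-distances: the proportion of differing sites
among comparable positions, where a comparable position has an unambiguous
A/C/G/T in both rows.  At the divergences involved (up to ~25%) the ranking
of neighbours, which is all the screen consumes, is insensitive to the
choice of distance correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align

_ACGT = set("ACGT")
_IUPAC = set("ACGTRYSWKMBDHVN")
_GAP = "-"

#: Column-consensus tie-break order: bases alphabetically, gap last.
_SYMBOL_ORDER = {s: i for i, s in enumerate("ACGT-")}


@dataclass
class MarkerAlignment:
    """A gapped multiple alignment of one marker's fragments."""

    marker_name: str
    rows: list[tuple[str, str]]  # (label, gapped sequence)

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def labels(self) -> list[str]:
        return [lbl for lbl, _ in self.rows]

    def row(self, label: str) -> str:
        for lbl, seq in self.rows:
            if lbl == label:
                return seq
        raise KeyError(label)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for lbl, seq in self.rows:
                fh.write(f">{lbl}\n{seq}\n")


@dataclass
class IndelReport:
    """Indel events of one query against its conspecific consensus."""

    accession: str
    marker_name: str
    indel_events: int = 0
    total_gap_columns: int = 0
    frameshift: bool = False
    evaluable: bool = True
    used_fallback_rows: bool = False


def _validate(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    # end gaps pay one opening but extend freely: truncated fragments are
    # cheap, while sliding a colinear row to dodge an internal gap is not
    aligner.open_end_gap_score = -5
    aligner.extend_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def _align_to_anchor(row: str, anchor: str) -> tuple[list[str], dict[int, str]]:
    """Map one row onto anchor coordinates.

    Returns (per-anchor-position characters, insertions keyed by the anchor
    position they precede).  Anchor positions not covered by the row (end
    truncation) are gaps.
    """
    alignment = _ALIGNER.align(anchor, row)[0]
    blocks_a, blocks_r = alignment.aligned
    aligned = [_GAP] * len(anchor)
    insertions: dict[int, str] = {}
    prev_r_end = 0
    prev_a_end = 0
    for (a0, a1), (r0, r1) in zip(blocks_a, blocks_r):
        if r0 > prev_r_end:  # row-only bases: insertion before anchor col a0
            insertions[a0] = insertions.get(a0, "") + row[prev_r_end:r0]
        aligned[a0:a1] = row[r0:r1]
        prev_r_end = r1
    if len(row) > prev_r_end:  # trailing row overhang
        insertions[len(anchor)] = insertions.get(len(anchor), "") + row[prev_r_end:]
    return aligned, insertions


def align_marker(
    fragments: list[tuple[str, str]] | list[str],
    marker_name: str = "",
) -> MarkerAlignment:
    """Anchored-star multiple alignment of marker fragments.

    The first sequence anchors the column space; deterministic for a fixed
    input order, and ungapping any row reproduces its input sequence.
    """
    if len(fragments) < 2:
        raise ValueError("need at least 2 sequences to align")
    if isinstance(fragments[0], str):
        fragments = [(f"seq{i}", s) for i, s in enumerate(fragments)]  # type: ignore[assignment]
    labels = [lbl for lbl, _ in fragments]
    seqs = [_validate(s) for _, s in fragments]

    anchor = seqs[0]
    per_row: list[tuple[list[str], dict[int, str]]] = [
        (list(anchor), {})
    ]
    for s in seqs[1:]:
        per_row.append(_align_to_anchor(s, anchor))

    insert_width = [0] * (len(anchor) + 1)
    for _, ins in per_row:
        for pos, text in ins.items():
            insert_width[pos] = max(insert_width[pos], len(text))

    rows_out: list[tuple[str, str]] = []
    for label, (aligned, ins) in zip(labels, per_row):
        parts: list[str] = []
        for j in range(len(anchor) + 1):
            if insert_width[j]:
                text = ins.get(j, "")
                parts.append(text + _GAP * (insert_width[j] - len(text)))
            if j < len(anchor):
                parts.append(aligned[j])
        rows_out.append((label, "".join(parts)))
    return MarkerAlignment(marker_name=marker_name, rows=rows_out)


def p_distance(a: str, b: str) -> float | None:
    """Uncorrected distance over comparable (both-unambiguous, ungapped) sites.

    ``None`` when no site is comparable — deliberately not 0, since absence
    of evidence for divergence is not evidence of identity.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned length mismatch: {len(a)} vs {len(b)}")
    comparable = mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _ACGT and y in _ACGT:
            comparable += 1
            if x != y:
                mismatches += 1
    if comparable == 0:
        return None
    return mismatches / comparable


def pdist_matrix(rows: list[str]) -> np.ndarray:
    """All-pairs p-distance for equal-length gapped rows (vectorized).

    Pairs with no comparable sites get ``nan``.
    """
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)
    ok = (arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T")
    n = len(rows)
    out = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok
        comp = both.sum(axis=1)
        diff = ((arr[i] != arr) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[i] = np.where(comp > 0, diff / np.maximum(comp, 1), np.nan)
    np.fill_diagonal(out, 0.0)
    return out


def column_consensus(rows: list[str]) -> str:
    """Majority symbol per column over A/C/G/T/gap; ambiguity codes do not
    vote.  Ties break alphabetically with bases preferred over gaps."""
    length = len(rows[0])
    out = []
    for j in range(length):
        counts: dict[str, int] = {}
        for r in rows:
            c = r[j]
            if c in _ACGT or c == _GAP:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("N")
            continue
        best = sorted(counts.items(), key=lambda kv: (-kv[1], _SYMBOL_ORDER[kv[0]]))[0][0]
        out.append(best)
    return "".join(out)


def _span(seq: str) -> tuple[int, int]:
    """[first, last+1) non-gap columns of a gapped row."""
    first = next((i for i, c in enumerate(seq) if c != _GAP), 0)
    last = next((i for i in range(len(seq) - 1, -1, -1) if seq[i] != _GAP), -1)
    return first, last + 1


def detect_indels(
    alignment: MarkerAlignment,
    query_label: str,
    conspecific_labels: list[str],
    used_fallback_rows: bool = False,
) -> IndelReport:
    """Count indel events of the query against its conspecific consensus.

    An event is a maximal gap run in either direction (query gap against a
    consensus base = deletion; query base against a consensus gap =
    insertion) inside the region where both query and consensus have
    sequence; alignment-truncation overhangs at either end never count.
    """
    query = alignment.row(query_label)
    comparison = [alignment.row(l) for l in conspecific_labels if l != query_label]
    report = IndelReport(accession=query_label, marker_name=alignment.marker_name,
                         used_fallback_rows=used_fallback_rows)
    if not comparison:
        report.evaluable = False
        return report

    consensus = column_consensus(comparison)
    q0, q1 = _span(query)
    c0, c1 = _span(consensus.replace("N", _GAP))
    lo, hi = max(q0, c0), min(q1, c1)

    events = gap_cols = 0
    ins_len = del_len = 0
    state = "match"
    for j in range(lo, hi):
        qc, cc = query[j], consensus[j]
        if qc == _GAP and cc in _ACGT:
            kind = "del"
        elif qc != _GAP and cc == _GAP:
            kind = "ins"
        else:
            kind = "match"
        if kind != "match":
            gap_cols += 1
            if kind == "del":
                del_len += 1
            else:
                ins_len += 1
            if kind != state:
                events += 1
        state = kind

    report.indel_events = events
    report.total_gap_columns = gap_cols
    report.frameshift = events > 0 and (ins_len - del_len) % 3 != 0
    return report
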