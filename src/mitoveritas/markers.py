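"""Locating the three protein-coding markers in a whole mitogenome.

The screen rests on three mitochondrial protein-coding genes — ND2 (1,041
bp), COI (696 bp) and cytochrome b (1,143 bp) — for which dense reference
panels exist in birds.  A marker is located in a query genome by bit-parallel
infix alignment of each reference marker (both strands) against the query;
the best-identity hit wins.  Queries are circular molecules stored linearly,
so the scan runs over the doubled sequence and coordinates are mapped back
modulo the query length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib

from .config import MARKER_CANONICAL_LENGTH, MARKER_MIN_USABLE_LENGTH, MARKER_NAMES
from .io_metadata import MitogenomeRecord, reverse_complement

log = logging.getLogger(__name__)


@dataclass
class MarkerProfile:
    """Reference sequences for one marker plus its length contract."""

    marker_name: str
    reference_seqs: list[tuple[str, str]]  # (species, sequence)

    def __post_init__(self) -> None:
        if self.marker_name not in MARKER_NAMES:
            raise ValueError(f"unknown marker {self.marker_name!r}")
        self.reference_seqs = [(sp, s.upper()) for sp, s in self.reference_seqs]

    @property
    def canonical_length(self) -> int:
        return MARKER_CANONICAL_LENGTH[self.marker_name]

    @property
    def min_usable_length(self) -> int:
        return MARKER_MIN_USABLE_LENGTH[self.marker_name]


@dataclass
class MarkerFragment:
    """An extracted marker region on the forward strand of the query.

    Coordinates are 0-based half-open.  When the hit spans the circular
    origin, ``wraps_origin`` is set and ``end`` exceeds the query length by
    the wrapped amount (slicing the doubled sequence reproduces the hit).
    """

    accession: str
    marker_name: str
    start: int
    end: int
    strand: str
    extracted_seq: str
    identity_to_locator: float
    usable: bool
    locator_species: str = ""
    wraps_origin: bool = False


def _cigar_columns(cigar: str) -> list[tuple[bool, bool]]:
    """Per-column (is_match, consumes_target) flags from an extended cigar."""
    cols: list[tuple[bool, bool]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols.extend([(ch == "=", ch in "=XD")] * n)
    return cols


def _best_hit(ref: str, target: str) -> tuple[float, float, int, int] | None:
    """Best infix alignment of ref in target.

    Returns ``(full_identity, trimmed_identity, start, end)``.  The full
    identity covers the whole reference alignment and gates whether the hit
    is accepted at all — so a short perfect fluke in unrelated sequence
    cannot pass.  The coordinates and trimmed identity come from the
    maximum-scoring sub-alignment (+1 match, -1 otherwise): when the marker
    copy is truncated, the aligner drags leftover reference bases into
    unrelated flank, and the trim cuts the span back to the homologous
    region.
    """
    res = edlib.align(ref, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    cols = _cigar_columns(res["cigar"])
    full_matches = sum(1 for m, _ in cols if m)
    full_identity = full_matches / len(cols) if cols else 0.0
    # max-scoring window; later start preferred on ties (shortest span)
    best_sum = -1
    best_span = (0, 0)
    running, run_start = 0, 0
    for i, (m, _) in enumerate(cols):
        if running <= 0:
            running, run_start = 0, i
        running += 1 if m else -1
        if running > best_sum:
            best_sum, best_span = running, (run_start, i + 1)
    lo, hi = best_span
    if hi <= lo:
        return None
    matches = sum(1 for m, _ in cols[lo:hi] if m)
    trimmed_identity = matches / (hi - lo)
    t0 = res["locations"][0][0]
    t_start = t0 + sum(1 for _, c in cols[:lo] if c)
    t_end = t0 + sum(1 for _, c in cols[:hi] if c)
    if t_end <= t_start:
        return None
    return full_identity, trimmed_identity, t_start, t_end


def extract_marker(
    query: MitogenomeRecord | str,
    profile: MarkerProfile,
    min_identity: float = 0.60,
    accession: str = "",
) -> MarkerFragment | None:
    """Locate ``profile``'s marker in the query genome.

    Every reference is aligned against the doubled query on both strands and
    the highest-identity hit is kept; ``None`` is returned when the best
    identity falls below ``min_identity`` or the query is shorter than the
    marker's usable floor.  The extracted sequence is reverse-complemented
    for minus-strand hits, so it always reads in the marker's orientation.
    """
    if isinstance(query, MitogenomeRecord):
        seq, accession = query.sequence, query.accession
    else:
        seq = query.upper()
    n = len(seq)
    if n <= profile.min_usable_length:
        log.info("%s: query (%d bp) at or below usable floor for %s",
                 accession, n, profile.marker_name)
        return None
    if not profile.reference_seqs:
        raise ValueError(f"profile {profile.marker_name} has no reference sequences")

    doubled = seq + seq
    best = None  # (full_identity, span, trimmed_identity, strand, start, end, species)
    for species, ref in profile.reference_seqs:
        for strand, oriented in (("+", ref), ("-", reverse_complement(ref))):
            hit = _best_hit(oriented, doubled)
            if hit is None:
                continue
            full_id, trim_id, s, e = hit
            key = (full_id, e - s)
            if best is None or key > (best[0], best[1]):
                best = (full_id, e - s, trim_id, strand, s, e, species)
    if best is None or best[0] < min_identity:
        log.info("%s: no %s hit above identity %.2f", accession,
                 profile.marker_name, min_identity)
        return None

    _, _, identity, strand, start, end, species = best
    if start >= n:
        start, end = start - n, end - n
    wraps = end > n
    extracted = doubled[start:end]
    if strand == "-":
        extracted = reverse_complement(extracted)
    usable = (end - start) > profile.min_usable_length
    return MarkerFragment(
        accession=accession,
        marker_name=profile.marker_name,
        start=start,
        end=end,
        strand=strand,
        extracted_seq=extracted,
        identity_to_locator=identity,
        usable=usable,
        locator_species=species,
        wraps_origin=wraps,
    )


def extract_all(
    query: MitogenomeRecord,
    profiles: dict[str, MarkerProfile],
    min_identity: float = 0.60,
) -> dict[str, MarkerFragment | None]:
    """Extraction attempt for every marker, usable or not."""
    return {
        name: extract_marker(query, profiles[name], min_identity)
        for name in MARKER_NAMES
        if name in profiles
    }


def usable_markers(
    query: MitogenomeRecord,
    profiles: dict[str, MarkerProfile],
    min_identity: float = 0.60,
) -> list[MarkerFragment]:
    """The usable marker fragments of a query (0-3).

    A query with no usable fragment cannot be assessed by the screen.
    """
    if set(profiles) != set(MARKER_NAMES):
        raise ValueError(f"profiles for all of {MARKER_NAMES} are required")
    found = extract_all(query, profiles, min_identity)
    return [f for f in found.values() if f is not None and f.usable]


def find_duplicated_span(
    query_seq: str,
    fragment: MarkerFragment,
    probe: int = 100,
    max_dist: int = 10,
    min_hits: int = 2,
) -> tuple[int, int] | None:
    """Self-comparison scan for a partially duplicated marker.

    Non-overlapping probes of the extracted marker are searched against the
    query with the marker's own location masked out; when ``min_hits`` or
    more probes hit elsewhere within ``max_dist`` edits, the union of hit
    coordinates is returned as the duplicated span.  Incorrectly assembled
    genomes carrying a second partial copy of a gene are caught this way.
    """
    seq = query_seq.upper()
    n = len(seq)
    masked = list(seq + seq[: max(0, fragment.end - n)])
    for i in range(fragment.start, fragment.end):
        masked[i] = "N"
    masked_seq = "".join(masked)[:n]

    frag = fragment.extracted_seq
    hits: list[tuple[int, int]] = []
    for off in range(0, len(frag) - probe + 1, probe):
        res = edlib.align(frag[off : off + probe], masked_seq, mode="HW",
                          task="locations", k=max_dist)
        if res["editDistance"] >= 0 and res["locations"]:
            s, e = res["locations"][0]
            hits.append((s, e + 1))
    if len(hits) < min_hits:
        return None
    return min(s for s, _ in hits), max(e for _, e in hits)


def load_marker_panel(path: str) -> dict[str, MarkerProfile]:
    """Read a marker reference FASTA with ``>Species_binomial|marker|id`` headers."""
    from Bio import SeqIO

    refs: dict[str, list[tuple[str, str]]] = {m: [] for m in MARKER_NAMES}
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2:
            raise ValueError(f"marker panel header {rec.id!r} lacks '|marker|' field")
        species = parts[0].replace("_", " ")
        marker = parts[1].upper()
        if marker not in MARKER_NAMES:
            raise ValueError(f"unknown marker {marker!r} in header {rec.id!r}")
        refs[marker].append((species, str(rec.seq).upper()))
    return {m: MarkerProfile(m, seqs) for m, seqs in refs.items() if seqs}
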