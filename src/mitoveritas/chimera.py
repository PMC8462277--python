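"""Windowed localization of heterospecific fragments in a mitogenome.

A chimeric deposit concatenates DNA of two or more species.  To localize
the foreign material, every reference genome in the panel is projected onto
the query's coordinates by global alignment, and sliding windows over the
query are assigned to the species with the smallest mean p-distance in that
window.  Runs of same-species windows become segments; the breakpoint
between two runs is refined to the base position that maximizes the number
of sites agreeing with the left species' sequence on the left plus those
agreeing with the right species' on the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .io_metadata import MitogenomeRecord, normalize_binomial

_GAP = ord("-")
_BASES = tuple(ord(c) for c in "ACGT")


@dataclass
class WindowAssignment:
    window_start: int
    window_end: int
    best_species: str
    best_distance: float
    second_species: str | None
    second_distance: float | None
    assessable: bool = True
    short_window: bool = False


@dataclass
class ChimeraSegment:
    """A maximal region of the query assigned to one species.

    ``mean_window_distance`` is the mean p-distance between the segment's
    windows and the winning species — near the intraspecific scale for a
    genuine donor fragment, far above it for error/numt-divergent regions
    that match nobody closely.
    """

    start: int
    end: int
    assigned_species: str
    is_heterospecific: bool = False
    divergence_from_authentic: float | None = None
    mean_window_distance: float = 0.0
    n_windows: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_one_based(self) -> tuple[int, int]:
        """1-based inclusive coordinates for human-readable reports."""
        return self.start + 1, self.end


@dataclass
class ChimeraReport:
    accession: str
    labeled_species: str
    segments: list[ChimeraSegment] = field(default_factory=list)
    possible_misidentified_source: bool = False

    @property
    def n_heterospecific_fragments(self) -> int:
        return sum(1 for s in self.segments if s.is_heterospecific)

    @property
    def assessed_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def heterospecific_proportion(self) -> float:
        """Percent of the assessed length assigned to other species."""
        if not self.segments:
            return 0.0
        het = sum(s.length for s in self.segments if s.is_heterospecific)
        return 100.0 * het / self.assessed_length

    @property
    def donor_species(self) -> set[str]:
        return {s.assigned_species for s in self.segments if s.is_heterospecific}

    @property
    def distinct_region_winners(self) -> set[str]:
        return {s.assigned_species for s in self.segments}

    def to_rows(self) -> list[dict]:
        return [
            {
                "accession": self.accession,
                "start": s.start,
                "end": s.end,
                "species": s.assigned_species,
                "heterospecific": s.is_heterospecific,
                "length": s.length,
                "divergence": s.divergence_from_authentic,
            }
            for s in self.segments
        ]


def project_onto(query_seq: str, panel_seq: str) -> np.ndarray:
    """Panel sequence rewritten in query coordinates via global alignment.

    Returns a byte array of query length holding the panel base aligned to
    each query position, with ``-`` where the panel has a gap.  Bases the
    panel inserts relative to the query have no query coordinate and are
    dropped.
    """
    q = query_seq.upper().encode()
    p = panel_seq.upper().encode()
    res = edlib.align(p, q, mode="NW", task="path")
    out = np.full(len(q), _GAP, dtype=np.uint8)
    qi = pi = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            out[qi : qi + n] = np.frombuffer(p[pi : pi + n], dtype=np.uint8)
            qi += n
            pi += n
        elif ch == "D":  # query-only: gap in projection
            qi += n
        elif ch == "I":  # panel-only: dropped
            pi += n
    return out


def _window_starts(length: int, window: int, step: int) -> list[tuple[int, int]]:
    if length <= window:
        return [(0, length)]
    starts = list(range(0, length - window + 1, step))
    spans = [(s, s + window) for s in starts]
    if spans[-1][1] < length:
        spans.append((starts[-1] + step, length))
    return spans


def windowed_assignment(
    query: MitogenomeRecord | str,
    panel: list[tuple[str, str]],
    window: int = 150,
    step: int = 50,
    labeled_species: str | None = None,
) -> list[WindowAssignment]:
    """Assign each window of the query to its nearest panel species.

    ``panel`` is a list of ``(species, whole-genome sequence)``.  Ties break
    toward the labeled species (fewer false chimera calls), then
    alphabetically.  A window where fewer than half the sites are comparable
    with any panel sequence is unassessable.
    """
    if not panel:
        raise ValueError("empty reference panel")
    if isinstance(query, MitogenomeRecord):
        labeled_species = labeled_species or query.species_on_record
        query_seq = query.sequence
    else:
        query_seq = query.upper()
    labeled_norm = normalize_binomial(labeled_species) if labeled_species else None

    q_arr = np.frombuffer(query_seq.encode(), dtype=np.uint8)
    q_ok = np.isin(q_arr, _BASES)
    species_names = sorted({sp for sp, _ in panel}, key=normalize_binomial)

    # per-row mismatch/comparable indicator vectors, grouped by species
    per_species: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {s: [] for s in species_names}
    any_comp = np.zeros(len(q_arr), dtype=bool)
    for sp, seq in panel:
        proj = project_onto(query_seq, seq)
        ok = q_ok & np.isin(proj, _BASES)
        mm = ok & (proj != q_arr)
        per_species[sp].append((mm, ok))
        any_comp |= ok

    out: list[WindowAssignment] = []
    full_window = min(window, len(q_arr))
    for s, e in _window_starts(len(q_arr), window, step):
        span = e - s
        if any_comp[s:e].sum() < 0.5 * span:
            out.append(WindowAssignment(s, e, "", float("nan"), None, None,
                                        assessable=False, short_window=span < full_window))
            continue
        dists: list[tuple[float, str]] = []
        for sp in species_names:
            vals = []
            for mm, ok in per_species[sp]:
                comp = int(ok[s:e].sum())
                if comp:
                    vals.append(int(mm[s:e].sum()) / comp)
            if vals:
                dists.append((sum(vals) / len(vals), sp))
        if not dists:
            out.append(WindowAssignment(s, e, "", float("nan"), None, None,
                                        assessable=False, short_window=span < full_window))
            continue

        def rank(item: tuple[float, str]) -> tuple[float, int, str]:
            d, sp = item
            norm = normalize_binomial(sp)
            return (d, 0 if norm == labeled_norm else 1, norm)

        dists.sort(key=rank)
        best_d, best_sp = dists[0]
        second = dists[1] if len(dists) > 1 else None
        out.append(
            WindowAssignment(
                s, e, best_sp, best_d,
                second[1] if second else None,
                second[0] if second else None,
                short_window=span < full_window,
            )
        )
    return out


def _species_consensus(rows: list[tuple[np.ndarray, np.ndarray]],
                       projections: list[np.ndarray]) -> np.ndarray:
    if len(projections) == 1:
        return projections[0]
    stack = np.stack(projections)
    out = stack[0].copy()
    # column majority among bases; first projection wins ties
    for b in _BASES:
        counts = (stack == b).sum(axis=0)
        out = np.where(counts * 2 > len(projections), np.uint8(b), out)
    return out


def segment_breakpoints(
    assignments: list[WindowAssignment],
    query_seq: str | None = None,
    species_sequences: dict[str, np.ndarray] | None = None,
    min_run: int = 1,
) -> list[ChimeraSegment]:
    """Merge window assignments into species segments with refined breakpoints.

    Runs shorter than ``min_run`` windows are absorbed into the neighbouring
    run (longer flank wins, left on ties).  When the query sequence and
    per-species projections are available, each breakpoint is refined by a
    per-site scan over the region spanned by the two boundary windows;
    otherwise the midpoint of the window overlap is used.
    """
    usable = [a for a in assignments if a.assessable]
    if not usable:
        return []

    runs: list[list[WindowAssignment]] = []
    for a in usable:
        if runs and runs[-1][0].best_species == a.best_species:
            runs[-1].append(a)
        else:
            runs.append([a])

    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, run in enumerate(runs):
            if len(run) < min_run:
                left = runs[i - 1] if i > 0 else None
                right = runs[i + 1] if i + 1 < len(runs) else None
                target = max((r for r in (left, right) if r is not None),
                             key=len, default=None)
                if target is left and left is not None:
                    left.extend(run)
                elif target is not None:
                    target[:0] = run
                runs.pop(i)
                # re-merge neighbours that now share a species
                j = 1
                while j < len(runs):
                    if runs[j][0].best_species == runs[j - 1][0].best_species:
                        runs[j - 1].extend(runs.pop(j))
                    else:
                        j += 1
                changed = True
                break

    assessed_start = usable[0].window_start
    assessed_end = usable[-1].window_end

    boundaries = [assessed_start]
    for left_run, right_run in zip(runs, runs[1:]):
        lo = left_run[-1].window_start
        hi = right_run[0].window_end
        lo, hi = max(lo, boundaries[-1]), min(hi, assessed_end)
        bp = None
        if query_seq is not None and species_sequences is not None:
            l_sp, r_sp = left_run[0].best_species, right_run[0].best_species
            if l_sp in species_sequences and r_sp in species_sequences:
                q = np.frombuffer(query_seq.upper().encode(), dtype=np.uint8)[lo:hi]
                ml = (species_sequences[l_sp][lo:hi] == q).astype(int)
                mr = (species_sequences[r_sp][lo:hi] == q).astype(int)
                # score(s) = matches-to-left in [lo, s) + matches-to-right in [s, hi)
                scores = np.concatenate(([0], np.cumsum(ml))) + (
                    mr.sum() - np.concatenate(([0], np.cumsum(mr)))
                )
                bp = lo + int(np.argmax(scores))
        if bp is None:
            bp = (lo + hi) // 2
        boundaries.append(bp)
    boundaries.append(assessed_end)

    segments = []
    for b0, b1, run in zip(boundaries, boundaries[1:], runs):
        if b1 > b0:
            segments.append(ChimeraSegment(
                start=b0, end=b1, assigned_species=run[0].best_species,
                mean_window_distance=sum(a.best_distance for a in run) / len(run),
                n_windows=len(run),
            ))
    # degenerate refinement can empty a run; re-merge equal neighbours
    merged: list[ChimeraSegment] = []
    for seg in segments:
        if merged and merged[-1].assigned_species == seg.assigned_species:
            prev = merged[-1]
            total = prev.n_windows + seg.n_windows
            prev.mean_window_distance = (
                prev.mean_window_distance * prev.n_windows
                + seg.mean_window_distance * seg.n_windows
            ) / max(total, 1)
            prev.n_windows = total
            prev.end = seg.end
        else:
            merged.append(seg)
    return merged


def chimera_stats(
    segments: list[ChimeraSegment],
    query_seq: str,
    labeled_species: str,
    authentic_projection: np.ndarray | None = None,
    accession: str = "",
) -> ChimeraReport:
    """Fragment counts, heterospecific proportion and per-fragment divergence.

    ``authentic_projection`` is an authentic conspecific genome projected
    onto the query's coordinates; without one, per-fragment divergence from
    the authentic sequence cannot be assessed and is left absent.
    """
    labeled_norm = normalize_binomial(labeled_species)
    q = np.frombuffer(query_seq.upper().encode(), dtype=np.uint8)
    for seg in segments:
        seg.is_heterospecific = normalize_binomial(seg.assigned_species) != labeled_norm
        if seg.is_heterospecific and authentic_projection is not None:
            a = authentic_projection[seg.start : seg.end]
            qs = q[seg.start : seg.end]
            ok = np.isin(a, _BASES) & np.isin(qs, _BASES)
            if ok.sum():
                seg.divergence_from_authentic = float(((a != qs) & ok).sum() / ok.sum())
    report = ChimeraReport(accession=accession, labeled_species=labeled_species,
                           segments=segments)
    if segments and all(s.is_heterospecific for s in segments):
        report.possible_misidentified_source = True
    return report


def analyze_chimera(
    query: MitogenomeRecord,
    panel: list[tuple[str, str]],
    window: int = 150,
    step: int = 50,
    min_run: int = 1,
    labeled_species: str | None = None,
) -> ChimeraReport:
    """End-to-end chimera localization for one query against a genome panel."""
    labeled = labeled_species or query.species_on_record
    assignments = windowed_assignment(query, panel, window=window, step=step,
                                      labeled_species=labeled)
    by_species: dict[str, list[np.ndarray]] = {}
    for sp, seq in panel:
        by_species.setdefault(sp, []).append(project_onto(query.sequence, seq))
    consensus = {
        sp: _species_consensus([], projs) for sp, projs in by_species.items()
    }
    segments = segment_breakpoints(assignments, query.sequence, consensus,
                                   min_run=min_run)
    labeled_norm = normalize_binomial(labeled)
    authentic = None
    for sp, cons in consensus.items():
        if normalize_binomial(sp) == labeled_norm:
            authentic = cons
            break
    return chimera_stats(segments, query.sequence, labeled,
                         authentic_projection=authentic,
                         accession=query.accession)
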