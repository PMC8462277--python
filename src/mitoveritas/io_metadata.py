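"""Sequence/metadata input, candidate filtering and label comparison.

A deposited mitogenome carries two species names: the one on the sequence
record and the one used in the describing paper (when there is one).  This
module joins sequences to their metadata, applies the candidate-inclusion
filters (length window, RefSeq, putative hybrids, pre-1800 source material)
and compares the two names under a user-supplied synonym map.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_IUPAC = set("ACGTRYSWKMBDHVN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MitogenomeRecord:
    """One deposited mitogenome with its dual labels and provenance flags."""

    accession: str
    sequence: str
    species_on_record: str
    species_in_paper: str | None = None
    year: int | None = None
    is_hybrid: bool = False
    pre1800_source: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise ValueError(
                f"{self.accession}: non-IUPAC characters {sorted(bad)} in sequence"
            )
        if not self.species_on_record:
            raise ValueError(f"{self.accession}: empty species_on_record")
        if self.species_in_paper == "":
            self.species_in_paper = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_refseq(self) -> bool:
        return self.accession.startswith("NC_")


@dataclass
class FilterReport:
    """Partition of the input accessions into retained and excluded."""

    retained: list[str]
    excluded: list[tuple[str, str]]  # (accession, reason)

    EXCLUSION_REASONS = ("too_short", "too_long", "refseq", "hybrid", "pre1800")

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, "retained", "") for a in self.retained]
        rows += [(a, "excluded", r) for a, r in self.excluded]
        return pd.DataFrame(rows, columns=["accession", "status", "reason"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class LabelComparison:
    accession: str
    names_agree: bool
    normalized_on_record: str
    normalized_in_paper: str
    no_paper_label: bool = False


_META_COLUMNS = [
    "accession",
    "species_on_record",
    "species_in_paper",
    "year",
    "is_hybrid",
    "pre1800",
]

_TRUE = {"1", "true", "yes", "t", "y"}


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    return str(value).strip().lower() in _TRUE


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.startswith(">") else "genbank"
    raise ValueError(f"{path}: empty sequence file")


def load_records(sequence_path: str | Path, metadata_path: str | Path) -> list[MitogenomeRecord]:
    """Join a FASTA/GenBank file with its metadata table, keyed by accession.

    Every sequence must have a metadata row; metadata rows without a sequence
    are ignored with a warning.  Sequences are uppercased and U mapped to T.
    """
    sequence_path, metadata_path = Path(sequence_path), Path(metadata_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(_META_COLUMNS[:2]) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata is missing columns {sorted(missing_cols)}")
    if meta["accession"].duplicated().any():
        dups = meta.loc[meta["accession"].duplicated(), "accession"].tolist()
        raise ValueError(f"duplicate accession(s) in metadata: {dups}")
    meta = meta.set_index("accession")

    records: list[MitogenomeRecord] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(sequence_path), _sniff_format(sequence_path)):
        accession = seq_rec.id.split()[0]
        if accession in seen:
            raise ValueError(f"duplicate accession in sequence file: {accession}")
        seen.add(accession)
        if accession not in meta.index:
            raise KeyError(f"accession {accession!r} has no metadata row")
        row = meta.loc[accession]
        year_raw = str(row.get("year", "")).strip()
        records.append(
            MitogenomeRecord(
                accession=accession,
                sequence=str(seq_rec.seq),
                species_on_record=str(row["species_on_record"]).strip(),
                species_in_paper=str(row.get("species_in_paper", "")).strip() or None,
                year=int(year_raw) if year_raw else None,
                is_hybrid=_as_bool(row.get("is_hybrid", "")),
                pre1800_source=_as_bool(row.get("pre1800", "")),
            )
        )
    unmatched = set(meta.index) - seen
    for accession in sorted(unmatched):
        log.warning("metadata row %s has no matching sequence; ignored", accession)
    return records


def filter_candidates(
    records: Iterable[MitogenomeRecord],
    min_len: int = 12_000,
    max_len: int = 25_000,
) -> FilterReport:
    """Apply the candidate-inclusion filters.

    A record is retained when ``min_len <= length <= max_len`` (both bounds
    inclusive) and it is not a RefSeq copy, not a putative hybrid, and not
    sourced from pre-1800 material.  Each excluded record carries exactly one
    reason: the first matching one in the order too_short, too_long, refseq,
    hybrid, pre1800.
    """
    retained: list[str] = []
    excluded: list[tuple[str, str]] = []
    for rec in records:
        if rec.length < min_len:
            excluded.append((rec.accession, "too_short"))
        elif rec.length > max_len:
            excluded.append((rec.accession, "too_long"))
        elif rec.is_refseq:
            excluded.append((rec.accession, "refseq"))
        elif rec.is_hybrid:
            excluded.append((rec.accession, "hybrid"))
        elif rec.pre1800_source:
            excluded.append((rec.accession, "pre1800"))
        else:
            retained.append(rec.accession)
    return FilterReport(retained=retained, excluded=excluded)


def normalize_binomial(name: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Canonical form of a binomial: case-folded, whitespace-collapsed,
    then mapped through the synonym table.

    Synonym keys may be full binomials (``Porzana akool -> Zapornia akool``)
    or bare genus names (``Porzana -> Zapornia``), applied in that order.
    """
    norm = re.sub(r"\s+", " ", name.strip()).lower()
    if synonym_map:
        lowered = {k.strip().lower(): v.strip().lower() for k, v in synonym_map.items()}
        if norm in lowered:
            norm = lowered[norm]
        else:
            parts = norm.split(" ", 1)
            if parts[0] in lowered and " " not in lowered[parts[0]]:
                parts[0] = lowered[parts[0]]
                norm = " ".join(parts)
    return norm


def compare_labels(
    record: MitogenomeRecord, synonym_map: Mapping[str, str] | None = None
) -> LabelComparison:
    """Compare the on-record and in-paper species names.

    When the record has no in-paper name the comparison is vacuously in
    agreement and flagged ``no_paper_label``.
    """
    on_record = normalize_binomial(record.species_on_record, synonym_map)
    if record.species_in_paper is None:
        return LabelComparison(record.accession, True, on_record, "", no_paper_label=True)
    in_paper = normalize_binomial(record.species_in_paper, synonym_map)
    return LabelComparison(record.accession, on_record == in_paper, on_record, in_paper)


def load_synonym_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``old_name<TAB>canonical_name``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("synonym table needs two columns: old_name, canonical_name")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_hybrid_pairs(path: str | Path) -> set[frozenset[str]]:
    """Read a two-column TSV of species pairs known to hybridize."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    pairs = set()
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        pairs.add(frozenset({normalize_binomial(a), normalize_binomial(b)}))
    return pairs
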