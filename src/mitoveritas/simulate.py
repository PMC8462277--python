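"""Synthetic reference panels and query cohorts with implanted defects.

The generator reproduces the statistical structure the screen assumes: a
multi-species panel in which intraspecific divergence (< 1%) sits far below
interspecific divergence (7.5-23.3%, the range observed for heterospecific
chimera fragments in published avian mitogenomes).  Species radiate from a
common ancestor on a star phylogeny — the simplest topology that pins both
divergence scales — and sequences evolve site-independently under a
two-parameter process with a transition/transversion ratio of 4.

Defect classes are implanted with exact ground truth: chimeric fragment
breakpoints, indel positions and counts, duplicated spans, and label swaps,
so every downstream detector can be scored against construction truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import pdist_matrix
from .config import MARKER_CANONICAL_LENGTH, MARKER_NAMES
from .io_metadata import MitogenomeRecord
from .markers import MarkerProfile

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Fixed marker offsets (bp) in every simulated genome, published so marker
#: extraction can be tested with and without its search step.
MARKER_OFFSETS = {"ND2": 2000, "COI": 5500, "CYTB": 9000}

_EPITHETS = ["alpha", "bravo", "carina", "delta", "echo", "foxtrot",
             "golfi", "hoteli", "india", "juliet", "kiloa", "lima"]


def marker_regions(offsets: dict[str, int] | None = None) -> dict[str, tuple[int, int]]:
    offsets = offsets or MARKER_OFFSETS
    return {m: (offsets[m], offsets[m] + MARKER_CANONICAL_LENGTH[m])
            for m in MARKER_NAMES}


@dataclass(frozen=True)
class PanelConfig:
    """Simulator settings; defaults are the study conditions the screen targets."""

    n_species: int = 8
    individuals_per_species: int = 2
    genome_length: int = 16_000
    stem_range: tuple[float, float] = (0.048, 0.11)   # expected subs/site to root
    tip_range: tuple[float, float] = (0.001, 0.004)   # individual from species ancestor
    intra_max: float = 0.01
    inter_min: float = 0.075
    inter_max: float = 0.233
    kappa: float = 4.0                                # transition/transversion ratio
    min_fragments: int = 1
    max_fragments: int = 10
    min_fragment_len: int = 70
    max_fragment_len: int = 11_911

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        if self.individuals_per_species < 1:
            raise ValueError("need at least 1 individual per species")
        if self.intra_max >= self.inter_min:
            raise ValueError("intra_max must be below inter_min")
        if self.genome_length < max(o + MARKER_CANONICAL_LENGTH[m]
                                    for m, o in MARKER_OFFSETS.items()):
            raise ValueError("genome too short to host the marker regions")


def _mutate(seq: np.ndarray, d: float, rng: np.random.Generator,
            kappa: float) -> np.ndarray:
    """One branch of length ``d`` expected substitutions/site.

    Each site substitutes with probability 1-exp(-d); a substituting site
    takes its transition partner with probability kappa/(kappa+2), else one
    of the two transversions.
    """
    out = seq.copy()
    if d <= 0:
        return out
    hit = rng.random(seq.size) < 1.0 - np.exp(-d)
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return out
    code = np.searchsorted(_BASES, out[idx])  # A,C,G,T -> 0..3
    is_ts = rng.random(idx.size) < kappa / (kappa + 2.0)
    offset = np.where(is_ts, 2, np.where(rng.random(idx.size) < 0.5, 1, 3))
    out[idx] = _BASES[(code + offset) % 4]
    return out


@dataclass
class SimulatedPanel:
    config: PanelConfig
    seed: int
    species: list[str]
    species_tree: str                     # newick, branch lengths in subs/site
    genomes: list[tuple[str, str, str]]   # (species, individual id, sequence)
    _ancestors: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def marker_profiles(self) -> dict[str, MarkerProfile]:
        regions = marker_regions()
        return {
            m: MarkerProfile(m, [(sp, seq[s:e]) for sp, _, seq in self.genomes])
            for m, (s, e) in regions.items()
        }

    def genome_panel(self) -> list[tuple[str, str]]:
        return [(sp, seq) for sp, _, seq in self.genomes]

    def new_individual(self, species: str, rng: np.random.Generator) -> str:
        """Simulate one more individual of a panel species."""
        t = rng.uniform(*self.config.tip_range)
        arr = _mutate(self._ancestors[species], t, rng, self.config.kappa)
        return arr.tobytes().decode()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "panel_genomes.fasta", "w") as fh:
            for sp, ind, seq in self.genomes:
                fh.write(f">{sp.replace(' ', '_')}|genome|{ind}\n{seq}\n")
        with open(outdir / "panel_markers.fasta", "w") as fh:
            for m, (s, e) in marker_regions().items():
                for sp, ind, seq in self.genomes:
                    fh.write(f">{sp.replace(' ', '_')}|{m}|{ind}\n{seq[s:e]}\n")
        (outdir / "species_tree.nwk").write_text(self.species_tree + "\n")


def simulate_panel(config: PanelConfig = PanelConfig(), seed: int = 0) -> SimulatedPanel:
    """Simulate the reference panel and assert its divergence regime.

    The realized (not just expected) distances are checked: mean
    intraspecific p-distance below ``intra_max`` and mean interspecific
    p-distance inside ``[inter_min, inter_max]``.
    """
    rng = np.random.default_rng(seed)
    root = rng.choice(_BASES, size=config.genome_length)
    species = [f"Aviana {_EPITHETS[i % len(_EPITHETS)]}{'' if i < len(_EPITHETS) else i}"
               for i in range(config.n_species)]
    stems = rng.uniform(*config.stem_range, size=config.n_species)
    ancestors: dict[str, np.ndarray] = {}
    genomes: list[tuple[str, str, str]] = []
    for sp, stem in zip(species, stems):
        anc = _mutate(root, float(stem), rng, config.kappa)
        ancestors[sp] = anc
        for j in range(config.individuals_per_species):
            t = rng.uniform(*config.tip_range)
            seq = _mutate(anc, t, rng, config.kappa)
            ind = f"REF{species.index(sp):02d}{chr(97 + j)}"
            genomes.append((sp, ind, seq.tobytes().decode()))
    newick = "(" + ",".join(
        f"{sp.replace(' ', '_')}:{stem:.4f}" for sp, stem in zip(species, stems)
    ) + ");"
    panel = SimulatedPanel(config=config, seed=seed, species=species,
                           species_tree=newick, genomes=genomes,
                           _ancestors=ancestors)

    dm = pdist_matrix([seq for _, _, seq in genomes])
    sp_of = [sp for sp, _, _ in genomes]
    intra = [dm[i, j] for i in range(len(sp_of)) for j in range(i + 1, len(sp_of))
             if sp_of[i] == sp_of[j]]
    inter = [dm[i, j] for i in range(len(sp_of)) for j in range(i + 1, len(sp_of))
             if sp_of[i] != sp_of[j]]
    if intra and not float(np.mean(intra)) < config.intra_max:
        raise RuntimeError("panel violates the intraspecific divergence bound")
    if not config.inter_min <= float(np.mean(inter)) <= config.inter_max:
        raise RuntimeError("panel violates the interspecific divergence range")
    return panel


# ---------------------------------------------------------------------------
# implants


@dataclass
class TruthRecord:
    accession: str
    implanted_class: str  # one of the six problem classes, or "clean"
    params: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {"accession": self.accession, "class": self.implanted_class,
                "param_json": json.dumps(self.params, sort_keys=True)}


def implant_chimera(
    query: str,
    donor: str,
    fragments: list[tuple[int, int]],
    config: PanelConfig = PanelConfig(),
    donor_species: str = "",
    accession: str = "",
) -> tuple[str, TruthRecord]:
    """Replace the listed query spans with the donor's homologous spans.

    Fragment count and lengths are validated against the configured ranges
    (defaults: 1-10 fragments of 70-11,911 bp).  Fragments must not overlap.
    """
    if not config.min_fragments <= len(fragments) <= config.max_fragments:
        raise ValueError(f"fragment count {len(fragments)} outside "
                         f"[{config.min_fragments}, {config.max_fragments}]")
    ordered = sorted(fragments)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if e1 > s2:
            raise ValueError("overlapping chimera fragments")
    out = list(query)
    for s, e in ordered:
        if not 0 <= s < e <= min(len(query), len(donor)):
            raise ValueError(f"fragment ({s}, {e}) out of range")
        if not config.min_fragment_len <= e - s <= config.max_fragment_len:
            raise ValueError(f"fragment length {e - s} outside "
                             f"[{config.min_fragment_len}, {config.max_fragment_len}]")
        out[s:e] = donor[s:e]
    truth = TruthRecord(accession, "chimera", {
        "donor_species": donor_species,
        "breakpoints": ordered,
        "heterospecific_bp": sum(e - s for s, e in ordered),
        "proportion_pct": round(100.0 * sum(e - s for s, e in ordered) / len(query), 2),
    })
    return "".join(out), truth


def implant_errors(
    query: str,
    n_substitutions: int,
    indel_spec: list[tuple[int, int, str]] | None = None,
    seed: int = 0,
    regions: list[tuple[int, int]] | None = None,
    accession: str = "",
) -> tuple[str, TruthRecord]:
    """Implant sequencing errors: uniform substitutions over the marker
    regions plus explicit indels ``(position, length, "ins"|"del")``.

    Indels are applied highest-position first so all stated coordinates
    refer to the unmodified query.
    """
    rng = np.random.default_rng(seed)
    regions = regions or list(marker_regions().values())
    out = np.frombuffer(query.encode(), dtype=np.uint8).copy()
    sites = np.concatenate([np.arange(s, e) for s, e in regions])
    if n_substitutions > 0:
        chosen = rng.choice(sites, size=min(n_substitutions, sites.size),
                            replace=False)
        code = np.searchsorted(_BASES, out[chosen])
        shift = rng.integers(1, 4, size=chosen.size)
        out[chosen] = _BASES[(code + shift) % 4]
    seq = list(out.tobytes().decode())
    indel_spec = indel_spec or []
    for pos, length, kind in sorted(indel_spec, reverse=True):
        if kind == "del":
            del seq[pos : pos + length]
        elif kind == "ins":
            insert = rng.choice(_BASES, size=length).tobytes().decode()
            seq[pos:pos] = insert
        else:
            raise ValueError(f"indel kind must be 'ins' or 'del', got {kind!r}")
    truth = TruthRecord(accession, "seq_errors_numts", {
        "n_substitutions": int(n_substitutions),
        "indels": [(int(p), int(l), k) for p, l, k in indel_spec],
        "n_indel_events": len(indel_spec),
    })
    return "".join(seq), truth


def implant_assembly_error(
    query: str,
    source_span: tuple[int, int],
    insert_position: int,
    accession: str = "",
) -> tuple[str, TruthRecord]:
    """Insert a copy of ``source_span`` at a nonhomologous position."""
    s, e = source_span
    if e <= s:
        raise ValueError("source span must have positive length")
    if not 0 <= s < e <= len(query) or not 0 <= insert_position <= len(query):
        raise ValueError("span or insert position out of range")
    out = query[:insert_position] + query[s:e] + query[insert_position:]
    truth = TruthRecord(accession, "incorrect_assembly", {
        "duplicated_span": [int(s), int(e)],
        "insert_position": int(insert_position),
    })
    return out, truth


# ---------------------------------------------------------------------------
# cohorts


#: Default class counts for a 60-record cohort, proportional to the relative
#: frequencies observed among published problematic avian mitogenomes
#: (misidentification > chimera > errors/numts >> assembly, mislabeling).
DEFAULT_CLASS_COUNTS = {
    "clean": 19,
    "misidentification": 17,
    "chimera": 12,
    "seq_errors_numts": 9,
    "incorrect_assembly": 1,
    "mislabeled_on_genbank": 1,
    "mislabeled_in_paper": 1,
}


@dataclass
class Cohort:
    panel: SimulatedPanel
    records: list[MitogenomeRecord]
    truth: pd.DataFrame
    hybrid_pairs: set[frozenset[str]] = field(default_factory=set)

    def truth_classes(self) -> dict[str, str]:
        return dict(zip(self.truth["accession"], self.truth["class"]))

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "accession": r.accession,
                "species_on_record": r.species_on_record,
                "species_in_paper": r.species_in_paper or "",
                "year": r.year or "",
                "is_hybrid": int(r.is_hybrid),
                "pre1800": int(r.pre1800_source),
            })
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.panel.write(outdir)
        with open(outdir / "queries.fasta", "w") as fh:
            for r in self.records:
                fh.write(f">{r.accession}\n{r.sequence}\n")
        self.metadata_frame().to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if self.hybrid_pairs:
            rows = [sorted(p) for p in sorted(self.hybrid_pairs, key=sorted)]
            pd.DataFrame(rows, columns=["species_a", "species_b"]).to_csv(
                outdir / "hybrid_pairs.tsv", sep="\t", index=False)


def _chimera_fragments(rng: np.random.Generator, genome_length: int,
                       max_len: int = 8000, min_len: int = 300) -> list[tuple[int, int]]:
    """1-2 donor fragments, each overlapping a marker region.

    Published chimeras were detectable precisely because foreign fragments
    overlapped at least one of the screened markers; fragments here always
    do, and at least one marker region is left majority-native.
    """
    regions = marker_regions()
    n_frag = int(rng.integers(1, 3))
    markers = list(rng.permutation(MARKER_NAMES))[:n_frag]
    markers.sort(key=lambda m: regions[m][0])
    cap = max_len if n_frag == 1 else 2500
    frags: list[tuple[int, int]] = []
    prev_end = 0
    for m in markers:
        ms, me = regions[m]
        length = int(rng.integers(min_len, cap + 1))
        lo = max(prev_end, ms - (length - 150))
        hi = max(lo, min(genome_length - length, me - 150))
        start = int(rng.integers(lo, hi + 1))
        frags.append((start, start + length))
        prev_end = start + length + 200
    return frags


def make_cohort(
    config: PanelConfig = PanelConfig(),
    seed: int = 42,
    n: int = 60,
    class_counts: dict[str, int] | None = None,
) -> Cohort:
    """Simulate a panel plus ``n`` query mitogenomes with implanted defects.

    Deterministic per seed.  Misidentification and the two mislabeling
    classes are label swaps; chimeras, errors/numts and assembly errors are
    sequence implants with exact truth parameters.
    """
    counts = dict(class_counts or DEFAULT_CLASS_COUNTS)
    if n != sum(counts.values()):
        raise ValueError(f"class counts sum to {sum(counts.values())}, not n={n}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    panel = simulate_panel(config, seed=seed)
    species = panel.species
    regions = marker_regions()

    classes = [c for c, k in counts.items() for _ in range(k)]
    rng.shuffle(classes)

    records: list[MitogenomeRecord] = []
    truths: list[TruthRecord] = []
    hybrid_pairs: set[frozenset[str]] = set()
    for i, cls in enumerate(classes):
        accession = f"Q{i + 1:04d}"
        year = int(rng.integers(2005, 2020))
        true_sp = species[int(rng.integers(len(species)))]
        seq = panel.new_individual(true_sp, rng)
        on_record, in_paper = true_sp, true_sp
        params: dict = {}

        if cls == "clean":
            truth = TruthRecord(accession, "clean", {"species": true_sp})
        elif cls == "misidentification":
            wrong = species[int(rng.integers(len(species)))]
            while wrong == true_sp:
                wrong = species[int(rng.integers(len(species)))]
            on_record = in_paper = wrong
            truth = TruthRecord(accession, "misidentification",
                                {"true_species": true_sp, "labeled_as": wrong})
        elif cls == "chimera":
            donor_sp = species[int(rng.integers(len(species)))]
            while donor_sp == true_sp:
                donor_sp = species[int(rng.integers(len(species)))]
            donor = panel.new_individual(donor_sp, rng)
            frags = _chimera_fragments(rng, config.genome_length)
            seq, truth = implant_chimera(seq, donor, frags, config,
                                         donor_species=donor_sp,
                                         accession=accession)
            truth.params["true_species"] = true_sp
        elif cls == "seq_errors_numts":
            marker = MARKER_NAMES[int(rng.integers(3))]
            ms, me = regions[marker]
            if rng.random() < 0.5:
                # frameshifting indels in one marker
                k = int(rng.integers(2, 6))
                positions = sorted(rng.choice(
                    np.arange(ms + 50, me - 50, 60), size=k, replace=False))
                spec = [(int(p), int(rng.integers(1, 3)),
                         "del" if rng.random() < 0.5 else "ins")
                        for p in positions]
                seq, truth = implant_errors(seq, 0, spec,
                                            seed=int(rng.integers(2**31)),
                                            accession=accession)
            else:
                # heavily divergent marker matching no species closely
                rate = rng.uniform(0.13, 0.18)
                n_sub = int(rate * (me - ms))
                seq, truth = implant_errors(seq, n_sub, [],
                                            seed=int(rng.integers(2**31)),
                                            regions=[(ms, me)],
                                            accession=accession)
                truth.params["marker"] = marker
                truth.params["rate"] = round(float(rate), 3)
        elif cls == "incorrect_assembly":
            cs, ce = regions["CYTB"]
            span_len = int(rng.integers(300, 601))
            s = int(rng.integers(cs, ce - span_len))
            seq, truth = implant_assembly_error(seq, (s, s + span_len),
                                                insert_position=14_500,
                                                accession=accession)
        elif cls == "mislabeled_on_genbank":
            wrong = species[(species.index(true_sp) + 1) % len(species)]
            on_record = wrong
            truth = TruthRecord(accession, "mislabeled_on_genbank",
                                {"true_species": true_sp, "genbank_label": wrong})
        elif cls == "mislabeled_in_paper":
            wrong = species[(species.index(true_sp) + 1) % len(species)]
            in_paper = wrong
            truth = TruthRecord(accession, "mislabeled_in_paper",
                                {"true_species": true_sp, "paper_label": wrong})
        else:
            raise ValueError(f"unknown class {cls!r}")

        records.append(MitogenomeRecord(
            accession=accession, sequence=seq,
            species_on_record=on_record, species_in_paper=in_paper, year=year,
        ))
        truths.append(truth)

    truth_df = pd.DataFrame([t.to_row() for t in truths])
    return Cohort(panel=panel, records=records, truth=truth_df,
                  hybrid_pairs=hybrid_pairs)
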