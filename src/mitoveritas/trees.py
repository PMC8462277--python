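"""Neighbor-joining gene trees and phylogenetic placement queries.

One tree per marker is built from uncorrected p-distances by neighbor
joining.  The screen's signals are topological (is the query inside the
clade of its own species' references?) and branch-length based (is it on a
conspicuously long terminal branch?); at the divergence scales involved
these signals are robust to the substitution model, which is why distance
trees stand in for likelihood ones.

Tip labels follow ``Species_binomial|accession``; the species part is
recovered by splitting on the first ``|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .align import MarkerAlignment, p_distance
from .io_metadata import normalize_binomial

log = logging.getLogger(__name__)


def make_label(species: str, accession: str) -> str:
    return f"{species.replace(' ', '_')}|{accession}"


def species_of(label: str) -> str:
    return label.split("|", 1)[0].replace("_", " ")


def accession_of(label: str) -> str:
    parts = label.split("|", 1)
    return parts[1] if len(parts) > 1 else parts[0]


@dataclass
class GeneTree:
    """A per-marker phylogeny with species-labeled tips.

    Wraps an unrooted tree (stored with an arbitrary rooting) and exposes
    the clade/bipartition queries the symptom detectors need.
    """

    marker_name: str
    tree: TreeNode

    @property
    def newick(self) -> str:
        return str(self.tree).strip()

    @property
    def tip_labels(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def terminal_branch(self, label: str) -> float:
        tip = self.tree.find(label)
        return float(tip.length or 0.0)

    def _sides(self) -> list[frozenset[str]]:
        """Tip sets of every edge, one side each (the rooted 'below' side)."""
        sides = []
        for node in self.tree.postorder(include_self=False):
            names = frozenset(t.name for t in node.tips(include_self=True))
            sides.append(names)
        return sides

    def smallest_clade_containing(self, labels: set[str]) -> frozenset[str]:
        """Smallest edge-bounded tip set (either side of some edge) that
        contains all of ``labels``; unrooted analogue of an MRCA clade."""
        all_tips = frozenset(self.tip_labels)
        if not labels <= all_tips:
            raise KeyError(f"labels not in tree: {sorted(labels - all_tips)}")
        best = all_tips
        for side in self._sides():
            for cand in (side, all_tips - side):
                if labels <= cand and len(cand) < len(best):
                    best = cand
        return best

    def is_monophyletic(self, labels: set[str], exclude: set[str] = frozenset()) -> bool:
        """True iff some edge splits ``labels`` exactly from everything else,
        ignoring the tips in ``exclude``."""
        all_tips = frozenset(self.tip_labels)
        target = frozenset(labels)
        if len(target) <= 1:
            return True
        for side in self._sides():
            for cand in (side, all_tips - side):
                if frozenset(cand) - exclude == target:
                    return True
        return False

    def sister_branch_length(self, label: str) -> float:
        """Length of the longest sibling edge at the tip's attachment node."""
        tip = self.tree.find(label)
        parent = tip.parent
        if parent is None:
            return 0.0
        sibs = [c for c in parent.children if c is not tip]
        if not sibs:
            return 0.0
        return max(float(s.length or 0.0) for s in sibs)


@dataclass
class PlacementSummary:
    """Where one query sits in one marker's gene tree, and how far it is
    from everything else in the marker alignment."""

    query_label: str
    marker_name: str
    inside_conspecific_clade: bool | None
    nearest_species: str
    nearest_distance: float
    nearest_conspecific_distance: float | None
    nearest_hetero_species: str | None
    nearest_hetero_distance: float | None
    terminal_branch: float
    conspecific_median_terminal: float | None
    tree_median_terminal: float
    sister_branch: float
    reference_resolved: bool
    single_reference: bool


def nj_tree(distances: np.ndarray, labels: list[str], marker_name: str = "") -> GeneTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    On additive matrices the tree's path lengths reproduce the input
    exactly.  Negative branch-length estimates are clamped to zero (logged).
    """
    distances = np.asarray(distances, dtype=float)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if distances.shape != (len(labels), len(labels)):
        raise ValueError("distance matrix shape does not match labels")
    if np.isnan(distances).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(distances, distances.T):
        raise ValueError("distance matrix is not symmetric")
    raw = nj(DistanceMatrix(distances, ids=labels), neg_as_zero=False)
    clamped = 0
    for node in raw.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        log.info("clamped %d negative NJ branch length(s) to 0", clamped)
    return GeneTree(marker_name=marker_name, tree=raw)


def reference_resolution(
    tree: GeneTree, species: str, exclude: set[str] = frozenset()
) -> bool:
    """Reciprocal-monophyly check for one species' reference tips.

    True iff the species' tips (ignoring ``exclude``, typically the query)
    form an exclusive clade.  A species with a single reference tip is
    trivially resolved; callers should treat that case with the
    single-reference caveat.  Raises if the species has no tip at all.
    """
    norm = normalize_binomial(species)
    tips = {
        lbl
        for lbl in tree.tip_labels
        if normalize_binomial(species_of(lbl)) == norm and lbl not in exclude
    }
    if not tips:
        raise KeyError(f"species {species!r} absent from tree")
    return tree.is_monophyletic(tips, exclude=exclude)


def place_query(
    tree: GeneTree, alignment: MarkerAlignment, query_label: str
) -> PlacementSummary:
    """Summarize one query's position in a marker tree.

    Clade membership comes from the tree; nearest-neighbour species and
    distances come straight from the alignment, so a tie or a slightly
    wrong topology cannot hide a zero-distance match.
    """
    if query_label not in tree.tip_labels:
        raise KeyError(f"query {query_label!r} not in tree")
    q_species = normalize_binomial(species_of(query_label))
    tip_set = set(tree.tip_labels)
    query_row = alignment.row(query_label)

    nearest: tuple[float, str] | None = None
    nearest_con: float | None = None
    nearest_het: tuple[float, str] | None = None
    for lbl, seq in alignment.rows:
        if lbl == query_label or lbl not in tip_set:
            continue
        d = p_distance(query_row, seq)
        if d is None:
            continue
        sp = species_of(lbl)
        key = (d, normalize_binomial(sp))
        if nearest is None or key < (nearest[0], normalize_binomial(nearest[1])):
            nearest = (d, sp)
        if normalize_binomial(sp) == q_species:
            nearest_con = d if nearest_con is None else min(nearest_con, d)
        else:
            if nearest_het is None or key < (nearest_het[0], normalize_binomial(nearest_het[1])):
                nearest_het = (d, sp)
    if nearest is None:
        raise ValueError(f"no comparable sequence for {query_label!r}")

    conspecific = {
        lbl for lbl in tip_set
        if lbl != query_label and normalize_binomial(species_of(lbl)) == q_species
    }
    inside: bool | None = None
    median_terminal: float | None = None
    resolved = True
    single_ref = False
    if conspecific:
        # grouping the query with all its conspecific references must not
        # drag in any heterospecific tip; a query sister to the conspecific
        # cherry is still "inside" in this sense
        clade = tree.smallest_clade_containing(conspecific | {query_label})
        heterospecific_in_clade = {
            lbl for lbl in clade
            if lbl != query_label and normalize_binomial(species_of(lbl)) != q_species
        }
        inside = not heterospecific_in_clade
        median_terminal = median(tree.terminal_branch(l) for l in conspecific)
        single_ref = len(conspecific) == 1
        resolved = reference_resolution(tree, species_of(query_label),
                                        exclude={query_label})

    return PlacementSummary(
        query_label=query_label,
        marker_name=tree.marker_name,
        inside_conspecific_clade=inside,
        nearest_species=nearest[1],
        nearest_distance=nearest[0],
        nearest_conspecific_distance=nearest_con,
        nearest_hetero_species=nearest_het[1] if nearest_het else None,
        nearest_hetero_distance=nearest_het[0] if nearest_het else None,
        terminal_branch=tree.terminal_branch(query_label),
        conspecific_median_terminal=median_terminal,
        tree_median_terminal=median(
            tree.terminal_branch(l) for l in tip_set if l != query_label
        ),
        sister_branch=tree.sister_branch_length(query_label),
        reference_resolved=resolved,
        single_reference=single_ref,
    )
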