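# Methods

## The screening model

The screen treats a mitogenome deposit as authentic until marker-level
evidence says otherwise. Its working assumptions are the ones that make
DNA-based species identification possible in birds: conspecific
mitochondrial sequences are close (typically well under 1% p-distance),
heterospecific sequences are far (several percent and up), and the two
scales rarely overlap. Every detector is a comparison of an observed
distance or tree position against those scales.

Three protein-coding markers carry the evidence — ND2 (1,041 bp), COI
(696 bp), cytochrome *b* (1,143 bp) — because reference coverage for them
is dense. A marker is usable only above a strict length floor (>600 bp
COI, >800 bp ND2/cytb); a query with no usable marker is reported as not
assessable rather than diagnosed.

## Pipeline components and numerical choices

**Candidate filtering.** Length window 12,000-25,000 bp, both bounds
inclusive; RefSeq copies (`NC_` prefix), putative hybrids and pre-1800
source material are excluded. Exclusion reasons are prioritized
(too_short, too_long, refseq, hybrid, pre1800) so every record carries
exactly one, deterministically. Pre-1800 sourcing cannot be inferred from
sequence and is a metadata flag defaulting to false.

**Marker location.** Each reference marker is aligned against the doubled
query (circular molecules stored linearly) on both strands with
bit-parallel edit-distance infix alignment. The acceptance gate is the
identity of the *full* reference alignment (floor 0.60, far below the
~0.77 implied by the largest heterospecific divergences the screen must
still locate), so a short perfect fluke in unrelated sequence cannot pass.
Reported coordinates come from the maximum-scoring sub-alignment (+1
match, -1 otherwise): without this trim, a truncated marker copy drags
leftover reference bases into flanking sequence and overstates its length.
Coordinates are 0-based half-open on the forward strand; origin-spanning
hits are flagged and keep `end > length`.

**Alignment.** Marker fragments are aligned by an anchored star strategy:
each row is pairwise-aligned to the first reference under affine scoring
(match +1, mismatch -1, gap open -5, extend -2; end gaps pay one opening
and extend free), and insertion columns are merged across rows. Two
choices matter. First, the affine penalty is load-bearing: a plain
edit-distance alignment trades two substitutions for an
insertion-deletion pair at equal cost and plants phantom indels in
divergent but colinear sequences, which would fire the indel symptom
falsely. Second, end gaps extend free but pay an opening, so truncated
fragments are cheap while sliding a colinear row to dodge an internal gap
is not. The alignment is deterministic for a fixed input order.

**Distances.** Uncorrected p-distance over comparable sites (both rows
unambiguous A/C/G/T). With zero comparable sites the distance is
undefined, not zero. No multiple-hit correction is applied: every decision
in the screen is a *ranking* of neighbours or a comparison against a
threshold far from saturation, and at ≤25% divergence the ranking under
p-distance and under model-corrected distances is the same.

**Trees.** Neighbor joining on p-distances, one tree per query per marker
(all references plus the focal query), with negative branch estimates
clamped to zero. Distance trees stand in for likelihood trees because the
symptoms are topological or branch-length signals that are robust at these
divergences, and NJ is exact on additive matrices — a property the tests
verify to 1e-9. "Inside the conspecific clade" means: the smallest clade
containing the query together with all conspecific references contains no
heterospecific tip. (The naive reading — smallest clade containing the
references alone — would call a query *outside* whenever NJ attaches it as
sister to the conspecific cherry, which happens routinely at near-zero
distances.) Reference resolution is reciprocal monophyly of the
conspecific references, ignoring the query; a single-reference species is
trivially resolved and flagged as such.

**Symptom thresholds** (all in `ScreenConfig`, all config-exposed):

| parameter | default | meaning |
|---|---|---|
| `tau_close` | 0.03 | p-distance at or below which a heterospecific match is "close" |
| `tau_deep` | 0.05 | nearest-conspecific distance above which a placement is deeply divergent |
| `tau_noid` | 0.10 | distance above which a sequence matches *no* species |
| `theta_lb` | 5.0 | long-branch multiplier over the conspecific median terminal |
| `lb_floor` | 0.005 | floor on that median, so near-identical references do not fire on noise |
| `multiple_indel_min` | 2 | indel events needed for the multiple-indels symptom |

The thresholds separate the simulator's two divergence scales
(intraspecific ≤1%, interspecific ≥7.5%) with wide margins; none encodes a
biological constant, and a user screening taxa with different population
structure should revisit them.

**Chimera localization.** Whole reference genomes are projected onto the
query's coordinates by global alignment; sliding windows (150 bp window,
50 bp step) are assigned to the species with the smallest mean p-distance,
with ties broken toward the labeled species so that noise does not create
chimera calls. Windows under 50% comparable sites are unassessable. Runs
of same-species windows become segments; each breakpoint is refined within
the two boundary windows to the base position maximizing per-site
agreement with the left species on the left plus the right species on the
right. The defaults resolve implanted breakpoints to a few bp (max error
under half a window across the test battery); fragments shorter than the
window (down to the 70 bp minimum the defect model allows) require
proportionally smaller window/step, a sensitivity-runtime trade-off the
tests document.

**Diagnosis rules** (first match wins): (1) references unresolved in every
usable marker with no symptom → could_not_be_verified; (2) record/paper
label mismatch adjudicated by the trees → mislabeled on one side; (3)
different species *closely* matching different regions → chimera; (4) a
self-duplicated span found by probe re-search of the marker against the
masked genome → incorrect_assembly; (5) multiple indels, or divergent
sequence matching no species → seq_errors_numts; (6) the same wrong
species in every usable marker with no long branch → misidentification
(annotated, never reclassified, when the species pair is a known
hybridizing pair — mitochondrial introgression is observationally
identical); (7) otherwise authentic, or manual review when symptoms fired
but no rule applied. Two refinements to rule (3) are worth stating: a
heterospecific segment counts as donor evidence only if its windows match
the winning species at the intraspecific scale (`tau_close`) — an
error/numt-divergent region "wins" some species only at 15-20% distance
and must not be mistaken for a donor fragment — and segments lying inside
a detected self-duplication span are discounted, because the duplicate
aligns against every species' copy of the same gene and produces phantom
foreign windows. Rationales retain all fired symptoms, so mixed cases keep
their secondary evidence.

**Single-marker counterfactual.** Each diagnosis can be recomputed from
one marker's evidence alone, with chimera segments clipped to that
marker's span. A chimera whose breakpoints miss the marker collapses to a
single-species region and is typically re-diagnosed as a
misidentification — quantifying why multi-marker screening recovers
defects single-marker screening cannot.

## The synthetic cohort

The generator emulates the statistical structure the screen assumes, not
mitogenome biology. Species radiate on a star phylogeny with stem lengths
drawn from 0.048-0.11 expected substitutions/site, giving realized
interspecific p-distances spanning roughly 8-20% — inside the 7.5-23.3%
regime observed for real heterospecific fragments; individuals diverge
from their species ancestor by 0.1-0.4%, keeping intraspecific distances
under 1%. Sequences evolve site-independently under a two-parameter
process (transition/transversion ratio 4). Markers sit at fixed, published
offsets. Each panel asserts its own realized divergence regime at
construction.

The default 60-query cohort implants classes in proportion to their
relative frequencies among published problematic avian mitogenomes
(misidentification 17, chimera 12, errors/numts 9, assembly 1, mislabeling
1+1, plus 19 clean). Chimera implants carry 1-2 donor fragments that
overlap a marker by at least 150 bp: observed chimeras are, by selection,
the ones whose foreign fragments hit a screened marker, and a generator
placing fragments uniformly would mostly produce cases no three-marker
screen could or should find. Error/numt implants use either 2-5 small
indels in one marker or 13-18% substitutions confined to one marker (above
`tau_noid` against every species, as real numt-divergent regions are).
Misidentification and the mislabeling classes are label swaps on clean
sequences.

What the simulator does **not** model — and hence what passing tests do
not demonstrate about real data: rate variation among sites and lineages,
non-star species topologies with very short internal branches,
incomplete lineage sorting or introgression (hybridizing pairs are only
annotated), indel polymorphism in real alignments, missing or mislabeled
*references*, and chimeras of closely related species, which the distance
scales here deliberately keep apart. On real cohorts the screen's
could_not_be_verified and manual-review outputs matter as much as the
positive calls.

## Problem sizes and determinism

The default verification battery screens one 60-query cohort against an
8-species × 2-individual panel (~1 minute on one CPU), localizes 50
single-fragment chimeras, and checks neighbor joining on 100 random
additive matrices of 4-12 taxa — sizes chosen so the whole suite runs in a
few minutes while every detector is exercised at its decision boundary.
All randomness flows from explicit seeds; identical cohort, configuration
and seed give byte-identical outputs.

## Known limitations

- Contamination below ~2-3% of the genome that clips only the tail of one
  marker can evade every symptom at default thresholds (one such implant
  in the default cohort does); real screens catch these only as "slightly
  longer branch" judgment calls.
- Breakpoints falling in regions where donor and recipient are locally
  identical are placed arbitrarily within the identical run.
- The BLAST-against-everything step of a manual investigation is replaced
  by `tau_noid` against the supplied panel; a divergent region matching a
  species absent from the panel is reported as matching nothing.
- The published/unpublished 2×2 comparison is provided as a plain Pearson
  chi-squared without continuity correction on user-defined strata.
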