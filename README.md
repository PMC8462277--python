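# mitoveritas

Authentication screening for mitochondrial genome sequences.

Public databases hold thousands of "reference" mitogenomes deposited with
little quality control, and a measurable fraction of them are wrong: the
specimen was misidentified, the assembly stitched together DNA of two or
three species (a chimera), the sequence carries numt or sequencing-error
artifacts, a gene was partially duplicated during assembly, or the record
and the describing paper disagree about the species name. Because these
deposits are reused — in phylogenies, divergence dating, DNA
identification, comparative analyses — an unflagged bad mitogenome
contaminates everything downstream.

`mitoveritas` automates the screening procedure a careful systematist would
apply, for cohorts of bird-scale mitogenomes (~16-17 kb):

1. **Markers.** Three protein-coding genes with dense reference coverage —
   ND2 (1,041 bp), COI (696 bp), cytochrome *b* (1,143 bp) — are located in
   each query by fast infix alignment against a reference panel (both
   strands; circularity handled by scanning the doubled sequence). A marker
   is usable evidence above a strict length floor (>600 bp for COI, >800 bp
   for the others).
2. **Gene trees.** Per-marker alignments give uncorrected p-distances
   (mismatches over comparable sites) and neighbor-joining gene trees; each
   query is placed relative to conspecific and heterospecific references.
3. **Symptoms.** Seven signals flag a record: multiple indels in a
   protein-coding alignment (S1); a close match with another species
   outside the conspecific clade (S2); a mismatch between gene trees (S3);
   a long terminal branch inside the conspecific clade (S4); a deep
   divergence outside it (S5); a distant position without any close match
   (S6); a sister lineage on a long branch (S7).
4. **Chimera localization.** Flagged queries are scanned with sliding
   windows (default 150 bp window / 50 bp step) against whole reference
   genomes projected onto the query's coordinates; each window is assigned
   to its nearest species, runs of windows become segments, and breakpoints
   are refined by a per-site split score.
5. **Diagnosis.** Ordered rules map the evidence to one verdict:
   `authentic`, `misidentification`, `chimera`, `seq_errors_numts`,
   `incorrect_assembly`, `mislabeled_in_paper`, `mislabeled_on_genbank`, or
   `could_not_be_verified` (e.g. when conspecific references are not
   reciprocally monophyletic).

A synthetic-data module simulates reference panels with realistic
divergence structure (intraspecific < 1%, interspecific 7.5-23.3%) and
implants every defect class with exact ground truth, so the entire pipeline
is verifiable end to end without downloading anything.

## Worked example

```python
import mitoveritas as mv

cohort = mv.make_cohort(seed=42, n=60)          # panel + 60 queries, truth known
results = mv.MitogenomeScreen.from_cohort(cohort).fit()
print(results.summary())
```

```
Mitogenome authentication screen
========================================
queries screened      : 60
not assessed          : 0
excluded by filters   : 0
verifiable            : 60
problematic           : 40 (66.7% of verifiable)
species with problems : 8

verdict counts
----------------------------------------
  authentic                  20
  misidentification          17
  chimera                    11
  seq_errors_numts            9
  incorrect_assembly          1
  mislabeled_in_paper         1
  mislabeled_on_genbank       1
```

The cohort implants 41 defective records among 19 clean ones; the screen
recovers the implanted class for 40 of the 41 and calls every clean record
authentic. (The one miss is a chimera contributing ~4.5% foreign DNA that
clips only the last ~160 bp of cytochrome *b* — the kind of marginal case
that in practice shows up only as a slightly longer branch.) Per-record
detail, including fired symptoms and chimera segments with refined
breakpoints, is in `results.to_frame()` and `results.write(outdir)`:

```
accession  species        verdict           symptoms
Q0001      aviana alpha   chimera           S4@COI;S5@CYTB;S7@CYTB;S3
Q0004      aviana foxtrot seq_errors_numts  S4@COI;S6@COI
Q0008      aviana bravo   misidentification S2@COI;S2@CYTB;S2@ND2
```

`results.single_marker_detectability()` recomputes every diagnosis from one
marker alone — chimeras whose breakpoints miss that marker collapse into
apparent misidentifications, which is why multi-marker screening matters.

The same pipeline runs from files:

```bash
mitoveritas simulate --seed 42 --out sim/
mitoveritas screen --queries sim/queries.fasta --meta sim/metadata.tsv \
    --panel sim/panel_markers.fasta --genomes sim/panel_genomes.fasta --out out/
mitoveritas report out/
```

## Scope

The package screens sequences against a user-supplied reference panel; it
does not query GenBank, resolve taxonomy beyond a user synonym table, infer
the laboratory origin of chimeras, or attempt full mitogenome annotation.
See `docs/methods.md` for the model, thresholds and known limitations.
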