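# bsjprimer

qPCR assay design for circular RNAs (circRNAs), built around the one
sequence that is unique to a circle: its back-splice junction (BSJ).

## The problem

circRNAs are covalently closed transcripts formed by back-splicing, in
which a downstream splice donor is joined to an upstream splice
acceptor. After circRNAs of interest are called from RNA-seq they are
routinely validated and quantified by RT-qPCR, which needs primers that
detect the circle but not its linear host gene. The only such sequence
is the BSJ itself: a primer pair whose amplicon spans the junction is
convergent (amplifiable) on the circle but divergent (non-functional)
on the linear transcript. Designing these assays at scale is fiddly —
the template is an artificial concatenation of two genomic flanks,
spliced or not depending on the annotation; common SNPs and stable RNA
secondary structure must be kept out of the annealing sites; and each
candidate pair has to be screened against the whole transcriptome for
amplifiable off-targets.

`bsjprimer` implements this as a batch pipeline, for anyone who has a
list of BSJ coordinates and a reference bundle (genome FASTA, exon
GTF, transcript FASTA, optional SNP BED):

1. **Template.** For a circle `[start, end)` the design template is
   `genome[end−f .. end) + genome[start .. start+f)` with flank
   `f = 150` nt by default (a 300-nt template; circles smaller than
   `2f` reduce the template to the circle size). When both circle ends
   fall in exons of an annotated transcript the same walk runs in that
   transcript's exonic coordinate space, so no intronic base enters
   the template. Minus-strand circles are presented in transcription
   orientation.
2. **Masking.** Template positions over common variants, and positions
   paired in a minimum-free-energy fold at least as stable as
   −5 kcal/mol, are flagged for exclusion.
3. **Design.** All junction-spanning placements are enumerated under
   hard windows — primer length 16–20–30 nt (min–opt–max), Tm
   58–59–60 °C (nearest-neighbor model, 50 mM monovalent / 3 mM
   divalent cations, 0.6 mM dNTP), ΔTm ≤ 2 °C, GC 30–50–80 %, amplicon
   50–250 nt, homopolymer runs ≤ 4 — and the 20 best-scoring pairs are
   kept.
4. **Filtering.** Each pair is screened against the transcriptome by
   exhaustive ungapped ≤3-mismatch search; a convergent co-occurrence
   is tolerated only with ≥ 4 mismatches in one primer or ≥ 5 in total
   (strict mode; 3/4 in loose mode). The amplicon is folded: ΔG below
   −15 kcal/mol rejects the pair, ΔG in [−15, −5] rejects it only when
   the structure reaches into a primer annealing site. Among survivors
   the smallest amplicon is selected.

Every engine the pipeline relies on (template walk, folding, Tm,
k-mismatch search) is deterministic and verified in the test suite
against brute-force oracles; a bundled synthetic-data generator plants
hairpins, SNPs and off-target sites with known ground truth.

## Worked example

```bash
python examples/design_assays.py
```

builds a synthetic reference bundle with three circRNAs and designs
assays for them:

```
circ_unspliced: DESIGNED
  forward  5'-CACACCAACACCAAACAC-3'  Tm 58.7 C, GC 50%
  reverse  5'-GTGTTGGGGTGTTTTGTG-3'  Tm 58.7 C, GC 50%
  amplicon 73 nt spanning the BSJ (smallest of 20 passing pairs)
...
design report
=============
total circRNAs     3
success rate       66.7%
```

Both primers sit inside their thermodynamic windows, the 73-nt amplicon
contains the junction (forward primer entirely on the donor side,
reverse on the acceptor side), and it is the smallest of the 20 pairs
that survived every filter. The spliced test circle fails with
`FAIL_NO_CANDIDATES (masked region overlap)` — its random template
folds strongly, so structure masking removes all annealing room; the
failure categories in the report mirror exactly this kind of diagnosis
for real batches. `examples/fold_and_mask.py` and
`examples/offtarget_screen.py` demonstrate the folding mask and the
mismatch-tolerance matrix in isolation.

The same pipeline is available as a CLI:

```bash
bsjprimer fixtures --outdir bundle --seed 1
bsjprimer design --circs bundle/circs.bed --genome bundle/genome.fa \
    --gtf bundle/annotation.gtf --transcriptome bundle/transcriptome.fa \
    --snps bundle/snps.bed --outdir results
```

writing `final_primers.tsv` (one row per circRNA), `all_passing.tsv`
and `design_report.txt`. All Table-style parameters are flags
(`--flank`, `--gc MIN,OPT,MAX`, `--tm MIN,OPT,MAX`, `--snp-filter
strict|loose`, `--offtarget-filter strict|loose`, `--coordinate-base
0|1`, …) with validated ranges.

## Documentation

`docs/methods.md` describes the models (folding energy model, Tm
model, specificity policy), their assumptions, the tunable parameters
and the known limitations.
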