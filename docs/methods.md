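# Methods

## Coordinates and template construction

All internal coordinates are 0-based half-open (BED convention); the
CLI accepts 1-based-inclusive circRNA lists via `--coordinate-base 1`
because published BSJ coordinate lists come in both conventions. A
circle `[start, end)` has its acceptor at `start` and its donor at
`end − 1`; the BSJ joins `end − 1` back to `start`.

The design template concatenates the donor-side flank to the
acceptor-side flank: `genome[end−f .. end) + genome[start .. start+f)`
with `f = min(flank, span // 2)` so the template never exceeds the
circle. The default flank of 150 nt per side gives the standard 300-nt
template; the CLI bounds the flank to 50–500 nt and the default
amplicon window to 50–`min(250, 2·flank)` nt.

**Splicing.** A template is spliced when at least one annotated
transcript carries both circle ends inside its exons ("inside or at
the boundary" is implemented as plain half-open containment of `start`
and `end − 1`). Transcripts are ranked: allowlisted ids first, then
largest total exonic length, then lexicographic id; the first
qualifying transcript is selected, and the flank walk then runs over
that transcript's exonic positions restricted to the circle, so no
intronic base (and no intronic SNP) can appear in the template. If the
selected transcript turns out not to cover both ends the builder falls
back to the unspliced walk with a logged warning rather than failing
the circle. When several transcripts qualify but disagree on exon
structure, the ranked-first rule decides; this is a deliberate,
documented tie-break, not an attempt to find a "best" isoform.

**Strand.** Minus-strand circles are reverse-complemented into
transcription orientation after the plus-strand walk; with symmetric
flanks the donor side again occupies the first `junction_index` bases,
so downstream code never branches on strand. Each template carries a
per-base `genome_map` so masks and tests can be checked base-by-base
against the genome.

## Masking

SNP masking flags every template position whose genomic source
overlaps a variant interval (plain BED input; conversion from other
variant formats is the user's concern). In the strict SNP mode primers
may not cover any flagged position; in the loose mode a candidate is
rejected only when a flag falls in the 3′-end half of the primer
(the half nearest the extending 3′ terminus, rounding the middle base
into the 3′ half), where a mismatch is most damaging to extension.

Structure masking folds the whole template once and, if the fold is at
least as stable as the cutoff (default −5 kcal/mol, matching the lower
edge of the amplicon rule's conditional band), flags every paired
position of the MFE structure. Weaker folds flag nothing — a template
always has *some* marginal self-complementarity, and masking it all
would sterilize design. Folding temperature defaults to 60 °C (the
annealing regime implied by the 58–60 °C Tm window) and is
configurable, but see the model's limitation below.

## Folding model

The built-in engine predicts a pseudoknot-free minimum-free-energy
structure under a deliberately small nearest-neighbor model:

* pairs A:T, C:G and the G:T wobble; N never pairs; every pair must
  enclose ≥ 3 nt (hairpin loop minimum);
* helix energy is the sum of stack terms from a fixed table,
  `ΔG(stack) = 0.4 − 0.5·(s₁ + s₂)` kcal/mol with pair strengths
  s(C:G) = 3, s(A:T) = 2, s(G:T) = 1 (so a GC/GC stack is
  −2.6 kcal/mol);
* helices shorter than 3 pairs contribute nothing (treated as
  unpaired);
* a helix closing a hairpin pays `3.0 + 0.3·(loop − 3)` kcal/mol;
  bulges, internal loops and multiloops are free.

ΔG is minimized by an O(n³) interval dynamic program (a numba kernel;
a 300-nt template folds in tens of milliseconds) with a deterministic
traceback. The model is small enough that the test suite verifies the
DP *exactly* against exhaustive enumeration of all structures on
sequences up to 14 nt (1000 random sequences), and simple enough that
fixtures can plant hairpins with predictable energies: a GC stem of
k pairs with a 4-nt loop folds at `−2.6(k−1) + 3.3` kcal/mol, so
stem 6 lands in the conditional band (−9.7) and stem 12 below the hard
threshold (−25.3). The stack table is parameterized at the annealing
temperature and is not rescaled by the `temperature` argument of the
engine contract; an adapter wrapping an external thermodynamic folder
can implement the same contract when physical energies matter.

## Melting temperature

Primer Tm uses the SantaLucia unified nearest-neighbor ΔH/ΔS set with
terminal initiation terms and, for palindromic primers, the symmetry
correction. Divalent cations are folded into an equivalent monovalent
concentration, `[Na⁺]eq = mono + 120·√(max(Mg − dNTP, 0))` (mM), the
entropy is salt-corrected by `0.368·(N−1)·ln[Na⁺]eq`, and
`Tm = ΔH / (ΔS + R·ln(CT/4))` at a total strand concentration of
250 nM. Defaults: 50 mM monovalent, 3 mM Mg²⁺, 0.6 mM dNTP. The tests
pin the implementation to an independent straight-line reimplementation
of the same tables (0.01 °C) and cross-check it against Biopython's
`Tm_NN` under identical conditions (0.05 °C).

## Candidate enumeration and ranking

All placements (forward start/length on the donor side, reverse
end/length on the acceptor side) are scanned; by default primers flank
the junction and only the amplicon spans it, matching the geometry in
which the pair is divergent on the host transcript. A
`junction_overlap` setting lets primers extend up to that many bases
across the BSJ for users who want junction-anchored primers; 0 is the
default. Hard windows: length 16–20–30 nt, Tm 58–59–60 °C, pair
ΔTm ≤ 2 °C, GC 30–50–80 %, amplicon 50–250 nt, homopolymer runs ≤ 4
(a standard manufacturability cap), no masked position under a primer.
Survivors are ranked by a documented penalty —
`|Tm−opt|` per primer + `|GC−opt|/10` + `0.1·|len−opt|` +
`0.5·ΔTm(pair)` — and the best 20 kept. The enumeration is exhaustive
and deterministic; on ≤ 80-nt toy templates the returned set equals a
brute-force oracle applying the same constraints independently.
Rejection causes are counted during the scan so an empty result can
name its dominant constraint (GC window, Tm window, homopolymer,
masked-region overlap) in the failure report.

## Specificity policy

Each primer is searched over both strands of every transcript by an
exhaustive ungapped Hamming scan with a per-primer limit of
3 mismatches (the contract of a short-read aligner's mismatch mode,
which is also ungapped). A *hit* is an amplifiable configuration: both
primers on one transcript, convergent (the plus-strand alignment
upstream of the minus-strand one), product ≤ 1000 nt (configurable).
This amplifiability reading is essential: every BSJ pair trivially
co-occurs on its own host transcript in divergent orientation, which
cannot amplify and must not count. Hits are judged by the
mismatch-tolerance matrix — strict: tolerated iff one primer has ≥ 4
mismatches or the pair ≥ 5 in total; loose: ≥ 3 / ≥ 4 — applied to the
unordered pair of counts. Sites needing ≥ 4 mismatches in a primer are
invisible to the ≤ 3-mismatch search, which is consistent with the
matrix tolerating them. One OFF_TARGET-classified hit fails the pair;
the report carries the worst hit (fewest total mismatches).

## Amplicon filter and selection

The amplicon of each surviving pair is folded with the same engine.
ΔG < −15 kcal/mol rejects outright; −15 ≤ ΔG ≤ −5 rejects only when a
paired position lies inside a primer annealing segment (first
`len(fwd)` or last `len(rev)` amplicon bases); ΔG > −5 always passes.
Both boundary values fall in the conditional band ("below −15" read as
strict, "between −15 and −5" as inclusive). Template and amplicon are
folded at one configurable temperature. The final assay is the passing
pair with the smallest amplicon — the geometry least likely to pick up
neighboring exons or intronic sequence — with ties broken by lower
penalty, then smaller forward start, then lexicographic forward
sequence (an arbitrary but fixed total order, so runs are
reproducible). Specificity and amplicon filters are independent
predicates; the passing set does not depend on their order.

## Synthetic data generator

`bsjprimer.fixtures` emulates the input bundle at desk scale: one
~12-kb chromosome, a 3-exon and a 1-exon transcript, a transcriptome
of their spliced sequences plus decoys, a small SNP track, and three
circRNAs — one spliced across the 3-exon chain, one 400-nt unspliced,
one 100-nt (template-reduction case). The unspliced circles sit in
A/C-only "control regions": under the model's pairing alphabet such
sequence cannot base-pair at all, so design there is governed purely by
the thermodynamic windows and planted features have fully predictable
effects. Planting utilities insert hairpins of chosen stem length
(energy known from the calibration above), convergent off-target sites
with exact per-primer mismatch counts (verified after planting by a
brute-force scan to exclude unintended matches), or the whole template
as a decoy transcript (making every candidate pair fail specificity).
All randomness flows from one integer seed; the same spec is
byte-identical across runs.

What the generator does **not** emulate: realistic exon/intron length
distributions, GC heterogeneity, repeat families, paralogous gene
families (the hard case for specificity in real genomes), and
transcriptome sizes beyond a few kilobases. Passing the planted-truth
suites therefore demonstrates that the decision rules and engines are
implemented correctly, not that the design success rate on real human
circRNAs will match any particular number; success rates on the random
synthetic templates (where strong folds are common under this model)
are not predictive of real batches.

## Numerical choices and degenerate inputs

Floating-point ties in the folding traceback are resolved by a fixed
scan order (tolerance 1e−7), so identical inputs give identical
structures. Circles smaller than 30 nt are rejected at parse time
(configurable); an empty half-open genome interval returns an empty
string; chromosome-bounds violations and unknown chromosomes fail only
the affected circRNA (`FAIL_RESOURCE`), never the batch. Sequences are
uppercased on input; N is allowed in references (never pairs, never
matches in the specificity scan, disallowed inside primers).

Problem sizes in the shipped tests and the acceptance script (fixture
chromosome ~12 kb, transcriptome ~4 kb, brute-force folding up to
14 nt, toy design templates of 60 nt) were chosen so each oracle
comparison is exhaustive at that size; the engines themselves have no
size-dependent switches.

## Known limitations

* The folding model ignores loop-type penalties beyond hairpins,
  dangling ends, temperature rescaling and pseudoknots; its energies
  are model-internal, not physical free energies from a full
  thermodynamic folder. The
  filter logic (cutoffs, primer-overlap rule) is the contract; the
  engine is pluggable.
* The specificity search is ungapped; indel off-targets are out of
  scope, as are genome-level (intron-spanning) off-targets and 3′-end
  destabilization models.
* No probe design, no primer-dimer screening across candidates, no
  multiplex compatibility.
* One transcript's exon chain defines a spliced template; circles
  spanning isoform-specific exon structures get the ranked transcript,
  not a consensus.
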