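"""Deterministic synthetic reference bundles with planted features.

Generates a genome FASTA, exon GTF, SNP BED, transcriptome FASTA and
circRNA BED that exercise every pipeline stage without downloads.  All
randomness flows from a single integer seed through one generator, so
the same spec always produces byte-identical files.

Planted ground truth (written to ``fixture.json``):

* a spliced circRNA whose ends coincide with exon boundaries of a
  multi-exon transcript;
* an unspliced 400-nt intergenic circRNA placed in a structure-free
  control region (random A/C sequence, which cannot base-pair under
  the folding model's A:T / C:G / G:T alphabet), so primer design
  there is governed purely by the thermodynamic windows;
* a circRNA smaller than twice the default flank (template reduction);
* SNPs inside the unspliced template, inside an intron (invisible to a
  spliced template), and a multi-base deletion interval;
* optional planted hairpins and off-target sites for failure-mode
  tests (:func:`plant_hairpin`, :func:`plant_offtarget`, and the
  bundle-level options of :class:`FixtureSpec`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq import revcomp

__all__ = [
    "FixtureSpec",
    "make_reference_bundle",
    "plant_hairpin",
    "plant_offtarget",
    "mutate_with_mismatches",
]

_BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5,
                    alphabet: str = "ACGT") -> str:
    if alphabet == "ACGT":
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choice(_BASES, size=length, p=p))
    letters = np.array(list(alphabet))
    return "".join(rng.choice(letters, size=length))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one reference bundle.

    The optional plant_* switches modify the unspliced 400-nt circRNA
    (chr1:6000-6400) to drive one failure mode deterministically:

    * ``junction_hairpin_stem`` > 0 plants a GC stem-loop centred on
      the BSJ so every amplicon contains it (stem 12 folds below
      -15 kcal/mol: amplicon hard-reject; the template fold flags the
      stem so primers sit outside it);
    * ``saturating_hairpin`` plants a stem covering nearly the whole
      template, leaving no room for any primer;
    * ``template_offtarget`` appends a decoy transcript containing the
      circRNA's template verbatim, so every candidate pair has a
      perfect convergent off-target.
    """

    seed: int = 1
    chrom: str = "chr1"
    chrom_length: int = 12000
    gc_fraction: float = 0.5
    junction_hairpin_stem: int = 0
    saturating_hairpin: bool = False
    template_offtarget: bool = False

    # fixed landmarks (0-based half-open)
    @property
    def tx1_exons(self):
        return ((1000, 1360), (1600, 1960), (2200, 2560))

    @property
    def tx2_exons(self):
        return ((4000, 5000),)

    @property
    def circ_unspliced(self):
        return (6000, 6400)

    @property
    def circ_small(self):
        return (7000, 7100)


def mutate_with_mismatches(seq: str, n_mismatches: int) -> str:
    """Introduce exactly *n_mismatches* deterministic substitutions,
    spread evenly along the sequence (A<->G, C<->T swaps)."""
    if n_mismatches == 0:
        return seq
    if n_mismatches > len(seq):
        raise ValueError("more mismatches than bases")
    swap = {"A": "G", "G": "A", "C": "T", "T": "C"}
    out = list(seq)
    step = len(seq) / (n_mismatches + 1)
    used = set()
    for k in range(1, n_mismatches + 1):
        pos = min(int(round(k * step)), len(seq) - 1)
        while pos in used:
            pos = (pos + 1) % len(seq)
        used.add(pos)
        out[pos] = swap[out[pos]]
    return "".join(out)


def plant_hairpin(sequence: str, position: int, stem: int, loop: int,
                  rng: np.random.Generator | None = None) -> tuple[str, dict]:
    """Overwrite ``sequence[position : position + 2*stem + loop)`` with a
    perfect GC stem-loop (stem arm, A-loop, reverse-complement arm).

    Overwriting (rather than inserting) keeps all other coordinates
    stable.  Returns the modified sequence and a description of the
    planted structure.
    """
    total = 2 * stem + loop
    if position < 0 or position + total > len(sequence):
        raise ValueError("insufficient space for hairpin")
    if loop < 3:
        raise ValueError("loop must be at least 3 nt")
    rng = rng or np.random.default_rng(0)
    arm = "".join(rng.choice(np.array(list("GC")), size=stem))
    insert = arm + "A" * loop + revcomp(arm)
    modified = sequence[:position] + insert + sequence[position + total:]
    info = {"kind": "HAIRPIN", "position": position, "stem": stem, "loop": loop,
            "arm": arm}
    return modified, info


def plant_offtarget(
    records: dict[str, str],
    fwd_seq: str,
    rev_seq: str,
    mismatches: tuple[int, int],
    spacing: int,
    transcript_id: str = "DECOY_OT",
    rng: np.random.Generator | None = None,
    flank: int = 60,
) -> tuple[dict[str, str], dict]:
    """Add a decoy transcript carrying a convergent binding site:
    the forward primer with m1 substitutions, a spacer, and the reverse
    complement of the reverse primer with m2 substitutions.

    The decoy background is A/C-only so it cannot accidentally provide
    a second binding site; a brute-force scan verifies that the only
    alignments within 3 mismatches are the intended ones.  Raises if
    that check fails.
    """
    from .reference_io import Transcriptome
    from .specificity import search_primer

    rng = rng or np.random.default_rng(0)
    m1, m2 = mismatches
    site = (
        mutate_with_mismatches(fwd_seq, m1)
        + random_sequence(rng, spacing, alphabet="AC")
        + revcomp(mutate_with_mismatches(rev_seq, m2))
    )
    decoy = (
        random_sequence(rng, flank, alphabet="AC")
        + site
        + random_sequence(rng, flank, alphabet="AC")
    )
    out = dict(records)
    if transcript_id in out:
        raise ValueError(f"transcript id {transcript_id!r} already present")
    out[transcript_id] = decoy

    product = len(fwd_seq) + spacing + len(rev_seq)
    info = {
        "kind": "OFFTARGET_SITE",
        "transcript_id": transcript_id,
        "m1": m1,
        "m2": m2,
        "fwd_position": flank,
        "rev_end": flank + len(site),
        "product_size": product,
    }

    # verify: no unintended <=3-mismatch alignments on the decoy
    decoy_only = Transcriptome({transcript_id: decoy})
    expect_fwd = [(flank, "+", m1)] if m1 <= 3 else []
    expect_rev = [(flank + len(site) - len(rev_seq), "-", m2)] if m2 <= 3 else []
    got_fwd = [(a.position, a.strand, a.mismatches)
               for a in search_primer(fwd_seq, decoy_only)]
    got_rev = [(a.position, a.strand, a.mismatches)
               for a in search_primer(rev_seq, decoy_only)]
    if got_fwd != expect_fwd or got_rev != expect_rev:
        raise ValueError(
            "planted off-target created unintended matches: "
            f"fwd {got_fwd} (expected {expect_fwd}), rev {got_rev} (expected {expect_rev})"
        )
    return out, info


def _spliced_sequence(genome_seq: str, exons) -> str:
    return "".join(genome_seq[s:e] for s, e in exons)


def make_reference_bundle(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle files and return their paths.

    Files: ``genome.fa``, ``annotation.gtf``, ``snps.bed``,
    ``transcriptome.fa``, ``circs.bed``, ``fixture.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    chrom_seq = random_sequence(rng, spec.chrom_length, gc=spec.gc_fraction)
    planted: list[dict] = []

    # structure-free control regions (A/C alphabet cannot pair)
    u0, u1 = spec.circ_unspliced
    s0, s1 = spec.circ_small
    chrom_seq = (
        chrom_seq[:u0]
        + random_sequence(rng, u1 - u0, alphabet="AC")
        + chrom_seq[u1:]
    )
    chrom_seq = (
        chrom_seq[:s0]
        + random_sequence(rng, s1 - s0, alphabet="AC")
        + chrom_seq[s1:]
    )

    if spec.junction_hairpin_stem:
        stem = spec.junction_hairpin_stem
        # stem-loop centred on the BSJ of the unspliced circ: first arm at
        # the donor end (template left of the junction), loop split across
        # the junction, second arm at the acceptor start
        arm = "".join(rng.choice(np.array(list("GC")), size=stem))
        left = arm + "AA"   # occupies genome [u1 - stem - 2, u1)
        right = "AA" + revcomp(arm)  # occupies genome [u0, u0 + stem + 2)
        chrom_seq = (
            chrom_seq[: u1 - len(left)] + left + chrom_seq[u1:]
        )
        chrom_seq = chrom_seq[:u0] + right + chrom_seq[u0 + len(right):]
        planted.append({"kind": "HAIRPIN", "where": "junction", "stem": stem,
                        "loop": 4, "circ": "circ_unspliced"})

    if spec.saturating_hairpin:
        # covers template positions [8, 292) of the 300-nt template
        stem, loop = 140, 4
        arm = "".join(rng.choice(np.array(list("GC")), size=stem))
        donor_part = arm + "AA"          # template [8, 150) -> genome [u1-142, u1)
        acceptor_part = "AA" + revcomp(arm)  # template [150, 292) -> genome [u0, u0+142)
        chrom_seq = chrom_seq[: u1 - len(donor_part)] + donor_part + chrom_seq[u1:]
        chrom_seq = chrom_seq[:u0] + acceptor_part + chrom_seq[u0 + len(acceptor_part):]
        planted.append({"kind": "HAIRPIN", "where": "template-saturating",
                        "stem": stem, "loop": loop, "circ": "circ_unspliced"})

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        fh.write(f">{spec.chrom}\n")
        for i in range(0, len(chrom_seq), 70):
            fh.write(chrom_seq[i : i + 70] + "\n")

    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        for tid, gid, exons in (
            ("TX1", "G1", spec.tx1_exons),
            ("TX2", "G2", spec.tx2_exons),
        ):
            for s, e in exons:
                fh.write(
                    f"{spec.chrom}\tfixture\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f'gene_id "{gid}"; transcript_id "{tid}";\n'
                )

    snp_entries = [
        (spec.chrom, 6055, 6056),  # inside the unspliced template (acceptor side)
        (spec.chrom, 1400, 1401),  # TX1 intron: invisible to a spliced template
        (spec.chrom, 50, 53),      # 3-base deletion interval
    ]
    snp_path = outdir / "snps.bed"
    with open(snp_path, "w") as fh:
        for chrom, s, e in snp_entries:
            fh.write(f"{chrom}\t{s}\t{e}\n")

    tx_records = {
        "TX1": _spliced_sequence(chrom_seq, spec.tx1_exons),
        "TX2": _spliced_sequence(chrom_seq, spec.tx2_exons),
        "DECOY1": random_sequence(rng, 1200, gc=spec.gc_fraction),
    }
    if spec.template_offtarget:
        f = 150
        template = chrom_seq[u1 - f : u1] + chrom_seq[u0 : u0 + f]
        tx_records["DECOY_TEMPLATE"] = (
            random_sequence(rng, 80, alphabet="AC")
            + template
            + random_sequence(rng, 80, alphabet="AC")
        )
        planted.append({"kind": "OFFTARGET_SITE", "where": "whole-template",
                        "transcript_id": "DECOY_TEMPLATE", "circ": "circ_unspliced"})
    transcriptome_path = outdir / "transcriptome.fa"
    with open(transcriptome_path, "w") as fh:
        for tid in tx_records:
            fh.write(f">{tid}\n{tx_records[tid]}\n")

    circ_rows = [
        (spec.chrom, spec.tx1_exons[0][0], spec.tx1_exons[-1][1], "circ_spliced", ".", "+"),
        (spec.chrom, u0, u1, "circ_unspliced", ".", "+"),
        (spec.chrom, s0, s1, "circ_small", ".", "+"),
    ]
    circ_path = outdir / "circs.bed"
    with open(circ_path, "w") as fh:
        for row in circ_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    manifest = {
        "seed": spec.seed,
        "chrom": spec.chrom,
        "chrom_length": spec.chrom_length,
        "transcripts": {
            "TX1": [list(e) for e in spec.tx1_exons],
            "TX2": [list(e) for e in spec.tx2_exons],
        },
        "circs": {
            "circ_spliced": {"interval": [spec.tx1_exons[0][0], spec.tx1_exons[-1][1]],
                             "expected_splice": "SPLICED",
                             "exonic_span": sum(e - s for s, e in spec.tx1_exons)},
            "circ_unspliced": {"interval": [u0, u1], "expected_splice": "UNSPLICED"},
            "circ_small": {"interval": [s0, s1], "expected_splice": "UNSPLICED"},
        },
        "snps": [list(e) for e in snp_entries],
        "planted": planted,
    }
    manifest_path = outdir / "fixture.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "genome": genome_path,
        "gtf": gtf_path,
        "snps": snp_path,
        "transcriptome": transcriptome_path,
        "circs": circ_path,
        "manifest": manifest_path,
    }
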