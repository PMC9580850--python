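"""BSJ template construction.

The design template is the donor-side flank concatenated to the
acceptor-side flank around the back-splice junction: on the circle the
donor (position ``end - 1``) is covalently joined to the acceptor
(position ``start``), so the linear design template reads

    genome[end - f .. end) + genome[start .. start + f)

for an unspliced + strand circle with effective flank ``f``.  When both
circle ends fall inside exons of an annotated transcript the same walk
runs in that transcript's exonic coordinate space (introns removed).
Minus-strand circles are presented in transcription orientation
(reverse complement, donor side still first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .reference_io import CircCoordinate, GenomeReference, TranscriptModel
from .seq import revcomp

log = logging.getLogger(__name__)

__all__ = [
    "Template",
    "SpliceStatus",
    "SpliceValue",
    "classify_ends",
    "effective_flank",
    "build_template",
]

SNP_FLAG = "SNP"
STRUCTURE_FLAG = "STRUCTURE"


class SpliceValue(Enum):
    SPLICED = "SPLICED"
    UNSPLICED = "UNSPLICED"


@dataclass(frozen=True)
class SpliceStatus:
    value: SpliceValue
    selected_transcript: Optional[str] = None

    def __post_init__(self):
        if self.value is SpliceValue.SPLICED and not self.selected_transcript:
            raise ValueError("SPLICED status requires a selected transcript")


@dataclass
class Template:
    """The BSJ-centred design template.

    ``sequence[:junction_index]`` comes from the donor side,
    ``sequence[junction_index:]`` from the acceptor side; the BSJ lies
    between indices ``junction_index - 1`` and ``junction_index``.
    ``genome_map[i]`` is the (chrom, position, strand) source of base i;
    ``mask[i]`` is the set of exclusion flags ({"SNP", "STRUCTURE"}).
    """

    circ_id: str
    sequence: str
    junction_index: int
    flank_left: int
    flank_right: int
    spliced: bool
    genome_map: list[tuple[str, int, str]]
    mask: list[set] = field(default_factory=list)
    selected_transcript: Optional[str] = None

    def __post_init__(self):
        if not self.mask:
            self.mask = [set() for _ in self.sequence]
        assert len(self.sequence) == self.flank_left + self.flank_right
        assert self.junction_index == self.flank_left
        assert len(self.genome_map) == len(self.sequence)
        assert len(self.mask) == len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def flagged_positions(self, flag: str) -> list[int]:
        return [i for i, m in enumerate(self.mask) if flag in m]


def classify_ends(
    circ: CircCoordinate, transcripts: Sequence[TranscriptModel]
) -> SpliceStatus:
    """Decide spliced vs unspliced template construction.

    The template is spliced iff some transcript (in ranked order) has
    both the acceptor position ``start`` and the donor position
    ``end - 1`` inside one of its exons; the first such transcript is
    selected.  An intronic end on every candidate transcript means the
    unspliced genomic sequence is used.
    """
    for t in transcripts:
        if t.chrom != circ.chrom:
            continue
        if t.contains_exonic(circ.start) and t.contains_exonic(circ.end - 1):
            return SpliceStatus(SpliceValue.SPLICED, t.transcript_id)
    return SpliceStatus(SpliceValue.UNSPLICED)


def effective_flank(circ_span: int, flank: int) -> int:
    """Per-side flank after circle-size reduction.

    A circle smaller than twice the requested flank cannot provide a
    full flank on both sides without wrapping past itself, so the
    template is reduced to the circle size: min(flank, circ_span // 2).
    """
    if circ_span < 2:
        raise ValueError("circle span must be at least 2")
    if flank < 1:
        raise ValueError("flank must be at least 1")
    return min(flank, circ_span // 2)


def build_template(
    circ: CircCoordinate,
    genome: GenomeReference,
    status: SpliceStatus,
    flank: int = 150,
    transcripts: Optional[Sequence[TranscriptModel]] = None,
) -> Template:
    """Construct the template for one circRNA.

    ``transcripts`` is consulted only when *status* is SPLICED, to find
    the selected transcript's exon chain.  If the selected transcript
    does not actually cover both circle ends the construction falls
    back to the unspliced walk with a warning.
    """
    if circ.chrom not in genome:
        raise KeyError(f"{circ.id}: chromosome {circ.chrom!r} not in genome")
    if circ.start < 0 or circ.end > genome.length(circ.chrom):
        raise ValueError(
            f"{circ.id}: [{circ.start}, {circ.end}) outside {circ.chrom} "
            f"(length {genome.length(circ.chrom)})"
        )

    selected: Optional[TranscriptModel] = None
    if status.value is SpliceValue.SPLICED:
        for t in transcripts or ():
            if t.transcript_id == status.selected_transcript:
                selected = t
                break
        if selected is None or not (
            selected.contains_exonic(circ.start)
            and selected.contains_exonic(circ.end - 1)
        ):
            log.warning(
                "%s: transcript %s does not cover both circle ends; "
                "falling back to unspliced template",
                circ.id,
                status.selected_transcript,
            )
            selected = None

    if selected is not None:
        positions = selected.exonic_positions(circ.start, circ.end)
        spliced = True
    else:
        positions = None
        spliced = False

    if positions is not None:
        span = len(positions)
        f = effective_flank(span, flank)
        donor_pos = positions[-f:]
        acceptor_pos = positions[:f]
    else:
        span = circ.span
        f = effective_flank(span, flank)
        donor_pos = list(range(circ.end - f, circ.end))
        acceptor_pos = list(range(circ.start, circ.start + f))

    plus_map = [(circ.chrom, p, "+") for p in donor_pos + acceptor_pos]
    plus_seq = _fetch_positions(genome, circ.chrom, donor_pos) + _fetch_positions(
        genome, circ.chrom, acceptor_pos
    )

    if circ.strand == "+":
        sequence, genome_map = plus_seq, plus_map
    else:
        # Transcription orientation: reverse-complement; with symmetric
        # flanks the donor side (circle 3' end in transcription order)
        # again occupies the first f bases.
        sequence = revcomp(plus_seq)
        genome_map = [(c, p, "-") for c, p, _ in reversed(plus_map)]

    return Template(
        circ_id=circ.id,
        sequence=sequence,
        junction_index=f,
        flank_left=f,
        flank_right=f,
        spliced=spliced,
        genome_map=genome_map,
        selected_transcript=selected.transcript_id if selected else None,
    )


def _fetch_positions(genome: GenomeReference, chrom: str, positions: list[int]) -> str:
    """Fetch bases at an ascending position list, batching contiguous runs."""
    if not positions:
        return ""
    parts = []
    run_start = prev = positions[0]
    for p in positions[1:]:
        if p != prev + 1:
            parts.append(genome.fetch(chrom, run_start, prev + 1))
            run_start = p
        prev = p
    parts.append(genome.fetch(chrom, run_start, prev + 1))
    return "".join(parts)


def template_to_fasta(templates: Sequence[Template]) -> str:
    """Debug dump: FASTA with ``circ_id|junction=<j>`` headers."""
    out = []
    for t in templates:
        out.append(f">{t.circ_id}|junction={t.junction_index}")
        out.append(t.sequence)
    return "\n".join(out) + "\n"
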