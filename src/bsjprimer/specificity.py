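"""Transcriptome off-target screening of primer pairs.

A primer pair is only dangerous on a transcript when it could actually
amplify: both primers align ungapped on the same transcript in
convergent orientation with a bounded product size.  Each found
configuration is classified with a mismatch-tolerance matrix: under the
strict policy a configuration is tolerated only when a single primer
carries at least 4 mismatches or the two primers carry at least 5 in
total; the loose policy lowers this to 3 / 4.  BSJ primers always match
their linear host transcript in divergent orientation, which can never
amplify and therefore never counts as an off-target.

The search is an exhaustive ungapped (Hamming) scan over both strands,
mirroring a short-read aligner's mismatch mode with a per-primer limit
of 3 — configurations needing 4 or more mismatches in one primer are
invisible to the search, which is exactly why the matrix tolerates them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .primer_design import PrimerPair
from .reference_io import Transcriptome
from .seq import encode, revcomp, validate_bases

__all__ = [
    "PrimerAlignment",
    "OffTargetHit",
    "SpecificityPolicy",
    "HitClass",
    "SpecificityVerdict",
    "search_primer",
    "pair_offtargets",
    "classify_hit",
    "specificity_verdict",
]

DEFAULT_MAX_MISMATCHES = 3
DEFAULT_MAX_PRODUCT = 1000


@dataclass(frozen=True)
class PrimerAlignment:
    """One ungapped match of a primer on a transcript.

    Strand '+' means the primer sequence matches the transcript
    forward; '-' means the primer matches the reverse complement (its
    3' end points to lower coordinates).
    """

    transcript_id: str
    position: int
    strand: str
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.position + self.length


@dataclass(frozen=True)
class OffTargetHit:
    """A potentially amplifiable convergent co-occurrence of both primers."""

    transcript_id: str
    m1: int
    m2: int
    product_size: int
    fwd_alignment: PrimerAlignment
    rev_alignment: PrimerAlignment


class HitClass(Enum):
    OFF_TARGET = "OFF_TARGET"
    TOLERATED = "TOLERATED"


@dataclass(frozen=True)
class SpecificityPolicy:
    """Mismatch-tolerance matrix, strict or loose.

    strict: tolerated iff max(m1, m2) >= 4 or m1 + m2 >= 5
    loose:  tolerated iff max(m1, m2) >= 3 or m1 + m2 >= 4
    The two primer labels are unordered.
    """

    mode: str = "strict"

    def __post_init__(self):
        if self.mode not in ("strict", "loose"):
            raise ValueError("policy mode must be 'strict' or 'loose'")

    @property
    def single_threshold(self) -> int:
        return 4 if self.mode == "strict" else 3

    @property
    def total_threshold(self) -> int:
        return 5 if self.mode == "strict" else 4

    def tolerates(self, m1: int, m2: int) -> bool:
        return max(m1, m2) >= self.single_threshold or m1 + m2 >= self.total_threshold


def classify_hit(m1: int, m2: int, policy: SpecificityPolicy) -> HitClass:
    """Classify one off-target configuration by its mismatch counts."""
    if m1 < 0 or m2 < 0:
        raise ValueError("mismatch counts must be non-negative")
    return HitClass.TOLERATED if policy.tolerates(m1, m2) else HitClass.OFF_TARGET


def search_primer(
    primer_seq: str,
    transcriptome: Transcriptome,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[PrimerAlignment]:
    """Exhaustive ungapped alignments of a primer over both strands.

    Returns every window with Hamming distance <= *max_mismatches*,
    ordered by (transcript id, position, strand).  N in a transcript
    never matches.
    """
    if len(primer_seq) < 8:
        raise ValueError("primer too short to search (< 8 nt)")
    validate_bases(primer_seq, allow_n=False)
    plen = len(primer_seq)
    patterns = (("+", encode(primer_seq)), ("-", encode(revcomp(primer_seq))))
    hits = []
    for tid in transcriptome.ids:
        arr = transcriptome.encoded(tid)
        if len(arr) < plen:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, plen)
        for strand, pat in patterns:
            mm = (windows != pat).sum(axis=1)
            for pos in np.nonzero(mm <= max_mismatches)[0]:
                hits.append(
                    PrimerAlignment(tid, int(pos), strand, int(mm[pos]), plen)
                )
    hits.sort(key=lambda a: (a.transcript_id, a.position, a.strand))
    return hits


def pair_offtargets(
    fwd_hits: Sequence[PrimerAlignment],
    rev_hits: Sequence[PrimerAlignment],
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> list[OffTargetHit]:
    """Combine single-primer alignments into amplifiable configurations.

    A configuration needs both primers on the same transcript, one on
    each strand, with the plus-strand alignment starting before the
    minus-strand one (convergent) and a product no longer than
    *max_product*.  Divergent or same-strand co-occurrences (the
    host-gene situation for BSJ primers) yield nothing.
    """
    out = []
    for a in fwd_hits:
        for b in rev_hits:
            if a.transcript_id != b.transcript_id or a.strand == b.strand:
                continue
            plus, minus = (a, b) if a.strand == "+" else (b, a)
            if plus.position >= minus.position:
                continue
            product = minus.end - plus.position
            if 0 < product <= max_product:
                out.append(
                    OffTargetHit(
                        transcript_id=a.transcript_id,
                        m1=a.mismatches,
                        m2=b.mismatches,
                        product_size=product,
                        fwd_alignment=a,
                        rev_alignment=b,
                    )
                )
    return out


@dataclass(frozen=True)
class SpecificityVerdict:
    passed: bool
    hits: tuple[OffTargetHit, ...]
    offending: tuple[OffTargetHit, ...]
    worst: Optional[OffTargetHit]


def specificity_verdict(
    pair: PrimerPair,
    transcriptome: Transcriptome,
    policy: Optional[SpecificityPolicy] = None,
    max_product: int = DEFAULT_MAX_PRODUCT,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> SpecificityVerdict:
    """Screen one primer pair; fail iff any configuration classifies as
    OFF_TARGET.  ``worst`` is the offending hit with the fewest total
    mismatches."""
    policy = policy or SpecificityPolicy()
    fwd_hits = search_primer(pair.fwd_seq, transcriptome, max_mismatches)
    rev_hits = search_primer(pair.rev_seq, transcriptome, max_mismatches)
    hits = pair_offtargets(fwd_hits, rev_hits, max_product)
    offending = tuple(
        h for h in hits if classify_hit(h.m1, h.m2, policy) is HitClass.OFF_TARGET
    )
    worst = min(offending, key=lambda h: (h.m1 + h.m2, h.transcript_id), default=None)
    return SpecificityVerdict(not offending, tuple(hits), offending, worst)
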