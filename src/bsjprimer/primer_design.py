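"""Constraint-based enumeration of BSJ-spanning primer pairs.

Instead of delegating to an external designer, all admissible
(forward start, forward length, reverse end, reverse length)
placements on the masked template are scanned against hard windows
(length, Tm, GC, Tm difference, amplicon size, homopolymer cap,
mask avoidance) and ranked by a documented penalty; the best
``n_candidates`` are returned.  The amplicon must contain the
junction, so the pair is convergent on the circle but divergent on
the linear host transcript.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .seq import max_homopolymer_run, revcomp
from .template_builder import SNP_FLAG, STRUCTURE_FLAG, Template
from .thermo import ThermoSettings, gc_content, melting_temperature

__all__ = ["PrimerPair", "CandidateResult", "enumerate_candidates", "penalty"]


@dataclass(frozen=True)
class PrimerPair:
    """A candidate forward/reverse primer pair on one template.

    Template coordinates are 0-based; the amplicon is
    ``template[fwd_start:rev_end]``.  ``rev_seq`` is the reverse
    complement of its template segment (the sequence of the oligo).
    """

    fwd_seq: str
    rev_seq: str
    fwd_start: int
    rev_end: int
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    amplicon_seq: str
    penalty: float

    @property
    def fwd_len(self) -> int:
        return len(self.fwd_seq)

    @property
    def rev_len(self) -> int:
        return len(self.rev_seq)

    @property
    def fwd_end(self) -> int:
        return self.fwd_start + self.fwd_len

    @property
    def rev_start(self) -> int:
        return self.rev_end - self.rev_len

    @property
    def amplicon_len(self) -> int:
        return self.rev_end - self.fwd_start


class CandidateResult(list):
    """Candidate list plus per-constraint rejection counts.

    Behaves as a plain list of :class:`PrimerPair`; ``rejections``
    records why single-primer or pair placements were discarded, and
    ``dominant_rejection`` names the most frequent cause (used in the
    failure report when the list is empty).
    """

    def __init__(self, pairs, rejections: Counter):
        super().__init__(pairs)
        self.rejections = rejections

    @property
    def dominant_rejection(self) -> str:
        if not self.rejections:
            return "no admissible placement"
        return self.rejections.most_common(1)[0][0]


def penalty(
    fwd_tm: float, rev_tm: float,
    fwd_gc: float, rev_gc: float,
    fwd_len: int, rev_len: int,
    settings: ThermoSettings,
) -> float:
    """Ranking penalty: 0 only when both primers meet every optimum.

    Weighted sum of per-primer |Tm - opt| (1 per degree C),
    |GC - opt| / 10, |len - opt| * 0.1, and 0.5 * |Tm difference|.
    """
    tm_opt = settings.primer_tm[1]
    gc_opt = settings.primer_gc[1]
    len_opt = settings.primer_len[1]
    return (
        abs(fwd_tm - tm_opt) + abs(rev_tm - tm_opt)
        + (abs(fwd_gc - gc_opt) + abs(rev_gc - gc_opt)) / 10.0
        + 0.1 * (abs(fwd_len - len_opt) + abs(rev_len - len_opt))
        + 0.5 * abs(fwd_tm - rev_tm)
    )


def pair_penalty(pair: PrimerPair, settings: ThermoSettings) -> float:
    return penalty(
        pair.fwd_tm, pair.rev_tm, pair.fwd_gc, pair.rev_gc,
        pair.fwd_len, pair.rev_len, settings,
    )


def _scan_primers(
    template: Template,
    lo: int,
    hi: int,
    is_forward: bool,
    settings: ThermoSettings,
    snp_mode: str,
    rejections: Counter,
):
    """All admissible single primers whose template segment lies in [lo, hi).

    Returns tuples (start, end, oligo_seq, tm, gc).  For the reverse
    primer the oligo is the reverse complement of the segment and its
    3' end maps to the segment start.
    """
    seq = template.sequence
    mask = template.mask
    len_min, _len_opt, len_max = settings.primer_len
    tm_min, _tm_opt, tm_max = settings.primer_tm
    gc_min, _gc_opt, gc_max = settings.primer_gc
    out = []
    for start in range(lo, hi - len_min + 1):
        for plen in range(len_min, min(len_max, hi - start) + 1):
            end = start + plen
            segment = seq[start:end]
            if "N" in segment:
                rejections["ambiguous base"] += 1
                continue
            flags = set().union(*mask[start:end]) if plen else set()
            if STRUCTURE_FLAG in flags:
                rejections["masked region overlap"] += 1
                continue
            if snp_mode == "strict":
                if SNP_FLAG in flags:
                    rejections["masked region overlap"] += 1
                    continue
            else:
                # loose: only the 3'-end half of the primer must be SNP-free
                half = plen - plen // 2
                if is_forward:
                    three_prime = range(end - half, end)
                else:
                    three_prime = range(start, start + half)
                if any(SNP_FLAG in mask[i] for i in three_prime):
                    rejections["masked region overlap"] += 1
                    continue
            oligo = segment if is_forward else revcomp(segment)
            if max_homopolymer_run(oligo) > settings.max_poly_x:
                rejections["homopolymer run"] += 1
                continue
            gc = gc_content(oligo)
            if not gc_min <= gc <= gc_max:
                rejections["GC window"] += 1
                continue
            tm = melting_temperature(
                oligo, settings.monovalent, settings.divalent, settings.dntp
            )
            if not tm_min <= tm <= tm_max:
                rejections["Tm window"] += 1
                continue
            out.append((start, end, oligo, tm, gc))
    return out


def enumerate_candidates(
    template: Template,
    settings: Optional[ThermoSettings] = None,
    snp_mode: str = "strict",
) -> CandidateResult:
    """Enumerate ranked BSJ-spanning primer pairs on a masked template.

    The forward primer lies entirely on the donor side
    (``[0, junction_index + junction_overlap)``), the reverse primer
    entirely on the acceptor side
    (``[junction_index - junction_overlap, len)``); the amplicon always
    contains the junction.  Candidates are sorted penalty-ascending
    (ties: smaller amplicon, then leftmost, then sequence) and the best
    ``n_candidates`` returned.  An empty result records the dominant
    rejection reason.
    """
    settings = settings or ThermoSettings()
    if snp_mode not in ("strict", "loose"):
        raise ValueError("snp_mode must be 'strict' or 'loose'")
    j = template.junction_index
    n = len(template.sequence)
    rejections: Counter = Counter()
    ov = settings.junction_overlap

    fwd = _scan_primers(
        template, 0, min(j + ov, n), True, settings, snp_mode, rejections
    )
    rev = _scan_primers(
        template, max(j - ov, 0), n, False, settings, snp_mode, rejections
    )

    amp_min, amp_max = settings.amplicon_len
    pairs = []
    for f_start, f_end, f_seq, f_tm, f_gc in fwd:
        for r_start, r_end, r_seq, r_tm, r_gc in rev:
            if r_start < f_end:
                continue
            # amplicon must contain the BSJ (indices j-1 and j)
            if not (f_start <= j - 1 and r_end >= j + 1):
                rejections["junction not spanned"] += 1
                continue
            amp_len = r_end - f_start
            if not amp_min <= amp_len <= amp_max:
                rejections["amplicon length window"] += 1
                continue
            if abs(f_tm - r_tm) > settings.max_tm_diff:
                rejections["Tm difference"] += 1
                continue
            pen = penalty(f_tm, r_tm, f_gc, r_gc, len(f_seq), len(r_seq), settings)
            pairs.append(
                PrimerPair(
                    fwd_seq=f_seq, rev_seq=r_seq,
                    fwd_start=f_start, rev_end=r_end,
                    fwd_tm=f_tm, rev_tm=r_tm, fwd_gc=f_gc, rev_gc=r_gc,
                    amplicon_seq=template.sequence[f_start:r_end],
                    penalty=pen,
                )
            )
    pairs.sort(key=lambda p: (p.penalty, p.amplicon_len, p.fwd_start, p.fwd_seq))
    return CandidateResult(pairs[: settings.n_candidates], rejections)
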