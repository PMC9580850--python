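"""Amplicon structure filtering, final selection, and the per-circRNA
design pipeline.

The amplicon rule: a fold more stable than the hard threshold
(-15 kcal/mol, exclusive) rejects the pair outright; a fold inside the
conditional band [-15, -5] rejects only when a paired position falls
inside one of the primer annealing segments; anything weaker than
-5 kcal/mol passes.  Among pairs passing every filter the one with the
smallest amplicon is selected — a short amplicon has the best chance of
amplifying only the BSJ region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .folding import BuiltinFolder
from .masking import (
    DEFAULT_FOLD_TEMPERATURE,
    DEFAULT_STRUCTURE_DG_CUTOFF,
    flag_snps,
    flag_structure,
)
from .primer_design import CandidateResult, PrimerPair, enumerate_candidates
from .reference_io import (
    CircCoordinate,
    GenomeReference,
    SnpTrack,
    Transcriptome,
    TranscriptModel,
)
from .specificity import SpecificityPolicy, specificity_verdict
from .template_builder import (
    SpliceStatus,
    SpliceValue,
    Template,
    build_template,
    classify_ends,
)
from .thermo import ThermoSettings

log = logging.getLogger(__name__)

__all__ = [
    "AmpliconDecision",
    "AmpliconVerdict",
    "FilterSettings",
    "DesignSettings",
    "DesignResources",
    "DesignStatus",
    "DesignOutcome",
    "amplicon_structure_verdict",
    "select_final",
    "run_design",
    "summarize",
    "DesignReport",
]


class AmpliconDecision(Enum):
    PASS = "PASS"
    REJECT_HARD = "REJECT_HARD"
    REJECT_PRIMER_OVERLAP = "REJECT_PRIMER_OVERLAP"


@dataclass(frozen=True)
class AmpliconVerdict:
    decision: AmpliconDecision
    delta_g: float
    overlapping_primer: Optional[str] = None  # "fwd" | "rev"


@dataclass(frozen=True)
class FilterSettings:
    """Post-design filter thresholds.

    ``dg_hard`` / ``dg_soft`` delimit the amplicon-structure rule
    (exactly -15 falls in the conditional band; exactly -5 does too).
    """

    dg_hard: float = -15.0
    dg_soft: float = -5.0
    specificity_mode: str = "strict"
    snp_mode: str = "strict"
    max_offtarget_product: int = 1000

    def __post_init__(self):
        if not self.dg_hard < self.dg_soft < 0:
            raise ValueError("need dg_hard < dg_soft < 0")


@dataclass(frozen=True)
class DesignSettings:
    """Everything tunable about one design run."""

    flank: int = 150
    splicing: bool = True
    thermo: ThermoSettings = field(default_factory=ThermoSettings)
    filters: FilterSettings = field(default_factory=FilterSettings)
    structure_dg_cutoff: float = DEFAULT_STRUCTURE_DG_CUTOFF
    fold_temperature: float = DEFAULT_FOLD_TEMPERATURE


@dataclass
class DesignResources:
    """Loaded reference inputs shared by all circRNAs of a run."""

    genome: GenomeReference
    transcripts: Sequence[TranscriptModel]
    snps: SnpTrack
    transcriptome: Transcriptome
    folding_engine: object = field(default_factory=BuiltinFolder)


class DesignStatus(Enum):
    DESIGNED = "DESIGNED"
    FAIL_NO_CANDIDATES = "FAIL_NO_CANDIDATES"
    FAIL_SPECIFICITY = "FAIL_SPECIFICITY"
    FAIL_AMPLICON_STRUCTURE = "FAIL_AMPLICON_STRUCTURE"
    FAIL_RESOURCE = "FAIL_RESOURCE"


@dataclass
class DesignOutcome:
    """Per-circRNA result: a selected pair, all passing pairs, or a
    categorized failure with detail."""

    circ_id: str
    status: DesignStatus
    circ: Optional[CircCoordinate] = None
    selected: Optional[PrimerPair] = None
    passing: list = field(default_factory=list)
    failure_detail: str = ""
    template: Optional[Template] = None

    def __post_init__(self):
        if (self.status is DesignStatus.DESIGNED) != (self.selected is not None):
            raise ValueError("DESIGNED iff a selected pair is present")
        if self.selected is not None and self.selected not in self.passing:
            raise ValueError("selected pair must be among the passing pairs")


def amplicon_structure_verdict(
    pair: PrimerPair,
    engine=None,
    settings: Optional[FilterSettings] = None,
    temperature: float = DEFAULT_FOLD_TEMPERATURE,
) -> AmpliconVerdict:
    """Apply the hard/conditional amplicon folding rule to one pair."""
    engine = engine or BuiltinFolder()
    settings = settings or FilterSettings()
    result = engine.fold(pair.amplicon_seq, temperature)
    dg = result.delta_g
    if dg < settings.dg_hard:
        return AmpliconVerdict(AmpliconDecision.REJECT_HARD, dg)
    if settings.dg_hard <= dg <= settings.dg_soft:
        amp_len = pair.amplicon_len
        fwd_region = range(0, pair.fwd_len)
        rev_region = range(amp_len - pair.rev_len, amp_len)
        paired = result.paired_positions
        if any(p in paired for p in fwd_region):
            return AmpliconVerdict(AmpliconDecision.REJECT_PRIMER_OVERLAP, dg, "fwd")
        if any(p in paired for p in rev_region):
            return AmpliconVerdict(AmpliconDecision.REJECT_PRIMER_OVERLAP, dg, "rev")
    return AmpliconVerdict(AmpliconDecision.PASS, dg)


def select_final(passing: Sequence[PrimerPair]) -> Optional[PrimerPair]:
    """Smallest amplicon wins; ties broken by lower penalty, then
    smaller forward start, then lexicographic forward sequence."""
    if not passing:
        return None
    return min(
        passing,
        key=lambda p: (p.amplicon_len, p.penalty, p.fwd_start, p.fwd_seq),
    )


def run_design(
    circ: CircCoordinate,
    resources: DesignResources,
    settings: Optional[DesignSettings] = None,
) -> DesignOutcome:
    """Run the full per-circRNA pipeline:

    template construction -> SNP/structure masking -> candidate
    enumeration -> transcriptome specificity -> amplicon folding ->
    smallest-amplicon selection.  The failure status names the last
    stage at which every surviving candidate was eliminated.
    """
    settings = settings or DesignSettings()

    try:
        if settings.splicing:
            status = classify_ends(circ, resources.transcripts)
        else:
            status = SpliceStatus(SpliceValue.UNSPLICED)
        template = build_template(
            circ,
            resources.genome,
            status,
            flank=settings.flank,
            transcripts=resources.transcripts,
        )
    except (KeyError, ValueError) as exc:
        return DesignOutcome(
            circ.id, DesignStatus.FAIL_RESOURCE, circ=circ, failure_detail=str(exc)
        )

    flag_snps(template, resources.snps)
    flag_structure(
        template,
        resources.folding_engine,
        settings.structure_dg_cutoff,
        settings.fold_temperature,
    )

    candidates: CandidateResult = enumerate_candidates(
        template, settings.thermo, settings.filters.snp_mode
    )
    if not candidates:
        return DesignOutcome(
            circ.id,
            DesignStatus.FAIL_NO_CANDIDATES,
            circ=circ,
            failure_detail=f"dominant constraint: {candidates.dominant_rejection}",
            template=template,
        )

    policy = SpecificityPolicy(settings.filters.specificity_mode)
    specific = []
    worst_detail = ""
    for pair in candidates:
        verdict = specificity_verdict(
            pair,
            resources.transcriptome,
            policy,
            settings.filters.max_offtarget_product,
        )
        if verdict.passed:
            specific.append(pair)
        elif verdict.worst is not None and not worst_detail:
            w = verdict.worst
            worst_detail = (
                f"worst off-target on {w.transcript_id}: "
                f"{w.m1}+{w.m2} mismatches, product {w.product_size} nt"
            )
    if not specific:
        return DesignOutcome(
            circ.id,
            DesignStatus.FAIL_SPECIFICITY,
            circ=circ,
            failure_detail=worst_detail or "all candidates have off-targets",
            template=template,
        )

    passing = []
    reject_detail = ""
    for pair in specific:
        verdict = amplicon_structure_verdict(
            pair,
            resources.folding_engine,
            settings.filters,
            settings.fold_temperature,
        )
        if verdict.decision is AmpliconDecision.PASS:
            passing.append(pair)
        elif not reject_detail:
            reject_detail = (
                f"amplicon dG {verdict.delta_g:.2f} kcal/mol "
                f"({verdict.decision.value})"
            )
    if not passing:
        return DesignOutcome(
            circ.id,
            DesignStatus.FAIL_AMPLICON_STRUCTURE,
            circ=circ,
            failure_detail=reject_detail,
            template=template,
        )

    selected = select_final(passing)
    return DesignOutcome(
        circ.id,
        DesignStatus.DESIGNED,
        circ=circ,
        selected=selected,
        passing=passing,
        template=template,
    )


@dataclass(frozen=True)
class DesignReport:
    total: int
    counts: dict
    success_rate: float  # percent

    def render(self) -> str:
        lines = [
            "design report",
            "=============",
            f"total circRNAs     {self.total}",
            f"success rate       {self.success_rate:.1f}%",
            "",
            "status breakdown",
        ]
        for status in DesignStatus:
            n = self.counts.get(status.value, 0)
            pct = 100.0 * n / self.total if self.total else 0.0
            lines.append(f"  {status.value:<24s} {n:>6d}  ({pct:.1f}%)")
        return "\n".join(lines) + "\n"


def summarize(outcomes: Sequence[DesignOutcome]) -> DesignReport:
    """Totals, per-status counts and the design success rate (percent)."""
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    counts: dict[str, int] = {s.value: 0 for s in DesignStatus}
    for o in outcomes:
        counts[o.status.value] += 1
    total = len(outcomes)
    rate = 100.0 * counts[DesignStatus.DESIGNED.value] / total
    return DesignReport(total=total, counts=counts, success_rate=rate)
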