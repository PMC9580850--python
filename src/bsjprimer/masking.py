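"""Template masking: flag positions primers must avoid.

Two sources of flags, applied before primer design:

* SNP — the genomic position behind a template base overlaps a
  common-variant interval (a variant under a primer shifts Tm and can
  abolish annealing in some samples);
* STRUCTURE — the base is paired in the template's minimum-free-energy
  fold and that fold is at least as stable as the cutoff (default
  -5 kcal/mol; weaker, transient structures are ignored so they do not
  sterilize the whole template).

Flagging is idempotent: re-running adds no new information.
"""

from __future__ import annotations

import logging
from typing import Optional

from .folding import BuiltinFolder, StructureResult
from .reference_io import SnpTrack
from .template_builder import SNP_FLAG, STRUCTURE_FLAG, Template

log = logging.getLogger(__name__)

__all__ = ["flag_snps", "flag_structure"]

DEFAULT_STRUCTURE_DG_CUTOFF = -5.0
DEFAULT_FOLD_TEMPERATURE = 60.0


def flag_snps(template: Template, snps: SnpTrack) -> int:
    """Add the SNP flag to every template position whose genomic source
    overlaps a variant interval.  Returns the number of flagged positions."""
    count = 0
    for i, (chrom, pos, _strand) in enumerate(template.genome_map):
        if snps.overlaps(chrom, pos):
            template.mask[i].add(SNP_FLAG)
            count += 1
    log.debug("%s: %d SNP-flagged positions", template.circ_id, count)
    return count


def flag_structure(
    template: Template,
    engine=None,
    structure_dg_cutoff: float = DEFAULT_STRUCTURE_DG_CUTOFF,
    temperature: float = DEFAULT_FOLD_TEMPERATURE,
) -> Optional[StructureResult]:
    """Fold the template and flag all paired positions, if the fold is
    at least as stable as *structure_dg_cutoff*.

    Returns the fold result (for reporting); positions are flagged only
    when ``delta_g <= structure_dg_cutoff``.
    """
    engine = engine or BuiltinFolder()
    result = engine.fold(template.sequence, temperature)
    if result.delta_g <= structure_dg_cutoff:
        for pos in result.paired_positions:
            template.mask[pos].add(STRUCTURE_FLAG)
        log.debug(
            "%s: fold dG=%.2f, %d structure-flagged positions",
            template.circ_id, result.delta_g, len(result.paired_positions),
        )
    return result
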