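"""Tabular output writers for a design run.

Three artifacts, written to the run's output directory:

* ``final_primers.tsv`` — one row per input circRNA (selected pair or
  failure status);
* ``all_passing.tsv`` — one row per primer pair that passed every
  filter, for every circRNA;
* ``design_report.txt`` — totals, per-status counts and the success
  rate.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .filtering import DesignOutcome, summarize

__all__ = ["FINAL_COLUMNS", "PASSING_COLUMNS", "write_outputs", "outcomes_to_frame"]

FINAL_COLUMNS = [
    "circ_id", "chrom", "start", "end", "strand", "status",
    "fwd_seq", "rev_seq", "fwd_tm", "rev_tm", "fwd_gc", "rev_gc",
    "amplicon_len", "n_passing", "failure_detail",
]

PASSING_COLUMNS = [
    "circ_id", "fwd_seq", "rev_seq", "fwd_start", "rev_end",
    "fwd_tm", "rev_tm", "fwd_gc", "rev_gc", "amplicon_len", "penalty",
]


def outcomes_to_frame(outcomes: Sequence[DesignOutcome]) -> pd.DataFrame:
    rows = []
    for o in outcomes:
        sel = o.selected
        rows.append({
            "circ_id": o.circ_id,
            "chrom": o.circ.chrom if o.circ else "",
            "start": o.circ.start if o.circ else "",
            "end": o.circ.end if o.circ else "",
            "strand": o.circ.strand if o.circ else "",
            "status": o.status.value,
            "fwd_seq": sel.fwd_seq if sel else "",
            "rev_seq": sel.rev_seq if sel else "",
            "fwd_tm": round(sel.fwd_tm, 2) if sel else "",
            "rev_tm": round(sel.rev_tm, 2) if sel else "",
            "fwd_gc": round(sel.fwd_gc, 1) if sel else "",
            "rev_gc": round(sel.rev_gc, 1) if sel else "",
            "amplicon_len": sel.amplicon_len if sel else "",
            "n_passing": len(o.passing),
            "failure_detail": o.failure_detail,
        })
    return pd.DataFrame(rows, columns=FINAL_COLUMNS)


def write_outputs(outcomes: Sequence[DesignOutcome], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    final_path = outdir / "final_primers.tsv"
    outcomes_to_frame(outcomes).to_csv(final_path, sep="\t", index=False)

    passing_rows = []
    for o in outcomes:
        for p in o.passing:
            passing_rows.append({
                "circ_id": o.circ_id,
                "fwd_seq": p.fwd_seq, "rev_seq": p.rev_seq,
                "fwd_start": p.fwd_start, "rev_end": p.rev_end,
                "fwd_tm": round(p.fwd_tm, 2), "rev_tm": round(p.rev_tm, 2),
                "fwd_gc": round(p.fwd_gc, 1), "rev_gc": round(p.rev_gc, 1),
                "amplicon_len": p.amplicon_len, "penalty": round(p.penalty, 4),
            })
    passing_path = outdir / "all_passing.tsv"
    pd.DataFrame(passing_rows, columns=PASSING_COLUMNS).to_csv(
        passing_path, sep="\t", index=False
    )

    report_path = outdir / "design_report.txt"
    report_path.write_text(summarize(outcomes).render())

    return {"final": final_path, "passing": passing_path, "report": report_path}
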