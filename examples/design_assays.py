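"""End-to-end circRNA qPCR assay design on a synthetic reference bundle.

Generates a small genome/annotation/transcriptome bundle with three
circRNAs, runs the full design pipeline on each, and prints the
selected primer pair (or the failure category) plus the batch report.
"""

import tempfile
from pathlib import Path

from bsjprimer import DesignResources, run_design, summarize
from bsjprimer.fixtures import FixtureSpec, make_reference_bundle
from bsjprimer.reference_io import (
    load_genome,
    load_snp_track,
    load_transcriptome,
    parse_circ_list,
    parse_exon_annotation,
)

with tempfile.TemporaryDirectory() as tmp:
    paths = make_reference_bundle(FixtureSpec(seed=1), Path(tmp))
    resources = DesignResources(
        genome=load_genome(paths["genome"]),
        transcripts=parse_exon_annotation(paths["gtf"]),
        snps=load_snp_track(paths["snps"]),
        transcriptome=load_transcriptome(paths["transcriptome"]),
    )
    outcomes = [run_design(c, resources) for c in parse_circ_list(paths["circs"])]

for o in outcomes:
    print(f"{o.circ_id}: {o.status.value}")
    if o.selected:
        p = o.selected
        print(f"  forward  5'-{p.fwd_seq}-3'  Tm {p.fwd_tm:.1f} C, GC {p.fwd_gc:.0f}%")
        print(f"  reverse  5'-{p.rev_seq}-3'  Tm {p.rev_tm:.1f} C, GC {p.rev_gc:.0f}%")
        print(f"  amplicon {p.amplicon_len} nt spanning the BSJ "
              f"(smallest of {len(o.passing)} passing pairs)")
    elif o.failure_detail:
        print(f"  {o.failure_detail}")

print()
print(summarize(outcomes).render())
# The amplicon always contains the back-splice junction, so the pair is
# convergent (amplifiable) only on the circle; on the linear host
# transcript the same primers point away from each other.
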