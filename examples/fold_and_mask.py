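"""Secondary-structure masking of a design template.

Builds a toy template containing one strong planted hairpin, folds it
with the built-in engine, and shows which positions the primer
enumerator is told to avoid.
"""

from bsjprimer.folding import fold
from bsjprimer.masking import flag_structure
from bsjprimer.seq import revcomp
from bsjprimer.template_builder import STRUCTURE_FLAG, Template

arm = "GCGCGGCCGG"                       # 10-bp GC stem
seq = "AC" * 20 + arm + "AAAA" + revcomp(arm) + "CA" * 20
template = Template(
    circ_id="demo", sequence=seq, junction_index=len(seq) // 2,
    flank_left=len(seq) // 2, flank_right=len(seq) - len(seq) // 2,
    spliced=False, genome_map=[("chr1", i, "+") for i in range(len(seq))],
)

result = flag_structure(template)
print("template:", seq)
print("fold:    ", result.pairing)
print(f"delta G = {result.delta_g:.1f} kcal/mol "
      "(<= -5: paired positions are masked)")
flagged = template.flagged_positions(STRUCTURE_FLAG)
print(f"{len(flagged)} masked positions: {flagged}")
print()
weak = fold("ACACA" + "GGG" + "AAAA" + "CCC" + "ACACA")
print(f"a 3-pair helix folds at {weak.delta_g:.1f} kcal/mol — weaker than "
      "the -5 kcal/mol cutoff, so it would not be masked")
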