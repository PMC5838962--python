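"""Design a G4-disrupting mutant and a loop control for the Huck motif.

Disruption substitutes G->A in the two inner guanine runs, which is the
most effective way to prevent quadruplex folding; the CG->TC loop control
keeps loop lengths (and hence the score) untouched, separating structure
effects from sequence effects.
"""

from g4ltr import (
    WILD_TYPE_MOTIFS,
    design_g4_mutant,
    design_loop_control,
    make_mutagenic_primer,
    scan,
)

seq = WILD_TYPE_MOTIFS["Huck"]
(hit,) = scan(seq, strands="+", seq_id="Huck")
print(f"wild-type : {seq}  (score {hit.score:.0f})")

disrupted = design_g4_mutant(seq, hit)
print(f"g4 mutant : {disrupted.mutant_seq}  ({len(disrupted.substitutions)} G->A)")
print(f"            re-scan over the motif finds "
      f"{len(scan(disrupted.mutant_seq, strands='+'))} hits")

control = design_loop_control(seq, hit, "CG", "TC")
(retained,) = scan(control.mutant_seq, strands="+")
print(f"loop ctrl : {control.mutant_seq}  (score {retained.score:.0f}, unchanged)")

primer = make_mutagenic_primer(seq, disrupted, flank=15)
print(f"primer    : {primer}")
print(
    "\nThe disrupting mutant loses detection entirely; the loop control "
    "keeps an identical-scoring PQS, so any expression difference between "
    "them tracks quadruplex structure, not the substituted bases."
)
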