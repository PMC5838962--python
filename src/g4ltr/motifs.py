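"""Experimentally characterised wild-type G4 motifs from maize LTRs.

Four short oligonucleotide motifs from the long terminal repeats of the
maize Gypsy retrotransposon families Huck, Gyma, Tekay and Dagaf.  Each
was shown to fold into a monomolecular G-quadruplex in vitro (CD
spectroscopy, UV melting, native PAGE); all carry four guanine runs with
short loops.  They serve as ground-truth positives for the scanner and as
templates for disruption and loop-control mutant design.
"""

from __future__ import annotations

WILD_TYPE_MOTIFS: dict[str, str] = {
    "Huck": "CGGGGATATAGGGGGAACGCAGGGACGCGGGGC",
    "Gyma": "CTGGGCGGGGATGACGCGGGGTAGAGCAGGGCT",
    "Tekay": "CAGGGGTTAGGGTTAGGGGATTTTGGGCC",
    "Dagaf": "TTGGGTGACCTAGGGGTAGGGTTAAGGGAGG",
}
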