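"""Scan candidate calcium-blade motifs in human protein segments.

The functional motif is a six-residue core D-x-[DNST]-x-[DN]-[GADN] whose
calcium ligands are completed by an acidic residue two positions after the
core (for the blade-type sites). Matching a 9-mer therefore means all the
sequence requirements for a blade-type calcium site are present.
"""

from camotif import MotifDefinition, scan

candidates = {
    "BBS2_HUMAN": ["DFDGDGKKE", "DLNSDGVNE"],
    "KPTN_HUMAN": ["DVDLDGRPE", "DLTGDGLQE"],
    "TIP_HUMAN": ["DFDGDGHMD", "DYNMDGYPD"],
}

definition = MotifDefinition(spacer=2)
for protein, segments in candidates.items():
    n = sum(1 for s in segments if scan(s, definition))
    print(f"{protein}: {n}/{len(segments)} segments match the motif pattern")

# A single Asp -> Glu change at the first motif position (the BBS2 D174E
# disease variant) breaks the pattern: Glu cannot occupy the first D position.
edited = "EFDGDGKKE"
print(f"D174E variant {edited}: {len(scan(edited, definition))} matches "
      "(calcium binding predicted lost)")
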