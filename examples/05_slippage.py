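"""Repeat expansion as a route to motif emergence.

Replication slippage on a hexanucleotide unit duplicates DG at the protein
level. Expanding a single DG tandemly shows when a functional core pattern
first appears: three aligned D positions are needed, i.e. at least DGDGDG.
"""

from camotif import MotifDefinition, scan
from camotif.synthetic import slippage_expand

seq = "LLNVLDGSTKL"
site = seq.index("DG")
core = MotifDefinition()  # core-only pattern, no tail requirement

for copies in range(4):
    expanded = slippage_expand(seq, site, copies)
    matches = scan(expanded, core)
    tract = "DG" * (copies + 1)
    print(f"+{copies} DG copies -> ...{tract}... : "
          f"{len(matches)} core match(es)")
# 0 and 1 extra copies give no match; from DGDGDG onward each further DG
# adds one more (overlapping) way to read D at positions 1, 3 and 5.
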