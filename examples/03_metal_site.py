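"""Characterize the coordination shell of a motif-bound calcium.

Shows the ligand classification (side-chain direct vs backbone carbonyl),
the relation of each ligand to the motif (positions 1/3/5, the carbonyl of
the residue after the motif, downstream additional residue) and the
additional-ligand separation, here generated at the calcium-blade value of
two residues.
"""

from camotif import (
    StructureSimConfig,
    build_site,
    find_motifs,
    link_site_to_motif,
    make_loop_structure,
)

structure, truth = make_loop_structure(
    StructureSimConfig(seed=7, extra_ligand_separation=2)
)
(hit,) = find_motifs(structure)
site = link_site_to_motif(build_site(structure, structure.metals[0]), hit)

print(f"{site.element} site, coordination number {site.coordination_number}")
for lig in site.ligands:
    print(
        f"  {lig.residue.res_name} {lig.residue.author_id} {lig.atom.name}"
        f"  {lig.distance:.2f} A  {lig.klass.value}  "
        f"[{lig.relation_to_motif.value}]"
    )
print(f"additional-ligand separation(s): {site.additional_separations} "
      "(residues strictly between motif position 6 and the extra ligand)")
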