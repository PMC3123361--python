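"""Find Dx[DN]xDG loops in a 3-D structure by pseudoatom search.

Builds a synthetic structure with a known calcium loop plus three decoy
loops of identical sequence but scrambled backbone, then scans it. Only the
genuine loop passes the geometric filter: the decoys match the sequence
constraints but not the pseudoatom geometry.
"""

from camotif import StructureSimConfig, find_motifs, make_loop_structure

structure, truth = make_loop_structure(
    StructureSimConfig(seed=42, n_decoys=3, noise_sigma=0.1)
)
print(f"structure {structure.id}: chains {sorted(structure.chains)} "
      f"(A = real site, {truth.decoy_chains} = decoys)")

hits = find_motifs(structure)
for hit in hits:
    print(
        f"hit: chain {hit.chain_id} @ {hit.start} {hit.motif_sequence} | "
        f"pseudoatom RMSD {hit.pseudo_rmsd:.2f} A | "
        f"extended-main-chain RMSD vs reference {hit.ext_rmsd_vs_ref:.2f} A | "
        f"metal bound: {hit.metal_bound}"
    )
print(f"planted truth: chain {truth.chain_id} @ {truth.motif_start}")
# The pseudoatom RMSD reflects only the 0.1 A coordinate noise; a value far
# below the 1.0 A acceptance cutoff means an essentially canonical loop.
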