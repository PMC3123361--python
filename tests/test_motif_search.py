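"""Pseudoatom motif search: planted truth, oracles, filters, context."""

import numpy as np
import pytest

from camotif import (
    StructureSimConfig,
    find_motifs,
    make_loop_structure,
    rmsd_vs_reference,
    secondary_context,
)
from camotif.geometry import kabsch_superpose
from camotif.motif_search import (
    MotifHit,
    _window_pseudocoords,
    default_query,
    extended_mainchain_pointset,
)
from camotif.peptide import ResidueSpec, build_peptide
from camotif.structio import Structure
from camotif.synthetic import FLANK_LEN, TEMPLATE_LOOP_SEQ


def brute_force_hits(structure, query, reference, cutoff):
    """Naive all-windows scan: constraints + full Kabsch on every window."""
    offsets = [off for off, _ in query.positions]
    allowed = [a for _, a in query.positions]
    ref_coords = query.reference_coords()
    accepted = set()
    for chain_id, residues in structure.chains.items():
        for i in range(len(residues) - 5):
            window6 = residues[i : i + 6]
            if not all(r.is_standard_aa for r in window6):
                continue
            if not all(
                window6[off].one_letter in al for off, al in zip(offsets, allowed)
            ):
                continue
            contiguous = all(
                b.index == a.index + 1
                and a.atom("CA") is not None
                and b.atom("CA") is not None
                and np.linalg.norm(a.atom("CA").coord - b.atom("CA").coord) < 4.5
                for a, b in zip(window6, window6[1:])
            )
            if not contiguous:
                continue
            cand = _window_pseudocoords(window6[:5], offsets)
            if cand is None:
                continue
            _, rmsd = kabsch_superpose(cand, ref_coords)
            if rmsd <= cutoff:
                accepted.add((chain_id, window6[0].author_id))
    return accepted


class TestFindMotifs:
    def test_planted_template_recovered_exactly(self, template, reference):
        structure, truth = template
        hits = find_motifs(structure, reference=reference)
        assert len(hits) == 1
        (hit,) = hits
        assert (hit.chain_id, hit.start) == (truth.chain_id, truth.motif_start)
        assert hit.pseudo_rmsd <= 0.01
        assert hit.ext_rmsd_vs_ref == pytest.approx(0.0, abs=1e-6)
        assert hit.motif_sequence == "DKDGDG"
        assert hit.has_gly6
        assert hit.metal_bound

    def test_d_position_mutations_block_detection(self):
        structure, _ = make_loop_structure(
            StructureSimConfig(seed=5, mutate_positions={1: "A", 3: "A", 5: "A"})
        )
        assert find_motifs(structure) == []

    def test_decoy_loops_yield_no_hits(self, reference):
        structure, truth = make_loop_structure(
            StructureSimConfig(seed=9, n_decoys=5)
        )
        hits = find_motifs(structure, reference=reference)
        assert {h.chain_id for h in hits} == {truth.chain_id}
        assert len(hits) == 1

    def test_noise_recall_at_default_cutoff(self, reference):
        """Recall over 100 noisy replicates at sigma = 0.2 A (fixed seeds)."""
        found = 0
        for i in range(100):
            structure, truth = make_loop_structure(
                StructureSimConfig(seed=1000 + i, noise_sigma=0.2)
            )
            hits = find_motifs(structure, reference=reference)
            found += any(h.start == truth.motif_start for h in hits)
        recall = found / 100
        assert recall >= 0.95
        assert recall == pytest.approx(0.97)  # pinned measurement, fixed seeds

    def test_equivalence_with_brute_force_oracle(self, reference):
        query = default_query(reference)
        for seed in range(20):
            structure, _ = make_loop_structure(
                StructureSimConfig(
                    seed=seed,
                    n_decoys=seed % 3,
                    noise_sigma=0.15 * (seed % 4),
                )
            )
            fast = {
                (h.chain_id, h.start)
                for h in find_motifs(structure, reference=reference)
            }
            slow = brute_force_hits(structure, query, reference, 1.0)
            assert fast == slow

    def test_cutoff_monotonicity(self, reference):
        structure, _ = make_loop_structure(
            StructureSimConfig(seed=21, noise_sigma=0.3, n_decoys=2)
        )
        previous: set = set()
        for cutoff in (0.05, 0.2, 0.5, 1.0, 2.0):
            hits = {
                (h.chain_id, h.start)
                for h in find_motifs(
                    structure, reference=reference, pseudo_rmsd_cutoff=cutoff
                )
            }
            assert previous <= hits
            previous = hits

    def test_no_duplicate_hits_and_sorted(self, reference):
        structure, _ = make_loop_structure(StructureSimConfig(seed=2, n_decoys=3))
        hits = find_motifs(structure, reference=reference)
        keys = [(h.chain_id, h.start) for h in hits]
        assert len(keys) == len(set(keys))
        assert keys == sorted(
            keys, key=lambda k: (k[0], [h.window_residues[0].index
                                        for h in hits if h.chain_id == k[0]][0])
        )

    def test_chain_order_independence(self, reference):
        structure, _ = make_loop_structure(StructureSimConfig(seed=2, n_decoys=2))
        reordered = Structure(
            id=structure.id,
            chains={
                cid: structure.chains[cid]
                for cid in reversed(list(structure.chains))
            },
        )
        a = [(h.chain_id, h.start) for h in find_motifs(structure, reference=reference)]
        b = [(h.chain_id, h.start) for h in find_motifs(reordered, reference=reference)]
        assert a == b

    def test_require_metal_filters_unbound(self, reference):
        bound, _ = make_loop_structure(StructureSimConfig(seed=3))
        unbound, _ = make_loop_structure(
            StructureSimConfig(seed=3, plant_metal=False)
        )
        assert len(find_motifs(bound, reference=reference, require_metal=True)) == 1
        assert find_motifs(unbound, reference=reference, require_metal=True) == []

    def test_invalid_cutoff_rejected(self, template_structure, reference):
        with pytest.raises(ValueError):
            find_motifs(template_structure, reference=reference,
                        pseudo_rmsd_cutoff=0.0)

    def test_empty_structure_yields_no_hits(self, reference):
        empty = Structure(id="x", chains={"A": []})
        assert find_motifs(empty, reference=reference) == []


class TestRmsdVsReference:
    def test_reference_vs_itself_is_zero(self, reference):
        hit = MotifHit(
            structure_id="ref", chain_id="A", start="1",
            window_residues=reference.residues, pseudo_rmsd=0.0,
        )
        assert rmsd_vs_reference(hit, reference) == pytest.approx(0.0, abs=1e-9)

    def test_extended_mainchain_pointset_labels(self, motif_window):
        ps = extended_mainchain_pointset(motif_window)
        assert len(ps) == 30
        expected = [
            f"{i}:{name}"
            for i in range(1, 7)
            for name in ("N", "CA", "C", "O", "CB")
        ]
        assert ps.labels == expected

    def test_all_gly_window_uses_virtual_cb(self):
        residues = build_peptide(
            [ResidueSpec("G", -80.0, 60.0 + 10 * i) for i in range(6)]
        )
        ps = extended_mainchain_pointset(residues)
        assert len(ps) == 30  # six virtual CBs included

    def test_missing_backbone_atom_reported(self, template):
        structure, _ = make_loop_structure(StructureSimConfig(seed=33))
        window = [r for r in structure.chains["A"][FLANK_LEN : FLANK_LEN + 6]]
        window[2].atoms = [a for a in window[2].atoms if a.name != "O"]
        with pytest.raises(ValueError, match="lacks backbone atom O"):
            extended_mainchain_pointset(window)


class TestSecondaryContext:
    def _structure_with_flanks(self, phi, psi):
        specs = (
            [ResidueSpec("A", phi, psi) for _ in range(6)]
            + [
                ResidueSpec(aa, p, q)
                for aa, (p, q) in zip(
                    TEMPLATE_LOOP_SEQ[:6],
                    [(-57.15, -20.02), (-21.88, -79.08), (-172.58, 62.76),
                     (141.14, 42.47), (-166.73, 73.66), (157.38, -18.85)],
                )
            ]
            + [ResidueSpec("A", phi, psi) for _ in range(6)]
        )
        residues = build_peptide(specs)
        structure = Structure(id="ctx", chains={"A": residues})
        hit = MotifHit(
            structure_id="ctx", chain_id="A", start=residues[6].author_id,
            window_residues=residues[6:12], pseudo_rmsd=0.0,
        )
        return structure, hit

    def test_idealized_helix_flanks(self):
        structure, hit = self._structure_with_flanks(-57.0, -47.0)
        assert secondary_context(hit, structure) == ("helix", "helix")

    def test_idealized_strand_flanks(self):
        structure, hit = self._structure_with_flanks(-120.0, 120.0)
        assert secondary_context(hit, structure) == ("strand", "strand")

    def test_random_coil_flanks(self):
        rng = np.random.default_rng(8)
        # alternating incompatible regions -> no majority label
        specs = []
        for i in range(6):
            specs.append(
                ResidueSpec("A", -57.0, -47.0) if i % 2 == 0
                else ResidueSpec("A", -120.0, 120.0)
            )
        coil = [
            (
                s.phi + rng.uniform(-10, 10),
                s.psi + rng.uniform(-10, 10),
            )
            for s in specs
        ]
        structure, hit = self._structure_with_flanks(-57.0, -47.0)
        chain = structure.chains["A"]
        rebuilt = build_peptide(
            [ResidueSpec("A", p, q) for p, q in coil]
            + [ResidueSpec(r.one_letter, -100.0, 100.0) for r in chain[6:12]]
            + [ResidueSpec("A", c[0], c[1]) for c in coil]
        )
        structure2 = Structure(id="coil", chains={"A": rebuilt})
        hit2 = MotifHit(
            structure_id="coil", chain_id="A", start=rebuilt[6].author_id,
            window_residues=rebuilt[6:12], pseudo_rmsd=0.0,
        )
        assert secondary_context(hit2, structure2) == ("other", "other")

    def test_short_flank_is_other(self, template, reference):
        structure, _ = make_loop_structure(StructureSimConfig(seed=12))
        chain = structure.chains["A"]
        truncated = Structure(id="t", chains={"A": chain[FLANK_LEN - 2 :]})
        hits = find_motifs(truncated, reference=reference)
        assert len(hits) == 1
        up, _ = secondary_context(hits[0], truncated)
        assert up == "other"
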