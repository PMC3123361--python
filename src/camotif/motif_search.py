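"""Pseudoatom substructure search for Dx[DN]xDG calcium-binding loops.

The query describes the three D positions of the motif (window offsets
0/2/4) by two pseudoatoms per residue — the C-alpha for the main chain and
the side-chain heavy-atom centroid (C-alpha for Gly) — together with
position-specific allowed residue sets: Asp at the first D position;
Asp/Asn/Ser/Thr at the second; Asp/Asn at the third. Candidate windows are
sequence-contiguous; accepted windows are scored by the pseudoatom RMSD
after least-squares superposition on the query and by the 30-atom
extended-main-chain RMSD against a reference EF-hand loop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    EXTENDED_MAINCHAIN_ATOMS,
    PointSet,
    kabsch_superpose,
    phi_psi,
    virtual_cbeta,
)
from .structio import Residue, Structure

logger = logging.getLogger(__name__)

#: Maximum neighbour C-alpha separation within a window (chain-break guard).
CA_CA_CONTIGUITY_CUTOFF = 4.5
#: Default pseudoatom RMSD acceptance threshold, Angstrom.
DEFAULT_PSEUDO_RMSD_CUTOFF = 1.0

#: Allowed residues at the three D positions (window offsets 0, 2, 4).
D_POSITION_ALLOWED = (
    frozenset("D"),
    frozenset("DNST"),
    frozenset("DN"),
)


@dataclass(frozen=True)
class PseudoatomQuery:
    """D-position query: allowed residue sets + reference pseudoatom coords.

    ``reference_pseudoatoms`` holds, for each constrained position, a
    (main-chain, side-chain) coordinate pair taken from the reference motif.
    """

    positions: tuple[tuple[int, frozenset[str]], ...]
    reference_pseudoatoms: tuple[tuple[np.ndarray, np.ndarray], ...]
    window_length: int = 5

    def __post_init__(self) -> None:
        offsets = [off for off, _ in self.positions]
        if offsets != sorted(set(offsets)) or any(
            off >= self.window_length for off in offsets
        ):
            raise ValueError("offsets must be strictly increasing and < window_length")
        if any(not allowed for _, allowed in self.positions):
            raise ValueError("allowed residue sets must be non-empty")
        if len(self.reference_pseudoatoms) != len(self.positions):
            raise ValueError("one pseudoatom pair required per constrained position")

    def reference_coords(self) -> np.ndarray:
        """Stacked (mc, sc) pseudoatom coordinates, shape (2 * n_positions, 3)."""
        coords = []
        for mc, sc in self.reference_pseudoatoms:
            coords.append(mc)
            coords.append(sc)
        return np.asarray(coords, float)


@dataclass
class ReferenceMotif:
    """Six-residue reference loop for extended-main-chain comparison."""

    source: str
    residues: list[Residue]

    def pointset(self) -> PointSet:
        ps = extended_mainchain_pointset(self.residues)
        if len(ps) != 30:
            raise ValueError("reference motif must yield 30 extended-main-chain atoms")
        return ps


@dataclass
class MotifHit:
    """A located Dx[DN]xDG instance."""

    structure_id: str
    chain_id: str
    start: str  # author number + icode of the first D
    window_residues: list[Residue]  # positions 1-6
    pseudo_rmsd: float
    ext_rmsd_vs_ref: float | None = None
    metal_bound: bool = False
    context: tuple[str, str] | None = None

    @property
    def motif_sequence(self) -> str:
        return "".join(r.one_letter for r in self.window_residues)

    @property
    def has_gly6(self) -> bool:
        return self.window_residues[5].res_name == "GLY"

    def to_json_dict(self) -> dict:
        return {
            "structure": self.structure_id,
            "chain": self.chain_id,
            "start": self.start,
            "motif_sequence": self.motif_sequence,
            "pseudo_rmsd": round(self.pseudo_rmsd, 3),
            "ext_rmsd_vs_ref": (
                None if self.ext_rmsd_vs_ref is None else round(self.ext_rmsd_vs_ref, 2)
            ),
            "has_gly6": self.has_gly6,
            "metal_bound": self.metal_bound,
            "context": list(self.context) if self.context else None,
        }


def sidechain_pseudoatom(residue: Residue) -> np.ndarray:
    """Side-chain heavy-atom centroid; C-alpha for Gly (or if none present)."""
    side = residue.sidechain_atoms()
    if side:
        return np.mean([a.coord for a in side], axis=0)
    ca = residue.atom("CA")
    if ca is None:
        raise ValueError(f"residue {residue.author_id} has no CA atom")
    return ca.coord


def mainchain_pseudoatom(residue: Residue) -> np.ndarray:
    ca = residue.atom("CA")
    if ca is None:
        raise ValueError(f"residue {residue.author_id} has no CA atom")
    return ca.coord


def extended_mainchain_pointset(residues: list[Residue]) -> PointSet:
    """N/CA/C/O plus (possibly virtual) CB for a six-residue window.

    The CB is constructed geometrically for Gly and for any residue whose
    real CB is missing (a warning is logged in the latter case).
    """
    if len(residues) != 6:
        raise ValueError("extended-main-chain windows are 6 residues")
    labels, coords = [], []
    for i, res in enumerate(residues):
        bb = {}
        for name in ("N", "CA", "C", "O"):
            atom = res.atom(name)
            if atom is None:
                raise ValueError(
                    f"residue {res.res_name} {res.author_id} lacks backbone atom {name}"
                )
            bb[name] = atom.coord
        cb_atom = res.atom("CB")
        if cb_atom is not None:
            cb = cb_atom.coord
        else:
            if res.res_name != "GLY":
                logger.warning(
                    "residue %s %s has no CB; virtual CB substituted",
                    res.res_name, res.author_id,
                )
            cb = virtual_cbeta(bb["N"], bb["CA"], bb["C"])
        for name in EXTENDED_MAINCHAIN_ATOMS:
            labels.append(f"{i + 1}:{name}")
            coords.append(cb if name == "CB" else bb[name])
    return PointSet(labels=labels, coords=np.array(coords))


def default_query(reference: ReferenceMotif) -> PseudoatomQuery:
    """The minimal D-position query built from a reference motif."""
    offsets = (0, 2, 4)
    pseudo = []
    for off in offsets:
        res = reference.residues[off]
        pseudo.append((mainchain_pseudoatom(res), sidechain_pseudoatom(res)))
    return PseudoatomQuery(
        positions=tuple(zip(offsets, D_POSITION_ALLOWED)),
        reference_pseudoatoms=tuple(pseudo),
    )


def _window_pseudocoords(
    window: list[Residue], offsets: list[int]
) -> np.ndarray | None:
    coords = []
    for off in offsets:
        res = window[off]
        try:
            coords.append(mainchain_pseudoatom(res))
            coords.append(sidechain_pseudoatom(res))
        except ValueError:
            return None
    return np.asarray(coords, float)


def _contiguous(window: list[Residue]) -> bool:
    for a, b in zip(window, window[1:]):
        if b.index != a.index + 1:
            return False
        ca_a, ca_b = a.atom("CA"), b.atom("CA")
        if ca_a is None or ca_b is None:
            return False
        if float(np.linalg.norm(ca_a.coord - ca_b.coord)) >= CA_CA_CONTIGUITY_CUTOFF:
            return False
    return True


def _prefilter(cand: np.ndarray, ref_dists: np.ndarray, cutoff: float) -> bool:
    """Sound distance-matrix reject before the Kabsch fit.

    After optimal superposition at RMSD r, any inter-pseudoatom distance can
    deviate from the query's by at most sqrt(2N) * r, so windows with a
    larger deviation cannot pass the cutoff. This prunes decoys without ever
    rejecting a window the full fit would accept.
    """
    d = np.linalg.norm(cand[:, None] - cand[None, :], axis=-1)
    iu = np.triu_indices(len(cand), 1)
    slack = math.sqrt(2 * len(cand)) * cutoff
    return bool(np.all(np.abs(d[iu] - ref_dists) <= slack))


def find_motifs(
    structure: Structure,
    query: PseudoatomQuery | None = None,
    reference: ReferenceMotif | None = None,
    pseudo_rmsd_cutoff: float = DEFAULT_PSEUDO_RMSD_CUTOFF,
    require_metal: bool = False,
    coordination_cutoff: float = 3.0,
    use_prefilter: bool = True,
) -> list[MotifHit]:
    """Scan all sequence-contiguous windows of a structure for motif instances.

    A hit must satisfy the per-position residue constraints, be contiguous
    (consecutive internal indices, neighbour CA-CA below 4.5 A), and fit the
    query pseudoatoms with RMSD at or below ``pseudo_rmsd_cutoff``. Hits
    carry the 30-atom extended-main-chain RMSD against ``reference`` when the
    six-residue window is complete. With ``require_metal`` only windows whose
    D-position side chains place at least two oxygen atoms within
    ``coordination_cutoff`` of one indexed metal are kept — an automated
    version of screening hits for bound metal.
    """
    if query is None:
        if reference is None:
            from .synthetic import reference_motif  # default packaged template
            reference = reference_motif()
        query = default_query(reference)
    if pseudo_rmsd_cutoff <= 0:
        raise ValueError("pseudo_rmsd_cutoff must be positive")

    offsets = [off for off, _ in query.positions]
    allowed_sets = [allowed for _, allowed in query.positions]
    ref_coords = query.reference_coords()
    iu = np.triu_indices(len(ref_coords), 1)
    ref_dists = np.linalg.norm(
        ref_coords[:, None] - ref_coords[None, :], axis=-1
    )[iu]
    ref_ps = reference.pointset() if reference is not None else None
    metal_coords = (
        np.array([m.coord for m in structure.metals]) if structure.metals else None
    )

    hits: list[MotifHit] = []
    for chain_id in sorted(structure.chains):
        residues = structure.chains[chain_id]
        # windows span window_length residues for matching, 6 for reporting
        for i in range(len(residues) - max(query.window_length, 6) + 1):
            window6 = residues[i : i + 6]
            match_window = residues[i : i + query.window_length]
            if not all(r.is_standard_aa for r in window6):
                continue
            if not all(
                match_window[off].one_letter in allowed
                for off, allowed in zip(offsets, allowed_sets)
            ):
                continue
            if not _contiguous(window6):
                continue
            cand = _window_pseudocoords(match_window, offsets)
            if cand is None:
                continue
            if use_prefilter and not _prefilter(cand, ref_dists, pseudo_rmsd_cutoff):
                continue
            _, prmsd = kabsch_superpose(cand, ref_coords)
            if prmsd > pseudo_rmsd_cutoff:
                continue
            if require_metal:
                if metal_coords is None or not _metal_screen(
                    match_window, offsets, metal_coords, coordination_cutoff
                ):
                    continue
            hit = MotifHit(
                structure_id=structure.id,
                chain_id=chain_id,
                start=window6[0].author_id,
                window_residues=window6,
                pseudo_rmsd=prmsd,
            )
            if metal_coords is not None:
                hit.metal_bound = _metal_screen(
                    match_window, offsets, metal_coords, coordination_cutoff
                )
            if ref_ps is not None:
                try:
                    hit.ext_rmsd_vs_ref = rmsd_vs_reference(hit, reference)
                except ValueError:
                    hit.ext_rmsd_vs_ref = None
            hits.append(hit)
    hits.sort(key=lambda h: (h.chain_id, h.window_residues[0].index))
    return hits


def _metal_screen(
    window: list[Residue],
    offsets: list[int],
    metal_coords: np.ndarray,
    cutoff: float,
) -> bool:
    """At least two D-position side-chain O atoms within cutoff of one metal."""
    oxy = []
    for off in offsets:
        for atom in window[off].sidechain_atoms():
            if atom.element == "O":
                oxy.append(atom.coord)
    if len(oxy) < 2:
        return False
    d = np.linalg.norm(np.array(oxy)[:, None] - metal_coords[None, :], axis=-1)
    return bool(np.any((d <= cutoff).sum(axis=0) >= 2))


def annotate_metal_binding(
    hits: list[MotifHit],
    structure: Structure,
    coordination_cutoff: float = 3.0,
) -> None:
    """Fill ``metal_bound`` on hits without filtering."""
    if not structure.metals:
        for hit in hits:
            hit.metal_bound = False
        return
    metal_coords = np.array([m.coord for m in structure.metals])
    for hit in hits:
        hit.metal_bound = _metal_screen(
            hit.window_residues, [0, 2, 4], metal_coords, coordination_cutoff
        )


def rmsd_vs_reference(hit: MotifHit, reference: ReferenceMotif) -> float:
    """30-atom extended-main-chain RMSD of a hit window vs the reference."""
    ps = extended_mainchain_pointset(hit.window_residues)
    _, value = kabsch_superpose(ps, reference.pointset())
    hit.ext_rmsd_vs_ref = value
    return value


# phi/psi regions for the simple secondary-structure labeller (an
# approximation of STRIDE-style assignment, used only for context reports)
def _phipsi_label(phi: float | None, psi: float | None) -> str:
    if phi is None or psi is None:
        return "other"
    if -120.0 <= phi <= -30.0 and -80.0 <= psi <= 5.0:
        return "helix"
    if -180.0 <= phi <= -45.0 and (psi >= 90.0 or psi <= -150.0):
        return "strand"
    return "other"


def secondary_context(
    hit: MotifHit, structure: Structure, flank: int = 6
) -> tuple[str, str]:
    """Majority phi/psi-region label of the 6 residues flanking the motif."""
    chain = structure.chains[hit.chain_id]
    first = hit.window_residues[0].index
    last = hit.window_residues[5].index

    def classify(segment: list[Residue]) -> str:
        if len(segment) < flank:
            return "other"
        bb = []
        for res in segment:
            coords = {n: res.atom(n) for n in ("N", "CA", "C")}
            if any(v is None for v in coords.values()):
                return "other"
            bb.append({n: a.coord for n, a in coords.items()})
        labels = [_phipsi_label(phi, psi) for phi, psi in phi_psi(bb)]
        # termini of the segment lack phi or psi; interior labels decide
        counts = {lab: labels.count(lab) for lab in ("helix", "strand", "other")}
        best = max(counts, key=counts.get)
        return best if counts[best] > len(labels) / 2 else "other"

    upstream = classify(chain[max(0, first - flank) : first])
    downstream = classify(chain[last + 1 : last + 1 + flank])
    context = (upstream, downstream)
    hit.context = context
    return context
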