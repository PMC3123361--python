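"""Metal coordination-shell analysis at calcium-binding motif sites.

Characterizes each bound metal: which protein atoms ligate it (side-chain
oxygens, backbone carbonyls, or polar atoms bridged through a water), how
the ligands relate to a detected Dx[DN]xDG motif (positions 1/3/5, the
carbonyl of the residue after position 6, or a downstream "additional"
acidic residue), the spacing of additional ligands, and binuclear centres
where two metals share ligand residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .structio import Atom, Residue, Structure

#: Default metal-ligand distance cutoff, Angstrom. Typical Ca-O bonds run
#: around 2.4 A; 3.0 A accommodates longer coordination bonds.
DEFAULT_COORDINATION_CUTOFF = 3.0
#: Hydrogen-bond cutoff for water-mediated ligation, Angstrom.
DEFAULT_WATER_HBOND_CUTOFF = 3.5


class LigandClass(str, Enum):
    SIDECHAIN_DIRECT = "sidechain_direct"
    BACKBONE_CARBONYL = "backbone_carbonyl"
    WATER_MEDIATED = "water_mediated"
    OTHER = "other"


class MotifRelation(str, Enum):
    MOTIF_POSITION_1 = "motif_position_1"
    MOTIF_POSITION_3 = "motif_position_3"
    MOTIF_POSITION_5 = "motif_position_5"
    MOTIF_PLUS1_CARBONYL = "motif_plus1_carbonyl"
    DOWNSTREAM_ADDITIONAL = "downstream_additional"
    UNRELATED = "unrelated"


@dataclass
class Ligand:
    """One ligating protein atom (directly or through a bridging water)."""

    residue: Residue
    atom: Atom
    distance: float  # Angstrom, atom to metal
    klass: LigandClass
    bridging_water: Atom | None = None
    relation_to_motif: MotifRelation | None = None

    def to_json_dict(self) -> dict:
        return {
            "chain": self.residue.chain_id,
            "residue": self.residue.res_name,
            "author_id": self.residue.author_id,
            "atom": self.atom.name,
            "distance": round(self.distance, 2),
            "class": self.klass.value,
            "via_water": self.bridging_water is not None,
            "relation_to_motif": (
                self.relation_to_motif.value if self.relation_to_motif else None
            ),
        }


@dataclass
class MetalSite:
    """One metal and its classified coordination shell."""

    metal: Atom
    element: str
    ligands: list[Ligand] = field(default_factory=list)
    linked_hit: "object | None" = None  # MotifHit, untyped to avoid cycle
    additional_separations: list[int] = field(default_factory=list)
    preceding_additional_flag: bool = False
    binuclear_partner: "MetalSite | None" = None

    @property
    def coordination_number(self) -> int:
        """Direct ligand atoms plus each bridging water counted once."""
        direct = sum(
            1 for lig in self.ligands if lig.klass != LigandClass.WATER_MEDIATED
        )
        waters = {
            id(lig.bridging_water)
            for lig in self.ligands
            if lig.klass == LigandClass.WATER_MEDIATED
        }
        return direct + len(waters)

    def ligand_residues(self) -> list[Residue]:
        seen: dict[tuple, Residue] = {}
        for lig in self.ligands:
            seen.setdefault(lig.residue.key(), lig.residue)
        return list(seen.values())

    def to_json_dict(self) -> dict:
        return {
            "element": self.element,
            "position": [round(float(v), 3) for v in self.metal.coord],
            "coordination_number": self.coordination_number,
            "ligands": [lig.to_json_dict() for lig in self.ligands],
            "additional_separations": list(self.additional_separations),
            "preceding_additional_flag": self.preceding_additional_flag,
        }


def coordination_shell(
    structure: Structure,
    metal: Atom,
    cutoff: float = DEFAULT_COORDINATION_CUTOFF,
    water_hbond_cutoff: float = DEFAULT_WATER_HBOND_CUTOFF,
) -> list[Ligand]:
    """Classified ligands of one metal, sorted by distance.

    All protein O/N atoms within ``cutoff`` of the metal are direct ligands
    (side-chain atom -> sidechain_direct, backbone O -> backbone_carbonyl,
    backbone N -> other). A water oxygen within ``cutoff`` recruits, as
    water_mediated ligands, the protein O/N atoms within
    ``water_hbond_cutoff`` of that water.
    """
    if not any(m is metal for m in structure.metals):
        raise KeyError(f"atom {metal.name} is not an indexed metal of {structure.id}")

    entries: list[tuple[Residue, Atom]] = []
    water_entries: list[tuple[Residue, Atom]] = []
    for res in structure.residues():
        for atom in res.atoms:
            if atom is metal:
                continue
            if res.is_water:
                if atom.element == "O":
                    water_entries.append((res, atom))
            elif atom.element in ("O", "N"):
                entries.append((res, atom))
    if not entries and not water_entries:
        return []

    ligands: list[Ligand] = []
    protein_coords = np.array([a.coord for _, a in entries])
    tree = cKDTree(protein_coords) if entries else None
    if tree is not None:
        for idx in sorted(tree.query_ball_point(metal.coord, cutoff)):
            res, atom = entries[idx]
            if atom.name == "O" or atom.name == "OXT":
                klass = LigandClass.BACKBONE_CARBONYL
            elif atom.name == "N":
                klass = LigandClass.OTHER
            else:
                klass = LigandClass.SIDECHAIN_DIRECT
            ligands.append(
                Ligand(
                    residue=res,
                    atom=atom,
                    distance=float(np.linalg.norm(atom.coord - metal.coord)),
                    klass=klass,
                )
            )

    # waters in the first shell bridge to protein polar atoms
    direct_ids = {id(lig.atom) for lig in ligands}
    for w_res, w_atom in water_entries:
        if float(np.linalg.norm(w_atom.coord - metal.coord)) > cutoff:
            continue
        if tree is None:
            continue
        for idx in sorted(tree.query_ball_point(w_atom.coord, water_hbond_cutoff)):
            res, atom = entries[idx]
            if id(atom) in direct_ids:
                continue  # already a direct ligand
            ligands.append(
                Ligand(
                    residue=res,
                    atom=atom,
                    distance=float(np.linalg.norm(atom.coord - metal.coord)),
                    klass=LigandClass.WATER_MEDIATED,
                    bridging_water=w_atom,
                )
            )
    ligands.sort(key=lambda lig: lig.distance)
    return ligands


def build_site(
    structure: Structure,
    metal: Atom,
    cutoff: float = DEFAULT_COORDINATION_CUTOFF,
    water_hbond_cutoff: float = DEFAULT_WATER_HBOND_CUTOFF,
) -> MetalSite:
    """Convenience wrapper: shell -> MetalSite."""
    return MetalSite(
        metal=metal,
        element=metal.element,
        ligands=coordination_shell(structure, metal, cutoff, water_hbond_cutoff),
    )


def link_site_to_motif(site: MetalSite, hit) -> MetalSite:
    """Annotate a site's ligands relative to a motif hit from the same structure.

    Additional-ligand separations follow the exclusive convention: the number
    of residues strictly between motif position 6 and the ligating residue,
    counted on the internal sequential index (robust to gaps in author
    numbering). A side-chain (or water-mediated) ligand from a residue
    *before* the motif raises ``preceding_additional_flag``: across all known
    structural contexts the additional ligand follows the motif, so a
    preceding one signals something unusual.
    """
    if hit.structure_id != "" and getattr(site.metal, "_structure_id", None) not in (
        None,
        hit.structure_id,
    ):
        raise ValueError("site and hit come from different structures")
    window = hit.window_residues
    chain_id = window[0].chain_id
    pos_index = {  # residue key -> motif position (1-based)
        res.key(): i + 1 for i, res in enumerate(window)
    }
    idx6 = window[5].index
    idx1 = window[0].index

    separations: list[int] = []
    flag = False
    for lig in site.ligands:
        key = lig.residue.key()
        pos = pos_index.get(key)
        if pos in (1, 3, 5) and lig.klass in (
            LigandClass.SIDECHAIN_DIRECT,
            LigandClass.WATER_MEDIATED,
        ):
            lig.relation_to_motif = MotifRelation[f"MOTIF_POSITION_{pos}"]
        elif (
            lig.residue.chain_id == chain_id
            and lig.residue.index == idx6 + 1
            and lig.klass == LigandClass.BACKBONE_CARBONYL
        ):
            lig.relation_to_motif = MotifRelation.MOTIF_PLUS1_CARBONYL
        elif lig.klass in (
            LigandClass.SIDECHAIN_DIRECT,
            LigandClass.WATER_MEDIATED,
        ) and lig.residue.chain_id == chain_id and lig.residue.index > idx6:
            lig.relation_to_motif = MotifRelation.DOWNSTREAM_ADDITIONAL
            separations.append(lig.residue.index - idx6 - 1)
        else:
            lig.relation_to_motif = MotifRelation.UNRELATED
            if (
                lig.klass == LigandClass.SIDECHAIN_DIRECT
                and lig.residue.chain_id == chain_id
                and lig.residue.index < idx1
            ):
                flag = True

    site.linked_hit = hit
    site.additional_separations = sorted(set(separations))
    site.preceding_additional_flag = flag
    return site


def detect_binuclear(
    sites: list[MetalSite], shared_ligand_min: int = 1
) -> list[tuple[MetalSite, MetalSite, list[Residue]]]:
    """Pairs of metal sites sharing at least ``shared_ligand_min`` ligand residues.

    A residue is shared when it ligates both metals (any ligand class; a
    bidentate carboxylate counts once). Each unordered pair is reported once.
    """
    pairs = []
    for i in range(len(sites)):
        res_i = {r.key(): r for r in sites[i].ligand_residues()}
        for j in range(i + 1, len(sites)):
            shared = [
                res for key, res in res_i.items()
                if any(key == r.key() for r in sites[j].ligand_residues())
            ]
            if len(shared) >= shared_ligand_min:
                sites[i].binuclear_partner = sites[j]
                sites[j].binuclear_partner = sites[i]
                pairs.append((sites[i], sites[j], shared))
    return pairs
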