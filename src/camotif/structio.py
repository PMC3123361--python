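"""Structure and sequence I/O.

Hierarchical coordinate model (Structure -> chains -> Residue -> Atom)
consumed by the motif-search and metal-analysis stages, read from / written
to fixed-column PDB via gemmi, plus FASTA and alignment readers via
Biopython. Author residue numbering (seq_num + insertion code) is kept as
the reporting coordinate system; a 0-based sequential index per chain is
maintained for window arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Data.IUPACData import protein_letters_3to1

logger = logging.getLogger(__name__)

#: The 20 canonical three-letter residue codes.
CANONICAL_AA3 = frozenset(
    code.upper() for code in protein_letters_3to1
)
THREE_TO_ONE = {code.upper(): one for code, one in protein_letters_3to1.items()}

#: Default element set treated as (potentially motif-bound) metals. EF-hand
#: type sites are crystallized with a variety of cations (the Mn-bound
#: galactosaminidase site being one example), so the set is configurable.
DEFAULT_METAL_ELEMENTS = frozenset(
    {"CA", "MN", "MG", "SR", "NA", "K", "ZN", "CD", "TB", "LA"}
)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

ALTLOC_POLICIES = ("highest_occupancy", "all", "first")


class StructureFormatError(ValueError):
    """Unparseable or empty coordinate / sequence file."""


@dataclass
class Atom:
    """One coordinate record."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} not in [0,1]")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element")
        self.element = self.element.upper()


@dataclass
class Residue:
    """One residue (or hetero group), identified by author numbering."""

    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    index: int = -1  # 0-based sequential position within the chain (file order)

    @property
    def is_standard_aa(self) -> bool:
        return self.res_name in CANONICAL_AA3

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def author_id(self) -> str:
        """Author number + insertion code, e.g. '212' or '52A'."""
        return f"{self.seq_num}{self.icode}".strip()

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def sidechain_atoms(self) -> list[Atom]:
        """Heavy side-chain atoms (beyond N, CA, C, O/OXT); excludes H."""
        backbone = {"N", "CA", "C", "O", "OXT"}
        return [
            a
            for a in self.atoms
            if a.name not in backbone and not a.element.startswith("H")
            and a.element != "D"
        ]

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)


@dataclass
class Structure:
    """Ordered chains of residues plus indexes of metals and waters."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    metal_elements: frozenset[str] = DEFAULT_METAL_ELEMENTS

    def __post_init__(self) -> None:
        self.reindex()

    def reindex(self) -> None:
        for residues in self.chains.values():
            for i, res in enumerate(residues):
                res.index = i

    @property
    def metals(self) -> list[Atom]:
        """Single-atom hetero groups whose element is in the metal set."""
        found = []
        for residues in self.chains.values():
            for res in residues:
                if (
                    len(res.atoms) == 1
                    and res.atoms[0].is_hetero
                    and res.atoms[0].element in self.metal_elements
                ):
                    found.append(res.atoms[0])
        return found

    @property
    def waters(self) -> list[Atom]:
        """Water oxygen atoms."""
        found = []
        for residues in self.chains.values():
            for res in residues:
                if res.is_water:
                    found.extend(a for a in res.atoms if a.element == "O")
        return found

    def residues(self) -> list[Residue]:
        return [res for residues in self.chains.values() for res in residues]

    def atoms(self) -> list[Atom]:
        return [a for res in self.residues() for a in res.atoms]

    def residue_of(self, atom: Atom) -> Residue:
        for res in self.residues():
            if any(a is atom for a in res.atoms):
                return res
        raise KeyError(f"atom {atom.name} not found in structure {self.id}")

    def protein_residues(self, chain_id: str) -> list[Residue]:
        """Standard amino-acid residues of one chain, file order."""
        return [r for r in self.chains.get(chain_id, []) if r.is_standard_aa]


def _select_altlocs(atoms: list[Atom], policy: str) -> list[Atom]:
    """Collapse alternate locations to one atom per name."""
    if policy == "all":
        return atoms
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            kept.append(group[0])
        elif policy == "first":
            kept.append(group[0])
        else:  # highest_occupancy; ties broken by altloc character order
            kept.append(max(group, key=lambda a: (a.occupancy, -ord(a.altloc or "~"))))
    return kept


def read_pdb(
    path: str | Path,
    altloc_policy: str = "highest_occupancy",
    metal_elements: frozenset[str] = DEFAULT_METAL_ELEMENTS,
) -> Structure:
    """Read a PDB (or mmCIF) file into the hierarchical model.

    Only the first MODEL of multi-model files is used (crystal structures
    are the target inputs). With ``altloc_policy="highest_occupancy"``
    exactly one alternate-location variant is kept per atom name, the one
    with the highest occupancy (ties broken by altloc character order).
    """
    if altloc_policy not in ALTLOC_POLICIES:
        raise ValueError(f"unknown altloc_policy {altloc_policy!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no coordinate records")
    if len(st) > 1:
        logger.warning("%s: %d models; using model 1 only", path.name, len(st))
    model = st[0]

    structure = Structure(id=st.name.lower() or path.stem, chains={},
                          metal_elements=metal_elements)
    n_atoms = 0
    for chain in model:
        residues: list[Residue] = []
        seen: set[tuple[int, str, str]] = set()
        for g_res in chain:
            key = (g_res.seqid.num, g_res.seqid.icode.strip(), g_res.name)
            if key in seen:
                logger.warning(
                    "%s: duplicate residue %s %s%s skipped",
                    path.name, g_res.name, g_res.seqid.num, g_res.seqid.icode,
                )
                continue
            seen.add(key)
            atoms = []
            for g_atom in g_res:
                try:
                    atoms.append(
                        Atom(
                            name=g_atom.name,
                            element=g_atom.element.name,
                            coord=np.array(
                                [g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]
                            ),
                            occupancy=min(max(g_atom.occ, 0.0), 1.0),
                            altloc=(g_atom.altloc or "").strip("\x00"),
                            is_hetero=g_res.het_flag == "H",
                            b_factor=g_atom.b_iso,
                        )
                    )
                except ValueError as exc:
                    logger.warning("%s: skipped atom record (%s)", path.name, exc)
            atoms = _select_altlocs(atoms, altloc_policy)
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_num=g_res.seqid.num,
                    icode=g_res.seqid.icode.strip(),
                    res_name=g_res.name.upper(),
                    atoms=atoms,
                )
            )
            n_atoms += len(atoms)
        if residues:
            structure.chains[chain.name] = residues
    if n_atoms == 0:
        raise StructureFormatError(f"{path}: no coordinate records")
    structure.reindex()
    return structure


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write the model as fixed-column PDB ATOM/HETATM records.

    Coordinates round-trip through :func:`read_pdb` to the PDB precision
    of 3 decimal places.
    """
    if not structure.chains or not any(structure.chains.values()):
        raise StructureFormatError("cannot write a structure with no residues")
    st = gemmi.Structure()
    st.name = structure.id
    model = _new_gemmi_model()
    for chain_id, residues in structure.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            g_res = gemmi.Residue()
            g_res.name = res.res_name
            g_res.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            g_res.het_flag = "H" if any(a.is_hetero for a in res.atoms) else "A"
            for atom in res.atoms:
                g_atom = gemmi.Atom()
                g_atom.name = atom.name
                g_atom.element = gemmi.Element(atom.element.capitalize())
                g_atom.pos = gemmi.Position(*atom.coord)
                g_atom.occ = atom.occupancy
                g_atom.b_iso = atom.b_factor
                if atom.altloc:
                    g_atom.altloc = atom.altloc
                g_res.add_atom(g_atom)
            chain.add_residue(g_res)
        model.add_chain(chain)
    st.add_model(model)
    path = Path(path)
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    return path


def _new_gemmi_model() -> "gemmi.Model":
    # gemmi changed the Model constructor (name string vs serial int)
    # across releases.
    try:
        return gemmi.Model("1")
    except TypeError:
        return gemmi.Model(1)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) pairs."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise StructureFormatError(f"{path}: no FASTA records")
    return records


def read_alignment(path: str | Path, format: str = "afa") -> list[tuple[str, str]]:
    """Read a multiple sequence alignment (aligned FASTA or Stockholm).

    Rows are uppercased; '.' gaps are normalized to '-'. All rows must have
    equal length.
    """
    fmt_map = {"afa": "fasta", "fasta": "fasta", "stockholm": "stockholm"}
    if format not in fmt_map:
        raise ValueError(f"unknown alignment format {format!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        aln = AlignIO.read(str(path), fmt_map[format])
    except ValueError as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    rows = [(rec.id, str(rec.seq).upper().replace(".", "-")) for rec in aln]
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) > 1:
        raise StructureFormatError(f"{path}: ragged alignment rows {sorted(lengths)}")
    return rows
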