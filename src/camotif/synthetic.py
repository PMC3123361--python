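"""Synthetic structures and sequences with known ground truth.

Every stage of the pipeline is testable without downloading anything: this
module generates (a) an idealized helix-loop-helix structure whose
12-residue DKDGDGTITTKE loop carries the Dx[DN]xDG motif and coordinates a
calcium ion in the canonical way — side-chain oxygens of loop positions
1/3/5 and the backbone carbonyl of position 7 at ~2.4-2.5 A, with a
downstream Glu completing the shell — plus configurable decoy loops, point
mutations and coordinate noise; and (b)
protein sequences with planted sequence motifs, Asp-enriched backgrounds
and DG-repeat (slippage) expansions.

The loop template is an idealized construction from documented internal
coordinates (ideal bond lengths/angles; the phi/psi and chi table below was
derived once by least-squares fitting the ligand distances named above), not
coordinates copied from any experimental structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import distance
from .motif_search import ReferenceMotif
from .peptide import ONE_TO_THREE, ResidueSpec, build_peptide, place_atom
from .seq_motif import CORE_POSITIONS, MotifDefinition, scan
from .structio import Atom, Residue, Structure

# ---------------------------------------------------------------------------
# Structural template: internal coordinates of the calcium loop

TEMPLATE_LOOP_SEQ = "DKDGDGTITTKE"
FLANK_LEN = 6
#: Motif = loop positions 1-6 (DKDGDG); canonical additional ligand = Glu at
#: loop position 12, i.e. five residues after the motif glycine.
CANONICAL_SEPARATION = 5

#: Loop backbone dihedrals (phi, psi) per residue, degrees.
TEMPLATE_PHI_PSI: tuple[tuple[float, float], ...] = (
    (-57.15, -20.02),
    (-21.88, -79.08),
    (-172.58, 62.76),
    (141.14, 42.47),
    (-166.73, 73.66),
    (157.38, -18.85),
    (-161.93, 169.14),
    (7.76, 159.28),
    (-51.98, -149.75),
    (-66.56, -10.00),
    (-71.25, -4.86),
    (-50.53, -48.55),
)

#: Side-chain chi angles per loop index (0-based), degrees.
TEMPLATE_CHIS: dict[int, list[float]] = {
    0: [-91.97, -173.61],   # Asp 1
    2: [-94.58, -14.65],    # Asp 3
    4: [-39.36, 0.00],      # Asp 5
    7: [-60.0, 170.0],      # Ile 8
    8: [-83.05],            # Thr 9 (water-bridged OG1)
    9: [30.0],              # Thr 10
    11: [120.76, -12.80, -19.21],  # Glu 12 (bidentate)
}

#: Calcium position in the template build frame.
TEMPLATE_METAL = np.array([5.499, 12.496, -8.748])

HELIX_PHI_PSI = (-57.0, -47.0)


class SimulationConfigError(ValueError):
    """Impossible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class StructureSimConfig:
    """Configuration of one synthetic structure build."""

    seed: int
    n_decoys: int = 0
    noise_sigma: float = 0.0  # A, iid Gaussian per coordinate axis
    mutate_positions: dict[int, str] = field(default_factory=dict)  # motif pos -> aa
    plant_metal: bool = True
    extra_ligand_separation: int = CANONICAL_SEPARATION

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise SimulationConfigError("noise_sigma must be >= 0")
        if self.n_decoys < 0:
            raise SimulationConfigError("n_decoys must be >= 0")
        if self.extra_ligand_separation < 0:
            raise SimulationConfigError("extra_ligand_separation must be >= 0")
        for pos, aa in self.mutate_positions.items():
            if not 1 <= pos <= 6:
                raise SimulationConfigError(f"mutate position {pos} outside motif 1-6")
            if aa.upper() not in ONE_TO_THREE:
                raise SimulationConfigError(f"unknown residue {aa!r}")


@dataclass
class StructureTruth:
    """Ground truth of a synthetic structure."""

    chain_id: str
    motif_start: str  # author id of the first D
    motif_author_ids: list[str]
    motif_mutated: bool
    ligand_distances: dict[str, float]
    extra_ligand: tuple[str, str, int] | None  # chain, author id, separation
    decoy_chains: list[str]
    noise_sigma: float

    def to_json_dict(self) -> dict:
        return {
            "chain": self.chain_id,
            "motif_start": self.motif_start,
            "motif_author_ids": self.motif_author_ids,
            "motif_mutated": self.motif_mutated,
            "ligand_distances": {
                k: round(v, 3) for k, v in self.ligand_distances.items()
            },
            "extra_ligand": list(self.extra_ligand) if self.extra_ligand else None,
            "decoy_chains": self.decoy_chains,
            "noise_sigma": self.noise_sigma,
        }


def _template_specs(
    loop_seq: str,
    chis: dict[int, list[float]],
    downstream_len: int = FLANK_LEN,
) -> list[ResidueSpec]:
    specs = [ResidueSpec("A", *HELIX_PHI_PSI) for _ in range(FLANK_LEN)]
    for i, aa in enumerate(loop_seq):
        phi, psi = TEMPLATE_PHI_PSI[i]
        specs.append(ResidueSpec(aa, phi, psi, chis=chis.get(i)))
    specs += [ResidueSpec("A", *HELIX_PHI_PSI) for _ in range(downstream_len)]
    return specs


def make_loop_structure(
    config: StructureSimConfig,
) -> tuple[Structure, StructureTruth]:
    """Build the synthetic calcium-loop structure and its ground truth.

    Chain A holds helix flanks around the motif loop; the additional acidic
    ligand sits ``extra_ligand_separation`` residues after the motif
    glycine. Decoy chains (B, C, ...) repeat the loop sequence with backbone
    dihedrals perturbed by at least 30 degrees, translated away from the
    site. Gaussian coordinate noise, when requested, applies to every atom.
    """
    rng = np.random.default_rng(config.seed)
    sep = config.extra_ligand_separation

    loop_seq = list(TEMPLATE_LOOP_SEQ)
    chis = {k: list(v) for k, v in TEMPLATE_CHIS.items()}
    for pos, aa in config.mutate_positions.items():
        loop_seq[pos - 1] = aa.upper()
        chis.pop(pos - 1, None)

    extra_loop_index: int | None = None
    downstream_len = FLANK_LEN
    if sep != CANONICAL_SEPARATION:
        extra_loop_index = 5 + sep + 1  # 0-based loop index of the extra ligand
        if extra_loop_index < 7:
            raise SimulationConfigError(
                f"separation {sep} would overlap the motif or its +1 carbonyl"
            )
        loop_seq[11] = "A"  # retire the canonical Glu 12
        chis.pop(11, None)
        if extra_loop_index >= 12:
            downstream_len = max(FLANK_LEN, extra_loop_index - 12 + 1 + 2)

    loop_str = "".join(loop_seq)

    def loop_to_chain_index(loop_i: int) -> int:
        return FLANK_LEN + loop_i

    if extra_loop_index is not None:
        chain_extra = loop_to_chain_index(extra_loop_index)
        residues = build_peptide(_template_specs(loop_str, chis, downstream_len))
        if chain_extra >= len(residues):
            raise SimulationConfigError(f"separation {sep} exceeds the chain")
        if extra_loop_index < 12:
            loop_seq[extra_loop_index] = "E"
            chis.pop(extra_loop_index, None)
            loop_str = "".join(loop_seq)
        glu_chis = None
        # rebuild with Glu at the extra position, then aim its side chain
        specs = _template_specs(loop_str, chis, downstream_len)
        if extra_loop_index >= 12:
            specs[chain_extra] = ResidueSpec(
                "E", specs[chain_extra].phi, specs[chain_extra].psi
            )
        trial = build_peptide(specs)
        glu_chis = _optimize_glu_chis_any(
            trial, chain_extra, TEMPLATE_METAL
        )
        if glu_chis is None:
            raise SimulationConfigError(
                f"extra ligand at separation {sep} cannot reach the metal"
            )
        specs[chain_extra] = ResidueSpec(
            "E", specs[chain_extra].phi, specs[chain_extra].psi, chis=glu_chis
        )
        residues = build_peptide(specs)
        extra_residue = residues[chain_extra]
    else:
        residues = build_peptide(_template_specs(loop_str, chis, downstream_len))
        extra_residue = residues[loop_to_chain_index(11)]
        if loop_seq[11] != "E":
            extra_residue = None

    # renumber chain A from 101 (distinct author numbers exercise reporting)
    for i, res in enumerate(residues):
        res.seq_num = 101 + i

    structure = Structure(id=f"synthetic-{config.seed}", chains={"A": residues})
    motif = residues[FLANK_LEN : FLANK_LEN + 6]

    truth_ligands: dict[str, float] = {}
    if config.plant_metal:
        metal_res = Residue(
            chain_id="M", seq_num=1, icode="", res_name="CA",
            atoms=[Atom("CA", "CA", TEMPLATE_METAL.copy(), is_hetero=True)],
        )
        structure.chains["M"] = [metal_res]
        for loop_i, name in ((0, "OD1"), (2, "OD1"), (4, "OD1"), (6, "O")):
            res = residues[loop_to_chain_index(loop_i)]
            atom = res.atom(name)
            if atom is not None:
                truth_ligands[f"loop{loop_i + 1}:{name}"] = distance(
                    atom.coord, TEMPLATE_METAL
                )
        if extra_residue is not None:
            oe1 = extra_residue.atom("OE1")
            if oe1 is not None:
                truth_ligands["extra:OE1"] = distance(oe1.coord, TEMPLATE_METAL)

    decoy_chains: list[str] = []
    for k in range(config.n_decoys):
        chain_id = chr(ord("B") + k) if k < 11 else f"D{k}"
        if chain_id in structure.chains:
            chain_id = f"D{k}"
        decoy = _decoy_loop(loop_str, rng, chain_id)
        offset = np.array([45.0 * (k + 1), 0.0, 0.0])
        for res in decoy:
            for atom in res.atoms:
                atom.coord = atom.coord + offset
        structure.chains[chain_id] = decoy
        decoy_chains.append(chain_id)

    if config.noise_sigma > 0:
        for res in structure.residues():
            for atom in res.atoms:
                atom.coord = atom.coord + rng.normal(
                    0.0, config.noise_sigma, size=3
                )

    structure.reindex()
    motif_mutated = any(
        loop_seq[pos - 1] not in allowed
        for pos, allowed in ((1, "D"), (3, "DNST"), (5, "DN"))
    )
    truth = StructureTruth(
        chain_id="A",
        motif_start=motif[0].author_id,
        motif_author_ids=[r.author_id for r in motif],
        motif_mutated=motif_mutated,
        ligand_distances=truth_ligands,
        extra_ligand=(
            ("A", extra_residue.author_id, sep) if extra_residue is not None else None
        ),
        decoy_chains=decoy_chains,
        noise_sigma=config.noise_sigma,
    )
    return structure, truth


def _optimize_glu_chis_any(
    residues: list[Residue], glu_index: int, metal: np.ndarray
) -> list[float] | None:
    """Aim the Glu at ``glu_index`` toward the metal by rebuilding only its
    side chain in place (the backbone stays fixed)."""
    from scipy.optimize import minimize

    res = residues[glu_index]
    bb = {n: res.atom(n).coord for n in ("N", "CA", "CB")}
    other_coords = np.array(
        [
            a.coord
            for ri, r in enumerate(residues)
            for a in r.atoms
            if ri != glu_index and not (abs(ri - glu_index) == 1 and a.name in ("N", "C", "O", "CA"))
        ]
    )

    def sidechain(x: np.ndarray) -> dict[str, np.ndarray]:
        chi1, chi2, chi3 = x
        cg = place_atom(bb["N"], bb["CA"], bb["CB"], 1.520, 114.1, chi1)
        cd = place_atom(bb["CA"], bb["CB"], cg, 1.516, 112.6, chi2)
        oe1 = place_atom(bb["CB"], cg, cd, 1.249, 118.4, chi3)
        oe2 = place_atom(bb["CB"], cg, cd, 1.249, 118.4, chi3 + 180.0)
        return {"CG": cg, "CD": cd, "OE1": oe1, "OE2": oe2}

    def objective(x: np.ndarray) -> float:
        sc = sidechain(x)
        cost = (distance(sc["OE1"], metal) - 2.4) ** 2
        cost += max(0.0, 2.4 - distance(sc["OE2"], metal)) ** 2
        for name, coord in sc.items():
            d = np.linalg.norm(other_coords - coord, axis=1)
            cost += float(np.sum(np.maximum(0.0, 2.8 - d) ** 2))
            if name in ("CG", "CD"):
                cost += max(0.0, 2.9 - distance(coord, metal)) ** 2
        return cost

    best_x, best_f = None, math.inf
    for chi1 in range(-180, 180, 30):
        for chi2 in range(-180, 180, 30):
            for chi3 in (-120, -60, 0, 60, 120, 180):
                f = objective(np.array([chi1, chi2, chi3], float))
                if f < best_f:
                    best_f, best_x = f, np.array([chi1, chi2, chi3], float)
    sol = minimize(objective, best_x, method="Nelder-Mead",
                   options={"xatol": 0.05, "fatol": 1e-8, "maxiter": 800})
    sc = sidechain(sol.x)
    if distance(sc["OE1"], metal) > 2.8:
        return None
    res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "CB")]
    for name in ("CG", "CD", "OE1", "OE2"):
        element = "O" if name.startswith("O") else "C"
        res.atoms.append(Atom(name, element, sc[name]))
    return [float(v) for v in sol.x]


def _decoy_loop(
    loop_seq: str, rng: np.random.Generator, chain_id: str
) -> list[Residue]:
    """Same composition as the motif loop, backbone dihedrals perturbed >=30 deg."""
    specs = []
    for i, aa in enumerate(loop_seq):
        phi, psi = TEMPLATE_PHI_PSI[i]
        d_phi = rng.uniform(30.0, 120.0) * rng.choice([-1.0, 1.0])
        d_psi = rng.uniform(30.0, 120.0) * rng.choice([-1.0, 1.0])
        specs.append(ResidueSpec(aa, phi + d_phi, psi + d_psi))
    return build_peptide(specs, chain_id=chain_id, start_seq_num=1)


_REFERENCE_CACHE: ReferenceMotif | None = None


def reference_motif() -> ReferenceMotif:
    """The packaged six-residue reference loop (noise-free template motif)."""
    global _REFERENCE_CACHE
    if _REFERENCE_CACHE is None:
        structure, _ = make_loop_structure(
            StructureSimConfig(seed=0, plant_metal=False)
        )
        _REFERENCE_CACHE = ReferenceMotif(
            source=(
                "idealized DKDGDG loop built from documented internal "
                "coordinates (synthetic stand-in for an EF-hand reference)"
            ),
            residues=structure.chains["A"][FLANK_LEN : FLANK_LEN + 6],
        )
    return _REFERENCE_CACHE


# ---------------------------------------------------------------------------
# Sequence generator

#: Background amino-acid frequencies (rough database composition).
DEFAULT_BACKGROUND = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_REJECTION_CAP = 500


@dataclass(frozen=True)
class SequenceSimConfig:
    """Configuration of one synthetic sequence set."""

    seed: int
    n_sequences: int = 10
    length: int = 200
    background_freqs: tuple[float, ...] | None = None  # in AA_ORDER
    planted_motifs: tuple[tuple[int, int], ...] = ()  # (1-based pos, spacer)
    asp_enrichment: float = 1.0
    dg_repeat_expansions: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences <= 0 or self.length <= 0:
            raise SimulationConfigError("n_sequences and length must be positive")
        if self.asp_enrichment < 1.0:
            raise SimulationConfigError("asp_enrichment must be >= 1")
        if self.dg_repeat_expansions < 0:
            raise SimulationConfigError("dg_repeat_expansions must be >= 0")
        spans = []
        for pos, spacer in self.planted_motifs:
            length = MotifDefinition(spacer=spacer).length
            if pos < 1 or pos + length - 1 > self.length:
                raise SimulationConfigError(
                    f"planted motif at {pos} (length {length}) outside sequence"
                )
            spans.append((pos, pos + length - 1))
        spans.sort()
        for (_, end_a), (start_b, _) in zip(spans, spans[1:]):
            if start_b <= end_a:
                raise SimulationConfigError("planted motifs overlap")

    def frequencies(self) -> np.ndarray:
        if self.background_freqs is not None:
            freqs = np.asarray(self.background_freqs, float)
            if len(freqs) != 20 or abs(freqs.sum() - 1.0) > 1e-6 or np.any(freqs < 0):
                raise SimulationConfigError("background_freqs must be a 20-simplex")
        else:
            freqs = np.array([DEFAULT_BACKGROUND[a] for a in AA_ORDER])
        freqs = freqs.copy()
        if self.asp_enrichment > 1.0:
            freqs[AA_ORDER.index("D")] *= self.asp_enrichment
        return freqs / freqs.sum()


@dataclass
class SequenceTruth:
    """Planted-motif and slippage ground truth per sequence."""

    motif_positions: dict[str, list[tuple[int, int]]]  # id -> (pos, spacer)
    slippage_sites: dict[str, tuple[int, int]]  # id -> (pos of DG tract, copies)

    def to_json_dict(self) -> dict:
        return {
            "motif_positions": {
                k: [list(t) for t in v] for k, v in self.motif_positions.items()
            },
            "slippage_sites": {k: list(v) for k, v in self.slippage_sites.items()},
        }


def _sample_background(
    rng: np.random.Generator, n: int, freqs: np.ndarray
) -> list[str]:
    return list(rng.choice(list(AA_ORDER), size=n, p=freqs))


def _core_matches(seq: str) -> list[int]:
    return [m.start for m in scan(seq, MotifDefinition())]


def _planted_motif_string(
    rng: np.random.Generator, spacer: int, freqs: np.ndarray
) -> str:
    letters = []
    for allowed in CORE_POSITIONS:
        if allowed is None:
            letters.append(str(rng.choice(list(AA_ORDER), p=freqs)))
        else:
            letters.append(str(rng.choice(sorted(allowed))))
    definition = MotifDefinition(spacer=spacer)
    if definition.tail_required:
        letters.extend(_sample_background(rng, spacer, freqs))
        letters.append(str(rng.choice(["D", "E"])))
    return "".join(letters)


def slippage_expand(sequence: str, site: int, copies: int) -> str:
    """Insert ``copies`` tandem DG units at a DG occurrence (0-based site)."""
    if sequence[site : site + 2] != "DG":
        raise ValueError(f"no DG unit at position {site}")
    return sequence[: site + 2] + "DG" * copies + sequence[site + 2 :]


def make_sequences(
    config: SequenceSimConfig,
) -> tuple[list[tuple[str, str]], SequenceTruth]:
    """Generate sequences with planted motifs and no spurious core matches.

    The background is rejection-sampled so that, before any slippage
    expansion, the only core-pattern occurrences are the planted ones.
    Slippage then inserts tandem DG copies at a marked DG site; matches it
    creates are part of the recorded truth, not spurious.
    """
    rng = np.random.default_rng(config.seed)
    freqs = config.frequencies()
    records: list[tuple[str, str]] = []
    motif_truth: dict[str, list[tuple[int, int]]] = {}
    slip_truth: dict[str, tuple[int, int]] = {}

    planted = sorted(config.planted_motifs)
    for s_idx in range(config.n_sequences):
        seq_id = f"synth_{s_idx + 1:04d}"
        planted_strs = {
            pos: _planted_motif_string(rng, spacer, freqs)
            for pos, spacer in planted
        }
        for attempt in range(_REJECTION_CAP):
            letters = _sample_background(rng, config.length, freqs)
            for pos, motif_str in planted_strs.items():
                letters[pos - 1 : pos - 1 + len(motif_str)] = list(motif_str)
            seq = "".join(letters)
            planted_spans = [
                (pos, pos + len(planted_strs[pos]) - 1) for pos in planted_strs
            ]
            spurious = [
                start
                for start in _core_matches(seq)
                if not any(lo <= start <= hi for lo, hi in planted_spans)
            ]
            if not spurious:
                break
        else:
            raise SimulationConfigError(
                "rejection sampling failed to remove spurious motifs; "
                "lower asp_enrichment or sequence length"
            )

        if config.dg_repeat_expansions > 0:
            site = _pick_dg_site(seq, planted_spans, rng)
            if site is None:
                # create a DG unit at a clear position, then expand it
                site = _make_dg_site(seq, planted_spans, rng)
                seq = seq[:site] + "DG" + seq[site + 2 :]
            seq = slippage_expand(seq, site, config.dg_repeat_expansions)
            slip_truth[seq_id] = (site + 1, config.dg_repeat_expansions)
            shifted = []
            for pos, spacer in planted:
                new_pos = pos if pos - 1 <= site else pos + 2 * config.dg_repeat_expansions
                shifted.append((new_pos, spacer))
            motif_truth[seq_id] = shifted
        else:
            motif_truth[seq_id] = list(planted)

        records.append((seq_id, seq))

    return records, SequenceTruth(
        motif_positions=motif_truth, slippage_sites=slip_truth
    )


def _pick_dg_site(
    seq: str, planted_spans: list[tuple[int, int]], rng: np.random.Generator
) -> int | None:
    sites = [
        i
        for i in range(len(seq) - 1)
        if seq[i : i + 2] == "DG"
        and not any(lo - 1 <= i + 1 <= hi + 1 for lo, hi in planted_spans)
    ]
    if not sites:
        return None
    return int(rng.choice(sites))


def _make_dg_site(
    seq: str, planted_spans: list[tuple[int, int]], rng: np.random.Generator
) -> int:
    margin = 8  # keep clear of planted motifs and sequence ends
    candidates = [
        i
        for i in range(margin, len(seq) - margin)
        if not any(lo - margin <= i + 1 <= hi + margin for lo, hi in planted_spans)
    ]
    if not candidates:
        raise SimulationConfigError("no room to seed a DG unit")
    return int(rng.choice(candidates))
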