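"""Sequence-level scanning for the calcium-binding functional motif.

The structural Dx[DN]xDG loop predicts a sequence signature: a six-residue
core ``D x [DNST] x [DN] [GADN]`` whose metal ligands (side chains of
positions 1/3/5 plus the backbone carbonyl after position 6) are completed
by a later acidic residue. At the sequence level the full functional motif
is therefore the core, a spacer of k residues, and an acidic tail ``[DE]``;
when the structurally observed spacing exceeds 30 residues the tail is
dropped and the core alone is scanned. Frequencies over alignments estimate
how well the motif is conserved among homologues.
"""

from __future__ import annotations

from dataclasses import dataclass

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Position-specific allowed residues of the six-residue core.
CORE_POSITIONS: tuple[frozenset[str] | None, ...] = (
    frozenset("D"),      # position 1
    None,                # position 2, wildcard
    frozenset("DNST"),   # position 3
    None,                # position 4, wildcard
    frozenset("DN"),     # position 5
    frozenset("GADN"),   # position 6
)

TAIL_SET = frozenset("DE")

#: Spacer length above which the acidic tail is not required.
MAX_TAIL_SPACER = 30


class SequenceAlphabetError(ValueError):
    """Sequence contains letters outside the amino-acid alphabet."""


@dataclass(frozen=True)
class MotifDefinition:
    """The scannable pattern: core, optional spacer, conditional acidic tail.

    ``spacer`` is the number of unconstrained residues between the core and
    the acidic tail; ``None`` (or a spacer above 30) means core-only.
    """

    spacer: int | None = None

    def __post_init__(self) -> None:
        if self.spacer is not None and self.spacer < 0:
            raise ValueError("spacer must be >= 0 or None")

    @property
    def tail_required(self) -> bool:
        return self.spacer is not None and self.spacer <= MAX_TAIL_SPACER

    @property
    def length(self) -> int:
        if self.tail_required:
            return 6 + self.spacer + 1
        return 6

    def positions(self) -> list[frozenset[str] | None]:
        """Per-position allowed sets; None = wildcard."""
        pos = list(CORE_POSITIONS)
        if self.tail_required:
            pos.extend([None] * self.spacer)
            pos.append(TAIL_SET)
        return pos


@dataclass(frozen=True)
class ScanMatch:
    """One motif occurrence; ``start`` is the 1-based position of the first D."""

    sequence_id: str
    start: int
    matched: str
    spacer_used: int | None


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    bad = sorted(set(seq) - AA_ALPHABET)
    if bad:
        raise SequenceAlphabetError(
            f"illegal sequence characters: {', '.join(bad)}"
        )
    return seq


def _match_at(seq: str, i: int, positions: list[frozenset[str] | None]) -> bool:
    for j, allowed in enumerate(positions):
        ch = seq[i + j]
        if allowed is None:
            if ch == "-":
                return False
        elif ch not in allowed:  # 'X' (and '-') never satisfy a constrained set
            return False
    return True


def scan(
    sequence: str,
    definition: MotifDefinition = MotifDefinition(),
    sequence_id: str = "",
) -> list[ScanMatch]:
    """All (possibly overlapping) motif matches, ascending by start.

    Case-insensitive; 'X' matches wildcard positions only.
    """
    seq = _validate(sequence)
    positions = definition.positions()
    n, m = len(seq), len(positions)
    matches = []
    for i in range(n - m + 1):
        if _match_at(seq, i, positions):
            matches.append(
                ScanMatch(
                    sequence_id=sequence_id,
                    start=i + 1,
                    matched=seq[i : i + m],
                    spacer_used=definition.spacer if definition.tail_required else None,
                )
            )
    return matches


def scan_all_spacings(
    sequence: str,
    spacings: list[int],
    sequence_id: str = "",
) -> list[ScanMatch]:
    """Union of scans over several spacer lengths, deduplicated by start.

    Spacings above 30 collapse to the core-only pattern. When several
    spacings match at one start, the smallest is reported.
    """
    if not spacings:
        raise ValueError("spacings must be non-empty")
    by_start: dict[int, ScanMatch] = {}
    for spacer in sorted(spacings):
        definition = MotifDefinition(spacer=spacer)
        for match in scan(sequence, definition, sequence_id):
            by_start.setdefault(match.start, match)
    return sorted(by_start.values(), key=lambda m: m.start)


def motif_frequency(
    alignment: list[tuple[str, str]],
    reference_id: str,
    reference_motif_start: int,
    definition: MotifDefinition = MotifDefinition(),
    margin: int = 6,
) -> tuple[float, list[tuple[str, bool]]]:
    """Fraction of alignment rows carrying the motif near a reference site.

    The reference row must contain a scan match at ``reference_motif_start``
    (1-based position in its *degapped* sequence). The alignment columns
    spanning that match, widened by ``margin`` columns on each side, are
    extracted for every row; a row counts as motif-bearing when its degapped
    subsequence from that window contains at least one match. Rows whose
    window is entirely gaps count as non-matching.

    Returns the fraction and the per-row boolean table.
    """
    rows = dict(alignment)
    if reference_id not in rows:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ref_row = rows[reference_id]
    ref_degapped = ref_row.replace("-", "")
    ref_matches = {m.start: m for m in scan(ref_degapped, definition, reference_id)}
    if reference_motif_start not in ref_matches:
        raise ValueError(
            f"reference {reference_id!r} has no motif at position "
            f"{reference_motif_start}"
        )
    match = ref_matches[reference_motif_start]

    # map degapped residue index (0-based) -> alignment column
    res_to_col = [i for i, ch in enumerate(ref_row) if ch != "-"]
    first_col = res_to_col[reference_motif_start - 1]
    last_col = res_to_col[reference_motif_start - 1 + len(match.matched) - 1]
    lo = max(0, first_col - margin)
    hi = min(len(ref_row), last_col + 1 + margin)

    table: list[tuple[str, bool]] = []
    n_hit = 0
    for row_id, row in alignment:
        window = row[lo:hi].replace("-", "")
        has = bool(window) and bool(scan(window, definition, row_id))
        table.append((row_id, has))
        n_hit += has
    return n_hit / len(alignment), table
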