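"""Reading, writing and validation of RNA secondary structures.

A secondary structure is a sequence over {A, C, G, U, N} together with a set
of base pairs ``(i, j)`` (1-based, ``i < j``).  Only pseudoknot-free (i.e.
non-crossing, nestable) pair sets are accepted: two pairs ``(i, j)`` and
``(k, l)`` cross when ``i < k < j < l``, and such structures cannot be
expressed in a single bracket family nor decomposed into the loop/stem tree
the layout engine operates on.

Supported text formats: dot-bracket (optionally preceded by a sequence line,
FASTA-style), CT and BPSEQ.  A dot-bracket writer is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

__all__ = [
    "SecondaryStructure",
    "StructureError",
    "ParseError",
    "PseudoknotError",
    "parse_dotbracket",
    "parse_ct",
    "parse_bpseq",
    "write_dotbracket",
    "validate_pseudoknot_free",
    "read_structure",
]

_CANONICAL_BASES = set("ACGUN")


class StructureError(ValueError):
    """A structure violates a secondary-structure invariant."""


class ParseError(StructureError):
    """Malformed input text for one of the supported formats."""


class PseudoknotError(StructureError):
    """The pair set contains crossing pairs (pseudoknot, unsupported)."""


def validate_pseudoknot_free(
    structure_or_pairs: Union["SecondaryStructure", Iterable[tuple[int, int]]],
) -> bool:
    """Return True iff no two pairs cross (``i < k < j < l``).

    Accepts either a :class:`SecondaryStructure` or a bare iterable of
    1-based ``(i, j)`` pairs (each index appearing at most once).
    """
    if isinstance(structure_or_pairs, SecondaryStructure):
        pairs = structure_or_pairs.pairs
    else:
        pairs = structure_or_pairs
    ordered = sorted(pairs)
    # Sweep openings left to right; enclosing closers must nest (stack).
    stack: list[int] = []
    for i, j in ordered:
        while stack and stack[-1] < i:
            stack.pop()
        if stack and j > stack[-1]:
            return False
        stack.append(j)
    return True


@dataclass(frozen=True)
class SecondaryStructure:
    """Sequence plus a non-crossing set of 1-based base pairs.

    Invariants (enforced at construction):

    * every index appears in at most one pair, ``1 <= i < j <= length``;
    * pairs are non-crossing (pseudoknot-free);
    * ``length == len(sequence)``.
    """

    sequence: str
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        n = len(self.sequence)
        if n == 0:
            raise StructureError("empty structure (length must be positive)")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= n):
                raise StructureError(f"pair ({i},{j}) out of range for length {n}")
            if i in seen or j in seen:
                raise StructureError(f"index in more than one pair: ({i},{j})")
            seen.add(i)
            seen.add(j)
        if not validate_pseudoknot_free(self.pairs):
            raise PseudoknotError("crossing base pairs (pseudoknot unsupported)")
        odd = sorted({c for c in self.sequence.upper() if c not in _CANONICAL_BASES})
        if odd:
            warnings.warn(
                f"non-canonical bases preserved verbatim: {''.join(odd)}",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def partner_table(self) -> list[int]:
        """0-indexed-free pairing table: ``t[i]`` is i's partner or 0; ``t[0]`` unused."""
        t = [0] * (self.length + 1)
        for i, j in self.pairs:
            t[i] = j
            t[j] = i
        return t


def parse_dotbracket(text: str, sequence: Optional[str] = None) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Only the round-bracket family is accepted; extended families would encode
    pseudoknots, which are out of scope.  Whitespace is ignored.  When
    ``sequence`` is omitted the sequence defaults to all-``N``.
    """
    symbols = [c for c in text if not c.isspace()]
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, c in enumerate(symbols, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ParseError(f"unbalanced at position {pos}: unmatched ')'")
            pairs.add((stack.pop(), pos))
        elif c == ".":
            continue
        elif c in "[]{}<>":
            raise ParseError(
                f"bracket family '{c}' at position {pos}: pseudoknot unsupported"
            )
        else:
            raise ParseError(f"invalid character '{c}' at position {pos}")
    if stack:
        raise ParseError(f"unbalanced at position {stack[0]}: unmatched '('")
    n = len(symbols)
    if sequence is None:
        sequence = "N" * n
    elif len(sequence) != n:
        raise ParseError(
            f"sequence length {len(sequence)} does not match structure length {n}"
        )
    return SecondaryStructure(sequence=sequence, pairs=frozenset(pairs))


def _records_to_structure(records: list[tuple[int, str, int]]) -> SecondaryStructure:
    """Build a structure from (index, base, partner) records (shared CT/BPSEQ tail)."""
    n = len(records)
    partner = {}
    bases = []
    for k, (idx, base, pt) in enumerate(records, start=1):
        if idx != k:
            raise ParseError(f"non-contiguous nucleotide index {idx} (expected {k})")
        if pt < 0 or pt > n:
            raise ParseError(f"pairing partner {pt} out of range at index {idx}")
        if pt == idx:
            raise ParseError(f"nucleotide {idx} paired with itself")
        partner[idx] = pt
        bases.append(base)
    pairs: set[tuple[int, int]] = set()
    for i, j in partner.items():
        if j == 0:
            continue
        if partner.get(j, 0) != i:
            raise ParseError(
                f"asymmetric pairing: row {i} pairs to {j} but row {j} pairs to {partner.get(j, 0)}"
            )
        pairs.add((min(i, j), max(i, j)))
    return SecondaryStructure(sequence="".join(bases), pairs=frozenset(pairs))


def parse_ct(text: str) -> SecondaryStructure:
    """Parse a CT record: header line with count, then one 6-column line per
    nucleotide (index, base, 5' neighbour, 3' neighbour, partner, natural
    index).  Trailing columns are ignored.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ParseError("empty CT input")
    header = lines[0].split()
    try:
        count = int(header[0])
    except (ValueError, IndexError):
        raise ParseError(f"CT header must start with the nucleotide count: {lines[0]!r}")
    body = lines[1:]
    if len(body) != count:
        raise ParseError(f"CT header count {count} != number of records {len(body)}")
    records = []
    for ln in body:
        cols = ln.split()
        if len(cols) < 6:
            raise ParseError(f"CT record has fewer than 6 columns: {ln!r}")
        try:
            idx, base, pt = int(cols[0]), cols[1], int(cols[4])
        except ValueError:
            raise ParseError(f"malformed CT record: {ln!r}")
        records.append((idx, base, pt))
    return _records_to_structure(records)


def parse_bpseq(text: str) -> SecondaryStructure:
    """Parse a BPSEQ record: one ``index base partner`` line per nucleotide
    (partner 0 = unpaired)."""
    records = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        cols = ln.split()
        if len(cols) != 3:
            raise ParseError(f"BPSEQ line must have 3 columns: {ln!r}")
        try:
            records.append((int(cols[0]), cols[1], int(cols[2])))
        except ValueError:
            raise ParseError(f"malformed BPSEQ line: {ln!r}")
    if not records:
        raise ParseError("empty BPSEQ input")
    return _records_to_structure(records)


def write_dotbracket(structure: SecondaryStructure) -> str:
    """Render the pair set as a dot-bracket string (round brackets only)."""
    if not validate_pseudoknot_free(structure.pairs):
        raise PseudoknotError("cannot write pseudoknot in one bracket family")
    out = ["."] * structure.length
    for i, j in structure.pairs:
        out[i - 1] = "("
        out[j - 1] = ")"
    return "".join(out)


def read_structure(text: str, fmt: str = "dotbracket") -> SecondaryStructure:
    """Parse file content in one of the supported formats.

    For ``dotbracket``, accepts a bare bracket string, an optional leading
    FASTA header line (``>...``), and an optional sequence line preceding the
    bracket line.
    """
    if fmt == "ct":
        return parse_ct(text)
    if fmt == "bpseq":
        return parse_bpseq(text)
    if fmt != "dotbracket":
        raise ValueError(f"unknown format: {fmt!r}")
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if not lines:
        raise ParseError("empty dot-bracket input")
    if len(lines) >= 2 and not any(c in "()." for c in lines[0]):
        return parse_dotbracket(lines[1], sequence=lines[0])
    return parse_dotbracket("".join(lines))
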