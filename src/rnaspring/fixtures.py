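"""Synthetic, valid, pseudoknot-free secondary structures for testing.

The generator builds dot-bracket strings by recursive interval subdivision —
pick a stem length, then continue the enclosed interval as a hairpin, an
internal/bulge loop or a multiloop — so structures are non-crossing by
construction, with every stem at least ``min_stem`` pairs and every hairpin
at least ``min_hairpin`` unpaired bases (3 by default, the physical
minimum).  Generation is deterministic per seed and O(n).

Sequences are filled in deterministically with complementary G-C/A-U pairs
on paired positions so fixtures look like plausible RNA rather than all-N.

A generic 76-nt tRNA-like cloverleaf (acceptor stem plus three hairpin arms
around one multiloop) ships as the canonical small fixture.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .structure_io import SecondaryStructure, parse_dotbracket

__all__ = [
    "GeneratorParams",
    "random_structure",
    "cloverleaf_fixture",
    "graded_suite",
    "CLOVERLEAF_DOTBRACKET",
]

CLOVERLEAF_DOTBRACKET = (
    "((((((("                   # acceptor stem (7 bp)
    ".."                        # multiloop spacer
    "((((........))))"          # D-like arm: 4 bp stem, 8-nt hairpin
    "."
    "(((((.......)))))"         # anticodon-like arm: 5 bp stem, 7-nt hairpin
    "....."                     # variable region
    "(((((.......)))))"         # T-like arm: 5 bp stem, 7-nt hairpin
    ")))))))"
    "...."                      # 3' tail
)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the random structure generator."""

    n: int
    seed: int = 0
    min_stem: int = 2
    min_hairpin: int = 3
    branch_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.n < self.min_hairpin:
            raise ValueError(
                f"n = {self.n} too small for min_hairpin = {self.min_hairpin}"
            )


def _fill_sequence(db: str, rng: random.Random) -> str:
    """Complementary bases on paired positions, A/U elsewhere (deterministic)."""
    seq = [""] * len(db)
    stack: list[int] = []
    for k, c in enumerate(db):
        if c == "(":
            stack.append(k)
        elif c == ")":
            i = stack.pop()
            if rng.random() < 0.6:
                seq[i], seq[k] = "G", "C"
            else:
                seq[i], seq[k] = "C", "G"
        else:
            seq[k] = rng.choice("AAUU")
    return "".join(seq)


def random_structure(params: GeneratorParams) -> SecondaryStructure:
    """Generate one valid non-crossing structure of length exactly ``params.n``."""
    rng = random.Random(params.seed)
    ms, mh, bp = params.min_stem, params.min_hairpin, params.branch_prob
    # Smallest interval that can host one complete stem + hairpin.
    min_helix = 2 * max(ms, 1) + mh

    def helix(length: int) -> str:
        smax = (length - mh) // 2
        s = rng.randint(max(ms, 1), smax)
        return "(" * s + interior(length - 2 * s) + ")" * s

    def interior(length: int) -> str:
        if length >= 2 * min_helix and rng.random() < bp:
            return multiloop(length)
        if length >= min_helix + 1 and rng.random() < 0.6:
            # internal/bulge continuation: one branch plus unpaired gaps
            spare = length - min_helix
            left = rng.randint(0, spare)
            right = rng.randint(0, spare - left)
            inner = min_helix + (spare - left - right)
            return "." * left + helix(inner) + "." * right
        return "." * length  # hairpin

    def multiloop(length: int) -> str:
        spare = length - 2 * min_helix
        g1 = rng.randint(0, spare)
        rest = spare - g1
        e1 = rng.randint(0, rest)
        rest -= e1
        g2 = rng.randint(0, rest)
        rest -= g2
        e2 = rng.randint(0, rest)
        g3 = rest - e2
        return (
            "." * g1
            + helix(min_helix + e1)
            + "." * g2
            + helix(min_helix + e2)
            + "." * g3
        )

    def exterior(length: int) -> str:
        out: list[str] = []
        remaining = length
        while remaining > 0:
            if remaining >= min_helix and rng.random() < 0.8:
                take = rng.randint(min_helix, remaining)
                out.append(helix(take))
                remaining -= take
            else:
                gap = rng.randint(1, remaining)
                out.append("." * gap)
                remaining -= gap
        return "".join(out)

    if ms < 1 or params.n < min_helix:
        db = "." * params.n
    else:
        db = exterior(params.n)
    assert len(db) == params.n
    return parse_dotbracket(db, sequence=_fill_sequence(db, rng))


def cloverleaf_fixture() -> SecondaryStructure:
    """The shipped 76-nt tRNA-like cloverleaf: one acceptor stem and three
    hairpin arms radiating from a single multiloop."""
    db = CLOVERLEAF_DOTBRACKET
    return parse_dotbracket(db, sequence=_fill_sequence(db, random.Random(76)))


def graded_suite(sizes: list[int], seed: int = 0) -> list[SecondaryStructure]:
    """One random structure per requested length, deterministic per seed."""
    return [
        random_structure(GeneratorParams(n=size, seed=seed * 100_003 + k))
        for k, size in enumerate(sizes)
    ]
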