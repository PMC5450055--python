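"""Loop/stem decomposition and the compressed graph representation.

A pseudoknot-free structure decomposes uniquely into structural elements:
every base pair becomes one element, and the unpaired regions organise into
loops classified by the number of bounding stems — hairpin (1 stem),
bulge (2 stems, unpaired on one side only), internal (2 stems, unpaired on
both sides), multiloop (>= 3 stems) and the always-present exterior region.

The *compressed graph* maps each element to a vertex: consecutive stacked
pairs of a stem are chained by edges, and each stem-terminal pair is linked
to its flanking loop vertex.  For pseudoknot-free input the result is a
tree, with far fewer vertexes than nucleotides.  The *detailed graph*
(one vertex per nucleotide, one edge per covalent/hydrogen bond) is kept as
a minimal baseline for comparison.

Loop vertexes record their *perimeter*: the circular arrangement, in
sequence order, of unpaired members (one slot each) and bounding pairs
(two slots each).  The force model and the nucleotide placement both read
angles off this arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .structure_io import PseudoknotError, SecondaryStructure, validate_pseudoknot_free

__all__ = [
    "BASE_PAIR",
    "HAIRPIN",
    "INTERNAL",
    "BULGE",
    "MULTI",
    "EXTERIOR",
    "LOOP_KINDS",
    "StructuralElement",
    "Vertex",
    "CompressedGraph",
    "DetailedGraph",
    "decompose_elements",
    "build_compressed_graph",
    "build_detailed_graph",
    "compression_ratio",
]

BASE_PAIR = "base_pair"
HAIRPIN = "hairpin_loop"
INTERNAL = "internal_loop"
BULGE = "bulge_loop"
MULTI = "multi_loop"
EXTERIOR = "exterior_loop"
LOOP_KINDS = frozenset({HAIRPIN, INTERNAL, BULGE, MULTI, EXTERIOR})

# Perimeter entries: ("nt", index) for an unpaired member, ("pair", (i, j))
# for a bounding pair.  For a loop closed by pair (i, j) the closing pair is
# listed first, so walking the list in order visits i, the interior in
# sequence order, then j, wrapping back to i.
PerimeterEntry = tuple[str, Union[int, tuple[int, int]]]


@dataclass(frozen=True)
class StructuralElement:
    """One element of the decomposition.

    ``members`` are the unpaired nucleotides of a loop, or the two paired
    positions of a base-pair element.  Loop elements additionally record the
    bounding pairs (``anchors``) and their full circular ``perimeter``.
    """

    kind: str
    members: tuple[int, ...]
    pair: Optional[tuple[int, int]] = None
    anchors: tuple[tuple[int, int], ...] = ()
    perimeter: tuple[PerimeterEntry, ...] = ()

    @property
    def is_loop(self) -> bool:
        return self.kind in LOOP_KINDS

    def sort_key(self) -> tuple:
        nts = list(self.members)
        for i, j in self.anchors:
            nts.extend((i, j))
        lo = min(nts) if nts else 0
        return (lo, 0 if self.is_loop else 1, self.pair or ())


@dataclass(frozen=True)
class Vertex:
    id: int
    element: StructuralElement

    @property
    def is_loop(self) -> bool:
        return self.element.is_loop

    @property
    def kind(self) -> str:
        return self.element.kind


@dataclass(frozen=True)
class CompressedGraph:
    """Tree of loop and base-pair vertexes for a pseudoknot-free structure."""

    n_nucleotides: int
    vertices: tuple[Vertex, ...]
    edges: frozenset[tuple[int, int]]
    adjacency: tuple[tuple[int, ...], ...]
    loop_ids: frozenset[int]
    # For each base-pair vertex: neighbour on the exterior side and on the
    # interior side (every base pair has exactly two neighbours in the tree).
    bp_outer: dict[int, int] = field(default_factory=dict)
    bp_inner: dict[int, int] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def neighbors(self, vid: int) -> tuple[int, ...]:
        return self.adjacency[vid]


@dataclass(frozen=True)
class DetailedGraph:
    """Baseline graph: one vertex per nucleotide, backbone + pairing edges."""

    n_nucleotides: int
    edges: frozenset[tuple[int, int]]


def _loop_interior(pt: list[int], start: int, stop: int):
    """Walk positions ``start..stop`` at the top level of that interval,
    yielding perimeter entries and collecting child pairs."""
    entries: list[PerimeterEntry] = []
    children: list[tuple[int, int]] = []
    k = start
    while k <= stop:
        j = pt[k]
        if j == 0:
            entries.append(("nt", k))
            k += 1
        else:
            entries.append(("pair", (k, j)))
            children.append((k, j))
            k = j + 1
    return entries, children


def decompose_elements(structure: SecondaryStructure) -> list[StructuralElement]:
    """Decompose a pseudoknot-free structure into base-pair and loop elements.

    Every nucleotide belongs to exactly one element: paired positions to
    their base-pair element, unpaired positions to the loop that contains
    them.  The exterior region is always materialised, even when empty.
    """
    if not validate_pseudoknot_free(structure.pairs):
        raise PseudoknotError("cannot decompose a pseudoknotted structure")
    pt = structure.partner_table()
    n = structure.length
    elements: list[StructuralElement] = []

    for i, j in sorted(structure.pairs):
        elements.append(StructuralElement(kind=BASE_PAIR, members=(i, j), pair=(i, j)))

    # Exterior loop: the unbounded region outside all pairs.
    ext_entries, ext_children = _loop_interior(pt, 1, n) if n else ([], [])
    elements.append(
        StructuralElement(
            kind=EXTERIOR,
            members=tuple(k for tag, k in ext_entries if tag == "nt"),
            anchors=tuple(ext_children),
            perimeter=tuple(ext_entries),
        )
    )

    # Interior loops: one per loop-closing pair, i.e. each pair (i, j) whose
    # enclosed region is not just the next stacked pair.
    for i, j in sorted(structure.pairs):
        if pt[i + 1] == j - 1 and i + 1 < j - 1:
            continue  # (i+1, j-1) stacked: interior continues within the stem
        entries, children = _loop_interior(pt, i + 1, j - 1)
        members = tuple(k for tag, k in entries if tag == "nt")
        if not children:
            kind = HAIRPIN
        elif len(children) == 1:
            (k1, _l1) = children[0]
            before = sum(1 for m in members if m < k1)
            after = len(members) - before
            kind = INTERNAL if (before > 0 and after > 0) else BULGE
        else:
            kind = MULTI
        elements.append(
            StructuralElement(
                kind=kind,
                members=members,
                anchors=((i, j),) + tuple(children),
                perimeter=(("pair", (i, j)),) + tuple(entries),
            )
        )

    elements.sort(key=StructuralElement.sort_key)
    return elements


def build_compressed_graph(structure: SecondaryStructure) -> CompressedGraph:
    """Build the compressed (loop + base-pair) graph of a structure.

    Vertex ids are deterministic: elements sorted by minimal involved
    nucleotide index (loops before base pairs on ties).
    """
    elements = decompose_elements(structure)
    vertices = tuple(Vertex(id=k, element=el) for k, el in enumerate(elements))
    by_pair = {v.element.pair: v.id for v in vertices if not v.is_loop}

    edges: set[tuple[int, int]] = set()

    def add_edge(a: int, b: int) -> None:
        edges.add((min(a, b), max(a, b)))

    # Stems: consecutive stacked pairs.
    pt = structure.partner_table()
    for (i, j), vid in by_pair.items():
        if (i + 1, j - 1) in by_pair and pt[i + 1] == j - 1:
            add_edge(vid, by_pair[(i + 1, j - 1)])

    # Loop vertexes connect to every bounding pair on their perimeter.
    bp_outer: dict[int, int] = {}
    bp_inner: dict[int, int] = {}
    for v in vertices:
        if not v.is_loop:
            continue
        closing = v.element.perimeter[0][1] if v.kind != EXTERIOR else None
        for tag, val in v.element.perimeter:
            if tag != "pair":
                continue
            bvid = by_pair[val]
            add_edge(v.id, bvid)
            if val == closing:
                bp_inner[bvid] = v.id  # loop lies on the interior side
            else:
                bp_outer[bvid] = v.id  # loop is the parent on the exterior side
    # Within stems, outer/inner neighbours follow the stacking direction.
    for (i, j), vid in by_pair.items():
        if (i + 1, j - 1) in by_pair and pt[i + 1] == j - 1:
            bp_inner[vid] = by_pair[(i + 1, j - 1)]
            bp_outer[by_pair[(i + 1, j - 1)]] = vid

    adjacency: list[list[int]] = [[] for _ in vertices]
    for a, b in edges:
        adjacency[a].append(b)
        adjacency[b].append(a)
    return CompressedGraph(
        n_nucleotides=structure.length,
        vertices=vertices,
        edges=frozenset(edges),
        adjacency=tuple(tuple(sorted(nb)) for nb in adjacency),
        loop_ids=frozenset(v.id for v in vertices if v.is_loop),
        bp_outer=bp_outer,
        bp_inner=bp_inner,
    )


def build_detailed_graph(structure: SecondaryStructure) -> DetailedGraph:
    """Baseline mapping: N vertexes, N-1 backbone edges plus one per pair."""
    edges = {(k, k + 1) for k in range(1, structure.length)}
    edges |= {(i, j) for i, j in structure.pairs}
    return DetailedGraph(n_nucleotides=structure.length, edges=frozenset(edges))


def compression_ratio(structure: SecondaryStructure) -> float:
    """Compressed vertex count divided by nucleotide count, in (0, 1]."""
    g = build_compressed_graph(structure)
    return g.n_vertices / structure.length
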