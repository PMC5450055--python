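"""Element decomposition and compressed/detailed graph construction.

The decomposition is cross-checked against a brute-force oracle that
classifies every position by its innermost enclosing pair (computed by
scanning all pairs per position), built independently of the production
interval-walking code.
"""

import networkx as nx
import pytest

import rnaspring as rs
from rnaspring.graph import (
    BASE_PAIR,
    BULGE,
    EXTERIOR,
    HAIRPIN,
    INTERNAL,
    MULTI,
)
from rnaspring.structure_io import PseudoknotError


def oracle_elements(structure):
    """Brute-force decomposition: for every position find its innermost
    enclosing pair by scanning the whole pair list, then group."""
    pairs = sorted(structure.pairs)
    n = structure.length

    def enclosing(k):
        best = None
        for (a, b) in pairs:
            if a < k < b and (best is None or a > best[0]):
                best = (a, b)
        return best

    paired = {i for p in pairs for i in p}
    # members of the loop closed by each pair (None = exterior)
    loop_members = {}
    for k in range(1, n + 1):
        if k in paired:
            continue
        loop_members.setdefault(enclosing(k), []).append(k)
    # child stems of each region: outermost pairs enclosed by it
    children = {}
    for (a, b) in pairs:
        enc = enclosing(a)
        children.setdefault(enc, []).append((a, b))
    out = {(BASE_PAIR, (i, j)) for i, j in pairs}
    regions = set(loop_members) | set(children) | {None}
    for reg in regions:
        mem = tuple(loop_members.get(reg, []))
        kids = sorted(children.get(reg, []))
        if reg is None:
            out.add((EXTERIOR, mem))
            continue
        i, j = reg
        if kids == [(i + 1, j - 1)] and not mem:
            continue  # stacked pair, no loop
        if not kids:
            kind = HAIRPIN
        elif len(kids) == 1:
            before = sum(1 for m in mem if m < kids[0][0])
            kind = INTERNAL if 0 < before < len(mem) else BULGE
        else:
            kind = MULTI
        out.add((kind, mem))
    return out


class TestDecomposition:
    def test_single_stem_hairpin(self):
        els = rs.decompose_elements(rs.parse_dotbracket("((((....))))"))
        bp = [e.pair for e in els if e.kind == BASE_PAIR]
        assert bp == [(1, 12), (2, 11), (3, 10), (4, 9)]
        hp = [e for e in els if e.kind == HAIRPIN]
        assert len(hp) == 1 and hp[0].members == (5, 6, 7, 8)
        ext = [e for e in els if e.kind == EXTERIOR]
        assert len(ext) == 1 and ext[0].members == ()

    def test_internal_loop(self):
        els = rs.decompose_elements(rs.parse_dotbracket("((..((....))..))"))
        kinds = {}
        for e in els:
            kinds.setdefault(e.kind, []).append(e)
        assert {e.pair for e in kinds[BASE_PAIR]} == {(1, 16), (2, 15), (5, 12), (6, 11)}
        assert kinds[INTERNAL][0].members == (3, 4, 13, 14)
        assert kinds[HAIRPIN][0].members == (7, 8, 9, 10)
        assert kinds[EXTERIOR][0].members == ()

    def test_pairless_strand_is_one_exterior(self):
        els = rs.decompose_elements(rs.parse_dotbracket("....."))
        assert len(els) == 1
        assert els[0].kind == EXTERIOR and els[0].members == (1, 2, 3, 4, 5)

    def test_bulge_vs_internal_classification(self):
        els = rs.decompose_elements(rs.parse_dotbracket("((.((...))))"))
        assert any(e.kind == BULGE for e in els)
        assert not any(e.kind == INTERNAL for e in els)

    def test_multiloop_classification(self):
        els = rs.decompose_elements(rs.parse_dotbracket("(.((...)).((...)).)"))
        assert sum(e.kind == MULTI for e in els) == 1

    def test_partition_property(self):
        for seed in range(20):
            s = rs.random_structure(rs.GeneratorParams(n=70, seed=seed))
            els = rs.decompose_elements(s)
            seen = []
            for e in els:
                seen.extend(e.members)
            assert sorted(seen) == list(range(1, s.length + 1))

    def test_matches_bruteforce_oracle_on_short_structures(self):
        checked = 0
        for seed in range(200):
            s = rs.random_structure(
                rs.GeneratorParams(n=7 + seed % 14, seed=seed, min_stem=1)
            )
            if s.length > 20:
                continue
            got = {
                (e.kind, e.pair if e.kind == BASE_PAIR else e.members)
                for e in rs.decompose_elements(s)
            }
            assert got == oracle_elements(s), rs.write_dotbracket(s)
            checked += 1
        assert checked > 50


class TestCompressedGraph:
    def test_single_stem_topology(self, hairpin_structure):
        g = rs.build_compressed_graph(hairpin_structure)
        assert g.n_vertices == 6 and len(g.edges) == 5
        by_pair = {v.element.pair: v.id for v in g.vertices if not v.is_loop}
        ext = next(v.id for v in g.vertices if v.kind == EXTERIOR)
        hp = next(v.id for v in g.vertices if v.kind == HAIRPIN)
        expected = {
            tuple(sorted((ext, by_pair[(1, 12)]))),
            tuple(sorted((by_pair[(1, 12)], by_pair[(2, 11)]))),
            tuple(sorted((by_pair[(2, 11)], by_pair[(3, 10)]))),
            tuple(sorted((by_pair[(3, 10)], by_pair[(4, 9)]))),
            tuple(sorted((by_pair[(4, 9)], hp))),
        }
        assert g.edges == frozenset(expected)

    def test_two_arm_exterior_degree(self):
        g = rs.build_compressed_graph(rs.parse_dotbracket(".((..)).((..))."))
        assert g.n_vertices == 7 and len(g.edges) == 6
        ext = next(v.id for v in g.vertices if v.kind == EXTERIOR)
        assert len(g.neighbors(ext)) == 2

    def test_pairless_strand(self):
        g = rs.build_compressed_graph(rs.parse_dotbracket("...."))
        assert g.n_vertices == 1 and len(g.edges) == 0

    def test_tree_property_on_generated_structures(self):
        for seed in range(40):
            s = rs.random_structure(rs.GeneratorParams(n=90, seed=seed))
            g = rs.build_compressed_graph(s)
            G = nx.Graph(list(g.edges))
            G.add_nodes_from(range(g.n_vertices))
            assert nx.is_connected(G)
            assert len(g.edges) == g.n_vertices - 1

    def test_vertex_count_census(self):
        for seed in range(20):
            s = rs.random_structure(rs.GeneratorParams(n=80, seed=seed))
            g = rs.build_compressed_graph(s)
            n_loops = len(g.loop_ids)
            n_bp = g.n_vertices - n_loops
            assert n_bp == len(s.pairs)

    def test_bp_outer_inner_cover_all_base_pairs(self, cloverleaf):
        g = rs.build_compressed_graph(cloverleaf)
        for v in g.vertices:
            if not v.is_loop:
                assert v.id in g.bp_outer and v.id in g.bp_inner
                assert set(g.neighbors(v.id)) == {g.bp_outer[v.id], g.bp_inner[v.id]}

    def test_deterministic_vertex_order(self, cloverleaf):
        g1 = rs.build_compressed_graph(cloverleaf)
        g2 = rs.build_compressed_graph(cloverleaf)
        assert [v.element for v in g1.vertices] == [v.element for v in g2.vertices]

    def test_pseudoknot_rejected(self):
        s = rs.SecondaryStructure("NNNN")
        object.__setattr__(s, "pairs", frozenset({(1, 3), (2, 4)}))
        with pytest.raises(PseudoknotError):
            rs.build_compressed_graph(s)


class TestDetailedGraphAndCompression:
    @pytest.mark.parametrize(
        "db,n_edges",
        [("((..))", 7), (".....", 4)],
    )
    def test_detailed_counts(self, db, n_edges):
        s = rs.parse_dotbracket(db)
        d = rs.build_detailed_graph(s)
        assert d.n_nucleotides == s.length
        assert len(d.edges) == n_edges

    def test_single_nucleotide(self):
        d = rs.build_detailed_graph(rs.parse_dotbracket("."))
        assert d.n_nucleotides == 1 and len(d.edges) == 0

    @pytest.mark.parametrize(
        "db,ratio",
        [("((((....))))", 0.5), (".((..)).((..)).", 7 / 15), ("....", 0.25)],
    )
    def test_compression_ratio(self, db, ratio):
        assert rs.compression_ratio(rs.parse_dotbracket(db)) == pytest.approx(ratio)

    def test_compression_beats_detailed_when_paired(self):
        for seed in range(20):
            s = rs.random_structure(rs.GeneratorParams(n=100, seed=seed))
            if s.pairs:
                g = rs.build_compressed_graph(s)
                assert g.n_vertices < s.length
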