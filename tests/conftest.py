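"""Shared fixtures and small synthetic systems for the test suite."""

import numpy as np
import pytest

import rnaspring as rs
from rnaspring.graph import BASE_PAIR, CompressedGraph, StructuralElement, Vertex


@pytest.fixture
def config1():
    return rs.preset_config(1)


@pytest.fixture
def config2():
    return rs.preset_config(2)


@pytest.fixture
def cloverleaf():
    return rs.cloverleaf_fixture()


@pytest.fixture
def hairpin_structure():
    return rs.parse_dotbracket("((((....))))")


def scalar_spring():
    """Two base-pair vertexes joined by one unit-rest-length spring.

    Base pairs feel no repulsion, so with vertex 0 fixed at the origin this
    is the textbook 1-D linear spring: the implicit update has the closed
    form x' = (x + dt*K*r) / (1 + dt*K) for x > 0.
    """
    el_a = StructuralElement(kind=BASE_PAIR, members=(1, 2), pair=(1, 2))
    el_b = StructuralElement(kind=BASE_PAIR, members=(3, 4), pair=(3, 4))
    graph = CompressedGraph(
        n_nucleotides=4,
        vertices=(Vertex(0, el_a), Vertex(1, el_b)),
        edges=frozenset({(0, 1)}),
        adjacency=((1,), (0,)),
        loop_ids=frozenset(),
    )
    state = rs.LayoutState(np.array([[0.0, 0.0], [2.0, 0.0]]))
    return graph, state, frozenset({0})


def force_oracle(vertex_id, state, graph, config):
    """Literal term-by-term sum of the repulsion and attraction closed forms
    (centre attraction), independent of the force-field implementation."""
    from rnaspring.forces import _edge_rest_length

    p = state.positions
    v_i = graph.vertices[vertex_id]
    total = np.zeros(2)
    if v_i.is_loop:
        for j in graph.loop_ids:
            if j == vertex_id:
                continue
            d = p[vertex_id] - p[j]
            dist = np.linalg.norm(d)
            total += config.G / dist**2 * (d / dist)
    for j in graph.neighbors(vertex_id):
        r = _edge_rest_length(v_i, graph.vertices[j], config)
        d = p[vertex_id] - p[j]
        dist = np.linalg.norm(d)
        total += config.K * ((p[j] - p[vertex_id]) + r * d / dist)
    return total
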