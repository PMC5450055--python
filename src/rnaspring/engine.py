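"""Initial layout, the simulation loop and the shipped configurations.

The initial layout places the nucleotides on a circle at equal arc spacing
and then positions every graph vertex at the arithmetic mean of its member
nucleotides — a cheap untangled starting point that respects the backbone
order.  The simulation then advances the chosen integrator until the net
force on every vertex falls to ``epsilon`` (or an iteration cap / divergence
guard trips).

Two configurations ship with the package: an explicit one (Forward Euler,
``dt = 0.01``, ``epsilon = 1e-4``) and an implicit one (Backward Euler,
``dt = 3.0``, ``epsilon = 0.3``, 5 Newton iterations per step) — a 300-fold
time-step ratio.  ``stability_scan`` sweeps a time-step grid and reports the
largest value at which a given integrator still converges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .forces import ForceField, SimulationConfig, resolve_coincident
from .graph import (
    EXTERIOR,
    CompressedGraph,
    StructuralElement,
    Vertex,
    build_compressed_graph,
)
from .integrators import LayoutState, backward_euler_step, forward_euler_step
from .structure_io import SecondaryStructure

__all__ = [
    "SimulationResult",
    "circular_layout",
    "init_vertex_positions",
    "initial_state",
    "simulate",
    "stability_scan",
    "preset_config",
    "two_loop_spring",
    "layout_structure",
    "DIVERGENCE_BOUND",
]

DIVERGENCE_BOUND = 1e9  # any coordinate beyond this flags divergence


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of a simulation run."""

    final_state: LayoutState
    iterations: int
    converged: bool
    diverged: bool
    max_force_history: np.ndarray  # per evaluated state, incl. the initial one


def circular_layout(structure: SecondaryStructure, spacing: float = 1.0) -> np.ndarray:
    """Place nucleotide ``i`` at angle ``2*pi*(i-1)/N`` on a circle of radius
    ``N * spacing / (2*pi)`` (equal arc spacing, centre at the origin).

    Returns an ``(N, 2)`` array; row ``i-1`` is nucleotide ``i``.
    """
    n = structure.length
    radius = n * spacing / (2.0 * math.pi)
    ang = 2.0 * math.pi * np.arange(n) / n
    return radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def _member_indices(element: StructuralElement) -> list[int]:
    if element.members:
        return list(element.members)
    # Empty-member loop (e.g. fully paired exterior): use its stem anchors.
    out: list[int] = []
    for i, j in element.anchors:
        out.extend((i, j))
    return out


def init_vertex_positions(
    graph: CompressedGraph, nuc_positions: np.ndarray
) -> LayoutState:
    """Each vertex at the arithmetic mean of its member nucleotides' positions.

    A loop with no unpaired members is placed at the centroid of its stem
    anchor nucleotides.
    """
    pos = np.zeros((graph.n_vertices, 2))
    for v in graph.vertices:
        idx = _member_indices(v.element)
        pos[v.id] = nuc_positions[np.array(idx) - 1].mean(axis=0)
    return LayoutState(pos, time=0.0, step_index=0)


def initial_state(
    structure: SecondaryStructure,
    graph: Optional[CompressedGraph] = None,
    spacing: float = 1.0,
) -> tuple[CompressedGraph, LayoutState]:
    """Convenience: circular layout + vertex averaging."""
    g = graph or build_compressed_graph(structure)
    return g, init_vertex_positions(g, circular_layout(structure, spacing))


def simulate(
    graph: CompressedGraph,
    config: SimulationConfig,
    integrator: Optional[str] = None,
    state: Optional[LayoutState] = None,
    fixed: frozenset[int] = frozenset(),
) -> SimulationResult:
    """Run the chosen integrator until equilibrium, the iteration cap, or
    divergence.

    ``integrator`` is ``"forward"`` or ``"backward"`` (defaults to
    ``config.integrator``).  Divergence (non-finite or runaway coordinates)
    is reported via the ``diverged`` flag, not an exception.  The run is
    deterministic for fixed inputs.
    """
    integ = integrator or config.integrator
    if integ not in ("forward", "backward"):
        raise ValueError(f"unknown integrator: {integ!r}")
    if state is None:
        raise ValueError("simulate requires an initial LayoutState")
    field = ForceField(graph, config)
    history: list[float] = []
    current = state
    iterations = 0
    converged = diverged = False
    prev_disp = None
    for it in range(config.max_iterations + 1):
        pos = current.positions
        if not np.all(np.isfinite(pos)) or np.abs(pos).max() > DIVERGENCE_BOUND:
            diverged = True
            break
        pos = resolve_coincident(pos, field)
        if pos is not current.positions:
            current = LayoutState(pos, current.time, current.step_index)
        mf = field.max_force(pos)
        history.append(mf)
        if not math.isfinite(mf):
            diverged = True
            break
        if mf <= config.epsilon:
            converged = True
            iterations = it
            break
        if it == config.max_iterations:
            iterations = it
            break
        if integ == "forward":
            current = forward_euler_step(current, graph, config, fixed=fixed, field_=field)
        else:
            before = current.positions
            current, _ = backward_euler_step(
                current, graph, config, fixed=fixed, field_=field,
                prev_displacement=prev_disp,
            )
            prev_disp = current.positions - before
        iterations = it + 1
    return SimulationResult(
        final_state=current,
        iterations=iterations,
        converged=converged,
        diverged=diverged,
        max_force_history=np.array(history),
    )


def stability_scan(
    graph: CompressedGraph,
    config_base: SimulationConfig,
    integrator: str,
    dt_values: Sequence[float],
    state: LayoutState,
    fixed: frozenset[int] = frozenset(),
) -> tuple[Optional[float], list[tuple[float, bool]]]:
    """Run ``simulate`` at each time-step (ascending) with all else fixed.

    Returns ``(largest converged dt or None, [(dt, converged), ...])``.
    """
    if list(dt_values) != sorted(dt_values) or any(dt <= 0 for dt in dt_values):
        raise ValueError("dt_values must be positive and ascending")
    table: list[tuple[float, bool]] = []
    best: Optional[float] = None
    for dt in dt_values:
        cfg = SimulationConfig(
            **{**config_base.__dict__, "dt": dt, "integrator": integrator}
        )
        res = simulate(graph, cfg, integrator, state=state, fixed=fixed)
        ok = res.converged and not res.diverged
        table.append((dt, ok))
        if ok:
            best = dt
    return best, table


def preset_config(which: int) -> SimulationConfig:
    """The two shipped experimental configurations.

    1: Forward Euler, K=10.0, G=0.01, dt=0.01, epsilon=1e-4.
    2: Backward Euler, K=10.0, G=0.01, dt=3.0, epsilon=0.3, 5 Newton
       iterations.
    """
    if which == 1:
        return SimulationConfig(
            K=10.0, G=0.01, dt=0.01, epsilon=0.0001, newton_iterations=0,
            max_iterations=200_000, integrator="forward",
        )
    if which == 2:
        return SimulationConfig(
            K=10.0, G=0.01, dt=3.0, epsilon=0.3, newton_iterations=5,
            max_iterations=2_000, integrator="backward",
        )
    raise ValueError(f"configuration must be 1 or 2, got {which!r}")


def two_loop_spring(
    separation: float = 1.5,
) -> tuple[CompressedGraph, LayoutState, frozenset[int]]:
    """Minimal test system: two loop vertexes joined by one spring, the
    first held fixed at the origin.

    The free vertex sees attraction with rest length equal to the
    nucleotide spacing plus loop-loop repulsion, making the closed-form
    stability and equilibrium analysis of a single 1-D spring applicable.
    Returns ``(graph, initial state, fixed ids)``.
    """
    el = StructuralElement(kind=EXTERIOR, members=(), pair=None)
    vertices = (Vertex(id=0, element=el), Vertex(id=1, element=el))
    graph = CompressedGraph(
        n_nucleotides=0,
        vertices=vertices,
        edges=frozenset({(0, 1)}),
        adjacency=((1,), (0,)),
        loop_ids=frozenset({0, 1}),
    )
    state = LayoutState(np.array([[0.0, 0.0], [separation, 0.0]]))
    return graph, state, frozenset({0})


def layout_structure(
    structure: SecondaryStructure,
    config: Optional[SimulationConfig] = None,
    integrator: Optional[str] = None,
) -> tuple[CompressedGraph, SimulationResult]:
    """Full pipeline: build graph, initialise, simulate."""
    cfg = config or preset_config(2)
    graph, state = initial_state(structure, spacing=cfg.nucleotide_spacing)
    result = simulate(graph, cfg, integrator, state=state)
    return graph, result
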