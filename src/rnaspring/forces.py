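"""Newtonian force model for the compressed-graph layout.

Every vertex is a massless particle in the plane.  Two forces act:

* **repulsion**, between loop vertexes only (base pairs do not repel),
  with inverse-square magnitude ``G / |Pi - Pj|^2`` directed away from the
  other loop;
* **attraction**, along graph edges, a linear spring with rest length
  ``r_ideal``: ``A = K * [(Pj - Pi) + r_ideal * U(Pi, Pj)]`` where ``U`` is
  the unit vector from ``Pj`` toward ``Pi``.  The force vanishes exactly at
  separation ``r_ideal``.

The simulation is first order: the net force directly sets the displacement
rate.  It stops when every vertex's net force magnitude is at most
``epsilon``.

Rest lengths derive from a single layout unit, the nucleotide spacing ``s``:
consecutive base pairs sit ``s`` apart, and a loop whose perimeter carries
``m`` slots (one per unpaired member, two per incident stem) is a circle of
radius ``s / (2 sin(pi / max(m, 3)))`` — the circumradius of a regular
``m``-gon with side ``s`` — so loops come out round with uniform arc spacing.

With *ideal-position attraction* enabled, a loop additionally stores, for
each stem protruding from it, an anchor point on its circumference (placed
by the perimeter slot arrangement and rotated rigidly with the loop's
current orientation).  The stem's terminal base pair is attracted straight
to that anchor — and the loop to the mirror target — which orients stems
radially around their parent loop instead of letting them collapse toward
the loop centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from .graph import EXTERIOR, CompressedGraph, StructuralElement, Vertex

if TYPE_CHECKING:  # pragma: no cover
    from .integrators import LayoutState

__all__ = [
    "Vec2",
    "SimulationConfig",
    "DegenerateGeometryError",
    "unit_vector",
    "repulsion",
    "attraction",
    "loop_radius",
    "loop_geometry",
    "compute_ideal_positions",
    "net_force",
    "is_equilibrium",
    "ForceField",
    "resolve_coincident",
]

Vec2 = np.ndarray  # shape (2,), float64

_DIST_FLOOR = 1e-12  # numerical floor inside vectorised kernels
_JITTER = 1e-6  # deterministic displacement applied to coincident vertexes
_GOLDEN_ANGLE = 2.399963229728653


class DegenerateGeometryError(ValueError):
    """Two interacting vertexes coincide; the unit vector is undefined."""


@dataclass
class SimulationConfig:
    """Tunable parameters of the force model and integrators.

    ``K``/``G`` are the attraction/repulsion coefficients, ``dt`` the
    time-step, ``epsilon`` the equilibrium force threshold,
    ``newton_iterations`` the per-step Newton budget of the implicit
    integrator.  ``nucleotide_spacing`` is the layout unit ``s``;
    ``r_ideal_bp`` the rest length between consecutive base pairs and
    ``pair_width`` the drawn distance between the two bases of one pair
    (both default to ``s``).
    """

    K: float = 10.0
    G: float = 0.01
    dt: float = 3.0
    epsilon: float = 0.3
    newton_iterations: int = 5
    r_ideal_bp: float = 1.0
    nucleotide_spacing: float = 1.0
    pair_width: float = 1.0
    max_iterations: int = 2000
    use_ideal_positions: bool = True
    integrator: str = "backward"

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.G < 0:
            raise ValueError("G must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.newton_iterations < 0:
            raise ValueError("newton_iterations must be non-negative")


# ---------------------------------------------------------------------------
# Elementary force terms (scalar reference implementations)
# ---------------------------------------------------------------------------

def unit_vector(p_i: Vec2, p_j: Vec2) -> Vec2:
    """Unit vector pointing from ``p_j`` toward ``p_i``."""
    d = np.asarray(p_i, dtype=float) - np.asarray(p_j, dtype=float)
    norm = math.hypot(d[0], d[1])
    if norm == 0.0:
        raise DegenerateGeometryError("coincident points: unit vector undefined")
    return d / norm


def repulsion(p_i: Vec2, p_j: Vec2, G: float) -> Vec2:
    """Inverse-square repulsion exerted on ``p_i`` by ``p_j``."""
    d = np.asarray(p_i, dtype=float) - np.asarray(p_j, dtype=float)
    d2 = float(d @ d)
    if d2 == 0.0:
        raise DegenerateGeometryError("coincident points: repulsion undefined")
    return (G / d2) * unit_vector(p_i, p_j)


def attraction(p_i: Vec2, p_j: Vec2, K: float, r_ideal: float) -> Vec2:
    """Spring attraction exerted on ``p_i`` by ``p_j`` with rest length ``r_ideal``."""
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if r_ideal == 0.0:
        # Pure point attraction; well defined even at coincidence.
        return K * (p_j - p_i)
    return K * ((p_j - p_i) + r_ideal * unit_vector(p_i, p_j))


# ---------------------------------------------------------------------------
# Loop geometry: radii, perimeter slot angles, orientation
# ---------------------------------------------------------------------------

def _slot_count(element: StructuralElement) -> int:
    n_nt = sum(1 for tag, _ in element.perimeter if tag == "nt")
    n_pair = sum(1 for tag, _ in element.perimeter if tag == "pair")
    return n_nt + 2 * n_pair


def loop_radius(element: StructuralElement, config: SimulationConfig) -> float:
    """Circumradius of the loop circle: regular m-gon with side ``s``."""
    m = _slot_count(element)
    s = config.nucleotide_spacing
    return s / (2.0 * math.sin(math.pi / max(m, 3)))


def _nominal_angles(element: StructuralElement):
    """Slot-centre angle per unpaired member and per bounding pair.

    Slots are allocated in perimeter (sequence) order, counter-clockwise;
    a bounding pair occupies two consecutive slots and its anchor sits at
    their shared boundary.
    """
    m = _slot_count(element)
    nt_angle: dict[int, float] = {}
    pair_angle: dict[tuple[int, int], float] = {}
    cursor = 0
    for tag, val in element.perimeter:
        if tag == "nt":
            nt_angle[val] = 2.0 * math.pi * (cursor + 0.5) / m
            cursor += 1
        else:
            pair_angle[val] = 2.0 * math.pi * (cursor + 1.0) / m
            cursor += 2
    return m, nt_angle, pair_angle


def loop_geometry(
    vertex: Vertex,
    positions: np.ndarray,
    graph: CompressedGraph,
    config: SimulationConfig,
):
    """Current geometry of a loop vertex: ``(radius, theta, nt_angle, pair_angle)``.

    ``theta`` is the rigid rotation aligning the nominal slot arrangement
    with the layout: the circular-mean best fit of the residual angles
    between each incident stem's current direction and its nominal anchor
    angle.  Averaging over all stems (rather than slaving the orientation to
    a single reference stem) keeps the rotation feedback contractive on
    large multiloops and exterior loops.  Angles in the returned maps are
    nominal; add ``theta`` to get layout angles.
    """
    el = vertex.element
    m, nt_angle, pair_angle = _nominal_angles(el)
    radius = loop_radius(el, config)
    by_pair = {graph.vertices[n].element.pair: n for n in graph.neighbors(vertex.id)
               if not graph.vertices[n].is_loop}
    sin_sum = cos_sum = 0.0
    for p, alpha in pair_angle.items():
        if p not in by_pair:
            continue
        d = positions[by_pair[p]] - positions[vertex.id]
        if float(d @ d) > 0.0:
            resid = math.atan2(d[1], d[0]) - alpha
            sin_sum += math.sin(resid)
            cos_sum += math.cos(resid)
    theta = math.atan2(sin_sum, cos_sum) if (sin_sum, cos_sum) != (0.0, 0.0) else 0.0
    return radius, theta, nt_angle, pair_angle


def compute_ideal_positions(
    loop_id: int,
    state: "LayoutState",
    graph: CompressedGraph,
    config: SimulationConfig,
) -> dict[int, Vec2]:
    """Anchor point on the loop circumference for each incident stem.

    Returns a map from incident base-pair vertex id to the anchor position;
    empty for a loop with no incident stems.  Anchors lie at distance
    ``loop_radius`` from the loop position and rotate rigidly with the
    loop's current orientation.
    """
    vertex = graph.vertices[loop_id]
    if not vertex.is_loop:
        raise ValueError(f"vertex {loop_id} is not a loop")
    positions = state.positions
    radius, theta, _nt, pair_angle = loop_geometry(vertex, positions, graph, config)
    out: dict[int, Vec2] = {}
    for nb in graph.neighbors(loop_id):
        nv = graph.vertices[nb]
        if nv.is_loop:
            continue
        alpha = pair_angle[nv.element.pair] + theta
        out[nb] = positions[loop_id] + radius * np.array(
            [math.cos(alpha), math.sin(alpha)]
        )
    return out


def _edge_rest_length(
    v_a: Vertex, v_b: Vertex, config: SimulationConfig
) -> float:
    """Rest length of the spring on edge (a, b) under centre attraction."""
    if v_a.is_loop and v_b.is_loop:
        return config.nucleotide_spacing
    if not v_a.is_loop and not v_b.is_loop:
        return config.r_ideal_bp
    loop = v_a if v_a.is_loop else v_b
    return loop_radius(loop.element, config)


# ---------------------------------------------------------------------------
# Per-vertex net force (reference path) and the equilibrium test
# ---------------------------------------------------------------------------

def net_force(
    vertex_id: int,
    state: "LayoutState",
    graph: CompressedGraph,
    config: SimulationConfig,
) -> Vec2:
    """Net force on one vertex: loop-loop repulsion plus edge attraction.

    Base-pair vertexes receive attraction only.  With ideal positions
    enabled, attraction across loop-stem edges targets the loop's anchor
    for that stem instead of the loop centre.
    """
    positions = state.positions
    p_i = positions[vertex_id]
    v_i = graph.vertices[vertex_id]
    force = np.zeros(2)
    if v_i.is_loop:
        for j in sorted(graph.loop_ids):
            if j != vertex_id:
                force += repulsion(p_i, positions[j], config.G)
    for j in graph.neighbors(vertex_id):
        v_j = graph.vertices[j]
        if config.use_ideal_positions and (v_i.is_loop != v_j.is_loop):
            if v_i.is_loop:
                anchor = compute_ideal_positions(vertex_id, state, graph, config)[j]
                force += config.K * (positions[j] - anchor)
            else:
                anchor = compute_ideal_positions(j, state, graph, config)[vertex_id]
                force += config.K * (anchor - p_i)
        else:
            force += attraction(
                p_i, positions[j], config.K, _edge_rest_length(v_i, v_j, config)
            )
    return force


def is_equilibrium(
    state: "LayoutState", graph: CompressedGraph, config: SimulationConfig
) -> bool:
    """True iff every vertex's net force magnitude is at most ``epsilon``."""
    field = ForceField(graph, config)
    return bool(field.max_force(state.positions) <= config.epsilon)


# ---------------------------------------------------------------------------
# Vectorised force field (used by the integrators and the engine)
# ---------------------------------------------------------------------------

class ForceField:
    """Vectorised evaluation of forces, implicit residuals and Jacobians.

    All methods take positions as ``(V, 2)`` float arrays.  The "frozen"
    variants evaluate each vertex's terms at its own trial position while
    every *other* vertex stays at the supplied reference positions — the
    per-vertex decoupling used by the implicit integrator.
    """

    def __init__(self, graph: CompressedGraph, config: SimulationConfig):
        self.graph = graph
        self.config = config
        V = graph.n_vertices
        self.n = V
        self.loop_idx = np.array(sorted(graph.loop_ids), dtype=int)
        is_loop = np.zeros(V, dtype=bool)
        is_loop[self.loop_idx] = True
        self.is_loop = is_loop

        plain_src: list[int] = []
        plain_dst: list[int] = []
        plain_r: list[float] = []
        # Ideal edges reference an anchor row: (loop, bp, nominal angle, radius).
        anc_loop: list[int] = []
        anc_bp: list[int] = []
        anc_alpha: list[float] = []
        anc_radius: list[float] = []
        anchor_row: dict[tuple[int, int], int] = {}
        ideal_src: list[int] = []
        ideal_row: list[int] = []
        ideal_mode: list[int] = []  # 1: bp toward loop anchor; 2: loop toward bp

        def anchor_entry(loop_v: Vertex, bp_v: Vertex) -> int:
            key = (loop_v.id, bp_v.id)
            if key not in anchor_row:
                _m, _nt, pair_angle = _nominal_angles(loop_v.element)
                anchor_row[key] = len(anc_loop)
                anc_loop.append(loop_v.id)
                anc_bp.append(bp_v.id)
                anc_alpha.append(pair_angle[bp_v.element.pair])
                anc_radius.append(loop_radius(loop_v.element, config))
            return anchor_row[key]

        for a, b in sorted(graph.edges):
            v_a, v_b = graph.vertices[a], graph.vertices[b]
            mixed = v_a.is_loop != v_b.is_loop
            if config.use_ideal_positions and mixed:
                loop_v = v_a if v_a.is_loop else v_b
                bp_v = v_b if v_a.is_loop else v_a
                row = anchor_entry(loop_v, bp_v)
                ideal_src.append(bp_v.id)
                ideal_row.append(row)
                ideal_mode.append(1)
                ideal_src.append(loop_v.id)
                ideal_row.append(row)
                ideal_mode.append(2)
            else:
                r = _edge_rest_length(v_a, v_b, config)
                plain_src.extend((a, b))
                plain_dst.extend((b, a))
                plain_r.extend((r, r))

        self.plain_src = np.array(plain_src, dtype=int)
        self.plain_dst = np.array(plain_dst, dtype=int)
        self.plain_r = np.array(plain_r, dtype=float)
        self.anc_loop = np.array(anc_loop, dtype=int)
        self.anc_bp = np.array(anc_bp, dtype=int)
        self.anc_alpha = np.array(anc_alpha, dtype=float)
        self.anc_radius = np.array(anc_radius, dtype=float)
        self.ideal_src = np.array(ideal_src, dtype=int)
        self.ideal_row = np.array(ideal_row, dtype=int)
        self.ideal_mode = np.array(ideal_mode, dtype=int)


    # -- frozen per-step quantities -------------------------------------

    def frozen_targets(self, pos: np.ndarray) -> np.ndarray:
        """Target points of the ideal-position edges, from reference positions.

        Returns an ``(M, 2)`` array aligned with ``ideal_src``; empty when
        ideal positions are disabled.
        """
        if self.ideal_src.size == 0:
            return np.zeros((0, 2))
        # Orientation per loop: circular mean of the residual angles between
        # each incident stem's direction and its nominal anchor angle.
        d = pos[self.anc_bp] - pos[self.anc_loop]
        ok = (d * d).sum(axis=1) > 0.0
        resid = np.where(ok, np.arctan2(d[:, 1], d[:, 0]) - self.anc_alpha, 0.0)
        sin_acc = np.zeros(self.n)
        cos_acc = np.zeros(self.n)
        np.add.at(sin_acc, self.anc_loop, np.where(ok, np.sin(resid), 0.0))
        np.add.at(cos_acc, self.anc_loop, np.where(ok, np.cos(resid), 0.0))
        theta = np.arctan2(sin_acc, cos_acc)
        theta[(sin_acc == 0.0) & (cos_acc == 0.0)] = 0.0
        phi = self.anc_alpha + theta[self.anc_loop]
        anchor = pos[self.anc_loop] + self.anc_radius[:, None] * np.stack(
            [np.cos(phi), np.sin(phi)], axis=1
        )
        targets = np.empty((self.ideal_src.size, 2))
        m1 = self.ideal_mode == 1
        m2 = ~m1
        targets[m1] = anchor[self.ideal_row[m1]]
        rows2 = self.ideal_row[m2]
        targets[m2] = pos[self.anc_bp[rows2]] - (anchor[rows2] - pos[self.anc_loop[rows2]])
        return targets

    # -- force / residual / Jacobian kernels ----------------------------

    def _forces(self, p_eval: np.ndarray, p_ref: np.ndarray, targets: np.ndarray) -> np.ndarray:
        K, G = self.config.K, self.config.G
        F = np.zeros((self.n, 2))
        L = self.loop_idx
        if L.size >= 2 and G > 0.0:
            diff = p_eval[L][:, None, :] - p_ref[L][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            np.fill_diagonal(d2, np.inf)
            d2 = np.maximum(d2, _DIST_FLOOR)
            inv = G / (d2 * np.sqrt(d2))
            F[L] += np.einsum("ij,ijk->ik", inv, diff)
        if self.plain_src.size:
            d = p_eval[self.plain_src] - p_ref[self.plain_dst]
            dist = np.maximum(np.sqrt((d * d).sum(axis=1)), _DIST_FLOOR)
            contrib = K * (-d + self.plain_r[:, None] * d / dist[:, None])
            np.add.at(F, self.plain_src, contrib)
        if self.ideal_src.size:
            contrib = K * (targets - p_eval[self.ideal_src])
            np.add.at(F, self.ideal_src, contrib)
        return F

    def net_forces(self, pos: np.ndarray) -> np.ndarray:
        """Net force on every vertex with all positions at the same time level."""
        return self._forces(pos, pos, self.frozen_targets(pos))

    def max_force(self, pos: np.ndarray) -> float:
        F = self.net_forces(pos)
        return float(np.sqrt((F * F).sum(axis=1)).max()) if F.size else 0.0

    def residuals(
        self, p_guess: np.ndarray, pos_n: np.ndarray, targets: np.ndarray
    ) -> np.ndarray:
        """Implicit-step residual ``F = -p_guess + p_n + dt * f(p_guess; p_n)``."""
        dt = self.config.dt
        return -p_guess + pos_n + dt * self._forces(p_guess, pos_n, targets)

    def jacobians(
        self, p_guess: np.ndarray, pos_n: np.ndarray
    ) -> np.ndarray:
        """Per-vertex 2x2 Jacobians of the implicit residual, analytic."""
        K, G, dt = self.config.K, self.config.G, self.config.dt
        I2 = np.eye(2)
        J = np.tile(-I2, (self.n, 1, 1))
        L = self.loop_idx
        if L.size >= 2 and G > 0.0:
            diff = p_guess[L][:, None, :] - pos_n[L][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            np.fill_diagonal(d2, np.inf)
            d2 = np.maximum(d2, _DIST_FLOOR)
            dist = np.sqrt(d2)
            outer = diff[:, :, :, None] * diff[:, :, None, :]
            term = (
                I2[None, None] / dist[:, :, None, None] ** 3
                - 3.0 * outer / dist[:, :, None, None] ** 5
            )
            term[np.isinf(d2)] = 0.0
            J[L] += dt * G * term.sum(axis=1)
        if self.plain_src.size:
            d = p_guess[self.plain_src] - pos_n[self.plain_dst]
            dist = np.maximum(np.sqrt((d * d).sum(axis=1)), _DIST_FLOOR)
            outer = d[:, :, None] * d[:, None, :]
            term = K * (
                -I2[None]
                + self.plain_r[:, None, None]
                * (I2[None] / dist[:, None, None] - outer / dist[:, None, None] ** 3)
            )
            np.add.at(J, self.plain_src, dt * term)
        if self.ideal_src.size:
            np.add.at(J, self.ideal_src, -dt * K * I2[None])
        return J

    def nearest_interaction_dist(
        self, pos: np.ndarray, pos_ref: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """Per-vertex distance to the nearest interacting partner (inf if none).

        With ``pos_ref`` given, each vertex is evaluated at ``pos`` while its
        partners sit at ``pos_ref`` (the frozen-neighbour geometry of the
        implicit solve).
        """
        if pos_ref is None:
            pos_ref = pos
        dmin = np.full(self.n, np.inf)
        L = self.loop_idx
        if L.size >= 2:
            diff = pos[L][:, None, :] - pos_ref[L][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            np.fill_diagonal(d2, np.inf)
            dmin[L] = np.sqrt(d2.min(axis=1))
        for src, dst in ((self.plain_src, self.plain_dst), (self.ideal_src, None)):
            if src.size == 0:
                continue
            if dst is None:
                # ideal edges: partner is the opposite endpoint
                rows = self.ideal_row
                other = np.where(self.ideal_mode == 1, self.anc_loop[rows], self.anc_bp[rows])
                dst = other
            d = np.sqrt(((pos[src] - pos_ref[dst]) ** 2).sum(axis=1))
            np.minimum.at(dmin, src, d)
        return dmin


def resolve_coincident(
    pos: np.ndarray, field: ForceField, tol: float = 1e-9
) -> np.ndarray:
    """Separate exactly coincident interacting vertexes.

    Applies a deterministic jitter of ``1e-6`` layout units in a direction
    derived from the vertex id (golden-angle spiral) to the higher-id member
    of each coincident interacting pair.  Returns the input array unchanged
    (same object) when no coincidence exists.
    """
    dmin = field.nearest_interaction_dist(pos)
    if not np.any(dmin < tol):
        return pos
    pos = pos.copy()
    for _ in range(8):
        moved = False
        pairs: list[tuple[int, int]] = []
        L = field.loop_idx
        for a in range(L.size):
            for b in range(a + 1, L.size):
                pairs.append((int(L[a]), int(L[b])))
        for a, b in field.graph.edges:
            pairs.append((a, b))
        for a, b in pairs:
            d = pos[a] - pos[b]
            if float(d @ d) < tol * tol:
                hi = max(a, b)
                ang = _GOLDEN_ANGLE * (hi + 1)
                pos[hi] = pos[hi] + _JITTER * np.array([math.cos(ang), math.sin(ang)])
                moved = True
        if not moved:
            break
    return pos
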