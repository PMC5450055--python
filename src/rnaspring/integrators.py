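"""Time integration: explicit (Forward Euler) and implicit (Backward Euler).

The explicit update is ``P_{n+1} = P_n + dt * f(P_n)`` with ``f`` the net
force; it is conditionally stable (on a linear spring of stiffness ``K`` the
error amplification per step is ``1 - dt*K``, so it diverges once
``dt*K > 2``).

The implicit update ``P_{n+1} = P_n + dt * f(P_{n+1})`` is solved per vertex
with that vertex's neighbours frozen at step ``n``, giving one independent
2-D root problem per vertex: find the zero of

    F(p) = -p + P_n + dt * f(p; neighbours at n).

Each root is approximated by a fixed number of Newton iterations using the
analytic 2x2 Jacobian of ``F``; all vertexes are then committed
simultaneously (Jacobi sweep), which keeps the step order-independent and
deterministic.  On the linear spring the implicit amplification factor is
``1 / (1 + dt*K) < 1`` for every positive ``dt`` — unconditional stability.

The Newton seed is the explicit update, clamped so that no vertex is thrown
past its nearest interacting neighbour (at large ``dt`` the raw explicit
displacement can tunnel a vertex through a neighbour, after which Newton
would converge to a spurious mirror-image root).  A singular Jacobian makes
the vertex keep its seed for that step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .forces import (
    DegenerateGeometryError,
    ForceField,
    SimulationConfig,
    Vec2,
    attraction,
    compute_ideal_positions,
    net_force,
    repulsion,
    resolve_coincident,
    _edge_rest_length,
)
from .graph import CompressedGraph

__all__ = [
    "LayoutState",
    "Residual2",
    "Jacobian2x2",
    "NewtonTrace",
    "SingularJacobianError",
    "forward_euler_step",
    "backward_residual",
    "compute_jacobian",
    "newton_step",
    "backward_euler_step",
    "NEWTON_EXIT_TOL",
    "SINGULARITY_FLOOR",
    "SEED_CLAMP_FRACTION",
]

logger = logging.getLogger("rnaspring")

NEWTON_EXIT_TOL = 1e-9  # early-exit residual norm
SINGULARITY_FLOOR = 1e-12  # |det D| below this triggers the seed fallback
SEED_CLAMP_FRACTION = 0.5  # explicit seed may move at most this fraction of
# the distance to the nearest interacting neighbour


class SingularJacobianError(ArithmeticError):
    """The 2x2 Jacobian is numerically singular."""


@dataclass(frozen=True)
class LayoutState:
    """Positions of all vertexes at one time-step."""

    positions: np.ndarray  # (V, 2) float64
    time: float = 0.0
    step_index: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be a (V, 2) array")
        object.__setattr__(self, "positions", pos)


@dataclass(frozen=True)
class Residual2:
    f_x: float
    f_y: float

    def as_array(self) -> Vec2:
        return np.array([self.f_x, self.f_y])

    @property
    def norm(self) -> float:
        return float(np.hypot(self.f_x, self.f_y))


@dataclass(frozen=True)
class Jacobian2x2:
    dfx_dx: float
    dfx_dy: float
    dfy_dx: float
    dfy_dy: float

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.dfx_dx, self.dfx_dy], [self.dfy_dx, self.dfy_dy]])

    @property
    def det(self) -> float:
        return self.dfx_dx * self.dfy_dy - self.dfx_dy * self.dfy_dx


@dataclass(frozen=True)
class NewtonTrace:
    """Per-vertex record of Newton iterates for one implicit step."""

    vertex_id: int
    iterates: tuple[tuple[int, tuple[float, float], float], ...]  # (k, position, |F|)
    singular_fallback: bool = False

    def first_below(self, tol: float) -> Optional[int]:
        """Smallest Newton index ``k`` with residual norm below ``tol``."""
        for k, _p, r in self.iterates:
            if r < tol:
                return k
        return None


# ---------------------------------------------------------------------------
# Explicit step
# ---------------------------------------------------------------------------

def forward_euler_step(
    state: LayoutState,
    graph: CompressedGraph,
    config: SimulationConfig,
    fixed: frozenset[int] = frozenset(),
    field_: Optional[ForceField] = None,
) -> LayoutState:
    """One explicit update of all vertexes from forces at step ``n``."""
    ff = field_ or ForceField(graph, config)
    pos = resolve_coincident(state.positions, ff)
    forces = ff.net_forces(pos)
    if not np.all(np.isfinite(forces)):
        raise DegenerateGeometryError("non-finite force in explicit step")
    new = pos + config.dt * forces
    if fixed:
        idx = list(fixed)
        new[idx] = pos[idx]
    return LayoutState(new, time=state.time + config.dt, step_index=state.step_index + 1)


# ---------------------------------------------------------------------------
# Implicit residual and Jacobian (scalar reference, per vertex)
# ---------------------------------------------------------------------------

def backward_residual(
    p_guess: Vec2,
    vertex_id: int,
    state: LayoutState,
    graph: CompressedGraph,
    config: SimulationConfig,
) -> Residual2:
    """Residual of the implicit equation at a trial position.

    Neighbour positions (and, in ideal mode, anchor targets) are taken from
    step ``n``; only this vertex moves to ``p_guess``.
    """
    p_guess = np.asarray(p_guess, dtype=float)
    positions = state.positions
    v_i = graph.vertices[vertex_id]
    f = np.zeros(2)
    if v_i.is_loop:
        for j in sorted(graph.loop_ids):
            if j != vertex_id:
                f += repulsion(p_guess, positions[j], config.G)
    for j in graph.neighbors(vertex_id):
        v_j = graph.vertices[j]
        if config.use_ideal_positions and (v_i.is_loop != v_j.is_loop):
            if v_i.is_loop:
                anchor = compute_ideal_positions(vertex_id, state, graph, config)[j]
                offset = anchor - positions[vertex_id]
                f += config.K * (positions[j] - (p_guess + offset))
            else:
                anchor = compute_ideal_positions(j, state, graph, config)[vertex_id]
                f += config.K * (anchor - p_guess)
        else:
            f += attraction(
                p_guess, positions[j], config.K, _edge_rest_length(v_i, v_j, config)
            )
    res = -p_guess + positions[vertex_id] + config.dt * f
    return Residual2(float(res[0]), float(res[1]))


def compute_jacobian(
    p_guess: Vec2,
    vertex_id: int,
    state: LayoutState,
    graph: CompressedGraph,
    config: SimulationConfig,
) -> Jacobian2x2:
    """Analytic 2x2 Jacobian of :func:`backward_residual` at ``p_guess``.

    Assembled term by term from the partial derivatives of the repulsion,
    attraction and unit-vector components; written out explicitly so it can
    be checked against finite differences.
    """
    p_guess = np.asarray(p_guess, dtype=float)
    positions = state.positions
    v_i = graph.vertices[vertex_id]
    K, G, dt = config.K, config.G, config.dt

    dfx_dx = dfx_dy = dfy_dx = dfy_dy = 0.0

    def unit_partials(dx: float, dy: float):
        dist = np.hypot(dx, dy)
        if dist == 0.0:
            raise DegenerateGeometryError("coincident points in Jacobian")
        r3 = dist**3
        dux_dx = dy * dy / r3
        dux_dy = -dy * dx / r3
        duy_dx = -dy * dx / r3
        duy_dy = dx * dx / r3
        return dist, dux_dx, dux_dy, duy_dx, duy_dy

    if v_i.is_loop:
        for j in sorted(graph.loop_ids):
            if j == vertex_id:
                continue
            dx, dy = p_guess - positions[j]
            dist, dux_dx, dux_dy, duy_dx, duy_dy = unit_partials(dx, dy)
            r2 = dist * dist  # squared distance
            ux, uy = dx / dist, dy / dist
            dfx_dx += dux_dx * G / r2 - 2.0 * G * dx / r2**2 * ux
            dfx_dy += dux_dy * G / r2 - 2.0 * G * dy / r2**2 * ux
            dfy_dx += duy_dx * G / r2 - 2.0 * G * dx / r2**2 * uy
            dfy_dy += duy_dy * G / r2 - 2.0 * G * dy / r2**2 * uy

    for j in graph.neighbors(vertex_id):
        v_j = graph.vertices[j]
        if config.use_ideal_positions and (v_i.is_loop != v_j.is_loop):
            # Point attraction toward a frozen target: derivative -K * I.
            dfx_dx += -K
            dfy_dy += -K
        else:
            r_ideal = _edge_rest_length(v_i, v_j, config)
            dx, dy = p_guess - positions[j]
            _dist, dux_dx, dux_dy, duy_dx, duy_dy = unit_partials(dx, dy)
            dfx_dx += K * (-1.0 + r_ideal * dux_dx)
            dfx_dy += K * (r_ideal * dux_dy)
            dfy_dx += K * (r_ideal * duy_dx)
            dfy_dy += K * (-1.0 + r_ideal * duy_dy)

    return Jacobian2x2(
        dfx_dx=-1.0 + dt * dfx_dx,
        dfx_dy=dt * dfx_dy,
        dfy_dx=dt * dfy_dx,
        dfy_dy=-1.0 + dt * dfy_dy,
    )


def newton_step(p_k: Vec2, residual: Residual2, jacobian: Jacobian2x2) -> Vec2:
    """One Newton update: ``p_{k+1} = p_k - D^{-1} F`` via the closed-form
    2x2 inverse."""
    det = jacobian.det
    if abs(det) < SINGULARITY_FLOOR:
        raise SingularJacobianError(f"|det D| = {abs(det):.3e} below floor")
    fx, fy = residual.f_x, residual.f_y
    inv_fx = (jacobian.dfy_dy * fx - jacobian.dfx_dy * fy) / det
    inv_fy = (-jacobian.dfy_dx * fx + jacobian.dfx_dx * fy) / det
    return np.asarray(p_k, dtype=float) - np.array([inv_fx, inv_fy])


# ---------------------------------------------------------------------------
# Implicit step (vectorised Jacobi sweep over all vertexes)
# ---------------------------------------------------------------------------

def backward_euler_step(
    state: LayoutState,
    graph: CompressedGraph,
    config: SimulationConfig,
    fixed: frozenset[int] = frozenset(),
    field_: Optional[ForceField] = None,
    collect_traces: bool = False,
    prev_displacement: Optional[np.ndarray] = None,
):
    """One implicit update; returns ``(new_state, traces)``.

    Each vertex solves its own 2-D root problem with neighbours frozen at
    step ``n``; the clamped explicit update seeds Newton, which runs for at
    most ``config.newton_iterations`` iterations (early exit below
    ``NEWTON_EXIT_TOL``).  ``traces`` is a list of :class:`NewtonTrace`
    (empty unless ``collect_traces``); residual norms are recorded at every
    iterate including the seed (k = 0).

    ``prev_displacement`` (the committed displacement of the previous step,
    as kept by the simulation loop) enables an anti-oscillation safeguard:
    a vertex whose proposed displacement reverses direction against its
    previous one commits only half of it.  The Jacobi sweep otherwise
    admits slowly-decaying (occasionally self-sustaining) period-2
    compression waves along stiff stems at large ``dt * K``; halving on
    reversal damps exactly those modes and leaves smooth monotone
    approaches — and any single step taken in isolation — untouched.
    """
    ff = field_ or ForceField(graph, config)
    pos = resolve_coincident(state.positions, ff)
    targets = ff.frozen_targets(pos)
    dt = config.dt

    forces = ff.net_forces(pos)
    disp = dt * forces
    dmin = ff.nearest_interaction_dist(pos)
    norms = np.sqrt((disp * disp).sum(axis=1))
    cap = SEED_CLAMP_FRACTION * dmin
    scale = np.ones(ff.n)
    over = norms > cap
    scale[over] = cap[over] / np.maximum(norms[over], _tiny)
    seed = pos + disp * scale[:, None]

    fixed_idx = np.array(sorted(fixed), dtype=int) if fixed else np.empty(0, dtype=int)
    if fixed_idx.size:
        seed[fixed_idx] = pos[fixed_idx]

    p = seed.copy()
    res = ff.residuals(p, pos, targets)
    res_norm = np.sqrt((res * res).sum(axis=1))
    singular = np.zeros(ff.n, dtype=bool)

    rec_norms = [res_norm.copy()]
    rec_pos = [p.copy()] if collect_traces else None

    active = np.ones(ff.n, dtype=bool)
    if fixed_idx.size:
        active[fixed_idx] = False
    for _k in range(config.newton_iterations):
        active &= res_norm >= NEWTON_EXIT_TOL
        if not active.any():
            break
        J = ff.jacobians(p, pos)
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        sing_now = active & (np.abs(det) < SINGULARITY_FLOOR)
        if sing_now.any():
            logger.warning(
                "singular Jacobian for vertexes %s; keeping explicit seed",
                np.nonzero(sing_now)[0].tolist(),
            )
            p[sing_now] = seed[sing_now]
            singular |= sing_now
            active &= ~sing_now
        upd = active
        if upd.any():
            d = np.where(np.abs(det) < SINGULARITY_FLOOR, 1.0, det)
            fx, fy = res[:, 0], res[:, 1]
            dx = (J[:, 1, 1] * fx - J[:, 0, 1] * fy) / d
            dy = (-J[:, 1, 0] * fx + J[:, 0, 0] * fy) / d
            step = np.stack([dx, dy], axis=1)
            # Damped Newton: accept the full step where it reduces the
            # residual norm, otherwise backtrack by halving.  A vertex whose
            # step cannot reduce the residual at all stays put this
            # iteration (the residual is non-convex near coincident
            # geometry and an unguarded step can overshoot violently).
            lam = np.where(upd, 1.0, 0.0)
            best_p = p.copy()
            best_norm = res_norm.copy()
            improved = np.zeros(ff.n, dtype=bool)
            for _bt in range(6):
                trial = p - lam[:, None] * step
                tr_res = ff.residuals(trial, pos, targets)
                tr_norm = np.sqrt((tr_res * tr_res).sum(axis=1))
                better = upd & ~improved & (tr_norm <= best_norm)
                best_p[better] = trial[better]
                best_norm[better] = tr_norm[better]
                improved |= better
                if improved[upd].all():
                    break
                lam = np.where(improved, lam, lam * 0.5)
            active &= improved  # stalled vertexes stop iterating
            p = best_p
        res = ff.residuals(p, pos, targets)
        res_norm = np.sqrt((res * res).sum(axis=1))
        rec_norms.append(res_norm.copy())
        if collect_traces:
            rec_pos.append(p.copy())

    if prev_displacement is not None:
        disp = p - pos
        reversed_ = (disp * prev_displacement).sum(axis=1) < 0.0
        if reversed_.any():
            p[reversed_] = pos[reversed_] + 0.5 * disp[reversed_]

    if fixed_idx.size:
        p[fixed_idx] = pos[fixed_idx]

    traces: list[NewtonTrace] = []
    if collect_traces:
        for vid in range(ff.n):
            iterates = tuple(
                (k, (float(rec_pos[k][vid, 0]), float(rec_pos[k][vid, 1])), float(rec_norms[k][vid]))
                for k in range(len(rec_norms))
            )
            traces.append(
                NewtonTrace(vertex_id=vid, iterates=iterates, singular_fallback=bool(singular[vid]))
            )

    new_state = LayoutState(p, time=state.time + dt, step_index=state.step_index + 1)
    return new_state, traces


_tiny = 1e-300
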