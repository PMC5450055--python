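"""From converged vertex positions to per-nucleotide coordinates and SVG.

Drawing conventions: the two bases of each pair sit symmetrically about
their vertex, perpendicular to the local stem axis, one pair width apart;
unpaired loop nucleotides sit on their loop's circle, at the perimeter slot
angles, between the flanking stem anchors and in sequence order.  Because
placement is constructive, loop circularity is exact and stem equidistance
reflects the quality of the converged vertex positions.

The SVG renderer emits one glyph (circle + base letter) per nucleotide, a
backbone polyline in sequence order and one tick per base pair.  The SVG
y-axis points down (native convention); flip y for comparisons with
mathematical-axis drawings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forces import SimulationConfig, loop_geometry
from .graph import CompressedGraph
from .integrators import LayoutState
from .structure_io import SecondaryStructure

__all__ = [
    "NucleotideLayout",
    "place_nucleotides",
    "render_svg",
    "overlap_score",
]


@dataclass(frozen=True)
class NucleotideLayout:
    """Per-nucleotide coordinates (row ``i-1`` is nucleotide ``i``) plus the
    pair set needed to enumerate drawn segments."""

    coordinates: np.ndarray  # (N, 2)
    pairs: frozenset[tuple[int, int]]

    @property
    def n(self) -> int:
        return self.coordinates.shape[0]


def place_nucleotides(
    graph: CompressedGraph,
    state: LayoutState,
    config: SimulationConfig,
) -> NucleotideLayout:
    """Map vertex positions to nucleotide coordinates."""
    pos = state.positions
    coords = np.zeros((graph.n_nucleotides, 2))
    pairs: set[tuple[int, int]] = set()

    for v in graph.vertices:
        if v.is_loop:
            radius, theta, nt_angle, _pa = loop_geometry(v, pos, graph, config)
            centre = pos[v.id]
            for idx, alpha in nt_angle.items():
                a = alpha + theta
                coords[idx - 1] = centre + radius * np.array([math.cos(a), math.sin(a)])
        else:
            i, j = v.element.pair
            pairs.add((i, j))
            outer = graph.bp_outer.get(v.id)
            inner = graph.bp_inner.get(v.id)
            if outer is not None and inner is not None:
                axis = pos[inner] - pos[outer]
            elif inner is not None:
                axis = pos[inner] - pos[v.id]
            elif outer is not None:
                axis = pos[v.id] - pos[outer]
            else:
                axis = np.array([1.0, 0.0])
            norm = math.hypot(axis[0], axis[1])
            if norm == 0.0:
                axis, norm = np.array([1.0, 0.0]), 1.0
            # 5' base on the clockwise side of the outward stem axis, which
            # matches the counter-clockwise perimeter ordering of the loops.
            perp = np.array([axis[1], -axis[0]]) / norm
            half = 0.5 * config.pair_width
            coords[i - 1] = pos[v.id] + half * perp
            coords[j - 1] = pos[v.id] - half * perp
    return NucleotideLayout(coordinates=coords, pairs=frozenset(pairs))


def render_svg(
    layout: NucleotideLayout,
    structure: SecondaryStructure,
    path: str,
    scale: float = 30.0,
    margin: float = 2.0,
) -> str:
    """Write a deterministic, self-contained SVG file; returns ``path``."""
    xy = layout.coordinates * scale
    lo = xy.min(axis=0) - margin * scale
    hi = xy.max(axis=0) + margin * scale
    width, height = hi - lo
    xy = xy - lo
    r_glyph = 0.35 * scale

    def fmt(v: float) -> str:
        return f"{v:.3f}"

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{fmt(width)}" '
        f'height="{fmt(height)}" viewBox="0 0 {fmt(width)} {fmt(height)}">',
        '<g stroke="#555" stroke-width="1.5" fill="none">',
        '<polyline class="backbone" points="'
        + " ".join(f"{fmt(x)},{fmt(y)}" for x, y in xy)
        + '"/>',
    ]
    for i, j in sorted(layout.pairs):
        (x1, y1), (x2, y2) = xy[i - 1], xy[j - 1]
        parts.append(
            f'<line class="pair" x1="{fmt(x1)}" y1="{fmt(y1)}" '
            f'x2="{fmt(x2)}" y2="{fmt(y2)}"/>'
        )
    parts.append("</g>")
    parts.append('<g font-family="monospace" text-anchor="middle" '
                 f'font-size="{fmt(0.45 * scale)}">')
    for k, (x, y) in enumerate(xy):
        base = structure.sequence[k]
        parts.append(
            f'<g class="nt"><circle cx="{fmt(x)}" cy="{fmt(y)}" r="{fmt(r_glyph)}" '
            'fill="#fff" stroke="#333" stroke-width="1"/>'
            f'<text x="{fmt(x)}" y="{fmt(y + 0.15 * scale)}">{base}</text></g>'
        )
    parts.append("</g>")
    parts.append("</svg>")
    text = "\n".join(parts) + "\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return path


def _segments(layout: NucleotideLayout) -> tuple[np.ndarray, np.ndarray, list[frozenset[int]]]:
    """Drawn segments: backbone (i, i+1) plus one per base pair.

    Returns start points, end points and the nucleotide-index sets used for
    the adjacency (shared-nucleotide) test.
    """
    xy = layout.coordinates
    starts, ends, who = [], [], []
    for i in range(1, layout.n):
        starts.append(xy[i - 1])
        ends.append(xy[i])
        who.append(frozenset({i, i + 1}))
    for i, j in sorted(layout.pairs):
        starts.append(xy[i - 1])
        ends.append(xy[j - 1])
        who.append(frozenset({i, j}))
    return np.array(starts), np.array(ends), who


def overlap_score(layout: NucleotideLayout) -> int:
    """Count pairs of non-adjacent drawn segments that intersect.

    Segments sharing a nucleotide index are adjacent and never counted; a
    score of zero means the drawing is untangled.  The score is invariant
    under rigid motions of the whole layout.
    """
    if layout.n < 2:
        return 0
    p, q, who = _segments(layout)
    d = q - p
    m = len(p)

    def cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

    # Broadcast proper segment-segment intersection test over all pairs.
    P1 = p[:, None, :]
    D1 = d[:, None, :]
    P2 = p[None, :, :]
    D2 = d[None, :, :]
    denom = cross(D1, D2)
    delta = P2 - P1
    t = np.full((m, m), np.nan)
    u = np.full((m, m), np.nan)
    nz = np.abs(denom) > 1e-12
    t[nz] = cross(delta, D2)[nz] / denom[nz]
    u[nz] = cross(delta, D1)[nz] / denom[nz]
    hit = nz & (t >= 0) & (t <= 1) & (u >= 0) & (u <= 1)
    # Collinear overlap: denom == 0 and the supports coincide.
    col = ~nz & (np.abs(cross(delta, D1)) < 1e-12)
    if col.any():
        for a, b in zip(*np.nonzero(col)):
            if a >= b:
                continue
            # project onto the longer segment
            da = d[a]
            L2 = float(da @ da)
            if L2 < 1e-24:
                continue
            t0 = float((p[b] - p[a]) @ da) / L2
            t1 = float((q[b] - p[a]) @ da) / L2
            if min(t0, t1) <= 1 and max(t0, t1) >= 0:
                hit[a, b] = hit[b, a] = True
    count = 0
    for a in range(m):
        for b in range(a + 1, m):
            if hit[a, b] and not (who[a] & who[b]):
                count += 1
    return count
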