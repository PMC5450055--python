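# Methods

## Structure model and decomposition

A secondary structure is a sequence over {A, C, G, U, N} plus a set of
1-based pairs `(i, j)`, `i < j`, in which no two pairs cross
(`i < k < j < l` is rejected — pseudoknots are out of scope, and extended
bracket families in dot-bracket input are refused rather than silently
flattened).  Parsers for dot-bracket, CT and BPSEQ enforce every invariant
(balanced brackets, symmetric pairing, contiguous indices); bases outside
the canonical alphabet are preserved verbatim with a warning — in
particular T is *not* silently mapped to U.

The decomposition assigns every nucleotide to exactly one element: each
base pair is its own element; unpaired bases belong to the loop whose
closing pair most tightly encloses them.  Loops are classified by bounding
stem count: hairpin (1), bulge (2, unpaired on one side), internal (2,
unpaired on both sides), multiloop (>= 3), and the always-materialised
exterior region.  A stem is a maximal run of stacked pairs; a bulge of any
size breaks it.  The compressed graph joins consecutive stacked pairs and
links each stem-terminal pair to its flanking loop; for valid input it is a
tree (`|E| = |V| - 1`), which the test suite cross-checks with networkx and
against a brute-force enclosing-pair oracle.

The exterior is materialised even when it has no unpaired bases so that
the outermost stems have an anchoring hub and multi-stem structures have a
repelling counterpart; its vertex initialises at the centroid of its stem
anchor nucleotides.

## Forces

Repulsion acts only between loop vertexes, `G / d^2` along the separating
direction; attraction acts along tree edges, `K [(P_j - P_i) +
r_ideal U(P_i, P_j)]`, vanishing exactly at separation `r_ideal`.  The
dynamics are first order: force equals displacement rate; there is no mass
or momentum.  The simulation stops when every vertex's net force magnitude
is at most `eps` (the force reading of the stopping rule; the alternative
"per-step movement below eps" reading differs only by the factor `dt` and
changes no reported outcome).

Rest lengths derive from one layout unit, the nucleotide spacing
`s = 1.0`:

* consecutive base pairs: `r_ideal = s`;
* a loop with `m` perimeter slots (one per unpaired member, two per
  incident stem) is a circle of radius `s / (2 sin(pi / max(m, 3)))` — the
  circumradius of a regular `m`-gon of side `s` — and loop-stem edges use
  that radius as rest length.

No published value exists for these spacings; the regular-polygon choice is
what makes loops round with uniform arc spacing, and all geometry tests are
stated relative to it.  The drawn pair width (distance between the two
bases of one pair) likewise defaults to `s`.

### Ideal-position attraction

With `use_ideal_positions` on (the default), each loop stores one anchor
per incident stem, placed on its circle at the angle the perimeter slot
arrangement dictates and rotated rigidly by the loop's current orientation.
Attraction across a loop-stem edge then targets the anchor instead of the
loop centre (pure point attraction, `K (anchor - P)`, with the mirrored
target applied to the loop), which orients stems radially around their
parent loops.  Base-pair-to-base-pair edges keep plain spring attraction.

The orientation is the circular-mean best fit of the residual angles
between each incident stem's current direction and its nominal anchor
angle.  An earlier variant that slaved the orientation to a single
reference stem proved non-contractive on large loops: the exterior circle
radius grows like `s m / (2 pi)`, so a small lateral move of the reference
stem swings every other anchor by a comparable amount and layouts of a few
hundred nucleotides oscillated instead of converging.  Averaging divides
that gain by the stem count and restored convergence on the whole test
suite.  Anchors are recomputed from the current state at every step (they
are cheap, and caching would let them lag the layout).

### Degenerate geometry

The unit vector is undefined at zero separation, so scalar force routines
raise a dedicated error, while the engine resolves exact coincidences
before each step with a deterministic jitter of 1e-6 units in a direction
derived from the vertex id (golden-angle spiral).  Vectorised kernels also
floor distances at 1e-12 so a transient near-coincidence cannot produce
non-finite intermediates.

## Integrators

Forward Euler updates all vertexes simultaneously from forces at the
current step.  Backward Euler freezes each vertex's neighbours at step `n`
and solves the per-vertex 2-D root problem
`F(p) = -p + P_n + dt f(p; neighbours_n) = 0` with Newton's method on the
analytic Jacobian (assembled term by term from the repulsion, attraction
and unit-vector partials; a standing property test checks every entry
against central finite differences at `h = 1e-6`).  All solutions commit
simultaneously (Jacobi sweep), keeping a step order-independent and
bit-deterministic.  On the linear spring the explicit error amplification
is `1 - dt K` per step (divergence for `dt K > 2`) and the implicit one
`1/(1 + dt K)` — unconditionally stable, which is what buys the 300-fold
time-step ratio between the two shipped configurations.

Numerical safeguards, in the order they act:

* **Seed clamp.**  The Newton seed is the explicit update, clamped to at
  most half the distance to the nearest interacting neighbour.  At
  `dt K = 30` the raw explicit displacement can throw a vertex past its
  neighbour; the residual is only piecewise smooth (the unit vector flips),
  and Newton started on the far side converges to a spurious mirror-image
  root.  On the scalar spring (`x_n = 2`, `K = 10`, `dt = 3`) the clamped
  seed lands at `x = 1` and one Newton step gives the exact implicit
  solution 32/31.
* **Damped Newton.**  Each iteration accepts the full step only if it
  reduces the residual norm, otherwise backtracks by halving (up to 6
  times; a vertex that cannot improve stays put for that step).  Near
  coincident geometry the transverse Jacobian eigenvalue of an attraction
  term crosses zero and an unguarded step overshoots by orders of
  magnitude.  With damping the residual norm is non-increasing across
  iterations in 100% of sampled vertex-steps.
* **Early exit** below residual norm 1e-9 (skips no-op iterations only);
  a singular Jacobian (`|det D| < 1e-12`) makes the vertex keep its seed
  for that step.
* **Anti-oscillation commit.**  Across steps, the Jacobi sweep admits
  slowly-decaying — and with the anchor nonlinearity occasionally
  self-sustaining — period-2 compression waves along stiff stems.  When a
  vertex's committed displacement anti-aligns with its displacement in the
  previous step, only half is committed.  Monotone trajectories, and any
  single step taken in isolation, are unaffected; the closed-form spring
  examples are reproduced bit-exactly.

Iteration caps replace wall-clock limits: 200,000 steps for the explicit
configuration and 2,000 for the implicit one, sized so structures up to
~400 nt finish at interactive scale.  Any coordinate beyond 1e9, or a
non-finite force, flags divergence (a reported outcome, not an exception).

## Initial layout, placement, rendering

Nucleotide `i` starts at angle `2 pi (i - 1)/N` on a circle of radius
`N s / (2 pi)`; each vertex starts at the arithmetic mean of its members'
positions.  After relaxation, the two bases of each pair are placed
symmetrically about their vertex, perpendicular to the local stem axis (the
direction between the vertex's outer and inner neighbours), with the 5'
base on the side consistent with the counter-clockwise perimeter ordering
of the loops; unpaired loop members go on their loop's circle at the slot
angles.  Placement is therefore constructive: loop-member radii are exact
by construction, while stem equidistance reflects how tightly the skeleton
converged.  The overlap score counts intersecting pairs of non-adjacent
drawn segments (backbone plus pair ticks) and is invariant under rigid
motions.  SVG output is deterministic text; its y-axis points down (native
SVG convention).

## Synthetic structures

The generator builds dot-bracket strings by recursive interval subdivision
(choose a stem length, then continue the enclosed interval as hairpin,
internal/bulge or two-branch multiloop with probability `branch_prob`), so
structures are non-crossing by construction — no rejection sampling.
Defaults: `min_stem = 2`, `min_hairpin = 3` (the physical minimum),
`branch_prob = 0.3`.  Sequences get complementary G-C/A-U letters on paired
positions.  What the generator emulates is the *size gradient and
branching topology* of curated RNA sets; it has no thermodynamic model, no
sequence realism and no non-canonical pairs, so passing tests demonstrate
correct graph construction and numerics on realistic topologies, not
biological plausibility of any particular structure.  The shipped 76-nt
cloverleaf (acceptor stem, three hairpin arms around one multiloop,
21 pairs, 26 vertexes) is a generic synthetic tRNA shape, not any
particular deposited structure.

The convergence suite uses 20 generated structures spanning 75-398 nt —
sized so the full suite relaxes in well under a minute on one core while
still covering an order of magnitude in length; the same suite, run with
anchor attraction on and off, underlies the overlap comparison.

## Known limitations

* The equilibrium threshold `eps = 0.3` of the implicit configuration
  certifies geometry only to about `eps / (2K)` ~ 1.5% in stem spacing at
  the stopping point; run with a tighter `eps` (e.g. 1e-3) when
  sub-percent equidistance matters — the skeleton itself converges to
  spreads around 1e-5.
* Pseudoknots are rejected, not drawn.
* Overlap is reduced by loop-loop repulsion and anchor attraction but not
  guaranteed zero for every topology; the score is reported so users know
  when manual untangling is needed.
* The per-vertex decoupled implicit solve converges linearly (Jacobi-like)
  near equilibrium; very long unbranched stems are the slowest cases.
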