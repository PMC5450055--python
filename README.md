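# rnaspring

Force-directed layout of pseudoknot-free RNA secondary structures.

RNA folds on itself into stems (runs of stacked base pairs) and loops
(hairpins, bulges, internal loops, multiloops and the exterior region).
Publication figures follow two conventions: loops are drawn as circles and
base pairs sit at a constant distance along each stem.  `rnaspring` computes
such layouts automatically: instead of simulating every nucleotide, it maps
each loop and each base pair to one vertex of a **compressed graph** (a tree
for pseudoknot-free structures, typically 3-4x fewer vertexes than
nucleotides), relaxes that graph under a Newtonian force model, then draws
the nucleotides on top of the converged skeleton and renders SVG.  It is
aimed at anyone who needs clean, reproducible secondary-structure figures
from dot-bracket/CT/BPSEQ files, and at readers interested in the numerics
of spring-embedder layouts.

## Model

Vertex `i` at position `P_i` experiences

* repulsion from every other **loop** vertex `j` (base pairs do not repel):
  `R(P_i, P_j) = G / |P_i - P_j|^2 * U(P_i, P_j)`,
* spring attraction along each graph edge:
  `A(P_i, P_j) = K [ (P_j - P_i) + r_ideal * U(P_i, P_j) ]`,

where `U(P_i, P_j)` is the unit vector from `P_j` toward `P_i` and
`r_ideal` the rest length (unit spacing between stacked pairs; the loop's
circumradius for loop-stem edges).  The motion is first order
(`dP/dt = F`) and stops when every vertex's net force is at most `eps`.

Two integrators advance the system:

* **Forward (explicit) Euler** — `P' = P + dt F(P)`; conditionally stable
  (a spring of stiffness `K` diverges once `dt K > 2`).
* **Backward (implicit) Euler** — `P' = P + dt F(P')`, solved per vertex
  with neighbours frozen at the previous step by damped Newton iterations
  on the analytic 2x2 Jacobian; stable at any `dt` (linear-case
  amplification `1/(1 + dt K)`).

The two shipped configurations are `(forward, K=10, G=0.01, dt=0.01,
eps=1e-4)` and `(backward, K=10, G=0.01, dt=3.0, eps=0.3, 5 Newton
iterations)` — a 300-fold time-step ratio.  Optionally, attraction across
loop-stem edges targets *ideal positions*: anchor points on the loop's
circumference that orient each protruding stem radially, which markedly
reduces stem/loop overlap.

## Worked example

Lay out a 76-nt tRNA-like cloverleaf (sequence line + dot-bracket line):

```sh
rnaspring generate --n 120 --seed 7 --out random.dbn   # or bring your own
rnaspring layout trna.dbn --config 2 --svg trna.svg
```

```
76 nt, 26 vertexes (5 loops): converged after 96 steps, max force 0.2917, overlap score 0
wrote trna.svg
```

The 76 nucleotides compress to 26 vertexes (21 base pairs, 5 loops).  Under
the implicit configuration the skeleton reaches force equilibrium
(`max force <= eps = 0.3`) in 96 time-steps; `overlap score 0` means no two
non-adjacent drawn segments intersect — the cloverleaf is untangled.  The
SVG shows one glyph per nucleotide, the backbone polyline and one tick per
base pair.

A stability scan reports the largest usable time-step per integrator:

```sh
rnaspring scan trna.dbn --integrator forward --dt-grid 0.005,0.01,0.02 --config 1
```

```
dt = 0.005      converged
dt = 0.01       converged
dt = 0.02       converged
largest stable dt: 0.02
```

The same scan with `--integrator backward` converges at every listed `dt`,
including values hundreds of times larger.

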