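# Methods

## Problem statement

Given closed triangulated surfaces (mm, common world frame) for skin, liver,
one tumor and a set of critical structures, find variable-length sets of
straight needle trajectories (entry on the skin, target in the tumor region)
that jointly ablate the tumor plus a safety margin while crossing no critical
structure.  The constrained multi-objective formulation is

minimize F(x) ∈ [0,1]⁶ subject to G(x) = 0,

with the six objectives and two constraints listed in the README.  All
objectives are normalized into [0,1] and quantities to be maximized enter as
1 − value, so every component is minimized.

## Geometry layer

No mesh library is assumed: STL/OBJ I/O, cleanup (vertex merge at 10⁻⁶ mm,
degenerate-face removal), consistent outward orientation (breadth-first
winding propagation per connected component, then a signed-volume sign fix)
and all predicates are implemented on numpy/scipy.

* Segment–mesh intersection: Möller–Trumbore over the triangles passing a
  per-triangle AABB prefilter; hits are ordered by arc parameter and merged
  when a segment pierces a shared edge (Δt < 10⁻⁹).
* Point containment: parity ray casting with a fixed "irrational" direction;
  a point whose ray grazes an edge or vertex is re-tested with up to four
  alternate directions.  Containment requires watertightness.
* Surface distance / closest point: exact point–triangle distance over the
  32 nearest-centroid candidates (cKDTree); when the candidate ring cannot
  certify the optimum (k-th centroid closer than the current bound plus the
  largest triangle circumradius) the query falls back to a vectorized
  all-triangles check.  Queries therefore equal brute-force testing.

These choices make every accelerated query bit-equal to exhaustive
evaluation, which the test suite checks against independent oracles.

## Environment

The entry surface is the subset of skin triangles whose vertices all lie
within the applicator reach (150 mm) of the tumor centroid.  The treatment
volume is a regular grid (default pitch 2 mm, anchored at the tumor
bounding-box minimum so different margins share grid points) keeping points
that are strictly within the margin of the tumor surface or inside the tumor,
inside the liver, and outside every vessel.  Margin dilation is a distance
test rather than a mesh offset: robust, grid-exact, and trivially monotone in
the margin.  The boundary test is strict (< margin), so a margin of 0 returns
interior points only.

## Ablation model

One needle ablates along the pullback chain: spheres of the ablation radius
r (default 10 mm) placed from the target backward in steps of the pullback
step (default r) for as long as a sphere still covers at least one previously
uncovered treatment point.  The union of the chain is approximated by the
capsule around the segment spanned by the centers — exact in the fine-step
limit, and within a hair-thin band of the sphere union at step = r.  The
ablations-per-applicator metric is the number of chain centers.

## GA operators

* **Sampling.**  Needle direction per individual = the principal axis of the
  treatment volume (largest second moment) with ~8° angular jitter, signed
  so the backward ray reaches the entry surface; pullback then sweeps the
  tumor lengthwise.  Targets are the deepest treatment points of
  transversally scattered columns; entries are the backward projections of
  the targets onto the entry surface.  Needle count = ceil(axis length / r)
  jittered by ±1.
* **Crossover.**  Children only reuse parent trajectories verbatim.  Child A
  greedily picks the trajectory with the largest marginal coverage subject to
  pairwise needle distance > r; child B is a random non-empty subset.  If a
  parent is the current best individual it is returned unchanged as its child
  and the other child is built greedily (convergence focus; the
  paper-level description does not fix the second child's recipe).
* **Mutation.**  Main loop: pick the input trajectory with the highest
  residual coverage, mutate it, add it to the intermediate solution, remove
  the points it covers; stop at coverage ≥ ε or when the input is exhausted
  (≤ |input| iterations).  A colliding trajectory is translated in steps of
  2 mm (max 10) along the outward normal at its first obstacle intersection —
  a pure translation of both endpoints, preserving bundle parallelism.  A
  non-colliding trajectory is refined by candidate comparison: one
  deterministic candidate nudging the needle toward the worst near-miss
  point, plus 5 Gaussian perturbations whose scales shrink geometrically from
  (σ_entry, σ_target) = (3, 2) mm down to 5% of that; candidates are scored
  by (residual points covered, − total distance shortfall of near-misses) and
  the original wins ties, so residual coverage never decreases.  The
  continuous shortfall term and the shrinking scales are what let a
  single-needle plan converge into the sub-millimetre target region where a
  10 mm sphere exactly covers a 10 mm tumor + 5 mm margin; fixed-scale
  integer-count scoring stalls at ~99.5% coverage.  After the loop a new
  needle aimed at the residual centroid is added if coverage < ε, the
  worst-performing needle (smallest marginal coverage; ties: longest, then
  lowest index) is deleted with probability p_remove = 0.35, and the plan is
  conformed.
* **Conform.**  Targets farther than one grid pitch from the treatment volume
  snap to the nearest treatment point; entries snap to the trajectory line's
  entry-surface crossing nearest the old entry (an entry strictly inside the
  body is kept — it marks a deliberately shortened over-long needle); lengths
  > 150 mm are shortened along the same line; needles with < 5 mm of liver
  path or < 20° to the skin/capsule tangent plane are removed.  The operator
  is idempotent.

## Optimizer

Standard NSGA-II with constrained domination (feasible ≻ infeasible;
infeasible ranked by sum(G); feasible by Pareto dominance on F), crowding
distance with infinite boundaries, binary tournament, μ+λ survival with
λ = μ = pop_size.  Variable-length individuals are transparent to the
machinery because it only sees the fixed-length F.  Defaults (unstated at
paper level, chosen once): population 40, ≤ 200 generations per attempt,
stagnation window 15 generations with tolerance 10⁻⁶ on the standard
deviation of the per-generation minimum of sum(G), ≤ 10 restarts keeping the
best candidate, early stop when feasible and the best f₄ improves by
< 10⁻⁴ over the window.  All randomness flows through one seeded generator;
identical seeds reproduce identical plans.

## Phantoms

Synthetic abdomens nest analytic meshes: skin ellipsoid (130 × 110 × 100 mm
semi-axes), liver ellipsoid (70 × 50 × 45 mm, offset), sphere-to-ellipsoid
tumors placed deep (jittered around the liver center) or subcapsular (a few
mm under the +z capsule), optional bar ribs in the skin–liver gap and a
tubular vessel passing the tumor at a configurable clearance.  The difficulty
suite grades 20 phantoms: 7 small deep tumors (8–14 mm, single-needle), 7
mid-size (20–40 mm, multi-needle), 6 subcapsular near vessel and ribs.
Phantoms emulate the four structure groups and nesting of segmented abdominal
CT; they do not emulate segmentation noise, non-convex organ shapes,
respiratory deformation or contacting structures, so a green phantom test
establishes the planning logic, not clinical performance.

## Numerical choices and scaling

Geometric tolerance 10⁻⁹ mm for coincidence, 10⁻⁶ mm for "on surface".
Coverage is a fraction of grid points, so its granularity is 1/|points|;
equality with 1.0 is exact, not approximate.  Angle assertions on icosphere
meshes carry ±6° facet-normal discretization.  Test and acceptance runs use
reduced GA budgets (populations 10–20, 25–60 generations) and the default
2 mm grid; the asserted properties (safety of returned plans, needle-count
recovery, oracle equality) do not depend on the budget, only the probability
of solving a phantom within it does.

## Known limitations

The repulsion step cannot resolve collisions whose obstacle normal is
parallel to the needle (it translates, never rotates); such needles are
flagged and usually eliminated by selection.  Ablation zones are spherical —
vendor ellipsoids and vessel cooling are out of scope.  One tumor per run;
insertion-guide spacing between needles beyond the clearance term is not
modelled.  Hard subcapsular phantoms occasionally exhaust the restart budget
at reduced test budgets and return an empty (honestly infeasible) result.
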