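# ablaplan

Automatic multi-needle trajectory planning for stereotactic radiofrequency
ablation (SRFA) of liver tumors.

Ablating a tumor larger than the ~1 cm reach of a single RFA probe requires
several needles whose overlapping ablation zones jointly cover the tumor plus
a 5–10 mm safety margin, while every needle stays clear of ribs, vessels and
neighbouring organs and respects insertion limits (≤ 150 mm depth, ≥ 5 mm of
liver on the path, ≥ 20° to the skin and liver-capsule tangent planes).
`ablaplan` searches the continuous space of (entry, target) point pairs over
triangulated anatomy meshes with a constrained multi-objective genetic
algorithm and returns multiple safe plans for the interventionalist to choose
from.

## Method

A candidate plan `x` is a variable-length list of trajectories, each encoded
as six coordinates (entry, target).  Plans are scored with

- **F(x) ∈ [0,1]⁶** — minimize: f₀ mean length, f₁ = 1 − mean in-tumor
  length (normalized by the longest treatment-volume chord), f₂ mean
  in-liver length, f₃ mean angle to the skin/capsule normals, f₄ = 1 −
  coverage of tumor + margin, f₅ needle count;
- **G(x) ∈ [0,∞)²** — g₀ = 1 if any needle crosses a critical structure or
  two needles come within the inter-needle clearance; g₁ = max(0, ε −
  coverage), the shortfall below the coverage threshold ε (default 0.98).

The optimizer is an NSGA-II loop (constrained non-dominated sorting,
crowding distance, binary tournament, elitist μ+λ survival) with
problem-specific operators:

- **sampling** builds near-parallel needle bundles along the longest axis of
  the treatment volume, with the needle count set by the axis-length /
  ablation-radius heuristic;
- **crossover** recombines whole trajectories from the two parents without
  altering coordinates (greedy marginal-coverage selection with needle
  spacing > ablation radius, or a random subset); the best individual is
  passed through unchanged;
- **mutation** greedily rebuilds a plan against the residual uncovered
  volume, pushes colliding needles along the obstacle surface normal, adds a
  needle when coverage is insufficient, deletes the worst-performing needle
  with probability 0.35, and conforms the result to the physical limits;
- **reinitialization** resamples the population (keeping the best candidate)
  when the minimum constraint violation stagnates, up to 10 restarts.

The ablation zone of one needle follows the pullback technique: spheres of
the ablation radius (default 10 mm) are chained backward from the target, so
the zone is a capsule around the active segment.  Coverage is measured on a
regular grid sampling (default 2 mm) of the margin-dilated tumor clipped to
the liver with vessels excluded.

## Worked example

```bash
ablaplan plan --phantom small_sphere --seed 7 --radius 10 --margin 5 \
              --pop-size 16 --generations 40 --out runs/demo
```

generates a synthetic abdomen with a 10 mm spherical tumor, plans with a
10 mm ablation radius and 5 mm margin, and prints the report of the best
feasible plan, e.g.

```
NT=1  C10=0.582  C5=1.000  C0=1.000  SN=5.66°  L=94.65 mm  ablations/applicator=2.00
16 feasible solution(s) written to runs/demo
```

One needle fully ablates the tumor with its 5 mm margin (C5 = C0 = 1.0); the
10 mm margin (C10) is only partially covered, as expected for a zone whose
radius equals the tumor radius plus the 5 mm margin and no more.  SN is the
mean insertion angle to the skin normal and L the mean needle length.  `runs/demo/solutions.json` holds
the whole feasible Pareto set — alternative plans trading needle count,
length and angle — and `best_plan.csv` the entry/target coordinates in mm.

`ablaplan evaluate plan.json --phantom small_sphere` scores an existing plan
file; `ablaplan phantom --name suite` exports the graded phantom suite as
STL for use with other tools.  Segmentation cases (STL/OBJ meshes or NIfTI
label masks, e.g. a 3D-IRCADb-01-style per-organ layout) are loaded through
a YAML manifest mapping structures to the four planning groups; see
`ablaplan.cases.load_segmentation_case`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated phantoms, the largest spherical tumor
diameter for which a single probe with a 10 mm ablation radius fully ablates
tumor plus 5 mm margin (reported in cm): it sweeps 8–12 mm spheres, samples
each treatment volume at 1 mm pitch, places one trajectory through the tumor
center and measures capsule coverage.
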