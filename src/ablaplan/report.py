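"""Plan reports: the clinical comparison metrics for a finished plan.

For a plan the report gives the trajectory count (NT), coverage of the tumor
dilated by 10, 5 and 0 mm (C10, C5, C0), the mean insertion angle to the
skin normal (SN, degrees), the mean trajectory length (L, mm) and the mean
number of pullback ablations per applicator.  The three coverages are
computed on treatment volumes rebuilt at each margin with the same grid
origin and spacing, so they are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .environment import Environment
from .objectives import PlannerParams, entry_angles
from .plan import Plan, ablation_positions, coverage_fraction

__all__ = ["PlanReport", "report_plan"]


@dataclass
class PlanReport:
    NT: int
    C10: float
    C5: float
    C0: float
    SN: float  # mean angle to skin normal at insertion, degrees
    L: float  # mean trajectory length, mm
    ablations_per_applicator: float

    def to_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:
        return (
            f"NT={self.NT}  C10={self.C10:.3f}  C5={self.C5:.3f}  "
            f"C0={self.C0:.3f}  SN={self.SN:.2f}\N{DEGREE SIGN}  L={self.L:.2f} mm  "
            f"ablations/applicator={self.ablations_per_applicator:.2f}"
        )


def report_plan(plan: Plan, env: Environment, params: PlannerParams) -> PlanReport:
    """Compute all report columns; a pure function of (plan, env, params)."""
    if len(plan) == 0:
        return PlanReport(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    coverages = {}
    for margin in (10.0, 5.0, 0.0):
        tv = env.rebuild_treatment(margin)
        coverages[margin] = coverage_fraction(
            plan, tv, params.ablation_radius_mm, params.pullback_step
        )
    angles, lengths, n_ablations = [], [], []
    for traj in plan:
        try:
            a_skin, _ = entry_angles(traj, env)
        except ValueError:
            a_skin = 90.0
        angles.append(a_skin)
        lengths.append(traj.length)
        zone = ablation_positions(
            traj, env.treatment, params.ablation_radius_mm, params.pullback_step
        )
        n_ablations.append(zone.n_ablations)
    return PlanReport(
        NT=len(plan),
        C10=coverages[10.0],
        C5=coverages[5.0],
        C0=coverages[0.0],
        SN=float(np.mean(angles)),
        L=float(np.mean(lengths)),
        ablations_per_applicator=float(np.mean(n_ablations)),
    )
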