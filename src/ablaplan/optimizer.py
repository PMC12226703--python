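"""Constrained NSGA-II main loop with stagnation-triggered reinitialization.

Selection uses constrained domination: a feasible plan always beats an
infeasible one; two infeasible plans are ordered by total constraint
violation sum(G); two feasible plans by Pareto dominance on the six
objectives.  Variable-length individuals are transparent to the machinery
because domination and crowding act on the fixed-length objective vector.

When no feasible solution exists and the per-generation minimum of sum(G)
stops moving (standard deviation below tolerance over a sliding window), the
population is reinitialized: the best candidate is kept and the rest is
resampled, up to ``max_restarts`` times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import Environment
from .objectives import EvalResult, PlannerParams, evaluate_plan
from .operators import (
    OperatorLog,
    Population,
    _best_key,
    crossover,
    mutate,
    sample_individual,
    sample_population,
)
from .plan import Plan, encode_plan

__all__ = [
    "nondominated_sort",
    "crowding_distance",
    "binary_tournament",
    "survival",
    "detect_stagnation",
    "reinitialize",
    "run",
    "PlannerResult",
    "OptimizerState",
]


# ---------------------------------------------------------------------------
# constrained non-dominated sorting
# ---------------------------------------------------------------------------

def _dominates(a: EvalResult, b: EvalResult) -> bool:
    if a.feasible != b.feasible:
        return a.feasible
    if not a.feasible:
        return a.sum_G < b.sum_G
    return bool(np.all(a.F <= b.F) and np.any(a.F < b.F))


def nondominated_sort(population: Population) -> list[list[int]]:
    """Partition indices into fronts under constrained domination."""
    evals = population.evals
    n = len(evals)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    counts = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(evals[i], evals[j]):
                dominated_by[i].append(j)
                counts[j] += 1
            elif _dominates(evals[j], evals[i]):
                dominated_by[j].append(i)
                counts[i] += 1
    fronts = []
    current = [i for i in range(n) if counts[i] == 0]
    while current:
        fronts.append(sorted(current))
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def crowding_distance(front_F) -> np.ndarray:
    """NSGA-II crowding distance for one front's objective vectors."""
    F = np.asarray(
        [ev.F if isinstance(ev, EvalResult) else ev for ev in front_F], dtype=np.float64
    )
    n, m = F.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        lo, hi = F[order[0], k], F[order[-1], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if hi - lo <= 0:
            continue
        gaps = (F[order[2:], k] - F[order[:-2], k]) / (hi - lo)
        dist[order[1:-1]] += gaps
    return dist


def _ranks_and_crowding(population: Population):
    fronts = nondominated_sort(population)
    rank = np.empty(len(population), dtype=np.int64)
    crowd = np.empty(len(population))
    for r, front in enumerate(fronts):
        rank[front] = r
        crowd[front] = crowding_distance([population.evals[i] for i in front])
    return fronts, rank, crowd


def binary_tournament(
    population: Population, rng: np.random.Generator, n_pairs: int = 1
):
    """Parent pairs; each slot won by (front rank, crowding distance, coin flip)."""
    _, rank, crowd = _ranks_and_crowding(population)

    def one() -> int:
        i, j = rng.integers(len(population)), rng.integers(len(population))
        if rank[i] != rank[j]:
            return int(i if rank[i] < rank[j] else j)
        if crowd[i] != crowd[j]:
            return int(i if crowd[i] > crowd[j] else j)
        return int(i if rng.random() < 0.5 else j)

    pairs = [(one(), one()) for _ in range(n_pairs)]
    return pairs if n_pairs > 1 else pairs[0]


def survival(parents: Population, offspring: Population, pop_size: int) -> Population:
    """Frontwise mu+lambda selection, last front split by crowding distance."""
    combined = Population(
        individuals=parents.individuals + offspring.individuals,
        evals=parents.evals + offspring.evals,
    )
    if len(combined) < pop_size:
        raise ValueError("combined population smaller than pop_size")
    fronts, _, crowd = _ranks_and_crowding(combined)
    chosen: list[int] = []
    for front in fronts:
        if len(chosen) + len(front) <= pop_size:
            chosen.extend(front)
        else:
            room = pop_size - len(chosen)
            # descending crowding, ties broken by combined-population index
            order = sorted(front, key=lambda i: (-crowd[i], i))
            chosen.extend(order[:room])
        if len(chosen) >= pop_size:
            break
    return Population(
        individuals=[combined.individuals[i] for i in chosen],
        evals=[combined.evals[i] for i in chosen],
    )


# ---------------------------------------------------------------------------
# stagnation / reinitialization
# ---------------------------------------------------------------------------

def detect_stagnation(min_G_history, window: int, tol: float) -> bool:
    """True when the minimum violation has flatlined while still infeasible."""
    if len(min_G_history) < window:
        return False
    recent = np.asarray(min_G_history[-window:])
    if recent[-1] <= 0.0:
        return False
    return float(np.std(recent)) < tol


def reinitialize(
    population: Population,
    env: Environment,
    params: PlannerParams,
    rng: np.random.Generator,
) -> Population:
    """Keep the best candidate verbatim, resample everyone else."""
    best_i = population.best_index
    individuals = [population.individuals[best_i]]
    evals = [population.evals[best_i]]
    for _ in range(params.pop_size - 1):
        individuals.append(sample_individual(env, params, rng))
        evals.append(None)
    return Population(individuals=individuals, evals=evals)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

@dataclass
class OptimizerState:
    generation: int = 0
    population: Population | None = None
    min_G_history: list = field(default_factory=list)
    restarts_used: int = 0


@dataclass
class PlannerResult:
    """Feasible Pareto-front plans plus run diagnostics."""

    solutions: list  # list[(Plan, EvalResult)], mutually non-dominated, sum(G)==0
    diagnostics: dict

    @property
    def feasible(self) -> bool:
        return len(self.solutions) > 0

    @property
    def best(self):
        """Solution with the highest coverage (ties: fewer needles)."""
        if not self.solutions:
            return None
        return min(self.solutions, key=lambda se: (-se[1].coverage, se[1].n_trajectories))


def _unique_feasible_front(population: Population):
    fronts = nondominated_sort(population)
    seen = set()
    out = []
    for i in fronts[0]:
        ev = population.evals[i]
        if not ev.feasible:
            continue
        key = encode_plan(population.individuals[i]).tobytes()
        if key in seen:
            continue
        seen.add(key)
        out.append((population.individuals[i], ev))
    out.sort(key=lambda se: (-se[1].coverage, se[1].n_trajectories, se[1].F.sum()))
    return out


def run(
    env: Environment,
    params: PlannerParams,
    log: OperatorLog | None = None,
    progress=None,
) -> PlannerResult:
    """Full GA: sample, then generations of mating/crossover/mutation/survival
    with stagnation-triggered restarts; returns the feasible Pareto set.

    Never raises on infeasibility: an empty solution list with diagnostics is
    returned when the budget is exhausted without a feasible plan.
    """
    rng = np.random.default_rng(params.seed)
    log = log if log is not None else OperatorLog()
    state = OptimizerState()
    population = sample_population(env, params, rng)
    population.evaluate(env, params)
    state.population = population

    converged = False
    f4_history: list[float] = []
    total_generations = 0
    while True:
        for _ in range(params.n_generations):
            best_plan = population.best
            pairs = binary_tournament(population, rng, n_pairs=max(1, params.pop_size // 2))
            if isinstance(pairs, tuple):
                pairs = [pairs]
            children: list[Plan] = []
            for i, j in pairs:
                ca, cb = crossover(
                    population.individuals[i],
                    population.individuals[j],
                    best_plan,
                    env,
                    params,
                    rng,
                    log,
                )
                children.append(mutate(ca, env, params, rng, log))
                children.append(mutate(cb, env, params, rng, log))
            offspring = Population(individuals=children, evals=[None] * len(children))
            offspring.evaluate(env, params)
            population = survival(population, offspring, params.pop_size)
            total_generations += 1
            state.generation = total_generations

            min_G = min(ev.sum_G for ev in population.evals)
            state.min_G_history.append(min_G)
            if min_G == 0.0:
                best_f4 = min(
                    float(ev.F[4]) for ev in population.evals if ev.feasible
                )
                f4_history.append(best_f4)
            else:
                f4_history.clear()
            if progress is not None:
                progress(state, population)

            if (
                len(f4_history) >= params.stagnation_window
                and f4_history[-params.stagnation_window] - f4_history[-1]
                < params.f4_improve_tol
            ):
                converged = True
                break
            if detect_stagnation(
                state.min_G_history, params.stagnation_window, params.stagnation_tol
            ):
                break
        else:
            # generation budget exhausted for this attempt
            if min(ev.sum_G for ev in population.evals) == 0.0:
                converged = True
        if converged or state.restarts_used >= params.max_restarts:
            break
        population = reinitialize(population, env, params, rng)
        population.evaluate(env, params)
        state.restarts_used += 1
        state.min_G_history.append(min(ev.sum_G for ev in population.evals))
        f4_history.clear()

    state.population = population
    solutions = _unique_feasible_front(population)
    diagnostics = {
        "generations": total_generations,
        "restarts": state.restarts_used,
        "seed": params.seed,
        "min_G": min(ev.sum_G for ev in population.evals),
        "operator_events": dict(log),
    }
    return PlannerResult(solutions=solutions, diagnostics=diagnostics)
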