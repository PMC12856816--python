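"""Minimum-set reserve selection by exact integer programming.

The problem: choose planning units x_i in {0,1} minimizing total proxy
cost sum(c_i x_i) subject to meeting every species' representation
target sum_i(a_ij x_i) >= T_j, with the existing reserve estate locked
in and — under the voluntary-declaration objective — all non-Indigenous
tenure locked out.  Solved to proven optimality with the HiGHS
mixed-integer solver behind ``scipy.optimize.milp``; a greedy
shortfall-per-cost heuristic is provided as a baseline and fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp
from shapely.ops import unary_union

from .units import LOCKED_IN_CLASSES, OBJECTIVE2_ELIGIBLE


class InfeasibleProblemError(ValueError):
    """Targets cannot be met with the selectable planning units."""

    def __init__(self, shortfalls: dict[str, float], label: str = ""):
        self.shortfalls = shortfalls
        msg = ", ".join(f"{sp}: {v:.3f} km2 short" for sp, v in shortfalls.items())
        super().__init__(f"infeasible problem{' (' + label + ')' if label else ''}: {msg}")


@dataclass
class PrioritizationProblem:
    costs: pd.Series
    features: pd.DataFrame  # PU x species amounts
    targets: pd.Series  # per species, km2
    locked_in: pd.Series  # bool per PU
    locked_out: pd.Series  # bool per PU
    objective: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if (self.locked_in & self.locked_out).any():
            raise ValueError("a PU cannot be both locked in and locked out")

    def check_feasible(self) -> None:
        avail = self.features.loc[~self.locked_out]
        supply = avail.sum(axis=0)
        short = {
            sp: float(self.targets[sp] - supply.get(sp, 0.0))
            for sp in self.targets.index
            if self.targets[sp] - supply.get(sp, 0.0) > 1e-9
        }
        if short:
            raise InfeasibleProblemError(short, self.label)


@dataclass
class Solution:
    problem: PrioritizationProblem
    selected: pd.Series  # bool per PU
    status: str
    gap: float = 0.0
    objective_value: float = 0.0

    def __post_init__(self) -> None:
        sel = self.selected
        pr = self.problem
        if (pr.locked_in & ~sel).any():
            raise ValueError("solution drops a locked-in PU")
        if (pr.locked_out & sel).any():
            raise ValueError("solution includes a locked-out PU")

    @property
    def selected_ids(self) -> pd.Index:
        return self.selected.index[self.selected]

    @property
    def new_ids(self) -> pd.Index:
        """Selected PUs beyond the locked-in estate."""
        return self.selected.index[self.selected & ~self.problem.locked_in]

    def coverage(self) -> pd.Series:
        got = self.problem.features.loc[self.selected_ids].sum(axis=0)
        return got

    def target_slack(self) -> pd.Series:
        """Achieved amount minus target, per species (>= 0 if feasible)."""
        got = self.coverage()
        return got.reindex(self.problem.targets.index).fillna(0.0) - self.problem.targets

    def audit(self, tol: float = 1e-6) -> None:
        slack = self.target_slack()
        if (slack < -tol).any():
            bad = slack[slack < -tol]
            raise AssertionError(f"targets violated: {bad.to_dict()}")


def build_problem(
    pus: pd.DataFrame,
    features: pd.DataFrame,
    targets: pd.Series,
    objective: int,
    label: str = "",
) -> PrioritizationProblem:
    """Assemble the minimum-set problem for one objective.

    Objective 1 (grow the reserve network from any tenure): existing
    PA/IPA PUs locked in, nothing locked out.  Objective 2 (grow the
    Indigenous protected-area network by voluntary declaration): same
    locked-in estate, every PU whose tenure is not Native Title (with or
    without pastoral use) or Indigenous freehold locked out.
    Feasibility after lock-out is checked up front, with a per-species
    shortfall report on failure.
    """
    if objective not in (1, 2):
        raise ValueError("objective must be 1 or 2")
    locked_in = pus["tenure"].isin(LOCKED_IN_CLASSES)
    if objective == 1:
        locked_out = pd.Series(False, index=pus.index)
    else:
        locked_out = ~pus["tenure"].isin(OBJECTIVE2_ELIGIBLE) & ~locked_in
    problem = PrioritizationProblem(
        costs=pus["cost"].astype(float),
        features=features.loc[pus.index],
        targets=targets.astype(float),
        locked_in=locked_in,
        locked_out=locked_out,
        objective=objective,
        label=label,
    )
    problem.check_feasible()
    return problem


def solve_exact(
    problem: PrioritizationProblem, gap: float = 0.0, time_limit: float | None = None
) -> Solution:
    """Solve the minimum-set ILP to proven optimality with HiGHS.

    Ties among equal-cost optima are pinned by a second solve that,
    subject to holding the optimal cost, minimizes the sum of selected
    PU indices — a deterministic, id-ordered tie-break that keeps
    repeated runs bit-identical.  Returns the best incumbent flagged
    ``"timeout"`` if the time limit bites before optimality is proven.
    """
    problem.check_feasible()
    c = problem.costs.to_numpy(dtype=float)
    n = len(c)

    A = problem.features.to_numpy(dtype=float).T  # species x PU
    tgt = problem.targets.reindex(problem.features.columns).fillna(0.0).to_numpy()
    keep = tgt > 0
    constraints = []
    if keep.any():
        constraints.append(LinearConstraint(A[keep], lb=tgt[keep], ub=np.inf))

    lb = problem.locked_in.to_numpy().astype(float)
    ub = 1.0 - problem.locked_out.to_numpy().astype(float)
    bounds = Bounds(lb=lb, ub=ub)
    options: dict = {"mip_rel_gap": gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c=c,
        constraints=constraints,
        bounds=bounds,
        integrality=np.ones(n),
        options=options,
    )
    if res.status == 2 or res.x is None:
        raise InfeasibleProblemError({}, problem.label or "solver reported infeasible")
    x = res.x > 0.5
    status = "optimal" if res.status == 0 else "timeout"
    if status == "optimal" and gap == 0.0:
        # tie-break among equal-cost optima: pin the optimal cost and
        # minimize the selected index sum (prefers low PU ids)
        z_star = float(c[x].sum())
        slack = max(1e-9, 1e-9 * abs(z_star))
        tie_constraints = constraints + [
            LinearConstraint(c[None, :], lb=-np.inf, ub=z_star + slack)
        ]
        res2 = milp(
            c=np.arange(1, n + 1, dtype=float),
            constraints=tie_constraints,
            bounds=bounds,
            integrality=np.ones(n),
            options={"mip_rel_gap": 0.0},
        )
        if res2.status == 0 and res2.x is not None:
            x = res2.x > 0.5
    sol = Solution(
        problem=problem,
        selected=pd.Series(x, index=problem.costs.index),
        status=status,
        gap=float(res.mip_gap) if res.mip_gap is not None else 0.0,
        objective_value=float(c[x].sum()),
    )
    sol.audit()
    return sol


def solve_greedy(problem: PrioritizationProblem) -> Solution:
    """Greedy baseline: repeatedly add the PU with the best ratio of
    capped target-shortfall reduction to cost until all targets are met.

    Never better than the exact solver; useful as an upper-bound oracle
    and as a fallback on very large instances.
    """
    problem.check_feasible()
    A = problem.features.to_numpy(dtype=float)
    c = problem.costs.to_numpy(dtype=float)
    tgt = problem.targets.reindex(problem.features.columns).fillna(0.0).to_numpy()
    selected = problem.locked_in.to_numpy().copy()
    blocked = problem.locked_out.to_numpy()
    achieved = A[selected].sum(axis=0)
    shortfall = np.maximum(tgt - achieved, 0.0)
    while shortfall.sum() > 1e-9:
        gain = np.minimum(A, shortfall[None, :]).sum(axis=1)
        gain[selected | blocked] = -1.0
        ratio = np.where(gain > 0, gain / np.maximum(c, 1e-12), -np.inf)
        best = int(np.argmax(ratio))
        if not np.isfinite(ratio[best]) or gain[best] <= 0:
            raise InfeasibleProblemError(
                {
                    sp: float(s)
                    for sp, s in zip(problem.features.columns, shortfall)
                    if s > 1e-9
                },
                problem.label,
            )
        selected[best] = True
        achieved += A[best]
        shortfall = np.maximum(tgt - achieved, 0.0)
    sol = Solution(
        problem=problem,
        selected=pd.Series(selected, index=problem.costs.index),
        status="greedy",
        objective_value=float(c[selected].sum()),
    )
    sol.audit()
    return sol


def boundary_length(geoms) -> float:
    """Total exposed edge length (km) of a set of PU polygons.

    Edges shared between two selected PUs cancel; region-border edges
    count fully.
    """
    geoms = list(geoms)
    if not geoms:
        return 0.0
    return float(unary_union(geoms).boundary.length)


def solution_metrics(
    solution: Solution, pus: pd.DataFrame, features: pd.DataFrame
) -> dict:
    """Table-style metrics for one optimal solution.

    Cost and tenure proportions are computed over newly selected PUs
    (the locked-in estate is sunk); area, boundary length and species
    coverage describe the whole resulting network.  Coverage for species
    j is 100 * (selected amount) / (total in-region amount), averaged
    without weights over all species, not just target species.
    """
    sel_ids = solution.selected_ids
    new_ids = solution.new_ids
    totals = features.sum(axis=0)
    got = features.loc[sel_ids].sum(axis=0)
    coverage = 100.0 * got / totals.replace(0.0, np.nan)
    new_tenure = pus.loc[new_ids, "tenure"]
    tenure_props = (
        (new_tenure.value_counts(normalize=True) * 100.0).to_dict() if len(new_ids) else {}
    )
    return {
        "n_pu_selected": int(len(sel_ids)),
        "n_pu_new": int(len(new_ids)),
        "proxy_cost_new": float(pus.loc[new_ids, "cost"].sum()),
        "area_km2": float(pus.loc[sel_ids, "area_km2"].sum()),
        "boundary_km": boundary_length(pus.loc[sel_ids, "geometry"]),
        "mean_coverage_pct": float(coverage.mean()),
        "coverage_pct": coverage,
        "tenure_proportions_new": tenure_props,
        "status": solution.status,
        "gap": solution.gap,
    }
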