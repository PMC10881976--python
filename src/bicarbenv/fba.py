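"""Flux balance analysis: deterministic LP optimisation of flux vectors.

The problem solved is the standard one

    max/min  v[objective]
    s.t.     S v = 0,   lb <= v <= ub

via ``scipy.optimize.linprog`` (HiGHS backend), with feasibility and
optimality tolerances of 1e-9 so that reported optima are reproducible to
well below the 1e-6 reporting precision.

Because LPs generically have alternate optima, single representative flux
vectors are produced by :func:`parsimonious_refine` (minimum total flux among
optima) and flux ranges at a fixed optimum by :func:`flux_range_at_optimum`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, ModelValidationError, stoichiometric_matrix

FEAS_TOL = 1e-9
REPORT_TOL = 1e-6

_LINPROG_OPTS = {
    "presolve": True,
    "primal_feasibility_tolerance": FEAS_TOL,
    "dual_feasibility_tolerance": FEAS_TOL,
}


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Dict[str, float]
    steady_state_residual: float

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def _status_name(code: int) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(code, "infeasible")


def _solve(model: MetabolicModel, c: np.ndarray) -> Tuple[str, float, np.ndarray]:
    """Minimize c.v subject to S v = 0 and the model bounds."""
    S = stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions.values()]
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options=_LINPROG_OPTS,
    )
    status = _status_name(res.status)
    x = res.x if res.x is not None else np.zeros(len(bounds))
    return status, float(res.fun) if res.fun is not None else np.nan, x


def solve_fba(model: MetabolicModel, objective: str, sense: str = "max") -> FluxSolution:
    """Optimise the flux of one reaction.

    Returns a :class:`FluxSolution`; infeasibility or unboundedness is
    reported through ``status``, never raised.
    """
    if objective not in model.reactions:
        raise ModelValidationError(f"objective reaction {objective!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    rids = model.reaction_ids
    c = np.zeros(len(rids))
    c[rids.index(objective)] = -1.0 if sense == "max" else 1.0
    status, fun, x = _solve(model, c)
    S = stoichiometric_matrix(model)
    residual = float(np.max(np.abs(S @ x))) if len(x) else 0.0
    obj = -fun if sense == "max" else fun
    return FluxSolution(
        status=status,
        objective_value=obj if status == "optimal" else np.nan,
        fluxes=dict(zip(rids, x)),
        steady_state_residual=residual,
    )


def set_bounds(model: MetabolicModel, reaction_id: str, lb: float, ub: float) -> MetabolicModel:
    """Return a copy of the model with new bounds on one reaction."""
    if lb > ub:
        raise ModelValidationError(f"lb {lb} > ub {ub} for {reaction_id!r}")
    if reaction_id not in model.reactions:
        raise ModelValidationError(f"unknown reaction {reaction_id!r}")
    out = model.copy()
    rxn = out.reactions[reaction_id]
    rxn.lower_bound = lb
    rxn.upper_bound = ub
    return out


def fix_flux(model: MetabolicModel, reaction_id: str, value: float) -> MetabolicModel:
    """Return a copy with the reaction flux pinned to ``value``."""
    return set_bounds(model, reaction_id, value, value)


def _fix_at_optimum(model: MetabolicModel, objective: str, sense: str) -> Tuple[MetabolicModel, FluxSolution]:
    primary = solve_fba(model, objective, sense)
    if not primary.optimal:
        return model, primary
    opt = primary.objective_value
    slack = max(1e-9 * abs(opt), 1e-9)
    rxn = model.reactions[objective]
    if sense == "max":
        fixed = set_bounds(model, objective, max(rxn.lower_bound, opt - slack), rxn.upper_bound)
    else:
        fixed = set_bounds(model, objective, rxn.lower_bound, min(rxn.upper_bound, opt + slack))
    return fixed, primary


def flux_range_at_optimum(
    model: MetabolicModel, objective: str, target: str, sense: str = "max"
) -> Tuple[float, float]:
    """Flux variability of ``target`` over the optimal face of ``objective``.

    The primary objective is first fixed at its optimum (within 1e-9
    relative), then the target flux is minimised and maximised.
    """
    if target not in model.reactions:
        raise ModelValidationError(f"unknown target reaction {target!r}")
    fixed, primary = _fix_at_optimum(model, objective, sense)
    if not primary.optimal:
        raise RuntimeError(f"primary objective not optimal: {primary.status}")
    lo = solve_fba(fixed, target, "min")
    hi = solve_fba(fixed, target, "max")
    return lo.objective_value, hi.objective_value


def parsimonious_refine(model: MetabolicModel, objective: str, sense: str = "max") -> FluxSolution:
    """Deterministic representative optimum: among all flux vectors attaining
    the objective optimum, return one minimising the total flux sum |v|.

    Implemented by the standard split of each flux into non-negative forward
    and reverse parts.
    """
    fixed, primary = _fix_at_optimum(model, objective, sense)
    if not primary.optimal:
        return primary

    rids = fixed.reaction_ids
    n = len(rids)
    S = stoichiometric_matrix(fixed).tocsc()
    # variables: p (forward), q (reverse); v = p - q
    A_eq = sparse.hstack([S, -S]).tocsc()
    bounds = []
    for r in fixed.reactions.values():
        bounds.append((max(0.0, r.lower_bound), max(0.0, r.upper_bound)))  # p
    for r in fixed.reactions.values():
        bounds.append((max(0.0, -r.upper_bound), max(0.0, -r.lower_bound)))  # q
    c = np.ones(2 * n)
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options=_LINPROG_OPTS,
    )
    if res.status != 0:
        return FluxSolution("infeasible", np.nan, {}, np.nan)
    v = res.x[:n] - res.x[n:]
    residual = float(np.max(np.abs(S @ v))) if n else 0.0
    return FluxSolution(
        status="optimal",
        objective_value=v[rids.index(objective)],
        fluxes=dict(zip(rids, v)),
        steady_state_residual=residual,
    )
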