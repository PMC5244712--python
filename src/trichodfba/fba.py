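"""Steady-state linear-program machinery.

Flux balance analysis (max c.v subject to S.v = 0, lb <= v <= ub), flux
variability analysis at a fraction of the optimum, bisection calibration of
the non-growth-associated maintenance flux against a measured growth rate,
and single gene/reaction knockout essentiality.  The LPs are solved through
cobrapy's optlang/GLPK backend; this module owns the contracts (statuses are
propagated, never silently zeroed) and the calibration/essentiality logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import cobra
from cobra.flux_analysis import flux_variability_analysis

from .core import stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "solve_fba",
    "run_fva",
    "calibrate_maintenance",
    "essentiality",
    "CalibrationError",
]

#: growth below this is "no growth" for essentiality classification, h-1
ESSENTIAL_THRESHOLD = 1e-6
#: knockouts below this fraction of wild type are "growth-reducing"
GROWTH_REDUCING_FRACTION = 0.99


class CalibrationError(RuntimeError):
    """Target growth rate unreachable within the maintenance bracket."""


@dataclass
class FluxSolution:
    """An FBA optimum: flux vector, objective value and solver status."""

    fluxes: pd.Series                 # reaction id -> mmol (g DW)-1 h-1
    objective_value: float | None     # h-1 for a biomass objective
    status: str                       # optimal | infeasible | unbounded | ...

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes[reaction_id])

    def steady_state_residual(self, model: cobra.Model) -> float:
        """max |S.v| over metabolites; ~0 for any accepted solution."""
        S = stoichiometric_matrix(model)
        v = self.fluxes.reindex([r.id for r in model.reactions]).to_numpy()
        return float(np.abs(S @ v).max())


def solve_fba(
    model: cobra.Model,
    objective: str | None = None,
    sense: str = "max",
) -> FluxSolution:
    """Solve the FBA LP; infeasible/unbounded statuses are propagated."""
    with model:
        if objective is not None:
            model.objective = objective
        model.objective_direction = "max" if sense == "max" else "min"
        solution = model.optimize(raise_error=False)
    if solution.status != "optimal":
        return FluxSolution(
            fluxes=pd.Series(dtype=float), objective_value=None,
            status=solution.status,
        )
    return FluxSolution(
        fluxes=solution.fluxes, objective_value=float(solution.objective_value),
        status="optimal",
    )


def run_fva(
    model: cobra.Model,
    reactions: list[str] | None = None,
    fraction_of_optimum: float = 1.0,
) -> pd.DataFrame:
    """Per-reaction [min, max] flux with the objective held at a fraction
    of its optimum; columns ``minimum``/``maximum`` indexed by reaction id."""
    reaction_list = None
    if reactions is not None:
        reaction_list = [model.reactions.get_by_id(r) for r in reactions]
    fva = flux_variability_analysis(
        model,
        reaction_list=reaction_list,
        fraction_of_optimum=fraction_of_optimum,
        processes=1,
    )
    return fva


def calibrate_maintenance(
    model: cobra.Model,
    target_growth: float,
    maintenance_id: str = "EN_ATP",
    bracket: tuple[float, float] = (0.0, 1000.0),
    tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Maintenance ATP flux at which predicted growth matches ``target_growth``.

    Growth is monotone non-increasing in the maintenance lower bound, so the
    root is found by bisection to |growth - target| <= ``tol`` (h-1).  The
    bracket must straddle the target, otherwise the achievable growth range
    is reported.
    """
    maint = model.reactions.get_by_id(maintenance_id)

    def growth_at(m: float) -> float:
        with model:
            maint.lower_bound = m
            if m > maint.upper_bound:
                maint.upper_bound = m
            value = model.slim_optimize(error_value=np.nan)
        return 0.0 if np.isnan(value) else float(value)

    lo, hi = bracket
    g_lo, g_hi = growth_at(lo), growth_at(hi)
    if not (g_hi - tol <= target_growth <= g_lo + tol):
        raise CalibrationError(
            f"target growth {target_growth} outside achievable range "
            f"[{g_hi:.6g}, {g_lo:.6g}] for maintenance in {bracket}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g_mid = growth_at(mid)
        if abs(g_mid - target_growth) <= tol:
            return mid
        if g_mid > target_growth:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach |growth - target| <= {tol} in {max_iter} iterations"
    )


def _classify(growth: float, wild_type: float) -> str:
    if growth < ESSENTIAL_THRESHOLD:
        return "essential"
    if growth < GROWTH_REDUCING_FRACTION * wild_type:
        return "growth-reducing"
    return "neutral"


def essentiality(
    model: cobra.Model,
    mode: str = "gene",
) -> pd.DataFrame:
    """Single-knockout growth screen.

    ``gene`` mode knocks out one gene at a time (every reaction whose GPR
    evaluates false without it is disabled; AND = complex requirement, OR =
    isozyme); ``reaction`` mode fixes one reaction to [0, 0].  An infeasible
    knockout LP counts as zero growth.  Returns a frame with columns
    ``growth`` (h-1) and ``classification``
    (essential | growth-reducing | neutral) indexed by gene/reaction id.
    """
    if mode not in ("gene", "reaction"):
        raise ValueError("mode must be 'gene' or 'reaction'")
    wild_type = model.slim_optimize(error_value=np.nan)
    if np.isnan(wild_type):
        raise RuntimeError("wild-type model is infeasible; nothing to screen")
    wild_type = float(wild_type)

    rows = []
    targets = model.genes if mode == "gene" else model.reactions
    for target in targets:
        with model:
            if mode == "gene":
                target.knock_out()
            else:
                target.bounds = (0.0, 0.0)
            growth = model.slim_optimize(error_value=np.nan)
        growth = 0.0 if np.isnan(growth) else max(float(growth), 0.0)
        rows.append((target.id, growth, _classify(growth, wild_type)))
    frame = pd.DataFrame(rows, columns=["id", "growth", "classification"])
    frame = frame.set_index("id")
    frame.attrs["wild_type_growth"] = wild_type
    frame.attrs["n_essential"] = int((frame["classification"] == "essential").sum())
    return frame
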