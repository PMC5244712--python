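"""Exhaustive vertex enumeration for small LPs.

Independent check of the FBA solver path: for max c.x subject to
A x = 0, lb <= x <= ub, every basic feasible solution is enumerated by
fixing n - rank(A) variables at a bound and solving for the rest.  Only
meant for n <= ~10 variables.
"""

from itertools import combinations, product

import numpy as np


def brute_force_lp(c, A, lb, ub, tol=1e-7):
    """Return (optimum value, vertex) or (None, None) if infeasible."""
    c = np.asarray(c, dtype=float)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = len(c)
    r = np.linalg.matrix_rank(A)
    best_val, best_x = None, None
    for nonbasic in combinations(range(n), n - r):
        basic = [j for j in range(n) if j not in nonbasic]
        A_B = A[:, basic]
        for bounds_choice in product(*[(lb[j], ub[j]) for j in nonbasic]):
            rhs = -A[:, list(nonbasic)] @ np.asarray(bounds_choice)
            x_B, residual, *_ = np.linalg.lstsq(A_B, rhs, rcond=None)
            x = np.empty(n)
            x[basic] = x_B
            x[list(nonbasic)] = bounds_choice
            if np.max(np.abs(A @ x)) > tol:
                continue
            if np.any(x < lb - tol) or np.any(x > ub + tol):
                continue
            val = float(c @ x)
            if best_val is None or val > best_val:
                best_val, best_x = val, x
    return best_val, best_x


def cobra_lp_arrays(model):
    """(c, S, lb, ub) arrays of a cobra model's FBA problem."""
    from cobra.util.array import create_stoichiometric_matrix
    from cobra.util.solver import linear_reaction_coefficients

    S = create_stoichiometric_matrix(model)
    coeffs = linear_reaction_coefficients(model)
    c = np.array([coeffs.get(r, 0.0) for r in model.reactions])
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return c, S, lb, ub
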