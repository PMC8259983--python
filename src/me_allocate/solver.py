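"""Growth-rate optimisation of mu-parametric ME models.

The coupling constraints make the stoichiometric matrix a function of the
growth rate, so the model cannot be optimised as a single LP.  Instead,
feasibility of ``{S(mu) v = 0, vL <= v <= vU, v_dilution = mu}`` is checked at
fixed mu and the maximal growth rate is located by bisection on a
(feasible, infeasible) bracket, following the standard ME-model binary-search
procedure.  The reference formulation runs in quad precision to tolerance
1e-13; this implementation runs double precision (scipy's HiGHS backend) with
a default tolerance of 1e-6 h^-1, adequate at toy scale.

Because the LP at fixed mu generally has alternate optima, reported flux
vectors are made deterministic by a parsimonious secondary objective:
minimise total absolute flux subject to feasibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .core import (
    MEError,
    MEModelSpec,
    NumericLP,
    ParametricLP,
    compile_parametric,
)

__all__ = [
    "MESolution",
    "SolverError",
    "BracketError",
    "feasible_at_mu",
    "maximize_growth",
    "solve_condition",
    "grid_maximize",
    "coupling_residuals",
]

FEASIBILITY_TOL = 1e-9
DEFAULT_MU_HI = 4.0  # h^-1; above any growth rate the toy models support
DEFAULT_TOL = 1e-6


class SolverError(MEError):
    """The LP backend failed numerically."""


class BracketError(MEError):
    """The initial (mu_lo, mu_hi) bracket does not enclose the optimum."""


@dataclass
class MESolution:
    """Optimal growth rate and the flux vector at that rate.

    ``bracket`` is the final (maximum feasible mu, minimum infeasible mu)
    pair of the bisection; its width is at most the tolerance when the
    status is ``optimal``.
    """

    mu_opt: float
    fluxes: pd.Series
    status: str  # optimal | infeasible_at_zero | tolerance_reached | no_growth
    iterations: int = 0
    bracket: tuple[float, float] = (0.0, 0.0)

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes.get(reaction_id, 0.0))


def _linprog_options() -> dict:
    return {"presolve": True, "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL}


def _solve_numeric(lp: NumericLP, parsimonious: bool = True
                   ) -> Optional[pd.Series]:
    """Solve one numeric instance; None if infeasible.

    Feasibility is decided with a zero objective; when feasible and
    ``parsimonious``, a second solve minimises sum |v| (reversible columns
    split into positive parts) so the returned vector is unique in practice.
    """
    n = lp.S.shape[1]
    if np.any(lp.lower > lp.upper):
        return None  # an explicitly empty bound interval (e.g. a mu cap)
    bounds = list(zip(lp.lower, lp.upper))
    res = linprog(np.zeros(n), A_eq=lp.S, b_eq=np.zeros(lp.S.shape[0]),
                  bounds=bounds, method="highs", options=_linprog_options())
    if res.status == 4:
        # numerical trouble at the feasibility boundary: retry without
        # presolve, then classify a persistent ambiguity as infeasible
        # (conservative: can only round the optimum down, never corrupt it)
        opts = _linprog_options()
        opts["presolve"] = False
        res = linprog(np.zeros(n), A_eq=lp.S, b_eq=np.zeros(lp.S.shape[0]),
                      bounds=bounds, method="highs", options=opts)
        if res.status == 4:
            return None
    if res.status == 2:  # infeasible
        return None
    if res.status != 0:
        raise SolverError(f"LP backend failure at mu={lp.mu}: {res.message}")
    if not parsimonious:
        return pd.Series(res.x, index=lp.reaction_ids)
    # split columns that can go negative: v_j = p_j - n_j, p,n >= 0
    neg = np.where(lp.lower < 0)[0]
    n_extra = len(neg)
    S2 = np.hstack([lp.S, -lp.S[:, neg]]) if n_extra else lp.S
    cost = np.ones(n + n_extra)
    bounds2 = []
    for j in range(n):
        lo, hi = lp.lower[j], lp.upper[j]
        bounds2.append((max(lo, 0.0), max(hi, 0.0)))
    for j in neg:
        bounds2.append((0.0, -lp.lower[j]))
    # p_j - n_j must respect [lo, hi] for split columns: p <= max(hi,0),
    # n <= -lo already enforced; cross constraint p - n >= lo is implied
    # because p >= 0 >= lo, and p - n <= hi needs a row when hi < inf.
    A_ub = None
    b_ub = None
    if n_extra:
        rows = []
        rhs = []
        for pos, j in enumerate(neg):
            row = np.zeros(n + n_extra)
            row[j] = 1.0  # p_j
            row[n + pos] = -1.0  # -n_j
            rows.append(row)
            rhs.append(lp.upper[j])
        A_ub = np.vstack(rows)
        b_ub = np.array(rhs)
    res2 = linprog(cost, A_eq=S2, b_eq=np.zeros(S2.shape[0]),
                   A_ub=A_ub, b_ub=b_ub, bounds=bounds2,
                   method="highs", options=_linprog_options())
    if res2.status != 0:
        # fall back on the feasibility-phase vector
        return pd.Series(res.x, index=lp.reaction_ids)
    x = res2.x[:n].copy()
    x[neg] = res2.x[neg] - res2.x[n:]
    return pd.Series(x, index=lp.reaction_ids)


def feasible_at_mu(model: MEModelSpec, mu: float,
                   parametric: Optional[ParametricLP] = None,
                   return_fluxes: bool = True,
                   parsimonious: bool = True
                   ) -> tuple[bool, Optional[pd.Series]]:
    """Feasibility of the model at a fixed growth rate.

    The model is always feasible at mu=0 (the zero flux vector, in the
    mu->0+ limit semantics for 1/mu rows).  Returns ``(is_feasible, fluxes)``
    with ``fluxes`` None when infeasible or not requested.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    plp = parametric if parametric is not None else compile_parametric(model)
    lp = plp.evaluate(mu, mu_zero_limit=(mu == 0.0))
    fluxes = _solve_numeric(lp, parsimonious=parsimonious and return_fluxes)
    if fluxes is None:
        return False, None
    return True, (fluxes if return_fluxes else None)


def maximize_growth(model: MEModelSpec, mu_lo: float = 0.0,
                    mu_hi: float = DEFAULT_MU_HI,
                    tol: float = DEFAULT_TOL) -> MESolution:
    """Bisection on mu maintaining a (feasible, infeasible) bracket.

    Raises :class:`BracketError` when the model is still feasible at
    ``mu_hi`` (choose a larger upper bound).  Ties at the bracket boundary
    resolve toward feasibility: the reported optimum is the last *feasible*
    point, with its parsimonious flux vector.
    """
    if not mu_hi > mu_lo or mu_lo < 0 or not tol > 0:
        raise ValueError("need mu_hi > mu_lo >= 0 and tol > 0")
    plp = compile_parametric(model)
    ok_lo, _ = feasible_at_mu(model, mu_lo, parametric=plp, return_fluxes=False)
    if not ok_lo:
        status = "infeasible_at_zero" if mu_lo == 0.0 else "infeasible_at_lo"
        return MESolution(mu_opt=float("nan"),
                          fluxes=pd.Series(dtype=float), status=status,
                          iterations=0, bracket=(mu_lo, mu_lo))
    ok_hi, _ = feasible_at_mu(model, mu_hi, parametric=plp, return_fluxes=False)
    if ok_hi:
        raise BracketError(
            f"model is feasible at mu_hi={mu_hi}; rerun with a larger mu_hi")
    lo, hi = mu_lo, mu_hi
    iterations = 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        ok, _ = feasible_at_mu(model, mid, parametric=plp, return_fluxes=False)
        iterations += 1
        if ok:
            lo = mid
        else:
            hi = mid
    ok, fluxes = feasible_at_mu(model, lo, parametric=plp, return_fluxes=True)
    if not ok:  # numerically possible only at the feasibility-tolerance edge
        raise SolverError(f"bracket endpoint mu={lo} lost feasibility on re-solve")
    status = "optimal" if lo > tol else ("no_growth" if mu_lo == 0.0 else "optimal")
    return MESolution(mu_opt=lo, fluxes=fluxes, status=status,
                      iterations=iterations, bracket=(lo, hi))


def solve_condition(model: MEModelSpec, media, tol: float = DEFAULT_TOL,
                    mu_hi: float = DEFAULT_MU_HI) -> MESolution:
    """Apply a media condition's exchange bounds, then maximise growth.

    Operates on a copy, so the input model is untouched.  Unknown exchange
    ids in the media are a configuration error.
    """
    from .conditions import apply_media  # local import to avoid a cycle

    work = model.copy()
    apply_media(work, media)
    return maximize_growth(work, mu_hi=mu_hi, tol=tol)


def grid_maximize(model: MEModelSpec, mu_hi: float = DEFAULT_MU_HI,
                  step: float = 1e-3) -> float:
    """Brute-force oracle: largest feasible mu on a regular grid.

    Independent of the bisection path; used for cross-checks.  Scans upward
    and returns the last feasible grid point (0.0 if only mu=0 is feasible).
    """
    plp = compile_parametric(model)
    best = 0.0
    n_steps = int(math.floor(mu_hi / step + 1e-12))
    for k in range(0, n_steps + 1):
        mu = k * step
        ok, _ = feasible_at_mu(model, mu, parametric=plp, return_fluxes=False)
        if ok:
            best = mu
        else:
            break
    return best


def coupling_residuals(model: MEModelSpec, solution: MESolution) -> pd.Series:
    """Relative residual |row . v| / max(1, |row| . |v|) per species balance.

    At a valid optimum every coupling (and mass-balance) row is satisfied to
    the LP feasibility tolerance.
    """
    plp = compile_parametric(model)
    mu = solution.mu_opt
    lp = plp.evaluate(mu, mu_zero_limit=(mu == 0.0))
    v = solution.fluxes.reindex(lp.reaction_ids).to_numpy()
    raw = lp.S @ v
    scale = np.maximum(1.0, np.abs(lp.S) @ np.abs(v))
    return pd.Series(np.abs(raw) / scale, index=lp.species_ids)
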