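"""Auxotroph construction and essential-nutrient limitation analysis.

An auxotroph is built by knocking out the reactions that synthesise an
essential biomass component and opening an uptake exchange for it instead.
The limitation profile then measures, for uptake caps ranging from 100% down
to 5% of the uptake at unconstrained optimum, the growth rate, the flux
state, and the mass fraction of protein allocated to each metabolic
subsystem — the model's predicted proteome re-allocation under nutrient
stress.  The excess analysis goes the other way: uptake is opened unbounded
and the change in subsystem protein mass against the prototroph is reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_UPPER, MEError, MEModelSpec, MEReaction, MEValidationError
from . import solver as _solver
from .solver import MESolution

__all__ = [
    "LimitationProfile",
    "make_auxotroph",
    "limitation_profile",
    "protein_allocation",
    "flux_response_summary",
    "excess_response",
    "DEFAULT_FRACTIONS",
]

logger = logging.getLogger(__name__)

MIN_GROWTH = 1e-3
# 20 points, 1.00 down to 0.05 in steps of 0.05
DEFAULT_FRACTIONS = tuple(round(1.0 - 0.05 * i, 2) for i in range(20))
UNLIMITED_UPTAKE = DEFAULT_UPPER


@dataclass
class LimitationProfile:
    metabolite_id: str
    optimal_uptake: float                       # mmol/gDW/h at max growth
    fractions: tuple[float, ...]
    growth: dict[float, float] = field(default_factory=dict)
    allocation: dict[float, dict[str, float]] = field(default_factory=dict)
    fluxes: dict[float, pd.Series] = field(default_factory=dict)

    def growth_series(self) -> pd.Series:
        return pd.Series({f: self.growth[f] for f in self.fractions})

    def allocation_frame(self) -> pd.DataFrame:
        """Subsystems x fractions frame of protein mass fractions."""
        return pd.DataFrame(self.allocation).fillna(0.0)

    def flux_frame(self) -> pd.DataFrame:
        """Reactions x fractions frame of fluxes."""
        return pd.DataFrame(self.fluxes).fillna(0.0)


def _exchange_for(model: MEModelSpec, metabolite_id: str,
                  create: bool = True) -> MEReaction:
    ex_id = f"EX_{metabolite_id}"
    if model.has_reaction(ex_id):
        return model.get_reaction(ex_id)
    if not create:
        raise MEError(f"no exchange reaction for {metabolite_id!r}")
    model.get_species(metabolite_id)  # raises if the metabolite is absent
    return model.add_reaction(MEReaction(
        id=ex_id, klass="exchange", stoichiometry={metabolite_id: -1.0},
        lower=0.0, upper=DEFAULT_UPPER, subsystem="exchange"))


def make_auxotroph(model: MEModelSpec, metabolite_id: str,
                   knockout_reactions: Sequence[str],
                   min_growth: float = MIN_GROWTH,
                   tol: float = _solver.DEFAULT_TOL,
                   mu_hi: float = _solver.DEFAULT_MU_HI) -> MEModelSpec:
    """Knock out biosynthesis and open uptake for one essential metabolite.

    The returned model (a copy) must be unable to grow with the metabolite's
    exchange closed — otherwise auxotrophy was not achieved and a validation
    error is raised.  The exchange is left open (unbounded uptake).
    """
    if not knockout_reactions:
        raise MEValidationError("empty knockout list cannot create an auxotroph")
    aux = model.copy()
    for rid in knockout_reactions:
        rxn = aux.get_reaction(rid)  # raises MEStructureError if absent
        rxn.lower = 0.0
        rxn.upper = 0.0
    exchange = _exchange_for(aux, metabolite_id, create=True)
    exchange.lower = 0.0  # closed for the auxotrophy check
    sol = _solver.maximize_growth(aux, mu_hi=mu_hi, tol=tol)
    if sol.status == "optimal" and sol.mu_opt > min_growth:
        raise MEValidationError(
            f"auxotrophy not achieved for {metabolite_id}: mu*="
            f"{sol.mu_opt:.4f} with the exchange closed")
    exchange.lower = -UNLIMITED_UPTAKE
    return aux


def limitation_profile(aux_model: MEModelSpec, metabolite_id: str,
                       fractions: Sequence[float] = DEFAULT_FRACTIONS,
                       tol: float = _solver.DEFAULT_TOL,
                       mu_hi: float = _solver.DEFAULT_MU_HI
                       ) -> LimitationProfile:
    """Growth, fluxes and protein allocation vs essential-metabolite supply.

    The uptake rate at unconstrained maximum growth defines 100%; each
    fraction f caps the uptake magnitude at f times that rate (an upper
    bound on uptake — the model may use less) and the model is re-optimized.
    """
    ex_id = f"EX_{metabolite_id}"
    if not aux_model.has_reaction(ex_id):
        raise MEError(f"auxotroph lacks exchange {ex_id!r}")
    base = _solver.maximize_growth(aux_model, mu_hi=mu_hi, tol=tol)
    if base.status != "optimal":
        raise MEError(f"auxotroph for {metabolite_id} cannot grow at all")
    optimal_uptake = abs(base[ex_id])
    if not optimal_uptake > 0:
        raise MEError(
            f"degenerate profile: optimal uptake of {metabolite_id} is 0")
    fractions = tuple(fractions)
    profile = LimitationProfile(metabolite_id=metabolite_id,
                                optimal_uptake=optimal_uptake,
                                fractions=fractions)
    work = aux_model.copy()
    exchange = work.get_reaction(ex_id)
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
        exchange.lower = -f * optimal_uptake
        sol = _solver.maximize_growth(work, mu_hi=mu_hi, tol=tol)
        mu = sol.mu_opt if sol.status == "optimal" else 0.0
        profile.growth[f] = mu
        profile.fluxes[f] = sol.fluxes
        profile.allocation[f] = (protein_allocation(sol, work)
                                 if mu > 0 else {})
    return profile


def protein_allocation(solution: MESolution, model: MEModelSpec
                       ) -> dict[str, float]:
    """Mass fraction of modeled protein allocated to each subsystem.

    Per complex, steady-state protein mass is formation flux x molecular
    weight / mu.  A complex catalysing reactions in several subsystems is
    split proportionally to its usage fluxes; complexes with no recorded
    usage fall back on their own subsystem annotation.  Fractions are
    normalized to sum to 1 over the modeled protein.
    """
    mu = solution.mu_opt
    if not mu > 0:
        raise MEError("protein allocation undefined at zero growth")
    masses: dict[str, float] = {}
    for sp in model.species:
        if sp.role not in ("enzyme_complex", "synthetase"):
            continue
        if sp.molecular_weight is None:
            continue
        try:
            formation = model.formation_reaction_of(sp.id)
        except MEError:
            continue
        mass = solution[formation.id] * sp.molecular_weight / mu
        if mass <= 0:
            continue
        usage = {}
        for rxn in model.reactions:
            if rxn.catalyst == sp.id:
                v = abs(solution[rxn.id])
                if v > 0:
                    sub = rxn.subsystem or "unassigned"
                    usage[sub] = usage.get(sub, 0.0) + v
        if usage:
            total = sum(usage.values())
            for sub, v in usage.items():
                masses[sub] = masses.get(sub, 0.0) + mass * v / total
        else:
            sub = sp.subsystem or "unassigned"
            masses[sub] = masses.get(sub, 0.0) + mass
    total_mass = sum(masses.values())
    if total_mass <= 0:
        return {}
    return {sub: m / total_mass for sub, m in sorted(masses.items())}


def _subsystem_masses(solution: MESolution, model: MEModelSpec
                      ) -> dict[str, float]:
    """Absolute protein mass (g/gDW) per subsystem (un-normalized allocation)."""
    fractions = protein_allocation(solution, model)
    mu = solution.mu_opt
    total = 0.0
    for sp in model.species:
        if sp.role in ("enzyme_complex", "synthetase") and \
                sp.molecular_weight is not None:
            try:
                formation = model.formation_reaction_of(sp.id)
            except MEError:
                continue
            total += max(solution[formation.id], 0.0) * sp.molecular_weight / mu
    return {sub: frac * total for sub, frac in fractions.items()}


def flux_response_summary(profile: LimitationProfile, top_n: int = 15,
                          group_tol: float = 1e-6) -> pd.DataFrame:
    """Growth-normalized, max-scaled flux series ranked by variability.

    Per reaction: flux/mu at each fraction, divided by the series maximum.
    Reactions whose normalized series coincide within ``group_tol``
    (perfectly correlated through the limitation) are merged into one row
    with a member count.  The ``top_n`` rows with the highest standard
    deviation across fractions are returned, widest variation first.
    """
    if len(profile.fractions) < 3:
        raise ValueError("need at least 3 fractions for a response summary")
    cols = [f for f in profile.fractions if profile.growth.get(f, 0.0) > 0]
    series: dict[str, np.ndarray] = {}
    flux_frame = profile.flux_frame()
    for rid in flux_frame.index:
        vals = np.array([flux_frame.loc[rid, f] / profile.growth[f]
                         for f in cols])
        peak = np.abs(vals).max()
        if peak <= 0:
            continue  # all-zero flux series excluded
        series[rid] = vals / peak
    groups: list[tuple[str, list[str], np.ndarray]] = []
    for rid in sorted(series):
        vals = series[rid]
        for _, members, ref in groups:
            if np.max(np.abs(vals - ref)) <= group_tol:
                members.append(rid)
                break
        else:
            groups.append((rid, [rid], vals))
    rows = []
    for rep, members, vals in groups:
        rows.append({"reaction": rep, "n_members": len(members),
                     "std": float(vals.std(ddof=0)),
                     **{f: float(v) for f, v in zip(cols, vals)}})
    out = pd.DataFrame(rows).sort_values(["std", "reaction"],
                                         ascending=[False, True],
                                         kind="mergesort")
    return out.head(top_n).set_index("reaction")


def excess_response(model: MEModelSpec,
                    aux_models: Mapping[str, MEModelSpec],
                    metabolites: Optional[Iterable[str]] = None,
                    threshold: float = 0.2,
                    tol: float = _solver.DEFAULT_TOL,
                    mu_hi: float = _solver.DEFAULT_MU_HI) -> pd.DataFrame:
    """Subsystem protein-mass log2 fold changes under nutrient excess.

    For each auxotroph, the essential metabolite's uptake is opened
    unbounded, the model solved, and growth-normalized subsystem protein
    mass compared to the prototroph.  Subsystems whose maximal |log2fc|
    across metabolites exceeds ``threshold`` are retained.
    """
    proto = _solver.maximize_growth(model, mu_hi=mu_hi, tol=tol)
    if proto.status != "optimal":
        raise MEError("prototroph is not solvable")
    base_masses = _subsystem_masses(proto, model)
    metabolites = list(metabolites) if metabolites is not None \
        else sorted(aux_models)
    rows = []
    for met in metabolites:
        aux = aux_models[met].copy()
        exchange = _exchange_for(aux, met, create=True)
        exchange.lower = -UNLIMITED_UPTAKE
        sol = _solver.maximize_growth(aux, mu_hi=mu_hi, tol=tol)
        if sol.status != "optimal":
            logger.warning("auxotroph for %s cannot grow in excess; skipped", met)
            continue
        masses = _subsystem_masses(sol, aux)
        for sub in sorted(set(base_masses) | set(masses)):
            a, b = masses.get(sub, 0.0), base_masses.get(sub, 0.0)
            if a > 0 and b > 0:
                lfc = math.log2(a / b)
            elif a == 0 and b == 0:
                lfc = 0.0
            else:
                lfc = math.copysign(float("inf"), a - b)
            rows.append({"metabolite": met, "subsystem": sub, "log2fc": lfc})
    table = pd.DataFrame(rows, columns=["metabolite", "subsystem", "log2fc"])
    if table.empty or not np.isfinite(threshold):
        return table.iloc[0:0]
    keep = (table.groupby("subsystem")["log2fc"]
            .apply(lambda s: np.nanmax(np.abs(s)) > threshold))
    kept_subs = keep[keep].index
    return table[table["subsystem"].isin(kept_subs)].reset_index(drop=True)
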