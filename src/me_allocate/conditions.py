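"""Media definitions and multi-condition growth scans.

A media condition is a set of exchange-reaction bounds plus an aerobicity
flag.  Nutrient panels follow the sole-source protocol: starting from a
glucose-minimal-style base condition, the base source of one element class
(C, N, P or S) is closed and a candidate nutrient's exchange is opened in its
place; oxygen availability is toggled independently.  Scanning a panel over
both aerobicities yields the condition x component demand table that the
composition statistics consume.

Exchange convention: an exchange reaction drains its species
(``species -> nothing``); uptake is a negative flux, so "closed" means a lower
bound of zero and an uptake limit of U means a lower bound of -U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import CoenzymeSpec, MEError, MEModelSpec
from .demand import (
    amino_acid_demand,
    coenzyme_demand,
    component_classes,
    normalize_composition,
    prosthetic_demand,
)
from . import solver as _solver

__all__ = [
    "MediaCondition",
    "ConfigError",
    "apply_media",
    "make_media",
    "scan_conditions",
    "ScanResult",
    "composition_matrix",
]

logger = logging.getLogger(__name__)

ELEMENT_CLASSES = ("C", "N", "P", "S")
DEFAULT_UPTAKE_LIMIT = 10.0  # mmol/gDW/h for the swapped sole source
DEFAULT_O2_UPTAKE = 20.0
MIN_GROWTH = 1e-3  # h^-1; growth-supporting classification cutoff


class ConfigError(MEError):
    """A media or panel entry references something the model does not have."""


@dataclass
class MediaCondition:
    condition_id: str
    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    aerobic: bool = True
    element_class: str = "C"
    nutrient_id: str = ""
    # exchange id providing each element in the base condition
    element_sources: dict[str, str] = field(default_factory=dict)
    o2_exchange: str = "EX_o2"

    def __post_init__(self) -> None:
        for ex, (lo, hi) in self.exchange_bounds.items():
            if lo > hi:
                raise ConfigError(f"media {self.condition_id}: {ex} lower > upper")
        if not self.aerobic:
            lo, hi = self.exchange_bounds.get(self.o2_exchange, (0.0, 0.0))
            if lo < 0:
                raise ConfigError(
                    f"media {self.condition_id}: anaerobic but O2 uptake open")


def apply_media(model: MEModelSpec, media: MediaCondition) -> MEModelSpec:
    """Overwrite exchange bounds in place per the media condition."""
    for ex_id, (lo, hi) in media.exchange_bounds.items():
        if not model.has_reaction(ex_id):
            raise ConfigError(
                f"media {media.condition_id}: no exchange reaction {ex_id!r}")
        rxn = model.get_reaction(ex_id)
        if rxn.klass != "exchange":
            raise ConfigError(
                f"media {media.condition_id}: {ex_id!r} is not an exchange")
        rxn.lower, rxn.upper = float(lo), float(hi)
    return model


def _exchange_id_for(model: MEModelSpec, nutrient_id: str) -> str:
    if model.has_reaction(nutrient_id):
        return nutrient_id
    guess = f"EX_{nutrient_id}"
    if model.has_reaction(guess):
        return guess
    raise ConfigError(f"nutrient {nutrient_id!r} has no exchange reaction")


def make_media(base: MediaCondition, nutrient_id: str, element_class: str,
               aerobic: bool, model: Optional[MEModelSpec] = None,
               uptake_limit: float = DEFAULT_UPTAKE_LIMIT,
               supplement: bool = False) -> MediaCondition:
    """Derive a sole-source media from the base condition.

    The base source of ``element_class`` is closed and the nutrient's
    exchange opened at ``uptake_limit``; sources of the other elements are
    untouched.  ``supplement=True`` keeps the base source open instead
    (supplementation protocol).  Aerobicity toggles the O2 lower bound.
    """
    if element_class not in ELEMENT_CLASSES:
        raise ConfigError(f"unknown element class {element_class!r}")
    if element_class not in base.element_sources:
        raise ConfigError(
            f"base media does not declare a source for element {element_class}")
    bounds = dict(base.exchange_bounds)
    ex_id = _exchange_id_for(model, nutrient_id) if model is not None \
        else (nutrient_id if nutrient_id in bounds else f"EX_{nutrient_id}")
    base_ex = base.element_sources[element_class]
    if not supplement and ex_id != base_ex:
        lo, hi = bounds.get(base_ex, (0.0, 1000.0))
        bounds[base_ex] = (0.0, hi)
    prev = bounds.get(ex_id, (0.0, 1000.0))
    bounds[ex_id] = (-abs(uptake_limit), prev[1])
    o2_prev = bounds.get(base.o2_exchange, (0.0, 1000.0))
    bounds[base.o2_exchange] = ((-DEFAULT_O2_UPTAKE, o2_prev[1]) if aerobic
                                else (0.0, o2_prev[1]))
    cid = f"{nutrient_id}_{element_class}_{'aer' if aerobic else 'ana'}"
    return replace(base, condition_id=cid, exchange_bounds=bounds,
                   aerobic=aerobic, element_class=element_class,
                   nutrient_id=nutrient_id)


@dataclass
class ScanResult:
    """Tidy outputs of a panel scan.

    ``demands``: one row per (condition, component) for growth-supporting
    conditions, with normalized demand.  ``growth``: one row per condition
    with its optimized growth rate and growth-supporting flag.
    """

    demands: pd.DataFrame
    growth: pd.DataFrame

    def to_csv(self, demands_path: str, growth_path: Optional[str] = None) -> None:
        self.demands.to_csv(demands_path, index=False)
        if growth_path is not None:
            self.growth.to_csv(growth_path, index=False)


def scan_conditions(model: MEModelSpec, coenzymes: Sequence[CoenzymeSpec],
                    panel: Iterable[tuple[str, str]], base: MediaCondition,
                    aerobicities: Sequence[bool] = (True, False),
                    tol: float = _solver.DEFAULT_TOL,
                    mu_hi: float = _solver.DEFAULT_MU_HI,
                    min_growth: float = MIN_GROWTH,
                    normalization: str = "per_protein_biomass",
                    uptake_limit: float = DEFAULT_UPTAKE_LIMIT) -> ScanResult:
    """Solve every (nutrient, element class, aerobicity) combination.

    Growth-supporting conditions (mu* > ``min_growth``) contribute normalized
    demand rows; the rest are recorded with mu* = 0.  Individual solver
    failures are logged and skipped, never abort the scan.  The input model
    is never mutated, so re-running is deterministic and order-independent.
    """
    demand_rows: list[dict] = []
    growth_rows: list[dict] = []
    panel = list(panel)
    for nutrient_id, element_class in panel:
        for aerobic in aerobicities:
            media = make_media(base, nutrient_id, element_class, aerobic,
                               model=model, uptake_limit=uptake_limit)
            try:
                sol = _solver.solve_condition(model, media, tol=tol, mu_hi=mu_hi)
            except MEError as exc:
                logger.warning("condition %s failed: %s", media.condition_id, exc)
                continue
            supported = (sol.status in ("optimal",) and sol.mu_opt > min_growth)
            growth_rows.append({
                "condition_id": media.condition_id, "nutrient_id": nutrient_id,
                "element_class": element_class, "aerobic": aerobic,
                "growth_rate": sol.mu_opt if supported else 0.0,
                "growth_supporting": supported,
            })
            if not supported:
                continue
            demands = {}
            demands.update(amino_acid_demand(sol, model))
            demands.update(prosthetic_demand(sol, model))
            demands.update(coenzyme_demand(sol, coenzymes))
            comp = normalize_composition(
                demands, sol, model, mode=normalization,
                condition_id=media.condition_id, aerobic=aerobic,
                element_class=element_class)
            classes = component_classes(model, coenzymes)
            for component, value in sorted(comp.demands.items()):
                demand_rows.append({
                    "condition_id": media.condition_id,
                    "nutrient_id": nutrient_id,
                    "element_class": element_class, "aerobic": aerobic,
                    "growth_rate": sol.mu_opt,
                    "component_id": component,
                    "component_class": classes.get(component, "other"),
                    "demand": value, "normalization": comp.normalization,
                })
    demand_cols = ["condition_id", "nutrient_id", "element_class", "aerobic",
                   "growth_rate", "component_id", "component_class", "demand",
                   "normalization"]
    growth_cols = ["condition_id", "nutrient_id", "element_class", "aerobic",
                   "growth_rate", "growth_supporting"]
    demands = pd.DataFrame(demand_rows, columns=demand_cols)
    growth = pd.DataFrame(growth_rows, columns=growth_cols)
    demands = demands.sort_values(["condition_id", "component_id"],
                                  kind="mergesort").reset_index(drop=True)
    growth = growth.sort_values("condition_id", kind="mergesort"
                                ).reset_index(drop=True)
    return ScanResult(demands=demands, growth=growth)


def composition_matrix(result: ScanResult) -> pd.DataFrame:
    """Wide condition x component matrix of demands (growth-supporting only)."""
    if result.demands.empty:
        return pd.DataFrame()
    return result.demands.pivot_table(index="condition_id",
                                      columns="component_id", values="demand",
                                      fill_value=0.0)
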