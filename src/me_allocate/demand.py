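"""Per-condition synthesis demands of amino acids, prosthetic groups and
coenzymes.

Given an optimal ME solution, the demand of each biomass constituent is read
off the fluxes that synthesise or install it:

* amino acids — translation flux times the amino-acid composition of each
  peptide, summed over peptides;
* prosthetic groups — the complex-formation fluxes of every enzyme complex
  that engrafts the group, weighted by its stoichiometry;
* coenzymes — the flux through the one designated reaction of the coenzyme's
  biosynthetic pathway (their network participation is too broad for a
  composition sum).

Two normalizations are provided: division by the growth rate (mmol/gDW,
the biomass-objective-function comparison convention) and division by the
total protein biomass flux of the simulation (mmol per g protein per h,
the convention for cross-condition composition comparisons).  Demands below
a small clamp threshold are zeroed first to suppress LP noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import (
    CoenzymeSpec,
    MEError,
    MEModelSpec,
    as_coefficient,
)

__all__ = [
    "BiomassComposition",
    "NormalizationError",
    "amino_acid_demand",
    "prosthetic_demand",
    "coenzyme_demand",
    "normalize_composition",
    "component_classes",
    "CLAMP",
]

CLAMP = 1e-12  # mmol/gDW/h; demands below this are treated as zero

NORMALIZATIONS = ("raw", "per_growth", "per_protein_biomass")


class NormalizationError(MEError):
    """Requested normalization has a zero denominator."""


@dataclass
class BiomassComposition:
    """Normalized synthesis demands for one growth condition."""

    condition_id: str
    aerobic: bool
    element_class: str
    growth_rate: float
    demands: dict[str, float] = field(default_factory=dict)
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        bad = {k: v for k, v in self.demands.items() if v < 0}
        if bad:
            raise ValueError(f"negative demands: {bad}")


def amino_acid_demand(solution, model: MEModelSpec) -> dict[str, float]:
    """demand[aa] = sum over peptides of v_translation * composition[aa]."""
    out: dict[str, float] = {}
    for rxn in model.reactions_of_class("translation"):
        v = solution[rxn.id]
        pep = model.translation_peptide(rxn)
        for aa, count in pep.peptide.composition.items():
            out[aa] = out.get(aa, 0.0) + v * count
    return out


def prosthetic_demand(solution, model: MEModelSpec) -> dict[str, float]:
    """demand[g] = sum of complex-formation fluxes installing group g."""
    groups = {s.id for s in model.species if s.role == "prosthetic_group"}
    out = {g: 0.0 for g in groups}
    for rxn in model.reactions_of_class("complex_formation"):
        v = solution[rxn.id]
        for sid, coeff in rxn.stoichiometry.items():
            if sid in groups:
                c = as_coefficient(coeff).const
                if c < 0:
                    out[sid] += v * (-c)
    return out


def coenzyme_demand(solution, coenzymes: Sequence[CoenzymeSpec]
                    ) -> dict[str, float]:
    """demand[c] = flux of the coenzyme's designated biosynthesis reaction."""
    out = {}
    for co in coenzymes:
        if co.biosynthesis_reaction not in solution.fluxes.index:
            raise MEError(
                f"coenzyme {co.id}: designated biosynthesis reaction "
                f"{co.biosynthesis_reaction!r} not in solution")
        out[co.id] = solution[co.biosynthesis_reaction]
    return out


def normalize_composition(raw: Mapping[str, float], solution,
                          model: MEModelSpec, mode: str,
                          condition_id: str = "", aerobic: bool = True,
                          element_class: str = "C",
                          clamp: float = CLAMP) -> BiomassComposition:
    """Divide raw demands by growth rate or by protein-biomass flux.

    ``per_growth`` yields mmol/gDW (the biomass-objective comparison axis);
    ``per_protein_biomass`` divides by the flux of the protein-biomass
    summary reaction.  A zero denominator is an error naming the condition.
    """
    if mode not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {mode!r}")
    clamped = {k: (0.0 if abs(v) < clamp else float(v)) for k, v in raw.items()}
    if mode == "raw":
        denom = 1.0
    elif mode == "per_growth":
        denom = solution.mu_opt
        if not denom > 0:
            raise NormalizationError(
                f"condition {condition_id or '<unnamed>'}: growth rate is 0, "
                "cannot normalize per growth")
    else:
        denom = solution[model.protein_biomass_summary_id]
        if not denom > 0:
            raise NormalizationError(
                f"condition {condition_id or '<unnamed>'}: protein-biomass "
                "flux is 0, cannot normalize per protein")
    demands = {k: v / denom for k, v in clamped.items()}
    return BiomassComposition(condition_id=condition_id, aerobic=aerobic,
                              element_class=element_class,
                              growth_rate=solution.mu_opt, demands=demands,
                              normalization=mode)


def component_classes(model: MEModelSpec,
                      coenzymes: Sequence[CoenzymeSpec] = ()
                      ) -> dict[str, str]:
    """Map component id -> {amino_acid, prosthetic, coenzyme}."""
    classes: dict[str, str] = {}
    amino_acids: set[str] = set()
    for sp in model.species:
        if sp.peptide is not None:
            amino_acids.update(sp.peptide.composition)
    for aa in amino_acids:
        classes[aa] = "amino_acid"
    for sp in model.species:
        if sp.role == "prosthetic_group":
            classes[sp.id] = "prosthetic"
    for co in coenzymes:
        classes[co.id] = "coenzyme"
    return classes
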