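"""Best-effort import of constraint-based models from COBRA JSON.

A plain metabolic (M-) model carries none of the expression machinery, so
the importer produces a metabolic-only :class:`MEModelSpec` — species,
reactions, bounds, subsystems, plus a biomass-dilution reaction mapped from
the model's objective — onto which coupling layers can be grafted by hand.
It is a convenience for bootstrapping toy studies from published networks,
not a full ME reconstruction path.
"""

from __future__ import annotations

from .core import MEModelSpec, MEReaction, MESpecies, MEStructureError

__all__ = ["from_cobra_json"]


def from_cobra_json(path: str) -> MEModelSpec:
    """Load a COBRA-format JSON metabolic model as a metabolic-only spec.

    The objective reaction becomes the biomass-dilution reaction (its
    stoichiometry is collapsed onto a single biomass pool).  Exchange
    reactions are detected as single-metabolite boundary reactions.
    """
    import cobra.io

    cmodel = cobra.io.load_json_model(path)
    spec = MEModelSpec()
    for met in cmodel.metabolites:
        spec.add_species(MESpecies(id=met.id, role="metabolite",
                                   compartment=met.compartment or "c"))
    spec.add_species(MESpecies(id="biomass", role="biomass_pool"))
    objective_ids = {r.id for r in cmodel.reactions
                     if r.objective_coefficient}
    if not objective_ids:
        raise MEStructureError("model has no objective reaction to map "
                               "onto biomass dilution")
    for rxn in cmodel.reactions:
        if rxn.id in objective_ids:
            continue
        klass = "exchange" if (rxn.boundary and len(rxn.metabolites) == 1) \
            else "metabolic"
        spec.add_reaction(MEReaction(
            id=rxn.id, klass=klass,
            stoichiometry={m.id: float(c) for m, c in rxn.metabolites.items()},
            lower=float(rxn.lower_bound), upper=float(rxn.upper_bound),
            subsystem=rxn.subsystem or None))
    # biomass: objective stoichiometry produces the pool, dilution drains it
    first = cmodel.reactions.get_by_id(sorted(objective_ids)[0])
    stoich = {m.id: float(c) for m, c in first.metabolites.items()}
    stoich["biomass"] = 1.0
    spec.add_reaction(MEReaction(id=f"{first.id}_synthesis", klass="summary",
                                 stoichiometry=stoich))
    spec.add_reaction(MEReaction(id="biomass_dilution",
                                 klass="biomass_dilution",
                                 stoichiometry={"biomass": -1.0}))
    spec.validate()
    return spec
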