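"""Hand-built micro-fixtures shared across test modules."""

import pandas as pd

from me_allocate.core import MEModelSpec, MEReaction, MESpecies


def single_enzyme_expression_model():
    """One enzyme with known mass and usage; returns (model, mu, fluxes)."""
    m = MEModelSpec()
    m.add_species(MESpecies(id="A", role="metabolite"))
    m.add_species(MESpecies(id="biomass", role="biomass_pool"))
    m.add_species(MESpecies(id="E1", role="enzyme_complex",
                            molecular_weight=30.0, subsystem="core"))
    m.add_reaction(MEReaction(id="EX_A", klass="exchange",
                              stoichiometry={"A": -1.0}, lower=-10.0))
    m.add_reaction(MEReaction(id="R1", klass="metabolic", catalyst="E1",
                              stoichiometry={"A": -1.0, "biomass": 1.0},
                              subsystem="core"))
    m.add_reaction(MEReaction(id="FORM_E1", klass="complex_formation",
                              stoichiometry={"A": -1.0, "E1": 1.0}))
    m.add_reaction(MEReaction(id="biomass_dilution", klass="biomass_dilution",
                              stoichiometry={"biomass": -1.0}))
    mu = 0.5
    fluxes = pd.Series({"EX_A": -1.0, "R1": mu, "FORM_E1": 0.01,
                        "biomass_dilution": mu})
    return m, mu, fluxes
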