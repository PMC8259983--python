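"""Coupling coenzyme biosynthesis to coenzyme use.

Coenzymes (NAD, folates, quinones, ...) are recycled carriers: mass balance
keeps their pools consistent but never forces their synthesis, which is why
metabolic models traditionally push them into a static biomass-constituent
demand.  Here the static demand is switched off and replaced with a
pseudo-first-order activity coupling: every reaction consuming the *uncharged*
form of a coenzyme has that coefficient inflated by ``(1 + mu/k_activity)``,
so each unit of charging flux leaks ``mu/k_activity`` of coenzyme out of the
pool and biosynthesis must replace it.  An explicit formation row
``v_formation,j = sum_i (mu/k_activity,ij) * v_usage,i`` mirrors the same
balance per coenzyme j.

``k_activity`` defaults to 1e4 h^-1 — a deliberately rough first-order
estimate; with mu of order 1 h^-1 the coupling is perturbative (coefficient
multiplier ~1.0001) and the model converges to the uncoupled one as
k_activity grows.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

from .core import (
    CoenzymeSpec,
    MEModelSpec,
    MEReaction,
    MESpecies,
    MEValidationError,
    MuCoefficient,
    as_coefficient,
)

__all__ = [
    "identify_coenzymes",
    "apply_coenzyme_coupling",
    "zero_biomass_constituent_demand",
    "charging_reactions_of",
    "read_coenzyme_table",
    "write_coenzyme_table",
]

logger = logging.getLogger(__name__)


def charging_reactions_of(model: MEModelSpec, coenzyme: CoenzymeSpec
                          ) -> list[MEReaction]:
    """Reactions that consume the uncharged form and produce the charged form."""
    out = []
    for rxn in model.reactions:
        lo = as_coefficient(rxn.stoichiometry.get(coenzyme.uncharged_species, 0.0))
        hi = as_coefficient(rxn.stoichiometry.get(coenzyme.charged_species, 0.0))
        if lo.const < 0 and hi.const > 0:
            out.append(rxn)
    return out


def identify_coenzymes(model: MEModelSpec, bof_members: set[str],
                       alias_map: Optional[Mapping[str, str]] = None
                       ) -> list[CoenzymeSpec]:
    """Select the coenzyme pairs that qualify for activity coupling.

    A candidate is any species with role ``coenzyme_uncharged`` carrying a
    ``partner`` (its charged form) and a designated ``biosynthesis_reaction``.
    It is retained iff

    1. it functions exclusively as a coenzyme: outside its biosynthesis
       reaction, every reaction consuming the uncharged species also produces
       the charged partner (i.e. is a charging reaction) — a species also
       drained as a biosynthetic precursor is excluded; and
    2. it, or a declared close derivative (``alias_map`` value), is a member
       of the biomass objective function ``bof_members``.

    Candidates flagged as coenzymes but lacking any charging reaction are
    skipped with a warning.  Output is sorted by id for determinism.
    """
    alias_map = dict(alias_map or {})
    found: list[CoenzymeSpec] = []
    for sp in sorted(model.species, key=lambda s: s.id):
        if sp.role != "coenzyme_uncharged" or sp.partner is None:
            continue
        if sp.biosynthesis_reaction is None:
            logger.warning("coenzyme candidate %s has no designated "
                           "biosynthesis reaction; skipped", sp.id)
            continue
        bof_name = alias_map.get(sp.id, sp.id)
        if bof_name not in bof_members and sp.partner not in bof_members:
            continue
        exclusively_coenzyme = True
        has_charging = False
        for rxn in model.reactions:
            if rxn.id == sp.biosynthesis_reaction:
                continue
            if rxn.lower == 0.0 and rxn.upper == 0.0:
                continue  # closed reactions (e.g. a zeroed static demand)
            coeff = as_coefficient(rxn.stoichiometry.get(sp.id, 0.0))
            if coeff.const >= 0:
                continue
            produces_charged = as_coefficient(
                rxn.stoichiometry.get(sp.partner, 0.0)).const > 0
            if produces_charged:
                has_charging = True
            else:
                exclusively_coenzyme = False
                break
        if not exclusively_coenzyme:
            continue
        if not has_charging:
            logger.warning("species %s flagged as coenzyme but has no "
                           "charging reaction", sp.id)
            continue
        found.append(CoenzymeSpec(
            id=sp.id, uncharged_species=sp.id, charged_species=sp.partner,
            biosynthesis_reaction=sp.biosynthesis_reaction))
    return found


def apply_coenzyme_coupling(model: MEModelSpec,
                            coenzymes: Iterable[CoenzymeSpec],
                            k_activity: Optional[float] = None) -> MEModelSpec:
    """Install the activity coupling for each coenzyme, in place.

    (a) In every reaction where the uncharged coenzyme is a reactant, the
    coefficient magnitude is multiplied by ``(1 + mu/k_activity)``; at mu=0
    the model is therefore unchanged.  (b) A formation-coupling row ties the
    designated formation reaction to ``sum_i (mu/k_activity,ij) * v_usage,i``
    over the charging reactions, carried by a pseudo-species.

    ``k_activity`` overrides the model's default for all listed coenzymes
    when given; per-(coenzyme, reaction) overrides in
    ``model.params.k_activity_overrides`` win over either.
    """
    p = model.params
    if k_activity is not None:
        if not k_activity > 0:
            raise MEValidationError(f"k_activity must be > 0, got {k_activity}")
        p.k_activity_default = float(k_activity)
    coenzymes = list(coenzymes)
    for co in coenzymes:
        if not model.has_reaction(co.formation_reaction):
            raise MEValidationError(
                f"coenzyme {co.id}: formation reaction "
                f"{co.formation_reaction!r} not in model")
        pseudo_id = f"coupling_coenzyme_{co.id}"
        if not model.has_species(pseudo_id):
            model.add_species(MESpecies(id=pseudo_id, role="pseudo"))
        model.get_reaction(co.formation_reaction).add_term(pseudo_id, 1.0)
        touched = 0
        for rxn in model.reactions:
            if rxn.id == co.formation_reaction:
                continue
            coeff = as_coefficient(rxn.stoichiometry.get(co.uncharged_species, 0.0))
            if coeff.const >= 0:
                continue
            k = p.k_activity_for(co.id, rxn.id)
            magnitude = -coeff.const
            # (1 + mu/k) * magnitude consumed; applied multiplicatively
            rxn.stoichiometry[co.uncharged_species] = MuCoefficient(
                const=coeff.const, mu=-magnitude / k,
                inv_mu=coeff.inv_mu, mu2=coeff.mu2)
            rxn.add_term(pseudo_id, -MuCoefficient(mu=magnitude / k))
            touched += 1
        if touched == 0:
            logger.warning("coenzyme %s: no reaction consumes its uncharged "
                           "form; coupling row is vacuous", co.id)
    model.coenzymes = coenzymes
    if "coenzyme" not in model.applied_couplings:
        model.applied_couplings.append("coenzyme")
    return model


def read_coenzyme_table(path: str) -> list[CoenzymeSpec]:
    """Load a coenzyme mapping TSV: columns coenzyme_id, uncharged_species,
    charged_species, biosynthesis_reaction (optional formation_reaction)."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    out = []
    for row in table.itertuples(index=False):
        out.append(CoenzymeSpec(
            id=row.coenzyme_id, uncharged_species=row.uncharged_species,
            charged_species=row.charged_species,
            biosynthesis_reaction=row.biosynthesis_reaction,
            formation_reaction=getattr(row, "formation_reaction", None)))
    return out


def write_coenzyme_table(coenzymes: Iterable[CoenzymeSpec], path: str) -> None:
    """Write the coenzyme mapping TSV consumed by :func:`read_coenzyme_table`."""
    import pandas as pd

    pd.DataFrame([{
        "coenzyme_id": c.id, "uncharged_species": c.uncharged_species,
        "charged_species": c.charged_species,
        "biosynthesis_reaction": c.biosynthesis_reaction,
        "formation_reaction": c.formation_reaction,
    } for c in coenzymes]).to_csv(path, sep="\t", index=False)


def zero_biomass_constituent_demand(model: MEModelSpec,
                                    reaction_id: str = "biomass_constituent_demand"
                                    ) -> MEModelSpec:
    """Close the static biomass-constituent demand reaction (both bounds 0).

    The activity coupling supersedes the static demand; this is a no-op when
    the reaction is absent, and idempotent.
    """
    if not model.has_reaction(reaction_id):
        logger.info("no %s reaction in model; nothing to zero", reaction_id)
        return model
    rxn = model.get_reaction(reaction_id)
    rxn.lower = 0.0
    rxn.upper = 0.0
    return model
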