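"""Toy ME-model and statistical-fixture generation.

The generator emits a small but structurally complete
metabolism-and-expression network so that every pipeline stage — constraint
assembly, coenzyme coupling, bisection optimisation, demand accounting,
panel scans, composition statistics, auxotroph limitation — runs end to end
with no external data.  The toy mirrors the structural phenomena the
analyses assume:

* a catabolic core with a fermentative route (high NAD turnover per ATP,
  low yield) and a respiratory branch (high yield; requires the quinone-pair
  coenzyme, a heme-analog prosthetic group on the terminal oxidase, a
  thiamine-analog prosthetic group on the pyruvate-dehydrogenase analog,
  and oxygen) — so aerobic and anaerobic optima differ in both growth rate
  and cofactor demand;
* amino-acid biosynthesis from C/N/S precursors, with the sulfur amino acid
  requiring an assimilation enzyme carrying a siroheme-analog group that an
  alternative organic sulfur source bypasses;
* per-enzyme expression chains (transcription unit -> mRNA -> peptide ->
  complex) plus ribosome and RNA-polymerase machinery, an optional
  tRNA/synthetase layer, and a protein-biomass summary feeding biomass
  dilution;
* one recycled coenzyme pair (NAD analog) with a dedicated biosynthesis
  pathway, plus the quinone pair on the aerobic branch;
* nutrient panels per element class including a non-catabolizable decoy and
  a cofactor-heavy substrate (a fatty-acid analog whose catabolism needs a
  flavin-analog prosthetic group and triples NAD turnover), planted so that
  outlier calling can recover it.

All randomness (peptide lengths and compositions, per-reaction effective
turnover numbers) flows from the single config seed; the same seed yields
byte-identical model JSON.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    CouplingParams,
    MEModelSpec,
    MEReaction,
    MESpecies,
    MEError,
    PeptideSpec,
    TranscriptionUnitSpec,
    build_enzyme_coupling,
    build_mrna_coupling,
    build_ribosome_coupling,
    build_rnap_coupling,
    build_synthetase_coupling,
    build_trna_coupling,
    per_second,
)
from .coenzymes import (
    apply_coenzyme_coupling,
    identify_coenzymes,
    zero_biomass_constituent_demand,
)
from .conditions import MediaCondition
from . import solver as _solver

__all__ = [
    "ToyConfig",
    "ClusterSpec",
    "generate_toy_me_model",
    "base_media_for",
    "generate_condition_panel",
    "generate_composition_table",
    "one_enzyme_model",
]


@dataclass
class ToyConfig:
    """Configuration of the toy ME network.

    ``n_enzymes`` is a lower target: the structural core uses about 13
    enzymes (20 with the aerobic branch); a larger value splits amino-acid
    biosynthesis across paralogs until the count is reached.
    """

    n_amino_acids: int = 5
    n_enzymes: int = 12
    include_trna_layer: bool = False
    aerobic_branch: bool = True
    coenzyme_pairs: int = 1   # 0: no activity coupling; 1: NAD analog
                              # (+ quinone pair with the aerobic branch)
    nutrient_panel_size: Optional[int] = None
    unmodeled_protein_fraction: float = 0.0
    k_activity: Optional[float] = None  # override of the 1e4 h^-1 default
    seed: int = 0
    self_check: bool = True

    def __post_init__(self) -> None:
        if self.n_amino_acids < 2:
            raise ValueError("need at least 2 amino acids")


# -- network constants -----------------------------------------------------

AA_MW_BASE = 0.105  # g/mmol, average amino-acid residue mass
ATP_PER_AA = 2.0    # translation energy cost per residue
UPTAKE = {"C": 10.0, "N": 10.0, "P": 5.0, "S": 5.0}
O2_UPTAKE = 20.0


def _aa_ids(n: int) -> list[str]:
    return [f"aa{i + 1}" for i in range(n)]


def generate_toy_me_model(config: ToyConfig) -> MEModelSpec:
    """Build, couple and self-check a toy ME model.

    The returned model has all coupling constraints applied (ribosome, RNAP,
    enzyme, mRNA, optional tRNA/synthetase, coenzyme activity), the static
    biomass-constituent demand zeroed, and its identified coenzymes stored
    on ``model.coenzymes``.  It is feasible at mu=0 and grows on the base
    aerobic glucose-analog minimal media; the generator solves once to prove
    it (disable with ``config.self_check=False``).
    """
    rng = np.random.default_rng(config.seed)
    model = MEModelSpec()
    p = model.params = CouplingParams(
        unmodeled_protein_fraction=config.unmodeled_protein_fraction)
    aas = _aa_ids(config.n_amino_acids)
    aa_s = aas[-1]  # the sulfur-bearing amino acid

    # ---- metabolites ----
    mets = ["glc", "nh4", "pi", "so4", "o2", "co2", "ac", "eth", "h2s",
            "pyr", "atp", "adp", "ntp", "nac", "fru", "man", "gal", "rib",
            "fa", "orn", "glyp", "cyst", "decoy_c", "decoy_n"]
    if config.aerobic_branch:
        mets.append("accoa")
    for m in mets:
        model.add_species(MESpecies(id=m, role="metabolite"))
    for aa in aas:
        model.add_species(MESpecies(id=aa, role="metabolite"))

    # ---- coenzyme pairs and prosthetic groups ----
    model.add_species(MESpecies(id="nad", role="coenzyme_uncharged",
                                partner="nadh", biosynthesis_reaction="NADSYN"))
    model.add_species(MESpecies(id="nadh", role="coenzyme_charged",
                                partner="nad"))
    prosthetics = ["thm", "fad", "plp", "sheme"]
    if config.aerobic_branch:
        model.add_species(MESpecies(id="q8", role="coenzyme_uncharged",
                                    partner="q8h2",
                                    biosynthesis_reaction="Q8SYN"))
        model.add_species(MESpecies(id="q8h2", role="coenzyme_charged",
                                    partner="q8"))
        prosthetics.append("heme")
    for g in prosthetics:
        model.add_species(MESpecies(id=g, role="prosthetic_group",
                                    molecular_weight=0.5))

    model.add_species(MESpecies(id="protein_biomass", role="biomass_pool"))
    model.add_species(MESpecies(id="biomass", role="biomass_pool"))

    # ---- exchanges ----
    open_uptake = {"glc": UPTAKE["C"], "nh4": UPTAKE["N"],
                   "pi": UPTAKE["P"], "so4": UPTAKE["S"], "o2": O2_UPTAKE}
    for m in ["glc", "nh4", "pi", "so4", "o2", "co2", "ac", "eth", "fru",
              "man", "gal", "rib", "fa", "orn", "glyp", "cyst",
              "decoy_c", "decoy_n"]:
        lb = -open_uptake.get(m, 0.0)
        model.add_reaction(MEReaction(
            id=f"EX_{m}", klass="exchange", stoichiometry={m: -1.0},
            lower=lb, upper=1000.0, subsystem="exchange"))

    # ---- metabolic core ----
    def met_rxn(rid, stoich, enzyme, subsystem, upper=1000.0):
        model.add_reaction(MEReaction(
            id=rid, klass="metabolic", stoichiometry=stoich, lower=0.0,
            upper=upper, catalyst=enzyme, subsystem=subsystem))

    enzymes: dict[str, dict] = {}  # enzyme id -> {copies, prosthetic: {g: n}}

    def enzyme(eid, copies=1, prosthetic=None):
        enzymes.setdefault(eid, {"copies": copies,
                                 "prosthetic": dict(prosthetic or {})})
        return eid

    met_rxn("GLYC", {"glc": -1, "nad": -2, "adp": -2,
                     "pyr": 2, "nadh": 2, "atp": 2},
            enzyme("E_glyc"), "glycolysis")
    met_rxn("FERM", {"pyr": -1, "nadh": -1, "ac": 1, "nad": 1},
            enzyme("E_ferm"), "fermentation")
    # more-reduced fermentation product balances redox when pyruvate is
    # drained into biomass anaerobically (ethanol-analog branch)
    met_rxn("FERM2", {"pyr": -1, "nadh": -2, "eth": 1, "nad": 2},
            enzyme("E_ferm2"), "fermentation")
    # storage polymer fills the biomass mass balance beyond machinery protein
    met_rxn("STORAGE", {"pyr": -1, "atp": -3, "adp": 3, "biomass": 0.09},
            enzyme("E_stor"), "storage")
    for sugar in ("fru", "man", "gal", "rib"):
        met_rxn(f"{sugar.upper()}ISO", {sugar: -1, "glc": 1},
                enzyme("E_sugar"), "sugar interconversion")
    met_rxn("ACCAT", {"ac": -1, "atp": -1, "nad": -1,
                      "pyr": 1, "nadh": 1, "adp": 1},
            enzyme("E_ac"), "acetate metabolism")
    met_rxn("FAOX", {"fa": -1, "nad": -3, "adp": -1,
                     "pyr": 3, "nadh": 3, "atp": 1},
            enzyme("E_faox", prosthetic={"fad": 1}), "beta oxidation")
    met_rxn("ORNDEAM", {"orn": -1, "nh4": 1},
            enzyme("E_orn", prosthetic={"plp": 1}), "nitrogen metabolism")
    met_rxn("GLYPHYD", {"glyp": -1, "pi": 1},
            enzyme("E_glyp"), "phosphorus metabolism")
    met_rxn("SULR", {"so4": -1, "nadh": -2, "atp": -1,
                     "h2s": 1, "nad": 2, "adp": 1},
            enzyme("E_sulr", prosthetic={"sheme": 1}), "sulfur assimilation")
    met_rxn("CYSTUP", {"cyst": -1, aa_s: 1},
            enzyme("E_cyst"), "sulfur assimilation")
    if config.aerobic_branch:
        met_rxn("PDH", {"pyr": -1, "nad": -1, "accoa": 1, "nadh": 1, "co2": 1},
                enzyme("E_pdh", prosthetic={"thm": 1}), "pyruvate metabolism")
        met_rxn("TCA", {"accoa": -1, "nad": -2, "adp": -1,
                        "nadh": 2, "co2": 2, "atp": 1},
                enzyme("E_tca"), "TCA cycle")
        met_rxn("NDH", {"nadh": -1, "q8": -1, "nad": 1, "q8h2": 1},
                enzyme("E_ndh"), "oxidative phosphorylation")
        met_rxn("CYTOX", {"q8h2": -1, "o2": -0.5, "adp": -2, "q8": 1, "atp": 2},
                enzyme("E_cytox", prosthetic={"heme": 1}),
                "oxidative phosphorylation")

    # amino-acid biosynthesis, optionally split across paralogs
    core_count = len(enzymes) + 5 + (3 if config.aerobic_branch else 0)
    n_aa_enzymes = max(1, min(config.n_amino_acids,
                              config.n_enzymes - core_count))
    aa_groups = np.array_split(np.arange(config.n_amino_acids), n_aa_enzymes)
    nh4_costs = 1.0 + rng.integers(0, 3, size=config.n_amino_acids)
    for g_idx, group in enumerate(aa_groups):
        eid = enzyme(f"E_aasyn{g_idx + 1}" if n_aa_enzymes > 1 else "E_aasyn")
        for i in group:
            stoich = {"pyr": -1.0, "nh4": -float(nh4_costs[i]),
                      "atp": -1.0, aas[i]: 1.0, "adp": 1.0}
            if aas[i] == aa_s:
                stoich["h2s"] = -1.0
            met_rxn(f"AASYN_{aas[i]}", stoich, eid, "amino acid biosynthesis")

    # cofactor biosynthesis (designated demand reactions for the coenzymes);
    # the NAD pathway is two-step via a niacin-analog precursor so that an
    # upstream knockout plus precursor uptake yields a working auxotroph
    met_rxn("NACSYN", {"pyr": -1, "nh4": -1, "atp": -1, "nac": 1, "adp": 1},
            enzyme("E_nacsyn"), "cofactor biosynthesis")
    met_rxn("NADSYN", {"nac": -1, "atp": -1, "nad": 1, "adp": 1},
            enzyme("E_nadsyn"), "cofactor biosynthesis")
    if config.aerobic_branch:
        met_rxn("THMSYN", {"pyr": -1, "nh4": -1, "atp": -1, "thm": 1, "adp": 1},
                enzyme("E_thmsyn"), "cofactor biosynthesis")
        met_rxn("Q8SYN", {"pyr": -1, "atp": -1, "q8": 1, "adp": 1},
                enzyme("E_q8syn"), "cofactor biosynthesis")
        met_rxn("HEMESYN", {"pyr": -1, "nh4": -1, "atp": -1, "heme": 1,
                            "adp": 1},
                enzyme("E_hemesyn"), "cofactor biosynthesis")
    met_rxn("FADSYN", {"pyr": -1, "nh4": -1, "atp": -1, "fad": 1, "adp": 1},
            enzyme("E_fadsyn"), "cofactor biosynthesis")
    met_rxn("PLPSYN", {"pyr": -1, "nh4": -1, "atp": -1, "plp": 1, "adp": 1},
            enzyme("E_plpsyn"), "cofactor biosynthesis")
    met_rxn("SHEMESYN", {"pyr": -1, "nh4": -1, "atp": -1, "sheme": 1,
                         "adp": 1},
            enzyme("E_shemesyn"), "cofactor biosynthesis")
    met_rxn("NTPSYN", {"pyr": -0.5, "pi": -1, "nh4": -0.5, "atp": -1,
                       "ntp": 1, "adp": 1},
            enzyme("E_ntpsyn"), "nucleotide biosynthesis")

    # vestigial static biomass-constituent demand (zeroed by the pipeline)
    bof_stoich = {"nad": -1.0, "thm": -1.0} if config.aerobic_branch \
        else {"nad": -1.0}
    if config.aerobic_branch:
        bof_stoich["q8"] = -1.0
    model.add_reaction(MEReaction(
        id="biomass_constituent_demand", klass="demand",
        stoichiometry=bof_stoich, lower=0.0, upper=0.05,
        subsystem="biomass"))
    bof_members = {m.lstrip() for m in bof_stoich}

    # ---- tRNA layer (optional) ----
    if config.include_trna_layer:
        enzyme("E_synth")  # shared aminoacyl-synthetase complex
        for aa in aas:
            model.add_species(MESpecies(id=f"trna_{aa}", role="tRNA"))
            model.add_species(MESpecies(id=f"ctrna_{aa}", role="charged_tRNA"))
            model.add_reaction(MEReaction(
                id=f"TRNASYN_{aa}", klass="metabolic",
                stoichiometry={"ntp": -20.0, f"trna_{aa}": 1.0},
                subsystem="tRNA biosynthesis"))
            model.add_reaction(MEReaction(
                id=f"CHARGE_{aa}", klass="tRNA_charging",
                stoichiometry={aa: -1.0, "atp": -1.0,
                               f"ctrna_{aa}": 1.0, "adp": 1.0},
                trna=f"trna_{aa}", synthetase="E_synth",
                subsystem="tRNA charging"))

    # ---- expression chains ----
    aa_mws = AA_MW_BASE + 0.01 * rng.random(config.n_amino_acids)

    def expression_chain(name: str, length: int, copies: float,
                         prosthetic: Optional[dict] = None,
                         target_role: str = "enzyme_complex",
                         extra_formation: Optional[dict] = None,
                         subsystem: Optional[str] = None) -> None:
        comp_counts = rng.multinomial(length,
                                      np.ones(config.n_amino_acids)
                                      / config.n_amino_acids)
        composition = {aas[i]: int(comp_counts[i])
                       for i in range(config.n_amino_acids) if comp_counts[i]}
        pep_mw = float(sum(aa_mws[aas.index(a)] * c
                           for a, c in composition.items()))
        pep_id, mrna_id, tu_id = f"pept_{name}", f"mrna_{name}", f"tu_{name}"
        model.add_species(MESpecies(
            id=pep_id, role="peptide", molecular_weight=pep_mw,
            peptide=PeptideSpec(id=pep_id, length=length,
                                composition=composition,
                                part_of_complexes=[(name, copies)])))
        model.add_species(MESpecies(id=mrna_id, role="mRNA"))
        model.add_species(MESpecies(
            id=tu_id, role="transcription_unit",
            tu=TranscriptionUnitSpec(id=tu_id, length=3 * length,
                                     encoded_mrnas=[mrna_id])))
        mw = pep_mw * copies + 0.5 * sum((prosthetic or {}).values())
        model.add_species(MESpecies(id=name, role=target_role,
                                    molecular_weight=mw, subsystem=subsystem))
        model.add_reaction(MEReaction(
            id=f"TX_{name}", klass="transcription",
            stoichiometry={"ntp": -3.0 * length, mrna_id: 1.0}, tu=tu_id,
            subsystem="transcription"))
        tl_stoich: dict = {"atp": -ATP_PER_AA * length,
                           "adp": ATP_PER_AA * length,
                           pep_id: 1.0, "protein_biomass": pep_mw}
        for a, c in composition.items():
            key = f"ctrna_{a}" if config.include_trna_layer else a
            tl_stoich[key] = tl_stoich.get(key, 0.0) - float(c)
        model.add_reaction(MEReaction(
            id=f"TL_{name}", klass="translation", stoichiometry=tl_stoich,
            mrna=mrna_id, subsystem="translation"))
        model.add_reaction(MEReaction(
            id=f"DEG_{name}", klass="mRNA_degradation", stoichiometry={},
            mrna=mrna_id, subsystem="mRNA degradation"))
        form_stoich = {pep_id: -copies, name: 1.0}
        for g, n_g in (prosthetic or {}).items():
            form_stoich[g] = -float(n_g)
        for sid, coeff in (extra_formation or {}).items():
            form_stoich[sid] = coeff
        model.add_reaction(MEReaction(
            id=f"FORM_{name}", klass="complex_formation",
            stoichiometry=form_stoich, subsystem="complex formation"))

    lengths = rng.integers(150, 401, size=len(enzymes))
    for (eid, info), length in zip(sorted(enzymes.items()), lengths):
        role = "synthetase" if eid == "E_synth" else "enzyme_complex"
        # dominant subsystem annotation for allocation fallback
        subs = [r.subsystem for r in model.reactions if r.catalyst == eid]
        expression_chain(eid, int(length), float(info["copies"]),
                         prosthetic=info["prosthetic"], target_role=role,
                         subsystem=subs[0] if subs else None)
    expression_chain("ribosome", 300, 10.0, target_role="enzyme_complex",
                     extra_formation={"ntp": -50.0},
                     subsystem="translation machinery")
    expression_chain("rnap", 350, 4.0, target_role="enzyme_complex",
                     subsystem="transcription machinery")

    # ---- biomass summary and dilution ----
    f_um = p.unmodeled_protein_fraction
    summary_stoich: dict = {"protein_biomass": -1.0, "biomass": 1.0}
    if f_um > 0:
        model.add_species(MESpecies(id="dummy_protein_biomass",
                                    role="biomass_pool"))
        summary_stoich = {"protein_biomass": -(1.0 - f_um),
                          "dummy_protein_biomass": -f_um, "biomass": 1.0}
        expression_chain("dummy_complex", 200, 1.0,
                         target_role="enzyme_complex",
                         subsystem="unmodeled protein")
        # dummy translation feeds the dummy pool instead of the modeled one
        tl = model.get_reaction("TL_dummy_complex")
        mw = tl.stoichiometry.pop("protein_biomass")
        tl.stoichiometry["dummy_protein_biomass"] = mw
    model.add_reaction(MEReaction(
        id="protein_biomass_to_biomass", klass="summary",
        stoichiometry=summary_stoich, subsystem="biomass"))
    model.add_reaction(MEReaction(
        id="biomass_dilution", klass="biomass_dilution",
        stoichiometry={"biomass": -1.0}, subsystem="biomass"))

    # ---- parameterization ----
    # metabolic turnover numbers: seeded draws around the catabolic scale;
    # the pyruvate-dehydrogenase analog is pinned fast (1500 s^-1), all
    # expression-machinery reactions keep the 65 s^-1 default
    for rxn in model.reactions_of_class("metabolic"):
        if rxn.catalyst is None:
            continue
        draw = float(rng.uniform(30.0, 200.0))
        p.k_eff_overrides[(rxn.catalyst, rxn.id)] = per_second(draw)
    if config.aerobic_branch:
        p.k_eff_overrides[("E_pdh", "PDH")] = per_second(1500.0)

    # ---- couplings ----
    build_ribosome_coupling(model)
    build_rnap_coupling(model)
    build_enzyme_coupling(model)
    build_mrna_coupling(model)
    if config.include_trna_layer:
        build_trna_coupling(model)
        build_synthetase_coupling(model)
    zero_biomass_constituent_demand(model)
    coenzymes = identify_coenzymes(model, bof_members=bof_members)
    # the quinone pair ships with the respiratory branch; coenzyme_pairs
    # counts the non-respiratory recycled pairs (1 = the NAD analog)
    keep = {"nad"} | ({"q8"} if config.aerobic_branch else set())
    if config.coenzyme_pairs == 0:
        coenzymes = []
    elif config.coenzyme_pairs < 2:
        coenzymes = [c for c in coenzymes if c.id in keep] or coenzymes
    apply_coenzyme_coupling(model, coenzymes, k_activity=config.k_activity)

    model.validate()
    if config.self_check:
        sol = _solver.maximize_growth(model, tol=1e-4)
        if sol.status != "optimal" or not sol.mu_opt > 0:
            raise MEError(
                "generator self-check failed: toy model does not grow on "
                f"base media (status {sol.status})")
    return model


def auxotroph_knockouts(model: MEModelSpec) -> dict[str, list[str]]:
    """Knockout lists rendering the toy auxotrophic for essential
    biomass components (rescuable by uptake of the named metabolite).

    The NAD-analog auxotroph is created upstream of the designated
    formation step, so the imported niacin-analog precursor still feeds
    the activity-coupled final synthesis reaction.
    """
    kos: dict[str, list[str]] = {}
    if model.has_reaction("NACSYN"):
        kos["nac"] = ["NACSYN"]
    if model.has_reaction("SHEMESYN"):
        kos["sheme"] = ["SHEMESYN"]
    for rxn in model.reactions:
        if rxn.id.startswith("AASYN_"):
            kos[rxn.id.removeprefix("AASYN_")] = [rxn.id]
    return kos


def base_media_for(model: MEModelSpec, aerobic: bool = True,
                   condition_id: str = "base") -> MediaCondition:
    """Glucose-analog minimal media: base C/N/P/S sources open, all
    alternative nutrient exchanges closed, secretions open."""
    bounds: dict[str, tuple[float, float]] = {}
    defaults = {"EX_glc": UPTAKE["C"], "EX_nh4": UPTAKE["N"],
                "EX_pi": UPTAKE["P"], "EX_so4": UPTAKE["S"]}
    for rxn in model.reactions_of_class("exchange"):
        if rxn.id in defaults:
            bounds[rxn.id] = (-defaults[rxn.id], 1000.0)
        elif rxn.id == "EX_o2":
            bounds[rxn.id] = (-O2_UPTAKE, 1000.0) if aerobic else (0.0, 1000.0)
        else:
            bounds[rxn.id] = (0.0, 1000.0)
    return MediaCondition(
        condition_id=condition_id, exchange_bounds=bounds, aerobic=aerobic,
        element_class="C", nutrient_id="glc",
        element_sources={"C": "EX_glc", "N": "EX_nh4",
                         "P": "EX_pi", "S": "EX_so4"},
        o2_exchange="EX_o2")


def generate_condition_panel(model: MEModelSpec,
                             config: Optional[ToyConfig] = None
                             ) -> list[tuple[str, str]]:
    """Nutrient panel: base sources, benign alternates, one decoy per C/N,
    and the planted cofactor-heavy fatty-acid analog."""
    panel = [("glc", "C"), ("fru", "C"), ("man", "C"), ("gal", "C"),
             ("rib", "C"), ("ac", "C"), ("fa", "C"), ("decoy_c", "C"),
             ("nh4", "N"), ("orn", "N"), ("decoy_n", "N"),
             ("pi", "P"), ("glyp", "P"),
             ("so4", "S"), ("cyst", "S")]
    panel = [(n, e) for n, e in panel if model.has_reaction(f"EX_{n}")]
    if config is not None and config.nutrient_panel_size is not None:
        panel = panel[:config.nutrient_panel_size]
    return panel


# --------------------------------------------------------------------------
# Closed-form solver fixture
# --------------------------------------------------------------------------

def one_enzyme_model(uptake: float, enzyme_cost: float,
                     k_eff: float) -> MEModelSpec:
    """Minimal self-replicator with a closed-form optimum.

    One nutrient S taken up at rate <= ``uptake``; one catalysed conversion
    S -> biomass with turnover ``k_eff``; enzyme formation costs
    ``enzyme_cost`` units of S per enzyme.  The balances give
    ``U = mu * (1 + enzyme_cost * mu / k_eff)``, hence
    ``mu* = k_eff * (-1 + sqrt(1 + 4*enzyme_cost*U/k_eff)) / (2*enzyme_cost)``.
    """
    model = MEModelSpec()
    model.add_species(MESpecies(id="S", role="metabolite"))
    model.add_species(MESpecies(id="E", role="enzyme_complex",
                                molecular_weight=enzyme_cost * 0.1))
    model.add_species(MESpecies(id="biomass", role="biomass_pool"))
    model.add_reaction(MEReaction(
        id="EX_S", klass="exchange", stoichiometry={"S": -1.0},
        lower=-abs(uptake), upper=1000.0))
    model.add_reaction(MEReaction(
        id="CAT", klass="metabolic", stoichiometry={"S": -1.0, "biomass": 1.0},
        catalyst="E", subsystem="core"))
    model.add_reaction(MEReaction(
        id="FORM_E", klass="complex_formation",
        stoichiometry={"S": -enzyme_cost, "E": 1.0}))
    model.add_reaction(MEReaction(
        id="biomass_dilution", klass="biomass_dilution",
        stoichiometry={"biomass": -1.0}))
    model.params.k_eff_overrides[("E", "CAT")] = k_eff
    build_enzyme_coupling(model)
    model.validate()
    return model


def one_enzyme_mu_star(uptake: float, enzyme_cost: float,
                       k_eff: float) -> float:
    """Closed-form optimum of :func:`one_enzyme_model`."""
    import math
    c, u, k = enzyme_cost, uptake, k_eff
    return k * (-1.0 + math.sqrt(1.0 + 4.0 * c * u / k)) / (2.0 * c)


# --------------------------------------------------------------------------
# Statistical fixtures
# --------------------------------------------------------------------------

@dataclass
class ClusterSpec:
    """Planted structure for synthetic demand tables.

    ``shifts`` lists, per cluster, the component indices shifted by
    ``log2_effect`` (in log2 space) relative to the background; ``noise_sd``
    is the log2-normal noise scale.
    """

    k: int = 2
    shifts: Optional[list[list[int]]] = None
    log2_effect: float = 1.0
    noise_sd: float = 0.1
    n_outliers: int = 0
    outlier_z: float = 5.0

    def resolved_shifts(self, n_components: int) -> list[list[int]]:
        if self.shifts is not None:
            return self.shifts
        per = max(1, n_components // max(self.k, 1))
        return [list(range(g * per, min((g + 1) * per, n_components)))
                for g in range(self.k)]


def generate_composition_table(n_conditions: int, n_components: int,
                               cluster_spec: ClusterSpec, seed: int = 0
                               ) -> tuple[pd.DataFrame, pd.Series,
                                          list[tuple[str, str]]]:
    """Log-normal demand table with planted clusters and outliers.

    Returns (table, true cluster labels, planted outlier (condition,
    component) pairs).  Outliers are placed post hoc at exactly
    ``outlier_z`` sample standard deviations above the column mean.
    """
    rng = np.random.default_rng(seed)
    spec = cluster_spec
    base_log2 = rng.uniform(-2.0, 2.0, size=n_components)
    labels = np.arange(n_conditions) % spec.k
    rng.shuffle(labels)
    log2_vals = np.tile(base_log2, (n_conditions, 1))
    shifts = spec.resolved_shifts(n_components)
    for g in range(spec.k):
        for comp in shifts[g]:
            log2_vals[labels == g, comp] += spec.log2_effect
    log2_vals += rng.normal(0.0, spec.noise_sd, size=log2_vals.shape)
    table = pd.DataFrame(
        np.exp2(log2_vals),
        index=[f"cond_{i:03d}" for i in range(n_conditions)],
        columns=[f"comp_{j:02d}" for j in range(n_components)])
    outliers: list[tuple[str, str]] = []
    for _ in range(spec.n_outliers):
        i = int(rng.integers(n_conditions))
        j = int(rng.integers(n_components))
        col = table.iloc[:, j]
        others = col.drop(col.index[i])
        # solve for the value achieving the requested sample z-score
        target_z = spec.outlier_z
        x = _value_at_z(others.to_numpy(), target_z)
        table.iloc[i, j] = x
        outliers.append((table.index[i], table.columns[j]))
    return table, pd.Series(labels, index=table.index, name="cluster"), outliers


def _value_at_z(others: np.ndarray, z: float) -> float:
    """Value x such that, pooled with ``others``, its sample z-score is z."""
    from scipy.optimize import brentq

    n = len(others) + 1
    mean_o, var_o = others.mean(), others.var(ddof=0)

    def score(x):
        mean = (others.sum() + x) / n
        var = (var_o * len(others)
               + (others.mean() - mean) ** 2 * len(others)
               + (x - mean) ** 2) / (n - 1)
        return (x - mean) / np.sqrt(var) - z

    max_z = (n - 1) / np.sqrt(n)
    if z >= max_z - 1e-9:
        raise ValueError(f"z={z} unreachable with n={n} (max {max_z:.3f})")
    if var_o <= (1e-12 * max(1.0, abs(mean_o))) ** 2:
        # constant background: any distinct value lands at the maximal
        # sample z of (n-1)/sqrt(n), which exceeds the requested z
        return float(2.0 * abs(mean_o) + 1.0)
    hi = mean_o + 10 * np.sqrt(var_o) * max(z, 1.0)
    while score(hi) < 0:
        hi *= 2.0
    return float(brentq(score, mean_o + 1e-12 * max(1.0, abs(mean_o)), hi))
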