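"""Domain types and constraint assembly for miniature metabolism-and-expression
(ME) models.

An ME model extends a stoichiometric metabolic network with the machinery that
produces it: transcription, translation, enzyme-complex formation and cofactor
provisioning.  The price of that mechanism is that stoichiometric coefficients
become functions of the growth rate ``mu`` — a ribosome translating a peptide of
length ``l_p`` must itself be formed at a rate proportional to
``l_p * (mu + r0*kappa_tau) / (c_ribo*kappa_tau)`` per unit translation flux,
an enzyme catalysing a reaction must be formed at ``mu / k_eff`` per unit flux,
and so on.  At any fixed ``mu`` the system is an ordinary linear program
``S(mu) v = 0``, ``vL <= v <= vU`` with the biomass-dilution flux pinned to
``mu``; growth maximisation is a line search over ``mu`` (see
:mod:`me_allocate.solver`).

Every coupling constraint is encoded as a species balance row: the machinery
species (ribosome, RNA polymerase, enzyme complex, tRNA, coenzyme) is produced
by its formation reaction and consumed by the reactions it enables, with a
mu-dependent coefficient.  Where no natural species exists for a row (mRNA
degradation, coenzyme formation) a pseudo-species is added, so the whole
problem remains a single ``S v = 0`` system.

Units: all rates are handled internally in h^-1; per-second turnover numbers
(e.g. the 65 s^-1 default effective turnover) are converted with
:func:`per_second` at load time.  Fluxes are mmol/gDW/h, molecular weights
g/mmol, protein-biomass flux g/gDW/h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping, Optional, Union

import numpy as np

__all__ = [
    "MEError",
    "MEStructureError",
    "MEValidationError",
    "SingularityError",
    "MuCoefficient",
    "as_coefficient",
    "per_second",
    "MESpecies",
    "PeptideSpec",
    "TranscriptionUnitSpec",
    "CouplingParams",
    "MEReaction",
    "MEModelSpec",
    "CoenzymeSpec",
    "NumericLP",
    "ParametricLP",
    "compile_parametric",
    "evaluate_at_mu",
    "build_ribosome_coupling",
    "build_rnap_coupling",
    "build_synthetase_coupling",
    "build_enzyme_coupling",
    "build_trna_coupling",
    "build_mrna_coupling",
    "SPECIES_ROLES",
    "REACTION_CLASSES",
]


class MEError(Exception):
    """Base class for all model errors."""


class MEStructureError(MEError):
    """A required structural element (reaction, species, link) is absent."""


class MEValidationError(MEError):
    """A model element violates its invariants."""


class SingularityError(MEError):
    """A mu-dependent coefficient is non-finite at the requested growth rate."""


def per_second(rate_per_s: float) -> float:
    """Convert a per-second rate constant to h^-1 (x3600)."""
    return float(rate_per_s) * 3600.0


# --------------------------------------------------------------------------
# mu-dependent coefficients
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MuCoefficient:
    """A stoichiometric coefficient of the form ``a + b*mu + c/mu + d*mu**2``.

    The affine and 1/mu parts cover the ribosome, RNA polymerase, enzyme,
    tRNA, mRNA and coenzyme coupling terms; the quadratic part carries the
    synthetase term ``(1 + mu/k_t) * mu/k_c = mu/k_c + mu^2/(k_t*k_c)``.
    """

    const: float = 0.0
    mu: float = 0.0
    inv_mu: float = 0.0
    mu2: float = 0.0

    def __call__(self, growth_rate: float) -> float:
        value = self.const + self.mu * growth_rate + self.mu2 * growth_rate ** 2
        if self.inv_mu != 0.0:
            if growth_rate == 0.0:
                raise SingularityError("1/mu coefficient evaluated at mu=0")
            value += self.inv_mu / growth_rate
        return value

    # -- small closed algebra so builders can accumulate terms -------------
    def __add__(self, other: Union["MuCoefficient", float, int]) -> "MuCoefficient":
        other = as_coefficient(other)
        return MuCoefficient(
            self.const + other.const,
            self.mu + other.mu,
            self.inv_mu + other.inv_mu,
            self.mu2 + other.mu2,
        )

    __radd__ = __add__

    def __sub__(self, other: Union["MuCoefficient", float, int]) -> "MuCoefficient":
        return self + (-as_coefficient(other))

    def __rsub__(self, other: Union[float, int]) -> "MuCoefficient":
        return as_coefficient(other) + (-self)

    def __neg__(self) -> "MuCoefficient":
        return MuCoefficient(-self.const, -self.mu, -self.inv_mu, -self.mu2)

    def __mul__(self, scalar: float) -> "MuCoefficient":
        s = float(scalar)
        return MuCoefficient(self.const * s, self.mu * s, self.inv_mu * s, self.mu2 * s)

    __rmul__ = __mul__

    @property
    def is_constant(self) -> bool:
        return self.mu == 0.0 and self.inv_mu == 0.0 and self.mu2 == 0.0

    def to_json(self) -> Union[float, dict]:
        if self.is_constant:
            return self.const
        out = {}
        for key in ("const", "mu", "inv_mu", "mu2"):
            v = getattr(self, key)
            if v != 0.0:
                out[key] = v
        return out

    @classmethod
    def from_json(cls, obj: Union[float, int, Mapping]) -> "MuCoefficient":
        if isinstance(obj, (int, float)):
            return cls(const=float(obj))
        return cls(
            const=float(obj.get("const", 0.0)),
            mu=float(obj.get("mu", 0.0)),
            inv_mu=float(obj.get("inv_mu", 0.0)),
            mu2=float(obj.get("mu2", 0.0)),
        )


Coefficient = Union[float, int, MuCoefficient]


def as_coefficient(value: Coefficient) -> MuCoefficient:
    if isinstance(value, MuCoefficient):
        return value
    return MuCoefficient(const=float(value))


# --------------------------------------------------------------------------
# Species
# --------------------------------------------------------------------------

SPECIES_ROLES = frozenset({
    "metabolite", "peptide", "mRNA", "transcription_unit", "tRNA",
    "charged_tRNA", "synthetase", "enzyme_complex", "coenzyme_uncharged",
    "coenzyme_charged", "prosthetic_group", "biomass_pool", "pseudo",
})


@dataclass
class PeptideSpec:
    """Amino-acid payload of a peptide species.

    ``length`` is the amino-acid count driving the ribosome coupling term;
    ``composition`` maps amino-acid species id to its count in the chain.
    """

    id: str
    length: int
    composition: dict[str, int] = field(default_factory=dict)
    part_of_complexes: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(c < 0 or int(c) != c for c in self.composition.values()):
            raise MEValidationError(
                f"peptide {self.id}: composition counts must be non-negative integers")
        total = sum(self.composition.values())
        if self.composition and total != self.length:
            raise MEValidationError(
                f"peptide {self.id}: composition sums to {total}, length is {self.length}")


@dataclass
class TranscriptionUnitSpec:
    id: str
    length: int  # nucleotides
    encoded_mrnas: list[str] = field(default_factory=list)


@dataclass
class MESpecies:
    id: str
    role: str
    compartment: str = "c"
    molecular_weight: Optional[float] = None  # g/mmol
    subsystem: Optional[str] = None
    partner: Optional[str] = None  # charged <-> uncharged coenzyme link
    biosynthesis_reaction: Optional[str] = None  # designated demand reaction
    peptide: Optional[PeptideSpec] = None
    tu: Optional[TranscriptionUnitSpec] = None

    def __post_init__(self) -> None:
        if self.role not in SPECIES_ROLES:
            raise MEValidationError(f"species {self.id}: unknown role {self.role!r}")
        if self.molecular_weight is not None and not self.molecular_weight > 0:
            raise MEValidationError(
                f"species {self.id}: molecular_weight must be > 0")


# --------------------------------------------------------------------------
# Coupling parameters
# --------------------------------------------------------------------------

@dataclass
class CouplingParams:
    """Rate constants and scales for every coupling-constraint class.

    Defaults: ``kappa_tau`` = 4.5 h^-1 and ``r0`` = 0.087 parameterise the
    RNA-to-protein growth law treated here as fixed symbols; effective
    turnover numbers default to 65 s^-1 (234000 h^-1); the coenzyme activity
    constant defaults to 1e4 h^-1; the unmodeled-protein fraction defaults
    to 0.
    """

    kappa_tau: float = 4.5           # h^-1
    r0: float = 0.087                # dimensionless
    c_ribo: float = 5000.0           # amino acids per ribosome-hour scale
    c_ribo_rnap: Optional[float] = None  # override for the RNAP constraint
    c_mrna: float = 10.0             # nucleotide scale per mRNA
    c_trna: dict[str, float] = field(default_factory=dict)
    c_trna_default: Optional[float] = 500.0
    k_deg: dict[str, float] = field(default_factory=dict)   # h^-1 per mRNA
    k_deg_default: float = 12.0
    k_eff_default: float = per_second(65.0)
    k_eff_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    k_eff_trna: float = per_second(65.0)
    k_eff_charging: float = per_second(65.0)
    k_activity_default: float = 1.0e4   # h^-1
    k_activity_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    unmodeled_protein_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kappa_tau", "c_ribo", "c_mrna", "k_eff_default",
                     "k_eff_trna", "k_eff_charging", "k_activity_default"):
            if not getattr(self, name) > 0:
                raise MEValidationError(f"CouplingParams.{name} must be > 0")
        if not 0.0 <= self.unmodeled_protein_fraction < 1.0:
            raise MEValidationError("unmodeled_protein_fraction must lie in [0, 1)")

    def k_eff_for(self, enzyme: str, reaction: str) -> float:
        k = self.k_eff_overrides.get((enzyme, reaction), self.k_eff_default)
        if not k > 0:
            raise MEValidationError(
                f"k_eff for ({enzyme}, {reaction}) must be > 0, got {k}")
        return k

    def k_activity_for(self, coenzyme: str, reaction: str) -> float:
        k = self.k_activity_overrides.get((coenzyme, reaction), self.k_activity_default)
        if not k > 0:
            raise MEValidationError(
                f"k_activity for ({coenzyme}, {reaction}) must be > 0, got {k}")
        return k

    def c_trna_for(self, trna: str) -> float:
        c = self.c_trna.get(trna, self.c_trna_default)
        if c is None:
            raise MEValidationError(f"no c_tRNA value for tRNA {trna!r}")
        return c

    def k_deg_for(self, mrna: str) -> float:
        return self.k_deg.get(mrna, self.k_deg_default)


# --------------------------------------------------------------------------
# Reactions
# --------------------------------------------------------------------------

REACTION_CLASSES = frozenset({
    "metabolic", "translation", "transcription", "complex_formation",
    "tRNA_charging", "coenzyme_charging", "mRNA_degradation", "exchange",
    "biomass_dilution", "demand", "summary",
})

DEFAULT_UPPER = 1000.0


@dataclass
class MEReaction:
    id: str
    klass: str
    stoichiometry: dict[str, Coefficient] = field(default_factory=dict)
    lower: float = 0.0
    upper: float = DEFAULT_UPPER
    catalyst: Optional[str] = None
    subsystem: Optional[str] = None
    # structural links used by the coupling builders
    mrna: Optional[str] = None        # translation / mRNA_degradation
    tu: Optional[str] = None          # transcription
    trna: Optional[str] = None        # tRNA_charging
    synthetase: Optional[str] = None  # tRNA_charging

    def __post_init__(self) -> None:
        if self.klass not in REACTION_CLASSES:
            raise MEValidationError(f"reaction {self.id}: unknown class {self.klass!r}")

    def coefficient(self, species_id: str) -> MuCoefficient:
        return as_coefficient(self.stoichiometry.get(species_id, 0.0))

    def add_term(self, species_id: str, term: Coefficient) -> None:
        """Accumulate ``term`` onto the coefficient of ``species_id``."""
        new = self.coefficient(species_id) + as_coefficient(term)
        self.stoichiometry[species_id] = new.const if new.is_constant else new

    def products(self) -> Iterator[tuple[str, MuCoefficient]]:
        for sid, coeff in self.stoichiometry.items():
            c = as_coefficient(coeff)
            if c.const > 0 or (c.const == 0 and c.mu > 0):
                yield sid, c

    def reactants(self) -> Iterator[tuple[str, MuCoefficient]]:
        for sid, coeff in self.stoichiometry.items():
            c = as_coefficient(coeff)
            if c.const < 0 or (c.const == 0 and c.mu < 0):
                yield sid, c


# --------------------------------------------------------------------------
# Coenzymes
# --------------------------------------------------------------------------

@dataclass
class CoenzymeSpec:
    """A recycled coenzyme pair and its designated biosynthesis reaction.

    ``biosynthesis_reaction`` is the pathway flux used for demand accounting;
    ``formation_reaction`` (defaulting to the same reaction) anchors the
    formation-coupling row.
    """

    id: str
    uncharged_species: str
    charged_species: str
    biosynthesis_reaction: str
    formation_reaction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.uncharged_species == self.charged_species:
            raise MEValidationError(
                f"coenzyme {self.id}: charged and uncharged species must differ")
        if self.formation_reaction is None:
            self.formation_reaction = self.biosynthesis_reaction


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

@dataclass
class MEModelSpec:
    """A complete mu-parametric ME model: species, reactions, parameters."""

    species: list[MESpecies] = field(default_factory=list)
    reactions: list[MEReaction] = field(default_factory=list)
    params: CouplingParams = field(default_factory=CouplingParams)
    biomass_dilution_id: str = "biomass_dilution"
    protein_biomass_summary_id: str = "protein_biomass_to_biomass"
    coenzymes: list[CoenzymeSpec] = field(default_factory=list)
    applied_couplings: list[str] = field(default_factory=list)

    # -- lookups -----------------------------------------------------------
    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_species(self, species_id: str) -> MESpecies:
        for s in self.species:
            if s.id == species_id:
                return s
        raise MEStructureError(f"no species {species_id!r} in model")

    def has_species(self, species_id: str) -> bool:
        return any(s.id == species_id for s in self.species)

    def get_reaction(self, reaction_id: str) -> MEReaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise MEStructureError(f"no reaction {reaction_id!r} in model")

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    def add_species(self, sp: MESpecies) -> MESpecies:
        if self.has_species(sp.id):
            raise MEValidationError(f"duplicate species id {sp.id!r}")
        self.species.append(sp)
        return sp

    def add_reaction(self, rxn: MEReaction) -> MEReaction:
        if self.has_reaction(rxn.id):
            raise MEValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)
        return rxn

    def reactions_of_class(self, klass: str) -> list[MEReaction]:
        return [r for r in self.reactions if r.klass == klass]

    def formation_reaction_of(self, complex_id: str) -> MEReaction:
        """The complex_formation reaction producing ``complex_id``."""
        for r in self.reactions_of_class("complex_formation"):
            if as_coefficient(r.stoichiometry.get(complex_id, 0.0)).const > 0:
                return r
        raise MEStructureError(
            f"no complex_formation reaction producing {complex_id!r}")

    def translation_peptide(self, rxn: MEReaction) -> MESpecies:
        for sid, coeff in rxn.stoichiometry.items():
            sp = self.get_species(sid)
            if sp.role == "peptide" and as_coefficient(coeff).const > 0:
                return sp
        raise MEStructureError(f"translation {rxn.id} produces no peptide")

    def copy(self) -> "MEModelSpec":
        import copy as _copy
        return _copy.deepcopy(self)

    # -- validation --------------------------------------------------------
    def validate(self) -> list[str]:
        """Check model invariants; raise on hard errors, return warnings."""
        warnings: list[str] = []
        ids = [s.id for s in self.species]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MEValidationError(f"duplicate species ids: {dupes}")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            dupes = sorted({i for i in rids if rids.count(i) > 1})
            raise MEValidationError(f"duplicate reaction ids: {dupes}")
        known = set(ids)
        for r in self.reactions:
            missing = [s for s in r.stoichiometry if s not in known]
            if missing:
                raise MEValidationError(
                    f"reaction {r.id}: unknown species {missing}")
            if r.lower > r.upper:
                raise MEValidationError(f"reaction {r.id}: lower > upper bound")
            if r.klass == "exchange" and len(r.stoichiometry) != 1:
                raise MEValidationError(
                    f"exchange {r.id} must touch exactly one species")
        dilution = self.reactions_of_class("biomass_dilution")
        if len(dilution) != 1 or dilution[0].id != self.biomass_dilution_id:
            raise MEValidationError(
                "model must contain exactly one biomass_dilution reaction "
                f"with id {self.biomass_dilution_id!r}")
        # nucleotide-triplet consistency where TUs are linked to peptides
        peptide_len = {s.id: s.peptide.length for s in self.species
                       if s.peptide is not None}
        for s in self.species:
            if s.tu is None:
                continue
            linked = []
            for mid in s.tu.encoded_mrnas:
                for t in self.reactions_of_class("translation"):
                    if t.mrna == mid:
                        pep = self.translation_peptide(t)
                        if pep.id in peptide_len:
                            linked.append(peptide_len[pep.id])
            if linked and s.tu.length < 3 * max(linked):
                raise MEValidationError(
                    f"TU {s.id}: length {s.tu.length} < 3x longest encoded "
                    f"peptide ({max(linked)} aa)")
        for r in self.reactions:
            if r.catalyst is not None and not self.has_species(r.catalyst):
                raise MEValidationError(
                    f"reaction {r.id}: unknown catalyst {r.catalyst!r}")
        for r in self.reactions:
            if r.catalyst is not None:
                try:
                    self.formation_reaction_of(r.catalyst)
                except MEStructureError:
                    warnings.append(
                        f"catalyst {r.catalyst} of {r.id} has no formation reaction")
        return warnings

    # -- serialization -----------------------------------------------------
    def to_json(self, path: Optional[str] = None, indent: int = 1) -> str:
        doc = {
            "species": [_species_to_json(s) for s in self.species],
            "reactions": [_reaction_to_json(r) for r in self.reactions],
            "params": _params_to_json(self.params),
            "biomass_dilution_id": self.biomass_dilution_id,
            "protein_biomass_summary_id": self.protein_biomass_summary_id,
            "coenzymes": [_drop_none(asdict(c)) for c in self.coenzymes],
            "applied_couplings": list(self.applied_couplings),
        }
        text = json.dumps(doc, indent=indent, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "MEModelSpec":
        """Load a model from a JSON string or a path to a JSON file."""
        if "\n" in source or source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            species=[_species_from_json(d) for d in doc["species"]],
            reactions=[_reaction_from_json(d) for d in doc["reactions"]],
            params=_params_from_json(doc.get("params", {})),
            biomass_dilution_id=doc.get("biomass_dilution_id", "biomass_dilution"),
            protein_biomass_summary_id=doc.get(
                "protein_biomass_summary_id", "protein_biomass_to_biomass"),
            coenzymes=[CoenzymeSpec(**d) for d in doc.get("coenzymes", [])],
            applied_couplings=list(doc.get("applied_couplings", [])),
        )


def _drop_none(d: dict) -> dict:
    return {k: v for k, v in d.items() if v is not None and v != [] and v != {}}


def _species_to_json(s: MESpecies) -> dict:
    d = {"id": s.id, "role": s.role, "compartment": s.compartment,
         "molecular_weight": s.molecular_weight, "subsystem": s.subsystem,
         "partner": s.partner, "biosynthesis_reaction": s.biosynthesis_reaction}
    if s.peptide is not None:
        d["peptide"] = _drop_none(asdict(s.peptide))
    if s.tu is not None:
        d["tu"] = _drop_none(asdict(s.tu))
    return _drop_none(d)


def _species_from_json(d: Mapping) -> MESpecies:
    d = dict(d)
    pep = d.pop("peptide", None)
    tu = d.pop("tu", None)
    sp = MESpecies(**d)
    if pep is not None:
        pep = dict(pep)
        pep["part_of_complexes"] = [tuple(x) for x in pep.get("part_of_complexes", [])]
        pep.setdefault("composition", {})
        sp.peptide = PeptideSpec(**pep)
    if tu is not None:
        sp.tu = TranscriptionUnitSpec(**tu)
    return sp


def _reaction_to_json(r: MEReaction) -> dict:
    d = {"id": r.id, "klass": r.klass,
         "stoichiometry": {sid: as_coefficient(c).to_json()
                           for sid, c in r.stoichiometry.items()},
         "lower": r.lower, "upper": r.upper, "catalyst": r.catalyst,
         "subsystem": r.subsystem, "mrna": r.mrna, "tu": r.tu,
         "trna": r.trna, "synthetase": r.synthetase}
    return _drop_none(d)


def _reaction_from_json(d: Mapping) -> MEReaction:
    d = dict(d)
    stoich = {sid: MuCoefficient.from_json(c)
              for sid, c in d.pop("stoichiometry", {}).items()}
    stoich = {sid: (c.const if c.is_constant else c) for sid, c in stoich.items()}
    d.setdefault("lower", 0.0)
    d.setdefault("upper", DEFAULT_UPPER)
    return MEReaction(stoichiometry=stoich, **d)


def _params_to_json(p: CouplingParams) -> dict:
    d = asdict(p)
    d["k_eff_overrides"] = {f"{e}|{r}": v for (e, r), v in p.k_eff_overrides.items()}
    d["k_activity_overrides"] = {
        f"{c}|{r}": v for (c, r), v in p.k_activity_overrides.items()}
    return d


def _params_from_json(d: Mapping) -> CouplingParams:
    d = dict(d)
    for key in ("k_eff_overrides", "k_activity_overrides"):
        raw = d.get(key, {})
        d[key] = {tuple(k.split("|", 1)): v for k, v in raw.items()}
    return CouplingParams(**d)


# --------------------------------------------------------------------------
# Coupling-constraint builders
# --------------------------------------------------------------------------

def _mark_applied(model: MEModelSpec, name: str) -> None:
    if name in model.applied_couplings:
        raise MEStructureError(f"coupling {name!r} already applied to this model")
    model.applied_couplings.append(name)


def build_ribosome_coupling(model: MEModelSpec, ribosome_id: str = "ribosome"
                            ) -> MEModelSpec:
    """Tie ribosome formation to total translation load.

    Adds, via the ribosome species balance, the row
    ``v_formation,Ribosome - sum_i l_p,i*(mu + r0*kappa_tau)/(c_ribo*kappa_tau)
    * v_translation,i = 0``.  The per-translation coefficient is affine in mu.
    """
    p = model.params
    try:
        model.formation_reaction_of(ribosome_id)
    except MEStructureError as exc:
        raise MEStructureError(
            f"ribosome coupling: no formation reaction for {ribosome_id!r}") from exc
    translations = model.reactions_of_class("translation")
    if not translations:
        raise MEStructureError("ribosome coupling: no translation reactions")
    for rxn in translations:
        length = model.translation_peptide(rxn).peptide.length
        coeff = MuCoefficient(const=length * p.r0 / p.c_ribo,
                              mu=length / (p.c_ribo * p.kappa_tau))
        rxn.add_term(ribosome_id, -coeff)
    _mark_applied(model, "ribosome")
    return model


def build_rnap_coupling(model: MEModelSpec, rnap_id: str = "rnap") -> MEModelSpec:
    """Tie RNA-polymerase formation to total transcription load.

    Row: ``v_formation,RNAP - sum_i l_TU,i*(mu + r0*kappa_tau)
    / (3*c_ribo*kappa_tau) * v_transcription,i = 0``.  The factor 3 converts
    nucleotide lengths onto the amino-acid scale of ``c_ribo``; a distinct
    RNAP catalytic constant can be supplied via ``params.c_ribo_rnap``.
    """
    p = model.params
    c = p.c_ribo_rnap if p.c_ribo_rnap is not None else p.c_ribo
    try:
        model.formation_reaction_of(rnap_id)
    except MEStructureError as exc:
        raise MEStructureError(
            f"RNAP coupling: no formation reaction for {rnap_id!r}") from exc
    transcriptions = model.reactions_of_class("transcription")
    if not transcriptions:
        raise MEStructureError("RNAP coupling: no transcription reactions")
    for rxn in transcriptions:
        if rxn.tu is None:
            raise MEStructureError(
                f"transcription {rxn.id} has no transcription-unit link")
        tu = model.get_species(rxn.tu).tu
        if tu is None:
            raise MEStructureError(
                f"species {rxn.tu} carries no transcription-unit payload")
        coeff = MuCoefficient(const=tu.length * p.r0 / (3.0 * c),
                              mu=tu.length / (3.0 * c * p.kappa_tau))
        rxn.add_term(rnap_id, -coeff)
    _mark_applied(model, "rnap")
    return model


def build_synthetase_coupling(model: MEModelSpec) -> MEModelSpec:
    """Tie synthetase formation to tRNA-charging flux.

    Row per synthetase j:
    ``v_formation,j - sum_i (1 + mu/k_eff,tRNA)*(mu/k_eff,charging)
    * v_charging,i = 0``; the coefficient carries a mu^2 term.
    """
    p = model.params
    charg = model.reactions_of_class("tRNA_charging")
    for rxn in charg:
        if rxn.synthetase is None:
            raise MEStructureError(
                f"tRNA charging {rxn.id} has no synthetase annotation")
        coeff = MuCoefficient(mu=1.0 / p.k_eff_charging,
                              mu2=1.0 / (p.k_eff_trna * p.k_eff_charging))
        rxn.add_term(rxn.synthetase, -coeff)
    _mark_applied(model, "synthetase")
    return model


def build_enzyme_coupling(model: MEModelSpec) -> MEModelSpec:
    """Tie enzyme-complex formation to catalysed flux: ``mu/k_eff`` enzyme
    consumed per unit usage flux, per catalysed reaction."""
    p = model.params
    for rxn in model.reactions:
        if rxn.catalyst is None or rxn.klass == "complex_formation":
            continue
        k_eff = p.k_eff_for(rxn.catalyst, rxn.id)
        rxn.add_term(rxn.catalyst, -MuCoefficient(mu=1.0 / k_eff))
    _mark_applied(model, "enzyme")
    return model


def build_trna_coupling(model: MEModelSpec) -> MEModelSpec:
    """Tie tRNA formation to its charging flux:
    ``(mu + kappa_tau*r0)/(kappa_tau*c_tRNA,j)`` tRNA per unit charging."""
    p = model.params
    for rxn in model.reactions_of_class("tRNA_charging"):
        if rxn.trna is None:
            raise MEStructureError(f"tRNA charging {rxn.id} has no tRNA link")
        c = p.c_trna_for(rxn.trna)
        coeff = MuCoefficient(const=p.r0 / c, mu=1.0 / (p.kappa_tau * c))
        rxn.add_term(rxn.trna, -coeff)
    _mark_applied(model, "trna")
    return model


def build_mrna_coupling(model: MEModelSpec) -> MEModelSpec:
    """Add the two mRNA rows per message: formation and degradation.

    Formation: translation consumes ``(mu + kappa_tau*r0)/(3*kappa_tau*c_mRNA)``
    mRNA per unit flux (balanced on the mRNA species).  Degradation:
    ``v_degradation,j = k_deg,j*(mu + kappa_tau*r0)/(3*kappa_tau*c_mRNA*mu)
    * v_translation,j``, carried by a pseudo-species since the degradation flux
    must not drain the mRNA balance a second time.  The 1/mu term makes the
    degradation row singular at mu=0.
    """
    p = model.params
    degradations = {r.mrna: r for r in model.reactions_of_class("mRNA_degradation")}
    for rxn in model.reactions_of_class("translation"):
        if rxn.mrna is None:
            raise MEStructureError(f"translation {rxn.id} has no mRNA link")
        form = MuCoefficient(const=p.r0 / (3.0 * p.c_mrna),
                             mu=1.0 / (3.0 * p.kappa_tau * p.c_mrna))
        rxn.add_term(rxn.mrna, -form)
        deg_rxn = degradations.get(rxn.mrna)
        if deg_rxn is None:
            continue
        k_deg = p.k_deg_for(rxn.mrna)
        deg = MuCoefficient(const=k_deg / (3.0 * p.kappa_tau * p.c_mrna),
                            inv_mu=k_deg * p.r0 / (3.0 * p.c_mrna))
        pseudo_id = f"coupling_mrna_deg_{rxn.mrna}"
        if not model.has_species(pseudo_id):
            model.add_species(MESpecies(id=pseudo_id, role="pseudo"))
        deg_rxn.add_term(pseudo_id, 1.0)
        rxn.add_term(pseudo_id, -deg)
    _mark_applied(model, "mrna")
    return model


# --------------------------------------------------------------------------
# Numeric LP assembly
# --------------------------------------------------------------------------

@dataclass
class NumericLP:
    """A fully numeric instance ``S v = 0``, ``lb <= v <= ub`` at one mu."""

    S: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    species_ids: list[str]
    reaction_ids: list[str]
    mu: float


class ParametricLP:
    """Compiled mu-parametric system: ``S(mu) = A0 + mu*A1 + A2/mu + mu^2*A3``.

    Compiling once and evaluating per mu keeps the bisection inner loop cheap
    and guarantees that two evaluations at the same mu are bit-identical.
    """

    def __init__(self, model: MEModelSpec):
        self.species_ids = [s.id for s in model.species]
        self.reaction_ids = [r.id for r in model.reactions]
        sidx = {s: i for i, s in enumerate(self.species_ids)}
        n_s, n_r = len(self.species_ids), len(self.reaction_ids)
        self.A0 = np.zeros((n_s, n_r))
        self.A1 = np.zeros((n_s, n_r))
        self.A2 = np.zeros((n_s, n_r))
        self.A3 = np.zeros((n_s, n_r))
        self.lower = np.array([r.lower for r in model.reactions], dtype=float)
        self.upper = np.array([r.upper for r in model.reactions], dtype=float)
        for j, rxn in enumerate(model.reactions):
            for sid, coeff in rxn.stoichiometry.items():
                c = as_coefficient(coeff)
                i = sidx[sid]
                self.A0[i, j] += c.const
                self.A1[i, j] += c.mu
                self.A2[i, j] += c.inv_mu
                self.A3[i, j] += c.mu2
        self.inv_mu_cols = sorted(set(np.nonzero(self.A2)[1].tolist()))
        try:
            self.dilution_col = self.reaction_ids.index(model.biomass_dilution_id)
        except ValueError as exc:
            raise MEStructureError(
                f"no biomass dilution reaction {model.biomass_dilution_id!r}"
            ) from exc
        # stored dilution bounds act as an explicit cap on feasible mu
        self.dilution_bounds = (self.lower[self.dilution_col],
                                self.upper[self.dilution_col])

    def evaluate(self, mu: float, mu_zero_limit: bool = False) -> NumericLP:
        if mu < 0:
            raise ValueError("growth rate must be non-negative")
        lower = self.lower.copy()
        upper = self.upper.copy()
        if mu == 0.0 and self.inv_mu_cols:
            if not mu_zero_limit:
                bad = self.reaction_ids[self.inv_mu_cols[0]]
                raise SingularityError(
                    f"reaction {bad!r} carries a 1/mu coefficient; "
                    "evaluation at mu=0 is singular")
            # mu->0+ limit: a diverging coefficient forces its flux to zero
            S = self.A0.copy()
            for col in self.inv_mu_cols:
                lower[col] = 0.0
                upper[col] = 0.0
                mask = self.A2[:, col] != 0.0
                S[mask, col] = 0.0
        elif mu == 0.0:
            S = self.A0.copy()
        else:
            S = self.A0 + mu * self.A1 + (1.0 / mu) * self.A2 + mu ** 2 * self.A3
        if not np.isfinite(S).all():
            i, j = np.argwhere(~np.isfinite(S))[0]
            raise SingularityError(
                f"non-finite coefficient in reaction {self.reaction_ids[j]!r} "
                f"(species {self.species_ids[i]!r}) at mu={mu}")
        lower[self.dilution_col] = mu
        if self.dilution_bounds[0] <= mu <= self.dilution_bounds[1]:
            upper[self.dilution_col] = mu
        else:
            upper[self.dilution_col] = mu - 1.0  # empty interval: infeasible
        return NumericLP(S=S, lower=lower, upper=upper,
                         species_ids=self.species_ids,
                         reaction_ids=self.reaction_ids, mu=mu)


def compile_parametric(model: MEModelSpec) -> ParametricLP:
    return ParametricLP(model)


def evaluate_at_mu(model: MEModelSpec, mu: float,
                   mu_zero_limit: bool = False) -> NumericLP:
    """Numeric LP at a fixed growth rate, with biomass dilution pinned to mu."""
    return compile_parametric(model).evaluate(mu, mu_zero_limit=mu_zero_limit)
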