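"""Coupling-coefficient assembly and numeric LP evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from me_allocate.core import (
    CouplingParams,
    MEModelSpec,
    MEReaction,
    MESpecies,
    MEStructureError,
    MEValidationError,
    MuCoefficient,
    PeptideSpec,
    SingularityError,
    TranscriptionUnitSpec,
    as_coefficient,
    build_enzyme_coupling,
    build_mrna_coupling,
    build_ribosome_coupling,
    build_rnap_coupling,
    build_synthetase_coupling,
    build_trna_coupling,
    compile_parametric,
    evaluate_at_mu,
    per_second,
)

# configuration used by the worked numeric examples below
EX_PARAMS = dict(kappa_tau=4.5, r0=0.087, c_ribo=0.25, c_mrna=1.0,
                 k_deg={"mrna_p1": 12.0})


def tiny_expression_model(length=300, params=None, with_deg=True,
                          kdeg_default=12.0):
    """One peptide/mRNA/TU chain plus ribosome and RNAP machinery."""
    p = CouplingParams(**(params or EX_PARAMS), k_deg_default=kdeg_default)
    m = MEModelSpec(params=p)
    for sid in ("aaX", "ntp"):
        m.add_species(MESpecies(id=sid, role="metabolite"))
    m.add_species(MESpecies(id="biomass", role="biomass_pool"))
    m.add_species(MESpecies(
        id="pept_p1", role="peptide",
        peptide=PeptideSpec(id="pept_p1", length=length,
                            composition={"aaX": length})))
    m.add_species(MESpecies(id="mrna_p1", role="mRNA"))
    m.add_species(MESpecies(
        id="tu_p1", role="transcription_unit",
        tu=TranscriptionUnitSpec(id="tu_p1", length=3 * length,
                                 encoded_mrnas=["mrna_p1"])))
    m.add_species(MESpecies(id="ribosome", role="enzyme_complex"))
    m.add_species(MESpecies(id="rnap", role="enzyme_complex"))
    m.add_reaction(MEReaction(id="TL_p1", klass="translation",
                              stoichiometry={"aaX": -length, "pept_p1": 1.0},
                              mrna="mrna_p1"))
    m.add_reaction(MEReaction(id="TX_p1", klass="transcription",
                              stoichiometry={"ntp": -3.0 * length,
                                             "mrna_p1": 1.0}, tu="tu_p1"))
    if with_deg:
        m.add_reaction(MEReaction(id="DEG_p1", klass="mRNA_degradation",
                                  stoichiometry={}, mrna="mrna_p1"))
    m.add_reaction(MEReaction(id="FORM_ribosome", klass="complex_formation",
                              stoichiometry={"pept_p1": -1.0,
                                             "ribosome": 1.0}))
    m.add_reaction(MEReaction(id="FORM_rnap", klass="complex_formation",
                              stoichiometry={"pept_p1": -1.0, "rnap": 1.0}))
    m.add_reaction(MEReaction(id="EX_aaX", klass="exchange",
                              stoichiometry={"aaX": -1.0}, lower=-10.0))
    m.add_reaction(MEReaction(id="EX_ntp", klass="exchange",
                              stoichiometry={"ntp": -1.0}, lower=-10.0))
    m.add_reaction(MEReaction(id="biomass_dilution", klass="biomass_dilution",
                              stoichiometry={"biomass": -1.0}))
    return m


class TestMuCoefficient:
    def test_evaluation_and_algebra(self):
        c = MuCoefficient(const=1.0, mu=2.0, inv_mu=3.0, mu2=0.5)
        assert c(2.0) == pytest.approx(1 + 4 + 1.5 + 2.0)
        assert (c + 1.0)(2.0) == pytest.approx(c(2.0) + 1.0)
        assert (-c)(2.0) == pytest.approx(-c(2.0))
        assert (c * 2)(2.0) == pytest.approx(2 * c(2.0))

    def test_singular_at_zero(self):
        with pytest.raises(SingularityError):
            MuCoefficient(inv_mu=1.0)(0.0)
        assert MuCoefficient(const=4.0)(0.0) == 4.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5),
           mu=st.floats(0.01, 10))
    def test_addition_is_pointwise(self, a, b, mu):
        x = MuCoefficient(const=a, mu=b)
        y = MuCoefficient(mu=a, inv_mu=b)
        assert (x + y)(mu) == pytest.approx(x(mu) + y(mu), rel=1e-12)

    def test_json_round_trip(self):
        c = MuCoefficient(const=1.5, mu=-2.0, inv_mu=0.25, mu2=1e-9)
        assert MuCoefficient.from_json(c.to_json()) == c
        assert MuCoefficient.from_json(3.0) == MuCoefficient(const=3.0)


class TestRibosomeCoupling:
    def test_worked_example(self):
        # l=300, kappa_tau=4.5, r0=0.087, c_ribo=0.25 at mu=1:
        # 300*(1 + 0.087*4.5)/(0.25*4.5) = 371.0667 ribosomes per unit flux
        m = build_ribosome_coupling(tiny_expression_model())
        coeff = as_coefficient(m.get_reaction("TL_p1").stoichiometry["ribosome"])
        assert coeff(1.0) == pytest.approx(-371.06667, rel=1e-6)
        # mu=0 limit: l*r0/c_ribo
        assert coeff(0.0) == pytest.approx(-300 * 0.087 / 0.25, rel=1e-12)

    def test_linearity_in_peptide_length(self):
        m1 = build_ribosome_coupling(tiny_expression_model(length=150))
        m2 = build_ribosome_coupling(tiny_expression_model(length=300))
        c1 = as_coefficient(m1.get_reaction("TL_p1").stoichiometry["ribosome"])
        c2 = as_coefficient(m2.get_reaction("TL_p1").stoichiometry["ribosome"])
        assert c2(0.7) == pytest.approx(2 * c1(0.7), rel=1e-12)

    def test_missing_formation_reaction_is_structural_error(self):
        m = tiny_expression_model()
        m.reactions = [r for r in m.reactions if r.id != "FORM_ribosome"]
        with pytest.raises(MEStructureError, match="ribosome"):
            build_ribosome_coupling(m)

    def test_double_application_rejected(self):
        m = build_ribosome_coupling(tiny_expression_model())
        with pytest.raises(MEStructureError, match="already applied"):
            build_ribosome_coupling(m)


class TestRnapCoupling:
    def test_factor_three_symmetry_with_ribosome(self):
        # a single-gene TU of length 3*l_p gives the same coefficient as
        # the ribosome term for that peptide
        m = tiny_expression_model()
        build_ribosome_coupling(m)
        build_rnap_coupling(m)
        rib = as_coefficient(m.get_reaction("TL_p1").stoichiometry["ribosome"])
        rnp = as_coefficient(m.get_reaction("TX_p1").stoichiometry["rnap"])
        for mu in (0.0, 0.3, 1.0, 2.5):
            assert rnp(mu) == pytest.approx(rib(mu), rel=1e-12)
        assert rnp(1.0) == pytest.approx(-371.06667, rel=1e-6)

    def test_rnap_override_constant(self):
        params = dict(EX_PARAMS)
        m = tiny_expression_model(params=params)
        m.params.c_ribo_rnap = 0.5  # distinct RNAP catalytic constant
        build_rnap_coupling(m)
        rnp = as_coefficient(m.get_reaction("TX_p1").stoichiometry["rnap"])
        assert rnp(0.0) == pytest.approx(-900 * 0.087 / (3 * 0.5), rel=1e-12)


class TestSynthetaseAndTrnaCoupling:
    def make_charging_model(self, c_trna_default=500.0):
        m = tiny_expression_model()
        m.add_species(MESpecies(id="trna_X", role="tRNA"))
        m.add_species(MESpecies(id="ctrna_X", role="charged_tRNA"))
        m.add_species(MESpecies(id="synthX", role="synthetase"))
        m.add_reaction(MEReaction(
            id="CHARGE_X", klass="tRNA_charging",
            stoichiometry={"aaX": -1.0, "ctrna_X": 1.0},
            trna="trna_X", synthetase="synthX"))
        m.params.c_trna_default = c_trna_default
        return m

    def test_synthetase_coefficient_value(self):
        # both rates at the 65 s^-1 default: (1 + mu/234000)*(mu/234000)
        m = self.make_charging_model()
        build_synthetase_coupling(m)
        coeff = as_coefficient(
            m.get_reaction("CHARGE_X").stoichiometry["synthX"])
        assert per_second(65.0) == 234000.0
        assert coeff(1.0) == pytest.approx(
            -(1 + 1 / 234000.0) * (1 / 234000.0), rel=1e-12)
        assert coeff(0.0) == 0.0
        # strictly increasing magnitude in mu
        mus = np.linspace(0.1, 3, 15)
        vals = [-coeff(mu) for mu in mus]
        assert np.all(np.diff(vals) > 0)

    def test_trna_coefficient_value_and_scaling(self):
        m = self.make_charging_model(c_trna_default=1.0)
        build_trna_coupling(m)
        coeff = as_coefficient(
            m.get_reaction("CHARGE_X").stoichiometry["trna_X"])
        # (mu + kappa*r0)/(kappa*c) at mu=1, kappa=4.5, r0=0.087, c=1
        assert coeff(1.0) == pytest.approx(-(1 + 0.3915) / 4.5, rel=1e-6)
        assert coeff(0.0) == pytest.approx(-0.087, rel=1e-12)
        m2 = self.make_charging_model(c_trna_default=2.0)
        build_trna_coupling(m2)
        coeff2 = as_coefficient(
            m2.get_reaction("CHARGE_X").stoichiometry["trna_X"])
        assert coeff2(0.9) == pytest.approx(coeff(0.9) / 2, rel=1e-12)

    def test_missing_annotations_raise(self):
        m = self.make_charging_model()
        m.get_reaction("CHARGE_X").synthetase = None
        with pytest.raises(MEStructureError, match="synthetase"):
            build_synthetase_coupling(m)
        m2 = self.make_charging_model(c_trna_default=None)
        with pytest.raises(MEValidationError, match="c_tRNA"):
            build_trna_coupling(m2)


class TestEnzymeCoupling:
    def two_reaction_model(self):
        m = MEModelSpec()
        m.add_species(MESpecies(id="A", role="metabolite"))
        m.add_species(MESpecies(id="B", role="metabolite"))
        m.add_species(MESpecies(id="biomass", role="biomass_pool"))
        m.add_species(MESpecies(id="E1", role="enzyme_complex"))
        m.add_reaction(MEReaction(id="EX_A", klass="exchange",
                                  stoichiometry={"A": -1.0}, lower=-10.0))
        m.add_reaction(MEReaction(id="R1", klass="metabolic", catalyst="E1",
                                  stoichiometry={"A": -1.0, "biomass": 1.0}))
        m.add_reaction(MEReaction(id="R2", klass="metabolic", catalyst="E1",
                                  stoichiometry={"A": -1.0, "B": 1.0},
                                  lower=0.3, upper=0.3))
        m.add_reaction(MEReaction(id="EX_B", klass="exchange",
                                  stoichiometry={"B": -1.0}))
        m.add_reaction(MEReaction(id="FORM_E1", klass="complex_formation",
                                  stoichiometry={"A": -2.0, "E1": 1.0}))
        m.add_reaction(MEReaction(id="biomass_dilution",
                                  klass="biomass_dilution",
                                  stoichiometry={"biomass": -1.0}))
        return m

    def test_pdh_style_override(self):
        m = self.two_reaction_model()
        m.params.k_eff_overrides[("E1", "R1")] = per_second(1500.0)
        build_enzyme_coupling(m)
        coeff = as_coefficient(m.get_reaction("R1").stoichiometry["E1"])
        assert per_second(1500.0) == 5.4e6
        for mu in (0.2, 1.0, 3.0):
            assert coeff(mu) == pytest.approx(-mu / 5.4e6, rel=1e-12)
        assert coeff(0.0) == 0.0

    def test_shared_enzyme_sums_usage(self):
        from me_allocate.solver import feasible_at_mu

        m = self.two_reaction_model()
        build_enzyme_coupling(m)
        k = m.params.k_eff_default
        mu = 0.8
        ok, fluxes = feasible_at_mu(m, mu)
        assert ok
        expected = (mu / k) * (fluxes["R1"] + fluxes["R2"])
        assert fluxes["FORM_E1"] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_k_eff_rejected(self):
        m = self.two_reaction_model()
        m.params.k_eff_overrides[("E1", "R1")] = -5.0
        with pytest.raises(MEValidationError, match="k_eff"):
            build_enzyme_coupling(m)


class TestMrnaCoupling:
    def test_formation_and_degradation_values(self):
        # kappa=4.5, r0=0.087, c_mRNA=1, k_deg=12: at mu=1 the formation
        # coefficient is (1+0.3915)/13.5 and degradation k_deg-fold larger
        params = dict(EX_PARAMS, c_mrna=1.0)
        m = tiny_expression_model(params=params)
        build_mrna_coupling(m)
        tl = m.get_reaction("TL_p1")
        form = as_coefficient(tl.stoichiometry["mrna_p1"])
        deg = as_coefficient(tl.stoichiometry["coupling_mrna_deg_mrna_p1"])
        assert form(1.0) == pytest.approx(-0.103074, rel=1e-4)
        assert deg(1.0) == pytest.approx(-1.236889, rel=1e-4)
        for mu in (0.25, 1.0, 2.0):
            assert deg(mu) / form(mu) == pytest.approx(12.0 / mu, rel=1e-12)

    def test_stable_mrna_has_zero_degradation_coefficient(self):
        m = tiny_expression_model(kdeg_default=0.0)
        m.params.k_deg = {}
        build_mrna_coupling(m)
        deg = as_coefficient(m.get_reaction("TL_p1")
                             .stoichiometry["coupling_mrna_deg_mrna_p1"])
        assert deg(1.0) == 0.0

    def test_degradation_row_singular_at_zero(self):
        m = build_mrna_coupling(tiny_expression_model())
        with pytest.raises(SingularityError, match="1/mu"):
            evaluate_at_mu(m, 0.0)
        # the mu->0+ limit forces the carrying flux to zero instead
        lp = evaluate_at_mu(m, 0.0, mu_zero_limit=True)
        j = lp.reaction_ids.index("TL_p1")
        assert lp.lower[j] == lp.upper[j] == 0.0


class TestEvaluateAtMu:
    def test_deterministic_and_affine(self, toy_model):
        lp1 = evaluate_at_mu(toy_model, 0.5)
        lp2 = evaluate_at_mu(toy_model, 0.5)
        assert np.array_equal(lp1.S, lp2.S)
        assert np.array_equal(lp1.lower, lp2.lower)
        # an affine coefficient a + b*mu evaluated at mu=2 equals a + 2b
        c = MuCoefficient(const=1.25, mu=-0.5)
        assert c(2.0) == 1.25 - 1.0

    def test_dilution_pinned_to_mu(self, toy_model):
        lp = evaluate_at_mu(toy_model, 0.37)
        j = lp.reaction_ids.index("biomass_dilution")
        assert lp.lower[j] == lp.upper[j] == 0.37

    def test_matches_hand_assembled_matrix(self):
        # <10-reaction fixture assembled by hand at mu=0.5
        m = TestEnzymeCoupling().two_reaction_model()
        m.params.k_eff_default = 100.0
        build_enzyme_coupling(m)
        lp = evaluate_at_mu(m, 0.5)
        S = np.zeros((4, 6))
        sidx = {s: i for i, s in enumerate(lp.species_ids)}
        ridx = {r: j for j, r in enumerate(lp.reaction_ids)}
        S[sidx["A"], ridx["EX_A"]] = -1
        S[sidx["A"], ridx["R1"]] = -1
        S[sidx["A"], ridx["R2"]] = -1
        S[sidx["A"], ridx["FORM_E1"]] = -2
        S[sidx["biomass"], ridx["R1"]] = 1
        S[sidx["biomass"], ridx["biomass_dilution"]] = -1
        S[sidx["B"], ridx["R2"]] = 1
        S[sidx["B"], ridx["EX_B"]] = -1
        S[sidx["E1"], ridx["FORM_E1"]] = 1
        S[sidx["E1"], ridx["R1"]] = -0.5 / 100.0
        S[sidx["E1"], ridx["R2"]] = -0.5 / 100.0
        assert np.allclose(lp.S, S, atol=0, rtol=0)

    def test_coefficients_nonnegative_default_parameterization(self, toy_model):
        # every coupling magnitude is non-negative for mu >= 0
        from me_allocate.core import as_coefficient

        for rxn in toy_model.reactions:
            for sid, coeff in rxn.stoichiometry.items():
                c = as_coefficient(coeff)
                for mu in (0.0, 0.5, 2.0):
                    if c.inv_mu and mu == 0.0:
                        continue
                    assert np.isfinite(c(mu))


class TestSerialization:
    def test_round_trip_bit_identical(self, toy_model):
        js = toy_model.to_json()
        back = MEModelSpec.from_json(js)
        lp1 = evaluate_at_mu(toy_model, 0.7)
        lp2 = evaluate_at_mu(back, 0.7)
        assert np.array_equal(lp1.S, lp2.S)
        assert np.array_equal(lp1.lower, lp2.lower)
        assert np.array_equal(lp1.upper, lp2.upper)
        assert back.to_json() == js

    def test_file_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "model.json"
        toy_model.to_json(str(path))
        back = MEModelSpec.from_json(str(path))
        assert [r.id for r in back.reactions] == \
            [r.id for r in toy_model.reactions]


class TestValidation:
    def test_duplicate_ids_rejected(self):
        m = tiny_expression_model()
        with pytest.raises(MEValidationError, match="duplicate"):
            m.add_species(MESpecies(id="aaX", role="metabolite"))

    def test_unknown_species_in_stoichiometry(self):
        m = tiny_expression_model()
        m.get_reaction("TL_p1").stoichiometry["ghost"] = 1.0
        with pytest.raises(MEValidationError, match="ghost"):
            m.validate()

    def test_exchange_touches_one_species(self):
        m = tiny_expression_model()
        m.get_reaction("EX_aaX").stoichiometry["ntp"] = 1.0
        with pytest.raises(MEValidationError, match="exactly one"):
            m.validate()

    def test_tu_triplet_consistency(self):
        m = tiny_expression_model()
        m.get_species("tu_p1").tu.length = 100  # < 3 * 300
        with pytest.raises(MEValidationError, match="3x"):
            m.validate()

    def test_peptide_composition_must_sum_to_length(self):
        with pytest.raises(MEValidationError, match="sums to"):
            PeptideSpec(id="p", length=10, composition={"a": 3, "b": 3})
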