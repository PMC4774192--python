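"""Metabolic control analysis: control coefficients and elasticities."""

import numpy as np
import pytest

import hepatokin as hk
from hepatokin.mca import (control_coefficients, elasticity_table,
                           epsilon_elasticity, pi_elasticity,
                           relative_elasticities, response_coefficients)
from hepatokin.network import build_network
from hepatokin.simulate import ClampSet

NEAR_EQUILIBRIUM = ["ALD", "EN", "GAPDH", "TPI", "PGK", "PGM"]


@pytest.fixture(scope="module")
def fasted_control(network, fasted_reference):
    return control_coefficients(network, "fasted", fasted_reference.clamps,
                                reference=fasted_reference)


@pytest.fixture(scope="module")
def fed_control(network, fed_reference):
    return control_coefficients(network, "fed", fed_reference.clamps,
                                reference=fed_reference)


class TestControlCoefficients:
    def test_summation_theorem_fasted(self, fasted_control):
        assert fasted_control.summation == pytest.approx(1.0, abs=0.02)

    def test_summation_theorem_fed(self, fed_control):
        assert fed_control.summation == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("rid", NEAR_EQUILIBRIUM)
    def test_near_equilibrium_steps_carry_no_control(self, rid,
                                                     fasted_control,
                                                     fed_control):
        assert abs(fasted_control.table.C[rid]) < 0.005
        assert abs(fed_control.table.C[rid]) < 0.005

    def test_smaller_perturbation_gives_similar_coefficients(
            self, network, fasted_reference):
        coarse = control_coefficients(network, "fasted",
                                      fasted_reference.clamps,
                                      perturbation=0.05,
                                      reference=fasted_reference)
        fine = control_coefficients(network, "fasted",
                                    fasted_reference.clamps,
                                    perturbation=0.005,
                                    reference=fasted_reference)
        for rid in coarse.table.index:
            c5, c05 = coarse.table.C[rid], fine.table.C[rid]
            if abs(c05) > 0.05:
                assert c5 == pytest.approx(c05, rel=0.10), rid
        assert abs(fine.summation - 1.0) < 0.005

    def test_reference_near_set_point_is_rejected(self, network):
        g = hk.set_point(network, "normal", glycogen_fill=0.5)
        with pytest.raises(ValueError, match="floor"):
            control_coefficients(network, "normal",
                                 ClampSet(glucose=g, glycogen_fill=0.5))

    def test_nucleotide_bookkeeping_reactions_have_zero_control(
            self, fasted_control):
        for rid in ("NDK_GTP", "NDK_mito_GTP", "NDK_UTP"):
            assert fasted_control.table.C[rid] == pytest.approx(0.0,
                                                                abs=1e-9)


class TestPiElasticity:
    def test_abundance_elasticity_is_unity(self, network, fasted_reference):
        for rid in ("GK", "PC", "GP", "LacT"):
            pi = pi_elasticity(network, rid, "vmax",
                               fasted_reference.concentrations,
                               gamma=fasted_reference.gamma,
                               alpha=fasted_reference.alpha.get(rid, 1.0))
            assert pi == pytest.approx(1.0, abs=1e-8)

    def test_allosteric_binding_constant_mirrors_effector_elasticity(
            self, network, fed_reference):
        # parameters entering only through X = E/p: epsilon = -pi
        cases = [("PFK1", "Fru26P2"), ("FBP1", "Fru26P2"),
                 ("GP", "Glc"), ("PK", "Fru16P2")]
        for rid, effector in cases:
            pi = pi_elasticity(network, rid, f"ka:{effector}",
                               fed_reference.concentrations,
                               gamma=fed_reference.gamma,
                               alpha=fed_reference.alpha.get(rid, 1.0))
            eps = epsilon_elasticity(network, rid, effector,
                                     fed_reference.concentrations,
                                     gamma=fed_reference.gamma,
                                     alpha=fed_reference.alpha.get(rid, 1.0))
            assert eps == pytest.approx(-pi, rel=1e-3, abs=1e-6), rid

    def test_central_difference_matches_closed_form_on_toy_law(self):
        # single-substrate saturable law: v = V * s / (Km + s);
        # pi wrt Km is -Km/(Km+s) in closed form
        doc = {"model": {},
               "species": {"S": {"init": 0.7}, "Q": {"init": 0.2}},
               "reactions": {"TOY": {"stoichiometry": {"S": -1, "Q": 1},
                                     "substrates": {"S": 0.4},
                                     "vmax_fed": 10.0}}}
        net = build_network(doc)
        conc = {"S": 0.7, "Q": 0.2}
        pi_km = pi_elasticity(net, "TOY", "km:S", conc)
        closed = -0.4 / (0.4 + 0.7)
        assert pi_km == pytest.approx(closed, abs=1e-6)
        assert pi_elasticity(net, "TOY", "vmax", conc) == pytest.approx(1.0)

    def test_zero_rate_normalization_fails(self, network):
        # equilibrium state of the NDK law: forward and reverse terms
        # cancel exactly, so the rate is zero and pi is undefined
        conc = {s: 1.0 for s in network.species_ids}
        conc.update(ATP=1.0, GDP=0.03, ADP=1.0, GTP=0.09)
        with pytest.raises(ZeroDivisionError):
            pi_elasticity(network, "NDK_GTP", "vmax", conc)


@pytest.fixture(scope="module")
def tables(network, fasted_reference, fasted_control):
    elas = elasticity_table(network, fasted_reference)
    return fasted_control, elas


class TestResponseCoefficients:
    def test_abundance_response_equals_control(self, tables):
        control, elas = tables
        resp = response_coefficients(control, elas)
        sub = resp.table[resp.table.parameter == "vmax"]
        np.testing.assert_allclose(sub.R, sub.C, rtol=1e-9)

    def test_zero_control_makes_all_responses_zero(self, tables):
        control, elas = tables
        resp = response_coefficients(control, elas)
        sub = resp.table[resp.table.reaction == "NDK_GTP"]
        assert (sub.R.abs() < 1e-9).all()

    def test_state_mismatch_rejected(self, network, fed_reference,
                                     fasted_control):
        elas_fed = elasticity_table(network, fed_reference)
        with pytest.raises(ValueError, match="different"):
            response_coefficients(fasted_control, elas_fed)

    def test_system_level_finite_difference_oracle(self, network,
                                                   fasted_reference,
                                                   fasted_control):
        # R_ik from C_i * pi_ik vs direct perturbation of the parameter
        # in a full steady-state re-solve
        import dataclasses
        from hepatokin.mca import _perturbed_law
        from hepatokin.simulate import steady_state
        elas = elasticity_table(network, fasted_reference)
        resp = response_coefficients(fasted_control, elas)
        picks = [("LacT", "km:Lac_ext"), ("PC", "km:Pyr_mito"),
                 ("GP", "ka:Glc")]
        h = 0.02
        for rid, pname in picks:
            row = resp.table[(resp.table.reaction == rid)
                             & (resp.table.parameter == pname)]
            if row.empty or abs(row.R.iloc[0]) < 0.01:
                continue
            law0 = network.reactions[rid].rate_law
            network.reactions[rid].rate_law = _perturbed_law(law0, pname,
                                                             1.0 + h)
            try:
                pert = steady_state(network, fasted_reference.clamps,
                                    "fasted",
                                    x0=fasted_reference.concentrations)
            finally:
                network.reactions[rid].rate_law = law0
            direct = ((pert.v_ex - fasted_reference.v_ex)
                      / fasted_reference.v_ex / h)
            assert direct == pytest.approx(row.R.iloc[0], rel=0.05,
                                           abs=0.01), (rid, pname)


class TestRelativeElasticities:
    def test_shares_sum_to_one_for_every_enzyme(self, network,
                                                fed_reference):
        elas = elasticity_table(network, fed_reference)
        for rid in elas.table.reaction.unique():
            shares = relative_elasticities(elas, rid)
            assert shares.sum() == pytest.approx(1.0, rel=1e-9)
            assert (shares >= 0).all()

    def test_single_parameter_enzyme_gets_full_share(self):
        doc = {"model": {},
               "species": {"S": {"init": 1.0}, "Q": {"init": 0.1}},
               "reactions": {"TOY": {"stoichiometry": {"S": -1, "Q": 1},
                                     "substrates": {},
                                     "vmax_fed": 5.0}}}
        net = build_network(doc)
        ref_conc = {"S": 1.0, "Q": 0.1}
        pi = pi_elasticity(net, "TOY", "vmax", ref_conc)
        assert pi == pytest.approx(1.0)

    def test_shares_invariant_under_sign_flips(self, network,
                                               fed_reference):
        elas = elasticity_table(network, fed_reference)
        shares = relative_elasticities(elas, "GK")
        flipped = elas.table.copy()
        flipped.loc[flipped.reaction == "GK", "pi"] *= -1
        import dataclasses
        elas2 = dataclasses.replace(elas, table=flipped)
        shares2 = relative_elasticities(elas2, "GK")
        np.testing.assert_allclose(shares.values, shares2.values)
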