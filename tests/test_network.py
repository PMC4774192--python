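"""Network construction, rate laws, stoichiometry, and unit conversion."""

import numpy as np
import pytest

import hepatokin as hk
from hepatokin.abundance import DEFAULT_ABUNDANCE, scale_vmax
from hepatokin.ratelaws import AllostericTerm
from hepatokin.units import TISSUE_WATER_FACTOR, convert_tissue_units

TABLE3_ROSTER = {
    "ALD", "EN", "FBP1", "FBP2", "GAPDH", "GK", "GlcT", "GlcT_ER", "GP",
    "G6P", "GPI", "G6PT_ER", "GS", "LacT", "LDH", "MDH", "MDH_mito",
    "NDK_UTP", "NDK_GTP", "NDK_mito_GTP", "PC", "PEPCK", "PEPCK_mito",
    "PEPT", "PFK1", "PFK2", "PGK", "PGM", "PK", "PyrT", "PyrMalT", "TPI",
}

PHOSPHO_ENZYMES = {"GP", "GS", "PK", "PFK2", "FBP2"}


class TestBuildNetwork:
    def test_roster_has_32_reactions(self, network):
        assert len(network.reactions) == 32
        assert set(network.reaction_ids) == TABLE3_ROSTER

    def test_all_fig1_metabolites_present(self, network):
        metabolites = {"DHAP", "Fru6P", "Fru16P2", "Fru26P2", "GAP", "Glc",
                       "Glc1P", "Glc6P", "Glyc", "Lac", "Mal", "OA", "P",
                       "PEP", "PP", "Pyr", "UDP_Glc", "13P2G", "2PG", "3PG"}
        assert metabolites <= set(network.species_ids)
        for cofactor in ("NAD", "NADH", "ADP", "ATP"):
            assert network.species[cofactor].clamped

    def test_clamped_species_not_in_dynamic_vector(self, network):
        assert set(network.dynamic_ids).isdisjoint(network.clamped_ids)
        assert "ATP" not in network.dynamic_ids

    def test_stoichiometric_matrix_has_no_zero_row(self, network):
        # brute-force scan: every dynamic species appears in >= 1 reaction
        S = network.stoichiometric_matrix()
        for i, sid in enumerate(network.dynamic_ids):
            hits = sum(1 for rxn in network.reactions.values()
                       if sid in rxn.stoichiometry)
            assert hits > 0, sid
            assert np.any(S[i] != 0), sid

    def test_all_clamped_network_has_empty_dynamic_vector(self, network):
        import yaml, importlib.resources
        doc = yaml.safe_load((importlib.resources.files("hepatokin.data")
                              / "liver_model.yaml").read_text())
        for sdoc in doc["species"].values():
            sdoc["clamped"] = True
        net = hk.build_network(doc)
        assert net.dynamic_ids == []
        assert net.stoichiometric_matrix().shape[0] == 0

    def test_unknown_species_reference_fails(self):
        doc = {"model": {}, "species": {"A": {"init": 1.0}},
               "reactions": {"R1": {"stoichiometry": {"A": -1, "B": 1},
                                    "substrates": {"A": 1.0},
                                    "vmax_fed": 1.0}}}
        with pytest.raises(ValueError, match="R1"):
            hk.build_network(doc)

    def test_missing_parameter_fails_with_reaction_id(self):
        doc = {"model": {}, "species": {"A": {"init": 1.0}},
               "reactions": {"R1": {"stoichiometry": {"A": -1},
                                    "substrates": {"A": 1.0}}}}
        with pytest.raises(KeyError, match="R1"):
            hk.build_network(doc)

    def test_phospho_pairs_only_for_interconvertible_enzymes(self, network):
        have = {rid for rid, r in network.reactions.items()
                if r.rate_law.is_phospho_pair}
        assert have == PHOSPHO_ENZYMES


class TestRates:
    def test_dcdt_matches_per_species_accounting(self, network, rng):
        # stoichiometric consistency against a brute-force tally
        for _ in range(5):
            conc = {s: float(rng.uniform(0.01, 2.0))
                    for s in network.species_ids}
            conc["Glyc"] = float(rng.uniform(10, 400))
            v = network.rates(conc, gamma=0.4)
            S = network.stoichiometric_matrix()
            dcdt = S @ v
            for i, sid in enumerate(network.dynamic_ids):
                manual = sum(
                    coef * v[network.reaction_ids.index(rid)]
                    for rid, rxn in network.reactions.items()
                    for sp, coef in rxn.stoichiometry.items() if sp == sid)
                assert dcdt[i] == pytest.approx(manual, abs=1e-10)

    def test_rates_finite_at_extreme_states(self, network):
        for scale in (1e-6, 1.0, 50.0):
            conc = {s: scale for s in network.species_ids}
            v = network.rates(conc, gamma=0.5)
            assert np.all(np.isfinite(v))

    @pytest.mark.parametrize("rid", sorted(PHOSPHO_ENZYMES))
    def test_rate_affine_in_gamma(self, network, rid, rng):
        conc = {s: float(rng.uniform(0.05, 1.0)) for s in network.species_ids}
        conc["Glyc"] = 200.0
        v0 = network.reaction_rate(rid, conc, gamma=0.0)
        v1 = network.reaction_rate(rid, conc, gamma=1.0)
        vmid = network.reaction_rate(rid, conc, gamma=0.5)
        v03 = network.reaction_rate(rid, conc, gamma=0.3)
        assert vmid == pytest.approx(0.5 * (v0 + v1), rel=1e-12)
        assert v03 == pytest.approx(0.7 * v0 + 0.3 * v1, rel=1e-12)

    def test_gamma_outside_unit_interval_fails(self, network):
        conc = network.initial_concentrations()
        with pytest.raises(ValueError):
            network.reaction_rate("GP", conc, gamma=1.2)
        with pytest.raises(ValueError):
            network.reaction_rate("GP", conc, gamma=-0.1)

    def test_negative_concentration_fails(self, network):
        conc = network.initial_concentrations()
        conc["Glc"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            network.reaction_rate("GK", conc, gamma=0.0)

    def test_rate_scales_linearly_with_abundance(self, network, rng):
        conc = {s: float(rng.uniform(0.05, 1.5))
                for s in network.species_ids}
        conc["Glyc"] = 150.0
        for rid in ("GK", "PC", "GP", "GlcT"):
            v1 = network.reaction_rate(rid, conc, gamma=0.4, alpha=1.0)
            v2 = network.reaction_rate(rid, conc, gamma=0.4, alpha=2.7)
            assert v2 == pytest.approx(2.7 * v1, rel=1e-12)

    def test_thermodynamic_sign_at_extreme_ratios(self, network):
        # reversible steps run forward at product-free states and
        # backward at substrate-free states
        conc = network.initial_concentrations()
        hi, lo = dict(conc), dict(conc)
        hi["Glc6P"], hi["Fru6P"] = 5.0, 1e-9
        lo["Glc6P"], lo["Fru6P"] = 1e-9, 5.0
        assert network.reaction_rate("GPI", hi) > 0
        assert network.reaction_rate("GPI", lo) < 0


class TestAllostericTerm:
    def test_inhibitor_with_zero_effector_is_neutral(self):
        t = AllostericTerm("X", binding_constant=0.5, mode="inhibitor")
        assert t.factor(0.0) == pytest.approx(1.0)

    def test_scale_invariance_of_binding_ratio(self):
        t1 = AllostericTerm("X", binding_constant=0.5, hill=1.7,
                            mode="activator", basal=0.1)
        t2 = AllostericTerm("X", binding_constant=1.0, hill=1.7,
                            mode="activator", basal=0.1)
        assert t1.factor(0.3) == pytest.approx(t2.factor(0.6), rel=1e-14)

    def test_monotone_and_bounded(self, rng):
        grid = np.linspace(0.0, 20.0, 200)
        act = AllostericTerm("X", 0.7, hill=2.0, mode="activator", basal=0.05)
        inh = AllostericTerm("X", 0.7, hill=2.0, mode="inhibitor", basal=0.0)
        fa = [act.factor(x) for x in grid]
        fi = [inh.factor(x) for x in grid]
        assert np.all(np.diff(fa) >= 0) and np.all(np.diff(fi) <= 0)
        assert all(0 < f <= 1 for f in fa + fi)

    def test_elasticity_antisymmetry_in_effector_and_binding_constant(
            self, rng):
        # numeric d(log f)/d(log p) == -d(log f)/d(log E), since the
        # factor depends on them only through X = E/p
        h = 1e-6
        for _ in range(10):
            term = AllostericTerm(
                "X", float(rng.uniform(0.1, 2.0)),
                hill=float(rng.uniform(0.5, 3.0)),
                mode=rng.choice(["activator", "inhibitor"]),
                basal=float(rng.uniform(0.0, 0.5)))
            e = float(rng.uniform(0.05, 5.0))
            el_e = (np.log(term.factor(e * (1 + h)))
                    - np.log(term.factor(e * (1 - h)))) / (2 * h)
            el_p = (np.log(term.factor(e, term.binding_constant * (1 + h)))
                    - np.log(term.factor(e, term.binding_constant * (1 - h)))
                    ) / (2 * h)
            assert el_p == pytest.approx(-el_e, rel=1e-4, abs=1e-7)

    def test_nonpositive_binding_constant_fails(self):
        with pytest.raises(ValueError):
            AllostericTerm("X", binding_constant=0.0)
        t = AllostericTerm("X", binding_constant=1.0)
        with pytest.raises(ValueError):
            t.factor(1.0, binding_constant=-2.0)


class TestAbundanceScaling:
    def test_printed_table_values(self):
        t = DEFAULT_ABUNDANCE
        assert t.alpha("GK", "fasted") == 0.23
        assert t.alpha("GK", "normal") == 0.48
        assert t.alpha("G6P", "diabetic") == 3.54
        assert t.alpha("PEPCK", "fasted") == 2.00
        assert t.range("GK", "fasted") == (0.12, 0.46)
        assert t.range("FBP1", "fasted") is None

    def test_fed_reference_identity(self, network):
        for rid in network.reaction_ids:
            assert scale_vmax(123.4, rid, "fed") == 123.4

    def test_scaling_examples(self):
        assert scale_vmax(100.0, "GK", "fasted") == pytest.approx(23.0)
        assert scale_vmax(100.0, "G6P", "diabetic") == pytest.approx(354.0)

    def test_unknown_state_fails_and_missing_enzyme_defaults_to_one(self):
        with pytest.raises(ValueError):
            scale_vmax(1.0, "GK", "hibernating")
        assert scale_vmax(55.0, "ALD", "fasted") == 55.0

    def test_means_lie_within_ranges(self):
        for enzyme, per_state in DEFAULT_ABUNDANCE.entries.items():
            for state, entry in per_state.items():
                if entry.range is not None:
                    lo, hi = entry.range
                    assert lo <= entry.mean <= hi, (enzyme, state)


class TestUnits:
    def test_stated_conversion_factor(self):
        assert convert_tissue_units(0.46) == pytest.approx(1.067)
        assert convert_tissue_units(0.0) == 0.0

    def test_linearity(self, rng):
        a, b = rng.uniform(0, 5, 2)
        assert convert_tissue_units(a + b) == pytest.approx(
            convert_tissue_units(a) + convert_tissue_units(b))

    def test_negative_amount_fails(self):
        with pytest.raises(ValueError):
            convert_tissue_units(-0.1)

    def test_flux_factor_consistent(self):
        assert TISSUE_WATER_FACTOR == pytest.approx(1.067 / 0.46)
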