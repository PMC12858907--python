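"""Strain-model containers, I/O round-trips, QC, and single-strain FBA."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemcom import (
    FormatError,
    Medium,
    Metabolite,
    ModelError,
    Reaction,
    SolverStatus,
    StrainModel,
    load_strain_model,
    solve_fba,
    strain_trait_summary,
    validate_strain_model,
)
from gemcom.core import is_inorganic, molecular_weight, parse_formula
from gemcom.io import read_medium_tsv, write_medium_tsv, write_sbml, write_toy_json
from gemcom.oracle import oracle_fba
from gemcom.synth import make_toy_strain, random_toy_model


class TestContainers:
    def test_exactly_one_biomass_required(self):
        mets = [Metabolite("a_c", "c")]
        with pytest.raises(ModelError, match="biomass"):
            StrainModel("s", mets, [Reaction("R", {"a_c": -1.0})])

    def test_exchange_flag_must_match_structure(self):
        mets = [Metabolite("a_e", "e"), Metabolite("a_c", "c")]
        rxns = [
            Reaction("T", {"a_e": -1.0, "a_c": 1.0}, is_exchange=True),
            Reaction("BIO", {"a_c": -1.0}, is_biomass=True),
        ]
        with pytest.raises(ModelError, match="exchange"):
            StrainModel("s", mets, rxns)

    def test_undeclared_metabolite_is_format_error(self):
        with pytest.raises(FormatError, match="ghost"):
            StrainModel(
                "s",
                [Metabolite("a_c", "c")],
                [Reaction("BIO", {"a_c": -1.0, "ghost": 1.0}, is_biomass=True)],
            )

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ModelError, match="bound"):
            Reaction("R", {}, lower_bound=5.0, upper_bound=-5.0)

    def test_medium_inorganic_default_rule(self):
        medium = Medium("m", {"glc": 10})
        organic = Metabolite("ace_e", "e", formula="C2H4O2")
        inorganic = Metabolite("pi_e", "e", formula="HPO4")
        unknown = Metabolite("x_e", "e")
        assert medium.amount_for(organic) == 0.0
        assert medium.amount_for(inorganic) == 1000.0
        assert medium.amount_for(unknown) == 0.0
        assert medium.amount_for(Metabolite("glc_e", "e", formula="C6H12O6")) == 10

    def test_formula_parsing_and_weights(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
        assert is_inorganic("HPO4") and not is_inorganic("C2H5NO2")
        assert molecular_weight("C6H12O6") == pytest.approx(180.156, abs=1e-3)
        with pytest.raises(FormatError):
            parse_formula("C6(H2O)6")


class TestIO:
    def test_toy_json_roundtrip_exact(self, tmp_path):
        model = make_toy_strain("d", [("glc", 8.5)], [("ace", 0.5)], biomass_yield=1.25)
        path = tmp_path / "d.json"
        write_toy_json(model, path)
        back = load_strain_model(path, "toy_json")
        assert back.strain_id == model.strain_id
        assert set(back.reactions) == set(model.reactions)
        for rid, rxn in model.reactions.items():
            other = back.reactions[rid]
            assert other.stoichiometry == rxn.stoichiometry
            assert (other.lower_bound, other.upper_bound) == (
                rxn.lower_bound, rxn.upper_bound)
            assert (other.is_exchange, other.is_biomass) == (
                rxn.is_exchange, rxn.is_biomass)

    def test_toy_json_counts(self, tmp_path, t1):
        path = tmp_path / "t1.json"
        write_toy_json(t1, path)
        back = load_strain_model(path)
        assert len(back.metabolites) == 2 and len(back.reactions) == 3

    def test_toy_json_undeclared_metabolite(self, tmp_path):
        payload = {
            "strain_id": "bad",
            "metabolites": [{"id": "a_c", "compartment": "c"}],
            "reactions": [
                {"id": "BIO", "stoich": {"a_c": -1, "ghost": 1}, "biomass": True}
            ],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(FormatError, match="ghost"):
            load_strain_model(path)

    def test_sbml_roundtrip_marks_objective_as_biomass(self, tmp_path):
        model = make_toy_strain("sb", [("glc", 10.0)], biomass_yield=0.9)
        path = tmp_path / "sb.xml"
        write_sbml(model, path)
        back = load_strain_model(path, "sbml_fbc")
        assert back.biomass_reaction.id == "BIOMASS"
        assert set(back.reactions) == set(model.reactions)
        for rid, rxn in model.reactions.items():
            other = back.reactions[rid]
            assert other.stoichiometry == pytest.approx(rxn.stoichiometry)
            assert other.lower_bound == pytest.approx(rxn.lower_bound)
            assert other.is_exchange == rxn.is_exchange

    def test_medium_tsv_roundtrip_and_comments(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "# carbon mix\nmetabolite_id\tamount_mmol_per_gDW\nglc\t50\ncit\t50\n"
        )
        medium = read_medium_tsv(path)
        assert medium.amounts == {"glc": 50.0, "cit": 50.0}
        out = tmp_path / "m2.tsv"
        write_medium_tsv(medium, out)
        assert read_medium_tsv(out).amounts == medium.amounts


class TestQC:
    def test_clean_chain_passes(self, t1):
        report = validate_strain_model(t1)
        assert not report.failures

    def test_leak_reaction_fails_closed_check(self, t1):
        model = t1.copy()
        model.reactions["LEAK"] = Reaction("LEAK", {"glc_c": 1.0}, 0.0, 1000.0)
        report = validate_strain_model(model)
        assert any(
            f.check == "closed_exchange_leak" and f.status == "FAIL" for f in report
        )

    def test_elemental_imbalance_detected(self):
        mets = [
            Metabolite("glc_e", "e", formula="C6H12O6"),
            Metabolite("glc_c", "c", formula="C6H12O6"),
        ]
        rxns = [
            Reaction("EX_glc", {"glc_e": -1.0}, -10, 1000, is_exchange=True),
            Reaction("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, 0, 1000),
            Reaction("DOUBLE", {"glc_c": 1.0}, 0, 1000),  # glc_c -> 2 glc_c net
            Reaction("BIO", {"glc_c": -1.0}, 0, 1000, is_biomass=True),
        ]
        model = StrainModel("bad", mets, rxns)
        report = validate_strain_model(model)
        assert any(
            f.check == "elemental_balance" and f.target == "DOUBLE"
            and f.status == "FAIL" for f in report
        )

    def test_missing_formulas_are_skipped_not_failed(self, t1):
        report = validate_strain_model(t1)
        skipped = [f for f in report if f.status == "SKIP"]
        assert {f.target for f in skipped} == {"T_glc"}


class TestFBA:
    def test_chain_limited_by_medium(self, t1, glc10):
        assert solve_fba(t1, glc10).objective_value == pytest.approx(10.0)

    def test_no_carbon_route_means_zero(self, t1):
        sol = solve_fba(t1, Medium("cit", {"cit": 100}))
        assert sol.status is SolverStatus.OPTIMAL
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_intrinsic_uptake_cap_binds_over_rich_medium(self):
        slow = make_toy_strain("slow", [("glc", 1.0)])
        sol = solve_fba(slow, Medium("rich", {"glc": 100}))
        assert sol.objective_value == pytest.approx(1.0)

    def test_steady_state_and_bounds_hold(self, t1, glc10):
        sol = solve_fba(t1, glc10)
        S, met_ids, rxn_ids = t1.stoichiometric_matrix()
        v = [sol.fluxes[r] for r in rxn_ids]
        residual = abs(S @ v).max()
        assert residual <= 1e-6

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_oracle(self, seed):
        model = random_toy_model(seed)
        medium = Medium("mix", {"glc": 12, "cit": 8, "ace": 5, "fum": 3})
        mine = solve_fba(model, medium).objective_value
        reference = oracle_fba(model, medium)
        assert mine == pytest.approx(reference, abs=1e-6)

    def test_agrees_with_cobrapy(self, glc10):
        """Independent end-to-end route: same model solved by COBRApy/GLPK."""
        from gemcom.io import to_cobra

        model = make_toy_strain("cx", [("glc", 10.0)], [("ace", 0.5)])
        cmodel = to_cobra(model)
        cmodel.reactions.EX_glc.lower_bound = -10.0
        expected = cmodel.optimize().objective_value
        assert solve_fba(model, glc10).objective_value == pytest.approx(
            expected, abs=1e-6
        )

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500), factor=st.floats(1.0, 4.0))
    def test_objective_monotone_in_medium_amount(self, seed, factor):
        """More of any nutrient can never reduce the growth optimum."""
        model = random_toy_model(seed)
        base = Medium("b", {"glc": 8, "cit": 8, "ace": 8, "fum": 8})
        richer = Medium("r", {k: v * factor for k, v in base.amounts.items()})
        lo = solve_fba(model, base).objective_value
        hi = solve_fba(model, richer).objective_value
        assert hi >= lo - 1e-6


class TestTraitSummary:
    def test_counts_and_per_medium_biomass(self, t1, glc10):
        record = strain_trait_summary(t1, [glc10, Medium("cit", {"cit": 10})])
        assert record["n_reactions"] == 3
        assert record["n_exchanges"] == 1
        assert record["n_transports"] == 1
        assert record["biomass[glc10]"] == pytest.approx(10.0)
        assert record["biomass[cit]"] == pytest.approx(0.0, abs=1e-9)

    def test_exchange_count_orders_generalist_over_specialist(self):
        a = make_toy_strain("a", [("glc", 10), ("cit", 10)])
        b = make_toy_strain("b", [("glc", 10)])
        ra = strain_trait_summary(a, [])
        rb = strain_trait_summary(b, [])
        assert ra["n_exchanges"] > rb["n_exchanges"]
        assert set(rb) == {
            "strain_id", "n_reactions", "n_exchanges", "n_transports", "n_metabolites",
        }
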