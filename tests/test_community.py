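"""Community assembly, the four scenario objectives, pFBA, and depletion."""

import pytest

from gemcom import (
    Medium,
    ModelError,
    ObjectiveSpec,
    assemble_community,
    max_target_biomass_profile,
    simulate_depletion,
    solve_community,
    solve_community_pfba,
    solve_fba,
    total_import,
)
from gemcom.core import namespaced
from gemcom.oracle import oracle_community
from gemcom.synth import chain_strain, make_toy_strain, random_oracle_community, random_toy_community


def pool_residual(solution):
    return max(
        abs(sum(pf.per_strain.values()) + pf.imported - pf.exported)
        for pf in solution.pool_flows.values()
    )


class TestAssembly:
    def test_shared_metabolite_appears_once(self, pair, glc10):
        a, b = pair
        community = assemble_community([a, b], glc10)
        assert community.shared_metabolites == ["glc_e", "x_e"]
        biomass = [
            rid for rid in community.strain_ids
        ]
        assert len(biomass) == 2

    def test_duplicate_strain_ids_rejected(self, t1, glc10):
        with pytest.raises(ModelError, match="duplicate"):
            assemble_community([t1, t1.copy()], glc10)

    def test_disjoint_exchange_metabolites_sum(self, glc10):
        a = make_toy_strain("a", [("glc", 10)])
        b = make_toy_strain("b", [("cit", 10)])
        community = assemble_community([a, b], glc10)
        assert len(community.shared_metabolites) == 2

    def test_single_strain_reduces_to_fba(self, t1, glc10):
        community = assemble_community([t1], glc10)
        csol = solve_community(community, ObjectiveSpec.no_limitation())
        fsol = solve_fba(t1, glc10)
        assert csol.objective_value == pytest.approx(fsol.objective_value, abs=1e-9)
        assert csol.fluxes[namespaced("t1", "BIOMASS")] == pytest.approx(
            fsol.fluxes["BIOMASS"], abs=1e-9
        )


class TestScenarios:
    """The worked cross-feeder pair: A (glc -> biomass+X, glc -> X) feeding
    B (2X -> biomass) on 10 glucose."""

    def test_no_limitation_total_15(self, pair_community):
        sol = solve_community(pair_community, ObjectiveSpec.no_limitation())
        assert sol.strain_biomass["A"] == pytest.approx(10.0, abs=1e-6)
        assert sol.strain_biomass["B"] == pytest.approx(5.0, abs=1e-6)
        assert sol.total_biomass == pytest.approx(15.0, abs=1e-6)

    def test_equal_abundance_mu_5(self, pair_community):
        sol = solve_community(pair_community, ObjectiveSpec.equal_abundance())
        assert sol.objective_value == pytest.approx(5.0, abs=1e-6)
        assert sol.strain_biomass["A"] == pytest.approx(sol.strain_biomass["B"], abs=1e-6)

    def test_target_strain_diverts_everything(self, pair_community):
        sol = solve_community(pair_community, ObjectiveSpec.target_strain("B"))
        assert sol.strain_biomass["B"] == pytest.approx(5.0, abs=1e-6)

    def test_defined_abundances_composition(self, pair_community):
        sol = solve_community(
            pair_community,
            ObjectiveSpec.defined_abundances({"A": 0.8, "B": 0.2}),
        )
        assert sol.strain_biomass["A"] == pytest.approx(
            4 * sol.strain_biomass["B"], abs=1e-6
        )

    def test_unknown_target_is_error(self, pair_community):
        with pytest.raises(ModelError, match="unknown target"):
            solve_community(pair_community, ObjectiveSpec.target_strain("Z"))

    def test_coupling_with_obligate_nongrower_returns_zero(self, glc10):
        grower = make_toy_strain("g", [("glc", 10)])
        starved = make_toy_strain("s", [("cit", 10)])
        community = assemble_community([grower, starved], glc10)
        sol = solve_community(community, ObjectiveSpec.equal_abundance())
        assert sol.ok
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_scenario_ordering_equal_vs_free(self, pair_community):
        mu = solve_community(pair_community, ObjectiveSpec.equal_abundance()).objective_value
        free = solve_community(pair_community, ObjectiveSpec.no_limitation()).total_biomass
        assert 2 * mu <= free + 1e-6

    def test_superset_monotonicity(self, pair, glc10):
        a, b = pair
        alone = solve_community(
            assemble_community([a], glc10), ObjectiveSpec.no_limitation()
        ).total_biomass
        both = solve_community(
            assemble_community([a, b], glc10), ObjectiveSpec.no_limitation()
        ).total_biomass
        assert both >= alone - 1e-6

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        models, medium = random_oracle_community(seed)
        community = assemble_community(list(models.values()), medium)
        mine = solve_community(community, ObjectiveSpec.no_limitation()).objective_value
        reference = oracle_community(community, ObjectiveSpec.no_limitation())
        assert mine == pytest.approx(reference, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_on_random_communities(self, seed):
        models, medium = random_toy_community(seed)
        community = assemble_community(list(models.values()), medium)
        sol = solve_community(community, ObjectiveSpec.no_limitation())
        assert sol.ok
        assert pool_residual(sol) <= 1e-6


class TestPFBA:
    def test_unused_carbon_import_vanishes(self, t1):
        medium = Medium("mix", {"glc": 10, "cit": 100})
        community = assemble_community([t1], medium)
        sol = solve_community_pfba(community, ObjectiveSpec.no_limitation())
        assert sol.pool_flows["glc_e"].imported == pytest.approx(10.0, abs=1e-6)

    def test_preserves_optimum_and_never_imports_more(self, pair_community):
        plain = solve_community(pair_community, ObjectiveSpec.no_limitation())
        pfba = solve_community_pfba(pair_community, ObjectiveSpec.no_limitation())
        assert pfba.objective_value == pytest.approx(
            plain.objective_value, rel=1e-6
        )
        assert total_import(pfba) <= total_import(plain) + 1e-6

    def test_import_total_unique_across_equivalent_transporters(self, glc10):
        """Two parallel glucose routes leave the flux split degenerate but
        the minimal import total well-defined."""
        from gemcom.core import Metabolite, Reaction, StrainModel

        model = StrainModel(
            "twin",
            [Metabolite("glc_e", "e"), Metabolite("glc_c", "c")],
            [
                Reaction("EX_glc", {"glc_e": -1.0}, -1000, 1000, is_exchange=True),
                Reaction("T1", {"glc_e": -1.0, "glc_c": 1.0}, 0, 1000),
                Reaction("T2", {"glc_e": -1.0, "glc_c": 1.0}, 0, 1000),
                Reaction("BIO", {"glc_c": -1.0}, 0, 1000, is_biomass=True),
            ],
        )
        community = assemble_community([model], glc10)
        sol = solve_community_pfba(community, ObjectiveSpec.no_limitation())
        assert total_import(sol) == pytest.approx(10.0, abs=1e-6)

    def test_classical_total_flux_mode(self, pair_community):
        sol = solve_community_pfba(
            pair_community, ObjectiveSpec.no_limitation(), mode="total_flux"
        )
        assert sol.total_biomass == pytest.approx(15.0, rel=1e-6)


class TestDepletion:
    def test_chain_consumes_one_unit_per_step(self, t1, glc10):
        community = assemble_community([t1], glc10)
        result = simulate_depletion(
            community, ObjectiveSpec.no_limitation(), dt=1.0, vmax=1.0
        )
        assert result.growth_time == pytest.approx(10.0)
        assert result.total_biomass == pytest.approx(10.0, abs=1e-6)
        assert result.stopped_because == "pool_exhausted"

    def test_zero_medium_stops_immediately(self, t1):
        community = assemble_community([t1], Medium("empty", {}))
        result = simulate_depletion(community, ObjectiveSpec.no_limitation())
        assert result.stopped_because == "no_growth"
        assert result.total_biomass == 0.0
        assert result.trajectory == []

    def test_pools_nonincreasing_without_secretion(self, t1, glc10):
        community = assemble_community([t1], glc10)
        result = simulate_depletion(
            community, ObjectiveSpec.no_limitation(), dt=1.0, vmax=3.0
        )
        glc_series = [step.remaining["glc_e"] for step in result.trajectory]
        assert all(b <= a + 1e-9 for a, b in zip(glc_series, glc_series[1:]))
        assert all(v >= -1e-9 for v in glc_series)

    def test_step_refinement_changes_little(self, t1, glc10):
        community = assemble_community([t1], glc10)
        coarse = simulate_depletion(
            community, ObjectiveSpec.no_limitation(), dt=1.0, vmax=1.0
        )
        fine = simulate_depletion(
            community, ObjectiveSpec.no_limitation(), dt=0.5, vmax=1.0
        )
        one_step = 1.0 * 1.0  # vmax * coarse dt
        assert abs(fine.total_biomass - coarse.total_biomass) <= one_step + 1e-6

    def test_invalid_steps_rejected(self, t1, glc10):
        community = assemble_community([t1], glc10)
        with pytest.raises(ModelError):
            simulate_depletion(community, ObjectiveSpec.no_limitation(), dt=0)
        with pytest.raises(ModelError):
            simulate_depletion(community, ObjectiveSpec.no_limitation(), vmax=-1)

    def test_cumulative_equals_step_sum(self, pair_community):
        result = simulate_depletion(
            pair_community, ObjectiveSpec.no_limitation(), dt=1.0, vmax=2.0
        )
        for sid, total in result.cumulative_biomass.items():
            steps = sum(s.biomass_increment[sid] for s in result.trajectory)
            assert total == pytest.approx(steps, abs=1e-9)


class TestTargetProfile:
    def test_pair_profile_matches_hand_lp(self, pair_community):
        profile = max_target_biomass_profile(pair_community, dt=1.0, vmax=20.0)
        assert profile["A"][0] == pytest.approx(10.0, abs=1e-6)
        assert profile["B"][0] == pytest.approx(5.0, abs=1e-6)

    def test_single_strain_reduction(self, t1, glc10):
        community = assemble_community([t1], glc10)
        profile = max_target_biomass_profile(community, dt=1.0, vmax=20.0)
        assert profile["t1"][0] == pytest.approx(
            solve_fba(t1, glc10).objective_value, abs=1e-6
        )

    def test_nongrower_reports_zero_not_error(self, glc10):
        grower = make_toy_strain("g", [("glc", 10)])
        starved = make_toy_strain("s", [("cit", 10)])
        community = assemble_community([grower, starved], glc10)
        profile = max_target_biomass_profile(community, dt=1.0, vmax=20.0)
        assert profile["s"][0] == pytest.approx(0.0, abs=1e-9)
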