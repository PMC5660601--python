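import numpy as np
import pytest

from nicheflow.community_fba import (
    UnboundedObjectiveError,
    brute_force_exchange_sets,
    build_community,
    curate_auxotrophies,
    enumerate_exchange_sets,
    member_growth_feasible,
    solve_fba,
    summarize_exchanges,
)
from nicheflow.model_io import MediumDefinition, Reaction, SpeciesModel
from nicheflow.synthetic_data import CommunitySimSpec, _build_toy_species


def chain_model(uptake_cap=10.0):
    """A_e -> A_c -> B_c -> biomass, all 1:1."""
    return SpeciesModel(
        species_id="chain",
        reactions=[
            Reaction("EX_a", {"a_e": -1.0}, lb=-uptake_cap, ub=1000),
            Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}),
            Reaction("CONV", {"a_c": -1.0, "b_c": 1.0}),
            Reaction("BIOMASS", {"b_c": -1.0}),
        ],
        biomass_reaction_id="BIOMASS",
    )


class TestSolveFba:
    def test_linear_chain_max_biomass_equals_uptake_cap(self):
        sol = solve_fba(chain_model(uptake_cap=10.0))
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(10.0)

    def test_closed_medium_gives_zero_growth(self):
        sol = solve_fba(chain_model(), medium=MediumDefinition({}))
        assert sol.objective == pytest.approx(0.0)

    def test_unbounded_objective_raises(self):
        model = SpeciesModel(
            species_id="loop",
            reactions=[
                Reaction("SRC", {"a_c": 1.0}, lb=0, ub=np.inf),
                Reaction("BIOMASS", {"a_c": -1.0}, lb=0, ub=np.inf),
            ],
            biomass_reaction_id="BIOMASS",
        )
        with pytest.raises(UnboundedObjectiveError):
            solve_fba(model)

    def test_agrees_with_cobra_formulation(self):
        """Independent LP formulation of the same constraints via cobrapy."""
        cobra = pytest.importorskip("cobra")
        rng = np.random.default_rng(7)
        model = chain_model()
        # randomize some bounds to make the check non-trivial
        caps = rng.uniform(2, 20, size=2)
        model.reactions[0] = model.reactions[0].with_bounds(-caps[0], 1000)
        model.reactions[2] = model.reactions[2].with_bounds(0, caps[1])
        ours = solve_fba(model).objective

        cm = cobra.Model("oracle")
        mets = {m: cobra.Metabolite(m) for m in model.metabolites}
        for r in model.reactions:
            cr = cobra.Reaction(r.id)
            cm.add_reactions([cr])
            cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
            cr.bounds = (r.lb, r.ub)
        cm.objective = "BIOMASS"
        theirs = cm.optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestCuration:
    def lab_model(self):
        """Can synthesize gln from carbon; biomass needs gln."""
        return SpeciesModel(
            species_id="lab",
            reactions=[
                Reaction("EX_carbon", {"carbon_e": -1.0}, lb=-10, ub=0),
                Reaction("T_carbon", {"carbon_e": -1.0, "carbon_c": 1.0}),
                Reaction("GLN_SYN", {"carbon_c": -1.0, "gln_c": 1.0}),
                Reaction("BIOMASS", {"gln_c": -1.0}),
            ],
            biomass_reaction_id="BIOMASS",
        )

    def test_blocking_only_synthesis_route_abolishes_growth(self):
        medium = MediumDefinition({"carbon_e": 10.0})
        base = self.lab_model()
        assert solve_fba(base, medium=medium).objective > 1
        curated = curate_auxotrophies(base, block_reactions=["GLN_SYN"])
        assert solve_fba(curated, medium=medium).objective == pytest.approx(0.0)
        # input untouched
        assert base.reaction("GLN_SYN").ub == 1000

    def test_added_uptake_plus_medium_restores_growth(self):
        curated = curate_auxotrophies(
            self.lab_model(), add_uptakes=["gln"], block_reactions=["GLN_SYN"]
        )
        medium = MediumDefinition({"carbon_e": 10.0, "gln_e": 5.0})
        assert solve_fba(curated, medium=medium).objective == pytest.approx(5.0)

    def test_blocked_reactions_carry_zero_flux(self):
        curated = curate_auxotrophies(self.lab_model(), block_reactions=["GLN_SYN"])
        r = curated.reaction("GLN_SYN")
        assert (r.lb, r.ub) == (0.0, 0.0)

    def test_unknown_block_ids_listed(self):
        with pytest.raises(KeyError, match="NOPE"):
            curate_auxotrophies(self.lab_model(), block_reactions=["NOPE", "GLN_SYN"])


class TestBuildCommunity:
    def test_single_species_feasibility_matches_monoculture(self):
        model = chain_model()
        medium = MediumDefinition({"a_e": 10.0})
        community = build_community([model], medium, mu_min=1.0)
        mono = solve_fba(model, medium=medium)
        assert member_growth_feasible(community, "chain", 1.0)
        assert member_growth_feasible(community, "chain", mono.objective - 1e-6)
        assert not member_growth_feasible(community, "chain", mono.objective + 1.0)

    def test_disjoint_species_create_no_transfer_variables(self):
        a = chain_model()
        b = SpeciesModel(
            species_id="other",
            reactions=[
                Reaction("EX_x", {"x_e": -1.0}, lb=-10, ub=1000),
                Reaction("T_x", {"x_e": -1.0, "x_c": 1.0}),
                Reaction("BIOMASS", {"x_c": -1.0}),
            ],
            biomass_reaction_id="BIOMASS",
        )
        community = build_community([a, b], MediumDefinition({"a_e": 10, "x_e": 10}))
        assert community.pair_candidates == []

    def test_duplicate_species_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_community([chain_model(), chain_model()], MediumDefinition({}))


class TestMemberFeasibility:
    def test_receiver_alone_infeasible_in_restricted_medium(self, two_species):
        (models, medium, _truth), spec = two_species
        receiver = [m for m in models if m.species_id == "receiver"]
        community = build_community(receiver, medium)
        assert not member_growth_feasible(community, "receiver", spec.mu_min)

    def test_receiver_feasible_with_donor_present(self, two_species):
        (models, medium, _truth), spec = two_species
        community = build_community(models, medium)
        assert member_growth_feasible(community, "receiver", spec.mu_min)

    def test_mu_zero_always_feasible(self, two_species):
        (models, medium, _), _ = two_species
        community = build_community([m for m in models if m.species_id == "receiver"], medium)
        assert member_growth_feasible(community, "receiver", 0.0)


class TestEnumeration:
    def test_single_obligate_exchange_found_and_minimal(self, two_species):
        (models, medium, truth), spec = two_species
        community = build_community(models, medium, mu_min=spec.mu_min)
        solutions = enumerate_exchange_sets(community)
        assert solutions.community_feasible
        assert all(truth <= set(sol.transfers) for sol in solutions)
        assert solutions[0].transfers == frozenset(truth)
        assert solutions[0].is_minimal

    def test_no_obligate_exchange_returns_single_empty_set(self):
        spec = CommunitySimSpec(
            biomass_requirements={"a": ["nh4"], "b": ["nh4"]},
            medium_metabolites={"nh4": 10.0},
        )
        from nicheflow.synthetic_data import generate_toy_community

        models, medium, truth = generate_toy_community(spec)
        assert truth == set()
        community = build_community(models, medium, mu_min=spec.mu_min)
        solutions = enumerate_exchange_sets(community, minimal_only=True)
        assert len(solutions) == 1
        assert solutions[0].transfers == frozenset()

    @pytest.mark.parametrize("fixture", ["two_species", "three_species"])
    def test_milp_matches_brute_force_minimal_sets(self, fixture, request):
        (models, medium, truth), spec = request.getfixturevalue(fixture)
        community = build_community(models, medium, mu_min=spec.mu_min)
        _, minimal = brute_force_exchange_sets(community, mu_min=spec.mu_min)
        solutions = enumerate_exchange_sets(community, minimal_only=True)
        assert {sol.transfers for sol in solutions} == set(minimal)
        # designed exchanges obligate: in every feasible set
        feasible, _ = brute_force_exchange_sets(community, mu_min=spec.mu_min)
        assert all(truth <= S for S in feasible)

    def test_member_order_does_not_change_solutions(self, three_species):
        (models, medium, _), spec = three_species
        sols_fwd = enumerate_exchange_sets(
            build_community(models, medium, mu_min=spec.mu_min)
        )
        sols_rev = enumerate_exchange_sets(
            build_community(models[::-1], medium, mu_min=spec.mu_min)
        )
        assert {s.transfers for s in sols_fwd} == {s.transfers for s in sols_rev}

    def test_medium_relaxation_never_removes_feasible_sets(self, two_species):
        (models, medium, _), spec = two_species
        community = build_community(models, medium, mu_min=spec.mu_min)
        feasible_before, _ = brute_force_exchange_sets(community, mu_min=spec.mu_min)
        richer = medium.with_added("bonus_e", 10.0)
        community2 = build_community(models, richer, mu_min=spec.mu_min)
        feasible_after, _ = brute_force_exchange_sets(community2, mu_min=spec.mu_min)
        assert set(feasible_before) <= set(feasible_after)

    def test_infeasible_community_flagged(self):
        starving = SpeciesModel(
            species_id="s",
            reactions=[
                Reaction("EX_a", {"a_e": -1.0}, lb=-10, ub=0),
                Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}),
                Reaction("BIOMASS", {"a_c": -1.0}),
            ],
            biomass_reaction_id="BIOMASS",
        )
        community = build_community([starving], MediumDefinition({}), mu_min=0.01)
        solutions = enumerate_exchange_sets(community)
        assert len(solutions) == 0
        assert not solutions.community_feasible


class TestSummarize:
    def test_empty_input_gives_empty_table(self):
        assert summarize_exchanges([]).empty

    def test_obligate_exchange_has_fraction_one(self, two_species):
        (models, medium, truth), spec = two_species
        community = build_community(models, medium, mu_min=spec.mu_min)
        table = summarize_exchanges(enumerate_exchange_sets(community))
        assert set(table["fraction"]) == {1.0}
        rows = {tuple(r) for r in table[["metabolite", "donor", "receiver"]].itertuples(index=False)}
        assert rows == truth

    def test_alternative_donors_split_fractions(self):
        # two donors can each feed the receiver; neither is obligate alone
        spec = CommunitySimSpec(
            biomass_requirements={"d1": ["nh4"], "d2": ["nh4"], "recv": ["gln", "nh4"]},
            designed_exchanges=[("gln", "d1", "recv"), ("gln", "d2", "recv")],
            medium_metabolites={"nh4": 10.0},
        )
        models = [_build_toy_species(spec, s) for s in spec.biomass_requirements]
        medium = MediumDefinition({"carbon_e": 10.0, "nh4_e": 10.0})
        community = build_community(models, medium, mu_min=spec.mu_min)
        solutions = enumerate_exchange_sets(community, minimal_only=True)
        table = summarize_exchanges(solutions)
        assert len(solutions) == 2
        assert (table["fraction"] < 1).all()
        assert table["fraction"].sum() >= 1
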