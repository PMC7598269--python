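"""Structure of the generated microstate network."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lxml import etree

from pghs1net.network import (
    DAMAGE_SINK,
    METABOLITES,
    CoxSiteState,
    HemeState,
    NetworkError,
    NetworkPolicy,
    ParameterSet,
    Profile,
    SpeciesKind,
    TyrState,
    build_network,
    enumerate_species,
    export_network,
    import_network_json,
    instantiate_reactions,
    validate_network,
)

#: Exhaustive template application over the default parameters yields this
#: many reactions (regression value frozen after the first enumeration).
N_REACTIONS_COMPLETE = 83
N_REACTIONS_PAPER = 55


class TestSpecies:
    def test_counts_and_kinds(self):
        species = enumerate_species()
        assert len(species) == 28
        kinds = [s.kind for s in species]
        assert kinds.count(SpeciesKind.CATALYTIC) == 24
        assert kinds.count(SpeciesKind.COX_DEAD) == 3
        assert kinds.count(SpeciesKind.FIE) == 1

    def test_catalytic_compositions_unique_and_exhaustive(self):
        comps = {
            (s.heme, s.tyr, s.cox_site)
            for s in enumerate_species()
            if s.kind is SpeciesKind.CATALYTIC
        }
        assert len(comps) == 24  # 3 x 2 x 4, no duplicates

    def test_canonical_labels(self, model):
        e1 = model.species_by_label("E1")
        assert (e1.heme, e1.tyr, e1.cox_site) == (
            HemeState.FE3_PP, TyrState.TYR, CoxSiteState.EMPTY,
        )
        e9 = model.species_by_label("E9")
        assert (e9.heme, e9.tyr, e9.cox_site) == (
            HemeState.FE4_PP, TyrState.TYR_RAD, CoxSiteState.AA_BOUND,
        )

    def test_half_the_catalytic_set_carries_the_tyrosyl_radical(self):
        tyr_rad = [
            s for s in enumerate_species()
            if s.kind is SpeciesKind.CATALYTIC and s.tyr is TyrState.TYR_RAD
        ]
        assert len(tyr_rad) == 12

    def test_only_one_heme_state_is_radical_bearing(self):
        assert [h for h in HemeState if h.radical_bearing] == [HemeState.FE4_PPRAD]


class TestReactions:
    def test_frozen_reaction_counts(self, model, paper_model):
        assert len(model.reactions) == N_REACTIONS_COMPLETE
        assert len(paper_model.reactions) == N_REACTIONS_PAPER

    def test_paper_set_is_subset_of_complete_set(self, model, paper_model):
        complete = {(r.template_id, r.reactant, r.product) for r in model.reactions}
        enumerated = {
            (r.template_id, r.reactant, r.product) for r in paper_model.reactions
        }
        assert enumerated < complete

    def test_aa_binding_rates(self, model):
        r1 = model.reaction_by_paper_number(1)
        assert (r1.reactant, r1.product) == ("E5", "E9")
        assert r1.kf == pytest.approx(690.0)
        assert r1.kr == pytest.approx(69.0)  # koff = kon * Kd

    def test_electron_transfer_is_slow_only_with_arachidonate_bound(self, model):
        r13 = model.reaction_by_paper_number(13)  # E2 -> E5, empty site
        r18 = model.reaction_by_paper_number(18)  # E10 -> E9, AA in site
        assert (r13.reactant, r13.kf) == ("E2", pytest.approx(310.0))
        assert (r18.reactant, r18.kf) == ("E10", pytest.approx(1.1))
        # a PGG2 radical in the site does not hinder the transfer
        g10_from_e7 = [
            r for r in model.reactions
            if r.template_id == "G10" and r.reactant == "E7"
        ]
        assert g10_from_e7[0].kf == pytest.approx(310.0)

    def test_only_binding_templates_are_reversible(self, model):
        for r in model.reactions:
            assert r.reversible == (r.template_id in ("G1", "G2"))

    def test_enzyme_moiety_closure(self, model):
        labels = set(model.species_labels())
        for r in model.reactions:
            assert r.reactant in labels and r.product in labels

    def test_rc_consumption_pairs_with_oc_production(self, model):
        for r in model.reactions:
            if r.metabolites.get("RC", 0) < 0:
                assert r.metabolites["RC"] == -1
                assert r.metabolites.get("OC", 0) == 1

    def test_no_inactivation_routes_when_rates_are_zero(self):
        """With all kin constants at zero no catalytic species can reach FIE
        or the COX-dead pool (the dead pool's internal peroxidase cycle
        remains, but nothing feeds it)."""
        params = ParameterSet.default().with_values(kin=0.0, kin1=0.0, kin2=0.0)
        reactions = instantiate_reactions(enumerate_species(), params)
        assert all(r.product != "FIE" for r in reactions)
        catalytic = {f"E{i}" for i in range(1, 25)}
        assert all(
            r.product not in {"D1", "D2", "D3"}
            for r in reactions
            if r.reactant in catalytic
        )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(shuffle_seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_template_application_is_order_independent(self, shuffle_seed):
        params = ParameterSet.default()
        species = enumerate_species()
        shuffled = species[:]
        random.Random(shuffle_seed).shuffle(shuffled)
        a = instantiate_reactions(species, params)
        b = instantiate_reactions(shuffled, params)
        assert a == b

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet.default().with_values(k2=-1.0)

    def test_unknown_policy_rejected(self):
        with pytest.raises(NetworkError):
            instantiate_reactions(
                enumerate_species(), ParameterSet.default(), policy="banana"
            )

    def test_adrenaline_profile_swaps_the_pox_block(self):
        pox = ParameterSet.default(Profile.ADRENALINE_H2O2)
        assert (pox.k5, pox.k6, pox.k7, pox.k8) == (0.06, 0.001, 0.001, 0.001)
        # the COX block is untouched
        assert pox.k2 == ParameterSet.default().k2


class TestValidation:
    def test_default_model_is_clean(self, model):
        diag = validate_network(model)
        assert diag.ok
        assert diag.unreachable_from_e1 == []

    def test_fie_is_absorbing(self, model):
        assert all(r.reactant != "FIE" for r in model.reactions)

    def test_e1_reaches_e12(self, model):
        import networkx as nx

        g = nx.DiGraph()
        for r in model.reactions:
            g.add_edge(r.reactant, r.product)
        assert nx.has_path(g, "E1", "E12")

    def test_removing_cox_death_makes_dead_states_unreachable(self, model):
        from dataclasses import replace as dc_replace

        from pghs1net.network import NetworkModel

        kept = tuple(
            dc_replace(r, index=i)
            for i, r in enumerate(r for r in model.reactions if r.template_id != "S3")
        )
        pruned = NetworkModel(model.species, kept, model.params, model.policy)
        diag = validate_network(pruned)
        assert {"D1", "D2", "D3"} <= set(diag.unreachable_from_e1)


class TestExport:
    def test_json_round_trip_is_exact(self, model):
        doc = export_network(model, "json")
        back = import_network_json(doc)
        assert back.species == model.species
        assert back.reactions == model.reactions
        assert back.params == model.params
        assert back.policy == model.policy
        assert export_network(back, "json") == doc

    def test_graphml_has_species_and_metabolite_nodes(self, model):
        import io

        import networkx as nx

        doc = export_network(model, "graphml")
        g = nx.read_graphml(io.StringIO(doc))
        assert g.number_of_nodes() == 28 + len(METABOLITES)

    def test_sbml_is_structurally_valid(self, model):
        doc = export_network(model, "sbml")
        root = etree.fromstring(doc.encode())
        ns = "{http://www.sbml.org/sbml/level3/version2/core}"
        assert root.tag == f"{ns}sbml"
        assert root.get("level") == "3" and root.get("version") == "2"
        mdl = root.find(f"{ns}model")
        species = mdl.find(f"{ns}listOfSpecies")
        assert len(species) == 28 + len(METABOLITES) + 1  # + damage sink
        reactions = mdl.find(f"{ns}listOfReactions")
        assert len(reactions) == len(model.reactions)
        mathml = "{http://www.w3.org/1998/Math/MathML}"
        assert all(
            rx.find(f"{ns}kineticLaw/{mathml}math") is not None for rx in reactions
        )

    def test_unsupported_format_rejected(self, model):
        with pytest.raises(ValueError):
            export_network(model, "sbtab")
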