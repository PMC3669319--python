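"""Species/community model construction, partitioning and validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfba.model import (
    Metabolite,
    MetaboliteRole,
    ModelError,
    Reaction,
    ReactionKind,
    assemble_community,
    build_species_model,
    parse_formula,
    partition_species_matrix,
    validate_community,
)
from cfba.fixtures import make_random_community, make_toy_consortium
from cfba.lp import maximize_growth_at_fractions
from cfba.model import FractionVector

I = MetaboliteRole.INTRACELLULAR
X = MetaboliteRole.CROSSFED_EXTRACELLULAR
U = MetaboliteRole.UNIQUE_EXTRACELLULAR


def tiny_species(species_id="s"):
    mets = [Metabolite("S_e", role=U), Metabolite("p", role=I)]
    rxns = [
        Reaction("t", {"S_e": -1, "p": 1}, upper_bound=1.0),
        Reaction("biomass", {"p": -0.1}, kind=ReactionKind.BIOMASS),
    ]
    return build_species_model(species_id, mets, rxns)


class TestBuildSpeciesModel:
    def test_minimal_chain_is_valid(self):
        sp = tiny_species()
        assert sp.N.shape == (2, 1)
        assert sp.reactions[0].kind is ReactionKind.UNIQUE_TRANSPORT
        assert sp.c[sp.metabolite_index()["p"]] == -0.1

    def test_toy_species_has_four_intracellular_processes(self, toy):
        sp = toy.get_species("glc_consumer")
        intra = [r for r in sp.reactions if r.kind is ReactionKind.INTRACELLULAR]
        # catabolism, respiration, product formation, anabolism (+ maintenance)
        assert {"cat", "res", "pro", "ana"} <= {r.id for r in intra}

    def test_two_biomass_reactions_rejected(self):
        mets = [Metabolite("p", role=I)]
        rxns = [
            Reaction("b1", {"p": -1}, kind=ReactionKind.BIOMASS),
            Reaction("b2", {"p": -1}, kind=ReactionKind.BIOMASS),
        ]
        with pytest.raises(ModelError, match="two biomass"):
            build_species_model("s", mets, rxns)

    def test_missing_biomass_rejected(self):
        with pytest.raises(ModelError, match="no biomass"):
            build_species_model("s", [Metabolite("p", role=I)],
                                [Reaction("r", {"p": 1})])

    def test_unknown_metabolite_rejected(self):
        rxns = [
            Reaction("r", {"ghost": 1}),
            Reaction("biomass", {}, kind=ReactionKind.BIOMASS),
        ]
        with pytest.raises(ModelError, match="unknown metabolite"):
            build_species_model("s", [Metabolite("p", role=I)], rxns)

    def test_duplicate_reaction_id_rejected(self):
        mets = [Metabolite("p", role=I)]
        rxns = [
            Reaction("r", {"p": 1}),
            Reaction("r", {"p": -1}),
            Reaction("biomass", {"p": -1}, kind=ReactionKind.BIOMASS),
        ]
        with pytest.raises(ModelError, match="duplicate reaction"):
            build_species_model("s", mets, rxns)

    def test_declared_kind_must_match_stoichiometry(self):
        mets = [Metabolite("p", role=I), Metabolite("C_e", role=X)]
        rxns = [
            Reaction("t", {"C_e": -1, "p": 1}, kind=ReactionKind.INTRACELLULAR),
            Reaction("biomass", {"p": -1}, kind=ReactionKind.BIOMASS),
        ]
        with pytest.raises(ModelError, match="implies crossfeed_transport"):
            build_species_model("s", mets, rxns)


class TestPartition:
    def test_crossfeed_transports_land_in_crossfeed_block(self, toy):
        sp = toy.get_species("glc_consumer")
        part = partition_species_matrix(sp)
        cf_cols = [sp.reactions[j].id for j in part.col_perm][
            part.n_cols[0]: part.n_cols[0] + part.n_cols[1]
        ]
        assert set(cf_cols) == {"t_succ", "t_nh3"}
        # cross-feeding transports touch the cross-fed extracellular rows
        assert part.block("crossfed", "crossfeed").nnz > 0
        assert part.block("crossfed", "intracellular").nnz == 0

    def test_no_crossfeeds_means_empty_crossfeed_blocks(self):
        sp = tiny_species()
        part = partition_species_matrix(sp)
        assert part.n_cols[1] == 0
        assert part.block("intracellular", "intracellular").shape[1] == 0
        # single transport column is the whole unique block
        assert part.n_cols[2] == 1

    def test_unpermute_recovers_original_matrix(self, toy):
        for sp in toy.species:
            part = partition_species_matrix(sp)
            assert (part.unpermuted() != sp.N).nnz == 0

    def test_blocks_tile_exactly(self, toy):
        sp = toy.get_species("n_fixer")
        part = partition_species_matrix(sp)
        total = sum(
            part.block(r, c).nnz
            for r in ("intracellular", "crossfed", "unique")
            for c in ("intracellular", "crossfeed", "unique")
        )
        assert total == sp.N.nnz


class TestAssembleCommunity:
    def test_disjoint_union_is_block_diagonal(self):
        a, b = tiny_species("a"), tiny_species("b")
        # same extracellular id in both without crossfed declaration -> error
        with pytest.raises(ModelError, match="must be declared cross-fed"):
            assemble_community([a, b], crossfed_ids=[])

        b2 = build_species_model("b", [
            Metabolite("T_e", role=U), Metabolite("p", role=I)
        ], [
            Reaction("t", {"T_e": -1, "p": 1}, upper_bound=1.0),
            Reaction("biomass", {"p": -0.1}, kind=ReactionKind.BIOMASS),
        ])
        cm = assemble_community([tiny_species("a"), b2], crossfed_ids=[])
        # rows: 2 intracellular + 2 unique extracellular
        assert len(cm.row_keys) == 4
        # columns: 2 reactions + 2 biomass + 0 exchanges
        assert len(cm.col_keys) == 4
        # species blocks share no rows
        dense = cm.C.toarray()
        a_cols = [i for i, k in enumerate(cm.col_keys) if "a__" in k or k.endswith("__a")]
        b_cols = [i for i, k in enumerate(cm.col_keys) if "b__" in k or k.endswith("__b")]
        rows_a = {r for c in a_cols for r in np.nonzero(dense[:, c])[0]}
        rows_b = {r for c in b_cols for r in np.nonzero(dense[:, c])[0]}
        assert rows_a.isdisjoint(rows_b)

    def test_crossfed_row_is_shared_and_gets_overflow(self, toy):
        succ_row = toy.row_keys.index("Succ_e")
        cols = set(np.nonzero(toy.C.toarray()[succ_row])[0])
        names = {toy.col_keys[c] for c in cols}
        assert "glc_consumer__t_succ" in names      # producer transport
        assert "n_fixer__t_succ" in names           # consumer transport
        assert "EX_Succ_e" in names                 # overflow exchange column
        ex = toy.get_exchange("EX_Succ_e")
        assert ex.lower_bound == 0.0                # efflux-only by default

    def test_unknown_crossfed_id_rejected(self):
        with pytest.raises(ModelError, match="unknown to every species"):
            assemble_community([tiny_species()], crossfed_ids=["ghost_e"])

    def test_exchange_on_intracellular_rejected(self):
        ex = Reaction("EX_p", {"p": -1}, kind=ReactionKind.ENV_EXCHANGE)
        with pytest.raises(ModelError, match="not an extracellular"):
            assemble_community([tiny_species()], crossfed_ids=[],
                               env_exchanges=[ex])

    def test_stoichiometric_content_conserved(self, toy):
        # every nonzero of each per-species N appears exactly once in C
        n_from_species = sum(sp.N.nnz for sp in toy.species)
        n_biomass = sum(np.count_nonzero(sp.c) for sp in toy.species)
        assert toy.C.nnz == n_from_species + n_biomass + len(toy.env_exchanges)

    def test_assembly_order_invariance(self):
        cm1 = make_random_community(3, seed=7)
        sp = [s.copy() for s in cm1.species]
        cm2 = assemble_community(
            [sp[2], sp[0], sp[1]], cm1.crossfed_metabolites,
            [e.copy() for e in cm1.env_exchanges], X_T=cm1.X_T,
        )
        assert cm1.C.nnz == cm2.C.nnz
        f = {s: 0.25 for s in cm1.species_ids}
        f[cm1.species_ids[0]] = 0.5
        s1 = maximize_growth_at_fractions(cm1, FractionVector(dict(f)))
        s2 = maximize_growth_at_fractions(cm2, FractionVector(dict(f)))
        assert s1.status == s2.status
        if s1.optimal:
            assert s1.mu == pytest.approx(s2.mu, abs=1e-9)


class TestValidation:
    def test_toy_fixture_validates_clean(self, toy):
        report = validate_community(toy)
        assert report.ok, report.issues
        assert report.n_reactions_balance_checked > 0

    def test_dead_end_crossfed_flagged(self):
        mets = [Metabolite("p", role=I), Metabolite("W_e", role=X),
                Metabolite("S_e", role=U)]
        rxns = [
            Reaction("t", {"S_e": -1, "p": 1}, upper_bound=1.0),
            Reaction("w", {"p": -1, "W_e": 1}, upper_bound=1.0),
            Reaction("biomass", {"p": -1}, kind=ReactionKind.BIOMASS),
        ]
        sp = build_species_model("s", mets, rxns)
        cm = assemble_community([sp], crossfed_ids=["W_e"])
        # remove the auto-added overflow to create the dead end
        cm.env_exchanges = [e for e in cm.env_exchanges if e.id != "EX_W_e"]
        report = validate_community(cm)
        assert not report.ok
        assert any("dead end" in i for i in report.issues)

    def test_elemental_imbalance_flagged(self):
        mets = [
            Metabolite("g", role=I, formula="C6H12O6"),
            Metabolite("pyr", role=I, formula="C3H4O3"),
            Metabolite("S_e", role=U, formula="C6H12O6"),
        ]
        rxns = [
            Reaction("t", {"S_e": -1, "g": 1}, upper_bound=1.0),
            Reaction("split", {"g": -1, "pyr": 2}, upper_bound=1.0),  # 4 H short
            Reaction("biomass", {"pyr": -1}, kind=ReactionKind.BIOMASS),
        ]
        cm = assemble_community([build_species_model("s", mets, rxns)], [])
        report = validate_community(cm)
        assert any("element H imbalanced by -4" in i for i in report.issues)

    def test_generated_fixtures_validate(self):
        for seed in (0, 1, 2):
            assert validate_community(make_random_community(3, seed=seed)).ok
        assert validate_community(make_toy_consortium()).ok


@given(st.dictionaries(
    st.sampled_from(["C", "H", "O", "N", "P", "S", "Fe"]),
    st.one_of(st.integers(1, 40).map(float),
              st.floats(0.1, 9.9).map(lambda x: round(x, 2))),
    min_size=1, max_size=5,
))
@settings(max_examples=60, derandomize=True)
def test_formula_parse_roundtrip(elements):
    text = "".join(
        f"{el}{int(n) if float(n).is_integer() else n:g}"
        if not (n == 1.0) else el
        for el, n in elements.items()
    )
    assert parse_formula(text) == pytest.approx(elements)
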