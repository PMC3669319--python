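"""Balanced-growth LP: closed forms, statuses, scaling, flux ranges."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import frac
from cfba.fixtures import (
    ToyConsortiumParams,
    make_minimal_pair,
    make_single_species,
    make_toy_consortium,
)
from cfba.lp import (
    LinearConstraint,
    Objective,
    SolutionStatus,
    UnboundedModelError,
    build_lp,
    flux_ranges_at_optimum,
    maximize_growth_at_fractions,
    optimize_flux_at_growth,
)
from cfba.model import (
    FractionVector,
    Metabolite,
    MetaboliteRole,
    ModelError,
    Reaction,
    ReactionKind,
    assemble_community,
    build_species_model,
)

I, U = MetaboliteRole.INTRACELLULAR, MetaboliteRole.UNIQUE_EXTRACELLULAR


class TestClosedForms:
    def test_single_species_mu_is_bound_over_biomass_coefficient(self):
        # biomass needs 0.1 mmol substrate per gDW, uptake capped at 1
        cm = make_single_species(yield_coeff=10.0, uptake_bound=1.0)
        sol = maximize_growth_at_fractions(cm, FractionVector({"solo": 1.0}))
        assert sol.optimal
        assert sol.mu == pytest.approx(10.0, abs=1e-9)

    @pytest.mark.parametrize("y,b,expected", [
        (0.1, 10.0, 1.0),
        (0.1, 0.0, 0.0),
        (0.25, 4.0, 1.0),
    ])
    def test_single_species_yield_times_bound(self, y, b, expected):
        cm = make_single_species(yield_coeff=y, uptake_bound=b)
        sol = maximize_growth_at_fractions(cm, FractionVector({"solo": 1.0}))
        assert sol.mu == pytest.approx(expected, abs=1e-9)

    def test_min_uptake_at_fixed_mu_is_mu_times_demand(self):
        cm = make_single_species(yield_coeff=0.1, uptake_bound=10.0)
        sol = optimize_flux_at_growth(cm, FractionVector({"solo": 1.0}),
                                      fixed_mu=0.5, flux_id="solo__t_s",
                                      sense="min")
        assert sol.optimal
        assert sol.q[("solo", "t_s")] == pytest.approx(0.5 * 10.0, abs=1e-9)

    def test_fixed_mu_above_optimum_is_infeasible(self):
        cm = make_single_species(yield_coeff=0.1, uptake_bound=10.0)
        sol = optimize_flux_at_growth(cm, FractionVector({"solo": 1.0}),
                                      fixed_mu=1.0 + 1e-6,
                                      flux_id="solo__t_s", sense="min")
        assert sol.status is SolutionStatus.INFEASIBLE


class TestLPStructure:
    def test_community_of_one_reduces_to_classical_fba_rows(self):
        cm = make_single_species()
        spec = build_lp(cm, FractionVector({"solo": 1.0}))
        # one row per metabolite, coefficients unscaled at f = 1
        A = spec.A_eq.toarray()
        t_col = spec.var_index("solo__t_s")
        s_row = spec.row_names.index("solo__s")
        assert A[s_row, t_col] == pytest.approx(1.0)

    def test_fraction_scaling_of_species_columns(self, toy):
        spec = build_lp(toy, frac(toy, 0.5))
        A = spec.A_eq.toarray()
        row = spec.row_names.index("glc_consumer__glc")
        col = spec.var_index("glc_consumer__cat")
        assert A[row, col] == pytest.approx(-0.5)  # stoich -1 scaled by f=0.5
        # exchange columns are unscaled
        ex_col = spec.var_index("EX_Glc_e")
        ex_row = spec.row_names.index("Glc_e")
        assert A[ex_row, ex_col] == pytest.approx(-1.0)

    def test_shared_mu_column_sums_both_biomass_contributions(self, toy):
        spec = build_lp(toy, frac(toy, 0.25))
        A = spec.A_eq.toarray()
        mu_col = spec.var_index("mu")
        row_i = spec.row_names.index("glc_consumer__bm")
        row_j = spec.row_names.index("n_fixer__bm")
        assert A[row_i, mu_col] == pytest.approx(0.25 * -10.0)
        assert A[row_j, mu_col] == pytest.approx(0.75 * -10.0)

    def test_fixed_mu_pins_the_mu_variable(self, toy):
        spec = build_lp(toy, frac(toy, 0.5), Objective.MIN_FLUX,
                        objective_flux="EX_Glc_e", fixed_mu=0.2)
        j = spec.var_index("mu")
        assert spec.lb[j] == spec.ub[j] == 0.2

    def test_unbounded_by_construction_refused(self):
        mets = [Metabolite("S_e", role=U), Metabolite("p", role=I)]
        rxns = [
            Reaction("t", {"S_e": -1, "p": 1}, upper_bound=np.inf),
            Reaction("biomass", {"p": -1}, kind=ReactionKind.BIOMASS),
        ]
        sp = build_species_model("s", mets, rxns)
        ex = Reaction("EX_S_e", {"S_e": -1}, kind=ReactionKind.ENV_EXCHANGE,
                      lower_bound=-np.inf, upper_bound=np.inf)
        cm = assemble_community([sp], [], [ex])
        with pytest.raises(UnboundedModelError, match="unbounded by construction"):
            build_lp(cm, FractionVector({"s": 1.0}))

    def test_lp_format_export_mentions_all_variables(self, toy):
        spec = build_lp(toy, frac(toy, 0.5))
        text = spec.to_lp_format()
        for name in spec.var_names:
            assert name in text


class TestMutualism:
    def test_broken_crossfeeding_kills_growth(self, toy):
        broken = toy.with_reaction_bounds({("n_fixer", "t_nh3"): (0.0, 0.0)})
        sol = maximize_growth_at_fractions(broken, frac(broken, 0.5))
        # producer and consumer must grow equally fast; with the ammonium
        # return route closed the community cannot grow at all
        assert (not sol.optimal) or sol.mu == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_residuals_small_at_optimum(self, toy):
        for f0 in (0.3, 0.5, 0.7):
            sol = maximize_growth_at_fractions(toy, frac(toy, f0))
            assert sol.optimal
            spec = build_lp(toy, frac(toy, f0))
            x = np.zeros(len(spec.var_names))
            for (sp, rxn), v in sol.q.items():
                x[spec.var_index(f"{sp}__{rxn}")] = v
            x[spec.var_index("mu")] = sol.mu
            for ex, v in sol.phi.items():
                x[spec.var_index(ex)] = v
            assert np.abs(spec.A_eq @ x).max() <= 1e-8
            assert (x >= spec.lb - 1e-9).all() and (x <= spec.ub + 1e-9).all()


class TestScalingLaw:
    @pytest.mark.parametrize("alpha", [0.5, 2.0, 10.0])
    def test_single_species_env_bound_scales_mu(self, alpha):
        base = make_single_species(yield_coeff=0.1, uptake_bound=np.inf,
                                   env_influx=10.0)
        scaled = make_single_species(yield_coeff=0.1, uptake_bound=np.inf,
                                     env_influx=10.0 * alpha)
        f = FractionVector({"solo": 1.0})
        mu0 = maximize_growth_at_fractions(base, f).mu
        mu1 = maximize_growth_at_fractions(scaled, f).mu
        assert mu1 == pytest.approx(alpha * mu0, abs=1e-8)

    def test_scaling_stops_when_another_bound_binds(self):
        # species-level uptake capacity 5 binds once the environmental
        # bound passes it: the optimum saturates instead of scaling
        base = make_single_species(yield_coeff=0.1, uptake_bound=5.0,
                                   env_influx=2.0)
        f = FractionVector({"solo": 1.0})
        mu = [maximize_growth_at_fractions(
            make_single_species(0.1, 5.0, env_influx=2.0 * a), f).mu
            for a in (1.0, 2.0, 10.0)]
        assert mu[1] == pytest.approx(2 * mu[0], abs=1e-8)
        assert mu[2] == pytest.approx(0.5, abs=1e-8)  # capped by uptake bound

    def test_yield_invariance_under_scaling(self):
        # mu / |phi_limiting| is the biomass yield: unchanged under scaling
        f = FractionVector({"solo": 1.0})
        yields = []
        for a in (1.0, 2.0, 10.0):
            cm = make_single_species(0.1, np.inf, env_influx=3.0 * a)
            sol = maximize_growth_at_fractions(cm, f)
            yields.append(sol.mu / -sol.phi["EX_S_e"])
        assert np.ptp(yields) <= 1e-10


class TestExtraConstraints:
    def test_interspecies_uptake_ratio_cap(self, toy):
        # cap the fixer's succinate uptake at a multiple of the producer's
        # glucose uptake; an extreme cap must reduce the optimum
        con = LinearConstraint(
            coeffs={"n_fixer__t_succ": 1.0, "glc_consumer__t_glc": -0.1},
            sense="<=", rhs=0.0,
        )
        free = maximize_growth_at_fractions(toy, frac(toy, 0.6))
        capped = maximize_growth_at_fractions(toy, frac(toy, 0.6), (con,))
        assert capped.status is SolutionStatus.INFEASIBLE or capped.mu < free.mu

    def test_unknown_flux_in_constraint_rejected(self, toy):
        con = LinearConstraint(coeffs={"nope__r": 1.0})
        with pytest.raises(ModelError, match="unknown flux"):
            build_lp(toy, frac(toy, 0.5), extra_constraints=(con,))


class TestFluxRanges:
    def test_unique_solution_has_tight_ranges(self):
        cm = make_single_species(yield_coeff=0.1, uptake_bound=10.0)
        ranges = flux_ranges_at_optimum(cm, FractionVector({"solo": 1.0}))
        for lo, hi in ranges.values():
            assert hi - lo <= 1e-8

    def test_duplicated_reaction_widens_its_range_not_the_sum(self):
        mets = [Metabolite("S_e", role=U), Metabolite("p", role=I)]
        rxns = [
            Reaction("t1", {"S_e": -1, "p": 1}, upper_bound=10.0),
            Reaction("t2", {"S_e": -1, "p": 1}, upper_bound=10.0),
            Reaction("biomass", {"p": -10.0}, kind=ReactionKind.BIOMASS),
        ]
        sp = build_species_model("s", mets, rxns)
        ex = Reaction("EX_S_e", {"S_e": -1}, kind=ReactionKind.ENV_EXCHANGE,
                      lower_bound=-10.0, upper_bound=0.0)
        cm = assemble_community([sp], [], [ex])
        f = FractionVector({"s": 1.0})
        ranges = flux_ranges_at_optimum(cm, f)
        # the pair is degenerate: each duplicate spans [0, 10]
        assert ranges["s__t1"] == pytest.approx((0.0, 10.0), abs=1e-7)
        assert ranges["s__t2"] == pytest.approx((0.0, 10.0), abs=1e-7)
        # while the total uptake is pinned by the environmental bound
        assert ranges["EX_S_e"] == pytest.approx((-10.0, -10.0), abs=1e-7)

    def test_ranges_contain_incumbent(self, toy):
        f = frac(toy, 0.6)
        sol = maximize_growth_at_fractions(toy, f)
        ranges = flux_ranges_at_optimum(toy, f, rel_tol=1e-9)
        for name, (lo, hi) in ranges.items():
            v = sol.flux(name)
            assert lo - 1e-6 <= v <= hi + 1e-6


@given(st.floats(0.01, 0.99))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_minimal_pair_matches_analytic_curve(f0):
    """μ*(f) of the minimal pair follows its closed-form piecewise curve."""
    cm = make_minimal_pair()
    sol = maximize_growth_at_fractions(cm, frac(cm, f0))
    if f0 <= 0.5:
        expected = min(2 * 50.0 * f0, 2 * 10.0)
    else:
        expected = 0.0
    assert sol.optimal
    assert sol.mu == pytest.approx(expected, abs=1e-7)
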