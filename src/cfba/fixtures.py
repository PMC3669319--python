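"""Deterministic synthetic consortia for analysis and testing.

The central fixture is an obligate mutualistic pair modelled after the
classic cross-feeding motif: a glucose consumer that excretes a carbon
compound (a succinate analog) and needs fixed nitrogen, paired with a
nitrogen fixer that lives on that carbon compound and returns ammonium.
Each species carries the four coarse-grained processes of reduced
stoichiometric growth models — catabolism, anabolism, respiration and
product formation — plus membrane transports and an ATP maintenance
drain.  All lumped reactions balance under a pseudo-elemental
bookkeeping (carbon/nitrogen tokens on metabolites; energy and redox
carriers are deliberately unannotated and excluded from balance checks).

The default coefficients are frozen design choices, documented below and
in the package methods note; they are chosen so the community displays
the canonical limitation regimes: an infeasible band at low abundance of
the glucose consumer, a rising growth-rate limb, an environment-limited
plateau of optimal fractions, and a decline driven by the nitrogen
fixer's energy burden.  With the defaults the maximal community growth
rate is exactly 2.0 h⁻¹ on the plateau f_glc ∈ [1/2, 5/6].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CommunityModel,
    Metabolite,
    MetaboliteRole,
    ModelError,
    Reaction,
    ReactionKind,
    SpeciesModel,
    assemble_community,
    build_species_model,
)

__all__ = [
    "ToyConsortiumParams",
    "make_toy_consortium",
    "make_single_species",
    "make_minimal_pair",
    "make_random_community",
    "make_screen_consortium",
]

INF = float("inf")

_I = MetaboliteRole.INTRACELLULAR
_X = MetaboliteRole.CROSSFED_EXTRACELLULAR
_U = MetaboliteRole.UNIQUE_EXTRACELLULAR


@dataclass
class ToyConsortiumParams:
    """Frozen coefficients and bounds of the mutualistic toy pair.

    Stoichiometric yields (dimensionless mmol/mmol):
      * catabolism of the glucose consumer: 1 glucose -> 2 precursor
        + ``cat_atp_yield`` ATP + 2 NADH
      * respiration: 1 NADH -> ``res_atp_yield`` ATP
      * product formation: 1 precursor -> 1 succinate analog
      * nitrogen fixation: 1 N2 + ``fix_atp_cost`` ATP -> 2 ammonium
      * anabolism: 1 precursor + ``ana_nh3_coeff`` ammonium -> 1 biomass
        precursor

    Bounds are specific fluxes (mmol·gDW⁻¹·h⁻¹) except ``glc_influx`` /
    ``n2_influx`` which are absolute environmental influxes (mmol·h⁻¹).
    ``maintenance`` is a non-growth ATP drain with a hard lower bound; it
    is what makes very skewed communities outright infeasible rather
    than merely non-growing.
    """

    glc_influx: float = 10.0
    n2_influx: float = INF
    qmax_glc: float = 20.0
    succ_export_bound: float = INF
    succ_uptake_bound: float = INF
    nh3_export_bound: float = INF
    nh3_uptake_bound: float = INF
    maintenance: float = 12.0
    biomass_demand: float = 10.0
    cat_atp_yield: float = 2.0
    res_atp_yield: float = 2.0
    fix_atp_cost: float = 4.0
    ana_nh3_coeff: float = 0.2
    X_T: float = 1.0


def _toy_glucose_consumer(p: ToyConsortiumParams) -> SpeciesModel:
    mets = [
        Metabolite("glc", role=_I, formula="C6"),
        Metabolite("prec", role=_I, formula="C3"),
        Metabolite("succ", role=_I, formula="C3"),
        Metabolite("nh3", role=_I, formula="N1"),
        Metabolite("bm", role=_I, formula=f"C3N{p.ana_nh3_coeff:g}"),
        Metabolite("atp", role=_I),
        Metabolite("nadh", role=_I),
        Metabolite("Glc_e", role=_U, formula="C6"),
        Metabolite("Succ_e", role=_X, formula="C3"),
        Metabolite("NH3_e", role=_X, formula="N1"),
    ]
    rxns = [
        Reaction("t_glc", {"Glc_e": -1, "glc": 1}, upper_bound=p.qmax_glc),
        Reaction("cat", {"glc": -1, "prec": 2, "atp": p.cat_atp_yield, "nadh": 2},
                 upper_bound=INF),
        Reaction("res", {"nadh": -1, "atp": p.res_atp_yield}, upper_bound=INF),
        Reaction("pro", {"prec": -1, "succ": 1}, upper_bound=INF),
        Reaction("ana", {"prec": -1, "nh3": -p.ana_nh3_coeff, "bm": 1},
                 upper_bound=INF),
        Reaction("t_succ", {"succ": -1, "Succ_e": 1}, upper_bound=p.succ_export_bound),
        Reaction("t_nh3", {"NH3_e": -1, "nh3": 1}, upper_bound=p.nh3_uptake_bound),
        Reaction("atpm", {"atp": -1}, lower_bound=p.maintenance, upper_bound=INF),
        Reaction("biomass", {"bm": -p.biomass_demand}, kind=ReactionKind.BIOMASS),
    ]
    return build_species_model("glc_consumer", mets, rxns)


def _toy_nitrogen_fixer(p: ToyConsortiumParams) -> SpeciesModel:
    mets = [
        Metabolite("succ", role=_I, formula="C3"),
        Metabolite("prec", role=_I, formula="C3"),
        Metabolite("co2", role=_I, formula="C1"),
        Metabolite("n2", role=_I, formula="N2"),
        Metabolite("nh3", role=_I, formula="N1"),
        Metabolite("bm", role=_I, formula=f"C3N{p.ana_nh3_coeff:g}"),
        Metabolite("atp", role=_I),
        Metabolite("nadh", role=_I),
        Metabolite("Succ_e", role=_X, formula="C3"),
        Metabolite("NH3_e", role=_X, formula="N1"),
        Metabolite("N2_e", role=_U, formula="N2"),
        Metabolite("CO2_e", role=_U, formula="C1"),
    ]
    rxns = [
        Reaction("t_succ", {"Succ_e": -1, "succ": 1}, upper_bound=p.succ_uptake_bound),
        Reaction("t_n2", {"N2_e": -1, "n2": 1}, upper_bound=INF),
        Reaction("cat", {"succ": -1, "prec": 1, "atp": 1, "nadh": 1},
                 upper_bound=INF),
        # full oxidation: maintenance energy without biomass carbon
        Reaction("ox", {"succ": -1, "co2": 3, "atp": 2}, upper_bound=INF),
        Reaction("res", {"nadh": -1, "atp": p.res_atp_yield}, upper_bound=INF),
        Reaction("fix", {"n2": -1, "atp": -p.fix_atp_cost, "nh3": 2},
                 upper_bound=INF),
        Reaction("ana", {"prec": -1, "nh3": -p.ana_nh3_coeff, "bm": 1},
                 upper_bound=INF),
        Reaction("t_nh3", {"nh3": -1, "NH3_e": 1}, upper_bound=p.nh3_export_bound),
        Reaction("t_co2", {"co2": -1, "CO2_e": 1}, upper_bound=INF),
        Reaction("atpm", {"atp": -1}, lower_bound=p.maintenance, upper_bound=INF),
        Reaction("biomass", {"bm": -p.biomass_demand}, kind=ReactionKind.BIOMASS),
    ]
    return build_species_model("n_fixer", mets, rxns)


def make_toy_consortium(
    params: ToyConsortiumParams | None = None,
    obligate: bool = True,
) -> CommunityModel:
    """Build the two-species mutualistic toy consortium.

    With ``obligate=True`` (default) the parameter set is rejected if
    either species could grow on its own under the community environment:
    the fixture is meant to represent obligate mutualism, where the
    community growth rate is zero at both simplex corners.
    """
    p = params or ToyConsortiumParams()
    for name in ("glc_influx", "qmax_glc", "biomass_demand", "cat_atp_yield",
                 "res_atp_yield", "X_T"):
        if getattr(p, name) <= 0:
            raise ModelError(f"toy consortium parameter {name} must be positive")
    if p.ana_nh3_coeff < 0:
        raise ModelError("toy consortium parameter ana_nh3_coeff must be >= 0")
    sp_i = _toy_glucose_consumer(p)
    sp_j = _toy_nitrogen_fixer(p)
    exchanges = [
        Reaction("EX_Glc_e", {"Glc_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=-p.glc_influx, upper_bound=0.0),
        Reaction("EX_N2_e", {"N2_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=-p.n2_influx, upper_bound=0.0),
        Reaction("EX_CO2_e", {"CO2_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=0.0, upper_bound=INF),
    ]
    cm = assemble_community(
        [sp_i, sp_j], crossfed_ids=["Succ_e", "NH3_e"],
        env_exchanges=exchanges, X_T=p.X_T,
    )
    if obligate:
        _reject_if_independently_viable(cm)
    return cm


def _reject_if_independently_viable(cm: CommunityModel) -> None:
    from .lp import maximize_growth_at_fractions  # deferred: avoids cycle
    from .model import FractionVector

    for sp in cm.species:
        solo = assemble_community(
            [sp.copy()],
            crossfed_ids=[m for m in cm.crossfed_metabolites
                          if m in sp.extracellular_ids()],
            env_exchanges=[ex.copy() for ex in cm.env_exchanges
                           if next(iter(ex.stoichiometry)) in sp.extracellular_ids()],
            X_T=cm.X_T,
        )
        sol = maximize_growth_at_fractions(solo, FractionVector({sp.species_id: 1.0}))
        if sol.optimal and sol.mu is not None and sol.mu > 1e-9:
            raise ModelError(
                f"species {sp.species_id!r} is independently viable "
                f"(mu={sol.mu:.3g}); not an obligate consortium"
            )


def make_single_species(
    yield_coeff: float = 0.1,
    uptake_bound: float = 10.0,
    env_influx: float = INF,
    species_id: str = "solo",
) -> CommunityModel:
    """One-species community with a closed-form optimum.

    A single substrate is imported (specific bound ``uptake_bound``) and
    converted to biomass at ``yield_coeff`` gDW per mmol, so
    μ* = min(uptake_bound, env_influx / X_T) · yield_coeff.
    """
    if yield_coeff <= 0:
        raise ModelError("yield_coeff must be positive")
    if uptake_bound < 0:
        raise ModelError("uptake_bound must be nonnegative")
    mets = [
        Metabolite("s", role=_I),
        Metabolite("S_e", role=_U),
    ]
    rxns = [
        Reaction("t_s", {"S_e": -1, "s": 1}, upper_bound=uptake_bound),
        Reaction("biomass", {"s": -1.0 / yield_coeff}, kind=ReactionKind.BIOMASS),
    ]
    sp = build_species_model(species_id, mets, rxns)
    ex = Reaction("EX_S_e", {"S_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                  lower_bound=-env_influx, upper_bound=0.0)
    return assemble_community([sp], crossfed_ids=[], env_exchanges=[ex], X_T=1.0)


def make_minimal_pair(
    qmax_glc: float = 50.0,
    glc_influx: float = 10.0,
) -> CommunityModel:
    """A deliberately tiny mutualistic pair (11 free LP variables).

    Designed for exhaustive cross-checks: small enough that the fixed-
    fraction optimum can be recomputed by brute-force enumeration of LP
    basic solutions.  The producer excretes the carbon cross-feed
    stoichiometrically with growth (plus a pure overflow route), the
    partner fixes nitrogen on demand, so the growth-rate curve over the
    fraction simplex is piecewise linear with a kink, a plateau and a
    sharp infeasible flank:

        μ*(f) = min(2·qmax_glc·f, 2·glc_influx/X_T)   for 0 < f ≤ 1/2
        μ*(f) = 0                                     for f > 1/2 or f = 0

    where f is the fraction of the glucose consumer.
    """
    mets_a = [
        Metabolite("g", role=_I, formula="C6"),
        Metabolite("nh3", role=_I, formula="N1"),
        Metabolite("bm", role=_I, formula="C3N0.4"),
        Metabolite("Glc_e", role=_U, formula="C6"),
        Metabolite("Succ_e", role=_X, formula="C3"),
        Metabolite("NH3_e", role=_X, formula="N1"),
    ]
    rxns_a = [
        Reaction("t_glc", {"Glc_e": -1, "g": 1}, upper_bound=qmax_glc),
        Reaction("grow", {"g": -1, "nh3": -0.4, "bm": 1, "Succ_e": 1},
                 upper_bound=INF),
        Reaction("dump", {"g": -1, "Succ_e": 2}, upper_bound=INF),
        Reaction("t_nh3", {"NH3_e": -1, "nh3": 1}, upper_bound=INF),
        Reaction("biomass", {"bm": -1.0}, kind=ReactionKind.BIOMASS),
    ]
    mets_b = [
        Metabolite("s", role=_I, formula="C3"),
        Metabolite("nh3", role=_I, formula="N1"),
        Metabolite("bm", role=_I, formula="C3N0.4"),
        Metabolite("Succ_e", role=_X, formula="C3"),
        Metabolite("NH3_e", role=_X, formula="N1"),
        Metabolite("N2_e", role=_U, formula="N2"),
    ]
    rxns_b = [
        Reaction("t_succ", {"Succ_e": -1, "s": 1}, upper_bound=INF),
        Reaction("grow", {"s": -1, "nh3": -0.4, "bm": 1}, upper_bound=INF),
        Reaction("fix", {"N2_e": -1, "nh3": 2}, upper_bound=INF),
        Reaction("t_nh3", {"nh3": -1, "NH3_e": 1}, upper_bound=INF),
        Reaction("biomass", {"bm": -1.0}, kind=ReactionKind.BIOMASS),
    ]
    sp_a = build_species_model("producer", mets_a, rxns_a)
    sp_b = build_species_model("partner", mets_b, rxns_b)
    exchanges = [
        Reaction("EX_Glc_e", {"Glc_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=-glc_influx, upper_bound=0.0),
        Reaction("EX_N2_e", {"N2_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=-INF, upper_bound=0.0),
        # exact cross-feed balances: overflow pinned to zero, so the LP has
        # only 11 free variables and brute-force vertex enumeration is cheap
        Reaction("EX_Succ_e", {"Succ_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=0.0, upper_bound=0.0),
        Reaction("EX_NH3_e", {"NH3_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=0.0, upper_bound=0.0),
    ]
    cm = assemble_community(
        [sp_a, sp_b], crossfed_ids=["Succ_e", "NH3_e"],
        env_exchanges=exchanges, X_T=1.0,
    )
    return cm


def make_random_community(
    n_species: int = 3,
    n_crossfeeds: int | None = None,
    seed: int = 0,
) -> CommunityModel:
    """Randomized producer→consumer chain community, feasible by design.

    Species k imports the chain metabolite excreted by species k−1
    (species 0 imports the environmental substrate) and converts it to
    biomass plus the next chain metabolite; every cross-fed metabolite
    can also overflow.  Production is stoichiometrically coupled to
    growth, so positive community growth exists only where the fractions
    match the chain's supply ratios — scaling fractions down the chain
    always yields such a point, so every generated community has a
    positive optimum somewhere on the simplex.  The same seed always
    yields the identical model.
    """
    if n_species < 1:
        raise ModelError("n_species must be >= 1")
    if n_crossfeeds is None:
        n_crossfeeds = n_species - 1
    rng = np.random.default_rng(seed)
    species = []
    crossfed: list[str] = []
    substrate = "S0_e"
    for k in range(n_species):
        upstream = substrate if k == 0 else f"M{k}_e"
        product = f"M{k + 1}_e"
        bm_yield = float(np.round(rng.uniform(0.5, 2.0), 3))
        prod_yield = float(np.round(rng.uniform(0.5, 2.0), 3))
        uptake_ub = float(np.round(rng.uniform(5.0, 15.0), 3))
        role_up = _U if k == 0 else _X
        mets = [
            Metabolite("a", role=_I),
            Metabolite("bm", role=_I),
            Metabolite(upstream, role=role_up),
        ]
        stoich = {"a": -1, "bm": bm_yield}
        last = k == n_species - 1
        if not last or n_crossfeeds >= n_species:
            mets.append(Metabolite(product, role=_X))
            stoich[product] = prod_yield
            crossfed.append(product)
        rxns = [
            Reaction("t_in", {upstream: -1, "a": 1}, upper_bound=uptake_ub),
            Reaction("conv", stoich, upper_bound=INF),
            Reaction("biomass", {"bm": -1.0}, kind=ReactionKind.BIOMASS),
        ]
        species.append(build_species_model(f"sp{k}", mets, rxns))
        if k > 0:
            crossfed.append(upstream)
    crossfed = sorted(set(crossfed))
    influx = float(np.round(rng.uniform(5.0, 15.0), 3))
    exchanges = [
        Reaction(f"EX_{substrate}", {substrate: -1.0},
                 kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=-influx, upper_bound=0.0),
    ]
    return assemble_community(species, crossfed_ids=crossfed,
                              env_exchanges=exchanges, X_T=1.0)


def make_screen_consortium(fix_bound: float = 5.0) -> CommunityModel:
    """Two species with three alternative carbon cross-feeds plus a decoy.

    The producer can excrete any of three carbon carriers derived from
    glucose; the consumer converts them back to biomass precursor at
    different carbon yields (M1: 1.0, M2: 2/3, M3: 0.8), so the minimum
    glucose uptake needed to hold a given community growth rate depends
    on which carrier the pair cross-feeds through.  ``M4_e`` is exported
    by the producer but has no consumer-side transporter (a blocked
    candidate).  Ammonium returned by the consumer closes an obligate
    loop; its production is capped (``fix_bound``) so the consumer keeps
    a non-vanishing optimal biomass share.
    """
    mets_a = [
        Metabolite("g", role=_I, formula="C6"),
        Metabolite("p", role=_I, formula="C3"),
        Metabolite("co2", role=_I, formula="C1"),
        Metabolite("nh3", role=_I, formula="N1"),
        Metabolite("bm", role=_I, formula="C3N0.2"),
        Metabolite("Glc_e", role=_U, formula="C6"),
        Metabolite("CO2A_e", role=_U, formula="C1"),
        Metabolite("M1_e", role=_X, formula="C3"),
        Metabolite("M2_e", role=_X, formula="C2"),
        Metabolite("M3_e", role=_X, formula="C3"),
        Metabolite("M4_e", role=_X, formula="C3"),
        Metabolite("NH3_e", role=_X, formula="N1"),
    ]
    rxns_a = [
        Reaction("t_glc", {"Glc_e": -1, "g": 1}, upper_bound=100.0),
        Reaction("cat", {"g": -1, "p": 2}, upper_bound=INF),
        Reaction("exp_m1", {"p": -1, "M1_e": 1}, upper_bound=INF),
        Reaction("exp_m2", {"p": -1, "M2_e": 1, "co2": 1}, upper_bound=INF),
        Reaction("exp_m3", {"p": -1, "M3_e": 1}, upper_bound=INF),
        Reaction("exp_m4", {"p": -1, "M4_e": 1}, upper_bound=INF),
        Reaction("t_co2", {"co2": -1, "CO2A_e": 1}, upper_bound=INF),
        Reaction("ana", {"p": -1, "nh3": -0.2, "bm": 1}, upper_bound=INF),
        Reaction("t_nh3", {"NH3_e": -1, "nh3": 1}, upper_bound=INF),
        Reaction("biomass", {"bm": -10.0}, kind=ReactionKind.BIOMASS),
    ]
    mets_b = [
        Metabolite("m1", role=_I, formula="C3"),
        Metabolite("m2", role=_I, formula="C2"),
        Metabolite("m3", role=_I, formula="C3"),
        Metabolite("p", role=_I, formula="C3"),
        Metabolite("co2", role=_I, formula="C1"),
        Metabolite("nh3", role=_I, formula="N1"),
        Metabolite("bm", role=_I, formula="C3N0.2"),
        Metabolite("M1_e", role=_X, formula="C3"),
        Metabolite("M2_e", role=_X, formula="C2"),
        Metabolite("M3_e", role=_X, formula="C3"),
        Metabolite("NH3_e", role=_X, formula="N1"),
        Metabolite("N2_e", role=_U, formula="N2"),
        Metabolite("CO2B_e", role=_U, formula="C1"),
    ]
    rxns_b = [
        Reaction("t_m1", {"M1_e": -1, "m1": 1}, upper_bound=INF),
        Reaction("t_m2", {"M2_e": -1, "m2": 1}, upper_bound=INF),
        Reaction("t_m3", {"M3_e": -1, "m3": 1}, upper_bound=INF),
        Reaction("use_m1", {"m1": -1, "p": 1}, upper_bound=INF),
        Reaction("use_m2", {"m2": -1, "p": 2.0 / 3.0}, upper_bound=INF),
        Reaction("use_m3", {"m3": -1, "p": 0.8, "co2": 0.6}, upper_bound=INF),
        Reaction("t_co2", {"co2": -1, "CO2B_e": 1}, upper_bound=INF),
        Reaction("fix", {"N2_e": -1, "nh3": 2}, upper_bound=fix_bound),
        Reaction("ana", {"p": -1, "nh3": -0.2, "bm": 1}, upper_bound=INF),
        Reaction("t_nh3", {"nh3": -1, "NH3_e": 1}, upper_bound=INF),
        Reaction("biomass", {"bm": -10.0}, kind=ReactionKind.BIOMASS),
    ]
    sp_a = build_species_model("producer", mets_a, rxns_a)
    sp_b = build_species_model("consumer", mets_b, rxns_b)
    exchanges = [
        Reaction("EX_Glc_e", {"Glc_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=-20.0, upper_bound=0.0),
        Reaction("EX_N2_e", {"N2_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=-INF, upper_bound=0.0),
        Reaction("EX_CO2A_e", {"CO2A_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=0.0, upper_bound=INF),
        Reaction("EX_CO2B_e", {"CO2B_e": -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=0.0, upper_bound=INF),
    ]
    return assemble_community(
        [sp_a, sp_b],
        crossfed_ids=["M1_e", "M2_e", "M3_e", "M4_e", "NH3_e"],
        env_exchanges=exchanges, X_T=1.0,
    )
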