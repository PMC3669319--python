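"""Independent oracles used to cross-check the LP implementation.

These deliberately avoid the package's solver path: the vertex
enumerator searches basic solutions of the balance system by brute
force, and the classical-FBA oracle goes through cobra (GLPK), a
completely separate modelling stack.
"""

from __future__ import annotations

import itertools

import numpy as np

from cfba.lp import LPSpec
from cfba.model import CommunityModel, FractionVector


def vertex_enumeration_optimum(spec: LPSpec) -> float | None:
    """Brute-force optimum of an LPSpec over basic feasible solutions.

    Enumerates all ways of fixing (n − rank) free variables at a finite
    bound, solves the resulting square-ish linear system, keeps feasible
    points, and returns the best objective value.  Only valid for
    bounded problems whose optimum is attained at a vertex (always the
    case here); returns None when no basic feasible point exists.
    Intended for instances with around a dozen free variables.
    """
    A = spec.A_eq.toarray()
    b = np.asarray(spec.b_eq, dtype=float)
    lb, ub = spec.lb.copy(), spec.ub.copy()
    n = A.shape[1]

    pinned = [j for j in range(n) if lb[j] == ub[j]]
    free_vars = [j for j in range(n) if lb[j] < ub[j]]
    # substitute pinned variables into the right-hand side
    b = b - A[:, pinned] @ lb[pinned]
    A_f = A[:, free_vars]
    rank = np.linalg.matrix_rank(A_f, tol=1e-10)
    n_fix = len(free_vars) - rank
    if n_fix < 0:
        raise ValueError("system over-determined beyond rank")

    best: float | None = None
    best_x: np.ndarray | None = None
    sign = -1.0 if spec.maximize else 1.0
    scale = max(1.0, np.abs(A_f).max())

    for fixed in itertools.combinations(range(len(free_vars)), n_fix):
        solve_cols = [k for k in range(len(free_vars)) if k not in fixed]
        bound_options = []
        for k in fixed:
            j = free_vars[k]
            opts = [v for v in (lb[j], ub[j]) if np.isfinite(v)]
            bound_options.append(opts)
        if any(not o for o in bound_options):
            continue
        for values in itertools.product(*bound_options):
            rhs = b.copy()
            for k, v in zip(fixed, values):
                rhs = rhs - A_f[:, k] * v
            sol, *_ = np.linalg.lstsq(A_f[:, solve_cols], rhs, rcond=None)
            resid = A_f[:, solve_cols] @ sol - rhs
            if np.abs(resid).max() > 1e-8 * scale:
                continue
            x = np.empty(n)
            x[pinned] = lb[pinned]
            for k, v in zip(fixed, values):
                x[free_vars[k]] = v
            for k, v in zip(solve_cols, sol):
                x[free_vars[k]] = v
            if (x < lb - 1e-9).any() or (x > ub + 1e-9).any():
                continue
            if spec.A_ub is not None:
                if (spec.A_ub @ x > spec.b_ub + 1e-9).any():
                    continue
            obj = float(spec.c_obj @ x)
            if best is None or sign * obj < sign * best:
                best, best_x = obj, x
    return best


def cobra_fba_optimum(cm: CommunityModel) -> float:
    """Classical FBA biomass optimum of a one-species community via cobra.

    Builds the equivalent cobra model from scratch (boundary exchanges
    with specific bounds φ = J / X_T, same reactions and biomass
    stoichiometry) and maximizes the biomass flux with cobra's default
    GLPK backend.
    """
    import cobra

    (sp,) = cm.species
    model = cobra.Model(sp.species_id)
    mets = {}
    for m in sp.metabolites:
        mets[m.id] = cobra.Metabolite(
            m.id, compartment="e" if m.is_extracellular else "c"
        )
    rxns = []
    for r in list(sp.reactions) + [sp.biomass]:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in list(sp.reactions) + [sp.biomass]:
        model.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: coef for mid, coef in r.stoichiometry.items()}
        )
    for ex in cm.env_exchanges:
        ce = cobra.Reaction(ex.id)
        lo, hi = cm.phi_bounds(ex.id)
        ce.lower_bound = max(lo, -1e6)  # GLPK dislikes infinities
        ce.upper_bound = min(hi, 1e6)
        model.add_reactions([ce])
        (mid,) = ex.stoichiometry
        ce.add_metabolites({mets[mid]: ex.stoichiometry[mid]})
    model.objective = sp.biomass.id
    sol = model.optimize()
    if sol.status != "optimal":
        return float("nan")
    return float(sol.objective_value)


def exhaustive_two_species_max(
    cm: CommunityModel, resolution: float
) -> tuple[float, float]:
    """(mu_max, argmax fraction of first species) by dense grid search."""
    from cfba.lp import maximize_growth_at_fractions

    sp0, sp1 = cm.species_ids
    m = int(round(1.0 / resolution))
    best = (-np.inf, np.nan)
    for k in range(m + 1):
        f0 = k / m
        sol = maximize_growth_at_fractions(
            cm, FractionVector({sp0: f0, sp1: 1.0 - f0})
        )
        if sol.optimal and sol.mu > best[0]:
            best = (sol.mu, f0)
    return best
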