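"""The fixed-fraction balanced-growth linear program.

Under balanced growth every metabolite amount is at steady state while
all species grow at one shared specific rate μ.  For each variable
metabolite i the community mass balance reads

    Σ_j f_j ( Σ_l n_{ij,l} q_{l,j} + c_{ij} μ ) + Σ_k b_{ik} φ_k = 0

with f_j the biomass fraction of species j, q_{l,j} its specific fluxes,
c_{ij} its biomass composition, φ_k = J_k / X_T the specific
environmental exchange fluxes, and b_{ik} the exchange stoichiometry.
With the fractions f fixed this is linear in (q, μ, φ): the community
growth rate can be maximized, or any named flux optimized at fixed μ, by
ordinary linear programming.  The shared μ multiplies every species'
biomass column, which encodes the equal-growth-rate requirement
structurally instead of via extra equality rows.

Solved with the HiGHS solver (scipy.optimize.linprog).  Infeasibility at
a fraction vector is a first-class status: it means no balanced-growth
state exists there, which is distinct from an optimal μ* of zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import CommunityModel, FractionVector, ModelError, SPECIES_SEP

__all__ = [
    "Objective",
    "SolutionStatus",
    "LinearConstraint",
    "LPSpec",
    "BalancedGrowthSolution",
    "UnboundedModelError",
    "SolverError",
    "build_lp",
    "solve_lp",
    "maximize_growth_at_fractions",
    "optimize_flux_at_growth",
    "flux_ranges_at_optimum",
]

#: solver feasibility tolerances (primal/dual)
FEASIBILITY_TOL = 1e-9
#: maximum allowed steady-state residual on any balance row at an optimum
RESIDUAL_TOL = 1e-8
#: a bound is reported as binding when the flux is within this distance
BINDING_TOL = 1e-7

MU_VAR = "mu"


class UnboundedModelError(ModelError):
    """The growth maximization is unbounded by construction."""


class SolverError(RuntimeError):
    """The LP backend failed for a reason other than infeasibility."""


class Objective(str, Enum):
    MAX_MU = "max_mu"
    MIN_FLUX = "min_flux"
    MAX_FLUX = "max_flux"


class SolutionStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass
class LinearConstraint:
    """A general linear row over named fluxes: Σ coeff·flux (sense) rhs.

    Flux names are ``"<species>__<reaction>"`` for specific fluxes, an
    exchange id for specific environmental fluxes, or ``"mu"``.  This is
    the mechanism for ecosystem-level couplings that are not simple
    bounds, e.g. capping one strain's uptake at a multiple of another's.
    """

    coeffs: dict[str, float]
    sense: str = "<="  # one of "<=", ">=", "=="
    rhs: float = 0.0

    def __post_init__(self) -> None:
        if self.sense not in ("<=", ">=", "=="):
            raise ModelError(f"unknown constraint sense {self.sense!r}")


@dataclass
class LPSpec:
    """A fully assembled LP: equality balances, bounds, and objective."""

    var_names: list[str]
    row_names: list[str]
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    c_obj: np.ndarray
    A_ub: sparse.csr_matrix | None = None
    b_ub: np.ndarray | None = None
    maximize: bool = False
    fractions: FractionVector | None = None

    def var_index(self, name: str) -> int:
        try:
            return self.var_names.index(name)
        except ValueError:
            raise KeyError(f"unknown flux id {name!r}") from None

    def to_lp_format(self) -> str:
        """Render as CPLEX-LP-format text (for debugging)."""
        def term(c, v):
            return f"{'+' if c >= 0 else '-'} {abs(c):.12g} {v} "
        lines = ["Maximize" if self.maximize else "Minimize", " obj: " + "".join(
            term(c, v) for c, v in zip(self.c_obj, self.var_names) if c != 0)]
        lines.append("Subject To")
        A = self.A_eq.tocoo()
        rows: dict[int, str] = {i: "" for i in range(len(self.row_names))}
        for i, j, v in zip(A.row, A.col, A.data):
            rows[i] += term(v, self.var_names[j])
        for i, name in enumerate(self.row_names):
            lines.append(f" {name}: {rows[i] or '0 ' + self.var_names[0] + ' '}= {self.b_eq[i]:.12g}")
        if self.A_ub is not None:
            U = self.A_ub.tocoo()
            urows: dict[int, str] = {i: "" for i in range(self.A_ub.shape[0])}
            for i, j, v in zip(U.row, U.col, U.data):
                urows[i] += term(v, self.var_names[j])
            for i in range(self.A_ub.shape[0]):
                lines.append(f" extra{i}: {urows[i]}<= {self.b_ub[i]:.12g}")
        lines.append("Bounds")
        for v, lo, hi in zip(self.var_names, self.lb, self.ub):
            lo_s = "-inf" if np.isinf(lo) else f"{lo:.12g}"
            hi_s = "+inf" if np.isinf(hi) else f"{hi:.12g}"
            lines.append(f" {lo_s} <= {v} <= {hi_s}")
        lines.append("End")
        return "\n".join(lines)


@dataclass
class BalancedGrowthSolution:
    status: SolutionStatus
    mu: float | None = None
    q: dict[tuple[str, str], float] = field(default_factory=dict)
    phi: dict[str, float] = field(default_factory=dict)
    objective_value: float | None = None
    duals: dict[str, float] | None = None
    binding: list[str] = field(default_factory=list)
    fractions: FractionVector | None = None

    @property
    def optimal(self) -> bool:
        return self.status is SolutionStatus.OPTIMAL

    def flux(self, flux_id: str) -> float:
        if flux_id == MU_VAR:
            return self.mu  # type: ignore[return-value]
        if flux_id in self.phi:
            return self.phi[flux_id]
        sp, _, rxn = flux_id.partition(SPECIES_SEP)
        return self.q[(sp, rxn)]


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def _has_limiting_bound(cm: CommunityModel) -> bool:
    """Whether any finite flux bound exists that can cap the optimum.

    A lower bound of exactly zero merely states irreversibility and can
    never cap a maximization, so it does not count.
    """
    def limiting(lb: float, ub: float) -> bool:
        return np.isfinite(ub) or (np.isfinite(lb) and lb != 0.0)

    for ex in cm.env_exchanges:
        if limiting(ex.lower_bound, ex.upper_bound):
            return True
    for s in cm.species:
        for r in s.reactions:
            if limiting(r.lower_bound, r.upper_bound):
                return True
    return False


def build_lp(
    cm: CommunityModel,
    f: FractionVector,
    objective: Objective = Objective.MAX_MU,
    objective_flux: str | None = None,
    fixed_mu: float | None = None,
    extra_constraints: Sequence[LinearConstraint] = (),
) -> LPSpec:
    """Assemble the balanced-growth LP at fixed biomass fractions.

    The community matrix C already holds the unscaled stoichiometry; here
    every species' reaction columns are scaled by its fraction f_j, the
    per-species biomass columns are collapsed (scaled by f_j) onto the
    single shared μ variable, and exchange columns pass through unscaled
    (their variables φ are already community-specific fluxes).
    """
    missing = set(cm.species_ids) - set(f.f)
    if missing:
        raise ModelError(f"fraction vector missing species {sorted(missing)}")
    if objective is not Objective.MAX_MU:
        if objective_flux is None:
            raise ModelError("flux objective requires a flux id")
        if fixed_mu is None:
            raise ModelError("flux objectives require fixed_mu")
    if fixed_mu is not None and fixed_mu < 0:
        raise ModelError(f"fixed_mu must be nonnegative, got {fixed_mu}")
    if objective is Objective.MAX_MU and fixed_mu is None and not _has_limiting_bound(cm):
        raise UnboundedModelError(
            "growth maximization is unbounded by construction: no environmental "
            "uptake bound or species flux bound is finite"
        )

    var_names: list[str] = []
    lb: list[float] = []
    ub: list[float] = []
    for s in cm.species:
        for r in s.reactions:
            var_names.append(f"{s.species_id}{SPECIES_SEP}{r.id}")
            lb.append(r.lower_bound)
            ub.append(r.upper_bound)
    mu_col = len(var_names)
    var_names.append(MU_VAR)
    if fixed_mu is not None:
        lb.append(fixed_mu)
        ub.append(fixed_mu)
    else:
        lb.append(0.0)
        ub.append(np.inf)
    for ex in cm.env_exchanges:
        var_names.append(ex.id)
        lo, hi = cm.phi_bounds(ex.id)
        lb.append(lo)
        ub.append(hi)
    vidx = {v: j for j, v in enumerate(var_names)}

    C = cm.C.tocoo()
    n_rows = len(cm.row_keys)
    rows, cols, vals = [], [], []
    # map community-matrix columns onto LP variables, applying f_j scaling
    col_map: list[tuple[int, float]] = []
    k = 0
    for s in cm.species:
        for _ in s.reactions:
            col_map.append((k, f[s.species_id]))
            k += 1
    for s in cm.species:
        col_map.append((mu_col, f[s.species_id]))  # biomass column -> shared mu
    for ex in cm.env_exchanges:
        col_map.append((vidx[ex.id], 1.0))

    n_q = sum(len(s.reactions) for s in cm.species)
    for i, j, v in zip(C.row, C.col, C.data):
        tgt, scale = col_map[j]
        if j < n_q:
            tgt = tgt  # q column
        rows.append(i)
        cols.append(tgt)
        vals.append(v * scale)
    A_eq = sparse.csr_matrix((vals, (rows, cols)), shape=(n_rows, len(var_names)))
    # duplicate (row, mu) entries from several biomass columns sum correctly
    A_eq.sum_duplicates()

    c_obj = np.zeros(len(var_names))
    maximize = False
    if objective is Objective.MAX_MU:
        c_obj[mu_col] = 1.0
        maximize = True
    else:
        c_obj[vidx[objective_flux]] = 1.0  # type: ignore[index]
        maximize = objective is Objective.MAX_FLUX

    A_ub = b_ub = None
    if extra_constraints:
        urows, ucols, uvals, brhs = [], [], [], []
        r_i = 0
        for con in extra_constraints:
            if con.sense == "==":
                senses = [(1.0, con.rhs), (-1.0, -con.rhs)]
            elif con.sense == "<=":
                senses = [(1.0, con.rhs)]
            else:
                senses = [(-1.0, -con.rhs)]
            for sgn, rhs in senses:
                for name, coef in con.coeffs.items():
                    if name not in vidx:
                        raise ModelError(
                            f"extra constraint references unknown flux {name!r}"
                        )
                    urows.append(r_i)
                    ucols.append(vidx[name])
                    uvals.append(sgn * coef)
                brhs.append(rhs)
                r_i += 1
        A_ub = sparse.csr_matrix((uvals, (urows, ucols)), shape=(r_i, len(var_names)))
        b_ub = np.array(brhs)

    return LPSpec(
        var_names=var_names,
        row_names=list(cm.row_keys),
        A_eq=A_eq,
        b_eq=np.zeros(n_rows),
        lb=np.array(lb, dtype=float),
        ub=np.array(ub, dtype=float),
        c_obj=c_obj,
        A_ub=A_ub,
        b_ub=b_ub,
        maximize=maximize,
        fractions=f,
    )


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

_HIGHS_OPTIONS = {
    "primal_feasibility_tolerance": FEASIBILITY_TOL,
    "dual_feasibility_tolerance": FEASIBILITY_TOL,
}


def solve_lp(spec: LPSpec) -> tuple[SolutionStatus, np.ndarray | None, object]:
    """Solve an LPSpec; returns (status, solution vector or None, raw result)."""
    sign = -1.0 if spec.maximize else 1.0
    res = linprog(
        sign * spec.c_obj,
        A_ub=spec.A_ub,
        b_ub=spec.b_ub,
        A_eq=spec.A_eq,
        b_eq=spec.b_eq,
        bounds=np.column_stack([spec.lb, spec.ub]),
        method="highs",
        options=dict(_HIGHS_OPTIONS),
    )
    if res.status == 0:
        return SolutionStatus.OPTIMAL, res.x, res
    if res.status == 2:
        return SolutionStatus.INFEASIBLE, None, res
    if res.status == 3:
        return SolutionStatus.UNBOUNDED, None, res
    raise SolverError(f"LP solver failure (status {res.status}): {res.message}")


def _extract_solution(
    cm: CommunityModel, spec: LPSpec, status: SolutionStatus,
    x: np.ndarray | None, res: object,
) -> BalancedGrowthSolution:
    if status is not SolutionStatus.OPTIMAL:
        return BalancedGrowthSolution(status=status, fractions=spec.fractions)
    assert x is not None
    residual = np.abs(spec.A_eq @ x - spec.b_eq)
    if residual.size and residual.max() > RESIDUAL_TOL:
        raise SolverError(
            f"steady-state residual {residual.max():.3e} exceeds {RESIDUAL_TOL}"
        )
    q: dict[tuple[str, str], float] = {}
    k = 0
    for s in cm.species:
        for r in s.reactions:
            q[(s.species_id, r.id)] = float(x[k])
            k += 1
    mu = float(x[spec.var_index(MU_VAR)])
    phi = {ex.id: float(x[spec.var_index(ex.id)]) for ex in cm.env_exchanges}
    binding = [
        name
        for name, v, lo, hi in zip(spec.var_names, x, spec.lb, spec.ub)
        if (np.isfinite(lo) and v - lo <= BINDING_TOL and lo != hi)
        or (np.isfinite(hi) and hi - v <= BINDING_TOL and lo != hi)
    ]
    duals = None
    eqlin = getattr(res, "eqlin", None)
    if eqlin is not None and getattr(eqlin, "marginals", None) is not None:
        duals = {
            row: float(d) for row, d in zip(spec.row_names, eqlin.marginals)
        }
    obj = float(spec.c_obj @ x)
    return BalancedGrowthSolution(
        status=status, mu=mu, q=q, phi=phi, objective_value=obj,
        duals=duals, binding=binding, fractions=spec.fractions,
    )


def maximize_growth_at_fractions(
    cm: CommunityModel,
    f: FractionVector,
    extra_constraints: Sequence[LinearConstraint] = (),
) -> BalancedGrowthSolution:
    """Maximal balanced-growth rate μ*(f) at fixed biomass fractions."""
    spec = build_lp(cm, f, Objective.MAX_MU, extra_constraints=extra_constraints)
    status, x, res = solve_lp(spec)
    return _extract_solution(cm, spec, status, x, res)


def optimize_flux_at_growth(
    cm: CommunityModel,
    f: FractionVector,
    fixed_mu: float,
    flux_id: str,
    sense: str = "min",
    extra_constraints: Sequence[LinearConstraint] = (),
) -> BalancedGrowthSolution:
    """Optimize a named flux subject to balanced growth at μ = fixed_mu.

    Returns INFEASIBLE when fixed_mu exceeds μ*(f).  ``flux_id`` is
    ``"<species>__<reaction>"``, an exchange id, or ``"mu"``.
    """
    objective = Objective.MIN_FLUX if sense == "min" else Objective.MAX_FLUX
    spec = build_lp(
        cm, f, objective, objective_flux=flux_id, fixed_mu=fixed_mu,
        extra_constraints=extra_constraints,
    )
    status, x, res = solve_lp(spec)
    return _extract_solution(cm, spec, status, x, res)


def flux_ranges_at_optimum(
    cm: CommunityModel,
    f: FractionVector,
    rel_tol: float = 0.0,
    flux_ids: Sequence[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Variability ranges of every flux over near-optimal solutions.

    Min and max of each flux subject to μ ≥ (1 − rel_tol)·μ*(f).  With
    alternate optima the incumbent flux vector is solver-dependent; these
    ranges are the reproducible statement about fluxes at the optimum.
    """
    best = maximize_growth_at_fractions(cm, f)
    if not best.optimal:
        raise ModelError(f"no optimum at f={f.f}: status {best.status.value}")
    spec = build_lp(cm, f, Objective.MAX_MU)
    mu_i = spec.var_index(MU_VAR)
    spec.lb[mu_i] = max(spec.lb[mu_i], (1.0 - rel_tol) * best.mu)  # type: ignore[operator]
    names = list(flux_ids) if flux_ids is not None else [
        v for v in spec.var_names if v != MU_VAR
    ]
    out: dict[str, tuple[float, float]] = {}
    for name in names:
        j = spec.var_index(name)
        lohi = []
        for maximize in (False, True):
            spec.c_obj = np.zeros(len(spec.var_names))
            spec.c_obj[j] = 1.0
            spec.maximize = maximize
            status, x, _ = solve_lp(spec)
            if status is not SolutionStatus.OPTIMAL:
                raise SolverError(
                    f"flux range subproblem for {name!r}: {status.value}"
                )
            lohi.append(float(x[j]))
        out[name] = (lohi[0], lohi[1])
    return out
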