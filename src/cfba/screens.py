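"""Phase planes over flux bounds, limitation regimes, cross-feed screens.

Scanning the maximal community growth rate over a 2-D grid of flux-bound
values is the community analogue of single-species phenotype phase plane
analysis.  Each cell re-optimizes the community over the whole fraction
simplex at those bounds.  Cells are classified by which of the scanned
bounds limits the optimum: neither (the environment limits), one (a
cross-feeding capacity limits), or both (dual limitation — relaxing
either bound raises the optimum).  Because the outer argmax over
fractions is located by grid refinement, a limiting bound is generally
not binding to solver precision in the inner LP at the refined argmax;
classification therefore probes each bound by a small envelope
perturbation with local re-optimization.  :func:`find_dual_limitation`
repeats the probe with full re-optimization from a fresh coarse scan,
as the slower, independent confirmation.

The cross-feeding screen asks which exchanged metabolite best explains
an observed community state: each candidate is opened one at a time
(all competing candidate routes closed), the growth rate is pinned to
the observed value, and the substrate uptake needed to support it is
minimized over fractions and fluxes.  Candidates are ranked by percent
change of that minimum against a reference metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .lp import (
    LinearConstraint,
    maximize_growth_at_fractions,
    optimize_flux_at_growth,
)
from .model import (
    CommunityModel,
    FractionVector,
    ModelError,
    ReactionKind,
)
from .optimize import (
    CommunityInfeasibleError,
    optimize_community,
    simplex_grid,
)

__all__ = [
    "PhaseRegime",
    "PhasePlaneResult",
    "ScreenStatus",
    "ScreenCandidate",
    "ScreenResult",
    "phase_plane",
    "find_dual_limitation",
    "crossfeed_screen",
]


class PhaseRegime(str, Enum):
    CROSSFEED_LIMITED = "crossfeed_limited"
    ENV_LIMITED = "env_limited"
    DUAL_LIMITED = "dual_limited"
    INFEASIBLE = "infeasible"


@dataclass
class PhasePlaneResult:
    cm: CommunityModel
    bound1: tuple[str, str]
    grid1: np.ndarray
    bound2: tuple[str, str]
    grid2: np.ndarray
    mu_max_grid: np.ndarray       # shape (len(grid1), len(grid2)); NaN infeasible
    regime_grid: np.ndarray       # PhaseRegime values, same shape
    argmax_grid: np.ndarray       # FractionVector per cell (object array)
    coarse_resolution: float
    refine_tol: float

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, b1 in enumerate(self.grid1):
            for j, b2 in enumerate(self.grid2):
                rows.append({
                    "bound1": b1, "bound2": b2,
                    "mu_max": self.mu_max_grid[i, j],
                    "regime": self.regime_grid[i, j].value
                    if isinstance(self.regime_grid[i, j], PhaseRegime)
                    else str(self.regime_grid[i, j]),
                })
        return pd.DataFrame(rows)


def _bounded_copy(
    cm: CommunityModel,
    bound1: tuple[str, str], v1: float,
    bound2: tuple[str, str], v2: float,
) -> CommunityModel:
    r1 = cm.get_species(bound1[0]).get_reaction(bound1[1])
    r2 = cm.get_species(bound2[0]).get_reaction(bound2[1])
    return cm.with_reaction_bounds({
        bound1: (r1.lower_bound, v1),
        bound2: (r2.lower_bound, v2),
    })


def _optimize_local(
    cm_cell: CommunityModel,
    f_start: FractionVector,
    step0: float,
    refine_tol: float,
) -> float | None:
    """Best μ reachable by local factor-5 refinement from ``f_start``."""
    from .optimize import _local_grid

    species = cm_cell.species_ids
    best_mu: float | None = None
    best_f = f_start
    sol = maximize_growth_at_fractions(cm_cell, f_start)
    if sol.optimal:
        best_mu = sol.mu
    step = step0
    while step > refine_tol and len(species) > 1:
        for f in _local_grid(best_f, species, step, halfwidth=5):
            sol = maximize_growth_at_fractions(cm_cell, f)
            if sol.optimal and (best_mu is None or sol.mu > best_mu):
                best_mu, best_f = sol.mu, f
        step /= 5.0
    return best_mu


def _classify_cell(
    cm_cell: CommunityModel,
    f: FractionVector,
    mu_best: float,
    bound1: tuple[str, str],
    bound2: tuple[str, str],
    step0: float,
    refine_tol: float,
    eps: float = 0.01,
    tol: float = 1e-6,
) -> PhaseRegime:
    """Regime of a cell by envelope perturbation of each scanned bound.

    A bound is limiting when lowering it by the relative perturbation
    ``eps`` (re-optimizing fractions locally around the incumbent
    argmax) lowers the optimum by more than ``tol``.  The inner-LP
    active set is unreliable here: the grid-refined argmax sits a small
    step away from the exact peak, where a truly limiting bound is not
    yet binding to solver precision.  For the same reason the probe
    signal must dominate the refinement granularity: both optima carry
    an error of order (slope × refine_tol), so ``eps`` is kept well
    above ``refine_tol``.
    """
    active = []
    for key in (bound1, bound2):
        rxn = cm_cell.get_species(key[0]).get_reaction(key[1])
        ub = rxn.upper_bound
        if not np.isfinite(ub):
            active.append(False)
            continue
        new_ub = ub * (1.0 - eps) if ub > 0 else 0.0
        if new_ub == ub:
            # a zero bound cannot be tightened: probe by opening it
            opened = cm_cell.with_reaction_bounds(
                {key: (rxn.lower_bound, eps)})
            mu_p = _optimize_local(opened, f, step0, refine_tol)
            active.append(mu_p is not None and mu_p - mu_best > tol)
            continue
        tightened = cm_cell.with_reaction_bounds(
            {key: (rxn.lower_bound, new_ub)})
        mu_p = _optimize_local(tightened, f, step0, refine_tol)
        active.append(mu_p is None or mu_best - mu_p > tol)
    if all(active):
        return PhaseRegime.DUAL_LIMITED
    if any(active):
        return PhaseRegime.CROSSFEED_LIMITED
    return PhaseRegime.ENV_LIMITED


def phase_plane(
    cm: CommunityModel,
    bound1: tuple[str, str],
    grid1: np.ndarray,
    bound2: tuple[str, str],
    grid2: np.ndarray,
    coarse_resolution: float = 0.05,
    refine_tol: float = 1e-6,
) -> PhasePlaneResult:
    """Maximal community growth rate over a 2-D grid of upper bounds.

    ``bound1``/``bound2`` are ``(species_id, reaction_id)`` pairs whose
    upper bounds are set to each grid value; at every cell the community
    is re-optimized over the biomass-fraction simplex.  Grids must be
    strictly increasing (the optimum is then nondecreasing along both
    axes, since raising an upper bound only relaxes the problem, up to
    the refinement granularity of the outer search).  ``refine_tol``
    deliberately defaults tighter than for one-off optimizations: cell
    values are compared against each other and against perturbed
    re-solves, so their refinement error must be small.
    """
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    for g, name in ((grid1, "grid1"), (grid2, "grid2")):
        if g.ndim != 1 or len(g) < 1 or (np.diff(g) <= 0).any():
            raise ModelError(f"{name} must be strictly increasing")
    for sp_id, rxn_id in (bound1, bound2):
        cm.get_species(sp_id).get_reaction(rxn_id)  # raises KeyError if absent
    mu = np.full((len(grid1), len(grid2)), np.nan)
    regime = np.empty((len(grid1), len(grid2)), dtype=object)
    argmax = np.empty((len(grid1), len(grid2)), dtype=object)
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            cell = _bounded_copy(cm, bound1, v1, bound2, v2)
            try:
                mu_best, f_best, _ = optimize_community(
                    cell, coarse_resolution, refine_tol
                )
            except CommunityInfeasibleError:
                regime[i, j] = PhaseRegime.INFEASIBLE
                continue
            mu[i, j] = mu_best
            argmax[i, j] = f_best
            regime[i, j] = _classify_cell(
                cell, f_best, mu_best, bound1, bound2,
                coarse_resolution, refine_tol,
            )
    return PhasePlaneResult(
        cm=cm, bound1=bound1, grid1=grid1, bound2=bound2, grid2=grid2,
        mu_max_grid=mu, regime_grid=regime, argmax_grid=argmax,
        coarse_resolution=coarse_resolution, refine_tol=refine_tol,
    )


def find_dual_limitation(
    pp: PhasePlaneResult,
    tol: float = 1e-6,
    eps: float = 1e-3,
) -> list[tuple[int, int]]:
    """Cells where shrinking either scanned bound lowers the optimum.

    Each candidate cell is re-solved twice with one bound reduced by the
    relative perturbation ``eps``; the cell is dual-limited when both
    perturbations reduce the optimal growth rate by more than ``tol``.
    Unlike the classification stored in the phase plane (which restarts
    from the incumbent argmax), this probe re-optimizes from a fresh
    coarse scan, serving as the independent confirmation.
    """
    refine = min(pp.refine_tol, 1e-6)
    cells: list[tuple[int, int]] = []
    for i, v1 in enumerate(pp.grid1):
        for j, v2 in enumerate(pp.grid2):
            base = pp.mu_max_grid[i, j]
            if not np.isfinite(base) or v1 == 0 or v2 == 0:
                continue
            dual = True
            for pert in ((v1 * (1 - eps), v2), (v1, v2 * (1 - eps))):
                cell = _bounded_copy(pp.cm, pp.bound1, pert[0], pp.bound2, pert[1])
                try:
                    mu_p, _, _ = optimize_community(
                        cell, pp.coarse_resolution, refine
                    )
                except CommunityInfeasibleError:
                    continue  # perturbation made it infeasible: limiting
                if base - mu_p <= tol:
                    dual = False
                    break
            if dual:
                cells.append((i, j))
    return cells


# ---------------------------------------------------------------------------
# cross-feeding metabolite screen
# ---------------------------------------------------------------------------

class ScreenStatus(str, Enum):
    OK = "ok"
    BLOCKED = "blocked"
    INFEASIBLE = "infeasible"


@dataclass
class ScreenCandidate:
    metabolite: str
    status: ScreenStatus
    min_uptake: float | None = None
    percent_change: float | None = None
    argmin_fractions: FractionVector | None = None


@dataclass
class ScreenResult:
    reference_metabolite: str
    fixed_mu: float
    substrate_exchange_id: str
    candidates: list[ScreenCandidate] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([
            {
                "metabolite": c.metabolite,
                "status": c.status.value,
                "min_uptake": c.min_uptake,
                "percent_change": c.percent_change,
            }
            for c in self.candidates
        ])
        return df.sort_values(
            "percent_change", na_position="last"
        ).reset_index(drop=True)


def _candidate_routes(cm: CommunityModel, met_id: str) -> dict[str, list[str]]:
    """Cross-feeding transports touching ``met_id``, per species."""
    routes: dict[str, list[str]] = {}
    for s in cm.species:
        hits = [
            r.id for r in s.reactions
            if r.kind is ReactionKind.CROSSFEED_TRANSPORT
            and met_id in r.stoichiometry
        ]
        if hits:
            routes[s.species_id] = hits
    return routes


def _min_substrate_uptake(
    cm: CommunityModel,
    fixed_mu: float,
    substrate_exchange_id: str,
    resolution: float,
    refine_tol: float,
    extra_constraints: tuple[LinearConstraint, ...] = (),
) -> tuple[float, FractionVector] | None:
    """Minimize substrate uptake magnitude at fixed μ over the simplex.

    Exchange fluxes are export-positive, so minimizing uptake means
    maximizing the (negative) exchange flux toward zero.
    """
    species = cm.species_ids

    def solve_at(f: FractionVector) -> float | None:
        sol = optimize_flux_at_growth(
            cm, f, fixed_mu, substrate_exchange_id, sense="max",
            extra_constraints=extra_constraints,
        )
        if not sol.optimal:
            return None
        return -sol.phi[substrate_exchange_id]

    best: tuple[float, FractionVector] | None = None
    for f in simplex_grid(species, resolution):
        up = solve_at(f)
        if up is not None and (best is None or up < best[0]):
            best = (up, f)
    if best is None:
        return None
    step = resolution
    while step > refine_tol and len(species) > 1:
        step /= 5.0
        from .optimize import _local_grid
        for f in _local_grid(best[1], species, step, halfwidth=5):
            up = solve_at(f)
            if up is not None and up < best[0]:
                best = (up, f)
    return best


def crossfeed_screen(
    cm: CommunityModel,
    candidate_ids: list[str],
    fixed_mu: float,
    substrate_exchange_id: str,
    reference_id: str,
    resolution: float = 0.02,
    refine_tol: float = 1e-4,
    in_addition_to_reference: bool = False,
    extra_constraints: tuple[LinearConstraint, ...] = (),
) -> ScreenResult:
    """Rank candidate cross-fed metabolites by substrate economy.

    For each candidate, all other candidates' transport routes are
    closed, the candidate's own routes are opened without capacity
    limits, the community growth rate is fixed at ``fixed_mu`` and the
    uptake of the named substrate exchange is minimized over fractions.
    A candidate transportable by fewer than two species is BLOCKED.
    With ``in_addition_to_reference`` the reference metabolite's routes
    stay open alongside each candidate instead of being closed.
    """
    if reference_id not in candidate_ids:
        candidate_ids = [reference_id] + list(candidate_ids)
    cm.get_exchange(substrate_exchange_id)
    result = ScreenResult(
        reference_metabolite=reference_id,
        fixed_mu=fixed_mu,
        substrate_exchange_id=substrate_exchange_id,
    )
    routes = {cid: _candidate_routes(cm, cid) for cid in candidate_ids}
    minima: dict[str, tuple[float, FractionVector] | None] = {}
    for cid in candidate_ids:
        if len(routes[cid]) < 2:
            result.candidates.append(
                ScreenCandidate(cid, ScreenStatus.BLOCKED)
            )
            minima[cid] = None
            continue
        updates: dict[tuple[str, str] | str, tuple[float, float]] = {}
        keep_open = {cid}
        if in_addition_to_reference:
            keep_open.add(reference_id)
        for other in candidate_ids:
            if other in keep_open:
                continue
            for sp_id, rxns in routes[other].items():
                for rxn_id in rxns:
                    updates[(sp_id, rxn_id)] = (0.0, 0.0)
        for opened in keep_open:
            for sp_id, rxns in routes[opened].items():
                for rxn_id in rxns:
                    rxn = cm.get_species(sp_id).get_reaction(rxn_id)
                    lb = -np.inf if rxn.lower_bound < 0 else 0.0
                    updates[(sp_id, rxn_id)] = (lb, np.inf)
        cell = cm.with_reaction_bounds(updates)
        best = _min_substrate_uptake(
            cell, fixed_mu, substrate_exchange_id, resolution, refine_tol,
            extra_constraints,
        )
        minima[cid] = best
        if best is None:
            result.candidates.append(
                ScreenCandidate(cid, ScreenStatus.INFEASIBLE)
            )
        else:
            result.candidates.append(
                ScreenCandidate(cid, ScreenStatus.OK, best[0],
                                argmin_fractions=best[1])
            )
    ref = minima.get(reference_id)
    if ref is not None:
        q_ref = ref[0]
        for cand in result.candidates:
            if cand.status is ScreenStatus.OK:
                if cand.metabolite == reference_id:
                    cand.percent_change = 0.0
                else:
                    cand.percent_change = 100.0 * (cand.min_uptake - q_ref) / q_ref
    return result
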