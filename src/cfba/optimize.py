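"""Outer optimization over the biomass-fraction simplex.

The balanced-growth problem is bilinear in fractions and fluxes, but at
fixed fractions it is an LP.  The global community optimum is therefore
found by repeating the LP over a deterministic grid on the fraction
simplex and refining locally around the incumbent — reproducible, unlike
derivative-free search heuristics, and the scan itself is a result: the
shape of μ*(f) distinguishes metabolic limitation regimes.

Fractions where no balanced-growth steady state exists are kept in the
scan with an explicit infeasible status; they are excluded from the
argmax but must not be conflated with μ* = 0 (a community that exists
but cannot grow).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lp import (
    LinearConstraint,
    SolutionStatus,
    maximize_growth_at_fractions,
)
from .model import CommunityModel, FractionVector, ModelError

__all__ = [
    "FractionScanResult",
    "OptimalRegion",
    "CommunityInfeasibleError",
    "simplex_grid",
    "scan_fractions",
    "optimize_community",
    "optimal_fraction_region",
    "scan_biomass_ratio",
]

#: default coarse scan resolutions by community size
DEFAULT_RESOLUTION_2 = 0.01
DEFAULT_RESOLUTION_N = 0.05
#: default refinement stopping step and plateau tolerance
DEFAULT_REFINE_TOL = 1e-5
DEFAULT_PLATEAU_TOL = 1e-6


class CommunityInfeasibleError(ModelError):
    """No fraction vector on the scan grid admits balanced growth."""


@dataclass
class FractionScanResult:
    """μ*(f) tabulated over a grid of biomass-fraction vectors."""

    species_order: list[str]
    grid: list[FractionVector]
    mu_star: np.ndarray          # NaN where not OPTIMAL
    status: list[SolutionStatus]
    ratios: np.ndarray | None = None  # set by scan_biomass_ratio

    @property
    def feasible(self) -> np.ndarray:
        return ~np.isnan(self.mu_star)

    @property
    def mu_max(self) -> float:
        if not self.feasible.any():
            raise CommunityInfeasibleError(
                "no feasible fraction vector in the scan"
            )
        return float(np.nanmax(self.mu_star))

    @property
    def argmax(self) -> FractionVector:
        if not self.feasible.any():
            raise CommunityInfeasibleError(
                "no feasible fraction vector in the scan"
            )
        return self.grid[int(np.nanargmax(self.mu_star))]

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            f"f_{sp}": [g[sp] for g in self.grid] for sp in self.species_order
        }
        if self.ratios is not None:
            data["ratio"] = self.ratios
        data["mu_star"] = self.mu_star
        data["status"] = [s.value for s in self.status]
        return pd.DataFrame(data)


@dataclass
class OptimalRegion:
    """The set {f : μ*(f) ≥ (1 − tol)·μ_max}.

    For two species this is one or more intervals in the first species'
    fraction; for larger communities the near-optimal grid points are
    reported instead.
    """

    tol: float
    mu_max: float
    intervals: list[tuple[float, float]] = field(default_factory=list)
    points: list[FractionVector] = field(default_factory=list)

    @property
    def width(self) -> float:
        return sum(hi - lo for lo, hi in self.intervals)


def simplex_grid(species: list[str], resolution: float) -> list[FractionVector]:
    """Uniform grid on the fraction simplex with step ``resolution``."""
    if not 0 < resolution <= 0.5:
        raise ModelError(f"resolution must be in (0, 0.5], got {resolution}")
    n = len(species)
    if n == 1:
        return [FractionVector({species[0]: 1.0})]
    m = int(round(1.0 / resolution))
    out = []
    for combo in itertools.combinations(range(m + n - 1), n - 1):
        ks = []
        prev = -1
        for c in combo:
            ks.append(c - prev - 1)
            prev = c
        ks.append(m + n - 2 - prev)
        out.append(FractionVector({sp: k / m for sp, k in zip(species, ks)}))
    return out


def scan_fractions(
    cm: CommunityModel,
    resolution: float = DEFAULT_RESOLUTION_2,
    extra_constraints: tuple[LinearConstraint, ...] = (),
    grid: list[FractionVector] | None = None,
) -> FractionScanResult:
    """Solve the balanced-growth LP on a simplex grid of fractions."""
    species = cm.species_ids
    if grid is None:
        grid = simplex_grid(species, resolution)
    mu = np.full(len(grid), np.nan)
    status: list[SolutionStatus] = []
    for i, f in enumerate(grid):
        sol = maximize_growth_at_fractions(cm, f, extra_constraints)
        status.append(sol.status)
        if sol.optimal:
            mu[i] = sol.mu
    return FractionScanResult(species, list(grid), mu, status)


def _local_grid(
    center: FractionVector, species: list[str], step: float, halfwidth: int
) -> list[FractionVector]:
    """Simplex points around ``center`` at spacing ``step``."""
    n = len(species)
    c = center.as_array(species)
    offsets = range(-halfwidth, halfwidth + 1)
    out = []
    for deltas in itertools.product(offsets, repeat=n - 1):
        d = np.array(deltas + (-sum(deltas),), dtype=float) * step
        f = c + d
        if abs(d[-1]) > halfwidth * step + 1e-15:
            continue
        if (f < -1e-12).any() or (f > 1 + 1e-12).any():
            continue
        f = np.clip(f, 0.0, 1.0)
        out.append(FractionVector.from_array(species, f / f.sum()))
    return out


def optimize_community(
    cm: CommunityModel,
    coarse_resolution: float | None = None,
    refine_tol: float = DEFAULT_REFINE_TOL,
    extra_constraints: tuple[LinearConstraint, ...] = (),
) -> tuple[float, FractionVector, FractionScanResult]:
    """Global maximal community growth rate over the fraction simplex.

    A coarse scan locates the incumbent; factor-5 local grid refinement
    around it proceeds until the fraction step drops below
    ``refine_tol``.  Refinement always includes the incumbent, so the
    result is never below the coarse-scan maximum.
    """
    species = cm.species_ids
    if coarse_resolution is None:
        coarse_resolution = (
            DEFAULT_RESOLUTION_2 if len(species) <= 2 else DEFAULT_RESOLUTION_N
        )
    scan = scan_fractions(cm, coarse_resolution, extra_constraints)
    if not scan.feasible.any():
        raise CommunityInfeasibleError(
            "community infeasible: no grid fraction admits balanced growth"
        )
    best_mu = scan.mu_max
    best_f = scan.argmax
    step = coarse_resolution
    while step > refine_tol and len(species) > 1:
        step /= 5.0
        local = _local_grid(best_f, species, step, halfwidth=5)
        for f in local:
            sol = maximize_growth_at_fractions(cm, f, extra_constraints)
            if sol.optimal and sol.mu > best_mu:
                best_mu, best_f = sol.mu, f
    return best_mu, best_f, scan


def optimal_fraction_region(
    cm: CommunityModel,
    scan: FractionScanResult,
    tol: float = DEFAULT_PLATEAU_TOL,
    extra_constraints: tuple[LinearConstraint, ...] = (),
    bisect_iter: int = 40,
) -> OptimalRegion:
    """Near-optimal fraction region(s) at relative tolerance ``tol``.

    For two species the endpoints of each contiguous near-optimal run
    are refined by bisection against the neighbouring grid points.
    """
    mu_max = scan.mu_max
    threshold = (1.0 - tol) * mu_max
    good = scan.feasible & (scan.mu_star >= threshold - 1e-15)
    region = OptimalRegion(tol=tol, mu_max=mu_max)
    species = scan.species_order
    if len(species) != 2:
        region.points = [g for g, ok in zip(scan.grid, good) if ok]
        return region

    sp0 = species[0]
    order = np.argsort([g[sp0] for g in scan.grid])
    xs = np.array([scan.grid[i][sp0] for i in order])
    ok = good[order]

    def predicate(x: float) -> bool:
        f = FractionVector({species[0]: x, species[1]: 1.0 - x})
        sol = maximize_growth_at_fractions(cm, f, extra_constraints)
        return sol.optimal and sol.mu >= threshold - 1e-15

    def bisect(inside: float, outside: float) -> float:
        for _ in range(bisect_iter):
            mid = 0.5 * (inside + outside)
            if predicate(mid):
                inside = mid
            else:
                outside = mid
        return inside

    i = 0
    while i < len(xs):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(xs) and ok[j + 1]:
            j += 1
        lo = xs[i] if i == 0 else bisect(xs[i], xs[i - 1])
        hi = xs[j] if j == len(xs) - 1 else bisect(xs[j], xs[j + 1])
        region.intervals.append((float(lo), float(hi)))
        i = j + 1
    return region


def scan_biomass_ratio(
    cm: CommunityModel,
    ratio_grid: np.ndarray,
    extra_constraints: tuple[LinearConstraint, ...] = (),
) -> FractionScanResult:
    """Scan μ* over the biomass ratio r = X_2 / X_1 of a two-species pair.

    Since f_2 = r / (1 + r), this is the fraction scan under a change of
    variables — convenient when experiments report strain ratios.
    """
    if len(cm.species) != 2:
        raise ModelError("biomass-ratio scan requires exactly two species")
    ratios = np.asarray(ratio_grid, dtype=float)
    if (ratios <= 0).any():
        raise ModelError("biomass ratios must be positive")
    sp1, sp2 = cm.species_ids
    grid = [
        FractionVector({sp1: 1.0 / (1.0 + r), sp2: r / (1.0 + r)})
        for r in ratios
    ]
    scan = scan_fractions(cm, grid=grid, extra_constraints=extra_constraints)
    scan.ratios = ratios
    return scan
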