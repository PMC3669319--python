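# Methods

## The balanced-growth community model

`cfba` implements community flux balance analysis: constraint-based
prediction of the metabolic state of a microbial consortium whose member
species all grow exponentially at one shared specific rate μ (h⁻¹) while
every variable metabolite — intracellular in each species and shared
extracellular — is at steady state. Under that balanced-growth
assumption the mass balance of metabolite *i* reads

    Σ_j f_j ( Σ_l n_{ij,l} q_{l,j} + c_{ij} μ ) + Σ_k b_{ik} φ_k = 0

where `f_j = X_j / X_T` is the biomass fraction of species *j* (constant
in time under balanced growth), `q_{l,j}` its specific fluxes
(mmol·gDW⁻¹·h⁻¹), `c_{ij}` its biomass composition (mmol per gDW,
consumed components negative), and `φ_k = J_k / X_T` the specific
environmental exchange fluxes. The full problem is bilinear (fractions
multiply fluxes), but at **fixed fractions** it is a linear program: one
equality row per metabolite, variables `q`, `φ` and a single shared μ
that multiplies every species' biomass column. Sharing one μ variable
encodes the equal-growth-rate requirement structurally — no extra
equality rows, no per-species growth variables.

Because the constraint set (without flux lower bounds above zero) is a
cone, the optimum scales proportionally with whichever environmental
influx bound is binding; what the optimization really fixes is the
biomass yield on the limiting substrate, exactly as in single-species
FBA. This scaling law is asserted by tests on fixtures whose other
bounds are deliberately non-binding.

The global community optimum is found by repeating the LP over a
deterministic grid on the fraction simplex and refining locally
(factor-5 grids around the incumbent) until the fraction step drops
below a tolerance. A grid-plus-refinement scheme was chosen over
derivative-free search because it is reproducible, trivially
restartable, and the scan itself is a deliverable: the shape of μ*(f)
distinguishes limitation regimes. Fractions where the LP is infeasible
are first-class results ("no balanced-growth state exists here"), kept
separate from μ* = 0 ("the community exists but cannot grow"); plotting
layers may render both as zero.

## Numerical choices

- Solver: HiGHS through `scipy.optimize.linprog`; primal/dual
  feasibility tolerances 1e-9. Every OPTIMAL solution is checked to have
  balance residuals ≤ 1e-8 on all rows; a violation raises a solver
  error rather than returning a silently wrong state.
- μ is constrained ≥ 0: washout/decay is outside the balanced-growth
  formalism. Fixing μ (chemostat mode, μ = dilution rate D) is
  implemented by pinning the μ variable's bounds.
- Growth maximization is refused up front ("unbounded by construction")
  when no finite bound exists that could cap the optimum — a lower
  bound of exactly zero only states irreversibility and does not count.
- Alternate optima: the incumbent flux vector at an optimum is
  solver-dependent, so reported flux claims go through FVA-style ranges
  (min/max of each flux subject to μ ≥ (1 − tol)·μ*).
- Default scan resolutions: 0.01 for two species, 0.05 for three or
  more; refinement to 1e-5. Plateau (near-optimal region) tolerance
  1e-6 relative, endpoints refined by bisection.
- Exchange sign convention: export-positive (exchanged metabolite gets
  coefficient −1); uptake is a negative exchange flux. Absolute
  environmental bounds J (mmol·h⁻¹) are converted once to specific
  bounds φ = J/X_T, keeping the LP dimensionally uniform; the total
  biomass X_T enters only through this conversion.
- Species identity of extracellular metabolites is by exact declared id
  match across models, never by name heuristics.

## Phase planes and limitation regimes

A phase plane re-optimizes the community (over all fractions) on a 2-D
grid of two reactions' upper bounds — typically the two cross-feeding
capacities. Cells are classified as environment-limited (neither
scanned bound limits), cross-feed-limited (one does) or dual-limited
(both do). Classification is by envelope finite differences: a bound is
limiting when lowering it by 1% and re-optimizing locally lowers the
optimum by more than 1e-6. An LP active-set test at the refined argmax
was tried first and abandoned: the outer argmax usually sits at a kink
of μ*(f), and a grid-refined argmax lies a small step away from the
exact peak where a truly limiting bound still has slack of order
(slope × refinement step) — far above any solver binding tolerance, so
the active set under-reports limitation. For the same reason the
phase-plane refinement tolerance defaults tighter (1e-6) than for
one-off optimizations: cell values are compared against each other and
against perturbed re-solves. `find_dual_limitation` repeats the probe
independently (ε = 1e-3, full re-optimization from a fresh coarse
scan); on the toy consortium both routes agree cell-for-cell and the
environment-limited plateau is flat to ~1e-15.

## The cross-feeding screen

Given an observed community growth rate (e.g. a chemostat dilution
rate), the screen asks which exchanged metabolite best explains the
data: each candidate is opened one at a time with unbounded transport
(all competing candidates' routes closed; optionally the reference
stays open as well), μ is fixed, and the substrate uptake needed to
sustain it is minimized over fractions and fluxes. Candidates are
ranked by percent change against the reference; a candidate lacking
transporters in at least two species is reported BLOCKED, with no
number. Uptake is reported as a positive magnitude (the exchange flux
itself is negative under the export-positive convention).

## What the synthetic consortia emulate

No coefficient set for the canonical two-species cross-feeding motif is
available as data, so the fixtures freeze their own, chosen to be
pseudo-elementally balanced (C/N tokens; energy and redox carriers are
deliberately unannotated and skipped by the balance validator) and to
reproduce the qualitative regime structure of an obligate mutualism:

- **Toy pair** (`make_toy_consortium`): a glucose consumer (uptake
  capacity 20 mmol·gDW⁻¹·h⁻¹) excreting a 3-carbon succinate analog,
  and a nitrogen fixer returning ammonium, each with catabolism,
  respiration, product formation and anabolism plus an ATP maintenance
  drain (lower bound 12 mmol ATP·gDW⁻¹·h⁻¹, a deliberately large toy
  value). Glucose influx 10 mmol·h⁻¹ at X_T = 1 gDW is limiting;
  dinitrogen is in excess. With these frozen round coefficients the
  unconstrained-cross-feeding optimum is exactly μ = 2.0 h⁻¹ on the
  plateau f_glc ∈ [1/2, 5/6]; below a critical consumer fraction
  (≈ 0.118) the maintenance demand of the partner cannot be met and no
  balanced-growth state exists at all. Maintenance is the essential
  ingredient for that infeasible flank: without a strictly positive
  flux lower bound the feasible set is a cone and any positive state
  could simply scale down. Conversely, the proportional-scaling law
  presumes no always-binding lower bound, so scaling tests use a
  maintenance-free variant with slack capacities. Tuning the ammonium
  export capacity reproduces the other regimes: 4 gives a unique
  optimal fraction (critical cross-feeding), 6 trims the plateau
  without lowering the optimum (above-critical), 2 lowers the maximum
  itself (below-critical).
- **Minimal pair** (`make_minimal_pair`): an 11-free-variable obligate
  pair whose μ*(f) is piecewise linear in closed form
  (min(2·qmax·f, 2·J) for f ≤ 1/2, else 0). Small enough for
  brute-force enumeration of LP basic solutions, which is the
  independent oracle for the LP path; its overflow exchanges are pinned
  to zero to keep the enumeration space minimal.
- **Random chain communities** (`make_random_community`): seeded
  producer→consumer chains with growth-coupled excretion; positive
  community growth exists only at chain-matched fractions, exercising
  the N-species scan and the merged-matrix bookkeeping.
- **Screen consortium** (`make_screen_consortium`): three alternative
  carbon carriers with consumer-side yields 1.0, 2/3 and 0.8 plus a
  producer-only decoy, giving a known screen ranking (0%, +10%, +5%,
  BLOCKED) at μ = 1 h⁻¹.

These fixtures emulate the structure of real consortium models —
shared extracellular pools, obligate exchange loops, capacity and
environmental limits — but not their scale (genome-scale networks have
thousands of reactions), their thermodynamics, or biological parameter
values; passing tests demonstrate correctness of the optimization
machinery, not predictions about any real community. Genome-scale SBML
models are supported through the same reader but are not part of the
test surface.

## Problem sizes and runtime

Tests and the acceptance script size their scans to run comfortably on
one CPU: fraction scans at resolution 0.01 (two species) or 0.02–0.05
(three), exhaustive-oracle comparisons at 1e-4 (two species) and 0.01
(three), phase planes up to 12×12 cells with per-cell refinement 1e-6.
These sizes are the package's own defaults for exploratory work; all
are parameters.

## Known limitations

- Balanced growth only: no dormant/non-growing steady states with
  exchange, no dynamic (time-resolved) extensions, no abiotic
  conversions in the environment.
- Single shared objective (community growth rate, equivalently yield);
  no multi-objective or game-theoretic formulations.
- The outer simplex search is exhaustive-plus-local-refinement; for
  many species (≳6) the grid grows combinatorially and a coarser
  resolution must be chosen explicitly.
- μ*(f) can have multiple local maxima under tuned capacity bounds; the
  coarse scan resolution must be fine enough to see every peak basin
  (the default 0.01 for two species is safe for the built-in fixtures).
- Compartments are limited to per-species intracellular plus one shared
  extracellular space; no gene–protein–reaction rules; reversibility is
  taken from bounds, not thermodynamic calculations.
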