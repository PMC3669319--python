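# cfba — community flux balance analysis at balanced growth

`cfba` predicts the metabolic state of a microbial consortium from the
stoichiometric models of its member species. For a community at
**balanced growth** — all species growing exponentially at one shared
specific rate μ, every intracellular and extracellular metabolite at
steady state — it computes the maximal community growth rate, the
optimal fractional biomass abundances, and all specific fluxes:
intracellular, cross-feeding and environmental exchange. On top of that
single optimization it provides the analyses consortium modellers
actually run: fraction scans and biomass-ratio scans, flux-bound phase
planes with limitation-regime classification (environment-, cross-feed-
or dual-limited), flux variability ranges, and a screen that ranks
candidate cross-feeding metabolites by how economically they explain an
observed growth rate.

It is written for systems biologists and microbial ecologists working
with constraint-based models of defined communities (syntrophic pairs,
synthetic consortia, chemostat enrichments).

## The model

For every variable metabolite *i* the community mass balance is

    Σ_j f_j ( Σ_l n_{ij,l} q_{l,j} + c_{ij} μ ) + Σ_k b_{ik} φ_k = 0

with biomass fractions `f_j = X_j/X_T` (constant under balanced
growth), specific fluxes `q` (mmol·gDW⁻¹·h⁻¹), biomass composition
`c_j`, and specific environmental exchanges `φ_k = J_k/X_T`. At fixed
`f` this is a linear program — one shared μ variable multiplies every
species' biomass column, enforcing equal growth rates structurally —
and the global optimum over the bilinear problem is found by scanning
and refining `f` on the simplex. Flux bounds
`q_min ≤ q ≤ q_max` carry the thermodynamic and capacity constraints;
with a single limiting influx bound the method maximizes biomass
yield on that substrate, just like classical FBA.

Species models are read from SBML Level 3 (with flux-bound and
objective annotations) or a plain two-section TSV dialect; a JSON/YAML
community config declares the species files, which extracellular ids
are cross-fed, environmental exchange bounds, total biomass and
optional chemostat settings. Deterministic synthetic consortia (an
obligate mutualistic pair, a minimal oracle pair, random chain
communities, a screen fixture) are built in, so everything below runs
without any external model files.

## Worked example

```python
from cfba import (make_toy_consortium, optimize_community,
                  optimal_fraction_region, maximize_growth_at_fractions)

cm = make_toy_consortium()          # obligate glucose-consumer / N-fixer pair
mu_max, f_best, scan = optimize_community(cm)
region = optimal_fraction_region(cm, scan)
print(f"mu_max = {mu_max:.4f} 1/h at f = {f_best.f}")
lo, hi = region.intervals[0]
print(f"optimal-fraction plateau: [{lo:.4f}, {hi:.4f}]")
sol = maximize_growth_at_fractions(cm, f_best)
print(f"glucose exchange flux phi = {sol.phi['EX_Glc_e']:.3f} mmol/gDW/h")
print(f"producer glucose uptake q = {sol.q[('glc_consumer','t_glc')]:.3f} mmol/gDW/h")
```

prints

```
mu_max = 2.0000 1/h at f = {'glc_consumer': 0.57, 'n_fixer': 0.43}
optimal-fraction plateau: [0.5000, 0.8333]
glucose exchange flux phi = -10.000 mmol/gDW/h
producer glucose uptake q = 17.544 mmol/gDW/h
```

The community grows at 2 h⁻¹, and any glucose-consumer fraction between
0.50 and 0.83 supports that optimum — a plateau, not a point, because
the cross-feeding capacities are unconstrained and only the
environmental glucose influx (10 mmol·h⁻¹, hence φ = −10 at
X_T = 1 gDW) limits the system. The producer's specific uptake (17.5)
stays below its capacity bound (20). Tightening the ammonium-export
capacity collapses the plateau to a unique optimal fraction or lowers
the optimum altogether; `cfba.phase_plane` maps those regimes over a
grid of capacity bounds and `cfba.find_dual_limitation` locates the
cells where both cross-feeding bounds limit growth simultaneously.

The same analyses are available from the shell:

```sh
cfba make-fixture --kind toy --out fixture/
cfba optimize --config fixture/community.yaml --out results/
cfba scan --config fixture/community.yaml --out results/ \
     --bound glc_consumer t_succ --bound n_fixer t_nh3 \
     --bound-grid 2,8,40 --bound-grid 2,8,40
cfba screen --config fixture/community.yaml ...   # cross-feed screen
```

Every run writes a manifest whose hash depends only on config, version
and solver settings, and identical runs produce bit-identical outputs.

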