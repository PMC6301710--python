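# Methods

## The reduced metabolic network

The bundled model lumps the anaerobic glycerol metabolism of *Clostridium
butyricum* into 16 reactions over 9 balanced intracellular metabolites
(glycerol, DHAP, pyruvate, acetyl-CoA, free CoA, NADH, reduced ferredoxin,
intracellular H₂, ATP).  The reductive branch converts glycerol to
1,3-propanediol with exactly one NADH consumed per PDO; the oxidative branch
carries the ATP/NADH stoichiometry of glycerol dehydrogenase + DHA kinase
(−1 ATP, +1 NADH per triose) and lower glycolysis (+2 ATP, +1 NADH), then
pyruvate:ferredoxin oxidoreductase (CO₂ + reduced ferredoxin).  Electrons
leave through hydrogenase (Fd→H₂), an NADH-dependent hydrogenase route, or a
ferredoxin-NAD⁺ reductase that turns Fd electrons into NADH — the electron
flexibility typical of clostridia, and the reason predicted PDO yields can
exceed the naive 2/3 bound.  Fermentative sinks are acetate (+1 ATP),
butyrate (+1 ATP per 2 acetyl-CoA, −2 NADH), lactate, ethanol and butanol.
An ATP hydrolysis reaction provides maintenance (lower bound = NGAM,
default 0) and an ATP sink.

Every metabolite carries a carbon count and a degree-of-reduction electron
count, and every reaction balances both exactly; the test suite asserts
carbon conservation along whole trajectories to 1e-6 relative.

### Biomass

Biomass is assembled from 8 macromolecule mass fractions (protein 0.52, RNA
0.155, DNA 0.03, lipid 0.075, teichoic acid 0.03, peptidoglycan 0.06,
carbohydrate 0.10, trace pool 0.03 — a typical gram-positive anaerobe;
fractions sum to 1) and 44 precursor species (20 amino acids, 4+4
nucleotides, 7 fatty acids, 3 polar lipids, 6 cofactors) declared by
chemical formula, so the carbon and electron demands of growth follow from
elemental bookkeeping rather than hand-set coefficients.  One mmol of
biomass weighs 1 g by the usual FBA normalisation, making the biomass flux
equal to μ in 1/h.  The lumped biomass reaction draws its carbon from
intracellular glycerol (C_X/3 mmol glycerol per gDW, C_X ≈ 37 mmol C/gDW),
consumes GAM = 40 mmol ATP/gDW (the conventional order for clostridial
genome-scale models; configurable) and releases the electron surplus of
glycerol over biomass as NADH.

Perturbation semantics, chosen to reproduce the observed dispersion
behaviour: precursor mass shares are perturbed independently (their spread
propagates into a biomass-molecular-weight dispersion of ~4 % at 30 %
coefficient RSD), while macromolecule fractions are renormalised to sum to
one after perturbation (a composition *shift*, keeping the mass bookkeeping
closed).

## The instantaneous flux problem

The objective is the growth-per-flux ratio

Z = μ / ( w·Σⱼ vⱼ² + (1−w)·v²_ATPprod ),

with v_ATPprod the stoichiometry-weighted sum of the substrate-level
phosphorylation fluxes (lower glycolysis ×2, acetate kinase, butyrate
kinase).  w = 1 under glycerol limitation favours parsimonious flux routing;
w = 0.04 at excess penalises ATP overproduction and reproduces the
overflow-metabolism phenotype (acetate at its kinetic cap, high PDO flux).
A configuration switch (`ObjectiveSpec(form="product")`) exposes the literal
product reading Z = μ·D instead.

With a free uptake *inequality* the ratio objective is scale-degenerate
(v → t·v, t → 0 drives Z → ∞), so the glycerol uptake flux is **pinned**
at its kinetic value (equality constraint); the Ghose–Tyagi law is the
realised uptake, not merely a cap.  One consequence: Z is a *decreasing*
function of the pinned uptake (more flux per unit growth), so monotonicity
of Z holds under relaxation of genuine inequality bounds (e.g. the acetate
cap) but not under "relaxation" of the uptake itself.

The ratio programme is concave-linear over convex-quadratic, which
Dinkelbach's algorithm solves to global optimality: each iteration maximises
μ − λ·D(v) — a convex QP over S·v = 0 and box bounds — and updates
λ = μ/D.  The QP is solved by a primal active-set method on the bound
constraints with least-squares KKT solves (robust to the rank deficiency
introduced by the conserved CoA/acetyl-CoA pair); scipy's SLSQP is the
fallback, and the test suite cross-checks the optimiser against brute-force
grid search on a two-degree-of-freedom toy network and against direct SLSQP
maximisation of the ratio on the full network.  Convergence tolerance:
relative Dinkelbach gap ≤ 1e-10; steady-state residual of any returned flux
state ≤ 1e-6.  Degenerate cases: zero pinned uptake (with NGAM = 0) returns
the zero flux vector with Z defined as 0.

## Dynamics

States are the extracellular concentrations (held in mM internally, g/L at
the interfaces; glycerol 92.09 g/mol, PDO 76.09 g/mol) and viable biomass X
(gDW/L).  Dead biomass leaves the catalytic pool and does not lyse back into
the medium.  The death constant and objective weight switch together at
15 g/L glycerol, the boundary itself belonging to the excess regime; no
hysteresis.

* **SOA** — forward Euler with per-step flux re-optimisation (default
  G = 100 intervals).  When a step would drive glycerol negative the uptake
  bound for that step is rescaled to consume exactly the remainder.
* **DA** — adaptive RK45 (rtol 1e-6) with the flux optimisation embedded in
  the right-hand side, warm-started from the previous solve; the 15 g/L
  crossing is an integration event and the integrator restarts there, so
  each segment has a smooth RHS.
* **DOA** — orthogonal collocation on finite elements (default 20 elements ×
  6 Gauss–Legendre points; all five classical families are available, and
  they agree to well below the reporting precision).  The coupled system
  (Lagrange-interpolant collocation residuals + per-node optimal fluxes) is
  solved per element by damped fixed-point sweeps between the linear
  collocation solve and the node flux optimisations.  Because the pinned-
  uptake instantaneous optimum is unique, the converged fixed point
  satisfies exactly the constraints of the simultaneous NLP and coincides
  with its optimum; this avoids a thousand-variable general NLP.  DOA
  refuses horizons in which glycerol crosses the switching concentration,
  since a single objective function must hold throughout.

Fed-batch reactors integrate d(V·z)/dt = F·S_F + V·S·v·X, d(V·X)/dt =
V·(μ−k_d)·X, dV/dt = F with V₀ = 1 L, V_max = 1.5 L; feeding stops when the
reactor is full.  F is either a constant α (L/h) or β·v_H⁺·X·V with v_H⁺
the summed acetate + butyrate + lactate secretion flux (each acid exported
with one proton) — the proportional-to-acidification law emulating feeding
coupled to pH control.  The feed contains glycerol only (nitrogen and
phosphorus assumed non-limiting), its concentration derived from a mass
percentage via a linear density rule ρ ≈ 998 + 2.6·(wt %) g/L.

**Culture metrics.** The culture time is the instant at which glycerol is
exhausted (< 0.1 g/L) *and* PDO formation has finished (within 0.1 % of its
final value — both conditions are needed because a tracking feed can hold
glycerol near zero while PDO still accumulates); productivity Q_PDO is final
PDO over that time, and yields are reported per consumed glycerol (mol/mol
and g/g) plus per fed-plus-initial glycerol (the fed-batch selection basis).

## Sensitivity analysis and the population balance model

The 60 perturbable inputs are the 44 precursor shares, 8 macromolecule
fractions, 3 acetate-secretion constants, 2 death constants and 3
glycerol-uptake constants.  Ensembles draw each parameter from an
independent normal with 30 % RSD (20 % for the glycerol-uptake group),
truncated positive by resampling; invalid kinetic combinations (e.g. a drawn
K_s ≥ K_i) fail model construction and are excluded with a reported count,
as are failed simulations.

**MPSA** classifies each draw as acceptable/unacceptable by comparing
per-output mean squared errors against the error-propagation thresholds
(6 g/L)², (0.057 g/L·h)², (0.052 mol/mol)² — the error statistic is the
*mean* of squared residuals so those per-observation thresholds apply
directly; a flag restores the raw sum.  A profile exactly at the threshold
is acceptable.  The K–S statistic between a parameter's two class-
conditional distributions scores its influence, against the critical value
D = 1.36/√K.  Note the convention uses the ensemble size K, not the
two-class effective size; the median null two-sample K–S for a balanced
split is ≈ 1.66/√K, so even inert parameters tend to exceed D — the
informative quantity is the ranking, with the glycerol-uptake kinetics far
above the rest.  For MPSA the predicted scalar outputs (Q, yield) are
evaluated over the same observation window as the data they are compared
with.

**PRCC** rank-transforms parameters and whole-culture outputs (Q_PDO,
Y_PDO/S) and correlates residuals after regressing out the other
parameters' ranks; a "pearson" mode gives plain correlations.  K must
comfortably exceed the 60 parameters for the partial correlations to be
meaningful.  On the reduced network the recovered directions are v_max and
K_i positive and K_s negative for PDO productivity, and the acetate basal
flux and accumulation rate positive for the yield.

**PBM.** Each "cell line" is an independent whole-culture simulation with
one draw of the chosen parameter group (precursors, macromolecules, death
constants, acetate kinetics, or all 57 — glycerol-uptake kinetics are
strain constants and excluded).  The dispersion summary is the pointwise
population RSD of PDO across cells; it peaks during decelerating growth and
settles at the final-titre dispersion.  On the reduced network the acetate
group dominates the final dispersion (~2 % at 30 % parameter RSD, against
~1–1.7 % for the other single groups), and ensemble means are converged to
well under 0.35 % by 900 cells.

## Design-space scans

Batch: a full factorial over 15 inoculum levels (0.01–0.15 g/L; the
exponential-phase inoculum cap is 0.12 g/L) × 13 initial glycerol levels
(5–65 g/L), each summarised by the culture metrics; the productivity argmax
sits near 45–46 g/L glycerol.  Fed-batch: grids over feed glycerol content
(mass %) × α or β (log-spaced; the ranges are configuration choices, defaults
10–80 % and α ∈ [2e-3, 5e-2] L/h, β ∈ [3e-5, 3e-3]).  Outcomes are
classified infeasible (simulation failure, no PDO, or self-poisoning —
residual glycerol at/beyond the uptake-inhibition concentration),
unconsumed-glycerol (pH-coupled mode, residual > 5 g/L), optimal (the
Pareto frontier of final PDO × productivity, with the pH-coupled mode
additionally requiring ≥ 45 % fed-basis mass conversion and ≤ 5 g/L
residual), else suboptimal.

## Synthetic data

Observation tables emulate the study design — two glycerol-limited
(< 15 g/L) and two glycerol-excess cultures; six sampling points for the
excess reference culture — by sampling simulated trajectories and applying
multiplicative Gaussian noise (5 % SD default) plus an additive 0.05 g/L
floor reflecting chromatographic detection limits, truncated at zero.
Sampling times are a regular grid by default.  Kinetic recovery fits
(Ghose–Tyagi and logistic) use multistart trust-region least squares with
asymptotic confidence intervals; one-sided or plateau-only designs are
flagged non-identifiable via the conditioning of the relative-sensitivity
Jacobian (smallest/largest singular value < 1e-2).

Because the generator shares the simulator's model family, validation
against synthetic observations demonstrates parameter recovery and
pipeline correctness, not biological adequacy: real fermentation data carry
autocorrelated sensor drift, irregular sampling and model mismatch that the
noise model does not emulate.

## Known limitations

* The lumped network grows faster than a genome-scale reconstruction under
  the same objective (μ ≈ 0.3/h at excess): titres and yields are
  reproduced, but batch times are ~40 % shorter and volumetric
  productivities correspondingly higher.
* No product inhibition: fed-batch frontiers are limited only by reactor
  volume, feed composition and glycerol self-inhibition, so high-feed
  optima exceed what product-inhibited cultures could reach.
* No pH chemistry, gas–liquid transfer, or lysis of dead biomass; the
  pH-coupled feed is the printed proportionality only.
* Problem sizes of the shipped analyses (ensembles to 3300 cells at reduced
  time resolution, 6×6 fed-batch grids) were chosen as desk-scale defaults;
  all are configuration-overridable.
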