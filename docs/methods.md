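# Methods

## The two-phenotype constraint-based model

A *Trichodesmium* trichome carries one genome but two metabolic programs.
Both phenotypes are represented by the same stoichiometric matrix S; a
phenotype is purely a set of flux-bound overrides:

| bound | diazotroph (DZ) | photoautotroph (PA) |
|---|---|---|
| Photosystem II | fixed 0 | free |
| nitrogenase | fixed 0.132 mmol gDW⁻¹ h⁻¹ (0.206 selectable) | fixed 0 |
| carbon source | glycogen, 0.927 mmol C gDW⁻¹ h⁻¹ | CO₂, fixed −0.927 |
| ammonium exchange | export-only | uptake-only |
| glycogen / N₂ exchange | uptake-only | export-only |
| photons | ≤ 80 µE shared over PSI + PSII | same |
| maintenance (EN_ATP) | lower bound 67.2 mmol ATP gDW⁻¹ h⁻¹ | 64.3 |

Sign convention: uptake negative, secretion positive.  The reconstruction's
±1000 sentinel is stored literally (never converted to infinity) so
listings round-trip bit-stably.  Maintenance is a *lower bound*, not an
equality: the calibration procedure (bisection of the bound until predicted
growth matches a measured rate, to 10⁻⁶ h⁻¹) relies on growth being
monotone non-increasing in it.  The 64.3/67.2 defaults follow the
calibrated values for this organism; note that published tabulations of
these two numbers disagree on which phenotype carries which value, and the
package follows the (twice-stated) prose assignment.

Steady-state claims are never made from a single FBA solution: the system
is underdetermined, so all flux-level statements are validated through FVA
envelopes.  Essentiality uses knockout growth < 10⁻⁶ h⁻¹ as "essential" and
< 99 % of wild type as "growth-reducing"; both thresholds are package
choices, exposed as module constants.

## Biomass construction

Macromolecule pools are built from monomer profiles in the residue-unit
convention standard for genome-scale models: "1 mmol of protein" is 1 mmol
of condensed residues, with molar mass the profile-weighted mean residue
mass (free monomer minus one water per bond).  Biomass coefficients are
mass_fraction / molar_mass after subtracting subset pools (phycoerythrin
and cyanophycin from protein; phycocyanin and chlorophyll from lipid) so
that double-assayed material is not counted twice.  Mass fractions are used
as printed by default — the measured columns do not close exactly to
1 g/g — with an optional normalize-to-1 switch.  Growth-associated
maintenance defaults to 544 mmol ATP per g DW.  The shipped amino-acid and
fatty-acid profiles are synthetic stand-ins (typical cyanobacterial usage);
the measured profiles live in a supplement that does not accompany the
article text.

## The population simulation

The dynamic simulation couples the two phenotype LPs through a well-mixed
batch medium carrying the two shared currencies, glycogen (glucose units,
6 C each) and ammonium.  The sequential order is fixed: the photoautotroph
computes its metabolism first, the diazotroph reacts.

* **PA step.** Maximize growth, with glycogen export forced to at least
  (µ^DZ Δt + 1) · |previous DZ consumption| · X^DZ/X^PA (the predictive
  supply estimate) and ammonium uptake capped by the medium stock.
* **DZ step.** Maximize ammonium export.  This is the shared-metabolite
  objective reading of "maximize µ^PA and v_NH₄⁺^DZ": the photoautotroph
  optimizes growth, the diazotroph optimizes the metabolite it exists to
  provide.  It reproduces two qualitative signatures of the organism —
  nitrogenase flux well above the physiological rate at population
  equilibrium, and obligatory ammonium leakage — that a pure
  growth-objective diazotroph does not.  A `dz_objective="biomass"` variant
  is available.  Glycogen uptake is capped by the population carbon
  constraint |v_CO₂^PA|/(6 f_DZ), by medium availability, and by the
  phenotype's standing physiological cap.
* **Released equalities.** In population runs the fixed carbon-uptake and
  nitrogenase rates become *inequality caps* (uptake up to the measured
  rate; nitrogenase free): the partner's demand, not a pinned flux, drives
  the exchange.  This choice is load-bearing: with uptake released all the
  way to the ±1000 sentinel, the diazotrophs' per-gram consumption is set
  by the history of the supply ratchet rather than by physiology, and the
  rest composition becomes inoculum-dependent.  With the caps in place the
  simulation converges to the same composition from any photoautotroph-
  majority or balanced inoculum.
* **Deficiency and differentiation.** Shortage is measured against
  *demand*: each consumer is re-solved with its availability cap relaxed
  (and the PA additionally without its forced-export burden), so a binding
  uptake bound registers as deficiency even though realized consumption can
  never exceed supply.  For each deficient metabolite the allocation
  coefficient α = (C_prod + C_cons)/C_cons (signed totals, clamped to
  [0, 1]) draws the pool X_δ = Σ_γ α σ^γ ΔX′^γ from the consumers and deals
  it to the producers by production shares.  The printed-index variant
  (`allocation_semantics="literal"`), which deals the pool back to the
  consumer side, is available; it conserves biomass but removes the
  restoring force.  With no deficiency, all excess growth goes to the
  photoautotrophs.  Allocation only redistributes the step's increment: a
  cell can lose at most what it gained, and ΣX is conserved exactly.
* **Grace and death.** For the first 3 steps a population may borrow a
  shared metabolite from an arbitrary environmental cache — but only if a
  live producer cell type for it exists.  This implements the bootstrap
  role of the cache (the sequential ordering would otherwise starve
  everyone at t = 0) while keeping single-phenotype inocula nonviable
  within grace + 1 steps, as both properties are described for the
  organism.  Borrowing is a bound relaxation, not a seeded stock: a
  pre-computed seed large enough to boot a mixed culture would also keep a
  PA-only culture alive past the grace window, contradicting the death
  rule.  Death is declared after 3 consecutive zero-growth steps.
* **Medium.** C_m(t) − C_m(t−1) equals production minus consumption
  exactly (consumption bounds are derived from the same start-of-step
  biomass used in the update, so the pool cannot go negative outside the
  grace window).

Metrics: µ_t = ln(ΣX_t/ΣX_{t−1})/Δt per step; µ_T over the horizon;
Y_{N→Env} = accumulated medium ammonium over total ammonium produced;
equilibrium composition as the final-window (last 10 % of steps) mean
fraction.  The ensemble study draws both initial biomasses independently
and uniformly on (0, X_total] from a single seeded generator, the inoculum
fraction being the ratio of the draws.

Defaults: horizon 400 h, Δt 1 h, grace 3 steps, initial total biomass
4·10⁻⁵ g DW L⁻¹ (chosen so that 400 h of growth at the measured 0.0146 h⁻¹
reaches the ~14 mg L⁻¹ scale reported for equilibrium-start cultures).

### Nitrogen-source scenarios

An alternative nitrogen source is supplied in excess by opening (or
temporarily adding) its exchange for the photoautotrophs, with a
diffusion-style transporter and a lumped, element-balanced catabolic
reaction for species not in the network; urea transport is ATP-dependent
(2 ATP), the amino acids cost 1 (glutamate) and 0.5 (glutamine) ATP per
transport event, and deaminating cells may re-secrete surplus ammonium.
Under a replete external nitrogen source, nitrogen deficiency — and hence
differentiation toward diazotrophs — cannot occur.  The source feeds the
growing photoautotrophs only; diazotrophs down-regulate fixation under
replete fixed nitrogen.  The resulting growth ladder is strict:
N₂ < urea < NH₄⁺ < glutamate < glutamine.

## The reduced network and its oracle

The toy network compresses the division of labour into 20 elementally
balanced reactions (photon capture split into PSII→NADPH and PSI→ATP,
lumped carbon fixation at (64 − 4)/6 ATP per carbon so one glycogen costs
~64 ATP, respiration at 5 ATP per carbon, an oxidative-PP NADPH
regenerator, nitrogenase at 16 ATP per N₂ with its electrons drawn from
1.5 CH₂O, and a biomass reaction with 38.1 mmol C and 6.05 mmol N per g DW
— 45.8 % carbon by mass and a C:N near Redfield).  The nicotinamide pool
uses an abstract element symbol so every reaction balances; the photon is
massless.  By construction the network passes the balance, dead-end and
futile-cycle screens, the diazotroph cannot grow without glycogen, and the
photoautotroph cannot grow without ammonium.

The equilibrium oracle scans the diazotroph fraction f on a coarse grid
(step 0.005) refined to 10⁻⁴ around the peak — the refinement keeps the
grid error two orders below the 2 % tolerance the simulation is held to —
and at each f solves the joint two-phenotype LP at stationarity (glycogen
supply = demand, ammonium supply ≥ demand, per-gDW bounds as in the
population run) for the maximum total growth f·µ^DZ + (1−f)·µ^PA.  The
oracle is built directly on scipy's HiGHS solver from the raw S matrices,
independent of the cobrapy/GLPK path used everywhere else.  The network's
photosystem split makes the two phenotypes inherently asymmetric, so no
parameter choice reduces the equilibrium to the symmetric ½ — the
meaningful oracle checks are location (photoautotroph majority), agreement
with the simulation, and monotonicity (raising the diazotroph carbon cap,
and with it the ammonium yield per gram of diazotroph, strictly lowers the
equilibrium fraction).

What the toy does *not* emulate: the full reconstruction's 971-reaction
redundancy (alternate optima, isozyme structure beyond one token pair),
photorespiration and photodamage, diffusion gradients along the trichome,
O₂ inhibition kinetics of nitrogenase, and day/night cycling.  Passing
tests on the toy therefore validate the *machinery* — constraint
application, LP contracts, allocation bookkeeping, convergence — not the
genome-scale flux predictions themselves, which require the published
reconstruction files.

## Numerical choices

GLPK with feasibility/optimality tolerances at solver defaults; steady
state asserted at ‖S·v‖∞ ≤ 10⁻⁹ (observed ~10⁻¹⁴ on the toy).  FVA at
fraction-of-optimum 1.0 by default.  Bisection terminates at
|growth − target| ≤ 10⁻⁶ h⁻¹.  Degenerate optima: only FVA-validated
statements are made about individual fluxes.  Zero-consumption metabolites
skip allocation (no division by zero); infeasible phenotype LPs record a
zero-growth step rather than aborting the run.  All randomness flows from
one `numpy` generator seeded explicitly.

## Known limitations

The equilibrium fraction of the reduced network (~0.068) is not the
organism's (~0.15); the toy's parameters set a different carbon/nitrogen
economy, and only the genome-scale reconstruction reproduces the published
composition.  The diazotroph's "independent optimum" under fully opened
glycogen is a sentinel artifact, reported as such.  Convergence from
diazotroph-dominated inocula (f₀ ≳ 0.7) is passive — the diazotroph pool
is diluted at the photoautotroph growth rate — and can exceed a 400 h
horizon, consistent with the slow convergence described for such inocula.
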