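# Methods

## Model overview

One simulation step couples three layers under a time-scale separation
assumption: signalling and metabolism equilibrate fast relative to
damage accumulation, so within a step of length `dt` both are treated
as being at (quasi-)steady state.

1. The enzyme pool available to the metabolic model is scaled to the
   intact-protein fraction, `pool * P/P_tot`, and the maintenance
   (NGAM) ATP-hydrolysis floor is set to `D/(P+D) * NGAM_max`.
2. The ecFBA is solved lexicographically (max growth, then min total
   enzyme usage at the fixed optimum).
3. Boolean inputs are thresholded from the solution (strict `>`):
   glucose from the uptake flux, oxidative stress from the
   damage-production flux, thioredoxin from the Trx enzyme usage of the
   *previous* step's regulated solution (presence of an expressed
   protein is a state, not an instantaneous flux; a freshly solved
   parsimonious optimum would always report zero).
4. The Boolean network is iterated synchronously to a fixed point from
   the previous step's state with the new inputs pinned.
5. The transcription-factor activities from `n_delay` steps ago set
   per-enzyme net ranks (sum of ±1 signs over active TFs); enzymes with
   rank > 0 get `e_min += delta_i * epsilon`, rank < 0 get
   `e_max -= delta_i * epsilon`, where `delta_i` is the admissible
   usage range from enzyme variability analysis at flexibility `gamma`,
   recomputed each step from the unregulated bounds (tightenings do not
   compound across steps). The regulated model is re-solved; its growth
   and damage-formation rates drive the ODE.
6. The ODE advances one step with rates held constant, using the exact
   solution of the linear system; a division triggers instantaneously
   when `M >= M0/s`.

Death is the first infeasible LP — whether the infeasibility comes
from the shrunken pool, the raised NGAM floor, regulation-tightened
bounds or a perturbation. Reaching `t_max` without death marks the
timeline *censored*.

## Parameters

| name | meaning | unit | default | rationale |
|---|---|---|---|---|
| `f0` | non-metabolic damage formation | 1/h | 1e-4 | slow basal damage; lifespan-scale |
| `r0` | damage repair | 1/h | 5e-4 | same order as `f0`; repair loses to retention |
| `epsilon` | regulation factor (fraction of `delta_i`) | – | 0.04 | strongest regulation the bound-tightening tolerates |
| `gamma` | flexibility of variability analysis | – | 0.05 | near-optimal band wide enough for non-trivial ranges |
| `s` | mother mass share at division | – | 0.75 | budding is asymmetric; within [0.5, 1] |
| `re` | damage retention factor | – | 0.3 | partial retention; within [0, 1] |
| `NGAM_max` | maintenance at fully damaged proteome | mmol/gDW/h | 0.7 | consensus-model maintenance magnitude |
| `P_tot` | total protein fraction | g/gDW | 0.46 | yeast proteome mass fraction |
| `dt` | step length | h | 0.1 | ≪ generation time (~1 h) |
| `n_delay` | regulation delay | steps | 2 | expression lags signalling |
| `t_max` | horizon | h | 100 | several-fold a wildtype lifespan |
| `glc_cin` | glucose-presence threshold | flux | 0.1 | ~12% of the young uptake |
| `d_c` | stress-presence threshold | flux | 1.5e-3 | ~2× the basal damage flux, crossed mid-life |
| `trx_c` | thioredoxin-presence threshold | usage | 1e-6 | any forced expression counts |

`M0 = 1` gDW is an arbitrary unit; only mass ratios matter for the
division trigger.

## The bundled fixture

The fixture is a deliberately small network whose *architecture*, not
its numbers, mirrors the biology: glucose uptake, lumped glycolysis,
fermentation to ethanol, pyruvate respiration, ethanol oxidation, an
ADP/ATP carrier, biomass, NGAM, and a ROS chain (electron leakage →
superoxide → either SOD → H₂O₂ → thioredoxin/catalase removal, or the
uncatalysed route to hydroxyl radical → protein damage → exchange).
Oxidising damage costs ATP, so any detox capacity forced by stress
regulation is used in preference.

Three kinetic choices generate the phase structure:

* Cytosolic ATP (growth) is cheapest per unit enzyme via fermentation,
  so a young cell with an abundant pool ferments maximally (phase I).
* Maintenance draws on a separate mitochondrial ATP pool, exported
  through a one-directional carrier, so only oxidative routes can pay
  the NGAM. A rising damage fraction therefore *recruits* oxygen
  consumption (phase II) — and with `NGAM_max = 0` the switch never
  happens, the model's central mechanistic claim.
* The enzyme-cheapest oxidative route burns ethanol, the cell's own
  fermentation by-product. While fermentation is strong the by-product
  covers it (net ethanol export); when growth fades the net exchange
  flips to uptake (phase III). Glucose-repression signalling
  (Snf1→Cat8-like derepression of the ethanol-oxidation enzyme) engages
  in the same window. Pyruvate respiration is the *glucose*-cheapest
  route and carries the chemostat at low dilution; overflow fermentation
  appears above a critical dilution rate (~0.2/h in the fixture) when
  the enzyme pool saturates.

Superoxide is booked in damage-equivalent pseudo-units (leakage
coefficient 1.0 per unit oxidative flux) so that the damage-formation
flux `f_m` is meaningful on the 1/h scale of the ODE; the exchange-flux
value is used directly as a first-order rate on `P`, a deliberate
conflation of flux and rate units inherited from the layer coupling.
An uncatalysed cytosolic ATPase lets glycolytic ATP be dissipated when
growth cannot absorb it (zero-growth chemostats); it carries no flux in
ordinary lifespan simulations.

What the fixture does **not** emulate: genome-scale redundancy (140+
enzymes, isoenzyme families), the full Yeastract-derived regulation
breadth, compartment pH/redox detail, nitrogen signalling, or absolute
flux values comparable to measured yeast data. Passing tests on the
fixture demonstrate the *mechanisms* (phase ordering, maintenance-driven
respiratory switch, retention-driven mortality, overflow metabolism),
not quantitative agreement with any measured lifespan.

In this small network, damage retention at division (multiplying `D`
by `1+re` each generation) dominates continuous repair unless
`r0` exceeds roughly `ln(1+re)` per generation time (~0.26/h), which
is why the censored-run checks use a repair rate far above `f0` rather
than a mere ten-fold excess.

## Numerical choices

* All LPs are solved with HiGHS via `scipy.optimize.linprog`;
  infeasibility is declared only from solver status. The solver is
  deterministic, so repeated solves are bit-identical.
* Lexicographic parsimony fixes growth at `(1 − 1e-9)` of its optimum
  (relative, plus 1e-15 absolute) before minimising usage, avoiding a
  numerically empty feasible set.
* The Boolean update is synchronous, at most `4·|components|`
  iterations, with cycle detection by state hashing. A limit cycle is
  reported, never silently resolved; the simulation then keeps the
  previous TF activities for that step and logs a warning.
* Rank ties (equally many active activators and repressors) regulate
  nothing. Bound tightenings that would invert `e_min > e_max` are
  capped at the midpoint of the previous interval.
* The ODE step is the exact solution of the linear system with rates
  frozen over `dt`; it conserves `P + D` to machine precision and
  handles the degenerate all-zero-rates case as identity.
* Division applies the retention bookkeeping exactly as stated
  (mother `P ← (1−re)P`, `D ← (1+re)D`; daughter mirrored). For
  `s ≠ 0.5` this arithmetic does not by itself conserve `P + D` inside
  each compartment; the ODE's constant-total-protein assumption
  restores `P = P_tot − D` at the next step, and recorded timeline
  rows are post-ODE states, so the conservation invariant holds at
  every recorded step. A fraction pushed beyond `[0, P_tot]` is capped
  with the complement adjusted (logged).
* Division is instantaneous at the first step where the mass trigger
  holds; there is no sub-step event location, so the mother's
  post-division mass can overshoot `M0` by at most one step of growth.
* Phase segmentation: phase I while `g ≥ (1−δ_g)·g_initial`
  (δ_g = 0.01), phase II from the first *sustained* drop (3
  consecutive steps), phase III from the first net ethanol uptake
  beyond 1e-6; labels forced monotone. The same classifier runs
  causally (no lookahead) during perturbed simulations to decide
  whether a phase-scoped perturbation is live.
* The chemostat experiment pins growth to the dilution rate, minimises
  glucose uptake, then applies parsimony; ethanol uptake is disallowed
  there (the feed contains glucose only).

## Design decisions on genuinely open points

* Update scheme and initial state of the Boolean layer (synchronous,
  previous state carried across steps) are conventions; both are
  configurable through the API.
* Whether regulation compounds: recomputed from fresh variability each
  step (the cheapest consistent reading).
* Which solution feeds the ODE: the post-regulation solve ("the
  regulated metabolic network" is the step's final word on fluxes).
* Overexpression fixes an enzyme's usage to 1.5× its post-regulation
  optimal usage at that step (so 1.5 × 0 = 0 for an unused enzyme).
* The tabular bundle dialect is canonical; SBML import maps species
  and reactions only, because enzyme/kcat annotations are not
  standardised across SBML-producing tools.

## Problem sizes

The suite and the acceptance script run the fixture at `dt = 0.1` for
the flagship wildtype simulation (~390 steps, ~10 LP solves per step)
and at `dt = 0.2` with faster damage rates for the 4×4 (f0, r0) sweep,
keeping a full run of everything in the low minutes on one CPU. These
are the package's chosen study sizes for the bundled network; the
loaders and solvers take any bundle of the same format.

## Known limitations

* Only the mother cell is simulated onward; daughters are recorded at
  birth but not followed (replicative-lifespan semantics, no pedigree).
* The enzyme-capacity coupling constrains forward fluxes
  (`v ≤ Σ kcat·u`, mirrored for reversible catalysed reactions); there
  is no thermodynamic or MILP machinery.
* Regulation in the fixture is weak by construction (4% of admissible
  ranges), so signalling knockouts shift damage fluxes and phase
  timing more than they shift division counts — lifespan-shifting
  knockout effects require a genome-scale bundle.
* Boolean semantics are synchronous and deterministic; asynchronous or
  probabilistic updating is out of scope.
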