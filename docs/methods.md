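# Methods

## Scope and model

`biostim` predicts the effect of metabolite supplements on the growth of
pollutant-degrading bacteria and on degradation of a target compound, using
constraint-based metabolic models. The core procedure is an iterative
dynamic flux balance analysis (dFBA) over a shared, finite extracellular
pool, wrapped by a screening grid (one simulation per candidate supplement
plus a baseline) and a validation stage that turns growth responses into
binary supplement-supports-species calls and scores them against
observations.

Assumptions of the dynamic loop:

1. **Finite starting doses.** The medium is a pool of metabolite amounts
   (mmol per gDW basis). Background mineral ions (K⁺, Mn²⁺, CO₂, Zn²⁺,
   SO₄²⁻, Cu²⁺, Ca²⁺, HPO₄²⁻, Mg²⁺, Fe²⁺, Cl⁻) are declared inexhaustible;
   only carbon/nitrogen sources are dosed finitely.
2. **Cycle-limited uptake.** Per round, a species may take up at most
   `min(vmax, available/total_biomass)` of each finite metabolite per gDW,
   with `vmax = 1 mmol·gDW⁻¹·round⁻¹` by default. Using *total* community
   biomass in the denominator guarantees aggregate draw never exceeds
   availability, independent of species order.
3. **Biomass update from the FBA optimum.** Each species maximizes its
   biomass flux μ against the same pool snapshot (simultaneous, not
   sequential, so no species-order nondeterminism), then
   `X ← X(1 + μ·Δt)` with Δt = 1 round. An additive variant `X ← X + μ` is
   available behind `SimConfig(biomass_update="additive")`; multiplicative
   is the default because it is the standard dFBA Euler step and makes
   population size drive uptake totals.
4. **Pool bookkeeping.** The pool gains/loses each species' net exchange
   fluxes scaled by its pre-update biomass. Negative amounts within
   `1e-9 × max(1, total biomass)` are clamped to zero (LP tolerance
   absorbed and scaled with the flux magnitudes flowing through the pool);
   anything more negative raises, since the uptake-cap construction should
   make it impossible.

Rounds repeat until the relative total-biomass increase falls below
`convergence_tol` (default 1e-6) or `max_rounds` (default 15) is reached.
There is no death, maintenance, pH or spatial term: biomass is
non-decreasing and the fixed point is starvation.

## FBA engine

`solve_fba` maximizes the biomass flux subject to `S·v = 0` and bounds,
via scipy's HiGHS interface behind an injected solver contract (solver
tolerances 1e-9; model-level assertions 1e-6, keeping solver noise
distinguishable from logic errors). FBA optima are generally non-unique;
because the dynamic loop needs one deterministic flux vector per tick, a
parsimonious secondary LP (minimize Σ|v| with the biomass flux pinned at
its optimum) is applied by default and can be switched off
(`tie_break="none"`). `solve_fva` reports per-reaction flux ranges at a
configurable fraction of the optimum. Media are encoded so that a missing
nutrient closes the exchange lower bound rather than breaking the LP:
starvation appears as a feasible zero-growth solution, never as silent
infeasibility, and true infeasibility is reported as such with an
undefined objective.

## Screening and dosing

Candidates are dosed equimolar (default 50 mmol/gDW, the standard
stimulant amount) or normalized to equal molar carbon versus glucose or
equal molar nitrogen versus the 5-nitrogen target compound. Normalized
doses are floored to integer mmol — the convention that reproduces the
printed dose tables (e.g. a C18 fatty acid at floor(300/18) = 16); an
exact-rational mode is available via `exact=True`. The target-compound
dose defaults to the same 50 mmol/gDW and is configurable. Candidates that
are flagged excluded (nonpractical additives — a curated input list, not a
computed property), that lack the normalization element, or whose
simulation fails are recorded and skipped so a grid always completes.
Screen tables carry every round up to the configured horizon; after a
simulation converges its final state is carried forward, which is exact
under growth-only dynamics and guarantees the fixed evaluation round
exists for every candidate.

## Validation

Fold change per (supplement, species) is biomass under the supplement
divided by baseline biomass at the same round (default round 3, matching
how the published simulation matrix was evaluated). Conventions for
degenerate baselines: 0 → +inf when the supplemented biomass is positive,
0/0 → 1. A cell is called positive at fold change ≥ 2 (inclusive).
Accuracy is (TP+TN)/total; precision TP/(TP+FP), reported as NaN with a
warning when nothing was called positive — never as 0, which would
fabricate a score. The shipped observation table transcribes, for four
degrader genera and six supplements, whether a significant abundance
increase was observed in supplemented soil; the shipped fold-change matrix
is a synthetic stand-in (marked as such in its filename and header) whose
≥ 2-fold classification matches the published call matrix, because the
underlying numeric values live in external supplementary data.

## Synthetic models

The generator builds toy species with the exact structure the pipeline
assumes: per menu supplement an exchange, a transporter and a conversion
`s_c → Y_s bm_c` into a common biomass precursor; one biomass reaction
(`bm_c + 0.05 hpo4_c →`, phosphate drawn from the unlimited mineral pool);
and, for degraders, the same pattern for an atrazine-like C8 target. FBA
growth on sole supplement *s* at uptake cap *v* is therefore `Y_s · v`
analytically — the construction is its own oracle. The biomass precursor
carries 20 mmol C per gDW (declared in model metadata), supplements drawn
by the community generator have carbon counts 2–12 with `Y = C/20`
(yields 0.1–0.6 gDW/mmol, a realistic heterotrophic range), and the target
yield 8/20 = 0.4 balances its C8 formula, so carbon conservation holds
exactly and is asserted in tests. What the toys do *not* emulate:
genome-scale network size and redundancy, byproduct cross-feeding,
nitrogen/energy co-limitation, and regulatory effects — so passing tests
demonstrate the correctness of the simulation machinery, not the realism
of any particular organism's predictions.

## Problem sizes and numerical choices

Tests and the acceptance script run on toy communities of 1–4 species
(≤ ~20 reactions each), horizons of 2–15 rounds, 20 random
parameterizations for the oracle-equivalence check, 100 random communities
for conservation properties, and 200 seeded flips for the
observation-recovery check — sizes chosen so every expected value is
hand-checkable while still exercising every code path. Ties in supplement
rankings break lexicographically by id; all randomness flows through
seeded `numpy` generators; simulations themselves are deterministic.

## Known limitations

- Growth-only dynamics (no death/maintenance) mean late-round biomass
  plateaus rather than declines; evaluation rounds should be early.
- The contention rule (caps from total biomass) is conservative: it can
  leave pool unclaimed in one round that is consumed in the next.
- The "1 unit per unit biomass" uptake cap is interpreted as
  mmol·gDW⁻¹·round⁻¹ and is configurable; no unit claim is made for
  percentage-style reporting of target depletion.
- Real deposited genome-scale models (SBML) run through the identical
  pipeline but are not bundled; identifier schemes are passed through
  uninterpreted.
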