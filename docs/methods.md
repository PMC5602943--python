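# Methods

## Model structure

The arena is a lattice of `width_y × length_x` unit cells (default 20 ×
400; the reduced scale used by the scenario matrix is 20 × 200). The x = 0
end is closed (no-flux mirror), the x = L end is open (absorbing ghost),
and the two sides wrap periodically — the geometry of a single dendrite of
a colony growing outward on a plate. Agents live at continuous positions;
every exchange with a field (deposit, sample, uptake) uses the containing
lattice cell, so thresholds are always compared against the same "local
concentration" an agent secretes into. Fields update once per step with an
explicit forward-time centred-space 5-point stencil (Δt = 1 step, Δx = 1
unit) followed by multiplication by (1 − λ); the stability bound
D ≤ 0.25 is enforced at configuration time.

Each step executes a fixed schedule: (1) diffusion/decay of all fields;
(2) the agent phase in a freshly shuffled order — sense, recompute the
behavioural state, feed (clamped by the local nutrient), pay maintenance
and emission costs, deposit secretions — so agents act on the environment
left by the agents before them; (3) random-walk movement; (4) a division
sweep (E ≥ T_D splits the energy exactly in half; the daughter appears
within 0.5 units and inherits state and generation + 1); (5) a death sweep
(E ≤ 0). All randomness is drawn from one seeded generator in a fixed
program order, making runs bitwise reproducible; the test suite replays
the identical stream through the pure-Python scalar rules to verify the
compiled agent loop.

State switching is memoryless and reversible: each step the state is a
pure function of the current local concentrations (activation at
S ≥ T_S, swarming additionally at F ≥ T_F, antibiotic ≥ kill threshold
forcing the ground state for sensitive species). There is no hysteresis,
no intracellular regulation, no mutation, and crowding has no effect
beyond a sanity cap on the seeding density.

## Parameters and calibration

The response thresholds are taken from the published parameterisation:
wild type T_D 12, T_S 10, T_F 10; elevated variants T_S 20 and/or T_F 45;
fit variants T_D 6; antibiotic-sensitive strain T_D 11 with response
threshold 10; producers trigger at T_AB 10 or 30 on the sensitive strain's
channel. All *rate* constants are this package's own calibration — the
original study's rate tables live in supplementary material that is not
reproduced here — and every one of them is exposed in the run config.

Defaults (per state: solitary / active / swarming, energies in units of
T_D): uptake 0.11 / 0.25 / 0.55, maintenance 0.12 / 0.17 / 0.20, movement
step 0 / 0.2 / 0.28, signal emission 0.06 / 0.08 / 0.10, factor emission
0 / 0.10 / 0.25, emission cost 0.05 per unit secreted, yield 1, newborn
and seeded energy T_D/2. Fields: nutrient immobile at 3000 per lattice
cell in single-species/default runs and 2000 in the shipped scenario
configuration; signal D 0.005, λ 0.03; factor D 0.05, λ 0.08; antibiotic
D 0.02, λ 0.05, emitted at 0.2 per producer-step. Seeding places agents
at ~25 per lattice cell at the track start (the seeding interval scales
with the inoculum so ignition conditions are inoculum-independent).

Why these numbers, in brief:

- **Dormant populations must not grow.** Solitary uptake (0.11) is below
  solitary maintenance (0.12): dormant cells subsist for hundreds of steps
  but never reach the division threshold, whatever the nutrient supply.
  The signalling-deaf control therefore starves without ever doubling.
- **Ignition.** The seeded cluster's solitary emission must push the local
  signal past the *highest* shipped activation threshold (20), with margin
  left when half the inoculum does not emit (the cheater pairing). The
  seed-strip signal peak scales as `inoculum · emission / √(D·λ)`, which
  motivates the very low signal diffusion. Active cells emit slightly more
  than solitary ones, so marginal activation self-amplifies into a clean
  ignition cascade rather than flickering at the threshold.
- **Front speed.** The colony advances as a motility-driven pulled wave;
  its speed is essentially `move_step · √(growth rate)` and must keep the
  front inside the track for the whole run at both scales (measured
  ~0.045 columns/step for the wild type). Signal or factor decay do *not*
  slow the front (the bulk's plume always leads), which pins the swarming
  step at 0.28.
- **Plateau stability.** The classifier demands the total count stay
  within 10% over a 20-generation trailing window. Population breathing is
  dominated by column-ignition pulses; with low field diffusion the
  activation contour is rough across the track's rows, the rows ignite
  asynchronously, and the pulses average out (measured plateau noise
  ~1–2%). The same roughness multiplies the number of founder lineages at
  the front, which keeps neutral drift in the symmetric control far from
  fixation over the run length.
- **Generation clock.** Fed swarming cells net ≈ 0.32 energy/step and
  divide every ~19 steps; with roughly half the population fed at the
  travelling front, the full-scale default run passes ≈ 110–116 mean
  generations in 5000 steps, the model's quantitative anchor.

## The synthetic data

This package generates all of its own data; there are no external inputs.
The simulation emulates clonal expansion of one or two strains along a
nutrient track under density-dependent (quorum-sensing) regulation. It
does not emulate: real AHL receptor kinetics, multi-signal regulons,
growth-rate plasticity, spatial nutrient replenishment, or mechanical
cell–cell interactions. Passing outcomes therefore demonstrate properties
of the threshold-gated behavioural model, not predictions for any
particular organism.

## Outcome classification

`NO_GROWTH` if the total count never doubles; else `COLLAPSE` if the final
total is ≤ 10% of its peak; else `EXCLUSION(winner, loser)` if exactly one
species' final share is ≤ 1% and the survivor's own count passes the
stability test; else `COEXISTENCE` if both shares exceed 1% and the total
passes it; anything else — grew, neither stabilised nor cleanly excluded —
counts as `COLLAPSE`. The stability window converts "20 generations" to
records through the run's own pooled mean-generation trajectory rather
than a fixed steps-per-generation constant. All cutoffs (2× growth, 10%
collapse, 1% extinction, 10% tolerance) are config fields echoed into
`result.json`. Scenario verdicts are majorities over five seeds.

## Design choices where the design was open

- Sequential-in-random-order agent updates (with synchronous fields):
  later agents see earlier agents' uptake and secretions; the per-step
  shuffle removes systematic first-mover bias (verified by a 20-seed sign
  test on the symmetric pairing).
- Nearest-lattice-cell sensing, no interpolation: keeps deposit, sample
  and consume mutually consistent.
- Antibiotic suppression (`ab_mode: suppress`) forces sensitive cells into
  the ground state, and death follows from starvation energetics; an
  instant-removal `kill` mode is available. The kill threshold (10) is a
  design choice; the source study names none.
- The antibiotic pair signals on private channels at slightly lower
  per-cell rates than the baseline strain, so the eavesdropper's elevated
  trigger (30) corresponds to genuine local dominance of the sensitive
  strain rather than its mere presence.
- Newborns (and seeded agents) start at T_D/2, the post-division level; a
  species-independent starting energy would let a T_D = 6 strain divide at
  the first step.

## Known limitations

Under this calibration the three "self-restraint" pairings — wild type
versus a fitter competitor carrying a higher signal and/or factor
threshold — and the high-trigger antibiotic pairing resolve to competitive
exclusion of the wild type (respectively of the sensitive strain), not to
the stable coexistence reported in the source study. The mechanism's
precondition does hold here: banded division rates show the fit
high-threshold species out-dividing the wild type only where the local
signal exceeds its threshold, and losing below it (asserted in the
acceptance suite). But invasion analysis shows the interaction is
bistable, not stabilised: with division gated purely by an energy
threshold and identical per-state rates across species, a T_D = 6 strain
divides twice as fast wherever both are active, and the frontal window in
which only the wild type grows washes past faster than the wild type's
division interval at any front speed the track budget allows. Regimes
harsh enough to reverse this (long famine pauses that exploit the fit
strain's smaller energy buffer) also destroy the fit strain's own
viability when grown alone, which is required independently. A stable
interior equilibrium evidently needs an asymmetry beyond the thresholds
themselves — e.g. division overheads or per-species metabolic scalings —
that the available parameterisation does not specify. This divergence is
deliberate and documented rather than patched over.

Other limitations: pulled-front founder drift makes the symmetric
pairing's final *ratio* seed-dependent (its label is not); the open end of
the track is only reached near the end of full-scale runs but would
distort longer ones; and the reduced scale, while qualitatively faithful
for the shipped scenarios, roughly halves the generation count of the
full-scale experiment.
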