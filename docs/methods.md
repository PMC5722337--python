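# Methods

## Model summary and assumptions

`castesim` simulates a fixed-size population partitioned into three castes
of differing true aggression.  The model is deliberately minimal: agents
have no memory, no reputation, no kin structure, and no choice — their
signal is fixed for life and can only spread by being copied into newborns.
Honesty is never rewarded directly; the only force acting against deception
is that a defeated agent whose signal mismatches its revealed aggression
forfeits a larger share of its resources to the winner (opportunistic
punishment: the punisher profits).  All selection flows through starvation:
agents whose resources fall strictly below 10% of their birth endowment are
replaced, and replacements inherit the signal of the richer of two randomly
drawn caste-mates.

Key structural assumptions, all deliberate:

- **Asymmetric update.**  Each tick only the focal agent's stored resources
  change.  The counterparty serves as an opponent and a resource *measure*;
  its own account is settled on the ticks in which it is focal.  Resources
  are therefore not conserved across the population; this is the original
  design, not an accounting bug, and it implies only the focal agent can
  die on a given tick.
- **One encounter per tick.**  No generational batching; with N agents and
  T ticks each lineage expects T/N focal turns (≈ 667 at the default
  3,000 agents × 2,000,000 ticks).
- **Castes are fixed.**  Newborns always replace their predecessor's slot
  in the same caste, so per-caste counts are invariants of a run.

## Parameters

| parameter | caste 0 | caste 1 | caste 2 | role |
|---|---|---|---|---|
| endowment (resource units) | 50 | 75 | 100 | birth resources; starvation threshold is 10% of it |
| metabolic cost factor (–) | 0.05 | 0.075 | 0.1 | flee cost; exists to make perpetual flight unsustainable |
| honest appropriation (–) | 0.25 | 0.50 | 0.75 | winner's share of an honest loser |
| dishonest appropriation (–) | 0.50 | 0.75 | 1.00 | winner's share of a dishonest loser; the gap to the column left is the punishment |

A 4-vector of scale factors in (0, 1] multiplies the four parameters across
all castes at once; the named regimes are default `[1,1,1,1]`, intermediate
`[0.5]*4`, minimal `[0.1]*4`, and the full-factorial sweep crosses a level
grid (default {1.0, 0.5, 0.25, 0.1}, i.e. 256 settings) over the four
parameters independently.  Runs start with 85% deceptive signalers.  Two
initialization details are underdetermined by the original description and
were fixed here for determinism and symmetry: the 85% applies *per caste*
(the study's per-caste liar counts all start near 850), and each deceptive
agent picks between its two wrong signals with equal probability.

## The fight-or-flight rule and its calibration

The original study specifies the encounter game's payoffs precisely but
describes the engagement decision only qualitatively: a party fights when
its resources are high enough or when the counterparty's signal is
peaceable, and the lower the ratio of current resources to endowment, the
likelier flight.  That leaves three genuinely open choices, which this
package isolates behind configuration switches:

- `flee_prob_form="linear"`: against any non-peaceable signal, fight with
  probability r = resources/endowment.  This is the minimal monotone
  reading of the text.
- `flee_prob_form="deferent"` (default): a signal strictly above the
  party's own caste always causes flight; the linear ratio rule applies
  only between apparent equals.  Deference is what makes bluffing pay.
- `flee_cost_base`: the flee cost is the caste's metabolic factor times
  either the birth endowment (`"endowment"`, a fixed per-caste amount) or
  the agent's `"current"` resources (default).

The shipped defaults were selected by a calibration against the study's
printed mortality summaries (per-caste replicate-mean death counts and mean
ages at death under the default and minimal regimes, 30 × 2M-tick runs): a
grid over {higher-signal rule} × {equal-signal rule: linear, quadratic,
square-root, hard thresholds} × {cost base} was scored on relative error.
The linear-everywhere rule produces roughly an order of magnitude too many
deaths (a full-endowment newborn always fights, and a dishonest loser
facing a high-caste winner forfeits 100% of its resources at once);
`deferent` + `current` is the best-fitting variant and also the only one
that reproduces the qualitative fingerprints of all three regimes
(deception purged under default punishment with the middle caste fastest;
high-caste deception frozen under minimal punishment; roughly a third of
the high caste still deceptive, and deceivers several-fold richer than
honest caste-mates, under intermediate punishment).

Calibration outcome, for honesty's sake: the chosen rule reproduces the
middle-caste default-regime mortality within a few percent and the
high-caste count within ~12%, but still over-produces low-caste deaths
(~+30%) and minimal-regime deaths (~+60% for caste 1).  The residual is
structural, not tunable: under minimal punishment a caste-1 agent *always*
fights a signal-0 counterparty (peaceable — this part of the rule is fixed
by the model's definition), more than half of those counterparties are
seducing caste-2 agents at the published equilibrium, and each such loss
costs 10% of current resources; that hazard alone bounds caste-1 lifespans
below the published value for any choice of the remaining switches.  The
corresponding acceptance tests are left failing rather than loosened, and
`scripts/acceptance.py` reports whatever the model actually produces.

## Random numbers and reproducibility

All randomness comes from a single splitmix64 stream per run, consumed in a
fixed documented order (see `castesim/rng.py`): initialization signals,
then per tick the focal index, counterparty index, engagement draw (only
when the rule calls for one), battle coin (only on exact ties), and
tournament draws (only on a death).  The stream was chosen over a library
generator because its state is a single 64-bit integer, which lets the
compiled kernel and the pure-Python reference engine consume *identical*
sequences: the test suite asserts bit-for-bit equality of snapshot tables,
death logs and focal-pick counts between the two engines.  Replicate i of a
batch uses the i-th output of a splitmix64 stream seeded with the batch
seed (truncated to 31 bits), so any replicate can be reproduced in
isolation.

Numerical notes: resource comparisons in battles and tournaments are exact
float comparisons (ties therefore occur mainly among newborns and in
degenerate configs, and are broken by a fair coin); flee costs floor
resources at zero; a losing party's forfeit is multiplicative, so resources
stay non-negative; appropriation fractions are capped at 1 after scaling.
Integer draws use modulo reduction (bias < 1e-15 for population-sized
bounds, and identical on both engines, which is what matters here).

## Recorders and outputs

A snapshot — per-(caste, signal) agent counts and mean resources, with the
mean recorded as missing for empty cells — is taken at tick 0, every
`snapshot_interval` ticks (default 1,000), and at the final tick.  Liar
counts are derived as caste size minus the honest diagonal.  Deaths are
logged individually (caste, signal, birth tick, death tick).  The CLI
writes tidy CSVs (`run_id, tick, caste, signal, count, mean_resources` and
`run_id, death_tick, caste, signal, age_at_death`) plus config metadata as
JSON, and the plotting module reproduces the study's figure style
(per-replicate grey trajectories, mean in black).

## Scales used by the test suite

The compiled engine runs the full published scale (3,000 agents, 2,000,000
ticks, 30 replications) in seconds, so the acceptance checks use it
directly.  The stochastic property checks (monotonicity of final deception
in the punishment scale; equivalence of single-caste societies) run at a
reduced scale of 300 agents × 200,000 ticks × 10 replicates — the same
expected focal picks per lineage as the full scale — and the engine-vs-
reference oracle comparison uses 30 agents × 10,000 ticks, where the naive
engine is still fast.

## What the generator does and does not emulate

All inputs are generated by the simulator itself from a config; there is no
external data.  Passing tests therefore demonstrate internal correctness
(the implemented rules, their invariants, and reproduction of the published
summary statistics where the engagement rule permits) — they say nothing
about real insect societies: the model abstracts away memory, reputation,
spatial structure, signal production costs, and any within-caste
heterogeneity beyond the signal itself.

## Known limitations

- The engagement rule is a calibrated reconstruction; the original code's
  exact rule is unpublished, and four of the six published mortality
  statistics are reproduced only approximately (see above).
- The egalitarian (single-caste) experiments in the original are not fully
  specified; this package defaults to 3,000 agents under the intermediate
  regime, matching the comparison the study draws, and exposes both knobs.
- A caste must have at least 3 members for deaths in it to be replaceable
  (the tournament needs two candidates besides the dying agent); `run`
  validates this, while the low-level primitives raise on short pools.
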