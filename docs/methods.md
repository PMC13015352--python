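# Model and methods

## The model

A filament is an ordered chain of cells. Every cell carries two pole
ages, an amount of a diffusible compound, and the absolute time of its
next division; every cell–cell connection carries its age. Growth is by
binary fission: each cell independently schedules its next division at
birth by drawing a waiting time from N(division_mean, division_sd),
truncated below at dt by resampling, and the simulation advances in
fixed steps of dt. A division replaces the parent with two adjacent
daughters: the outer pole of each daughter inherits the parent's
corresponding pole age, the two new inner poles and the new connection
start at age 0, and the parent's compound is split equally. Pole-age
bookkeeping makes "cell age" (the mean of the two pole ages) a
replicative-age proxy: in a filament grown from one founder the terminal
cells carry the founder's original poles and are always the oldest.

Defaults (all config-exposed):

| parameter | default | meaning |
| --- | --- | --- |
| dt | 0.01 | simulation step, in units of the mean cell cycle |
| division_mean, division_sd | 1.0, 0.05 | division-time law N(1, 0.05); 0.05 is read as the standard deviation (CV 5%), the common convention for cycle-time noise |
| production_per_step | 1 | compound added to every cell each step |
| D | 0.01 | dimensionless exchange fraction per step between neighbours, and across each free end (environment treated as zero concentration) |
| n_fragmentations | 100 | logged events per run |
| target_size | 32 | calibration target for the mean adult size |

The compound update is an explicit Euler step on the unit-spaced chain
with absorbing boundaries, all fluxes evaluated on the pre-step state:
`d_i' = d_i + 1 + D·(d_{i-1} + d_{i+1} - 2 d_i)` with the missing
neighbour of a terminal cell replaced by 0. The scheme conserves mass up
to production and boundary loss exactly and is contracting for D ≤ 0.5.

## Step ordering and event handling

Within one step: ages advance; the compound field updates (only when the
active rule reads it); the fragmentation rule is evaluated; then all
divisions whose scheduled time has passed execute one at a time in
scheduled order. Rules whose cue can *rise* at a division — mechanical
stress, the at-division lottery, and combinations involving stress — are
re-evaluated after each single division. This interleaving is what makes
the stress rule exactly rigid: even when two divisions land in the same
dt step, the threshold is seen at the first cell count that satisfies
it, so fragmentation always occurs at N = 2⌊θ⌋+3 and the adult-size
standard deviation is identically zero. A `batched` update order
(all divisions first, one rule evaluation at the end of the step) is
kept as a config option for sensitivity analysis; under it the stress
rule occasionally fires one division late and loses exact rigidity.

All cells/connections satisfying a rule in the same step fire in the
same event; this is the only source of >2-offspring events, and with
continuous-valued ages such coincidences essentially never happen for
the age rules, as intended. Side ties (the structural midpoint tie of
the stress rule; equal neighbour concentrations or equally old adjacent
connections) are broken by a fair coin from the run's seeded generator.
An event that releases no viable sibling — the death variant shedding a
terminal cell — is logged as a shedding, not a reproduction, and by
default does not count toward the stop condition (config-flagged,
because the alternative reading is defensible).

After each reproduction the engine follows the largest viable daughter
(ties uniform at random). Every run starts from a single age-0 cell, so
each run includes its own growth transient, and batches are assembled
from ceil(total/100) runs seeded with child seeds derived from the
master seed. Identical seeds give identical runs; the engine's
jump-ahead over steps in which neither a division nor a threshold
crossing can occur (possible for the linearly growing age cues and for
stress, which changes only at divisions) is a pure optimization with a
provably conservative bound, so trajectories equal naive per-step
iteration.

## Classification

Events are classified by viable offspring sizes, checked in order:
complete dissociation (≥3 offspring, all single cells), unicellular
propagule (≥1 singleton and ≥1 multicellular offspring), equal binary
(two offspring, each within the inclusive 40–60% band, evaluated in
integer arithmetic), unequal binary (any other two-offspring event),
other. A 2-cell parent splitting into (1, 1) is deliberately classified
as an equal binary split rather than a dissociation: dissociation is
meant to capture the simultaneous severing of every connection of a
multicellular chain, and counting ordinary fission of a 2-cell filament
would make the stochastic baselines "dissociate" every time a break
happened to land on a 2-cell filament, which contradicts the observation
that genuine simultaneous multi-connection severing never arises for
most rules.

The partition counter uses the standard two-variable recurrence for
partitions with bounded largest part plus conjugation to filter on a
minimum number of parts; it exposes `min_parts` because "ways a group
can divide" is quoted both with and without the trivial single-group
partition (42 for n = 10 with min_parts 1; 8348 for n = 32 with
min_parts 2).

## Calibration

`calibrate_threshold` minimizes the mean squared error of adult sizes
against the target over a coarse grid, then refines once between the
best grid point's neighbours; ties go to the smaller θ. Every candidate
is scored on the same master seed, so the child-run seeds coincide and
the comparison between neighbouring candidates is paired (common random
numbers) — important because the objective is noisy for the stochastic
and age rules. Default grids bracket the thresholds appropriate for the
default 32-cell target; other targets (and the aging variant, which
needs much larger connection-age thresholds because growth slows) should
pass an explicit grid. For rules with wide adult-size distributions the
squared-error objective trades mean against variance, so the calibrated
mean adult size can sit below the target (e.g. the compound rule
calibrates to a mean near 26–28 rather than 32); this is a property of
the stated objective, not of the search.

Batch sizes: the library default is 2,000 events per calibration
candidate; the test suite uses 400 and the acceptance script 800, with
final summaries on 10,000-event batches — sizes chosen so the mode
frequencies are resolved to roughly a percentage point at desk scale.

## What the simulations do and do not show

The generator *is* the study system: there is no external data, and all
conclusions are about this idealized filament (permanent bonds, 1-D
geometry, no nutrient limits, no cell motility, no population dynamics).
Observed behaviours at the calibrated defaults:

* mechanical stress: σ = 0, all equal binary splits;
* connection age: σ < 0.35 (θ between division waves), all equal splits;
* cell age: adult sizes from a handful to >60 cells, ~51% unicellular
  propagules, <1% of events at exactly the target size;
* diffusible compound: broad adult sizes, unequal splits the dominant
  mode, and a few percent of events with three or more offspring;
* stochastic baselines: the widest adult-size distributions, unequal
  splits dominating;
* death variant: unicellular propagules disappear (the triggering
  terminal cell dies, so the filament merely sheds it) and equal splits
  take over for the cell-age rule;
* aging variant: division slowing accumulated through pole-age
  inheritance effectively freezes old terminal lineages, desynchronizes
  growth, and pushes the connection-age rule toward unequal splits —
  under this implementation the steady split ratio sits near 0.355, just
  outside the 40% equal-split boundary, so almost all events classify as
  unequal. Because that ratio lies close to the classification edge, the
  unequal-split *frequency* under aging is highly sensitive to the exact
  strength of the aging penalty;
* AND combinations of cell age and compound bias the mean adult size
  above the target, OR combinations below it, and the scanned (θ1, θ2)
  grids contain pairs whose L2 error beats either cue alone.

Two caveats on the compound and stochastic-in-time rules. With the
default parameters the compound field is dominated by division-phase
noise — each cell cycles between roughly d/2 and d/2 + 100 between
halvings, far larger than the few-unit spatial differences that per-step
exchange at D = 0.01 can build — so the triggering cell's position is
close to uniform over the filament interior, and the equal/unequal
balance among binary splits reflects that geometry (roughly a fifth of
interior cut positions fall in the equal-split band). A substantially
larger exchange fraction would flip the field into a smooth,
position-dominated profile and markedly raise the unequal-split share;
D is kept at its stated default. Similarly, for per-step independent
severing calibrated to a 32-cell mean, the expected number of breaks per
step is ~0.01, so simultaneous (>2-offspring) events are a ~1–2% effect;
large multi-offspring fractions would require break clustering beyond
what per-step independence can produce at this adult size.

## Numerical choices and edge cases

* Division detection at the first step boundary at or after the
  scheduled time; no sub-step interpolation.
* Division-time draws below dt are resampled (probability ~1e-89 at the
  default CV; defined for robustness). With sd = 0 the law is the exact
  mean. Under aging, the drawing daughter's current age (half its
  inherited outer-pole age at birth) is added after truncation.
* Thresholds are compared strictly (`> θ`); crossing-step prediction
  rounds down so a firing step can never be jumped over.
* A rule that cannot fire within `max_steps` or before the filament
  exceeds `max_cells` raises an explicit non-termination error, which
  calibration treats as an infinite score.
* A 1-cell filament whose cue exceeds θ has no connection to sever and
  is left alone (under the death variant it would be an extinction,
  raised as an error).
* Compound is clipped at zero after each step; at D ≤ 0.5 the clip is
  provably inert.

## Known limitations

The aging and death variants reproduce the qualitative shifts described
above but sit on classification boundaries (see the aging caveat), so
their mode percentages are delicate. Mode percentages for the
compound-based and stochastic-in-time rules depend on the compound
regime and break-clustering caveats discussed above. The partition
counter is exact but unrelated to dynamics; it quantifies the space of
conceivable allocations only.
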