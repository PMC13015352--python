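"""Discrete-time simulation of the filament life cycle.

A run starts from a single age-0 cell and advances in steps of ``dt``.
Each cell schedules its next binary fission at birth by drawing a waiting
time from a normal law N(division_mean, division_sd) truncated below at
``dt`` (under the aging variant the cell's current age is added, so old
cells divide more slowly). Pole and connection ages accrue with simulated
time; if the active rule reads the diffusible compound, one
production+diffusion step is applied every ``dt``.

Within a step the order of operations is: ages advance, compound updates,
the fragmentation rule is evaluated, and divisions whose scheduled time
has passed are then executed one at a time in scheduled order. Rules whose
cue a division can raise (mechanical stress, stochastic at division, and
combinations involving stress) are re-evaluated immediately after each
division, so a threshold is always seen at the first cell count that
satisfies it even when several divisions fall in the same step. Setting
``update_order="batched"`` instead executes all due divisions first and
evaluates the rule once at the end of the step, for sensitivity analysis.

When a rule fires, the event is logged with the parent's size immediately
before severing, the offspring multiset is classified, and the simulation
continues with the largest viable daughter (ties resolved uniformly at
random). An event that releases no viable sibling — e.g. the death variant
shedding a single dead cell — is counted as a shedding, not a
reproduction, unless ``count_shedding`` is set. The run stops after
``n_fragmentations`` logged events.

For rules that do not read the compound, the loop jumps over steps in
which neither a division nor a threshold crossing can occur (cell and
connection ages grow linearly, stress changes only at divisions, so the
first step at which a rule can fire is known); the jump is a lower bound
on the true crossing step, making the trajectory identical to naive
per-step iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dynamics import DiffusionParams, advance_ages, diffuse_step
from .filament import Filament, divide_cell
from .lifecycle import FragmentationEvent, classify
from .rules import (
    CombinedRuleSpec,
    RuleSpec,
    SeveringDecision,
    apply_decision,
    eval_stochastic_at_division,
    evaluate,
)

__all__ = [
    "EngineConfig",
    "RunRecord",
    "NonTerminationError",
    "SimulationError",
    "draw_division_time",
    "run",
    "run_many",
    "collect_events",
]


class SimulationError(RuntimeError):
    """The tracked lineage died out (no viable fragment remained)."""


class NonTerminationError(RuntimeError):
    """The rule failed to fire within the configured step/size budget."""


@dataclass(frozen=True)
class EngineConfig:
    """Full configuration of one simulation run."""

    rule: RuleSpec | CombinedRuleSpec
    seed: int | None = None
    dt: float = 0.01
    division_mean: float = 1.0
    division_sd: float = 0.05
    n_fragmentations: int = 100
    aging: bool = False
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    count_shedding: bool = False
    update_order: str = "interleaved"
    max_steps: int = 2_000_000
    max_cells: int = 20_000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.division_mean <= 0:
            raise ValueError("division_mean must be positive")
        if self.division_sd < 0:
            raise ValueError("division_sd must be non-negative")
        if self.n_fragmentations < 1:
            raise ValueError("n_fragmentations must be at least 1")
        if self.update_order not in ("interleaved", "batched"):
            raise ValueError("update_order must be 'interleaved' or 'batched'")


@dataclass
class RunRecord:
    """Events and provenance of one run."""

    events: list[FragmentationEvent]
    seed: int | None
    config: EngineConfig
    n_sheddings: int = 0
    n_steps: int = 0
    t_end: float = 0.0


def draw_division_time(
    rng: np.random.Generator,
    mean: float = 1.0,
    sd: float = 0.05,
    dt: float = 0.01,
    age: float = 0.0,
) -> float:
    """One waiting time until a cell's next division.

    Drawn from N(mean, sd) truncated below at ``dt`` by resampling (draws
    below dt are vanishingly rare at the default CV of 5%, but the
    truncation keeps every schedule strictly in the future). Under the
    aging variant the caller passes the cell's current ``age``, which is
    added to the drawn time.
    """
    if sd <= 0:
        return max(mean, dt) + age
    x = rng.normal(mean, sd)
    while x < dt:
        x = rng.normal(mean, sd)
    return x + age


def _needs_compound(spec: RuleSpec | CombinedRuleSpec) -> bool:
    if isinstance(spec, CombinedRuleSpec):
        return "compound" in (spec.rule1.cue, spec.rule2.cue)
    return spec.cue == "compound"


def _division_sensitive(spec: RuleSpec | CombinedRuleSpec) -> bool:
    """Can a division, by itself, newly satisfy the rule?

    Only the stress cue can rise at a division (cell and connection ages
    never increase, compound only halves). OR-combinations involving
    stress inherit the sensitivity; an AND-combination does too since its
    other condition may already hold.
    """
    if isinstance(spec, CombinedRuleSpec):
        return "stress" in (spec.rule1.cue, spec.rule2.cue)
    return spec.cue == "stress"


def _steps_to_possible_trigger(
    f: Filament, spec: RuleSpec | CombinedRuleSpec, dt: float
) -> float:
    """A lower bound on the number of steps until the rule could fire.

    ``inf`` means the rule can only fire as a consequence of a division.
    Rules that must be checked every step (compound-based, stochastic in
    time) return 1.
    """
    if isinstance(spec, CombinedRuleSpec):
        # conservative: the earlier of the two cues' own bounds
        return min(
            _steps_to_possible_trigger(f, spec.rule1, dt),
            _steps_to_possible_trigger(f, spec.rule2, dt),
        )
    cue = spec.cue
    if cue in ("compound", "stochastic_in_time"):
        return 1
    if cue in ("stress", "stochastic_at_division"):
        return math.inf
    if cue == "cell_age":
        v = float(np.max(f.cell_ages()))
    else:  # connection_age
        if f.n == 1:
            return math.inf
        v = float(np.max(f.conn_age))
    if v > spec.threshold:
        return 1
    # first k with v + k*dt > threshold; round down so a firing step can
    # never be skipped (landing early just re-evaluates)
    return max(1, math.ceil((spec.threshold - v) / dt - 1e-9))


def _select_largest(
    fragments: list[Filament], rng: np.random.Generator
) -> Filament:
    sizes = [fr.n for fr in fragments]
    largest = max(sizes)
    winners = [i for i, s in enumerate(sizes) if s == largest]
    pick = winners[0] if len(winners) == 1 else winners[int(rng.integers(len(winners)))]
    return fragments[pick]


def run(config: EngineConfig) -> RunRecord:
    """Simulate one lineage until ``n_fragmentations`` events are logged."""
    rng = np.random.default_rng(config.seed)
    spec = config.rule
    dt = config.dt
    label = spec.label
    needs_compound = _needs_compound(spec)
    division_sensitive = _division_sensitive(spec)
    interleaved = config.update_order == "interleaved"
    at_division_rule = (
        isinstance(spec, RuleSpec) and spec.cue == "stochastic_at_division"
    )

    f = Filament.single_cell(
        next_division_at=draw_division_time(
            rng, config.division_mean, config.division_sd, dt
        )
    )
    events: list[FragmentationEvent] = []
    record = RunRecord(events=events, seed=config.seed, config=config)
    steps = 0
    stop_count = 0

    def handle(decision: SeveringDecision, t: float) -> None:
        """Apply a nonempty decision; update the tracked filament."""
        nonlocal f, stop_count
        parent = f.n
        fragments = apply_decision(f, decision)
        if not fragments:
            raise SimulationError(
                f"rule {label!r} removed the last viable cell at t={t:.2f}"
            )
        if len(fragments) == 1:
            record.n_sheddings += 1
            if config.count_shedding:
                stop_count += 1
            f = fragments[0]
            return
        sizes = tuple(sorted((fr.n for fr in fragments), reverse=True))
        events.append(
            FragmentationEvent(
                time=t,
                parent_size=parent,
                offspring_sizes=sizes,
                mode=classify(parent, sizes),
                rule=label,
            )
        )
        stop_count += 1
        f = _select_largest(fragments, rng)

    while stop_count < config.n_fragmentations:
        if steps >= config.max_steps:
            raise NonTerminationError(
                f"rule {label!r} (threshold "
                f"{getattr(spec, 'threshold', 'n/a')}) produced only "
                f"{stop_count} events within {config.max_steps} steps"
            )
        if f.n > config.max_cells:
            raise NonTerminationError(
                f"filament exceeded max_cells={config.max_cells} under rule "
                f"{label!r} (threshold {getattr(spec, 'threshold', 'n/a')})"
            )

        # how far can we jump without missing a division or a crossing?
        t_now = steps * dt
        next_div = float(np.min(f.next_division_at))
        if math.isinf(next_div):
            k_div = math.inf
        else:
            k_div = max(1, math.ceil((next_div - t_now) / dt - 1e-9))
        if needs_compound:
            k = 1
        else:
            k = min(k_div, _steps_to_possible_trigger(f, spec, dt))
        if math.isinf(k):
            raise NonTerminationError(
                f"rule {label!r} can never fire again (no divisions "
                f"scheduled and no crossing ahead)"
            )
        k = int(min(k, config.max_steps - steps))
        k = max(k, 1)

        advance_ages(f, k * dt)
        steps += k
        t = steps * dt
        if needs_compound:
            diffuse_step(f, config.diffusion)

        if interleaved and not at_division_rule:
            decision = evaluate(f, spec, rng)
            if decision:
                handle(decision, t)
                if stop_count >= config.n_fragmentations:
                    break

        # divisions due by now, one at a time in scheduled order
        while True:
            j = int(np.argmin(f.next_division_at))
            if f.next_division_at[j] > t + 1e-9:
                break
            age_l = 0.5 * f.pole_age_left[j]
            age_r = 0.5 * f.pole_age_right[j]
            t_l = t + draw_division_time(
                rng,
                config.division_mean,
                config.division_sd,
                dt,
                age=age_l if config.aging else 0.0,
            )
            t_r = t + draw_division_time(
                rng,
                config.division_mean,
                config.division_sd,
                dt,
                age=age_r if config.aging else 0.0,
            )
            divide_cell(f, j, t, (t_l, t_r))
            if at_division_rule:
                if eval_stochastic_at_division(rng, spec.threshold):
                    kills: frozenset[int] = frozenset()
                    if spec.death_variant:
                        kills = frozenset(
                            {j if rng.random() < 0.5 else j + 1}
                        )
                    handle(
                        SeveringDecision(connections=frozenset({j}), kills=kills),
                        t,
                    )
            elif interleaved and division_sensitive:
                decision = evaluate(f, spec, rng)
                if decision:
                    handle(decision, t)
            if stop_count >= config.n_fragmentations:
                break

        if (
            not interleaved
            and not at_division_rule
            and stop_count < config.n_fragmentations
        ):
            decision = evaluate(f, spec, rng)
            if decision:
                handle(decision, t)

    record.n_steps = steps
    record.t_end = steps * dt
    return record


def run_many(config: EngineConfig, n_events_total: int) -> list[RunRecord]:
    """Independent replicate runs totalling at least ``n_events_total`` events.

    Launches ``ceil(n_events_total / n_fragmentations)`` runs, each seeded
    with a distinct child seed derived from the master seed, so the full
    concatenated event list is reproducible. Use :func:`collect_events` to
    flatten and truncate to exactly ``n_events_total``.
    """
    if n_events_total < 1:
        raise ValueError("n_events_total must be at least 1")
    n_runs = -(-n_events_total // config.n_fragmentations)
    child_seeds = np.random.default_rng(config.seed).integers(
        2**31, size=n_runs
    )
    return [
        run(replace(config, seed=int(s))) for s in child_seeds
    ]


def collect_events(
    records: Sequence[RunRecord], limit: int | None = None
) -> list[FragmentationEvent]:
    """Flatten run records into one event list, optionally truncated."""
    out: list[FragmentationEvent] = []
    for rec in records:
        out.extend(rec.events)
        if limit is not None and len(out) >= limit:
            return out[:limit]
    return out
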