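"""Fragmentation rules: which connections sever (and which cells die).

Six single rules are supported. Four read an intrinsic cue and fire when a
cell (or connection) exceeds a threshold θ:

* ``cell_age`` — a cell whose mean pole age exceeds θ breaks its *older*
  adjacent connection (a terminal cell breaks its only one);
* ``connection_age`` — any connection older than θ breaks;
* ``compound`` — a cell whose compound amount exceeds θ breaks the
  connection toward its higher-concentration neighbour;
* ``stress`` — a cell with ``min(n_L, n_R) > θ`` breaks the connection on
  its more populous side (``n_L > n_R`` severs the left-side bond).

Two stochastic baselines complete the set: ``stochastic_at_division``
(a connection created by a division breaks immediately with probability
``p``) and ``stochastic_in_time`` (every connection breaks independently
with per-step probability θ).

All cells/connections that satisfy a rule within the same step fire in the
same event, which is what allows the compound and stochastic-in-time rules
to produce more than two offspring at once. Side ties (equal neighbour
concentrations, equally old adjacent connections, the exact midpoint under
the stress rule) are broken by a fair coin from the caller's seeded
generator; with continuous ages such ties essentially never arise except
for the structural stress-rule tie at an odd-length midpoint.

Under the death variant a cell-level rule removes the triggering cell and
severs both its connections; for connection-level rules (connection age
and the stochastic rules) one of the two cells flanking each broken
connection is chosen uniformly at random and removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .filament import Filament

__all__ = [
    "CUES",
    "DETERMINISTIC_CUES",
    "RuleSpec",
    "CombinedRuleSpec",
    "SeveringDecision",
    "eval_cell_age_rule",
    "eval_connection_age_rule",
    "eval_compound_rule",
    "eval_stress_rule",
    "eval_stochastic_at_division",
    "eval_stochastic_in_time",
    "eval_combined",
    "evaluate",
    "apply_decision",
]

DETERMINISTIC_CUES = ("cell_age", "connection_age", "compound", "stress")
STOCHASTIC_CUES = ("stochastic_at_division", "stochastic_in_time")
CUES = DETERMINISTIC_CUES + STOCHASTIC_CUES

#: cues for which the triggering entity is a cell (the cell dies under the
#: death variant) rather than a connection
_CELL_LEVEL_CUES = ("cell_age", "compound", "stress")


@dataclass(frozen=True)
class RuleSpec:
    """A single fragmentation rule: a cue, its threshold, variant flags.

    For the stochastic cues ``threshold`` is a probability in [0, 1]
    (per new connection for ``stochastic_at_division``, per connection per
    step for ``stochastic_in_time``).
    """

    cue: str
    threshold: float
    death_variant: bool = False

    def __post_init__(self) -> None:
        if self.cue not in CUES:
            raise ValueError(f"unknown cue {self.cue!r}; expected one of {CUES}")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.cue in STOCHASTIC_CUES and not 0.0 <= self.threshold <= 1.0:
            raise ValueError("stochastic rules need a probability in [0, 1]")

    @property
    def label(self) -> str:
        return self.cue


@dataclass(frozen=True)
class CombinedRuleSpec:
    """Two deterministic rules joined by Boolean logic.

    With ``logic="and"`` a cell fires only when its own cue values satisfy
    both thresholds at once; with ``"or"`` either suffices. The severing
    policy of ``rule1`` takes precedence whenever both rules fired for the
    same cell. ``scope="filament"`` is a softer AND for sensitivity
    analysis: cells satisfying the first cue fire provided *some* cell
    satisfies the second.
    """

    rule1: RuleSpec
    rule2: RuleSpec
    logic: Literal["and", "or"]
    scope: Literal["cell", "filament"] = "cell"

    def __post_init__(self) -> None:
        if self.logic not in ("and", "or"):
            raise ValueError("logic must be 'and' or 'or'")
        if self.scope not in ("cell", "filament"):
            raise ValueError("scope must be 'cell' or 'filament'")
        for r in (self.rule1, self.rule2):
            if r.cue not in DETERMINISTIC_CUES:
                raise ValueError("only deterministic cues can be combined")
        if self.rule1.cue == self.rule2.cue:
            raise ValueError("combined rules must use two different cues")

    @property
    def death_variant(self) -> bool:
        return self.rule1.death_variant or self.rule2.death_variant

    @property
    def label(self) -> str:
        return f"{self.rule1.cue}+{self.rule2.cue}:{self.logic}"


@dataclass(frozen=True)
class SeveringDecision:
    """Connections to break and cells to remove in one event."""

    connections: frozenset[int] = field(default_factory=frozenset)
    kills: frozenset[int] = field(default_factory=frozenset)

    def __bool__(self) -> bool:
        return bool(self.connections) or bool(self.kills)


_EMPTY = SeveringDecision()


def _coin(rng: np.random.Generator | None) -> bool:
    """True → pick the left/lower-index option."""
    if rng is None:
        return True
    return rng.random() < 0.5


# --------------------------------------------------------------------- #
# per-cell severing policies (which adjacent connection a triggering cell
# breaks); return None when the cell has no connection at all


def _older_adjacent_connection(
    f: Filament, i: int, rng: np.random.Generator | None
) -> int | None:
    n = f.n
    if n == 1:
        return None
    if i == 0:
        return 0
    if i == n - 1:
        return n - 2
    left, right = f.conn_age[i - 1], f.conn_age[i]
    if left > right:
        return i - 1
    if right > left:
        return i
    return i - 1 if _coin(rng) else i


def _toward_richer_neighbour(
    f: Filament, i: int, rng: np.random.Generator | None
) -> int | None:
    n = f.n
    if n == 1:
        return None
    if i == 0:
        return 0
    if i == n - 1:
        return n - 2
    left, right = f.compound[i - 1], f.compound[i + 1]
    if left > right:
        return i - 1
    if right > left:
        return i
    return i - 1 if _coin(rng) else i


def _toward_larger_side(
    f: Filament, i: int, rng: np.random.Generator | None
) -> int | None:
    n = f.n
    if n == 1:
        return None
    n_l, n_r = i, n - 1 - i
    if n_l > n_r:
        return i - 1
    if n_r > n_l:
        return i
    return i - 1 if _coin(rng) else i


_POLICIES = {
    "cell_age": _older_adjacent_connection,
    "connection_age": _older_adjacent_connection,  # used in combinations
    "compound": _toward_richer_neighbour,
    "stress": _toward_larger_side,
}


def _cue_values(f: Filament, cue: str) -> np.ndarray:
    """Per-cell value of a deterministic cue.

    For ``connection_age`` (a per-connection quantity) the per-cell value
    used in Boolean combinations is the age of the cell's oldest adjacent
    connection.
    """
    if cue == "cell_age":
        return f.cell_ages()
    if cue == "compound":
        return f.compound
    if cue == "stress":
        idx = np.arange(f.n)
        return np.minimum(idx, f.n - 1 - idx).astype(float)
    if cue == "connection_age":
        if f.n == 1:
            return np.full(1, -math.inf)
        vals = np.full(f.n, -math.inf)
        vals[:-1] = f.conn_age
        vals[1:] = np.maximum(vals[1:], f.conn_age)
        return vals
    raise ValueError(f"unknown deterministic cue {cue!r}")


def _cell_rule_decision(
    f: Filament,
    triggered: np.ndarray,
    policy_cues: list[str],
    rng: np.random.Generator | None,
    death: bool,
) -> SeveringDecision:
    """Turn per-cell trigger flags into a decision.

    ``policy_cues[i]`` names the severing policy for cell ``i`` (only read
    where ``triggered`` is True; combined OR rules mix policies).
    """
    idx = np.flatnonzero(triggered)
    if idx.size == 0:
        return _EMPTY
    if death:
        return SeveringDecision(kills=frozenset(int(i) for i in idx))
    conns: set[int] = set()
    for i in idx:
        c = _POLICIES[policy_cues[i]](f, int(i), rng)
        if c is not None:
            conns.add(c)
    if not conns:
        return _EMPTY
    return SeveringDecision(connections=frozenset(conns))


def _connection_rule_decision(
    mask: np.ndarray, rng: np.random.Generator | None, death: bool
) -> SeveringDecision:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return _EMPTY
    conns = frozenset(int(j) for j in idx)
    kills: set[int] = set()
    if death:
        # one of the two cells flanking each broken connection dies
        for j in idx:
            kills.add(int(j) if _coin(rng) else int(j) + 1)
    return SeveringDecision(connections=conns, kills=frozenset(kills))


# --------------------------------------------------------------------- #
# the six single rules


def eval_cell_age_rule(
    filament: Filament,
    threshold: float,
    rng: np.random.Generator | None = None,
    death_variant: bool = False,
) -> SeveringDecision:
    """Cells older (mean pole age) than θ break their older connection."""
    triggered = filament.cell_ages() > threshold
    cues = ["cell_age"] * filament.n
    return _cell_rule_decision(filament, triggered, cues, rng, death_variant)


def eval_connection_age_rule(
    filament: Filament,
    threshold: float,
    rng: np.random.Generator | None = None,
    death_variant: bool = False,
) -> SeveringDecision:
    """Every connection older than θ breaks."""
    return _connection_rule_decision(
        filament.conn_age > threshold, rng, death_variant
    )


def eval_compound_rule(
    filament: Filament,
    threshold: float,
    rng: np.random.Generator | None = None,
    death_variant: bool = False,
) -> SeveringDecision:
    """Cells holding more compound than θ break toward the richer side."""
    triggered = filament.compound > threshold
    cues = ["compound"] * filament.n
    return _cell_rule_decision(filament, triggered, cues, rng, death_variant)


def eval_stress_rule(
    filament: Filament,
    threshold: float,
    rng: np.random.Generator | None = None,
    death_variant: bool = False,
) -> SeveringDecision:
    """Cells with ``min(n_L, n_R) > θ`` break on their more populous side."""
    idx = np.arange(filament.n)
    triggered = np.minimum(idx, filament.n - 1 - idx) > threshold
    cues = ["stress"] * filament.n
    return _cell_rule_decision(filament, triggered, cues, rng, death_variant)


def eval_stochastic_at_division(rng: np.random.Generator, p: float) -> bool:
    """Does a connection just created by a division break immediately?

    Called exactly once per division-born connection, at creation time.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    return bool(rng.random() < p)


def eval_stochastic_in_time(
    filament: Filament,
    threshold: float,
    rng: np.random.Generator,
    death_variant: bool = False,
) -> SeveringDecision:
    """Each connection breaks independently with probability θ this step."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("per-step break probability must lie in [0, 1]")
    m = filament.n - 1
    if m == 0:
        return _EMPTY
    mask = rng.random(m) < threshold
    return _connection_rule_decision(mask, rng, death_variant)


def eval_combined(
    filament: Filament,
    spec: CombinedRuleSpec,
    rng: np.random.Generator | None = None,
) -> SeveringDecision:
    """Evaluate a Boolean combination of two deterministic rules."""
    v1 = _cue_values(filament, spec.rule1.cue)
    v2 = _cue_values(filament, spec.rule2.cue)
    t1 = v1 > spec.rule1.threshold
    t2 = v2 > spec.rule2.threshold
    if spec.logic == "and":
        if spec.scope == "filament":
            triggered = t1 if t2.any() else np.zeros_like(t1)
        else:
            triggered = t1 & t2
        cues = [spec.rule1.cue] * filament.n
    else:  # or
        triggered = t1 | t2
        # rule1's severing policy wins where both fired
        cues = [
            spec.rule1.cue if t1[i] else spec.rule2.cue for i in range(filament.n)
        ]
    return _cell_rule_decision(
        filament, triggered, cues, rng, spec.death_variant
    )


def evaluate(
    filament: Filament,
    spec: RuleSpec | CombinedRuleSpec,
    rng: np.random.Generator | None = None,
) -> SeveringDecision:
    """Dispatch to the right rule evaluator.

    ``stochastic_at_division`` has no time-triggered component and always
    returns an empty decision here; the engine tests division-born
    connections via :func:`eval_stochastic_at_division` as they appear.
    """
    if isinstance(spec, CombinedRuleSpec):
        return eval_combined(filament, spec, rng)
    if spec.cue == "cell_age":
        return eval_cell_age_rule(filament, spec.threshold, rng, spec.death_variant)
    if spec.cue == "connection_age":
        return eval_connection_age_rule(
            filament, spec.threshold, rng, spec.death_variant
        )
    if spec.cue == "compound":
        return eval_compound_rule(filament, spec.threshold, rng, spec.death_variant)
    if spec.cue == "stress":
        return eval_stress_rule(filament, spec.threshold, rng, spec.death_variant)
    if spec.cue == "stochastic_in_time":
        if rng is None:
            raise ValueError("stochastic rules need a random generator")
        return eval_stochastic_in_time(
            filament, spec.threshold, rng, spec.death_variant
        )
    if spec.cue == "stochastic_at_division":
        return _EMPTY
    raise ValueError(f"unknown cue {spec.cue!r}")


def apply_decision(
    filament: Filament, decision: SeveringDecision
) -> list[Filament]:
    """Sever all marked connections, remove marked cells, return fragments.

    All marks are applied simultaneously. A removed cell severs both its
    connections and is excluded from the returned fragments, so the total
    cell count across fragments equals the parent's count minus the number
    of removed cells.
    """
    if not decision:
        raise ValueError("cannot apply an empty severing decision")
    n = filament.n
    for j in decision.connections:
        if not 0 <= j < n - 1:
            raise IndexError(f"connection index {j} out of range for n={n}")
    for k in decision.kills:
        if not 0 <= k < n:
            raise IndexError(f"cell index {k} out of range for n={n}")

    cut = np.zeros(max(n - 1, 0), dtype=bool)
    for j in decision.connections:
        cut[j] = True
    for k in decision.kills:
        if k > 0:
            cut[k - 1] = True
        if k < n - 1:
            cut[k] = True

    fragments: list[Filament] = []
    start = 0
    for stop in [*np.flatnonzero(cut) + 1, n]:
        # a killed cell always ends up isolated in its own segment
        if not (stop - start == 1 and start in decision.kills):
            fragments.append(filament.extract(start, stop))
        start = stop
    return fragments
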