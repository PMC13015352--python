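"""Fragmentation rules against independent brute-force oracles."""

import math

import numpy as np
import pytest

from filafrag import (
    Cell,
    CombinedRuleSpec,
    Filament,
    RuleSpec,
    SeveringDecision,
    apply_decision,
    eval_cell_age_rule,
    eval_combined,
    eval_compound_rule,
    eval_connection_age_rule,
    eval_stochastic_at_division,
    eval_stochastic_in_time,
    eval_stress_rule,
    evaluate,
)


class FixedCoins:
    """Stand-in random stream with scripted uniform draws."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, size=None):
        if size is None:
            return self.values.pop(0)
        return np.array([self.values.pop(0) for _ in range(size)])


# ------------------------------------------------------------------ #
# independent oracle: plain-loop re-implementation over Cell records


def oracle_decision(filament, cue, theta):
    """Brute-force, loop-based rule check for tie-free filaments."""
    n = filament.n
    ages = [
        (filament.pole_age_left[i] + filament.pole_age_right[i]) / 2
        for i in range(n)
    ]
    conns = set()
    if cue == "connection_age":
        for j in range(n - 1):
            if filament.conn_age[j] > theta:
                conns.add(j)
        return conns
    for i in range(n):
        if cue == "cell_age":
            fired = ages[i] > theta
        elif cue == "compound":
            fired = filament.compound[i] > theta
        elif cue == "stress":
            fired = min(i, n - 1 - i) > theta
        if not fired or n == 1:
            continue
        if cue == "cell_age":
            if i == 0:
                conns.add(0)
            elif i == n - 1:
                conns.add(n - 2)
            else:
                conns.add(i - 1 if filament.conn_age[i - 1] > filament.conn_age[i] else i)
        elif cue == "compound":
            if i == 0:
                conns.add(0)
            elif i == n - 1:
                conns.add(n - 2)
            else:
                conns.add(i - 1 if filament.compound[i - 1] > filament.compound[i + 1] else i)
        elif cue == "stress":
            if i > n - 1 - i:
                conns.add(i - 1)
            elif i < n - 1 - i:
                conns.add(i)
            else:  # exact middle: oracle only used with tie-free sizes
                raise AssertionError("tie in oracle")
    return conns


def random_filament(rng, n):
    cells = [
        Cell(
            pole_age_left=float(rng.uniform(0, 6)),
            pole_age_right=float(rng.uniform(0, 6)),
            compound=float(rng.uniform(0, 200)),
        )
        for _ in range(n)
    ]
    from filafrag import Connection

    conns = [Connection(age=float(rng.uniform(0, 5))) for _ in range(n - 1)]
    return Filament(cells, conns)


EVALS = {
    "cell_age": eval_cell_age_rule,
    "connection_age": eval_connection_age_rule,
    "compound": eval_compound_rule,
    "stress": eval_stress_rule,
}


@pytest.mark.parametrize("cue", ["cell_age", "connection_age", "compound", "stress"])
def test_rules_match_brute_force(cue, rng):
    """Vectorized evaluation equals a plain-loop oracle on random state."""
    thetas = {"cell_age": 3.0, "connection_age": 2.5, "compound": 100.0, "stress": 3}
    for n in range(1, 13):
        if cue == "stress" and n % 2 == 1 and (n - 1) // 2 > thetas[cue]:
            continue  # exact-middle tie handled separately
        for _ in range(5):
            f = random_filament(rng, n)
            got = EVALS[cue](f, thetas[cue], rng)
            assert set(got.connections) == oracle_decision(f, cue, thetas[cue])
            assert not got.kills


class TestCellAgeRule:
    def test_below_threshold_is_empty(self, build_filament):
        f = build_filament([(1, 1), (2, 2)], conn_ages=[0.5])
        assert not eval_cell_age_rule(f, 5.0)

    def test_terminal_trigger_releases_singleton(self, build_filament):
        f = build_filament([(9, 1), (1, 1), (1, 1)], conn_ages=[2.0, 0.5])
        d = eval_cell_age_rule(f, 4.0)
        assert set(d.connections) == {0}
        assert [fr.n for fr in apply_decision(f, d)] == [1, 2]

    def test_interior_cell_breaks_older_side(self, build_filament):
        f = build_filament([(1, 1), (8, 8), (1, 1)], conn_ages=[3.0, 1.0])
        d = eval_cell_age_rule(f, 5.0)
        assert set(d.connections) == {0}

    def test_death_variant_kills_trigger(self, build_filament):
        f = build_filament([(9, 9), (1, 1), (1, 1)], conn_ages=[1.0, 0.5])
        d = eval_cell_age_rule(f, 5.0, death_variant=True)
        assert set(d.kills) == {0} and not d.connections
        frags = apply_decision(f, d)
        assert [fr.n for fr in frags] == [2]  # dead singleton excluded


class TestCompoundRule:
    def test_breaks_toward_richer_neighbour(self, build_filament):
        f = build_filament([(0, 0)] * 3, compounds=[7.0, 50.0, 3.0])
        d = eval_compound_rule(f, 40.0)
        assert set(d.connections) == {0}

    def test_terminal_trigger_uses_only_connection(self, build_filament):
        f = build_filament([(0, 0)] * 3, compounds=[50.0, 7.0, 3.0])
        d = eval_compound_rule(f, 40.0)
        assert set(d.connections) == {0}


class TestStressRule:
    @pytest.mark.parametrize("n", range(1, 50))
    def test_firing_size_threshold(self, n):
        """Max stress is floor((N-1)/2): firing needs N >= 2θ+3."""
        theta = 4
        f = Filament([Cell() for _ in range(n)])
        d = eval_stress_rule(f, theta, FixedCoins([0.3] * n))
        if n < 2 * theta + 3:
            assert not d
        else:
            assert d

    def test_33_cell_filament_severs_a_middle_connection(self):
        f = Filament([Cell() for _ in range(33)])
        d = eval_stress_rule(f, 15, FixedCoins([0.9]))
        frags = apply_decision(f, d)
        assert sorted(fr.n for fr in frags) == [16, 17]


class TestStochasticRules:
    def test_at_division_extremes(self, rng):
        assert not eval_stochastic_at_division(rng, 0.0)
        assert eval_stochastic_at_division(rng, 1.0)

    def test_at_division_break_fraction(self, rng):
        draws = sum(eval_stochastic_at_division(rng, 0.1) for _ in range(10_000))
        # binomial three-sigma band around p = 0.1
        assert abs(draws / 10_000 - 0.1) < 3 * math.sqrt(0.1 * 0.9 / 10_000)

    def test_in_time_extremes(self, rng):
        f = Filament([Cell() for _ in range(6)])
        assert not eval_stochastic_in_time(f, 0.0, rng)
        d = eval_stochastic_in_time(f, 1.0, rng)
        assert set(d.connections) == {0, 1, 2, 3, 4}
        assert [fr.n for fr in apply_decision(f, d)] == [1] * 6

    def test_in_time_expected_breaks(self, rng):
        f = Filament([Cell() for _ in range(21)])
        theta = 0.05
        total = sum(
            len(eval_stochastic_in_time(f, theta, rng).connections)
            for _ in range(4000)
        )
        expect = 4000 * 20 * theta
        assert abs(total - expect) < 4 * math.sqrt(expect)


class TestCombined:
    def _aged_compound_filament(self, build_filament):
        return build_filament(
            [(6, 6), (1, 1), (6, 6)],
            compounds=[10.0, 90.0, 10.0],
            conn_ages=[2.0, 1.0],
        )

    def test_and_with_unsatisfiable_second_threshold_never_fires(
        self, build_filament
    ):
        f = self._aged_compound_filament(build_filament)
        spec = CombinedRuleSpec(
            RuleSpec("cell_age", 4.0), RuleSpec("compound", math.inf), "and"
        )
        assert not eval_combined(f, spec)

    def test_and_with_always_satisfied_second_threshold_is_rule1(
        self, build_filament
    ):
        f = self._aged_compound_filament(build_filament)
        spec = CombinedRuleSpec(
            RuleSpec("cell_age", 4.0), RuleSpec("compound", 0.0), "and"
        )
        d1 = eval_cell_age_rule(f, 4.0)
        assert eval_combined(f, spec).connections == d1.connections

    def test_or_with_infinite_second_threshold_is_rule1(self, build_filament):
        f = self._aged_compound_filament(build_filament)
        spec = CombinedRuleSpec(
            RuleSpec("cell_age", 4.0), RuleSpec("compound", math.inf), "or"
        )
        d1 = eval_cell_age_rule(f, 4.0)
        assert eval_combined(f, spec).connections == d1.connections

    def test_and_requires_both_on_same_cell(self, build_filament):
        f = self._aged_compound_filament(build_filament)
        # old cells are poor, rich cell is young: per-cell AND never fires
        spec = CombinedRuleSpec(
            RuleSpec("cell_age", 4.0), RuleSpec("compound", 50.0), "and"
        )
        assert not eval_combined(f, spec)
        # filament-scope AND fires on the age-triggering cells
        spec_f = CombinedRuleSpec(
            RuleSpec("cell_age", 4.0), RuleSpec("compound", 50.0), "and",
            scope="filament",
        )
        d = eval_combined(f, spec_f)
        assert d.connections == eval_cell_age_rule(f, 4.0).connections

    def test_or_merges_and_rule1_policy_wins(self, build_filament):
        f = build_filament(
            [(6, 6), (1, 1), (1, 1)],
            compounds=[10.0, 10.0, 90.0],
            conn_ages=[2.0, 1.0],
        )
        spec = CombinedRuleSpec(
            RuleSpec("cell_age", 4.0), RuleSpec("compound", 50.0), "or"
        )
        d = eval_combined(f, spec)
        assert set(d.connections) == {0, 1}

    def test_stochastic_cues_not_combinable(self):
        with pytest.raises(ValueError):
            CombinedRuleSpec(
                RuleSpec("cell_age", 1.0),
                RuleSpec("stochastic_in_time", 0.5),
                "and",
            )

    def test_same_cue_rejected(self):
        with pytest.raises(ValueError):
            CombinedRuleSpec(
                RuleSpec("cell_age", 1.0), RuleSpec("cell_age", 2.0), "or"
            )


class TestMirrorSymmetry:
    @pytest.mark.parametrize("cue", ["cell_age", "connection_age", "compound", "stress"])
    def test_mirrored_filament_gives_mirrored_decision(self, cue, rng):
        thetas = {"cell_age": 3.0, "connection_age": 2.5, "compound": 100.0, "stress": 2}
        for n in (2, 5, 8, 11):
            f = random_filament(rng, n)
            d = EVALS[cue](f, thetas[cue], FixedCoins([0.3] * n))
            dm = EVALS[cue](f.mirrored(), thetas[cue], FixedCoins([0.7] * n))
            assert {n - 2 - j for j in d.connections} == set(dm.connections)

    def test_stress_midpoint_tie_mirrors_with_mirrored_coin(self):
        f = Filament([Cell() for _ in range(7)])
        d = eval_stress_rule(f, 2, FixedCoins([0.2]))
        dm = eval_stress_rule(f, 2, FixedCoins([0.8]))
        (j,), (jm,) = d.connections, dm.connections
        assert j == 7 - 2 - jm


class TestApplyDecision:
    def test_single_middle_cut(self):
        f = Filament([Cell() for _ in range(32)])
        frags = apply_decision(f, SeveringDecision(frozenset({15})))
        assert [fr.n for fr in frags] == [16, 16]

    def test_multiple_cuts(self):
        f = Filament([Cell() for _ in range(10)])
        frags = apply_decision(f, SeveringDecision(frozenset({0, 4})))
        assert [fr.n for fr in frags] == [1, 4, 5]

    def test_kill_interior_cell(self):
        f = Filament([Cell() for _ in range(5)])
        frags = apply_decision(f, SeveringDecision(kills=frozenset({2})))
        assert [fr.n for fr in frags] == [2, 2]

    def test_cell_count_conserved(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 20))
            f = random_filament(rng, n)
            cuts = frozenset(
                int(j) for j in rng.choice(n - 1, size=min(3, n - 1), replace=False)
            )
            kills = frozenset(
                int(k) for k in rng.choice(n, size=1)
            )
            frags = apply_decision(f, SeveringDecision(cuts, kills))
            assert sum(fr.n for fr in frags) == n - len(kills)

    def test_empty_decision_rejected(self):
        with pytest.raises(ValueError):
            apply_decision(Filament([Cell(), Cell()]), SeveringDecision())

    def test_stale_indices_rejected(self):
        with pytest.raises(IndexError):
            apply_decision(
                Filament([Cell(), Cell()]), SeveringDecision(frozenset({5}))
            )


def test_dispatcher_routes_every_cue(rng, build_filament):
    f = build_filament([(9, 9), (1, 1)], compounds=[500.0, 0.0], conn_ages=[5.0])
    for cue, theta in [
        ("cell_age", 1.0),
        ("connection_age", 1.0),
        ("compound", 1.0),
        ("stochastic_in_time", 1.0),
    ]:
        assert evaluate(f, RuleSpec(cue, theta), rng)
    assert not evaluate(f, RuleSpec("stress", 5.0), rng)
    assert not evaluate(f, RuleSpec("stochastic_at_division", 1.0), rng)
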