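"""Reproduction-mode classification and offspring-partition combinatorics.

A fragmentation event is classified by the multiset of viable offspring
sizes it produces, into one of five modes (checked in this order):

1. ``complete_dissociation`` — three or more offspring, every one a
   single cell;
2. ``unicellular_propagule`` — at least one single-cell offspring together
   with at least one multicellular offspring;
3. ``equal_binary`` — exactly two offspring, each between 40% and 60%
   (inclusive) of the parent's size;
4. ``unequal_binary`` — exactly two offspring not matching the above;
5. ``other`` — anything else (three or more offspring, none unicellular).

The precedence resolves the overlap of a (1, n-1) split in favour of the
unicellular propagule. A 2-cell parent splitting into (1, 1) is an
ordinary binary fission and classifies as an equal binary split;
"dissociation" is reserved for the simultaneous severing of every
connection of a multicellular chain, which requires at least three
offspring. (Were (1, 1) counted as dissociation, any stochastic
fragmentation rule would produce dissociations every time the break
happened to hit a 2-cell filament, whereas simultaneous multi-connection
severing genuinely never arises for most rules.)

The theoretical space of offspring allocations for a parent of ``n`` cells
is the set of integer partitions of ``n``; :func:`count_partitions`
enumerates it with a minimum-parts filter because a "reproduction" may or
may not be required to produce at least two offspring groups (a group of
10 cells admits 42 partitions in total, while a group of 32 admits 8348
partitions into two or more daughter groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

__all__ = ["MODES", "FragmentationEvent", "classify", "count_partitions"]

MODES = (
    "unicellular_propagule",
    "equal_binary",
    "unequal_binary",
    "complete_dissociation",
    "other",
)


@dataclass(frozen=True)
class FragmentationEvent:
    """One logged reproduction event.

    ``parent_size`` is the adult size: the number of cells in the filament
    immediately before severing (including, under the death variant, any
    cell about to be removed). ``offspring_sizes`` contains viable
    offspring only, sorted in descending order.
    """

    time: float
    parent_size: int
    offspring_sizes: tuple[int, ...]
    mode: str
    rule: str

    @property
    def n_offspring(self) -> int:
        return len(self.offspring_sizes)


def classify(parent_size: int, offspring_sizes: Sequence[int]) -> str:
    """Classify one fragmentation event into a reproduction mode.

    ``offspring_sizes`` must hold at least two viable offspring; the 40-60%
    window of the equal-binary mode is evaluated in exact integer
    arithmetic (``2 * parent <= 5 * size <= 3 * parent``), with both
    endpoints inclusive.
    """
    sizes = [int(s) for s in offspring_sizes]
    if len(sizes) < 2:
        raise ValueError("a classified event needs at least two viable offspring")
    if any(s < 1 for s in sizes):
        raise ValueError("offspring sizes must be positive")
    parent_size = int(parent_size)

    if len(sizes) >= 3 and all(s == 1 for s in sizes):
        return "complete_dissociation"
    if any(s == 1 for s in sizes) and any(s > 1 for s in sizes):
        return "unicellular_propagule"
    if len(sizes) == 2 and all(
        2 * parent_size <= 5 * s <= 3 * parent_size for s in sizes
    ):
        return "equal_binary"
    if len(sizes) == 2:
        return "unequal_binary"
    return "other"


@lru_cache(maxsize=None)
def _partitions_with_parts_at_most(n: int, m: int) -> int:
    """Partitions of ``n`` into at most ``m`` parts (= parts all <= m)."""
    # standard two-variable recurrence on largest part
    if n == 0:
        return 1
    if m == 0:
        return 0
    if m > n:
        m = n
    return _partitions_with_parts_at_most(n - m, m) + _partitions_with_parts_at_most(
        n, m - 1
    )


def count_partitions(n: int, min_parts: int = 1) -> int:
    """Number of unordered integer partitions of ``n`` with >= ``min_parts`` parts.

    ``count_partitions(n, 1)`` is the full partition number p(n);
    ``min_parts=2`` excludes the trivial single-group "partition" and counts
    genuine ways of dividing a parent group into daughter groups.
    """
    n = int(n)
    min_parts = int(min_parts)
    if n < 1:
        raise ValueError("n must be at least 1")
    if min_parts < 1:
        raise ValueError("min_parts must be at least 1")
    total = _partitions_with_parts_at_most(n, n)
    # by conjugation, partitions with at most k parts == with parts <= k
    return total - _partitions_with_parts_at_most(n, min_parts - 1)
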