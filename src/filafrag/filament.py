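"""Core domain types for one-dimensional multicellular filaments.

A filament is an ordered chain of cells joined by connections. Cells
reproduce by binary fission and daughters stay attached, so a filament of
``n`` cells always carries exactly ``n - 1`` connections; connection ``j``
joins cells ``j`` and ``j + 1``. Indices are 0-based internally; anything
user-facing (logs, CSV output) reports 1-based positions.

Each cell tracks the ages of its two poles. Binary fission creates two
fresh (age-0) inner poles while the outer poles are inherited, so pole ages
encode the division history of the chain: the mean pole age serves as the
cell-age cue read by fragmentation rules, and in a filament grown from a
single founder the terminal cells carry the founder's original poles and
are therefore the oldest cells.

Hot-path state lives in flat numpy arrays on :class:`Filament`;
:class:`Cell` and :class:`Connection` are lightweight record views used for
construction and inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "Cell",
    "Connection",
    "Filament",
    "cell_age",
    "divide_cell",
    "downstream_counts",
]


@dataclass
class Cell:
    """A single cell: two pole ages, compound content, division schedule."""

    pole_age_left: float = 0.0
    pole_age_right: float = 0.0
    compound: float = 0.0
    next_division_at: float = math.inf
    alive: bool = True


@dataclass
class Connection:
    """A cell-cell bond; ``age`` is the time since the creating division."""

    age: float = 0.0


class Filament:
    """Ordered chain of cells with aged connections, stored as flat arrays.

    Parameters
    ----------
    cells
        Cells in left-to-right order.
    connections
        The ``n - 1`` connections, or None for all-new (age 0) connections.
    """

    __slots__ = (
        "pole_age_left",
        "pole_age_right",
        "compound",
        "next_division_at",
        "alive",
        "conn_age",
    )

    def __init__(
        self,
        cells: Iterable[Cell] | None = None,
        connections: Iterable[Connection] | None = None,
    ):
        cells = list(cells) if cells is not None else [Cell()]
        if not cells:
            raise ValueError("a filament must contain at least one cell")
        n = len(cells)
        self.pole_age_left = np.array([c.pole_age_left for c in cells], dtype=float)
        self.pole_age_right = np.array([c.pole_age_right for c in cells], dtype=float)
        self.compound = np.array([c.compound for c in cells], dtype=float)
        self.next_division_at = np.array(
            [c.next_division_at for c in cells], dtype=float
        )
        self.alive = np.array([c.alive for c in cells], dtype=bool)
        if connections is None:
            self.conn_age = np.zeros(n - 1, dtype=float)
        else:
            self.conn_age = np.array([c.age for c in connections], dtype=float)
        self._validate()

    # ------------------------------------------------------------------ #
    # construction helpers

    @classmethod
    def single_cell(cls, next_division_at: float = math.inf) -> "Filament":
        """A newborn one-cell filament (all ages zero, no compound)."""
        return cls([Cell(next_division_at=next_division_at)])

    @classmethod
    def from_arrays(
        cls,
        pole_age_left: np.ndarray,
        pole_age_right: np.ndarray,
        compound: np.ndarray,
        next_division_at: np.ndarray,
        alive: np.ndarray,
        conn_age: np.ndarray,
    ) -> "Filament":
        """Fast internal constructor; arrays are adopted without copying."""
        f = cls.__new__(cls)
        f.pole_age_left = pole_age_left
        f.pole_age_right = pole_age_right
        f.compound = compound
        f.next_division_at = next_division_at
        f.alive = alive
        f.conn_age = conn_age
        return f

    def _validate(self) -> None:
        n = len(self.pole_age_left)
        if len(self.conn_age) != n - 1:
            raise ValueError(
                f"a filament of {n} cells needs exactly {n - 1} connections, "
                f"got {len(self.conn_age)}"
            )
        if np.any(self.pole_age_left < 0) or np.any(self.pole_age_right < 0):
            raise ValueError("pole ages must be non-negative")
        if np.any(self.compound < 0):
            raise ValueError("compound amounts must be non-negative")
        if np.any(self.conn_age < 0):
            raise ValueError("connection ages must be non-negative")

    # ------------------------------------------------------------------ #
    # views

    @property
    def n(self) -> int:
        """Number of cells."""
        return len(self.pole_age_left)

    def __len__(self) -> int:
        return self.n

    def cell(self, index: int) -> Cell:
        """A record copy of the cell at ``index``."""
        index = self._check_cell_index(index)
        return Cell(
            pole_age_left=float(self.pole_age_left[index]),
            pole_age_right=float(self.pole_age_right[index]),
            compound=float(self.compound[index]),
            next_division_at=float(self.next_division_at[index]),
            alive=bool(self.alive[index]),
        )

    def connection(self, index: int) -> Connection:
        if not 0 <= index < self.n - 1:
            raise IndexError(f"connection index {index} out of range")
        return Connection(age=float(self.conn_age[index]))

    @property
    def cells(self) -> list[Cell]:
        return [self.cell(i) for i in range(self.n)]

    @property
    def connections(self) -> list[Connection]:
        return [Connection(age=float(a)) for a in self.conn_age]

    def cell_ages(self) -> np.ndarray:
        """Mean pole age of every cell (the cell-age cue)."""
        return 0.5 * (self.pole_age_left + self.pole_age_right)

    def copy(self) -> "Filament":
        return Filament.from_arrays(
            self.pole_age_left.copy(),
            self.pole_age_right.copy(),
            self.compound.copy(),
            self.next_division_at.copy(),
            self.alive.copy(),
            self.conn_age.copy(),
        )

    def mirrored(self) -> "Filament":
        """The left-right reflection (pole ages swap sides)."""
        return Filament.from_arrays(
            self.pole_age_right[::-1].copy(),
            self.pole_age_left[::-1].copy(),
            self.compound[::-1].copy(),
            self.next_division_at[::-1].copy(),
            self.alive[::-1].copy(),
            self.conn_age[::-1].copy(),
        )

    def extract(self, start: int, stop: int) -> "Filament":
        """The sub-filament of cells ``start:stop`` (contiguous fragment)."""
        if not (0 <= start < stop <= self.n):
            raise ValueError(f"invalid fragment range [{start}, {stop})")
        return Filament.from_arrays(
            self.pole_age_left[start:stop].copy(),
            self.pole_age_right[start:stop].copy(),
            self.compound[start:stop].copy(),
            self.next_division_at[start:stop].copy(),
            self.alive[start:stop].copy(),
            self.conn_age[start : stop - 1].copy(),
        )

    def _check_cell_index(self, index: int) -> int:
        index = int(index)
        if not 0 <= index < self.n:
            raise IndexError(f"cell index {index} out of range for n={self.n}")
        return index

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Filament(n={self.n})"


def cell_age(cell: Cell) -> float:
    """Age of a cell, defined as the mean of its two pole ages."""
    if not cell.alive:
        raise ValueError("cannot take the age of a dead cell")
    return 0.5 * (cell.pole_age_left + cell.pole_age_right)


def divide_cell(
    filament: Filament,
    index: int,
    now: float,
    division_times: tuple[float, float] = (math.inf, math.inf),
) -> Filament:
    """Replace cell ``index`` by two adjacent daughters (binary fission).

    The outer pole of each daughter inherits the parent's corresponding
    pole age; the two new inner poles start at age 0, as does the new
    connection between the daughters. The parent's compound is split
    equally. ``division_times`` are the daughters' absolute
    ``next_division_at`` schedules (the engine draws these from the
    division-time law); they must lie in the future of ``now``.

    The filament is modified in place and returned. The left daughter
    occupies the parent's slot.
    """
    index = filament._check_cell_index(index)
    if not filament.alive[index]:
        raise ValueError(f"cannot divide dead cell at index {index}")
    t_left, t_right = division_times
    if t_left <= now or t_right <= now:
        raise ValueError("daughter division times must lie strictly after 'now'")

    half = filament.compound[index] / 2.0
    filament.pole_age_left = np.insert(filament.pole_age_left, index + 1, 0.0)
    filament.pole_age_right = np.insert(filament.pole_age_right, index, 0.0)
    filament.compound = np.insert(filament.compound, index, half)
    filament.compound[index + 1] = half
    filament.next_division_at = np.insert(filament.next_division_at, index, t_left)
    filament.next_division_at[index + 1] = t_right
    filament.alive = np.insert(filament.alive, index, True)
    filament.conn_age = np.insert(filament.conn_age, index, 0.0)
    return filament


def downstream_counts(filament: Filament, index: int) -> tuple[int, int]:
    """Numbers of cells on each side of cell ``index``: ``(n_L, n_R)``.

    These always satisfy ``n_L + n_R = N - 1`` for a filament of N cells.
    """
    index = filament._check_cell_index(index)
    return index, filament.n - 1 - index
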