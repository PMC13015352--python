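"""Per-step updates of the information sources fragmentation rules read.

Four intrinsic cues are maintained on a filament:

* **cell age** — mean pole age; grows linearly with simulated time;
* **connection age** — time since the division that created the bond;
* **diffusible compound** — produced by every cell at a fixed amount per
  simulation step and exchanged with neighbours (and lost across the free
  ends to the environment) by explicit first-order diffusion on the chain;
* **mechanical stress** — ``s_i = min(n_L, n_R)``, the smaller of the two
  downstream cell counts, a proxy that peaks at the filament midpoint
  where bending loads on a growing chain concentrate.

The diffusion update is an explicit Euler step on a unit-spaced chain with
zero-concentration (absorbing) boundaries: all fluxes are evaluated on the
pre-step state, then production and the net flux are applied at once. The
scheme is stable and monotonicity-preserving for ``D <= 0.5``; the default
``D = 0.01`` is far inside that region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filament import Filament, downstream_counts

__all__ = [
    "DiffusionParams",
    "advance_ages",
    "diffuse_step",
    "stress",
    "stress_profile",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the compound dynamics.

    production_per_step
        Amount added to every cell each simulation step (default 1).
    D
        Dimensionless exchange fraction per step between neighbouring
        cells, and across each free end to the environment (default 0.01).
    """

    production_per_step: float = 1.0
    D: float = 0.01

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("diffusion constant D must be non-negative")
        if self.production_per_step < 0:
            raise ValueError("production_per_step must be non-negative")


def advance_ages(filament: Filament, dt: float) -> Filament:
    """Add ``dt`` to every pole age and every connection age, in place."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    filament.pole_age_left += dt
    filament.pole_age_right += dt
    filament.conn_age += dt
    return filament


def diffuse_step(filament: Filament, params: DiffusionParams) -> Filament:
    """One production + diffusion step of the compound field, in place.

    Every cell gains ``production_per_step``; each neighbour pair then
    exchanges ``D * (d_neighbour - d_i)`` and each terminal cell loses
    ``D * d_i`` across its free end, all fluxes computed from the pre-step
    amounts. Total compound therefore changes by exactly
    ``n * production - D * (d_first + d_last)`` per step.
    """
    d = filament.compound
    padded = np.zeros(len(d) + 2)
    padded[1:-1] = d
    lap = padded[:-2] + padded[2:] - 2.0 * d
    np.add(d, params.production_per_step + params.D * lap, out=d)
    # explicit Euler with D <= 0.5 cannot undershoot zero, but guard against
    # pathological parameter choices
    np.maximum(d, 0.0, out=d)
    return filament


def stress(filament: Filament, index: int) -> int:
    """Mechanical-stress cue of one cell: ``min(n_L, n_R)``."""
    n_l, n_r = downstream_counts(filament, index)
    return min(n_l, n_r)


def stress_profile(filament: Filament) -> np.ndarray:
    """The stress cue for every cell; unimodal with its peak at the middle."""
    idx = np.arange(filament.n)
    return np.minimum(idx, filament.n - 1 - idx)
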