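"""Configuration parsing and file output (CSV event logs, JSON summaries).

A simulation is described by a flat key/value mapping (YAML on disk) whose
defaults are the model's standard settings: dt 0.01, division times
N(1, 0.05), diffusion constant 0.01 with production 1 per step, stop after
100 events per run, target adult size 32. Every run directory receives a
config snapshot alongside its outputs so results are reproducible from the
snapshot and the recorded master seed alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .analysis import ModeSummary, SizeSummary, events_frame
from .dynamics import DiffusionParams
from .engine import EngineConfig
from .lifecycle import FragmentationEvent
from .rules import CombinedRuleSpec, RuleSpec

__all__ = [
    "CONFIG_DEFAULTS",
    "build_config",
    "load_config_file",
    "config_to_dict",
    "write_events_csv",
    "read_events_csv",
    "write_summary_json",
]

#: flat config schema with defaults; ``rule`` and ``theta`` are required
CONFIG_DEFAULTS: dict[str, Any] = {
    "rule": None,
    "theta": None,
    "rule2": None,
    "theta2": None,
    "logic": None,
    "scope": "cell",
    "death": False,
    "aging": False,
    "seed": None,
    "events": 100,
    "target_size": 32,
    "dt": 0.01,
    "division_mean": 1.0,
    "division_sd": 0.05,
    "n_fragmentations": 100,
    "D": 0.01,
    "production_per_step": 1.0,
    "count_shedding": False,
    "update_order": "interleaved",
    "max_steps": 2_000_000,
    "max_cells": 20_000,
}


def build_config(settings: Mapping[str, Any]) -> tuple[EngineConfig, dict[str, Any]]:
    """Turn a flat settings mapping into an EngineConfig.

    Returns the engine config and the fully resolved flat mapping
    (defaults applied) for snapshotting. Unknown or missing required keys
    raise ``KeyError`` naming the key.
    """
    unknown = set(settings) - set(CONFIG_DEFAULTS)
    if unknown:
        raise KeyError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    resolved = {**CONFIG_DEFAULTS, **dict(settings)}
    for required in ("rule", "theta"):
        if resolved[required] is None:
            raise KeyError(f"missing required config key: {required}")

    rule: RuleSpec | CombinedRuleSpec = RuleSpec(
        cue=str(resolved["rule"]),
        threshold=float(resolved["theta"]),
        death_variant=bool(resolved["death"]),
    )
    if resolved["rule2"] is not None:
        if resolved["theta2"] is None or resolved["logic"] is None:
            missing = "theta2" if resolved["theta2"] is None else "logic"
            raise KeyError(f"missing required config key: {missing}")
        rule = CombinedRuleSpec(
            rule1=rule,
            rule2=RuleSpec(
                cue=str(resolved["rule2"]),
                threshold=float(resolved["theta2"]),
                death_variant=bool(resolved["death"]),
            ),
            logic=str(resolved["logic"]).lower(),  # type: ignore[arg-type]
            scope=str(resolved["scope"]),  # type: ignore[arg-type]
        )
    config = EngineConfig(
        rule=rule,
        seed=None if resolved["seed"] is None else int(resolved["seed"]),
        dt=float(resolved["dt"]),
        division_mean=float(resolved["division_mean"]),
        division_sd=float(resolved["division_sd"]),
        n_fragmentations=int(resolved["n_fragmentations"]),
        aging=bool(resolved["aging"]),
        diffusion=DiffusionParams(
            production_per_step=float(resolved["production_per_step"]),
            D=float(resolved["D"]),
        ),
        count_shedding=bool(resolved["count_shedding"]),
        update_order=str(resolved["update_order"]),
        max_steps=int(resolved["max_steps"]),
        max_cells=int(resolved["max_cells"]),
    )
    return config, resolved


def load_config_file(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a key/value mapping")
    return data


def config_to_dict(config: EngineConfig) -> dict[str, Any]:
    """Flatten an EngineConfig back to the snapshot schema."""
    rule = config.rule
    flat: dict[str, Any] = {
        "rule2": None,
        "theta2": None,
        "logic": None,
        "scope": "cell",
    }
    if isinstance(rule, CombinedRuleSpec):
        flat.update(
            rule=rule.rule1.cue,
            theta=rule.rule1.threshold,
            rule2=rule.rule2.cue,
            theta2=rule.rule2.threshold,
            logic=rule.logic,
            scope=rule.scope,
            death=rule.death_variant,
        )
    else:
        flat.update(rule=rule.cue, theta=rule.threshold, death=rule.death_variant)
    flat.update(
        seed=config.seed,
        aging=config.aging,
        dt=config.dt,
        division_mean=config.division_mean,
        division_sd=config.division_sd,
        n_fragmentations=config.n_fragmentations,
        D=config.diffusion.D,
        production_per_step=config.diffusion.production_per_step,
        count_shedding=config.count_shedding,
        update_order=config.update_order,
        max_steps=config.max_steps,
        max_cells=config.max_cells,
    )
    return flat


def write_events_csv(
    events: Sequence[FragmentationEvent],
    path: str | Path,
    seed: int | None = None,
) -> None:
    """One row per event; offspring sizes are a semicolon-joined column."""
    df = events_frame(events)
    df["seed"] = seed
    df.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[FragmentationEvent]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        FragmentationEvent(
            time=float(row.time),
            parent_size=int(row.parent_size),
            offspring_sizes=tuple(
                int(s) for s in str(row.offspring_sizes).split(";")
            ),
            mode=str(row.mode),
            rule=str(row.rule),
        )
        for row in df.itertuples()
    ]


def write_summary_json(
    size_summary: SizeSummary,
    mode_summary: ModeSummary,
    path: str | Path,
    extra: Mapping[str, Any] | None = None,
) -> None:
    payload: dict[str, Any] = {
        "size": {
            **asdict(size_summary),
            "histogram": {
                str(k): v for k, v in size_summary.histogram.items()
            },
        },
        "modes": asdict(mode_summary),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
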