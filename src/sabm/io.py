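"""Plain-text interchange formats.

Networks travel as directed edge-list CSV (wave, ego_id, alter_id),
attributes and behaviors as header CSV, parameters as JSON keyed by effect
name, and generated panels as a bundle directory with a YAML manifest.
Simulation traces export as line-delimited CSV records.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ACTOR_COLUMNS,
    ActorTable,
    BehaviorPanel,
    EffectParameterSet,
    InvalidStateError,
    NetworkPanel,
)


def write_network_csv(network: NetworkPanel, path) -> None:
    rows = []
    for w, x in enumerate(network.waves):
        egos, alters = np.nonzero(x)
        rows.append(pd.DataFrame({"wave": w, "ego_id": egos, "alter_id": alters}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_network_csv(path, n_actors: int, n_waves: int | None = None) -> NetworkPanel:
    """Edge lists do not record isolates, so the actor count is explicit."""
    df = pd.read_csv(path)
    if n_waves is None:
        n_waves = int(df["wave"].max()) + 1 if len(df) else 1
    waves = []
    for w in range(n_waves):
        x = np.zeros((n_actors, n_actors), dtype=np.int8)
        sub = df[df["wave"] == w]
        x[sub["ego_id"].to_numpy(), sub["alter_id"].to_numpy()] = 1
        waves.append(x)
    return NetworkPanel(waves)


def write_actors_csv(actors: ActorTable, path) -> None:
    df = actors.frame.copy()
    df.insert(0, "actor_id", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_actors_csv(path) -> ActorTable:
    df = pd.read_csv(path)
    if "actor_id" in df.columns:
        df = df.sort_values("actor_id").drop(columns="actor_id").reset_index(drop=True)
    df["income_imputed"] = df["income_imputed"].astype(bool)
    return ActorTable(df[list(ACTOR_COLUMNS)])


def write_behavior_csv(behavior: BehaviorPanel, path) -> None:
    n_waves, n = behavior.values.shape
    rows = pd.DataFrame(
        {
            "actor_id": np.tile(np.arange(n), n_waves),
            "wave": np.repeat(np.arange(n_waves), n),
            behavior.name: behavior.values.ravel(),
        }
    )
    rows.to_csv(path, index=False)


def read_behavior_csv(path, z_min: int, z_max: int, **overrides) -> BehaviorPanel:
    df = pd.read_csv(path)
    value_col = [c for c in df.columns if c not in ("actor_id", "wave")]
    if len(value_col) != 1:
        raise InvalidStateError(f"expected one behavior column, found {value_col}")
    name = value_col[0]
    n_waves = int(df["wave"].max()) + 1
    n = int(df["actor_id"].max()) + 1
    values = np.zeros((n_waves, n), dtype=np.int64)
    values[df["wave"].to_numpy(), df["actor_id"].to_numpy()] = df[name].to_numpy()
    return BehaviorPanel(name, values, z_min, z_max, **overrides)


def write_params_json(params: EffectParameterSet, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2))


def read_params_json(path) -> EffectParameterSet:
    return EffectParameterSet.from_dict(json.loads(Path(path).read_text()))


def write_trace_csv(trace, path) -> None:
    rows = pd.DataFrame(
        {
            "step": [s.index for s in trace.ministeps],
            "actor": [s.actor for s in trace.ministeps],
            "type": [s.change_type for s in trace.ministeps],
            "action": [s.action for s in trace.ministeps],
        }
    )
    rows.to_csv(path, index=False)


def write_panel_bundle(directory, panel) -> None:
    """Write a SyntheticPanel as a directory of CSVs plus a YAML manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_actors_csv(panel.actors, d / "actors.csv")
    write_network_csv(panel.network, d / "network.csv")
    write_behavior_csv(panel.behavior, d / "behavior.csv")
    manifest = {
        "n_actors": panel.actors.n_actors,
        "n_waves": panel.network.n_waves,
        "behavior": {
            "name": panel.behavior.name,
            "z_min": int(panel.behavior.z_min),
            "z_max": int(panel.behavior.z_max),
        },
        "seed": panel.seed,
        "ground_truth": {k: float(v) for k, v in panel.ground_truth.to_dict().items()},
        "config": _config_to_plain(panel.config),
    }
    (d / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def _config_to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _config_to_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {k: _config_to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_panel_bundle(directory):
    """Load a panel bundle; returns (actors, network, behavior, manifest)."""
    d = Path(directory)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    actors = read_actors_csv(d / "actors.csv")
    network = read_network_csv(
        d / "network.csv", manifest["n_actors"], manifest["n_waves"]
    )
    beh_meta = manifest["behavior"]
    behavior = read_behavior_csv(
        d / "behavior.csv", beh_meta["z_min"], beh_meta["z_max"]
    )
    return actors, network, behavior, manifest
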