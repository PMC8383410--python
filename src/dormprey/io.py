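"""Configuration files, trajectory/metric/sweep export, provenance.

Parameter sets travel as flat key-value configs (JSON or YAML, keys named
exactly as the ``ParameterSet`` fields, plus optional ``initial_state``,
``t_span`` and ``solver`` blocks); unknown keys are an error so that a
typo in a sweep spec fails loudly instead of silently running defaults.

Trajectories export as tidy CSV (columns time, p, y1, y2, z) with a JSON
sidecar carrying the exact parameters and solver settings that produced
them — enough to regenerate any figure from its files alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .model import PARAM_ORDER, ParameterSet, State
from .simulate import SolverSettings, Trajectory
from .sweeps import SweepGrid

__all__ = [
    "load_config",
    "dump_config",
    "params_hash",
    "write_trajectory",
    "read_trajectory",
    "write_metrics",
    "write_sweep",
]

_CONFIG_KEYS = set(PARAM_ORDER) | {"initial_state", "t_span", "solver"}
_SOLVER_KEYS = {"rtol", "atol", "method", "output_dt"}


class ConfigError(ValueError):
    """A configuration file is malformed."""


def _parse_config(raw: Any, source: str) -> dict:
    if raw is None:
        raise ConfigError(f"{source}: empty configuration")
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: expected a flat mapping, got {type(raw).__name__}")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(
            f"{source}: unknown key(s) {sorted(unknown)}; "
            f"valid keys are the parameter names {list(PARAM_ORDER)} "
            "plus 'initial_state', 't_span', 'solver'"
        )
    out: dict[str, Any] = {}
    param_part = {k: v for k, v in raw.items() if k in PARAM_ORDER}
    out["params"] = ParameterSet.from_dict({**ParameterSet().to_dict(), **param_part})
    if "initial_state" in raw:
        out["initial"] = State.from_iterable(raw["initial_state"])
    if "t_span" in raw:
        span = raw["t_span"]
        if not (isinstance(span, (list, tuple)) and len(span) == 2):
            raise ConfigError(f"{source}: t_span must be a [start, end] pair, got {span!r}")
        out["t_span"] = (float(span[0]), float(span[1]))
    if "solver" in raw:
        block = raw["solver"]
        if not isinstance(block, dict):
            raise ConfigError(f"{source}: solver block must be a mapping")
        unknown = set(block) - _SOLVER_KEYS
        if unknown:
            raise ConfigError(
                f"{source}: unknown solver key(s) {sorted(unknown)}; valid: {sorted(_SOLVER_KEYS)}"
            )
        out["settings"] = SolverSettings(**block)
    return out


def load_config(path: str | Path) -> dict:
    """Read a JSON or YAML scenario config.

    Returns a dict with keys ``params`` (always) and, when present in the
    file, ``initial``, ``t_span`` and ``settings``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON: {exc}") from exc
    else:
        import yaml

        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    return _parse_config(raw, str(path))


def dump_config(
    path: str | Path,
    params: ParameterSet,
    initial: State | None = None,
    t_span: tuple[float, float] | None = None,
    settings: SolverSettings | None = None,
) -> None:
    """Write a scenario config; format follows the file extension."""
    doc: dict[str, Any] = params.to_dict()
    if initial is not None:
        doc["initial_state"] = [initial.p, initial.y1, initial.y2, initial.z]
    if t_span is not None:
        doc["t_span"] = list(t_span)
    if settings is not None:
        doc["solver"] = settings.to_dict()
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        import yaml

        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def params_hash(params: ParameterSet) -> str:
    """Short stable digest of a parameter set (provenance records)."""
    payload = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(traj: Trajectory) -> dict:
    import dormprey

    return {
        "package": "dormprey",
        "version": dormprey.__version__,
        "params": {k: repr(float(v)) for k, v in traj.params.to_dict().items()},
        "params_hash": params_hash(traj.params),
        "solver": traj.settings.to_dict(),
        "t_span": list(traj.t_span),
        "n_samples": len(traj),
    }


def write_trajectory(traj: Trajectory, csv_path: str | Path) -> Path:
    """Write the tidy CSV plus a ``.json`` provenance sidecar.

    Floats are written with ``repr`` round-trip precision so re-reading
    the CSV reproduces the trajectory bit for bit.
    """
    csv_path = Path(csv_path)
    traj.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps(_provenance(traj), indent=2) + "\n")
    return csv_path


def read_trajectory(csv_path: str | Path) -> Trajectory:
    """Re-read an exported trajectory (sidecar restores its provenance)."""
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    expected = ["time", "p", "y1", "y2", "z"]
    if list(frame.columns) != expected:
        raise ConfigError(f"{csv_path}: expected columns {expected}, got {list(frame.columns)}")
    sidecar = csv_path.with_suffix(".json")
    params = ParameterSet()
    settings = SolverSettings()
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        params = ParameterSet.from_dict(
            {k: float(v) for k, v in meta.get("params", {}).items()}
        )
        if "solver" in meta:
            settings = SolverSettings(**meta["solver"])
    return Trajectory(
        times=frame["time"].to_numpy(),
        states=frame[["p", "y1", "y2", "z"]].to_numpy(),
        params=params,
        settings=settings,
    )


def write_metrics(records: list[dict], path: str | Path) -> Path:
    """Write metric records as JSON (or append-mode CSV for batch runs)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frame = pd.DataFrame(records)
        header = not path.exists()
        frame.to_csv(path, mode="a", header=header, index=False)
    else:
        path.write_text(json.dumps(records, indent=2, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")


def write_sweep(grid: SweepGrid, csv_path: str | Path) -> Path:
    """Long-format CSV of a winner map plus a JSON header sidecar."""
    csv_path = Path(csv_path)
    grid.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
    header = {
        "axis1": {"parameter": list(grid.axis1.names), "values": list(grid.axis1.values)},
        "axis2": {"parameter": list(grid.axis2.names), "values": list(grid.axis2.values)},
        "window": list(grid.window),
        "base_params": grid.base.to_dict(),
        "base_params_hash": params_hash(grid.base),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(header, indent=2) + "\n")
    return csv_path


def plot_sweep(grid: SweepGrid, path: str | Path) -> Path:
    """Optional heatmap rendering of a winner map (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    codes = np.select(
        [grid.winners == "PA", grid.winners == "dormitive", grid.winners == "none"],
        [0, 1, 2],
        default=3,
    ).astype(float)
    cmap = ListedColormap(["#1f77b4", "#d62728", "#7f7f7f", "#ffffff"])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.pcolormesh(
        np.asarray(grid.axis2.values),
        np.asarray(grid.axis1.values),
        codes,
        cmap=cmap,
        vmin=-0.5,
        vmax=3.5,
        shading="nearest",
    )
    ax.set_xlabel(grid.axis2.label)
    ax.set_ylabel(grid.axis1.label)
    ax.set_title("winner map (blue PA / red dormitive / grey none)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
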