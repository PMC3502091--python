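"""Serialization: trajectory CSVs, run manifests, parameter loading."""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .params import (AgentParams, BodyCircuitParams, ParameterError,
                     load_parameter_file)
from .model import TIMESERIES_COLUMNS, TimeSeries

__all__ = ["load_params", "write_timeseries", "read_timeseries", "RunManifest"]

_FLOAT_FMT = "%.8g"  # lossless well past the 6-significant-digit contract


def load_params(path: str | Path | None = None,
                ) -> tuple[dict[str, AgentParams], BodyCircuitParams]:
    """Agent set and body/circuit parameters, from a JSON file or the
    packaged defaults.  Raises :class:`~gaswash.params.ParameterError`
    with a field-level message on any invariant violation."""
    agents, body, _ = load_parameter_file(path)
    return agents, body


def write_timeseries(ts: TimeSeries, path: str | Path) -> Path:
    """Write a trajectory as CSV with the fixed header
    ``t_min,f_d,fgf,v_a,f_i,f_a,f_vrg,f_mus,f_fat,f_mv``."""
    path = Path(path)
    try:
        ts.to_dataframe().to_csv(path, index=False,
                                 float_format=_FLOAT_FMT)
    except OSError as exc:
        raise OSError(f"cannot write trajectory to {path}: {exc}") from exc
    return path


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a trajectory CSV written by :func:`write_timeseries`.

    Phase bookkeeping and the mass-balance accumulators are not stored
    in the CSV and come back empty.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read trajectory from {path}: {exc}") from exc
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty trajectory")
    cols = {("t" if c == "t_min" else c): np.asarray(df[c], dtype=float)
            for c in TIMESERIES_COLUMNS}
    return TimeSeries(**cols)


@dataclass
class RunManifest:
    """Everything needed to reproduce one simulation output
    bit-identically: tool version, parameter provenance, the scenario,
    and the integrator settings."""

    scenario: dict
    dt_s: float
    reporting_dt_s: float
    params_source: str = "packaged"
    version: str = __version__
    seed: int | None = None
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())
    platform: str = field(default_factory=platform.platform)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json() + "\n")
        return path

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"manifest: unknown keys {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls.from_json(Path(path).read_text())


def scenario_to_dict(scenario) -> dict:
    """JSON-compatible description of a Scenario (agent by name if it
    matches a packaged agent, else fully inlined)."""
    d = {
        "agent": scenario.agent.name,
        "washout_va": scenario.washout_va,
        "post_recovery_va": scenario.post_recovery_va,
        "maintenance_duration": scenario.maintenance_duration,
        "observation_duration": scenario.observation_duration,
    }
    body = dataclasses.asdict(scenario.body)
    d["body"] = body
    return d


def scenario_from_dict(d: dict, agents: dict[str, AgentParams]):
    from .protocol import Scenario
    from .params import resolve_agent_name

    name = resolve_agent_name(str(d["agent"]))
    if name not in agents:
        raise ParameterError(f"agent: unknown agent {d['agent']!r}")
    body = BodyCircuitParams(**d["body"]) if "body" in d \
        else BodyCircuitParams()
    return Scenario(
        agent=agents[name],
        washout_va=float(d.get("washout_va", 5.0)),
        post_recovery_va=float(d.get("post_recovery_va", 5.0)),
        maintenance_duration=float(d.get("maintenance_duration", 480.0)),
        observation_duration=float(d.get("observation_duration", 120.0)),
        body=body,
    )
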