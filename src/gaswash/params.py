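"""Physiological and pharmacological parameter sets.

Agents are described by their blood/gas and tissue/gas partition
coefficients (lambda) and their MAC (minimum alveolar concentration,
expressed as a partial pressure in vol% of one atmosphere).  The patient
and breathing circuit are described by compartment volumes, cardiac
output, and the fractional blood flows to the three classical tissue
groups: the vessel-rich group (VRG, proxy for the central nervous
system), the muscle group (MG), and the fat group.

The defaults packaged in ``data/parameters.json`` describe a 70 kg adult
on a circle breathing system and the three volatile agents desflurane,
sevoflurane and isoflurane.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


class ParameterError(ValueError):
    """A parameter value violates its physical constraints."""


def _require(cond: bool, field: str, message: str) -> None:
    if not cond:
        raise ParameterError(f"{field}: {message}")


@dataclass(frozen=True)
class AgentParams:
    """One volatile anesthetic agent.

    Parameters
    ----------
    name
        Agent identifier (e.g. ``"isoflurane"``).
    mac
        Partial pressure at 1 MAC, vol% of 1 atm.
    lambda_blood
        Blood/gas partition coefficient (dimensionless).
    lambda_vrg, lambda_mus, lambda_fat
        Tissue/gas partition coefficients of the vessel-rich, muscle and
        fat groups.  Tissue capacity for agent is ``volume * lambda``.
    """

    name: str
    mac: float
    lambda_blood: float
    lambda_vrg: float
    lambda_mus: float
    lambda_fat: float

    def __post_init__(self) -> None:
        _require(self.mac > 0, "mac", "must be > 0")
        for f in ("lambda_blood", "lambda_vrg", "lambda_mus", "lambda_fat"):
            _require(getattr(self, f) > 0, f, "partition coefficient must be > 0")
        _require(
            self.lambda_fat > self.lambda_mus,
            "lambda_fat",
            "fat solubility must exceed muscle solubility",
        )

    @property
    def macawake(self) -> float:
        """MACawake threshold, 0.3 MAC, vol%."""
        return 0.3 * self.mac


@dataclass(frozen=True)
class BodyCircuitParams:
    """Patient compartments plus the anesthesia breathing circuit.

    Volumes in litres, flows in L/min.  ``f_vrg``/``f_mus``/``f_fat``
    are fractions of cardiac output perfusing each tissue group; the
    packaged values (0.758/0.18/0.06) sum to 0.998 and are used verbatim
    — venous return is weighted by the perfused flow ``q_perfused``.
    """

    weight: float = 70.0       # kg, metadata only
    v_circuit: float = 8.0     # L
    frc: float = 2.5           # L, functional residual capacity
    q_total: float = 5.0       # L/min cardiac output
    v_vrg: float = 6.0         # L
    v_mus: float = 33.0        # L
    v_fat: float = 14.5        # L
    f_vrg: float = 0.758
    f_mus: float = 0.18
    f_fat: float = 0.06

    def __post_init__(self) -> None:
        for f in ("weight", "v_circuit", "frc", "q_total",
                  "v_vrg", "v_mus", "v_fat", "f_vrg", "f_mus", "f_fat"):
            _require(getattr(self, f) > 0, f, "must be > 0")
        s = self.f_vrg + self.f_mus + self.f_fat
        _require(s <= 1.0 + 1e-9, "f_vrg+f_mus+f_fat",
                 f"tissue flow fractions sum to {s:g}, must be <= 1")

    @property
    def q_vrg(self) -> float:
        return self.f_vrg * self.q_total

    @property
    def q_mus(self) -> float:
        return self.f_mus * self.q_total

    @property
    def q_fat(self) -> float:
        return self.f_fat * self.q_total

    @property
    def q_perfused(self) -> float:
        """Total tissue-perfusing flow, L/min (sum of the three groups)."""
        return self.q_vrg + self.q_mus + self.q_fat


@dataclass(frozen=True)
class VentSettings:
    """Piecewise-constant controls applied during one protocol phase.

    f_d : delivered (vaporizer) partial pressure, vol%
    fgf : fresh gas flow into the circuit, L/min
    v_a : alveolar minute ventilation, L/min
    """

    f_d: float
    fgf: float
    v_a: float

    def __post_init__(self) -> None:
        _require(0.0 <= self.f_d <= 100.0, "f_d", "must lie in [0, 100] vol%")
        _require(self.fgf >= 0, "fgf", "must be >= 0")
        _require(self.v_a >= 0, "v_a", "must be >= 0")


_AGENT_FIELDS = ("name", "lambda_blood", "lambda_vrg", "lambda_mus",
                 "lambda_fat", "mac")


def _agent_from_dict(d: dict) -> AgentParams:
    missing = [k for k in _AGENT_FIELDS if k not in d]
    _require(not missing, "agent", f"missing keys {missing}")
    return AgentParams(
        name=str(d["name"]),
        mac=float(d["mac"]),
        lambda_blood=float(d["lambda_blood"]),
        lambda_vrg=float(d["lambda_vrg"]),
        lambda_mus=float(d["lambda_mus"]),
        lambda_fat=float(d["lambda_fat"]),
    )


def _body_from_dict(d: dict) -> BodyCircuitParams:
    allowed = {f.name for f in dataclasses.fields(BodyCircuitParams)}
    unknown = set(d) - allowed
    _require(not unknown, "body", f"unknown keys {sorted(unknown)}")
    return BodyCircuitParams(**{k: float(v) for k, v in d.items()})


def load_parameter_file(path: str | Path | None = None):
    """Load an agent/body parameter file.

    With ``path=None`` the packaged defaults are loaded.  Returns
    ``(agents, body, overpressure_fd)`` where ``agents`` maps agent name
    to :class:`AgentParams` and ``overpressure_fd`` maps agent name to
    the wash-in overpressure vaporizer setting (vol%).
    """
    if path is None:
        text = resources.files("gaswash.data").joinpath("parameters.json").read_text()
    else:
        text = Path(path).read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParameterError(f"parameter file is not valid JSON: {exc}") from exc
    _require(isinstance(raw, dict), "root", "must be a JSON object")
    _require("agents" in raw, "agents", "missing section")
    agents = {}
    for d in raw["agents"]:
        a = _agent_from_dict(d)
        _require(a.name not in agents, "agents", f"duplicate agent {a.name!r}")
        agents[a.name] = a
    body = _body_from_dict(raw.get("body", {}))
    overpressure = {str(k): float(v)
                    for k, v in raw.get("overpressure_fd", {}).items()}
    for name, fd in overpressure.items():
        _require(0 < fd <= 100, f"overpressure_fd[{name}]",
                 "must lie in (0, 100] vol%")
    return agents, body, overpressure


def default_agents() -> dict[str, AgentParams]:
    """The three packaged agents keyed by name."""
    return load_parameter_file()[0]


def default_body() -> BodyCircuitParams:
    return load_parameter_file()[1]


def default_overpressure() -> dict[str, float]:
    """Packaged wash-in overpressure F_D per agent, vol%."""
    return load_parameter_file()[2]


#: short aliases accepted by the command line
AGENT_ALIASES = {
    "iso": "isoflurane",
    "sevo": "sevoflurane",
    "des": "desflurane",
}


def resolve_agent_name(name: str) -> str:
    return AGENT_ALIASES.get(name.lower(), name.lower())
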