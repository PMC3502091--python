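"""Administration, washout and post-recovery protocols.

The standard protocol simulated by :func:`run_scenario` is:

1. **Induction + maintenance** (default 480 min): wash-in at an
   agent-specific overpressure vaporizer setting with FGF 1 L/min and
   normoventilation (V_A 5 L/min) until the alveolar pressure first
   reaches 1 MAC, then a vaporizer servo holds F_A exactly at 1 MAC
   for the rest of the maintenance period.
2. **Washout**: the vaporizer is shut (F_D 0) and FGF raised to
   10 L/min; ventilation is either continued normoventilation
   (V_A 5) or hyperventilation (V_A 10).  The phase ends when the
   vessel-rich-group pressure F_VRG (the CNS proxy) falls to MACawake
   (0.3 MAC), with a 240-min cap.
3. **Post-recovery observation** (default 120 min): ventilation is
   switched to the scenario's post-recovery level (hypoventilation
   0.5-2.5 L/min, or continued 5/10) and F_VRG is watched for a
   rebound above MACawake (rehypnotization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .params import (AgentParams, BodyCircuitParams, VentSettings,
                     default_body, default_overpressure)
from .model import Phase, SimState, TimeSeries, simulate_phases
from .metrics import EmergenceResult, detect_rehypnotization, time_to_threshold

__all__ = [
    "Scenario", "ScenarioRun", "ProtocolPhase",
    "UnreachableTargetError", "induction_controller", "build_protocol",
    "run_scenario",
    "MAINTENANCE_FGF", "MAINTENANCE_VA", "WASHOUT_FGF", "WASHOUT_CAP_MIN",
    "POST_RECOVERY_LEVELS",
]

log = logging.getLogger(__name__)

#: a protocol phase is a model phase with a name and an end condition
ProtocolPhase = Phase

MAINTENANCE_FGF = 1.0    # L/min
MAINTENANCE_VA = 5.0     # L/min
WASHOUT_FGF = 10.0       # L/min, high flow to minimize rebreathing
WASHOUT_CAP_MIN = 240.0  # give up if MACawake is never reached
#: post-recovery alveolar ventilation grid, L/min (hypoventilation
#: levels plus continued normo- and hyperventilation)
POST_RECOVERY_LEVELS = (0.5, 1.0, 1.5, 2.5, 5.0, 10.0)


class UnreachableTargetError(ValueError):
    """The alveolar target exceeds what the vaporizer setting allows."""


@dataclass(frozen=True)
class Scenario:
    """One simulated arm of the emergence study."""

    agent: AgentParams
    washout_va: float = 5.0          # L/min: 5 = NV, 10 = HV
    post_recovery_va: float = 5.0    # L/min
    maintenance_duration: float = 480.0  # min, induction included
    observation_duration: float = 120.0  # min after MACawake
    body: BodyCircuitParams = field(default_factory=default_body)

    def __post_init__(self) -> None:
        if self.maintenance_duration <= 0:
            raise ValueError("maintenance_duration must be > 0")
        if self.observation_duration <= 0:
            raise ValueError("observation_duration must be > 0")
        for f in ("washout_va", "post_recovery_va"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")

    @property
    def washout_mode(self) -> str:
        return "HV" if self.washout_va > MAINTENANCE_VA else "NV"

    def label(self) -> str:
        return (f"{self.agent.name}/{self.washout_mode}"
                f"/post{self.post_recovery_va:g}")


@dataclass
class ScenarioRun:
    """A completed scenario: full trajectory plus emergence metrics."""

    scenario: Scenario
    timeseries: TimeSeries
    emergence: EmergenceResult


def induction_controller(agent: AgentParams, body: BodyCircuitParams,
                         target_mac_multiple: float = 1.0,
                         overpressure_fd: float | None = None,
                         fgf: float = MAINTENANCE_FGF,
                         v_a: float = MAINTENANCE_VA,
                         until_t: float = 480.0) -> ProtocolPhase:
    """Build the induction+maintenance phase.

    The vaporizer is held at ``overpressure_fd`` (packaged default per
    agent) until F_A first reaches ``target_mac_multiple`` MAC, after
    which F_A is held exactly at target by back-computing F_D from the
    circuit balance.  With the vaporizer set exactly at target the
    alveolar pressure approaches it asymptotically and the servo never
    engages.
    """
    target = target_mac_multiple * agent.mac
    if overpressure_fd is None:
        overpressure_fd = default_overpressure().get(agent.name)
        if overpressure_fd is None:
            raise UnreachableTargetError(
                f"no packaged overpressure F_D for agent {agent.name!r}")
    if overpressure_fd < target:
        raise UnreachableTargetError(
            f"overpressure F_D {overpressure_fd:g} vol% cannot attain the "
            f"alveolar target {target:g} vol% (steady state equals F_D)")
    return ProtocolPhase(
        name="maintenance",
        vent=VentSettings(f_d=overpressure_fd, fgf=fgf, v_a=v_a),
        until_t=until_t,
        clamp_fa=target,
    )


def build_protocol(scenario: Scenario,
                   overpressure_fd: float | None = None,
                   ) -> list[ProtocolPhase]:
    """The three-phase schedule (maintenance, washout, post-recovery)
    for one scenario."""
    agent = scenario.agent
    phases = [
        induction_controller(agent, scenario.body,
                             overpressure_fd=overpressure_fd,
                             until_t=scenario.maintenance_duration),
        ProtocolPhase(
            name="washout",
            vent=VentSettings(f_d=0.0, fgf=WASHOUT_FGF,
                              v_a=scenario.washout_va),
            stop_var="f_vrg", stop_when="le", stop_level=agent.macawake,
            max_duration=WASHOUT_CAP_MIN,
        ),
        ProtocolPhase(
            name="post_recovery",
            vent=VentSettings(f_d=0.0, fgf=WASHOUT_FGF,
                              v_a=scenario.post_recovery_va),
            duration=scenario.observation_duration,
        ),
    ]
    return phases


def run_scenario(scenario: Scenario,
                 reporting_dt_s: float = 1.0,
                 dt_s: float = 0.25,
                 probe_times: tuple[float, ...] = (30.0,)) -> ScenarioRun:
    """Simulate one scenario end-to-end and compute emergence metrics.

    Deterministic: rerunning yields a bit-identical trajectory.  Raises
    :class:`~gaswash.model.ThresholdNotReachedError` if F_VRG does not
    reach MACawake within the washout cap.
    """
    phases = build_protocol(scenario)
    ts = simulate_phases(SimState.zero(), phases, scenario.agent,
                         scenario.body, reporting_dt_s=reporting_dt_s,
                         dt_s=dt_s)
    t_cut = scenario.maintenance_duration
    t_macawake = time_to_threshold(ts, "f_vrg", scenario.agent.macawake,
                                   from_t=t_cut)
    log.info("%s: MACawake at %.3f min after cut-off",
             scenario.label(), t_macawake - t_cut)
    emergence = detect_rehypnotization(ts, scenario.agent, t_macawake,
                                       t_cut, probe_times=probe_times)
    if emergence.rehypnotized:
        log.info("%s: rehypnotization, peak F_VRG %.3f vol%% at +%.1f min",
                 scenario.label(), emergence.peak_post_fvrg,
                 emergence.t_peak)
    return ScenarioRun(scenario=scenario, timeseries=ts, emergence=emergence)
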