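"""The full emergence study: washout times, hyperventilation speed-up,
and the rehypnotization matrix over all scenarios.

The 36 study arms share their maintenance and washout segments (six
unique agent x washout-mode combinations); :func:`run_study` simulates
each shared segment once and branches the six post-recovery arms from
the MACawake crossing state, which is bit-identical to running each
scenario end-to-end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .params import AgentParams, default_agents
from .model import SimState, TimeSeries, simulate_phases
from .metrics import (EmergenceResult, detect_rehypnotization,
                      format_minutes, percent_reduction, time_to_threshold)
from .protocol import (POST_RECOVERY_LEVELS, Scenario, build_protocol)
from .scenarios import WASHOUT_MODES

__all__ = ["StudyResult", "run_study"]

log = logging.getLogger(__name__)

_MODE = {5.0: "NV", 10.0: "HV"}


@dataclass
class StudyResult:
    """Bundle of all study outputs.

    ``washout_times`` maps (agent, mode) to minutes from cut-off to
    MACawake; ``reductions`` maps agent to the percent reduction of that
    time by hyperventilation; ``arms`` maps (agent, mode, post_va) to
    the arm's :class:`~gaswash.metrics.EmergenceResult`.
    ``washout_traces`` hold the full maintenance+washout trajectories;
    ``arm_traces`` only the post-recovery segment of each arm.
    """

    washout_times: dict[tuple[str, str], float]
    reductions: dict[str, float]
    arms: dict[tuple[str, str, float], EmergenceResult]
    washout_traces: dict[tuple[str, str], TimeSeries] = field(default_factory=dict)
    arm_traces: dict[tuple[str, str, float], TimeSeries] = field(default_factory=dict)

    def rehyp_matrix(self) -> pd.DataFrame:
        """Boolean rehypnotization verdicts, rows (agent, washout mode),
        columns post-recovery V_A."""
        agents = sorted({k[0] for k in self.arms})
        modes = ["NV", "HV"]
        levels = sorted({k[2] for k in self.arms})
        idx = pd.MultiIndex.from_product([agents, modes],
                                         names=["agent", "washout"])
        df = pd.DataFrame(index=idx, columns=levels, dtype=bool)
        for (a, m, v), res in self.arms.items():
            df.loc[(a, m), v] = res.rehypnotized
        df.columns.name = "post_va"
        return df

    def peak_matrix(self) -> pd.DataFrame:
        """Peak post-recovery F_VRG (vol%), same layout as the
        rehypnotization matrix."""
        df = self.rehyp_matrix().astype(float)
        for (a, m, v), res in self.arms.items():
            df.loc[(a, m), v] = res.peak_post_fvrg
        return df

    def summary_frame(self) -> pd.DataFrame:
        """Washout times (min and mm:ss) and percent reductions."""
        rows = []
        for (agent, mode), t in sorted(self.washout_times.items()):
            rows.append({
                "agent": agent, "washout": mode,
                "t_macawake_min": round(t, 4),
                "t_macawake": format_minutes(t),
                "reduction_pct": (round(self.reductions[agent])
                                  if mode == "HV" else 0),
            })
        return pd.DataFrame(rows)

    def write_outputs(self, outdir: str | Path) -> list[Path]:
        """Write study_summary.csv, rehypnotization_matrix.csv and the
        per-scenario trace CSVs; returns the written paths."""
        from .io import write_timeseries

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        p = outdir / "study_summary.csv"
        self.summary_frame().to_csv(p, index=False)
        written.append(p)
        p = outdir / "rehypnotization_matrix.csv"
        self.rehyp_matrix().to_csv(p)
        written.append(p)
        p = outdir / "peak_fvrg_matrix.csv"
        self.peak_matrix().round(4).to_csv(p)
        written.append(p)
        for (agent, mode), ts in self.washout_traces.items():
            p = outdir / f"washout_{agent}_{mode}.csv"
            write_timeseries(ts, p)
            written.append(p)
        for (agent, mode, va), ts in self.arm_traces.items():
            p = outdir / f"post_{agent}_{mode}_va{va:g}.csv"
            write_timeseries(ts, p)
            written.append(p)
        return written


def run_study(agents: dict[str, AgentParams] | None = None,
              post_levels: tuple[float, ...] = POST_RECOVERY_LEVELS,
              maintenance_duration: float = 480.0,
              observation_duration: float = 120.0,
              reporting_dt_s: float = 1.0,
              dt_s: float = 0.25,
              keep_traces: bool = True) -> StudyResult:
    """Simulate the full 3 x 2 x 6 emergence study.

    Deterministic; completes in well under two minutes on one CPU.
    """
    if agents is None:
        agents = default_agents()
    washout_times: dict[tuple[str, str], float] = {}
    arms: dict[tuple[str, str, float], EmergenceResult] = {}
    washout_traces = {}
    arm_traces = {}
    for name, agent in agents.items():
        for mode_va in WASHOUT_MODES:
            mode = _MODE[mode_va]
            base = Scenario(agent=agent, washout_va=mode_va,
                            post_recovery_va=post_levels[0],
                            maintenance_duration=maintenance_duration,
                            observation_duration=observation_duration)
            phases = build_protocol(base)[:2]  # maintenance + washout
            ts_base = simulate_phases(SimState.zero(), phases, agent,
                                      base.body,
                                      reporting_dt_s=reporting_dt_s,
                                      dt_s=dt_s)
            t_cross = ts_base.events["washout"]
            washout_times[(name, mode)] = t_cross - maintenance_duration
            log.info("%s/%s: MACawake at %s", name, mode,
                     format_minutes(t_cross - maintenance_duration))
            if keep_traces:
                washout_traces[(name, mode)] = ts_base
            start = ts_base.final_state()
            for post_va in post_levels:
                arm = Scenario(agent=agent, washout_va=mode_va,
                               post_recovery_va=post_va,
                               maintenance_duration=maintenance_duration,
                               observation_duration=observation_duration)
                post_phase = build_protocol(arm)[2]
                ts_post = simulate_phases(start, [post_phase], agent,
                                          arm.body,
                                          reporting_dt_s=reporting_dt_s,
                                          dt_s=dt_s)
                full = TimeSeries.concat(ts_base, ts_post)
                res = detect_rehypnotization(
                    full, agent,
                    t_macawake=time_to_threshold(
                        full, "f_vrg", agent.macawake,
                        from_t=maintenance_duration),
                    t_cutoff=maintenance_duration)
                arms[(name, mode, post_va)] = res
                if keep_traces:
                    arm_traces[(name, mode, post_va)] = ts_post
    reductions = {
        name: percent_reduction(washout_times[(name, "NV")],
                                washout_times[(name, "HV")])
        for name in agents
    }
    return StudyResult(washout_times=washout_times, reductions=reductions,
                       arms=arms, washout_traces=washout_traces,
                       arm_traces=arm_traces)
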