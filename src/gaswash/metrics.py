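"""Derived emergence quantities.

Covers the closed-form alveolar clearance index, threshold-crossing
(time-to-MACawake) detection on simulated trajectories, the percent
speed-up of recovery produced by hyperventilation, and rehypnotization
detection (rebound of the CNS-proxy partial pressure above MACawake
after initial awakening).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import AgentParams
from .model import TimeSeries

__all__ = [
    "EmergenceResult", "NoCrossingError",
    "clearance", "clearance_table", "time_to_threshold",
    "percent_reduction", "detect_rehypnotization",
]

#: (cardiac output, alveolar ventilation) columns of the standard
#: clearance sensitivity table; the first pair is the baseline.
CLEARANCE_GRID = ((5.0, 5.0), (5.0, 2.5), (5.0, 10.0), (2.5, 5.0), (10.0, 5.0))


class NoCrossingError(ValueError):
    """The trace never crosses the requested level."""


@dataclass
class EmergenceResult:
    """Emergence outcome of one washout/post-recovery scenario.

    Times are minutes from agent cut-off.  ``fvrg_fraction_at`` maps a
    probe time to F_VRG at that probe divided by the maintenance F_VRG.
    """

    agent: str
    t_macawake: float
    rehypnotized: bool
    peak_post_fvrg: float
    t_peak: float
    fvrg_fraction_at: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_macawake <= 0:
            raise ValueError("t_macawake must be > 0")


def clearance(lambda_bg: float, q: float, v_a: float) -> float:
    """Fractional alveolar clearance ``1 / (1 + lambda_bg * Q / V_A)``.

    The index is the fraction of the agent delivered to the alveoli by
    venous blood that is eliminated by ventilation; it rises with
    ventilation and falls with solubility and cardiac output.
    """
    if v_a <= 0:
        raise ValueError("v_a must be > 0")
    if q <= 0:
        raise ValueError("q must be > 0")
    if lambda_bg < 0:
        raise ValueError("lambda_bg must be >= 0")
    return 1.0 / (1.0 + lambda_bg * q / v_a)


def clearance_table(agents: dict[str, AgentParams],
                    grid=CLEARANCE_GRID) -> pd.DataFrame:
    """Clearance of each agent over a (Q, V_A) grid, plus each cell as a
    percentage of the baseline (first grid pair).

    Returns a DataFrame with one ``("clearance", agent)`` row and one
    ``("% of baseline", agent)`` row per agent; columns are the (Q, V_A)
    pairs.  Values are unrounded; display rounds clearance to 2 decimals
    and percentages to integers.
    """
    cols = pd.MultiIndex.from_tuples(grid, names=["q", "v_a"])
    rows = {}
    for name, agent in agents.items():
        vals = np.array([clearance(agent.lambda_blood, q, va)
                         for q, va in grid])
        rows[("clearance", name)] = vals
        rows[("% of baseline", name)] = 100.0 * vals / vals[0]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["quantity", "agent"])
    return df


def format_clearance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Round to display precision: clearance 2 dp, percentages integer."""
    out = table.copy().astype(object)
    for idx in out.index:
        if idx[0] == "clearance":
            out.loc[idx] = [f"{v:.2f}" for v in table.loc[idx]]
        else:
            out.loc[idx] = [f"{v:.0f}%" for v in table.loc[idx]]
    return out


def time_to_threshold(ts: TimeSeries, variable: str, level: float,
                      from_t: float = 0.0) -> float:
    """First time (minutes, absolute) at which ``variable`` crosses
    ``level`` after ``from_t``, located by linear interpolation between
    reporting samples.

    A crossing means the trace passes from one side of the level to the
    other (either direction); a trace that starts exactly at the level
    must first leave it.  Raises :class:`NoCrossingError` if the trace
    never crosses.
    """
    t = ts.t
    v = ts.column(variable)
    mask = t >= from_t - 1e-12
    if not mask.any():
        raise NoCrossingError(f"trace ends before from_t={from_t:g}")
    t = t[mask]
    v = v[mask]
    s = v - level
    # indices where the sign changes (or the trace touches the level)
    prod = s[:-1] * s[1:]
    hits = np.nonzero(prod <= 0)[0]
    for i in hits:
        if s[i] == 0 and s[i + 1] == 0:
            continue
        if s[i] == 0 and i > 0:
            continue  # leaving the level, not crossing it
        if s[i + 1] == s[i]:
            continue
        return float(t[i] + (t[i + 1] - t[i]) * s[i] / (s[i] - s[i + 1]))
    raise NoCrossingError(
        f"{variable} never crosses {level:g} vol% after t={from_t:g} min")


def percent_reduction(t_nv: float, t_hv: float) -> float:
    """Percent reduction of a recovery time by hyperventilation:
    ``100 * (t_nv - t_hv) / t_nv``.  Rounded only at presentation."""
    if t_nv <= 0:
        raise ValueError("t_nv must be > 0")
    return 100.0 * (t_nv - t_hv) / t_nv


def detect_rehypnotization(ts: TimeSeries, agent: AgentParams,
                           t_macawake: float, t_cutoff: float,
                           probe_times: tuple[float, ...] = (30.0,),
                           ) -> EmergenceResult:
    """Scan the trajectory strictly after the MACawake crossing for a
    rebound of F_VRG above MACawake (0.3 MAC).

    ``t_macawake`` and ``t_cutoff`` are absolute trajectory times (the
    crossing and the agent cut-off).  Rehypnotization requires a strict
    exceedance of the threshold; touching it exactly does not count.
    ``probe_times`` (minutes from cut-off) give F_VRG decrement
    fractions relative to the maintenance value at cut-off.
    """
    if ts.t[-1] - t_macawake < 10.0:
        raise ValueError("post-recovery window shorter than 10 min")
    threshold = agent.macawake
    after = ts.t > t_macawake + 1e-9
    if not after.any():
        raise ValueError("trajectory does not extend past the crossing")
    fv = ts.f_vrg[after]
    tt = ts.t[after]
    i_peak = int(np.argmax(fv))
    peak = float(fv[i_peak])
    fractions = {}
    f_maint = ts.value_at("f_vrg", t_cutoff)
    for probe in probe_times:
        t_abs = t_cutoff + probe
        if ts.t[0] <= t_abs <= ts.t[-1]:
            fractions[probe] = ts.value_at("f_vrg", t_abs) / f_maint
    return EmergenceResult(
        agent=agent.name,
        t_macawake=t_macawake - t_cutoff,
        rehypnotized=bool(peak > threshold),
        peak_post_fvrg=peak,
        t_peak=float(tt[i_peak]) - t_cutoff,
        fvrg_fraction_at=fractions,
    )


def format_minutes(minutes: float) -> str:
    """Render a duration as ``"M min S s"`` (seconds to the nearest s)."""
    total_s = round(minutes * 60)
    return f"{total_s // 60} min {total_s % 60} s"
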