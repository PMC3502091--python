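"""Compartmental mass-balance model of inhaled-anesthetic kinetics.

The body and breathing system are represented by five well-mixed
compartments exchanging agent, with all pressures expressed as partial
pressures in vol% of 1 atm and time in minutes:

* the breathing **circuit** (volume ``V_C``), receiving fresh gas at
  flow ``FGF`` carrying the delivered pressure ``F_D``, and exchanging
  gas with the lungs at the alveolar minute ventilation ``V_A``;
* the **alveolar** compartment (volume ``FRC``).  Blood leaving the
  lung is assumed instantaneously equilibrated with alveolar gas
  (``F_A = F_a``), so pulmonary uptake is
  ``lambda_B/G * Q_p * (F_A - F_mv)`` with ``Q_p`` the perfused cardiac
  output and ``F_mv`` the mixed-venous pressure;
* three **perfusion-limited tissue groups** — vessel-rich (VRG, the
  CNS proxy), muscle (MG) and fat — each with capacity
  ``V_i * lambda_i`` and uptake ``lambda_B/G * Q_i * (F_A - F_i)``.

The governing equations::

    dF_I/dt = [FGF*(F_D - F_I) + V_A*(F_A - F_I)] / V_C
    dF_A/dt = [V_A*(F_I - F_A) - lam_bg*Q_p*(F_A - F_mv)] / FRC
    dF_i/dt = lam_bg*Q_i*(F_A - F_i) / (V_i*lam_i)      i in {VRG, MG, fat}
    F_mv    = sum_i Q_i*F_i / sum_i Q_i

Blood acts purely as a carrier (no blood compartment volume).  The
system conserves agent exactly: the stored amount
``V_C*F_I + FRC*F_A + sum_i V_i*lam_i*F_i`` changes only through the
fresh-gas inflow ``FGF*F_D`` and the circuit overflow ``FGF*F_I``.

Integration uses a fixed-step classical 4th-order Runge-Kutta scheme
(default step 0.25 s); the system is non-stiff at physiological
parameter values (shortest time constant ~ tens of seconds).  Phases in
which the alveolar pressure is clamped (vaporizer servo during
maintenance) are advanced by the exact closed-form solution of the then
decoupled tissue equations; see :mod:`gaswash.protocol`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

from .params import AgentParams, BodyCircuitParams, VentSettings

__all__ = [
    "SimState", "Rates", "TimeSeries", "Phase",
    "mixed_venous", "derivative", "integrate", "simulate_phases",
    "InvalidParameterError", "ThresholdNotReachedError", "IntegrationError",
]

#: index of each state variable in the internal state vector
_VAR_INDEX = {"f_i": 0, "f_a": 1, "f_vrg": 2, "f_mus": 3, "f_fat": 4}

TIMESERIES_COLUMNS = ("t_min", "f_d", "fgf", "v_a", "f_i", "f_a",
                      "f_vrg", "f_mus", "f_fat", "f_mv")


class InvalidParameterError(ValueError):
    """A capacity term of the ODE is zero or negative."""


class ThresholdNotReachedError(RuntimeError):
    """An event-terminated phase hit its time cap without the event."""


class IntegrationError(RuntimeError):
    """The integrator failed to advance (non-finite state)."""


@dataclass(frozen=True)
class SimState:
    """Instantaneous partial pressures of all compartments (vol%)."""

    t: float = 0.0
    f_i: float = 0.0
    f_a: float = 0.0
    f_vrg: float = 0.0
    f_mus: float = 0.0
    f_fat: float = 0.0

    @classmethod
    def zero(cls, t: float = 0.0) -> "SimState":
        return cls(t=t)

    def pressures(self) -> tuple[float, float, float, float, float]:
        return (self.f_i, self.f_a, self.f_vrg, self.f_mus, self.f_fat)


@dataclass(frozen=True)
class Rates:
    """Time derivatives of the compartment pressures, vol%/min."""

    f_i: float
    f_a: float
    f_vrg: float
    f_mus: float
    f_fat: float


class _Coeffs:
    """Precomputed rate coefficients for one (agent, body) pair."""

    __slots__ = ("vc", "frc", "q", "qp", "lqp", "k", "cap", "lam_bg")

    def __init__(self, agent: AgentParams, body: BodyCircuitParams):
        self.vc = body.v_circuit
        self.frc = body.frc
        self.q = (body.q_vrg, body.q_mus, body.q_fat)
        self.qp = body.q_perfused
        self.lam_bg = agent.lambda_blood
        self.lqp = agent.lambda_blood * self.qp
        lams = (agent.lambda_vrg, agent.lambda_mus, agent.lambda_fat)
        vols = (body.v_vrg, body.v_mus, body.v_fat)
        self.cap = tuple(v * l for v, l in zip(vols, lams))
        for name, c in (("v_circuit", self.vc), ("frc", self.frc),
                        ("v_vrg*lambda_vrg", self.cap[0]),
                        ("v_mus*lambda_mus", self.cap[1]),
                        ("v_fat*lambda_fat", self.cap[2])):
            if c <= 0:
                raise InvalidParameterError(f"capacity {name} must be > 0")
        self.k = tuple(self.lam_bg * qi / ci
                       for qi, ci in zip(self.q, self.cap))

    def storage(self, y: Sequence[float]) -> float:
        """Agent amount held in all compartments, vol%*L."""
        return (self.vc * y[0] + self.frc * y[1]
                + self.cap[0] * y[2] + self.cap[1] * y[3]
                + self.cap[2] * y[4])


def mixed_venous(state: SimState, body: BodyCircuitParams) -> float:
    """Mixed-venous partial pressure: flow-weighted mean of the tissue
    pressures, vol%.  Always lies within [min, max] tissue pressure."""
    return (body.q_vrg * state.f_vrg + body.q_mus * state.f_mus
            + body.q_fat * state.f_fat) / body.q_perfused


def derivative(state: SimState, vent: VentSettings, agent: AgentParams,
               body: BodyCircuitParams) -> Rates:
    """Right-hand side of the mass-balance ODE at ``state``."""
    c = _Coeffs(agent, body)
    d = _deriv(state.pressures(), vent.f_d, vent.fgf, vent.v_a, c)
    return Rates(*d)


def _deriv(y, fd, fgf, va, c: _Coeffs):
    fi, fa, fv, fm, ff = y
    fmv = (c.q[0] * fv + c.q[1] * fm + c.q[2] * ff) / c.qp
    return (
        (fgf * (fd - fi) + va * (fa - fi)) / c.vc,
        (va * (fi - fa) - c.lqp * (fa - fmv)) / c.frc,
        c.k[0] * (fa - fv),
        c.k[1] * (fa - fm),
        c.k[2] * (fa - ff),
    )


def _rk4(y, h, fd, fgf, va, c: _Coeffs):
    """One classical RK4 step of length ``h`` minutes on the 5 pressures
    plus the running circuit-overflow integral ``int FGF*F_I dt``."""
    p = y[:5]
    k1 = _deriv(p, fd, fgf, va, c)
    h2 = 0.5 * h
    p2 = tuple(a + h2 * b for a, b in zip(p, k1))
    k2 = _deriv(p2, fd, fgf, va, c)
    p3 = tuple(a + h2 * b for a, b in zip(p, k2))
    k3 = _deriv(p3, fd, fgf, va, c)
    p4 = tuple(a + h * b for a, b in zip(p, k3))
    k4 = _deriv(p4, fd, fgf, va, c)
    h6 = h / 6.0
    out = tuple(a + h6 * (b1 + 2 * b2 + 2 * b3 + b4)
                for a, b1, b2, b3, b4 in zip(p, k1, k2, k3, k4))
    # same quadrature for the overflow integral (integrand FGF*F_I)
    aout = y[5] + h6 * fgf * (p[0] + 2 * p2[0] + 2 * p3[0] + p4[0])
    return out + (aout,)


@dataclass
class Phase:
    """One protocol phase: constant vent settings plus an end condition.

    Exactly one of ``duration`` (minutes), ``until_t`` (absolute end
    time, minutes) or a threshold event (``stop_var``/``stop_when``/
    ``stop_level``) must be given.  Threshold phases may carry a time
    cap (``max_duration`` or ``until_t``); reaching the cap raises
    :class:`ThresholdNotReachedError` when ``cap_is_error`` else ends
    the phase normally.

    ``clamp_fa`` switches the phase to servo mode: the alveolar
    pressure is held exactly at the given level, the tissue equations
    are advanced by their closed-form exponentials, and the inspired and
    delivered pressures are back-computed from the circuit balance.
    While the clamped alveolar pressure has not yet been attained the
    phase integrates the free system at ``vent.f_d`` (wash-in
    overpressure) until ``f_a`` first reaches the clamp level.
    """

    name: str
    vent: VentSettings
    duration: float | None = None
    until_t: float | None = None
    stop_var: str | None = None
    stop_when: str = "ge"
    stop_level: float | None = None
    max_duration: float | None = None
    cap_is_error: bool = True
    clamp_fa: float | None = None

    def __post_init__(self) -> None:
        modes = sum(x is not None
                    for x in (self.duration, self.until_t, self.stop_var))
        if self.clamp_fa is None:
            if modes != 1:
                raise ValueError(
                    f"phase {self.name!r}: exactly one end condition required")
        else:
            if self.duration is None and self.until_t is None:
                raise ValueError(
                    f"phase {self.name!r}: clamp phases need a duration")
            if self.clamp_fa <= 0:
                raise ValueError(f"phase {self.name!r}: clamp level must be > 0")
        if self.stop_var is not None:
            if self.stop_var not in _VAR_INDEX:
                raise ValueError(f"unknown monitored variable {self.stop_var!r}")
            if self.stop_when not in ("ge", "le"):
                raise ValueError("stop_when must be 'ge' or 'le'")
            if self.stop_level is None or self.stop_level <= 0:
                raise ValueError("threshold level must be > 0")
        if self.duration is not None and self.duration <= 0:
            raise ValueError(f"phase {self.name!r}: duration must be > 0")


@dataclass
class TimeSeries:
    """Trajectory sampled at the reporting interval.

    Columns are 1-D arrays of equal length; ``t`` is strictly
    increasing with constant spacing inside each phase (the final
    sample of an event-terminated phase lands on the event time).
    ``events`` maps the name of each event-terminated phase to the time
    at which its threshold was met.  ``net_input``/``net_output`` are
    the cumulative fresh-gas agent inflow and circuit overflow outflow
    (vol%*L) over the simulated interval.
    """

    t: np.ndarray
    f_d: np.ndarray
    fgf: np.ndarray
    v_a: np.ndarray
    f_i: np.ndarray
    f_a: np.ndarray
    f_vrg: np.ndarray
    f_mus: np.ndarray
    f_fat: np.ndarray
    f_mv: np.ndarray
    phase: np.ndarray = field(default=None)  # type: ignore[assignment]
    phase_names: list[str] = field(default_factory=list)
    events: dict[str, float] = field(default_factory=dict)
    net_input: float = 0.0
    net_output: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.t)
        if n == 0:
            raise ValueError("empty trajectory")
        for name in ("f_d", "fgf", "v_a", "f_i", "f_a",
                     "f_vrg", "f_mus", "f_fat", "f_mv"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} has wrong length")
        if self.phase is None:
            self.phase = np.zeros(n, dtype=np.int32)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def column(self, name: str) -> np.ndarray:
        if name not in TIMESERIES_COLUMNS and name != "t":
            raise KeyError(name)
        return getattr(self, "t" if name == "t_min" else name)

    def value_at(self, name: str, t: float) -> float:
        """Linear interpolation of a column at time ``t`` (minutes)."""
        if not (self.t[0] <= t <= self.t[-1]):
            raise ValueError(f"t={t:g} outside trajectory "
                             f"[{self.t[0]:g}, {self.t[-1]:g}]")
        return float(np.interp(t, self.t, self.column(name)))

    def final_state(self) -> SimState:
        return SimState(t=float(self.t[-1]), f_i=float(self.f_i[-1]),
                        f_a=float(self.f_a[-1]), f_vrg=float(self.f_vrg[-1]),
                        f_mus=float(self.f_mus[-1]), f_fat=float(self.f_fat[-1]))

    def to_dataframe(self):
        import pandas as pd

        data = {col: self.column(col) for col in TIMESERIES_COLUMNS}
        return pd.DataFrame(data)

    @classmethod
    def concat(cls, first: "TimeSeries", second: "TimeSeries") -> "TimeSeries":
        """Join two back-to-back trajectories.  If the second starts at
        the first's end time its first row replaces the first's last row
        (phase-boundary convention: the boundary row carries the new
        phase's settings)."""
        drop = 1 if abs(second.t[0] - first.t[-1]) < 1e-9 else 0
        sl = slice(0, len(first) - drop)
        offset = len(first.phase_names)
        cols = {}
        for name in ("t", "f_d", "fgf", "v_a", "f_i", "f_a",
                     "f_vrg", "f_mus", "f_fat", "f_mv"):
            a, b = getattr(first, name), getattr(second, name)
            cols[name] = np.concatenate([a[sl], b])
        phase = np.concatenate([first.phase[sl], second.phase + offset])
        events = dict(first.events)
        events.update(second.events)
        return cls(**cols, phase=phase,
                   phase_names=first.phase_names + second.phase_names,
                   events=events,
                   net_input=first.net_input + second.net_input,
                   net_output=first.net_output + second.net_output)


class _Recorder:
    """Accumulates reporting rows, replacing the previous row when a new
    phase re-records the boundary time with its own settings."""

    def __init__(self) -> None:
        self.rows: list[tuple] = []
        self.phase_idx: list[int] = []

    def add(self, t, vent_fd, fgf, va, y, pidx) -> None:
        if self.rows and t <= self.rows[-1][0] + 1e-9:
            self.rows.pop()
            self.phase_idx.pop()
        self.rows.append((t, vent_fd, fgf, va, y[0], y[1], y[2], y[3], y[4]))
        self.phase_idx.append(pidx)


def _event_crossed(val: float, level: float, when: str) -> bool:
    return val >= level if when == "ge" else val <= level


def _refine_event(y0, h_hi, val0, val_hi, level, idx, fd, fgf, va, c):
    """Locate the step fraction at which the monitored variable meets
    ``level``, by secant iteration on single RK4 steps from ``y0``."""
    lo, hi = 0.0, h_hi
    vlo, vhi = val0, val_hi
    h = h_hi
    y = None
    for _ in range(4):
        if vhi == vlo:
            break
        h = lo + (level - vlo) * (hi - lo) / (vhi - vlo)
        h = min(max(h, 1e-12), h_hi)
        y = _rk4(y0, h, fd, fgf, va, c)
        v = y[idx]
        if (v - level) * (vhi - level) > 0:
            hi, vhi = h, v
        else:
            lo, vlo = h, v
        if abs(v - level) < 1e-12:
            break
    if y is None:
        y = _rk4(y0, h_hi, fd, fgf, va, c)
        h = h_hi
    return h, y


def _run_free_phase(rec, y, t0, phase: Phase, c: _Coeffs, h, m, pidx,
                    stop_override=None):
    """Advance the free ODE through one phase.

    Returns ``(y, t_end, event_hit)``.  ``m`` is steps per report.
    ``stop_override`` lets the clamp handler reuse this routine for its
    wash-in stage.
    """
    vent = phase.vent
    fd, fgf, va = vent.f_d, vent.fgf, vent.v_a
    stop_var = stop_override[0] if stop_override else phase.stop_var
    stop_when = stop_override[1] if stop_override else phase.stop_when
    stop_level = stop_override[2] if stop_override else phase.stop_level
    if phase.duration is not None:
        horizon = phase.duration
    elif phase.until_t is not None:
        horizon = phase.until_t - t0
    else:
        horizon = phase.max_duration
        if horizon is None:
            raise ValueError(f"phase {phase.name!r}: unbounded event phase")
    if horizon <= 1e-12:
        return y, t0, False

    rec.add(t0, fd, fgf, va, y, pidx)
    idx = _VAR_INDEX[stop_var] if stop_var is not None else None
    if idx is not None and _event_crossed(y[idx], stop_level, stop_when):
        # already past the threshold at phase entry
        return y, t0, True

    n_full = int(math.floor(horizon / h + 1e-9))
    rem = horizon - n_full * h
    i = 0
    while True:
        if i < n_full:
            step = h
        elif rem > 1e-12:
            step = rem
        else:
            break
        y_prev = y
        y = _rk4(y, step, fd, fgf, va, c)
        if not math.isfinite(y[1]):
            raise IntegrationError(f"non-finite state in phase {phase.name!r}")
        i += 1
        t = t0 + (i * h if i <= n_full else horizon)
        if idx is not None and _event_crossed(y[idx], stop_level, stop_when):
            hc, y = _refine_event(y_prev, step, y_prev[idx], y[idx],
                                  stop_level, idx, fd, fgf, va, c)
            t = t - step + hc
            rec.add(t, fd, fgf, va, y, pidx)
            return y, t, True
        if i % m == 0 or step != h:
            rec.add(t, fd, fgf, va, y, pidx)
        if i > n_full:
            break
    t_end = t0 + horizon
    rec.add(t_end, fd, fgf, va, y, pidx)
    return y, t_end, False


def _run_clamp_phase(rec, y, t0, phase: Phase, c: _Coeffs, h, m, report_dt,
                     pidx):
    """Servo stage: hold ``f_a`` at the clamp level with the tissue
    equations advanced exactly; returns ``(y, t_end, net_input_inc)``.

    The wash-in stage (free ODE at the phase's ``f_d`` until ``f_a``
    reaches the clamp level) is run first.  The instantaneous circuit
    re-pressurization at servo engagement is booked as delivered agent
    so that global mass balance still closes.
    """
    vent = phase.vent
    fgf, va = vent.fgf, vent.v_a
    if va <= 0 or fgf <= 0:
        raise InvalidParameterError(
            "clamped maintenance requires fgf > 0 and v_a > 0")
    level = phase.clamp_fa
    t_end_abs = phase.until_t if phase.until_t is not None \
        else t0 + phase.duration
    net_in = 0.0

    # wash-in: overpressure until f_a first reaches the clamp level
    y, t, hit = _run_free_phase(
        rec, y, t0, phase, c, h, m, pidx,
        stop_override=("f_a", "ge", level))
    net_in += vent.fgf * vent.f_d * (t - t0)
    if not hit or t_end_abs - t <= 1e-9:
        # target approached asymptotically (f_d == target): no servo stage
        return y, t, net_in

    # engage servo: snap f_a, re-pressurize circuit to the balancing f_i
    fv0, fm0, ff0 = y[2], y[3], y[4]
    d = (fv0 - level, fm0 - level, ff0 - level)
    fmv0 = level + (c.q[0] * d[0] + c.q[1] * d[1] + c.q[2] * d[2]) / c.qp
    fi0 = level + (c.lqp / va) * (level - fmv0)
    net_in += c.vc * (fi0 - y[0]) + c.frc * (level - y[1])
    aout = y[5]

    T = t_end_abs - t
    ts = np.arange(0.0, T, report_dt)
    ts = np.append(ts, T) if T - ts[-1] > 1e-9 else ts
    k = np.array(c.k)
    dv = np.array(d)
    w = np.array(c.q) / c.qp
    e = np.exp(-np.outer(ts, k))                      # (n, 3)
    tissues = level + e * dv                          # pressures over time
    fmv = level + e @ (w * dv)
    fi = level + (c.lqp / va) * (level - fmv)
    dfmv = -(e @ (w * dv * k))
    dfi = -(c.lqp / va) * dfmv
    fd_star = fi + (c.vc * dfi - va * (level - fi)) / fgf
    fd_star = np.maximum(fd_star, 0.0)
    for j in range(len(ts)):
        rec.add(t + ts[j], float(fd_star[j]), fgf, va,
                (float(fi[j]), level, float(tissues[j, 0]),
                 float(tissues[j, 1]), float(tissues[j, 2])), pidx)

    # exact phase totals for the mass ledger
    int_fi = level * T - (c.lqp / va) * float(
        np.sum(w * dv * (1.0 - np.exp(-k * T)) / k))
    aout += fgf * int_fi
    y_end = (float(fi[-1]), level, float(tissues[-1, 0]),
             float(tissues[-1, 1]), float(tissues[-1, 2]), aout)
    d_store = c.storage(y_end) - c.storage((fi0, level, fv0, fm0, ff0))
    net_in += d_store + fgf * int_fi - fgf * 0.0  # inflow balances storage+overflow
    return y_end, t_end_abs, net_in


def simulate_phases(initial: SimState, phases: Sequence[Phase],
                    agent: AgentParams, body: BodyCircuitParams,
                    reporting_dt_s: float = 1.0,
                    dt_s: float = 0.25) -> TimeSeries:
    """Integrate a sequence of :class:`Phase` objects.

    Deterministic: identical inputs give bit-identical trajectories.
    ``reporting_dt_s`` should be an integer multiple of ``dt_s``.
    """
    if dt_s <= 0 or reporting_dt_s <= 0:
        raise ValueError("dt_s and reporting_dt_s must be > 0")
    c = _Coeffs(agent, body)
    h = dt_s / 60.0
    report_dt = reporting_dt_s / 60.0
    m = max(1, round(reporting_dt_s / dt_s))
    rec = _Recorder()
    y = initial.pressures() + (0.0,)
    t = initial.t
    net_in = 0.0
    events: dict[str, float] = {}
    names: list[str] = []
    for pidx, phase in enumerate(phases):
        names.append(phase.name)
        log.info("phase %s: start t=%.4f min, f_d=%g fgf=%g v_a=%g",
                 phase.name, t, phase.vent.f_d, phase.vent.fgf,
                 phase.vent.v_a)
        if phase.clamp_fa is not None:
            y, t, inc = _run_clamp_phase(rec, y, t, phase, c, h, m,
                                         report_dt, pidx)
            net_in += inc
        else:
            t_start = t
            y, t, hit = _run_free_phase(rec, y, t, phase, c, h, m, pidx)
            net_in += phase.vent.fgf * phase.vent.f_d * (t - t_start)
            if phase.stop_var is not None:
                if hit:
                    events[phase.name] = t
                elif phase.cap_is_error:
                    raise ThresholdNotReachedError(
                        f"phase {phase.name!r}: {phase.stop_var} never "
                        f"{'reached' if phase.stop_when == 'ge' else 'fell to'}"
                        f" {phase.stop_level:g} vol% within the time cap")
    arr = np.array(rec.rows, dtype=float)
    fmv = (c.q[0] * arr[:, 6] + c.q[1] * arr[:, 7]
           + c.q[2] * arr[:, 8]) / c.qp
    return TimeSeries(
        t=arr[:, 0], f_d=arr[:, 1], fgf=arr[:, 2], v_a=arr[:, 3],
        f_i=arr[:, 4], f_a=arr[:, 5], f_vrg=arr[:, 6], f_mus=arr[:, 7],
        f_fat=arr[:, 8], f_mv=fmv,
        phase=np.array(rec.phase_idx, dtype=np.int32),
        phase_names=names, events=events,
        net_input=net_in, net_output=y[5])


def integrate(initial: SimState,
              vent_schedule: Iterable[tuple[float, VentSettings]],
              agent: AgentParams, body: BodyCircuitParams,
              reporting_dt_s: float = 1.0,
              dt_s: float = 0.25) -> TimeSeries:
    """Integrate the free system through a schedule of
    ``(duration_minutes, VentSettings)`` segments."""
    phases = []
    for i, (dur, vent) in enumerate(vent_schedule):
        if dur <= 0:
            raise ValueError("segment durations must be > 0")
        phases.append(Phase(name=f"segment{i}", vent=vent, duration=dur))
    if not phases:
        raise ValueError("empty schedule")
    return simulate_phases(initial, phases, agent, body,
                           reporting_dt_s=reporting_dt_s, dt_s=dt_s)
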