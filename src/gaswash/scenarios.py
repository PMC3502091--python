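"""Scenario generation: the full study grid and perturbed variants.

The study grid crosses the three packaged agents with two washout
ventilation modes (normo- and hyperventilation) and six post-recovery
ventilation levels.  Perturbations scale a single body or protocol
parameter (muscle volume, fat volume, cardiac output, or anesthesia
duration) by a list of multipliers — optionally sampled at random
within the multiplier range — to probe sensitivity of rehypnotization
risk to body habitus and case length.

Scaling a tissue volume by default preserves perfusion *per unit
tissue*: the tissue's blood flow scales with its volume, cardiac output
rises by the increment, and the other tissues' absolute flows are
unchanged.  This keeps the tissue's wash-in/wash-out time constant
fixed, so a bigger muscle group reaches the same partial pressure during
maintenance and then releases proportionally more agent during
hypoventilation.  Pass ``scale_flow=False`` to :func:`perturb` to hold
the absolute tissue flow fixed instead (perfusion per unit tissue then
falls as the tissue grows; under that variant a larger, *less
pressurized* muscle can lower the early rebound).  No fuller
anthropometric closure model is applied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .params import AgentParams, default_agents
from .protocol import POST_RECOVERY_LEVELS, Scenario

__all__ = ["PerturbationSpec", "study_grid", "perturb"]

#: scenario/body parameters that may be perturbed
PERTURBABLE = ("v_mus", "v_fat", "q_total", "maintenance_duration")

WASHOUT_MODES = (5.0, 10.0)  # L/min: NV, HV


@dataclass(frozen=True)
class PerturbationSpec:
    """A one-parameter sweep.

    ``multipliers`` are applied deterministically in order.  If
    ``n_random`` is positive, that many additional multipliers are drawn
    uniformly between the smallest and largest listed multiplier using
    ``seed`` (expansion is deterministic for a fixed seed).
    """

    parameter: str
    multipliers: tuple[float, ...]
    seed: int = 0
    n_random: int = 0

    def __post_init__(self) -> None:
        if self.parameter not in PERTURBABLE:
            raise ValueError(
                f"parameter must be one of {PERTURBABLE}, got "
                f"{self.parameter!r}")
        if not self.multipliers:
            raise ValueError("at least one multiplier required")
        if any(m <= 0 for m in self.multipliers):
            raise ValueError("multipliers must be > 0")
        if self.n_random < 0:
            raise ValueError("n_random must be >= 0")

    def expand(self) -> list[float]:
        """All multipliers, listed then random-sampled ones."""
        out = list(self.multipliers)
        if self.n_random:
            rng = np.random.default_rng(self.seed)
            lo, hi = min(out), max(out)
            out.extend(float(m) for m in rng.uniform(lo, hi, self.n_random))
        return out


def study_grid(agents: dict[str, AgentParams] | None = None,
               ) -> list[Scenario]:
    """The 36 scenarios of the emergence study: 3 agents x 2 washout
    modes x 6 post-recovery ventilation levels, all unique."""
    if agents is None:
        agents = default_agents()
    return [
        Scenario(agent=agent, washout_va=mode, post_recovery_va=post)
        for agent in agents.values()
        for mode in WASHOUT_MODES
        for post in POST_RECOVERY_LEVELS
    ]


_TISSUE_FLOW_FIELD = {"v_mus": "f_mus", "v_fat": "f_fat"}


def _scale_tissue_volume(body, vol_field: str, m: float,
                         scale_flow: bool):
    new = {vol_field: getattr(body, vol_field) * m}
    if scale_flow:
        # tissue flow grows with its volume; cardiac output absorbs the
        # increment so every other tissue keeps its absolute flow
        flow_field = _TISSUE_FLOW_FIELD[vol_field]
        f_t = getattr(body, flow_field)
        q_new = body.q_total * (1.0 + f_t * (m - 1.0))
        scale = body.q_total / q_new
        fractions = {f: getattr(body, f) * scale
                     for f in ("f_vrg", "f_mus", "f_fat")}
        fractions[flow_field] = f_t * m * scale
        new.update(q_total=q_new, **fractions)
    return dataclasses.replace(body, **new)


def perturb(base: Scenario, spec: PerturbationSpec,
            scale_flow: bool = True) -> list[Scenario]:
    """One scenario per multiplier, scaling the chosen parameter.

    The identity multiplier returns the base scenario unchanged.
    ``scale_flow`` controls whether tissue-volume multipliers carry
    their blood flow along (see module docstring).  Raises
    :class:`~gaswash.params.ParameterError` (via dataclass validation)
    if a resulting parameter set is invalid.
    """
    out = []
    for m in spec.expand():
        if m == 1.0:
            out.append(base)
        elif spec.parameter == "maintenance_duration":
            out.append(dataclasses.replace(
                base, maintenance_duration=base.maintenance_duration * m))
        elif spec.parameter in _TISSUE_FLOW_FIELD:
            body = _scale_tissue_volume(base.body, spec.parameter, m,
                                        scale_flow)
            out.append(dataclasses.replace(base, body=body))
        else:
            body = dataclasses.replace(
                base.body,
                **{spec.parameter: getattr(base.body, spec.parameter) * m})
            out.append(dataclasses.replace(base, body=body))
    return out
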