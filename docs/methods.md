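# Methods

## Model structure and assumptions

The simulator is a five-compartment, perfusion-limited kinetic model of
a volatile anesthetic in a patient on a circle breathing system. All
agent levels are partial pressures in vol% of 1 atm; time is carried in
minutes.

* **Circuit** (volume `v_circuit`, default 8 L): well mixed; receives
  fresh gas at `fgf` carrying the vaporizer pressure `f_d`, exchanges
  gas with the lungs at the alveolar ventilation `v_a`, and spills the
  excess at its own mixed pressure. A single well-mixed circuit is
  used: there is no separate inspired-limb delay, and consequently some
  expired agent is re-inspired even at high fresh gas flow — in quasi
  steady state `F_I/F_A → V_A/(FGF+V_A)` (1/3 at FGF 10, V_A 5). This
  residual rebreathing is a real property of a mixed circuit volume and
  is load-bearing for the rehypnotization results: it lowers the
  effective alveolar clearance during emergence, which is exactly when
  the inspired limb carries returned agent.
* **Alveolar space** (`frc`, default 2.5 L): blood leaving the lung is
  assumed fully equilibrated with alveolar gas (`F_A = F_a`); pulmonary
  uptake is `λ_B/G · Q_p · (F_A − F_v̄)`.
* **Tissues** (VRG/muscle/fat): each perfusion-limited with capacity
  `V_i·λ_i` and time constant `τ_i = V_i·λ_i / (λ_B/G·Q_i)`
  (isoflurane: ≈2.6 min VRG, ≈127 min muscle, ≈2600 min fat). The
  vessel-rich group stands in for the CNS. Venous return is the
  flow-weighted mean of tissue pressures, weighted by the perfused flow
  `Q_p = ΣQ_i = 0.998·Q`; the packaged flow fractions
  (75.8/18/6 %) are used verbatim rather than renormalized to 1.

Not modelled (out of scope by design): dead space, V/Q mismatch,
metabolism, inter-tissue diffusion, intra-tissue heterogeneity
(gray/white matter), CO₂- or age-dependent physiology, and
concentration/second-gas volume effects. In particular, raising `v_a`
does not alter cerebral blood flow — the simulated hyperventilation is
inherently *isocapnic*, which is the clean theoretical case that
clinical hyperventilation techniques try to approximate with CO₂
rebreathing or admixture.

## Protocol

`run_scenario` executes three phases:

1. **Induction + maintenance** (default 480 min total, FGF 1, V_A 5):
   the vaporizer is held at an agent-specific overpressure (18/5/3 vol%
   for des/sevo/iso) until `F_A` first reaches the 1-MAC target, then an
   algebraic servo holds `F_A` exactly at target: the tissue equations
   decouple into first-order systems with constant drive and are
   advanced by their exact exponentials, while `F_I` and `F_D` are
   back-computed from the alveolar and circuit balances. Two
   idealizations, both documented deviations from a human operator
   titrating a vaporizer: (a) at servo engagement the circuit pressure
   is adjusted instantaneously to the balancing value (the jump is
   booked as delivered agent so the mass ledger still closes); (b) the
   back-computed `F_D` is not capped at the overpressure setting — for
   isoflurane it transiently requires ≈4.9 vol% just after engagement.
   Enforcing the cap would need a chattering hybrid controller and
   changes the end-of-maintenance state negligibly (the transient lasts
   minutes against a 127-min muscle time constant). With the vaporizer
   set exactly at target, `F_A` approaches the target asymptotically
   and the servo never engages.
2. **Washout** (F_D 0, FGF 10, V_A 5 or 10): ends when `F_VRG` falls to
   MACawake = 0.3·MAC, detected in-step and refined by secant iteration
   so the phase switches exactly at the crossing; capped at 240 min
   (error beyond that).
3. **Post-recovery observation** (F_D 0, FGF 10, default 120 min) at
   the scenario's `post_recovery_va`. Rehypnotization is a *strict*
   exceedance of 0.3·MAC by `F_VRG` at any sample strictly after the
   crossing; touching the threshold does not count. The default
   decrement probe reports `F_VRG(cut-off + 30 min)` relative to the
   maintenance value.

The 120-min observation window covers every rebound seen across the
study grid (peaks occur 5–40 min after the crossing) and is
configurable.

## Numerics

* Free phases use a fixed-step classical RK4 with step 0.25 s. The
  system is non-stiff at physiological parameters (fastest mode
  ≈(V_A+λQ_p)/FRC ≈ 7 min⁻¹, giving h·k ≈ 0.03); halving the step
  changes reported pressures by far less than the tested 10⁻⁶ vol%.
  Against a matrix-exponential oracle the trajectories agree to
  ~10⁻⁹ vol%.
* Clamped (servo) phases are advanced in closed form — exact, not
  approximate.
* Threshold events are located by linear interpolation inside the
  integration step, then polished with up to four secant iterations on
  partial RK4 steps; trajectory post-processing detects crossings by
  linear interpolation between 1-s reporting samples, so event times
  are resolution-independent to well under a second.
* Reporting default is 1 sample/s; rows are written at a fixed grid
  within each phase plus the exact phase-end time. At a phase boundary
  the single boundary row carries the *new* phase's settings.
* Mass ledger: fresh-gas inflow and circuit-overflow outflow integrals
  are carried with RK4-consistent quadrature; stored amount minus net
  input closes to ~10⁻¹² relative over full protocols (tested at
  10⁻⁶).
* Degenerate inputs: zero capacities are rejected at construction; an
  overpressure below target raises immediately (the steady state equals
  `f_d`); ties at thresholds resolve to "no event" for rehypnotization
  (strict inequality) and to the first touch for time-to-threshold.

## Scenario generation and sensitivity semantics

`study_grid()` enumerates the 36 standard arms (3 agents × 2 washout
modes × 6 post-recovery ventilation levels). `perturb()` scales one
parameter (`v_mus`, `v_fat`, `q_total`, `maintenance_duration`) by a
multiplier list, optionally extended by uniform random multipliers from
a seeded generator (deterministic per seed).

Tissue-volume perturbations preserve **perfusion per unit tissue** by
default: the tissue's blood flow scales with its volume and cardiac
output absorbs the increment, leaving other tissues' absolute flows and
the tissue's own time constant unchanged. This choice was genuinely
open, and it matters: with the alternative (`scale_flow=False`, tissue
flow fixed while volume grows) a larger muscle group is *less
pressurized* at cut-off, and the post-recovery peak `F_VRG` becomes
non-monotone in muscle size — measured for isoflurane after a full
8-h maintenance, peaks 0.496/0.507/0.499/0.473 vol% at ×0.75/1/1.5/2.
With flow scaling, "more muscle ⇒ larger rebound" holds as a simulator
property over moderate habitus ranges (×0.75–×1.5, the range asserted
in tests); at extreme multipliers (×2) the interaction with total
cardiac output can again bend the curve. The directional effect of
maintenance duration (longer case ⇒ larger rebound) is monotone as
expected.

What the generator emulates — and what it does not: it produces the
deterministic scenario grid and parameter-scaled variants of one
idealized patient. It does not model population variability,
measurement noise, spontaneous-ventilation dynamics, airway events, or
anesthetic agent mixtures; passing tests therefore validate the kinetic
mechanism, not predictive accuracy for any individual patient.

## Problem sizes

Default runs integrate the full protocol (≈8 h maintenance + washout +
2 h observation) at 0.25-s steps with 1-s reporting; a scenario takes
well under a second and the full 36-arm study a few seconds on one
core. The test suite runs every study arm end-to-end at these default
resolutions (no scaled-down physics).

## Known limitations

* The servo idealizations above (instantaneous circuit adjustment,
  uncapped back-computed `F_D`).
* The single well-mixed circuit overstates rebreathing relative to a
  circle system with directional valves at high FGF, and understates
  mixing delay at low FGF.
* MACawake is a fixed population threshold (0.3 MAC); no
  pharmacodynamic variability or hysteresis.
* Emergence times are sensitive to the unmodelled dead space and V/Q
  spread; absolute times should be read as model quantities, not
  patient predictions.
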