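"""Decoding-motif simulators: activation thresholds, cFFLs, and the iFFL.

The motifs are concrete minimal forms of the network-motif literature's
schematics, built on the same hourly recursion as the simple kinetic model:

* **Activation threshold** - a Hill gate on the *excess over basal* input:
  ``eff = basal + (x - basal) * H(x)`` with ``H(x) = x^n / (x^n + theta^n)``.
  Gating the excess (rather than the whole input) preserves the basal steady
  state, so an un-induced target sits flat instead of decaying, and theta=0
  opens the gate completely (H=1), reducing *exactly* to simple regulation.
  The gate acts on p53->mRNA production (transcriptional level) or on
  mRNA->protein production (translational level).

* **cFFL** - X drives an intermediate Y (first-order kinetics, optional
  delay, production gated by a Hill term in X so Y only accumulates while X
  is high); Z production requires X (linear) AND Y above its threshold
  (soft AND: product with a Hill gate in Y applied to the excess input).
  Because Y needs sustained X to accumulate, the loop is a persistence
  detector: brief oscillatory pulses never open the gate, a sustained rise
  does.

* **iFFL** - Y as above, but Z's excess production is divisively repressed
  once Y accumulates: ``excess / (1 + rho * H_y(y))``.  Sustained input
  builds Y and silences the protein; pulsed input leaves Y low and the
  protein is induced - inverting the mRNA-to-protein correspondence.

Nulling each motif's distinguishing parameter (theta = 0, y_threshold = 0,
repression = 0) recovers the simple kinetic model trace exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import KineticParams, TimeCourse, TimeGrid
from .kinetic_model import hourly_times, interp_hourly, simulate_mrna, simulate_protein
from .expression_io import fold_change, max_fold_change


def hill(x: np.ndarray | float, theta: float, n: float) -> np.ndarray | float:
    """Hill activation term x^n / (x^n + theta^n); identically 1 when theta<=0."""
    if theta < 0:
        raise ValueError("negative threshold")
    x = np.asarray(x, float)
    if theta == 0:
        return np.ones_like(x)
    xn = np.power(np.maximum(x, 0.0), n)
    return xn / (xn + theta ** n)


def gated_excess(x: np.ndarray, basal: float, gate: np.ndarray) -> np.ndarray:
    """basal + (x - basal) * gate: threshold applied to the induced excess."""
    return basal + (x - basal) * gate


@dataclass(frozen=True)
class ThresholdSpec:
    theta: float = 0.0
    hill_n: float = 4.0
    level: str = "translational"  # or "transcriptional"

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("negative theta")
        if self.level not in ("transcriptional", "translational"):
            raise ValueError(f"unknown threshold level {self.level!r}")


@dataclass(frozen=True)
class FFLSpec:
    topology: str = "coherent"            # coherent | incoherent
    level: str = "posttranscriptional"    # transcriptional | posttranscriptional
    y_production: float = 0.5             # per hour
    y_degradation: float = 0.1            # per hour
    y_delay: float = 0.5                  # hours
    y_threshold: float = 0.5              # Y level at which the gate half-opens
    y_hill_n: float = 4.0
    x_half: float = 1.5                   # X level half-activating Y production
    x_hill_n: float = 4.0
    repression: float = 10.0              # iFFL repression strength rho
    target: str = "translation"           # iFFL/cFFL-post act on translation|stability

    def __post_init__(self) -> None:
        if self.topology not in ("coherent", "incoherent"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if min(self.y_production, self.y_degradation) < 0:
            raise ValueError("Y rates must be non-negative")
        if self.y_delay < 0:
            raise ValueError("y_delay must be non-negative")


@dataclass
class MotifTraces:
    y: TimeCourse | None
    mrna: TimeCourse
    protein: TimeCourse


def _threshold_input(tc: TimeCourse, theta: float, n: float, step: float) -> TimeCourse:
    times, x = interp_hourly(tc, step=step)
    eff = gated_excess(x, x[0], hill(x, theta, n))
    return TimeCourse(tc.species, tc.condition, tc.replicate, TimeGrid(tuple(times)), eff)


def simulate_threshold(
    input_trace: TimeCourse,
    spec: ThresholdSpec,
    kinetics: KineticParams,
    step: float = 1.0,
) -> MotifTraces:
    """Simple regulation with an activation threshold at one level.

    transcriptional: the p53 input driving mRNA production is gated.
    translational: the mRNA input driving protein production is gated.
    """
    if spec.level == "transcriptional":
        p53_eff = _threshold_input(input_trace, spec.theta, spec.hill_n, step)
        mrna = simulate_mrna(p53_eff, kinetics.kp_mrna, kinetics.kd_mrna, step=step)
        prot = simulate_protein(mrna, kinetics.kp_prot, kinetics.kd_prot,
                                tdel=kinetics.tdel, step=step)
    else:
        mrna = simulate_mrna(input_trace, kinetics.kp_mrna, kinetics.kd_mrna, step=step)
        mrna_eff = _threshold_input(mrna, spec.theta, spec.hill_n, step)
        prot = simulate_protein(mrna_eff, kinetics.kp_prot, kinetics.kd_prot,
                                tdel=kinetics.tdel, step=step)
        prot.species = mrna.species
    return MotifTraces(y=None, mrna=mrna, protein=prot)


def simulate_y(x_trace: TimeCourse, spec: FFLSpec, step: float = 1.0) -> TimeCourse:
    """First-order intermediate Y driven by gated, delayed X.

    y(t) = (1 - kd_y) y(t-1) + kp_y * H(x(t-1-y_delay); x_half, n), starting
    from the basal steady state.
    """
    times, x = interp_hourly(x_trace, step=step)
    x_del = np.interp(times - spec.y_delay, times, x, left=x[0])
    drive = np.asarray(hill(x_del, spec.x_half, spec.x_hill_n), float)
    y0 = spec.y_production * float(drive[0]) / max(spec.y_degradation, 1e-6)
    y = np.empty_like(x)
    y[0] = y0
    a = 1.0 - spec.y_degradation * step
    for i in range(1, y.size):
        y[i] = a * y[i - 1] + spec.y_production * step * drive[i - 1]
    return TimeCourse("Y", x_trace.condition, x_trace.replicate,
                      TimeGrid(tuple(times)), y)


def simulate_cffl(
    x_trace: TimeCourse,
    spec: FFLSpec,
    kinetics: KineticParams,
    step: float = 1.0,
) -> MotifTraces:
    """Coherent FFL: Z requires both X and accumulated Y (AND gate).

    transcriptional level: the AND gate sits on mRNA synthesis.
    posttranscriptional level: mRNA is simply regulated and the gate sits on
    protein synthesis (translation; ``target="stability"`` instead lowers the
    protein degradation rate when Y is high).
    """
    if spec.topology != "coherent":
        raise ValueError("simulate_cffl requires a coherent topology")
    y = simulate_y(x_trace, spec, step=step)
    gate = np.asarray(hill(y.levels, spec.y_threshold, spec.y_hill_n), float)
    times = y.grid
    _, x = interp_hourly(x_trace, step=step)

    if spec.level == "transcriptional":
        x_eff = TimeCourse(x_trace.species, x_trace.condition, x_trace.replicate,
                           times, gated_excess(x, x[0], gate))
        mrna = simulate_mrna(x_eff, kinetics.kp_mrna, kinetics.kd_mrna, step=step)
        prot = simulate_protein(mrna, kinetics.kp_prot, kinetics.kd_prot,
                                tdel=kinetics.tdel, step=step)
    else:
        mrna = simulate_mrna(x_trace, kinetics.kp_mrna, kinetics.kd_mrna, step=step)
        if spec.target == "stability":
            prot = _simulate_protein_kd_modulated(mrna, kinetics, 1.0 - 0.9 * gate, step)
        else:
            prot = _gated_translation(mrna, kinetics, gate, step)
    return MotifTraces(y=y, mrna=mrna, protein=prot)


def simulate_iffl(
    x_trace: TimeCourse,
    spec: FFLSpec,
    kinetics: KineticParams,
    step: float = 1.0,
) -> MotifTraces:
    """Incoherent FFL: X activates Z while accumulated Y represses it.

    The induced excess of Z's translation input is divided by
    (1 + repression * H(y)); with ``target="stability"`` the repressor raises
    the protein degradation rate instead.
    """
    if spec.topology != "incoherent":
        raise ValueError("simulate_iffl requires an incoherent topology")
    y = simulate_y(x_trace, spec, step=step)
    gate = np.asarray(hill(y.levels, spec.y_threshold, spec.y_hill_n), float)
    repress = 1.0 / (1.0 + spec.repression * gate)
    mrna = simulate_mrna(x_trace, kinetics.kp_mrna, kinetics.kd_mrna, step=step)
    if spec.target == "stability":
        prot = _simulate_protein_kd_modulated(
            mrna, kinetics, 1.0 + spec.repression * gate, step, invert=True)
    else:
        prot = _gated_translation(mrna, kinetics, repress, step)
    return MotifTraces(y=y, mrna=mrna, protein=prot)


def _gated_translation(
    mrna: TimeCourse,
    kinetics: KineticParams,
    gate_factor: np.ndarray,
    step: float,
) -> TimeCourse:
    """Protein recursion with the induced excess of the delayed mRNA input
    scaled by a time-varying gate evaluated at translation time t (the Y gate
    acts when the protein is being made, not when its mRNA was)."""
    times, m = interp_hourly(mrna, step=step)
    m_del = np.interp(times - kinetics.tdel, times, m, left=m[0])
    eff = m[0] + (m_del - m[0]) * np.asarray(gate_factor, float)
    kd = kinetics.kd_prot
    p0 = kinetics.kp_prot * m[0] / max(kd, 1e-3)
    p = np.empty_like(m)
    p[0] = p0
    a = 1.0 - kd * step
    for i in range(1, p.size):
        p[i] = a * p[i - 1] + kinetics.kp_prot * step * eff[i]
    return TimeCourse(mrna.species, mrna.condition, mrna.replicate,
                      TimeGrid(tuple(times)), p)


def _simulate_protein_kd_modulated(
    mrna: TimeCourse,
    kinetics: KineticParams,
    kd_factor: np.ndarray,
    step: float,
    invert: bool = False,
) -> TimeCourse:
    """Protein recursion with a time-varying degradation rate (stability variants)."""
    times, m = interp_hourly(mrna, step=step)
    m_del = np.interp(times - kinetics.tdel, times, m, left=m[0])
    kd = np.clip(kinetics.kd_prot * np.asarray(kd_factor, float), 0.0, 1.0)
    p0 = kinetics.kp_prot * m[0] / max(kd[0], 1e-3)
    p = np.empty_like(m)
    p[0] = p0
    for i in range(1, p.size):
        p[i] = (1.0 - kd[i] * step) * p[i - 1] + kinetics.kp_prot * step * m_del[i]
    return TimeCourse(mrna.species, mrna.condition, mrna.replicate,
                      TimeGrid(tuple(times)), p)


def null_spec(spec: ThresholdSpec | FFLSpec) -> ThresholdSpec | FFLSpec:
    """Null the motif's distinguishing parameter (reduces to simple regulation)."""
    if isinstance(spec, ThresholdSpec):
        return replace(spec, theta=0.0)
    if spec.topology == "coherent":
        return replace(spec, y_threshold=0.0)
    return replace(spec, repression=0.0)


def exclusivity_index(
    trace_osc: TimeCourse,
    trace_rising: TimeCourse,
    fc_threshold: float = 1.15,
    window: tuple[float, float] = (1.0, 9.0),
) -> tuple[str, float]:
    """Apply the protein induction fold-change criterion per condition.

    Returns one of {"none", "osc_only", "rising_only"} plus the margin
    (difference of the two max fold changes, oscillatory minus rising).
    """
    if trace_osc.basal <= 0 or trace_rising.basal <= 0:
        raise ValueError("zero basal level")
    mx_osc = max_fold_change(fold_change(trace_osc), window)
    mx_rise = max_fold_change(fold_change(trace_rising), window)
    osc_ind = mx_osc > fc_threshold
    rise_ind = mx_rise > fc_threshold
    if osc_ind and not rise_ind:
        label = "osc_only"
    elif rise_ind and not osc_ind:
        label = "rising_only"
    else:
        label = "none"
    return label, float(mx_osc - mx_rise)
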