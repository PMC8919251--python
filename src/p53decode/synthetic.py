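"""Synthetic p53 waveforms and mechanism-labeled gene cohorts.

The generator emulates the study design every downstream stage assumes: two
p53 input regimes (oscillatory: damped pulse train with a 5.5 h period and a
first peak at 2 h; rising: saturating monotone increase), genes wired to the
input through one of five decoding mechanisms (simple regulation, activation
threshold, transcriptional / post-transcriptional coherent FFLs, incoherent
FFL), two replicates, and multiplicative log-normal measurement noise that is
independent across replicates and observations.

The oscillatory waveform is a baseline plus damped Gaussian pulse train
(the study reports period and peak times but no waveform equation); the
damping factor reproduces the reduced second peak.  The nominal second-peak
center is first_peak + period = 7.5 h; both are parameters.

Each mechanism has an *archetype* parameterization chosen so that its
noiseless record lands in the intended dynamical category (the round-trip
property): simple regulation covers categories a (fast mRNA and protein
turnover), b (fast mRNA, stable protein) and e (slow mRNA turnover);
medium/high translational activation thresholds cover g and k; the
transcriptional cFFL covers j, the post-transcriptional cFFL d, and the
iFFL h.  Cohort draws jitter the archetype rates within documented ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (CONDITIONS, OSCILLATORY, RISING, GeneRecord,
                         KineticParams, TimeCourse, TimeGrid)
from .kinetic_model import hourly_times, simulate_mrna, simulate_protein, sample_at
from .motif_models import (FFLSpec, MotifTraces, ThresholdSpec, simulate_cffl,
                           simulate_iffl, simulate_threshold)

MECHANISMS = ("simple", "threshold", "cffl_transcriptional",
              "cffl_posttranscriptional", "iffl")

DEFAULT_MECHANISM_MIX = {
    "simple": 0.55,
    "threshold": 0.20,
    "cffl_transcriptional": 0.08,
    "cffl_posttranscriptional": 0.09,
    "iffl": 0.08,
}


@dataclass(frozen=True)
class P53WaveformSpec:
    """Parameters of one p53 input regime.

    Levels are relative abundance; times in hours.  ``pulse_width`` is the
    Gaussian sigma of each pulse (default 1.2 h, giving a peak:trough ratio
    above 3 on the default waveform); ``damping`` scales successive pulse
    amplitudes (0.6 reproduces the reduced second peak).
    """

    kind: str = OSCILLATORY
    period: float = 5.5
    first_peak_time: float = 2.0
    pulse_width: float = 1.2
    damping: float = 0.6
    baseline: float = 0.2
    amplitude: float = 1.0
    rise_rate: float = 0.25     # per hour, rising kind
    plateau: float = 2.0        # asymptotic increase above baseline, rising kind

    def __post_init__(self) -> None:
        if self.kind not in CONDITIONS:
            raise ValueError(f"kind must be one of {CONDITIONS}")
        if self.period <= 0:
            raise ValueError("non-positive period")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must lie in (0, 1]")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")


OSC_P53_SPEC = P53WaveformSpec(kind=OSCILLATORY)
RISING_P53_SPEC = P53WaveformSpec(kind=RISING)


def p53_waveform(spec: P53WaveformSpec, times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, float)
    if spec.kind == OSCILLATORY:
        levels = np.full_like(t, spec.baseline)
        k = 0
        while True:
            center = spec.first_peak_time + k * spec.period
            if center > t.max() + 4 * spec.pulse_width:
                break
            amp = spec.amplitude * spec.damping ** k
            levels = levels + amp * np.exp(-((t - center) ** 2) / (2 * spec.pulse_width ** 2))
            k += 1
        return levels
    return spec.baseline + spec.plateau * (1.0 - np.exp(-spec.rise_rate * t))


def gen_p53(spec: P53WaveformSpec, grid: TimeGrid) -> TimeCourse:
    """Evaluate a p53 input waveform on a sampling grid."""
    if len(grid) == 0:
        raise ValueError("empty grid")
    levels = p53_waveform(spec, grid.array)
    return TimeCourse("p53", spec.kind, 1, grid, levels)


def hourly_p53(spec: P53WaveformSpec, tmax: float = 24.0, step: float = 1.0) -> TimeCourse:
    times = hourly_times(tmax, step)
    return TimeCourse("p53", spec.kind, 1, TimeGrid(tuple(times)),
                      p53_waveform(spec, times))


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal observation noise with unit mean."""

    cv: float = 0.1

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("negative cv")

    def apply(self, levels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return np.asarray(levels, float).copy()
        sigma = math.sqrt(math.log(1.0 + self.cv ** 2))
        factors = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=np.shape(levels))
        return np.asarray(levels, float) * factors


@dataclass
class MechanismSpec:
    """A gene's decoding mechanism plus its kinetic and motif parameters."""

    mechanism: str
    kinetics: KineticParams = field(default_factory=KineticParams)
    threshold: ThresholdSpec | None = None
    ffl: FFLSpec | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "threshold" and self.threshold is None:
            raise ValueError("threshold mechanism requires a ThresholdSpec")
        if self.mechanism.startswith("cffl"):
            if self.ffl is None or self.ffl.topology != "coherent":
                raise ValueError("cFFL mechanism requires a coherent FFLSpec")
            want = "transcriptional" if self.mechanism.endswith("transcriptional") and \
                not self.mechanism.endswith("posttranscriptional") else "posttranscriptional"
            if self.ffl.level != want:
                raise ValueError(f"FFLSpec.level must be {want!r} for {self.mechanism}")
        if self.mechanism == "iffl" and (self.ffl is None or self.ffl.topology != "incoherent"):
            raise ValueError("iFFL mechanism requires an incoherent FFLSpec")


def simulate_clean(mech: MechanismSpec, p53: TimeCourse, step: float = 1.0) -> MotifTraces:
    """Noiseless hourly mRNA/protein traces for one mechanism and input."""
    k = mech.kinetics
    if mech.mechanism == "simple":
        mrna = simulate_mrna(p53, k.kp_mrna, k.kd_mrna, step=step)
        prot = simulate_protein(mrna, k.kp_prot, k.kd_prot, tdel=k.tdel, step=step)
        return MotifTraces(y=None, mrna=mrna, protein=prot)
    if mech.mechanism == "threshold":
        return simulate_threshold(p53, mech.threshold, k, step=step)
    if mech.mechanism in ("cffl_transcriptional", "cffl_posttranscriptional"):
        return simulate_cffl(p53, mech.ffl, k, step=step)
    return simulate_iffl(p53, mech.ffl, k, step=step)


def simulate_gene(
    mech: MechanismSpec,
    p53_osc: TimeCourse,
    p53_rise: TimeCourse,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 2,
    rng: np.random.Generator | None = None,
    gene_id: str = "gene",
    grid: TimeGrid | None = None,
) -> GeneRecord:
    """Simulate one gene under both p53 regimes with replicate noise.

    The clean trajectories come from the kinetic/motif simulators; each
    replicate observation is the clean level at the sampling grid times a
    multiplicative log-normal factor, independent across replicates and
    time points.  Ground-truth mechanism and parameters are stored.
    """
    if p53_osc.grid.times != p53_rise.grid.times:
        raise ValueError("p53 inputs must share one grid")
    if rng is None:
        rng = np.random.default_rng(0)
    grid = grid or TimeGrid()
    record = GeneRecord(gene_id=gene_id, mechanism=mech.mechanism,
                        params={"kinetics": mech.kinetics})
    for condition, p53 in ((OSCILLATORY, p53_osc), (RISING, p53_rise)):
        traces = simulate_clean(mech, p53)
        for modality, tc in (("mRNA", traces.mrna), ("protein", traces.protein)):
            clean = sample_at(tc, grid)
            for rep in range(1, n_replicates + 1):
                obs = TimeCourse(gene_id, condition, rep, grid,
                                 noise.apply(clean.levels, rng))
                record.courses(modality)[(condition, rep)] = obs
    return record


# --- archetype parameterizations -------------------------------------------
# Motif constants are stated in the input's relative units and were chosen by
# forward simulation of the default waveforms so that each mechanism expresses
# its designed qualitative behavior (see docs/methods.md).

#: Y wiring shared by the feed-forward archetypes: Y production engages only
#: while p53 exceeds the oscillatory peak (x_half above the pulse maximum),
#: so pulses leave Y low while the rising regime accumulates it.
_SLOW_Y = dict(y_production=0.5, y_degradation=0.05, y_delay=0.5,
               x_half=1.4, x_hill_n=8.0)
_FAST_Y = dict(y_production=3.0, y_degradation=0.6, y_delay=0.0,
               x_half=1.25, x_hill_n=8.0)


def archetype(letter: str) -> MechanismSpec:
    """Documented parameter set whose noiseless record maps to the category."""
    if letter == "a":   # oscillatory mRNA and protein: fast turnover of both
        return MechanismSpec("simple", KineticParams(1, 0.9, 1, 0.9, 0.5))
    if letter == "b":   # oscillatory mRNA, stable protein accumulates
        return MechanismSpec("simple", KineticParams(1, 0.9, 1, 0.2, 0.5))
    if letter == "e":   # slow mRNA turnover smooths the input; protein rises
        return MechanismSpec("simple", KineticParams(1, 0.3, 1, 0.45, 0.5))
    if letter == "d":   # post-transcriptional cFFL: persistence-gated translation
        return MechanismSpec(
            "cffl_posttranscriptional", KineticParams(1, 0.9, 1, 0.5, 0.0),
            ffl=FFLSpec(topology="coherent", level="posttranscriptional",
                        y_threshold=1.6, y_hill_n=24.0, **_SLOW_Y))
    if letter == "j":   # transcriptional cFFL: persistence-gated transcription
        return MechanismSpec(
            "cffl_transcriptional", KineticParams(1, 0.5, 1, 0.5, 0.0),
            ffl=FFLSpec(topology="coherent", level="transcriptional",
                        y_threshold=1.0, y_hill_n=8.0, **_SLOW_Y))
    if letter == "h":   # iFFL: sustained input accumulates the repressor
        return MechanismSpec(
            "iffl", KineticParams(1, 0.9, 1, 0.7, 2.0),
            ffl=FFLSpec(topology="incoherent", y_threshold=1.5, y_hill_n=8.0,
                        repression=150.0, **_FAST_Y))
    if letter == "g":   # medium translational threshold: rising-only protein
        return MechanismSpec(
            "threshold", KineticParams(1, 0.25, 1, 0.5, 0.0),
            threshold=ThresholdSpec(theta=_THETA_MEDIUM, hill_n=8.0,
                                    level="translational"))
    if letter == "k":   # high translational threshold: protein never induced
        return MechanismSpec(
            "threshold", KineticParams(1, 0.25, 1, 0.5, 0.0),
            threshold=ThresholdSpec(theta=_THETA_HIGH, hill_n=8.0,
                                    level="translational"))
    raise KeyError(f"no archetype for category {letter!r}")


def _mrna_scale_bounds() -> tuple[float, float]:
    """Max mRNA level (0-9 h) of the slow-turnover gene under each regime."""
    osc = simulate_mrna(hourly_p53(OSC_P53_SPEC), 1.0, 0.25)
    rise = simulate_mrna(hourly_p53(RISING_P53_SPEC), 1.0, 0.25)
    mask = osc.grid.window_mask(0, 9)
    return float(osc.levels[mask].max()), float(rise.levels[mask].max())


_OSC_MAX, _RISE_MAX = _mrna_scale_bounds()
#: medium threshold sits between the regimes' mRNA maxima; high sits above both
_THETA_MEDIUM = 0.5 * (_OSC_MAX + _RISE_MAX)
_THETA_HIGH = 2.0 * _RISE_MAX

ARCHETYPE_LETTERS = ("a", "b", "e", "d", "j", "h", "g", "k")


def load_motif_preset(name: str) -> MechanismSpec:
    """Load a named motif preset from the shipped presets file.

    Threshold presets may state theta symbolically ("medium"/"high"), which
    resolves against the default waveforms' mRNA level bounds.
    """
    import yaml
    from importlib import resources

    with resources.files("p53decode.data").joinpath("motif_presets.yaml").open() as fh:
        presets = yaml.safe_load(fh)["presets"]
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    entry = presets[name]
    kinetics = KineticParams(**entry["kinetics"])
    threshold = None
    ffl = None
    if "threshold" in entry:
        t = dict(entry["threshold"])
        theta = t.pop("theta")
        if theta == "medium":
            theta = _THETA_MEDIUM
        elif theta == "high":
            theta = _THETA_HIGH
        threshold = ThresholdSpec(theta=float(theta), **t)
    if "ffl" in entry:
        ffl = FFLSpec(**entry["ffl"])
    return MechanismSpec(entry["mechanism"], kinetics, threshold=threshold, ffl=ffl)


MOTIF_PRESET_NAMES = ("SESN1-like", "RAD51C-like", "HSPG2-like",
                      "HOXC13-like", "FDXR-like", "BAX-like")


def _draw_mechanism_spec(mechanism: str, rng: np.random.Generator) -> MechanismSpec:
    """Cohort draw: jitter the relevant archetype within documented ranges."""
    jit = lambda v, lo=0.9, hi=1.1: float(v * rng.uniform(lo, hi))
    if mechanism == "simple":
        letter = rng.choice(["a", "b", "e"], p=[0.4, 0.3, 0.3])
        base = archetype(letter)
        k = base.kinetics
        kin = KineticParams(jit(k.kp_mrna, 0.5, 2.0),
                            float(np.clip(jit(k.kd_mrna), 0.02, 0.98)),
                            jit(k.kp_prot, 0.5, 2.0),
                            float(np.clip(jit(k.kd_prot), 0.02, 0.98)),
                            k.tdel)
        return MechanismSpec("simple", kin)
    if mechanism == "threshold":
        letter = rng.choice(["g", "k"])
        base = archetype(letter)
        return replace(base, threshold=replace(base.threshold,
                                               theta=jit(base.threshold.theta, 0.95, 1.05)))
    letter = {"cffl_transcriptional": "j",
              "cffl_posttranscriptional": "d", "iffl": "h"}[mechanism]
    base = archetype(letter)
    kin = base.kinetics
    jkin = KineticParams(jit(kin.kp_mrna), kin.kd_mrna, jit(kin.kp_prot),
                         kin.kd_prot, kin.tdel)
    return replace(base, kinetics=jkin)


def gen_cohort(
    n_genes: int,
    mechanism_mix: dict[str, float] | None = None,
    seed: int = 0,
    cv: float = 0.1,
    n_replicates: int = 2,
    grid: TimeGrid | None = None,
) -> list[GeneRecord]:
    """Generate a mechanism-labeled cohort; deterministic given the seed."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    mix = dict(mechanism_mix or DEFAULT_MECHANISM_MIX)
    unknown = set(mix) - set(MECHANISMS)
    if unknown:
        raise ValueError(f"unknown mechanisms in mix: {sorted(unknown)}")
    names = sorted(mix)
    probs = np.array([mix[m] for m in names], float)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(f"mechanism mix sums to {probs.sum()}, not 1")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    grid = grid or TimeGrid()
    p53_osc = hourly_p53(OSC_P53_SPEC)
    p53_rise = hourly_p53(RISING_P53_SPEC)
    noise = NoiseModel(cv=cv)
    width = len(str(n_genes))
    cohort = []
    for i in range(n_genes):
        mechanism = str(rng.choice(names, p=probs))
        mech = _draw_mechanism_spec(mechanism, rng)
        gene_id = f"G{i:0{width}d}"
        cohort.append(simulate_gene(mech, p53_osc, p53_rise, noise,
                                    n_replicates, rng, gene_id, grid))
    return cohort


def gen_recovery_cohort(
    n_genes: int = 200,
    seed: int = 0,
    cv: float = 0.05,
    kd_range: tuple[float, float] = (0.05, 0.95),
    n_replicates: int = 2,
    grid: TimeGrid | None = None,
) -> list[GeneRecord]:
    """Simple-regulation genes with degradation rates spanning ``kd_range``.

    Used for parameter-recovery evaluation: both degradation constants are
    drawn uniformly over the range and the delay from {0, 0.5, ..., 2} h.
    """
    rng = np.random.default_rng(seed)
    grid = grid or TimeGrid()
    p53_osc = hourly_p53(OSC_P53_SPEC)
    p53_rise = hourly_p53(RISING_P53_SPEC)
    noise = NoiseModel(cv=cv)
    width = len(str(n_genes))
    cohort = []
    for i in range(n_genes):
        kin = KineticParams(
            kp_mrna=float(rng.uniform(0.5, 2.0)),
            kd_mrna=float(rng.uniform(*kd_range)),
            kp_prot=float(rng.uniform(0.5, 2.0)),
            kd_prot=float(rng.uniform(*kd_range)),
            tdel=float(rng.choice(np.arange(0.0, 2.01, 0.5))),
        )
        mech = MechanismSpec("simple", kin)
        cohort.append(simulate_gene(mech, p53_osc, p53_rise, noise,
                                    n_replicates, rng, f"R{i:0{width}d}", grid))
    return cohort


def write_cohort(cohort: list[GeneRecord], outdir: str | Path) -> dict[str, Path]:
    """Write mRNA/protein tables plus the ground-truth sidecar table."""
    from .expression_io import ExpressionTable

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for modality, fname in (("mRNA", "mrna.csv"), ("protein", "protein.csv")):
        table = ExpressionTable(modality=modality)
        for rec in cohort:
            for tc in rec.courses(modality).values():
                table.add(tc)
        path = outdir / fname
        table.write(path)
        paths[modality] = path
    truth = pd.DataFrame([
        {
            "gene_id": rec.gene_id,
            "mechanism": rec.mechanism,
            "kp_mrna": rec.params["kinetics"].kp_mrna,
            "kd_mrna": rec.params["kinetics"].kd_mrna,
            "kp_prot": rec.params["kinetics"].kp_prot,
            "kd_prot": rec.params["kinetics"].kd_prot,
            "tdel": rec.params["kinetics"].tdel,
        }
        for rec in cohort
    ])
    truth_path = outdir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    return paths


def gen_annotation(cohort: list[GeneRecord], seed: int = 0,
                   frac_antiproliferative: float = 0.3) -> dict[str, str]:
    """Synthetic functional-class annotation (antiproliferative vs other)."""
    rng = np.random.default_rng(seed)
    return {rec.gene_id: ("antiproliferative" if rng.random() < frac_antiproliferative
                          else "other")
            for rec in cohort}
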