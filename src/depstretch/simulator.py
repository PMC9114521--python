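"""Synthetic device and controller simulator.

Stands in for the physical chip: stochastic single-cell capture at each
port, saturating stretch responses imaged at fixed frame rate, and the
three-state (capture -> stretch -> release) threshold-triggered
controller, so the whole analysis pipeline is testable without hardware.

What it emulates
----------------
* Per-port capture as independent categorical draws (none / single /
  multiple) keyed by the narrow-mouth size; the 6 μm mouth defaults to a
  single-capture probability of 0.842, matching bead characterisation of
  the chip.
* Cell populations with lognormal true strain (mean and CV configurable),
  lognormal resting length, a small broken-cell probability, and a
  first-order (saturating-exponential) stretch response with time
  constant tau:   L(t) = L0 (1 + eps_true (1 - exp(-t/tau))) + noise.
* The controller: capture rounds until the single-cell count reaches a
  threshold, a stretch phase of exactly the configured duration sampled
  at the frame rate, and a release phase emptying the ports with a
  configurable efficiency.

The min/max strain estimator applied to noisy traces is positively
biased (extremes of noisy samples); the default noise level (0.02 μm,
sub-pixel detector jitter) keeps that bias small — quantified in the
package's methods note and in the recovery report this module computes.

All randomness flows through one ``numpy.random.Generator`` per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mechanics import (
    LengthTrace,
    analyze_traces,
    calibrate_stress,
)

__all__ = [
    "CaptureModel",
    "PopulationModel",
    "ControllerConfig",
    "Cell",
    "CycleRecord",
    "EventLog",
    "simulate_capture",
    "sample_cells",
    "simulate_stretch_trace",
    "run_cycles",
    "end_to_end_recovery",
    "RecoveryReport",
]

EMPTY, SINGLE, MULTIPLE = 0, 1, 2


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class CaptureModel:
    """Per-port, per-round occupancy probabilities keyed by mouth size (μm).

    Each value is (p_none, p_single, p_multiple), summing to 1.  The 6 μm
    narrow mouth — the size selected for the device — defaults to
    p_single = 0.842.
    """

    probs: dict = field(
        default_factory=lambda: {6.0: (0.10, 0.842, 0.058)}
    )

    def __post_init__(self) -> None:
        for key, p in self.probs.items():
            p = tuple(p)
            if len(p) != 3 or any(not 0 <= x <= 1 for x in p):
                raise ValueError(f"probabilities for mouth {key} must be in [0,1]")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"probabilities for mouth {key} must sum to 1")

    def for_mouth(self, mouth: float) -> tuple[float, float, float]:
        try:
            return tuple(self.probs[mouth])
        except KeyError:
            raise ValueError(
                f"no capture probabilities for mouth size {mouth} μm "
                f"(known: {sorted(self.probs)})"
            ) from None


@dataclass(frozen=True)
class PopulationModel:
    """Generative model of one cell population.

    ``mean_strain`` / ``cv_strain`` parameterise a lognormal true-strain
    distribution; ``length_mean_um`` / ``cv_length`` the resting length;
    ``noise_sd_um`` the per-frame detection noise; ``p_broken`` the chance
    a cell lyses in the trap; ``tau_s`` the first-order response time.
    """

    label: str = "normal"
    mean_strain: float = 0.0864
    cv_strain: float = 0.6
    length_mean_um: float = 15.0
    cv_length: float = 0.10
    noise_sd_um: float = 0.02
    p_broken: float = 0.02
    tau_s: float = 2.0

    def __post_init__(self) -> None:
        if not (self.mean_strain > 0 and self.length_mean_um > 0):
            raise ValueError("mean strain and mean length must be > 0")
        if self.cv_strain < 0 or self.cv_length < 0 or self.noise_sd_um < 0:
            raise ValueError("spread parameters must be >= 0")
        if not 0 <= self.p_broken <= 1:
            raise ValueError("p_broken must be a probability")
        if self.tau_s < 0:
            raise ValueError("tau_s must be >= 0")


@dataclass(frozen=True)
class ControllerConfig:
    """Operating point of the three-state controller.

    Defaults are the device's working settings: capture at 3 μL/h until
    ``capture_count_threshold`` singles are trapped, stretch 10 s at
    10 Vp-p / 12 MHz sampled at 50 fps, release at 150 μL/min.
    """

    capture_count_threshold: int = 10
    stretch_duration_s: float = 10.0
    voltage_vpp: float = 10.0
    frequency_hz: float = 12e6
    capture_flow_ul_h: float = 3.0
    release_flow_ul_min: float = 150.0
    frame_rate_fps: float = 50.0
    release_count_target: int = 0
    release_efficiency: float = 1.0
    max_capture_attempts: int = 25
    attempt_period_s: float = 6.0
    release_duration_s: float = 5.0

    def __post_init__(self) -> None:
        positive = (
            "capture_count_threshold", "stretch_duration_s", "voltage_vpp",
            "frequency_hz", "capture_flow_ul_h", "release_flow_ul_min",
            "frame_rate_fps", "max_capture_attempts", "attempt_period_s",
            "release_duration_s",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.release_count_target < 0:
            raise ValueError("release_count_target must be >= 0")
        if not 0 <= self.release_efficiency <= 1:
            raise ValueError("release_efficiency must be a probability")


@dataclass(frozen=True)
class Cell:
    """A sampled cell: true strain, resting length and broken flag."""

    cell_id: str
    true_strain: float
    length_um: float
    broken: bool


def simulate_capture(
    model: CaptureModel,
    n_ports: int,
    rng,
    mouth: float = 6.0,
) -> np.ndarray:
    """One capture round: independent occupancy draw per port.

    Returns an int array of length ``n_ports`` with values 0 (empty),
    1 (single cell) or 2 (multiple cells).  Reproducible for a fixed
    seed/generator.
    """
    if n_ports < 1:
        raise ValueError("n_ports must be >= 1")
    p = model.for_mouth(mouth)
    return _rng(rng).choice(3, size=n_ports, p=p)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with given mean and coefficient of
    variation; degenerate (sigma=0) when cv=0."""
    s2 = np.log1p(cv**2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def sample_cells(
    model: PopulationModel, n: int, rng, id_prefix: str = ""
) -> list[Cell]:
    """Draw ``n`` i.i.d. cells from a population model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = _rng(rng)
    mu_s, sd_s = _lognormal_params(model.mean_strain, model.cv_strain)
    mu_l, sd_l = _lognormal_params(model.length_mean_um, model.cv_length)
    strains = gen.lognormal(mu_s, sd_s, size=n) if sd_s > 0 else np.full(n, model.mean_strain)
    lengths = gen.lognormal(mu_l, sd_l, size=n) if sd_l > 0 else np.full(n, model.length_mean_um)
    broken = gen.random(n) < model.p_broken
    prefix = id_prefix or model.label
    return [
        Cell(f"{prefix}_{i:06d}", float(strains[i]), float(lengths[i]), bool(broken[i]))
        for i in range(n)
    ]


#: Fractional length collapse of a broken cell's trace.
BROKEN_COLLAPSE = 0.7
#: Collapse time constant of a broken cell, s.
BROKEN_TAU_S = 1.0


def simulate_stretch_trace(
    cell: Cell,
    config: ControllerConfig,
    rng,
    population: PopulationModel | None = None,
    group: str | None = None,
    batch_id: str | None = None,
) -> LengthTrace:
    """Length trace of one cell over a stretch phase.

    Samples ``frame_rate * duration + 1`` frames.  Intact cells follow the
    saturating first-order response
    ``L0 (1 + eps (1 - exp(-t/tau)))`` plus Gaussian detection noise;
    broken cells emit a collapsing trace instead (length falls to
    ``1 - BROKEN_COLLAPSE`` of resting), which downstream QC flags.
    """
    gen = _rng(rng)
    pop = population or PopulationModel()
    n_frames = int(round(config.stretch_duration_s * config.frame_rate_fps)) + 1
    t = np.arange(n_frames) / config.frame_rate_fps
    if cell.broken:
        rise = -BROKEN_COLLAPSE * (1.0 - np.exp(-t / BROKEN_TAU_S))
    elif pop.tau_s == 0:
        # instantaneous response: resting length at t=0, full stretch after
        rise = np.full_like(t, cell.true_strain)
        rise[0] = 0.0
    else:
        rise = cell.true_strain * (1.0 - np.exp(-t / pop.tau_s))
    lengths = cell.length_um * (1.0 + rise)
    if pop.noise_sd_um > 0:
        lengths = lengths + gen.normal(0.0, pop.noise_sd_um, size=n_frames)
    return LengthTrace(
        cell_id=cell.cell_id, times=t, lengths=lengths,
        group=group or pop.label, batch_id=batch_id,
    )


@dataclass
class CycleRecord:
    """One capture–stretch–release cycle of the controller."""

    index: int
    t_capture: float
    t_stretch: float
    t_release: float
    t_end: float
    n_attempts: int
    occupancy: np.ndarray
    n_single: int
    n_multiple: int
    n_empty: int
    traces: list[LengthTrace]
    n_released: int
    occupancy_end: np.ndarray

    def state_times(self) -> list[tuple[float, str]]:
        return [
            (self.t_capture, "capture"),
            (self.t_stretch, "stretch"),
            (self.t_release, "release"),
        ]

    def to_json_dict(self) -> dict:
        return {
            "cycle": self.index,
            "t_capture": self.t_capture,
            "t_stretch": self.t_stretch,
            "t_release": self.t_release,
            "t_end": self.t_end,
            "n_attempts": self.n_attempts,
            "occupancy": self.occupancy.tolist(),
            "n_single": self.n_single,
            "n_multiple": self.n_multiple,
            "n_empty": self.n_empty,
            "n_traces": len(self.traces),
            "n_released": self.n_released,
            "occupancy_end": self.occupancy_end.tolist(),
        }


@dataclass
class EventLog:
    """Append-only record of a simulated run."""

    seed: int | None
    controller: ControllerConfig
    n_ports: int
    cycles: list[CycleRecord] = field(default_factory=list)

    @property
    def traces(self) -> list[LengthTrace]:
        return [tr for c in self.cycles for tr in c.traces]

    @property
    def events(self) -> list[tuple[float, str]]:
        return [ev for c in self.cycles for ev in c.state_times()]

    @property
    def n_measured(self) -> int:
        return sum(c.n_single for c in self.cycles)

    def throughput_cells_per_min(self) -> float:
        if not self.cycles:
            return 0.0
        total_t = self.cycles[-1].t_end
        return 60.0 * self.n_measured / total_t if total_t > 0 else 0.0


def run_cycles(
    controller: ControllerConfig,
    capture_model: CaptureModel,
    population: PopulationModel,
    n_cycles: int,
    rng,
    n_ports: int = 20,
    mouth: float = 6.0,
) -> EventLog:
    """Simulate ``n_cycles`` capture–stretch–release cycles.

    Per cycle: capture rounds over the still-empty ports until the number
    of single-occupied ports reaches the threshold (or the attempt cap),
    a stretch phase emitting one trace per single-occupied port (broken
    cells emit collapsing traces; multiple-occupancy ports are counted
    but not measured), then a release phase clearing each occupied port
    with probability ``release_efficiency``.  Un-released cells stay in
    place and are not re-measured.
    """
    if controller.capture_count_threshold > n_ports:
        raise ValueError(
            f"capture threshold {controller.capture_count_threshold} exceeds "
            f"{n_ports} ports; unreachable"
        )
    gen = _rng(rng)
    seed = rng if isinstance(rng, (int, np.integer)) else None
    log = EventLog(seed=seed, controller=controller, n_ports=n_ports)
    occupancy = np.zeros(n_ports, dtype=int)
    stale = np.zeros(n_ports, dtype=bool)  # left over from earlier cycles
    t = 0.0
    for ci in range(n_cycles):
        t_capture = t
        fresh_single = 0
        attempts = 0
        while attempts < controller.max_capture_attempts:
            attempts += 1
            empty = occupancy == EMPTY
            if empty.any():
                draw = simulate_capture(capture_model, int(empty.sum()), gen, mouth)
                occupancy[empty] = draw
            fresh_single = int(np.sum((occupancy == SINGLE) & ~stale))
            if fresh_single >= controller.capture_count_threshold:
                break
        t_stretch = t_capture + attempts * controller.attempt_period_s
        measured_ports = np.flatnonzero((occupancy == SINGLE) & ~stale)
        cells = sample_cells(
            population, max(len(measured_ports), 1), gen,
            id_prefix=f"{population.label}_c{ci:04d}",
        )[: len(measured_ports)]
        traces = [
            simulate_stretch_trace(
                cell, controller, gen, population=population,
                group=population.label, batch_id=f"cycle{ci:04d}",
            )
            for cell in cells
        ]
        t_release = t_stretch + controller.stretch_duration_s
        occ_after_capture = occupancy.copy()
        n_multiple = int(np.sum(occ_after_capture == MULTIPLE))
        n_empty = int(np.sum(occ_after_capture == EMPTY))
        occupied = occupancy != EMPTY
        release_draw = gen.random(n_ports) < controller.release_efficiency
        released = occupied & release_draw
        occupancy[released] = EMPTY
        stale[released] = False
        stale[occupancy != EMPTY] = True
        t_end = t_release + controller.release_duration_s
        log.cycles.append(
            CycleRecord(
                index=ci,
                t_capture=t_capture,
                t_stretch=t_stretch,
                t_release=t_release,
                t_end=t_end,
                n_attempts=attempts,
                occupancy=occ_after_capture,
                n_single=len(measured_ports),
                n_multiple=n_multiple,
                n_empty=n_empty,
                traces=traces,
                n_released=int(released.sum()),
                occupancy_end=occupancy.copy(),
            )
        )
        t = t_end
    return log


@dataclass(frozen=True)
class GroupRecovery:
    """Recovered vs. true summary for one simulated group."""

    label: str
    n_sampled: int
    n_valid: int
    true_mean_strain: float
    recovered_mean_strain: float
    strain_se: float
    true_modulus_pa: float
    recovered_modulus_pa: float

    @property
    def strain_rel_error(self) -> float:
        return (
            self.recovered_mean_strain - self.true_mean_strain
        ) / self.true_mean_strain


@dataclass(frozen=True)
class RecoveryReport:
    """End-to-end parameter-recovery harness output."""

    groups: tuple[GroupRecovery, ...]
    stress_pa: float

    @property
    def mean_strain_delta(self) -> float:
        return (
            self.groups[1].recovered_mean_strain
            - self.groups[0].recovered_mean_strain
        )


def end_to_end_recovery(
    model_a: PopulationModel,
    model_b: PopulationModel,
    n_per_group: int,
    seed,
    controller: ControllerConfig | None = None,
    calibration: tuple[float, float] = (203.7, 0.0864),
) -> RecoveryReport:
    """Generate two groups, run the full analysis, compare to truth.

    For each group: sample ``n_per_group`` cells, simulate their stretch
    traces, run the strain pipeline with QC, and report the recovered
    mean strain (with its Monte-Carlo standard error) against the
    generator's true mean, plus group moduli E = sigma / mean-strain at
    the calibrated stress.
    """
    controller = controller or ControllerConfig()
    gen = _rng(seed)
    stress = calibrate_stress(*calibration)
    groups = []
    for model in (model_a, model_b):
        cells = sample_cells(model, n_per_group, gen)
        traces = [
            simulate_stretch_trace(c, controller, gen, population=model)
            for c in cells
        ]
        df = analyze_traces(traces, stress=stress)
        ok = df[df.qc_flag == "ok"]
        rec_mean = float(ok.strain.mean())
        se = float(ok.strain.std(ddof=1) / np.sqrt(len(ok)))
        groups.append(
            GroupRecovery(
                label=model.label,
                n_sampled=n_per_group,
                n_valid=int(len(ok)),
                true_mean_strain=model.mean_strain,
                recovered_mean_strain=rec_mean,
                strain_se=se,
                true_modulus_pa=stress / model.mean_strain,
                recovered_modulus_pa=stress / rec_mean,
            )
        )
    return RecoveryReport(groups=tuple(groups), stress_pa=stress)
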