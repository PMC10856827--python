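"""Synthetic running cohorts with a known hierarchical variance structure.

Emulates a repeated-measures IMU running study: each participant runs on
``n_days`` separate days on each of several surfaces, two runs per day enter
the analysis, and every run is processed twice against two different
sensor-to-segment calibration trials.  Joint-angle channels are a fixed
periodic template waveform per signal, shifted by additive offsets drawn once
per runner, per day, per run, per calibration and per stride.  Because a pure
offset shifts the whole waveform, every discrete feature extracted downstream
inherits the offsets unchanged, and the intraclass correlation of any feature
is known analytically from the variance components:

    ICC = sigma2_runner / (sigma2_runner + sigma2_error)

where ``sigma2_error`` sums the component variances that differ between the
two compared measurements (day, run and calibration draws for a between-day
pair; the run draw for a within-day pair; the calibration draw for a
calibration pair; plus ``sigma2_stride / n`` for every comparison in which the
two measurements average independent stride noise over ``n`` cycles).

The right-foot anterior-posterior position channel is a per-stride cosine
whose maxima fall exactly on the true cycle-boundary samples, so downstream
peak-picking can be verified against the generator's ground truth at sample
resolution.  The two calibration copies of one run share all stride data and
differ only by the calibration offset, mirroring reprocessing of the same
recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as _features
from .io import SessionRecording

COMPARISON_TYPES = ("between_day", "within_day", "calibration")


@dataclass(frozen=True)
class LevelVariances:
    """Variance components (deg^2) of the additive offsets for one signal."""

    runner: float = 0.0
    day: float = 0.0
    run: float = 0.0
    calibration: float = 0.0
    stride: float = 0.0

    def __post_init__(self) -> None:
        for name in ("runner", "day", "run", "calibration", "stride"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance component {name!r} must be >= 0")


@dataclass(frozen=True)
class Bump:
    """Raised-cosine bump, exactly zero outside (center - width/2, center + width/2)."""

    amplitude: float
    center: float
    width: float


@dataclass(frozen=True)
class WaveformTemplate:
    """Periodic template: baseline plus raised-cosine bumps over cycle phase [0, 1)."""

    baseline: float
    bumps: tuple[Bump, ...] = ()

    def __call__(self, phase: np.ndarray) -> np.ndarray:
        phase = np.asarray(phase, dtype=float) % 1.0
        out = np.full_like(phase, self.baseline)
        for b in self.bumps:
            d = phase - b.center
            inside = np.abs(d) < b.width / 2.0
            out = out + np.where(
                inside, b.amplitude * np.cos(np.pi * d / b.width) ** 2, 0.0
            )
        return out


# Template shapes cover plausible running ranges; baselines and in-stance bump
# peaks are placed so that the nine discrete features take realistic values
# (initial knee flexion ~7.5 deg, peak knee flexion ~42.5 deg, peak hip
# adduction ~-9.4 deg, peak ankle eversion ~11.8 deg, ...).  The exact shape is
# irrelevant to the reliability arithmetic, which depends on offsets only.
DEFAULT_TEMPLATES: dict[str, WaveformTemplate] = {
    "hip_flexion": WaveformTemplate(34.77, (Bump(-40.0, 0.525, 0.85),)),
    "hip_abduction": WaveformTemplate(-0.15, (Bump(-9.27, 0.20, 0.40), Bump(9.30, 0.70, 0.45))),
    "knee_flexion": WaveformTemplate(7.53, (Bump(35.0, 0.20, 0.40), Bump(72.0, 0.70, 0.45))),
    "ankle_dorsiflexion": WaveformTemplate(
        6.83, (Bump(14.85, 0.15, 0.30), Bump(-27.0, 0.45, 0.25), Bump(8.0, 0.80, 0.30))
    ),
    "ankle_eversion": WaveformTemplate(-7.47, (Bump(19.30, 0.25, 0.50),)),
}

# Illustrative defaults: per-signal components sized so that between-day error
# variance is roughly four times the within-day error variance (between-day
# absolute differences about twice the within-day ones) and the implied ICCs
# fall in the ranges reported for IMU-based running kinematics.
DEFAULT_VARIANCES: dict[str, LevelVariances] = {
    "hip_flexion": LevelVariances(16.0, 1.2, 0.4, 0.3, 4.0),
    "hip_abduction": LevelVariances(6.0, 1.8, 0.5, 0.45, 3.0),
    "knee_flexion": LevelVariances(20.0, 1.0, 0.5, 0.1, 4.0),
    "ankle_dorsiflexion": LevelVariances(8.0, 2.5, 0.5, 0.8, 4.0),
    "ankle_eversion": LevelVariances(6.0, 3.0, 0.6, 1.0, 4.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study design, variance structure and signal parameters of one cohort.

    Defaults reproduce the emulated protocol: 17 runners x 5 days x 2 surfaces
    x 2 analyzed runs (protocol labels 1 and 3) x 2 calibrations, 48 strides
    per run (46 detectable cycles, ~40 after the default transient trim),
    240 Hz sampling, self-selected speed ~3.47 m/s measured by timing gates
    with 0.05 m/s gate noise, and stride frequency ~1.40 Hz.
    """

    n_participants: int = 17
    n_days: int = 5
    surfaces: tuple[str, ...] = ("asphalt", "woodchip")
    runs: tuple[int, ...] = (1, 3)  # protocol labels of the analyzed runs
    calibrations: tuple[int, ...] = (1, 2)
    strides_per_run: int = 48
    sample_rate: float = 240.0
    variance_components: Mapping[str, LevelVariances] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCES)
    )
    templates: Mapping[str, WaveformTemplate] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )
    foot_ap_amplitude: float = 0.4  # m, AP excursion of the foot relative to the pelvis
    speed_mean: float = 3.47  # m/s, between-runner mean self-selected speed
    speed_sd: float = 0.30  # m/s, between-runner SD of true speed
    gate_noise_sd: float = 0.05  # m/s, timing-gate measurement noise per run
    stride_freq_mean: float = 1.40  # Hz
    stride_freq_sd: float = 0.10  # Hz, between-runner SD
    stride_freq_within_sd: float = 0.035  # Hz, run-to-run SD within a runner
    period_jitter_frac: float = 0.0  # per-stride period jitter, fraction of the period
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ValueError("counts must be >= 1")
        if not self.surfaces or not self.runs or not self.calibrations:
            raise ValueError("need at least one surface, run and calibration")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if min(self.period_jitter_frac, self.gate_noise_sd, self.stride_freq_within_sd) < 0:
            raise ValueError("noise magnitudes must be >= 0")
        for sig in self.variance_components:
            if sig not in self.templates:
                raise ValueError(f"variance components given for unknown signal {sig!r}")

    @property
    def runs_per_day(self) -> int:
        return len(self.runs)

    @property
    def calibrations_per_day(self) -> int:
        return len(self.calibrations)

    @property
    def participant_ids(self) -> list[str]:
        width = max(2, len(str(self.n_participants)))
        return [f"P{i + 1:0{width}d}" for i in range(self.n_participants)]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort, for recovery checks downstream."""

    config: SimulationConfig
    participant_ids: list[str]
    stride_period_s: dict[str, float]  # per participant, rounded to sample resolution
    true_speed: dict[str, float]  # per participant, m/s
    boundaries: dict[tuple, np.ndarray]  # (pid, day, surface, run) -> boundary times, s
    level_offsets: dict[tuple, dict[str, float]]  # full record key -> signal -> offset
    stride_offsets: dict[tuple, dict[str, np.ndarray]]  # run key -> signal -> per-stride
    template_features: dict[str, float]  # variable -> feature value of the pure template

    def true_icc(self, variable: str, comparison_type: str, n_strides_averaged: int | None = None) -> float:
        return truth_icc(self, variable, comparison_type, n_strides_averaged)


def template_features(
    templates: Mapping[str, WaveformTemplate] | None = None,
    specs: Sequence[_features.VariableSpec] = _features.DEFAULT_SPECS,
) -> dict[str, float]:
    """Discrete feature values of the pure templates on the 101-point grid."""
    templates = dict(DEFAULT_TEMPLATES) if templates is None else templates
    grid = np.arange(101) / 100.0
    waves = {sig: tpl(grid) for sig, tpl in templates.items()}
    return {spec.name: _features.extract_value(waves[spec.signal], spec) for spec in specs}


def _draw_levels(config: SimulationConfig, rng: np.random.Generator):
    """Draw all runner/day/run/calibration-level quantities in documented order.

    Order: base stride frequencies, true speeds, then per signal (in the
    insertion order of ``config.variance_components``) the runner, day, run
    and calibration effect arrays.  Per-run draws (stride-frequency deviation,
    period jitter, stride offsets, gate noise) happen later, in nested
    participant -> surface -> day -> run order.
    """
    n, nd = config.n_participants, config.n_days
    ns, nr, nc = len(config.surfaces), len(config.runs), len(config.calibrations)
    sf = rng.normal(config.stride_freq_mean, config.stride_freq_sd, n)
    sf = np.clip(sf, 0.5, None)
    speed = rng.normal(config.speed_mean, config.speed_sd, n)
    effects: dict[str, dict[str, np.ndarray]] = {}
    for sig, v in config.variance_components.items():
        effects[sig] = {
            "runner": rng.normal(0.0, math.sqrt(v.runner), n),
            "day": rng.normal(0.0, math.sqrt(v.day), (n, ns, nd)),
            "run": rng.normal(0.0, math.sqrt(v.run), (n, ns, nd, nr)),
            "calibration": rng.normal(0.0, math.sqrt(v.calibration), (n, ns, nd, nc)),
        }
    return sf, speed, effects


def _run_period_samples(
    config: SimulationConfig, sf_base: float, rng: np.random.Generator
) -> int:
    """Integer-sample stride period of one run (base SF plus run-to-run deviation)."""
    sf_run = sf_base
    if config.stride_freq_within_sd > 0:
        sf_run = max(sf_base + rng.normal(0.0, config.stride_freq_within_sd), 0.5)
    return max(int(round(config.sample_rate / sf_run)), 2)


def generate_cohort(config: SimulationConfig) -> tuple[list[SessionRecording], SimulationTruth]:
    """Generate one full cohort of session recordings plus its ground truth.

    One recording per participant x day x surface x analyzed run x calibration
    copy.  Identical seeds give bit-identical cohorts.
    """
    if config.strides_per_run < 3:
        raise ValueError("strides_per_run must be >= 3 (cannot trim and average)")
    rng = np.random.default_rng(config.seed)
    pids = config.participant_ids
    sf_base, speed, effects = _draw_levels(config, rng)
    signals = list(config.variance_components)
    fs = config.sample_rate
    S = config.strides_per_run

    records: list[SessionRecording] = []
    truth = SimulationTruth(
        config=config,
        participant_ids=pids,
        # nominal period at zero run-to-run SF deviation, sample-resolution
        stride_period_s={
            pid: max(int(round(fs / sf_base[i])), 2) / fs for i, pid in enumerate(pids)
        },
        true_speed={pid: float(speed[i]) for i, pid in enumerate(pids)},
        boundaries={},
        level_offsets={},
        stride_offsets={},
        template_features=template_features(config.templates),
    )

    for ip, pid in enumerate(pids):
        for isurf, surface in enumerate(config.surfaces):
            for iday in range(config.n_days):
                day = iday + 1
                for irun, run in enumerate(config.runs):
                    base_period = _run_period_samples(config, sf_base[ip], rng)
                    if config.period_jitter_frac > 0:
                        jitter = rng.normal(0.0, config.period_jitter_frac, S)
                        periods = np.maximum(
                            np.round(base_period * (1.0 + jitter)).astype(int), 2
                        )
                    else:
                        periods = np.full(S, base_period, dtype=int)
                    bounds = np.concatenate(([0], np.cumsum(periods)))
                    n_samples = int(bounds[-1]) + 1
                    time = np.arange(n_samples) / fs
                    stride_idx = np.append(np.repeat(np.arange(S), periods), S - 1)
                    local = np.arange(n_samples) - bounds[stride_idx]
                    phase = local / periods[stride_idx]
                    ap = config.foot_ap_amplitude * np.cos(2.0 * np.pi * phase)

                    stride_off = {
                        sig: rng.normal(
                            0.0, math.sqrt(config.variance_components[sig].stride), S
                        )
                        for sig in signals
                    }
                    gate_noise = rng.normal(0.0, config.gate_noise_sd)
                    run_key = (pid, day, surface, run)
                    truth.boundaries[run_key] = bounds / fs
                    truth.stride_offsets[run_key] = stride_off

                    base_wave = {}
                    for sig in signals:
                        eff = effects[sig]
                        level = (
                            eff["runner"][ip]
                            + eff["day"][ip, isurf, iday]
                            + eff["run"][ip, isurf, iday, irun]
                        )
                        base_wave[sig] = (
                            config.templates[sig](phase) + level + stride_off[sig][stride_idx]
                        )

                    for ical, cal in enumerate(config.calibrations):
                        rec_signals = {"foot_ap_position": ap}
                        offsets = {}
                        for sig in signals:
                            eff = effects[sig]
                            cal_off = eff["calibration"][ip, isurf, iday, ical]
                            rec_signals[sig] = base_wave[sig] + cal_off
                            offsets[sig] = float(
                                eff["runner"][ip]
                                + eff["day"][ip, isurf, iday]
                                + eff["run"][ip, isurf, iday, irun]
                                + cal_off
                            )
                        truth.level_offsets[(pid, day, surface, run, cal)] = offsets
                        records.append(
                            SessionRecording(
                                participant_id=pid,
                                day=day,
                                surface=surface,
                                run=run,
                                calibration=cal,
                                sample_rate=fs,
                                time=time,
                                signals=rec_signals,
                                avg_speed=float(speed[ip] + gate_noise),
                            )
                        )
    return records, truth


def simulate_feature_table(
    config: SimulationConfig, n_strides_averaged: int | None = None
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw a cohort's discrete-feature table directly from the offset model.

    Level draws are identical in distribution (and in order) to
    :func:`generate_cohort`; stride-level noise enters as its run average with
    variance ``sigma2_stride / n_strides_averaged``, which is what waveform
    averaging over that many cycles produces.  Orders of magnitude faster than
    synthesising and re-segmenting 240 Hz waveforms; use for Monte-Carlo
    studies of the reliability statistics.
    """
    if n_strides_averaged is None:
        n_strides_averaged = config.strides_per_run
    if n_strides_averaged < 1:
        raise ValueError("n_strides_averaged must be >= 1")
    rng = np.random.default_rng(config.seed)
    pids = config.participant_ids
    sf_base, speed, effects = _draw_levels(config, rng)
    signals = list(config.variance_components)
    tf = template_features(config.templates)
    var_specs = [s for s in _features.DEFAULT_SPECS if s.signal in config.variance_components]

    truth = SimulationTruth(
        config=config,
        participant_ids=pids,
        stride_period_s={
            pid: max(int(round(config.sample_rate / sf_base[i])), 2) / config.sample_rate
            for i, pid in enumerate(pids)
        },
        true_speed={pid: float(speed[i]) for i, pid in enumerate(pids)},
        boundaries={},
        level_offsets={},
        stride_offsets={},
        template_features=tf,
    )

    rows = []
    for ip, pid in enumerate(pids):
        for isurf, surface in enumerate(config.surfaces):
            for iday in range(config.n_days):
                day = iday + 1
                for irun, run in enumerate(config.runs):
                    period = _run_period_samples(config, sf_base[ip], rng)
                    sf_measured = config.sample_rate / period
                    stride_mean = {
                        sig: rng.normal(
                            0.0,
                            math.sqrt(
                                config.variance_components[sig].stride / n_strides_averaged
                            ),
                        )
                        for sig in signals
                    }
                    gate_noise = rng.normal(0.0, config.gate_noise_sd)
                    for ical, cal in enumerate(config.calibrations):
                        row = {
                            "participant": pid,
                            "day": day,
                            "surface": surface,
                            "run": run,
                            "calibration": cal,
                        }
                        offsets = {}
                        for sig in signals:
                            eff = effects[sig]
                            offsets[sig] = float(
                                eff["runner"][ip]
                                + eff["day"][ip, isurf, iday]
                                + eff["run"][ip, isurf, iday, irun]
                                + eff["calibration"][ip, isurf, iday, ical]
                            )
                        truth.level_offsets[(pid, day, surface, run, cal)] = offsets
                        for spec in var_specs:
                            row[spec.name] = (
                                tf[spec.name] + offsets[spec.signal] + stride_mean[spec.signal]
                            )
                        row["RS"] = float(speed[ip] + gate_noise)
                        row["SF"] = float(sf_measured)
                        rows.append(row)
    return pd.DataFrame(rows), truth


def _error_variance(
    v: LevelVariances, comparison_type: str, n_strides_averaged: int
) -> float:
    """Variance of the measurement error that differs within one comparison pair."""
    stride_term = v.stride / n_strides_averaged
    if comparison_type == "between_day":
        # different day => independent day, run and calibration draws
        return v.day + v.run + v.calibration + stride_term
    if comparison_type == "within_day":
        # same day and calibration, different run
        return v.run + stride_term
    if comparison_type == "calibration":
        # same run (shared stride data), different calibration
        return v.calibration
    raise KeyError(f"unknown comparison type {comparison_type!r}")


def analytic_icc(
    config: SimulationConfig,
    variable: str,
    comparison_type: str,
    n_strides_averaged: int | None = None,
) -> float:
    """Analytic (population) ICC of one variable under one comparison design."""
    if comparison_type not in COMPARISON_TYPES:
        raise KeyError(f"unknown comparison type {comparison_type!r}")
    if n_strides_averaged is None:
        n_strides_averaged = config.strides_per_run
    if variable == "RS":
        err = 0.0 if comparison_type == "calibration" else config.gate_noise_sd**2
        total = config.speed_sd**2 + err
        return 1.0 if total == 0 else config.speed_sd**2 / total
    if variable == "SF":
        # run-to-run SF deviation is the error source (sample-resolution
        # rounding of the period is neglected); shared within a calibration pair
        err = 0.0 if comparison_type == "calibration" else config.stride_freq_within_sd**2
        total = config.stride_freq_sd**2 + err
        return 1.0 if total == 0 else config.stride_freq_sd**2 / total
    signal = _features.VARIABLE_SIGNALS.get(variable)
    if signal is None or signal not in config.variance_components:
        raise KeyError(f"unknown variable {variable!r}")
    v = config.variance_components[signal]
    err = _error_variance(v, comparison_type, n_strides_averaged)
    total = v.runner + err
    return 1.0 if total == 0 else v.runner / total


def truth_icc(
    truth: SimulationTruth,
    variable: str,
    comparison_type: str,
    n_strides_averaged: int | None = None,
) -> float:
    """Analytic ICC for a generated cohort's ground truth (0 <= value <= 1)."""
    return analytic_icc(truth.config, variable, comparison_type, n_strides_averaged)
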