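"""Synthetic vital-sign simulator with ground-truth PSH episodes.

Generates per-patient HR/RR/SBP trends on a 0.5 Hz grid: a stationary
AR(1) Gaussian baseline (the simplest autocorrelated stand-in for real
trend dynamics) punctuated by recurrent, abrupt-onset elevation
episodes.  Episode starts come from a Poisson process (default 4/day),
durations from a log-normal moment-matched to mean 42 min / sd 16 min
and truncated to [2 min, 2 h]; candidates that would overlap or leave
an inter-episode gap under 2 minutes are rejected.  During an episode
every signal's mean shifts upward by its configured delta (HR +35 bpm,
RR +12 /min, SBP +45 mmHg — simultaneous elevation across channels,
matching PSH phenomenology) with 30 s linear onset/offset ramps and a
doubled noise sd inside the episode core.  The ground-truth episode
set records the un-ramped cores.

Everything is reproducible from an integer seed; cohorts derive
independent per-patient seeds from a master seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .episodes import EpisodeSet, write_episodes_csv
from .signal_model import SignalError, SignalKind, VitalSignSeries, write_vitals_csv

logger = logging.getLogger(__name__)

MIN_INTER_EPISODE_GAP_S = 120.0


class SimulationError(SignalError):
    """The configuration cannot produce a valid simulated record."""


@dataclass(frozen=True)
class SignalParams:
    """Baseline mean/sd and within-episode mean shift for one signal."""

    mean: float
    sd: float
    delta: float

    def __post_init__(self) -> None:
        if self.sd < 0 or self.delta < 0:
            raise SimulationError("sd and delta must be non-negative")


def _default_signals() -> dict[SignalKind, SignalParams]:
    return {
        SignalKind.HR: SignalParams(mean=80.0, sd=5.0, delta=35.0),
        SignalKind.RR: SignalParams(mean=14.0, sd=2.0, delta=12.0),
        SignalKind.SBP: SignalParams(mean=120.0, sd=8.0, delta=45.0),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults encode the annotated-case phenomenology: recurrent
    episodes (4/day), log-normal durations with mean 42 min and sd
    16 min truncated to [2 min, 2 h], abrupt (30 s ramp) onset/offset,
    and simultaneous HR/RR/SBP elevation over an autocorrelated
    baseline (lag-1 correlation 0.95 at 0.5 Hz).
    """

    duration_days: float = 14.0
    sampling_hz: float = 0.5
    signals: Mapping[SignalKind, SignalParams] = field(default_factory=_default_signals)
    ar1_phi: float = 0.95
    episode_rate_per_day: float = 4.0
    episode_duration_mean_min: float = 42.0
    episode_duration_sd_min: float = 16.0
    episode_duration_lo_min: float = 2.0
    episode_duration_hi_min: float = 120.0
    episode_sd_multiplier: float = 2.0
    ramp_s: float = 30.0
    artifact_rate_per_day: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_days <= 0 or self.sampling_hz <= 0:
            raise SimulationError("duration_days and sampling_hz must be positive")
        if not 0 <= self.ar1_phi < 1:
            raise SimulationError("ar1_phi must lie in [0, 1)")
        if self.episode_rate_per_day < 0:
            raise SimulationError("episode_rate_per_day must be >= 0")
        if not 0 < self.episode_duration_lo_min < self.episode_duration_hi_min:
            raise SimulationError("duration truncation bounds must be ordered and positive")
        if self.episode_sd_multiplier <= 0 or self.ramp_s < 0:
            raise SimulationError("episode_sd_multiplier must be > 0 and ramp_s >= 0")
        object.__setattr__(
            self, "signals", {SignalKind(k): v for k, v in self.signals.items()}
        )

    @property
    def duration_s(self) -> float:
        return self.duration_days * 86400.0


@dataclass(frozen=True)
class SimulatedPatient:
    """One simulated patient: three aligned series plus ground truth."""

    patient_id: str
    hr: VitalSignSeries
    rr: VitalSignSeries
    sbp: VitalSignSeries
    truth: EpisodeSet
    config: SimConfig
    seed: int

    def series(self) -> tuple[VitalSignSeries, VitalSignSeries, VitalSignSeries]:
        return (self.hr, self.rr, self.sbp)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a log-normal to the given mean and sd (pre-truncation)."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_duration_s(rng: np.random.Generator, config: SimConfig) -> float:
    mu, sigma = _lognormal_params(config.episode_duration_mean_min, config.episode_duration_sd_min)
    lo, hi = config.episode_duration_lo_min, config.episode_duration_hi_min
    for _ in range(1000):
        d = float(rng.lognormal(mu, sigma))
        if lo <= d <= hi:
            return d * 60.0
    raise SimulationError("could not draw an episode duration inside the truncation bounds")


def _draw_episode_cores(rng: np.random.Generator, config: SimConfig) -> list[tuple[float, float]]:
    """Poisson-process starts with rejection of overlaps and short gaps."""
    if config.episode_rate_per_day == 0:
        return []
    if config.episode_duration_lo_min * 60.0 + 2 * config.ramp_s > config.duration_s:
        raise SimulationError("record too short to place any episode within the duration bounds")
    lam = config.episode_rate_per_day * config.duration_days
    k = int(rng.poisson(lam))
    starts = np.sort(rng.uniform(0.0, config.duration_s, size=k))
    accepted: list[tuple[float, float]] = []
    for s in starts:
        d = _draw_duration_s(rng, config)
        if s - config.ramp_s < 0 or s + d + config.ramp_s > config.duration_s:
            continue
        if accepted and s < accepted[-1][1] + MIN_INTER_EPISODE_GAP_S:
            continue
        accepted.append((float(s), float(s + d)))
    return accepted


def _ar1_baseline(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary zero-mean AR(1) sample path with marginal sd ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innovations = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), size=n)
    innovations[0] = rng.normal(0.0, sd)  # stationary initial state
    return lfilter([1.0], [1.0, -phi], innovations)


def _episode_profile(t: np.ndarray, cores: list[tuple[float, float]], ramp_s: float) -> np.ndarray:
    """0-1 elevation profile: 1 on cores, linear ramps just outside them."""
    profile = np.zeros_like(t)
    for a, b in cores:
        core = (t >= a) & (t < b)
        profile[core] = 1.0
        if ramp_s > 0:
            up = (t >= a - ramp_s) & (t < a)
            profile[up] = np.maximum(profile[up], 1.0 - (a - t[up]) / ramp_s)
            down = (t >= b) & (t < b + ramp_s)
            profile[down] = np.maximum(profile[down], 1.0 - (t[down] - b) / ramp_s)
    return profile


def simulate_patient(config: SimConfig, seed: int, patient_id: str = "sim") -> SimulatedPatient:
    """Simulate one patient's HR/RR/SBP record with ground-truth episodes.

    Bit-identical for identical (config, seed, patient_id).
    """
    rng = np.random.default_rng(seed)
    n = int(round(config.duration_s * config.sampling_hz))
    t = np.arange(n, dtype=float) / config.sampling_hz

    cores = _draw_episode_cores(rng, config)
    profile = _episode_profile(t, cores, config.ramp_s)
    in_core = np.zeros(n, dtype=bool)
    for a, b in cores:
        lo, hi = np.searchsorted(t, [a, b], side="left")
        in_core[lo:hi] = True
    noise_scale = np.where(in_core, config.episode_sd_multiplier, 1.0)

    artifact_idx: np.ndarray | None = None
    if config.artifact_rate_per_day > 0:
        k_art = int(rng.poisson(config.artifact_rate_per_day * config.duration_days))
        if k_art:
            artifact_idx = rng.integers(0, n, size=k_art)

    series: dict[SignalKind, VitalSignSeries] = {}
    artifact_values = {SignalKind.HR: 300.0, SignalKind.RR: 120.0, SignalKind.SBP: 400.0}
    for kind in (SignalKind.HR, SignalKind.RR, SignalKind.SBP):
        p = config.signals[kind]
        baseline = _ar1_baseline(rng, n, p.sd, config.ar1_phi)
        values = p.mean + baseline * noise_scale + p.delta * profile
        if artifact_idx is not None:
            values = values.copy()
            values[artifact_idx] = artifact_values[kind]  # out-of-range spikes
        series[kind] = VitalSignSeries(
            patient_id=patient_id,
            signal_kind=kind,
            timestamps=t,
            values=values,
            nominal_rate_hz=config.sampling_hz,
        )

    truth = EpisodeSet(patient_id=patient_id, intervals=tuple(cores), source="truth")
    return SimulatedPatient(
        patient_id=patient_id,
        hr=series[SignalKind.HR],
        rr=series[SignalKind.RR],
        sbp=series[SignalKind.SBP],
        truth=truth,
        config=config,
        seed=seed,
    )


def control_config(base: SimConfig | None = None) -> SimConfig:
    """A control (non-PSH) configuration: same baselines, no episodes."""
    base = base or SimConfig()
    return replace(base, episode_rate_per_day=0.0)


@dataclass(frozen=True)
class SimulatedCohort:
    """Simulated case/control cohort with group labels."""

    patients: tuple[SimulatedPatient, ...]
    labels: Mapping[str, str]  # patient_id -> "PSH+" | "PSH-"
    seed: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit vitals.csv, truth_episodes.csv, groups.csv in the shared dialects."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vitals": out / "vitals.csv",
            "truth": out / "truth_episodes.csv",
            "groups": out / "groups.csv",
        }
        write_vitals_csv((s for p in self.patients for s in p.series()), paths["vitals"])
        write_episodes_csv((p.truth for p in self.patients), paths["truth"])
        pd.DataFrame(
            [{"patient_id": pid, "label": lab} for pid, lab in self.labels.items()],
            columns=["patient_id", "label"],
        ).to_csv(paths["groups"], index=False, lineterminator="\n", encoding="utf-8")
        return paths


def simulate_cohort(
    n_cases: int,
    n_controls: int,
    case_config: SimConfig | None = None,
    ctrl_config: SimConfig | None = None,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a case/control cohort with independent per-patient seeds.

    Controls must be episode-free by construction: their configuration
    needs either a zero episode rate or all-zero elevation deltas.
    """
    case_config = case_config or SimConfig()
    ctrl_config = ctrl_config or control_config(case_config)
    deltas_zero = all(p.delta == 0 for p in ctrl_config.signals.values())
    if ctrl_config.episode_rate_per_day != 0 and not deltas_zero:
        raise SimulationError("control config must have episode rate 0 or all deltas 0")

    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_cases + n_controls)
    patients: list[SimulatedPatient] = []
    labels: dict[str, str] = {}
    for i in range(n_cases):
        pid = f"case{i + 1:02d}"
        patients.append(simulate_patient(case_config, int(child_seeds[i]), pid))
        labels[pid] = "PSH+"
    for j in range(n_controls):
        pid = f"ctrl{j + 1:02d}"
        patients.append(simulate_patient(ctrl_config, int(child_seeds[n_cases + j]), pid))
        labels[pid] = "PSH-"
    return SimulatedCohort(patients=tuple(patients), labels=labels, seed=seed)
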