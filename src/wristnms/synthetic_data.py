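"""Synthetic neuromuscular "subjects" for end-to-end testing.

Generates the full experiment of the single-DoF wrist protocol: triangular
angle profiles (1 s ramp up, 500 ms pause, 1 s ramp down), three repetitions
of both directions of all three DoFs in randomized order.  Ground-truth muscle
excitations are computed with the calibration tracker on the noiseless model,
so they are dynamically consistent by construction.  Motor-unit spike trains
come from a rate-coding motoneuron-pool model (recruitment threshold + linear
rate gain, Gaussian-renewal ISIs) and are corrupted with decomposition-like
failure modes: missed spikes, per-repetition unit dropout, and silence below a
fraction of the maximal angle.  A surrogate multichannel EMG (excitation-
modulated band-limited noise at 2048 Hz) makes the TD baseline runnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .calibration import TrackingConfig, tracking_excitations
from .musculoskeletal import (
    DOF_NAMES,
    MUSCLE_NAMES,
    ExcitationTrajectory,
    WristModel,
    default_wrist_model,
)
from .spike_features import SpikeTrainSet, WindowGrid, build_window_grid

__all__ = [
    "TaskProfile",
    "MotoneuronPool",
    "CorruptionSpec",
    "EMGRecording",
    "Trial",
    "Dataset",
    "DatasetConfig",
    "generate_task_profile",
    "ground_truth_excitations",
    "sample_spikes",
    "corrupt_spikes",
    "synthesize_emg",
    "default_pools",
    "generate_dataset",
]

DIRECTIONS = ("positive", "negative")

#: default per-direction ranges of motion (rad): FE, RU, PS
DEFAULT_ROM = {"FE": 1.2, "RU": 0.4, "PS": 1.4}


@dataclass(frozen=True)
class TaskProfile:
    dof: str
    direction: str
    range_of_motion: float
    ramp_duration: float = 1.0
    pause_duration: float = 0.5
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.dof not in DOF_NAMES:
            raise ValueError(f"unknown DoF {self.dof!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.range_of_motion <= 0 or self.ramp_duration <= 0:
            raise ValueError("range_of_motion and ramp_duration must be positive")
        if self.pause_duration < 0 or self.sample_rate <= 0:
            raise ValueError("invalid pause_duration or sample_rate")

    @property
    def duration(self) -> float:
        return 2 * self.ramp_duration + self.pause_duration

    @property
    def peak(self) -> float:
        return self.range_of_motion if self.direction == "positive" else -self.range_of_motion


@dataclass
class MotoneuronPool:
    """Rate-coding pool: units recruit above a threshold and fire at
    ``min(r_max, r_min + gain * (e - threshold))`` pps with Gaussian-renewal
    inter-spike intervals."""

    muscle: str
    thresholds: np.ndarray  # excitation fraction in [0, 1), ascending
    gains: np.ndarray  # pps per unit excitation
    r_min: float = 8.0
    r_max: float = 35.0
    isi_cov: float = 0.2

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, float)
        self.gains = np.asarray(self.gains, float)
        if np.any(self.thresholds < 0) or np.any(self.thresholds >= 1):
            raise ValueError("thresholds must lie in [0, 1)")
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be sorted ascending")
        if self.r_min <= 0 or self.r_max < self.r_min:
            raise ValueError("need 0 < r_min <= r_max")

    @property
    def n_units(self) -> int:
        return int(self.thresholds.size)

    def rate(self, excitation: np.ndarray, j: int) -> np.ndarray:
        """Instantaneous rate of unit j; zero below its threshold."""
        e = np.asarray(excitation, float)
        lam = np.minimum(self.r_max, self.r_min + self.gains[j] * (e - self.thresholds[j]))
        return np.where(e > self.thresholds[j], lam, 0.0)


@dataclass(frozen=True)
class CorruptionSpec:
    miss_probability: float = 0.1
    dropout_probability: float = 0.15
    silence_angle_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.miss_probability, self.dropout_probability, self.silence_angle_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("corruption probabilities must lie in [0, 1]")


@dataclass
class EMGRecording:
    samples: np.ndarray  # channels x time
    sample_rate: float = 2048.0
    channel_layout: tuple[int, int] = (4, 4)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples must be finite")

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sample_rate


@dataclass
class Trial:
    task: TaskProfile
    times: np.ndarray
    kinematics: np.ndarray  # n x 3
    true_excitations: ExcitationTrajectory
    spikes: SpikeTrainSet
    spikes_clean: SpikeTrainSet
    emg: EMGRecording | None
    repetition_index: int

    @property
    def actuated_dof(self) -> int:
        return DOF_NAMES.index(self.task.dof)


@dataclass
class Dataset:
    trials: list[Trial]
    model: WristModel
    grid: WindowGrid
    pools: dict[str, MotoneuronPool]
    seed: int

    def select(self, dof: str | None = None, direction: str | None = None,
               repetitions: Sequence[int] | None = None) -> list[Trial]:
        out = []
        for tr in self.trials:
            if dof is not None and tr.task.dof != dof:
                continue
            if direction is not None and tr.task.direction != direction:
                continue
            if repetitions is not None and tr.repetition_index not in repetitions:
                continue
            out.append(tr)
        return out

    def save(self, out_dir: str | Path, write_emg: bool = True) -> None:
        """Write the dataset as plain-text files plus a YAML manifest."""
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": self.seed, "trials": []}
        self.model.to_yaml(out / "model.yaml")
        for i, tr in enumerate(self.trials):
            stem = f"trial{i:02d}_{tr.task.dof}_{tr.task.direction}_rep{tr.repetition_index}"
            kin = pd.DataFrame(tr.kinematics, columns=[f"q_{d}" for d in DOF_NAMES])
            kin.insert(0, "time_s", tr.times)
            kin.to_csv(out / f"{stem}_kinematics.csv", index=False)
            tr.true_excitations.to_csv(out / f"{stem}_excitations.csv")
            tr.spikes.to_json(out / f"{stem}_spikes.json")
            entry = {
                "stem": stem,
                "dof": tr.task.dof,
                "direction": tr.task.direction,
                "repetition": tr.repetition_index,
                "range_of_motion": tr.task.range_of_motion,
            }
            if write_emg and tr.emg is not None:
                np.savetxt(out / f"{stem}_emg.csv",
                           tr.emg.samples.T, delimiter=",", fmt="%.6g")
                entry["emg_sample_rate"] = tr.emg.sample_rate
            manifest["trials"].append(entry)
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def generate_task_profile(task: TaskProfile) -> tuple[np.ndarray, np.ndarray]:
    """Triangular single-DoF angle profile: ramp up, pause at peak, ramp down.

    Returns ``(times, q)`` with q of shape (n, 3); the two non-actuated DoFs
    are identically zero.
    """
    n = int(round(task.duration * task.sample_rate)) + 1
    t = np.arange(n) / task.sample_rate
    r, p = task.ramp_duration, task.pause_duration
    up = np.clip(t / r, 0.0, 1.0)
    down = np.clip((t - r - p) / r, 0.0, 1.0)
    profile = (up - down) * task.peak
    q = np.zeros((n, 3))
    q[:, DOF_NAMES.index(task.dof)] = profile
    return t, q


def ground_truth_excitations(
    model: WristModel,
    times: np.ndarray,
    kinematics: np.ndarray,
    grid: WindowGrid,
    cfg: TrackingConfig | None = None,
) -> ExcitationTrajectory:
    """Dynamically consistent excitations for noiseless reference kinematics.

    Thin wrapper over the calibration tracker so that synthetic ground truth
    and calibration supervision share one code path.
    """
    exc, _ = tracking_excitations(model, times, kinematics, grid, cfg)
    return exc


def sample_spikes(
    pool: MotoneuronPool,
    excitation: ExcitationTrajectory,
    duration: float,
    seed: int | np.random.SeedSequence,
    dt: float = 0.001,
) -> SpikeTrainSet:
    """Draw spike trains from the pool given its muscle's excitation.

    Inhomogeneous Gaussian-renewal process by time rescaling: the integrated
    rate of each recruited unit is crossed by renewal increments drawn from
    ``N(1, isi_cov^2)`` (truncated at 0.1), so the local mean rate equals the
    rate-coding law and the ISI coefficient of variation is ``isi_cov`` under
    constant excitation.  Deterministic given the seed.
    """
    if pool.muscle in excitation.muscle_names:
        col = excitation.muscle_names.index(pool.muscle)
    else:
        col = 0
    t_fine = np.arange(0.0, duration, dt)
    e = excitation.at(t_fine)[:, col]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(pool.n_units)
    trains: dict[str, np.ndarray] = {}
    for j in range(pool.n_units):
        rng = np.random.default_rng(children[j])
        lam = pool.rate(e, j)
        cum = np.concatenate([[0.0], np.cumsum(lam) * dt])
        total = cum[-1]
        spikes = []
        s = 0.0
        while True:
            s += max(rng.normal(1.0, pool.isi_cov), 0.1)
            if s >= total:
                break
            k = int(np.searchsorted(cum, s, side="right") - 1)
            # linear interpolation inside the fine step
            frac = (s - cum[k]) / max(cum[k + 1] - cum[k], 1e-30)
            spikes.append(t_fine[k] + frac * dt if k < t_fine.size else duration)
        times = np.asarray(spikes)
        trains[f"{pool.muscle}_u{j:02d}"] = times[np.argsort(times)] if times.size else times
    return SpikeTrainSet(trains, trial_duration=duration)


def corrupt_spikes(
    spikes: SpikeTrainSet,
    spec: CorruptionSpec,
    times: np.ndarray,
    kinematics: np.ndarray,
    actuated_dof: int | None = None,
) -> SpikeTrainSet:
    """Decomposition-like corruption: a pure filter on the spike trains.

    Each spike is independently deleted with ``miss_probability``; each unit
    is deleted entirely with ``dropout_probability`` (per repetition, i.e. per
    call); all spikes occurring while the actuated angle is below
    ``silence_angle_fraction`` of its maximal excursion are deleted.
    """
    q = np.asarray(kinematics, float)
    t = np.asarray(times, float)
    if actuated_dof is None:
        actuated_dof = int(np.argmax(np.abs(q).max(axis=0)))
    qa = np.abs(q[:, actuated_dof])
    rom = float(qa.max())
    threshold = spec.silence_angle_fraction * rom
    rng = np.random.default_rng(spec.seed)
    out: dict[str, np.ndarray] = {}
    for uid in spikes.unit_ids:
        st = spikes.trains[uid]
        if rng.random() < spec.dropout_probability:
            out[uid] = np.empty(0)
            continue
        if st.size == 0:
            out[uid] = st
            continue
        keep = rng.random(st.size) >= spec.miss_probability
        if rom > 0 and threshold > 0:
            angle_at = np.interp(st, t, qa)
            keep &= angle_at >= threshold
        out[uid] = st[keep]
    return SpikeTrainSet(out, spikes.trial_duration, spikes.dof_label)


def synthesize_emg(
    excitations: ExcitationTrajectory,
    n_channels: int,
    mixing_seed: int | np.random.SeedSequence,
    noise_seed: int | np.random.SeedSequence | None = None,
    duration: float | None = None,
    sample_rate: float = 2048.0,
    baseline_rms: float = 0.05,
    band: tuple[float, float] = (20.0, 500.0),
) -> EMGRecording:
    """Surrogate interference EMG: excitation-modulated band-limited noise.

    Channel c is ``sum_m w_cm e_m(t) n_cm(t)`` plus independent baseline
    noise, all noise band-limited white with unit RMS.  The channel/muscle
    weights ``w_cm`` model the fixed electrode geometry and depend only on
    ``mixing_seed`` (one draw per subject); the noise carriers depend on
    ``noise_seed`` (one draw per trial, defaults to the mixing seed).
    """
    from scipy.signal import butter, sosfiltfilt

    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    mix_ss = (mixing_seed if isinstance(mixing_seed, np.random.SeedSequence)
              else np.random.SeedSequence(mixing_seed))
    if noise_seed is None:
        noise_seed = mix_ss
    noise_ss = (noise_seed if isinstance(noise_seed, np.random.SeedSequence)
                else np.random.SeedSequence(noise_seed))
    mix_rng = np.random.default_rng(mix_ss)
    rng = np.random.default_rng(noise_ss)
    if duration is None:
        step = float(np.median(np.diff(excitations.times))) if excitations.n_windows > 1 else 0.1
        duration = float(excitations.times[-1] + step)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    e = excitations.at(t)  # n x m
    n_muscles = e.shape[1]
    sos = butter(4, band, btype="bandpass", fs=sample_rate, output="sos")

    def bl_noise(shape):
        x = sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
        return x / np.sqrt(np.mean(x**2, axis=-1, keepdims=True))

    w = mix_rng.uniform(0.1, 1.0, size=(n_channels, n_muscles))
    carriers = bl_noise((n_channels, n_muscles, n))
    signal = np.einsum("cm,cmn,nm->cn", w, carriers, e)
    signal += baseline_rms * bl_noise((n_channels, n))
    rows = int(np.floor(np.sqrt(n_channels)))
    return EMGRecording(signal, sample_rate, (rows, int(np.ceil(n_channels / rows))))


@dataclass
class DatasetConfig:
    """Everything needed to generate one synthetic subject."""

    rom: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROM))
    ramp_duration: float = 1.0
    pause_duration: float = 0.5
    kinematics_rate: float = 100.0
    window_length: float = 0.100
    window_step: float = 0.090
    units_per_muscle: int = 20
    threshold_range: tuple[float, float] = (0.0, 0.6)
    gain_range: tuple[float, float] = (40.0, 60.0)
    r_min: float = 8.0
    r_max: float = 35.0
    isi_cov: float = 0.2
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    n_emg_channels: int = 16
    emg_sample_rate: float = 2048.0
    include_emg: bool = True
    n_repetitions: int = 3
    tracking: TrackingConfig = field(default_factory=TrackingConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "corruption" in doc:
            doc["corruption"] = CorruptionSpec(**doc["corruption"])
        if "tracking" in doc:
            doc["tracking"] = TrackingConfig(**doc["tracking"])
        return cls(**doc)


def default_pools(config: DatasetConfig, rng: np.random.Generator) -> dict[str, MotoneuronPool]:
    pools = {}
    for muscle in MUSCLE_NAMES:
        thresholds = np.sort(rng.uniform(*config.threshold_range, size=config.units_per_muscle))
        gains = rng.uniform(*config.gain_range, size=config.units_per_muscle)
        pools[muscle] = MotoneuronPool(
            muscle, thresholds, gains, config.r_min, config.r_max, config.isi_cov
        )
    return pools


def generate_dataset(
    config: DatasetConfig | None = None,
    seed: int = 0,
    model: WristModel | None = None,
) -> Dataset:
    """Generate one synthetic subject: 3 reps x 2 directions x 3 DoFs.

    Trial order is randomized by the seed; per-trial ground truth (noiseless
    excitations and uncorrupted spike trains) is retained for testing.
    """
    config = config or DatasetConfig()
    model = model or default_wrist_model()
    root = np.random.SeedSequence(seed)
    pool_ss, order_ss, mixing_ss, trial_root = root.spawn(4)
    pools = default_pools(config, np.random.default_rng(pool_ss))

    duration = 2 * config.ramp_duration + config.pause_duration
    grid = build_window_grid(duration, config.window_length, config.window_step)

    # one tracking run per unique profile, shared across repetitions
    profiles: list[TaskProfile] = [
        TaskProfile(dof, direction, config.rom[dof], config.ramp_duration,
                    config.pause_duration, config.kinematics_rate)
        for dof in DOF_NAMES
        for direction in DIRECTIONS
    ]
    truth: dict[TaskProfile, tuple[np.ndarray, np.ndarray, ExcitationTrajectory]] = {}
    for task in profiles:
        t, q = generate_task_profile(task)
        exc = ground_truth_excitations(model, t, q, grid, config.tracking)
        truth[task] = (t, q, exc)

    trial_seeds = trial_root.spawn(len(profiles) * config.n_repetitions * 3)
    trials: list[Trial] = []
    k = 0
    for rep in range(1, config.n_repetitions + 1):
        for task in profiles:
            t, q, exc = truth[task]
            spike_ss, corrupt_ss, emg_ss = trial_seeds[k], trial_seeds[k + 1], trial_seeds[k + 2]
            k += 3
            unit_sets = [
                sample_spikes(pools[m], exc, duration, child)
                for m, child in zip(MUSCLE_NAMES, spike_ss.spawn(len(MUSCLE_NAMES)))
            ]
            merged = SpikeTrainSet(
                {uid: st for s in unit_sets for uid, st in s.trains.items()},
                duration, dof_label=task.dof,
            )
            spec = replace(config.corruption,
                           seed=int(corrupt_ss.generate_state(1)[0]))
            corrupted = corrupt_spikes(merged, spec, t, q, DOF_NAMES.index(task.dof))
            emg = None
            if config.include_emg:
                emg = synthesize_emg(exc, config.n_emg_channels, mixing_ss, emg_ss,
                                     duration=duration,
                                     sample_rate=config.emg_sample_rate)
            trials.append(Trial(task, t, q, exc, corrupted, merged, emg, rep))
    order = np.random.default_rng(order_ss).permutation(len(trials))
    return Dataset([trials[i] for i in order], model, grid, pools, seed)
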