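"""Sliding-window spike-count features from decomposed motor-unit spike trains.

The decomposed-spike-count (DSC) feature is the number of discharges of each
motor-unit spike train inside each observation window of a sliding grid.  The
same grid is shared by every downstream stage (excitation trajectories, TD
features, regression targets), so the grid object built here is passed around
the whole pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrainSet",
    "WindowGrid",
    "DSCMatrix",
    "build_window_grid",
    "extract_dsc",
    "activity_mask",
]

#: default observation window length (s)
DEFAULT_WINDOW_LENGTH = 0.100
#: default window step (s): 100 ms windows with 10 ms overlap
DEFAULT_WINDOW_STEP = 0.090


@dataclass
class SpikeTrainSet:
    """Per-trial discharge times of a set of decomposed motor units.

    Parameters
    ----------
    trains
        Mapping from unit id to a sorted array of discharge times in seconds.
    trial_duration
        Duration of the trial in seconds; all times must lie in
        ``[0, trial_duration]``.
    dof_label
        Optional label of the task (DoF) in which the units were detected.
    """

    trains: dict[str, np.ndarray]
    trial_duration: float
    dof_label: str | None = None

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for uid, times in self.trains.items():
            t = np.asarray(times, dtype=float)
            if t.ndim != 1:
                raise ValueError(f"train {uid!r} must be 1-D")
            if t.size and (np.any(np.diff(t) <= 0)):
                raise ValueError(f"train {uid!r} not strictly increasing")
            if t.size and (t[0] < 0 or t[-1] > self.trial_duration):
                raise ValueError(
                    f"train {uid!r} has discharges outside [0, trial_duration]"
                )
            clean[uid] = t
        self.trains = clean

    @property
    def unit_ids(self) -> list[str]:
        return list(self.trains)

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    # -- I/O ---------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "trial_duration": self.trial_duration,
            "dof_label": self.dof_label,
            "trains": {uid: t.tolist() for uid, t in self.trains.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpikeTrainSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            trains={u: np.asarray(t, float) for u, t in payload["trains"].items()},
            trial_duration=float(payload["trial_duration"]),
            dof_label=payload.get("dof_label"),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per discharge."""
        rows = [
            (uid, t)
            for uid, times in self.trains.items()
            for t in times
        ]
        return pd.DataFrame(rows, columns=["unit", "time_s"])


@dataclass(frozen=True)
class WindowGrid:
    """Uniform sliding-window grid over one trial."""

    window_length: float
    window_step: float
    start_times: np.ndarray = field(repr=False)

    @property
    def n_windows(self) -> int:
        return int(len(self.start_times))

    @property
    def centers(self) -> np.ndarray:
        return self.start_times + self.window_length / 2.0

    @property
    def end(self) -> float:
        """End of the last window."""
        return float(self.start_times[-1] + self.window_length)


@dataclass
class DSCMatrix:
    """windows x units matrix of spike counts on a :class:`WindowGrid`."""

    counts: np.ndarray
    grid: WindowGrid
    unit_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.grid.n_windows, len(self.unit_ids)):
            raise ValueError("counts shape does not match grid/unit ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.unit_ids)
        df.insert(0, "window_start_s", self.grid.start_times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, window_length: float = DEFAULT_WINDOW_LENGTH) -> "DSCMatrix":
        df = pd.read_csv(path)
        starts = df.pop("window_start_s").to_numpy(float)
        step = float(starts[1] - starts[0]) if len(starts) > 1 else window_length
        grid = WindowGrid(window_length, step, starts)
        return cls(df.to_numpy(int), grid, list(df.columns))


def build_window_grid(
    trial_duration: float,
    window_length: float = DEFAULT_WINDOW_LENGTH,
    window_step: float = DEFAULT_WINDOW_STEP,
) -> WindowGrid:
    """Build the sliding-window grid for a trial.

    Windows start at 0 and advance by ``window_step`` for as long as the full
    window fits inside the trial, giving
    ``floor((trial_duration - window_length) / window_step) + 1`` windows.
    """
    if window_length <= 0 or window_step <= 0:
        raise ValueError("window_length and window_step must be positive")
    if window_step > window_length + 1e-12:
        raise ValueError("window_step must not exceed window_length")
    if trial_duration < window_length:
        raise ValueError("trial_duration shorter than one window")
    # small epsilon guards against float drop of the last exactly-fitting window
    n = int(np.floor((trial_duration - window_length) / window_step + 1e-9)) + 1
    starts = np.arange(n) * window_step
    return WindowGrid(window_length, window_step, starts)


def extract_dsc(spikes: SpikeTrainSet, grid: WindowGrid) -> DSCMatrix:
    """Count discharges of each train inside each half-open window.

    ``counts[w, j] = #{t in train_j : start_w <= t < start_w + length}``.
    A spike at exactly the trial end falls outside the last half-open window
    and is dropped.
    """
    if grid.end > spikes.trial_duration + 1e-9:
        raise ValueError("window grid extends beyond the trial")
    starts = grid.start_times
    counts = np.zeros((grid.n_windows, spikes.n_units), dtype=int)
    for j, uid in enumerate(spikes.unit_ids):
        t = spikes.trains[uid]
        if t.size == 0:
            continue
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"train {uid!r} not sorted")
        lo = np.searchsorted(t, starts, side="left")
        hi = np.searchsorted(t, starts + grid.window_length, side="left")
        counts[:, j] = hi - lo
    return DSCMatrix(counts, grid, spikes.unit_ids)


def activity_mask(dsc: DSCMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-(window, unit) activity plus a per-window any-active flag.

    A unit is active in a window iff its count is positive; a window is active
    iff any unit is active in it.
    """
    unit_active = dsc.counts > 0
    window_active = unit_active.any(axis=1)
    return unit_active, window_active
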