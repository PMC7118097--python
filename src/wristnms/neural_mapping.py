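"""Neural regression: motor units to muscle excitations.

Motor units are assigned to muscle-tendon units by spike/excitation
coincidence (excitation positive at >= 80 % of a unit's discharges; units
meeting the criterion for several muscles are assigned to all of them).  For
each assigned (muscle, unit) pair a robust linear model excitation ~ spike
count is fitted by iteratively reweighted least squares with the Tukey
bisquare weight, using only windows in which the unit fired.  At prediction
time the per-muscle excitation is the median of the active units' estimates,
with a per-muscle ANN on TD features as fallback for windows without any
active assigned unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .emg_baseline import ANNModel, PCAModel, apply_pca, predict_ann, train_ann
from .musculoskeletal import MUSCLE_NAMES, ExcitationTrajectory
from .spike_features import DSCMatrix, SpikeTrainSet

__all__ = [
    "AssignmentMap",
    "LinearUnitModel",
    "NeuralModel",
    "RankDeficiencyError",
    "assign_units",
    "fit_unit_regressor",
    "irls_bisquare",
    "train_neural_model",
    "predict_excitations",
]

#: excitation values above this count as "greater than zero"
EXCITATION_TOL = 1e-6
#: bisquare tuning constant (95 % Gaussian efficiency)
BISQUARE_C = 4.685


class RankDeficiencyError(ValueError):
    """Raised when the regressor has no usable variation."""


@dataclass
class AssignmentMap:
    assignments: dict[str, set[str]]  # unit id -> muscle names
    unassigned: set[str]
    coincidence_threshold: float = 0.8
    zero_spike_units: set[str] = field(default_factory=set)

    def muscles_of(self, unit: str) -> set[str]:
        return self.assignments.get(unit, set())

    def units_of(self, muscle: str) -> list[str]:
        return [u for u, ms in self.assignments.items() if muscle in ms]


@dataclass
class LinearUnitModel:
    muscle: str
    unit: str
    intercept: float
    slope: float
    iterations: int = 0
    final_scale: float = 0.0

    def predict(self, counts: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(counts, float)


@dataclass
class NeuralModel:
    assignment: AssignmentMap
    unit_models: dict[tuple[str, str], LinearUnitModel]
    fallback: dict[str, ANNModel]
    fallback_pca: PCAModel | None = None
    fallback_only_muscles: set[str] = field(default_factory=set)
    muscle_names: tuple[str, ...] = MUSCLE_NAMES


def _excitation_at_spikes(exc: ExcitationTrajectory, spike_times: np.ndarray) -> np.ndarray:
    """Nearest-sample lookup of the excitation matrix at each discharge time."""
    centers = exc.times + 0.0  # window start times define the sample grid
    idx = np.clip(np.searchsorted(centers, spike_times, side="right") - 1, 0, exc.n_windows - 1)
    return exc.values[idx]


def assign_units(
    spikes: SpikeTrainSet | Sequence[SpikeTrainSet],
    excitations: ExcitationTrajectory | Sequence[ExcitationTrajectory],
    threshold: float = 0.8,
    excitation_tol: float = EXCITATION_TOL,
) -> AssignmentMap:
    """Assign motor units to muscles by spike/excitation coincidence.

    A unit is assigned to every muscle whose excitation exceeds
    ``excitation_tol`` at the time of at least ``threshold`` of its
    discharges.  Multiple trials may be passed as parallel sequences; the
    coincidence fraction is then pooled over all trials.  Units with zero
    discharges are flagged unassigned.
    """
    if isinstance(spikes, SpikeTrainSet):
        spikes = [spikes]
        excitations = [excitations]
    if len(spikes) != len(excitations):
        raise ValueError("spikes and excitations must pair up per trial")
    muscle_names = excitations[0].muscle_names
    totals: dict[str, int] = {}
    hits: dict[str, np.ndarray] = {}
    for st, exc in zip(spikes, excitations):
        for uid, times in st.trains.items():
            totals.setdefault(uid, 0)
            hits.setdefault(uid, np.zeros(len(muscle_names), dtype=int))
            if times.size == 0:
                continue
            e = _excitation_at_spikes(exc, times)
            totals[uid] += times.size
            hits[uid] += (e > excitation_tol).sum(axis=0)

    assignments: dict[str, set[str]] = {}
    unassigned: set[str] = set()
    zero_spike: set[str] = set()
    for uid, n in totals.items():
        if n == 0:
            zero_spike.add(uid)
            unassigned.add(uid)
            continue
        frac = hits[uid] / n
        muscles = {muscle_names[m] for m in np.flatnonzero(frac >= threshold - 1e-12)}
        if muscles:
            assignments[uid] = muscles
        else:
            unassigned.add(uid)
    return AssignmentMap(assignments, unassigned, threshold, zero_spike)


def irls_bisquare(
    X: np.ndarray,
    y: np.ndarray,
    c: float = BISQUARE_C,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, int, float]:
    """Iteratively reweighted least squares with the Tukey bisquare weight.

    Returns ``(beta, iterations, final_scale)``.  The scale is the normalized
    median absolute deviation of the residuals; when it collapses (perfect
    fit) the current estimate is returned.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    scale = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        r = y - X @ beta
        scale = float(np.median(np.abs(r - np.median(r))) / 0.6745)
        if scale < 1e-12:
            break
        # guard against scale collapse (e.g. tightly clustered residuals at
        # discrete regressor values rejecting every point): inflate the scale
        # until enough points carry weight for a determined fit
        w = np.zeros_like(r)
        for _ in range(60):
            u = r / (c * scale)
            w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
            if np.count_nonzero(w) > X.shape[1]:
                break
            scale *= 1.5
        else:
            break
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta, it, scale


def fit_unit_regressor(
    dsc_column: np.ndarray,
    excitation: np.ndarray,
    spike_mask: np.ndarray | None = None,
    muscle: str = "",
    unit: str = "",
) -> LinearUnitModel:
    """Robust linear fit of excitation on the unit's spike counts.

    Only windows in which the unit fired (``spike_mask``, default count >= 1)
    enter the fit.  Constant spike counts raise :class:`RankDeficiencyError`.
    """
    x = np.asarray(dsc_column, float)
    y = np.asarray(excitation, float)
    if spike_mask is None:
        spike_mask = x >= 1
    x, y = x[spike_mask], y[spike_mask]
    if np.unique(x).size < 2:
        raise RankDeficiencyError(
            f"unit {unit!r}: needs >= 2 distinct spike counts among spiking windows"
        )
    X = np.column_stack([np.ones_like(x), x])
    beta, iters, scale = irls_bisquare(X, y)
    if not np.all(np.isfinite(beta)):
        raise RankDeficiencyError(f"unit {unit!r}: non-finite coefficients")
    return LinearUnitModel(muscle, unit, float(beta[0]), float(beta[1]), iters, scale)


def train_neural_model(
    dsc: Sequence[DSCMatrix],
    excitations: Sequence[ExcitationTrajectory],
    td_features: Sequence[np.ndarray],
    assignment: AssignmentMap,
    fallback_pca: PCAModel | None = None,
    ann_restarts: int = 50,
    ann_seed: int | None = None,
    ann_max_iter: int = 100,
) -> NeuralModel:
    """Fit per-(muscle, unit) linear models and per-muscle fallback ANNs.

    All calibration trials are pooled: spike counts, excitations and TD
    features are concatenated on their (identical) window grids.  Muscles
    that end up with no usable unit model are flagged fallback-only.
    """
    if not (len(dsc) == len(excitations) == len(td_features)):
        raise ValueError("trial sequences must have equal length")
    muscle_names = excitations[0].muscle_names

    # pooled per-unit counts; units absent from a trial contribute zero rows
    all_units = sorted({u for d in dsc for u in d.unit_ids})
    n_rows = sum(d.grid.n_windows for d in dsc)
    counts = np.zeros((n_rows, len(all_units)))
    exc_all = np.zeros((n_rows, len(muscle_names)))
    absent = np.zeros((n_rows, len(all_units)), dtype=bool)
    r0 = 0
    for d, e in zip(dsc, excitations):
        r1 = r0 + d.grid.n_windows
        present = {u: j for j, u in enumerate(d.unit_ids)}
        for j, u in enumerate(all_units):
            if u in present:
                counts[r0:r1, j] = d.counts[:, present[u]]
            else:
                absent[r0:r1, j] = True
        exc_all[r0:r1] = e.values
        r0 = r1

    unit_models: dict[tuple[str, str], LinearUnitModel] = {}
    for uid, muscles in assignment.assignments.items():
        if uid not in all_units:
            continue
        j = all_units.index(uid)
        mask = (counts[:, j] >= 1) & ~absent[:, j]
        for muscle in muscles:
            m = muscle_names.index(muscle)
            try:
                unit_models[(muscle, uid)] = fit_unit_regressor(
                    counts[:, j], exc_all[:, m], mask, muscle, uid
                )
            except RankDeficiencyError:
                continue

    td_all = np.vstack([np.asarray(t, float) for t in td_features])
    scores = apply_pca(fallback_pca, td_all) if fallback_pca is not None else td_all
    fallback: dict[str, ANNModel] = {}
    seeds = np.random.SeedSequence(ann_seed).spawn(len(muscle_names))
    for m, muscle in enumerate(muscle_names):
        fallback[muscle] = train_ann(
            scores, exc_all[:, m], restarts=ann_restarts,
            seed=int(seeds[m].generate_state(1)[0]), max_iter=ann_max_iter,
        )
    fallback_only = {
        mname for mname in muscle_names
        if not any(k[0] == mname for k in unit_models)
    }
    return NeuralModel(assignment, unit_models, fallback, fallback_pca,
                       fallback_only, tuple(muscle_names))


def predict_excitations(
    model: NeuralModel,
    dsc: DSCMatrix,
    td_features: np.ndarray | None = None,
) -> ExcitationTrajectory:
    """Median-ensemble muscle excitations with ANN fallback.

    Per window and muscle the estimates of all assigned units that fired in
    that window are pooled and their median taken; windows without any active
    assigned unit fall back to the muscle's ANN on TD features.  The result is
    clamped to [0, 1].
    """
    n_w = dsc.grid.n_windows
    muscle_names = model.muscle_names
    out = np.zeros((n_w, len(muscle_names)))
    unit_idx = {u: j for j, u in enumerate(dsc.unit_ids)}

    fallback_scores = None
    if td_features is not None:
        td = np.asarray(td_features, float)
        fallback_scores = (
            apply_pca(model.fallback_pca, td) if model.fallback_pca is not None else td
        )

    for m, muscle in enumerate(muscle_names):
        models = [
            (unit_idx[u], model.unit_models[(muscle, u)])
            for u in model.assignment.units_of(muscle)
            if (muscle, u) in model.unit_models and u in unit_idx
        ]
        need_fallback = np.ones(n_w, dtype=bool)
        if models:
            cols = np.array([j for j, _ in models])
            active = dsc.counts[:, cols] >= 1  # n_w x n_models
            est = np.array([lm.predict(dsc.counts[:, j]) for j, lm in models]).T
            has_active = active.any(axis=1)
            for w in np.flatnonzero(has_active):
                out[w, m] = np.median(est[w, active[w]])
            need_fallback = ~has_active
        if need_fallback.any():
            if muscle not in model.fallback:
                raise ValueError(f"no fallback ANN for muscle {muscle!r}")
            if fallback_scores is None:
                raise ValueError("TD features required for fallback windows")
            out[need_fallback, m] = predict_ann(
                model.fallback[muscle], fallback_scores[need_fallback]
            )
    np.clip(out, 0.0, 1.0, out=out)
    return ExcitationTrajectory(dsc.grid.start_times, out, muscle_names)
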