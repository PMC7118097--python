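"""End-to-end evaluation: gating, the full spike-to-kinematics chain, the two
ANN baselines, and repetition-level cross-validation.

The full chain predicts kinematics from decomposed spike trains: spike counts
drive the median-ensemble neural mapping to muscle excitations, a single-DoF
gate identifies the actuated DoF from the agonist pattern, the wrist model is
forward-simulated open loop, and the output is rescaled to recorded units.
Evaluation uses repetition-level cross-validation (2 train / 1 test
repetitions per direction per DoF), fully retraining every fitted artifact on
the training folds only, and reports R-squared and RMSE (degrees) per DoF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import KinematicsScaler, TrackingConfig, fit_scaler, tracking_excitations
from .emg_baseline import (
    ANNModel,
    concat_td_dsc,
    extract_td,
    fit_pca,
    apply_pca,
    lowpass_estimates,
    predict_ann,
    preprocess_emg,
    train_ann,
)
from .musculoskeletal import (
    DOF_NAMES,
    MUSCLE_NAMES,
    ExcitationTrajectory,
    WristModel,
    forward_simulate,
)
from .neural_mapping import NeuralModel, assign_units, predict_excitations, train_neural_model
from .spike_features import DSCMatrix, WindowGrid, extract_dsc
from .synthetic_data import DIRECTIONS, Dataset, Trial

__all__ = [
    "GatingRule",
    "gate_excitations",
    "run_dsc_nms",
    "r2",
    "rmse",
    "make_folds",
    "crossvalidate",
    "compare_methods",
    "METHODS",
]

METHODS = ("td", "td_dsc", "dsc_nms")

_FCU, _FCR, _ECU, _ECRL, _PT, _SUP = (MUSCLE_NAMES.index(m) for m in
                                      ("FCU", "FCR", "ECU", "ECRL", "PT", "SUP"))


@dataclass(frozen=True)
class GatingRule:
    """Single-DoF gate from agonist-pair activity.

    Agonist sets follow the moment-arm signs: flexion {FCR, FCU}, extension
    {ECRL, ECU}, radial {FCR, ECRL}, ulnar {FCU, ECU}, pronation {PT},
    supination {SUP}.  A DoF direction counts as actuated only when every
    muscle of its agonist set is active (excitation > epsilon).
    """

    epsilon: float = 0.05

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def gate_excitations(
    excitations: ExcitationTrajectory, rule: GatingRule | None = None
) -> tuple[ExcitationTrajectory, np.ndarray]:
    """Apply the single-DoF gate; returns gated excitations + active-DoF mask.

    Per window: a complete flexion or extension agonist pair selects FE and
    suppresses RU (and vice versa for a deviation pair); if both an FE pair
    and an RU pair are active, or any of the four wrist muscles is active
    alone, both FE and RU are estimated.  PS is gated by PT/SUP individually.
    Sub-threshold excitations are zeroed; gating never increases any value.
    """
    rule = rule or GatingRule()
    e = excitations.values
    act = e > rule.epsilon
    flex = act[:, _FCU] & act[:, _FCR]
    ext = act[:, _ECU] & act[:, _ECRL]
    rad = act[:, _FCR] & act[:, _ECRL]
    uln = act[:, _FCU] & act[:, _ECU]
    fe_pair = flex | ext
    ru_pair = rad | uln
    any_wrist = act[:, [_FCU, _FCR, _ECU, _ECRL]].any(axis=1)

    dof_mask = np.zeros((e.shape[0], 3), dtype=bool)
    dof_mask[:, 0] = fe_pair | (~ru_pair & any_wrist)
    dof_mask[:, 1] = ru_pair | (~fe_pair & any_wrist)
    dof_mask[:, 2] = act[:, _PT] | act[:, _SUP]

    gated = np.where(act, e, 0.0)
    out = ExcitationTrajectory(excitations.times, gated, excitations.muscle_names)
    return out, dof_mask


def run_dsc_nms(
    trial: Trial,
    neural_model: NeuralModel,
    wrist_model: WristModel,
    scaler: KinematicsScaler,
    grid: WindowGrid,
    rule: GatingRule | None = None,
    sim_dt: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Full open-loop chain for one trial.

    Spike counts -> neural mapping -> gate -> forward dynamics -> inverse
    scaling.  Returns ``(window_times, q_deg_like)`` with the prediction
    sampled at the window start times, in recorded (pre-scaling) radians.
    """
    dsc = extract_dsc(trial.spikes, grid)
    td = None
    if trial.emg is not None:
        filt = preprocess_emg(trial.emg.samples, trial.emg.sample_rate)
        td = extract_td(filt, grid, trial.emg.sample_rate).values
    exc = predict_excitations(neural_model, dsc, td)
    gated, dof_mask = gate_excitations(exc, rule)
    _, q_sim, _ = forward_simulate(
        wrist_model, gated, dt=sim_dt, duration=trial.times[-1], dof_gate=dof_mask
    )
    sim_t = np.arange(q_sim.shape[0]) * sim_dt
    q_win = np.column_stack(
        [np.interp(grid.start_times, sim_t, q_sim[:, d]) for d in range(3)]
    )
    return grid.start_times, scaler.inverse(q_win)


def r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination: 1 - SSE/SST."""
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.size != y_hat.size or y.size < 2:
        raise ValueError("need equal-length series with >= 2 samples")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ValueError("R^2 undefined for zero-variance reference")
    sse = float(np.sum((y - y_hat) ** 2))
    return 1.0 - sse / sst


def rmse(y: np.ndarray, y_hat: np.ndarray, degrees: bool = True) -> float:
    """Root-mean-square error; in degrees by default (inputs in radians)."""
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.size != y_hat.size or y.size < 1:
        raise ValueError("need equal-length series")
    err = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    return float(np.degrees(err)) if degrees else err


def make_folds(
    n_repetitions: int, folds: int, repeats: int, seed: int,
    cells: list[tuple[str, str]] | None = None,
) -> list[list[dict[tuple[str, str], int]]]:
    """Random repetition-level fold assignments.

    For every repeat a random permutation of the repetition indices is drawn
    independently for each (DoF, direction) cell; fold f holds out repetition
    ``perm[f]`` of each cell (the remaining repetitions train).  Returns
    ``assignments[repeat][fold][cell] -> test repetition index (1-based)``.
    """
    if folds > n_repetitions:
        raise ValueError("more folds than repetitions")
    cells = cells or [(d, s) for d in DOF_NAMES for s in DIRECTIONS]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        perms = {cell: rng.permutation(n_repetitions) + 1 for cell in cells}
        out.append([{cell: int(perms[cell][f]) for cell in cells} for f in range(folds)])
    return out


@dataclass
class _FittedMethods:
    scaler: KinematicsScaler
    neural_model: NeuralModel | None = None
    ann_models: dict[str, dict[str, ANNModel]] = field(default_factory=dict)
    pca: dict[str, object] = field(default_factory=dict)
    dsc_units: list[str] = field(default_factory=list)
    train_tags: tuple = ()


def _trial_dsc(trial: Trial, grid: WindowGrid, unit_ids: list[str]) -> DSCMatrix:
    """DSC with a fixed unit-column universe (zeros for absent units)."""
    local = extract_dsc(trial.spikes, grid)
    counts = np.zeros((grid.n_windows, len(unit_ids)), dtype=int)
    pos = {u: j for j, u in enumerate(local.unit_ids)}
    for j, u in enumerate(unit_ids):
        if u in pos:
            counts[:, j] = local.counts[:, pos[u]]
    return DSCMatrix(counts, grid, list(unit_ids))


def _trial_td(trial: Trial, grid: WindowGrid) -> np.ndarray:
    filt = preprocess_emg(trial.emg.samples, trial.emg.sample_rate)
    return extract_td(filt, grid, trial.emg.sample_rate).values


def _window_kinematics(trial: Trial, grid: WindowGrid) -> np.ndarray:
    return np.column_stack(
        [np.interp(grid.start_times, trial.times, trial.kinematics[:, d]) for d in range(3)]
    )


def _fit_methods(
    train: list[Trial],
    dataset: Dataset,
    methods: tuple[str, ...],
    seed: int,
    ann_restarts: int,
    ann_max_iter: int,
    tracking: TrackingConfig,
) -> _FittedMethods:
    grid = dataset.grid
    model = dataset.model
    scaler = fit_scaler(np.vstack([t.kinematics for t in train]), model)
    fitted = _FittedMethods(scaler=scaler, train_tags=tuple(id(t) for t in train))
    unit_ids = sorted({u for t in train for u in t.spikes.unit_ids})
    fitted.dsc_units = unit_ids

    need_td = any(m in methods for m in ("td", "td_dsc", "dsc_nms"))
    td_train = [_trial_td(t, grid) for t in train] if need_td else None
    dsc_train = [_trial_dsc(t, grid, unit_ids) for t in train]
    kin_train = [_window_kinematics(t, grid) for t in train]

    ss = np.random.SeedSequence(seed)
    seeds = {m: s for m, s in zip(("td", "td_dsc", "dsc_nms"), ss.spawn(3))}

    if "dsc_nms" in methods:
        # calibration supervision: tracking excitations on scaled kinematics
        exc_train = []
        for t in train:
            exc, _ = tracking_excitations(
                model, t.times, scaler.scale(t.kinematics), grid, tracking,
                actuated_dof=t.actuated_dof,
            )
            exc_train.append(exc)
        assignment = assign_units(
            [t.spikes for t in train], exc_train
        )
        pca_fb = fit_pca(np.vstack(td_train))
        fitted.neural_model = train_neural_model(
            dsc_train, exc_train, td_train, assignment,
            fallback_pca=pca_fb, ann_restarts=ann_restarts,
            ann_seed=int(seeds["dsc_nms"].generate_state(1)[0]),
            ann_max_iter=ann_max_iter,
        )

    for method in ("td", "td_dsc"):
        if method not in methods:
            continue
        if method == "td":
            feats = np.vstack(td_train)
        else:
            feats = np.vstack(
                [concat_td_dsc(_td_as_matrix(td, grid), d) for td, d in zip(td_train, dsc_train)]
            )
        pca = fit_pca(feats)
        scores = apply_pca(pca, feats)
        targets = np.vstack(kin_train)
        fitted.pca[method] = pca
        dof_seeds = seeds[method].spawn(3)
        fitted.ann_models[method] = {
            dof: train_ann(
                scores, targets[:, d], restarts=ann_restarts,
                seed=int(dof_seeds[d].generate_state(1)[0]), max_iter=ann_max_iter,
            )
            for d, dof in enumerate(DOF_NAMES)
        }
    return fitted


def _td_as_matrix(td_values: np.ndarray, grid: WindowGrid):
    from .emg_baseline import TDMatrix

    return TDMatrix(td_values, grid, td_values.shape[1] // 4)


def _predict_method(
    method: str,
    trial: Trial,
    fitted: _FittedMethods,
    dataset: Dataset,
    rule: GatingRule,
    lowpass_cutoff: float,
) -> np.ndarray:
    grid = dataset.grid
    if method == "dsc_nms":
        _, q_hat = run_dsc_nms(
            trial, fitted.neural_model, dataset.model, fitted.scaler, grid, rule
        )
        return q_hat
    td = _trial_td(trial, grid)
    if method == "td":
        feats = td
    else:
        feats = concat_td_dsc(
            _td_as_matrix(td, grid), _trial_dsc(trial, grid, fitted.dsc_units)
        )
    scores = apply_pca(fitted.pca[method], feats)
    est = np.column_stack(
        [predict_ann(fitted.ann_models[method][dof], scores) for dof in DOF_NAMES]
    )
    window_rate = 1.0 / grid.window_step
    return lowpass_estimates(est, lowpass_cutoff, window_rate)


def crossvalidate(
    dataset: Dataset,
    methods: tuple[str, ...] = METHODS,
    folds: int = 3,
    repeats: int = 10,
    seed: int = 0,
    subject: str = "S1",
    ann_restarts: int = 50,
    ann_max_iter: int = 100,
    gating: GatingRule | None = None,
    lowpass_cutoff: float = 1.5,
    tracking: TrackingConfig | None = None,
) -> pd.DataFrame:
    """Repetition-level cross-validated evaluation of the selected methods.

    Per repeat and fold, two repetitions of each direction of each DoF train
    every fitted artifact (scaler, calibration excitations, assignment, unit
    regressors, PCA loadings, ANNs); the held-out repetition is evaluated.
    Metrics are computed per DoF over the concatenated test trajectories.
    Returns a tidy table with columns method, subject, repeat, fold, dof, r2,
    rmse_deg, seed.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    reps_present = sorted({t.repetition_index for t in dataset.trials})
    n_reps = len(reps_present)
    cells = [(d, s) for d in DOF_NAMES for s in DIRECTIONS]
    for cell in cells:
        for rep in reps_present:
            if not dataset.select(*cell, repetitions=[rep]):
                raise ValueError(f"missing repetition {rep} for cell {cell}")
    assignments = make_folds(n_reps, folds, repeats, seed, cells)
    gating = gating or GatingRule()
    tracking = tracking or TrackingConfig()

    rows = []
    ss = np.random.SeedSequence(seed + 1)
    fit_seeds = iter(ss.spawn(repeats * folds))
    for rep_i, per_fold in enumerate(assignments):
        for fold_i, test_map in enumerate(per_fold):
            train, test = [], []
            for tr in dataset.trials:
                cell = (tr.task.dof, tr.task.direction)
                (test if tr.repetition_index == test_map[cell] else train).append(tr)
            fitted = _fit_methods(
                train, dataset, methods, int(next(fit_seeds).generate_state(1)[0]),
                ann_restarts, ann_max_iter, tracking,
            )
            preds = {
                m: [_predict_method(m, t, fitted, dataset, gating, lowpass_cutoff) for t in test]
                for m in methods
            }
            kin = [_window_kinematics(t, dataset.grid) for t in test]
            for m in methods:
                for d, dof in enumerate(DOF_NAMES):
                    y = np.concatenate([k[:, d] for k in kin])
                    y_hat = np.concatenate([p[:, d] for p in preds[m]])
                    rows.append(
                        {
                            "method": m,
                            "subject": subject,
                            "repeat": rep_i,
                            "fold": fold_i,
                            "dof": dof,
                            "r2": r2(y, y_hat),
                            "rmse_deg": rmse(y, y_hat),
                            "seed": seed,
                        }
                    )
    return pd.DataFrame(rows)


def compare_methods(results: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary: mean and sd of each metric per method and DoF."""
    if results.empty:
        raise ValueError("empty results")
    agg = results.groupby(["method", "dof"]).agg(
        r2_mean=("r2", "mean"),
        r2_sd=("r2", lambda s: s.std(ddof=0) if len(s) > 1 else 0.0),
        rmse_deg_mean=("rmse_deg", "mean"),
        rmse_deg_sd=("rmse_deg", lambda s: s.std(ddof=0) if len(s) > 1 else 0.0),
        n=("r2", "size"),
    )
    return agg.reset_index()
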