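"""Interference-EMG baseline: TD features, PCA, and small LM-trained ANNs.

The comparison path extracts classical time-domain (TD) features — root mean
square, slope-sign changes, zero crossings and waveform length — from the
rectified, band-pass-filtered multichannel EMG on the shared window grid,
reduces them with PCA keeping 98 % of the training variance, and regresses
targets with a one-hidden-layer (3 tanh units) network trained by
Levenberg-Marquardt, taking the best of several random restarts.  The same
network is reused as the per-muscle fallback of the neural mapping.  Kinematic
estimates of the baselines are low-pass filtered post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt
from sklearn.decomposition import PCA

from .spike_features import DSCMatrix, WindowGrid

__all__ = [
    "TDMatrix",
    "PCAModel",
    "ANNModel",
    "preprocess_emg",
    "extract_td",
    "fit_pca",
    "apply_pca",
    "train_ann",
    "predict_ann",
    "predict_ann_dof",
    "lowpass_estimates",
    "concat_td_dsc",
]

TD_FEATURE_NAMES = ("RMS", "SSC", "ZC", "WL")


@dataclass
class TDMatrix:
    """windows x (channels * 4) TD feature matrix (per channel: RMS, SSC, ZC, WL)."""

    values: np.ndarray
    grid: WindowGrid
    n_channels: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.grid.n_windows, self.n_channels * 4):
            raise ValueError("TD matrix shape mismatch")

    @property
    def feature_names(self) -> list[str]:
        return [f"ch{c}_{f}" for c in range(self.n_channels) for f in TD_FEATURE_NAMES]


def preprocess_emg(
    samples: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = (20.0, 500.0),
    order: int = 4,
    rectify_first: bool = True,
) -> np.ndarray:
    """Full-wave rectification then zero-phase Butterworth band-pass.

    ``rectify_first=False`` switches to the conventional filter-then-rectify
    order for sensitivity checks.
    """
    x = np.atleast_2d(np.asarray(samples, float))
    if sample_rate <= 1000:
        raise ValueError("sample rate must exceed 1 kHz")
    lo, hi = band
    if hi >= sample_rate / 2 or lo <= 0:
        raise ValueError("band edges must lie inside (0, Nyquist)")
    sos = butter(order, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    if rectify_first:
        return sosfiltfilt(sos, np.abs(x), axis=-1)
    return np.abs(sosfiltfilt(sos, x, axis=-1))


def _window_slices(grid: WindowGrid, sample_rate: float, n_samples: int):
    length = int(round(grid.window_length * sample_rate))
    for t0 in grid.start_times:
        i0 = int(round(t0 * sample_rate))
        i1 = min(i0 + length, n_samples)
        yield i0, i1


def extract_td(
    filtered: np.ndarray,
    grid: WindowGrid,
    sample_rate: float,
    deadband_frac: float = 0.01,
) -> TDMatrix:
    """TD features per window and channel.

    RMS = sqrt(mean x^2); ZC counts sign changes whose amplitude step exceeds
    the deadband; SSC counts slope-sign changes with at least one adjacent
    slope above the deadband; WL is the summed absolute first difference.  The
    deadband is ``deadband_frac`` of each channel's whole-signal RMS.
    """
    x = np.atleast_2d(np.asarray(filtered, float))
    n_ch, n_samp = x.shape
    if grid.end > n_samp / sample_rate + 1e-9:
        raise ValueError("window grid extends beyond the signal")
    delta = deadband_frac * np.sqrt(np.mean(x**2, axis=1))
    out = np.zeros((grid.n_windows, n_ch * 4))
    for w, (i0, i1) in enumerate(_window_slices(grid, sample_rate, n_samp)):
        seg = x[:, i0:i1]
        d = np.diff(seg, axis=1)
        rms = np.sqrt(np.mean(seg**2, axis=1))
        zc = np.sum(
            (seg[:, :-1] * seg[:, 1:] < 0) & (np.abs(d) >= delta[:, None]), axis=1
        )
        slope_change = d[:, :-1] * d[:, 1:] < 0
        big = (np.abs(d[:, :-1]) >= delta[:, None]) | (np.abs(d[:, 1:]) >= delta[:, None])
        ssc = np.sum(slope_change & big, axis=1)
        wl = np.sum(np.abs(d), axis=1)
        out[w] = np.column_stack([rms, ssc, zc, wl]).reshape(-1)
    return TDMatrix(out, grid, n_ch)


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray  # n_components x n_features
    explained_variance_ratio: np.ndarray
    target_variance: float

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[0])


def fit_pca(train_features: np.ndarray, target_variance: float = 0.98) -> PCAModel:
    """PCA loadings from training features, keeping >= target variance."""
    X = np.asarray(train_features, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training windows")
    full = PCA(svd_solver="full").fit(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    k = int(np.searchsorted(cum, target_variance - 1e-12) + 1)
    k = min(k, full.components_.shape[0])
    return PCAModel(
        mean=full.mean_,
        loadings=full.components_[:k],
        explained_variance_ratio=full.explained_variance_ratio_[:k],
        target_variance=target_variance,
    )


def apply_pca(model: PCAModel, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, float)
    return (X - model.mean) @ model.loadings.T


# ---------------------------------------------------------------------------
# small feed-forward network trained with Levenberg-Marquardt
# ---------------------------------------------------------------------------


@dataclass
class ANNModel:
    """1-hidden-layer (tanh) network with linear output, single target."""

    w1: np.ndarray  # n_hidden x n_in
    b1: np.ndarray  # n_hidden
    w2: np.ndarray  # n_hidden
    b2: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_offset: float
    y_scale: float
    train_record: dict = field(default_factory=dict)


def _net_forward(w1, b1, w2, b2, X):
    H = np.tanh(X @ w1.T + b1)
    return H @ w2 + b2, H


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta, n_hidden, n_in):
    i = n_hidden * n_in
    w1 = theta[:i].reshape(n_hidden, n_in)
    b1 = theta[i : i + n_hidden]
    w2 = theta[i + n_hidden : i + 2 * n_hidden]
    b2 = theta[i + 2 * n_hidden]
    return w1, b1, w2, b2


def _lm_fit(X, y, theta0, n_hidden, max_iter=100, lam0=1e-2, tol=1e-10):
    """Levenberg-Marquardt on the network residuals."""
    n, n_in = X.shape
    theta = theta0.copy()
    lam = lam0
    w1, b1, w2, b2 = _unpack(theta, n_hidden, n_in)
    pred, H = _net_forward(w1, b1, w2, b2, X)
    r = y - pred
    sse = float(r @ r)
    for _ in range(max_iter):
        dH = (1.0 - H**2) * w2  # n x h : d pred / d z_k
        J = np.empty((n, theta.size))
        J[:, : n_hidden * n_in] = (dH[:, :, None] * X[:, None, :]).reshape(n, -1)
        J[:, n_hidden * n_in : n_hidden * n_in + n_hidden] = dH
        J[:, n_hidden * n_in + n_hidden : n_hidden * n_in + 2 * n_hidden] = H
        J[:, -1] = 1.0
        g = J.T @ r
        if np.max(np.abs(g)) < tol:
            break
        JtJ = J.T @ J
        improved = False
        for _ in range(12):
            try:
                step = np.linalg.solve(JtJ + lam * np.eye(theta.size), g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            cand = theta + step
            w1, b1, w2, b2 = _unpack(cand, n_hidden, n_in)
            pred_c, H_c = _net_forward(w1, b1, w2, b2, X)
            r_c = y - pred_c
            sse_c = float(r_c @ r_c)
            if sse_c < sse:
                theta, r, sse, H = cand, r_c, sse_c, H_c
                lam = max(lam / 10, 1e-12)
                improved = True
                break
            lam *= 10
        if not improved or lam > 1e10:
            break
    return theta, sse


def train_ann(
    features: np.ndarray,
    targets: np.ndarray,
    n_hidden: int = 3,
    restarts: int = 50,
    seed: int | None = None,
    max_iter: int = 100,
    val_fraction: float = 0.2,
) -> ANNModel:
    """Train ``restarts`` networks from random initializations, keep the best.

    Each restart is trained with Levenberg-Marquardt; the selected network is
    the one with the lowest MSE on a 20 % held-out validation split of the
    training windows.  Features are standardized and targets mapped to
    [-1, 1] internally; predictions are returned on the original scale.
    """
    X = np.asarray(features, float)
    y = np.asarray(targets, float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features/targets misaligned")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale < 1e-12] = 1.0
    Xs = (X - x_mean) / x_scale
    y_lo, y_hi = float(y.min()), float(y.max())
    y_scale = (y_hi - y_lo) / 2.0 or 1.0
    y_offset = (y_hi + y_lo) / 2.0
    ys = (y - y_offset) / y_scale

    n = X.shape[0]
    n_val = max(int(round(val_fraction * n)), 1) if n > 4 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx = perm
    Xtr, ytr = Xs[tr_idx], ys[tr_idx]
    Xval, yval = (Xs[val_idx], ys[val_idx]) if n_val else (Xtr, ytr)

    best = None
    errors = []
    for _ in range(restarts):
        theta0 = rng.normal(scale=0.5, size=n_hidden * X.shape[1] + 2 * n_hidden + 1)
        theta, _ = _lm_fit(Xtr, ytr, theta0, n_hidden, max_iter=max_iter)
        w1, b1, w2, b2 = _unpack(theta, n_hidden, X.shape[1])
        pred_val, _ = _net_forward(w1, b1, w2, b2, Xval)
        err = float(np.mean((yval - pred_val) ** 2))
        errors.append(err)
        if best is None or err < best[0]:
            best = (err, theta)
    w1, b1, w2, b2 = _unpack(best[1], n_hidden, X.shape[1])
    return ANNModel(
        w1=w1, b1=b1, w2=w2, b2=float(b2),
        x_mean=x_mean, x_scale=x_scale,
        y_offset=y_offset, y_scale=y_scale,
        train_record={"restarts": restarts, "selection_errors": errors,
                      "best_error": best[0]},
    )


def predict_ann(model: ANNModel, features: np.ndarray) -> np.ndarray:
    X = (np.atleast_2d(np.asarray(features, float)) - model.x_mean) / model.x_scale
    pred, _ = _net_forward(model.w1, model.b1, model.w2, model.b2, X)
    return pred * model.y_scale + model.y_offset


def predict_ann_dof(models: dict[str, ANNModel], scores: np.ndarray,
                    lowpass_cutoff: float | None = 1.5,
                    window_rate: float | None = None) -> np.ndarray:
    """Per-DoF kinematics estimates from PCA scores, one network per DoF."""
    from .musculoskeletal import DOF_NAMES

    missing = [d for d in DOF_NAMES if d not in models]
    if missing:
        raise ValueError(f"missing ANN model for DoF(s): {missing}")
    est = np.column_stack([predict_ann(models[d], scores) for d in DOF_NAMES])
    if lowpass_cutoff is not None:
        if window_rate is None:
            raise ValueError("window_rate required for post-hoc low-pass")
        est = lowpass_estimates(est, lowpass_cutoff, window_rate)
    return est


def lowpass_estimates(series: np.ndarray, cutoff: float, sample_rate: float,
                      order: int = 2) -> np.ndarray:
    """Zero-phase low-pass of estimate streams (columns are channels)."""
    if cutoff >= sample_rate / 2:
        raise ValueError("cutoff must be below Nyquist")
    x = np.asarray(series, float)
    sos = butter(order, cutoff, btype="lowpass", fs=sample_rate, output="sos")
    padlen = min(3 * (2 * len(sos) + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum())),
                 x.shape[0] - 1)
    return sosfiltfilt(sos, x, axis=0, padlen=padlen)


def concat_td_dsc(td: TDMatrix, dsc: DSCMatrix) -> np.ndarray:
    """Column-wise concatenation of TD and DSC blocks (TD first)."""
    if td.grid.n_windows != dsc.grid.n_windows or not np.allclose(
        td.grid.start_times, dsc.grid.start_times
    ):
        raise ValueError("TD and DSC window grids differ")
    return np.hstack([td.values, dsc.counts.astype(float)])
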