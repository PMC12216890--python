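"""Decoding of behavior from neural population activity.

Three decoder families:

* gait-event detection with a multiclass regularized LDA on binned rate
  windows preceding each event (classes: foot-strike, foot-off, none),
  detections declared on upward 80%-posterior crossings with a 100 ms
  same-class refractory period, scored by the mean F-score of the two
  event classes against the true event times;
* task classification from per-cycle behavioral features with 5-fold
  cross-validated regularized LDA;
* Wiener-filter reconstruction of EMG envelopes (100 ms window) and joint
  kinematics/velocities (300 ms window) from lagged population rates, with
  the ridge parameter chosen by 5-fold cross-validation on a calibration
  task and performance reported as R^2 on the remaining tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .prep import FS_RATE, GaitEventTable, RateMatrix

CLASS_NONE, CLASS_STRIKE, CLASS_OFF = 0, 1, 2
POSTERIOR_THRESHOLD = 0.80
REFRACTORY_MS = 100.0
MATCH_TOLERANCE_MS = 125.0
POSTERIOR_STEP_MS = 10.0

DEFAULT_L_GRID = (100, 200, 300, 400, 500)        # ms of neural history
DEFAULT_B_GRID = (5, 10)                          # bins within the window
DEFAULT_REG_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 0.5)  # LDA shrinkage


@dataclass
class EventDecoderModel:
    lda: LinearDiscriminantAnalysis
    feature_len_ms: int
    n_bins: int
    reg: float
    calibration_task: object
    fs: float = FS_RATE
    threshold: float = POSTERIOR_THRESHOLD
    refractory_ms: float = REFRACTORY_MS
    cv_score: float = float("nan")

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.refractory_ms <= 0:
            raise ValueError("refractory period must be positive")
        if (self.feature_len_ms * self.fs / 1000.0) % self.n_bins:
            raise ValueError("window length must be an integral number of bins")


def _bin_window(rates: np.ndarray, end_idx: np.ndarray, l_samp: int, b: int):
    """Mean-binned features of the windows ending at ``end_idx`` (exclusive).

    Returns (len(end_idx), channels * b).  Uses a cumulative sum so many
    windows are extracted at once.
    """
    csum = np.concatenate([np.zeros((rates.shape[0], 1)), np.cumsum(rates, axis=1)],
                          axis=1)
    width = l_samp // b
    edges = np.array([end_idx - l_samp + width * j for j in range(b + 1)]).T
    feats = (csum[:, edges[:, 1:]] - csum[:, edges[:, :-1]]) / width
    # feats: channels x windows x bins -> windows x (channels*bins)
    return feats.transpose(1, 0, 2).reshape(len(end_idx), -1)


def _event_times(events: GaitEventTable, task):
    rows = events.for_task(task).sort_values("t_strike_start")
    strikes = rows.t_strike_start.to_numpy().tolist()
    if len(rows):
        strikes.append(float(rows.t_strike_end.iloc[-1]))
    offs = rows.t_foot_off.to_numpy().tolist()
    return np.asarray(strikes), np.asarray(offs)


def _training_set(rates: RateMatrix, events: GaitEventTable, task,
                  l_ms: int, b: int):
    strikes, offs = _event_times(events, task)
    marks = np.concatenate([strikes, offs])
    labels = np.concatenate([
        np.full(strikes.size, CLASS_STRIKE), np.full(offs.size, CLASS_OFF)
    ])
    order = np.argsort(marks)
    marks, labels = marks[order], labels[order]
    mids = (marks[:-1] + marks[1:]) / 2.0          # "none" exemplars
    times = np.concatenate([marks, mids])
    y = np.concatenate([labels, np.full(mids.size, CLASS_NONE)])
    l_samp = int(round(l_ms * rates.fs / 1000.0))
    idx = np.round(times * rates.fs).astype(int)
    ok = (idx >= l_samp) & (idx <= rates.n_samples)
    x = _bin_window(rates.rates, idx[ok], l_samp, b)
    return x, y[ok]


def fit_event_decoder(rates: RateMatrix, events: GaitEventTable, calibration_task,
                      l_grid=DEFAULT_L_GRID, b_grid=DEFAULT_B_GRID,
                      reg_grid=DEFAULT_REG_GRID, n_folds: int = 5,
                      seed: int = 0) -> EventDecoderModel:
    """Calibrate the gait-event rLDA on one task.

    Feature length, bin count and shrinkage are selected by stratified
    cross-validation on the calibration task (score: mean F over the two
    event classes); ties prefer shorter windows, then fewer bins, then
    stronger regularization.  The returned model is refit on the whole
    calibration task.
    """
    if calibration_task not in events.task_ids:
        raise ValueError(f"calibration task {calibration_task!r} not in events")
    results = []
    for l_ms in l_grid:
        for b in b_grid:
            x, y = _training_set(rates, events, calibration_task, l_ms, b)
            counts = np.bincount(y, minlength=3)
            if counts[CLASS_STRIKE] < 10 or counts[CLASS_OFF] < 10:
                raise ValueError("fewer than 10 events per class")
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            for reg in reg_grid:
                scores = []
                for tr, te in skf.split(x, y):
                    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=reg)
                    lda.fit(x[tr], y[tr])
                    scores.append(_classwise_f(y[te], lda.predict(x[te])))
                results.append((float(np.mean(scores)), l_ms, b, reg))
    best_score = max(r[0] for r in results)
    ties = [r for r in results if r[0] >= best_score - 1e-12]
    ties.sort(key=lambda r: (r[1], r[2], -r[3]))
    _, l_ms, b, reg = ties[0]
    x, y = _training_set(rates, events, calibration_task, l_ms, b)
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=reg)
    lda.fit(x, y)
    return EventDecoderModel(lda=lda, feature_len_ms=l_ms, n_bins=b, reg=reg,
                             calibration_task=calibration_task, fs=rates.fs,
                             cv_score=best_score)


def _classwise_f(y_true, y_pred) -> float:
    """Mean F-score of the two gait-event classes."""
    fs = []
    for c in (CLASS_STRIKE, CLASS_OFF):
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        fs.append(2 * p * r / (p + r) if p + r else 0.0)
    return float(np.mean(fs))


def _match_events(det_times: np.ndarray, true_times: np.ndarray,
                  tol_s: float):
    """Greedily match detections to the nearest unmatched true event."""
    matched_true = np.zeros(true_times.size, dtype=bool)
    tp = 0
    for t in det_times:
        if true_times.size == 0:
            break
        dist = np.abs(true_times - t)
        dist[matched_true] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= tol_s:
            matched_true[j] = True
            tp += 1
    fp = det_times.size - tp
    fn = true_times.size - tp
    return tp, fp, fn


def run_event_decoder(model: EventDecoderModel, rates: RateMatrix,
                      events: GaitEventTable, tasks=None,
                      tolerance_ms: float = MATCH_TOLERANCE_MS,
                      step_ms: float = POSTERIOR_STEP_MS) -> dict:
    """Detect gait events in (held-out) tasks and score against the truth.

    Posteriors are evaluated on a sliding grid; a detection is an upward
    crossing of the 80% threshold, with same-class detections inside the
    refractory window suppressed.  Detections are matched to the nearest
    unmatched true event of the same class within the tolerance; the
    F-score is the mean over the foot-strike and foot-off classes.
    """
    if tasks is None:
        tasks = [t for t in events.task_ids if t != model.calibration_task]
    l_samp = int(round(model.feature_len_ms * rates.fs / 1000.0))
    step = int(round(step_ms * rates.fs / 1000.0))
    refr = model.refractory_ms / 1000.0
    per_class = {CLASS_STRIKE: [0, 0, 0], CLASS_OFF: [0, 0, 0]}
    detections = {}
    for task in tasks:
        rows = events.for_task(task)
        t0 = float(rows.t_strike_start.min())
        t1 = float(rows.t_strike_end.max())
        i0 = max(l_samp, int(round(t0 * rates.fs)) - l_samp)
        i1 = min(rates.n_samples, int(round(t1 * rates.fs)) + step)
        end_idx = np.arange(i0, i1, step)
        x = _bin_window(rates.rates, end_idx, l_samp, model.n_bins)
        proba = model.lda.predict_proba(x)
        times = end_idx / rates.fs
        true_strikes, true_offs = _event_times(events, task)
        for cls, truth in ((CLASS_STRIKE, true_strikes), (CLASS_OFF, true_offs)):
            col = list(model.lda.classes_).index(cls)
            p = proba[:, col]
            above = p >= model.threshold
            crossing = above & ~np.concatenate([[False], above[:-1]])
            det = []
            last = -np.inf
            for t in times[crossing]:
                if t - last >= refr:
                    det.append(t)
                    last = t
            det = np.asarray(det)
            detections[(task, cls)] = det
            tp, fp, fn = _match_events(det, truth, tolerance_ms / 1000.0)
            per_class[cls][0] += tp
            per_class[cls][1] += fp
            per_class[cls][2] += fn
    scores = {}
    f_values = []
    for cls, name in ((CLASS_STRIKE, "foot_strike"), (CLASS_OFF, "foot_off")):
        tp, fp, fn = per_class[cls]
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        scores[name] = {"precision": p, "recall": r, "f": f,
                        "tp": tp, "fp": fp, "fn": fn}
        f_values.append(f)
    scores["f_score"] = float(np.mean(f_values))
    scores["detections"] = detections
    return scores


# ---------------------------------------------------------------------------
# Task classification from behavioral features
# ---------------------------------------------------------------------------

def classify_task(features: np.ndarray, labels: np.ndarray, n_folds: int = 5,
                  shrinkage="auto", seed: int = 0):
    """5-fold cross-validated rLDA task classification.

    Returns ``(accuracy, confusion)`` where the confusion matrix rows are
    true tasks (row sums equal the per-task trial counts) pooled over the
    folds.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 tasks")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    accs = []
    for tr, te in skf.split(features, labels):
        if np.unique(labels[tr]).size < classes.size:
            raise ValueError("a task is absent from a training fold")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        lda.fit(features[tr], labels[tr])
        pred = lda.predict(features[te])
        accs.append(float(np.mean(pred == labels[te])))
        for yt, yp in zip(labels[te], pred):
            confusion[np.searchsorted(classes, yt),
                      np.searchsorted(classes, yp)] += 1
    return float(np.mean(accs)), confusion


# ---------------------------------------------------------------------------
# Wiener filter reconstruction
# ---------------------------------------------------------------------------

@dataclass
class WienerModel:
    weights: np.ndarray        # (n_lags * channels + 1) x outputs, incl. intercept
    lags_ms: np.ndarray
    window_ms: float
    lam: float
    degree: int
    poly: np.ndarray | None    # per-output polynomial coefficients (degree > 1)
    calibration_task: object = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite Wiener weights")


def _lagged_design(rates: np.ndarray, sample_idx: np.ndarray,
                   lag_samples: np.ndarray) -> np.ndarray:
    cols = [rates[:, sample_idx - lag] for lag in lag_samples]
    x = np.concatenate(cols, axis=0).T           # samples x (lags*channels)
    return np.column_stack([x, np.ones(len(sample_idx))])


def fit_apply_wiener(rates: np.ndarray, targets: np.ndarray, *, window_ms: float,
                     calibration_idx: np.ndarray, eval_idx: dict | None = None,
                     lambda_grid=None, n_folds: int = 5, degree: int = 1,
                     lag_step_ms: float = 10.0, stride_ms: float = 10.0,
                     fs: float = FS_RATE, calibration_task=None):
    """Wiener(-cascade) reconstruction of target time series from rates.

    ``calibration_idx`` are the 1 kHz sample indices of the calibration
    task; ``eval_idx`` maps names to held-out index arrays.  The filter
    uses lags 0, 10, ..., window-10 ms; the ridge parameter is chosen by
    5-fold contiguous-block cross-validation on the calibration samples,
    the final model is fit on all of them, and R^2 = 1 - Var(err)/Var(y)
    is reported per target on each evaluation set.  ``degree`` > 1 adds a
    static per-output polynomial after the linear stage.
    """
    rates = np.asarray(rates, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    lag_step = int(round(lag_step_ms * fs / 1000.0))
    n_lags = int(round(window_ms / lag_step_ms))
    if n_lags < 1:
        raise ValueError("window shorter than one lag")
    lag_samples = np.arange(n_lags) * lag_step
    stride = max(1, int(round(stride_ms * fs / 1000.0)))

    def usable(idx):
        idx = np.asarray(idx)
        return idx[(idx >= lag_samples.max())][::stride]

    cal = usable(calibration_idx)
    x_cal = _lagged_design(rates, cal, lag_samples)
    y_cal = targets[:, cal].T
    if lambda_grid is None:
        scale = float(np.mean(np.sum(x_cal[:, :-1] ** 2, axis=0)))
        lambda_grid = scale * np.logspace(-6, 2, 9)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))

    fold = np.minimum((np.arange(len(cal)) * n_folds) // len(cal), n_folds - 1)
    cv_scores = np.zeros(lambda_grid.size)
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        gram = x_cal[tr].T @ x_cal[tr]
        xty = x_cal[tr].T @ y_cal[tr]
        for i, lam in enumerate(lambda_grid):
            reg = lam * np.eye(gram.shape[0])
            reg[-1, -1] = 0.0                    # do not penalize the intercept
            w = np.linalg.solve(gram + reg, xty)
            pred = x_cal[te] @ w
            cv_scores[i] += _mean_r2(y_cal[te], pred)
    lam = float(lambda_grid[int(np.argmax(cv_scores))])
    gram = x_cal.T @ x_cal
    reg = lam * np.eye(gram.shape[0])
    reg[-1, -1] = 0.0
    weights = np.linalg.solve(gram + reg, x_cal.T @ y_cal)

    poly = None
    if degree > 1:
        lin = x_cal @ weights
        poly = np.stack([
            np.polyfit(lin[:, j], y_cal[:, j], degree) for j in range(y_cal.shape[1])
        ])
    model = WienerModel(weights=weights, lags_ms=lag_samples / fs * 1000.0,
                        window_ms=window_ms, lam=lam, degree=degree, poly=poly,
                        calibration_task=calibration_task)

    results = {"lambda": lam, "cv_curve": cv_scores / n_folds, "eval_r2": {}}
    for name, idx in (eval_idx or {}).items():
        idx = usable(idx)
        pred = apply_wiener(model, rates, idx, fs=fs)
        truth = targets[:, idx].T
        results["eval_r2"][name] = np.array([
            _r2_single(truth[:, j], pred[:, j]) for j in range(truth.shape[1])
        ])
    return model, results


def apply_wiener(model: WienerModel, rates: np.ndarray, sample_idx: np.ndarray,
                 fs: float = FS_RATE) -> np.ndarray:
    lag_samples = np.round(model.lags_ms * fs / 1000.0).astype(int)
    x = _lagged_design(np.asarray(rates, dtype=float), sample_idx, lag_samples)
    pred = x @ model.weights
    if model.poly is not None:
        pred = np.column_stack([
            np.polyval(model.poly[j], pred[:, j]) for j in range(pred.shape[1])
        ])
    return pred


def _r2_single(y, y_hat) -> float:
    total = np.var(y)
    if total == 0:
        return float("nan")
    return 1.0 - float(np.var(y - y_hat) / total)


def _mean_r2(y, y_hat) -> float:
    return float(np.mean([_r2_single(y[:, j], y_hat[:, j])
                          for j in range(y.shape[1])]))


def savgol_velocity(positions: np.ndarray, window: int, polyorder: int,
                    fs: float = 100.0) -> np.ndarray:
    """First-derivative Savitzky-Golay velocity estimate of uniformly
    sampled positions (last axis = time)."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    return savgol_filter(np.asarray(positions, dtype=float), window, polyorder,
                         deriv=1, delta=1.0 / fs, axis=-1)
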