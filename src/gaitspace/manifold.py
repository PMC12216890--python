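"""Neural-manifold dimensionality and the alignment index.

The manifold of a dataset is the span of its leading principal components;
its dimensionality is the smallest number of components whose cumulative
variance exceeds a threshold (90% by default).  Single-task, all-task,
leave-one-task-out and channel-subsampled variants are provided, together
with the alignment index: the fraction of one task's variance retained when
its activity is projected into another task's manifold, normalized by the
variance retained in its own manifold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .prep import PeriGaitTensor

VARIANCE_THRESHOLD = 0.90


@dataclass
class ManifoldModel:
    """PCA manifold: per-channel mean, orthonormal encoder/decoder, spectrum."""

    mean: np.ndarray          # per-channel mean
    encoder: np.ndarray       # m x n, rows orthonormal (E_m)
    spectrum: np.ndarray      # all eigenvalues, descending
    threshold: float
    d: int                    # manifold dimensionality at the threshold

    @property
    def decoder(self) -> np.ndarray:
        """n x m decoding matrix, the transpose of the encoder."""
        return self.encoder.T

    def captured_variance(self, x: np.ndarray, m: int | None = None) -> float:
        """Fraction of the (centered) variance of ``x`` retained after
        projection into the leading ``m``-dimensional manifold, computed
        through the reconstruction error."""
        if m is None:
            m = self.d
        e = self.encoder[:m]
        xc = x - x.mean(axis=1, keepdims=True)
        recon = e.T @ (e @ xc)
        total = float(np.sum(xc ** 2))
        if total == 0.0:
            raise ValueError("cannot compute captured variance of all-zero data")
        return (total - float(np.sum((xc - recon) ** 2))) / total


def dimensionality_from_spectrum(spectrum: np.ndarray,
                                 threshold: float = VARIANCE_THRESHOLD) -> int:
    """Smallest number of components with cumulative variance strictly
    greater than ``threshold``.

    A 1e-9 guard keeps constructions that land exactly on the threshold
    (e.g. equal-variance planted components) on the "not exceeded" side
    regardless of floating-point summation order.
    """
    total = spectrum.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum")
    cum = np.cumsum(spectrum) / total
    return int(np.searchsorted(cum, threshold + 1e-9, side="right") + 1)


def pca_dimensionality(x: np.ndarray,
                       threshold: float = VARIANCE_THRESHOLD):
    """PCA manifold of a channels x samples matrix and its dimensionality.

    Returns ``(model, d)``; the input is centered per channel internally.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a channels x samples matrix with >= 2 samples")
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    if not np.any(xc):
        raise ValueError("all-zero (or constant) data has no manifold")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    spectrum = s ** 2 / (x.shape[1] - 1)
    d = dimensionality_from_spectrum(spectrum, threshold)
    model = ManifoldModel(mean=mean[:, 0], encoder=u.T, spectrum=spectrum,
                          threshold=threshold, d=d)
    return model, d


def dimensionality_ceiling(task_duration_ms: float,
                           filter_width_ms: float) -> float:
    """Upper bound on measurable manifold dimensionality: the task duration
    divided by the width of the rate-smoothing filter, to one decimal."""
    return round(task_duration_ms / filter_width_ms, 1)


# ---------------------------------------------------------------------------
# Dimensionality battery
# ---------------------------------------------------------------------------

def _task_matrix(tensor: PeriGaitTensor, tasks, channels) -> np.ndarray:
    return tensor.subset_channels(channels).concatenated(tasks)


def dimensionality_battery(tensor: PeriGaitTensor, n_sub: int = 32,
                           reps: int = 1000, threshold: float = VARIANCE_THRESHOLD,
                           seed: int = 0) -> dict:
    """Single-task, all-task, leave-one-out dimensionalities on random
    channel subsamples.

    Each quantity is the mean over ``reps`` seeded draws of ``n_sub``
    channels (all active channels are used without subsampling when the
    region has no more than ``n_sub``).  PCA runs on single-cycle warped
    activity concatenated over cycles, not on trial averages.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    active = tensor.active_channels()
    if active.size < 2:
        raise ValueError("not enough active channels")
    rng = np.random.default_rng(seed)
    tasks = tensor.tasks
    subsample = active.size > n_sub
    n_draws = reps if subsample else 1
    single = np.zeros((n_draws, len(tasks)))
    alltask = np.zeros(n_draws)
    loo = np.zeros((n_draws, len(tasks)))
    for r in range(n_draws):
        channels = (rng.choice(active, size=n_sub, replace=False)
                    if subsample else active)
        for j, t in enumerate(tasks):
            _, single[r, j] = pca_dimensionality(
                _task_matrix(tensor, [t], channels), threshold)
        _, alltask[r] = pca_dimensionality(
            _task_matrix(tensor, tasks, channels), threshold)
        for j, t in enumerate(tasks):
            rest = [u for u in tasks if u != t]
            _, loo[r, j] = pca_dimensionality(
                _task_matrix(tensor, rest, channels), threshold)
    mean_single = single.mean(axis=0)
    mean_all = float(alltask.mean())
    return {
        "single_task_d": {t: float(v) for t, v in zip(tasks, mean_single)},
        "mean_single_task_d": float(mean_single.mean()),
        "all_task_d": mean_all,
        "delta_dim": mean_all - float(mean_single.mean()),
        "leave_one_out_drop": {
            t: mean_all - float(loo[:, j].mean()) for j, t in enumerate(tasks)
        },
        "reps": n_draws,
        "n_sub": int(n_sub if subsample else active.size),
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# Alignment index
# ---------------------------------------------------------------------------

def captured_variance_fraction(x: np.ndarray, basis: np.ndarray) -> float:
    """Variance of (centered) ``x`` captured inside ``span(basis)``, via the
    reconstruction-error form: (||X||^2 - ||X - D E X||^2) / ||X||^2."""
    basis = np.asarray(basis, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    total = float(np.sum(xc ** 2))
    if total == 0.0:
        raise ValueError("all-zero data")
    recon = basis @ (basis.T @ xc)
    return (total - float(np.sum((xc - recon) ** 2))) / total


def alignment_index(tensor: PeriGaitTensor, task_a, task_b,
                    m: int | None = None,
                    threshold: float = VARIANCE_THRESHOLD) -> float:
    """Alignment index of task ``a`` activity with task ``b``'s manifold.

    Both manifolds are built from the trial-averaged peri-gait activity of
    their own task.  A common dimension ``m`` is used for numerator and
    denominator; the default is the larger of the two tasks' threshold
    dimensionalities.
    """
    avg = tensor.trial_average()
    active = tensor.active_channels()
    tasks = tensor.tasks
    xa = avg[active][:, tasks.index(task_a), :]
    xb = avg[active][:, tasks.index(task_b), :]
    model_a, da = pca_dimensionality(xa, threshold)
    model_b, db = pca_dimensionality(xb, threshold)
    if m is None:
        m = max(da, db)
    if m > min(len(model_a.spectrum), len(model_b.spectrum)):
        raise ValueError("m exceeds the rank of one task's data")
    into_b = captured_variance_fraction(xa, model_b.decoder[:, :m])
    into_a = captured_variance_fraction(xa, model_a.decoder[:, :m])
    if into_a == 0.0:
        raise ValueError("task a retains no variance in its own manifold")
    return into_b / into_a


def alignment_index_table(tensor: PeriGaitTensor, m: int | None = None,
                          threshold: float = VARIANCE_THRESHOLD):
    """All ordered task pairs' alignment indices and their session mean."""
    rows = [
        (a, b, alignment_index(tensor, a, b, m=m, threshold=threshold))
        for a, b in permutations(tensor.tasks, 2)
    ]
    table = pd.DataFrame(rows, columns=["task_a", "task_b", "alignment_index"])
    return float(table.alignment_index.mean()), table
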