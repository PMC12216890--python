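"""Communication subspaces between regions via ridge + reduced-rank regression.

The activity of a target region Y (samples x q) is predicted from a source
region X (samples x p) with ridge regression,

    B_ridge = (X'X + lambda I)^-1 X'Y,

the regularizer chosen by 10-fold cross-validation with the one-standard-
error rule (largest lambda whose mean R^2 is within one SE of the best).
The ridge prediction X B_ridge is then compressed: V holds its leading
principal directions, B_rrr(m) = B_ridge V_m V_m', and the model rank
m_rrr is the smallest m whose prediction retains at least 95% of the
variance the full ridge prediction explains.  The first m_rrr columns of
B_bar = B_ridge V, orthonormalized, span the communication subspace of the
source region.

Samples are the concatenated time-warped peri-gait cycles of a single
task; cross-validation folds are contiguous blocks of whole gait cycles to
respect the temporal autocorrelation within a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prep import N_PHASE, PeriGaitTensor

RRR_VARIANCE_KEPT = 0.95
N_FOLDS = 10
LAMBDA_GRID_SIZE = 20
LAMBDA_GRID_SPAN = (1e-4, 1e4)     # x mean diagonal of X'X


@dataclass
class CommModel:
    b_ridge: np.ndarray        # p x q
    lambda_grid: np.ndarray
    lambda_star: float
    cv_mean_r2: np.ndarray     # per grid lambda
    cv_se_r2: np.ndarray
    v: np.ndarray              # q x q principal directions of the ridge prediction
    r2_curve: np.ndarray       # R^2(m), m = 1..q
    m_rrr: int
    b_bar: np.ndarray          # p x q, B_ridge V
    basis: np.ndarray          # p x m_rrr orthonormal communication basis
    n_samples: int

    def b_rrr(self, m: int) -> np.ndarray:
        vm = self.v[:, :m]
        return self.b_ridge @ vm @ vm.T


def pooled_r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Variance-weighted multi-output R^2: 1 - Var(Y - Yhat) / Var(Y)."""
    resid = np.sum((y - y_hat) ** 2)
    total = np.sum((y - y.mean(axis=0)) ** 2)
    if total == 0:
        raise ValueError("target has no variance")
    return 1.0 - float(resid / total)


def _ridge_solve(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    p = x.shape[1]
    return np.linalg.solve(x.T @ x + lam * np.eye(p), x.T @ y)


def default_lambda_grid(x: np.ndarray) -> np.ndarray:
    scale = float(np.mean(np.sum(x ** 2, axis=0)))     # mean diagonal of X'X
    lo, hi = LAMBDA_GRID_SPAN
    return scale * np.logspace(np.log10(lo), np.log10(hi), LAMBDA_GRID_SIZE)


def _contiguous_folds(n_samples: int, n_folds: int, block: int):
    """Fold assignment over contiguous blocks of ``block`` samples."""
    n_blocks = n_samples // block
    if n_blocks < n_folds:
        raise ValueError(
            f"only {n_blocks} cycles available for {n_folds}-fold CV"
        )
    block_fold = (np.arange(n_blocks) * n_folds) // n_blocks
    fold = np.repeat(block_fold, block)
    if fold.size < n_samples:                          # trailing partial block
        fold = np.concatenate([fold, np.full(n_samples - fold.size, n_folds - 1)])
    return fold


def fit_ridge_cv(x: np.ndarray, y: np.ndarray,
                 lambda_grid: np.ndarray | None = None,
                 n_folds: int = N_FOLDS, cycle_len: int = N_PHASE):
    """Cross-validated ridge fit of Y on X (both centered internally).

    Returns ``(b_ridge, lambda_star, cv_table)`` where ``cv_table`` is a
    dict with the grid, the per-lambda mean held-out R^2 and its SE.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must share the sample axis")
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(x)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))
    fold = _contiguous_folds(x.shape[0], n_folds, cycle_len)
    r2 = np.empty((lambda_grid.size, n_folds))
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        xt, yt = x[tr], y[tr]
        gram = xt.T @ xt
        xty = xt.T @ yt
        for i, lam in enumerate(lambda_grid):
            b = np.linalg.solve(gram + lam * np.eye(x.shape[1]), xty)
            r2[i, f] = pooled_r2(y[te], x[te] @ b)
    if not np.all(np.isfinite(r2)):
        raise ValueError("non-finite cross-validated R^2")
    mean_r2 = r2.mean(axis=1)
    se_r2 = r2.std(axis=1, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmax(mean_r2))
    ok = np.flatnonzero(mean_r2 >= mean_r2[best] - se_r2[best])
    lambda_star = float(lambda_grid[ok[-1]])           # largest admissible lambda
    b_ridge = _ridge_solve(x, y, lambda_star)
    return b_ridge, lambda_star, {
        "lambda_grid": lambda_grid, "mean_r2": mean_r2, "se_r2": se_r2,
    }


def fit_rrr(x: np.ndarray, y: np.ndarray, b_ridge: np.ndarray,
            variance_kept: float = RRR_VARIANCE_KEPT):
    """Reduced-rank path of a fitted ridge model.

    Returns ``(v, r2_curve, m_rrr)``: the principal directions of the ridge
    prediction, the in-sample R^2 of every rank-m truncation, and the
    smallest rank explaining at least ``variance_kept`` of the variance the
    full ridge prediction explains.
    """
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    y_hat = x @ b_ridge
    # principal directions of the prediction in target-channel space
    _, _, vt = np.linalg.svd(y_hat, full_matrices=False)
    v = vt.T                                           # q x q
    q = v.shape[1]
    r2_curve = np.empty(q)
    for m in range(1, q + 1):
        vm = v[:, :m]
        r2_curve[m - 1] = pooled_r2(y, y_hat @ vm @ vm.T)
    r2_full = pooled_r2(y, y_hat)
    target = variance_kept * r2_full
    admissible = np.flatnonzero(r2_curve >= target)
    if admissible.size == 0:
        raise ValueError("no rank reaches the required variance fraction")
    m_rrr = int(admissible[0] + 1)
    return v, r2_curve, m_rrr


def communication_basis(b_bar: np.ndarray, m_rrr: int) -> np.ndarray:
    """Orthonormalize the first ``m_rrr`` columns of B_bar into the
    source-channel-space communication basis.  Rank-deficient columns are
    dropped with a warning (the basis then has fewer columns)."""
    cols = b_bar[:, :m_rrr]
    u, s, _ = np.linalg.svd(cols, full_matrices=False)
    keep = s > s[0] * 1e-10 if s.size else np.zeros(0, dtype=bool)
    if keep.sum() < m_rrr:
        import warnings
        warnings.warn(
            f"communication columns rank-deficient: {int(keep.sum())} < {m_rrr}"
        )
    return u[:, keep]


def fit_communication_model(x: np.ndarray, y: np.ndarray,
                            lambda_grid: np.ndarray | None = None,
                            n_folds: int = N_FOLDS,
                            cycle_len: int = N_PHASE,
                            variance_kept: float = RRR_VARIANCE_KEPT) -> CommModel:
    """Full pipeline: ridge CV, reduced-rank path, communication basis."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    b_ridge, lambda_star, cv = fit_ridge_cv(xc, yc, lambda_grid,
                                            n_folds=n_folds, cycle_len=cycle_len)
    v, r2_curve, m_rrr = fit_rrr(xc, yc, b_ridge, variance_kept)
    b_bar = b_ridge @ v
    basis = communication_basis(b_bar, m_rrr)
    return CommModel(b_ridge=b_ridge, lambda_grid=cv["lambda_grid"],
                     lambda_star=lambda_star, cv_mean_r2=cv["mean_r2"],
                     cv_se_r2=cv["se_r2"], v=v, r2_curve=r2_curve,
                     m_rrr=m_rrr, b_bar=b_bar, basis=basis,
                     n_samples=x.shape[0])


def task_design_matrices(source: PeriGaitTensor, target: PeriGaitTensor, task):
    """Samples x channels matrices for one task: warped cycles concatenated,
    restricted to active channels and matched cycle-for-cycle."""
    if source.cycles(task) != target.cycles(task):
        raise ValueError("source and target retained different cycles")
    xs = source.subset_channels(source.active_channels()).blocks[task]
    ys = target.subset_channels(target.active_channels()).blocks[task]
    x = xs.transpose(1, 2, 0).reshape(-1, xs.shape[0])
    y = ys.transpose(1, 2, 0).reshape(-1, ys.shape[0])
    return x, y
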