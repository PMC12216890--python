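"""Demixed PCA with gait-phase (task-independent) and task marginalizations.

Trial-averaged peri-gait activity X (channels x tasks x 100 phase samples,
centered per channel) is split into a task-independent part X_TI (the mean
over tasks, replicated) and a task-dependent remainder X_TD = X - X_TI.
The two parts are orthogonal by construction, so their squared norms add.

For each marginalization the demixing problem min ||X_m - F D X||^2 is
solved in closed form: a (ridge-regularized) linear regression of X_m on X
followed by projection onto the leading principal directions of the fitted
prediction.  Modes from both marginalizations are pooled and ordered by
total explained variance; a mode is labelled task-independent when more
than half of its variance is accounted for by the TI part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import N_PHASE, PeriGaitTensor

TI = "task-independent"
TD = "task-dependent"

DEFAULT_MODES_PER_MARG = 10


@dataclass
class DpcaMode:
    decoder: np.ndarray       # length n, unit norm
    encoder: np.ndarray       # length n, least-squares reconstruction axis
    marginalization: str      # which loss the mode was fit under
    ti_pct: float             # % of total data variance, TI part
    td_pct: float
    label: str = ""

    @property
    def total_pct(self) -> float:
        return self.ti_pct + self.td_pct

    def __post_init__(self):
        if not self.label:
            self.label = TI if self.ti_pct > 0.5 * self.total_pct else TD


@dataclass
class DpcaDecomposition:
    modes: list               # DpcaMode, ordered by total explained variance
    mean: np.ndarray          # per-channel mean removed before fitting
    x_ti: np.ndarray          # channels x tasks x 100 marginalization tensors
    x_td: np.ndarray
    total_energy: float       # ||X||^2 of the centered trial-averaged tensor
    residual_pct: float       # 100 * ||X - sum_k f_k d_k X||^2 / ||X||^2
    ridge_mu: float
    channel_index: np.ndarray  # active channels the decomposition refers to

    def modes_with_label(self, label: str) -> list:
        return [m for m in self.modes if m.label == label]

    def subspace_basis(self, label: str, k: int) -> np.ndarray:
        """Orthonormal basis (n x k) of the k leading modes of one label."""
        modes = self.modes_with_label(label)
        if len(modes) < k:
            raise ValueError(
                f"requested {k} {label} modes but only {len(modes)} available"
            )
        axes = np.column_stack([m.encoder for m in modes[:k]])
        q, r = np.linalg.qr(axes)
        return q * np.sign(np.diag(r))

    def ti_subspace_variance_pct(self) -> float:
        """Total variance explained by the task-independent subspace:
        the summed variance of all TI-labelled modes."""
        return float(sum(m.total_pct for m in self.modes_with_label(TI)))


def marginalize(avg: np.ndarray):
    """Split a centered trial-averaged tensor into TI and TD parts.

    ``avg`` has shape channels x tasks x 100 and should already have the
    per-channel overall mean removed.  Returns ``(x_ti, x_td)`` of the same
    shape; ``x_ti`` is the across-task mean replicated along the task axis.
    """
    avg = np.asarray(avg, dtype=float)
    if avg.ndim != 3:
        raise ValueError("expected channels x tasks x phase tensor")
    ti = np.broadcast_to(avg.mean(axis=1, keepdims=True), avg.shape).copy()
    td = avg - ti
    if avg.shape[1] == 1:
        import warnings
        warnings.warn("single task: task-dependent part is identically zero")
    return ti, td


def _centered_average(tensor: PeriGaitTensor):
    active = tensor.active_channels()
    avg = tensor.trial_average()[active]
    mean = avg.mean(axis=(1, 2), keepdims=True)
    return avg - mean, mean[:, 0, 0], active


def fit_dpca(tensor: PeriGaitTensor,
             n_modes_per_marg: int = DEFAULT_MODES_PER_MARG,
             ridge_mu: float | None = None) -> DpcaDecomposition:
    """Fit the two-marginalization demixed PCA to a peri-gait tensor.

    ``ridge_mu`` defaults to ``1e-6 * ||X||^2 / n`` (the trial-averaged
    tensor is well-conditioned, so the ridge only stabilizes inversion).
    """
    avg, mean, active = _centered_average(tensor)
    n = avg.shape[0]
    x = avg.reshape(n, -1)
    x_ti_t, x_td_t = marginalize(avg)
    rank = np.linalg.matrix_rank(x)
    if n_modes_per_marg > rank:
        raise ValueError(
            f"n_modes_per_marg={n_modes_per_marg} exceeds rank(X)={rank}"
        )
    total_energy = float(np.sum(x ** 2))
    if ridge_mu is None:
        ridge_mu = 1e-6 * total_energy / n
    gram = x @ x.T + ridge_mu * np.eye(n)
    modes: list[DpcaMode] = []
    for marg, x_m in ((TI, x_ti_t.reshape(n, -1)), (TD, x_td_t.reshape(n, -1))):
        a = np.linalg.solve(gram.T, (x_m @ x.T).T).T    # X_m X' (X X' + mu I)^-1
        fitted = a @ x
        u, s, vt = np.linalg.svd(fitted, full_matrices=False)
        q = min(n_modes_per_marg, np.sum(s > s[0] * 1e-12) if s.size else 0)
        for k in range(q):
            d_raw = u[:, k] @ a
            nrm = np.linalg.norm(d_raw)
            if nrm == 0:
                continue
            d = d_raw / nrm
            proj = d @ x                                # 1 x samples
            denom = float(proj @ proj)
            f = (x_m @ proj) / denom
            modes.append(_score_mode(d, f, marg, x, x_ti_t.reshape(n, -1),
                                     x_td_t.reshape(n, -1), total_energy))
    modes.sort(key=lambda m: m.total_pct, reverse=True)
    residual = _joint_residual_pct(modes, x, total_energy)
    return DpcaDecomposition(modes=modes, mean=mean, x_ti=x_ti_t, x_td=x_td_t,
                             total_energy=total_energy, residual_pct=residual,
                             ridge_mu=ridge_mu, channel_index=active)


def _score_mode(d, f, marg, x, x_ti, x_td, total_energy) -> DpcaMode:
    # per-part variance of a rank-1 mode: ||X_m||^2 - ||X_m - f d' X_m||^2,
    # expressed as a percentage of the total data variance
    def part_pct(x_m):
        recon = np.outer(f, d @ x_m)
        return 100.0 * (np.sum(x_m ** 2) - np.sum((x_m - recon) ** 2)) / total_energy

    return DpcaMode(decoder=d, encoder=f, marginalization=marg,
                    ti_pct=float(part_pct(x_ti)), td_pct=float(part_pct(x_td)))


def _joint_residual_pct(modes, x, total_energy) -> float:
    if not modes:
        return 100.0
    f = np.column_stack([m.encoder for m in modes])
    d = np.vstack([m.decoder for m in modes])
    resid = x - f @ (d @ x)
    return 100.0 * float(np.sum(resid ** 2)) / total_energy


def variance_table(decomp: DpcaDecomposition) -> dict:
    """Per-mode and per-subspace variance accounting.

    Returns a dict with a per-mode DataFrame, subspace-level sums over
    same-label modes, the marginalization totals (the pie-chart numbers),
    and the unassigned remainder so that modes + remainder total 100%.
    """
    rows = [
        (i, m.label, m.marginalization, m.total_pct, m.ti_pct, m.td_pct)
        for i, m in enumerate(decomp.modes)
    ]
    table = pd.DataFrame(rows, columns=["mode", "label", "marginalization",
                                        "total_pct", "ti_pct", "td_pct"])
    assigned = float(table.total_pct.sum())
    return {
        "per_mode": table,
        "subspace_pct": {
            TI: float(table.loc[table.label == TI, "total_pct"].sum()),
            TD: float(table.loc[table.label == TD, "total_pct"].sum()),
        },
        "marginalization_pct": {
            TI: 100.0 * float(np.sum(decomp.x_ti ** 2)) / decomp.total_energy,
            TD: 100.0 * float(np.sum(decomp.x_td ** 2)) / decomp.total_energy,
        },
        "unassigned_pct": 100.0 - assigned,
        "joint_residual_pct": decomp.residual_pct,
    }


def remove_modes(rates: np.ndarray, decomp: DpcaDecomposition, which: str,
                 k: int | None = None):
    """Project the k leading modes of one label out of a rate matrix.

    ``rates`` is the full-resolution channels x time matrix restricted to
    the decomposition's channels (``decomp.channel_index``); the removal is
    X <- X - sum_j f_j d_j' X applied to per-channel-centered activity with
    the mean added back.  ``which`` is "task-independent", "task-dependent"
    or "both" (all pooled modes).  Returns ``(reduced, removed_fraction)``.
    """
    rates = np.asarray(rates, dtype=float)
    if which == "both":
        modes = decomp.modes
    elif which in (TI, TD):
        modes = decomp.modes_with_label(which)
    else:
        raise ValueError(f"which must be {TI!r}, {TD!r} or 'both'")
    if k is None:
        k = len(modes)
    if k > len(modes):
        raise ValueError(f"k={k} exceeds the {len(modes)} available {which} modes")
    if k == 0:
        return rates.copy(), 0.0
    chosen = modes[:k]
    f = np.column_stack([m.encoder for m in chosen])
    d = np.vstack([m.decoder for m in chosen])
    mean = rates.mean(axis=1, keepdims=True)
    xc = rates - mean
    removed = f @ (d @ xc)
    reduced = xc - removed + mean
    total = float(np.sum(xc ** 2))
    frac = float(np.sum(xc ** 2) - np.sum((xc - removed) ** 2)) / total if total else 0.0
    return reduced, frac
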