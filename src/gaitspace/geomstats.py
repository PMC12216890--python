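"""Subspace geometry and Monte-Carlo null machinery.

Principal angles between subspaces (arccos of the singular values of
Wa' Wb), the Delta-angles statistic contrasting a communication subspace's
alignment with the task-dependent vs task-independent subspaces, and the
resampling nulls used throughout: cycle bootstraps that turn resampled
pseudo-datasets into pseudo-tasks, circular phase shuffles, uniform-angle
chance draws, and Haar-random subspace chance levels.  P-values follow the
one-sided Monte-Carlo convention p = (1 + #{null >= observed}) / (1 + N),
whose floor at N = 2000 is 1/2001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .prep import N_PHASE, PeriGaitTensor, circular_sd

NULL_MODES = ("bootstrap-split", "bootstrap-5", "phase-shuffle",
              "pgp-uniform", "subspace-random", "target-shuffle")
DEFAULT_N = 2000


@dataclass
class Subspace:
    """Orthonormal basis of a linear subspace of channel space."""

    basis: np.ndarray                 # n x m, orthonormal columns
    kind: str = ""                    # task-independent / task-dependent / communication / random
    region: str = ""

    def __post_init__(self):
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.ndim != 2 or self.basis.shape[1] == 0:
            raise ValueError("subspace basis must be n x m with m >= 1")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.basis.shape[1]), atol=1e-8):
            raise ValueError("subspace basis columns must be orthonormal")

    @property
    def dim(self) -> int:
        return self.basis.shape[1]

    @property
    def ambient_dim(self) -> int:
        return self.basis.shape[0]


@dataclass
class StatResult:
    """Observed statistic with its Monte-Carlo null distribution."""

    observed: float
    null: np.ndarray
    direction: str                   # "greater" or "less"
    seed: int
    mode: str = ""
    p: float = field(init=False)

    def __post_init__(self):
        self.null = np.asarray(self.null, dtype=float)
        self.p = mc_pvalue(self.observed, self.null, self.direction)

    @property
    def n(self) -> int:
        return self.null.size

    def summary(self) -> dict:
        return {
            "observed": self.observed, "p": self.p, "N": self.n,
            "null_mean": float(self.null.mean()),
            "null_sd": float(self.null.std(ddof=1)) if self.n > 1 else float("nan"),
            "null_sem": float(self.null.std(ddof=1) / math.sqrt(self.n)) if self.n > 1 else float("nan"),
            "direction": self.direction, "seed": self.seed, "mode": self.mode,
        }


def paired_difference(a: "StatResult", b: "StatResult",
                      direction: str = "greater") -> "StatResult":
    """Compare two statistics under the null that their difference equals
    the difference of their noise contributions: the null sample is the
    draw-wise difference of the two (equally sized, same-seed-structured)
    null distributions."""
    if a.n != b.n:
        raise ValueError("paired nulls require equal draw counts")
    return StatResult(observed=a.observed - b.observed, null=a.null - b.null,
                      direction=direction, seed=a.seed,
                      mode=f"paired({a.mode},{b.mode})")


def mc_pvalue(observed: float, null: np.ndarray, direction: str = "greater") -> float:
    """One-sided Monte-Carlo permutation p-value with the add-one convention."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if direction == "greater":
        extreme = int(np.sum(null >= observed))
    elif direction == "less":
        extreme = int(np.sum(null <= observed))
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return (1 + extreme) / (1 + null.size)


# ---------------------------------------------------------------------------
# Principal angles
# ---------------------------------------------------------------------------

def principal_angles(a: Subspace | np.ndarray, b: Subspace | np.ndarray) -> np.ndarray:
    """Principal angles between two subspaces, ascending, in degrees.

    Computed as the arccos of the singular values of Wa' Wb, clipped to
    [0, 90] degrees; the number of angles is min(dim a, dim b).
    """
    wa = a.basis if isinstance(a, Subspace) else np.asarray(a, dtype=float)
    wb = b.basis if isinstance(b, Subspace) else np.asarray(b, dtype=float)
    if wa.shape[1] == 0 or wb.shape[1] == 0:
        raise ValueError("zero-dimensional subspace")
    s = np.linalg.svd(wa.T @ wb, compute_uv=False)
    angles = np.degrees(np.arccos(np.clip(s, -1.0, 1.0)))
    return np.sort(np.clip(angles, 0.0, 90.0))


def delta_angles(comm: Subspace, td5: Subspace, ti5: Subspace,
                 required_dim: int = 5) -> float:
    """Mean CS-TD principal angle minus mean CS-TI principal angle.

    Positive values mean the communication subspace is preferentially
    aligned with the task-independent subspace.  The TD and TI subspaces
    must be built from exactly ``required_dim`` leading modes.
    """
    for name, sub in (("task-dependent", td5), ("task-independent", ti5)):
        if sub.dim != required_dim:
            raise ValueError(
                f"{name} subspace has {sub.dim} modes, need exactly {required_dim}"
            )
    cs_td = principal_angles(comm, td5).mean()
    cs_ti = principal_angles(comm, ti5).mean()
    return float(cs_td - cs_ti)


def haar_subspace(n: int, m: int, rng) -> Subspace:
    """Haar-random m-dimensional subspace of R^n (orthonormalized Gaussians)."""
    q, r = np.linalg.qr(rng.standard_normal((n, m)))
    return Subspace(q * np.sign(np.diag(r)), kind="random")


# ---------------------------------------------------------------------------
# Surrogate builders
# ---------------------------------------------------------------------------

def phase_shuffle_tensor(tensor: PeriGaitTensor, rng) -> PeriGaitTensor:
    """Advance every (channel, cycle) warped trace by an independent
    uniformly-random circular gait-phase shift."""
    blocks = {}
    for task, blk in tensor.blocks.items():
        n_ch, n_cyc, _ = blk.shape
        shifts = rng.integers(0, N_PHASE, size=(n_ch, n_cyc))
        cols = (np.arange(N_PHASE)[None, None, :] + shifts[:, :, None]) % N_PHASE
        blocks[task] = np.take_along_axis(blk, cols, axis=2)
    return PeriGaitTensor(blocks, region=tensor.region,
                          constant_flags=tensor.constant_flags.copy())


def bootstrap_pseudo_tasks(tensor: PeriGaitTensor, task, k: int, rng) -> PeriGaitTensor:
    """Resample one task's cycles with replacement into ``k`` pseudo-datasets,
    presented as a tensor with ``k`` pseudo-tasks."""
    blk = tensor.blocks[task]
    n_cyc = blk.shape[1]
    blocks = {}
    for j in range(k):
        idx = rng.integers(0, n_cyc, size=n_cyc)
        blocks[f"pseudo{j}"] = blk[:, idx, :]
    return PeriGaitTensor(blocks, region=tensor.region,
                          constant_flags=tensor.constant_flags.copy())


# ---------------------------------------------------------------------------
# Null engine
# ---------------------------------------------------------------------------

def null_engine(mode: str, statistic=None, *, tensor: PeriGaitTensor | None = None,
                n_draws: int = DEFAULT_N, seed: int = 0, observed: float | None = None,
                direction: str = "greater", n_angles: int = 5,
                circ_sd_form: str = "angular_deviation",
                subspace_ambient: int | None = None, subspace_dim: int | None = None,
                n_pseudo: int | None = None) -> StatResult:
    """Draw an N-sample null distribution of a statistic.

    Modes
    -----
    ``bootstrap-split`` / ``bootstrap-5``
        Per draw and per task, resample gait cycles with replacement into 2
        (respectively 5) pseudo-datasets presented as pseudo-tasks;
        ``statistic(pseudo_tensor)`` is evaluated and averaged over the
        original tasks.  Used for the noise contribution to cross-task
        correlation / alignment index (split) and PGP-spread / TI-variance
        (five pseudo-tasks).
    ``phase-shuffle`` / ``target-shuffle``
        Per draw, circularly shift every (channel, cycle) trace of
        ``tensor`` by an independent uniform gait phase and evaluate
        ``statistic(shuffled_tensor)``; for target-shuffle the caller
        passes the target-region tensor and a statistic that refits the
        communication subspace against the intact source.
    ``pgp-uniform``
        Per draw, ``n_angles`` uniform circular angles; the statistic is
        their circular standard deviation in degrees (chance level of the
        preferred-gait-phase spread).
    ``subspace-random``
        Per draw, a Haar-random ``subspace_dim``-dimensional subspace of
        ``subspace_ambient``-space is passed to ``statistic``.
    """
    if mode not in NULL_MODES:
        raise ValueError(f"unknown null mode {mode!r}")
    if n_draws < 1:
        raise ValueError("need at least one null draw")
    rng = np.random.default_rng(seed)
    null = np.empty(n_draws)

    if mode == "pgp-uniform":
        for i in range(n_draws):
            angles = rng.uniform(0.0, 2.0 * np.pi, size=n_angles)
            null[i] = math.degrees(circular_sd(angles, form=circ_sd_form))
    elif mode in ("phase-shuffle", "target-shuffle"):
        if tensor is None or statistic is None:
            raise ValueError(f"{mode} needs a tensor and a statistic")
        for i in range(n_draws):
            null[i] = statistic(phase_shuffle_tensor(tensor, rng))
    elif mode in ("bootstrap-split", "bootstrap-5"):
        if tensor is None or statistic is None:
            raise ValueError(f"{mode} needs a tensor and a statistic")
        k = n_pseudo or (2 if mode == "bootstrap-split" else 5)
        for i in range(n_draws):
            vals = [
                statistic(bootstrap_pseudo_tasks(tensor, task, k, rng))
                for task in tensor.tasks
            ]
            null[i] = float(np.mean(vals))
    elif mode == "subspace-random":
        if statistic is None or subspace_ambient is None or subspace_dim is None:
            raise ValueError("subspace-random needs statistic, ambient and dim")
        for i in range(n_draws):
            null[i] = statistic(haar_subspace(subspace_ambient, subspace_dim, rng))

    obs = float(observed) if observed is not None else float(null.mean())
    return StatResult(observed=obs, null=null, direction=direction,
                      seed=seed, mode=mode)
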