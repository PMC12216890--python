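"""Synthetic multi-task gait sessions with planted latent structure.

The generator emulates chronic multi-electrode recordings from a cortical
region while an animal performs several locomotor tasks: gait-phase-locked
population activity is built from a small number of smooth periodic latent
trajectories, split into a task-independent (TI) set shared by every task
and a task-dependent (TD) set that differs between tasks, mapped into
channel space through mutually orthonormal loading bases, and emitted as a
1 kHz rate record (optionally Poisson spikes) together with the gait-event
table. Because the signal is constructed as ``loadings @ latents + noise``
with everything stored, every downstream statistic (variance fractions,
manifold dimensionality, communication-map rank and alignment, decoder
accuracy) has a closed-form target.

Channel loadings are drawn from a real-Fourier orthogonal basis whose TI
and TD blocks have equal row norms, so every channel carries the same
signal variance and the same TI/TD split; per-channel z-scoring downstream
is then a uniform rescaling and the planted variance fractions are
preserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .prep import FS_RATE, N_PHASE, N_STANCE, GaitEventTable

DURATION_BOUNDS = (0.3, 1.5)     # s, truncation of cycle durations
STANCE_BOUNDS = (0.2, 0.8)       # admissible stance fraction range


# ---------------------------------------------------------------------------
# Configuration and ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Parameters of a synthetic session.

    Defaults emulate the recording regime of the study this package models:
    5 locomotor tasks, ~100 retained gait cycles per task with ~0.94 s mean
    duration, 64 channels per region, stance centred at 60% of the cycle,
    and a task-independent variance fraction of 0.68 (an S1-like region).
    """

    n_tasks: int = 5
    cycles_per_task: int = 100
    n_channels: int = 64
    n_ti_latents: int = 5
    n_td_latents: int = 5
    ti_variance_fraction: float = 0.68
    harmonic_order: int = 8
    baseline_rate: float = 30.0       # Hz
    gain: float = 8.0                 # Hz, per-channel RMS of the planted signal
    noise_sd: float = 2.0             # Hz, white rate noise per 1 kHz sample
    cycle_duration_mean: float = 0.94  # s
    cycle_duration_sd: float = 0.10    # s
    stance_fraction_mean: float = 0.60
    stance_fraction_sd: float = 0.03
    comm_rank: int = 3
    comm_alignment: float = 1.0       # 1 = map reads only TI latents, 0 = only TD
    comm_target_channels: int = 32
    spike_mode: str = "rates_only"    # or "poisson"
    region_name: str = "source"
    task_gap: float = 1.0             # s of signal-free recording between tasks
    seed: int = 0

    def __post_init__(self):
        counts = dict(n_tasks=self.n_tasks, cycles_per_task=self.cycles_per_task,
                      n_channels=self.n_channels, n_ti_latents=self.n_ti_latents,
                      n_td_latents=self.n_td_latents, harmonic_order=self.harmonic_order,
                      comm_rank=self.comm_rank,
                      comm_target_channels=self.comm_target_channels)
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value}")
        if not 0.0 <= self.ti_variance_fraction <= 1.0:
            raise ValueError("ti_variance_fraction must lie in [0, 1]")
        if not 0.0 <= self.comm_alignment <= 1.0:
            raise ValueError("comm_alignment must lie in [0, 1]")
        if self.n_ti_latents + self.n_td_latents > self.n_channels:
            raise ValueError("n_ti_latents + n_td_latents exceeds n_channels")
        if self.n_ti_latents + 2 * self.n_td_latents > 2 * self.harmonic_order:
            raise ValueError(
                "the 2*harmonic_order-dimensional periodic function space "
                "cannot hold n_ti_latents TI waveforms plus 2*n_td_latents "
                "TD waveform pairs; raise harmonic_order"
            )
        lo, hi = STANCE_BOUNDS
        if not lo < self.stance_fraction_mean < hi:
            raise ValueError(
                f"stance_fraction_mean must lie in ({lo}, {hi})"
            )
        if self.spike_mode not in ("rates_only", "poisson"):
            raise ValueError(f"unknown spike_mode {self.spike_mode!r}")
        if self.noise_sd < 0 or self.gain < 0 or self.baseline_rate < 0:
            raise ValueError("rates and noise must be non-negative")


@dataclass
class RegionRecord:
    """Raw (pre-z-score) recording of one region."""

    name: str
    rates: np.ndarray | None          # channels x time, Hz; None in poisson mode
    spike_times: list | None          # per-channel spike time arrays, s
    fs: float = FS_RATE

    @property
    def n_channels(self) -> int:
        if self.rates is not None:
            return self.rates.shape[0]
        return len(self.spike_times)


@dataclass
class Session:
    """In-memory session: region records, gait events, optional behavior."""

    regions: dict
    events: GaitEventTable
    fs: float = FS_RATE
    n_samples: int = 0
    emg: np.ndarray | None = None           # 6 x time envelopes
    kinematics: np.ndarray | None = None    # 12 x time landmark coordinates
    meta: dict = field(default_factory=dict)

    @property
    def span(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SyntheticGroundTruth:
    """Everything planted into a synthetic session."""

    config: SynthConfig
    ti_basis: np.ndarray              # n_channels x n_ti, orthonormal columns
    td_basis: np.ndarray              # n_channels x n_td, orthonormal columns
    ti_trajectories: np.ndarray       # n_ti x 100, orthonormal rows, zero mean
    td_trajectories: np.ndarray       # n_td x n_tasks x 100, zero task-mean
    ti_amplitude: float
    td_amplitude: float
    signal_tensor: np.ndarray         # n_channels x n_tasks x 100, noiseless, Hz
    phase_trace: np.ndarray           # 1 kHz gait phase in [0, 100); NaN in gaps
    task_index_trace: np.ndarray      # 1 kHz task index; -1 in gaps
    seed: int
    comm_map: np.ndarray | None = None           # B_true, p x q
    comm_input_basis: np.ndarray | None = None   # p x rank, orthonormal
    comm_rank: int | None = None
    comm_alignment: float | None = None
    emg_weights: np.ndarray | None = None        # 6 x n_latents
    emg_baseline: np.ndarray | None = None
    kin_weights: np.ndarray | None = None        # 12 x n_latents (referenced)

    @property
    def n_latents(self) -> int:
        return self.ti_basis.shape[1] + self.td_basis.shape[1]

    def latent_trace(self) -> np.ndarray:
        """Planted latent time series at 1 kHz, (n_ti + n_td) x time.

        TI rows are scaled by the TI amplitude and TD rows by the TD
        amplitude, matching their contribution to the channel signal.
        """
        return _latents_at(self)

    def variance_fractions(self) -> tuple[float, float]:
        """(TI, TD) fractions of the noiseless trial-averaged signal energy."""
        x = self.signal_tensor
        x = x - x.mean(axis=(1, 2), keepdims=True)
        flat = x.reshape(x.shape[0], -1)
        e_ti = float(np.sum((flat.T @ self.ti_basis) ** 2))
        e_tot = float(np.sum(x ** 2))
        return e_ti / e_tot, 1.0 - e_ti / e_tot


# ---------------------------------------------------------------------------
# Latent trajectories
# ---------------------------------------------------------------------------

def _fourier_curves(n_curves: int, harmonic_order: int, rng) -> np.ndarray:
    """Random zero-mean Fourier series on the 100-sample circular phase grid."""
    phase = np.arange(N_PHASE) * (2.0 * np.pi / N_PHASE)
    curves = np.zeros((n_curves, N_PHASE))
    for i in range(n_curves):
        for k in range(1, harmonic_order + 1):
            a, b = rng.standard_normal(2)
            curves[i] += a * np.cos(k * phase) + b * np.sin(k * phase)
    return curves


def _orthonormal_rows(mat: np.ndarray) -> np.ndarray:
    """Orthonormalize the rows of ``mat`` (Gram-Schmidt via QR)."""
    q, r = np.linalg.qr(mat.T)
    # fix signs so the result is deterministic and correlates with the input
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return (q * signs).T


def make_latent_trajectories(config: SynthConfig, rng):
    """Planted TI and TD latent trajectories.

    TI trajectories are identical across tasks (rows orthonormal over the
    phase grid).  Each TD trajectory rotates between a private pair of
    waveforms across tasks::

        z_j(task t) = (cos(2*pi*t/T + phi_j) g_{2j} + sin(...) g_{2j+1}) / sqrt(T)

    where the g's are orthonormal waveforms orthogonal to the TI span of
    the periodic function space.  This yields: zero mean across tasks at
    every phase sample (so TD task-concatenations are orthogonal to every
    TI concatenation and variance fractions add), orthonormal
    concatenations, and - within every single task - TD time courses that
    are mutually orthogonal, orthogonal to the TI courses, and of equal
    energy, so single-task fits (communication-subspace rank, alignment)
    see a balanced planted structure.
    """
    ti = _orthonormal_rows(_fourier_curves(config.n_ti_latents,
                                           config.harmonic_order, rng))
    n_td, n_tasks = config.n_td_latents, config.n_tasks
    raw = _fourier_curves(2 * n_td, config.harmonic_order, rng)
    raw = raw - (raw @ ti.T) @ ti                # project out the TI span
    g = _orthonormal_rows(raw)                   # 2*n_td waveforms, orthonormal
    if np.linalg.matrix_rank(np.vstack([ti, g]), tol=1e-8) < config.n_ti_latents + 2 * n_td:
        raise ValueError(
            "harmonic_order too small: need 2*harmonic_order >= "
            "n_ti_latents + 2*n_td_latents for independent TD waveforms"
        )
    theta = 2.0 * np.pi * np.arange(n_tasks) / n_tasks
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_td)
    td = np.empty((n_td, n_tasks, N_PHASE))
    for j in range(n_td):
        ang = theta + phi[j]
        td[j] = (np.outer(np.cos(ang), g[2 * j])
                 + np.outer(np.sin(ang), g[2 * j + 1])) / math.sqrt(n_tasks)
    return ti, td


# ---------------------------------------------------------------------------
# Channel loading bases with flat row norms
# ---------------------------------------------------------------------------

def _real_fourier_columns(n: int):
    """Real Fourier basis columns of R^n grouped as (flat singles, cos/sin pairs)."""
    ch = np.arange(n)
    singles = [np.full(n, 1.0 / math.sqrt(n))]
    if n % 2 == 0:
        singles.append(np.cos(np.pi * ch) / math.sqrt(n))   # Nyquist, entries +-1/sqrt(n)
    pairs = []
    for k in range(1, (n - 1) // 2 + 1):
        c = math.sqrt(2.0 / n) * np.cos(2.0 * np.pi * k * ch / n)
        s = math.sqrt(2.0 / n) * np.sin(2.0 * np.pi * k * ch / n)
        pairs.append((c, s))
    return singles, pairs


def make_channel_bases(n_channels: int, n_ti: int, n_td: int, rng):
    """Mutually orthonormal TI and TD channel bases with equal row norms.

    Each block is assembled from whole cos/sin Fourier pairs (jointly flat
    across channels) plus, for odd counts, one of the individually-flat
    columns (constant or Nyquist), then rotated by a random orthogonal
    matrix within the block, which preserves both orthonormality and the
    flat row-norm property.
    """
    singles, pairs = _real_fourier_columns(n_channels)
    need_singles = (n_ti % 2) + (n_td % 2)
    if need_singles > len(singles):
        raise ValueError(
            "cannot build equal-row-norm bases: with an odd channel count at "
            "most one of n_ti_latents/n_td_latents may be odd"
        )
    if n_ti + n_td > n_channels:
        raise ValueError("n_ti + n_td exceeds n_channels")
    order = rng.permutation(len(pairs))
    pool = [pairs[i] for i in order]
    singles = list(singles)

    def take(count):
        cols = []
        if count % 2 == 1:
            cols.append(singles.pop(0))
        while len(cols) < count:
            c, s = pool.pop(0)
            cols.extend([c, s])
        return np.column_stack(cols)

    ti_block = take(n_ti)
    td_block = take(n_td)

    def rotate(block):
        k = block.shape[1]
        q, r = np.linalg.qr(rng.standard_normal((k, k)))
        q *= np.sign(np.diag(r))
        return block @ q

    return rotate(ti_block), rotate(td_block)


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        good = draw[(draw > lo) & (draw < hi)]
        out[filled:filled + good.size] = good
        filled += good.size
    return out


def _generate_events(config: SynthConfig, rng):
    """Cycle timing: contiguous cycles within a task, gaps between tasks."""
    lo, hi = DURATION_BOUNDS
    s_lo, s_hi = STANCE_BOUNDS
    rows = []
    t = config.task_gap
    for task in range(config.n_tasks):
        durations = _truncated_normal(rng, config.cycle_duration_mean,
                                      config.cycle_duration_sd, lo, hi,
                                      config.cycles_per_task)
        fracs = np.clip(
            rng.normal(config.stance_fraction_mean, config.stance_fraction_sd,
                       config.cycles_per_task),
            s_lo + 0.01, s_hi - 0.01,
        )
        for c in range(config.cycles_per_task):
            d = durations[c]
            rows.append((f"task{task}", c, t, t + fracs[c] * d, t + d))
            t += d
        t += config.task_gap
    table = pd.DataFrame(rows, columns=["task_id", "cycle_index",
                                        "t_strike_start", "t_foot_off",
                                        "t_strike_end"])
    span = t + config.task_gap
    return GaitEventTable(table), span


def _phase_of_cycle(n_stance_samp: int, n_total_samp: int) -> np.ndarray:
    """Gait phase (period 100) of each 1 kHz sample within one cycle."""
    j = np.arange(n_total_samp, dtype=float)
    phase = np.empty(n_total_samp)
    st = j < n_stance_samp
    phase[st] = N_STANCE * j[st] / n_stance_samp
    n_swing_samp = n_total_samp - n_stance_samp
    phase[~st] = N_STANCE + (N_PHASE - N_STANCE) * (j[~st] - n_stance_samp) / n_swing_samp
    return phase


def _interp_circular(curves: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Evaluate curves sampled at integer phases 0..99 at fractional phases."""
    ext = np.concatenate([curves, curves[..., :1]], axis=-1)   # wrap 100 -> 0
    lo = np.floor(phase).astype(int)
    frac = phase - lo
    return ext[..., lo] * (1.0 - frac) + ext[..., lo + 1] * frac


def _signal_amplitudes(config: SynthConfig):
    """Per-latent amplitudes so the noiseless signal has per-channel RMS
    ``gain`` and the exact planted TI variance fraction."""
    total = config.gain ** 2 * config.n_channels * config.n_tasks * N_PHASE
    f = config.ti_variance_fraction
    a_ti = math.sqrt(f * total / (config.n_ti_latents * config.n_tasks))
    a_td = math.sqrt((1.0 - f) * total / config.n_td_latents)
    return a_ti, a_td


def generate_session(config: SynthConfig):
    """Generate a session for one region, with its planted ground truth.

    Deterministic given ``config.seed``.  Returns ``(session, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    events, span = _generate_events(config, rng)
    ti_traj, td_traj = make_latent_trajectories(config, rng)
    ti_basis, td_basis = make_channel_bases(config.n_channels,
                                            config.n_ti_latents,
                                            config.n_td_latents, rng)
    a_ti, a_td = _signal_amplitudes(config)

    # noiseless per-task channel trajectories on the phase grid
    signal_tensor = (
        np.einsum("ci,ip->cp", ti_basis, a_ti * ti_traj)[:, None, :]
        + np.einsum("cj,jtp->ctp", td_basis, a_td * td_traj)
    )   # n_channels x n_tasks x 100, Hz (centered)

    n_samples = int(math.ceil(span * FS_RATE))
    phase_trace = np.full(n_samples, np.nan)
    task_trace = np.full(n_samples, -1, dtype=int)
    rates = np.full((config.n_channels, n_samples), config.baseline_rate)
    task_ids = events.task_ids
    for row in events.table.itertuples():
        task = task_ids.index(row.task_id)
        s0 = int(round(row.t_strike_start * FS_RATE))
        s1 = int(round(row.t_foot_off * FS_RATE))
        s2 = int(round(row.t_strike_end * FS_RATE))
        phase_trace[s0:s2] = _phase_of_cycle(s1 - s0, s2 - s0)
        task_trace[s0:s2] = task
    for task in range(config.n_tasks):
        idx = np.flatnonzero(task_trace == task)
        rates[:, idx] += _interp_circular(signal_tensor[:, task, :],
                                          phase_trace[idx])
    if config.noise_sd > 0:
        rates = rates + rng.normal(0.0, config.noise_sd, size=rates.shape)

    if config.spike_mode == "poisson":
        lam = np.clip(rates, 0.0, None) / FS_RATE
        counts = rng.poisson(lam)
        spike_times = []
        for ch in range(config.n_channels):
            idx = np.repeat(np.arange(n_samples), counts[ch])
            spike_times.append((idx + rng.random(idx.size)) / FS_RATE)
        record = RegionRecord(config.region_name, None, spike_times)
    else:
        record = RegionRecord(config.region_name, rates, None)

    session = Session(regions={config.region_name: record}, events=events,
                      fs=FS_RATE, n_samples=n_samples,
                      meta={"seed": config.seed, "span": span})
    truth = SyntheticGroundTruth(
        config=config, ti_basis=ti_basis, td_basis=td_basis,
        ti_trajectories=ti_traj, td_trajectories=td_traj,
        ti_amplitude=a_ti, td_amplitude=a_td,
        signal_tensor=signal_tensor, phase_trace=phase_trace,
        task_index_trace=task_trace, seed=config.seed,
    )
    return session, truth


def _latents_at(truth: SyntheticGroundTruth) -> np.ndarray:
    """Amplitude-scaled latent time series at 1 kHz (zero inside gaps)."""
    cfg = truth.config
    n = truth.phase_trace.size
    z = np.zeros((cfg.n_ti_latents + cfg.n_td_latents, n))
    valid = ~np.isnan(truth.phase_trace)
    phase = truth.phase_trace[valid]
    z[:cfg.n_ti_latents, valid] = truth.ti_amplitude * _interp_circular(
        truth.ti_trajectories, phase)
    for task in range(cfg.n_tasks):
        idx = np.flatnonzero(truth.task_index_trace == task)
        z[cfg.n_ti_latents:, idx] = truth.td_amplitude * _interp_circular(
            truth.td_trajectories[:, task, :], truth.phase_trace[idx])
    return z


# ---------------------------------------------------------------------------
# Planted communication target
# ---------------------------------------------------------------------------

def plant_comm_target(session: Session, config: SynthConfig,
                      truth: SyntheticGroundTruth,
                      target_name: str = "target"):
    """Add a target region whose activity is a known low-rank linear readout
    of the source region's latent signal.

    The rank-``comm_rank`` map reads channel-space directions interpolated
    between the planted TI basis (``comm_alignment=1``) and TD basis
    (``comm_alignment=0``).  Returns the new record; ``truth`` is updated
    in place with ``comm_map`` (B_true) and the input basis.
    """
    cfg = config
    r = cfg.comm_rank
    if r > min(truth.n_latents, cfg.comm_target_channels):
        raise ValueError("comm_rank exceeds min(source latents, target channels)")
    if cfg.comm_alignment > 0 and r > cfg.n_ti_latents:
        raise ValueError("comm_rank exceeds the number of TI latents")
    if cfg.comm_alignment < 1 and r > cfg.n_td_latents:
        raise ValueError("comm_rank exceeds the number of TD latents")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))

    def _haar_cols(k, m):
        q, rr = np.linalg.qr(rng.standard_normal((k, m)))
        return q * np.sign(np.diag(rr))

    alpha = cfg.comm_alignment
    ti_dirs = truth.ti_basis @ _haar_cols(cfg.n_ti_latents, r)
    td_dirs = truth.td_basis @ _haar_cols(cfg.n_td_latents, r)
    mix = alpha * ti_dirs + (1.0 - alpha) * td_dirs
    u_in, rr = np.linalg.qr(mix)
    u_in *= np.sign(np.diag(rr))                 # p x r orthonormal

    source = session.regions[truth.config.region_name]
    if source.rates is None:
        raise ValueError("comm target requires a rate-mode source record")
    centered = _noiseless_source_signal(truth)
    comp = centered.T @ u_in                     # time x r latent readouts
    rms = comp.std(axis=0)
    rms[rms == 0] = 1.0
    v_out = _haar_cols(cfg.comm_target_channels, r)
    b_true = u_in @ np.diag(cfg.gain / rms) @ v_out.T      # p x q, rank r
    y = centered.T @ b_true                      # time x q
    y = y.T + cfg.baseline_rate
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=y.shape)
    record = RegionRecord(target_name, y, None)
    session.regions[target_name] = record
    truth.comm_map = b_true
    truth.comm_input_basis = u_in
    truth.comm_rank = r
    truth.comm_alignment = alpha
    return record


def _noiseless_source_signal(truth: SyntheticGroundTruth) -> np.ndarray:
    """Noiseless centered source signal at 1 kHz (channels x time, Hz)."""
    cfg = truth.config
    w = np.concatenate([truth.ti_basis, truth.td_basis], axis=1)
    return w @ _latents_at(truth)


# ---------------------------------------------------------------------------
# Behavioral readouts
# ---------------------------------------------------------------------------

N_MUSCLES = 6
N_LANDMARKS = 4          # hip, knee, ankle, toe; x, y, z each


def generate_behavior(session: Session, truth: SyntheticGroundTruth,
                      emg_noise_sd: float = 0.0, kin_noise_sd: float = 0.0):
    """Attach EMG envelopes and joint kinematics as linear latent readouts.

    EMG envelopes are rectified (non-negative) readouts of the latents with
    a positive baseline.  Kinematic channels are x, y, z coordinates of 4
    hindlimb landmarks, referenced to the mean position across the
    landmarks, so the across-landmark mean is zero at every sample.
    """
    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729]))
    z = _latents_at(truth)                       # latents x time (amplitude-scaled)
    scale = z.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    zn = z / scale                               # unit-RMS latents

    emg_w = rng.standard_normal((N_MUSCLES, truth.n_latents)) / math.sqrt(truth.n_latents)
    emg_base = 3.0 + rng.random(N_MUSCLES) * 2.0
    emg = np.maximum(emg_base[:, None] + emg_w @ zn, 0.0)
    if emg_noise_sd > 0:
        emg = np.maximum(emg + rng.normal(0, emg_noise_sd, emg.shape), 0.0)

    kin_w = rng.standard_normal((3 * N_LANDMARKS, truth.n_latents)) / math.sqrt(truth.n_latents)
    kin = kin_w @ zn
    kin = kin.reshape(3, N_LANDMARKS, -1)
    kin = kin - kin.mean(axis=1, keepdims=True)  # reference to landmark mean
    kin = kin.reshape(3 * N_LANDMARKS, -1)
    if kin_noise_sd > 0:
        kin = kin + rng.normal(0, kin_noise_sd, kin.shape)
        kin = kin.reshape(3, N_LANDMARKS, -1)
        kin = kin - kin.mean(axis=1, keepdims=True)
        kin = kin.reshape(3 * N_LANDMARKS, -1)

    session.emg = emg
    session.kinematics = kin
    truth.emg_weights = emg_w / scale.T          # weights on raw latent trace
    truth.emg_baseline = emg_base
    ref = np.kron(np.eye(3), np.eye(N_LANDMARKS) - np.full((N_LANDMARKS, N_LANDMARKS),
                                                           1.0 / N_LANDMARKS))
    truth.kin_weights = ref @ (kin_w / scale.T)
    return emg, kin
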