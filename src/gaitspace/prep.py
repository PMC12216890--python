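"""Pre-processing of gait-locked neural recordings.

Turns per-channel spike trains (or raw rate traces) into smoothed, z-scored
rate matrices sampled at 1 kHz, and segments them into peri-gait tensors:
each retained gait cycle is time-warped onto a canonical 100-sample phase
grid in which stance occupies samples 0-59 and swing samples 60-99.

Gait cycles are rejected before warping when their total duration exceeds
1.5 s, or when their stance duration is an outlier of the per-task stance
distribution (outside 1.5x the interquartile range around [Q1, Q3]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

N_PHASE = 100          # samples per warped gait cycle
N_STANCE = 60          # stance occupies phase samples 0..59
N_SWING = N_PHASE - N_STANCE
FS_RATE = 1000         # Hz, sampling rate of rate matrices
MAX_CYCLE_DURATION = 1.5      # s, cycles longer than this are rejected
IQR_FACTOR = 1.5              # stance-duration outlier fence
DEG_PER_PHASE = 360.0 / N_PHASE   # phase sample -> degrees

EVENT_COLUMNS = ["task_id", "cycle_index", "t_strike_start", "t_foot_off", "t_strike_end"]


class GaitEventTable:
    """Table of gait cycles: one row per cycle with foot-strike/foot-off times.

    Each cycle spans the epoch between two consecutive foot strikes;
    stance lasts from ``t_strike_start`` to ``t_foot_off`` and swing from
    ``t_foot_off`` to ``t_strike_end``.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in EVENT_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"gait event table missing columns: {missing}")
        table = table[EVENT_COLUMNS].reset_index(drop=True)
        bad = ~(
            (table.t_strike_start < table.t_foot_off)
            & (table.t_foot_off < table.t_strike_end)
        )
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid event ordering at row {row}: require "
                "t_strike_start < t_foot_off < t_strike_end"
            )
        self.table = table

    @property
    def task_ids(self) -> list:
        return sorted(self.table.task_id.unique().tolist())

    def durations(self) -> pd.Series:
        return self.table.t_strike_end - self.table.t_strike_start

    def stance_durations(self) -> pd.Series:
        return self.table.t_foot_off - self.table.t_strike_start

    def for_task(self, task_id) -> pd.DataFrame:
        return self.table[self.table.task_id == task_id]

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "GaitEventTable":
        return cls(pd.read_csv(path))


@dataclass
class RateMatrix:
    """Per-channel z-scored firing rates at 1 kHz.

    ``constant_flags`` marks channels whose raw rate had zero variance over
    the session; those rows are kept (as zeros) but excluded from analyses.
    """

    rates: np.ndarray          # channels x time
    fs: float = FS_RATE
    region: str = ""
    constant_flags: np.ndarray | None = None

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise ValueError("rates must be channels x time")
        if self.constant_flags is None:
            self.constant_flags = np.zeros(self.rates.shape[0], dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.rates.shape[0]

    @property
    def n_samples(self) -> int:
        return self.rates.shape[1]


class PeriGaitTensor:
    """Warped peri-gait activity: channels x tasks x cycles x 100 phase samples.

    Cycle counts differ between tasks, so per-task blocks are stored in a
    dict keyed by task id, each of shape (channels, cycles, 100).
    """

    def __init__(self, blocks: dict, region: str = "",
                 constant_flags: np.ndarray | None = None):
        if not blocks:
            raise ValueError("empty peri-gait tensor")
        n_ch = None
        for task, arr in blocks.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3 or arr.shape[2] != N_PHASE:
                raise ValueError(
                    f"task {task}: block must be channels x cycles x {N_PHASE}"
                )
            if n_ch is None:
                n_ch = arr.shape[0]
            elif arr.shape[0] != n_ch:
                raise ValueError("inconsistent channel counts between tasks")
            blocks[task] = arr
        self.blocks = dict(sorted(blocks.items(), key=lambda kv: str(kv[0])))
        self.region = region
        if constant_flags is None:
            constant_flags = np.zeros(n_ch, dtype=bool)
        self.constant_flags = np.asarray(constant_flags, dtype=bool)

    @property
    def tasks(self) -> list:
        return list(self.blocks.keys())

    @property
    def n_tasks(self) -> int:
        return len(self.blocks)

    @property
    def n_channels(self) -> int:
        return next(iter(self.blocks.values())).shape[0]

    def cycles(self, task) -> int:
        return self.blocks[task].shape[1]

    def active_channels(self) -> np.ndarray:
        return np.flatnonzero(~self.constant_flags)

    def trial_average(self) -> np.ndarray:
        """Trial-averaged tensor, channels x tasks x 100."""
        return np.stack([blk.mean(axis=1) for blk in self.blocks.values()], axis=1)

    def concatenated(self, tasks=None) -> np.ndarray:
        """Single-cycle activity concatenated over cycles: channels x (100*cycles)."""
        if tasks is None:
            tasks = self.tasks
        parts = [
            self.blocks[t].reshape(self.n_channels, -1) for t in tasks
        ]
        return np.concatenate(parts, axis=1)

    def subset_channels(self, idx) -> "PeriGaitTensor":
        idx = np.asarray(idx)
        return PeriGaitTensor(
            {t: blk[idx] for t, blk in self.blocks.items()},
            region=self.region,
            constant_flags=self.constant_flags[idx],
        )

    def subset_tasks(self, tasks) -> "PeriGaitTensor":
        return PeriGaitTensor(
            {t: self.blocks[t] for t in tasks},
            region=self.region,
            constant_flags=self.constant_flags.copy(),
        )


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------

BIN_WIDTH = 0.010        # s, spike-count window
BIN_STEP = 0.0005        # s, window step (2 kHz intermediate rate)
SMOOTH_SD = 0.050        # s, Gaussian kernel standard deviation


def estimate_rates(spike_times, span, region: str = "") -> RateMatrix:
    """Estimate smoothed, z-scored firing rates from per-channel spike times.

    Spikes are counted in sliding 10 ms windows advanced in 0.5 ms steps
    (an intermediate 2 kHz rate estimate in Hz), smoothed with a Gaussian
    kernel of 50 ms standard deviation, z-scored per channel over the whole
    session, and decimated to 1 kHz by keeping every second sample.
    """
    if span < 1.0:
        raise ValueError("session span must be at least 1 s")
    n_fine = int(math.floor(span / BIN_STEP))
    t_fine = np.arange(n_fine) * BIN_STEP
    half = BIN_WIDTH / 2.0
    rows = []
    for st in spike_times:
        st = np.sort(np.asarray(st, dtype=float))
        if st.size and (st[0] < 0 or st[-1] > span):
            raise ValueError("spike times must lie within the session span")
        counts = (
            np.searchsorted(st, t_fine + half, side="left")
            - np.searchsorted(st, t_fine - half, side="left")
        )
        rows.append(counts / BIN_WIDTH)
    raw = np.asarray(rows, dtype=float)
    sigma_samples = SMOOTH_SD / BIN_STEP
    smooth = gaussian_filter1d(raw, sigma=sigma_samples, axis=1,
                               mode="constant", cval=0.0)
    z, flags = zscore(smooth)
    n_out = int(math.floor(span * FS_RATE))
    return RateMatrix(z[:, ::2][:, :n_out], fs=FS_RATE, region=region,
                      constant_flags=flags)


def zscore(rates: np.ndarray):
    """Z-score each channel over the session; constant channels are flagged
    and left at zero rather than divided by a zero standard deviation."""
    rates = np.asarray(rates, dtype=float)
    mean = rates.mean(axis=1, keepdims=True)
    sd = rates.std(axis=1, keepdims=True)
    flags = sd[:, 0] <= 0.0
    safe_sd = np.where(sd > 0.0, sd, 1.0)
    return (rates - mean) / safe_sd, flags


def zscore_rates(raw: np.ndarray, fs: float = FS_RATE, region: str = "") -> RateMatrix:
    """Z-score a raw (already sampled) rate matrix into a :class:`RateMatrix`."""
    z, flags = zscore(raw)
    return RateMatrix(z, fs=fs, region=region, constant_flags=flags)


# ---------------------------------------------------------------------------
# Segmentation and time warping
# ---------------------------------------------------------------------------

def _warp_segment(seg: np.ndarray, n_out: int) -> np.ndarray:
    """Linearly resample ``seg`` (channels x time) to ``n_out`` samples."""
    n_in = seg.shape[1]
    if n_in < 2:
        raise ValueError("segment too short to warp")
    x_out = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(x_out).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = x_out - lo
    return seg[:, lo] * (1.0 - frac) + seg[:, hi] * frac


def segment_and_warp(rates: RateMatrix, events: GaitEventTable,
                     max_duration: float = MAX_CYCLE_DURATION,
                     iqr_factor: float = IQR_FACTOR):
    """Cut gait cycles out of a rate matrix and warp each onto the 100-sample
    phase grid (stance -> 60 samples, swing -> 40 samples).

    Returns ``(tensor, rejection_log)`` where the log is a DataFrame of the
    dropped cycles with a ``reason`` column ("duration" or "stance_iqr").
    The duration rule is applied first; the stance IQR fence is computed per
    task over the duration-surviving cycles only.
    """
    fs = rates.fs
    rejected = []
    blocks = {}
    for task in events.task_ids:
        rows = events.for_task(task)
        durations = (rows.t_strike_end - rows.t_strike_start).to_numpy()
        keep_dur = durations <= max_duration
        for idx in np.flatnonzero(~keep_dur):
            rejected.append((task, int(rows.cycle_index.iloc[idx]), "duration"))
        surv = rows[keep_dur]
        stance = (surv.t_foot_off - surv.t_strike_start).to_numpy()
        if stance.size:
            q1, q3 = np.percentile(stance, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
            keep_iqr = (stance >= lo) & (stance <= hi)
        else:
            keep_iqr = np.zeros(0, dtype=bool)
        for idx in np.flatnonzero(~keep_iqr):
            rejected.append((task, int(surv.cycle_index.iloc[idx]), "stance_iqr"))
        final = surv[keep_iqr]
        if len(final) < 3:
            raise ValueError(
                f"task {task!r}: only {len(final)} gait cycles survive rejection "
                "(need at least 3)"
            )
        warped = np.empty((rates.n_channels, len(final), N_PHASE))
        for j, (_, row) in enumerate(final.iterrows()):
            s0 = int(round(row.t_strike_start * fs))
            s1 = int(round(row.t_foot_off * fs))
            s2 = int(round(row.t_strike_end * fs))
            if s2 > rates.n_samples:
                raise ValueError(
                    f"task {task!r} cycle {int(row.cycle_index)} extends past "
                    "the end of the recording"
                )
            warped[:, j, :N_STANCE] = _warp_segment(rates.rates[:, s0:s1], N_STANCE)
            warped[:, j, N_STANCE:] = _warp_segment(rates.rates[:, s1:s2], N_SWING)
        blocks[task] = warped
    log = pd.DataFrame(rejected, columns=["task_id", "cycle_index", "reason"])
    tensor = PeriGaitTensor(blocks, region=rates.region,
                            constant_flags=rates.constant_flags.copy())
    return tensor, log


# ---------------------------------------------------------------------------
# Circular statistics on gait phases
# ---------------------------------------------------------------------------

def circular_sd(angles_rad: np.ndarray, form: str = "angular_deviation") -> float:
    """Circular standard deviation of a sample of angles, in radians.

    Default is the angular deviation sqrt(2*(1 - Rbar)); the alternative
    ``form="log"`` gives sqrt(-2*ln(Rbar)).
    """
    angles_rad = np.asarray(angles_rad, dtype=float)
    rbar = np.abs(np.exp(1j * angles_rad).mean())
    if form == "angular_deviation":
        return float(np.sqrt(max(0.0, 2.0 * (1.0 - rbar))))
    if form == "log":
        rbar = max(rbar, np.finfo(float).tiny)
        return float(np.sqrt(-2.0 * np.log(rbar)))
    raise ValueError(f"unknown circular s.d. form {form!r}")


def phase_to_rad(phase_samples) -> np.ndarray:
    """Convert phase samples (period 100) to radians."""
    return np.asarray(phase_samples, dtype=float) * (2.0 * np.pi / N_PHASE)


# ---------------------------------------------------------------------------
# Peri-gait summary statistics
# ---------------------------------------------------------------------------

@dataclass
class PerigaitStats:
    """Per-channel peri-gait summary plus population-level cross-task numbers."""

    per_channel: pd.DataFrame
    pgp_per_task: pd.DataFrame            # channel x task preferred gait phase
    cross_task_correlation: float         # population value (self-pairs excluded)
    correlation_by_combination: pd.DataFrame
    population_pgp_circ_sd_deg: float
    circ_sd_form: str = "angular_deviation"


def preferred_gait_phase(mean_trace: np.ndarray) -> int:
    """Phase sample of peak activity; argmax ties broken by smallest index."""
    return int(np.argmax(mean_trace))


def cross_task_correlation(tensor: PeriGaitTensor,
                           include_self: bool = False) -> tuple[float, pd.DataFrame]:
    """Population cross-task correlation of single-cycle peri-gait activity.

    For every channel and every pair of gait cycles, the Pearson correlation
    between the two warped traces is computed; values are averaged first over
    cycle pairs within a task combination, then over channels, then over
    the task combinations (pairs of distinct tasks unless ``include_self``).
    """
    tasks = tensor.tasks
    active = tensor.active_channels()
    combos = []
    rows = []
    for i, ta in enumerate(tasks):
        for tb in tasks[i:]:
            if ta == tb and not include_self:
                self_pair = True
            else:
                self_pair = ta == tb
            a = tensor.blocks[ta][active]        # ch x ca x 100
            b = tensor.blocks[tb][active]
            az = _standardize_traces(a)
            bz = _standardize_traces(b)
            # mean over all cycle pairs of corr = corr of sums / (ca*cb)
            corr = np.einsum("cip,cjp->cij", az, bz) / (N_PHASE - 1)
            if ta == tb:
                # exclude a cycle paired with itself
                n = corr.shape[1]
                mask = ~np.eye(n, dtype=bool)
                per_channel = corr[:, mask].reshape(corr.shape[0], -1).mean(axis=1)
            else:
                per_channel = corr.reshape(corr.shape[0], -1).mean(axis=1)
            value = float(per_channel.mean())
            rows.append((ta, tb, value, self_pair))
            if not self_pair:
                combos.append(value)
    table = pd.DataFrame(rows, columns=["task_a", "task_b", "mean_r", "self_pair"])
    population = float(np.mean(combos)) if combos else float("nan")
    return population, table


def _standardize_traces(block: np.ndarray) -> np.ndarray:
    """Standardize each (channel, cycle) trace to zero mean, unit variance."""
    m = block.mean(axis=2, keepdims=True)
    s = block.std(axis=2, keepdims=True, ddof=1)
    s = np.where(s > 0, s, np.inf)       # constant trace -> zero contribution
    return (block - m) / s


def perigait_stats(tensor: PeriGaitTensor,
                   circ_sd_form: str = "angular_deviation") -> PerigaitStats:
    """Per-channel mean rate, modulation depth, preferred gait phase per task,
    PGP circular s.d. across tasks, and cross-task correlation summaries."""
    if tensor.n_tasks < 2:
        raise ValueError("cross-task statistics require at least 2 tasks")
    avg = tensor.trial_average()         # ch x task x 100
    tasks = tensor.tasks
    active = set(tensor.active_channels().tolist())
    records = []
    pgp_rows = []
    circ_sds = []
    for ch in range(tensor.n_channels):
        overall = avg[ch].mean(axis=0)
        mean_rate = float(overall.mean())
        mod_depth = float(overall.max() - overall.min())
        if ch not in active:
            records.append((ch, mean_rate, mod_depth, np.nan, True))
            pgp_rows.append([np.nan] * len(tasks))
            continue
        pgps = [preferred_gait_phase(avg[ch, t]) for t in range(len(tasks))]
        sd_deg = math.degrees(circular_sd(phase_to_rad(pgps), form=circ_sd_form))
        records.append((ch, mean_rate, mod_depth, sd_deg, False))
        pgp_rows.append(pgps)
        circ_sds.append(sd_deg)
    per_channel = pd.DataFrame(
        records,
        columns=["channel", "mean_rate", "modulation_depth",
                 "pgp_circ_sd_deg", "constant"],
    )
    pgp_per_task = pd.DataFrame(pgp_rows, columns=[str(t) for t in tasks])
    population_corr, combo_table = cross_task_correlation(tensor)
    return PerigaitStats(
        per_channel=per_channel,
        pgp_per_task=pgp_per_task,
        cross_task_correlation=population_corr,
        correlation_by_combination=combo_table,
        population_pgp_circ_sd_deg=float(np.mean(circ_sds)) if circ_sds else float("nan"),
        circ_sd_form=circ_sd_form,
    )
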