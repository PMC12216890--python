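# gaitspace

Subspace analysis of gait-locked neural population activity: how much of a
cortical region's activity during locomotion is shared across tasks, how
much is task-specific, and which of the two a region *communicates* to
another region.

The package is written for systems neuroscientists analysing multi-channel
recordings (e.g. Utah arrays in premotor, motor, and somatosensory cortex)
from animals performing several locomotor tasks, and for anyone who wants a
fully testable reference implementation of this analysis chain on synthetic
data with known ground truth.

## What it computes

Given per-channel spike trains (or rate traces) and a gait-event table
(foot-strike / foot-off times per cycle, task labels):

1. **Peri-gait tensors** — rates estimated in 10 ms windows at 0.5 ms
   steps, Gaussian-smoothed (σ = 50 ms), z-scored, decimated to 1 kHz;
   cycles rejected by a 1.5 s duration rule and a per-task 1.5×IQR stance
   rule; each cycle warped onto a 100-sample phase grid (stance → 60
   samples, swing → 40).
2. **Manifolds** — dimensionality *d* = smallest number of principal
   components exceeding 90% cumulative variance; single-task, all-task,
   leave-one-task-out and channel-subsampled variants; the alignment index
   `AI = (‖X‖² − ‖X − D_m E_m X‖²) / ‖X‖²`-based ratio of cross- to
   self-projected variance between task manifolds.
3. **Demixed PCA** — the trial-averaged tensor splits orthogonally into a
   task-independent part `X_TI` (across-task mean) and task-dependent
   remainder `X_TD`; per marginalization, minimize `‖X_m − F D X‖²` in
   closed form; modes labelled TI when >50% of their variance is
   task-independent; mode removal from full-resolution rates.
4. **Communication subspaces** — ridge regression
   `B = (XᵀX + λI)⁻¹XᵀY` of a target region on a source region (10-fold
   CV, one-SE rule for λ), reduced-rank restriction via the principal
   directions of the prediction, `m_RRR` = smallest rank keeping ≥95% of
   the ridge-explained variance, communication basis = orthonormalized
   leading columns of `B̄ = B_ridge V`.
5. **Geometry & statistics** — principal angles
   `θ_i = arccos σ_i(W_aᵀW_b)`; Δangles = mean CS–TD angle − mean CS–TI
   angle (positive ⇒ the communication subspace is TI-aligned); cycle
   bootstraps, circular phase shuffles, uniform-angle and Haar-random
   subspace chance levels; Monte-Carlo p-values `(1 + #extreme)/(1 + N)`.
6. **Decoders** — regularized-LDA detection of foot-strike/foot-off events
   (80% posterior threshold, 100 ms refractory, mean two-class F-score),
   rLDA task classification, and Wiener-filter reconstruction of EMG
   envelopes / joint kinematics with Savitzky-Golay velocities.

A synthetic-session generator (`gaitspace.synth`) plants known
task-independent and task-dependent latent subspaces with configurable
variance fractions, a low-rank inter-region map with configurable
TI/TD alignment, and linearly-read-out behavior, so every quantity above
has a closed-form target. See `docs/methods.md` for the model and its
design choices.

## Worked example

```python
import gaitspace as g

cfg = g.SynthConfig(n_tasks=5, cycles_per_task=40, n_channels=48,
                    n_ti_latents=5, n_td_latents=5,
                    ti_variance_fraction=0.68, comm_rank=3,
                    comm_alignment=1.0, noise_sd=1.0, seed=42)
session, truth = g.generate_session(cfg)
g.plant_comm_target(session, cfg, truth)

_, src, _ = g.cli_io.prepare_region(session, "source")
_, tgt, _ = g.cli_io.prepare_region(session, "target")

decomp = g.fit_dpca(src)
x, y = g.comms.task_design_matrices(src, tgt, "task0")
model = g.fit_communication_model(x, y)

ti5 = g.Subspace(decomp.subspace_basis(g.dpca.TI, 5))
td5 = g.Subspace(decomp.subspace_basis(g.dpca.TD, 5))
delta = g.delta_angles(g.Subspace(model.basis), td5, ti5)
chance = g.null_engine("subspace-random",
                       statistic=lambda s: g.delta_angles(s, td5, ti5),
                       subspace_ambient=model.basis.shape[0],
                       subspace_dim=model.basis.shape[1],
                       n_draws=2000, seed=42, observed=delta)
```

Output:

```
retained cycles per task: [40, 40, 39, 40, 40]
TI subspace variance: 67.6% (planted: 68%)
communication rank m_RRR = 3 (planted: 3)
delta angles = +87.4 deg, chance +0.01 +- 4.75, p = 0.0005
```

Reading it: the demixed decomposition recovers the planted 68%
task-independent variance to within half a point; reduced-rank regression
finds exactly the planted rank-3 communication map; and because the map
was planted to read the TI subspace (`comm_alignment=1`), the
communication subspace sits ~87° closer to the TI than to the TD modes —
far outside the Haar-random chance distribution (p at the Monte-Carlo
floor for 2000 draws).

A command-line interface mirrors the library
(`gaitspace simulate|prep|manifold|dpca|comms|geom|decode|run|report`);
`gaitspace run --seed 7 --out results` executes the whole chain on a
synthetic session and writes tidy CSV/JSON per stage.

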