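"""Demixed PCA: marginalization algebra, mode recovery, removal."""

import numpy as np
import pytest

import gaitspace as g
from gaitspace.dpca import TD, TI, fit_dpca, marginalize, remove_modes, variance_table
from gaitspace.prep import N_PHASE, PeriGaitTensor


def _planted_tensor(ti_frac=0.7, n_ch=12, n_tasks=4, n_cycles=6, noise=0.0,
                    seed=0, n_ti=2, n_td=2, harmonic_order=5):
    cfg = g.SynthConfig(n_tasks=n_tasks, cycles_per_task=n_cycles,
                        n_channels=n_ch, n_ti_latents=n_ti, n_td_latents=n_td,
                        harmonic_order=harmonic_order,
                        ti_variance_fraction=ti_frac, noise_sd=noise, seed=seed)
    session, truth = g.generate_session(cfg)
    _, tensor, _ = g.cli_io.prepare_region(session, "source")
    return tensor, truth


class TestMarginalize:
    def test_identical_tasks_have_zero_td(self):
        avg = np.repeat(np.random.default_rng(0).normal(size=(5, 1, N_PHASE)),
                        4, axis=1)
        avg -= avg.mean(axis=(1, 2), keepdims=True)
        _, td = marginalize(avg)
        np.testing.assert_allclose(td, 0, atol=1e-12)

    def test_zero_task_mean_has_zero_ti(self):
        rng = np.random.default_rng(1)
        avg = rng.normal(size=(5, 4, N_PHASE))
        avg -= avg.mean(axis=1, keepdims=True)
        ti, td = marginalize(avg)
        np.testing.assert_allclose(ti, 0, atol=1e-12)
        np.testing.assert_allclose(td, avg, atol=1e-12)

    def test_orthogonality_and_pythagoras(self):
        rng = np.random.default_rng(2)
        avg = rng.normal(size=(6, 5, N_PHASE))
        avg -= avg.mean(axis=(1, 2), keepdims=True)
        ti, td = marginalize(avg)
        assert abs(np.sum(ti * td)) < 1e-9
        assert np.sum(avg ** 2) == pytest.approx(
            np.sum(ti ** 2) + np.sum(td ** 2), rel=1e-12)

    def test_single_task_warns(self):
        avg = np.random.default_rng(3).normal(size=(4, 1, N_PHASE))
        with pytest.warns(UserWarning):
            marginalize(avg)


class TestFitDpca:
    def test_pure_ti_data_yields_fully_ti_leading_mode(self):
        tensor, _ = _planted_tensor(ti_frac=1.0, n_td=1)
        decomp = fit_dpca(tensor, n_modes_per_marg=2)
        lead = decomp.modes[0]
        assert lead.label == TI
        assert lead.ti_pct / lead.total_pct == pytest.approx(1.0, abs=1e-6)

    def test_planted_variance_split_recovered(self):
        tensor, _ = _planted_tensor(ti_frac=0.7, n_cycles=20, noise=0.0, seed=4)
        decomp = fit_dpca(tensor, n_modes_per_marg=4)
        assert decomp.ti_subspace_variance_pct() == pytest.approx(70.0, abs=1.0)

    def test_top_ti_mode_projections_coincide_across_tasks(self):
        tensor, _ = _planted_tensor(ti_frac=0.6, n_cycles=20, noise=0.0, seed=5)
        decomp = fit_dpca(tensor, n_modes_per_marg=4)
        mode = decomp.modes_with_label(TI)[0]
        avg = tensor.trial_average()[decomp.channel_index]
        avg = avg - avg.mean(axis=(1, 2), keepdims=True)
        traj = np.einsum("c,ctp->tp", mode.decoder, avg)
        spread = np.max(np.abs(traj - traj.mean(axis=0)))
        assert spread < 0.05 * np.max(np.abs(traj))

    def test_per_mode_ti_td_sum_to_total(self, small_tensor):
        decomp = fit_dpca(small_tensor, n_modes_per_marg=5)
        for m in decomp.modes:
            assert m.ti_pct + m.td_pct == pytest.approx(m.total_pct, abs=1e-6)

    def test_closed_form_matches_svd_oracle_on_toy(self):
        """On a noiseless planted 6-channel toy (where each marginalization
        is exactly a channel-space projection of the data), the closed-form
        fit with a vanishing ridge reproduces the truncated-SVD optimum of
        each marginalization tensor."""
        cfg = g.SynthConfig(n_tasks=3, cycles_per_task=4, n_channels=6,
                            n_ti_latents=2, n_td_latents=2, harmonic_order=3,
                            ti_variance_fraction=0.6, noise_sd=0.0, seed=12)
        _, truth = g.generate_session(cfg)
        avg = truth.signal_tensor - truth.signal_tensor.mean(axis=(1, 2),
                                                             keepdims=True)
        blocks = {f"t{k}": np.repeat(avg[:, k:k + 1, :], 2, axis=1)
                  for k in range(cfg.n_tasks)}
        tensor = PeriGaitTensor(blocks)
        q = 2
        decomp = fit_dpca(tensor, n_modes_per_marg=q, ridge_mu=1e-12)
        x = avg.reshape(6, -1)
        for label in (TI, TD):
            x_m = (decomp.x_ti if label == TI else decomp.x_td).reshape(6, -1)
            modes = [m for m in decomp.modes if m.marginalization == label][:q]
            f = np.column_stack([m.encoder for m in modes])
            d = np.vstack([m.decoder for m in modes])
            u, s, vt = np.linalg.svd(x_m, full_matrices=False)
            oracle = (u[:, :q] * s[:q]) @ vt[:q]
            np.testing.assert_allclose(f @ (d @ x), oracle, atol=1e-8)

    def test_labels_invariant_to_permutation_and_scaling(self):
        tensor, _ = _planted_tensor(ti_frac=0.5, n_cycles=10, noise=0.5, seed=7)
        decomp = fit_dpca(tensor, n_modes_per_marg=4)
        perm = np.random.default_rng(8).permutation(tensor.n_channels)
        scaled = PeriGaitTensor(
            {t: 3.7 * blk[perm] for t, blk in tensor.blocks.items()})
        decomp2 = fit_dpca(scaled, n_modes_per_marg=4)
        assert [m.label for m in decomp.modes] == [m.label for m in decomp2.modes]
        for a, b in zip(decomp.modes, decomp2.modes):
            assert a.total_pct == pytest.approx(b.total_pct, abs=1e-6)

    def test_too_many_modes_errors(self, small_tensor):
        with pytest.raises(ValueError, match="rank"):
            fit_dpca(small_tensor, n_modes_per_marg=500)


class TestVarianceTable:
    def test_conservation(self, small_tensor):
        decomp = fit_dpca(small_tensor, n_modes_per_marg=5)
        vt = variance_table(decomp)
        total = vt["per_mode"].total_pct.sum() + vt["unassigned_pct"]
        assert total == pytest.approx(100.0, abs=1e-9)
        assert vt["marginalization_pct"][TI] + vt["marginalization_pct"][TD] == \
            pytest.approx(100.0, abs=1e-9)

    def test_single_mode_data_fully_explained(self):
        phase = np.arange(N_PHASE) * 2 * np.pi / N_PHASE
        sig = np.outer(np.array([1.0, -0.5, 2.0]), np.sin(phase))
        blocks = {f"t{k}": np.repeat(sig[:, None, :], 2, axis=1)
                  for k in range(2)}
        decomp = fit_dpca(PeriGaitTensor(blocks), n_modes_per_marg=1)
        assert decomp.modes[0].total_pct == pytest.approx(100.0, abs=1e-6)


class TestRemoveModes:
    def test_k_zero_is_identity(self, small_tensor):
        decomp = fit_dpca(small_tensor, n_modes_per_marg=3)
        rng = np.random.default_rng(9)
        rates = rng.normal(size=(len(decomp.channel_index), 500))
        out, frac = remove_modes(rates, decomp, TI, k=0)
        np.testing.assert_array_equal(out, rates)
        assert frac == 0.0

    def test_removing_everything_leaves_joint_residual(self, small_tensor):
        decomp = fit_dpca(small_tensor, n_modes_per_marg=5)
        avg = small_tensor.trial_average()[decomp.channel_index]
        avg = avg - avg.mean(axis=(1, 2), keepdims=True)
        x = avg.reshape(avg.shape[0], -1)
        out, frac = remove_modes(x, decomp, "both")
        resid_pct = 100.0 * np.sum((out - out.mean(axis=1, keepdims=True)) ** 2) \
            / decomp.total_energy
        assert resid_pct == pytest.approx(decomp.residual_pct, abs=1e-6)

    def test_removing_ti_modes_decorrelates_planted_ti_latents(self):
        tensor, truth = _planted_tensor(ti_frac=0.95, n_cycles=20, noise=0.0,
                                        seed=10, n_ti=2, n_td=1)
        decomp = fit_dpca(tensor, n_modes_per_marg=3)
        avg = tensor.trial_average()[decomp.channel_index]
        x = (avg - avg.mean(axis=(1, 2), keepdims=True)).reshape(avg.shape[0], -1)
        out, frac = remove_modes(x, decomp, TI)
        assert frac > 0.9
        ti_signal = np.tile(truth.ti_trajectories, (1, tensor.n_tasks))
        for latent in ti_signal:
            for ch in out:
                if np.std(ch) < 1e-9:
                    continue
                r = np.corrcoef(latent, ch)[0, 1]
                assert abs(r) <= 0.05

    def test_k_exceeding_modes_errors(self, small_tensor):
        decomp = fit_dpca(small_tensor, n_modes_per_marg=3)
        with pytest.raises(ValueError, match="exceeds"):
            remove_modes(np.zeros((len(decomp.channel_index), 10)), decomp,
                         TI, k=99)
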