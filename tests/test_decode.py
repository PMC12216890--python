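"""Gait-event detection, task classification, Wiener reconstruction."""

import numpy as np
import pandas as pd
import pytest

import gaitspace as g
from gaitspace.decode import (_match_events, classify_task, fit_apply_wiener,
                              fit_event_decoder, run_event_decoder,
                              savgol_velocity, CLASS_OFF, CLASS_STRIKE)
from gaitspace.prep import RateMatrix

from conftest import make_events


@pytest.fixture(scope="module")
def decodable_session():
    """Strongly phase-locked, mostly task-independent session."""
    cfg = g.SynthConfig(n_tasks=3, cycles_per_task=20, n_channels=24,
                        n_ti_latents=4, n_td_latents=2, harmonic_order=4,
                        ti_variance_fraction=0.95, noise_sd=1.0, seed=21)
    session, truth = g.generate_session(cfg)
    rates, tensor, _ = g.cli_io.prepare_region(session, "source")
    active = tensor.active_channels()
    rmat = RateMatrix(rates.rates[active], fs=rates.fs)
    return session, rmat, tensor


SMALL_GRIDS = dict(l_grid=(200, 300), b_grid=(5,), reg_grid=(1e-3, 1e-2, 1e-1))


class TestFitEventDecoder:
    def test_separable_session_reaches_high_cv_score(self, decodable_session):
        session, rmat, _ = decodable_session
        model = fit_event_decoder(rmat, session.events, "task0", **SMALL_GRIDS)
        assert model.cv_score >= 0.9
        assert model.feature_len_ms in SMALL_GRIDS["l_grid"]
        assert model.reg in SMALL_GRIDS["reg_grid"]

    def test_label_shuffle_drops_to_chance(self, decodable_session):
        """Permuting event identities must destroy the decoder's CV score
        (permutation oracle for the absence of leakage)."""
        session, rmat, _ = decodable_session
        rows = session.events.for_task("task0").copy()
        rng = np.random.default_rng(0)
        # shuffle foot-off positions within cycles: events no longer phase-locked
        dur = (rows.t_strike_end - rows.t_strike_start).to_numpy()
        rows["t_foot_off"] = rows.t_strike_start + dur * rng.uniform(0.25, 0.75,
                                                                     len(rows))
        shuffled = g.GaitEventTable(
            pd.concat([rows, session.events.table[
                session.events.table.task_id != "task0"]]))
        model = fit_event_decoder(rmat, shuffled, "task0", **SMALL_GRIDS)
        real = fit_event_decoder(rmat, session.events, "task0", **SMALL_GRIDS)
        assert model.cv_score < real.cv_score - 0.15

    def test_too_few_events_errors(self, decodable_session):
        _, rmat, _ = decodable_session
        rows = [("t", i, 1.0 + i, 1.6 + i, 2.0 + i) for i in range(4)]
        with pytest.raises(ValueError, match="(fewer than 10|at least 3)"):
            fit_event_decoder(rmat, make_events(rows), "t", **SMALL_GRIDS)


class _StubLda:
    """Posterior injector for detection-logic tests."""

    classes_ = np.array([0, 1, 2])

    def __init__(self, prob_fn, n_times, step):
        self.prob_fn = prob_fn

    def predict_proba(self, x):
        return self.prob_fn(len(x))


def _stub_model(prob_fn):
    model = g.EventDecoderModel.__new__(g.EventDecoderModel)
    model.lda = _StubLda(prob_fn, 0, 0)
    model.feature_len_ms = 100
    model.n_bins = 5
    model.reg = 0.01
    model.calibration_task = "cal"
    model.fs = 1000
    model.threshold = 0.8
    model.refractory_ms = 100.0
    return model


class TestRunEventDecoder:
    def test_refractory_merges_nearby_crossings(self):
        """Two 80% crossings of the same class 50 ms apart yield one
        detection."""
        events = make_events([("test", 0, 1.0, 1.6, 2.0),
                              ("test", 1, 2.0, 2.6, 3.0),
                              ("test", 2, 3.0, 3.6, 4.0)])
        rates = RateMatrix(np.zeros((3, 5000)))

        def prob_fn(n):
            p = np.zeros((n, 3))
            p[:, 0] = 1.0
            # two crossings 50 ms apart (5 steps at 10 ms), then quiet
            for i in (30, 35):
                if i < n:
                    p[i] = [0.1, 0.9, 0.0]
                    if i + 1 < n:
                        p[i + 1] = [1.0, 0.0, 0.0]
            return p

        model = _stub_model(prob_fn)
        out = run_event_decoder(model, rates, events, tasks=["test"])
        strike = out["foot_strike"]
        assert strike["tp"] + strike["fp"] == 1

    def test_perfect_detections_give_unit_fscore(self, decodable_session):
        session, rmat, _ = decodable_session
        events = session.events

        strikes = {}
        for task in events.task_ids:
            rows = events.for_task(task)
            s = rows.t_strike_start.to_numpy().tolist()
            s.append(float(rows.t_strike_end.iloc[-1]))
            strikes[task] = (np.asarray(s), rows.t_foot_off.to_numpy())

        # emulate an ideal detector by scoring the truth against itself
        for task, (s, o) in strikes.items():
            tp, fp, fn = _match_events(s, s, 0.125)
            assert fp == 0 and fn == 0

    def test_matching_tolerance_bounds_pairing(self):
        det = np.array([1.0, 2.0, 3.0])
        truth = np.array([1.05, 2.3, 2.95])
        tp, fp, fn = _match_events(det, truth, 0.125)
        assert (tp, fp, fn) == (2, 1, 1)


class TestClassifyTask:
    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(250, 6))
        y = np.repeat(np.arange(5), 50)
        acc, _ = classify_task(x, y)
        assert abs(acc - 0.2) < 0.12       # binomial CI around chance

    def test_separated_means_high_accuracy(self):
        rng = np.random.default_rng(6)
        means = rng.normal(scale=6.0, size=(5, 6))
        x = np.concatenate([means[k] + rng.normal(size=(40, 6))
                            for k in range(5)])
        y = np.repeat(np.arange(5), 40)
        acc, conf = classify_task(x, y)
        assert acc >= 0.95

    def test_confusion_rows_sum_to_task_counts(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(120, 4))
        y = np.repeat(np.arange(3), 40)
        _, conf = classify_task(x, y)
        np.testing.assert_array_equal(conf.sum(axis=1), [40, 40, 40])


class TestWiener:
    def test_delayed_channel_reconstructed_noiselessly(self):
        rng = np.random.default_rng(8)
        rates = rng.normal(size=(4, 6000))
        target = np.roll(rates[2], 20)[None, :]     # 20 ms delay, in window
        idx = np.arange(400, 6000)
        model, res = fit_apply_wiener(
            rates, target, window_ms=100, calibration_idx=idx[:4000],
            eval_idx={"held": idx[4000:]})
        assert res["eval_r2"]["held"][0] >= 0.999

    def test_independent_noise_not_predictable(self):
        rng = np.random.default_rng(9)
        rates = rng.normal(size=(4, 6000))
        target = rng.normal(size=(1, 6000))
        idx = np.arange(400, 6000)
        _, res = fit_apply_wiener(
            rates, target, window_ms=100, calibration_idx=idx[:4000],
            eval_idx={"held": idx[4000:]})
        assert res["eval_r2"]["held"][0] <= 0.05

    def test_planted_lag_profile_recovered(self):
        rng = np.random.default_rng(10)
        rates = rng.normal(size=(3, 8000))
        lags = [0, 10, 30]                           # ms
        w_true = np.array([1.5, -2.0, 0.7])
        target = sum(w * np.roll(rates[c], lag)
                     for c, (w, lag) in enumerate(zip(w_true, lags)))[None, :]
        idx = np.arange(400, 8000)
        model, _ = fit_apply_wiener(rates, target, window_ms=100,
                                    calibration_idx=idx)
        weights = model.weights[:-1, 0].reshape(10, 3)   # lags x channels
        recovered = np.array([weights[0, 0], weights[1, 1], weights[3, 2]])
        corr = np.corrcoef(recovered, w_true)[0, 1]
        assert corr >= 0.95

    def test_planted_behavior_readout_recovered_heldout(self, noiseless_session):
        """On noiseless synthetic data the kinematic readout is an exact
        linear function of the rates, so held-out cycles of the calibration
        task reconstruct almost perfectly."""
        session, truth, _ = noiseless_session
        g.generate_behavior(session, truth)
        ev = session.events.for_task("task0")
        segs = [np.arange(int(round(r.t_strike_start * 1000)),
                          int(round(r.t_strike_end * 1000)))
                for r in ev.itertuples()]
        half = len(segs) // 2
        cal = np.concatenate(segs[:half])
        held = np.concatenate(segs[half:])
        rates = session.regions["source"].rates
        _, res = fit_apply_wiener(rates, session.kinematics, window_ms=100,
                                  calibration_idx=cal,
                                  eval_idx={"held": held})
        assert np.min(res["eval_r2"]["held"]) >= 0.99

    def test_window_shorter_than_lag_errors(self):
        with pytest.raises(ValueError, match="lag"):
            fit_apply_wiener(np.zeros((2, 1000)), np.zeros((1, 1000)),
                             window_ms=5, calibration_idx=np.arange(100, 900))


class TestSavgolVelocity:
    def test_constant_position_zero_velocity(self):
        v = savgol_velocity(np.full((2, 200), 3.3), window=11, polyorder=2)
        np.testing.assert_allclose(v, 0, atol=1e-10)

    def test_linear_position_gives_slope(self):
        fs = 100.0
        t = np.arange(300) / fs
        v = savgol_velocity(2.5 * t, window=11, polyorder=2, fs=fs)
        np.testing.assert_allclose(v[20:-20], 2.5, atol=1e-9)

    def test_quadratic_exact_for_polyorder_two(self):
        fs = 100.0
        t = np.arange(300) / fs
        pos = 0.5 * t ** 2
        v = savgol_velocity(pos, window=15, polyorder=2, fs=fs)
        np.testing.assert_allclose(v[20:-20], t[20:-20], atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            savgol_velocity(np.zeros(100), window=10, polyorder=2)
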