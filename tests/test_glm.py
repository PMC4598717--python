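"""Design matrices, OLS fits and contrast maps."""

import numpy as np
import pandas as pd
import pytest

import plastimap as pm
from plastimap import glm as G
from plastimap.maps import BoldRun


def _events(onsets, trial_type="Addition", correct=True, duration=9.5):
    return pd.DataFrame({"onset": onsets, "duration": duration,
                         "trial_type": trial_type, "correct": correct,
                         "rt": 1000.0})


class TestCanonicalHrf:
    def test_peak_near_six_seconds(self):
        h = G.canonical_hrf(dt=0.1)
        assert np.argmax(h) * 0.1 == pytest.approx(5.0, abs=1.5)
        assert h.max() == 1.0

    def test_undershoot_present(self):
        h = G.canonical_hrf(dt=0.1)
        late = h[int(12 / 0.1):int(25 / 0.1)]
        assert late.min() < 0
        assert abs(late.min()) < 0.3  # ~1/6 of the peak

    def test_matches_nilearn_spm_shape(self):
        nilearn_glm = pytest.importorskip("nilearn.glm.first_level")
        ref = nilearn_glm.spm_hrf(0.1, oversampling=1, time_length=32.0)
        mine = G.canonical_hrf(dt=0.1)
        n = min(len(ref), len(mine))
        r = np.corrcoef(ref[:n], mine[:n])[0, 1]
        assert r > 0.99


class TestBuildDesign:
    def test_correct_only_events_give_four_task_columns(self):
        ev = pd.concat([_events(np.arange(0, 120, 20.0)),
                        _events(np.arange(10, 130, 20.0), "Control")],
                       ignore_index=True)
        dm = G.build_design(ev, n_volumes=80, tr=2.0)
        task_cols = [n for n in dm.names if not n.startswith("drift")
                     and n != "intercept"]
        assert task_cols == ["add_correct", "add_correct_deriv",
                             "ctrl_correct", "ctrl_correct_deriv"]
        assert dm.rank == dm.matrix.shape[1]

    def test_single_event_column_matches_convolution_oracle(self):
        # independent dense convolution oracle (scipy) for one 9.5 s boxcar
        from scipy.signal import fftconvolve
        ev = _events([0.0])
        n_vol, tr, dt = 40, 2.0, 0.1
        dm = G.build_design(ev, n_vol, tr)
        col = dm.matrix[:, dm.condition_columns["add_correct"]]
        t_fine = np.arange(0, n_vol * tr + 32, dt)
        box = ((t_fine >= 0) & (t_fine < 9.5)).astype(float)
        oracle = fftconvolve(box, G.canonical_hrf(dt))[:len(t_fine)] * dt
        sample = oracle[np.round(np.arange(n_vol) * tr / dt).astype(int)]
        np.testing.assert_allclose(col, sample, atol=1e-8)
        # boxcar response builds up: peak later than the HRF peak itself
        peak_t = np.argmax(col) * tr
        assert 6.0 <= peak_t <= 14.0

    def test_trial_order_irrelevant(self):
        ev = pd.concat([_events([0.0, 40.0, 80.0]),
                        _events([20.0, 60.0], "Control")], ignore_index=True)
        dm1 = G.build_design(ev, 60, 2.0)
        dm2 = G.build_design(ev.sample(frac=1, random_state=1), 60, 2.0)
        np.testing.assert_allclose(dm1.matrix, dm2.matrix)

    def test_event_past_run_end_rejected(self):
        with pytest.raises(ValueError, match="past run end"):
            G.build_design(_events([100.0]), n_volumes=50, tr=2.0)

    def test_no_events_leaves_drift_only_then_contrast_fails(self):
        ev = _events([])
        dm = G.build_design(ev, 60, 2.0)
        assert dm.condition_columns == {}
        run = BoldRun(data=np.zeros((2, 2, 2, 60)), tr=2.0,
                      mask=np.ones((2, 2, 2), bool))
        fit = G.fit_glm(run, dm)
        with pytest.raises(ValueError, match="absent sub-conditions"):
            G.contrast_map(fit)

    def test_derivative_orthogonal_to_main_column(self):
        ev = _events([0.0, 30.0, 60.0])
        dm = G.build_design(ev, 50, 2.0)
        main = dm.matrix[:, dm.condition_columns["add_correct"]]
        deriv = dm.matrix[:, dm.condition_columns["add_correct"] + 1]
        assert abs(main @ deriv) < 1e-10


class TestFitGlm:
    def test_duplicated_column_rejected(self):
        ev = _events([0.0, 30.0])
        dm = G.build_design(ev, 40, 2.0)
        bad = G.DesignMatrix(
            matrix=np.column_stack([dm.matrix, dm.matrix[:, 0]]),
            names=dm.names + ["dup"], tr=2.0,
            condition_columns=dm.condition_columns, n_drift=dm.n_drift)
        run = BoldRun(data=np.zeros((2, 2, 2, 40)), tr=2.0,
                      mask=np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError, match="rank deficient"):
            G.fit_glm(run, bad)

    def test_pure_noise_betas_centred_on_zero(self):
        rng = np.random.default_rng(0)
        ev = pd.concat([_events(np.arange(0, 200, 25.0)),
                        _events(np.arange(12.5, 200, 25.0), "Control")],
                       ignore_index=True)
        dm = G.build_design(ev, 120, 2.0)
        run = BoldRun(data=rng.standard_normal((6, 6, 6, 120)), tr=2.0,
                      mask=np.ones((6, 6, 6), bool))
        fit = G.fit_glm(run, dm)
        col = dm.condition_columns["add_correct"]
        vals = fit.betas[col][run.mask]
        assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(len(vals))


class TestContrastMap:
    def _fitted(self, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        cfg = pm.SimulationConfig(
            grid_shape=(8, 8, 8), noise_sd=0.4, subject_pattern_sd=0.0,
            motion_spike_rate=0.0, smoothness_fwhm_mm=0.0,
            aberrant_region_spec=[pm.Region(center=(4, 4, 4), radius_mm=8.0)],
            task_region_spec=[], seed=seed)
        ev = pm.generate_design(cfg, rng)
        add = np.full(cfg.grid_shape, effect)
        run, _ = pm.simulate_bold(ev, add, np.zeros(cfg.grid_shape), cfg, rng,
                                  inject_spikes=False)
        dm = G.build_design(ev, run.n_volumes, run.tr)
        return G.fit_glm(run, dm), run

    def test_contrast_antisymmetry(self):
        fit, _ = self._fitted(seed=1, effect=1.0)
        con_ab, t_ab = G.contrast_map(fit, {"add_correct": 1, "ctrl_correct": -1})
        con_ba, t_ba = G.contrast_map(fit, {"add_correct": -1, "ctrl_correct": 1})
        np.testing.assert_allclose(con_ab.data, -con_ba.data, equal_nan=True)
        np.testing.assert_allclose(t_ab.data, -t_ba.data, equal_nan=True)

    def test_equal_amplitudes_give_t_centred_on_zero(self):
        fit, run = self._fitted(seed=2, effect=0.0)
        _, t = G.contrast_map(fit)
        vals = t.data[run.mask]
        assert abs(np.mean(vals)) < 3 / np.sqrt(len(vals))

    def test_single_run_average_is_identity(self):
        fit, _ = self._fitted(seed=3, effect=1.0)
        _, t = G.contrast_map(fit)
        avg = G.average_runs([t])
        np.testing.assert_array_equal(avg.data, t.data)

    def test_two_run_average_is_mean(self):
        fit, _ = self._fitted(seed=4, effect=1.0)
        _, t1 = G.contrast_map(fit)
        t2 = t1.with_data(t1.data + 1.0)
        avg = G.average_runs([t1, t2])
        np.testing.assert_allclose(avg.data, t1.data + 0.5, equal_nan=True)
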