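"""Synthetic cohort generator: schedules, determinism, ground-truth structure."""

import numpy as np
import pandas as pd
import pytest

import plastimap as pm
from plastimap.synth import Region, normalization_by_subject


class TestGenerateDesign:
    def test_default_run_has_12_trials_per_condition(self):
        ev = pm.generate_design(pm.SimulationConfig(seed=1))
        assert len(ev) == 24
        assert ev["trial_type"].value_counts().to_dict() == {"Addition": 12,
                                                             "Control": 12}

    def test_onsets_strictly_increasing_and_within_run(self):
        cfg = pm.SimulationConfig(seed=3)
        ev = pm.generate_design(cfg)
        onsets = ev["onset"].to_numpy()
        assert np.all(np.diff(onsets) > 0)
        assert (onsets + ev["duration"]).max() <= cfg.derived_run_seconds

    def test_zero_trials_gives_empty_table(self):
        cfg = pm.SimulationConfig(trials_per_condition_per_run=0)
        ev = pm.generate_design(cfg)
        assert ev.empty

    def test_same_seed_gives_identical_schedule(self):
        cfg = pm.SimulationConfig(seed=7)
        ev1 = pm.generate_design(cfg, np.random.default_rng(7))
        ev2 = pm.generate_design(cfg, np.random.default_rng(7))
        pd.testing.assert_frame_equal(ev1, ev2)

    def test_schedule_overflow_rejected(self):
        cfg = pm.SimulationConfig(run_seconds=100.0)  # 24 x 10s + rests will not fit
        with pytest.raises(ValueError, match="exceeds configured run length"):
            pm.generate_design(cfg)

    def test_rests_occupy_schedule_time(self):
        # with six 10 s rests the last trial must end near the full 300 s
        cfg = pm.SimulationConfig(seed=2)
        ev = pm.generate_design(cfg)
        assert (ev["onset"] + ev["duration"]).max() > 250.0


class TestConfigValidation:
    def test_bad_coupling_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            pm.SimulationConfig(plasticity_gain_coupling=1.5)

    def test_region_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside grid"):
            pm.SimulationConfig(aberrant_region_spec=[
                Region(center=(99, 0, 0), radius_mm=5.0)])

    def test_retention_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="retention"):
            pm.SimulationConfig(aberrant_region_spec=[
                Region(center=(5, 5, 5), radius_mm=5.0, post_retention_mean=1.5)])

    def test_yaml_round_trip(self, tmp_path):
        cfg = pm.SimulationConfig(seed=5, noise_sd=0.5)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = pm.SimulationConfig.from_yaml(path)
        assert back == cfg


class TestGenerateCohort:
    def test_manifest_has_60_session_entries(self, default_cohort):
        assert len(default_cohort.manifest) == 60
        assert default_cohort.manifest.groupby(["group", "session"]).size().eq(15).all()

    def test_same_seed_bit_identical(self):
        cfg = pm.SimulationConfig(seed=42)
        a = pm.generate_cohort(cfg)
        b = pm.generate_cohort(cfg)
        for key in a.maps:
            np.testing.assert_array_equal(a.maps[key].data, b.maps[key].data)
        pd.testing.assert_frame_equal(a.behavior, b.behavior)
        pd.testing.assert_frame_equal(a.ground_truth.subjects, b.ground_truth.subjects)

    def test_ground_truth_structure(self, default_cohort):
        gt = default_cohort.ground_truth
        amps = gt.amplitudes
        mld = amps[amps.group == "MLD"]
        td = amps[amps.group == "TD"]
        # MLD over-activates aberrant regions before tutoring; TD never does
        assert (mld["amp_pre"] > 0).all()
        assert (td["amp_pre"] == 0).all()
        # normalization magnitude = pre - post >= 0 by construction
        assert (mld["normalization"] >= 0).all()
        assert (mld["amp_post"] <= mld["amp_pre"] + 1e-12).all()

    def test_behavior_accuracies_in_unit_interval(self, default_cohort):
        acc = default_cohort.behavior["accuracy"]
        assert acc.between(0, 1).all()

    def test_full_retention_preserves_excess(self):
        regions = [Region(center=(12, 14, 12), radius_mm=12.0, pre_effect=3.0,
                          post_retention_mean=1.0, post_retention_sd=0.0)]
        cfg = pm.SimulationConfig(seed=9, aberrant_region_spec=regions)
        co = pm.generate_cohort(cfg)
        amps = co.ground_truth.amplitudes
        mld = amps[amps.group == "MLD"]
        np.testing.assert_allclose(mld["amp_post"], mld["amp_pre"])

    def test_normalization_tracks_retention_latent(self, default_cohort):
        # subjects with a lower retention latent normalize more
        gt = default_cohort.ground_truth
        norm = normalization_by_subject(gt)
        sub = gt.subjects.set_index("subject_id").loc[norm.index]
        r = np.corrcoef(norm.to_numpy(), sub["retention_latent"].to_numpy())[0, 1]
        assert r < -0.5

    def test_cohort_written_to_disk(self, tmp_path):
        cfg = pm.SimulationConfig(seed=2, n_per_group=2)
        co = pm.generate_cohort(cfg, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "ground_truth.json").exists()
        man = pd.read_csv(tmp_path / "manifest.csv")
        assert len(man) == 8
        assert all((tmp_path / p).name.endswith(".nii.gz")
                   for p in man["path"].map(lambda s: s.split("/")[-1]))


class TestSimulateBold:
    def test_noiseless_signal_matches_regressor_amplitudes(self, tiny_bold_config):
        import plastimap.glm as G
        from dataclasses import replace
        cfg = replace(tiny_bold_config, noise_sd=0.0)
        rng = np.random.default_rng(0)
        ev = pm.generate_design(cfg, rng, accuracy=0.9)
        add = np.full(cfg.grid_shape, 1.5)
        ctrl = np.zeros(cfg.grid_shape)
        run, spikes = pm.simulate_bold(ev, add, ctrl, cfg, rng, inject_spikes=False)
        assert spikes.size == 0
        design = G.build_design(ev, run.n_volumes, run.tr)
        fit = G.fit_glm(run, design)
        for label in ("add_correct", "add_incorrect"):
            if label in design.condition_columns:
                col = design.condition_columns[label]
                np.testing.assert_allclose(
                    fit.betas[col][run.mask], 1.5, atol=1e-6)

    def test_spike_rate_zero_injects_nothing(self, tiny_bold_config):
        rng = np.random.default_rng(1)
        ev = pm.generate_design(tiny_bold_config, rng)
        run, spikes = pm.simulate_bold(ev, np.zeros((10, 10, 10)),
                                       np.zeros((10, 10, 10)), tiny_bold_config, rng)
        assert spikes.size == 0
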