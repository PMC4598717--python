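import numpy as np
import pytest

import plastimap as pm
from plastimap import inference
from plastimap.synth import Region


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (maps mode), shared across tests."""
    return pm.generate_cohort(pm.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_kmin(default_cohort):
    """Cluster-extent threshold for the default cohort geometry/smoothness."""
    co = default_cohort
    man = co.manifest
    ids = {g: man[man.group == g].subject_id.unique() for g in ("MLD", "TD")}
    pre_mld = [co.maps[(s, "pre")] for s in ids["MLD"]]
    pre_td = [co.maps[(s, "pre")] for s in ids["TD"]]
    resid = inference.group_residuals(pre_mld) + inference.group_residuals(pre_td)
    fwhm = inference.estimate_smoothness(resid, co.brain_mask)
    return inference.cluster_extent_threshold(co.brain_mask, fwhm, height_p=0.01,
                                              alpha=0.01, n_sim=2000, seed=7,
                                              n_per_group=15)


@pytest.fixture()
def tiny_bold_config():
    """Small-grid configuration for full BOLD-mode tests."""
    return pm.SimulationConfig(
        grid_shape=(10, 10, 10), n_per_group=3, noise_sd=0.5,
        subject_pattern_sd=0.3, motion_spike_rate=0.0,
        aberrant_region_spec=[Region(center=(5, 5, 5), radius_mm=8.0,
                                     pre_effect=2.0)],
        task_region_spec=[Region(center=(3, 7, 4), radius_mm=6.0,
                                 base_amplitude=1.0)],
        seed=21)


def group_session_maps(cohort, group, session):
    man = cohort.manifest
    sids = man[man.group == group].subject_id.unique()
    return [cohort.maps[(s, session)] for s in sids]
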