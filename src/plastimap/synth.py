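"""Synthetic two-group, two-session cohort generator.

Emulates the study design that every downstream analysis assumes: an MLD
(mathematical learning disability) and a TD (typically developing) group of
15 children each, scanned before and after tutoring, two runs per session
with 12 Addition and 12 Control trials (9.5 s trial window after a 0.5 s
fixation) and six jittered 10 s rests.  The MLD group over-activates a set
of designated "aberrant" regions before tutoring; after tutoring each MLD
child retains only a fraction (its retention) of that excess.  A latent
per-subject normalization magnitude is coupled (correlation rho) to the
child's accuracy gain, which is what the Brain Plasticity Index analysis is
meant to recover.

Two modes are provided: ``maps`` generates session-level activation maps
directly (fast; the default for cohort-scale studies) and ``bold`` generates
full 4-D BOLD runs with events and motion traces to exercise the despiking
and GLM modules.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from . import glm as _glm
from .maps import BoldRun, StatMap, ellipsoid_mask

GROUPS = ("MLD", "TD")
SESSIONS = ("pre", "post")


@dataclass
class Region:
    """One activation focus: Gaussian profile around a voxel-space center."""

    center: tuple[int, int, int]
    radius_mm: float                 # Gaussian sigma = radius/2
    pre_effect: float = 0.0          # MLD-only excess amplitude before tutoring
    post_retention_mean: float = 0.2
    post_retention_sd: float = 0.15
    base_amplitude: float = 0.0      # shared task activation (both groups)


def _default_aberrant_regions() -> list[Region]:
    # prefrontal / insular / parietal / ventral temporal-occipital analogues
    # of the over-engaged foci; heterogeneous excess amplitudes so that
    # z-scored *patterns* (not just levels) differ between groups before
    # tutoring.  base_amplitude 0: the group-difference mask selects exactly
    # the voxels where the control group barely responds.
    return [
        Region(center=(6, 19, 15), radius_mm=14.0, pre_effect=4.5,
               post_retention_sd=0.35),
        Region(center=(17, 19, 14), radius_mm=14.0, pre_effect=3.2,
               post_retention_sd=0.35),
        Region(center=(7, 11, 17), radius_mm=14.0, pre_effect=5.2,
               post_retention_sd=0.35),
        Region(center=(16, 8, 8), radius_mm=14.0, pre_effect=2.9,
               post_retention_sd=0.35),
    ]


def _default_task_regions() -> list[Region]:
    # shared arithmetic-task activation, identical in both groups, placed
    # away from the aberrant foci
    return [
        Region(center=(12, 25, 12), radius_mm=10.0, base_amplitude=2.0),
        Region(center=(4, 5, 8), radius_mm=10.0, base_amplitude=1.5),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults emulate the study design."""

    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 2.0
    n_per_group: int = 15
    tr_seconds: float = 2.0
    trial_window_seconds: float = 9.5
    fixation_seconds: float = 0.5
    trials_per_condition_per_run: int = 12
    n_runs: int = 2
    n_rests: int = 6
    rest_seconds: float = 10.0
    run_seconds: float | None = None     # derived from the schedule when None
    aberrant_region_spec: list[Region] = field(default_factory=_default_aberrant_regions)
    task_region_spec: list[Region] = field(default_factory=_default_task_regions)
    noise_sd: float = 0.5
    ar1_rho: float = 0.3
    smoothness_fwhm_mm: float = 6.0
    subject_pattern_sd: float = 1.2      # stable idiosyncratic spatial pattern
    amplitude_subject_sd: float = 0.30   # multiplicative spread of activation strength
    plasticity_gain_coupling: float = 0.6
    motion_spike_rate: float = 0.02
    # behavioural model (accuracy as proportions, RT in ms)
    accuracy_pre_mean: dict = field(default_factory=lambda: {"MLD": 0.72, "TD": 0.85})
    accuracy_pre_sd: dict = field(default_factory=lambda: {"MLD": 0.07, "TD": 0.05})
    gain_mean: dict = field(default_factory=lambda: {"MLD": 0.15, "TD": 0.02})
    gain_sd: dict = field(default_factory=lambda: {"MLD": 0.15, "TD": 0.04})
    rt_mean_ms: dict = field(default_factory=lambda: {
        ("MLD", "pre"): 3400.0, ("MLD", "post"): 3250.0,
        ("TD", "pre"): 3300.0, ("TD", "post"): 2800.0})
    rt_sd_ms: float = 450.0                  # within-subject trial-level spread
    rt_subject_sd_ms: float = 800.0          # stable between-subject speed offset
    rt_session_jitter_ms: float = 250.0      # day-to-day speed fluctuation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_group", "trials_per_condition_per_run", "n_runs"):
            if getattr(self, name) < 0 or (name != "trials_per_condition_per_run"
                                           and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.plasticity_gain_coupling <= 1.0):
            raise ValueError("plasticity_gain_coupling must lie in [0, 1]")
        for reg in self.aberrant_region_spec:
            if not (0.0 <= reg.post_retention_mean <= 1.0):
                raise ValueError("post_retention_mean must lie in [0, 1]")
            if any(not (0 <= c < s) for c, s in zip(reg.center, self.grid_shape)):
                raise ValueError(f"region center {reg.center} outside grid {self.grid_shape}")
        if not (0.0 <= self.motion_spike_rate < 1.0):
            raise ValueError("motion_spike_rate must lie in [0, 1)")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must lie in [0, 1)")

    # -- schedule geometry ---------------------------------------------------
    @property
    def n_task_trials(self) -> int:
        return 2 * self.trials_per_condition_per_run

    @property
    def trial_slot_seconds(self) -> float:
        return self.fixation_seconds + self.trial_window_seconds

    @property
    def schedule_seconds(self) -> float:
        return (self.n_task_trials * self.trial_slot_seconds
                + self.n_rests * self.rest_seconds)

    @property
    def derived_run_seconds(self) -> float:
        return self.run_seconds if self.run_seconds is not None else self.schedule_seconds

    @property
    def n_volumes(self) -> int:
        return int(np.ceil(self.derived_run_seconds / self.tr_seconds))

    @property
    def session_trials(self) -> int:
        return self.trials_per_condition_per_run * self.n_runs

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["rt_mean_ms"] = {f"{g}:{s}": v for (g, s), v in self.rt_mean_ms.items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("aberrant_region_spec", "task_region_spec"):
            if key in d:
                d[key] = [Region(**{**r, "center": tuple(r["center"])}) for r in d[key]]
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "rt_mean_ms" in d:
            d["rt_mean_ms"] = {tuple(k.split(":")): v for k, v in d["rt_mean_ms"].items()}
        return cls(**d)


def null_config(**overrides) -> SimulationConfig:
    """A noise-only cohort: no task or group structure anywhere."""
    regions = [Region(center=r.center, radius_mm=r.radius_mm, pre_effect=0.0,
                      post_retention_mean=r.post_retention_mean,
                      post_retention_sd=r.post_retention_sd, base_amplitude=0.0)
               for r in _default_aberrant_regions()]
    defaults = dict(aberrant_region_spec=regions, task_region_spec=[],
                    subject_pattern_sd=0.0, plasticity_gain_coupling=0.0)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# event schedules
# ---------------------------------------------------------------------------

def _rest_positions(rng: np.random.Generator, n_trials: int, n_rests: int,
                    min_separation: int = 2) -> np.ndarray:
    """Gap indices (0..n_trials) where rests go, >= ``min_separation`` apart."""
    if n_rests == 0:
        return np.array([], dtype=int)
    for _ in range(10_000):
        pos = np.sort(rng.choice(n_trials + 1, size=n_rests, replace=False))
        if n_rests == 1 or np.diff(pos).min() >= min_separation:
            return pos
    raise RuntimeError("could not place rests with the requested separation")


def generate_design(config: SimulationConfig, rng: np.random.Generator | None = None, *,
                    accuracy: float = 0.85, control_accuracy: float | None = None,
                    rt_mean_ms: float = 3000.0, rt_sd_ms: float | None = None
                    ) -> pd.DataFrame:
    """One run's event table: onset, duration, trial_type, correct, rt.

    Trials of the two conditions are randomly interleaved; rests are placed
    at jittered gaps at least two trials apart.  Per-trial correctness is
    Bernoulli with the subject's true accuracy; RTs (ms) are Gaussian,
    truncated to the response window.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if control_accuracy is None:
        control_accuracy = min(0.98, accuracy + 0.12)
    if rt_sd_ms is None:
        rt_sd_ms = config.rt_sd_ms
    n_cond = config.trials_per_condition_per_run
    if config.schedule_seconds > config.derived_run_seconds + 1e-9:
        raise ValueError(
            f"schedule ({config.schedule_seconds:.1f}s) exceeds configured run length "
            f"({config.derived_run_seconds:.1f}s)")
    if n_cond == 0:
        return pd.DataFrame(columns=["onset", "duration", "trial_type", "correct", "rt"])

    trial_types = rng.permutation(["Addition"] * n_cond + ["Control"] * n_cond)
    rests = _rest_positions(rng, len(trial_types), config.n_rests)
    rows = []
    t = 0.0
    for i, trial_type in enumerate(trial_types):
        t += config.rest_seconds * np.count_nonzero(rests == i)
        onset = t + config.fixation_seconds
        p = accuracy if trial_type == "Addition" else control_accuracy
        correct = bool(rng.random() < p)
        rt = float(np.clip(rng.normal(rt_mean_ms, rt_sd_ms), 300.0,
                           config.trial_window_seconds * 1000.0))
        rows.append({"onset": onset, "duration": config.trial_window_seconds,
                     "trial_type": str(trial_type), "correct": correct, "rt": rt})
        t = onset + config.trial_window_seconds
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial building blocks
# ---------------------------------------------------------------------------

def region_profile(region: Region, config: SimulationConfig) -> np.ndarray:
    """Gaussian bump with sigma = radius/2 (mm), unit peak."""
    grids = np.indices(config.grid_shape).astype(float)
    sigma_vox = (region.radius_mm / 2.0) / config.voxel_size_mm
    d2 = sum((g - c) ** 2 for g, c in zip(grids, region.center))
    return np.exp(-0.5 * d2 / sigma_vox ** 2)


def smooth_noise(rng: np.random.Generator, config: SimulationConfig,
                 mask: np.ndarray) -> np.ndarray:
    """Unit-variance (in-mask) Gaussian field smoothed to the configured FWHM."""
    field3 = rng.standard_normal(config.grid_shape)
    sigma_vox = config.smoothness_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) \
        / config.voxel_size_mm
    if sigma_vox > 0:
        field3 = gaussian_filter(field3, sigma_vox)
    sd = field3[mask].std()
    return field3 / sd if sd > 0 else field3


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Latents stored alongside every generated cohort (recovery oracle)."""

    subjects: pd.DataFrame        # one row per subject: latents and true scores
    amplitudes: pd.DataFrame      # subject x session x region excess amplitude
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subjects": self.subjects.to_dict(orient="records"),
            "amplitudes": self.amplitudes.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _draw_subject_latents(config: SimulationConfig, rng: np.random.Generator
                          ) -> pd.DataFrame:
    """Per-subject latents: retention, coupled gain, accuracy, amplitude scale."""
    rho = config.plasticity_gain_coupling
    rows = []
    for group in GROUPS:
        for i in range(config.n_per_group):
            sid = f"{group.lower()}{i + 1:02d}"
            u = rng.standard_normal()              # retention latent (MLD)
            w = rng.standard_normal()              # independent gain noise
            # multiplicative activation strength, floored at a physical minimum
            amp_scale = max(0.3, 1.0 + config.amplitude_subject_sd
                            * rng.standard_normal())
            rt_offset = config.rt_subject_sd_ms * rng.standard_normal()
            acc_pre = float(np.clip(
                rng.normal(config.accuracy_pre_mean[group], config.accuracy_pre_sd[group]),
                0.52, 0.98))
            if group == "MLD":
                # normalization magnitude is monotone in -u, so corr(-u, v) = rho
                v = -rho * u + np.sqrt(1.0 - rho ** 2) * w
            else:
                v = w
            gain = config.gain_mean[group] + config.gain_sd[group] * v
            # logistic squash keeps accuracy in (0, 1) while staying
            # first-order additive around the operating point
            acc_post = float(expit(logit(acc_pre) + gain / (acc_pre * (1 - acc_pre))))
            rows.append({"subject_id": sid, "group": group, "retention_latent": u,
                         "gain_latent": v, "amp_scale": amp_scale,
                         "rt_offset_ms": rt_offset,
                         "acc_true_pre": acc_pre, "acc_true_post": acc_post,
                         "true_gain": acc_post - acc_pre})
    return pd.DataFrame(rows)


def _amplitude_table(config: SimulationConfig, subjects: pd.DataFrame) -> pd.DataFrame:
    """Per subject x region excess amplitudes at both sessions."""
    rows = []
    for _, sub in subjects.iterrows():
        for r, reg in enumerate(config.aberrant_region_spec):
            if sub["group"] == "MLD":
                pre = reg.pre_effect * sub["amp_scale"]
                retention = float(np.clip(
                    reg.post_retention_mean + reg.post_retention_sd * sub["retention_latent"],
                    0.0, 1.0))
                post = pre * retention
            else:
                pre = post = 0.0
                retention = np.nan
            rows.append({"subject_id": sub["subject_id"], "group": sub["group"],
                         "region": r, "amp_pre": pre, "amp_post": post,
                         "retention": retention,
                         "normalization": pre - post})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------

def simulate_bold(events: pd.DataFrame, addition_amplitude: np.ndarray,
                  control_amplitude: np.ndarray, config: SimulationConfig,
                  rng: np.random.Generator, *, mask: np.ndarray | None = None,
                  inject_spikes: bool | None = None
                  ) -> tuple[BoldRun, np.ndarray]:
    """Forward-simulate one BOLD run from an event table.

    signal(v, t) = addition_amplitude(v) * x_A(t) + control_amplitude(v) * x_C(t)
    where x_c is the 9.5 s boxcar of condition c's onsets convolved with the
    canonical HRF, sampled at TR.  Noise is AR(1) in time with spatially
    smoothed Gaussian innovations of sd ``noise_sd``.  Motion spikes
    (displacement above the despiking threshold, plus a matching global
    intensity excursion) are injected at ``motion_spike_rate``; the second
    return value is the array of spiked volume indices (ground truth).
    """
    if mask is None:
        mask = ellipsoid_mask(config.grid_shape)
    n_vol = config.n_volumes
    tr = config.tr_seconds
    hrf = _glm.canonical_hrf()
    regressors = {}
    for cond in ("Addition", "Control"):
        onsets = events.loc[events["trial_type"] == cond, "onset"].to_numpy(float)
        regressors[cond] = _glm._convolve_boxcar(
            onsets, config.trial_window_seconds, n_vol, tr, hrf)

    data = (addition_amplitude[..., None] * regressors["Addition"]
            + control_amplitude[..., None] * regressors["Control"])

    if config.noise_sd > 0:
        rho = config.ar1_rho
        noise = np.empty(config.grid_shape + (n_vol,))
        prev = smooth_noise(rng, config, mask)
        noise[..., 0] = prev
        scale = np.sqrt(1.0 - rho ** 2)
        for t in range(1, n_vol):
            prev = rho * prev + scale * smooth_noise(rng, config, mask)
            noise[..., t] = prev
        data = data + config.noise_sd * noise
    data += 100.0   # baseline intensity so global-signal fractions are meaningful

    # motion: slow drift plus optional injected spikes
    motion = np.cumsum(rng.normal(0.0, 0.01, size=(n_vol, 6)), axis=0)
    spikes = np.array([], dtype=int)
    if inject_spikes is None:
        inject_spikes = config.motion_spike_rate > 0
    if inject_spikes and config.motion_spike_rate > 0 and n_vol > 2:
        n_spikes = rng.binomial(n_vol - 2, config.motion_spike_rate)
        if n_spikes:
            spikes = np.sort(rng.choice(np.arange(1, n_vol - 1), size=n_spikes,
                                        replace=False))
            for k in spikes:
                motion[k, 0] += rng.uniform(2.0, 3.5) * rng.choice([-1.0, 1.0])
                data[..., k] *= 1.0 + rng.uniform(0.06, 0.12)

    run = BoldRun(data=data, tr=tr, mask=mask, motion=motion,
                  voxel_size=config.voxel_size_mm)
    return run, spikes


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated cohort: manifest, maps (or runs), behaviour, ground truth."""

    manifest: pd.DataFrame
    maps: dict                      # (subject_id, session) -> StatMap
    behavior: pd.DataFrame
    ground_truth: GroundTruth
    brain_mask: np.ndarray
    config: SimulationConfig
    events: dict = field(default_factory=dict)   # (subject, session, run) -> DataFrame
    runs: dict = field(default_factory=dict)     # (subject, session, run) -> BoldRun
    spikes: dict = field(default_factory=dict)   # (subject, session, run) -> indices


def _session_map(config: SimulationConfig, rng: np.random.Generator,
                 sub: pd.Series, session: str, amps: pd.DataFrame,
                 profiles_aberrant: list[np.ndarray], profiles_task: list[np.ndarray],
                 subject_pattern: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Synthesize one session-level activation (t-like) map."""
    amp_col = f"amp_{session}"
    sub_amps = amps[amps["subject_id"] == sub["subject_id"]].sort_values("region")
    structured = np.zeros(config.grid_shape)
    for reg, prof in zip(config.task_region_spec, profiles_task):
        structured += reg.base_amplitude * prof
    # excess amplitudes already carry the subject scale (via _amplitude_table);
    # divide it back out here so the overall amp_scale multiplies everything once
    for (_, arow), reg, prof in zip(sub_amps.iterrows(),
                                    config.aberrant_region_spec, profiles_aberrant):
        structured += (reg.base_amplitude
                       + arow[amp_col] / max(sub["amp_scale"], 1e-9)) * prof
    data = (sub["amp_scale"] * structured
            + config.subject_pattern_sd * subject_pattern
            + config.noise_sd * smooth_noise(rng, config, mask))
    data[~mask] = np.nan
    return data


def generate_cohort(config: SimulationConfig, *, mode: str = "maps",
                    out_dir: str | Path | None = None) -> Cohort:
    """Generate a complete cohort; same seed gives a bit-identical cohort.

    ``maps`` mode produces one session-level t-like StatMap per subject and
    session.  ``bold`` mode additionally produces events, motion traces and
    4-D runs per subject/session/run, and the session maps are left for the
    GLM stage to compute.
    """
    if mode not in ("maps", "bold"):
        raise ValueError(f"unknown mode {mode!r}")
    root = np.random.SeedSequence(config.seed)
    latent_rng = np.random.default_rng(root.spawn(1)[0])
    subjects = _draw_subject_latents(config, latent_rng)
    amps = _amplitude_table(config, subjects)
    mask = ellipsoid_mask(config.grid_shape)
    profiles_aberrant = [region_profile(r, config) for r in config.aberrant_region_spec]
    profiles_task = [region_profile(r, config) for r in config.task_region_spec]

    maps: dict = {}
    events: dict = {}
    runs: dict = {}
    spikes: dict = {}
    manifest_rows = []
    behavior_rows = []
    subject_streams = root.spawn(len(subjects) + 1)[1:]

    for (_, sub), stream in zip(subjects.iterrows(), subject_streams):
        rng = np.random.default_rng(stream)
        subject_pattern = smooth_noise(rng, config, mask)
        for session in SESSIONS:
            acc_true = sub[f"acc_true_{session}"]
            if mode == "maps":
                data = _session_map(config, rng, sub, session, amps,
                                    profiles_aberrant, profiles_task,
                                    subject_pattern, mask)
                smap = StatMap(data, "t", subject=sub["subject_id"],
                               group=sub["group"], session=session,
                               voxel_size=config.voxel_size_mm,
                               df=2 * (config.n_volumes - 10))
                maps[(sub["subject_id"], session)] = smap
                n_tr = config.session_trials
                n_correct = int(rng.binomial(n_tr, acc_true)) if n_tr else 0
                accuracy = n_correct / n_tr if n_tr else 0.0
                rt = float(sub["rt_offset_ms"]
                           + rng.normal(0.0, config.rt_session_jitter_ms)
                           + rng.normal(config.rt_mean_ms[(sub["group"], session)],
                                        config.rt_sd_ms / np.sqrt(max(n_correct, 1))))
            else:
                session_events = []
                for r in range(config.n_runs):
                    ev = generate_design(
                        config, rng, accuracy=acc_true,
                        rt_mean_ms=(config.rt_mean_ms[(sub["group"], session)]
                                    + sub["rt_offset_ms"]
                                    + rng.normal(0.0, config.rt_session_jitter_ms)))
                    sub_amps = amps[amps["subject_id"] == sub["subject_id"]]
                    add_amp = np.zeros(config.grid_shape)
                    for reg, prof in zip(config.task_region_spec, profiles_task):
                        add_amp += sub["amp_scale"] * reg.base_amplitude * prof
                    for (_, arow), reg, prof in zip(
                            sub_amps.sort_values("region").iterrows(),
                            config.aberrant_region_spec, profiles_aberrant):
                        add_amp += (sub["amp_scale"] * reg.base_amplitude
                                    + arow[f"amp_{session}"]) * prof
                    ctrl_amp = 0.3 * add_amp
                    run, spk = simulate_bold(ev, add_amp, ctrl_amp, config, rng,
                                             mask=mask)
                    key = (sub["subject_id"], session, f"run{r + 1}")
                    events[key] = ev
                    runs[key] = run
                    spikes[key] = spk
                    session_events.append(ev)
                from .behavior import score_session
                summary = score_session(session_events, subject_id=sub["subject_id"],
                                        session=session)
                accuracy = summary.accuracy
                rt = summary.rt if summary.rt_defined else np.nan

            manifest_rows.append({
                "subject_id": sub["subject_id"], "group": sub["group"],
                "session": session, "run": "avg",
                "path": "", "accuracy": accuracy, "rt_median_mean": rt})
            behavior_rows.append({
                "subject_id": sub["subject_id"], "group": sub["group"],
                "session": session, "accuracy": accuracy, "rt": rt,
                "acc_true": acc_true})

    manifest = pd.DataFrame(manifest_rows)
    behavior = pd.DataFrame(behavior_rows)
    gt = GroundTruth(subjects=subjects, amplitudes=amps, config=config)
    cohort = Cohort(manifest=manifest, maps=maps, behavior=behavior,
                    ground_truth=gt, brain_mask=mask, config=config,
                    events=events, runs=runs, spikes=spikes)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    """Serialize a cohort: NIfTI maps, TSV events, CSV manifest, JSON truth."""
    out_dir.mkdir(parents=True, exist_ok=True)
    for (sid, session), smap in cohort.maps.items():
        path = out_dir / f"{sid}_{session}_t.nii.gz"
        smap.save(path)
        sel = ((cohort.manifest["subject_id"] == sid)
               & (cohort.manifest["session"] == session))
        cohort.manifest.loc[sel, "path"] = str(path)
    for (sid, session, run), ev in cohort.events.items():
        ev.to_csv(out_dir / f"{sid}_{session}_{run}_events.tsv", sep="\t", index=False)
    for (sid, session, run), bold in cohort.runs.items():
        bold.save(out_dir / f"{sid}_{session}_{run}_bold.nii.gz")
        np.savetxt(out_dir / f"{sid}_{session}_{run}_motion.txt", bold.motion,
                   fmt="%.6f")
    cohort.manifest.to_csv(out_dir / "manifest.csv", index=False)
    cohort.behavior.to_csv(out_dir / "behavior.csv", index=False)
    cohort.ground_truth.to_json(out_dir / "ground_truth.json")
    cohort.config.to_yaml(out_dir / "config.yaml")


def normalization_by_subject(gt: GroundTruth) -> pd.Series:
    """True normalization magnitude per MLD subject (sum over regions)."""
    mld = gt.amplitudes[gt.amplitudes["group"] == "MLD"]
    return mld.groupby("subject_id")["normalization"].sum()
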