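"""Event-related GLM: design matrices, voxelwise OLS, and contrast/t maps.

The trial model follows the arithmetic-verification paradigm: each trial is a
9.5 s boxcar at its onset, convolved with the canonical double-gamma
hemodynamic response function (peak 6 s, undershoot 16 s, peak:undershoot
ratio 6:1, 32 s support) and its temporal derivative.  Four sub-conditions
are modelled (Addition/Control x correct/incorrect); the contrast of
interest is Addition-correct minus Control-correct, with derivative columns
excluded from the contrast.  Rest periods are left unmodelled.  Cosine drift
regressors (128 s cutoff) and an intercept complete the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .maps import BoldRun, StatMap

#: sub-condition labels, in the order (trial_type, correct)
SUBCONDITIONS = {
    ("Addition", True): "add_correct",
    ("Control", True): "ctrl_correct",
    ("Addition", False): "add_incorrect",
    ("Control", False): "ctrl_incorrect",
}

DEFAULT_CONTRAST = {"add_correct": 1.0, "ctrl_correct": -1.0}

_HRF_LENGTH = 32.0  # seconds of HRF support
_HRF_DT = 0.1       # oversampling step for convolution (s)


def canonical_hrf(dt: float = _HRF_DT, length: float = _HRF_LENGTH) -> np.ndarray:
    """Double-gamma HRF sampled every ``dt`` seconds, peak normalized to 1.

    Peak at 6 s, undershoot at 16 s, undershoot amplitude 1/6 of the peak.
    """
    t = np.arange(0.0, length, dt)
    def gpdf(x, shape):
        with np.errstate(divide="ignore"):
            logp = (shape - 1) * np.log(np.maximum(x, 1e-12)) - x - gammaln(shape)
        out = np.exp(logp)
        out[x <= 0] = 0.0
        return out
    h = gpdf(t, 6.0) - gpdf(t, 16.0) / 6.0
    return h / h.max()


def hrf_temporal_derivative(dt: float = _HRF_DT, length: float = _HRF_LENGTH) -> np.ndarray:
    """Finite-difference temporal derivative of the canonical HRF."""
    h = canonical_hrf(dt, length)
    d = np.gradient(h, dt)
    return d / np.abs(d).max()


def _convolve_boxcar(onsets: np.ndarray, duration: float, n_volumes: int, tr: float,
                     kernel: np.ndarray, dt: float = _HRF_DT) -> np.ndarray:
    """Boxcar regressor at ``onsets`` convolved with ``kernel``, sampled at TR."""
    total = n_volumes * tr
    n_fine = int(np.ceil(total / dt)) + len(kernel)
    box = np.zeros(n_fine)
    for onset in onsets:
        i0 = int(round(onset / dt))
        i1 = int(round((onset + duration) / dt))
        box[i0:min(i1, n_fine)] += 1.0
    conv = np.convolve(box, kernel)[:n_fine] * dt
    sample_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[sample_idx]


def cosine_drift(n_volumes: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete cosine high-pass basis: components with period > ``cutoff`` s."""
    n_basis = int(np.floor(2.0 * n_volumes * tr / cutoff))
    t = np.arange(n_volumes)
    cols = [np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * t + 1) * k / (2 * n_volumes))
            for k in range(1, n_basis + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """Time x regressor design with condition bookkeeping."""

    matrix: np.ndarray
    names: list[str]
    tr: float
    condition_columns: dict[str, int]   # sub-condition -> HRF column index
    n_drift: int

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("names do not match design columns")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def build_design(events: pd.DataFrame, n_volumes: int, tr: float, *,
                 high_pass_cutoff: float = 128.0,
                 orthogonalize_derivative: bool = True) -> DesignMatrix:
    """Build the event-related design matrix for one run.

    ``events`` needs columns ``onset``, ``duration``, ``trial_type`` and
    ``correct``.  Each present sub-condition contributes one HRF column and
    one temporal-derivative column; empty sub-conditions are omitted.  Raises
    if any event extends past the end of the run.
    """
    required = {"onset", "duration", "trial_type", "correct"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    run_end = n_volumes * tr
    if len(events) and (events["onset"] + events["duration"]).max() > run_end + 1e-9:
        bad = events.loc[(events["onset"] + events["duration"]).idxmax()]
        raise ValueError(
            f"event at onset {bad['onset']:.1f}s extends past run end ({run_end:.1f}s)")

    hrf = canonical_hrf()
    dhrf = hrf_temporal_derivative()
    cols, names = [], []
    condition_columns: dict[str, int] = {}
    for (trial_type, correct), label in SUBCONDITIONS.items():
        sel = events[(events["trial_type"] == trial_type)
                     & (events["correct"].astype(bool) == correct)]
        if sel.empty:
            continue
        onsets = sel["onset"].to_numpy(float)
        duration = float(sel["duration"].iloc[0])
        main = _convolve_boxcar(onsets, duration, n_volumes, tr, hrf)
        deriv = _convolve_boxcar(onsets, duration, n_volumes, tr, dhrf)
        if orthogonalize_derivative:
            denom = main @ main
            if denom > 0:
                deriv = deriv - main * (deriv @ main) / denom
        condition_columns[label] = len(cols)
        cols.append(main)
        names.append(label)
        cols.append(deriv)
        names.append(label + "_deriv")

    drift = cosine_drift(n_volumes, tr, high_pass_cutoff)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")

    X = np.column_stack(cols)
    dm = DesignMatrix(matrix=X, names=names, tr=tr,
                      condition_columns=condition_columns, n_drift=drift.shape[1])
    if dm.rank < X.shape[1]:
        # name the offending columns for the error message
        _, r = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return dm


@dataclass
class GlmFit:
    """Voxelwise OLS result for one run."""

    betas: np.ndarray          # (n_regressors, x, y, z); NaN outside mask
    resid_var: np.ndarray      # (x, y, z)
    df: int
    design: DesignMatrix
    mask: np.ndarray
    residuals: np.ndarray | None = None  # (x, y, z, time) if kept


def fit_glm(run: BoldRun, design: DesignMatrix, *, keep_residuals: bool = False) -> GlmFit:
    """Ordinary least squares at every in-mask voxel."""
    X = design.matrix
    if run.n_volumes != design.n_volumes:
        raise ValueError(f"run has {run.n_volumes} volumes but design has {design.n_volumes}")
    rank = design.rank
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Y = run.data[run.mask].T                      # (time, n_voxels)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y                               # (p, n_voxels)
    resid = Y - X @ beta
    df = run.n_volumes - rank
    rvar = (resid ** 2).sum(axis=0) / df

    shape = run.data.shape[:3]
    betas = np.full((X.shape[1],) + shape, np.nan)
    betas[:, run.mask] = beta
    resid_var = np.full(shape, np.nan)
    resid_var[run.mask] = rvar
    residuals = None
    if keep_residuals:
        residuals = np.full(shape + (run.n_volumes,), np.nan)
        residuals[run.mask] = resid.T
    return GlmFit(betas=betas, resid_var=resid_var, df=df, design=design,
                  mask=run.mask, residuals=residuals)


def contrast_map(fit: GlmFit, contrast: dict[str, float] | None = None, *,
                 subject: str = "", group: str = "", session: str = "",
                 run_label: str = "") -> tuple[StatMap, StatMap]:
    """Contrast and t maps for a linear combination of HRF condition betas.

    The contrast references sub-condition HRF columns only (derivatives are
    never part of the contrast).  Voxels with zero residual variance are
    masked out of the t map.
    """
    if contrast is None:
        contrast = DEFAULT_CONTRAST
    design = fit.design
    missing = [c for c in contrast if c not in design.condition_columns]
    if missing:
        raise ValueError(
            f"contrast references absent sub-conditions: {missing} "
            f"(present: {sorted(design.condition_columns)})")
    X = design.matrix
    c = np.zeros(X.shape[1])
    for name, w in contrast.items():
        c[design.condition_columns[name]] = w
    con = np.tensordot(c, fit.betas, axes=1)
    xtx_inv = np.linalg.pinv(X.T @ X)
    cvar = float(c @ xtx_inv @ c)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(fit.resid_var * cvar)
        t = con / se
    t[(fit.resid_var == 0)] = np.nan
    meta = dict(subject=subject, group=group, session=session, run=run_label)
    return (StatMap(con, "contrast", df=fit.df, **meta),
            StatMap(t, "t", df=fit.df, **meta))


def average_runs(maps: list[StatMap], *, mode: str = "contrast") -> StatMap:
    """Combine per-run maps into one session map.

    ``contrast`` mode averages contrast values and recomputes a fixed-effects
    t is not possible without SEs, so for contrast maps it is a plain mean;
    for t maps (``mode='t'``) it averages t values directly (flag-selectable
    alternative).  A single map is returned unchanged.
    """
    if not maps:
        raise ValueError("no maps to average")
    if len(maps) == 1:
        return maps[0]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN outside mask
        data = np.nanmean([m.data for m in maps], axis=0)
    df = sum(m.df or 0 for m in maps)
    out = maps[0].with_data(data)
    out.run = "avg"
    out.df = df if df else None
    return out


def fixed_effects_t(con_maps: list[StatMap], se_maps: list[np.ndarray]) -> StatMap:
    """Fixed-effects combination: mean contrast over pooled standard error."""
    con = np.mean([m.data for m in con_maps], axis=0)
    var = np.sum([se ** 2 for se in se_maps], axis=0) / len(se_maps) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = con / np.sqrt(var)
    df = sum(m.df or 0 for m in con_maps)
    out = con_maps[0].with_data(t)
    out.kind = "t"
    out.df = df
    out.run = "avg"
    return out


def t_threshold(height_p: float, df: float, two_sided: bool = False) -> float:
    """Critical t for a voxelwise height threshold ``P < height_p``."""
    q = 1 - height_p / 2 if two_sided else 1 - height_p
    return float(stats.t.ppf(q, df))
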