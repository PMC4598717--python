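"""Volume despiking and motion quality control.

Volumes whose scan-to-scan displacement exceeds 0.5 voxels (1.562 mm at the
study's 3.125 mm in-plane resolution) or whose global signal deviates from
the run baseline by more than 5% are replaced by linear interpolation of the
nearest clean neighbours (AFNI-style repair).  Subjects are excluded when
20% or more of their frames were interpolated, or when in-scanner accuracy
is not strictly above 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import BoldRun

#: radius (mm) at which rotations are converted to arc displacement
ROTATION_RADIUS_MM = 65.0
#: default displacement threshold: 0.5 voxels at 3.125 mm
DISPLACEMENT_THRESHOLD_MM = 1.562
#: default global-signal spike threshold (fraction of baseline)
GLOBAL_SIGNAL_THRESHOLD = 0.05
#: inclusion fails at or above this interpolated-frame fraction
MAX_INTERPOLATED_FRACTION = 0.20
#: in-scanner accuracy must be strictly above this
MIN_ACCURACY = 0.50


def displacement(motion: np.ndarray, *, radius_mm: float = ROTATION_RADIUS_MM,
                 per_axis: bool = False) -> np.ndarray:
    """Scan-to-scan displacement series (mm) from 6 realignment parameters.

    ``motion`` is (n_volumes, 6): translations x, y, z in mm and rotations
    pitch, roll, yaw in degrees.  Rotations are converted to arc length at
    ``radius_mm``.  The combined measure is the Euclidean norm of the
    six-dimensional frame-to-frame change; ``per_axis=True`` instead returns
    the maximum absolute single-parameter change.  The first volume has
    displacement 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (n_volumes, 6), got {motion.shape}")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters contain non-finite values")
    params = motion.copy()
    params[:, 3:] = np.deg2rad(params[:, 3:]) * radius_mm
    delta = np.diff(params, axis=0)
    if per_axis:
        disp = np.abs(delta).max(axis=1)
    else:
        disp = np.sqrt((delta ** 2).sum(axis=1))
    return np.concatenate([[0.0], disp])


@dataclass
class QcReport:
    """Per-run despiking outcome."""

    displacement: np.ndarray
    global_signal: np.ndarray
    flagged: np.ndarray                  # sorted indices of repaired volumes
    n_volumes: int
    mean_displacement: float
    threshold_mm: float = DISPLACEMENT_THRESHOLD_MM
    global_threshold: float = GLOBAL_SIGNAL_THRESHOLD

    @property
    def repaired_fraction(self) -> float:
        return len(self.flagged) / self.n_volumes

    def to_dict(self) -> dict:
        return {
            "n_volumes": self.n_volumes,
            "flagged": [int(i) for i in self.flagged],
            "repaired_fraction": self.repaired_fraction,
            "mean_displacement_mm": self.mean_displacement,
            "threshold_mm": self.threshold_mm,
            "global_threshold": self.global_threshold,
        }


def _interpolate_flagged(data: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Replace flagged volumes by linear interpolation of clean neighbours.

    Flagged volumes at the run edges are copied from the nearest clean
    volume.  Unflagged volumes are returned bit-identical.
    """
    n = data.shape[-1]
    good = np.setdiff1d(np.arange(n), flagged)
    if good.size == 0:
        raise ValueError("all volumes flagged; run is unrecoverable")
    out = data.copy()
    for i in flagged:
        before = good[good < i]
        after = good[good > i]
        if before.size and after.size:
            lo, hi = before[-1], after[0]
            w = (i - lo) / (hi - lo)
            out[..., i] = (1 - w) * data[..., lo] + w * data[..., hi]
        elif after.size:        # leading edge
            out[..., i] = data[..., after[0]]
        else:                   # trailing edge
            out[..., i] = data[..., before[-1]]
    return out


def despike(run: BoldRun, motion: np.ndarray | None = None, *,
            threshold_mm: float = DISPLACEMENT_THRESHOLD_MM,
            global_threshold: float = GLOBAL_SIGNAL_THRESHOLD,
            global_baseline: str = "median") -> tuple[BoldRun, QcReport]:
    """Repair motion- and global-signal-spike volumes in one run.

    A volume is flagged when its scan-to-scan displacement exceeds
    ``threshold_mm`` or its in-mask mean intensity deviates from the run
    baseline (run median by default, or the previous volume with
    ``global_baseline='previous'``) by more than ``global_threshold``.

    Flagging and repair are iterated to a fixed point (the flag set only
    grows, and interpolation is always computed from the original data of
    clean volumes), and the realignment parameters of flagged volumes are
    interpolated along with the data.  A despiked run therefore contains
    nothing left to flag, which makes the operation idempotent.
    """
    if motion is None:
        motion = run.motion
    if motion is None:
        raise ValueError("no motion parameters available for despiking")
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != run.n_volumes:
        raise ValueError(
            f"motion rows ({motion.shape[0]}) do not match volumes ({run.n_volumes})")
    if global_baseline not in ("median", "previous"):
        raise ValueError(f"unknown global_baseline {global_baseline!r}")

    disp0 = displacement(motion)
    gs0 = run.data[run.mask].mean(axis=0)

    def gs_deviation(gs: np.ndarray) -> np.ndarray:
        if global_baseline == "median":
            ref = np.median(gs)
            return np.abs(gs - ref) / np.abs(ref)
        prev = np.concatenate([[gs[0]], gs[:-1]])
        return np.abs(gs - prev) / np.abs(prev)

    flagged = np.flatnonzero((disp0 > threshold_mm)
                             | (gs_deviation(gs0) > global_threshold))
    repaired = run.data
    fixed_motion = motion
    for _ in range(run.n_volumes):
        repaired = _interpolate_flagged(run.data, flagged)
        fixed_motion = _interpolate_flagged(motion.T, flagged).T
        new = np.flatnonzero(
            (displacement(fixed_motion) > threshold_mm)
            | (gs_deviation(repaired[run.mask].mean(axis=0)) > global_threshold))
        grown = np.union1d(flagged, new)
        if grown.size == flagged.size:
            break
        flagged = grown

    report = QcReport(displacement=disp0, global_signal=gs0, flagged=flagged,
                      n_volumes=run.n_volumes, mean_displacement=float(disp0[1:].mean())
                      if run.n_volumes > 1 else 0.0,
                      threshold_mm=threshold_mm, global_threshold=global_threshold)
    out = BoldRun(data=repaired, tr=run.tr, mask=run.mask, motion=fixed_motion,
                  voxel_size=run.voxel_size)
    return out, report


def qc_gate(reports: pd.DataFrame, behavioral: pd.DataFrame, *,
            max_interp_fraction: float = MAX_INTERPOLATED_FRACTION,
            min_accuracy: float = MIN_ACCURACY) -> pd.DataFrame:
    """Apply the study inclusion criteria per subject.

    ``reports`` needs columns ``subject_id`` and ``repaired_fraction`` (total
    fraction of interpolated frames across the subject's runs); ``behavioral``
    needs ``subject_id`` and ``accuracy``.  A subject is excluded when the
    interpolated fraction is >= 20% or accuracy is <= 50% (strict).  Missing
    QC or behaviour for any subject is an error, never a silent pass.
    """
    qc_subjects = set(reports["subject_id"])
    beh_subjects = set(behavioral["subject_id"])
    if qc_subjects != beh_subjects:
        raise ValueError(
            f"QC/behaviour subject mismatch: only-QC={sorted(qc_subjects - beh_subjects)}, "
            f"only-behaviour={sorted(beh_subjects - qc_subjects)}")
    frac = reports.groupby("subject_id")["repaired_fraction"].mean()
    acc = behavioral.groupby("subject_id")["accuracy"].mean()
    rows = []
    for sid in sorted(qc_subjects):
        reasons = []
        if frac[sid] >= max_interp_fraction:
            reasons.append(f"interpolated_fraction {frac[sid]:.3f} >= {max_interp_fraction}")
        if not acc[sid] > min_accuracy:
            reasons.append(f"accuracy {acc[sid]:.3f} <= {min_accuracy}")
        rows.append({"subject_id": sid, "interpolated_fraction": float(frac[sid]),
                     "accuracy": float(acc[sid]), "included": not reasons,
                     "reasons": "; ".join(reasons)})
    return pd.DataFrame(rows)


def read_motion(path: str | Path) -> np.ndarray:
    """Read a 6-column realignment-parameter file (whitespace or tab separated)."""
    arr = np.loadtxt(str(path))
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 6:
        raise ValueError(f"expected 6 columns in {path}, got {arr.shape[1]}")
    return arr
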