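"""Statistical map and BOLD-run containers with NIfTI-1 serialization.

A :class:`StatMap` is the currency passed between modules: one 3-D volume of
beta / contrast / t / z values together with its provenance (subject, group,
session, run).  Values are finite inside the brain mask and NaN outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

MAP_KINDS = ("beta", "contrast", "t", "z")


@dataclass
class StatMap:
    """One 3-D statistical volume with provenance."""

    data: np.ndarray
    kind: str
    subject: str = ""
    group: str = ""
    session: str = ""
    run: str = "avg"
    voxel_size: float = 2.0
    df: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {MAP_KINDS}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"StatMap data must be 3-D, got shape {self.data.shape}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of defined (non-NaN) voxels."""
        return np.isfinite(self.data)

    def with_data(self, data: np.ndarray) -> "StatMap":
        return replace(self, data=np.asarray(data, dtype=float))

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header["descrip"] = f"{self.kind};{self.subject};{self.session};{self.run}".encode()[:80]
        return img

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(self.to_nifti(), str(path))
        return path


def load_stat_map(path: str | Path, *, kind: str = "t", subject: str = "",
                  group: str = "", session: str = "", run: str = "avg") -> StatMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    voxel = float(img.header.get_zooms()[0])
    return StatMap(data=data, kind=kind, subject=subject, group=group,
                   session=session, run=run, voxel_size=voxel)


@dataclass
class BoldRun:
    """One 4-D BOLD series (x, y, z, time) with TR, mask and motion parameters."""

    data: np.ndarray
    tr: float
    mask: np.ndarray
    motion: np.ndarray = field(default=None)  # (n_volumes, 6): x,y,z mm; pitch,roll,yaw deg
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BoldRun data must be 4-D, got shape {self.data.shape}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match spatial dimensions of data")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.n_volumes, 6):
                raise ValueError(
                    f"motion must have shape ({self.n_volumes}, 6), got {self.motion.shape}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))
        return path


def ellipsoid_mask(shape: tuple[int, int, int], margin: float = 1.0) -> np.ndarray:
    """Axis-aligned ellipsoid inscribed in the grid — a stand-in brain mask."""
    grids = np.indices(shape).astype(float)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [max((s / 2.0 - margin), 1.0) for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0
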