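"""Brain Plasticity Index: pattern change between sessions and its link to gains.

BPI = 1 - r, where r is the Pearson correlation over in-mask voxels between
a subject's z-transformed pre-tutoring and post-tutoring activation maps
(the same pre-tutoring group-difference mask and z-transform convention as
the classifier).  BPI is 0 for identical patterns, 1 for orthogonal ones
and 2 for sign-flipped ones: the more the pattern changed, the higher the
index.  Relating BPI to the accuracy gain (post minus pre) asks whether
children whose activation patterns changed more also improved more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import pearson
from .maps import StatMap
from .mvpa import z_transform


@dataclass
class BpiRecord:
    subject_id: str
    bpi: float
    performance_gain: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.bpi <= 2.0):
            raise ValueError(f"bpi {self.bpi} outside [0, 2]")
        if not (-1.0 <= self.performance_gain <= 1.0):
            raise ValueError(f"gain {self.performance_gain} outside [-1, 1]")


def bpi(pre_map: StatMap | np.ndarray, post_map: StatMap | np.ndarray,
        mask: np.ndarray) -> float:
    """1 minus the in-mask spatial correlation of z-transformed pre/post maps."""
    pre_data = pre_map.data if isinstance(pre_map, StatMap) else np.asarray(pre_map)
    post_data = post_map.data if isinstance(post_map, StatMap) else np.asarray(post_map)
    if pre_data.shape != post_data.shape:
        raise ValueError("pre and post maps have different shapes")
    zpre = z_transform(pre_data, mask)
    zpost = z_transform(post_data, mask)
    r = float(np.mean(zpre * zpost))     # Pearson r of two z-scored vectors
    return 1.0 - r


def bpi_table(maps: dict, behavior: pd.DataFrame, mask: np.ndarray, *,
              group: str = "MLD") -> pd.DataFrame:
    """Per-subject BPI and performance gain for one group.

    ``maps`` is keyed by (subject_id, session); ``behavior`` has one row per
    subject-session with ``accuracy``.
    """
    wide = behavior.pivot_table(index=["subject_id", "group"], columns="session",
                                values="accuracy").reset_index()
    wide = wide[wide["group"] == group]
    rows = []
    for _, row in wide.iterrows():
        sid = row["subject_id"]
        value = bpi(maps[(sid, "pre")], maps[(sid, "post")], mask)
        gain = float(row["post"] - row["pre"])
        rec = BpiRecord(subject_id=sid, bpi=value, performance_gain=gain)
        rows.append({"subject_id": sid, "bpi": rec.bpi,
                     "performance_gain": rec.performance_gain})
    return pd.DataFrame(rows)


def relate_bpi_to_gain(records: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between BPI and performance gain."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    return pearson(records["bpi"].to_numpy(float),
                   records["performance_gain"].to_numpy(float))


def baseline_predictor_screen(records: pd.DataFrame,
                              covariates: pd.DataFrame) -> pd.DataFrame:
    """Correlate each baseline covariate with performance gain (uncorrected).

    Missing covariate values are dropped listwise per covariate, with the
    retained n reported.  An all-missing covariate is an error.
    """
    merged = records.merge(covariates, on="subject_id", how="left")
    rows = []
    for col in covariates.columns:
        if col == "subject_id":
            continue
        sub = merged[[col, "performance_gain"]].dropna()
        if sub.empty:
            raise ValueError(f"covariate {col!r} has no observed values")
        if len(sub) < 3:
            raise ValueError(f"covariate {col!r} has fewer than 3 observed values")
        r, p = pearson(sub[col].to_numpy(float),
                       sub["performance_gain"].to_numpy(float))
        rows.append({"covariate": col, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)
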