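"""Behavioural scoring and the study's behavioural statistics.

Accuracy is the proportion of correct Addition trials pooled over a
session's runs; reaction time is the mean across runs of each run's median
RT over correct trials (milliseconds).  Group comparisons use two-sided
t-tests with Cohen's d derived from t and n, Kolmogorov-Smirnov normality
checks (Lilliefors-corrected by default), and Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors


@dataclass
class BehavioralSummary:
    """Per subject-session behavioural scores."""

    subject_id: str
    session: str
    accuracy: float
    rt: float | None                 # ms; None when undefined
    rt_defined: bool
    task: str = "in_scanner_verification"
    n_trials: int = 0
    n_correct: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError(f"accuracy {self.accuracy} outside [0, 1]")
        if self.rt_defined and (self.rt is None or self.rt <= 0):
            raise ValueError("rt flagged defined but non-positive")


def score_session(runs: list[pd.DataFrame], *, subject_id: str = "",
                  session: str = "", condition: str = "Addition",
                  task: str = "in_scanner_verification") -> BehavioralSummary:
    """Score one session from its per-run event tables.

    Accuracy pools correct/total ``condition`` trials over runs.  RT is the
    mean over runs of the per-run median RT of correct trials; a run with no
    correct trials contributes nothing, and if no run has a correct trial
    the RT is flagged undefined (never silently zero).
    """
    if not runs:
        raise ValueError("need at least one run")
    n_correct = 0
    n_total = 0
    run_medians = []
    for ev in runs:
        sel = ev[ev["trial_type"] == condition]
        n_total += len(sel)
        correct = sel[sel["correct"].astype(bool)]
        n_correct += len(correct)
        if len(correct):
            rts = correct["rt"].to_numpy(float)
            rts = rts[np.isfinite(rts)]
            if len(rts):
                run_medians.append(float(np.median(rts)))
    accuracy = n_correct / n_total if n_total else 0.0
    rt_defined = bool(run_medians)
    rt = float(np.mean(run_medians)) if rt_defined else None
    return BehavioralSummary(subject_id=subject_id, session=session,
                             accuracy=accuracy, rt=rt, rt_defined=rt_defined,
                             task=task, n_trials=n_total, n_correct=n_correct)


@dataclass
class EffectSizeReport:
    """Two-sided t-test with Cohen's d derived from t and n."""

    t_statistic: float
    df: int
    p_two_sided: float
    cohen_d: float
    design: str                       # "paired" | "independent"
    n1: int
    n2: int | None = None

    @property
    def d_rounded(self) -> float:
        """Presentation value: |d| to 2 decimal places."""
        return round(abs(self.cohen_d), 2)

    @property
    def t_rounded(self) -> float:
        return round(self.t_statistic, 3)


def cohen_d_from_t(t: float, *, design: str, n: int | None = None,
                   n1: int | None = None, n2: int | None = None) -> float:
    """Convert a t statistic to Cohen's d.

    Paired design: d = t / sqrt(n).  Independent design (pooled-SD
    equivalent): d = t * sqrt(1/n1 + 1/n2).
    """
    if design == "paired":
        if n is None:
            raise ValueError("paired design needs n")
        return t / np.sqrt(n)
    if design == "independent":
        if n1 is None or n2 is None:
            raise ValueError("independent design needs n1 and n2")
        return t * np.sqrt(1.0 / n1 + 1.0 / n2)
    raise ValueError(f"unknown design {design!r}")


def ttest_effect(a: np.ndarray, b: np.ndarray, design: str = "independent") -> EffectSizeReport:
    """Two-sided t-test with effect size.

    Raises on zero variance in both samples (t undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if design == "paired":
        if len(a) != len(b):
            raise ValueError("paired design requires equal lengths")
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            raise ValueError("zero variance of paired differences; t undefined")
        res = stats.ttest_rel(a, b)
        n = len(a)
        d = cohen_d_from_t(float(res.statistic), design="paired", n=n)
        return EffectSizeReport(float(res.statistic), n - 1, float(res.pvalue), d,
                                "paired", n)
    if design == "independent":
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            raise ValueError("zero variance in both samples; t undefined")
        res = stats.ttest_ind(a, b)
        n1, n2 = len(a), len(b)
        d = cohen_d_from_t(float(res.statistic), design="independent", n1=n1, n2=n2)
        return EffectSizeReport(float(res.statistic), n1 + n2 - 2, float(res.pvalue), d,
                                "independent", n1, n2)
    raise ValueError(f"unknown design {design!r}")


def ks_normality(values: np.ndarray, *, lilliefors_correction: bool = True
                 ) -> tuple[float, float]:
    """One-sample K-S test against a normal with estimated moments.

    Because the moments are estimated from the data, the default p-value uses
    the Lilliefors correction; ``lilliefors_correction=False`` gives the
    naive K-S p for comparison.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("K-S normality needs n >= 4")
    if np.allclose(values.std(ddof=1), 0.0):
        raise ValueError("constant input; normality test degenerate")
    if lilliefors_correction:
        stat, p = lilliefors(values, dist="norm")
        return float(stat), float(p)
    stat, p = stats.kstest(values, "norm", args=(values.mean(), values.std(ddof=1)))
    return float(stat), float(p)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        raise ValueError("constant vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def behavioral_stats_table(behavior: pd.DataFrame) -> pd.DataFrame:
    """The study's battery of behavioural comparisons as a tidy table.

    ``behavior`` has one row per subject-session with columns ``subject_id``,
    ``group``, ``session``, ``accuracy`` and ``rt``.  Produces within-group
    pre/post paired tests and between-group independent tests at each
    session, for accuracy and RT.
    """
    rows = []
    wide = behavior.pivot_table(index=["subject_id", "group"], columns="session",
                                values=["accuracy", "rt"]).reset_index()

    def record(label, maker):
        try:
            rep = maker()
        except ValueError:        # degenerate cell (e.g. zero variance at tiny n)
            return
        rows.append({"comparison": label, "design": rep.design, "t": rep.t_statistic,
                     "df": rep.df, "p": rep.p_two_sided, "cohen_d": rep.d_rounded})

    for measure in ("accuracy", "rt"):
        for grp in sorted(behavior["group"].unique()):
            sub = wide[wide["group"] == grp]
            pre = sub[(measure, "pre")].to_numpy(float)
            post = sub[(measure, "post")].to_numpy(float)
            ok = np.isfinite(pre) & np.isfinite(post)
            if ok.sum() >= 2:
                record(f"{grp}: {measure} post vs pre",
                       lambda: ttest_effect(post[ok], pre[ok], "paired"))
        for ses in ("pre", "post"):
            groups = sorted(behavior["group"].unique())
            if len(groups) == 2:
                g1 = wide[wide["group"] == groups[0]][(measure, ses)].dropna().to_numpy(float)
                g2 = wide[wide["group"] == groups[1]][(measure, ses)].dropna().to_numpy(float)
                if len(g1) >= 2 and len(g2) >= 2:
                    record(f"{groups[0]} vs {groups[1]}: {measure} at {ses}",
                           lambda: ttest_effect(g1, g2, "independent"))
    return pd.DataFrame(rows)
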