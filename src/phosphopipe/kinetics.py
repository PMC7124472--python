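"""Trehalase activity from glucose-release time courses.

Neutral trehalase hydrolyzes one trehalose into two glucose molecules, so
the amount of trehalose degraded is (glucose - blank) / 2.  Activity is the
least-squares slope through the origin of trehalose degraded versus time
(the reaction starts at zero product), normalized to protein content.
Treated-vs-mock activities are compared with a classical pooled-variance
(Student) unpaired two-sided t test; relative activity is the ratio of the
treated to the mock group mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


@dataclass
class TimeCourse:
    sample_id: str
    points: tuple[tuple[float, float], ...]  # (time min, glucose amount)
    blank: float
    protein: float

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise DataError(f"{self.sample_id}: need at least 2 time points")
        times = [t for t, _ in self.points]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise DataError(f"{self.sample_id}: times must strictly increase")
        if self.protein <= 0:
            raise DataError(f"{self.sample_id}: protein must be positive")


@dataclass
class ActivityResult:
    sample_id: str
    slope: float  # trehalose degraded per minute
    normalized: float  # slope / protein


def glucose_to_trehalose(glucose: float, blank: float) -> float:
    """Net glucose over blank converted to trehalose degraded (2 glucose
    per trehalose), floored at 0 since amounts are physical."""
    return max((glucose - blank) / 2.0, 0.0)


def fit_zero_intercept_slope(
    points: Sequence[tuple[float, float]]
) -> float:
    """Least-squares line through the origin: slope = sum(t*y) / sum(t^2)."""
    t = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    denom = float((t**2).sum())
    if denom == 0.0:
        raise DataError("all time points are zero")
    return float((t * y).sum() / denom)


def activity(course: TimeCourse) -> ActivityResult:
    pts = [
        (t, glucose_to_trehalose(g, course.blank)) for t, g in course.points
    ]
    slope = fit_zero_intercept_slope(pts)
    return ActivityResult(
        sample_id=course.sample_id,
        slope=slope,
        normalized=slope / course.protein,
    )


def relative_activity(
    treated: Sequence[float], mock: Sequence[float], pairwise: bool = False
) -> float:
    """Treated / mock normalized activity, as a ratio of group means by
    default (mean of per-replicate ratios with ``pairwise=True``)."""
    treated = np.asarray(treated, dtype=float)
    mock = np.asarray(mock, dtype=float)
    if pairwise:
        if len(treated) != len(mock):
            raise DataError("pairwise ratio needs equal group sizes")
        return float(np.mean(treated / mock))
    m = float(mock.mean())
    if m <= 0:
        raise DataError("mock mean activity must be positive")
    return float(treated.mean() / m)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided unpaired Student's t test (pooled variance).

    Degenerate edge rule: zero pooled variance yields p = 1 when the means
    are equal and p = 0 otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (
        na + nb - 2
    )
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(float("inf"), diff), 0.0
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), na + nb - 2))
    return float(t), p


def process_table(df: pd.DataFrame, pairwise: bool = False) -> tuple[
    pd.DataFrame, pd.DataFrame
]:
    """Per-sample activities and per-strain treated-vs-mock comparisons.

    Input columns: sample_id, strain, treatment (drug/mock), replicate,
    time, glucose, blank, protein; one row per time point.
    """
    sample_rows = []
    meta = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time")
        course = TimeCourse(
            sample_id=str(sid),
            points=tuple(zip(grp["time"], grp["glucose"])),
            blank=float(grp["blank"].iloc[0]),
            protein=float(grp["protein"].iloc[0]),
        )
        res = activity(course)
        meta[sid] = (grp["strain"].iloc[0], grp["treatment"].iloc[0])
        sample_rows.append(
            {
                "sample_id": sid,
                "strain": meta[sid][0],
                "treatment": meta[sid][1],
                "slope": res.slope,
                "normalized": res.normalized,
            }
        )
    samples = pd.DataFrame(sample_rows)
    strain_rows = []
    for strain, grp in samples.groupby("strain", sort=False):
        drug = grp.loc[grp["treatment"] == "drug", "normalized"].to_numpy()
        mock = grp.loc[grp["treatment"] == "mock", "normalized"].to_numpy()
        if len(drug) == 0 or len(mock) == 0:
            continue
        rel = relative_activity(drug, mock, pairwise=pairwise)
        if len(drug) >= 2 and len(mock) >= 2:
            t, p = compare_groups(drug, mock)
        else:
            t, p = float("nan"), float("nan")
        strain_rows.append(
            {"strain": strain, "relative_activity": rel, "t": t, "p": p}
        )
    return samples, pd.DataFrame(strain_rows)
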