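"""LC-MS feature alignment, calibration quantitation, and time-course statistics.

Covers the quantitation side of the workflow: aligning per-sample peak
tables within retention-time and mass tolerances, internal-standard QC by
percent relative standard deviation, ordinary-least-squares calibration over
an 8-point standard series, and a Friedman rank test for within-subject
change over a repeated-measures time course (complete blocks; chi-square
approximation with an exact permutation mode for small designs).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureTable",
    "CalibrationCurve",
    "TimeCourseResult",
    "align_features",
    "percent_rsd",
    "fit_calibration",
    "quantify",
    "friedman_test",
    "timecourse_summary",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS fit of response (IS-normalised area ratio) on concentration."""

    slope: float
    intercept: float
    r_squared: float
    conc_range: Tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class TimeCourseResult:
    """Per-timepoint medians/quartiles plus the Friedman test result."""

    timepoints: Tuple[float, ...]
    medians: Tuple[float, ...]
    q1: Tuple[float, ...]
    q3: Tuple[float, ...]
    friedman_statistic: float
    p_value: float
    n_subjects: int


#: Long-format aligned feature table; columns sample, feature, mz, rt, area.
FeatureTable = pd.DataFrame

FEATURE_COLUMNS = ["sample", "feature", "mz", "rt", "area"]


def align_features(
    tables: Dict[str, pd.DataFrame],
    rt_tol: float = 0.10,
    mz_tol: float = 0.05,
) -> FeatureTable:
    """Align per-sample peak tables into one feature table.

    Each per-sample table needs columns mz, rt, area.  Peaks are clustered
    greedily in descending area order: a peak joins the first existing
    cluster whose centroid is within both tolerances and that does not yet
    contain a peak from the same sample; otherwise it seeds a new cluster.
    Cluster centroids are running means.  Defaults follow typical TOF
    alignment settings: 0.10 min retention time, 0.05 Da mass.
    """
    if not tables:
        raise ValueError("no sample tables supplied")
    rows = []
    for sample, df in tables.items():
        for _, r in df.iterrows():
            rows.append((sample, float(r["mz"]), float(r["rt"]), float(r["area"])))
    rows.sort(key=lambda r: -r[3])
    clusters: List[dict] = []
    assignments = []
    for sample, mz, rt, area in rows:
        target = None
        for cl in clusters:
            if (
                abs(mz - cl["mz"]) <= mz_tol
                and abs(rt - cl["rt"]) <= rt_tol
                and sample not in cl["samples"]
            ):
                target = cl
                break
        if target is None:
            target = {"mz": mz, "rt": rt, "samples": set(), "n": 0,
                      "members": []}
            clusters.append(target)
        target["samples"].add(sample)
        target["members"].append((sample, mz, rt, area))
        target["n"] += 1
        target["mz"] += (mz - target["mz"]) / target["n"]
        target["rt"] += (rt - target["rt"]) / target["n"]
    clusters.sort(key=lambda cl: (cl["mz"], cl["rt"]))
    out = []
    for idx, cl in enumerate(clusters):
        fid = f"F{idx + 1:04d}"
        for sample, mz, rt, area in sorted(cl["members"]):
            out.append((sample, fid, mz, rt, area))
    return pd.DataFrame(out, columns=FEATURE_COLUMNS)


def percent_rsd(values: Sequence[float]) -> float:
    """Percent relative standard deviation: sample SD / mean * 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("mean is zero; %RSD undefined")
    return float(arr.std(ddof=1) / mean * 100.0)


def fit_calibration(
    concentrations: Sequence[float], responses: Sequence[float]
) -> CalibrationCurve:
    """Ordinary least squares of response on concentration."""
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size != resp.size:
        raise ValueError("concentration/response length mismatch")
    if conc.size < 2 or np.unique(conc).size < 2:
        raise ValueError("need at least two distinct concentrations")
    fit = stats.linregress(conc, resp)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        conc_range=(float(conc.min()), float(conc.max())),
        n_points=int(conc.size),
    )


def quantify(
    curve: CalibrationCurve, response: float
) -> Tuple[float, bool]:
    """Invert the calibration: concentration and an in-calibrated-range flag."""
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    conc = (response - curve.intercept) / curve.slope
    lo, hi = curve.conc_range
    tol = 1e-9 * max(1.0, hi - lo)  # absorb round-off at the range edges
    in_range = (lo - tol) <= conc <= (hi + tol)
    return float(conc), in_range


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from an n x k midrank matrix."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction: divide by 1 - sum(t^3 - t) / (n (k^3 - k))
    tie_sum = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_sum / (n * (k**3 - k))
    if denom <= 0:
        return 0.0  # every block fully tied: no evidence of change
    return q / denom


def _row_ranks(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values)


def _exact_p(ranks: np.ndarray, observed: float) -> float:
    """Exact permutation p-value: each block's ranks permuted uniformly.

    The statistic depends on the column rank sums (block tie patterns are
    fixed), so the permutation distribution is built by convolving, block by
    block, the distribution of the block's rank vector over its distinct
    permutations.
    """
    n, k = ranks.shape
    states: Dict[Tuple[float, ...], float] = {tuple([0.0] * k): 1.0}
    for row in ranks:
        perms = set(itertools.permutations(row))
        w = 1.0 / len(perms)
        new: Dict[Tuple[float, ...], float] = {}
        for state, p in states.items():
            for perm in perms:
                key = tuple(s + v for s, v in zip(state, perm))
                new[key] = new.get(key, 0.0) + p * w
        states = new
    # recompute the statistic for each final column-sum vector
    tie_sum = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_sum / (n * (k**3 - k))
    p_ge = 0.0
    for col_sums, p in states.items():
        q = (
            12.0 / (n * k * (k + 1)) * sum(c**2 for c in col_sums)
            - 3.0 * n * (k + 1)
        )
        stat = 0.0 if denom <= 0 else q / denom
        if stat >= observed - 1e-9:
            p_ge += p
    return min(1.0, p_ge)


def friedman_test(
    blocks: np.ndarray, method: str = "auto"
) -> Tuple[float, float]:
    """Friedman rank test on an n-subjects x k-timepoints matrix.

    Within-subject midranks with tie correction; the statistic is

        Q = [12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)] / C

    with C the usual tie-correction factor, referred to chi-square with k-1
    degrees of freedom.  ``method``: 'chi2' for the asymptotic p-value,
    'exact' for full permutation enumeration (feasible for small n, k),
    'auto' picks exact when n <= 6 and k <= 4.  Blocks must be complete
    (no NaN); incomplete data should be handled listwise by the caller.
    """
    arr = np.asarray(blocks, dtype=float)
    if arr.ndim != 2:
        raise ValueError("blocks must be a 2-D subjects x timepoints array")
    n, k = arr.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 subjects and >= 2 timepoints")
    if np.isnan(arr).any():
        raise ValueError("incomplete blocks: remove subjects with missing values")
    ranks = _row_ranks(arr)
    statistic = _friedman_statistic(ranks)
    if method == "auto":
        method = "exact" if (n <= 6 and k <= 4) else "chi2"
    if method == "exact":
        p = _exact_p(ranks, statistic)
    elif method == "chi2":
        p = float(stats.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(statistic), float(p)


def timecourse_summary(
    values: np.ndarray,
    timepoints: Sequence[float],
    method: str = "chi2",
) -> TimeCourseResult:
    """Median (Q1-Q3) per timepoint plus the Friedman test over subjects."""
    arr = np.asarray(values, dtype=float)
    if arr.shape[1] != len(timepoints):
        raise ValueError("timepoint count mismatch")
    stat, p = friedman_test(arr, method=method)
    return TimeCourseResult(
        timepoints=tuple(float(t) for t in timepoints),
        medians=tuple(np.median(arr, axis=0).tolist()),
        q1=tuple(np.percentile(arr, 25, axis=0).tolist()),
        q3=tuple(np.percentile(arr, 75, axis=0).tolist()),
        friedman_statistic=stat,
        p_value=p,
        n_subjects=arr.shape[0],
    )
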