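"""Cohort stratification and survival analysis on ECT/cell-type fractions.

Patients are stratified by hierarchical clustering of their ECT-fraction
vectors (correlation distance, Ward linkage) or by median splits of a
single fraction; groups are compared with Kaplan-Meier curves and the
k-sample log-rank test (implemented directly, observed-minus-expected
with hypergeometric variance, so the statistic is auditable); hazard
ratios come from a Cox proportional-hazards model (Efron tie handling,
delegated to lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter

__all__ = [
    "LogRankResult",
    "stratify_patients",
    "km_logrank",
    "median_stratify",
    "risk_groups",
    "cox_multivariate",
]


def stratify_patients(
    ect_fractions: pd.DataFrame, k: int = 4
) -> tuple[pd.Series, np.ndarray]:
    """Cluster samples on ECT fractions: 1 - Pearson distance, Ward, cut at k.

    Returns per-sample subgroup labels ("C1".. ordered by descending
    subgroup size) and the linkage matrix.  Samples with constant
    fraction vectors (correlation undefined) are excluded from the
    clustering and assigned post hoc to the subgroup with the nearest
    Euclidean centroid, with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    values = ect_fractions.to_numpy(dtype=float)
    n = values.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    sd = values.std(axis=1)
    ok = sd > 0
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} constant sample row(s) assigned post hoc",
            RuntimeWarning,
        )
    core = values[ok]
    if core.shape[0] < k:
        raise ValueError("too few non-constant samples to form k subgroups")
    dist = scipy.spatial.distance.pdist(core, metric="correlation")
    linkage = sch.linkage(dist, method="ward")
    flat = sch.fcluster(linkage, k, criterion="maxclust")
    labels = np.empty(n, dtype=int)
    labels[ok] = flat
    if (~ok).any():
        centroids = np.vstack([core[flat == c].mean(axis=0)
                               for c in range(1, k + 1)])
        for i in np.flatnonzero(~ok):
            labels[i] = 1 + int(
                np.argmin(np.linalg.norm(centroids - values[i], axis=1))
            )
    # order subgroup ids by size
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: f"C{new + 1}" for new, old in enumerate(order)}
    out = pd.Series([remap[v] for v in labels], index=ect_fractions.index,
                    name="subgroup")
    return out, linkage


@dataclass
class LogRankResult:
    """K-sample log-rank test with per-group Kaplan-Meier curves."""

    statistic: float | None
    p_value: float | None
    df: int
    groups: pd.DataFrame  # group, n, events
    curves: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    note: str = ""


def km_logrank(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence[object],
) -> LogRankResult:
    """Kaplan-Meier curves per group and the k-sample log-rank test.

    The statistic is the classical observed-minus-expected quadratic
    form with hypergeometric variance at each distinct event time,
    chi-squared with k-1 degrees of freedom.  With no events anywhere
    the test is undefined and an explicit "no-events" result is
    returned.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if time.shape != event.shape or time.shape != group.shape:
        raise ValueError("time, event and group must align")
    names = [g for g in pd.unique(group)]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g in names:
        if not (group == g).any():
            raise ValueError(f"group {g!r} has no subjects")

    curves = {}
    summary = []
    for g in names:
        mask = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(g))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[str(g)] = sf
        summary.append({"group": str(g), "n": int(mask.sum()),
                        "events": int(event[mask].sum())})
    groups_df = pd.DataFrame(summary)

    if event.sum() == 0:
        return LogRankResult(None, None, len(names) - 1, groups_df, curves,
                             note="no-events")

    k = len(names)
    gidx = np.array([names.index(g) for g in group])
    event_times = np.unique(time[event == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n_j = at_risk.sum()
        n_ij = np.bincount(gidx[at_risk], minlength=k).astype(float)
        dying = at_risk & (time == t) & (event == 1)
        d_j = dying.sum()
        d_ij = np.bincount(gidx[dying], minlength=k).astype(float)
        observed += d_ij
        expected += d_j * n_ij / n_j
        if n_j > 1:
            factor = d_j * (n_j - d_j) / (n_j - 1)
            p = n_ij / n_j
            cov += factor * (np.diag(p) - np.outer(p, p))
    z = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    stat = float(z @ np.linalg.pinv(v) @ z)
    p_value = float(scipy.stats.chi2.sf(stat, k - 1))
    return LogRankResult(stat, p_value, k - 1, groups_df, curves)


def median_stratify(values: Sequence[float]) -> np.ndarray:
    """Split samples at the median: "low" = below, "high" = at or above.

    Ties at the median go to "high" (so with odd n the median sample is
    "high").  All-identical values cannot be stratified.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    med = np.median(v)
    if np.all(v == v[0]):
        raise ValueError("all values identical; stratification impossible")
    return np.where(v < med, "low", "high")


def risk_groups(
    detox_fraction: Sequence[float], tgfb_fraction: Sequence[float]
) -> np.ndarray:
    """Two-marker risk split: low risk = high protective and low adverse.

    A sample is "low risk" when its first (protective) fraction is at or
    above that fraction's median AND its second (adverse) fraction is
    below its own median; every other sample is "high risk".
    """
    a = np.asarray(detox_fraction, dtype=float)
    b = np.asarray(tgfb_fraction, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fraction vectors must align on samples")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("degenerate median: all values identical")
    low = (a >= np.median(a)) & (b < np.median(b))
    return np.where(low, "low risk", "high risk")


def cox_multivariate(
    time: Sequence[float],
    event: Sequence[int],
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Cox proportional-hazards fit; HR with 95% Wald CI and p per covariate.

    Categorical covariates are dummy-encoded against their first level.
    Efron approximation for tied event times.  Raises on single-level
    covariates, on fewer events than parameters, and (explicitly, with
    the fitter's diagnostics) on non-convergence.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cov = covariates.copy()
    for c in cov.columns:
        if cov[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} has a single level")
    cov = pd.get_dummies(cov, drop_first=True, dtype=float)
    if event.sum() < cov.shape[1]:
        raise ValueError(
            f"{int(event.sum())} events for {cov.shape[1]} parameters"
        )
    df = cov.reset_index(drop=True)
    df["time"] = time
    df["event"] = event
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = fitter.summary
    out = pd.DataFrame(
        {
            "covariate": s.index,
            "coef": s["coef"].to_numpy(),
            "se": s["se(coef)"].to_numpy(),
            "hazard_ratio": s["exp(coef)"].to_numpy(),
            "ci_lower": s["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": s["exp(coef) upper 95%"].to_numpy(),
            "p_value": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out
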