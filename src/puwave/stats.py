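"""Cohort-level statistics for marker tables.

Nonparametric throughout: group summaries as median [25th, 75th
percentile] with linear-interpolation quantiles, Mann-Whitney U with
effect size r = |Z|/sqrt(N), Fisher's exact test (two-sided by
probability ordering), Spearman rank correlation, and empirical ROC
analysis with trapezoidal AUC and the Youden-index cutoff. No
multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, ParameterError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    effect_size_r: float | None = None
    method: str = ""

    @property
    def p_printed(self) -> str:
        return format_p(self.p_value)


@dataclass
class ROCResult:
    auc: float
    thresholds: np.ndarray = field(repr=False)
    sensitivity: np.ndarray = field(repr=False)
    specificity: np.ndarray = field(repr=False)
    youden_cutoff: float = float("nan")
    sensitivity_at_cutoff: float = float("nan")
    specificity_at_cutoff: float = float("nan")


def format_p(p: float) -> str:
    """Printed p-value convention: floor at <0.001, cap at 0.999."""
    if p < 0.001:
        return "<0.001"
    return f"{min(p, 0.999):.3f}"


def summarize_groups(tbl: pd.DataFrame, marker: str, group_col: str = "group") -> dict:
    """Per-group median [25th, 75th percentile] of one marker."""
    if marker not in tbl.columns:
        raise ParameterError(f"marker {marker!r} not in table")
    out = {}
    for g, sub in tbl.groupby(group_col, sort=True):
        vals = sub[marker].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise DataError(f"group {g!r} has no values for {marker!r}")
        q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75])  # linear interpolation
        out[g] = {"median": float(med), "q25": float(q25), "q75": float(q75),
                  "n": int(vals.size)}
    return out


def mann_whitney_r(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test with effect size r.

    The p-value is exact (full null enumeration) for small tie-free
    samples (n1+n2 <= 12), otherwise a normal approximation with
    continuity and tie correction. The effect size is r = |Z|/sqrt(N)
    with Z taken from the tie-corrected normal approximation without
    continuity correction (the conventional definition, reported as a
    magnitude).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    if n1 + n2 <= 12 and not ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        method = "normal approximation (tie/continuity corrected)"
    u = float(res.statistic)
    # tie-corrected Z without continuity correction, for the effect size
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (u - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    r = abs(z) / np.sqrt(n)
    return TestResult(statistic=u, p_value=float(res.pvalue), n1=n1, n2=n2,
                      effect_size_r=float(r), method=method)


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Two-sided p by probability ordering: the sum of hypergeometric
    probabilities of all tables (at fixed margins) no more probable
    than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ParameterError("Fisher test requires a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and np.any(t != np.floor(t)):
        raise DataError("counts must be non-negative integers")
    t = t.astype(int)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p),
                      n1=int(t[0].sum()), n2=int(t[1].sum()),
                      method="Fisher exact (probability ordering)")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    p-value from the t-approximation. Constant input leaves rho
    undefined (NaN, flagged in ``method``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(statistic=float("nan"), p_value=float("nan"),
                          n1=x.size, n2=x.size, method="undefined: constant input")
    rho, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p), n1=x.size, n2=x.size,
                      method="Spearman (t approximation)")


def roc_analysis(scores, labels) -> ROCResult:
    """Empirical ROC curve, AUC and Youden-index cutoff.

    Thresholds are midpoints between adjacent distinct scores (plus
    sentinels); a subject is called positive when score >= threshold.
    AUC is the trapezoidal area under the empirical curve (equal to
    U/(n1·n2) of the rank test). Ties in the Youden index are broken
    toward higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.size != y.size:
        raise DataError("scores and labels must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes must be present")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    sens = np.array([(s[y] >= t).mean() for t in thresholds])
    spec = np.array([(s[~y] < t).mean() for t in thresholds])
    # integrate the (FPR, sens) staircase over increasing FPR; points with
    # equal FPR are ordered by ascending sensitivity so vertical steps
    # contribute no spurious area
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())
    pick = best[np.argmax(spec[best])]
    return ROCResult(auc=auc, thresholds=thresholds, sensitivity=sens,
                     specificity=spec, youden_cutoff=float(thresholds[pick]),
                     sensitivity_at_cutoff=float(sens[pick]),
                     specificity_at_cutoff=float(spec[pick]))


def marker_panel_report(tbl: pd.DataFrame, markers: list[str] | None = None,
                        group_col: str = "group", positive_group: str | None = None) -> dict:
    """Group summaries, rank tests, effect sizes and ROC per marker.

    One machine-readable report; no multiple-testing correction.
    ``positive_group`` (default: first group alphabetically reversed,
    i.e. the one meant as cases) defines ROC labels.
    """
    groups = sorted(tbl[group_col].dropna().unique().tolist())
    if len(groups) != 2:
        raise DataError(f"need exactly 2 groups, found {groups}")
    positive = positive_group or groups[0]
    if positive not in groups:
        raise ParameterError(f"positive group {positive!r} not in {groups}")
    negative = [g for g in groups if g != positive][0]
    markers = markers or [c for c in tbl.columns
                          if c not in (group_col, "id")
                          and np.issubdtype(tbl[c].dtype, np.number)]
    report: dict = {"groups": {"positive": positive, "negative": negative},
                    "markers": {}}
    for m in markers:
        sub = tbl[[group_col, m]].dropna()
        x = sub.loc[sub[group_col] == positive, m].to_numpy(dtype=float)
        y = sub.loc[sub[group_col] == negative, m].to_numpy(dtype=float)
        test = mann_whitney_r(x, y)
        scores = np.concatenate([x, y])
        lab = np.concatenate([np.ones(x.size), np.zeros(y.size)])
        roc = roc_analysis(scores, lab)
        direction = ">="
        if roc.auc < 0.5:
            # marker is lower in cases: report its discriminative ability
            # with a flipped decision rule
            roc = roc_analysis(-scores, lab)
            roc.youden_cutoff = -roc.youden_cutoff
            direction = "<="
        report["markers"][m] = {
            "summary": summarize_groups(sub, m, group_col),
            "mann_whitney": {"U": test.statistic, "p": test.p_value,
                             "p_printed": test.p_printed, "r": test.effect_size_r,
                             "method": test.method},
            "roc": {"auc": roc.auc, "youden_cutoff": roc.youden_cutoff,
                    "direction": direction,
                    "sensitivity": roc.sensitivity_at_cutoff,
                    "specificity": roc.specificity_at_cutoff},
        }
    return report
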