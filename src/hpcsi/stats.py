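"""Hemisphere and group statistics for ROI metabolite ratios.

Paired t-tests compare ipsilateral vs contralateral ROIs within a group.
Group comparisons (naive vs injured) are gated on assumptions at
alpha = 0.05: Shapiro-Wilk normality per group and Brown-Forsythe
(median-centered Levene) equality of variances; if both pass, a one-way
ANOVA runs, otherwise Kruskal-Wallis with Dunn's post-hoc rank test.
No multiple-comparison correction is applied (small, pre-planned set of
comparisons).  Hemisphere asymmetry is summarized by the relative
difference (ipsi - contra) / contra, averaged per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "GroupSample",
    "ComparisonResult",
    "relative_difference",
    "paired_compare",
    "group_compare",
    "dunn_posthoc",
    "summarize",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSample:
    """Per-subject values of one metric for one group."""

    values: tuple[float, ...]
    group: str = ""
    metric: str = ""

    def __post_init__(self) -> None:
        if any(not np.isfinite(v) for v in self.values):
            raise ValueError("undefined values may not enter statistical tests")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    normality_ok: bool | None = None
    equal_variance_ok: bool | None = None
    n_per_group: tuple[int, ...] = ()
    mean_se: tuple[tuple[float, float], ...] = ()
    warnings: list[str] = field(default_factory=list)
    posthoc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def relative_difference(ipsi: float, contra: float) -> float:
    """Hemisphere asymmetry (ipsi - contra) / contra."""
    if contra == 0:
        raise ValueError("relative difference undefined for contra == 0")
    return (ipsi - contra) / contra


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
    return float(np.mean(v)), se


def paired_compare(ipsi: GroupSample, contra: GroupSample) -> ComparisonResult:
    """Two-sided paired t-test of matched ipsi/contra values.

    Zero-variance differences are degenerate for the t statistic; by
    convention they are reported with p = 1 and a warning (statistic 0 for
    identical vectors, +/-inf when the common difference is nonzero, so
    the |t| -> inf behaviour remains visible).
    """
    a = np.asarray(ipsi.values, dtype=float)
    b = np.asarray(contra.values, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired test requires n >= 2")

    diff = a - b
    notes: list[str] = []
    if np.std(diff, ddof=1) == 0:
        d = float(diff[0])
        stat = 0.0 if d == 0 else float(np.sign(d) * np.inf)
        p = 1.0
        notes.append("zero within-pair variance; p = 1 by convention")
        warnings.warn(notes[-1], stacklevel=2)
    else:
        t = sps.ttest_rel(a, b)
        stat, p = float(t.statistic), float(t.pvalue)
    return ComparisonResult(
        "paired t-test",
        stat,
        p,
        n_per_group=(a.size, b.size),
        mean_se=(_mean_se(a), _mean_se(b)),
        warnings=notes,
    )


def dunn_posthoc(groups: list[GroupSample]) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests (tie-corrected, unadjusted p)."""
    values = [np.asarray(g.values, dtype=float) for g in groups]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    split = np.cumsum([v.size for v in values])[:-1]
    group_ranks = np.split(ranks, split)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ni, nj = values[i].size, values[j].size
            se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
            z = (np.mean(group_ranks[i]) - np.mean(group_ranks[j])) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append(
                {
                    "group_a": groups[i].group or str(i),
                    "group_b": groups[j].group or str(j),
                    "z": float(z),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def group_compare(*groups: GroupSample, alpha: float = ALPHA) -> ComparisonResult:
    """Assumption-gated comparison of two or more independent groups.

    Runs Shapiro-Wilk per group and Brown-Forsythe across groups; both
    passing selects one-way ANOVA, otherwise Kruskal-Wallis with Dunn's
    post-hoc.  The result records which path ran.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    values = [np.asarray(g.values, dtype=float) for g in groups]
    if any(v.size < 3 for v in values):
        raise ValueError("each group needs n >= 3 for the normality gate")
    if all(np.ptp(v) == 0 for v in values) and np.ptp(np.concatenate(values)) == 0:
        raise ValueError("all values identical; no test is defined")

    notes: list[str] = []
    normal = True
    for g, v in zip(groups, values):
        if np.ptp(v) == 0:
            normal = False
            notes.append(f"constant values in group {g.group!r}; normality fails")
            continue
        if sps.shapiro(v).pvalue < alpha:
            normal = False
    try:
        bf_p = float(sps.levene(*values, center="median").pvalue)
    except ValueError:
        bf_p = 0.0
    equal_var = bf_p >= alpha

    if normal and equal_var:
        res = sps.f_oneway(*values)
        stat, p, name, posthoc = float(res.statistic), float(res.pvalue), "one-way ANOVA", None
    else:
        res = sps.kruskal(*values)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "Kruskal-Wallis"
        posthoc = dunn_posthoc(list(groups))
        notes.append("assumption gate failed; Kruskal-Wallis with Dunn's post-hoc")
    return ComparisonResult(
        name,
        stat,
        p,
        normality_ok=normal,
        equal_variance_ok=equal_var,
        n_per_group=tuple(v.size for v in values),
        mean_se=tuple(_mean_se(v) for v in values),
        warnings=notes,
        posthoc=posthoc,
    )


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group summary of a (subject, group, ipsi, contra) metric table.

    Reports mean +/- SE (SE = SD/sqrt(n)) per hemisphere, the per-subject
    relative difference averaged within the group (the default convention)
    and the ratio-of-means variant ``(mean_ipsi - mean_contra)/mean_contra``.
    A single-subject group has undefined (NaN) standard errors.
    """
    required = {"subject", "group", "ipsi", "contra"}
    if not required.issubset(table.columns):
        raise ValueError(f"summary table needs columns {sorted(required)}")
    rows = []
    for group, sub in table.groupby("group", sort=True):
        ipsi = sub["ipsi"].to_numpy(dtype=float)
        contra = sub["contra"].to_numpy(dtype=float)
        rel = np.array(
            [relative_difference(i, c) for i, c in zip(ipsi, contra)], dtype=float
        )
        m_i, se_i = _mean_se(ipsi)
        m_c, se_c = _mean_se(contra)
        m_r, se_r = _mean_se(rel)
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "ipsi_mean": m_i,
                "ipsi_se": se_i,
                "contra_mean": m_c,
                "contra_se": se_c,
                "rel_diff_mean": m_r,
                "rel_diff_se": se_r,
                "rel_diff_of_means": relative_difference(m_i, m_c),
            }
        )
    return pd.DataFrame(rows)
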