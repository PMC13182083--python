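"""Group comparisons and distributional summaries.

Rank tests mirror standard epidemiological reporting at large n: the
Mann-Whitney U test with midranks and a tie-corrected normal approximation
(reported as a Z value), and the Kruskal-Wallis H test with tie correction
against a chi-square reference.  Severity distributions and Cronbach's
alpha round out the descriptive stage.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import SEVERITY_LEVELS, phq9_severity

__all__ = [
    "mann_whitney_u",
    "kruskal_wallis",
    "severity_distribution",
    "group_summary",
    "cronbach_alpha",
]


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]):
    """Mann-Whitney U with midranks; (U, Z, two-sided p).

    U counts pairs where a value from the first group exceeds one from the
    second (ties count half).  Z is the normal approximation with
    tie-corrected variance and no continuity correction, the standard
    large-sample form.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    correction = stats.tiecorrect(ranks)
    if correction == 0.0:
        return float(u), 0.0, 1.0  # every value identical
    var_u = n1 * n2 * (n + 1) / 12.0 * correction
    z = (u - mean_u) / np.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(u), float(z), float(min(p, 1.0))


def kruskal_wallis(groups: Sequence[Sequence[float]]):
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0  # all observations identical
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def severity_distribution(data) -> pd.DataFrame:
    """Counts and percentages per severity band (none/mild/moderate/severe).

    Accepts a DataFrame with a ``severity`` column, a sequence of severity
    labels, or a sequence of integer PHQ-9 totals.
    """
    if isinstance(data, pd.DataFrame):
        labels = data["severity"].tolist()
    else:
        data = list(data)
        if not data:
            raise ValueError("empty dataset")
        if isinstance(data[0], str):
            labels = data
        else:
            labels = [phq9_severity(int(v)) for v in data]
    if not labels:
        raise ValueError("empty dataset")
    counts = pd.Series(labels).value_counts()
    out = pd.DataFrame(
        {
            "count": [int(counts.get(band, 0)) for band in SEVERITY_LEVELS],
        },
        index=pd.Index(SEVERITY_LEVELS, name="severity"),
    )
    out["percent"] = out["count"] / out["count"].sum() * 100.0
    return out


def group_summary(
    data: pd.DataFrame, value: str, by: str
) -> pd.DataFrame:
    """Per-group median (Q1, Q3) plus the appropriate rank test.

    Two groups get a Mann-Whitney Z; three or more get Kruskal-Wallis H.
    """
    groups = [g[value].to_numpy(float) for _, g in data.groupby(by, observed=True)]
    labels = [k for k, _ in data.groupby(by, observed=True)]
    if len(groups) == 2:
        _, statistic, p = mann_whitney_u(groups[0], groups[1])
        test = "mann-whitney"
    else:
        statistic, p = kruskal_wallis(groups)
        test = "kruskal-wallis"
    rows = []
    for label, g in zip(labels, groups):
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        rows.append(
            {
                by: label,
                "median": med,
                "q1": q1,
                "q3": q3,
                "n": g.size,
                "statistic": statistic,
                "p_value": p,
                "test": test,
            }
        )
    return pd.DataFrame(rows)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / total variance)."""
    x = np.asarray(item_matrix, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 and k >= 2")
    if np.any(~np.isfinite(x)):
        raise ValueError("item matrix contains missing or non-finite values")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total scores have zero variance")
    return float(k / (k - 1) * (1.0 - item_var / total_var))
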