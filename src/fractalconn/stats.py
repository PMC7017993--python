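"""Nonparametric group comparison of fractal-dimension measures.

Small, heterogeneous clinical groups rule out normality assumptions, so the
omnibus test is Kruskal-Wallis (tie-corrected, chi-squared approximation),
post-hoc pairwise tests are Mann-Whitney U (reported with the
``min(U_ab, U_ba)`` convention), and the family of pairwise p-values within
one measure is controlled with the Benjamini-Hochberg step-up procedure at
5% FDR. Group summaries are medians with 25-75% IQRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "mann_whitney_u",
    "benjamini_hochberg",
    "pearson_r",
    "summarize_groups",
    "compare_groups",
]


@dataclass
class GroupComparison:
    """Full comparison of one measure across condition groups."""

    groups: dict
    medians_iqr: dict  # label -> (median, q25, q75)
    kw: tuple[float, float]  # (H, p)
    pairwise: list  # (pair, U, p, fdr_reject)
    fdr_q: float


def kruskal_wallis(groups: dict[str, list[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-squared p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(s.size == 0 for s in samples):
        raise ValueError("empty group")
    if sum(s.size for s in samples) < 3:
        raise ValueError("need at least 3 observations in total")
    flat = np.concatenate(samples)
    if np.all(flat == flat[0]):
        raise ValueError("all observations identical: H undefined")
    h, p = scipy.stats.kruskal(*samples)
    return float(h), float(p)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U, reported as min(U_ab, U_ba).

    Ties count one half toward each direction. The p-value uses the exact
    distribution when both samples have n <= 20 and there are no ties, and
    the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_ab = float(res.statistic)
    u = min(u_ab, a.size * b.size - u_ab)
    return u, float(res.pvalue)


def benjamini_hochberg(pvals, q: float = 0.05) -> list[bool]:
    """Benjamini-Hochberg step-up rejections at FDR ``q``, in input order."""
    pvals = list(pvals)
    if not pvals:
        return []
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(arr, alpha=q, method="fdr_bh")
    return [bool(r) for r in reject]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def summarize_groups(groups: dict[str, list[float]]) -> dict[str, tuple[float, float, float]]:
    """Median and linear-interpolation quartiles per group."""
    out = {}
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"empty group {label!r}")
        med, q25, q75 = np.percentile(v, [50, 25, 75])
        out[label] = (float(med), float(q25), float(q75))
    return out


def compare_groups(
    groups: dict[str, list[float]], fdr_q: float = 0.05
) -> GroupComparison:
    """Omnibus + pairwise comparison of one measure across groups.

    BH correction is applied across the family of all pairwise tests for
    this measure.
    """
    labels = list(groups)
    kw = kruskal_wallis(groups)
    pairs = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    tested = [(pair, *mann_whitney_u(groups[pair[0]], groups[pair[1]])) for pair in pairs]
    rejects = benjamini_hochberg([t[2] for t in tested], q=fdr_q)
    return GroupComparison(
        groups={k: list(v) for k, v in groups.items()},
        medians_iqr=summarize_groups(groups),
        kw=kw,
        pairwise=[(pair, u, p, rej) for (pair, u, p), rej in zip(tested, rejects)],
        fdr_q=fdr_q,
    )
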