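"""External cluster validation: score comparisons across clusters.

Continuous instrument scores are compared across clusters with one-way
ANOVA followed by the Tukey-Kramer studentized-range test (the unequal-n
generalisation of Tukey's HSD); the binary Berlin risk label is compared
with Pearson's chi-squared test for the omnibus R x C table and, pairwise,
with the Yates continuity-corrected 2 x 2 chi-squared plus an odds ratio
with a log-normal 95% CI.

The continuity-correction split — uncorrected omnibus, corrected pairwise —
mirrors the convention of the statistical tooling this analysis style uses
(both statistics are reproduced against their reference values in the test
suite) and is noted in the report footer.

ANOVA and Tukey-Kramer accept either raw per-cluster vectors or
``(n, mean, SD)`` summary triplets: the exact sum-of-squares decomposition
only needs those moments, which lets published summary tables be re-analysed
directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

REPORT_FOOTER = (
    "Omnibus chi-squared: Pearson, uncorrected. Pairwise 2x2 chi-squared: "
    "Yates continuity-corrected. OR: odds of high risk, first cluster over "
    "second, log-normal 95% CI."
)


# ---------------------------------------------------------------------------
# One-way ANOVA (raw or summary mode)
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    F: float
    p: float
    msw: float
    df_between: int
    df_within: int
    ns: tuple
    means: tuple
    sds: tuple


def anova_oneway(
    groups: Sequence | None = None,
    summaries: Sequence[tuple] | None = None,
) -> AnovaResult:
    """One-way fixed-effects ANOVA.

    Pass either ``groups`` (raw per-cluster vectors) or ``summaries``
    (per-cluster ``(n, mean, SD)`` triplets).  F = MSB/MSW with
    MSB = sum n_i (m_i - grand)^2 / (k-1) and
    MSW = sum (n_i - 1) s_i^2 / (n - k); p from the F distribution.
    """
    if (groups is None) == (summaries is None):
        raise ConfigurationError("pass exactly one of groups / summaries")
    if groups is not None:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        ns = np.array([a.size for a in arrays])
        means = np.array([a.mean() if a.size else np.nan for a in arrays])
        sds = np.array([a.std(ddof=1) if a.size > 1 else np.nan for a in arrays])
    else:
        ns = np.array([int(s[0]) for s in summaries])
        means = np.array([float(s[1]) for s in summaries])
        sds = np.array([float(s[2]) for s in summaries])
    k = ns.size
    if k < 2:
        raise ConfigurationError("ANOVA needs at least 2 groups")
    if (ns < 2).any():
        raise ConfigurationError("every group needs n >= 2")
    n = int(ns.sum())
    grand = float((ns * means).sum() / n)
    msb = float((ns * (means - grand) ** 2).sum() / (k - 1))
    msw = float(((ns - 1) * sds**2).sum() / (n - k))
    if msb == 0.0:
        F = 0.0  # identical group means (the 0/0 case counts as no effect)
    elif msw == 0.0:
        F = math.inf
    else:
        F = msb / msw
    p = float(stats.f.sf(F, k - 1, n - k)) if math.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F), p=p, msw=msw, df_between=k - 1, df_within=n - k,
        ns=tuple(int(x) for x in ns), means=tuple(map(float, means)),
        sds=tuple(map(float, sds)),
    )


# ---------------------------------------------------------------------------
# Tukey-Kramer post-hoc comparisons
# ---------------------------------------------------------------------------


@dataclass
class PairwiseComparison:
    pair: tuple  # (i, j) group indices
    difference: float
    ci_low: float
    ci_high: float
    p: float


def tukey_kramer(
    groups: Sequence | None = None,
    summaries: Sequence[tuple] | None = None,
    alpha: float = 0.05,
) -> list[PairwiseComparison]:
    """All pairwise mean comparisons under the studentized-range law.

    difference = m_i - m_j; SE = sqrt(MSW/2 * (1/n_i + 1/n_j));
    CI = difference +/- q(alpha; k, df_within) * SE; the adjusted p is the
    studentized-range tail probability of |difference| / SE.
    """
    res = anova_oneway(groups=groups, summaries=summaries)
    k, df = len(res.ns), res.df_within
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df))
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = res.means[i] - res.means[j]
            se = math.sqrt(res.msw / 2.0 * (1.0 / res.ns[i] + 1.0 / res.ns[j]))
            if se == 0.0:
                p = 1.0
                lo = hi = diff
            else:
                q_stat = abs(diff) / se
                p = float(np.clip(stats.studentized_range.sf(q_stat, k, df), 0.0, 1.0))
                lo, hi = diff - q_crit * se, diff + q_crit * se
            out.append(PairwiseComparison((i, j), float(diff), float(lo), float(hi), p))
    return out


# ---------------------------------------------------------------------------
# Categorical statistics
# ---------------------------------------------------------------------------


def chi2_rxc(counts) -> tuple[float, int, float]:
    """Pearson chi-squared on an R x C table, no continuity correction."""
    t = np.asarray(counts, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ConfigurationError("counts must be a non-negative 2-D table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ConfigurationError("all margins must be positive")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def chi2_2x2_yates(counts) -> tuple[float, float]:
    """Yates continuity-corrected chi-squared for a 2 x 2 table.

    N (|ad - bc| - N/2)^2 / (row and column margin product), clamped to 0
    when |ad - bc| < N/2.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ConfigurationError("counts must be a non-negative 2x2 table")
    (a, b), (c, d) = t
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ConfigurationError("all margins must be positive")
    N = t.sum()
    num = N * max(abs(a * d - b * c) - N / 2.0, 0.0) ** 2
    x2 = num / margins
    return float(x2), float(stats.chi2.sf(x2, 1))


def odds_ratio(counts, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Odds ratio of a 2 x 2 table with a log-normal CI.

    Rows are groups, columns are (low, high); the OR is the odds of "high"
    in the first row over the second.  Zero cells get the Haldane-Anscombe
    +0.5 adjustment.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ConfigurationError("counts must be a non-negative 2x2 table")
    if t.sum() == 0:
        raise ConfigurationError("table is all zero")
    if (t == 0).any():
        t = t + 0.5
    (low1, high1), (low2, high2) = t
    o = (high1 / low1) / (high2 / low2)
    se = math.sqrt((1.0 / t).sum())
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lo, hi = math.exp(math.log(o) - z * se), math.exp(math.log(o) + z * se)
    return float(o), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Table-style report
# ---------------------------------------------------------------------------

CONTINUOUS_SCORES = (
    "psqi_global",
    "gsrs_total",
    "nq_global",
    "nq_balance",
    "nq_diversity",
    "nq_moderation",
    "nq_behavior",
)


def format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class ValidationReport:
    partition: str
    cluster_sizes: dict
    rows: pd.DataFrame
    footer: str = REPORT_FOOTER


def build_report(scored: pd.DataFrame, labels, partition: str = "train") -> ValidationReport:
    """Per-score omnibus and pairwise statistics across clusters.

    Continuous scores: ANOVA F/p plus Tukey-Kramer differences with 95%
    CIs.  Berlin risk: omnibus Pearson chi-squared on the k x 2 low/high
    table, pairwise Yates chi-squared and odds ratios.  Clusters with fewer
    than 2 rows cause the affected tests to be skipped with a warning row.
    """
    labels = np.asarray(labels)
    if len(labels) != len(scored):
        raise ConfigurationError("labels must align with scored rows")
    uniq = np.unique(labels)
    sizes = {str(u): int((labels == u).sum()) for u in uniq}
    cluster_names = {u: chr(ord("A") + i) for i, u in enumerate(uniq)}
    pair_names = [
        (cluster_names[uniq[i]], cluster_names[uniq[j]])
        for i in range(len(uniq)) for j in range(i + 1, len(uniq))
    ]
    rows = []

    usable = all((labels == u).sum() >= 2 for u in uniq)
    for score in CONTINUOUS_SCORES:
        values = pd.to_numeric(scored[score], errors="coerce").to_numpy(float)
        groups = [values[labels == u] for u in uniq]
        if not usable:
            rows.append({"score": score, "statistic": "F", "value": np.nan,
                         "p": np.nan, "note": "skipped: cluster with n < 2"})
            continue
        res = anova_oneway(groups=groups)
        rows.append({
            "score": score, "comparison": "omnibus", "statistic": "F",
            "value": res.F, "p": res.p, "p_text": format_p(res.p),
            "group_means": res.means, "group_sds": res.sds,
        })
        for comp, (gi, gj) in zip(tukey_kramer(groups=groups), pair_names):
            rows.append({
                "score": score, "comparison": f"{gi} vs {gj}",
                "statistic": "difference", "value": comp.difference,
                "ci_low": comp.ci_low, "ci_high": comp.ci_high,
                "p": comp.p, "p_text": format_p(comp.p),
            })

    risk = scored["berlin_risk"].to_numpy(object)
    table = np.array(
        [[(risk[labels == u] == "low").sum(), (risk[labels == u] == "high").sum()]
         for u in uniq], dtype=float,
    )
    x2, dof, p = chi2_rxc(table)
    rows.append({
        "score": "berlin_risk", "comparison": "omnibus", "statistic": "chi2",
        "value": x2, "p": p, "p_text": format_p(p), "df": dof,
        "counts_low_high": table.astype(int).tolist(),
    })
    idx_pairs = [(i, j) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    for (i, j), (gi, gj) in zip(idx_pairs, pair_names):
        sub = table[[i, j]]
        x2p, pp = chi2_2x2_yates(sub)
        o, (lo, hi) = odds_ratio(sub)
        rows.append({
            "score": "berlin_risk", "comparison": f"{gi} vs {gj}",
            "statistic": "OR", "value": o, "ci_low": lo, "ci_high": hi,
            "chi2": x2p, "p": pp, "p_text": format_p(pp),
        })
    return ValidationReport(partition=partition, cluster_sizes=sizes,
                            rows=pd.DataFrame(rows))
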