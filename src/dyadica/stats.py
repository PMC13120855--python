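"""Nonparametric statistics toolkit for behavior metric tables.

Mirrors the analysis conventions used throughout the package's reports:
Mann-Whitney U (two-sample, paired, or one-sample against a null
median), two-sample Kolmogorov-Smirnov for time-evolving or cumulative
distributions, Kruskal-Wallis with post-hoc Dunn tests and compact
letter groupings, exact binomial tests for binary outcomes,
Benjamini-Hochberg correction, Cohen's d effect sizes, and Tukey-style
outlier fences (flag-only: outliers are never removed from any
quantification).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


def stars(p: float) -> str:
    """Significance stars: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    test: str
    statistic: float
    p: float
    p_adjusted: float
    n: tuple[int, ...]
    paired: bool = False
    effect_size: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 and 0 <= self.p_adjusted <= 1):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted < self.p - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")

    @property
    def stars(self) -> str:
        return stars(self.p_adjusted)


def rank_tests(
    groups: Sequence[Sequence[float]],
    kind: str = "mw",
    paired: bool = False,
    null_median: Optional[float] = None,
    alternative: str = "two-sided",
) -> TestResult:
    """Rank-based comparison of distributions.

    ``kind``: ``mw`` (Mann-Whitney U / Wilcoxon), ``ks`` (two-sample
    Kolmogorov-Smirnov) or ``kw`` (Kruskal-Wallis, >2 groups allowed).
    One group plus ``null_median`` runs the one-sample signed-rank test;
    ``paired=True`` with two groups runs the paired signed-rank test.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    ns = tuple(len(g) for g in gs)
    if kind == "mw":
        if len(gs) == 1:
            if null_median is None:
                raise ValueError("one-sample test needs a null median")
            stat, p = sps.wilcoxon(gs[0] - null_median, alternative=alternative)
            name = "wilcoxon-one-sample"
        elif paired:
            if ns[0] != ns[1]:
                raise ValueError("paired samples must have equal lengths")
            stat, p = sps.wilcoxon(gs[0] - gs[1], alternative=alternative)
            name = "wilcoxon-paired"
        else:
            stat, p = sps.mannwhitneyu(gs[0], gs[1], alternative=alternative)
            name = "mann-whitney"
    elif kind == "ks":
        if len(gs) != 2:
            raise ValueError("ks requires exactly two groups")
        stat, p = sps.ks_2samp(gs[0], gs[1], alternative=alternative)
        name = "kolmogorov-smirnov"
    elif kind == "kw":
        if len(gs) < 2:
            raise ValueError("kw requires at least two groups")
        stat, p = sps.kruskal(*gs)
        name = "kruskal-wallis"
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return TestResult(name, float(stat), float(p), float(p), ns, paired=paired)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dunn_letters(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Post-hoc Dunn tests with BH correction and compact letter display.

    Dunn's z compares mean ranks from the pooled (tie-corrected) ranking;
    pairwise p-values are BH-adjusted. Two groups share a letter iff they
    are *not* significantly different at ``alpha``; letters are the
    maximal cliques of the non-significance graph, ordered by group.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in gs):
        raise ValueError("empty group")
    k = len(gs)
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(k)]
    pooled = np.concatenate(gs)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    pos = 0
    for g in gs:
        mean_ranks.append(ranks[pos : pos + len(g)].mean())
        pos += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    raw_ps = []
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        rows.append({"group1": labels[i], "group2": labels[j], "z": z, "p": p})
        raw_ps.append(p)
    adj = bh_adjust(raw_ps)
    for r, a in zip(rows, adj):
        r["p_adjusted"] = a
        r["significant"] = a < alpha
    table = pd.DataFrame(rows)

    graph = nx.Graph()
    graph.add_nodes_from(range(k))
    for (i, j), a in zip(pairs, adj):
        if a >= alpha:
            graph.add_edge(i, j)
    cliques = sorted(nx.find_cliques(graph), key=lambda c: (min(c), -len(c)))
    letters: dict[str, str] = {lab: "" for lab in labels}
    for letter_idx, clique in enumerate(cliques):
        ch = chr(ord("a") + letter_idx)
        for i in sorted(clique):
            letters[labels[i]] += ch
    return table, letters


def cohens_d(
    group_a: Sequence[float],
    group_b: Sequence[float],
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Cohen's d with a normal-approximation confidence interval.

    d = (mean_a − mean_b) / pooled SD, pooling variances with n−1
    weights; the CI uses the standard large-sample variance of d.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb - 2)))
    z = sps.norm.ppf(0.5 + confidence / 2)
    return float(d), (float(d - z * se), float(d + z * se))


def binomial_compare(
    successes: int,
    n: int,
    null_p: Optional[float] = None,
    second: Optional[tuple[int, int]] = None,
    alternative: str = "two-sided",
) -> TestResult:
    """Exact binomial comparison of binary-outcome frequencies.

    One-sample: ``successes/n`` against ``null_p``. Two-sample: the
    exact conditional (Fisher / hypergeometric) test of
    ``successes/n`` vs ``second = (s2, n2)``.
    """
    if not 0 <= successes <= n or n <= 0:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if second is not None:
        s2, n2 = second
        if not 0 <= s2 <= n2 or n2 <= 0:
            raise ValueError(f"invalid counts: {s2}/{n2}")
        table = [[successes, n - successes], [s2, n2 - s2]]
        odds, p = sps.fisher_exact(table, alternative=alternative)
        return TestResult(
            "fisher-exact", float(odds), float(p), float(p), (n, n2)
        )
    if null_p is None:
        raise ValueError("need null_p for a one-sample test or a second sample")
    res = sps.binomtest(successes, n, null_p, alternative=alternative)
    return TestResult(
        "binomial", successes / n, float(res.pvalue), float(res.pvalue), (n,)
    )


def outlier_fences(sample: Sequence[float]) -> dict:
    """Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) with outlier flags.

    Quartiles use linear interpolation. Values are only *flagged* —
    downstream quantifications and tests always retain them.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flags = (x > hi) | (x < lo)
    return {
        "Q1": float(q1),
        "Q3": float(q3),
        "lower_fence": float(lo),
        "upper_fence": float(hi),
        "flags": flags,
        "outliers": x[flags],
    }


def report_table(results: Sequence[TestResult], units: str = "flies") -> pd.DataFrame:
    """Publication-style summary table of test results."""
    return pd.DataFrame(
        {
            "test": [r.test for r in results],
            "n": [r.n for r in results],
            "units": units,
            "paired": [r.paired for r in results],
            "corrected": [r.p_adjusted != r.p for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "effect_size": [r.effect_size for r in results],
            "stars": [r.stars for r in results],
        }
    )
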