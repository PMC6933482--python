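"""Normality-gated comparisons and exact small-sample nonparametric tests.

With three groups of 3-5 participants, large-sample approximations to the
Mann-Whitney U and Spearman null distributions are unreliable, so both are
computed by full enumeration here (every rank arrangement / permutation).
Location tests follow the reporting convention of small neurofeedback
studies: check normality with the D'Agostino-Pearson omnibus K^2 test at
alpha = 0.05, run the parametric test when it passes and the nonparametric
one otherwise, and record which branch actually ran.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

GATE_ALPHA = 0.05
GATE_MIN_N = 8  # K^2 is defined for n >= 8
EXACT_PERM_MAX_N = 10
EXACT_ENUM_MAX = 10**6


@dataclass
class TestResult:
    """One statistical test: statistic, p, and how it was obtained."""

    name: str
    statistic: float
    p: float
    n: int
    normal: bool | None = None  # outcome of the normality gate, None if skipped
    method: str = ""  # "exact", "approx", "parametric", "nonparametric", ...
    posthoc: pd.DataFrame | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p out of range: {self.p}")


# ----------------------------------------------------------------------
# Exact Mann-Whitney U
# ----------------------------------------------------------------------

def _u_null_tail_p(u: float, n1: int, n2: int, ranks: np.ndarray) -> float:
    """Two-tailed tail probability of U over all C(n1+n2, n1) arrangements.

    ``ranks`` are the pooled (tie-averaged) ranks of the observed data, so
    ties are handled by enumerating assignments of the actual rank vector.
    """
    total = math.comb(n1 + n2, n1)
    lo = min(u, n1 * n2 - u)
    hi = n1 * n2 - lo
    eps = 1e-9
    count = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n1 + n2), n1):
        u1 = ranks[list(idx)].sum() - offset
        if u1 <= lo + eps or u1 >= hi - eps:
            count += 1
    return count / total


def mannwhitney_u(x, y) -> tuple[float, float]:
    """U statistic (reported as min(U1, U2)) from two samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return min(u1, n1 * n2 - u1), u1


def mannwhitney_exact(x, y) -> TestResult:
    """Mann-Whitney U test with an exact two-tailed p by full enumeration.

    Enumerates every assignment of the pooled ranks to the two groups (no
    normal approximation, no continuity correction); falls back to the
    large-sample approximation, with the method recorded, when the
    enumeration would exceed ``EXACT_ENUM_MAX`` arrangements.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if min(n1, n2) < 1:
        raise ValueError("both samples must be non-empty")
    u, u1 = mannwhitney_u(x, y)
    if math.comb(n1 + n2, n1) <= EXACT_ENUM_MAX:
        ranks = sps.rankdata(np.concatenate([x, y]))
        p = _u_null_tail_p(u1, n1, n2, ranks)
        method = "exact"
    else:
        p = float(sps.mannwhitneyu(x, y, method="asymptotic").pvalue)
        method = "approx"
    return TestResult("mann-whitney U", float(u), float(p), n1 + n2, method=method)


def mannwhitney_exact_from_u(u: float, n1: int, n2: int) -> TestResult:
    """Exact two-tailed p for a printed U statistic with untied data."""
    ranks = np.arange(1, n1 + n2 + 1, dtype=float)
    p = _u_null_tail_p(u, n1, n2, ranks)
    return TestResult("mann-whitney U", float(u), float(p), n1 + n2, method="exact")


# ----------------------------------------------------------------------
# Exact Spearman permutation p
# ----------------------------------------------------------------------

def _perm_chunks(values: np.ndarray, chunk: int = 40320):
    buf = []
    for p in permutations(values):
        buf.append(p)
        if len(buf) == chunk:
            yield np.asarray(buf)
            buf = []
    if buf:
        yield np.asarray(buf)


def spearman_exact(x, y, exact_max_n: int = EXACT_PERM_MAX_N) -> TestResult:
    """Spearman rank correlation with an exact two-tailed permutation p.

    For n <= ``exact_max_n`` all n! pairings are enumerated and p is the
    fraction with |rho| at least the observed |rho|; beyond that the t
    approximation is used and recorded.  Constant input leaves rho
    undefined and is flagged rather than silently returned as 0.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("spearman rho", float("nan"), float("nan"), n,
                          method="undefined", note="constant input: rho undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        cx = rx - rx.mean()
        denom = np.sqrt((cx**2).sum())
        count = total = 0
        for block in _perm_chunks(ry):
            cy = block - block.mean(axis=1, keepdims=True)
            r = (cy @ cx) / (denom * np.sqrt((cy**2).sum(axis=1)))
            count += int((np.abs(r) >= abs(rho) - 1e-12).sum())
            total += len(block)
        p = count / total
        method = "exact"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "approx"
    return TestResult("spearman rho", rho, float(p), n, method=method)


# ----------------------------------------------------------------------
# Normality-gated location tests
# ----------------------------------------------------------------------

def _gate(values: np.ndarray) -> tuple[bool | None, str]:
    """D'Agostino-Pearson omnibus K^2 normality gate at alpha = 0.05."""
    if len(values) < GATE_MIN_N:
        return None, f"n={len(values)} < {GATE_MIN_N}: K^2 gate skipped"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = sps.normaltest(values).pvalue
    return bool(p >= GATE_ALPHA), ""


def one_sample_vs_zero(values, mu: float = 0.0) -> TestResult:
    """One-sample location test against zero behind the normality gate.

    Normal data (K^2 p >= 0.05) get a two-tailed one-sample t-test; otherwise
    a Wilcoxon signed-rank test, exact for n < 25.  Samples too small for the
    gate (n < 8) go straight to Wilcoxon, flagged.
    """
    v = np.asarray(values, float) - mu
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 values")
    if np.all(v == 0):
        return TestResult("one-sample (degenerate)", float("nan"), float("nan"), n,
                          method="undefined", note="all values equal the null value")
    normal, note = _gate(v)
    if normal:
        t, p = sps.ttest_1samp(v, 0.0)
        return TestResult("one-sample t", float(t), float(p), n,
                          normal=normal, method="parametric")
    mode = "exact" if n < 25 and not np.any(v == 0) else "auto"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = sps.wilcoxon(v, method=mode)
    return TestResult("wilcoxon signed-rank", float(w), float(p), n,
                      normal=normal, method=f"nonparametric/{mode}", note=note)


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum post-hoc with tie correction, Bonferroni-adjusted p."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        n = len(groups[g])
        mean_ranks[g] = ranks[start : start + n].mean()
        sizes[g] = n
        start += n
    ncomp = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie) * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = min(1.0, 2 * sps.norm.sf(abs(z)) * ncomp)
        rows.append({"group1": a, "group2": b, "statistic": z, "p_adj": p})
    return pd.DataFrame(rows)


def compare_groups(groups: dict[str, "np.ndarray | list"]) -> TestResult:
    """Omnibus comparison of >= 2 groups behind the per-group normality gate.

    All groups normal: one-way ANOVA with Tukey HSD post-hoc.  Otherwise (or
    when any group is too small to gate): Kruskal-Wallis with Dunn's
    Bonferroni-adjusted post-hoc.  The post-hoc table covers all pairs.
    """
    groups = {g: np.asarray(v, float) for g, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every group needs at least 2 values")
    labels = list(groups)
    gates = [_gate(groups[g]) for g in labels]
    gate_known = [g for g, _ in gates if g is not None]
    all_normal = bool(gate_known) and all(gate_known) and all(g is not None for g, _ in gates)
    note = "; ".join(n for _, n in gates if n)
    n_total = sum(len(v) for v in groups.values())
    if all_normal:
        f, p = sps.f_oneway(*groups.values())
        tk = sps.tukey_hsd(*groups.values())
        rows = [
            {"group1": labels[i], "group2": labels[j],
             "statistic": float(tk.statistic[i, j]), "p_adj": float(tk.pvalue[i, j])}
            for i, j in combinations(range(len(labels)), 2)
        ]
        return TestResult("one-way ANOVA", float(f), float(p), n_total, normal=True,
                          method="parametric/tukey", posthoc=pd.DataFrame(rows))
    h, p = sps.kruskal(*groups.values())
    return TestResult("kruskal-wallis H", float(h), float(p), n_total,
                      normal=False if gate_known else None,
                      method="nonparametric/dunn", posthoc=_dunn_posthoc(groups), note=note)


def fdr_bh(pvalues, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg selection mask at level q."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
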