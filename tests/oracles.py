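"""Brute-force reference implementations used only by the tests.

Each oracle is an independent, enumeration-based computation of a
statistic the package computes by other means; they are deliberately
slow and simple.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full enumeration of the
    C(n1+n2, n1) assignments of pooled ranks to the first group."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)

    def midrank(v):
        lo = sum(1 for u in pooled if u < v)
        eq = sum(1 for u in pooled if u == v)
        return lo + (eq + 1) / 2.0
    w_obs = sum(midrank(v) for v in x)
    all_ranks = [midrank(v) for v in pooled]
    n1 = len(x)
    mean_w = sum(all_ranks) * n1 / len(pooled)
    d_obs = abs(w_obs - mean_w)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = sum(all_ranks[i] for i in combo)
        total += 1
        if abs(w - mean_w) >= d_obs - 1e-12:
            count += 1
    return count / total


def bh_by_hand(pvals):
    """Benjamini-Hochberg by direct application of p * m / rank with
    step-up monotonization, original order preserved."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        val = min(pvals[i] * m / (pos + 1), 1.0)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def auc_by_pairs(scores, labels, case="malignant") -> float:
    """AUC as the fraction of case-control pairs won, ties half."""
    cases = [s for s, l in zip(scores, labels) if l == case]
    ctrls = [s for s, l in zip(scores, labels) if l != case]
    wins = 0.0
    for a in cases:
        for b in ctrls:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(cases) * len(ctrls))


def mhl_by_windows(patterns) -> float:
    """MHL by materializing every (read, offset, length) window."""
    patterns = [str(p) for p in patterns]
    if not patterns:
        return float("nan")
    L = len(patterns[0])
    windows = {}  # length -> list of bool(all methylated)
    for p in patterns:
        for length in range(1, L + 1):
            for off in range(L - length + 1):
                w = p[off:off + length]
                if "." in w:
                    continue
                windows.setdefault(length, []).append(all(c == "1" for c in w))
    num = den = 0.0
    for length, flags in windows.items():
        num += length * (sum(flags) / len(flags))
        den += length
    return num / den if den else float("nan")


def spearman_rho_by_hand(x, y) -> float:
    """Pearson correlation of midranks, computed longhand."""
    def midranks(v):
        out = []
        for a in v:
            lo = sum(1 for b in v if b < a)
            eq = sum(1 for b in v if b == a)
            out.append(lo + (eq + 1) / 2.0)
        return out
    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    return sxy / math.sqrt(sxx * syy)


def spearman_exact_perm_p(x, y) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 7)."""
    rho_obs = abs(spearman_rho_by_hand(x, y))
    y = list(y)
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_rho_by_hand(x, perm)) >= rho_obs - 1e-12:
            count += 1
    return count / total
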