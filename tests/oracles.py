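"""Independent brute-force evaluations of the agreement statistics.

Every function here re-derives its statistic directly from the defining
formula with explicit Python loops — no shared code with the package's
vectorised implementations — so the two routes can be compared on random
tables.
"""

from __future__ import annotations

import itertools
import math


def brute_weighted_kappa(a, b, categories, quadratic=True) -> float:
    """Cohen's weighted kappa by explicit summation over every cell."""
    cats = sorted(categories)
    k = len(cats)
    n = len(a)
    span = cats[-1] - cats[0]

    def w(i, j):
        if quadratic:
            return 1.0 - ((cats[i] - cats[j]) / span) ** 2
        return 1.0 if i == j else 0.0

    p = [[0.0] * k for _ in range(k)]
    for x, y in zip(a, b):
        p[cats.index(x)][cats.index(y)] += 1.0 / n
    row = [sum(p[i][j] for j in range(k)) for i in range(k)]
    col = [sum(p[i][j] for i in range(k)) for j in range(k)]
    p_o = sum(w(i, j) * p[i][j] for i in range(k) for j in range(k))
    p_e = sum(w(i, j) * row[i] * col[j] for i in range(k) for j in range(k))
    return (p_o - p_e) / (1.0 - p_e)


def brute_fleiss_kappa(labels_by_item, categories) -> float:
    """Fleiss' kappa evaluated item by item from its defining formula."""
    cats = sorted(categories)
    n_items = len(labels_by_item)
    n_raters = len(labels_by_item[0])
    p_j = []
    for c in cats:
        total = sum(row.count(c) for row in labels_by_item)
        p_j.append(total / (n_items * n_raters))
    p_bar = 0.0
    for row in labels_by_item:
        s = sum(row.count(c) ** 2 for c in cats)
        p_bar += (s - n_raters) / (n_raters * (n_raters - 1))
    p_bar /= n_items
    p_e = sum(p * p for p in p_j)
    return (p_bar - p_e) / (1.0 - p_e)


def brute_cochran_q(grid) -> float:
    """Cochran's Q from the textbook formula, explicit sums."""
    n = len(grid)
    k = len(grid[0])
    col = [sum(grid[i][j] for i in range(n)) for j in range(k)]
    row = [sum(grid[i][j] for j in range(k)) for i in range(n)]
    num = (k - 1) * (k * sum(c * c for c in col) - sum(col) ** 2)
    den = k * sum(row) - sum(r * r for r in row)
    return num / den


def brute_mcnemar_exact_p(b, c) -> float:
    """Two-sided exact binomial McNemar p, via explicit tail sums."""
    n = b + c
    m = min(b, c)
    tail = sum(math.comb(n, i) for i in range(m + 1)) / 2.0**n
    return min(1.0, 2.0 * tail)


def brute_mcnemar_chi2(b, c) -> float:
    """Continuity-corrected McNemar chi-squared statistic."""
    return (abs(b - c) - 1.0) ** 2 / (b + c)


def brute_holm(p_values):
    """Holm step-down adjustment by direct stepping through the sorted p's."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def brute_wilcoxon_exact_p(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Assumes no zeros and no tied absolute values (each |d| distinct).
    """
    n = len(diffs)
    ranks = _rank(sorted(abs(d) for d in diffs), [abs(d) for d in diffs])
    w_obs = sum(r if d > 0 else -r for d, r in zip(diffs, ranks))
    count = 0
    total = 0
    for signs in itertools.product((1, -1), repeat=n):
        w = sum(s * r for s, r in zip(signs, ranks))
        total += 1
        if abs(w) >= abs(w_obs):
            count += 1
    return count / total


def _rank(sorted_vals, vals):
    return [sorted_vals.index(v) + 1 for v in vals]
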