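"""Brute-force oracles, independent of the library code paths they check.

Everything here is written from first principles (enumeration, grids,
permutations) so that agreement with the package's scipy-backed routines is
a genuine cross-validation, not a tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins.

    Probability of each table is the (central) hypergeometric mass computed
    from factorials; the two-sided p sums masses not exceeding the observed
    one (with the customary 1 + 1e-7 relative guard against float ties).
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)

    def log_mass(x: int) -> float:
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - (c1 - x) + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    masses = {x: math.exp(log_mass(x)) for x in range(lo, hi + 1)}
    obs = masses[a]
    return min(1.0, sum(m for m in masses.values() if m <= obs * (1 + 1e-7)))


def conditional_mle_or_grid(table, log_lo=-9.0, log_hi=9.0, n_grid=4501):
    """Conditional-MLE odds ratio by brute-force likelihood scan.

    Maximizes the noncentral-hypergeometric log-likelihood
    a·log(psi) − log Σ_x w_x psi^x over a log-psi grid; support endpoints
    (a zero cell) drive the likelihood monotonically to 0 or +inf.
    Returns (value, grid_step) — the value is exact 0.0/inf at endpoints
    and accurate to about one grid step in log-psi otherwise.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if lo == hi:
        return float("nan"), 0.0  # degenerate margin: a single possible table
    if a == hi:
        return float("inf"), 0.0
    if a == lo:
        return 0.0, 0.0
    support = np.arange(lo, hi + 1)
    log_w = np.array(
        [
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - (c1 - x) + 1)
            for x in support
        ]
    )
    log_psi = np.linspace(log_lo, log_hi, n_grid)
    # log C(psi) = logsumexp over support of (log w + x log psi)
    mat = log_w[:, None] + support[:, None] * log_psi[None, :]
    mmax = mat.max(axis=0)
    log_c = mmax + np.log(np.exp(mat - mmax).sum(axis=0))
    loglik = a * log_psi - log_c
    step = log_psi[1] - log_psi[0]
    return float(np.exp(log_psi[np.argmax(loglik)])), float(step)


def cmle_or_margin_class(r1: int, r2: int, c1: int, log_lo=-9.0, log_hi=9.0,
                         n_grid=4501):
    """Grid-scan conditional-MLE OR for every table in one margin class.

    Returns (support, values, step): one likelihood-grid maximization per
    possible upper-left cell a, sharing the log-normalizer across the class.
    """
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    log_w = np.array(
        [
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - (c1 - x) + 1)
            for x in support
        ]
    )
    log_psi = np.linspace(log_lo, log_hi, n_grid)
    mat = log_w[:, None] + support[:, None] * log_psi[None, :]
    mmax = mat.max(axis=0)
    log_c = mmax + np.log(np.exp(mat - mmax).sum(axis=0))
    step = log_psi[1] - log_psi[0]
    values = []
    for a in support:
        if lo == hi:
            values.append(float("nan"))
        elif a == hi:
            values.append(float("inf"))
        elif a == lo:
            values.append(0.0)
        else:
            values.append(float(np.exp(log_psi[np.argmax(a * log_psi - log_c)])))
    return support, values, float(step)


def fisher_p_margin_class(r1: int, r2: int, c1: int):
    """Two-sided Fisher p for every table in one margin class."""
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    log_mass = np.array(
        [
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - (c1 - x) + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
            for x in support
        ]
    )
    masses = np.exp(log_mass)
    pvals = [
        min(1.0, float(masses[masses <= m * (1 + 1e-7)].sum())) for m in masses
    ]
    return support, pvals


def ranksum_permutation_oracle(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Statistic is the Mann–Whitney U of the first group; the two-sided p is
    the fraction of assignments at least as far from the null mean nm/2 as
    the observed U.  Assumes tie-free data.
    """
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            count += 1
    return count / total


def bh_stepup_oracle(pvals):
    """Benjamini–Hochberg adjusted p-values by the direct step-up formula."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted
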