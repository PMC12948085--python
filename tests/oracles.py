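"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries) they check:
exhaustive enumeration for the rank-sum test, a literal step-up loop for
Benjamini-Hochberg, pair counting for ROC-AUC, an explicit life table for
the log-rank statistic, a grid search of the Breslow partial likelihood
for Cox, and per-sample sorting for the rank signature score.
"""

from __future__ import annotations

import itertools

import numpy as np


def exact_rank_sum_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments.

    Assumes tie-free pooled values. p = P(|U - nm/2| >= |u_obs - nm/2|)
    under the permutation null.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled), dtype=np.int64)
    ranks[order] = np.arange(1, len(pooled) + 1)
    n, m = len(a), len(b)
    nm = n * m
    u_obs = int(ranks[:n].sum() - n * (n + 1) // 2)
    u_low = min(u_obs, nm - u_obs)
    u_high = nm - u_low
    count = 0
    total = 0
    base = n * (n + 1) // 2
    for comb in itertools.combinations(range(n + m), n):
        u = int(ranks[list(comb)].sum()) - base
        total += 1
        if u <= u_low or u >= u_high:
            count += 1
    return count / total


def bh_step_up(p) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up with a cumulative minimum."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    prev = 1.0
    for i in range(n - 1, -1, -1):
        rank = i + 1
        val = min(prev, p[order[i]] * n / rank, 1.0)
        adj[order[i]] = val
        prev = val
    return adj


def pair_counting_auc(scores, labels) -> float:
    """AUC = P(score+ > score-) + P(tie)/2 by explicit pair enumeration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).reshape(-1)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def logrank_statistic(times_a, events_a, times_b, events_b) -> float:
    """Log-rank chi-square via an explicit life table (O-E with
    hypergeometric variance, group A as the observed arm)."""
    ta = np.asarray(times_a, float)
    tb = np.asarray(times_b, float)
    ea = np.asarray(events_a, int)
    eb = np.asarray(events_b, int)
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O = E = V = 0.0
    for t in event_times:
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        n = na + nb
        d = ((ta == t) & (ea == 1)).sum() + ((tb == t) & (eb == 1)).sum()
        da = ((ta == t) & (ea == 1)).sum()
        O += da
        E += d * na / n
        if n > 1:
            V += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def breslow_partial_loglik(beta: float, times, events, x) -> float:
    """Cox partial log-likelihood with Breslow tie handling."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for tk in np.unique(t[e == 1]):
        dead = (t == tk) & (e == 1)
        at_risk = t >= tk
        ll += beta * x[dead].sum() - dead.sum() * np.log(np.exp(beta * x[at_risk]).sum())
    return ll


def grid_cox_mle(times, events, x, lo=-3.0, hi=3.0, step=1e-3) -> float:
    grid = np.arange(lo, hi + step, step)
    ll = [breslow_partial_loglik(b, times, events, x) for b in grid]
    return float(grid[int(np.argmax(ll))])


def rank_signature_scores(values: np.ndarray, set_cols) -> np.ndarray:
    """Per-sample normalized mean-rank score by explicit sorting."""
    n = values.shape[1]
    k = len(set_cols)
    out = np.empty(values.shape[0])
    for i, row in enumerate(values):
        order = np.argsort(row, kind="mergesort")
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        # average ranks for ties
        for v in np.unique(row):
            mask = row == v
            ranks[mask] = ranks[mask].mean()
        raw = ranks[list(set_cols)].mean()
        low = (k + 1) / 2
        high = n - (k - 1) / 2
        out[i] = (raw - low) / (high - low)
    return out
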