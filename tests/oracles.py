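"""Independent brute-force reference implementations used only as test
oracles; deliberately naive (factorial enumeration, per-subject loops)
and kept free of the production code paths they check."""

import itertools

import numpy as np
import pandas as pd


def assignment_bruteforce(treated_scores, control_scores, control_ids=None):
    """Exhaustive min-cost 1:1 assignment over all injective mappings.

    Returns (total_cost, assignment) where assignment maps treated index
    -> control index.  Ties in total cost break toward the smaller sum
    of control ranks (i.e. lower-id controls preferred), mirroring the
    documented tie-break.
    """
    k, m = len(treated_scores), len(control_scores)
    r = min(k, m)
    best = None
    for t_subset in itertools.combinations(range(k), r):
        for c_perm in itertools.permutations(range(m), r):
            cost = sum(abs(treated_scores[t] - control_scores[c])
                       for t, c in zip(t_subset, c_perm))
            ranksum = sum(c_perm)
            key = (round(cost, 12), ranksum)
            if best is None or key < best[0]:
                best = (key, dict(zip(t_subset, c_perm)))
    return best[0][0], best[1]


def sequential_obm_bruteforce(df, scores):
    """Naive reference for the sequential matching pass.

    Processes distinct transplant days in order; at each day matches the
    not-yet-matched newly treated to eligible controls (not yet
    transplanted, event-free strictly beyond the day, unmatched) by
    factorial enumeration.  Returns (total_distance, pairs) with pairs
    as (treated_id, control_id, day) tuples.
    """
    fup = {r.id: min(r.death_time if pd.notna(r.death_time) else np.inf,
                     r.censor_time) for r in df.itertuples()}
    tx = {r.id: r.tx_time for r in df.itertuples()}
    days = sorted({t for t in tx.values() if pd.notna(t)})
    matched = set()
    pairs = []
    total = 0.0
    for day in days:
        treated = sorted(i for i in tx if pd.notna(tx[i]) and tx[i] == day
                         and i not in matched)
        controls = sorted(i for i in tx
                          if (pd.isna(tx[i]) or tx[i] > day)
                          and fup[i] > day and i not in matched)
        if not treated or not controls:
            continue
        ts = [scores[i] for i in treated]
        cs = [scores[i] for i in controls]
        cost, assign = assignment_bruteforce(ts, cs)
        total += cost
        for t_idx, c_idx in assign.items():
            pairs.append((treated[t_idx], controls[c_idx], day))
            matched.add(treated[t_idx])
            matched.add(controls[c_idx])
    return total, pairs


def weighted_logrank_bruteforce(times, events, groups, weight="peto"):
    """Direct-summation two-sample weighted log-rank statistic.

    Explicit per-time loops: hypergeometric mean/variance at every
    distinct event time, Peto-Peto pooled modified survival weights
    S~(t) = prod (1 - d/(n+1)).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g1 = groups == np.unique(groups)[0]
    uniq = sorted(set(times[events == 1]))
    num = 0.0
    den = 0.0
    s_tilde = 1.0
    for u in uniq:
        n = int((times >= u).sum())
        n1 = int((times[g1] >= u).sum())
        d = int(((times == u) & (events == 1)).sum())
        d1 = int(((times == u) & (events == 1) & g1).sum())
        s_tilde *= 1.0 - d / (n + 1.0)
        w = s_tilde if weight == "peto" else 1.0
        e1 = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        num += w * (d1 - e1)
        den += w * w * v
    return num ** 2 / den


def cox_partial_likelihood_1d(beta, times, events, x):
    """Explicit Breslow partial likelihood for one covariate."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def grid_maximize_1d(times, events, x, lo=-5.0, hi=5.0, n=20001):
    """1-D grid-search maximizer of the explicit partial likelihood."""
    grid = np.linspace(lo, hi, n)
    lls = [cox_partial_likelihood_1d(b, times, events, x) for b in grid]
    return float(grid[int(np.argmax(lls))])
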