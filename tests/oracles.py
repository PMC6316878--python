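"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own code paths: exact rational
arithmetic for the Hardy-Weinberg test, explicit risk-set recomputation for
Kaplan-Meier, and exhaustive relabelling for permutation p-values.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import factorial

import numpy as np
from scipy import stats


def hwe_enumeration(n0: int, n1: int, n2: int) -> float:
    """Exact HWE p by enumerating every het count with the same allele totals,
    using exact fractions (sum of configurations no more probable than the
    observed one)."""
    n = n0 + n1 + n2
    n_alt = n1 + 2 * n2
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0
    probs: dict[int, Fraction] = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        if hom_common < 0:
            continue
        probs[h] = Fraction(
            factorial(n) * 2**h,
            factorial(hom_common) * factorial(h) * factorial(hom_rare),
        )
    total = sum(probs.values())
    p_obs = probs[n1]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


def km_brute_force(times, events):
    """Product-limit estimate at each distinct event time via explicit
    risk-set counting."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(times[events].tolist())):
        at_risk = sum(1 for x in times if x >= t)
        deaths = sum(1 for x, e in zip(times, events) if x == t and e)
        s *= 1.0 - deaths / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_brute_force(groups):
    """k-group log-rank statistic via explicit per-event-time hypergeometric
    moments (independent of the package implementation)."""
    k = len(groups)
    times = [np.asarray(t, dtype=float) for t, _ in groups]
    events = [np.asarray(e, dtype=bool) for _, e in groups]
    all_event_times = sorted(set(np.concatenate([t[e] for t, e in zip(times, events)]).tolist()))
    o = np.zeros(k)
    e_exp = np.zeros(k)
    v = np.zeros((k, k))
    for t in all_event_times:
        n_i = np.array([float(sum(1 for x in tt if x >= t)) for tt in times])
        d_i = np.array(
            [float(sum(1 for x, ev in zip(tt, ee) if x == t and ev))
             for tt, ee in zip(times, events)]
        )
        n_tot, d_tot = n_i.sum(), d_i.sum()
        o += d_i
        e_exp += d_tot * n_i / n_tot
        if n_tot > 1:
            for a in range(k):
                for b in range(k):
                    delta = 1.0 if a == b else 0.0
                    v[a, b] += (
                        d_tot * (n_tot - d_tot) / (n_tot - 1)
                        * (n_i[a] / n_tot) * (delta - n_i[b] / n_tot)
                    )
    z = (o - e_exp)[:-1]
    stat = float(z @ np.linalg.pinv(v[:-1, :-1]) @ z)
    return stat, float(stats.chi2.sf(stat, k - 1))


def exact_permutation_response_p(outcome, groups):
    """Exhaustively permute a binary outcome and return the proportion of
    arrangements whose Pearson chi-square p is <= the observed one."""
    outcome = np.asarray(outcome)
    groups = np.asarray(groups)

    def chi2_p(y):
        tab = np.zeros((int(groups.max()) + 1, 2))
        for g, o in zip(groups, y):
            tab[g, o] += 1
        tab = tab[tab.sum(axis=1) > 0]
        if tab.shape[0] < 2 or (tab.sum(axis=0) == 0).any():
            return 1.0
        return float(stats.chi2_contingency(tab, correction=False)[1])

    p_obs = chi2_p(outcome)
    n_le = 0
    total = 0
    for perm in itertools.permutations(range(outcome.size)):
        total += 1
        if chi2_p(outcome[list(perm)]) <= p_obs + 1e-12:
            n_le += 1
    return p_obs, n_le / total
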