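"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (exact integer arithmetic, exhaustive
enumeration, direct formula evaluation) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import itertools
import math
from math import comb


def hypergeom_numerators(n_total: int, k_category: int, n_draw: int) -> dict[int, int]:
    """Exact integer numerators comb(K, x) * comb(N-K, n-x) over the support."""
    lo = max(0, n_draw - (n_total - k_category))
    hi = min(n_draw, k_category)
    return {x: comb(k_category, x) * comb(n_total - k_category, n_draw - x)
            for x in range(lo, hi + 1)}


def fisher_exact_p(a: int, b: int, c: int, d: int, alternative: str) -> float:
    """Fisher exact p by exact hypergeometric tail summation.

    Table [[a, b], [c, d]]; margins N = a+b+c+d, K = a+c, n = a+b.  The
    two-sided p sums every table whose exact probability is <= that of the
    observed table (integer comparison, no float ties).
    """
    n_total, k_cat, n_draw = a + b + c + d, a + c, a + b
    nums = hypergeom_numerators(n_total, k_cat, n_draw)
    denom = comb(n_total, n_draw)
    obs = nums[a]
    if alternative == "greater":
        total = sum(v for x, v in nums.items() if x >= a)
    elif alternative == "two-sided":
        total = sum(v for v in nums.values() if v <= obs)
    else:
        raise ValueError(alternative)
    return total / denom


def rank_sum_exact_p(x: list[float], y: list[float]) -> float:
    """Two-sided Mann-Whitney p by exhaustive enumeration of group labels.

    Valid for tie-free data and small groups only.
    """
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    obs_u = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    n = len(pooled)
    mean_u = n1 * (len(y)) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(obs_u - mean_u) - 1e-12:
            count += 1
    return count / total


def set_partitions(items: list):
    """Yield every partition of ``items`` as a list of lists."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def naive_modularity(nodes: list, edges: list[tuple], labels: dict) -> float:
    """Newman-Girvan modularity by the direct O(n^2) double sum."""
    m = len(edges)
    if m == 0:
        return 0.0
    adj = {(a, b) for a, b, *_ in edges} | {(b, a) for a, b, *_ in edges}
    deg = {v: 0 for v in nodes}
    for a, b, *_ in edges:
        deg[a] += 1
        deg[b] += 1
    q = 0.0
    for i in nodes:
        for j in nodes:
            if labels[i] == labels[j]:
                aij = 1.0 if (i, j) in adj else 0.0
                q += aij - deg[i] * deg[j] / (2 * m)
    return q / (2 * m)


def naive_coupled_h(net_a, net_b, aligned: set, labels: dict, kappa: float) -> float:
    """Direct evaluation of the coupled objective, independent of the package."""
    qa = naive_modularity(net_a.nodes, net_a.edges,
                          {g: labels[(net_a.layer, g)] for g in net_a.nodes})
    qb = naive_modularity(net_b.nodes, net_b.edges,
                          {g: labels[(net_b.layer, g)] for g in net_b.nodes})
    usable = [g for g in aligned
              if (net_a.layer, g) in labels and (net_b.layer, g) in labels]
    coup = 0.0
    if usable:
        same = sum(labels[(net_a.layer, g)] == labels[(net_b.layer, g)]
                   for g in usable)
        coup = kappa * same / len(usable)
    return qa + qb + coup


def km_hand(times_events: list[tuple[float, int]]) -> dict[float, float]:
    """Product-limit estimator by hand: returns S at each event time."""
    records = sorted(times_events)
    s = 1.0
    out = {}
    n_at_risk = len(records)
    i = 0
    while i < len(records):
        t = records[i][0]
        d = sum(1 for tt, e in records if tt == t and e == 1)
        n = sum(1 for tt, _ in records if tt >= t)
        if d > 0:
            s *= 1 - d / n
            out[t] = s
        i += sum(1 for tt, _ in records if tt == t)
    return out


def adjusted_rand_index(a: list[int], b: list[int]) -> float:
    """ARI by the direct contingency formula."""
    assert len(a) == len(b)
    n = len(a)
    from collections import Counter
    pairs = Counter(zip(a, b))
    rows = Counter(a)
    cols = Counter(b)
    sum_comb = sum(comb(v, 2) for v in pairs.values())
    sum_rows = sum(comb(v, 2) for v in rows.values())
    sum_cols = sum(comb(v, 2) for v in cols.values())
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total
    max_index = (sum_rows + sum_cols) / 2
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)
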