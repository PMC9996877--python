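"""Independent brute-force oracles used to cross-check the implementation.

Everything here follows the method definitions literally with explicit
loops and no shared code with the package internals.
"""

from __future__ import annotations

import numpy as np


def ssgsea_direct(expression: dict[str, float], gene_set, alpha: float) -> float:
    """Direct-summation ssGSEA ES for one sample.

    ``expression`` maps gene -> value.  Ranks are computed by counting
    (average ranks on ties); the walk visits genes in decreasing rank with
    stable tie order by insertion position, matching the documented policy.
    """
    genes = list(expression)
    values = [expression[g] for g in genes]
    n = len(genes)
    ranks = []
    for i, v in enumerate(values):
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    order = sorted(range(n), key=lambda i: (-ranks[i], i))
    in_set = [genes[i] in set(gene_set) for i in order]
    r_sorted = [ranks[i] for i in order]
    denom = sum(r_sorted[k] ** alpha for k in range(n) if in_set[k])
    n_out = n - sum(in_set)
    es = 0.0
    p_hit = 0.0
    p_miss = 0.0
    for k in range(n):
        if in_set[k]:
            p_hit += (r_sorted[k] ** alpha) / denom
        else:
            p_miss += 1.0 / n_out
        es += p_hit - p_miss
    return es


def ks_tag_direct(positions, n: int) -> float:
    """One-sided KS component by direct max over j, tie -> -b."""
    positions = sorted(positions)
    t = len(positions)
    a = max((j + 1) / t - positions[j] / n for j in range(t))
    b = max(positions[j] / n - j / t for j in range(t))
    return a if a > b else -b


def ks_connectivity_direct(up_positions, down_positions, n: int) -> float:
    ks_up = ks_tag_direct(up_positions, n)
    ks_down = ks_tag_direct(down_positions, n)
    if np.sign(ks_up) == np.sign(ks_down):
        return 0.0
    return ks_up - ks_down


def km_direct(times, events):
    """Product-limit estimate at distinct observed times, by definition."""
    pairs = sorted(zip(times, events))
    distinct = sorted(set(t for t, _ in pairs))
    s = 1.0
    out = []
    for t in distinct:
        at_risk = sum(1 for ti, _ in pairs if ti >= t)
        d = sum(1 for ti, ei in pairs if ti == t and ei == 1)
        if d:
            s *= 1 - d / at_risk
        out.append((t, at_risk, d, s))
    return out
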