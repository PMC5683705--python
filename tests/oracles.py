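"""Brute-force reference implementations used as independent oracles.

Everything here is written from the mathematical definitions with plain
loops, deliberately independent of the package's vectorized code paths.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def mi_oracle(x, y, n_bins: int) -> float:
    """Mutual information (bits) of equal-width-binned x and binary y.

    Bins are [s_k, s_{k+1}) with the last bin closed; built by scanning
    the split points one value at a time.
    """
    x = list(map(float, x))
    y = list(map(int, y))
    lo, hi = min(x), max(x)
    n = len(x)
    bins = []
    if hi == lo:
        bins = [0] * n
    else:
        splits = [lo + (hi - lo) * k / n_bins for k in range(1, n_bins)]
        for v in x:
            b = 0
            for s in splits:
                if v >= s:
                    b += 1
            bins.append(b)
    joint = {}
    for b, c in zip(bins, y):
        joint[(b, c)] = joint.get((b, c), 0) + 1
    px = {}
    py = {}
    for (b, c), cnt in joint.items():
        px[b] = px.get(b, 0) + cnt
        py[c] = py.get(c, 0) + cnt
    mi = 0.0
    for (b, c), cnt in joint.items():
        p = cnt / n
        mi += p * math.log2(p / ((px[b] / n) * (py[c] / n)))
    return max(mi, 0.0)


def bh_oracle(pvalues) -> list[float]:
    """BH adjusted values by the definition: min over j >= rank of m*p(j)/j."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos, i in enumerate(order):
        best = min(m * p[order[j]] / (j + 1) for j in range(rank_pos, m))
        adj[i] = min(best, 1.0)
    return adj


def hypergeom_tail_oracle(k: int, population: int, successes: int,
                          draws: int) -> float:
    """P(X >= k) by summing the hypergeometric pmf term by term."""
    total = 0.0
    for i in range(k, min(successes, draws) + 1):
        total += (math.comb(successes, i) * math.comb(population - successes,
                                                      draws - i)
                  / math.comb(population, draws))
    return min(total, 1.0)


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher exact p by enumerating tables with fixed margins.

    Sums the probabilities of all tables no more probable than the one
    observed (the standard 'by probability' two-sided rule).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(a_):
        b_, c_ = r1 - a_, c1 - a_
        d_ = r2 - c_
        if min(b_, c_, d_) < 0:
            return None
        return (math.comb(r1, a_) * math.comb(r2, c_)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for a_ in range(0, min(r1, c1) + 1):
        p = prob(a_)
        if p is not None and p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def connected_subgraphs(graph, max_size: int):
    """All connected induced node sets of size <= max_size (as tuples).

    Simple anchored expansion: each subgraph is generated from its
    smallest node, extending only with larger-labelled neighbors.
    """
    out = []

    def extend(sub, ext, anchor):
        out.append(tuple(sub))
        if len(sub) == max_size:
            return
        ext = list(ext)
        while ext:
            v = ext.pop()
            new_ext = ext + [u for u in graph[v]
                             if u > anchor and u not in sub and u not in ext]
            extend(sub + [v], new_ext, anchor)

    for v in sorted(graph.nodes):
        extend([v], [u for u in graph[v] if u > v], v)
    return out


def pairset_jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


def exhaustive_best_module(graph, score_fn, max_size: int):
    """Maximum score over all connected subgraphs up to ``max_size``."""
    best = -np.inf
    best_sub = None
    for sub in connected_subgraphs(graph, max_size):
        s = score_fn(sub)
        if s > best:
            best, best_sub = s, sub
    return best, best_sub
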