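"""Independent brute-force oracles used to check the package implementations.

Everything here is deliberately naive (enumeration, direct recomputation)
and shares no code with the library paths it validates.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def hypergeom_upper_tail(n_universe, n_pathway, n_draw, observed):
    """P(X >= observed) by summing the hypergeometric pmf directly."""
    total = 0.0
    for k in range(observed, min(n_pathway, n_draw) + 1):
        total += (
            comb(n_pathway, k) * comb(n_universe - n_pathway, n_draw - k)
        ) / comb(n_universe, n_draw)
    return total


def hypergeom_by_enumeration(universe, pathway, drawn_size, observed):
    """P(X >= observed) by enumerating every size-`drawn_size` subset."""
    universe = sorted(universe)
    pathway = set(pathway)
    hits = 0
    total = 0
    for combo in itertools.combinations(universe, drawn_size):
        total += 1
        if len(pathway.intersection(combo)) >= observed:
            hits += 1
    return hits / total


def fisher_one_sided_by_enumeration(table):
    """One-sided (greater in cell [0,0]) Fisher p by enumerating tables with
    the same margins."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)
            if 0 <= x <= col1 and 0 <= row1 - x <= n - col1
            else 0.0
        )

    return sum(prob(x) for x in range(a, min(row1, col1) + 1))


def signed_rank_exact_p(diffs):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4
    stat_obs = abs(w_obs - mean_w)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= stat_obs - 1e-12:
            count += 1
    return count / 2**n


def rank_sum_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group labelings."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    # midranks for ties
    order = np.argsort(pooled)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            mid = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = mid
        i = j + 1
    w_obs = ranks[:n].sum()
    mean_w = n * (n + m + 1) / 2
    stat_obs = abs(w_obs - mean_w)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        total += 1
        w = ranks[list(combo)].sum()
        if abs(w - mean_w) >= stat_obs - 1e-9:
            count += 1
    return count / total


def gsea_running_sum(ordered_hits, weights, exponent):
    """Brute-force weighted KS running sum; returns (ES, running array)."""
    n = len(ordered_hits)
    w = [abs(x) ** exponent for x in weights]
    hit_total = sum(wi for wi, h in zip(w, ordered_hits) if h)
    n_hit = sum(ordered_hits)
    n_miss = n - n_hit
    running = []
    s = 0.0
    for wi, h in zip(w, ordered_hits):
        if h:
            s += wi / hit_total if hit_total > 0 else 1.0 / n_hit
        else:
            s -= 1.0 / n_miss
        running.append(s)
    rmax, rmin = max(running), min(running)
    es = rmax if rmax >= -rmin - 1e-12 else rmin  # positive wins (near-)ties
    return es, running


def auroc_trapezoid(labels, scores):
    """AUROC by sorting scores and walking the ROC steps (ties averaged)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for s in pos:
        wins += np.sum(s > neg) + 0.5 * np.sum(s == neg)
    return wins / (len(pos) * len(neg))


def degree_filter_bruteforce(edge_pairs, max_degree):
    """Single-pass filter: drop metabolites with > max_degree distinct
    partners, then drop proteins left without partners. Returns pair set."""
    met_partners = {}
    for m, p in edge_pairs:
        met_partners.setdefault(m, set()).add(p)
    keep_m = {m for m, ps in met_partners.items() if len(ps) <= max_degree}
    return {(m, p) for m, p in edge_pairs if m in keep_m}


def deltam_bruteforce(edges, log2fc):
    """Edge-scan deltaM: edges are (met, prot, role) triples."""
    by_met = {}
    for m, p, role in edges:
        by_met.setdefault(m, []).append((p, role))
    out = {}
    for m, partners in by_met.items():
        up = sorted({p for p, r in partners if r in ("product", "both")})
        down = sorted({p for p, r in partners if r in ("substrate", "both")})
        du = sum(log2fc[p] for p in up if p in log2fc)
        dd = sum(log2fc[p] for p in down if p in log2fc)
        out[m] = du - dd
    return out
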