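"""Brute-force reference implementations used only as test oracles.

Each function here is written in the most literal way possible (loops, set
algebra, textbook formulas) and stays independent of the package code paths
it checks.
"""

from itertools import combinations

import numpy as np


def groupby_mean(protein_ids, intensities):
    """Protein means via an explicit dict-of-lists loop."""
    groups = {}
    for pep, prot in protein_ids.items():
        groups.setdefault(prot, []).append(intensities.loc[pep])
    return {
        prot: np.mean(np.vstack(rows), axis=0) for prot, rows in groups.items()
    }


def bh_stepup(p):
    """Benjamini-Hochberg by the literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def welch_t(a, b):
    """Welch two-sample t and its Satterthwaite p-value, textbook formulas."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def upgma_cophenetic(dist):
    """Average-linkage agglomeration by hand; returns the cophenetic matrix
    and the sorted merge heights."""
    n = dist.shape[0]
    members = {i: [i] for i in range(n)}
    d = {
        frozenset((i, j)): float(dist[i, j]) for i, j in combinations(range(n), 2)
    }
    coph = np.zeros((n, n))
    active = list(range(n))
    next_id = n
    heights = []
    while len(active) > 1:
        h, a, b = min(
            (d[frozenset((a, b))], a, b)
            for a, b in combinations(sorted(active), 2)
        )
        heights.append(h)
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = h
        na, nb = len(members[a]), len(members[b])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((next_id, c))] = (
                na * d[frozenset((a, c))] + nb * d[frozenset((b, c))]
            ) / (na + nb)
        members[next_id] = members[a] + members[b]
        active.remove(a)
        active.remove(b)
        active.append(next_id)
        next_id += 1
    return coph, sorted(heights)


def ks_enrichment(hit_positions, n_total):
    """Classical (unweighted) KS running statistic on hit positions:
    signed extremum of hits-so-far/Nh - misses-so-far/(N - Nh)."""
    hits = set(hit_positions)
    nh = len(hits)
    running = []
    cum = 0.0
    for i in range(n_total):
        if i in hits:
            cum += 1.0 / nh
        else:
            cum -= 1.0 / (n_total - nh)
        running.append(cum)
    running = np.array(running)
    return running[np.argmax(np.abs(running))]


def signal_to_noise(a, b, floor_rel=0.2, floor_abs=0.2):
    """Signal-to-noise per the plain formula with SD floors."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    mu_a, mu_b = a.mean(), b.mean()
    s_a = max(a.std(ddof=1), floor_rel * abs(mu_a), floor_abs)
    s_b = max(b.std(ddof=1), floor_rel * abs(mu_b), floor_abs)
    return (mu_a - mu_b) / (s_a + s_b)


def venn_regions(sets):
    """All exclusive Venn regions of named sets by direct set algebra."""
    names = list(sets)
    out = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            rest = [sets[c] for c in names if c not in combo]
            out[frozenset(combo)] = inside.difference(*rest) if rest else inside
    return out
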