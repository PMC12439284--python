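"""Independent reference implementations used to validate the package.

Everything here is deliberately naive -- brute-force enumeration, O(n^3)
loops, direct transcription of textbook formulas -- and shares no code with
the implementations under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- dyad IBD-mode likelihoods by generative enumeration --------------------


def enumerate_mode_probs(g1, g2, alleles, probs, null_allele=None):
    """P(observed pair | IBD mode 0/1/2) by summing over every allele draw.

    Mode 0 draws four independent alleles; mode 1 draws a shared allele plus
    one free allele per genotype; mode 2 draws two alleles copied into both.
    When ``null_allele`` is given, the drawn true genotypes are mapped to
    apparent genotypes (null homozygote -> unobservable, skipped; null het ->
    apparent homozygote) and draws matching the observed pair are summed.
    """
    alleles = list(alleles)
    probs = dict(zip(alleles, probs))

    def apparent(t):
        a, b = t
        if null_allele is None:
            return tuple(sorted(t))
        if a == null_allele and b == null_allele:
            return None
        if a == null_allele:
            return (b, b)
        if b == null_allele:
            return (a, a)
        return tuple(sorted(t))

    g1 = tuple(sorted(g1))
    g2 = tuple(sorted(g2))

    def match(t1, t2):
        return apparent(t1) == g1 and apparent(t2) == g2

    p0 = p1 = p2 = 0.0
    for w, x, y, z in itertools.product(alleles, repeat=4):
        if match((w, x), (y, z)):
            p0 += probs[w] * probs[x] * probs[y] * probs[z]
    for s, x, y in itertools.product(alleles, repeat=3):
        if match((s, x), (s, y)):
            p1 += probs[s] * probs[x] * probs[y]
    for x, y in itertools.product(alleles, repeat=2):
        if match((x, y), (x, y)):
            p2 += probs[x] * probs[y]
    return p0, p1, p2


def enumerate_sib_pair_distribution(p):
    """Exact distribution of an (ordered) full-sib genotype pair at one
    biallelic locus with allele frequencies ``p = (pA, pB)``, by enumeration
    of parental genotypes and meioses. Genotypes are sorted allele tuples."""
    alleles = [0, 1]
    dist: dict[tuple, float] = {}
    for m1, m2, f1, f2 in itertools.product(alleles, repeat=4):
        pg = p[m1] * p[m2] * p[f1] * p[f2]
        for a1, b1, a2, b2 in itertools.product(range(2), repeat=4):
            child1 = tuple(sorted(((m1, m2)[a1], (f1, f2)[b1])))
            child2 = tuple(sorted(((m1, m2)[a2], (f1, f2)[b2])))
            dist[(child1, child2)] = dist.get((child1, child2), 0.0) + pg / 16.0
    return dist


# -- naive average-linkage clustering ---------------------------------------


def naive_upgma(dist):
    """O(n^3) average linkage recomputing every inter-cluster mean each step.

    Ties broken by the lowest smallest original member. Returns the merge
    list [(frozenset_left, frozenset_right, height), ...] root-last.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            h = np.mean([dist[i, j] for i in ca for j in cb])
            key = (h, min(min(ca), min(cb)))
            if best is None or key < best[0]:
                best = (key, a, b, h)
        _, a, b, h = best
        ca, cb = clusters[a], clusters[b]
        merges.append((ca, cb, h))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(ca | cb)
    return merges


def scan_passing_clusters(merges, rm_matrix, threshold):
    """Exhaustive scan of every merge node for maximal clusters whose
    cross-children mean relatedness passes the threshold: a node passes if
    its own cross mean >= threshold and no ancestor node passes."""
    passing = []
    for ca, cb, _h in merges:
        mean_r = np.mean([rm_matrix[i, j] for i in ca for j in cb])
        if mean_r >= threshold:
            passing.append(ca | cb)
    maximal = [
        s for s in passing
        if not any(s < t for t in passing)
    ]
    return sorted(maximal, key=min)


# -- rank tests by direct formula -------------------------------------------


def rankdata_avg(values):
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kw_hand(values, groups):
    """Kruskal-Wallis H with tie correction, written from the rank formula."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    N = len(values)
    ranks = rankdata_avg(values)
    h = 0.0
    for g in np.unique(groups):
        sel = groups == g
        h += sel.sum() * (ranks[sel].mean() - (N + 1) / 2.0) ** 2
    h *= 12.0 / (N * (N + 1))
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return h / correction


def dunn_hand(values, groups, g1, g2):
    """Dunn z for one group pair from mean ranks and the tie-corrected SE."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    N = len(values)
    ranks = rankdata_avg(values)
    r1 = ranks[groups == g1].mean()
    r2 = ranks[groups == g2].mean()
    n1 = (groups == g1).sum()
    n2 = (groups == g2).sum()
    _, counts = np.unique(values, return_counts=True)
    ties = np.sum(counts**3 - counts)
    var = (N * (N + 1) / 12.0 - ties / (12.0 * (N - 1))) * (1 / n1 + 1 / n2)
    return (r1 - r2) / math.sqrt(var)


def holm_stepdown(pvals):
    """Holm adjustment straight from its step-down definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adjusted[i] = min(running, 1.0)
    return adjusted


# -- Hardy-Weinberg exact p by full enumeration (biallelic) -----------------


def hwe_exact_biallelic(n_aa, n_ab, n_bb):
    """Exact conditional HWE p-value for a biallelic table by enumerating
    every heterozygote count compatible with the observed allele counts."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab

    def log_prob(h):
        aa = (na - h) // 2
        bb = n - aa - h
        return (
            math.lgamma(n + 1)
            - math.lgamma(aa + 1)
            - math.lgamma(h + 1)
            - math.lgamma(bb + 1)
            + h * math.log(2.0)
            + math.lgamma(na + 1)
            + math.lgamma(2 * n - na + 1)
            - math.lgamma(2 * n + 1)
        )

    feasible = [
        h for h in range(na % 2, min(na, 2 * n - na) + 1, 2)
        if (na - h) // 2 >= 0 and n - (na - h) // 2 - h >= 0
    ]
    probs = {h: math.exp(log_prob(h)) for h in feasible}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


# -- Weir & Cockerham f, independent transcription --------------------------


def wc_f_hand(genotypes):
    """W&C (1984) within-sample f from the per-allele b and c components,
    transcribed independently; ``genotypes`` is an (n, 2) allele array."""
    g = np.asarray(genotypes)
    n = len(g)
    sb = sc = 0.0
    for allele in np.unique(g):
        dose = (g == allele).sum(axis=1)
        p = dose.sum() / (2 * n)
        hbar = np.mean(dose == 1)
        sb += n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
        sc += hbar / 2.0
    return 1.0 - sc / (sb + sc)
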