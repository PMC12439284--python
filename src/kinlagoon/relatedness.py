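"""Maximum-likelihood pairwise relatedness for codominant markers.

For a non-inbred dyad the genotype pair at a locus depends on the IBD-mode
probabilities k = (k0, k1, k2): the chances of sharing 0, 1 or 2 alleles
identical by descent. Relatedness is r = k2 + k1/2. Per locus we compute
(a, b, c) = P(observed pair | mode 0/1/2) under Hardy-Weinberg proportions,
then maximise the multilocus likelihood

    L(k) = prod_l (k0 * a_l + k1 * b_l + k2 * c_l)

over the probability simplex with an EM algorithm (dense grid search is
available as a cross-check). Null alleles are handled by (i) estimating a
per-locus null-allele frequency by EM from apparent-homozygote excess, and
(ii) marginalising each observed apparent genotype over the true genotypes
compatible with it (an apparent homozygote may be a visible/null
heterozygote) before conditioning on the IBD mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io import MISSING, GenotypeMatrix

#: sentinel label for the (invisible) null allele
NULL = -1

#: interior starting point for the EM on the k-simplex
_K_START = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


@dataclass
class LocusFrequencies:
    """Visible-allele frequencies plus the null-allele frequency at one locus.

    Invariant: sum(freqs) + null_freq == 1 (within 1e-10), null_freq in [0, 1).
    """

    locus: str
    alleles: np.ndarray
    freqs: np.ndarray
    null_freq: float = 0.0

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.alleles.shape != self.freqs.shape:
            raise ValueError("alleles and freqs must have the same length")
        if np.any(self.freqs < -1e-12) or not 0 <= self.null_freq < 1:
            raise ValueError("frequencies must be nonnegative, null_freq in [0,1)")
        total = float(self.freqs.sum()) + self.null_freq
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"frequencies at {self.locus} sum to {total}, not 1")

    def freq_map(self) -> dict[int, float]:
        """Allele label -> frequency, including the null allele when present."""
        fm = {int(a): float(p) for a, p in zip(self.alleles, self.freqs)}
        if self.null_freq > 0:
            fm[NULL] = self.null_freq
        return fm

    def expected_heterozygosity(self) -> float:
        """1 - sum p^2 over visible alleles renormalised to the visible pool."""
        p = self.freqs / self.freqs.sum()
        return float(1.0 - np.sum(p**2))


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise ML relatedness with per-pair locus counts.

    ``r`` is (n, n) with NaN on the diagonal and for pairs sharing no typed
    locus; ``n_loci`` counts the loci both members have scored.
    """

    ids: list[str]
    r: np.ndarray
    n_loci: np.ndarray
    low_confidence_min_loci: int = 5

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.r = np.asarray(self.r, dtype=float)
        self.n_loci = np.asarray(self.n_loci, dtype=np.int64)
        if self.r.shape != (n, n) or self.n_loci.shape != (n, n):
            raise ValueError("matrix shapes must be (n, n)")
        off = ~np.eye(n, dtype=bool)
        vals = self.r[off]
        vals = vals[np.isfinite(vals)]
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValueError("relatedness values outside [0, 1]")
        if not np.allclose(self.r, self.r.T, equal_nan=True):
            raise ValueError("relatedness matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) values in scipy condensed order."""
        return self.r[np.triu_indices(self.n, 1)]

    def pair_r(self, id1: str, id2: str) -> float:
        i, j = self.ids.index(id1), self.ids.index(id2)
        return float(self.r[i, j])

    def low_confidence_mask(self) -> np.ndarray:
        """Pairs sharing fewer typed loci than the configured minimum."""
        mask = self.n_loci < self.low_confidence_min_loci
        np.fill_diagonal(mask, False)
        return mask

    def subset(self, ids: Sequence[str]) -> "RelatednessMatrix":
        rows = [self.ids.index(s) for s in ids]
        ix = np.ix_(rows, rows)
        return RelatednessMatrix(
            list(ids), self.r[ix].copy(), self.n_loci[ix].copy(),
            self.low_confidence_min_loci,
        )


# -- allele-frequency estimation -------------------------------------------


def _counting_frequencies(gm: GenotypeMatrix, j: int) -> tuple[np.ndarray, np.ndarray]:
    obs = gm.locus_alleles(j)
    if obs.size < 4:
        raise ValueError(f"locus {gm.loci[j]}: fewer than 2 typed individuals")
    alleles, counts = np.unique(obs, return_counts=True)
    return alleles, counts / counts.sum()


def estimate_frequencies_em(
    gm: GenotypeMatrix,
    with_null: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
    missing_as_null: float = 0.0,
) -> list[LocusFrequencies]:
    """Per-locus allele frequencies, optionally with a null allele by EM.

    Without the null component the estimates are plain allele counts. With it,
    each apparent homozygote AA is treated in the E-step as a mixture of the
    true homozygote AA (weight p_A / (p_A + 2*p0)) and the visible-by-null
    heterozygote A0; a share ``missing_as_null`` of the missing cells enters
    as null homozygotes. The M-step re-normalises expected allele counts, so
    the iteration maximises the HWE likelihood of the apparent genotypes.
    Non-convergence within ``max_iter`` warns and returns the last iterate.
    """
    if not 0 <= missing_as_null <= 1:
        raise ValueError("missing_as_null must be in [0, 1]")
    out: list[LocusFrequencies] = []
    for j, locus in enumerate(gm.loci):
        alleles, p_count = _counting_frequencies(gm, j)
        if not with_null:
            out.append(LocusFrequencies(locus, alleles, p_count, 0.0))
            continue
        col = gm.alleles[:, j, :]
        typed = col[col[:, 0] != MISSING]
        n_missing = gm.n_individuals - len(typed)
        het = typed[typed[:, 0] != typed[:, 1]]
        hom = typed[typed[:, 0] == typed[:, 1], 0]
        index = {int(a): i for i, a in enumerate(alleles)}
        het_counts = np.zeros(len(alleles))
        for a in het.ravel():
            het_counts[index[int(a)]] += 1
        hom_alleles, hom_n = np.unique(hom, return_counts=True)
        hom_idx = np.array([index[int(a)] for a in hom_alleles], dtype=int)
        m_eff = missing_as_null * n_missing

        p0 = 0.05
        p = p_count * (1 - p0)
        for _ in range(max_iter):
            counts = het_counts.copy()
            null_count = 2.0 * m_eff
            if hom_idx.size:
                pa = p[hom_idx]
                w = np.where(pa + 2 * p0 > 0, pa / (pa + 2 * p0), 1.0)
                counts[hom_idx] += hom_n * (1 + w)
                null_count += float(np.sum(hom_n * (1 - w)))
            total = 2.0 * (len(typed) + m_eff)
            p_new = counts / total
            p0_new = null_count / total
            delta = max(float(np.max(np.abs(p_new - p))), abs(p0_new - p0))
            p, p0 = p_new, p0_new
            if delta < tol:
                break
        else:
            warnings.warn(
                f"null-allele EM did not converge at locus {locus}", RuntimeWarning
            )
        # guard against tiny negative drift from float cancellation
        p0 = max(p0, 0.0)
        scale = p.sum() + p0
        out.append(LocusFrequencies(locus, alleles, p / scale, p0 / scale))
    return out


def frequency_loglik(
    gm: GenotypeMatrix, j: int, lf: LocusFrequencies, missing_as_null: float = 0.0
) -> float:
    """HWE log-likelihood of apparent genotypes at locus column j.

    The objective the null-allele EM climbs: apparent heterozygotes have
    probability 2*p_a*p_b, apparent homozygotes p_a^2 + 2*p_a*p0, and a share
    ``missing_as_null`` of missing cells counts as null homozygotes (p0^2).
    """
    fm = {int(a): float(p) for a, p in zip(lf.alleles, lf.freqs)}
    p0 = lf.null_freq
    col = gm.alleles[:, j, :]
    ll = 0.0
    n_missing = 0
    for a, b in col:
        if a == MISSING:
            n_missing += 1
            continue
        if a == b:
            ll += float(np.log(fm[int(a)] ** 2 + 2 * fm[int(a)] * p0))
        else:
            ll += float(np.log(2 * fm[int(a)] * fm[int(b)]))
    if missing_as_null > 0 and n_missing and p0 > 0:
        ll += missing_as_null * n_missing * 2 * float(np.log(p0))
    return ll


# -- dyad IBD-mode likelihoods ---------------------------------------------


def _compatible_true(genotype: tuple[int, int], null_freq: float):
    """True genotypes compatible with an observed apparent genotype.

    A het (a, b) can only be the true het. An apparent homozygote (a, a) can
    be the true homozygote or, when a null allele segregates, the (null, a)
    heterozygote. True genotypes are unordered tuples with NULL sorted first.
    """
    a, b = genotype
    if a != b:
        return [(a, b)]
    if null_freq > 0:
        return [(a, a), (NULL, a)]
    return [(a, a)]


def _hwe_prob(t: tuple[int, int], fm: dict[int, float]) -> float:
    a, b = t
    return fm[a] * fm[b] * (1.0 if a == b else 2.0)


def _one_ibd_prob(t1: tuple[int, int], t2: tuple[int, int], fm: dict[int, float]) -> float:
    """P(true pair | exactly one allele shared IBD).

    Generative sum over the shared allele s (population draw) and the two
    free alleles: the shared allele must appear in both genotypes; the free
    allele of each genotype is then forced to its remaining allele.
    """

    def remaining(t: tuple[int, int], s: int) -> float:
        u, v = t
        if u == v:
            return fm[u] if u == s else 0.0
        if s == u:
            return fm[v]
        if s == v:
            return fm[u]
        return 0.0

    total = 0.0
    for s in set(t1) & set(t2):
        total += fm[s] * remaining(t1, s) * remaining(t2, s)
    return total


def dyad_mode_likelihoods(
    g1: tuple[int, int], g2: tuple[int, int], lf: LocusFrequencies
) -> tuple[float, float, float]:
    """(a, b, c) = P(observed genotype pair | 0, 1, 2 alleles shared IBD).

    Both genotypes must be scored at the locus. With a positive null-allele
    frequency each observed apparent genotype is marginalised over its
    compatible true genotypes before conditioning on the IBD mode.
    """
    if MISSING in g1 or MISSING in g2:
        raise ValueError("dyad_mode_likelihoods requires both genotypes scored")
    fm = lf.freq_map()
    for allele in (*g1, *g2):
        if allele not in fm:
            raise ValueError(
                f"allele {allele} absent from frequencies at locus {lf.locus}; "
                "estimate frequencies on the same genotype matrix"
            )
    g1 = (min(g1), max(g1))
    g2 = (min(g2), max(g2))
    a = b = c = 0.0
    for t1 in _compatible_true(g1, lf.null_freq):
        p1 = _hwe_prob(t1, fm)
        for t2 in _compatible_true(g2, lf.null_freq):
            a += p1 * _hwe_prob(t2, fm)
            b += _one_ibd_prob(t1, t2, fm)
            if t1 == t2:
                c += p1
    return a, b, c


# -- multilocus ML over the k-simplex --------------------------------------


def em_k_coefficients(
    abc: np.ndarray, tol: float = 1e-8, max_iter: int = 2000
) -> np.ndarray:
    """Maximise the dyad likelihood over k for one pair.

    ``abc`` is (n_loci, 3). Multiplicative EM updates from the interior start
    (1/3, 1/3, 1/3); each update replaces k_m by the mean posterior
    probability of mode m across loci, which monotonically increases L(k).
    """
    return _em_block(abc[None, :, :], np.ones((1, abc.shape[0]), bool), tol, max_iter)[0]


def _em_block(
    X: np.ndarray, W: np.ndarray, tol: float, max_iter: int
) -> np.ndarray:
    """Vectorised simplex EM for a block of pairs.

    X: (n_pairs, n_loci, 3) mode likelihoods (untyped loci arbitrary),
    W: (n_pairs, n_loci) typed-locus mask. Returns k (n_pairs, 3).
    """
    n_pairs = X.shape[0]
    k = np.tile(np.asarray(_K_START), (n_pairs, 1))
    nl = W.sum(axis=1).astype(float)
    active = nl > 0
    Xw = X * W[:, :, None]
    for _ in range(max_iter):
        if not active.any():
            break
        ka = k[active]
        num = Xw[active] * ka[:, None, :]  # (p, l, 3)
        denom = num.sum(axis=2)
        denom[denom <= 0] = 1.0  # untyped or impossible locus: no contribution
        post = num / denom[:, :, None]
        k_new = post.sum(axis=1) / nl[active, None]
        delta = np.abs(k_new - ka).max(axis=1)
        k[active] = k_new
        still = delta >= tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    return k


def grid_k_coefficients(abc: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Dense grid search over the k-simplex; cross-check for the EM route."""
    k0 = np.arange(0.0, 1.0 + step / 2, step)
    grid = []
    for a0 in k0:
        k1s = np.arange(0.0, 1.0 - a0 + step / 2, step)
        for a1 in k1s:
            grid.append((a0, a1, max(1.0 - a0 - a1, 0.0)))
    G = np.asarray(grid)
    with np.errstate(divide="ignore"):
        ll = np.log(np.clip(abc @ G.T, 1e-300, None)).sum(axis=0)
    return G[int(np.argmax(ll))]


def relatedness_from_k(k: np.ndarray) -> np.ndarray:
    """r = k2 + k1/2."""
    k = np.asarray(k, dtype=float)
    return k[..., 2] + 0.5 * k[..., 1]


def _locus_pair_tables(
    gm: GenotypeMatrix, freqs: Sequence[LocusFrequencies]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per locus: genotype codes per individual and the (a,b,c) lookup table.

    Codes are -1 for missing; tables are (K, K, 3) computed once per unique
    genotype pair, which keeps the full-matrix likelihood linear in pairs.
    """
    codes_per_locus: list[np.ndarray] = []
    tables: list[np.ndarray] = []
    for j, lf in enumerate(freqs):
        col = [tuple(gt) for gt in gm.alleles[:, j, :]]
        uniq = sorted({g for g in col if g[0] != MISSING})
        code_of = {g: i for i, g in enumerate(uniq)}
        codes = np.array(
            [code_of.get(g, -1) for g in col], dtype=np.int64
        )
        K = len(uniq)
        table = np.empty((K, K, 3), dtype=float)
        for i1, ga in enumerate(uniq):
            for i2 in range(i1, K):
                gb = uniq[i2]
                table[i1, i2] = table[i2, i1] = dyad_mode_likelihoods(ga, gb, lf)
        codes_per_locus.append(codes)
        tables.append(table)
    return codes_per_locus, tables


def ml_relatedness(
    gm: GenotypeMatrix,
    freqs: Sequence[LocusFrequencies],
    method: str = "em",
    tol: float = 1e-8,
    max_iter: int = 2000,
    grid_step: float = 0.01,
    min_loci: int = 5,
    block_size: int = 20000,
) -> RelatednessMatrix:
    """Full pairwise ML relatedness matrix.

    Frequencies must come from the same (post-filter) genotype matrix so every
    observed allele has a frequency. Pairs sharing no typed locus get NaN;
    pairs sharing fewer than ``min_loci`` are flagged low-confidence but still
    estimated. ``method`` is "em" (default) or "grid".
    """
    if method not in ("em", "grid"):
        raise ValueError("method must be 'em' or 'grid'")
    if len(freqs) != gm.n_loci:
        raise ValueError("one LocusFrequencies per locus required")
    n, L = gm.n_individuals, gm.n_loci
    codes_per_locus, tables = _locus_pair_tables(gm, freqs)
    iu, ju = np.triu_indices(n, 1)
    n_pairs = iu.size
    r_cond = np.full(n_pairs, np.nan)
    nl_cond = np.zeros(n_pairs, dtype=np.int64)

    for start in range(0, n_pairs, block_size):
        sl = slice(start, min(start + block_size, n_pairs))
        bi, bj = iu[sl], ju[sl]
        m = bi.size
        X = np.ones((m, L, 3))
        W = np.zeros((m, L), dtype=bool)
        for l in range(L):
            ci, cj = codes_per_locus[l][bi], codes_per_locus[l][bj]
            typed = (ci >= 0) & (cj >= 0)
            if typed.any():
                X[typed, l, :] = tables[l][ci[typed], cj[typed]]
                W[:, l] = typed
        # per-locus scaling keeps products away from underflow; the MLE of k
        # is invariant to it
        scale = X.max(axis=2, keepdims=True)
        scale[scale <= 0] = 1.0
        X /= scale
        nl = W.sum(axis=1)
        if method == "em":
            k = _em_block(X, W, tol, max_iter)
        else:
            k = np.vstack(
                [grid_k_coefficients(X[p][W[p]], grid_step) for p in range(m)]
            )
        r_blk = relatedness_from_k(k)
        r_blk[nl == 0] = np.nan
        r_cond[sl] = r_blk
        nl_cond[sl] = nl

    r = np.full((n, n), np.nan)
    nloci = np.zeros((n, n), dtype=np.int64)
    r[iu, ju] = r_cond
    r[ju, iu] = r_cond
    nloci[iu, ju] = nl_cond
    nloci[ju, iu] = nl_cond
    return RelatednessMatrix(list(gm.ids), r, nloci, low_confidence_min_loci=min_loci)


def dyad_relatedness(
    g1: np.ndarray,
    g2: np.ndarray,
    freqs: Sequence[LocusFrequencies],
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> np.ndarray:
    """ML relatedness for a batch of pre-paired dyads.

    ``g1``/``g2`` are (n_dyads, n_loci, 2) apparent-genotype arrays (as from
    the dyad simulator); loci with either member missing are skipped. Mode
    likelihoods are cached per unique genotype pair per locus.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    n, L = g1.shape[0], g1.shape[1]
    if g2.shape != g1.shape or L != len(freqs):
        raise ValueError("dyad arrays must be (n, n_loci, 2) and match freqs")
    X = np.ones((n, L, 3))
    W = np.zeros((n, L), dtype=bool)
    for j, lf in enumerate(freqs):
        cache: dict[tuple, tuple[float, float, float]] = {}
        for d in range(n):
            a = (int(g1[d, j, 0]), int(g1[d, j, 1]))
            b = (int(g2[d, j, 0]), int(g2[d, j, 1]))
            if a[0] == MISSING or b[0] == MISSING:
                continue
            key = (a, b) if a <= b else (b, a)
            if key not in cache:
                cache[key] = dyad_mode_likelihoods(key[0], key[1], lf)
            X[d, j] = cache[key]
            W[d, j] = True
    scale = X.max(axis=2, keepdims=True)
    scale[scale <= 0] = 1.0
    X /= scale
    k = _em_block(X, W, tol, max_iter)
    r = relatedness_from_k(k)
    r[W.sum(axis=1) == 0] = np.nan
    return r


def pair_log_likelihood(abc: np.ndarray, k: np.ndarray) -> float:
    """Multilocus log L(k) for one pair; abc is (n_loci, 3)."""
    mix = abc @ np.asarray(k, dtype=float)
    return float(np.log(np.clip(mix, 1e-300, None)).sum())


# -- duplicate removal ------------------------------------------------------


def remove_duplicates(
    rm: RelatednessMatrix, gm: GenotypeMatrix, threshold: float = 0.95
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Collapse putative repeat samples (pairs with r above ``threshold``).

    Pairs above the threshold define a graph; within each connected component
    exactly one individual is kept -- the one with fewest missing loci, ties
    broken by lexicographically smallest id. Returns the retained ids (input
    order) and the list of above-threshold pairs (id1, id2, r).
    """
    if rm.ids != list(gm.ids):
        raise ValueError("relatedness matrix and genotype matrix ids differ")
    n = rm.n
    iu, ju = np.triu_indices(n, 1)
    with np.errstate(invalid="ignore"):
        hit = rm.r[iu, ju] > threshold
    pairs = [
        (rm.ids[i], rm.ids[j], float(rm.r[i, j]))
        for i, j in zip(iu[hit], ju[hit])
    ]
    if not pairs:
        return list(rm.ids), []
    rows = iu[hit]
    cols = ju[hit]
    graph = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    missing = gm.missing_loci_count()
    drop: set[str] = set()
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        if members.size < 2:
            continue
        keep = min(members, key=lambda i: (missing[i], rm.ids[i]))
        drop.update(rm.ids[i] for i in members if i != keep)
    retained = [s for s in rm.ids if s not in drop]
    return retained, pairs
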