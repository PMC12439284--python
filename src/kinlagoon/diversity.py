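"""Per-locus diversity statistics for a single population sample.

Covers allele counts, observed and expected heterozygosity, a Monte-Carlo
exact Hardy-Weinberg test conditional on the observed allele counts, the
Weir & Cockerham (1984) within-population inbreeding coefficient f (F_IS)
with a permutation p-value, and the Holm ("sequential Bonferroni") step-down
multiple-testing adjustment. Missing genotypes are excluded locus-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

#: returned by tests that cannot be run (e.g. monomorphic locus)
NOT_TESTABLE = None


@dataclass
class LocusSummary:
    locus: str
    n_typed: int
    Na: int
    Ho: float
    He: float
    He_unbiased: float
    hwe_p: float | None = NOT_TESTABLE
    Fis: float | None = None


def _typed_genotypes(gm: GenotypeMatrix, j: int) -> np.ndarray:
    col = gm.alleles[:, j, :]
    return col[col[:, 0] != MISSING]


def locus_summary(gm: GenotypeMatrix) -> list[LocusSummary]:
    """Na, Ho and He per locus.

    He is the uncorrected 1 - sum p_i^2 from sample allele frequencies (the
    GenAlEx convention); the small-sample unbiased variant (2n/(2n-1) factor)
    is reported alongside but not used downstream. Degenerate loci (no typed
    individuals, or monomorphic) are flagged, not fatal.
    """
    out = []
    for j, locus in enumerate(gm.loci):
        typed = _typed_genotypes(gm, j)
        n = len(typed)
        if n == 0:
            out.append(LocusSummary(locus, 0, 0, float("nan"), float("nan"), float("nan")))
            continue
        alleles, counts = np.unique(typed, return_counts=True)
        p = counts / counts.sum()
        he = float(1.0 - np.sum(p**2))
        he_u = he * (2 * n) / (2 * n - 1) if n > 1 else float("nan")
        ho = float(np.mean(typed[:, 0] != typed[:, 1]))
        out.append(LocusSummary(locus, n, len(alleles), ho, he, he_u))
    return out


def summary_frame(summaries: list[LocusSummary]) -> pd.DataFrame:
    df = pd.DataFrame([vars(s) for s in summaries]).set_index("locus")
    return df


# -- Hardy-Weinberg exact test ---------------------------------------------


def _log_table_prob(genotype_counts: dict[tuple[int, int], int],
                    allele_counts: dict[int, int], n: int) -> float:
    """Levene's conditional probability of a genotype table given allele counts.

    log P = log n! + sum_a log n_a! - log (2n)! + h log 2 - sum_g log n_g!
    with h the number of heterozygous individuals.
    """
    h = sum(c for (a, b), c in genotype_counts.items() if a != b)
    lp = math.lgamma(n + 1) - math.lgamma(2 * n + 1) + h * math.log(2.0)
    for c in allele_counts.values():
        lp += math.lgamma(c + 1)
    for c in genotype_counts.values():
        lp -= math.lgamma(c + 1)
    return lp


def _genotype_counts(pairs: np.ndarray) -> dict[tuple[int, int], int]:
    pairs = np.sort(pairs, axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return {(int(a), int(b)): int(c) for (a, b), c in zip(uniq, counts)}


def hwe_exact_test(
    gm: GenotypeMatrix, locus: str, n_mc: int = 100_000, seed: int | None = None
) -> float | None:
    """Monte-Carlo exact Hardy-Weinberg test at one locus.

    Conditions on the observed allele counts: observed alleles are randomly
    re-paired into genotypes ``n_mc`` times and the fraction of tables at
    least as improbable (conditional probability <= observed, within float
    slack) is reported with the observed table included in the tally, so the
    p-value is always positive. Monomorphic loci are not testable (None).
    """
    j = gm.loci.index(locus)
    typed = _typed_genotypes(gm, j)
    if len(typed) < 2:
        return NOT_TESTABLE
    alleles, counts = np.unique(typed, return_counts=True)
    if len(alleles) < 2:
        return NOT_TESTABLE
    n = len(typed)
    allele_counts = {int(a): int(c) for a, c in zip(alleles, counts)}
    lp_obs = _log_table_prob(_genotype_counts(typed), allele_counts, n)
    rng = np.random.default_rng(seed)
    pool = typed.ravel().copy()
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        lp = _log_table_prob(_genotype_counts(pool.reshape(-1, 2)), allele_counts, n)
        if lp <= lp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_mc + 1)


# -- Weir & Cockerham F_IS --------------------------------------------------


def _wc_components(typed: np.ndarray) -> tuple[float, float]:
    """Sums over alleles of the W&C (1984) single-sample variance components.

    Returns (sum_b, sum_c) where, per allele A with sample frequency p and
    observed heterozygote frequency h (fraction of individuals carrying A
    heterozygously), b = n/(n-1) * [p(1-p) - (2n-1)/(4n) h] and c = h/2.
    f = 1 - sum_c / (sum_b + sum_c).
    """
    n = len(typed)
    alleles = np.unique(typed)
    sum_b = sum_c = 0.0
    for a in alleles:
        carry = typed == a
        p = carry.sum() / (2 * n)
        h = np.mean(carry.sum(axis=1) == 1)
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        sum_b += b
        sum_c += h / 2
    return sum_b, sum_c


def fis_weir_cockerham(
    gm: GenotypeMatrix,
    n_perm: int = 0,
    seed: int | None = None,
) -> tuple[dict[str, float | None], float, float | None]:
    """Weir & Cockerham f (F_IS) per locus and multilocus.

    The multilocus value is the ratio of variance components summed across
    loci. With ``n_perm`` > 0, a permutation p-value is computed by shuffling
    alleles among individuals within each locus (destroying within-individual
    correlation while fixing allele counts); one-sided for heterozygote
    deficit (f_perm >= f_obs), with the observed value included in the tally.
    Monomorphic loci are undefined (None) and excluded from the sums.
    """
    per_locus: dict[str, float | None] = {}
    tot_b = tot_c = 0.0
    typed_cols = []
    for j, locus in enumerate(gm.loci):
        typed = _typed_genotypes(gm, j)
        if len(typed) < 2 or len(np.unique(typed)) < 2:
            per_locus[locus] = None
            continue
        b, c = _wc_components(typed)
        per_locus[locus] = 1.0 - c / (b + c) if (b + c) != 0 else None
        tot_b += b
        tot_c += c
        typed_cols.append(typed)
    if tot_b + tot_c == 0:
        raise ValueError("F_IS undefined: no polymorphic locus")
    f_multi = 1.0 - tot_c / (tot_b + tot_c)
    if n_perm <= 0:
        return per_locus, f_multi, None
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        pb = pc = 0.0
        for typed in typed_cols:
            pool = typed.ravel().copy()
            rng.shuffle(pool)
            b, c = _wc_components(pool.reshape(-1, 2))
            pb += b
            pc += c
        f_perm = 1.0 - pc / (pb + pc) if (pb + pc) != 0 else 0.0
        if f_perm >= f_multi - 1e-12:
            hits += 1
    return per_locus, f_multi, (hits + 1) / (n_perm + 1)


# -- sequential Bonferroni (Holm) ------------------------------------------


def sequential_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjustment, returned in input order.

    Sort ascending, multiply the i-th smallest p by (m - i + 1), enforce a
    non-decreasing cumulative maximum, cap at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted
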