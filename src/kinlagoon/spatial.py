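"""Spatial analysis of kinship: distances, relatedness classes, balanced
rank tests, and the within-family dispersion permutation test.

Pairs of individuals are binned into relatedness classes and the geographic
(great-circle) distances between pair members are compared across classes.
Because high-relatedness classes are tiny relative to the unrelated mass,
every class is subsampled to the size of the least represented class before
each Kruskal-Wallis test; the procedure is repeated R times and summarised by
the median p-value with a 2.5-97.5 percentile interval. Significance is
declared when the median p is below 0.05 and the interval does not overlap
0.05. Dunn's post hoc z-tests (Bonferroni-adjusted) run on the same balanced
subsamples and are summarised by the elementwise median adjusted p.

Pairs sharing an individual are not independent; as in standard practice for
this design the pair is nevertheless the unit of analysis (a documented
caveat, not corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .families import FamilyAssignment
from .io import SampleMetadata

#: mean Earth radius, km
EARTH_RADIUS_KM = 6371.0088

#: default relatedness-class edges; include the quarter/half/0.6/0.75 kinship
#: cut points, last bin closed at 1
DEFAULT_CLASS_EDGES = (0.0, 0.0625, 0.125, 0.25, 0.5, 0.6, 0.75, 1.0)


@dataclass
class RelatednessClassSpec:
    """Ordered bin edges over [0, 1]; bins are [lo, hi), the last closed."""

    edges: tuple[float, ...] = DEFAULT_CLASS_EDGES

    def __post_init__(self) -> None:
        e = tuple(float(x) for x in self.edges)
        if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("edges must be strictly increasing")
        if e[0] != 0.0 or e[-1] != 1.0:
            raise ValueError("edges must cover [0, 1]")
        self.edges = e

    @property
    def n_classes(self) -> int:
        return len(self.edges) - 1

    def labels(self) -> list[str]:
        out = []
        for i, (lo, hi) in enumerate(zip(self.edges, self.edges[1:])):
            closer = "]" if i == self.n_classes - 1 else ")"
            out.append(f"[{lo:g},{hi:g}{closer}")
        return out

    def assign(self, r: np.ndarray) -> np.ndarray:
        """Bin index per value; the top edge belongs to the last bin."""
        r = np.asarray(r, dtype=float)
        if np.any((r < 0) | (r > 1)):
            raise ValueError("relatedness values must lie in [0, 1]")
        idx = np.digitize(r, self.edges[1:-1], right=False)
        return idx


@dataclass
class BootstrapKWResult:
    """Balanced Kruskal-Wallis bootstrap summary."""

    n_iterations: int
    p_values: np.ndarray
    median_p: float
    p_ci: tuple[float, float]
    min_class_size: int
    significant: bool
    dunn_median_p: pd.DataFrame | None = None
    class_labels: list[str] = field(default_factory=list)


def pairwise_distances(meta: SampleMetadata) -> np.ndarray:
    """Great-circle (haversine) distance matrix in km, mean Earth radius.

    Symmetric with zero diagonal; individuals with missing coordinates get
    NaN rows/columns and their pairs are excluded downstream.
    """
    coords = np.radians(meta.coords())
    lat, lon = coords[:, 0], coords[:, 1]
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


def classify_pairs(
    rm, spec: RelatednessClassSpec | Sequence[float] = DEFAULT_CLASS_EDGES
) -> pd.DataFrame:
    """Relatedness-class label for every unordered pair with a defined r.

    Returns a DataFrame (i, j, id1, id2, r, class_index, class_label); pairs
    with undefined relatedness (no shared typed locus) are omitted.
    """
    if not isinstance(spec, RelatednessClassSpec):
        spec = RelatednessClassSpec(tuple(spec))
    iu, ju = np.triu_indices(rm.n, 1)
    r = rm.r[iu, ju]
    ok = np.isfinite(r)
    iu, ju, r = iu[ok], ju[ok], r[ok]
    idx = spec.assign(r)
    labels = spec.labels()
    return pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "id1": [rm.ids[k] for k in iu],
            "id2": [rm.ids[k] for k in ju],
            "r": r,
            "class_index": idx,
            "class_label": [labels[k] for k in idx],
        }
    )


def class_counts(pairs: pd.DataFrame, spec: RelatednessClassSpec) -> pd.Series:
    counts = pairs["class_index"].value_counts().reindex(
        range(spec.n_classes), fill_value=0
    )
    counts.index = spec.labels()
    return counts


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df).

    Requires at least two groups with one value each; if every value is tied
    the statistic is 0 and p is 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    samples = [values[groups == g] for g in uniq]
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def dunn_posthoc(
    values: np.ndarray, groups: np.ndarray, adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on joint ranks with tie correction.

    Two-sided p-values, Bonferroni-multiplied by the number of comparisons
    k(k-1)/2 and capped at 1 (``adjust="none"`` returns raw p). Returns a
    symmetric DataFrame indexed by group label, NaN on the diagonal.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    k = uniq.size
    if k < 2:
        raise ValueError("dunn_posthoc needs at least two groups")
    N = values.size
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in uniq}
    n_of = {g: int((groups == g).sum()) for g in uniq}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    m = k * (k - 1) // 2
    out = pd.DataFrame(np.nan, index=uniq, columns=uniq)
    for x in range(k):
        for y in range(x + 1, k):
            gx, gy = uniq[x], uniq[y]
            se = np.sqrt(var_base * (1.0 / n_of[gx] + 1.0 / n_of[gy]))
            z = (mean_rank[gx] - mean_rank[gy]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(p * m, 1.0)
            out.loc[gx, gy] = out.loc[gy, gx] = p
    return out


def bootstrap_balanced_kw(
    distances: np.ndarray,
    pair_classes: np.ndarray,
    R: int = 1000,
    seed: int | None = None,
    with_replacement: bool = False,
    collect_dunn: bool = True,
    class_labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> BootstrapKWResult:
    """Balanced-resampling Kruskal-Wallis over relatedness classes.

    ``distances`` and ``pair_classes`` are aligned per-pair vectors. Each of
    the R iterations subsamples every class to the smallest class's size
    (without replacement by default, so pairs stay distinct within an
    iteration; with replacement available) and runs the tie-corrected
    Kruskal-Wallis test. Reported: the per-iteration p-values, their median,
    the 2.5-97.5 percentile interval, and the robust-significance call
    (median p < alpha and interval not overlapping alpha). When
    ``collect_dunn`` is set, Bonferroni-adjusted Dunn p-values are computed
    on the same subsamples and summarised by their elementwise median.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    distances = np.asarray(distances, dtype=float)
    pair_classes = np.asarray(pair_classes)
    ok = np.isfinite(distances)
    distances, pair_classes = distances[ok], pair_classes[ok]
    uniq = np.unique(pair_classes)
    if uniq.size < 2:
        raise ValueError("need at least two non-empty relatedness classes")
    members = {g: np.flatnonzero(pair_classes == g) for g in uniq}
    n_min = min(idx.size for idx in members.values())
    if n_min == 0:
        raise ValueError("smallest class is empty")
    rng = np.random.default_rng(seed)
    pvals = np.empty(R)
    dunn_stack: list[pd.DataFrame] = []
    for it in range(R):
        take = np.concatenate(
            [
                rng.choice(members[g], size=n_min, replace=with_replacement)
                for g in uniq
            ]
        )
        vals = distances[take]
        grp = pair_classes[take]
        _, pvals[it] = kruskal_wallis(vals, grp)
        if collect_dunn:
            dunn_stack.append(dunn_posthoc(vals, grp))
    median_p = float(np.median(pvals))
    ci = (float(np.percentile(pvals, 2.5)), float(np.percentile(pvals, 97.5)))
    # interval "not overlapping" the threshold, given median below it,
    # means the upper percentile also sits below it
    significant = median_p < alpha and ci[1] < alpha
    dunn_median = None
    if collect_dunn:
        arr = np.stack([d.to_numpy() for d in dunn_stack])
        dunn_median = pd.DataFrame(
            np.median(arr, axis=0), index=dunn_stack[0].index,
            columns=dunn_stack[0].columns,
        )
        if class_labels is not None:
            names = {g: class_labels[int(g)] for g in uniq}
            dunn_median = dunn_median.rename(index=names, columns=names)
    labels = (
        [class_labels[int(g)] for g in uniq] if class_labels is not None else
        [str(g) for g in uniq]
    )
    return BootstrapKWResult(
        n_iterations=R,
        p_values=pvals,
        median_p=median_p,
        p_ci=ci,
        min_class_size=int(n_min),
        significant=bool(significant),
        dunn_median_p=dunn_median,
        class_labels=labels,
    )


def family_dispersion_test(
    fa: FamilyAssignment,
    dist_matrix: np.ndarray,
    ids: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Are family members spatially closer than random label assignments?

    Observed statistic: mean pairwise geographic distance within families,
    pooled over all within-family pairs. Null: the multiset of family labels
    (including the singleton non-labels) is permuted across individuals
    ``n_perm`` times. One-sided p = fraction of null statistics <= observed,
    with the observed arrangement included in the tally.
    """
    if not fa.families:
        raise ValueError("no family of size >= 2")
    index = {s: i for i, s in enumerate(ids)}
    groups = [np.array([index[s] for s in m]) for m in fa.families.values()]

    def pooled_mean(gs: list[np.ndarray]) -> float:
        tot = 0.0
        cnt = 0
        for g in gs:
            block = dist_matrix[np.ix_(g, g)]
            iu = np.triu_indices(g.size, 1)
            vals = block[iu]
            vals = vals[np.isfinite(vals)]
            tot += vals.sum()
            cnt += vals.size
        return tot / cnt

    observed = pooled_mean(groups)
    rng = np.random.default_rng(seed)
    n = len(ids)
    sizes = [g.size for g in groups]
    hits = 0
    null_sum = 0.0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        start = 0
        permuted = []
        for s in sizes:
            permuted.append(perm[start : start + s])
            start += s
        stat = pooled_mean(permuted)
        null_sum += stat
        if stat <= observed + 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return observed, null_sum / n_perm, p
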