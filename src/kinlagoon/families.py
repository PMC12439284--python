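"""Family delineation from a pairwise relatedness matrix.

The relatedness matrix is turned into the distance 1 - r and clustered with
UPGMA (average linkage). Each internal node N merging clusters C1 (size n1)
and C2 (size n2) is scored with the cross-cluster mean relatedness

    rbar_N = (1 / (n1 * n2)) * sum_{i in C1} sum_{j in C2} r_ij,

the statistic that defines families: a top-down sweep from the root emits the
largest clusters whose node score reaches the threshold (default 0.25, the
theoretical half-sib kinship) and does not descend further, regardless of
deeper nodes. Leaves never form families alone; the result is a partition of
the individuals into families (size >= 2) and singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .relatedness import RelatednessMatrix


@dataclass
class DendrogramNode:
    """One UPGMA fusion; leaves are nodes with ``leaf_index`` set.

    ``merge_height`` is the average inter-cluster distance at the fusion
    (0 for leaves); ``leaves`` are the row indices under the node;
    ``mean_relatedness`` is the cross-cluster rbar_N (NaN for leaves).
    """

    node_id: int
    merge_height: float
    leaves: np.ndarray
    children: Optional[tuple["DendrogramNode", "DendrogramNode"]] = None
    leaf_index: Optional[int] = None
    mean_relatedness: float = float("nan")

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def size(self) -> int:
        return self.leaves.size

    def internal_nodes(self):
        """Yield every internal node under (and including) this one."""
        if self.is_leaf:
            return
        yield self
        for child in self.children:
            yield from child.internal_nodes()


@dataclass
class FamilyAssignment:
    """Partition into families (member-id lists, size >= 2) and singletons."""

    families: dict[str, list[str]]
    singletons: list[str]
    family_mean_r: dict[str, float] = field(default_factory=dict)

    def membership(self, ids: list[str]) -> list[str]:
        """Per-individual cluster labels, singletons as unique labels."""
        label = {}
        for fam, members in self.families.items():
            for m in members:
                label[m] = fam
        return [label.get(s, f"_solo_{s}") for s in ids]

    @property
    def n_in_families(self) -> int:
        return sum(len(m) for m in self.families.values())


def distance_from_relatedness(rm: RelatednessMatrix) -> np.ndarray:
    """1 - r with a zero diagonal; pairs with no shared typed locus (NaN r)
    are placed at the maximal distance 1 (treated as unrelated)."""
    d = 1.0 - rm.r
    d[np.isnan(d)] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


def upgma(dist: np.ndarray) -> DendrogramNode:
    """Average-linkage agglomeration of a square distance matrix.

    The merge height of joining two clusters is the arithmetic mean of all
    inter-cluster pairwise distances (carried exactly by the Lance-Williams
    update). Input must be symmetric with a zero diagonal. Returns the root.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(dist < 0):
        raise ValueError("distances must be nonnegative")
    if n == 1:
        return DendrogramNode(0, 0.0, np.array([0]), leaf_index=0)
    Z = linkage(squareform(dist, checks=False), method="average")
    nodes: list[DendrogramNode] = [
        DendrogramNode(i, 0.0, np.array([i]), leaf_index=i) for i in range(n)
    ]
    for row, (left, right, height, _count) in enumerate(Z):
        a, b = nodes[int(left)], nodes[int(right)]
        nodes.append(
            DendrogramNode(
                n + row,
                float(height),
                np.concatenate([a.leaves, b.leaves]),
                children=(a, b),
            )
        )
    return nodes[-1]


def node_mean_relatedness(node: DendrogramNode, rm: RelatednessMatrix) -> float:
    """Cross-cluster mean relatedness rbar_N at a fusion node.

    The mean runs over all (i, j) with i in one child and j in the other --
    the 1/(n1*n2)-normalised double sum -- not over all within-node pairs.
    """
    if node.is_leaf:
        raise ValueError("rbar_N is defined at internal nodes only")
    c1, c2 = node.children
    block = rm.r[np.ix_(c1.leaves, c2.leaves)]
    if np.isnan(block).any():
        raise ValueError("missing relatedness value for a cross-cluster pair")
    return float(block.mean())


def within_mean_relatedness(node: DendrogramNode, rm: RelatednessMatrix) -> float:
    """Mean relatedness over all pairs inside the node's leaf set (diagnostic)."""
    leaves = node.leaves
    if leaves.size < 2:
        return float("nan")
    block = rm.r[np.ix_(leaves, leaves)]
    iu = np.triu_indices(leaves.size, 1)
    return float(np.nanmean(block[iu]))


def annotate(root: DendrogramNode, rm: RelatednessMatrix) -> DendrogramNode:
    """Fill mean_relatedness at every internal node (in place)."""
    for node in root.internal_nodes():
        node.mean_relatedness = node_mean_relatedness(node, rm)
    return root


def extract_families(
    root: DendrogramNode, rm: RelatednessMatrix, threshold: float = 0.25
) -> FamilyAssignment:
    """Largest clusters whose fusion-node rbar_N reaches the threshold.

    Top-down from the root: a node whose score passes emits its entire leaf
    set as one family and is not descended into; otherwise both children are
    visited. The output partitions all individuals; every family's defining
    node score is >= threshold by construction (asserted).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    families: dict[str, list[str]] = {}
    singletons: list[str] = []
    family_mean_r: dict[str, float] = {}

    stack = [root]
    emitted: list[DendrogramNode] = []
    while stack:
        node = stack.pop()
        if node.is_leaf:
            singletons.append(rm.ids[node.leaf_index])
            continue
        score = node.mean_relatedness
        if np.isnan(score):
            score = node_mean_relatedness(node, rm)
            node.mean_relatedness = score
        if score >= threshold:
            emitted.append(node)
        else:
            stack.extend(node.children[::-1])
    # stable family numbering by smallest member index
    emitted.sort(key=lambda nd: int(nd.leaves.min()))
    for i, node in enumerate(emitted, start=1):
        assert node.mean_relatedness >= threshold
        fam = f"FAM{i:04d}"
        families[fam] = [rm.ids[k] for k in sorted(node.leaves)]
        family_mean_r[fam] = within_mean_relatedness(node, rm)
    covered = sum(len(m) for m in families.values()) + len(singletons)
    assert covered == rm.n, "family extraction must partition the individuals"
    return FamilyAssignment(families, sorted(singletons), family_mean_r)


def family_summary(fa: FamilyAssignment, rm: RelatednessMatrix) -> dict:
    """Headline numbers: counts, size distribution, coverage, mean kinship."""
    sizes = np.array([len(m) for m in fa.families.values()], dtype=float)
    n_total = fa.n_in_families + len(fa.singletons)
    per_family_r = {}
    index = {s: i for i, s in enumerate(rm.ids)}
    for fam, members in fa.families.items():
        rows = [index[s] for s in members]
        block = rm.r[np.ix_(rows, rows)]
        iu = np.triu_indices(len(rows), 1)
        per_family_r[fam] = float(np.nanmean(block[iu]))
    return {
        "n_families": len(fa.families),
        "size_mean": float(sizes.mean()) if sizes.size else 0.0,
        "size_sd": float(sizes.std(ddof=1)) if sizes.size > 1 else 0.0,
        "size_max": int(sizes.max()) if sizes.size else 0,
        "pct_in_families": 100.0 * fa.n_in_families / n_total if n_total else 0.0,
        "n_families_gt3": int(np.sum(sizes > 3)),
        "mean_within_family_r": (
            float(np.mean(list(per_family_r.values()))) if per_family_r else 0.0
        ),
        "per_family_mean_r": per_family_r,
    }


def to_newick(root: DendrogramNode, ids: list[str]) -> str:
    """Newick rendering with branch lengths from merge heights and rbar_N as
    internal-node labels (when annotated)."""

    def build(node: DendrogramNode, parent_height: float) -> str:
        length = parent_height - node.merge_height
        if node.is_leaf:
            return f"{ids[node.leaf_index]}:{length:.6g}"
        a, b = node.children
        inner = f"({build(a, node.merge_height)},{build(b, node.merge_height)})"
        label = (
            f"rbar_{node.mean_relatedness:.4f}"
            if np.isfinite(node.mean_relatedness)
            else ""
        )
        return f"{inner}{label}:{length:.6g}"

    return build(root, root.merge_height) + ";"
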