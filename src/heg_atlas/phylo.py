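"""Distance-based phylogenetics for HNHE families.

Distances are gap-excluded p-distances from pairwise global alignments (or
Poisson-corrected, on request); trees come from a from-scratch Saitou-Nei
neighbour-joining with deterministic tie-breaking; bootstrap support
resamples the columns of a supplied multiple alignment (bootstrap therefore
requires equal-length aligned sequences — pairwise-distance mode has no
well-defined column set to resample).  Tree "clusters" are maximal subtrees
whose leaf-to-leaf path lengths all stay below a stated cut, named with
Roman numerals in decreasing size order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2_contingency
from skbio import TreeNode

from ._align import global_p_distance, validate_protein


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")


@dataclass
class ClusterLabeling:
    labels: dict[str, str]
    threshold: float


def pairwise_distance_matrix(
    proteins: Mapping[str, str], model: str = "p"
) -> DistanceMatrix:
    """Pairwise distances from global alignments of unaligned proteins.

    ``model="p"`` is the gap-excluded p-distance (mismatch fraction over
    residue-residue columns); ``model="poisson"`` applies -ln(1 - p).
    """
    if len(proteins) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    labels = sorted(proteins)
    for lab in labels:
        validate_protein(proteins[lab], lab)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = global_p_distance(proteins[labels[i]], proteins[labels[j]])
            if model == "poisson":
                p = -math.log(max(1e-12, 1.0 - p))
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=labels, d=d)


def alignment_distance_matrix(aligned: Mapping[str, str]) -> DistanceMatrix:
    """Gap-excluded p-distances straight from an equal-length alignment."""
    labels = sorted(aligned)
    lengths = {len(aligned[lab]) for lab in labels}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    arr = np.array([list(aligned[lab]) for lab in labels])
    return DistanceMatrix(labels=labels, d=_p_distances(arr))


def _p_distances(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    d = np.zeros((n, n))
    gap = arr == "-"
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(gap[i] | gap[j])
            nv = int(valid.sum())
            d[i, j] = d[j, i] = (
                float((arr[i, valid] != arr[j, valid]).sum()) / nv if nv else 1.0
            )
    return d


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    At each step the pair minimising the Q-criterion is joined (ties broken
    by the lexicographically smallest pair of subtree-minimum labels);
    branch lengths come from the standard two-point formulas, with negative
    lengths clipped to zero and the deficit moved to the sister branch.  The
    result is an unrooted tree represented with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    D = dm.d.copy()
    nodes = [TreeNode(name=lab) for lab in dm.labels]
    minlab = list(dm.labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        ii, jj = np.where(Q <= qmin + tol)
        candidates = [(i, j) for i, j in zip(ii, jj) if i < j]
        i, j = min(candidates, key=lambda p: tuple(sorted((minlab[p[0]], minlab[p[1]]))))
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = float(li), float(lj)
        parent.extend([a, b])
        newd = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[: len(keep), : len(keep)] = D[np.ix_(keep, keep)]
        D2[-1, : len(keep)] = D2[: len(keep), -1] = newd[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        minlab = [minlab[k] for k in keep] + [min(minlab[i], minlab[j])]

    # resolve the final star of three
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.0, 0.5 * (d01 + d02 - d12))
    l1 = max(0.0, 0.5 * (d01 + d12 - d02))
    l2 = max(0.0, 0.5 * (d02 + d12 - d01))
    root = TreeNode()
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = float(length)
        root.append(node)
    return root


def leaf_path_lengths(tree: TreeNode) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaf pairs."""
    tips = sorted(tree.tips(), key=lambda t: t.name)
    labels = [t.name for t in tips]
    dm = tree.tip_tip_distances(endpoints=labels)
    return DistanceMatrix(labels=labels, d=np.asarray(dm.data))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode, leaf_set: frozenset[str]) -> set[frozenset]:
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaf_set) - 1:
            out.add(frozenset({side, leaf_set - side}))
    return out


def bootstrap_support(
    aligned: Mapping[str, str], n_replicates: int = 1000, seed: int | None = None
) -> TreeNode:
    """NJ tree from an alignment with column-resampling bootstrap supports.

    Each replicate resamples alignment columns with replacement, recomputes
    gap-excluded p-distances and an NJ tree; an internal edge's support is
    the percentage of replicates containing the same bipartition.  Supports
    are attached as ``node.support`` (int, 0-100) on internal nodes.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = sorted(aligned)
    lengths = {len(aligned[lab]) for lab in labels}
    if len(lengths) != 1:
        raise ValueError("bootstrap requires an equal-length multiple alignment")
    (length,) = lengths
    arr = np.array([list(aligned[lab]) for lab in labels])
    tree = neighbor_joining(DistanceMatrix(labels=labels, d=_p_distances(arr)))
    leaf_set = frozenset(labels)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        rep = neighbor_joining(
            DistanceMatrix(labels=labels, d=_p_distances(arr[:, cols]))
        )
        for bp in _bipartitions(rep, leaf_set):
            counts[bp] = counts.get(bp, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        bp = frozenset({side, leaf_set - side})
        node.support = round(100 * counts.get(bp, 0) / n_replicates)
    return tree


def to_newick_with_support(tree: TreeNode) -> str:
    """Newick string with bootstrap supports as internal node labels."""
    from io import StringIO

    clone = tree.copy()
    for node in clone.non_tips(include_self=False):
        if hasattr(node, "support"):
            node.name = str(node.support)
            node.support = None  # skbio would otherwise serialize it a second time
    buf = StringIO()
    clone.write(buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# Cluster extraction and metadata association
# ---------------------------------------------------------------------------

def _roman(n: int) -> str:
    vals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = ""
    for v, s in vals:
        while n >= v:
            out += s
            n -= v
    return out


def extract_tree_clusters(tree: TreeNode, cut_distance: float) -> ClusterLabeling:
    """Cut a tree into clusters of mutually close leaves.

    A cluster is a maximal subtree (an edge-side of the unrooted tree) whose
    internal leaf-to-leaf path lengths are all <= ``cut_distance``; clusters
    are named I, II, ... in decreasing size (ties by smallest member label).
    Both sides of every edge are considered, so the result does not depend
    on where the unrooted tree happens to be rooted for representation.
    """
    if cut_distance <= 0:
        raise ValueError("cut_distance must be > 0")

    tips = sorted(tree.tips(), key=lambda t: t.name)
    labels = [t.name for t in tips]
    all_leaves = frozenset(labels)
    dmat = tree.tip_tip_distances(endpoints=labels)
    dist = np.asarray(dmat.data)
    index = {lab: i for i, lab in enumerate(labels)}

    candidates: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node is tree:
            continue
        side = (
            frozenset({node.name})
            if node.is_tip()
            else frozenset(t.name for t in node.tips())
        )
        candidates.add(side)
        if side != all_leaves:
            candidates.add(all_leaves - side)
    candidates.add(all_leaves)

    def diameter(leafset: frozenset[str]) -> float:
        idx = [index[l] for l in leafset]
        return float(dist[np.ix_(idx, idx)].max()) if len(idx) > 1 else 0.0

    tight = [c for c in candidates if diameter(c) <= cut_distance]
    tight.sort(key=lambda c: (-len(c), min(c)))
    clusters: list[list[str]] = []
    covered: set[str] = set()
    for cand in tight:
        if cand & covered:
            continue
        clusters.append(sorted(cand))
        covered |= cand
        if covered == all_leaves:
            break
    clusters.sort(key=lambda c: (-len(c), c[0]))
    labels = {}
    for i, members in enumerate(clusters):
        for m in members:
            labels[m] = _roman(i + 1)
    return ClusterLabeling(labels=labels, threshold=cut_distance)


def cramers_v(a: np.ndarray, b: np.ndarray) -> float:
    """Cramer's V for two categorical labelings (no continuity correction)."""
    table = _contingency(a, b)
    chi2 = chi2_contingency(table, correction=False)[0]
    n = table.sum()
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k))) if k > 0 else float("nan")


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)), dtype=int)
    np.add.at(table, (ia, ib), 1)
    return table


def association_test(
    labels_a: Mapping[str, str] | Sequence[str],
    labels_b: Mapping[str, str] | Sequence[str],
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test of association between two categorical labelings.

    Returns (Cramer's V, permutation p-value with the add-one rule
    ``(count_ge + 1) / (n_perm + 1)``); labels_b is permuted.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(labels_a, Mapping) and isinstance(labels_b, Mapping):
        if set(labels_a) != set(labels_b):
            raise ValueError("labelings must cover the same item set")
        keys = sorted(labels_a)
        a = np.array([labels_a[k] for k in keys])
        b = np.array([labels_b[k] for k in keys])
    else:
        a = np.asarray(list(labels_a))
        b = np.asarray(list(labels_b))
        if len(a) != len(b):
            raise ValueError("labelings must cover the same item set")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("association is undefined with a single category on either side")
    v_obs = cramers_v(a, b)
    rng = np.random.default_rng(seed)
    count = 0
    b_perm = b.copy()
    for _ in range(n_perm):
        rng.shuffle(b_perm)
        if cramers_v(a, b_perm) >= v_obs - 1e-12:
            count += 1
    return v_obs, (count + 1) / (n_perm + 1)
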