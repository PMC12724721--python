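"""Ortholog clustering and gene-content phage clustering.

The cohort's proteins are compared all-against-all with a local affine-gap
aligner; an edge is kept only when percent identity and *bidirectional*
coverage (both sequences) clear the thresholds — the classic 50% identity /
50% coverage orthology gate.  The resulting similarity graph is partitioned
with a from-scratch Markov Clustering (MCL) implementation, and phages are
then clustered by ortholog presence/absence with average-linkage
agglomeration on Jaccard distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._align import local_align, validate_protein
from .io import PhageGenome


@dataclass(frozen=True)
class SimilarityEdge:
    """An accepted protein-similarity edge (stored once, a < b)."""

    a: str
    b: str
    pct_identity: float
    cov_a: float
    cov_b: float
    score: float


@dataclass
class OrthologPartition:
    """A partition of the cohort's genes into ortholog clusters.

    Cluster ids are ``OC0001`` ... assigned by (size descending, then the
    lexicographically smallest member), so numbering is deterministic.
    """

    clusters: list[frozenset[str]]

    def __post_init__(self) -> None:
        order = sorted(
            range(len(self.clusters)),
            key=lambda i: (-len(self.clusters[i]), min(self.clusters[i])),
        )
        self.clusters = [frozenset(self.clusters[i]) for i in order]
        self.cluster_ids = [f"OC{i + 1:04d}" for i in range(len(self.clusters))]
        self._member_to_cluster: dict[str, str] = {}
        for cid, members in zip(self.cluster_ids, self.clusters):
            for m in members:
                if m in self._member_to_cluster:
                    raise ValueError(f"gene {m} appears in more than one cluster")
                self._member_to_cluster[m] = cid

    def cluster_of(self, gene_id: str) -> str:
        return self._member_to_cluster[gene_id]

    def members(self, cluster_id: str) -> frozenset[str]:
        return self.clusters[self.cluster_ids.index(cluster_id)]

    @property
    def gene_ids(self) -> set[str]:
        return set(self._member_to_cluster)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "cluster_id": c}
            for c, members in zip(self.cluster_ids, self.clusters)
            for g in sorted(members)
        ]
        return pd.DataFrame(rows)


@dataclass
class PhageClustering:
    """Gene-content clustering of phage genomes (letters A, B, C, ...)."""

    labels: dict[str, str]
    linkage_record: np.ndarray
    column_linkage: np.ndarray | None = None


def all_vs_all_similarity(
    proteins: Mapping[str, str],
    min_identity: float = 50.0,
    min_coverage: float = 0.5,
    prescreen: bool = False,
    prescreen_k: int = 5,
) -> list[SimilarityEdge]:
    """All-against-all protein similarity with a bidirectional identity/coverage gate.

    An edge (a, b) is kept iff the best local alignment has
    ``pct_identity >= min_identity`` and covers at least ``min_coverage`` of
    *both* sequences.  The default run is exhaustive (every pair aligned);
    ``prescreen=True`` skips pairs sharing no exact ``prescreen_k``-mer — a
    word seed, as in seeded database search, appropriate for cohort-scale
    runs where biologically related pairs sit far above the identity gate
    and share dozens of words, but capable of dropping pairs hovering at the
    threshold.
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 protein sequences")
    if not (0 <= min_identity <= 100) or not (0 <= min_coverage <= 1):
        raise ValueError("thresholds out of range")
    for gene_id, seq in proteins.items():
        validate_protein(seq, gene_id)
    edges: list[SimilarityEdge] = []
    ids = sorted(proteins)
    kmer_sets = {}
    if prescreen:
        k = prescreen_k
        kmer_sets = {
            gid: frozenset(
                proteins[gid][i : i + k] for i in range(len(proteins[gid]) - k + 1)
            )
            for gid in ids
        }
    for a, b in combinations(ids, 2):
        sa, sb = proteins[a], proteins[b]
        if prescreen and kmer_sets[a].isdisjoint(kmer_sets[b]):
            continue
        res = local_align(sa, sb)
        if (
            res.pct_identity >= min_identity
            and res.cov_a >= min_coverage
            and res.cov_b >= min_coverage
        ):
            edges.append(
                SimilarityEdge(a, b, res.pct_identity, res.cov_a, res.cov_b, res.score)
            )
    return edges


# ---------------------------------------------------------------------------
# Markov Clustering
# ---------------------------------------------------------------------------

def mcl(
    edges: Sequence[SimilarityEdge] | Sequence[tuple],
    nodes: Iterable[str] | None = None,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> OrthologPartition:
    """Markov Clustering of a weighted similarity graph.

    The column-stochastic flow matrix is built from edge scores with a
    self-loop per node equal to its maximum incident edge weight (1 for
    isolated nodes).  Iterates expansion (matrix power), inflation
    (entry-wise power + column renormalisation) and pruning of entries below
    ``prune_threshold`` until the largest entry change falls below ``tol``.
    Clusters are read off as attractor-connected components; singletons are
    allowed.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    edge_tuples = [
        (e.a, e.b, e.score) if isinstance(e, SimilarityEdge) else (e[0], e[1], float(e[2]))
        for e in edges
    ]
    node_set = set(nodes) if nodes is not None else set()
    for a, b, _ in edge_tuples:
        node_set.add(a)
        node_set.add(b)
    if not node_set:
        raise ValueError("graph has no nodes")
    labels = sorted(node_set)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    W = np.zeros((n, n))
    for a, b, s in edge_tuples:
        i, j = index[a], index[b]
        W[i, j] = max(W[i, j], s)
        W[j, i] = W[i, j]
    loop = W.max(axis=0)
    loop[loop <= 0] = 1.0
    W[np.diag_indices(n)] = loop

    M = W / W.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M /= M.sum(axis=0, keepdims=True)
        M[M < prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if prev.shape == M.shape and np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge; clusters read from current matrix")

    # attractors: rows with mass on the diagonal
    attractors = [i for i in range(n) if M[i, i] > 0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    for i in attractors:
        for j in np.nonzero(M[i])[0]:
            union(i, int(j))
    clusters: dict[int, set[str]] = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(labels[i])
    return OrthologPartition(list(clusters.values()))


# ---------------------------------------------------------------------------
# Gene-content matrix and phage clustering
# ---------------------------------------------------------------------------

def build_gene_content_matrix(
    partition: OrthologPartition, genomes: Sequence[PhageGenome]
) -> pd.DataFrame:
    """Genome x ortholog-cluster count matrix (rows genomes, columns clusters)."""
    gene_to_genome = {g.gene_id: gm.genome_id for gm in genomes for g in gm.genes}
    orphans = partition.gene_ids - set(gene_to_genome)
    if orphans:
        raise ValueError(f"partition contains genes of no known genome: {sorted(orphans)[:5]}")
    genome_ids = sorted(gm.genome_id for gm in genomes)
    counts = pd.DataFrame(
        0, index=genome_ids, columns=list(partition.cluster_ids), dtype=int
    )
    for cid, members in zip(partition.cluster_ids, partition.clusters):
        for gene_id in members:
            counts.loc[gene_to_genome[gene_id], cid] += 1
    return counts


def two_way_hcl(
    matrix: pd.DataFrame,
    k: int,
    metric: str = "jaccard",
    linkage: str = "average",
) -> PhageClustering:
    """Two-way hierarchical clustering of the gene-content matrix.

    Genomes are clustered on binarised (presence/absence) profiles with the
    given distance and linkage; the column-side dendrogram over ortholog
    clusters is computed the same way for reporting.  Rows are sorted
    lexicographically before linkage so the result is invariant to input row
    order; cluster letters are assigned in order of each cluster's
    lexicographically smallest genome.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix.index):
        raise ValueError("k exceeds the number of genomes")
    mat = matrix.sort_index(axis=0).sort_index(axis=1)
    presence = (mat.values > 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero rows give NaN jaccard; none occur here
        d_rows = pdist(presence, metric=metric)
        Z = hierarchy.linkage(d_rows, method=linkage)
        col_Z = None
        if presence.shape[1] >= 2:
            d_cols = pdist(presence.T, metric=metric)
            col_Z = hierarchy.linkage(d_cols, method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    genome_ids = list(mat.index)
    first_member: dict[int, str] = {}
    for gid, c in zip(genome_ids, flat):
        first_member.setdefault(int(c), gid)
    letter_of = {
        c: chr(ord("A") + rank)
        for rank, c in enumerate(sorted(first_member, key=lambda c: first_member[c]))
    }
    labels = {gid: letter_of[int(c)] for gid, c in zip(genome_ids, flat)}
    return PhageClustering(labels=labels, linkage_record=Z, column_linkage=col_Z)


def suggest_k(matrix: pd.DataFrame, k_range: range | None = None) -> int:
    """Silhouette-based suggestion for the number of phage clusters (reported,
    never auto-applied)."""
    from scipy.spatial.distance import squareform

    mat = matrix.sort_index(axis=0)
    presence = (mat.values > 0)
    d = pdist(presence, metric="jaccard")
    Z = hierarchy.linkage(d, method="average")
    sq = squareform(d)
    n = len(mat.index)
    best_k, best_s = 2, -np.inf
    for k in k_range or range(2, min(n, 11)):
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        s = _mean_silhouette(sq, flat)
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def _mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    vals = []
    for i in range(n):
        same = labels == labels[i]
        same[i] = False
        if not same.any():
            continue
        a = dist[i, same].mean()
        b = min(
            dist[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        vals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(vals)) if vals else 0.0
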