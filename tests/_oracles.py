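"""Independent reference implementations used only as test oracles.

Everything here is written from first principles, separately from the
package code paths it checks: a quadratic-DP Gotoh aligner (local and
global, protein and nucleotide), a dict-based Markov Clustering, and a
random additive-tree generator with exact path-length matrices.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

# package-wide conventions mirrored here: gap of length k costs 11 + k
PROT_OPEN, PROT_EXT = -12.0, -1.0
NT_MATCH, NT_MISMATCH, NT_OPEN, NT_EXT = 2.0, -3.0, -7.0, -2.0
NEG = -1e30


def _prot_sub(x: str, y: str) -> float:
    return float(_BLOSUM62[x][y])


def _nt_sub(x: str, y: str) -> float:
    return NT_MATCH if x == y else NT_MISMATCH


def gotoh_local(a: str, b: str, sub=_prot_sub, open_=PROT_OPEN, ext=PROT_EXT):
    """Brute-force affine-gap local alignment.

    Returns (score, matches, columns, a_span, b_span) with identity counted
    over all alignment columns (gaps included) like the package does.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), 0.0)
    Ix = np.full((n + 1, m + 1), NEG)   # gap in b (a residue vs gap)
    Iy = np.full((n + 1, m + 1), NEG)   # gap in a
    ptr = np.zeros((n + 1, m + 1, 3), dtype=np.int8)  # traceback state choices
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub(ai, b[j - 1])
            # state M
            cands = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1], 0.0)
            k = int(np.argmax(cands))
            M[i, j] = cands[k] + s
            ptr[i, j, 0] = k
            # state Ix
            cx = (M[i - 1, j] + open_, Ix[i - 1, j] + ext)
            kx = 0 if cx[0] >= cx[1] else 1
            Ix[i, j] = cx[kx]
            ptr[i, j, 1] = kx
            # state Iy
            cy = (M[i, j - 1] + open_, Iy[i, j - 1] + ext)
            ky = 0 if cy[0] >= cy[1] else 1
            Iy[i, j] = cy[ky]
            ptr[i, j, 2] = ky
            if M[i, j] > best:
                best, bi, bj = M[i, j], i, j
    if best <= 0:
        return 0.0, 0, 0, (0, 0), (0, 0)
    # traceback from (bi, bj) in state M; a local path starts and ends on a match
    i, j, state = bi, bj, 0
    matches = columns = 0
    a_start, a_end = bi, bi
    b_start, b_end = bj, bj
    while True:
        if state == 0:
            columns += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            choice = ptr[i, j, 0]
            i, j = i - 1, j - 1
            a_start, b_start = i, j
            if choice == 3:
                break
            if choice == 0 and (i == 0 or j == 0 or M[i, j] <= 0):
                break  # extending through a non-positive prefix gains nothing
            state = int(choice)  # 0->M, 1->Ix, 2->Iy
        elif state == 1:
            choice = ptr[i, j, 1]
            columns += 1
            i -= 1
            a_start = i
            state = 0 if choice == 0 else 1
        else:
            choice = ptr[i, j, 2]
            columns += 1
            j -= 1
            b_start = j
            state = 0 if choice == 0 else 2
    return best, matches, columns, (a_start, a_end), (b_start, b_end)


def gotoh_global_score(a: str, b: str, sub=_prot_sub, open_=PROT_OPEN, ext=PROT_EXT) -> float:
    """Score of the best global affine-gap alignment (end gaps penalized)."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Iy[0, j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub(ai, b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + open_, Ix[i - 1, j] + ext)
            Iy[i, j] = max(M[i, j - 1] + open_, Iy[i, j - 1] + ext)
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


def similarity_edges_bruteforce(proteins: dict, min_identity=50.0, min_coverage=0.5):
    """Kept-edge set under the bidirectional identity/coverage gate,
    recomputed with the independent DP aligner."""
    from itertools import combinations

    edges = set()
    for x, y in combinations(sorted(proteins), 2):
        a, b = proteins[x], proteins[y]
        score, matches, columns, sa, sb = gotoh_local(a, b)
        if columns == 0:
            continue
        identity = 100.0 * matches / columns
        cov_a = (sa[1] - sa[0]) / len(a)
        cov_b = (sb[1] - sb[0]) / len(b)
        if identity >= min_identity and cov_a >= min_coverage and cov_b >= min_coverage:
            edges.add((x, y))
    return edges


# ---------------------------------------------------------------------------
# Reference Markov Clustering (dict-based, written independently)
# ---------------------------------------------------------------------------

def reference_mcl(
    nodes,
    weighted_edges,
    inflation=2.0,
    expansion=2,
    prune_threshold=1e-5,
    max_iter=200,
    tol=1e-8,
):
    """MCL on a weighted graph, kept as dict-of-dict column vectors.

    Same algorithmic conventions as the package (self-loop = max incident
    weight or 1, column-stochastic, expansion/inflation/pruning, attractor
    reading), implemented with explicit per-column dictionaries.
    """
    nodes = sorted(set(nodes) | {v for e in weighted_edges for v in e[:2]})
    adj = {u: {} for u in nodes}
    for a, b, w in weighted_edges:
        w = float(w)
        adj[a][b] = max(adj[a].get(b, 0.0), w)
        adj[b][a] = adj[a][b]
    for u in nodes:
        incident = [w for v, w in adj[u].items() if v != u]
        adj[u][u] = max(incident) if incident else 1.0

    def normalize(cols):
        out = {}
        for u, col in cols.items():
            total = sum(col.values())
            out[u] = {v: w / total for v, w in col.items()}
        return out

    # columns[u] = flow out of u
    columns = normalize({u: dict(adj[u]) for u in nodes})
    for _ in range(max_iter):
        prev = columns
        cur = columns
        for _ in range(expansion - 1):
            nxt = {}
            for u in nodes:
                acc = {}
                for mid, w1 in cur[u].items():
                    for v, w2 in columns[mid].items():
                        acc[v] = acc.get(v, 0.0) + w1 * w2
                nxt[u] = acc
            cur = nxt
        inflated = {
            u: {v: w ** inflation for v, w in cur[u].items()} for u in nodes
        }
        inflated = normalize(inflated)
        pruned = {
            u: {v: w for v, w in inflated[u].items() if w >= prune_threshold}
            for u in nodes
        }
        columns = normalize(pruned)
        delta = 0.0
        for u in nodes:
            keys = set(prev[u]) | set(columns[u])
            for v in keys:
                delta = max(delta, abs(prev[u].get(v, 0.0) - columns[u].get(v, 0.0)))
        if delta < tol:
            break

    attractors = [u for u in nodes if columns[u].get(u, 0.0) > 0]
    parent = {u: u for u in nodes}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    # node v joins attractor u when v's column puts mass on row u
    for u in attractors:
        for v in nodes:
            if columns[v].get(u, 0.0) > 0.0:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[ru] = rv
    groups = {}
    for u in nodes:
        groups.setdefault(find(u), set()).add(u)
    return {frozenset(g) for g in groups.values()}


# ---------------------------------------------------------------------------
# Random additive trees for NJ exactness checks
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with branch lengths in [0.1, 1.0].

    Returns (labels, distance matrix, set of non-trivial bipartitions as
    frozensets-of-frozensets).
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # grow by sequential leaf attachment onto random edges of a 3-leaf star
    # adjacency: node -> {neighbor: length}
    adj: dict[int, dict[int, float]] = {}
    next_id = n_taxa

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    center = next_id
    next_id += 1
    for leaf in range(min(3, n_taxa)):
        add_edge(leaf, center, float(rng.uniform(0.1, 1.0)))
    for leaf in range(3, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        split = float(rng.uniform(0.2, 0.8)) * w
        mid = next_id
        next_id += 1
        del adj[u][v]
        del adj[v][u]
        add_edge(u, mid, split)
        add_edge(mid, v, w - split)
        add_edge(leaf, mid, float(rng.uniform(0.1, 1.0)))

    # leaf-to-leaf path lengths by BFS
    n = n_taxa
    D = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n):
            D[src, dst] = dist[dst]

    # bipartitions: removing each internal edge splits the leaves
    leafset = frozenset(labels)
    biparts = set()
    internal_edges = [
        (u, v) for u in adj for v in adj[u] if u < v and u >= n_taxa and v >= n_taxa
    ]
    for u, v in internal_edges:
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y != v and y not in seen and not (x == u and y == v):
                    seen.add(y)
                    stack.append(y)
        side = frozenset(labels[i] for i in seen if i < n_taxa)
        if 1 < len(side) < n_taxa - 1:
            biparts.add(frozenset({side, leafset - side}))
    return labels, D, biparts


def tree_bipartitions(tree, labels):
    """Non-trivial bipartitions of an skbio TreeNode."""
    leafset = frozenset(labels)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leafset) - 1:
            out.add(frozenset({side, leafset - side}))
    return out
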