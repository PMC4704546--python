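"""Independent oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: the p-distance
oracle is a character-by-character loop, and the tree oracle scores every
unrooted topology by least-squares edge fitting.
"""

from __future__ import annotations

import itertools

import numpy as np

MISSING = {"-", "N", "?"}


def site_loop_pdistance(a: str, b: str) -> tuple[float, int]:
    """Per-pair p-distance by an explicit site loop (pairwise deletion)."""
    assert len(a) == len(b)
    comp = 0
    mism = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in MISSING or y in MISSING:
            continue
        comp += 1
        if x != y:
            mism += 1
    if comp == 0:
        return float("nan"), 0
    return mism / comp, comp


# ---------------------------------------------------------------------------
# exhaustive unrooted-topology enumeration with least-squares branch fitting

def enumerate_topologies(taxa: list[str]):
    """All unrooted binary topologies over ``taxa`` as edge lists.

    Nodes are taxon labels (leaves) or integers (internal); an edge list is a
    list of frozenset node pairs.
    """
    assert len(taxa) >= 3
    base = [frozenset((taxa[i], 0)) for i in range(3)]
    trees = [(base, 1)]
    for taxon in taxa[3:]:
        nxt = []
        for edges, n_internal in trees:
            for k, edge in enumerate(edges):
                u, v = tuple(edge)
                new_node = n_internal
                new_edges = edges[:k] + edges[k + 1 :]
                new_edges += [
                    frozenset((u, new_node)),
                    frozenset((v, new_node)),
                    frozenset((taxon, new_node)),
                ]
                nxt.append((new_edges, n_internal + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def _adjacency(edges):
    adj = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def _path_edges(adj, src, dst):
    """Edges along the unique path src -> dst (tree assumed)."""
    stack = [(src, None, [])]
    while stack:
        node, prev, path = stack.pop()
        if node == dst:
            return path
        for nb in adj[node]:
            if nb != prev:
                stack.append((nb, node, path + [frozenset((node, nb))]))
    raise AssertionError("no path found")


def split_of_edge(edges, edge, taxa):
    """Canonical bipartition key of one edge: the lexicographically lesser side."""
    adj = _adjacency(edges)
    u, v = tuple(edge)
    # leaves reachable from u without crossing the edge
    side = set()
    stack = [(u, v)]
    while stack:
        node, block = stack.pop()
        if node in taxa_set(taxa) and not isinstance(node, int):
            side.add(node)
        for nb in adj[node]:
            if nb != block and frozenset((node, nb)) != edge:
                stack.append((nb, node))
    side = frozenset(x for x in side if not isinstance(x, int))
    other = frozenset(taxa) - side
    a, b = tuple(sorted(side)), tuple(sorted(other))
    return min((len(a), a), (len(b), b))


def taxa_set(taxa):
    return set(taxa)


def ls_fit(edges, taxa, D):
    """Least-squares branch lengths for one topology; returns (rss, lengths).

    ``lengths`` maps canonical bipartition keys to fitted edge lengths.
    """
    edge_list = list(edges)
    adj = _adjacency(edge_list)
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    X = np.zeros((len(pairs), len(edge_list)))
    y = np.zeros(len(pairs))
    index = {e: k for k, e in enumerate(edge_list)}
    for row, (i, j) in enumerate(pairs):
        for e in _path_edges(adj, taxa[i], taxa[j]):
            X[row, index[e]] = 1.0
        y[row] = D[i, j]
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((X @ b - y) ** 2).sum())
    lengths = {split_of_edge(edge_list, e, taxa): float(b[k]) for e, k in index.items()}
    return rss, lengths


def best_ls_tree(taxa, D):
    """Exhaustive search: the topology with minimal least-squares residual."""
    best = None
    for edges in enumerate_topologies(taxa):
        rss, lengths = ls_fit(edges, taxa, D)
        if best is None or rss < best[0]:
            best = (rss, edges, lengths)
    rss, edges, lengths = best
    splits = {split_of_edge(edges, e, taxa) for e in edges}
    return rss, splits, lengths


def random_additive_matrix(rng: np.random.Generator, n: int):
    """A random additive distance matrix plus its generating splits/lengths."""
    taxa = [f"T{i}" for i in range(n)]
    # random topology by random edge insertion
    edges = [frozenset((taxa[i], 0)) for i in range(3)]
    n_internal = 1
    for taxon in taxa[3:]:
        edge = edges[rng.integers(0, len(edges))]
        u, v = tuple(edge)
        edges.remove(edge)
        edges += [
            frozenset((u, n_internal)),
            frozenset((v, n_internal)),
            frozenset((taxon, n_internal)),
        ]
        n_internal += 1
    lengths = {e: float(rng.uniform(0.05, 1.0)) for e in edges}
    adj = _adjacency(edges)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(lengths[e] for e in _path_edges(adj, taxa[i], taxa[j]))
            D[i, j] = D[j, i] = d
    true_splits = {split_of_edge(edges, e, taxa) for e in edges}
    true_lengths = {split_of_edge(edges, e, taxa): l for e, l in lengths.items()}
    return taxa, D, true_splits, true_lengths


# ---------------------------------------------------------------------------
# dendropy tree -> split/length maps (independent of package internals)

def dendropy_edge_lengths(tree, taxa):
    """Map canonical bipartition keys of every edge to its branch length.

    For the two child edges of a rooted seed (or around an unrooted seed
    node's adjacent edges representing the same split), lengths of duplicated
    keys are summed, matching the unrooted-edge view.
    """
    universe = frozenset(taxa)
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = universe - side
        a, b = tuple(sorted(side)), tuple(sorted(other))
        key = min((len(a), a), (len(b), b))
        out[key] = out.get(key, 0.0) + (node.edge.length or 0.0)
    return out


def dendropy_splits(tree, taxa):
    return set(dendropy_edge_lengths(tree, taxa))
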