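"""Neighbor-joining from p-distance matrices, nonparametric bootstrap
support, outgroup rooting, and species-specific cluster scoring.

Trees are dendropy objects throughout; bootstrap supports (percent of
replicates containing a bipartition) are carried as internal node labels, so
they survive newick round-trips in the common "support-as-internal-label"
dialect.  Cluster scoring accepts any rooted, support-annotated tree — not
just the NJ trees built here — so externally inferred ML/MP topologies can be
scored with the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignment_io import MarkerAlignment
from .distances import DistanceMatrix, encode_alignment, pairwise_matrix

__all__ = [
    "neighbor_joining",
    "bootstrap_support",
    "root_tree",
    "midpoint_root",
    "ClusterReport",
    "species_specific_clusters",
    "read_newick",
    "write_newick",
    "node_support",
]


# ---------------------------------------------------------------------------
# newick I/O

def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a newick tree; internal node labels (e.g. supports) are kept as labels."""
    src = str(source)
    kwargs = dict(
        schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True
    )
    if "(" in src and ";" in src:  # a newick string rather than a path
        return dendropy.Tree.get(data=src, **kwargs)
    return dendropy.Tree.get(path=src, **kwargs)


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Write a tree as newick, preserving branch lengths and internal labels."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    if path is not None:
        Path(path).write_text(s)
    return s


def node_support(node: dendropy.Node) -> float | None:
    """Bootstrap support carried on a node: its label parsed as a number.

    Leaves have trivial bipartitions and are supported at 100 by convention.
    """
    if node.is_leaf():
        return 100.0
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# neighbor joining

def _nj_arrays(D: np.ndarray, labels: list[str]):
    """Saitou-Nei agglomeration. Returns (children, edge_lengths, final_join).

    ``children`` maps each internal join to its two cluster indices with the
    already-clamped edge lengths.  Ties in the Q criterion are broken by the
    lexicographically smallest pair of cluster representative labels (the
    minimum leaf label inside each cluster), which makes the topology
    deterministic for degenerate inputs.
    """
    n = len(labels)
    active = list(range(n))
    reps = {i: labels[i] for i in range(n)}
    D = D.copy()
    joins: list[tuple[int, int, int, float, float]] = []  # (new, i, j, li, lj)
    next_id = n
    # D is indexed by a dense "slot" per active cluster
    idx_of = {c: i for i, c in enumerate(active)}
    M = D

    def _pair_key(ci: int, cj: int):
        a, b = reps[ci], reps[cj]
        return (a, b) if a <= b else (b, a)

    while len(active) > 3:
        m = len(active)
        sub = M[np.ix_([idx_of[c] for c in active], [idx_of[c] for c in active])]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qvals = Q[iu]
        qmin = qvals.min()
        ties = np.where(qvals == qmin)[0]
        best = min(ties, key=lambda t: _pair_key(active[iu[0][t]], active[iu[1][t]]))
        a, b = int(iu[0][best]), int(iu[1][best])
        ci, cj = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        # clamp negative branch lengths to 0, transferring the deficit to the
        # sibling edge so the tip-to-tip path length is preserved
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        # distances from the new node to every other active cluster
        new_slot = idx_of[ci]  # reuse ci's slot
        for c in active:
            if c in (ci, cj):
                continue
            k = idx_of[c]
            duk = 0.5 * (sub[a, idx_of_sub(active, c)] + sub[b, idx_of_sub(active, c)] - dij)
            M[new_slot, k] = M[k, new_slot] = duk
        joins.append((next_id, ci, cj, float(li), float(lj)))
        reps[next_id] = min(reps[ci], reps[cj])
        idx_of[next_id] = new_slot
        active = [c for c in active if c not in (ci, cj)] + [next_id]
        next_id += 1

    return joins, active, M, idx_of, next_id


def idx_of_sub(active: list[int], c: int) -> int:
    return active.index(c)


def neighbor_joining(m: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted neighbor-joining tree from a fully defined distance matrix.

    Negative branch lengths are clamped to zero with the deficit transferred
    to the sibling edge.  The returned tree is unrooted (trifurcating seed
    node for >= 3 specimens).
    """
    if m.n < 2:
        raise ValueError("neighbor_joining needs at least 2 specimens")
    if np.isnan(m.d).any():
        iu, ju = np.where(np.isnan(np.triu(m.d, k=1) + np.tril(np.full_like(m.d, 0))))
        bad = [(m.labels[i], m.labels[j]) for i, j in zip(iu, ju) if i < j][:5]
        raise ValueError(
            "distance matrix contains undefined (no comparable sites) pairs, "
            f"e.g. {bad}; impute these distances or remove the specimens before tree building"
        )
    tns = dendropy.TaxonNamespace(m.labels)
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(m.labels):
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes[i] = nd

    if m.n == 2:
        root = dendropy.Node()
        for i, ln in ((0, float(m.d[0, 1])), (1, 0.0)):
            root.add_child(nodes[i])
            nodes[i].edge.length = ln
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = root
        tree.is_rooted = False
        return tree

    D = m.d.astype(float).copy()
    joins, active, M, idx_of, next_id = _nj_arrays(D, list(m.labels))
    for new, ci, cj, li, lj in joins:
        nd = dendropy.Node()
        nd.add_child(nodes[ci])
        nodes[ci].edge.length = li
        nd.add_child(nodes[cj])
        nodes[cj].edge.length = lj
        nodes[new] = nd

    # final: exactly 3 active clusters join at the central (seed) node via the
    # three-point formulas
    center = dendropy.Node()
    a, b, c = active
    dab = M[idx_of[a], idx_of[b]]
    dac = M[idx_of[a], idx_of[c]]
    dbc = M[idx_of[b], idx_of[c]]
    lens = {
        a: 0.5 * (dab + dac - dbc),
        b: 0.5 * (dab + dbc - dac),
        c: 0.5 * (dac + dbc - dab),
    }
    for cl in (a, b, c):
        center.add_child(nodes[cl])
        nodes[cl].edge.length = max(float(lens[cl]), 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions and bootstrap

def _leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _canon(side: frozenset[str], universe: frozenset[str]):
    """Orientation-free bipartition key: the lesser of the two sides."""
    other = universe - side
    a = tuple(sorted(side))
    b = tuple(sorted(other))
    return min((len(a), a), (len(b), b))


def tree_bipartitions(tree: dendropy.Tree) -> dict:
    """Map canonical nontrivial bipartition keys to their (internal) nodes."""
    universe = _leaf_labels(tree)
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) <= 1 or len(universe - side) <= 1:
            continue  # trivial
        out[_canon(side, universe)] = node
    return out


def _pair_site_arrays(aln: MarkerAlignment):
    """Per unordered pair, per column: mismatch and comparability indicators.

    Bootstrap distances for any column-resample then reduce to two
    matrix-vector products, which keeps 1000-replicate runs cheap.
    """
    X = encode_alignment(aln)
    valid = X >= 0
    n, L = X.shape
    iu, ju = np.triu_indices(n, k=1)
    Wm = np.empty((len(iu), L), dtype=np.float32)
    Cm = np.empty((len(iu), L), dtype=np.float32)
    pos = 0
    for i in range(n - 1):
        k = n - 1 - i
        comp = valid[i] & valid[i + 1 :]
        Cm[pos : pos + k] = comp
        Wm[pos : pos + k] = (X[i] != X[i + 1 :]) & comp
        pos += k
    return Wm, Cm, (iu, ju), n, L


def _condensed_to_square(vals: np.ndarray, pair_idx, n: int) -> np.ndarray:
    iu, ju = pair_idx
    D = np.zeros((n, n), dtype=float)
    D[iu, ju] = vals
    D[ju, iu] = vals
    return D


def bootstrap_support(
    aln: MarkerAlignment,
    n_reps: int = 1000,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times (seeded); an NJ
    tree is built on each replicate and each internal edge of the full-data
    tree receives the percentage of retained replicates containing its
    bipartition.  Replicates in which some pair loses all comparable sites
    have no defined distance matrix; they are dropped and counted on the
    returned tree (``tree.bootstrap_dropped``).
    """
    aln.require_rows(3, "bootstrap_support")
    if aln.length < 1:
        raise ValueError("bootstrap_support needs at least one alignment column")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    Wm, Cm, pair_idx, n, L = _pair_site_arrays(aln)
    mism = Wm.sum(axis=1)
    comp = Cm.sum(axis=1)
    if (comp == 0).any():
        raise ValueError("alignment contains pairs with no comparable sites")
    full_d = _condensed_to_square(mism / comp, pair_idx, n)
    dm = DistanceMatrix(
        labels=list(aln.ids),
        species=list(aln.species),
        d=full_d,
        sites=_condensed_to_square(comp, pair_idx, n).astype(np.int64),
    )
    tree = neighbor_joining(dm)
    target = tree_bipartitions(tree)
    counts = dict.fromkeys(target, 0)

    rng = np.random.default_rng(seed)
    dropped = 0
    retained = 0
    for _ in range(n_reps):
        w = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(np.float32)
        cw = Cm @ w
        if (cw == 0).any():
            dropped += 1
            continue
        mw = Wm @ w
        Dr = _condensed_to_square(mw / cw, pair_idx, n)
        rep_dm = DistanceMatrix(
            labels=list(aln.ids),
            species=list(aln.species),
            d=Dr,
            sites=_condensed_to_square(cw, pair_idx, n).astype(np.int64),
        )
        rep_tree = neighbor_joining(rep_dm)
        rep_keys = tree_bipartitions(rep_tree).keys()
        retained += 1
        for key in rep_keys:
            if key in counts:
                counts[key] += 1

    if retained == 0:
        raise ValueError("every bootstrap replicate produced undefined distances")
    support_map = {}
    for key, node in target.items():
        sup = 100.0 * counts[key] / retained
        node.label = f"{sup:g}"
        support_map[key] = sup
    tree.bootstrap_replicates = n_reps
    tree.bootstrap_retained = retained
    tree.bootstrap_dropped = dropped
    tree.support_map = support_map
    return tree


# ---------------------------------------------------------------------------
# rooting

def _harvest_support_map(tree: dendropy.Tree) -> dict:
    if hasattr(tree, "support_map"):
        return dict(tree.support_map)
    universe = _leaf_labels(tree)
    out = {}
    for key, node in tree_bipartitions(tree).items():
        sup = node_support(node)
        if sup is not None:
            out[key] = sup
    return out


def _reannotate_supports(tree: dendropy.Tree, support_map: dict) -> None:
    universe = _leaf_labels(tree)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) <= 1 or len(universe - side) <= 1:
            node.label = None
            continue
        key = _canon(side, universe)
        node.label = f"{support_map[key]:g}" if key in support_map else None
    tree.support_map = dict(support_map)


def root_tree(t: dendropy.Tree, outgroup) -> dendropy.Tree:
    """Root a tree on the edge subtending the smallest clade containing ``outgroup``.

    ``outgroup`` is a set of leaf labels that must form one side of a
    bipartition of the unrooted tree (a single leaf always qualifies).
    Support labels are preserved across the rerooting.
    """
    outgroup = frozenset(outgroup)
    universe = _leaf_labels(t)
    missing = outgroup - universe
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")
    if not outgroup:
        raise ValueError("outgroup must be non-empty")
    support_map = _harvest_support_map(t)

    target_edge = None
    if len(outgroup) == 1:
        (label,) = outgroup
        leaf = next(lf for lf in t.leaf_node_iter() if lf.taxon.label == label)
        target_edge = leaf.edge
    else:
        for node in t.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if side == outgroup or side == universe - outgroup:
                target_edge = node.edge
                break
        if target_edge is None:
            raise ValueError(
                f"outgroup {sorted(outgroup)} is not monophyletic in the unrooted tree: "
                "no edge separates it from the remaining leaves"
            )
    length = target_edge.length or 0.0
    t.reroot_at_edge(target_edge, length1=length / 2, length2=length / 2)
    t.is_rooted = True
    _reannotate_supports(t, support_map)
    return t


def midpoint_root(t: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a tree, preserving support labels."""
    support_map = _harvest_support_map(t)
    t.reroot_at_midpoint()
    t.is_rooted = True
    _reannotate_supports(t, support_map)
    return t


# ---------------------------------------------------------------------------
# species-specific clusters

@dataclass
class ClusterReport:
    """Per-species monophyly/support verdicts and the headline percentage.

    ``percent_species_specific`` uses species with >= 2 specimens as the
    denominator (singletons are trivially monophyletic and carry no signal);
    ``percent_all_species`` reports the all-species variant alongside.
    """

    per_species: pd.DataFrame
    cutoff: float
    n_counted: int
    n_species: int
    percent_species_specific: float
    percent_all_species: float

    def to_frame(self) -> pd.DataFrame:
        return self.per_species


def species_specific_clusters(
    t: dendropy.Tree,
    species_of: dict[str, str] | None = None,
    cutoff: float = 70.0,
) -> ClusterReport:
    """Score species-specific clusters on a rooted, support-annotated tree.

    A species is monophyletic when some clade contains exactly its specimens;
    it counts as a supported species-specific cluster when that clade's
    support is >= ``cutoff``.  ``species_of`` maps leaf labels to species; if
    omitted, leaf labels of the form ``"Genus species|specimen"`` are not
    guessed — the mapping is required.
    """
    if species_of is None:
        raise ValueError("species_of mapping (leaf label -> species) is required")
    leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
    unknown = [l for l in leaves if l not in species_of]
    if unknown:
        raise ValueError(f"leaves without species mapping: {unknown[:5]}")
    members: dict[str, set[str]] = {}
    for l in leaves:
        members.setdefault(species_of[l], set()).add(l)

    clades: dict[frozenset, dendropy.Node] = {}
    for node in t.preorder_node_iter():
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        clades[clade] = node

    rows = []
    n_counted = 0
    n_hits = 0
    n_hits_all = 0
    for sp in sorted(members):
        spec_set = frozenset(members[sp])
        counted = len(spec_set) >= 2
        node = clades.get(spec_set)
        mono = node is not None
        support = node_support(node) if node is not None else None
        supported = mono and support is not None and support >= cutoff
        if counted:
            n_counted += 1
            n_hits += supported
        n_hits_all += supported
        rows.append(
            {
                "species": sp,
                "n_specimens": len(spec_set),
                "counted": counted,
                "monophyletic": mono,
                "support": support if support is not None else float("nan"),
                "species_specific_cluster": bool(supported),
            }
        )
    n_species = len(members)
    pct = 100.0 * n_hits / n_counted if n_counted else float("nan")
    pct_all = 100.0 * n_hits_all / n_species if n_species else float("nan")
    return ClusterReport(
        per_species=pd.DataFrame(rows),
        cutoff=cutoff,
        n_counted=n_counted,
        n_species=n_species,
        percent_species_specific=pct,
        percent_all_species=pct_all,
    )


def bootstrap_nj_tree(aln: MarkerAlignment, n_reps: int, seed: int) -> dendropy.Tree:
    """Convenience alias mirroring the CLI: full-data NJ with bootstrap supports."""
    return bootstrap_support(aln, n_reps=n_reps, seed=seed)
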