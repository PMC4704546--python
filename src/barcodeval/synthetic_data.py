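"""Seeded simulator for multi-species, multi-individual, multi-marker
barcode datasets.

The generator emulates the structure of a regional barcode study: ~30
well-delimited woody species, a handful of individuals each, and four markers
— three plastid regions that share one uniparentally inherited genealogy and
one nuclear region with an independent genealogy.  Species relationships come
from a pure-birth (Yule) tree; individuals within a species coalesce under a
neutral Kingman coalescent grafted below the species tip and truncated at the
species' divergence time (no incomplete lineage sorting — species in a
barcode reference library are established taxa, and the generator guarantees
the true genealogy respects them).  Sequences evolve by Jukes-Cantor
substitution; spacer-like markers additionally receive indels so the gap
handling of every downstream statistic is exercised, and per-(specimen,
marker) dropout emulates amplification/sequencing failure.

All lengths are expressed in expected substitutions per site at unit marker
rate; the helpers :func:`expected_p_distance` / :func:`expected_intra_p` and
their inverses convert between divergence and observable p-distance when
calibrating a study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .alignment_io import MarkerAlignment, SpecimenRecord, write_alignment, write_metadata

__all__ = [
    "MarkerSpec",
    "SimulationConfig",
    "expected_p_distance",
    "divergence_for_p",
    "depth_for_inter_p",
    "expected_intra_p",
    "theta_for_intra_p",
    "simulate_species_tree",
    "simulate_dataset",
    "SyntheticDataset",
    "write_dataset",
]


# ---------------------------------------------------------------------------
# Jukes-Cantor calibration helpers

def expected_p_distance(d: float) -> float:
    """Expected p-distance between two sequences separated by ``d`` substitutions/site."""
    if d < 0:
        raise ValueError("divergence must be >= 0")
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def divergence_for_p(p: float) -> float:
    """Inverse of :func:`expected_p_distance` (p must be < 0.75)."""
    if not 0 <= p < 0.75:
        raise ValueError("p must be in [0, 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def depth_for_inter_p(p: float) -> float:
    """Species-tree depth whose tip pairs show expected interspecific p-distance ``p``.

    Two tips of different species are separated by twice the (calibrated mean)
    MRCA depth, so this is ``divergence_for_p(p) / 2``.
    """
    return divergence_for_p(p) / 2.0


def expected_intra_p(theta: float) -> float:
    """Expected intraspecific p-distance under the coalescent + JC model.

    The pairwise path length within a species is exponential with mean
    ``theta``; averaging the JC map over that distribution gives
    ``0.75 * a / (1 + a)`` with ``a = 4 theta / 3``.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    a = 4.0 * theta / 3.0
    return 0.75 * a / (1.0 + a)


def theta_for_intra_p(p: float) -> float:
    """Inverse of :func:`expected_intra_p`."""
    if not 0 <= p < 0.75:
        raise ValueError("p must be in [0, 0.75)")
    return 0.75 * p / (0.75 - p)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class MarkerSpec:
    """One simulated marker: name, aligned length, genome, relative rate, and
    whether it behaves like an intergenic spacer (receives indels)."""

    name: str
    length: int
    genome: str = "plastid"  # or "nuclear"
    rate_scale: float = 1.0
    spacer: bool = False

    def __post_init__(self) -> None:
        if self.genome not in ("plastid", "nuclear"):
            raise ValueError("genome must be 'plastid' or 'nuclear'")
        if self.length < 1 or self.rate_scale < 0:
            raise ValueError("length must be >= 1 and rate_scale >= 0")


def _default_markers() -> tuple[MarkerSpec, ...]:
    # Lengths match the aligned widths of a typical four-marker plant study;
    # rate scales follow the relative nucleotide diversities of the same
    # markers (rbcL most conserved, trnH-psbA most variable).
    return (
        MarkerSpec("rbcL", 580, "plastid", 0.35, spacer=False),
        MarkerSpec("matK", 939, "plastid", 0.85, spacer=False),
        MarkerSpec("trnH-psbA", 707, "plastid", 1.5, spacer=True),
        MarkerSpec("ITS", 850, "nuclear", 1.0, spacer=True),
    )


def _default_missing() -> dict[str, float]:
    # Per-marker dropout emulating realized amplification+sequencing failure
    # in a four-marker study (final matrices of 68-89 sequences out of 112).
    return {"rbcL": 0.39, "matK": 0.42, "trnH-psbA": 0.20, "ITS": 0.29}


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for one synthetic dataset.

    ``interspecific_depth`` is the species-tree depth in expected
    substitutions/site at unit rate (tip pairs of different species are
    separated by twice this, on average); ``intraspecific_theta`` is the
    expected pairwise within-species divergence.  ``min_divergence_frac``
    floors the shallowest species split at that fraction of the mean
    interspecific divergence (0 recovers an unconstrained Yule tree).
    """

    n_species: int = 30
    individuals_per_species: int | tuple[int, ...] = 3
    markers: tuple[MarkerSpec, ...] = field(default_factory=_default_markers)
    interspecific_depth: float = 0.055
    intraspecific_theta: float = 0.005
    indel_rate: float = 0.02
    mean_indel_length: float = 4.0
    missing_rate: float | dict[str, float] = field(default_factory=_default_missing)
    min_divergence_frac: float = 0.25
    seed: int = 0

    def individuals(self) -> list[int]:
        if isinstance(self.individuals_per_species, int):
            return [self.individuals_per_species] * self.n_species
        if len(self.individuals_per_species) != self.n_species:
            raise ValueError("per-species individual counts must have length n_species")
        return list(self.individuals_per_species)

    def missing_for(self, marker: str) -> float:
        if isinstance(self.missing_rate, dict):
            return self.missing_rate.get(marker, 0.0)
        return self.missing_rate

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        for v in (self.interspecific_depth, self.intraspecific_theta, self.indel_rate):
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError("rates and depths must be finite and >= 0")
        if not 0 <= self.min_divergence_frac <= 1:
            raise ValueError("min_divergence_frac must be in [0, 1]")


# ---------------------------------------------------------------------------
# lightweight genealogy nodes (internal)

class _GNode:
    __slots__ = ("children", "length", "name", "time")

    def __init__(self, name=None, time=0.0):
        self.children: list[_GNode] = []
        self.length = 0.0
        self.name = name
        self.time = time  # time before present

    def leaves(self):
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


def simulate_species_tree(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Pure-birth species tree, calibrated in substitutions/site at unit rate.

    Node depths are affinely adjusted so (i) the mean pairwise tip divergence,
    pushed through the JC p-distance map, equals
    ``expected_p_distance(2 * interspecific_depth)`` and (ii) the shallowest
    split is at least ``min_divergence_frac`` of the mean (see class docs).
    For two species this reduces to a single split at exactly
    ``interspecific_depth``.  Tip labels are ``S00 .. S<n-1>``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_species
    names = [f"S{i:02d}" for i in range(n)]
    if n == 1:
        t = dendropy.Tree.get(data=f"{names[0]}:0.0;", schema="newick")
        return t

    root = _simulate_yule_nodes(n, rng)
    _calibrate_depths(root, cfg)
    return _gnode_to_dendropy(root, names)


def _simulate_yule_nodes(n: int, rng: np.random.Generator) -> _GNode:
    """Yule topology with uncalibrated split depths (time before present)."""
    t = 0.0
    birth_times = []
    for k in range(1, n):
        t += rng.exponential(1.0 / k)
        birth_times.append(t)
    t_obs = birth_times[-1] + rng.exponential(1.0 / n)
    split_depths = [t_obs - bt for bt in birth_times]  # oldest split first

    root = _GNode(time=split_depths[0])
    a, b = _GNode(time=0.0), _GNode(time=0.0)
    root.children = [a, b]
    extant = [a, b]
    for d in split_depths[1:]:
        idx = int(rng.integers(0, len(extant)))
        node = extant[idx]
        node.time = d
        c1, c2 = _GNode(time=0.0), _GNode(time=0.0)
        node.children = [c1, c2]
        extant[idx] = c1
        extant.append(c2)
    return root


def _internal_nodes(root: _GNode) -> list[_GNode]:
    out = []
    stack = [root]
    while stack:
        nd = stack.pop()
        if nd.children:
            out.append(nd)
            stack.extend(nd.children)
    return out


def _pairwise_mrca_depths(root: _GNode) -> list[float]:
    """Depth of the MRCA of every unordered tip pair (each pair once)."""
    depths = []

    def rec(node: _GNode) -> int:
        if not node.children:
            return 1
        sizes = [rec(c) for c in node.children]
        total = sum(sizes)
        # pairs whose MRCA is exactly this node: cross-child pairs
        cross = (total * total - sum(s * s for s in sizes)) // 2
        depths.extend([node.time] * cross)
        return total

    rec(root)
    return depths


def _calibrate_depths(root: _GNode, cfg: SimulationConfig) -> None:
    target = cfg.interspecific_depth
    internals = _internal_nodes(root)
    if target == 0:
        for nd in internals:
            nd.time = 0.0
        return
    pair_depths = np.asarray(_pairwise_mrca_depths(root))
    mean_d, min_d = pair_depths.mean(), pair_depths.min()
    floor = cfg.min_divergence_frac * target
    if mean_d > min_d and floor < target:
        # affine map t -> a t + b sending (mean, min) -> (target, floor)
        a = (target - floor) / (mean_d - min_d)
        b = floor - a * min_d
    else:
        a, b = target / mean_d, 0.0
    for nd in internals:
        nd.time = a * nd.time + b
    # nonlinear refinement: uniform scale s so the mean JC-mapped pairwise
    # divergence matches the closed-form target exactly
    times = np.asarray([a * d + b for d in pair_depths])
    goal = expected_p_distance(2.0 * target)

    def mean_p(s: float) -> float:
        return float(np.mean(0.75 * (1.0 - np.exp(-8.0 * s * times / 3.0))))

    lo, hi = 0.25, 4.0
    while mean_p(hi) < goal:
        hi *= 2
    while mean_p(lo) > goal:
        lo /= 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < goal:
            lo = mid
        else:
            hi = mid
    s = 0.5 * (lo + hi)
    for nd in internals:
        nd.time *= s


def _gnode_to_dendropy(root: _GNode, names: list[str]) -> dendropy.Tree:
    # assign names to tips in left-to-right order so contiguous clades get
    # adjacent species numbers
    tips = list(root.leaves())
    for tip, name in zip(tips, names):
        tip.name = name
    tns = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(gn: _GNode) -> dendropy.Node:
        if not gn.children:
            nd = dendropy.Node(taxon=tns.get_taxon(gn.name))
        else:
            nd = dendropy.Node()
        for c in gn.children:
            child = build(c)
            nd.add_child(child)
            child.edge.length = max(gn.time - c.time, 0.0)
        return nd

    tree.seed_node = build(root)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# genealogies and sequence evolution

def _coalescent_subtree(
    tip_names: list[str],
    theta: float,
    ceiling: float,
    rng: np.random.Generator,
) -> _GNode:
    """Kingman coalescent over ``tip_names`` with expected pairwise divergence
    ``theta``, truncated at ``ceiling`` (remaining lineages merge just below it)."""
    nodes = [_GNode(name=nm, time=0.0) for nm in tip_names]
    if len(nodes) == 1:
        return nodes[0]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        # pairwise coalescence at rate 2/theta per pair gives E[pair time] =
        # theta/2 and hence expected pairwise path length theta
        if theta > 0:
            t += rng.exponential(theta / 2.0 / (k * (k - 1) / 2.0))
        if theta == 0 or t >= ceiling:
            t = min(t, ceiling)
            # force-merge everything remaining at the ceiling (or at 0)
            merged = _GNode(time=t)
            merged.children = nodes
            return merged
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = _GNode(time=t)
        parent.children = [nodes[i], nodes[j]]
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)] + [parent]
    return nodes[0]


def _genealogy(
    species_tree: dendropy.Tree,
    tips_per_species: dict[str, list[str]],
    theta: float,
    rng: np.random.Generator,
) -> _GNode:
    """Graft within-species coalescents onto the species tree."""
    # species node times
    def to_gnode(nd: dendropy.Node) -> _GNode:
        if nd.is_leaf():
            sp = nd.taxon.label
            parent_time = _node_time(nd.parent_node) if nd.parent_node else float("inf")
            return _coalescent_subtree(tips_per_species[sp], theta, parent_time, rng)
        g = _GNode(time=_node_time(nd))
        g.children = [to_gnode(c) for c in nd.child_nodes()]
        return g

    times = {}

    def _node_time(nd: dendropy.Node) -> float:
        if nd in times:
            return times[nd]
        # depth below = max distance to a leaf (ultrametric, so any path works)
        if nd.is_leaf():
            t = 0.0
        else:
            c = nd.child_nodes()[0]
            t = _node_time(c) + (c.edge.length or 0.0)
        times[nd] = t
        return t

    root = to_gnode(species_tree.seed_node)
    return root


def _evolve_sequences(
    root: _GNode,
    length: int,
    rate: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Jukes-Cantor evolution along the genealogy; returns leaf name -> int8 codes."""
    out: dict[str, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=length).astype(np.int8)

    stack = [(root, root_seq, root.time)]
    while stack:
        node, seq, parent_time = stack.pop()
        if node is not root:
            b = max(parent_time - node.time, 0.0) * rate
            if b > 0:
                p_change = 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))
                hit = rng.random(length) < p_change
                n_hit = int(hit.sum())
                if n_hit:
                    seq = seq.copy()
                    # uniform among the three other bases
                    seq[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit).astype(np.int8)) % 4
        if not node.children:
            out[node.name] = seq
        else:
            for c in node.children:
                stack.append((c, seq, node.time))
    return out


def _apply_indels(
    leaf_seqs: dict[str, np.ndarray],
    root: _GNode,
    length: int,
    indel_rate: float,
    mean_len: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Overlay indels: deletion events knock out a window in a subtree; insertion
    events add a subtree-private column block (gap everywhere else).

    Events occur on each branch at rate ``indel_rate`` per site per unit
    branch length.  The true alignment is returned directly (column registry),
    so no alignment step is ever needed downstream.
    """
    # collect branches: (node, branch_length)
    branches: list[tuple[_GNode, float]] = []

    def walk(nd: _GNode, parent_time: float) -> None:
        if parent_time is not None:
            branches.append((nd, max(parent_time - nd.time, 0.0)))
        for c in nd.children:
            walk(c, nd.time)

    walk(root, None)

    deletions: list[tuple[set[str], int, int]] = []  # (leaves, start, stop)
    insertions: list[tuple[set[str], int, np.ndarray]] = []  # (leaves, anchor, content)
    geom_p = 1.0 / max(mean_len, 1.0)
    for nd, blen in branches:
        n_events = rng.poisson(indel_rate * length * blen)
        if not n_events:
            continue
        leaves = {lf.name for lf in nd.leaves()}
        for _ in range(n_events):
            w = int(rng.geometric(geom_p))
            start = int(rng.integers(0, length))
            if rng.random() < 0.5:
                deletions.append((leaves, start, min(start + w, length)))
            else:
                insertions.append((leaves, start, rng.integers(0, 4, size=w).astype(np.int8)))

    names = sorted(leaf_seqs)
    base = "ACGT"
    # ancestral columns with per-leaf deletion masks
    masks = {nm: np.zeros(length, dtype=bool) for nm in names}
    for leaves, start, stop in deletions:
        for nm in leaves:
            if nm in masks:
                masks[nm][start:stop] = True

    # order insertions by anchor then event order for a stable column layout
    ins_by_anchor: dict[int, list[tuple[set[str], np.ndarray]]] = {}
    for leaves, anchor, content in insertions:
        ins_by_anchor.setdefault(anchor, []).append((leaves, content))

    rows = {nm: [] for nm in names}
    for col in range(length):
        for nm in names:
            if masks[nm][col]:
                rows[nm].append("-")
            else:
                rows[nm].append(base[leaf_seqs[nm][col]])
        for leaves, content in ins_by_anchor.get(col, []):
            block = "".join(base[b] for b in content)
            gaps = "-" * len(content)
            for nm in names:
                rows[nm].append(block if nm in leaves else gaps)
    return {nm: "".join(parts) for nm, parts in rows.items()}


# ---------------------------------------------------------------------------
# full dataset

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    records: dict[str, SpecimenRecord]
    alignments: dict[str, MarkerAlignment]
    raw: dict[str, list[tuple[str, str]]]
    species_tree: dendropy.Tree


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Simulate a complete multi-marker dataset under ``cfg`` (byte-reproducible
    for a fixed seed)."""
    ss = np.random.SeedSequence(cfg.seed)
    keys = ["species_tree", "genealogy_plastid", "genealogy_nuclear", "markers", "missing"]
    streams = {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}

    species_tree = simulate_species_tree(cfg, streams["species_tree"])
    counts = cfg.individuals()
    species_names = [f"S{i:02d}" for i in range(cfg.n_species)]
    tips_per_species = {
        sp: [f"{sp}_i{j}" for j in range(counts[i])] for i, sp in enumerate(species_names)
    }

    # two genealogy classes: all plastid markers share one; nuclear markers
    # draw an independent one (same species tree, independent coalescents)
    genealogies = {
        "plastid": _genealogy(species_tree, tips_per_species, cfg.intraspecific_theta,
                              streams["genealogy_plastid"]),
        "nuclear": _genealogy(species_tree, tips_per_species, cfg.intraspecific_theta,
                              streams["genealogy_nuclear"]),
    }

    # taxonomy bookkeeping: three species per genus, two genera per family,
    # assigned in tip order so higher taxa tend to be tree-contiguous
    records: dict[str, SpecimenRecord] = {}
    for i, sp in enumerate(species_names):
        genus = f"Genus{i // 3:02d}"
        family = f"Family{i // 6:02d}"
        for tip in tips_per_species[sp]:
            records[tip] = SpecimenRecord(
                specimen_id=tip, species=f"{genus} species{i:02d}", genus=genus, family=family
            )
    species_label = {sp: records[tips_per_species[sp][0]].species for sp in species_names}

    marker_rng = streams["markers"]
    missing_rng = streams["missing"]
    alignments: dict[str, MarkerAlignment] = {}
    raw: dict[str, list[tuple[str, str]]] = {}
    all_tips = [t for sp in species_names for t in tips_per_species[sp]]

    for spec in cfg.markers:
        gen = genealogies[spec.genome]
        leaf_codes = _evolve_sequences(gen, spec.length, spec.rate_scale, marker_rng)
        if spec.spacer and cfg.indel_rate > 0:
            aligned = _apply_indels(
                leaf_codes, gen, spec.length, cfg.indel_rate, cfg.mean_indel_length, marker_rng
            )
        else:
            base = "ACGT"
            aligned = {nm: "".join(base[b] for b in codes) for nm, codes in leaf_codes.items()}

        drop_p = cfg.missing_for(spec.name)
        keep = [t for t in all_tips if missing_rng.random() >= drop_p]
        ids = [t for t in all_tips if t in set(keep)]
        aln = MarkerAlignment(
            marker=spec.name,
            ids=ids,
            species=[records[t].species for t in ids],
            seqs=[aligned[t] for t in ids],
        )
        alignments[spec.name] = aln
        raw[spec.name] = [(t, aligned[t].replace("-", "")) for t in ids]
        for t in ids:
            records[t].sequences[spec.name] = aligned[t]

    # relabel species-tree tips with full species names for downstream joins
    for leaf in species_tree.leaf_node_iter():
        leaf.taxon.label = species_label[leaf.taxon.label]

    return SyntheticDataset(
        config=cfg,
        records=records,
        alignments=alignments,
        raw=raw,
        species_tree=species_tree,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Emit per-marker aligned FASTA, degapped raw FASTA, metadata CSV, the true
    species tree, and a config echo.  Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, aln in ds.alignments.items():
        p = out / f"{name}.aligned.fasta"
        write_alignment(aln, p)
        paths[f"aligned:{name}"] = p
        p2 = out / f"{name}.raw.fasta"
        with open(p2, "w") as fh:
            for sid, seq in ds.raw[name]:
                fh.write(f">{sid}\n{seq}\n")
        paths[f"raw:{name}"] = p2
    meta = out / "metadata.csv"
    write_metadata(ds.records, meta)
    paths["metadata"] = meta
    tre = out / "species_tree.nwk"
    tre.write_text(ds.species_tree.as_string(schema="newick"))
    paths["species_tree"] = tre
    cfgp = out / "config_echo.txt"
    cfgp.write_text(repr(ds.config) + "\n")
    paths["config"] = cfgp
    return paths
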