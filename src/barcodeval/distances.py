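"""Uncorrected p-distances, intra/interspecific partitioning, and
barcoding-gap summaries.

All distances are uncorrected proportions of mismatching sites computed with
*pairwise deletion*: for each pair of sequences, any column in which either
sequence carries a gap ('-'), an N, or a '?' is excluded from the comparison.
A pair with zero comparable sites has an undefined distance (stored as NaN)
and is excluded from every downstream summary, with the exclusion counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_io import AlignmentError, MarkerAlignment

__all__ = [
    "encode_sequence",
    "p_distance",
    "DistanceMatrix",
    "pairwise_matrix",
    "partition_distances",
    "GapSummary",
    "gap_summary",
]

# A,C,G,T -> 0..3; missing symbols -> -1
_CODE = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
for _b in "N-?n":
    _CODE[ord(_b)] = -1


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8: A,C,G,T -> 0..3, missing -> -1."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == -2).any():
        bad = sorted({seq[i] for i in np.where(arr == -2)[0]})
        raise AlignmentError(f"unsupported sequence characters {bad}")
    return arr


def encode_alignment(aln: MarkerAlignment) -> np.ndarray:
    """Encode all rows of an alignment as an (n, L) int8 matrix."""
    return np.vstack([encode_sequence(s) for s in aln.seqs])


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Uncorrected p-distance between two aligned sequences.

    Returns ``(distance, comparable_sites)``; the distance is NaN when no
    site is comparable after pairwise deletion.
    """
    if len(a) != len(b):
        raise AlignmentError(f"sequences have unequal lengths {len(a)} and {len(b)}")
    xa, xb = encode_sequence(a), encode_sequence(b)
    comp = (xa >= 0) & (xb >= 0)
    n = int(comp.sum())
    if n == 0:
        return float("nan"), 0
    mism = int(((xa != xb) & comp).sum())
    return mism / n, n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix with comparable-site counts.

    ``d[i, j]`` is NaN exactly where ``sites[i, j] == 0``.
    """

    labels: list[str]
    species: list[str]
    d: np.ndarray
    sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n) or self.sites.shape != (n, n):
            raise ValueError("distance/site matrices must be square over labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, specimen_id: str) -> int:
        try:
            return self.labels.index(specimen_id)
        except ValueError:
            raise KeyError(f"specimen {specimen_id!r} not in distance matrix")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index_of(a), self.index_of(b)])

    def n_undefined_pairs(self) -> int:
        """Number of unordered off-diagonal pairs with no comparable sites."""
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.d[iu]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        """Square CSV with a header row/column of specimen ids."""
        self.to_frame().to_csv(path, index_label="specimen_id", float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, species_of: dict[str, str] | None = None) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = [str(c) for c in df.columns]
        d = df.to_numpy(dtype=float)
        sites = np.where(np.isnan(d), 0, 1).astype(np.int64)
        np.fill_diagonal(sites, 1)
        species = [species_of.get(l, "") if species_of else "" for l in labels]
        return cls(labels=labels, species=species, d=d, sites=sites)

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square distance format (undefined pairs written as -1)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(
                    "-1" if np.isnan(v) else f"{v:.10f}" for v in self.d[i]
                )
                fh.write(f"{lab:<10s} {row}\n")


def pairwise_matrix(aln: MarkerAlignment) -> DistanceMatrix:
    """Compute all unordered-pair p-distances for an alignment (pairwise deletion)."""
    aln.require_rows(2, "pairwise_matrix")
    X = encode_alignment(aln)
    valid = X >= 0
    n = X.shape[0]
    d = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        comp = valid[i] & valid[i + 1 :]
        mism = (X[i] != X[i + 1 :]) & comp
        c = comp.sum(axis=1)
        m = mism.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(c > 0, m / np.maximum(c, 1), np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
        sites[i, i + 1 :] = c
        sites[i + 1 :, i] = c
    sites[np.diag_indices(n)] = valid.sum(axis=1)
    diag_undefined = sites.diagonal() == 0
    if diag_undefined.any():
        d[np.diag_indices(n)] = np.where(diag_undefined, np.nan, 0.0)
    return DistanceMatrix(labels=list(aln.ids), species=list(aln.species), d=d, sites=sites)


def partition_distances(
    m: DistanceMatrix, return_counts: bool = False
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, int]:
    """Split defined unordered pairs into intraspecific and interspecific lists.

    A pair is intraspecific iff both specimens carry the same species string.
    Undefined pairs (zero comparable sites) are excluded; their count is
    returned when ``return_counts`` is set.
    """
    sp = np.asarray(m.species, dtype=object)
    iu, ju = np.triu_indices(m.n, k=1)
    vals = m.d[iu, ju]
    defined = ~np.isnan(vals)
    same = sp[iu] == sp[ju]
    intra = vals[defined & same]
    inter = vals[defined & ~same]
    if return_counts:
        return intra, inter, int((~defined).sum())
    return intra, inter


@dataclass
class GapSummary:
    """Barcoding-gap summary: distance histograms and threshold fractions."""

    intra: np.ndarray
    inter: np.ndarray
    bin_width: float
    bin_edges: np.ndarray
    intra_hist: np.ndarray
    inter_hist: np.ndarray
    threshold_x: float
    frac_inter_above_x: float
    frac_intra_below_x: float
    max_intra: float
    min_inter: float
    overlap: bool
    n_undefined_pairs: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Binned relative frequencies, one row per bin."""
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "intra_freq": self.intra_hist,
                "inter_freq": self.inter_hist,
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_intra": len(self.intra),
                    "n_inter": len(self.inter),
                    "threshold_x": self.threshold_x,
                    "frac_inter_above_x": self.frac_inter_above_x,
                    "frac_intra_below_x": self.frac_intra_below_x,
                    "max_intra": self.max_intra,
                    "min_inter": self.min_inter,
                    "overlap": self.overlap,
                    "n_undefined_pairs": self.n_undefined_pairs,
                }
            ]
        )


def gap_summary(
    intra,
    inter,
    bin_width: float = 0.01,
    threshold_x: float = 0.05,
    n_undefined_pairs: int = 0,
) -> GapSummary:
    """Summarise the barcoding gap between intra- and interspecific distances.

    ``frac_inter_above_x`` is the proportion of interspecific distances
    strictly greater than ``threshold_x``; ``frac_intra_below_x`` the
    proportion of intraspecific distances strictly lower.  The overlap flag is
    true when max(intra) >= min(inter), i.e. when there is no gap.
    """
    intra = np.asarray(list(intra), dtype=float)
    inter = np.asarray(list(inter), dtype=float)
    if intra.size == 0 and inter.size == 0:
        raise ValueError("gap_summary requires at least one non-empty distance list")
    hi = float(max(intra.max(initial=0.0), inter.max(initial=0.0)))
    n_bins = max(1, int(np.ceil(hi / bin_width - 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    if edges[-1] < hi:  # guard against rounding
        edges = np.append(edges, edges[-1] + bin_width)

    def _relfreq(vals: np.ndarray) -> np.ndarray:
        if vals.size == 0:
            return np.zeros(len(edges) - 1)
        counts, _ = np.histogram(vals, bins=edges)
        return counts / vals.size

    max_intra = float(intra.max()) if intra.size else float("nan")
    min_inter = float(inter.min()) if inter.size else float("nan")
    return GapSummary(
        intra=intra,
        inter=inter,
        bin_width=bin_width,
        bin_edges=edges,
        intra_hist=_relfreq(intra),
        inter_hist=_relfreq(inter),
        threshold_x=threshold_x,
        frac_inter_above_x=float((inter > threshold_x).mean()) if inter.size else float("nan"),
        frac_intra_below_x=float((intra < threshold_x).mean()) if intra.size else float("nan"),
        max_intra=max_intra,
        min_inter=min_inter,
        overlap=bool(intra.size and inter.size and max_intra >= min_inter),
        n_undefined_pairs=n_undefined_pairs,
    )
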