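"""Marker variability statistics: polymorphic and parsimony-informative
sites, gapped sites, nucleotide diversity, haplotype counting, and raw
sequence-length summaries.

All site-based statistics use *complete deletion*: any alignment column in
which any sequence carries '-', 'N' or '?' is excluded before counting, so a
"usable" site is fully resolved in every row.  This matches the convention of
population-genetics packages that discount gapped/missing columns when
reporting polymorphism tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, median
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_io import MarkerAlignment
from .distances import encode_alignment

__all__ = [
    "site_classes",
    "polymorphic_and_pic",
    "nucleotide_diversity",
    "haplotypes",
    "shared_haplotypes",
    "length_stats",
    "DiversityStats",
    "marker_diversity",
]


def site_classes(aln: MarkerAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Partition columns into gap/missing sites and fully-resolved usable sites.

    Returns ``(gap_sites, usable_sites)`` as sorted column-index arrays.
    """
    aln.require_rows(2, "site_classes")
    X = encode_alignment(aln)
    gap_col = (X < 0).any(axis=0)
    cols = np.arange(X.shape[1])
    return cols[gap_col], cols[~gap_col]


def _usable_matrix(aln: MarkerAlignment) -> np.ndarray:
    X = encode_alignment(aln)
    return X[:, (X >= 0).all(axis=0)]


def polymorphic_and_pic(aln: MarkerAlignment) -> tuple[int, int]:
    """Count polymorphic and parsimony-informative sites over usable columns.

    A usable column is polymorphic when >= 2 distinct bases occur, and
    parsimony-informative when >= 2 distinct bases each occur in >= 2 rows.
    """
    U = _usable_matrix(aln)
    if U.shape[1] == 0:
        return 0, 0
    n_poly = 0
    n_pic = 0
    for col in U.T:
        counts = np.bincount(col, minlength=4)
        states = counts > 0
        if states.sum() >= 2:
            n_poly += 1
            if (counts >= 2).sum() >= 2:
                n_pic += 1
    return n_poly, n_pic


def nucleotide_diversity(aln: MarkerAlignment) -> float:
    """Nucleotide diversity (pi): mean pairwise mismatch proportion over usable sites."""
    aln.require_rows(2, "nucleotide_diversity")
    U = _usable_matrix(aln)
    L = U.shape[1]
    if L == 0:
        raise ValueError(
            f"alignment {aln.marker!r} has no usable (ungapped, fully resolved) sites"
        )
    n = U.shape[0]
    total = 0
    for i in range(n - 1):
        total += int((U[i] != U[i + 1 :]).sum())
    n_pairs = n * (n - 1) // 2
    return total / (n_pairs * L)


def haplotypes(aln: MarkerAlignment) -> tuple[int, dict[str, int]]:
    """Collapse sequences identical over usable sites into haplotypes.

    Haplotypes are numbered by first occurrence (0-based); returns the count
    and a specimen_id -> haplotype index assignment.
    """
    if aln.n_rows == 0:
        return 0, {}
    if aln.n_rows == 1:
        return 1, {aln.ids[0]: 0}
    U = _usable_matrix(aln)
    seen: dict[bytes, int] = {}
    assignment: dict[str, int] = {}
    for sid, row in zip(aln.ids, U):
        key = row.tobytes()
        if key not in seen:
            seen[key] = len(seen)
        assignment[sid] = seen[key]
    return len(seen), assignment


def shared_haplotypes(aln: MarkerAlignment) -> list[dict]:
    """Report haplotypes shared across species.

    Returns one entry per haplotype observed in more than one species, with
    the haplotype index, the species involved, and the specimens carrying it.
    Useful for spotting markers that cannot separate congeners (e.g. a single
    haplotype shared by all members of a genus).
    """
    _, assignment = haplotypes(aln)
    sp_of = aln.species_of()
    by_h: dict[int, list[str]] = {}
    for sid, h in assignment.items():
        by_h.setdefault(h, []).append(sid)
    out = []
    for h, sids in sorted(by_h.items()):
        species = sorted({sp_of[s] for s in sids})
        if len(species) > 1:
            out.append({"haplotype": h, "species": species, "specimens": sorted(sids)})
    return out


def length_stats(raw: Iterable[str | tuple[str, str]]) -> tuple[float, float, int]:
    """Mean and median unaligned sequence length.

    Accepts raw sequence strings or ``(id, sequence)`` pairs; gap and pad
    characters ('-', '?'), if present, are not counted.  Returns
    ``(mean, median, n)``.
    """
    lengths = []
    for item in raw:
        seq = item[1] if isinstance(item, tuple) else item
        lengths.append(len(seq) - seq.count("-") - seq.count("?"))
    if not lengths:
        raise ValueError("length_stats requires at least one sequence")
    return float(mean(lengths)), float(median(lengths)), len(lengths)


@dataclass
class DiversityStats:
    """One marker's variability summary (one row of a marker-comparison table)."""

    marker: str
    n_sequences: int
    mean_length: float
    median_length: float
    alignment_length: int
    n_polymorphic: int
    n_pic: int
    n_gap_sites: int
    pi: float
    n_haplotypes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def marker_diversity(
    aln: MarkerAlignment,
    raw: Sequence[str | tuple[str, str]] | None = None,
) -> DiversityStats:
    """Compute the full variability summary for one marker.

    ``raw`` supplies unaligned sequences for the length statistics; when
    omitted, lengths are taken from the alignment rows with gaps removed.
    """
    gap_sites, usable = site_classes(aln)
    n_poly, n_pic = polymorphic_and_pic(aln)
    pi = nucleotide_diversity(aln) if usable.size else float("nan")
    n_hap, _ = haplotypes(aln)
    mean_len, median_len, _ = length_stats(raw if raw is not None else aln.seqs)
    return DiversityStats(
        marker=aln.marker,
        n_sequences=aln.n_rows,
        mean_length=mean_len,
        median_length=median_len,
        alignment_length=aln.length,
        n_polymorphic=n_poly,
        n_pic=n_pic,
        n_gap_sites=int(gap_sites.size),
        pi=pi,
        n_haplotypes=n_hap,
    )
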