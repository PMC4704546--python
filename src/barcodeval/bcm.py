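"""The 'best close match' species-identification test.

Every specimen is queried in turn against all other specimens in the matrix
(leave-one-out).  A similarity threshold is first derived from the empirical
distribution of intraspecific distances: the smallest observed intraspecific
distance below which at least 95% (by default) of all intraspecific distances
fall.  Candidates for a query are all other specimens at a defined distance
less than or equal to the threshold.  The query is then classified:

* ``correct``   - every nearest candidate (the tie set at the minimum
                  candidate distance) is conspecific;
* ``ambiguous`` - the tie set mixes conspecific and heterospecific specimens;
* ``incorrect`` - no conspecific is in the tie set (the nearest candidates
                  all belong to other species);
* ``no_match``  - no specimen at all lies within the threshold.

The threshold is computed once per distance matrix (per marker or per marker
combination).  Queries of singleton species — species represented by exactly
one specimen, for which no conspecific exists anywhere — follow the same
rules (hence can never be ``correct``) and are additionally counted so that
identification percentages can be reported with and without them in the
denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_io import MarkerAlignment
from .distances import DistanceMatrix, pairwise_matrix, partition_distances

__all__ = [
    "CATEGORIES",
    "BCMThreshold",
    "compute_threshold",
    "BCMResult",
    "classify_query",
    "BCMReport",
    "bcm_summary",
    "bcm_summary_from_matrix",
]

CATEGORIES = ("correct", "ambiguous", "incorrect", "no_match")


@dataclass(frozen=True)
class BCMThreshold:
    """The identification threshold: an empirical quantile of intraspecific distances."""

    value: float
    percentile: float
    n_intra_pairs: int


def compute_threshold(intra, percentile: float = 0.95) -> BCMThreshold:
    """Smallest observed intraspecific distance d with P(intra <= d) >= percentile."""
    vals = np.sort(np.asarray(list(intra), dtype=float))
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("compute_threshold requires at least one intraspecific distance")
    if not 0 < percentile <= 1:
        raise ValueError(f"percentile must be in (0, 1], got {percentile}")
    idx = math.ceil(percentile * vals.size) - 1
    return BCMThreshold(value=float(vals[idx]), percentile=percentile, n_intra_pairs=vals.size)


@dataclass(frozen=True)
class BCMResult:
    query_id: str
    species: str
    category: str
    best_match_id: str | None
    best_distance: float
    n_candidates: int
    is_singleton: bool


def classify_query(
    query_id: str,
    m: DistanceMatrix,
    t: BCMThreshold,
    tie_tol: float = 0.0,
) -> BCMResult:
    """Classify one query against all other specimens in the matrix.

    Undefined distances (zero comparable sites) never make a specimen a
    candidate.  ``tie_tol`` widens the tie set around the minimum candidate
    distance; the default of 0 keeps classification exact and deterministic.
    """
    if m.n < 2:
        raise ValueError("classify_query needs a matrix of at least 2 specimens")
    q = m.index_of(query_id)
    dq = m.d[q].copy()
    dq[q] = np.nan
    species = np.asarray(m.species, dtype=object)
    conspecific_exists = bool(((species == species[q]) & (np.arange(m.n) != q)).any())

    candidates = np.where(~np.isnan(dq) & (dq <= t.value))[0]
    if candidates.size == 0:
        return BCMResult(
            query_id=query_id,
            species=str(species[q]),
            category="no_match",
            best_match_id=None,
            best_distance=float("nan"),
            n_candidates=0,
            is_singleton=not conspecific_exists,
        )
    d_min = float(dq[candidates].min())
    tie = candidates[dq[candidates] <= d_min + tie_tol]
    tie_conspecific = species[tie] == species[q]
    if tie_conspecific.all():
        category = "correct"
    elif tie_conspecific.any():
        category = "ambiguous"
    else:
        category = "incorrect"
    # deterministic representative: smallest label among nearest candidates
    nearest = candidates[dq[candidates] == d_min]
    best = min(m.labels[i] for i in nearest)
    return BCMResult(
        query_id=query_id,
        species=str(species[q]),
        category=category,
        best_match_id=best,
        best_distance=d_min,
        n_candidates=int(candidates.size),
        is_singleton=not conspecific_exists,
    )


@dataclass
class BCMReport:
    """Per-query classifications plus category counts and percentages.

    ``percent`` uses all evaluated queries as denominator; ``percent_non_singleton``
    excludes queries from singleton species.
    """

    results: list[BCMResult]
    threshold: BCMThreshold
    tie_tol: float = 0.0

    @property
    def n_queries(self) -> int:
        return len(self.results)

    @property
    def n_singleton_queries(self) -> int:
        return sum(r.is_singleton for r in self.results)

    def counts(self, include_singletons: bool = True) -> dict[str, int]:
        out = dict.fromkeys(CATEGORIES, 0)
        for r in self.results:
            if include_singletons or not r.is_singleton:
                out[r.category] += 1
        return out

    def percentages(self, include_singletons: bool = True) -> dict[str, float]:
        counts = self.counts(include_singletons)
        total = sum(counts.values())
        if total == 0:
            return dict.fromkeys(CATEGORIES, float("nan"))
        return {k: 100.0 * v / total for k, v in counts.items()}

    def per_query_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query_id": r.query_id,
                    "species": r.species,
                    "category": r.category,
                    "best_match_id": r.best_match_id if r.best_match_id is not None else "",
                    "best_distance": r.best_distance,
                    "n_candidates": r.n_candidates,
                    "is_singleton": r.is_singleton,
                }
                for r in self.results
            ]
        )

    def summary_frame(self) -> pd.DataFrame:
        counts_all = self.counts(True)
        pct_all = self.percentages(True)
        counts_ns = self.counts(False)
        pct_ns = self.percentages(False)
        rows = []
        for cat in CATEGORIES:
            rows.append(
                {
                    "category": cat,
                    "count": counts_all[cat],
                    "percent": pct_all[cat],
                    "count_non_singleton": counts_ns[cat],
                    "percent_non_singleton": pct_ns[cat],
                }
            )
        df = pd.DataFrame(rows)
        df.attrs["threshold"] = self.threshold.value
        df.attrs["n_singleton_queries"] = self.n_singleton_queries
        return df


def bcm_summary_from_matrix(
    m: DistanceMatrix,
    percentile: float = 0.95,
    tie_tol: float = 0.0,
) -> BCMReport:
    """Leave-one-out best-close-match over a precomputed distance matrix."""
    if len(set(m.species)) < 2:
        raise ValueError("best close match requires at least 2 species in the matrix")
    intra, _ = partition_distances(m)
    if intra.size == 0:
        raise ValueError(
            "no intraspecific distances available to set a threshold "
            "(every species is a singleton or all conspecific pairs are undefined)"
        )
    threshold = compute_threshold(intra, percentile)
    results = [classify_query(sid, m, threshold, tie_tol) for sid in m.labels]
    return BCMReport(results=results, threshold=threshold, tie_tol=tie_tol)


def bcm_summary(
    aln: MarkerAlignment,
    percentile: float = 0.95,
    tie_tol: float = 0.0,
) -> BCMReport:
    """Best-close-match identification test for one marker alignment."""
    return bcm_summary_from_matrix(pairwise_matrix(aln), percentile, tie_tol)
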