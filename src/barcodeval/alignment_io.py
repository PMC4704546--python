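"""Data model and I/O for aligned marker matrices, specimen metadata, and
multi-marker concatenation.

The central containers are :class:`SpecimenRecord` (one vouchered individual
with its per-marker sequences) and :class:`MarkerAlignment` (an equal-length
aligned matrix for one marker or a concatenation, with specimen -> species
labels carried along).  Concatenation follows the combination-scheme logic
used in multi-marker barcode studies: a specimen enters a combined
supermatrix only if it has sequence for at least ``min_markers_required`` of
the scheme's markers, and absent blocks are padded with a missing-data
character that every downstream statistic treats as non-comparable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignmentError",
    "MetadataError",
    "FilterError",
    "SpecimenRecord",
    "MarkerAlignment",
    "CombinationScheme",
    "read_metadata",
    "write_metadata",
    "read_alignment",
    "read_fasta",
    "write_alignment",
    "concatenate_markers",
    "write_tables",
    "read_tables",
]

#: Characters accepted in sequences.  Anything in MISSING_CHARS is treated as
#: missing data by every downstream comparison.
ALPHABET = frozenset("ACGTN-?")
MISSING_CHARS = frozenset("N-?")


class AlignmentError(ValueError):
    """Raised for ragged or otherwise malformed alignments."""


class MetadataError(KeyError):
    """Raised when a sequence id cannot be resolved to specimen metadata."""


class FilterError(ValueError):
    """Raised when a filtering step leaves nothing to analyse."""


def _validate_sequence(seq: str, ident: str) -> str:
    seq = seq.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise AlignmentError(
            f"sequence {ident!r} contains unsupported characters {sorted(bad)}; "
            f"allowed alphabet is {''.join(sorted(ALPHABET))} "
            "(IUPAC ambiguity codes other than N are not supported)"
        )
    return seq


@dataclass
class SpecimenRecord:
    """One vouchered individual: identity, taxonomy, and per-marker sequences."""

    specimen_id: str
    species: str
    genus: str = ""
    family: str = ""
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise MetadataError("specimen_id must be non-empty")
        if not self.species:
            raise MetadataError(f"specimen {self.specimen_id!r}: species must be non-empty")
        if not self.genus:
            # binomials carry the genus in the first token
            self.genus = self.species.split()[0]
        self.sequences = {
            m: _validate_sequence(s, f"{self.specimen_id}/{m}") for m, s in self.sequences.items()
        }


@dataclass
class MarkerAlignment:
    """Equal-length aligned sequences for one marker (or a concatenation).

    ``block_map`` is populated for concatenations and maps each constituent
    marker name to its half-open column range ``(start, stop)``.
    """

    marker: str
    ids: list[str]
    species: list[str]
    seqs: list[str]
    block_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len({len(self.ids), len(self.species), len(self.seqs)}) != 1:
            raise AlignmentError("ids, species and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate specimen ids in alignment: {dupes}")
        self.seqs = [_validate_sequence(s, i) for i, s in zip(self.ids, self.seqs)]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(
                f"alignment {self.marker!r} is ragged: row lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    def species_of(self) -> dict[str, str]:
        return dict(zip(self.ids, self.species))

    def row(self, specimen_id: str) -> str:
        try:
            return self.seqs[self.ids.index(specimen_id)]
        except ValueError:
            raise MetadataError(f"specimen {specimen_id!r} not in alignment {self.marker!r}")

    def require_rows(self, n: int, op: str) -> None:
        if self.n_rows < n:
            raise AlignmentError(
                f"{op} needs at least {n} sequences; alignment {self.marker!r} has {self.n_rows}"
            )


@dataclass(frozen=True)
class CombinationScheme:
    """A multi-marker combination: which markers, how many a specimen must have,
    and the pad character for absent blocks."""

    markers: tuple[str, ...]
    min_markers_required: int = 1
    fill_char: str = "?"
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.min_markers_required <= len(self.markers):
            raise ValueError(
                f"min_markers_required must be in [1, {len(self.markers)}], "
                f"got {self.min_markers_required}"
            )
        if self.fill_char not in ("N", "?"):
            raise ValueError("fill_char must be 'N' or '?'")
        if not self.label:
            object.__setattr__(self, "label", "+".join(self.markers))


def read_metadata(path: str | Path) -> dict[str, SpecimenRecord]:
    """Read a specimen metadata CSV (specimen_id, species, genus, family)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"specimen_id", "species"}
    if not required.issubset(df.columns):
        raise MetadataError(f"metadata {path} must have columns {sorted(required)}")
    records: dict[str, SpecimenRecord] = {}
    for row in df.itertuples(index=False):
        rec = SpecimenRecord(
            specimen_id=row.specimen_id,
            species=row.species,
            genus=getattr(row, "genus", ""),
            family=getattr(row, "family", ""),
        )
        if rec.specimen_id in records:
            raise MetadataError(f"duplicate specimen_id {rec.specimen_id!r} in {path}")
        records[rec.specimen_id] = rec
    return records


def write_metadata(records: Mapping[str, SpecimenRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "genus": r.genus,
                "family": r.family,
            }
            for r in records.values()
        ]
    )
    df.to_csv(path, index=False)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly unaligned) FASTA as ``[(id, sequence), ...]`` in file order.

    The FASTA id token must equal the specimen id exactly; descriptions are
    ignored deliberately so joins against metadata are bit-exact.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, _validate_sequence(str(rec.seq), rec.id)))
    if not out:
        raise AlignmentError(f"no sequences found in {path}")
    return out


def read_alignment(
    fasta_path: str | Path,
    metadata: Mapping[str, SpecimenRecord] | str | Path,
    marker: str | None = None,
) -> MarkerAlignment:
    """Read an aligned FASTA and attach species labels from metadata.

    Rows keep FASTA order.  Every FASTA id must resolve to a specimen record;
    ragged rows raise :class:`AlignmentError`.
    """
    if not isinstance(metadata, Mapping):
        metadata = read_metadata(metadata)
    entries = read_fasta(fasta_path)
    ids, seqs = zip(*entries)
    missing = [i for i in ids if i not in metadata]
    if missing:
        raise MetadataError(f"FASTA ids absent from metadata: {missing}")
    name = marker or Path(fasta_path).stem
    return MarkerAlignment(
        marker=name,
        ids=list(ids),
        species=[metadata[i].species for i in ids],
        seqs=list(seqs),
    )


def write_alignment(aln: MarkerAlignment, path: str | Path) -> None:
    """Write an alignment (or any id->sequence set) as plain FASTA."""
    with open(path, "w") as fh:
        for ident, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{ident}\n{seq}\n")


def concatenate_markers(
    alignments: Sequence[MarkerAlignment],
    scheme: CombinationScheme,
) -> MarkerAlignment:
    """Build a supermatrix from per-marker alignments under a combination scheme.

    A specimen survives iff it has sequence in >= ``min_markers_required`` of
    the scheme's markers; blocks for absent markers are padded with
    ``fill_char`` over the marker's full aligned width.  Column blocks follow
    scheme order and the block map is retained on the result.  Rows are
    emitted in sorted specimen-id order so the surviving set and the output
    bytes are independent of input row order.
    """
    by_marker = {a.marker: a for a in alignments}
    absent = [m for m in scheme.markers if m not in by_marker]
    if absent:
        raise AlignmentError(f"scheme {scheme.label!r} needs alignments for markers {absent}")
    parts = [by_marker[m] for m in scheme.markers]

    species_of: dict[str, str] = {}
    for part in parts:
        for sid, sp in zip(part.ids, part.species):
            prev = species_of.setdefault(sid, sp)
            if prev != sp:
                raise MetadataError(
                    f"specimen {sid!r} has conflicting species labels {prev!r} / {sp!r}"
                )

    survivors = sorted(
        sid
        for sid in species_of
        if sum(sid in p.ids for p in parts) >= scheme.min_markers_required
    )
    if not survivors:
        raise FilterError(
            f"no specimen has >= {scheme.min_markers_required} of markers {list(scheme.markers)}"
        )

    block_map: dict[str, tuple[int, int]] = {}
    start = 0
    for part in parts:
        block_map[part.marker] = (start, start + part.length)
        start += part.length

    rows = []
    for sid in survivors:
        chunks = []
        for part in parts:
            if sid in part.ids:
                chunks.append(part.row(sid))
            else:
                chunks.append(scheme.fill_char * part.length)
        rows.append("".join(chunks))

    return MarkerAlignment(
        marker=scheme.label,
        ids=survivors,
        species=[species_of[s] for s in survivors],
        seqs=rows,
        block_map=block_map,
    )


def write_tables(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as CSV with a header row and stable column order."""
    frame.to_csv(path, index=False, float_format="%.10g")


def read_tables(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_tables`."""
    return pd.read_csv(path)


def write_block_map(aln: MarkerAlignment, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["marker", "start", "stop"])
        for marker, (start, stop) in aln.block_map.items():
            w.writerow([marker, start, stop])
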