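"""Aligned-sequence containers, masking, site classification and concatenation.

Alignments arrive pre-aligned (one FASTA per locus); no de novo alignment is
performed here.  Coordinates are 0-based half-open internally and 1-based
closed in report files.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "SampleRecord",
    "SiteClasses",
    "AlignmentError",
    "read_alignment",
    "write_alignment",
    "mask_columns",
    "classify_sites",
    "concatenate",
    "read_metadata",
    "write_metadata",
]

# Uppercase alphabet accepted in alignment rows: bases, gap, N and the other
# IUPAC ambiguity codes.  U is normalised to T on input.
_ALPHABET = set("ACGT-NRYSWKMBDHV")

# Numeric codes: A,C,G,T -> 0..3 so that a transition partner is ``code ^ 2``
# and the two transversion partners are ``code ^ 1`` and ``code ^ 3``.
# Everything else (gap, N, ambiguity) is UNUSABLE (255).
UNUSABLE = np.uint8(255)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate ids, ...)."""


@dataclass
class Alignment:
    """Equal-length aligned sequences for one locus.

    Attributes
    ----------
    locus_name : str
    sample_ids : list of unique sample identifiers (row order).
    rows : list of uppercase sequences over ``{A,C,G,T,-,N,IUPAC}``.
    column_map : original column index of each retained column, set by
        :func:`mask_columns`; ``None`` for unmasked alignments.
    """

    locus_name: str
    sample_ids: list[str]
    rows: list[str]
    column_map: list[int] | None = None
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError(f"{self.locus_name}: empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_name}: unequal row lengths {sorted(lengths)}"
            )
        if self.length < 1:
            raise AlignmentError(f"{self.locus_name}: zero-length alignment")
        if len(self.sample_ids) != len(self.rows):
            raise AlignmentError(f"{self.locus_name}: ids/rows mismatch")
        dupes = [s for s, k in Counter(self.sample_ids).items() if k > 1]
        if dupes:
            raise AlignmentError(f"{self.locus_name}: duplicate ids {dupes}")
        norm = []
        for sid, row in zip(self.sample_ids, self.rows):
            row = row.upper().replace("U", "T")
            bad = set(row) - _ALPHABET
            if bad:
                raise AlignmentError(
                    f"{self.locus_name}/{sid}: invalid symbols {sorted(bad)}"
                )
            norm.append(row)
        self.rows = norm

    @property
    def n_samples(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def codes(self) -> np.ndarray:
        """(n_samples, L) uint8 matrix; non-ACGT symbols are UNUSABLE."""
        if self._codes is None:
            arr = np.full((self.n_samples, self.length), UNUSABLE, dtype=np.uint8)
            for i, row in enumerate(self.rows):
                arr[i] = [_CODE.get(c, 255) for c in row]
            self._codes = arr
        return self._codes

    def subset(self, sample_ids: list[str]) -> "Alignment":
        """Row subset in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise AlignmentError(f"{self.locus_name}: unknown samples {missing}")
        return Alignment(
            self.locus_name,
            list(sample_ids),
            [self.rows[index[s]] for s in sample_ids],
            column_map=self.column_map,
        )

    def take_columns(self, cols: "np.ndarray | list[int]") -> "Alignment":
        cols = list(map(int, cols))
        old = self.column_map if self.column_map is not None else range(self.length)
        old = list(old)
        return Alignment(
            self.locus_name,
            list(self.sample_ids),
            ["".join(r[j] for j in cols) for r in self.rows],
            column_map=[old[j] for j in cols],
        )


@dataclass
class SampleRecord:
    """Metadata for one sample: species hypothesis, lineage, geography, habitat."""

    sample_id: str
    species: str | None = None
    lineage: str | None = None
    geography: str | None = None
    habitat: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.lineage and not self.species:
            raise ValueError(
                f"{self.sample_id}: lineage label requires a species label"
            )


@dataclass
class SiteClasses:
    """Column classification counts for one alignment."""

    length: int
    conserved: int
    variable: int
    parsimony_informative: int
    singleton: int

    @property
    def percent_informative(self) -> float:
        return 100.0 * self.parsimony_informative / self.length


def read_alignment(path: str | Path, locus_name: str | None = None) -> Alignment:
    """Read one aligned FASTA file into an :class:`Alignment`.

    Rows are uppercased and U mapped to T; unequal lengths, duplicate ids and
    empty files raise :class:`AlignmentError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    return Alignment(
        locus_name or path.stem,
        [r.id for r in records],
        [str(r.seq) for r in records],
    )


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.sample_ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def mask_columns(aln: Alignment, policy: str = "drop_incomplete") -> Alignment:
    """Drop unusable columns (complete deletion).

    ``drop_incomplete`` removes every column containing a gap, N or IUPAC
    ambiguity in any row, mirroring global exclusion of incomplete data before
    analysis; ``keep`` returns the alignment unchanged.  The returned
    alignment's ``column_map`` records original column indices.
    """
    if policy == "keep":
        return aln
    if policy != "drop_incomplete":
        raise ValueError(f"unknown mask policy {policy!r}")
    usable = (aln.codes() != UNUSABLE).all(axis=0)
    if not usable.any():
        raise AlignmentError(f"{aln.locus_name}: masking removed every column")
    return aln.take_columns(np.flatnonzero(usable))


def classify_sites(aln: Alignment) -> SiteClasses:
    """Count conserved / variable / parsimony-informative / singleton columns.

    A column is parsimony-informative when at least two distinct states are
    each carried by at least two rows; variable-but-not-informative columns
    are singletons.  Only unambiguous bases are counted as states, so the
    classification of a masked alignment is exact.
    """
    if aln.n_samples < 2:
        raise AlignmentError("site classification needs >=2 rows")
    codes = aln.codes()
    conserved = variable = informative = singleton = 0
    for j in range(aln.length):
        col = codes[:, j]
        col = col[col != UNUSABLE]
        counts = np.bincount(col, minlength=4) if col.size else np.zeros(4, int)
        states = int((counts > 0).sum())
        if states <= 1:
            conserved += 1
        else:
            variable += 1
            if int((counts >= 2).sum()) >= 2:
                informative += 1
            else:
                singleton += 1
    return SiteClasses(aln.length, conserved, variable, informative, singleton)


@dataclass
class LocusSpan:
    """Placement of one locus inside a concatenated alignment (0-based half-open)."""

    locus_name: str
    start: int
    end: int


def concatenate(
    alns: list[Alignment],
    samples: str = "intersection",
    name: str = "combined",
) -> tuple[Alignment, list[LocusSpan]]:
    """Concatenate per-locus alignments into a combined dataset.

    ``intersection`` (default) keeps only samples sequenced for all loci;
    ``union`` keeps every sample, encoding a missing locus as an all-N row
    (excluded pairwise downstream).  Returns the combined alignment and the
    per-locus column spans.
    """
    if not alns:
        raise AlignmentError("nothing to concatenate")
    if samples == "intersection":
        keep = [s for s in alns[0].sample_ids if all(s in a.sample_ids for a in alns)]
        if not keep:
            raise AlignmentError("no sample is present in every locus")
    elif samples == "union":
        keep = []
        for a in alns:
            keep.extend(s for s in a.sample_ids if s not in keep)
    else:
        raise ValueError(f"unknown sample policy {samples!r}")

    spans: list[LocusSpan] = []
    parts: dict[str, list[str]] = {s: [] for s in keep}
    offset = 0
    for a in alns:
        index = {s: i for i, s in enumerate(a.sample_ids)}
        for s in keep:
            if s in index:
                parts[s].append(a.rows[index[s]])
            else:
                parts[s].append("N" * a.length)
        spans.append(LocusSpan(a.locus_name, offset, offset + a.length))
        offset += a.length
    combined = Alignment(name, keep, ["".join(parts[s]) for s in keep])
    return combined, spans


def write_locus_map(spans: list[LocusSpan], path: str | Path) -> None:
    """Locus map TSV with 1-based closed coordinates."""
    pd.DataFrame(
        {
            "locus": [s.locus_name for s in spans],
            "start": [s.start + 1 for s in spans],
            "end": [s.end for s in spans],
        }
    ).to_csv(path, sep="\t", index=False)


_META_COLS = ["sample_id", "species", "lineage", "geography", "habitat"]


def read_metadata(path: str | Path) -> dict[str, SampleRecord]:
    """Read the sample metadata TSV (header: sample_id species lineage geography habitat)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    out: dict[str, SampleRecord] = {}
    for rec in df.itertuples(index=False):
        sr = SampleRecord(
            rec.sample_id,
            rec.species or None,
            rec.lineage or None,
            rec.geography or None,
            rec.habitat or None,
        )
        if sr.sample_id in out:
            raise ValueError(f"duplicate metadata row for {sr.sample_id}")
        out[sr.sample_id] = sr
    return out


def write_metadata(records: dict[str, SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "species": r.species or "",
                "lineage": r.lineage or "",
                "geography": r.geography or "",
                "habitat": r.habitat or "",
            }
            for r in records.values()
        ],
        columns=_META_COLS,
    ).to_csv(path, sep="\t", index=False)
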