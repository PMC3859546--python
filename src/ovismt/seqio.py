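"""Sequence and metadata I/O, and anchoring to reference coordinates.

All genomic positions in this package are 1-based, inclusive, on the sheep
mitochondrial reference (GenBank AF010406). Sequences read from FASTA are
uppercased; gap characters ('-') are retained so pre-aligned input flows
through unchanged. 'N' is treated as missing data downstream (pairwise
deletion), the standard convention for ancient-DNA-grade sequence.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO as _BioSeqIO

__all__ = [
    "SeqRecord",
    "CoordinateMap",
    "AlignedSeq",
    "read_fasta",
    "write_fasta",
    "anchor_to_reference",
    "extract_region",
    "read_metadata",
]

VALID_RESIDUES = frozenset("ACGTN-")


@dataclasses.dataclass
class SeqRecord:
    """A named nucleotide sequence with free-form metadata.

    meta carries sample annotations (group, breed, era, lat, lon, ...).
    """

    id: str
    residues: str
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        self.residues = self.residues.upper()
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass
class CoordinateMap:
    """Maps columns of a sequence to 1-based reference positions.

    column_to_ref[i] is the reference position of column i (0-based column
    index), or 0 for gap columns. Mapped positions are strictly increasing.
    """

    ref_start: int
    column_to_ref: np.ndarray  # int array, 0 marks a gap column

    def __post_init__(self) -> None:
        self.column_to_ref = np.asarray(self.column_to_ref, dtype=np.int64)
        mapped = self.column_to_ref[self.column_to_ref > 0]
        if mapped.size and not np.all(np.diff(mapped) > 0):
            raise ValueError("mapped reference positions must be strictly increasing")
        self._ref_to_col = {int(r): i for i, r in enumerate(self.column_to_ref) if r > 0}

    @property
    def ref_end(self) -> int:
        mapped = self.column_to_ref[self.column_to_ref > 0]
        return int(mapped[-1]) if mapped.size else 0

    def ref_to_column(self, ref_pos: int) -> int:
        """0-based column of a reference position; KeyError if unmapped."""
        return self._ref_to_col[int(ref_pos)]

    def covers(self, ref_pos: int) -> bool:
        return int(ref_pos) in self._ref_to_col

    @classmethod
    def identity(cls, ref_start: int, length: int) -> "CoordinateMap":
        return cls(ref_start, np.arange(ref_start, ref_start + length))


@dataclasses.dataclass
class AlignedSeq:
    """A sequence together with its reference-coordinate map."""

    record: SeqRecord
    coords: CoordinateMap

    @property
    def id(self) -> str:
        return self.record.id

    def base_at(self, ref_pos: int) -> str | None:
        """Base at a reference position, or None if the position is unmapped."""
        if not self.coords.covers(ref_pos):
            return None
        return self.record.residues[self.coords.ref_to_column(ref_pos)]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords (uppercased, gaps retained).

    Raises ValueError on duplicate ids, naming the offender. An empty file
    yields an empty list.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def _kmer_anchor(seq: str, ref: str, k: int) -> tuple[int, int] | None:
    """First exact shared k-mer: (seq_offset, ref_offset), or None."""
    ref_index: dict[str, int] = {}
    for j in range(len(ref) - k + 1):
        kmer = ref[j : j + k]
        if "N" not in kmer and "-" not in kmer and kmer not in ref_index:
            ref_index[kmer] = j
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer or "-" in kmer:
            continue
        j = ref_index.get(kmer)
        if j is not None:
            return i, j
    return None


def anchor_to_reference(
    seq: SeqRecord, ref: SeqRecord, k: int = 20, ref_start: int = 1
) -> CoordinateMap:
    """Assign each column of `seq` a reference position.

    Strategy: if `seq` is already gap-aligned to the reference length, the
    map is read off directly. Otherwise an exact k-mer seed (default k=20)
    fixes the offset and coordinates extend ungapped in both directions —
    adequate for the substitution-only divergence this package deals with;
    indel-rich input should be supplied pre-aligned.

    `ref_start` is the reference position of the reference's first column
    (e.g. 15437 for a control-region fragment of AF010406).

    Raises ValueError when no anchor is found, advising pre-alignment.
    """
    s, r = seq.residues, ref.residues
    if len(s) == len(r):
        # treat as pre-aligned (columnwise) to the reference
        cols = np.zeros(len(s), dtype=np.int64)
        pos = ref_start - 1
        for i, c in enumerate(r):
            if c != "-":
                pos += 1
            cols[i] = 0 if s[i] == "-" else pos
        # gap columns in seq are unmapped
        return CoordinateMap(ref_start, cols)
    hit = _kmer_anchor(s, r, k)
    if hit is None:
        raise ValueError(
            f"no exact {k}-mer shared between {seq.id!r} and the reference; "
            "supply pre-aligned input instead"
        )
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -0.5
    # free end gaps: the query may cover only part of the reference
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aln = aligner.align(r.replace("-", ""), s.replace("-", ""))[0]
    cols = np.zeros(len(s), dtype=np.int64)
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        # both blocks advance together: ungapped stretch
        cols[q0:q1] = np.arange(t0, t1) + ref_start
    return CoordinateMap(ref_start, cols)


def extract_region(
    seq: SeqRecord, cmap: CoordinateMap, start: int, end: int
) -> SeqRecord:
    """Subsequence covering reference interval [start, end], 1-based inclusive.

    Gap columns inside the interval are dropped from the result, so the
    returned length is (end - start + 1) minus gap columns.
    """
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    if not (cmap.covers(start) and cmap.covers(end)):
        raise ValueError(
            f"region [{start}, {end}] outside mapped range "
            f"for sequence {seq.id!r}"
        )
    c0 = cmap.ref_to_column(start)
    c1 = cmap.ref_to_column(end)
    sub = seq.residues[c0 : c1 + 1].replace("-", "")
    return SeqRecord(seq.id, sub, dict(seq.meta))


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV (header must contain 'id').

    Optional columns: group, breed, lat, lon, era. Coordinates are validated
    (lat within [-90, 90], lon within [-180, 180]).
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("metadata table must have an 'id' column")
    for col, lo, hi in (("lat", -90.0, 90.0), ("lon", -180.0, 180.0)):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="raise")
            bad = vals.dropna()[(vals.dropna() < lo) | (vals.dropna() > hi)]
            if len(bad):
                raise ValueError(
                    f"{col} out of range [{lo}, {hi}]: {bad.iloc[0]}"
                )
            df[col] = vals
    return df


def check_metadata_ids(
    df: pd.DataFrame, records: Iterable[SeqRecord]
) -> list[str]:
    """Ids present in the table but absent from the sequences (warn-level)."""
    have = {r.id for r in records}
    return [i for i in df["id"] if i not in have]
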