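"""Reading and writing of the sequence and table formats used across the toolkit.

All coordinates exchanged through these types are 0-based, half-open.
FASTQ quality strings are phred+33 only; other encodings are rejected rather
than guessed, because a silently mis-decoded quality string corrupts trimming.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

TRUTH_COLUMNS = [
    "molecule_id",
    "sample_index",
    "ref_id",
    "start",
    "end",
    "barcode_left",
    "barcode_right",
]


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class SequenceRecord:
    """An identified DNA sequence with optional per-base phred qualities."""

    id: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        qual = None if self.quality is None else self.quality[::-1]
        return SequenceRecord(self.id, reverse_complement(self.sequence), qual)


@dataclass(slots=True)
class MoleculeTruth:
    """Ground truth for one simulated source fragment.

    ``start``/``end`` are a 0-based half-open interval on ``ref_id``. The two
    barcodes tag the left (``start``) and right (``end``) ends of the fragment.
    """

    molecule_id: str
    sample_index: str
    ref_id: str
    start: int
    end: int
    barcode_left: str
    barcode_right: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"molecule {self.molecule_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.barcode_left == self.barcode_right:
            raise ValueError(f"molecule {self.molecule_id}: identical end barcodes")


@dataclass
class ReportTable:
    """Rows of (metric, value, stratum) collected by analysis stages."""

    rows: list[tuple[str, object, str]] = field(default_factory=list)

    def add(self, metric: str, value: object, stratum: str = "") -> None:
        if any(m == metric and s == stratum for m, _, s in self.rows):
            raise ValueError(f"duplicate metric {metric!r} in stratum {stratum!r}")
        self.rows.append((metric, value, stratum))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["metric", "value", "stratum"])

    def write(self, path: PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA file (optionally gzipped).

    Sequences are uppercased and U is mapped to T. Records with empty
    sequences, and files with leading non-header content, raise FormatError.
    """
    with _open_text(path) as handle:
        first = handle.read(1)
        if first == "":
            return
        if first != ">":
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            yield SequenceRecord(rec.id, seq)


def read_fastq(path: PathLike) -> Iterator[SequenceRecord]:
    """Stream 4-line phred+33 FASTQ records (optionally gzipped)."""
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                yield SequenceRecord(
                    rec.id,
                    str(rec.seq).upper(),
                    list(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:  # Bio.SeqIO signals malformed records this way
            raise FormatError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            if rec.quality is None:
                raise FormatError(f"record {rec.id!r}: FASTQ output requires qualities")
            qual = "".join(chr(q + 33) for q in rec.quality)
            handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def write_truth_table(truths: Sequence[MoleculeTruth], path: PathLike) -> None:
    frame = pd.DataFrame(
        [[getattr(t, c) for c in TRUTH_COLUMNS] for t in truths],
        columns=TRUTH_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_truth_table(path: PathLike) -> list[MoleculeTruth]:
    frame = pd.read_csv(
        path, sep="\t", dtype={"sample_index": str}, keep_default_na=False
    )
    if list(frame.columns) != TRUTH_COLUMNS:
        unknown = [c for c in frame.columns if c not in TRUTH_COLUMNS]
        raise FormatError(f"{path}: unexpected truth-table columns {unknown}")
    return [
        MoleculeTruth(
            molecule_id=str(row.molecule_id),
            sample_index=str(row.sample_index),
            ref_id=str(row.ref_id),
            start=int(row.start),
            end=int(row.end),
            barcode_left=str(row.barcode_left),
            barcode_right=str(row.barcode_right),
        )
        for row in frame.itertuples()
    ]
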