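"""Readers and writers for the plain-text formats used throughout the pipeline.

All coordinates in this package are 1-based, fully closed, on the transcript
sense strand.  Sequences are stored in DNA alphabet (T, not U), upper case;
the duplex code converts to RNA internally.  All readers are gzip-transparent
and reject malformed input with a located error rather than silently dropping
records.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

CDNA_CLASSES = (
    "non-translating",
    "protein-coding",
    "pseudogene",
    "rRNA",
    "snoRNA",
    "snRNA",
    "SRP-RNA",
    "tRNA",
)

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequence letters are normalized to upper case.  Duplicate identifiers
    raise ``ValueError`` naming the identifier; an empty file returns an
    empty mapping with a warning.
    """
    records: dict[str, str] = {}
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            name = title.split()[0]
            if name in records:
                raise ValueError(f"duplicate FASTA identifier: {name!r} in {path}")
            records[name] = seq.upper()
    if not records:
        warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
    return records


def write_fasta(records: dict[str, str], path) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n{seq.upper()}\n")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)
# ---------------------------------------------------------------------------

class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str


def read_fastq(path) -> Iterator[FastqRead]:
    """Stream FASTQ records; bounded memory.

    Raises ``ValueError`` with the 1-based record index on a truncated
    record or a sequence/quality length mismatch.
    """
    with _open_text(path) as handle:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                index += 1
                if len(seq) != len(qual):
                    raise ValueError(
                        f"sequence/quality length mismatch at record {index} in {path}"
                    )
                yield FastqRead(title, seq.upper(), qual)
        except ValueError as exc:
            # Biopython raises on structurally broken records; locate it.
            raise ValueError(f"malformed FASTQ record {index + 1} in {path}: {exc}") from exc


def write_fastq(reads: Iterable[FastqRead], path) -> int:
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            if len(read.sequence) != len(read.quality):
                raise ValueError(f"sequence/quality length mismatch for read {read.name!r}")
            handle.write(f"@{read.name}\n{read.sequence}\n+\n{read.quality}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Count tables (TSV, features x samples)
# ---------------------------------------------------------------------------

def read_count_table(path) -> pd.DataFrame:
    """Read a features x samples TSV count table.

    First column is the feature identifier; cells must be numeric and
    non-negative (error reports row and column).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r} in {path}")
        if (numeric < 0).any():
            row = df.index[(numeric < 0).argmax()]
            raise ValueError(f"negative cell at row {row!r}, column {col!r} in {path}")
        df[col] = numeric
    return df


def write_count_table(table: pd.DataFrame, path, index_label: str = "feature") -> None:
    table.to_csv(path, sep="\t", index_label=index_label)


# ---------------------------------------------------------------------------
# Transcript models (FASTA + TSV sidecar)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """A transcript in transcript space: sequence plus class/chromosome labels."""

    id: str
    cdna_class: str
    chromosome: str
    exon_length: int
    sequence: str

    def __post_init__(self):
        if self.cdna_class not in CDNA_CLASSES:
            raise ValueError(f"unknown cDNA class {self.cdna_class!r} for {self.id}")
        if self.exon_length != len(self.sequence):
            raise ValueError(
                f"exon_length {self.exon_length} != sequence length "
                f"{len(self.sequence)} for {self.id}"
            )


def write_transcript_models(models: Iterable[TranscriptModel], fasta_path, table_path) -> None:
    models = list(models)
    write_fasta({m.id: m.sequence for m in models}, fasta_path)
    rows = pd.DataFrame(
        {
            "id": [m.id for m in models],
            "cdna_class": [m.cdna_class for m in models],
            "chromosome": [m.chromosome for m in models],
            "exon_length": [m.exon_length for m in models],
        }
    )
    rows.to_csv(table_path, sep="\t", index=False)


def read_transcript_models(fasta_path, table_path) -> dict[str, TranscriptModel]:
    seqs = read_fasta(fasta_path)
    table = pd.read_csv(table_path, sep="\t")
    models: dict[str, TranscriptModel] = {}
    for row in table.itertuples(index=False):
        if row.id not in seqs:
            raise ValueError(f"transcript {row.id!r} in {table_path} missing from {fasta_path}")
        models[row.id] = TranscriptModel(
            id=row.id,
            cdna_class=row.cdna_class,
            chromosome=str(row.chromosome),
            exon_length=int(row.exon_length),
            sequence=seqs[row.id],
        )
    return models


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ("sample", "group", "organ", "path")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a tab-separated sample sheet with columns sample/group/organ/path."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {missing}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
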