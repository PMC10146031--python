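"""Readers and writers for the external formats the toolchain touches.

FASTA / FASTQ (Phred+33) for reads, Stockholm or aligned FASTA for the
training alignment, and TSV tables for sub-region hits and ASV abundances.
Parsing is strict: duplicate ids, ragged alignments, and truncated records
raise :class:`FormatError` rather than being silently repaired, because a
dropped read would bias every downstream count.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SeqRecord:
    """A single read or template sequence.

    ``quality`` holds Phred scores (already decoded from Phred+33) when the
    record came from FASTQ, otherwise ``None``.
    """

    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("record with empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r} has empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Msa:
    """A multiple sequence alignment over {A,C,G,T,-}."""

    rows: list[tuple[str, str]]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError("alignment needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.n_columns = lengths.pop()


@dataclass
class HitTable:
    """Located sub-regions, one row per read that scored above threshold.

    Coordinates are 1-based inclusive and always reported on the forward
    strand of the read; ``strand`` records which orientation matched the
    model.
    """

    rows: list[tuple[str, int, int, int, int, str, float]] = field(
        default_factory=list
    )

    COLUMNS = (
        "read_id",
        "read_start",
        "read_end",
        "model_start",
        "model_end",
        "strand",
        "bit_score",
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.COLUMNS))

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HitTable) and self.rows == other.rows


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SeqRecord]:
    """Parse a FASTA file into :class:`SeqRecord` objects.

    Sequences are uppercased and RNA 'U' is mapped to 'T'.  Duplicate ids
    and empty files are format errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, _normalize(str(rec.seq))))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_fastq(path) -> list[SeqRecord]:
    """Parse strict 4-line FASTQ records with Phred+33 qualities.

    A trailing partial record is reported with its (1-based) record index;
    Biopython's lenient multi-line parser is deliberately not used here so
    that truncation points to the offending record.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise FormatError(f"empty FASTQ file {path}")
    if len(lines) % 4 != 0:
        raise FormatError(
            f"truncated FASTQ record {len(lines) // 4 + 1} in {path}"
        )
    for i in range(0, len(lines), 4):
        idx = i // 4 + 1
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"malformed FASTQ record {idx} in {path}")
        if len(qual) != len(seq):
            raise FormatError(
                f"FASTQ record {idx}: quality/sequence length mismatch"
            )
        rid = header[1:].split()[0]
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r}")
        seen.add(rid)
        records.append(
            SeqRecord(rid, _normalize(seq), [ord(c) - 33 for c in qual])
        )
    return records


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else [40] * len(rec)
            fh.write(
                f"@{rec.id}\n{rec.sequence}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_msa(path, dialect: str = "afa") -> Msa:
    """Read an alignment in Stockholm (``stockholm``) or aligned-FASTA
    (``afa``) dialect.  '.' and '-' gap characters are both normalized to
    '-'; ``#=GC``/``#=GR`` annotation lines are ignored by the Stockholm
    parser."""
    fmt = {"stockholm": "stockholm", "afa": "fasta"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    rows = [
        (rec.id, _normalize(str(rec.seq)).replace(".", "-")) for rec in aln
    ]
    return Msa(rows)


def write_msa(msa: Msa, path, dialect: str = "afa") -> None:
    if dialect == "afa":
        with open(path, "w") as fh:
            for rid, row in msa.rows:
                fh.write(f">{rid}\n{row}\n")
    elif dialect == "stockholm":
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            width = max(len(rid) for rid, _ in msa.rows) + 2
            for rid, row in msa.rows:
                fh.write(f"{rid:<{width}}{row}\n")
            fh.write("//\n")
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# hit tables and abundance tables
# ---------------------------------------------------------------------------

def write_hit_table(hits: HitTable, path) -> None:
    hits.to_frame().to_csv(path, sep="\t", index=False)


def read_hit_table(path) -> HitTable:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "strand": str})
    if list(df.columns) != list(HitTable.COLUMNS):
        raise FormatError(
            f"hit table {path} has columns {list(df.columns)}, "
            f"expected {list(HitTable.COLUMNS)}"
        )
    rows = [
        (
            str(r.read_id),
            int(r.read_start),
            int(r.read_end),
            int(r.model_start),
            int(r.model_end),
            str(r.strand),
            float(r.bit_score),
        )
        for r in df.itertuples(index=False)
    ]
    return HitTable(rows)


def write_abundance_table(df: pd.DataFrame, path) -> None:
    """Write an ASV x sample integer count table (rows = ASV ids)."""
    df.to_csv(path, sep="\t", index=True, index_label="asv_id")


def read_abundance_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="asv_id")
    return df.astype(int)
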