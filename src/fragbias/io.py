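"""Reading and writing the formats the pipeline touches.

Canonical coordinates throughout the package are 0-based half-open (BED
convention). A ``one_based`` switch on the table readers converts 1-based
inclusive input on the way in. FASTQ is Phred+33; gzip is handled
transparently by file extension.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path
from typing import NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import log, phred_to_string, string_to_phred

STRANDS = frozenset("+-")
END_TYPES = frozenset({"5p", "3p"})

#: column order of the extended BED6 mapped-read table
TABLE_COLUMNS = [
    "ref", "start", "end", "read_id", "count", "strand", "end_type", "seq", "quals",
]


class FastqRead(NamedTuple):
    """One sequencing read as it appears in FASTQ."""

    read_id: str
    seq: str
    quals: list[int]


@dataclasses.dataclass(frozen=True)
class MappedRead:
    """One aligned read with its location, orientation and base calls.

    ``seq`` is the read as sequenced: for a minus-strand (3') read it is the
    reverse complement of the reference slice ``[start, end)``.
    ``n_candidate_locations`` records how many placements the read had before
    multi-mapped resolution (1 for uniquely mapped reads).
    """

    read_id: str
    ref: str
    start: int
    end: int
    strand: str
    end_type: str
    seq: str
    quals: tuple[int, ...]
    n_candidate_locations: int = 1

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"{self.read_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.read_id}: unknown strand {self.strand!r}")
        if self.end_type not in END_TYPES:
            raise ValueError(f"{self.read_id}: unknown end_type {self.end_type!r}")
        if len(self.quals) != len(self.seq):
            raise ValueError(f"{self.read_id}: quals/seq length mismatch")
        if self.n_candidate_locations < 1:
            raise ValueError(f"{self.read_id}: n_candidate_locations < 1")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path) -> list[FastqRead]:
    """Parse a Phred+33 FASTQ file into a list of reads.

    Malformed records raise ``ValueError`` annotated with the (1-based)
    record number.
    """
    reads: list[FastqRead] = []
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                reads.append(
                    FastqRead(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])
                )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ near record {len(reads) + 1}: {exc}") from exc
    return reads


def write_fastq(reads, path) -> None:
    """Write reads (anything with read_id/seq/quals) as Phred+33 FASTQ."""
    with _open_text(path, "wt") as handle:
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(r.quals)
            SeqIO.write(rec, handle, "fastq")


# ---------------------------------------------------------------------------
# Mapped-read table (BED6-extended TSV)
# ---------------------------------------------------------------------------

def reads_to_frame(reads) -> pd.DataFrame:
    """Convert MappedRead records to the extended-BED6 table layout."""
    return pd.DataFrame(
        {
            "ref": [r.ref for r in reads],
            "start": [r.start for r in reads],
            "end": [r.end for r in reads],
            "read_id": [r.read_id for r in reads],
            "count": [r.n_candidate_locations for r in reads],
            "strand": [r.strand for r in reads],
            "end_type": [r.end_type for r in reads],
            "seq": [r.seq for r in reads],
            "quals": [phred_to_string(r.quals) for r in reads],
        }
    )


def frame_to_reads(frame: pd.DataFrame, one_based: bool = False) -> list[MappedRead]:
    """Build validated MappedRead records from a table.

    ``one_based=True`` converts 1-based inclusive coordinates to the
    canonical 0-based half-open convention (start - 1, end unchanged).
    Unknown extra columns are ignored here; use the frame-level round trip
    to preserve them.
    """
    missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"mapped-read table is missing columns: {missing}")
    reads = []
    for i, row in enumerate(frame.itertuples(index=False)):
        start, end = int(row.start), int(row.end)
        if one_based:
            start -= 1
        try:
            reads.append(
                MappedRead(
                    read_id=str(row.read_id),
                    ref=str(row.ref),
                    start=start,
                    end=end,
                    strand=str(row.strand),
                    end_type=str(row.end_type),
                    seq=str(row.seq),
                    quals=tuple(string_to_phred(str(row.quals))),
                    n_candidate_locations=int(row.count),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return reads


def read_mapped_frame(path) -> pd.DataFrame:
    """Read the mapped-read TSV as a DataFrame, extra columns untouched."""
    return pd.read_csv(path, sep="\t", dtype={"ref": str, "read_id": str})


def write_mapped_frame(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_mapped_table(path, one_based: bool = False) -> list[MappedRead]:
    """Read and validate a mapped-read table into MappedRead records."""
    return frame_to_reads(read_mapped_frame(path), one_based=one_based)


def write_mapped_table(reads, path) -> None:
    """Write MappedRead records (or a prepared DataFrame) as TSV."""
    frame = reads if isinstance(reads, pd.DataFrame) else reads_to_frame(reads)
    write_mapped_frame(frame, path)


# ---------------------------------------------------------------------------
# Optional SAM adapter
# ---------------------------------------------------------------------------

def read_sam(path, end_type_from_mate: bool = True) -> list[MappedRead]:
    """Thin adapter mapping ungapped primary SAM alignments onto MappedRead.

    Spliced (N-containing CIGAR) reads contribute their leftmost aligned
    block only; the number of such truncations is logged. Unmapped,
    secondary and supplementary records are skipped. ``end_type`` is taken
    from the mate flag (read2 -> 3p) when ``end_type_from_mate`` is set,
    else every read is 5p.
    """
    import pysam

    reads: list[MappedRead] = []
    n_spliced = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            seq = aln.query_sequence
            quals = aln.query_qualities
            if seq is None:
                continue
            start = aln.reference_start
            end = aln.reference_end
            cigar = aln.cigartuples or []
            if any(op == 3 for op, _ in cigar):  # N: keep leftmost block
                n_spliced += 1
                block_len = next(n for op, n in cigar if op == 0)
                end = start + block_len
                seq = seq[:block_len]
                quals = quals[:block_len] if quals is not None else None
            end_type = "3p" if (end_type_from_mate and aln.is_read2) else "5p"
            if quals is None:
                quals = [30] * len(seq)
            reads.append(
                MappedRead(
                    read_id=aln.query_name,
                    ref=aln.reference_name,
                    start=start,
                    end=end,
                    strand="-" if aln.is_reverse else "+",
                    end_type=end_type,
                    seq=seq,
                    quals=tuple(quals),
                )
            )
    if n_spliced:
        log.info("read_sam: truncated %d spliced alignments to their leftmost block", n_spliced)
    return reads
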