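"""Standard-format I/O: FASTA, FASTQ, BED, TSV and SAM round trips.

Sequence containers are plain Python strings throughout the package;
Biopython handles FASTA/FASTQ serialisation and pysam handles SAM.
Coordinates are BED-style 0-based half-open externally; SAM's 1-based
coordinates are converted at this boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a (possibly aligned) FASTA file into an ordered id -> sequence map."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str],
                descriptions: Mapping[str, str] | None = None) -> None:
    recs = [
        SeqRecord(Seq(s), id=name,
                  description=(descriptions or {}).get(name, ""))
        for name, s in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTQ into a list of (name, sequence); qualities are discarded."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str]],
                quality_char: str = "I") -> None:
    """Write (name, sequence) pairs as FASTQ with constant placeholder qualities."""
    qscore = ord(quality_char) - 33
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
    del qscore


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    name: str = "."
    score: float | str = "."
    strand: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"BED interval must have end > start, got {self.chrom}:{self.start}-{self.end}")


def read_bed(path: str | os.PathLike) -> list[BedInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                iv = BedInterval(
                    fields[0], int(fields[1]), int(fields[2]),
                    fields[3] if len(fields) > 3 else ".",
                    fields[4] if len(fields) > 4 else ".",
                    fields[5] if len(fields) > 5 else ".",
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    return out


def write_bed(path: str | os.PathLike, intervals: Iterable[BedInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score}\t{iv.strand}\n")


def write_tsv(path: str | os.PathLike, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- SAM -------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedRead:
    """Minimal internal alignment record (0-based position; CIGAR kept verbatim)."""
    qname: str
    flag: int
    chrom: str
    pos: int          # 0-based leftmost reference position; -1 if unmapped
    mapq: int
    cigar: str
    seq: str

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)


def read_sam(path: str | os.PathLike) -> list[AlignedRead]:
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            out.append(AlignedRead(
                qname=aln.query_name,
                flag=aln.flag,
                chrom=aln.reference_name or "*",
                pos=aln.reference_start if aln.reference_start is not None else -1,
                mapq=aln.mapping_quality,
                cigar=aln.cigarstring or "*",
                seq=aln.query_sequence or "*",
            ))
    return out


def write_sam(path: str | os.PathLike, records: Sequence[AlignedRead],
              references: Mapping[str, int]) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            aln = pysam.AlignedSegment(fh.header)
            aln.query_name = rec.qname
            aln.flag = rec.flag
            if rec.chrom != "*" and not rec.is_unmapped:
                aln.reference_id = fh.header.references.index(rec.chrom)
                aln.reference_start = rec.pos
            aln.mapping_quality = rec.mapq
            if rec.cigar != "*":
                aln.cigarstring = rec.cigar
            if rec.seq != "*":
                aln.query_sequence = rec.seq
            fh.write(aln)
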