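"""Minimal exact-seed read mapper for synthetic genomes.

Sufficient for error-free synthetic reads against genomes of a few
megabases: a k-mer index locates candidate placements and a read is
"mapped" only when it matches the reference full-length and exactly,
uniquely. Anything else (element-derived reads against a masked
reference, junction-spanning reads) is reported unmapped, which is
precisely the behaviour the insertion caller exploits. External
alignments in SAM are accepted through :func:`pairs_from_sam` as an
alternative source of the same records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .reads import ReadPair
from .seqio import AlignedRead, revcomp


def mask_intervals(genome: str, intervals: Iterable[tuple[int, int]]) -> str:
    """Replace the given 0-based half-open intervals with N runs."""
    out = list(genome)
    for s, e in intervals:
        out[s:e] = "N" * (e - s)
    return "".join(out)


@dataclass(frozen=True)
class Placement:
    chrom: str
    start: int    # 0-based
    strand: str


class GenomeIndex:
    """Exact-match k-mer index over one chromosome."""

    def __init__(self, genome: str, k: int = 31, chrom: str = "chr1",
                 max_hits_per_seed: int = 50):
        self.genome = genome.upper()
        self.k = k
        self.chrom = chrom
        self._index: dict[str, list[int]] = {}
        idx = self._index
        g = self.genome
        for i in range(len(g) - k + 1):
            kmer = g[i: i + k]
            if "N" in kmer:
                continue
            hits = idx.setdefault(kmer, [])
            if len(hits) <= max_hits_per_seed:
                hits.append(i)
        self.max_hits_per_seed = max_hits_per_seed

    def _candidates(self, read: str) -> set[int]:
        k = self.k
        offsets = [0]
        if len(read) > k:
            offsets.append(len(read) - k)
        if len(read) > 2 * k:
            offsets.append((len(read) - k) // 2)
        cands: set[int] = set()
        for off in offsets:
            for pos in self._index.get(read[off: off + k], ()):
                start = pos - off
                if start >= 0:
                    cands.add(start)
        return cands

    def map_exact(self, read: str) -> Placement | None:
        """Unique full-length exact placement of the read (either strand),
        else None (including multi-mapping and partial matches)."""
        if len(read) < self.k:
            return None
        placements = []
        for strand, seq in (("+", read.upper()), ("-", revcomp(read.upper()))):
            for start in self._candidates(seq):
                if self.genome[start: start + len(seq)] == seq:
                    placements.append(Placement(self.chrom, start, strand))
        uniq = {(p.start, p.strand) for p in placements}
        if len(uniq) != 1:
            return None
        return placements[0]


def map_pairs(pairs: Iterable[ReadPair], index: GenomeIndex
              ) -> list[tuple[ReadPair, Placement | None, Placement | None]]:
    return [(p, index.map_exact(p.r1), index.map_exact(p.r2)) for p in pairs]


def pairs_from_sam(path) -> list[tuple[ReadPair, Placement | None, Placement | None]]:
    """Reconstruct mapped-pair records from a (name-grouped or unsorted) SAM
    file produced by an external aligner. Only primary alignments are used;
    a mate is considered placed when mapped with a full-length match CIGAR."""
    from .seqio import read_sam

    by_name: dict[str, dict[int, AlignedRead]] = {}
    for rec in read_sam(path):
        if rec.flag & (0x100 | 0x800):   # secondary / supplementary
            continue
        mate = 2 if rec.flag & 0x80 else 1
        by_name.setdefault(rec.qname, {})[mate] = rec

    out = []
    for name, mates in sorted(by_name.items()):
        if 1 not in mates or 2 not in mates:
            continue
        r1, r2 = mates[1], mates[2]

        def seq_of(rec: AlignedRead) -> str:
            s = rec.seq
            return revcomp(s) if rec.flag & 0x10 else s

        def placement(rec: AlignedRead) -> Placement | None:
            if rec.is_unmapped or rec.cigar in ("*", ""):
                return None
            if rec.cigar != f"{len(rec.seq)}M":
                return None
            return Placement(rec.chrom, rec.pos, "-" if rec.flag & 0x10 else "+")

        out.append((ReadPair(name, seq_of(r1), seq_of(r2)),
                    placement(r1), placement(r2)))
    return out
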