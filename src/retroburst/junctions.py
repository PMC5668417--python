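"""Exhaustive recombination-junction fragment library.

The family's multiple alignment is collapsed into a degenerate consensus:
a wildcard at every column where at least one member differs (substitution
or indel), with the observed variants — including the gap — listed per
wildcard. Sliding a fixed-length window (default 145 bp, chosen to sit
inside a 150 bp read) one position at a time, every combination of
variants is expanded into a fragment; the union over windows is then
deduplicated and purged of every sequence occurring in the reference
genome (on either strand by default). Because the genome contains each
parental element, all single-parent windows are removed by the genome
screen, leaving precisely the fragments that witness an inter-member
mosaic — recombination-like junctions. Reads are then scanned for exact
fragment matches and the hit count reported per 1000 element-mapping
reads.

Combinations involving a gap variant realise to fewer real bases than the
window spans; these are re-windowed by extending the expansion into
subsequent columns until exactly ``window_length`` real bases have been
emitted, so every fragment is read-length-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import revcomp

GAP = "-"


class CombinationBudgetError(RuntimeError):
    """Raised when a window's variant cross-product exceeds the budget."""


@dataclass(frozen=True)
class ConsensusPattern:
    """Degenerate consensus over a family alignment.

    ``consensus`` holds the shared base per column, ``*`` at wildcard
    columns; ``wildcards`` maps wildcard column -> lexicographically
    ordered tuple of observed variants (``-`` for a gap). The original
    alignment is retained so every member remains reconstructable by
    picking its own variant at every wildcard.
    """
    consensus: str
    wildcards: dict[int, tuple[str, ...]]
    alignment: dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(self.consensus)

    def member_variant(self, member: str, column: int) -> str:
        return self.alignment[member][column]


def build_consensus(alignment: Mapping[str, str]) -> ConsensusPattern:
    """Collapse a multiple alignment into a :class:`ConsensusPattern`."""
    if not alignment:
        raise ValueError("empty alignment")
    seqs = {m: s.upper() for m, s in alignment.items()}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    n = lengths.pop()
    if n == 0:
        raise ValueError("empty alignment")

    consensus: list[str] = []
    wildcards: dict[int, tuple[str, ...]] = {}
    rows = list(seqs.values())
    for c in range(n):
        observed = {row[c] for row in rows}
        if len(observed) == 1:
            consensus.append(next(iter(observed)))
        else:
            consensus.append("*")
            wildcards[c] = tuple(sorted(observed))
    return ConsensusPattern("".join(consensus), wildcards, dict(seqs))


@dataclass(frozen=True)
class JunctionLibrary:
    """Deduplicated, genome-purged set of fixed-length junction fragments."""
    fragments: tuple[str, ...]          # sorted; determinism contract
    window_length: int
    provenance: dict[str, tuple[int, int]]   # fragment -> (window start column, combo index)
    raw_window_counts: dict[int, int]        # window start column -> combos expanded
    purged_genome: int                       # fragments removed by the genome screen
    both_strand_purge: bool = True
    _search: frozenset = field(default=None, repr=False, compare=False)
    _fwd: frozenset = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def forward_set(self) -> frozenset:
        if self._fwd is None:
            object.__setattr__(self, "_fwd", frozenset(self.fragments))
        return self._fwd

    @property
    def search_set(self) -> frozenset:
        """Fragments plus their reverse complements, for strand-agnostic scans."""
        if self._search is None:
            object.__setattr__(self, "_search",
                               self.forward_set
                               | frozenset(revcomp(f) for f in self.fragments))
        return self._search

    def matches_read(self, read: str) -> str | None:
        """First library fragment contained in ``read`` (either strand), or None."""
        w = self.window_length
        s = self.search_set
        fwd = self.forward_set
        for i in range(len(read) - w + 1):
            window = read[i: i + w]
            if window in s:
                return window if window in fwd else revcomp(window)
        return None


def _expand_window(pattern: ConsensusPattern, start: int, window_length: int,
                   budget: int) -> tuple[list[str], int]:
    """All realisations of ``window_length`` real bases beginning at column
    ``start``. Gap variants emit nothing and the expansion runs on into
    later columns until the length is reached; realisations that run off
    the alignment end are dropped (the window no longer fits)."""
    import itertools
    import math

    consensus = pattern.consensus
    wildcards = pattern.wildcards
    n = pattern.n_columns

    # Fast path: no gaps anywhere in the nominal window, so columns map
    # one-to-one to bases and the realisation is a plain cross-product.
    end = start + window_length
    if end <= n:
        span = consensus[start:end]
        wc_cols = [c for c in range(start, end) if span[c - start] == "*"]
        if GAP not in span and all(GAP not in wildcards[c] for c in wc_cols):
            n_combo = math.prod(len(wildcards[c]) for c in wc_cols)
            if n_combo > budget:
                raise CombinationBudgetError(
                    f"window at column {start}: combination budget {budget} exceeded")
            template = list(span)
            out = []
            for combo in itertools.product(*(wildcards[c] for c in wc_cols)):
                for c, v in zip(wc_cols, combo):
                    template[c - start] = v
                out.append("".join(template))
            return out, n_combo

    out: list[str] = []
    raw = 0
    # Iterative DFS: (column, accumulated string)
    stack = [(start, "")]
    while stack:
        col, acc = stack.pop()
        while True:
            if len(acc) == window_length:
                out.append(acc)
                raw += 1
                if raw > budget:
                    raise CombinationBudgetError(
                        f"window at column {start}: combination budget {budget} exceeded")
                break
            if col >= n:
                break
            base = consensus[col]
            if base == "*":
                variants = wildcards[col]
                # keep one branch inline, push the others
                for v in variants[1:]:
                    stack.append((col + 1, acc + (v if v != GAP else "")))
                v0 = variants[0]
                acc = acc + (v0 if v0 != GAP else "")
                col += 1
            elif base == GAP:
                col += 1
            else:
                acc += base
                col += 1
    return out, raw


def enumerate_fragments(pattern: ConsensusPattern, genome: str,
                        window_length: int = 145, step: int = 1,
                        max_combinations_per_window: int = 10 ** 6,
                        both_strand_purge: bool = True,
                        extra_purge_sequences: Sequence[str] = ()) -> JunctionLibrary:
    """Enumerate, deduplicate and genome-purge all window realisations.

    ``extra_purge_sequences`` optionally removes fragments occurring in
    additional references (e.g. single-parent ecDNA forms, so that an aged
    member's own reconstituted LTR does not register as an inter-member
    junction).
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    genome = genome.upper()

    candidates: dict[str, tuple[int, int]] = {}
    raw_counts: dict[int, int] = {}
    for start in range(0, pattern.n_columns, step):
        realised, raw = _expand_window(pattern, start, window_length,
                                       max_combinations_per_window)
        if not realised:
            continue
        raw_counts[start] = raw
        for idx, frag in enumerate(realised):
            if frag not in candidates:
                candidates[frag] = (start, idx)

    purge_targets = [genome]
    purge_targets.extend(s.upper() for s in extra_purge_sequences)
    purged = set()
    for target in purge_targets:
        for strand_seq in ((target, revcomp(target)) if both_strand_purge else (target,)):
            for i in range(len(strand_seq) - window_length + 1):
                w = strand_seq[i: i + window_length]
                if w in candidates:
                    purged.add(w)

    kept = sorted(f for f in candidates if f not in purged)
    provenance = {f: candidates[f] for f in kept}
    return JunctionLibrary(fragments=tuple(kept), window_length=window_length,
                           provenance=provenance, raw_window_counts=raw_counts,
                           purged_genome=len(purged),
                           both_strand_purge=both_strand_purge)


@dataclass(frozen=True)
class JunctionSearchResult:
    matches: pd.DataFrame         # read_index, read_name, fragment, offset, strand
    n_matching_reads: int
    n_reads: int
    onsen_mapping_read_count: int
    rate_per_1000: float


def search_junctions(reads: Iterable[str | tuple[str, str]],
                     library: JunctionLibrary,
                     onsen_mapping_read_count: int) -> JunctionSearchResult:
    """Scan reads for exact junction-fragment matches (either strand).

    A read counts once however many fragments it contains (a read-level
    statistic); the rate is per 1000 element-mapping reads as given by
    ``onsen_mapping_read_count``.
    """
    if onsen_mapping_read_count <= 0:
        raise ValueError("onsen_mapping_read_count must be > 0")
    w = library.window_length
    search = library.search_set
    fwd = library.forward_set

    rows = []
    n_reads = 0
    for idx, item in enumerate(reads):
        name, seq = item if isinstance(item, tuple) else (str(idx), item)
        n_reads += 1
        seq = seq.upper()
        for i in range(len(seq) - w + 1):
            window = seq[i: i + w]
            if window in search:
                if window in fwd:
                    rows.append((idx, name, window, i, "+"))
                else:
                    rows.append((idx, name, revcomp(window), i, "-"))
                break  # read-level statistic: first hit is enough
    matches = pd.DataFrame(rows, columns=["read_index", "read_name", "fragment",
                                          "offset", "strand"])
    n_match = len(rows)
    rate = 1000.0 * n_match / onsen_mapping_read_count
    return JunctionSearchResult(matches=matches, n_matching_reads=n_match,
                                n_reads=n_reads,
                                onsen_mapping_read_count=onsen_mapping_read_count,
                                rate_per_1000=rate)
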