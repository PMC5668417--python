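"""New-insertion calling, LTR reconstruction, parental painting and scoring.

Insertions are called from two independent evidence classes computed
against an element-masked reference: discordant pairs (one mate uniquely
mapped to a chromosome, the other unmapped but matching an element LTR)
and junction reads (unmapped reads spanning the element/genome boundary,
whose element part is trimmed and whose genomic residue is remapped to
give a base-exact junction coordinate — the 5'- and 3'-side coordinates
differ by the target-site duplication length). Candidate calls require
both evidence classes, and clusters also present in a control sample are
removed as pre-existing copies or artefacts.

The element-side mates of pairs anchored around an insertion point are
re-assembled by greedy maximal-overlap merging to reconstruct the
inserted LTR, which is then "painted": each position is compared with the
parental members' sequences, compatible member sets are tracked along the
sequence, and a minimal-switch parental assignment (fewest parent
changes; ties broken by fewest distinct parents, then lexicographically)
summarises the mosaic. Positions incompatible with every parent are
reported as novel polymorphisms (reverse-transcription errors). Parental
contributions are scored on a 12-point scale per insertion, split evenly
among its contributing parents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .burst import single_parent_ecdna
from .family import FamilyModel
from .mapper import GenomeIndex, Placement
from .reads import ReadPair
from .seqio import revcomp

POINTS_PER_INSERTION = 12


# --- evidence collection ---------------------------------------------------

@dataclass(frozen=True)
class AnchorRecord:
    """A discordant pair: genomic mate placed, element mate unmapped-but-LTR."""
    chrom: str
    position: int       # flank boundary implied by the mapped mate
    side: str           # "L": element to the right; "R": element to the left
    element_mate: str   # sequence of the unmapped mate, as sequenced
    pair_name: str


@dataclass(frozen=True)
class JunctionRead:
    chrom: str
    coord: int          # genomic base adjacent to the element edge
    side: str           # "left" (flank|element start) or "right" (element end|flank)
    element_part: str   # element-forward portion of the read
    read_name: str


def _kmer_set(seqs: Iterable[str], k: int, include_rc: bool = True) -> set[str]:
    out: set[str] = set()
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            out.add(s[i: i + k])
        if include_rc:
            rc = revcomp(s)
            for i in range(len(rc) - k + 1):
                out.add(rc[i: i + k])
    return out


def _shares_kmer(read: str, kmers: set[str], k: int, stride: int = 7) -> bool:
    if len(read) < k:
        return False
    positions = list(range(0, len(read) - k + 1, stride))
    if positions[-1] != len(read) - k:
        positions.append(len(read) - k)
    return any(read[i: i + k] in kmers for i in positions)


def find_discordant_pairs(mapped_pairs: Sequence[tuple[ReadPair, Placement | None, Placement | None]],
                          ltr_sequences: Iterable[str],
                          seed_length: int = 31) -> list[AnchorRecord]:
    """Anchors where exactly one mate maps uniquely and the unmapped mate
    matches an element LTR (shares an exact seed with it, either strand).

    ``mapped_pairs`` come from the internal mapper against the
    element-masked genome, or from an external SAM via
    :func:`retroburst.mapper.pairs_from_sam`.
    """
    ltr_kmers = _kmer_set(ltr_sequences, seed_length)
    anchors: list[AnchorRecord] = []
    for pair, p1, p2 in mapped_pairs:
        if (p1 is None) == (p2 is None):
            continue  # concordant or fully unmapped
        placed, unmapped_seq = (p1, pair.r2) if p1 is not None else (p2, pair.r1)
        mate_len = len(pair.r1 if p1 is not None else pair.r2)
        if not _shares_kmer(unmapped_seq.upper(), ltr_kmers, seed_length):
            continue
        if placed.strand == "+":
            anchors.append(AnchorRecord(placed.chrom, placed.start + mate_len,
                                        "L", unmapped_seq, pair.name))
        else:
            anchors.append(AnchorRecord(placed.chrom, placed.start,
                                        "R", unmapped_seq, pair.name))
    return anchors


def find_junction_reads(reads: Iterable[tuple[str, str]],
                        element_start: str, element_end: str,
                        index: GenomeIndex,
                        min_residual: int = 31) -> list[JunctionRead]:
    """Junction reads spanning a genome/element boundary.

    ``element_start``/``element_end`` are the family-shared element edge
    motifs. The element part is recognised in either read orientation and
    trimmed; the genomic residue must remap uniquely and full-length
    (accounting for the target-site duplication, whose presence makes the
    two sides' coordinates differ by exactly the TSD length). Residues
    shorter than ``min_residual`` are discarded.
    """
    element_start = element_start.upper()
    element_end = element_end.upper()
    out: list[JunctionRead] = []
    for name, read in reads:
        read = read.upper()
        found = None
        for s in (read, revcomp(read)):
            i = s.find(element_start)
            if i >= min_residual:
                flank = s[:i]
                pl = index.map_exact(flank)
                if pl is not None:
                    if pl.strand == "+":
                        found = JunctionRead(pl.chrom, pl.start + len(flank),
                                             "left", s[i:], name)
                    else:
                        found = JunctionRead(pl.chrom, pl.start, "right", s[i:], name)
                    break
            j = s.rfind(element_end)
            if j >= 0:
                cut = j + len(element_end)
                residual = s[cut:]
                if len(residual) >= min_residual:
                    pl = index.map_exact(residual)
                    if pl is not None:
                        if pl.strand == "+":
                            found = JunctionRead(pl.chrom, pl.start, "right",
                                                 s[:cut], name)
                        else:
                            found = JunctionRead(pl.chrom, pl.start + len(residual),
                                                 "left", s[:cut], name)
                        break
        if found is not None:
            out.append(found)
    return out


# --- insertion calling -----------------------------------------------------

@dataclass(frozen=True)
class InsertionCall:
    chrom: str
    start: int                   # 0-based; [start, end) is the duplicated target site
    end: int
    tsd_sequence: str | None
    n_discordant: int
    n_junction_left: int
    n_junction_right: int
    present_in_control: bool
    near_known_element: bool = False

    @property
    def tsd_length(self) -> int:
        return self.end - self.start


def _clusters(coords: Sequence[int], width: int) -> list[list[int]]:
    if not coords:
        return []
    coords = sorted(coords)
    out = [[coords[0]]]
    for c in coords[1:]:
        if c - out[-1][-1] <= width:
            out[-1].append(c)
        else:
            out.append([c])
    return out


def _mode(values: Sequence[int]) -> int:
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def call_insertions(anchors: Sequence[AnchorRecord],
                    junctions: Sequence[JunctionRead],
                    control_anchors: Sequence[AnchorRecord] = (),
                    control_junctions: Sequence[JunctionRead] = (),
                    genome: str | None = None,
                    known_element_intervals: Sequence[tuple[int, int]] = (),
                    min_discordant: int = 2, min_junction_per_side: int = 1,
                    cluster_width: int = 500,
                    include_flagged: bool = False) -> list[InsertionCall]:
    """Intersect junction-read and discordant-pair clusters into calls.

    Coordinates are 0-based half-open; the call interval is the duplicated
    target site (modal right-side coordinate to modal left-side
    coordinate). Clusters present in the control evidence, or overlapping
    known element copies, are flagged and excluded unless
    ``include_flagged``.
    """
    calls: list[InsertionCall] = []
    junc_coords = [j.coord for j in junctions]
    anchor_pos = sorted(a.position for a in anchors)
    control_pos = sorted([a.position for a in control_anchors]
                         + [j.coord for j in control_junctions])

    for cluster in _clusters(junc_coords, cluster_width):
        lo, hi = cluster[0], cluster[-1]
        in_cluster = [j for j in junctions if lo <= j.coord <= hi]
        lefts = [j.coord for j in in_cluster if j.side == "left"]
        rights = [j.coord for j in in_cluster if j.side == "right"]
        if len(lefts) < min_junction_per_side or len(rights) < min_junction_per_side:
            continue
        n_anch = sum(1 for p in anchor_pos if lo - cluster_width <= p <= hi + cluster_width)
        if n_anch < min_discordant:
            continue
        right_mode, left_mode = _mode(rights), _mode(lefts)
        start, end = right_mode, max(left_mode, right_mode)
        in_control = any(lo - cluster_width <= p <= hi + cluster_width
                         for p in control_pos)
        near_known = any(s - cluster_width <= start <= e + cluster_width
                         for s, e in known_element_intervals)
        tsd = genome[start:end] if genome is not None and end > start else None
        call = InsertionCall(
            chrom=in_cluster[0].chrom, start=start, end=end, tsd_sequence=tsd,
            n_discordant=n_anch, n_junction_left=len(lefts),
            n_junction_right=len(rights),
            present_in_control=in_control, near_known_element=near_known)
        if include_flagged or not (in_control or near_known):
            calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


# --- LTR reconstruction ----------------------------------------------------

@dataclass(frozen=True)
class ReconstructedInsertion:
    call: InsertionCall
    contigs: tuple[str, ...]       # assembled element-side contigs, longest first
    ltr_sequence: str | None       # leading LTR when anchored at the element start
    complete: bool                 # True when the LTR was fully recovered


def _orient(seq: str, ref_kmers: set[str], k: int = 21) -> str:
    fwd = sum(seq[i: i + k] in ref_kmers for i in range(0, len(seq) - k + 1, 5))
    rc = revcomp(seq)
    rev = sum(rc[i: i + k] in ref_kmers for i in range(0, len(rc) - k + 1, 5))
    return seq if fwd >= rev else rc


def assemble_greedy(seqs: Sequence[str], min_overlap: int = 30) -> list[str]:
    """Greedy overlap assembly of exact (error-free) sequences.

    Seeds a contig with the longest remaining fragment and extends it in
    both directions by the fragment with the largest exact suffix/prefix
    overlap (>= ``min_overlap``); contained fragments are absorbed.
    Deterministic: ties resolve lexicographically.
    """
    pieces = sorted(set(s.upper() for s in seqs if s), key=lambda f: (-len(f), f))
    contigs: list[str] = []
    unused = list(pieces)
    while unused:
        contig = unused.pop(0)
        grew = True
        while grew:
            grew = False
            unused = [p for p in unused if p not in contig]
            # rightward: largest k with contig suffix == piece prefix
            best = None  # (overlap, piece)
            for p in unused:
                for k in range(min(len(p), len(contig)) - 1, min_overlap - 1, -1):
                    if contig.endswith(p[:k]):
                        if len(p) > k and (best is None or (k, p) > best):
                            best = (k, p)
                        break
            if best is not None:
                k, p = best
                contig = contig + p[k:]
                unused.remove(p)
                grew = True
                continue
            # leftward: largest k with piece suffix == contig prefix
            best = None
            for p in unused:
                for k in range(min(len(p), len(contig)) - 1, min_overlap - 1, -1):
                    if p.endswith(contig[:k]):
                        if len(p) > k and (best is None or (k, p) > best):
                            best = (k, p)
                        break
            if best is not None:
                k, p = best
                contig = p[: len(p) - k] + contig
                unused.remove(p)
                grew = True
        contigs.append(contig)
    return sorted(contigs, key=lambda f: (-len(f), f))


def reconstruct_ltr(call: InsertionCall, anchors: Sequence[AnchorRecord],
                    junction_reads: Sequence[JunctionRead],
                    family: FamilyModel,
                    cluster_width: int = 500, min_overlap: int = 30,
                    min_anchored_pairs: int = 2,
                    edge_motif_length: int = 30) -> ReconstructedInsertion:
    """Re-assemble the element-side mates anchored around one insertion.

    Both LTRs of an integrated molecule are identical, so element-side
    mates from the 5' and the 3' edges sample the same LTR sequence; their
    greedy assembly, anchored at the family-shared element start motif,
    yields the inserted LTR. With insufficient coverage the reconstruction
    is returned partial and flagged.
    """
    # forward-only k-mers: orientation is decided by which strand matches
    ref_kmers = _kmer_set([m.seq for m in family.members]
                          + [single_parent_ecdna(m) for m in family.members],
                          21, include_rc=False)
    lo, hi = call.start - cluster_width, call.end + cluster_width
    local = [a.element_mate for a in anchors if lo <= a.position <= hi]
    if len(local) < min_anchored_pairs:
        return ReconstructedInsertion(call, (), None, False)
    pieces = [_orient(s.upper(), ref_kmers) for s in local]
    ltr_len = family.config.ltr_length
    for j in junction_reads:
        if lo <= j.coord <= hi:
            part = j.element_part
            # right-side junction parts are the element's 3' end = LTR end;
            # re-express them in leading-LTR coordinates (the two LTRs match).
            pieces.append(part if j.side == "left" else part[-ltr_len:])
    contigs = assemble_greedy(pieces, min_overlap=min_overlap)
    # Element-side mates spanning the genome/element boundary carry flank
    # bases, so the element start motif marks the LTR origin inside the contig.
    start_motif = family.shared_element_prefix(edge_motif_length)
    ltr_seq = None
    complete = False
    for contig in contigs:
        i = contig.find(start_motif)
        if i >= 0:
            ltr_seq = contig[i: i + ltr_len]
            complete = len(contig) - i >= ltr_len
            break
    return ReconstructedInsertion(call, tuple(contigs), ltr_seq, complete)


# --- parental painting -----------------------------------------------------

@dataclass(frozen=True)
class PaintedElement:
    id: str
    sequence: str
    intervals: tuple[tuple[int, int, frozenset], ...]   # tile the sequence
    minimal_path: tuple[str, ...]       # one member per interval
    n_parents: int                      # distinct members in the minimal solution
    novel: tuple[tuple[int, str], ...]  # positions incompatible with every parent

    @property
    def minimal_parents(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.minimal_path)))


class PaintingError(ValueError):
    pass


def _min_switch_paint(sets: Sequence[frozenset], node_budget: int = 2_000_000
                      ) -> tuple[list, int]:
    """Exact minimal-switch assignment over per-run compatible sets.

    Returns (path, n_switches) minimising, in order: number of parent
    changes, number of distinct parents, lexicographic path.
    """
    G = len(sets)
    members_per = [sorted(s) for s in sets]
    # cost-to-go: f[i][m] = min switches for runs i..G-1 with run i on m
    f: list[dict] = [dict() for _ in range(G)]
    for m in members_per[-1]:
        f[G - 1][m] = 0
    for i in range(G - 2, -1, -1):
        nxt = f[i + 1]
        best_next = min(nxt.values())
        for m in members_per[i]:
            stay = nxt.get(m)
            f[i][m] = min(best_next + 1, stay) if stay is not None else best_next + 1
    s_star = min(f[0].values())

    best: list | None = None  # [distinct, path]
    nodes = 0

    def dfs(i: int, switches: int, used: frozenset, path: list):
        nonlocal best, nodes
        nodes += 1
        if nodes > node_budget:
            raise PaintingError("painting search budget exceeded")
        if best is not None and len(used) > best[0]:
            return
        if i == G:
            cand = [len(used), path[:]]
            if best is None or cand < best:
                best = cand
            return
        prev = path[-1] if path else None
        for m in members_per[i]:
            add = 0 if (prev is None or m == prev) else 1
            if switches + add + f[i][m] > s_star:
                continue  # cannot reach the switch optimum any more
            path.append(m)
            dfs(i + 1, switches + add, used | {m}, path)
            path.pop()

    dfs(0, 0, frozenset(), [])
    assert best is not None
    return best[1], s_star


def paint_parentage(sequence: str, member_variants: Mapping[str, Sequence[str]],
                    element_id: str = "element") -> PaintedElement:
    """Paint a sequence with the parental members compatible with it.

    ``member_variants`` maps member -> one or more reference strings of
    the same length as ``sequence`` (e.g. the 5' and 3' LTR of each member
    when painting a reconstructed LTR, or the single-parent ecDNA form
    when painting a whole molecule); the member is compatible at a
    position when any of its variants matches there. Positions compatible
    with no member are novel polymorphisms, excluded from painting.
    """
    n = len(sequence)
    seq = sequence.upper()
    all_members = frozenset(member_variants)
    if not all_members:
        raise PaintingError("no members to paint against")
    for m, variants in member_variants.items():
        for v in variants:
            if len(v) != n:
                raise PaintingError(
                    f"variant of member {m} has length {len(v)} != sequence {n}")

    variant_list = {m: [v.upper() for v in vs] for m, vs in member_variants.items()}
    informative: list[tuple[int, frozenset]] = []
    novel: list[tuple[int, str]] = []
    for i in range(n):
        compat = frozenset(m for m, vs in variant_list.items()
                           if any(v[i] == seq[i] for v in vs))
        if not compat:
            novel.append((i, seq[i]))
        elif compat != all_members:
            informative.append((i, compat))

    if not informative:
        member = sorted(all_members)[0]
        return PaintedElement(element_id, sequence,
                              ((0, n, all_members),), (member,), 1, tuple(novel))

    # group consecutive equal compatible sets into runs
    runs: list[tuple[int, frozenset]] = []   # (first informative column, set)
    for col, s in informative:
        if not runs or runs[-1][1] != s:
            runs.append((col, s))
    sets = [s for _, s in runs]
    path, _ = _min_switch_paint(sets)

    # merge runs that the minimal path keeps on one member AND whose sets equal
    intervals: list[tuple[int, int, frozenset]] = []
    starts = [0] + [col for col, _ in runs[1:]] + [n]
    for k, (col, s) in enumerate(runs):
        intervals.append((starts[k], starts[k + 1], s))

    return PaintedElement(element_id, sequence, tuple(intervals), tuple(path),
                          len(set(path)), tuple(novel))


def ltr_variants(family: FamilyModel) -> dict[str, list[str]]:
    """Per member, the 5' and 3' LTR sequences (deduplicated for young members)."""
    out = {}
    for m in family.members:
        variants = [m.ltr5]
        if m.ltr3 != m.ltr5:
            variants.append(m.ltr3)
        out[m.id] = variants
    return out


def ecdna_variants(family: FamilyModel) -> dict[str, list[str]]:
    """Per member, its single-parent ecDNA form (for whole-molecule painting)."""
    return {m.id: [single_parent_ecdna(m)] for m in family.members}


def report_novel_polymorphisms(painted: Sequence[PaintedElement]) -> pd.DataFrame:
    """Positions incompatible with every parental member, with context."""
    rows = []
    for p in painted:
        for pos, base in p.novel:
            ctx = p.sequence[max(0, pos - 10): pos + 11]
            rows.append((p.id, pos, base, ctx))
    return pd.DataFrame(rows, columns=["element", "position", "base", "context"])


# --- contribution scoring --------------------------------------------------

@dataclass(frozen=True)
class ContributionTable:
    per_insertion: pd.DataFrame   # insertion, member, score
    totals: pd.Series             # member -> summed score
    relative: pd.Series           # member -> fraction of all points


def contribution_scores(painted: Sequence[PaintedElement]) -> ContributionTable:
    """12-point parental contribution scores.

    Each insertion distributes 12 points evenly over the distinct parents
    of its minimal painting solution: 12 to a single parent, 6 each to
    two, 4 each to three, and so on; scores per insertion always sum to 12.
    """
    rows = []
    for p in painted:
        parents = p.minimal_parents
        if len(parents) == 0:
            raise ValueError(f"insertion {p.id} has no parents")
        score = POINTS_PER_INSERTION / len(parents)
        for m in parents:
            rows.append((p.id, m, score))
    per = pd.DataFrame(rows, columns=["insertion", "member", "score"])
    totals = per.groupby("member")["score"].sum() if len(per) else pd.Series(dtype=float)
    relative = totals / totals.sum() if len(per) else totals
    return ContributionTable(per_insertion=per, totals=totals, relative=relative)
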