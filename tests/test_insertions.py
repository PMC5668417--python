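"""Insertion calling, reconstruction, painting and contribution scoring."""

import itertools

import numpy as np
import pytest

from retroburst.insertions import (PaintedElement, _min_switch_paint,
                                   assemble_greedy, call_insertions,
                                   contribution_scores, ecdna_variants,
                                   find_discordant_pairs, find_junction_reads,
                                   ltr_variants, paint_parentage,
                                   reconstruct_ltr, report_novel_polymorphisms)
from retroburst.mapper import GenomeIndex, Placement, map_pairs, mask_intervals
from retroburst.reads import ReadPair
from retroburst.seqio import AlignedRead, read_sam, revcomp, write_sam


# --- mapper ----------------------------------------------------------------

def test_mapper_exact_unique_and_masked(divergent_family):
    fam = divergent_family
    masked = mask_intervals(fam.genome, [(s, e) for s, e, _ in fam.element_intervals])
    idx = GenomeIndex(masked)
    flank = fam.genome[500:650]
    pl = idx.map_exact(flank)
    assert pl == Placement("chr1", 500, "+")
    assert idx.map_exact(revcomp(flank)) == Placement("chr1", 500, "-")
    mutated = ("A" if flank[70] != "A" else "C").join([flank[:70], flank[71:]])
    assert idx.map_exact(mutated) is None
    element_read = fam.members[0].seq[100:250]
    assert idx.map_exact(element_read) is None


def test_sam_round_trip_with_soft_clips(tmp_path):
    records = [
        AlignedRead("r1", 0, "chr1", 99, 60, "30S120M", "A" * 150),
        AlignedRead("r2", 16, "chr1", 300, 60, "150M", "C" * 150),
        AlignedRead("r3", 4, "*", -1, 0, "*", "G" * 150),
    ]
    path = tmp_path / "t.sam"
    write_sam(path, records, {"chr1": 100_000})
    back = read_sam(path)
    assert [(r.qname, r.flag, r.pos, r.cigar) for r in back] == \
        [(r.qname, r.flag, r.pos, r.cigar) for r in records]


# --- evidence --------------------------------------------------------------

def test_concordant_pair_is_not_an_anchor(burst_setup):
    fam = burst_setup["family"]
    idx = burst_setup["index"]
    g = fam.genome
    pair = ReadPair("conc", g[1000:1150], revcomp(g[1250:1400]))
    mapped = map_pairs([pair], idx)
    anchors = find_discordant_pairs(mapped, [m.ltr5 for m in fam.members])
    assert anchors == []


def test_anchor_positions_flank_planted_insertions(burst_setup):
    planted = burst_setup["planted"]
    anchors = burst_setup["anchors"]
    sites = [t.start for t in planted]
    element_edges = [b for s, e, _ in burst_setup["family"].element_intervals
                     for b in (s, e)]
    near_any = 0
    for a in anchors:
        close_site = any(abs(a.position - s) <= 600 for s in sites)
        close_element = any(abs(a.position - b) <= 600 for b in element_edges)
        assert close_site or close_element  # pre-existing copies are controls
        near_any += close_site
    assert near_any > 0


def test_junction_read_from_constructed_read(burst_setup):
    fam = burst_setup["family"]
    idx = burst_setup["index"]
    start_motif = fam.shared_element_prefix(30)
    end_motif = fam.shared_element_suffix(30)
    flank = fam.genome[2000:2080]
    read = flank + fam.members[0].seq[:70]
    recs = find_junction_reads([("j", read)], start_motif, end_motif, idx)
    assert len(recs) == 1
    assert recs[0].side == "left" and recs[0].coord == 2080
    inside = fam.members[0].seq[10:160]
    assert find_junction_reads([("i", inside)], start_motif, end_motif, idx) == []


def test_junction_sides_differ_by_tsd(burst_setup):
    planted = {t.start: t for t in burst_setup["planted"]}
    by_site = {}
    for j in burst_setup["junction_reads"]:
        for s in planted:
            if abs(j.coord - s) <= 10:
                by_site.setdefault(s, {"left": set(), "right": set()})[j.side].add(j.coord)
    assert by_site
    for s, sides in by_site.items():
        if sides["left"] and sides["right"]:
            assert max(sides["left"]) - min(sides["right"]) == planted[s].tsd_length


# --- calling ---------------------------------------------------------------

def test_call_insertions_trivial_cases():
    assert call_insertions([], [], [], []) == []


def test_full_recovery_of_planted_insertions(burst_setup):
    calls = call_insertions(
        burst_setup["anchors"], burst_setup["junction_reads"],
        burst_setup["control_anchors"], burst_setup["control_junctions"],
        genome=burst_setup["family"].genome)
    truth = {(t.chrom, t.start, t.end) for t in burst_setup["planted"]}
    called = {(c.chrom, c.start, c.end) for c in calls}
    assert called == truth  # 100% recall and precision, exact coordinates
    for c in calls:
        g = burst_setup["family"].genome
        assert c.tsd_sequence == g[c.start: c.end]


def test_shared_clusters_removed_by_control(burst_setup):
    # treating the progeny evidence as its own control removes everything
    calls = call_insertions(
        burst_setup["anchors"], burst_setup["junction_reads"],
        burst_setup["anchors"], burst_setup["junction_reads"],
        genome=burst_setup["family"].genome)
    assert calls == []


# --- reconstruction --------------------------------------------------------

def test_assemble_greedy_merges_overlapping_pieces():
    rng = np.random.default_rng(5)
    target = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
    pieces = [target[i: i + 120] for i in range(0, 380, 40)] + [target[380:500]]
    contigs = assemble_greedy(pieces, min_overlap=30)
    assert contigs[0] == target


def test_reconstructed_ltrs_match_truth(burst_setup):
    fam = burst_setup["family"]
    truth = burst_setup["truth"]
    calls = call_insertions(
        burst_setup["anchors"], burst_setup["junction_reads"],
        burst_setup["control_anchors"], burst_setup["control_junctions"],
        genome=fam.genome)
    by_site = {t.start: t for t in burst_setup["planted"]}
    ltr_len = fam.config.ltr_length
    n_exact = 0
    for call in calls:
        rec = reconstruct_ltr(call, burst_setup["anchors"],
                              burst_setup["junction_reads"], fam)
        true_ltr = truth.molecule(by_site[call.start].ecdna_id).seq[:ltr_len]
        assert rec.complete
        assert rec.ltr_sequence == true_ltr
        n_exact += 1
    assert n_exact == len(by_site)


# --- painting --------------------------------------------------------------

def _brute_force_paint(sets):
    """Oracle: exhaustively minimise (switches, distinct, path)."""
    best = None
    for path in itertools.product(*[sorted(s) for s in sets]):
        switches = sum(a != b for a, b in zip(path, path[1:]))
        key = (switches, len(set(path)), path)
        if best is None or key < best:
            best = key
    return list(best[2]), best[0]


@pytest.mark.parametrize("seed", range(8))
def test_min_switch_paint_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    members = ["A", "B", "C", "D"][: int(rng.integers(2, 5))]
    sets = []
    for _ in range(int(rng.integers(2, 8))):
        k = int(rng.integers(1, len(members) + 1))
        sets.append(frozenset(rng.choice(members, size=k, replace=False)))
    path, s = _min_switch_paint(sets)
    opath, os = _brute_force_paint(sets)
    assert s == os
    assert path == opath


def test_paint_pure_sequence_single_interval(divergent_family):
    fam = divergent_family
    m = fam.members[2]
    painted = paint_parentage(m.ltr5, ltr_variants(fam), "pure")
    assert painted.n_parents == 1
    assert all(m.id in s for _, _, s in painted.intervals)
    assert painted.novel == ()


def test_paint_constructed_chimera_two_parents(divergent_family):
    fam = divergent_family
    a, b = fam.members[2], fam.members[7]
    cut = 150
    chimera = a.ltr5[:cut] + b.ltr5[cut:]
    painted = paint_parentage(chimera, ltr_variants(fam), "chimera")
    # intervals tile the sequence and adjacent sets differ
    assert painted.intervals[0][0] == 0
    assert painted.intervals[-1][1] == len(chimera)
    for (s1, e1, x), (s2, e2, y) in zip(painted.intervals, painted.intervals[1:]):
        assert e1 == s2 and x != y
    assert painted.n_parents == 2
    assert set(painted.minimal_parents) == {a.id, b.id}


def test_paint_flags_novel_positions(divergent_family):
    fam = divergent_family
    seq = list(fam.members[0].ltr5)
    pos = 123
    seq[pos] = "A" if seq[pos] != "A" else "T"
    # ensure the base differs from every member variant at that position
    variants = ltr_variants(fam)
    while any(v[pos] == seq[pos] for vs in variants.values() for v in vs):
        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    painted = paint_parentage("".join(seq), variants, "mut")
    assert [p for p, _ in painted.novel] == [pos]
    table = report_novel_polymorphisms([painted])
    assert list(table["position"]) == [pos]


def test_error_free_painting_reports_no_novel_polymorphisms(burst_setup):
    fam = burst_setup["family"]
    variants = ecdna_variants(fam)
    for mol in burst_setup["molecules"][:8]:
        painted = paint_parentage(mol.seq, variants, mol.id)
        assert painted.novel == ()


# --- scoring ---------------------------------------------------------------

def _painted_with_parents(parents, idx=0):
    return PaintedElement(f"i{idx}", "A", ((0, 1, frozenset(parents)),),
                          tuple(parents), len(set(parents)), ())


@pytest.mark.parametrize("k,expected", [(1, 12.0), (2, 6.0), (3, 4.0),
                                        (4, 3.0), (5, 2.4), (6, 2.0)])
def test_contribution_points_per_parent(k, expected):
    painted = [_painted_with_parents([f"M{i}" for i in range(k)])]
    table = contribution_scores(painted)
    assert set(table.per_insertion["score"]) == {expected}
    assert table.per_insertion["score"].sum() == pytest.approx(12.0)


def test_contribution_totals_and_relative_frequencies():
    painted = [_painted_with_parents(["A"], 0),
               _painted_with_parents(["A", "B"], 1),
               _painted_with_parents(["B", "C", "D"], 2)]
    table = contribution_scores(painted)
    assert table.totals["A"] == 18.0
    assert table.totals["B"] == 10.0
    assert table.relative.sum() == pytest.approx(1.0)
    assert table.per_insertion.groupby("insertion")["score"].sum().eq(12.0).all()
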