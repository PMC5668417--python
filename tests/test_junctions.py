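"""Junction library: consensus, enumeration vs brute force, search."""

import itertools

import pytest

from retroburst.burst import simulate_burst, single_parent_ecdna
from retroburst.junctions import (CombinationBudgetError, build_consensus,
                                  enumerate_fragments, search_junctions)
from retroburst.reads import all_read_sequences, sequence_reads
from retroburst.seqio import revcomp


def brute_force_library(alignment, genome, window_length, both_strand=True):
    """Independent oracle: all windows of all parent mosaics (any member
    choice per alignment column), minus every genome window."""
    members = list(alignment.values())
    cols = len(members[0])
    windows = set()
    for choice in itertools.product(range(len(members)), repeat=cols):
        mosaic = "".join(members[choice[c]][c] for c in range(cols))
        mosaic = mosaic.replace("-", "")
        for i in range(len(mosaic) - window_length + 1):
            windows.add(mosaic[i: i + window_length])
    purge = set()
    strands = (genome, revcomp(genome)) if both_strand else (genome,)
    for s in strands:
        for i in range(len(s) - window_length + 1):
            purge.add(s[i: i + window_length])
    return windows - purge


def test_identical_members_have_no_wildcards():
    pat = build_consensus({"a": "ACGTACGT", "b": "ACGTACGT"})
    assert pat.wildcards == {}
    assert pat.consensus == "ACGTACGT"


def test_single_substitution_wildcard():
    pat = build_consensus({"a": "ACGT", "b": "AGGT"})
    assert pat.wildcards == {1: ("C", "G")}
    assert pat.consensus == "A*GT"


def test_deletion_becomes_gap_variant():
    pat = build_consensus({"a": "ACGTAC", "b": "AC--AC"})
    assert pat.wildcards == {2: ("-", "G"), 3: ("-", "T")}


def test_empty_alignment_rejected():
    with pytest.raises(ValueError):
        build_consensus({})
    with pytest.raises(ValueError):
        build_consensus({"a": "ACG", "b": "AC"})


def test_two_member_toy_two_wildcards():
    # 2 members, 2 biallelic wildcards in one 10 bp window: 4 combinations,
    # 2 purged as parental, 2 junction fragments remain
    a = "AAACTTTGGC"
    b = "AAAGTTTGAC"
    genome = a + "TTTTTTTTTTTT" + b
    pat = build_consensus({"a": a, "b": b})
    lib = enumerate_fragments(pat, genome, window_length=10)
    assert lib.raw_window_counts[0] == 4
    assert len(lib) == 2
    assert set(lib.fragments) == {"AAACTTTGAC", "AAAGTTTGGC"}


def test_zero_wildcard_window_contributes_nothing():
    a = "ACGTACGTAC"
    genome = a + "GGGGG"
    pat = build_consensus({"a": a, "b": a})
    lib = enumerate_fragments(pat, genome, window_length=6)
    assert len(lib) == 0


def test_variant_product_rule():
    # wildcard variant sets of sizes 3 and 2 in one window: 6 raw combos
    aln = {"a": "AAACAAATAA", "b": "AAAGAAACAA", "c": "AAATAAATAA"}
    pat = build_consensus(aln)
    lib = enumerate_fragments(pat, "T" * 40, window_length=10)
    assert lib.raw_window_counts[0] == 6


@pytest.mark.parametrize("seed", range(4))
def test_oracle_equivalence_on_random_toy_alignments(seed):
    import numpy as np
    rng = np.random.default_rng(seed)
    cols = 10
    n_members = 3
    window = 6
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=cols))
    aln = {}
    for m in range(n_members):
        s = list(base)
        for _ in range(rng.integers(1, 4)):
            c = int(rng.integers(cols))
            s[c] = "ACGT-"[int(rng.integers(5))]
        aln[f"m{m}"] = "".join(s)
    flank = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
    genome = flank.join(s.replace("-", "") for s in aln.values())
    pat = build_consensus(aln)
    lib = enumerate_fragments(pat, genome, window_length=window)
    oracle = brute_force_library(aln, genome, window)
    assert set(lib.fragments) == oracle


def test_library_invariants_on_small_family(small_family):
    fam = small_family
    pat = build_consensus(fam.alignment)
    lib = enumerate_fragments(pat, fam.genome)
    # determinism
    lib2 = enumerate_fragments(pat, fam.genome)
    assert lib.fragments == lib2.fragments
    # no duplicates; purge soundness on a deterministic sample
    assert len(set(lib.fragments)) == len(lib.fragments)
    rc_genome = revcomp(fam.genome)
    for frag in lib.fragments[:: max(1, len(lib.fragments) // 300)]:
        assert frag not in fam.genome and frag not in rc_genome


def test_budget_exceeded_names_window():
    aln = {"a": "AAAAAAAAAA", "b": "CCCCCCCCCC"}
    pat = build_consensus(aln)
    with pytest.raises(CombinationBudgetError, match="column 0"):
        enumerate_fragments(pat, "G" * 30, window_length=10,
                            max_combinations_per_window=10)


def test_parental_reads_give_zero_rate(small_family):
    fam = small_family
    pat = build_consensus(fam.alignment)
    lib = enumerate_fragments(pat, fam.genome)
    reads = all_read_sequences(sequence_reads(
        {m.id: m.seq for m in fam.members}, 20.0, per_base_error=0.0, seed=1))
    result = search_junctions(reads, lib, len(reads))
    assert result.n_matching_reads == 0
    assert result.rate_per_1000 == 0.0


def test_single_fragment_read_matches_either_strand(small_family):
    fam = small_family
    pat = build_consensus(fam.alignment)
    lib = enumerate_fragments(pat, fam.genome)
    assert len(lib) > 0
    frag = lib.fragments[0]
    padded = frag + "ACGTA"
    res = search_junctions([padded, revcomp(padded)], lib, 1000)
    assert res.n_matching_reads == 2
    assert set(res.matches["strand"]) == {"+", "-"}


def test_planted_junctions_detected_per_truth():
    # All-young family: every ecDNA molecule is an element-coordinate
    # mosaic, so "reads matched by the library" must equal the oracle
    # "reads containing a molecule window absent from the genome",
    # obtained by direct substring scan of the simulation truth.
    from retroburst.family import FamilyConfig, make_family
    cfg = FamilyConfig(n_members=4, element_length=900, ltr_length=200,
                       u3_length=100, host_length=30_000,
                       target_ltr_identities=(1.0,) * 4,
                       expression_weights=(1.0,) * 4,
                       inter_member_divergence=0.01, seed=12)
    fam = make_family(cfg)
    pat = build_consensus(fam.alignment)
    lib = enumerate_fragments(pat, fam.genome)
    molecules, _ = simulate_burst(fam, 25, switch_rate=1.0,
                                  r_transfer_recomb_prob=0.8, seed=2)
    pairs = sequence_reads({m.id: m.seq for m in molecules}, 15.0,
                           per_base_error=0.0, seed=3)
    named_reads = []
    for p in pairs:
        named_reads.append((p.name + "/1", p.r1))
        named_reads.append((p.name + "/2", p.r2))
    result = search_junctions(named_reads, lib, len(named_reads))
    matched = set(result.matches["read_name"])

    window = lib.window_length
    genome_windows = set()
    for s in (fam.genome, revcomp(fam.genome)):
        for i in range(len(s) - window + 1):
            genome_windows.add(s[i: i + window])
    truth_windows = set()
    for mol in molecules:
        for i in range(len(mol.seq) - window + 1):
            w = mol.seq[i: i + window]
            if w not in genome_windows:
                truth_windows.add(w)
                truth_windows.add(revcomp(w))

    expected = set()
    for name, read in named_reads:
        if any(read[i: i + window] in truth_windows
               for i in range(len(read) - window + 1)):
            expected.add(name)
    assert matched == expected
    assert len(expected) > 0
    # single-parent molecules never produce matches
    by_id = {m.id: m for m in molecules}
    for name in matched:
        assert by_id[name.rsplit("/", 1)[0].split("|")[0]].is_recombinant


def test_detection_counts_increase_with_coverage(small_family):
    fam = small_family
    pat = build_consensus(fam.alignment)
    lib = enumerate_fragments(pat, fam.genome,
                              extra_purge_sequences=[single_parent_ecdna(m)
                                                     for m in fam.members])
    molecules, _ = simulate_burst(fam, 25, switch_rate=1.0,
                                  r_transfer_recomb_prob=0.8, seed=4)
    templates = {m.id: m.seq for m in molecules}
    low = search_junctions(all_read_sequences(
        sequence_reads(templates, 4.0, per_base_error=0.0, seed=5)), lib, 1000)
    high = search_junctions(all_read_sequences(
        sequence_reads(templates, 16.0, per_base_error=0.0, seed=5)), lib, 1000)
    assert high.n_matching_reads >= low.n_matching_reads


def test_search_requires_positive_denominator(small_family):
    fam = small_family
    pat = build_consensus(fam.alignment)
    lib = enumerate_fragments(pat, fam.genome)
    with pytest.raises(ValueError):
        search_junctions([], lib, 0)
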