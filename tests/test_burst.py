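"""Burst simulation: co-packaging, template switching, integration."""

import math

import pytest

from retroburst.burst import integrate, simulate_burst, single_parent_ecdna
from retroburst.family import FamilyConfig, make_family
from retroburst.seqio import revcomp


@pytest.fixture(scope="module")
def young_pair_family():
    cfg = FamilyConfig(n_members=2, element_length=1200, ltr_length=200,
                       u3_length=100, host_length=30_000,
                       target_ltr_identities=(1.0, 1.0),
                       expression_weights=(1.0, 1.0),
                       inter_member_divergence=0.01, seed=5)
    return make_family(cfg)


def test_zero_rates_give_pure_parents(young_pair_family):
    fam = young_pair_family
    mols, _ = simulate_burst(fam, 10, switch_rate=0.0,
                             r_transfer_recomb_prob=0.0, rt_error_rate=0.0,
                             seed=1)
    by_id = {m.id: m for m in fam.members}
    for mol in mols:
        assert not mol.is_recombinant
        assert mol.switch_positions == ()
        parent = by_id[mol.parent_pair[0]]
        # young members: the reconstituted LTR equals the parental LTR,
        # so the molecule equals the chromosomal element verbatim
        assert mol.seq == parent.seq
        L, ltr = len(mol.seq), fam.config.ltr_length
        assert mol.seq[:ltr] == mol.seq[L - ltr:]


def test_hetero_parental_fraction_is_binomial_half(young_pair_family):
    # two equally weighted members drawn independently: P(different) = 1/2
    n = 600
    mols, _ = simulate_burst(young_pair_family, n, switch_rate=0.0,
                             r_transfer_recomb_prob=1.0, seed=2)
    hetero = sum(m.parent_pair[0] != m.parent_pair[1] for m in mols)
    sigma = math.sqrt(n * 0.25)
    assert abs(hetero - n / 2) <= 3 * sigma


def test_molecule_sequence_matches_truth_segments(young_pair_family):
    fam = young_pair_family
    mols, _ = simulate_burst(fam, 40, switch_rate=1.0,
                             r_transfer_recomb_prob=0.7, rt_error_rate=1e-4,
                             seed=3)
    by_id = {m.id: m for m in fam.members}
    ltr, u3, L = fam.config.ltr_length, fam.config.u3_length, fam.config.element_length
    for mol in mols:
        # rebuild from the declared segments, then apply the declared RT errors
        rebuilt = list("".join(by_id[p].seq[lo:hi] for lo, hi, p in mol.segments))
        # segments describe donors in element coordinates; LTR segments use
        # the reconstituted LTR, so check via direct slice comparison instead
        errors = dict(mol.rt_errors)
        mismatches = [i for i in range(L)
                      if mol.seq[i] != rebuilt[i]]
        # every residual mismatch must be a recorded RT error or sit in a
        # reconstituted-LTR region whose donor differs between LTR copies
        for i in mismatches:
            in_u3 = i < u3 or (L - ltr) <= i < (L - ltr + u3)
            assert i in errors or in_u3
        for pos, base in mol.rt_errors:
            assert mol.seq[pos] == base


def test_switch_positions_lie_inside_alignment(young_pair_family):
    fam = young_pair_family
    mols, _ = simulate_burst(fam, 50, switch_rate=2.0,
                             r_transfer_recomb_prob=0.5, seed=4)
    n_cols = fam.config.element_length
    for mol in mols:
        for c in mol.switch_positions:
            assert 0 <= c < n_cols
        if mol.parent_pair[0] == mol.parent_pair[1]:
            assert mol.switch_positions == ()


def test_old_member_ecdna_has_reconstituted_identical_ltrs():
    cfg = FamilyConfig(n_members=1, element_length=1200, ltr_length=200,
                       u3_length=100, host_length=20_000,
                       target_ltr_identities=(0.95,),
                       expression_weights=(1.0,), seed=6)
    fam = make_family(cfg)
    m = fam.members[0]
    assert m.ltr5 != m.ltr3
    ec = single_parent_ecdna(m)
    ltr = cfg.ltr_length
    assert ec[:ltr] == ec[-ltr:]
    assert ec[:cfg.u3_length] == m.ltr3[:cfg.u3_length]
    assert ec[cfg.u3_length:ltr] == m.ltr5[cfg.u3_length:]


def test_planted_junction_occurs_verbatim_in_ecdna(young_pair_family):
    # ground-truth round trip: around every recorded switch the molecule
    # carries the donor's bases on each side
    fam = young_pair_family
    mols, _ = simulate_burst(fam, 60, switch_rate=0.5,
                             r_transfer_recomb_prob=1.0, seed=7)
    by_id = {m.id: m for m in fam.members}
    found_recombinant = False
    for mol in mols:
        if not mol.is_recombinant:
            continue
        found_recombinant = True
        for lo, hi, donor in mol.segments:
            if hi - lo >= 30:
                assert by_id[donor].seq[lo:hi] in mol.seq or \
                    mol.seq[lo:hi] == by_id[donor].seq[lo:hi]
    assert found_recombinant


def test_integrate_zero_insertions_is_identity(young_pair_family):
    fam = young_pair_family
    mols, _ = simulate_burst(fam, 3, seed=8)
    progeny, records = integrate(mols, fam.genome, 0, seed=8)
    assert progeny == fam.genome and records == []


def test_integrate_length_conservation(young_pair_family):
    fam = young_pair_family
    mols, truth = simulate_burst(fam, 5, seed=9)
    progeny, records = integrate(mols, fam.genome, 4, tsd_length=5, seed=9,
                                 element_intervals=fam.element_intervals,
                                 truth=truth)
    expected = len(fam.genome) + sum(
        len(truth.molecule(r.ecdna_id).seq) + r.tsd_length for r in records)
    assert len(progeny) == expected


def test_75_insertions_on_megabase_genome_recoverable():
    cfg = FamilyConfig(n_members=2, element_length=1200, ltr_length=200,
                       u3_length=100, host_length=1_000_000,
                       target_ltr_identities=(1.0, 1.0),
                       expression_weights=(1.0, 1.0),
                       inter_member_divergence=0.01, seed=10)
    fam = make_family(cfg)
    mols, truth = simulate_burst(fam, 10, r_transfer_recomb_prob=0.5, seed=11)
    progeny, records = integrate(mols, fam.genome, 75, tsd_length=5, seed=11,
                                 element_intervals=fam.element_intervals,
                                 truth=truth, min_spacing=3000)
    assert len(records) == 75
    by_id = {m.id: m for m in mols}
    # verify each insertion by direct sequence comparison in progeny
    # coordinates (records sorted; offsets accumulate left to right)
    offset = 0
    for rec in records:
        mol_seq = by_id[rec.ecdna_id].seq
        if rec.strand == "-":
            mol_seq = revcomp(mol_seq)
        p = rec.start + offset
        tsd = fam.genome[rec.start: rec.start + rec.tsd_length]
        assert progeny[p: p + rec.tsd_length] == tsd
        assert progeny[p + rec.tsd_length: p + rec.tsd_length + len(mol_seq)] == mol_seq
        assert progeny[p + rec.tsd_length + len(mol_seq):
                       p + 2 * rec.tsd_length + len(mol_seq)] == tsd
        offset += len(mol_seq) + rec.tsd_length


def test_seeded_burst_is_reproducible(young_pair_family):
    a, _ = simulate_burst(young_pair_family, 10, switch_rate=1.0,
                          r_transfer_recomb_prob=0.5, rt_error_rate=1e-4, seed=12)
    b, _ = simulate_burst(young_pair_family, 10, switch_rate=1.0,
                          r_transfer_recomb_prob=0.5, rt_error_rate=1e-4, seed=12)
    assert [m.seq for m in a] == [m.seq for m in b]
    assert [m.parent_pair for m in a] == [m.parent_pair for m in b]
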