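"""Shared fixtures: one paper-like family (with its junction library) and
one fully simulated burst with mapped evidence, both session-scoped since
they are deterministic and moderately expensive."""

from __future__ import annotations

import pytest

from retroburst.burst import integrate, simulate_burst
from retroburst.family import FamilyConfig, make_family, paper_like_config
from retroburst.junctions import build_consensus, enumerate_fragments
from retroburst.mapper import GenomeIndex, map_pairs, mask_intervals
from retroburst.reads import sequence_reads
from retroburst import insertions as ins


@pytest.fixture(scope="session")
def paper_family():
    """Eight members, LTR identities {100,100,100,99,99,98,97,97}%, one
    near-identical young pair — the paper-like default family."""
    return make_family(paper_like_config(seed=1))


@pytest.fixture(scope="session")
def paper_pattern(paper_family):
    return build_consensus(paper_family.alignment)


@pytest.fixture(scope="session")
def paper_library(paper_family, paper_pattern):
    return enumerate_fragments(paper_pattern, paper_family.genome)


@pytest.fixture(scope="session")
def small_family():
    """A compact 4-member family for tests that need a full junction
    library but not the paper-scale one."""
    cfg = FamilyConfig(n_members=4, element_length=900, ltr_length=200,
                       u3_length=100, host_length=30_000,
                       target_ltr_identities=(1.0, 1.0, 0.99, 0.97),
                       expression_weights=(1.0,) * 4,
                       inter_member_divergence=0.005, seed=7)
    return make_family(cfg)


@pytest.fixture(scope="session")
def divergent_family():
    """Eight members at 1% divergence: enough informative sites that
    parental segments are usually member-identifiable."""
    cfg = FamilyConfig(n_members=8, inter_member_divergence=0.01,
                       target_ltr_identities=(1.0, 1.0, 1.0, 0.99, 0.99,
                                              0.98, 0.97, 0.97),
                       expression_weights=(1.0,) * 8, seed=11)
    return make_family(cfg)


@pytest.fixture(scope="session")
def burst_setup(divergent_family):
    """A complete simulated burst: ecDNA with LTR-junction recombination,
    20 chromosomal insertions with 5 bp TSDs, 30x error-free paired reads
    of progeny and of the unmutated reference, plus mapped evidence."""
    fam = divergent_family
    molecules, truth = simulate_burst(fam, 30, switch_rate=0.0,
                                      r_transfer_recomb_prob=0.9,
                                      rt_error_rate=0.0, seed=21)
    progeny, planted = integrate(molecules, fam.genome, 20, tsd_length=5,
                                 seed=22, element_intervals=fam.element_intervals,
                                 truth=truth)
    progeny_pairs = sequence_reads({"progeny": progeny}, 30.0,
                                   per_base_error=0.0, seed=23)
    control_pairs = sequence_reads({"chr1": fam.genome}, 30.0,
                                   per_base_error=0.0, seed=24)
    # deep ecDNA sequencing with fragments sized so that the partner of a
    # blunt 5'-terminal mate often falls wholly inside the R/U5 segment,
    # where discriminatory evidence for recombinant LTRs lives
    ecdna_pairs = sequence_reads({m.id: m.seq for m in molecules}, 300.0,
                                 fragment_mean=310.0, fragment_sd=40.0,
                                 per_base_error=0.0, seed=25)

    masked = mask_intervals(fam.genome,
                            [(s, e) for s, e, _ in fam.element_intervals])
    index = GenomeIndex(masked)
    ltr_seqs = [m.ltr5 for m in fam.members] + [m.ltr3 for m in fam.members]
    start_motif = fam.shared_element_prefix(30)
    end_motif = fam.shared_element_suffix(30)

    def evidence(pairs):
        mapped = map_pairs(pairs, index)
        anchors = ins.find_discordant_pairs(mapped, ltr_seqs)
        unmapped = [(p.name + suffix, r)
                    for p, p1, p2 in mapped
                    for suffix, r, placed in (("/1", p.r1, p1), ("/2", p.r2, p2))
                    if placed is None]
        junction_reads = ins.find_junction_reads(unmapped, start_motif,
                                                 end_motif, index)
        return anchors, junction_reads

    anchors, junction_reads = evidence(progeny_pairs)
    control_anchors, control_junctions = evidence(control_pairs)
    return {
        "family": fam, "molecules": molecules, "truth": truth,
        "progeny": progeny, "planted": planted,
        "progeny_pairs": progeny_pairs, "control_pairs": control_pairs,
        "ecdna_pairs": ecdna_pairs, "index": index,
        "anchors": anchors, "junction_reads": junction_reads,
        "control_anchors": control_anchors,
        "control_junctions": control_junctions,
    }
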