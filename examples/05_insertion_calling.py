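"""Call new insertions, reconstruct their LTRs and score parental origin.

Progeny reads are mapped to the element-masked reference; discordant
pairs and junction reads are clustered, intersected and control-
subtracted into insertion calls (the 5'/3' junction offsets differ by the
target-site duplication). Element-side mates are re-assembled into the
inserted LTR, painted with the compatible parental members along the
sequence, and each insertion distributes 12 contribution points evenly
over its parents.
"""

from retroburst.burst import integrate, simulate_burst
from retroburst.family import FamilyConfig, make_family
from retroburst.insertions import (call_insertions, contribution_scores,
                                   find_discordant_pairs, find_junction_reads,
                                   ltr_variants, paint_parentage,
                                   reconstruct_ltr)
from retroburst.mapper import GenomeIndex, map_pairs, mask_intervals
from retroburst.reads import sequence_reads

config = FamilyConfig(n_members=8, inter_member_divergence=0.01,
                      target_ltr_identities=(1.0, 1.0, 1.0, 0.99, 0.99,
                                             0.98, 0.97, 0.97),
                      expression_weights=(1.0,) * 8, seed=11)
family = make_family(config)
molecules, truth = simulate_burst(family, 30, r_transfer_recomb_prob=0.9, seed=21)
progeny, planted = integrate(molecules, family.genome, 12, tsd_length=5,
                             seed=22, element_intervals=family.element_intervals,
                             truth=truth)

masked = mask_intervals(family.genome,
                        [(s, e) for s, e, _ in family.element_intervals])
index = GenomeIndex(masked)
ltrs = [m.ltr5 for m in family.members] + [m.ltr3 for m in family.members]
start, end = family.shared_element_prefix(30), family.shared_element_suffix(30)


def evidence(pairs):
    mapped = map_pairs(pairs, index)
    anchors = find_discordant_pairs(mapped, ltrs)
    unmapped = [(p.name + sfx, r) for p, p1, p2 in mapped
                for sfx, r, pl in (("/1", p.r1, p1), ("/2", p.r2, p2))
                if pl is None]
    return anchors, find_junction_reads(unmapped, start, end, index)


anchors, junctions = evidence(sequence_reads({"progeny": progeny}, 30.0,
                                             per_base_error=0.0, seed=23))
c_anchors, c_junctions = evidence(sequence_reads({"chr1": family.genome}, 30.0,
                                                 per_base_error=0.0, seed=24))
calls = call_insertions(anchors, junctions, c_anchors, c_junctions,
                        genome=family.genome)
print(f"{len(calls)} calls for {len(planted)} planted insertions "
      f"(TSD length {calls[0].tsd_length} bp at every call)")

painted = []
for i, call in enumerate(calls):
    rec = reconstruct_ltr(call, anchors, junctions, family)
    if rec.complete:
        painted.append(paint_parentage(rec.ltr_sequence, ltr_variants(family),
                                       f"ins{i + 1}"))
scores = contribution_scores(painted)
print(f"\nreconstructed and painted {len(painted)} LTRs; "
      f"contribution totals (12 points per insertion, split per parent):")
print(scores.totals.to_string())
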