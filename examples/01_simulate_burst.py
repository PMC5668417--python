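"""Simulate a transposition burst and inspect its ground truth.

Builds the paper-like eight-member family (three young members with
identical LTRs, five old ones at 97-99% LTR identity), co-packages
transcripts pairwise, and reverse-transcribes them into linear ecDNA with
template switching. The printed fractions show how often the first strand
transfer produced a recombinant LTR.
"""

from retroburst.burst import integrate, simulate_burst
from retroburst.family import make_family, paper_like_config

family = make_family(paper_like_config(seed=1))
print("members (id, 5'/3' LTR identity):")
for m in family.members:
    print(f"  {m.id}: {m.ltr_identity():.2%}")

molecules, truth = simulate_burst(family, n_molecules=50, switch_rate=0.2,
                                  r_transfer_recomb_prob=0.8,
                                  rt_error_rate=6.25e-5, seed=2)
n_recomb = sum(m.is_recombinant for m in molecules)
n_rt = sum(len(m.rt_errors) for m in molecules)
print(f"\n{len(molecules)} ecDNA molecules, {n_recomb} recombinant "
      f"({n_recomb / len(molecules):.0%}), {n_rt} RT errors in "
      f"{sum(len(m.seq) for m in molecules) / 1000:.0f} kb")
print("first recombinant molecule:",
      next(m for m in molecules if m.is_recombinant).parent_pair,
      "switches at", next(m for m in molecules if m.is_recombinant).switch_positions)

progeny, insertions = integrate(molecules, family.genome, n_insertions=10,
                                tsd_length=5, seed=3,
                                element_intervals=family.element_intervals,
                                truth=truth)
print(f"\nprogeny genome: {len(progeny):,} bp "
      f"(+{len(progeny) - len(family.genome):,} bp from 10 insertions, "
      f"each flanked by a 5 bp target-site duplication)")
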