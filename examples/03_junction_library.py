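"""Build the exhaustive recombination-junction library and search reads.

Every 145 bp window over the family consensus is expanded into all
combinations of the observed polymorphisms; after removing duplicates and
every sequence present in the genome (which contains each parent), what
remains are exactly the windows that witness an inter-member mosaic. Reads
from pure parents therefore never match; reads across real template-switch
junctions do.
"""

from retroburst.burst import simulate_burst, single_parent_ecdna
from retroburst.family import FamilyConfig, make_family
from retroburst.junctions import (build_consensus, enumerate_fragments,
                                  search_junctions)
from retroburst.reads import all_read_sequences, sequence_reads

config = FamilyConfig(n_members=4, element_length=900, ltr_length=200,
                      u3_length=100, host_length=30_000,
                      target_ltr_identities=(1.0, 1.0, 0.99, 0.97),
                      expression_weights=(1.0,) * 4,
                      inter_member_divergence=0.005, seed=7)
family = make_family(config)
pattern = build_consensus(family.alignment)
library = enumerate_fragments(pattern, family.genome,
                              extra_purge_sequences=[single_parent_ecdna(m)
                                                     for m in family.members])
print(f"{len(pattern.wildcards)} polymorphic columns -> "
      f"{len(library):,} unique 145 bp junction fragments "
      f"({library.purged_genome:,} candidates purged against the genome)")

parental = all_read_sequences(sequence_reads(
    {m.id: m.seq for m in family.members}, 20.0, per_base_error=0.0, seed=1))
print("parental reads:",
      search_junctions(parental, library, len(parental)).rate_per_1000,
      "matches per 1000 (specificity: exactly zero)")

molecules, _ = simulate_burst(family, 25, switch_rate=1.0,
                              r_transfer_recomb_prob=0.8, seed=2)
burst = all_read_sequences(sequence_reads(
    {m.id: m.seq for m in molecules}, 15.0, per_base_error=0.0, seed=3))
result = search_junctions(burst, library, len(burst))
print(f"burst ecDNA reads: {result.n_matching_reads} of {len(burst)} match "
      f"-> {result.rate_per_1000:.1f} per 1000 element-mapping reads")
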