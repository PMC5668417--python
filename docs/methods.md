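# Methods

## The process being modelled

LTR retrotransposons replicate through an RNA intermediate: transcription
starts in the 5' LTR, two transcripts are co-packaged into a virus-like
particle, and reverse transcription — with its two strand transfers —
produces a linear, blunt-ended extrachromosomal DNA (ecDNA) flanked by two
*identical* LTRs, which an integrase then inserts into the host genome
behind a short target-site duplication (TSD). Because the particle holds
two templates, reverse transcriptase can recombine them: the first strand
transfer may land on the co-packaged partner (using the R-region homology
shared by all LTRs), and copy-choice switches can occur along the internal
coding region. A transposition burst in a family containing both young
members (identical LTRs) and old ones (5'/3' LTR identity eroded by age)
therefore produces mosaic progeny, which is what this package detects.

## Synthetic family and burst

`make_family` derives all members from one ancestral element
(`5'LTR + CDS + 3'LTR`; the LTR splits into U3 and R/U5). Members receive
substitutions at `inter_member_divergence` per mutable base; substitutions
falling in the LTR are mirrored into both copies (they predate the
member's last transposition). Ageing then mutates exactly
`round((1−identity)·ltr_length)` positions in one LTR copy each, so the
realised 5'/3' identity is exact to rounding. The first and last 30 bp of
every element are held invariant, modelling the terminal motifs an
integrase requires; this is also what guarantees the family-shared LTR
start sequence used for blunt-end detection. The host genome is random
sequence with one embedded copy of each member.

Defaults (chosen once as this package's study conditions): 8 members,
element 2500 bp, LTR 300 bp (U3 150), divergence 0.002 substitutions/bp,
5'/3' identities {100, 100, 100, 99, 99, 98, 97, 97}%, one near-identical
young sibling pair (1 distinguishing substitution), host 120 kb,
expression weights dominated by the young members with one silent old
member. At these settings each member carries enough private sites for
three independent 70 bp addresses while the junction library's
combinatorial expansion stays near the million-fragment scale of a real
eight-member family; the polymorphism density is deliberately below that
of real families, whose LTR regions are far more diverged.

`simulate_burst` draws the two co-packaged templates independently from
the expression weights. With probability `r_transfer_recomb_prob` the
first strand transfer jumps to the partner, reconstituting an LTR whose
U3 comes from the partner's 3' LTR and whose R/U5 comes from the
initiator's 5' LTR; the junction is placed at the U3|R boundary, the
determinate point of the R-homology-mediated transfer. Internal switches
are a Poisson process (`switch_rate` per kb of CDS) toggling between the
two templates right to left. Both LTRs of a molecule are identical copies
of the reconstituted LTR. RT errors are uniform substitutions over the
finished molecule (default 6.25e-5/bp, i.e. ~10 per 160 kb). Truth
records per molecule: the ordered parent pair, switch columns, RT errors,
and a donor-segment tiling. A molecule drawn twice from the same member
records no switches — recombination between identical templates is
invisible and is not counted.

`integrate` samples insertion sites uniformly outside existing element
copies (minimum spacing 2 kb, so calls are unambiguous at default cluster
width), duplicating `tsd_length` host bases (default 5 bp, typical for
Copia-type integrases) around each insertion; strand is random.
`sequence_reads` draws fragments uniformly from linear templates
(normal length, default 350±40 bp, clipped to the template), samples both
strands, and applies independent per-base substitutions (default 1/1060,
one imperfect 150 bp read in ~7). Linearity means ecDNA termini appear as
read starts flush with the LTR extremities. All randomness flows from one
seeded NumPy generator per call; identical seeds give byte-identical
FASTQ/BED output.

## Member assignment

Addresses are 70 bp windows occurring — on either strand — in exactly one
member; candidates shared by several members are discarded, never
assigned by priority. Three addresses per member are taken greedily from
regions separated by at least one address length ("independent regions").
A member lacking three such regions is grouped with its nearest relatives
until windows unique to the group (present in all and only its members)
supply three regions; one member-unique window per sibling serves as the
distinguishing address. Counting is read-level perfect matching on both
strands (DNA sequencing is unstranded); the member count is the
arithmetic mean over its addresses, normalised as `raw × 1e6 /
library_size` with the mapped-read count as library size. Pooled group
counts are apportioned by the ratio at the distinguishing addresses; zero
coverage there leaves the pool split evenly and flagged. ecDNA abundance
is the heat-minus-control difference of normalised counts. Absolute
counts depend on which addresses the derivation picks; this is inherent
to the address approach.

## Junction library

`build_consensus` collapses the (user-supplied or simulator-trivial)
alignment into a consensus with a wildcard at every column where any
member differs, including gaps; variant lists are sorted
lexicographically. The package does not compute multiple alignments —
library content depends on the alignment, so it is an explicit input.
`enumerate_fragments` slides a window (default 145 bp, sized to sit
inside a 150 bp read) by one column at a time and expands the
cross-product of variants; in the ungapped case the per-window raw count
is exactly the product of variant-list sizes. Combinations containing a
gap realise short and are extended into subsequent columns until exactly
`window_length` real bases are emitted, keeping every fragment
read-length compatible. A per-window budget (default 1e6) guards against
combinatorial explosion with a descriptive error. The candidate set is
deduplicated and purged of every window of the genome, on both strands by
default (reads are unstranded); because the genome contains every parent,
all single-parent windows disappear and the survivors witness
inter-member mosaics only. `extra_purge_sequences` optionally removes the
members' single-parent ecDNA forms as well: an aged member's reconstituted
LTR is a genuine intra-element 5'/3' mosaic absent from the chromosome,
and without this purge it registers as recombination — which is arguably
correct but not inter-member. Matching uses hashed fixed-length window
sets (fragments plus reverse complements), giving exact substring
semantics with O(1) membership per read window; a read counts once
regardless of how many fragments it contains, and rates are per 1000
element-mapping reads.

## Error models

`P_error` is estimated as the non-perfect-matching fraction of
element-mapping reads. The closed form multiplies `n · ℓ · P_error ·
P_position · P_base` with no internal rounding (two decimals at report
time). The published parameter set (n=1000, ℓ=2, 0.1415, 0.0066, 0.3333)
gives 0.6225 → 0.62. For a synthetic family the package computes the
matched ℓ exactly (`effective_ell`): the mean number of
(position, alternative-base) single-swap opportunities per read of the
universe that convert it into a library-matching read, unioned over every
context in which the read occurs. Since exactly one of the
`read_length × 3` swap outcomes happens per mutated read, the permutation
mean equals `n · P_error · ℓ_eff/(read_length·3)` in expectation, which is
the formula with `P_position = 1/read_length`, `P_base = 1/3`.

The permutation null draws `n_draws` reads with replacement from the
deduplicated forward-strand read universe of the members, mutates each
with probability `P_error` — a single uniformly placed swap to a uniformly
chosen alternative base, matching the one-swap reading of the per-read
error probability; a multi-swap Poisson mode exists behind a flag for
sensitivity analysis — and searches only mutated reads against the
library. Rates are per 1000 *drawn* reads, the same denominator as the
observed statistic. Mean and max over permutations (default 500) are
reported, and `compare_observed_to_null` emits the observed/mean ratio
and a flag for exceeding the null max.

## Blunt-end ecDNA pairs

A mate qualifies when it (or its reverse complement) begins at position 0
with the family-shared LTR start (default 20 bp, validated against all
members); chromosomal copies carry upstream flank and fail the
position-0 requirement. A fragment coincidentally starting exactly at a
chromosomal element boundary, or at the internal 3' LTR start of an ecDNA
molecule, is indistinguishable from a blunt terminus — an intrinsic
limitation of the motif approach shared with any position-anchored
detector; tests verify that every candidate traces to a motif-flush
fragment end. Retained pairs must match the reference set perfectly on
both mates. The reference set contains, per member, the chromosomal
element *and* its single-parent ecDNA form, because an old member's
reconstituted LTR is absent from its element and such genuine
single-parent reads must not be discarded. Each mate's compatible member
set is computed by exact containment (either strand); disjoint sets make
the pair discriminatory — evidence of a recombinant LTR — and
intersecting sets non-discriminatory. Where a mate covers a
5'-versus-3'-LTR distinguishing polymorphism of an old member, the LTR
end is annotated. Discriminatory and non-discriminatory counts partition
the retained pairs exactly.

## Insertion mapping

Reads are mapped to the element-masked reference. The built-in mapper is
a k-mer exact-seed index accepting only unique full-length exact matches
— sufficient for error-free synthetic genomes up to a few megabases;
external SAM alignments can be substituted through `pairs_from_sam`.
Discordant pairs (one mate uniquely placed, the other unmapped but
sharing an exact 31-mer with an LTR) anchor insertions; unmapped reads
containing the family-shared element start or end motif are trimmed and
their genomic residue (≥31 bp) remapped to give junction coordinates —
the left (flank|element) and right (element|flank) coordinates differ by
exactly the TSD length. Calls require, within a 500 bp cluster, at least
one junction read per side and two discordant pairs, and are removed when
control evidence (or a known element copy) lies within the cluster width;
these explicit thresholds replace the manual assessment a human analyst
would perform. Coordinates are reported 0-based half-open, the interval
being the duplicated target site.

LTR reconstruction collects the element-side mates anchored near a call
and the element parts of its junction reads, orients them by forward
k-mer sharing with the family, and merges them by greedy
maximal-exact-overlap extension (minimum overlap 30 bp) — adequate for
error-free mates from a ≤2.5 kb element, not a general-purpose assembler.
Because the two LTRs of an integrated molecule are identical, mates from
both edges sample the same LTR, whose sequence is read off the contig at
the element start motif. Mosaic placement of internal-end pieces relative
to the repeat is ambiguous by nature; only the LTR itself is promised.

Painting compares a sequence position-by-position with per-member
variant sets (5' and 3' LTRs for LTR painting; single-parent ecDNA forms
for whole molecules). The compatible member set is recorded at every
informative position, maximal runs of constant set tile the sequence, and
positions compatible with no member are excluded as novel polymorphisms
(the RT-error report). A minimal-switch parent path is computed exactly —
fewest parent changes, then fewest distinct parents, then lexicographic —
by dynamic programming with a pruned search for tie-breaking (node budget
2e6, never reached at these problem sizes; verified against exhaustive
enumeration on small instances). The full ambiguity sets are always
reported alongside: when a segment carries no donor-identifying site the
minimal solution legitimately collapses to fewer parents, and no method
could do otherwise. Contribution scoring assigns each insertion 12 points
split evenly over the distinct parents of its minimal solution.

## Pipeline

`run_pipeline` executes simulate → reads → assign → junctions → error
model → ecDNA pairs → insertions on one configuration object (unknown
keys rejected), writes FASTA/FASTQ/BED/TSV outputs, and records every
parameter plus a SHA-256 checksum of every output file in
`manifest.json`; a fixed seed reproduces the manifest exactly. The thin
`retroburst` CLI wraps this and the closed-form error model.

## Problem sizes and what the tests show

The test suite runs the full stack at reduced scale: 20–30 ecDNA
molecules, 20 insertions at 30× error-free coverage on a ~140 kb
reference, junction libraries from 0.2–1.3 million fragments,
permutation nulls at 500 permutations × 2000 draws, and 160 kb of ecDNA
for the RT-error rate. Burst-recovery checks use an equal-weight family
at 1% divergence so that parental segments usually carry
donor-identifying sites — the regime in which pair recovery is
information-theoretically possible; the blunt-pair analysis uses deep
(300×) ecDNA reads with 310±40 bp fragments so the partner of a
5'-terminal mate regularly falls wholly inside the R/U5 segment, the
geometry that yields discriminatory pairs.

The simulator emulates substitution-level divergence, pairwise
co-packaging, one strand-transfer junction at the U3|R boundary, uniform
internal switches, exact TSDs and uniform substitution sequencing error.
It does not model indel divergence between members (though gapped input
alignments are fully supported in the junction library), quality-score
structure, PCR duplicates (the assay of interest is PCR-free), circular
ecDNA intermediates, three-template co-packaging (observed once in real
data, possibly via extrachromosomal recombination — a documented
limitation), or chromatin/siRNA regulation. Passing tests therefore show
the algorithms are correct under these idealisations, not that real
libraries are free of artefacts the simulator does not generate.
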