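"""Transposition-burst simulation: ecDNA synthesis and chromosomal integration.

Each extrachromosomal DNA (ecDNA) molecule is the reverse-transcription
product of two co-packaged transcripts drawn independently from the
family's expression weights (the retroviral "pseudodiploid" rule). Two
recombination routes are modelled:

* the first (minus-strand) transfer may land on the co-packaged partner,
  which reconstitutes an LTR whose U3 comes from the partner's 3' LTR and
  whose R/U5 comes from the initiating template's 5' LTR — the junction
  sits at the U3|R boundary, where the R-region homology mediates the jump;
* internal copy-choice switches along the coding region, placed as a
  Poisson process per kb of internal sequence.

Both LTRs of a molecule are identical copies of the reconstituted LTR, and
reverse-transcription substitution errors are sprinkled uniformly over the
finished molecule. All coordinates are alignment columns, which for
families built by :func:`retroburst.family.make_family` coincide with
element positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .family import BASES, FamilyModel, Member
from .seqio import BedInterval, revcomp


@dataclass(frozen=True)
class EcdnaMolecule:
    id: str
    seq: str
    parent_pair: tuple[str, str]            # (initiating template, co-packaged partner)
    switch_positions: tuple[int, ...]       # alignment columns; empty for single-parent
    rt_errors: tuple[tuple[int, str], ...]  # (position in molecule, new base)
    segments: tuple[tuple[int, int, str], ...]  # (start, end, donor member) tiling the molecule

    @property
    def is_recombinant(self) -> bool:
        return len(self.switch_positions) > 0

    @property
    def contributing_parents(self) -> tuple[str, ...]:
        seen = []
        for _, _, p in self.segments:
            if p not in seen:
                seen.append(p)
        return tuple(sorted(seen))


@dataclass(frozen=True)
class InsertionTruth:
    chrom: str
    start: int        # 0-based; [start, start+tsd) is the duplicated target site
    end: int
    strand: str
    tsd_length: int
    ecdna_id: str


@dataclass
class BurstTruth:
    """Machine-readable ground truth for one simulated burst."""
    molecules: list[EcdnaMolecule] = field(default_factory=list)
    insertions: list[InsertionTruth] = field(default_factory=list)

    def molecule(self, ecdna_id: str) -> EcdnaMolecule:
        for m in self.molecules:
            if m.id == ecdna_id:
                return m
        raise KeyError(ecdna_id)

    def insertions_as_bed(self) -> list[BedInterval]:
        return [
            BedInterval(t.chrom, t.start, max(t.end, t.start + 1),
                        name=t.ecdna_id, score=t.tsd_length, strand=t.strand)
            for t in self.insertions
        ]


def reconstituted_ltr(u3_donor: Member, initiator: Member) -> str:
    """The ecDNA LTR: U3 from the donor's 3' LTR + R/U5 from the initiator's 5' LTR."""
    u3 = u3_donor.u3_length
    return u3_donor.ltr3[:u3] + initiator.ltr5[u3:]


def single_parent_ecdna(member: Member) -> str:
    """The ecDNA sequence produced when both co-packaged transcripts come from
    ``member``: both LTRs are the member's own reconstituted LTR. For young
    members (identical LTRs) this equals the chromosomal element."""
    ltr = reconstituted_ltr(member, member)
    return ltr + member.internal + ltr


def simulate_burst(family: FamilyModel, n_molecules: int,
                   switch_rate: float = 0.0,
                   r_transfer_recomb_prob: float = 0.0,
                   rt_error_rate: float = 0.0,
                   seed: int = 0,
                   expression_weights=None) -> tuple[list[EcdnaMolecule], BurstTruth]:
    """Simulate ``n_molecules`` ecDNA molecules.

    ``switch_rate`` is internal copy-choice switches per kb of internal
    sequence; ``r_transfer_recomb_prob`` is the probability that the first
    strand transfer lands on the co-packaged partner; ``rt_error_rate`` is
    reverse-transcription substitutions per bp of finished molecule.
    """
    if switch_rate < 0 or r_transfer_recomb_prob < 0 or rt_error_rate < 0:
        raise ValueError("rates must be nonnegative")
    weights = np.asarray(expression_weights if expression_weights is not None
                         else family.expression_weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("expression weights must sum to > 0")
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)

    cfg = family.config
    L, ltr, u3 = cfg.element_length, cfg.ltr_length, cfg.u3_length
    internal_lo, internal_hi = ltr, L - ltr
    internal_len = internal_hi - internal_lo

    molecules: list[EcdnaMolecule] = []
    for i in range(n_molecules):
        a_idx, b_idx = rng.choice(len(probs), size=2, p=probs)
        a, b = family.members[a_idx], family.members[b_idx]

        jumped = bool(rng.random() < r_transfer_recomb_prob)
        u3_donor = b if jumped else a

        # Internal mosaic: synthesis proceeds from the 3' end of the internal
        # region leftwards on whichever template the first transfer selected,
        # toggling between the two co-packaged templates at each switch.
        n_switch = min(rng.poisson(switch_rate * internal_len / 1000.0), internal_len)
        switch_cols = sorted(int(internal_lo + c) for c in
                             rng.choice(internal_len, size=n_switch, replace=False))
        # Traverse right-to-left; a switch at column c means the template
        # changes for all columns < c.
        boundaries = sorted(switch_cols, reverse=True)
        segments_internal: list[tuple[int, int, Member]] = []
        current = u3_donor
        hi = internal_hi
        for c in boundaries:
            segments_internal.append((c, hi, current))
            current = a if current is b else b
            hi = c
        segments_internal.append((internal_lo, hi, current))
        segments_internal.reverse()

        internal_seq = "".join(m.seq[lo:hi] for lo, hi, m in segments_internal)
        ltr_seq = reconstituted_ltr(u3_donor, a)
        seq = ltr_seq + internal_seq + ltr_seq

        if a is b:
            recorded_switches: list[int] = []
        else:
            recorded_switches = [u3] if jumped else []
            recorded_switches += switch_cols

        # Truth segments over molecule coordinates (5'LTR, internal, 3'LTR).
        segs: list[tuple[int, int, str]] = [(0, u3, u3_donor.id), (u3, ltr, a.id)]
        segs += [(lo, hi, m.id) for lo, hi, m in segments_internal]
        segs += [(L - ltr, L - ltr + u3, u3_donor.id), (L - ltr + u3, L, a.id)]
        merged: list[tuple[int, int, str]] = []
        for lo, hi2, p in segs:
            if merged and merged[-1][2] == p and merged[-1][1] == lo:
                merged[-1] = (merged[-1][0], hi2, p)
            else:
                merged.append((lo, hi2, p))

        n_err = rng.poisson(rt_error_rate * len(seq))
        rt_errors: list[tuple[int, str]] = []
        if n_err > 0:
            seq_list = list(seq)
            for pos in rng.choice(len(seq), size=min(n_err, len(seq)), replace=False):
                old = seq_list[pos]
                new = [x for x in BASES if x != old][rng.integers(3)]
                seq_list[pos] = new
                rt_errors.append((int(pos), new))
            seq = "".join(seq_list)
            rt_errors.sort()

        molecules.append(EcdnaMolecule(
            id=f"ec{i + 1}", seq=seq, parent_pair=(a.id, b.id),
            switch_positions=tuple(sorted(recorded_switches)),
            rt_errors=tuple(rt_errors),
            segments=tuple(merged)))

    return molecules, BurstTruth(molecules=molecules)


def integrate(molecules, genome: str, n_insertions: int, tsd_length: int = 5,
              seed: int = 0, element_intervals=(), truth: BurstTruth | None = None,
              min_spacing: int = 2000, edge_margin: int = 1000,
              chrom: str = "chr1") -> tuple[str, list[InsertionTruth]]:
    """Integrate ``n_insertions`` molecules (sampled with replacement) into
    ``genome`` at sites outside existing element copies, each flanked by an
    exact ``tsd_length`` bp target-site duplication.

    Returns the progeny genome and the truth records (reference
    coordinates; ``[start, start+tsd)`` is the duplicated target site).
    Progeny length = input length + sum(molecule length + tsd_length).
    """
    if n_insertions == 0:
        return genome, []
    if not molecules:
        raise ValueError("no ecDNA molecules to integrate")
    rng = np.random.default_rng(seed)

    forbidden = [(max(0, s - edge_margin), e + edge_margin) for s, e, _ in element_intervals]
    candidates = []
    lo = edge_margin
    hi = len(genome) - edge_margin
    if hi <= lo:
        raise ValueError("genome too short for requested insertions")

    sites: list[int] = []
    attempts = 0
    while len(sites) < n_insertions:
        attempts += 1
        if attempts > 200 * n_insertions:
            raise ValueError("genome too short for requested insertions")
        p = int(rng.integers(lo, hi))
        if any(s <= p < e for s, e in forbidden):
            continue
        if any(abs(p - q) < min_spacing for q in sites):
            continue
        sites.append(p)
    del candidates

    records: list[InsertionTruth] = []
    for p in sites:
        mol = molecules[int(rng.integers(len(molecules)))]
        strand = "+" if rng.integers(2) == 0 else "-"
        records.append(InsertionTruth(chrom, p, p + tsd_length, strand, tsd_length, mol.id))

    progeny = genome
    by_id = {m.id: m for m in molecules}
    for rec in sorted(records, key=lambda r: -r.start):
        mol_seq = by_id[rec.ecdna_id].seq
        if rec.strand == "-":
            mol_seq = revcomp(mol_seq)
        p = rec.start
        progeny = progeny[: p + rec.tsd_length] + mol_seq + progeny[p:]

    records.sort(key=lambda r: r.start)
    if truth is not None:
        truth.insertions = records
    return progeny, records
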