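"""Linear ecDNA detection from blunt-end read pairs and parental typing.

Reverse transcription yields a linear, blunt-ended molecule whose termini
are the LTR extremities, so a read starting exactly at the family-shared
LTR start sequence — with no upstream bases — is diagnostic of ecDNA
rather than of a chromosomal copy embedded in flanking DNA. Retained
pairs must match known family sequences perfectly; each mate is then
assigned the set of members containing it verbatim, and a pair whose two
mate sets are disjoint ("discriminatory") evidences a recombinant LTR
built from two different members.

Perfect matching is performed against both the chromosomal element of
each member and its single-parent ecDNA form: an aged member's ecDNA
carries a reconstituted LTR (its own 3' U3 joined to its own 5' R/U5)
that is genuinely absent from the chromosome, and matching against the
element alone would wrongly discard such reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .burst import single_parent_ecdna
from .family import FamilyModel
from .reads import ReadPair
from .seqio import revcomp


@dataclass(frozen=True)
class BluntCandidate:
    pair_id: str
    mate5: str       # canonical orientation: starts with the LTR start motif
    mate3: str       # partner mate, canonical orientation (element-forward)


@dataclass(frozen=True)
class BluntPair:
    pair_id: str
    mate5: str
    mate3: str
    members5: frozenset[str]
    members3: frozenset[str]
    classification: str  # "discriminatory" | "non-discriminatory"
    ltr_end5: dict | None = None   # member -> "5p"/"3p"/None where determinable
    ltr_end3: dict | None = None

    @property
    def is_discriminatory(self) -> bool:
        return self.classification == "discriminatory"


def shared_ltr_start(family: FamilyModel, length: int = 20) -> str:
    """The family-shared 5' LTR start sequence (configuration-time check)."""
    return family.shared_element_prefix(length)


def find_blunt_ltr_reads(pairs: Iterable[ReadPair],
                         ltr_start_sequence: str) -> list[BluntCandidate]:
    """Select pairs with one mate beginning exactly at the LTR start.

    A mate qualifies iff it (or its reverse complement) begins at position
    0 with the motif; reads carrying upstream bases before the motif do
    not begin with it and are thereby excluded, which separates blunt
    ecDNA termini from chromosomal copies.
    """
    motif = ltr_start_sequence.upper()
    if not motif:
        raise ValueError("empty LTR start sequence")
    out: list[BluntCandidate] = []
    for pair in pairs:
        for blunt, partner in ((pair.r1, pair.r2), (pair.r2, pair.r1)):
            canon = None
            if blunt.startswith(motif):
                canon = blunt
            else:
                rc = revcomp(blunt)
                if rc.startswith(motif):
                    canon = rc
            if canon is not None:
                # Partner of a 5'-terminal mate reads back toward it on the
                # opposite strand; re-orient element-forward.
                out.append(BluntCandidate(pair.name, canon, revcomp(partner)))
                break
    return out


def reference_sequences(family: FamilyModel) -> dict[str, tuple[str, str]]:
    """Per member: (chromosomal element, single-parent ecDNA form)."""
    return {m.id: (m.seq, single_parent_ecdna(m)) for m in family.members}


def _compatible_members(mate: str, refs: Mapping[str, tuple[str, str]]) -> frozenset[str]:
    rc = revcomp(mate)
    hits = set()
    for mid, seqs in refs.items():
        for s in seqs:
            if mate in s or rc in s:
                hits.add(mid)
                break
    return frozenset(hits)


def _ltr_end_attribution(mate: str, family: FamilyModel,
                         members: frozenset[str]) -> dict[str, str | None]:
    """For matched old members, report whether the mate is specific to the
    5' or the 3' LTR of the chromosomal element (None when both or when it
    covers no distinguishing polymorphism)."""
    out: dict[str, str | None] = {}
    rc = revcomp(mate)
    for mid in members:
        m = family.member(mid)
        occs = []
        for probe in (mate, rc):
            start = 0
            while True:
                i = m.seq.find(probe, start)
                if i < 0:
                    break
                occs.append((i, i + len(probe)))
                start = i + 1
        if not occs:
            out[mid] = None
            continue
        ltr, L = m.ltr_length, m.length
        in5 = all(e <= ltr for s, e in occs)
        in3 = all(s >= L - ltr for s, e in occs)
        out[mid] = "5p" if (in5 and not in3) else "3p" if (in3 and not in5) else None
    return out


def assign_pair_parents(candidate: BluntCandidate,
                        refs: Mapping[str, tuple[str, str]],
                        family: FamilyModel | None = None) -> BluntPair | None:
    """Assign per-mate compatible member sets and classify the pair.

    Returns None if either mate fails perfect matching. Discriminatory iff
    the two sets are disjoint (non-empty by the perfect filter).
    """
    s5 = _compatible_members(candidate.mate5, refs)
    s3 = _compatible_members(candidate.mate3, refs)
    if not s5 or not s3:
        return None
    cls = "discriminatory" if s5.isdisjoint(s3) else "non-discriminatory"
    end5 = end3 = None
    if family is not None:
        end5 = _ltr_end_attribution(candidate.mate5, family, s5)
        end3 = _ltr_end_attribution(candidate.mate3, family, s3)
    return BluntPair(candidate.pair_id, candidate.mate5, candidate.mate3,
                     s5, s3, cls, end5, end3)


def perfect_pair_filter(candidates: Iterable[BluntCandidate],
                        refs: Mapping[str, tuple[str, str]],
                        family: FamilyModel | None = None) -> list[BluntPair]:
    """Keep only pairs whose both mates perfectly match at least one
    reference sequence (either strand), with parental sets attached."""
    out = []
    for cand in candidates:
        bp = assign_pair_parents(cand, refs, family)
        if bp is not None:
            out.append(bp)
    return out


@dataclass(frozen=True)
class PairTabulation:
    table: pd.DataFrame          # members5, members3, classification, count
    n_discriminatory: int
    n_non_discriminatory: int

    @property
    def total(self) -> int:
        return self.n_discriminatory + self.n_non_discriminatory


def tabulate_pairs(blunt_pairs: Sequence[BluntPair]) -> PairTabulation:
    """Contingency counts per ordered (5' set, 3' set) signature."""
    counts: dict[tuple[tuple[str, ...], tuple[str, ...], str], int] = {}
    for bp in blunt_pairs:
        key = (tuple(sorted(bp.members5)), tuple(sorted(bp.members3)),
               bp.classification)
        counts[key] = counts.get(key, 0) + 1
    rows = [{"members5": "+".join(k[0]), "members3": "+".join(k[1]),
             "classification": k[2], "count": v}
            for k, v in sorted(counts.items())]
    table = pd.DataFrame(rows, columns=["members5", "members3",
                                        "classification", "count"])
    n_disc = sum(1 for bp in blunt_pairs if bp.is_discriminatory)
    return PairTabulation(table=table, n_discriminatory=n_disc,
                          n_non_discriminatory=len(blunt_pairs) - n_disc)
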