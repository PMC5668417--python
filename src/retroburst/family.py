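"""Synthetic LTR-retrotransposon family construction.

A family is derived from a single ancestral element of layout
``5'LTR + internal CDS + 3'LTR`` where the LTR is subdivided into U3 and
R/U5. Members diverge from the ancestor by substitutions; within each
member the two LTRs additionally diverge from one another to a configured
5'/3' identity, which encodes the member's age (young members have
identical LTRs, old members do not). The first and last few tens of bases
of every element are held invariant, mimicking the terminal sequences an
integrase requires, so a family-shared LTR start motif always exists.

Members are embedded once each into a random host chromosome with unique
flanks, giving the reference genome for the downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

BASES = "ACGT"


@dataclass(frozen=True)
class FamilyConfig:
    """Parameters of a synthetic retrotransposon family.

    ``target_ltr_identities`` is the per-member 5'-vs-3' LTR identity in
    [0, 1]; 1.0 marks a young member. ``inter_member_divergence`` is the
    substitution rate per bp separating each member from the common
    ancestor. ``near_identical_pairs`` lists member index pairs that are
    collapsed to near-identity (the second member is rebuilt as a copy of
    the first plus ``near_identical_distance`` private substitutions),
    reproducing the highly-homologous sibling pattern seen in real
    families.
    """

    n_members: int = 8
    element_length: int = 2500
    ltr_length: int = 300
    u3_length: int = 150
    target_ltr_identities: Sequence[float] = (1.0,) * 8
    inter_member_divergence: float = 0.002
    expression_weights: Sequence[float] = (1.0,) * 8
    near_identical_pairs: Sequence[tuple[int, int]] = ()
    near_identical_distance: int = 1
    host_length: int = 120_000
    gc_content: float = 0.36
    conserved_terminal_length: int = 30
    seed: int = 0

    @property
    def r_u5_length(self) -> int:
        return self.ltr_length - self.u3_length

    def validate(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not (0 < self.u3_length < self.ltr_length):
            raise ValueError("need 0 < u3_length < ltr_length")
        if 2 * self.ltr_length >= self.element_length:
            raise ValueError("need 2*ltr_length < element_length")
        if len(self.target_ltr_identities) != self.n_members:
            raise ValueError("one LTR identity target per member required")
        for t in self.target_ltr_identities:
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"impossible LTR identity target {t}")
        if len(self.expression_weights) != self.n_members:
            raise ValueError("one expression weight per member required")
        if any(w < 0 for w in self.expression_weights):
            raise ValueError("expression weights must be nonnegative")
        if sum(self.expression_weights) <= 0:
            raise ValueError("expression weights must sum to > 0")
        if not (0.0 <= self.inter_member_divergence < 1.0):
            raise ValueError("inter_member_divergence must be in [0, 1)")
        for a, b in self.near_identical_pairs:
            if not (0 <= a < self.n_members and 0 <= b < self.n_members and a != b):
                raise ValueError(f"bad near-identical pair ({a}, {b})")
            if self.target_ltr_identities[a] != self.target_ltr_identities[b]:
                raise ValueError("near-identical pair members need equal identity targets")
        if 2 * self.conserved_terminal_length >= self.ltr_length:
            raise ValueError("conserved terminal region must fit inside the LTR")


@dataclass(frozen=True)
class Member:
    id: str
    label: str
    seq: str          # full element: 5'LTR + internal + 3'LTR
    ltr_length: int
    u3_length: int

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def domains(self) -> dict[str, tuple[int, int]]:
        """Non-overlapping domain intervals tiling the element (0-based half-open)."""
        L, ltr, u3 = self.length, self.ltr_length, self.u3_length
        return {
            "5LTR_U3": (0, u3),
            "5LTR_RU5": (u3, ltr),
            "CDS": (ltr, L - ltr),
            "3LTR_U3": (L - ltr, L - ltr + u3),
            "3LTR_RU5": (L - ltr + u3, L),
        }

    @property
    def ltr5(self) -> str:
        return self.seq[: self.ltr_length]

    @property
    def ltr3(self) -> str:
        return self.seq[-self.ltr_length:]

    @property
    def internal(self) -> str:
        return self.seq[self.ltr_length: self.length - self.ltr_length]

    def ltr_identity(self) -> float:
        diffs = sum(a != b for a, b in zip(self.ltr5, self.ltr3))
        return 1.0 - diffs / self.ltr_length


@dataclass(frozen=True)
class FamilyModel:
    """A realised family: members, their (ungapped) alignment, and the host genome."""

    config: FamilyConfig
    members: tuple[Member, ...]
    genome: str
    element_intervals: tuple[tuple[int, int, str], ...]  # (start, end, member id) in genome

    @property
    def alignment(self) -> dict[str, str]:
        """Multiple alignment of full elements. Members share the ancestor's
        coordinate system with no indels, so the alignment is the sequences
        themselves and columns map one-to-one to element positions."""
        return {m.id: m.seq for m in self.members}

    @property
    def expression_weights(self) -> tuple[float, ...]:
        return tuple(self.config.expression_weights)

    def member(self, member_id: str) -> Member:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    def shared_element_prefix(self, length: int) -> str:
        """Family-shared element (5' LTR) start sequence, used for blunt-end
        ecDNA detection. Raises if the members do not share ``length`` bases."""
        prefix = self.members[0].seq[:length]
        for m in self.members[1:]:
            if m.seq[:length] != prefix:
                raise ValueError(
                    f"members do not share a {length} bp element start sequence")
        return prefix

    def shared_element_suffix(self, length: int) -> str:
        suffix = self.members[0].seq[-length:]
        for m in self.members[1:]:
            if m.seq[-length:] != suffix:
                raise ValueError(
                    f"members do not share a {length} bp element end sequence")
        return suffix


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def _substitute(rng: np.random.Generator, seq: list[str], positions: np.ndarray) -> None:
    for pos in positions:
        old = seq[pos]
        alternatives = [b for b in BASES if b != old]
        seq[pos] = alternatives[rng.integers(3)]


def make_family(config: FamilyConfig) -> FamilyModel:
    """Realise a synthetic family from ``config``.

    The realised 5'/3' LTR identity of each member is exact to rounding on
    the LTR length: divergence positions are drawn without replacement and
    each is mutated in exactly one of the two LTR copies, so the realised
    identity equals ``1 - round((1-target)*ltr_length)/ltr_length``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L, ltr, cons = config.element_length, config.ltr_length, config.conserved_terminal_length

    # Ancestral element: one LTR reused at both ends.
    anc_ltr = _random_seq(rng, ltr, config.gc_content)
    anc_internal = _random_seq(rng, L - 2 * ltr, config.gc_content)

    # Mutable positions exclude the integrase-required terminal motifs
    # (element start = first `cons` bp of the LTR, element end = last `cons` bp).
    # LTR substitutions mirror into the 3' copy, whose last `cons` bases are
    # the element end motif — so both LTR terminal regions stay invariant.
    mutable = np.concatenate([np.arange(cons, ltr - cons), np.arange(ltr, L - ltr)])
    ltr_mutable = np.arange(cons, ltr - cons)   # LTR positions free to age/diverge

    members: list[Member] = []
    for i in range(config.n_members):
        mid = f"M{i + 1}"
        template = list(anc_ltr + anc_internal)   # 5'LTR + internal; 3'LTR mirrored later

        n_sub = round(config.inter_member_divergence * len(mutable))
        if n_sub > 0:
            _substitute(rng, template, rng.choice(mutable, size=n_sub, replace=False))

        ltr_seq = template[:ltr]
        ltr5, ltr3 = list(ltr_seq), list(ltr_seq)
        target = config.target_ltr_identities[i]
        n_age = round((1.0 - target) * ltr)
        if n_age > len(ltr_mutable):
            raise ValueError(f"identity target {target} needs more divergence "
                             f"positions than the LTR interior provides")
        if n_age > 0:
            for pos in rng.choice(ltr_mutable, size=n_age, replace=False):
                copy = ltr5 if rng.integers(2) == 0 else ltr3
                old = copy[pos]
                copy[pos] = [b for b in BASES if b != old][rng.integers(3)]

        seq = "".join(ltr5) + "".join(template[ltr:]) + "".join(ltr3)
        members.append(Member(mid, mid, seq, ltr, config.u3_length))

    for a, b in config.near_identical_pairs:
        # Rebuild member b as a copy of a with a handful of private CDS substitutions.
        src = members[a]
        seq = list(src.seq)
        cds_lo, cds_hi = src.domains["CDS"]
        for pos in rng.choice(np.arange(cds_lo, cds_hi),
                              size=config.near_identical_distance, replace=False):
            old = seq[pos]
            seq[pos] = [x for x in BASES if x != old][rng.integers(3)]
        members[b] = replace(members[b], seq="".join(seq))

    if config.inter_member_divergence > 0 or config.near_identical_pairs:
        seqs = [m.seq for m in members]
        if len(set(seqs)) != len(seqs):
            raise RuntimeError("members are not mutually distinguishable; "
                               "increase inter_member_divergence or change seed")

    # Host genome: members embedded once each, evenly spaced with unique flanks.
    host = _random_seq(rng, config.host_length, config.gc_content)
    n = config.n_members
    gap = config.host_length // (n + 1)
    if gap < 2 * L:
        raise ValueError("host_length too short to space the element copies")
    pieces, intervals, cursor_host, cursor_out = [], [], 0, 0
    for i, m in enumerate(members):
        flank = host[cursor_host: gap * (i + 1)]
        pieces.append(flank)
        cursor_out += len(flank)
        intervals.append((cursor_out, cursor_out + m.length, m.id))
        pieces.append(m.seq)
        cursor_out += m.length
        cursor_host = gap * (i + 1)
    pieces.append(host[cursor_host:])
    genome = "".join(pieces)

    return FamilyModel(config=config, members=tuple(members),
                       genome=genome, element_intervals=tuple(intervals))


def paper_like_config(seed: int = 0, **overrides) -> FamilyConfig:
    """An eight-member family shaped like the heat-activated Copia78/Onsen
    family of Arabidopsis Col-0: three young members with identical LTRs
    (two of them nearly indistinguishable siblings), and five old members
    with 5'/3' LTR identities of 99, 99, 98, 97 and 97 percent. Expression
    weights mirror the observed heat response: young members dominate, one
    old member is strongly active, and one member is silent.
    """
    cfg = FamilyConfig(
        n_members=8,
        target_ltr_identities=(1.0, 1.0, 1.0, 0.99, 0.99, 0.98, 0.97, 0.97),
        near_identical_pairs=((0, 1),),
        expression_weights=(30.0, 25.0, 20.0, 10.0, 8.0, 1.0, 0.0, 6.0),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
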