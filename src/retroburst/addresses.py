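"""Per-member read assignment via member-specific sequence "addresses".

Each family member is identified by a small number (default three) of
fixed-length (default 70 bp) sequences anchored in independent polymorphic
regions, each occurring in exactly one member (checked on both strands).
Reads are assigned by perfect string matching of these addresses, the
member count being the arithmetic mean over its addresses, normalised to
mapped library size. Members without enough independent unique windows —
near-identical siblings — are pooled into a group carrying shared group
addresses, and the pooled count is subsequently apportioned using one
distinguishing-polymorphism address per sibling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .family import FamilyModel
from .seqio import revcomp


@dataclass(frozen=True)
class AddressGroup:
    members: tuple[str, ...]
    group_addresses: tuple[str, ...]
    distinguishing: dict[str, str]  # member -> address unique to that member (may be empty)


@dataclass(frozen=True)
class AddressSet:
    address_length: int
    n_addresses: int
    member_addresses: dict[str, tuple[str, ...]]  # singletons only
    groups: tuple[AddressGroup, ...]
    unassignable: tuple[str, ...]

    def all_members(self) -> list[str]:
        out = list(self.member_addresses)
        for g in self.groups:
            out.extend(g.members)
        out.extend(self.unassignable)
        return out

    def as_fasta_dict(self) -> dict[str, str]:
        recs = {}
        for m, addrs in self.member_addresses.items():
            for i, a in enumerate(addrs, 1):
                recs[f"{m}_addr{i}"] = a
        for g in self.groups:
            gid = "+".join(g.members)
            for i, a in enumerate(g.group_addresses, 1):
                recs[f"group_{gid}_addr{i}"] = a
            for m, a in g.distinguishing.items():
                recs[f"{m}_distinguishing"] = a
        return recs


def _window_owners(members: Mapping[str, str], k: int) -> dict[str, set[str]]:
    """Map every k-window (forward) to the set of members containing it on
    either strand."""
    fwd: dict[str, set[str]] = {}
    for mid, seq in members.items():
        for i in range(len(seq) - k + 1):
            fwd.setdefault(seq[i: i + k], set()).add(mid)
    owners: dict[str, set[str]] = {}
    for w, who in fwd.items():
        merged = set(who)
        rc = revcomp(w)
        if rc in fwd:
            merged |= fwd[rc]
        owners[w] = merged
    return owners


def _greedy_regions(offsets: Sequence[int], k: int, separation: int) -> list[int]:
    """Pick one offset per region, regions being separated by >= separation bases."""
    picked: list[int] = []
    for o in sorted(offsets):
        if not picked or o >= picked[-1] + k + separation:
            picked.append(o)
    return picked


def derive_addresses(family: FamilyModel, address_length: int = 70,
                     n_addresses: int = 3,
                     separation: int | None = None) -> AddressSet:
    """Derive member addresses from the family sequences.

    A window is a candidate for member m only if it occurs (on either
    strand) in m and in no other member; windows shared by several members
    are discarded rather than assigned by priority. Members that cannot
    supply ``n_addresses`` candidates in regions separated by at least one
    address length are merged with their closest relatives into a group.
    """
    if separation is None:
        separation = address_length
    k = address_length
    seqs = {m.id: m.seq for m in family.members}
    owners = _window_owners(seqs, k)

    def unique_offsets(target: set[str], within: str) -> list[int]:
        """Offsets in `within`'s sequence whose window is owned by exactly `target`."""
        seq = seqs[within]
        return [i for i in range(len(seq) - k + 1)
                if owners.get(seq[i: i + k]) == target]

    member_addresses: dict[str, tuple[str, ...]] = {}
    failing: list[str] = []
    for mid, seq in seqs.items():
        picks = _greedy_regions(unique_offsets({mid}, mid), k, separation)
        if len(picks) >= n_addresses:
            member_addresses[mid] = tuple(seq[o: o + k] for o in picks[:n_addresses])
        else:
            failing.append(mid)

    groups: list[AddressGroup] = []
    unassignable: list[str] = []
    remaining = list(failing)

    def hamming(a: str, b: str) -> int:
        if len(a) != len(b):
            return max(len(a), len(b))
        return sum(x != y for x, y in zip(a, b))

    while remaining:
        mid = remaining.pop(0)
        group = {mid}
        others = sorted((m for m in seqs if m not in group),
                        key=lambda m: (hamming(seqs[mid], seqs[m]), m))
        picks: list[int] = []
        for cand in others:
            group.add(cand)
            picks = _greedy_regions(unique_offsets(set(group), mid), k, separation)
            if len(picks) >= n_addresses:
                break
        if len(picks) < n_addresses:
            unassignable.append(mid)
            continue
        group_addrs = tuple(seqs[mid][o: o + k] for o in picks[:n_addresses])
        distinguishing: dict[str, str] = {}
        for gm in sorted(group):
            own = unique_offsets({gm}, gm)
            if own:
                distinguishing[gm] = seqs[gm][own[0]: own[0] + k]
        groups.append(AddressGroup(tuple(sorted(group)), group_addrs, distinguishing))
        for gm in group:
            if gm in remaining:
                remaining.remove(gm)
            member_addresses.pop(gm, None)

    return AddressSet(address_length=k, n_addresses=n_addresses,
                      member_addresses=member_addresses,
                      groups=tuple(groups), unassignable=tuple(unassignable))


@dataclass
class MemberCounts:
    """Raw and normalised per-member counts plus pooled-group bookkeeping."""
    table: pd.DataFrame                 # member, raw_mean, normalized, library_size
    address_counts: dict[str, int]      # every individual address sequence -> read count
    group_pooled: dict[tuple[str, ...], float]        # group members -> pooled raw mean
    group_distinguishing: dict[tuple[str, ...], dict[str, int]]
    library_size: int
    unsplit_groups: list[tuple[str, ...]] = field(default_factory=list)

    def raw(self, member: str) -> float:
        row = self.table.loc[self.table["member"] == member]
        return float(row["raw_mean"].iloc[0])

    def normalized(self, member: str) -> float:
        row = self.table.loc[self.table["member"] == member]
        return float(row["normalized"].iloc[0])


def _count_reads_with(addresses: Sequence[str], reads: Iterable[str]) -> dict[str, int]:
    counts = {a: 0 for a in addresses}
    pairs = [(a, revcomp(a)) for a in addresses]
    for r in reads:
        for a, arc in pairs:
            if a in r or arc in r:
                counts[a] += 1
    return counts


def split_group_counts(pooled: float, distinguishing_counts: Mapping[str, int]
                       ) -> tuple[dict[str, float], bool]:
    """Apportion a pooled group count by the ratio observed at the
    distinguishing polymorphism. Returns (per-member counts, split_ok);
    with zero coverage at the distinguishing sites the pooled count is
    returned unsplit (spread evenly) and flagged."""
    total = sum(distinguishing_counts.values())
    members = sorted(distinguishing_counts)
    if total == 0:
        n = max(len(members), 1)
        return {m: pooled / n for m in members}, False
    return {m: pooled * distinguishing_counts[m] / total for m in members}, True


def count_member_reads(reads: Iterable[str], addresses: AddressSet,
                       library_size: int) -> MemberCounts:
    """Count reads per member by perfect address matching (either strand).

    A read increments an address count iff the address is an exact
    substring of the read or of its reverse complement; the member count
    is the arithmetic mean over its addresses, normalised per million
    mapped reads. Pooled groups are split via their distinguishing
    addresses.
    """
    if library_size < 0:
        raise ValueError("library_size must be >= 0")
    reads = list(reads)
    every_address: list[str] = []
    for addrs in addresses.member_addresses.values():
        every_address.extend(addrs)
    for g in addresses.groups:
        every_address.extend(g.group_addresses)
        every_address.extend(g.distinguishing.values())
    counts = _count_reads_with(every_address, reads)

    scale = 1e6 / library_size if library_size > 0 else 0.0
    rows = []
    group_pooled: dict[tuple[str, ...], float] = {}
    group_dist: dict[tuple[str, ...], dict[str, int]] = {}
    unsplit: list[tuple[str, ...]] = []

    for mid, addrs in sorted(addresses.member_addresses.items()):
        raw = sum(counts[a] for a in addrs) / len(addrs)
        rows.append((mid, raw, raw * scale))
    for g in addresses.groups:
        pooled = sum(counts[a] for a in g.group_addresses) / len(g.group_addresses)
        dist = {m: counts[a] for m, a in g.distinguishing.items()}
        for m in g.members:
            dist.setdefault(m, 0)
        group_pooled[g.members] = pooled
        group_dist[g.members] = dist
        per_member, ok = split_group_counts(pooled, dist)
        if not ok:
            unsplit.append(g.members)
        for m in sorted(g.members):
            raw = per_member[m]
            rows.append((m, raw, raw * scale))

    rows.sort()
    table = pd.DataFrame(rows, columns=["member", "raw_mean", "normalized"])
    table["library_size"] = library_size
    return MemberCounts(table=table, address_counts=counts,
                        group_pooled=group_pooled, group_distinguishing=group_dist,
                        library_size=library_size, unsplit_groups=unsplit)


def ecdna_abundance(heat: MemberCounts, control: MemberCounts) -> pd.DataFrame:
    """Heat-minus-control differential of normalised per-member counts.

    Both inputs must be normalised on their own library sizes; the
    differential is the heat normalised count minus the control normalised
    count, member by member.
    """
    h = heat.table.set_index("member")["normalized"]
    c = control.table.set_index("member")["normalized"]
    members = sorted(set(h.index) | set(c.index))
    out = pd.DataFrame({
        "member": members,
        "heat_normalized": [h.get(m, 0.0) for m in members],
        "control_normalized": [c.get(m, 0.0) for m in members],
    })
    out["differential"] = out["heat_normalized"] - out["control_normalized"]
    return out
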