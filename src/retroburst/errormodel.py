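"""Null models for recombination-like reads arising from sequencing error.

Two complementary estimators quantify how many junction-library hits are
expected from NGS substitution errors alone:

* a closed-form product, ``r_expected = n * ell * P_error * P_position *
  P_base`` — ``n`` element-mapping reads, ``ell`` the number of
  error-position opportunities per read that can fake a junction,
  ``P_error`` the per-read probability of a random nucleotide swap,
  ``P_position = 1/read_length`` and ``P_base = 1/3``;
* a permutation null: draw reads with replacement from the universe of
  all distinct read-length windows of the parental elements, mutate each
  with probability ``P_error`` (one uniformly placed swap to a uniformly
  chosen alternative base), and search only the mutated reads against the
  junction library, repeating (default 500 times) to obtain the mean and
  maximum false-recombinant rate per 1000 drawn reads.

For a synthetic family the formula's ``ell`` can be computed exactly as
the mean number of single-swap (position, base) opportunities per
universe read (:func:`effective_ell`), which makes the permutation mean
equal to the closed form in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .junctions import ConsensusPattern, JunctionLibrary
from .seqio import revcomp

_ALTS = {b: tuple(x for x in "ACGT" if x != b) for b in "ACGT"}


@dataclass(frozen=True)
class ErrorModelParams:
    """Symbols of the closed-form false-recombinant formula."""
    n: float = 1000.0          # element-mapping reads
    ell: float = 2.0           # minimum error positions faking a junction
    p_error: float = 0.1415    # per-read probability of a nucleotide swap
    p_position: float = 0.0066  # probability the swap hits one required position
    p_base: float = 0.3333     # probability the swap yields the required base

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.ell < 1:
            raise ValueError("ell must be >= 1")
        for name in ("p_error", "p_position", "p_base"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


def expected_false_recombinants(params: ErrorModelParams) -> float:
    """The literal product ``n * ell * P_error * P_position * P_base``.

    No internal rounding; round only at reporting time (two decimals by
    convention).
    """
    params.validate()
    return params.n * params.ell * params.p_error * params.p_position * params.p_base


def estimate_p_error(reads: Iterable[str], members: Mapping[str, str],
                     assume_mapped: bool = True, seed_length: int = 31) -> float:
    """Per-read swap probability from the non-perfect-matching fraction.

    A read is perfect iff it is an exact substring of some member sequence
    on either strand. With ``assume_mapped`` the whole input is taken as
    element-mapping; otherwise membership requires sharing at least one
    ``seed_length``-mer with the members, and reads failing that are
    excluded from the denominator.
    """
    haystacks = []
    for s in members.values():
        s = s.upper()
        haystacks.append(s)
        haystacks.append(revcomp(s))
    joined = "\n".join(haystacks)

    seed_set: set[str] | None = None
    if not assume_mapped:
        seed_set = set()
        for s in haystacks:
            for i in range(len(s) - seed_length + 1):
                seed_set.add(s[i: i + seed_length])

    total = imperfect = 0
    for r in reads:
        r = r.upper()
        perfect = r in joined
        if not perfect and seed_set is not None:
            if not any(r[i: i + seed_length] in seed_set
                       for i in range(0, max(1, len(r) - seed_length + 1))):
                continue
        total += 1
        if not perfect:
            imperfect += 1
    if total == 0:
        raise ValueError("no element-mapping reads")
    return imperfect / total


def build_read_universe(members: Mapping[str, str], read_length: int = 150,
                        step: int = 1, return_provenance: bool = False):
    """All distinct ``read_length`` windows of the member sequences at
    ``step``-bp resolution (forward strand), deduplicated and sorted.

    With ``return_provenance`` also returns a map read -> (member, offset)
    of its first occurrence.
    """
    seen: dict[str, tuple[str, int]] = {}
    for mid, seq in members.items():
        seq = seq.upper()
        if len(seq) < read_length:
            warnings.warn(f"member {mid} shorter than read_length; skipped")
            continue
        for i in range(0, len(seq) - read_length + 1, step):
            w = seq[i: i + read_length]
            if w not in seen:
                seen[w] = (mid, i)
    universe = sorted(seen)
    if return_provenance:
        return universe, seen
    return universe


@dataclass(frozen=True)
class PermutationResult:
    rates: tuple[float, ...]   # per-permutation rate per 1000 drawn reads
    n_permutations: int
    n_draws: int
    p_error: float
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.rates))

    @property
    def max(self) -> float:
        return float(np.max(self.rates))


def permutation_null(universe: Sequence[str], n_draws: int, p_error: float,
                     library: JunctionLibrary, n_permutations: int = 500,
                     seed: int = 0, multi_swap: bool = False) -> PermutationResult:
    """Permutation null model for false recombination-like reads.

    Per permutation, ``n_draws`` reads are drawn with replacement from the
    universe; each is mutated with probability ``p_error`` (one uniform
    swap; with ``multi_swap`` a Poisson(-log(1-p_error)) number of swaps,
    for sensitivity analysis); only mutated reads are searched against the
    library, and the rate is reported per 1000 *drawn* reads.
    """
    if not universe:
        raise ValueError("empty read universe")
    if not (0.0 <= p_error <= 1.0):
        raise ValueError("p_error must be in [0, 1]")
    rng = np.random.default_rng(seed)
    U = len(universe)
    rates = []
    for _ in range(n_permutations):
        n_mut = rng.binomial(n_draws, p_error)
        hits = 0
        if n_mut and p_error > 0:
            idx = rng.integers(0, U, size=n_mut)
            for j in idx:
                read = universe[j]
                if multi_swap:
                    n_swaps = max(1, rng.poisson(-np.log1p(-p_error)))
                else:
                    n_swaps = 1
                out = list(read)
                for _ in range(n_swaps):
                    pos = int(rng.integers(len(out)))
                    out[pos] = _ALTS[out[pos]][rng.integers(3)] \
                        if out[pos] in _ALTS else out[pos]
                if library.matches_read("".join(out)) is not None:
                    hits += 1
        rates.append(1000.0 * hits / n_draws)
    return PermutationResult(rates=tuple(rates), n_permutations=n_permutations,
                             n_draws=n_draws, p_error=p_error, seed=seed)


def effective_ell(universe_provenance: Mapping[str, tuple[str, int]],
                  pattern: ConsensusPattern, library: JunctionLibrary,
                  read_length: int = 150) -> float:
    """Exact single-swap opportunity count for a synthetic family.

    For each universe read, counts the (position, alternative base) pairs
    whose swap yields a read containing a library fragment; only swaps at
    polymorphic alignment columns can do so, which keeps the scan cheap.
    The mean over the universe is the ``ell`` that makes the closed-form
    formula (with ``P_position = 1/read_length``, ``P_base = 1/3``) agree
    with the permutation null in expectation. Requires an ungapped
    alignment (columns == positions).
    """
    for variants in pattern.wildcards.values():
        if "-" in variants:
            raise ValueError("effective_ell requires an ungapped alignment")
    member_seqs = {m: s for m, s in pattern.alignment.items()}
    wc_cols = sorted(pattern.wildcards)

    total = 0
    n_reads = 0
    for read in universe_provenance:
        n_reads += 1
        # A read may occur in several contexts (e.g. both LTR copies of a
        # young member); candidate swap positions are unioned over all of
        # them, since a swap only creates a library fragment at a column
        # where members differ.
        candidates: set[tuple[int, str]] = set()
        for seq in member_seqs.values():
            start = 0
            while True:
                off = seq.find(read, start)
                if off < 0:
                    break
                for col in wc_cols:
                    i = col - off
                    if 0 <= i < read_length:
                        for v in pattern.wildcards[col]:
                            if v != read[i]:
                                candidates.add((i, v))
                start = off + 1
        for i, v in sorted(candidates):
            mutated = read[:i] + v + read[i + 1:]
            if library.matches_read(mutated) is not None:
                total += 1
    if n_reads == 0:
        raise ValueError("empty universe")
    return total / n_reads


@dataclass(frozen=True)
class NullComparison:
    observed_rate: float
    null_mean: float
    null_max: float
    r_expected: float
    ratio_to_null_mean: float
    exceeds_null_max: bool


def compare_observed_to_null(observed_rate: float, null: PermutationResult,
                             r_expected: float) -> NullComparison:
    """Compare an observed recombination-read rate (per 1000) to the
    permutation null and the closed-form expectation."""
    mean = null.mean
    ratio = observed_rate / mean if mean > 0 else float("inf") if observed_rate > 0 else 1.0
    return NullComparison(
        observed_rate=observed_rate, null_mean=mean, null_max=null.max,
        r_expected=r_expected, ratio_to_null_mean=ratio,
        exceeds_null_max=bool(observed_rate > null.max))
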