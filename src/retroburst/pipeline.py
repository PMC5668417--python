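"""End-to-end synthetic benchmark: simulate a burst, then run every
analysis stage against the simulation's own ground truth.

Configuration is a flat mapping with per-stage sections; unknown keys are
rejected, every effective parameter is echoed into a machine-readable run
manifest together with a SHA-256 checksum of every output file, and a
fixed seed reproduces the manifest byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from . import addresses as addr
from . import burst as burst_mod
from . import ecdna as ecdna_mod
from . import errormodel as err_mod
from . import insertions as ins_mod
from . import junctions as junc_mod
from .family import FamilyConfig, make_family, paper_like_config
from .mapper import GenomeIndex, map_pairs, mask_intervals
from .reads import all_read_sequences, sequence_reads, write_pair_fastq
from .seqio import BedInterval, write_bed, write_fasta, write_tsv


@dataclass
class RunConfig:
    """All stage parameters with package defaults; unknown keys rejected."""
    seed: int = 1
    outdir: str = "retroburst_run"
    paper_like_family: bool = True
    family: dict = field(default_factory=dict)        # FamilyConfig overrides
    n_molecules: int = 60
    switch_rate: float = 0.0
    r_transfer_recomb_prob: float = 0.8
    rt_error_rate: float = 6.25e-5
    n_insertions: int = 20
    tsd_length: int = 5
    coverage: float = 30.0
    ecdna_coverage: float = 20.0
    read_length: int = 150
    fragment_mean: float = 350.0
    fragment_sd: float = 40.0
    per_base_error: float = 0.0
    window_length: int = 145
    address_length: int = 70
    n_addresses: int = 3
    ltr_start_length: int = 20
    n_permutations: int = 100
    n_draws: int = 2000

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        fam_known = {f.name for f in fields(FamilyConfig)}
        fam_unknown = set(cfg.family) - fam_known
        if fam_unknown:
            raise ValueError(f"unknown family keys: {sorted(fam_unknown)}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}

    def record(stage: str, **info):
        manifest["stages"][stage] = info

    # --- simulate ---------------------------------------------------------
    fam_overrides = dict(config.family)
    if config.paper_like_family:
        family_cfg = paper_like_config(seed=seed, **fam_overrides)
    else:
        family_cfg = FamilyConfig(seed=seed, **fam_overrides)
    family = make_family(family_cfg)
    molecules, truth = burst_mod.simulate_burst(
        family, config.n_molecules, switch_rate=config.switch_rate,
        r_transfer_recomb_prob=config.r_transfer_recomb_prob,
        rt_error_rate=config.rt_error_rate, seed=seed + 1)
    progeny, ins_truth = burst_mod.integrate(
        molecules, family.genome, config.n_insertions,
        tsd_length=config.tsd_length, seed=seed + 2,
        element_intervals=family.element_intervals, truth=truth)

    write_fasta(out / "members.fa", {m.id: m.seq for m in family.members})
    write_fasta(out / "genome.fa", {"chr1": family.genome})
    write_fasta(out / "ecdna.fa", {m.id: m.seq for m in molecules})
    write_bed(out / "insertions_truth.bed", truth.insertions_as_bed())
    record("simulate", n_molecules=len(molecules), n_insertions=len(ins_truth),
           n_recombinant=sum(m.is_recombinant for m in molecules))

    # --- reads ------------------------------------------------------------
    progeny_pairs = sequence_reads({"progeny": progeny}, config.coverage,
                                   read_length=config.read_length,
                                   fragment_mean=config.fragment_mean,
                                   fragment_sd=config.fragment_sd,
                                   per_base_error=config.per_base_error,
                                   seed=seed + 3)
    control_pairs = sequence_reads({"chr1": family.genome}, config.coverage,
                                   read_length=config.read_length,
                                   fragment_mean=config.fragment_mean,
                                   fragment_sd=config.fragment_sd,
                                   per_base_error=config.per_base_error,
                                   seed=seed + 4)
    ecdna_pairs_sim = sequence_reads({m.id: m.seq for m in molecules},
                                     config.ecdna_coverage,
                                     read_length=config.read_length,
                                     fragment_mean=config.fragment_mean,
                                     fragment_sd=config.fragment_sd,
                                     per_base_error=config.per_base_error,
                                     seed=seed + 5)
    write_pair_fastq(progeny_pairs, out / "progeny_R1.fq", out / "progeny_R2.fq")
    record("reads", n_progeny_pairs=len(progeny_pairs),
           n_control_pairs=len(control_pairs), n_ecdna_pairs=len(ecdna_pairs_sim))

    # --- assign -----------------------------------------------------------
    address_set = addr.derive_addresses(family, config.address_length,
                                        config.n_addresses)
    ecdna_reads = all_read_sequences(ecdna_pairs_sim)
    counts = addr.count_member_reads(ecdna_reads, address_set, len(ecdna_reads))
    write_tsv(out / "member_counts.tsv", counts.table)
    write_fasta(out / "addresses.fa", address_set.as_fasta_dict())
    record("assign", n_groups=len(address_set.groups),
           unassignable=list(address_set.unassignable))

    # --- junctions --------------------------------------------------------
    pattern = junc_mod.build_consensus(family.alignment)
    library = junc_mod.enumerate_fragments(
        pattern, family.genome, window_length=config.window_length,
        extra_purge_sequences=[burst_mod.single_parent_ecdna(m)
                               for m in family.members])
    result = junc_mod.search_junctions(ecdna_reads, library, len(ecdna_reads))
    write_tsv(out / "junction_matches.tsv", result.matches)
    record("junctions", library_size=len(library),
           rate_per_1000=result.rate_per_1000)

    # --- errormodel -------------------------------------------------------
    universe, prov = err_mod.build_read_universe(
        {m.id: m.seq for m in family.members}, config.read_length,
        return_provenance=True)
    ell = err_mod.effective_ell(prov, pattern, library, config.read_length)
    p_err = 1.0 - (1.0 - 1.0 / 1060.0) ** config.read_length
    params = err_mod.ErrorModelParams(n=1000, ell=max(ell, 1.0), p_error=p_err,
                                      p_position=1.0 / config.read_length,
                                      p_base=1.0 / 3.0)
    r_exp = err_mod.expected_false_recombinants(params)
    null = err_mod.permutation_null(universe, config.n_draws, p_err, library,
                                    n_permutations=config.n_permutations,
                                    seed=seed + 6)
    verdict = err_mod.compare_observed_to_null(result.rate_per_1000, null, r_exp)
    record("errormodel", r_expected=r_exp, effective_ell=ell,
           null_mean=null.mean, null_max=null.max,
           observed_rate=verdict.observed_rate,
           exceeds_null_max=verdict.exceeds_null_max)

    # --- ecdna-pairs ------------------------------------------------------
    motif = ecdna_mod.shared_ltr_start(family, config.ltr_start_length)
    candidates = ecdna_mod.find_blunt_ltr_reads(ecdna_pairs_sim, motif)
    refs = ecdna_mod.reference_sequences(family)
    blunt = ecdna_mod.perfect_pair_filter(candidates, refs, family)
    tab = ecdna_mod.tabulate_pairs(blunt)
    write_tsv(out / "blunt_pairs.tsv", tab.table)
    record("ecdna_pairs", n_candidates=len(candidates), n_retained=len(blunt),
           n_discriminatory=tab.n_discriminatory,
           n_non_discriminatory=tab.n_non_discriminatory)

    # --- insertions -------------------------------------------------------
    masked = mask_intervals(family.genome,
                            [(s, e) for s, e, _ in family.element_intervals])
    index = GenomeIndex(masked)
    ltr_seqs = [m.ltr5 for m in family.members] + [m.ltr3 for m in family.members]
    start_motif = family.shared_element_prefix(30)
    end_motif = family.shared_element_suffix(30)

    def evidence(pairs):
        mapped = map_pairs(pairs, index)
        anchors = ins_mod.find_discordant_pairs(mapped, ltr_seqs)
        unmapped = [(p.name + suffix, r)
                    for p, p1, p2 in mapped
                    for suffix, r, placed in (("/1", p.r1, p1), ("/2", p.r2, p2))
                    if placed is None]
        junction_reads = ins_mod.find_junction_reads(unmapped, start_motif,
                                                     end_motif, index)
        return anchors, junction_reads

    anchors, junction_reads = evidence(progeny_pairs)
    c_anchors, c_junctions = evidence(control_pairs)
    calls = ins_mod.call_insertions(anchors, junction_reads, c_anchors,
                                    c_junctions, genome=family.genome)
    write_bed(out / "insertion_calls.bed", [
        BedInterval(c.chrom, c.start, max(c.end, c.start + 1),
                    name=f"call{i+1}", score=c.n_discordant)
        for i, c in enumerate(calls)])

    truth_sites = {(t.chrom, t.start) for t in truth.insertions}
    called_sites = {(c.chrom, c.start) for c in calls}
    tp = len(truth_sites & called_sites)
    recall = tp / len(truth_sites) if truth_sites else 1.0
    precision = tp / len(called_sites) if called_sites else 1.0

    painted = []
    for i, call in enumerate(calls):
        rec = ins_mod.reconstruct_ltr(call, anchors, junction_reads, family)
        if rec.ltr_sequence and rec.complete:
            painted.append(ins_mod.paint_parentage(
                rec.ltr_sequence, ins_mod.ltr_variants(family), f"call{i+1}"))
    if painted:
        scores = ins_mod.contribution_scores(painted)
        write_tsv(out / "contribution_scores.tsv",
                  scores.per_insertion)
    record("insertions", n_calls=len(calls), recall=recall, precision=precision,
           n_painted=len(painted))

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
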