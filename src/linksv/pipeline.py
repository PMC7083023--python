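"""End-to-end SV calling: orchestrates alignment input, molecule
recovery, split matching, quasi-clique clustering, and depth filtering."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import CallerConfig
from .depth import DepthThresholds, filter_by_molecule_depth
from .evaluate import reciprocal_overlap
from .graph import SVCall, build_sv_graph, clique_to_call, find_quasi_cliques
from .io import (ReadPairs, RegionMask, classify_pairs,
                 estimate_concordance_bounds, read_bam_pairs)
from .molecules import (MoleculeStats, compute_depth_profile,
                        estimate_molecule_stats, recover_submolecules)
from .output import write_bedpe, write_vcf
from .splits import (CandidateSplits, DiscordantIndex, SizeWindows,
                     anchor_translocation_splits, count_pair_support,
                     enumerate_candidate_splits, filter_splits_by_rp,
                     match_split_molecule_pairs)

log = logging.getLogger("linksv")


@dataclass
class CallResult:
    calls: list[SVCall]
    stats: MoleculeStats | None
    profile: object | None
    report: dict = field(default_factory=dict)

    @property
    def pass_calls(self) -> list[SVCall]:
        return [c for c in self.calls if c.filter_status == "PASS"]


def _dedupe_pass_calls(calls: list[SVCall], mu: float) -> list[SVCall]:
    """Quasi-clique peeling can emit several cliques for one event; keep
    the best-supported PASS call among same-type calls overlapping > 50%
    reciprocally (insertion loci within mu/2 for 3-breakpoint types)."""
    order = sorted(range(len(calls)),
                   key=lambda i: (-calls[i].n_split_molecules,
                                  -calls[i].rp_support, i))
    kept: list[int] = []
    for i in order:
        c = calls[i]
        if c.filter_status != "PASS":
            continue
        dup = False
        for j in kept:
            k = calls[j]
            if k.sv_type != c.sv_type or k.chrom1 != c.chrom1:
                continue
            if reciprocal_overlap(k.body, c.body) <= 0.5:
                continue
            if c.bp3 is not None:
                if k.chrom2 != c.chrom2 or \
                        abs(k.insertion_point - c.insertion_point) > mu / 2:
                    continue
            dup = True
            break
        if dup:
            c.filter_status = "duplicate"
        else:
            kept.append(i)
    return calls


def call_from_pairs(pairs: ReadPairs, chrom_lengths: dict[str, int],
                    config: CallerConfig | None = None,
                    mask: RegionMask | None = None) -> CallResult:
    """Run the full caller on canonicalized read pairs."""
    config = config or CallerConfig()
    report: dict = {}

    if config.concordance_min is not None and config.concordance_max is not None:
        bounds = (config.concordance_min, config.concordance_max)
    elif len(pairs):
        bounds = estimate_concordance_bounds(pairs, config.insert_nsd,
                                             config.insert_sample)
    else:
        bounds = (0, 1000)
    report["concordance_bounds"] = list(bounds)

    frags, disc, counts = classify_pairs(pairs, mask, *bounds)
    report.update(counts)
    log.info("classified %d pairs: %d fragments, %d discordant, %d masked",
             counts["n_pairs"], counts["n_fragments"], counts["n_discordant"],
             counts["n_masked"])

    if len(frags) < 2:
        report["n_submolecules"] = 0
        report["n_calls"] = 0
        report["n_pass"] = 0
        return CallResult([], None, None, report)

    # two-pass molecule recovery bootstrapping mu_molecule
    stats0 = MoleculeStats.from_mu(config.initial_mu, 0.0,
                                   T=config.t_override, Q=config.q_override,
                                   min_length=config.resolved_min_length(
                                       config.initial_mu))
    subs = recover_submolecules(frags, stats0)
    stats = estimate_molecule_stats(subs, T=config.t_override,
                                    Q=config.q_override,
                                    min_length=config.resolved_min_length(
                                        config.initial_mu))
    stats.min_length = config.resolved_min_length(stats.mu)
    subs = recover_submolecules(frags, stats)
    stats = estimate_molecule_stats(subs, T=config.t_override,
                                    Q=config.q_override,
                                    min_length=config.resolved_min_length(
                                        stats.mu))
    report["n_submolecules"] = len(subs)
    report["mu_molecule"] = round(stats.mu, 1)
    report["sigma_molecule"] = round(stats.sigma, 1)
    log.info("recovered %d submolecules (mu=%.0f, sigma=%.0f)",
             len(subs), stats.mu, stats.sigma)

    profile = compute_depth_profile(subs, mask, chrom_lengths,
                                    config.depth_bin_size)
    report["mu_depth"] = round(profile.mu_depth, 2)
    report["sigma_depth"] = round(profile.sigma_depth, 2)

    index = DiscordantIndex(disc)
    splits = enumerate_candidate_splits(subs, stats,
                                        config.max_splits_per_barcode)
    report["n_candidate_splits"] = len(splits)
    pad = int(bounds[1])
    surviving = filter_splits_by_rp(splits, index, int(stats.T) + pad)
    report["n_supported_splits"] = len(surviving)
    tra = anchor_translocation_splits(disc, subs, stats,
                                      config.tra_anchor_window)
    report["n_translocation_splits"] = len(tra)
    all_splits = CandidateSplits.concat(surviving, tra)

    windows = SizeWindows(config.min_del_size, config.min_inv_size,
                          config.min_dup_size, config.min_tra_size,
                          config.max_event_size, config.dup_min_distance)
    sm_pairs = match_split_molecule_pairs(all_splits, index, stats, windows,
                                          config.min_rp_support, pad)
    report["n_split_molecule_pairs"] = len(sm_pairs)
    log.info("%d candidate splits -> %d supported, %d split molecule pairs",
             len(splits), len(surviving) + len(tra), len(sm_pairs))

    G = build_sv_graph(sm_pairs)
    min_support = config.resolved_min_support
    cliques = find_quasi_cliques(G, config.gamma, min_vertices=min_support)
    report["n_quasi_cliques"] = len(cliques)
    chrom_names = pairs.chroms if pairs.chroms else tuple(chrom_lengths)
    calls = [clique_to_call(q, sm_pairs, chrom_names, min_support)
             for q in cliques]
    # recompute read-pair support over the consensus windows
    from .splits import SplitMoleculePair, count_read_pair_support
    for call, q in zip(calls, cliques):
        ref = sm_pairs[q.members[0]]
        call.rp_support = count_read_pair_support(
            call.sv_type, ref.chrom1, call.bp1, call.bp2, ref.chrom2,
            call.bp3, index, pad)
    report["n_calls"] = len(calls)

    thresholds = DepthThresholds(config.dup_depth_sigma,
                                 config.del_depth_mu_coeff,
                                 config.del_depth_sd_coeff,
                                 config.tra_depth_band_sigma)
    calls = filter_by_molecule_depth(calls, profile, thresholds)
    calls = _dedupe_pass_calls(calls, stats.mu)
    calls.sort(key=lambda c: (c.chrom1, c.body[0], c.sv_type))
    report["n_pass"] = sum(1 for c in calls if c.filter_status == "PASS")
    log.info("%d quasi-cliques -> %d calls, %d PASS", len(cliques),
             len(calls), report["n_pass"])
    return CallResult(calls, stats, profile, report)


def run_pipeline(bam_path, mask_path=None, config: CallerConfig | None = None,
                 out_prefix: str | None = None) -> CallResult:
    """BAM in, BEDPE + VCF + run report out."""
    import yaml

    config = config or CallerConfig()
    mask = RegionMask.from_bed(mask_path) if mask_path else RegionMask.empty()
    pairs, counts, chrom_lengths = read_bam_pairs(
        bam_path, config.barcode_tag, config.min_mapq)
    result = call_from_pairs(pairs, chrom_lengths, config, mask)
    result.report = {**counts, **result.report}
    if out_prefix:
        write_bedpe(result.calls, f"{out_prefix}.bedpe")
        write_vcf(result.calls, chrom_lengths, f"{out_prefix}.vcf")
        with open(f"{out_prefix}.report.yaml", "w") as fh:
            yaml.safe_dump(result.report, fh, sort_keys=False)
    return result
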