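"""Reusable benchmark experiments over the synthetic cohort generators.

Each function wires generators to a pipeline stage and measures a recovery
or calibration quantity; the analysis drivers and the acceptance script
call these rather than re-implementing the plumbing.  All experiments are
deterministic given their seed.
"""

from __future__ import annotations

import numpy as np

from .aid import permutation_test, scan_motifs
from .consensus import collapse_family
from .model import PipelineConfig, SiteCountTable
from .simulate import (
    ErrorProfile,
    SpikeSpec,
    default_sites,
    simulate_aid_mutations,
    simulate_cohort_counts,
    simulate_gene_with_motifs,
    simulate_read_families,
)
from .validation import iterate_validation, validate_cohort

__all__ = [
    "spike_recovery",
    "null_false_site_rate",
    "spike_validation_rate",
    "consensus_error_rates",
    "permutation_calibration",
    "aid_power",
]


def _spiked_cohort(n_pairs, n_sites, mean_depth, error_rate, n_spikes, spike_vaf, seed):
    sites = default_sites(n_sites)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_sites, size=n_spikes, replace=False)
    spikes = [
        SpikeSpec(site=sites[j], sample_id=f"P{i % n_pairs:02d}-T", true_vaf=spike_vaf)
        for i, j in enumerate(sorted(chosen))
    ]
    tumors, normals, truth = simulate_cohort_counts(
        n_pairs, n_sites, mean_depth, ErrorProfile(rate=error_rate),
        spikes, seed=seed, sites=sites,
    )
    return SiteCountTable.concat(tumors, normals), tumors, truth, sites


def spike_recovery(
    n_pairs: int = 30,
    n_sites: int = 500,
    mean_depth: float = 2000,
    error_rate: float = 1e-3,
    n_spikes: int = 50,
    spike_vaf: float = 0.02,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Iterative-validation recovery of spiked low-VAF variants.

    Candidates are every (tumor sample, site) pair, so both sensitivity on
    the spiked pairs and false retention on the clean grid are measured.
    """
    cfg = config or PipelineConfig()
    counts, tumors, truth, sites = _spiked_cohort(
        n_pairs, n_sites, mean_depth, error_rate, n_spikes, spike_vaf, seed
    )
    candidates = [(s, site.key) for s in tumors.samples for site in sites]
    carried, log = iterate_validation(
        counts, candidates, retain_alpha=cfg.retain_alpha, final_alpha=cfg.final_alpha
    )
    true_pairs = truth.true_pairs
    recovered = carried & true_pairs
    return {
        "n_spikes": len(true_pairs),
        "n_recovered": len(recovered),
        "sensitivity": len(recovered) / len(true_pairs) if true_pairs else float("nan"),
        "n_false_retained": len(carried - true_pairs),
        "n_candidates": len(candidates),
        "n_rounds": max(rec.iteration for rec in log),
    }


def null_false_site_rate(
    n_replicates: int = 100,
    n_pairs: int = 30,
    n_sites: int = 500,
    mean_depth: float = 2000,
    error_rate: float = 1e-3,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Fraction of null cohorts (no spikes) retaining any false site."""
    cfg = config or PipelineConfig()
    root = np.random.SeedSequence(seed)
    with_false = 0
    total_false = 0
    for child in root.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        sites = default_sites(n_sites)
        tumors, normals, _ = simulate_cohort_counts(
            n_pairs, n_sites, mean_depth, ErrorProfile(rate=error_rate),
            seed=rep_seed, sites=sites,
        )
        counts = SiteCountTable.concat(tumors, normals)
        candidates = [(s, site.key) for s in tumors.samples for site in sites]
        carried, _ = iterate_validation(
            counts, candidates, retain_alpha=cfg.retain_alpha, final_alpha=cfg.final_alpha
        )
        with_false += bool(carried)
        total_false += len(carried)
    return {
        "n_replicates": n_replicates,
        "replicates_with_false_site": with_false,
        "fraction_with_false_site": with_false / n_replicates,
        "total_false_sites": total_false,
    }


def spike_validation_rate(
    n_pairs: int = 30,
    n_sites: int = 500,
    mean_depth: float = 2000,
    error_rate: float = 1e-3,
    n_spikes: int = 50,
    spike_vaf: float = 0.02,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Full classification of spiked candidates: PASS / TUMOR_ONLY rate.

    Mirrors an orthogonal-validation experiment where the candidate list is
    the set of previously discovered variants: each spiked (tumor, site)
    pair is validated against the cohort background, its matched normal is
    tested, and the fraction ending PASS or TUMOR_ONLY is the validation
    rate.
    """
    cfg = config or PipelineConfig()
    counts, tumors, truth, sites = _spiked_cohort(
        n_pairs, n_sites, mean_depth, error_rate, n_spikes, spike_vaf, seed
    )
    candidates = sorted(truth.true_pairs)
    pair_map = {f"P{i:02d}-T": f"P{i:02d}-N" for i in range(n_pairs)}
    outcomes, _ = validate_cohort(counts, candidates, pair_map, cfg)
    statuses = [o.status for o in outcomes]
    n_validated = sum(s in ("PASS", "TUMOR_ONLY") for s in statuses)
    return {
        "n_candidates": len(outcomes),
        "n_pass": statuses.count("PASS"),
        "n_tumor_only": statuses.count("TUMOR_ONLY"),
        "n_fail": statuses.count("FAIL"),
        "n_low_depth": statuses.count("LOW_DEPTH"),
        "validation_rate_pct": 100.0 * n_validated / len(outcomes),
    }


def consensus_error_rates(
    n_families: int = 10_000,
    error_rate: float = 0.05,
    min_size: int = 5,
    max_size: int = 10,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Raw per-read vs consensus per-family error after collapsing."""
    cfg = config or PipelineConfig()
    fams = simulate_read_families(
        n_families,
        lambda rng: int(rng.integers(min_size, max_size + 1)),
        true_base="A",
        error_rate=error_rate,
        seed=seed,
    )
    site = ("chr1", 100)
    n_reads = wrong_reads = n_consensus = wrong_consensus = 0
    for fam in fams:
        for read in fam.members:
            n_reads += 1
            wrong_reads += read.base_calls[site] != "A"
        cread = collapse_family(fam, min_family_size=cfg.min_family_size)
        if cread is not None:
            n_consensus += 1
            wrong_consensus += cread.consensus_calls[site] != "A"
    return {
        "n_families": n_families,
        "raw_error_rate": wrong_reads / n_reads,
        "consensus_error_rate": wrong_consensus / n_consensus,
    }


def permutation_calibration(
    length: int = 1000,
    motif_fraction: float = 0.2,
    n_mut: int = 19,
    n_perm: int = 100_000,
    seed: int = 0,
) -> dict:
    """Mean simulated motif hits vs the analytic expectation n_mut x fraction."""
    seq = simulate_gene_with_motifs(length, motif_fraction, seed=seed)
    index = scan_motifs(seq)
    result = permutation_test(index, n_mut=n_mut, observed=n_mut, n_perm=n_perm, seed=seed)
    expected = n_mut * index.motif_fraction
    # hypergeometric variance of the per-replicate hit count
    n, k_, n_mut_ = len(index.placement_space), len(index.motif_positions), n_mut
    var = n_mut_ * (k_ / n) * (1 - k_ / n) * (n - n_mut_) / (n - 1)
    return {
        "mean_sim": result.mean_sim,
        "expected_mean": expected,
        "mc_se": float(np.sqrt(var / n_perm)),
        "realised_fraction": index.motif_fraction,
    }


def aid_power(
    n_replicates: int = 25,
    length: int = 1000,
    motif_fraction: float = 0.2,
    n_mut: int = 19,
    motif_bias: float = 5.0,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the permutation test on AID-biased mutation placement."""
    seq = simulate_gene_with_motifs(length, motif_fraction, seed=seed)
    index = scan_motifs(seq)
    root = np.random.SeedSequence(seed + 1)
    rejections = 0
    for child in root.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        positions = simulate_aid_mutations(seq, n_mut, motif_bias=motif_bias, seed=rep_seed)
        observed = sum(p in index.motif_positions for p in positions)
        result = permutation_test(index, n_mut=n_mut, observed=observed,
                                  n_perm=n_perm, seed=rep_seed)
        rejections += result.p_empirical < alpha
    return {
        "n_replicates": n_replicates,
        "power": rejections / n_replicates,
    }
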