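"""Synthetic-data generators for every input the pipeline consumes.

The real study cohort (deep tumor/normal amplicon sequencing of ~30
Hodgkin lymphoma pairs) is controlled-access, so these generators emulate
its statistical structure at desk scale: per-site background sequencing
error with optional between-sample overdispersion (beta-binomial), uneven
consensus depths around 2,000-4,000x (negative binomial), true variants
spiked at allele fractions in the 0.5-25% range the study observed, UMI
read families with independent per-read base errors, and gene sequences
with controllable WRC/GYW motif density plus AID-biased mutation
placement as a positive control.

All generators are deterministic given a seed; per-sample substreams are
derived with ``numpy.random.SeedSequence.spawn`` so partial reruns
reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aid import scan_motifs
from .consensus import ReadFamily, TaggedRead
from .model import GenomicSite, SiteCountTable

__all__ = [
    "ErrorProfile",
    "SpikeSpec",
    "SimTruth",
    "default_sites",
    "simulate_cohort_counts",
    "simulate_read_families",
    "simulate_gene_with_motifs",
    "simulate_aid_mutations",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class ErrorProfile:
    """Background error model: per-site rate and between-sample dispersion.

    ``rate`` is a scalar or per-site array of background error fractions;
    ``dispersion`` is the beta concentration for between-sample variation
    (0 = pure binomial; larger values still mean the beta mean equals
    ``rate``, with variance shrinking as dispersion grows).
    """

    rate: float | Sequence[float] = 1e-3
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        rates = np.atleast_1d(np.asarray(self.rate, dtype=float))
        if np.any((rates < 0) | (rates >= 0.5)):
            raise ValueError("error rates must satisfy 0 <= rate < 0.5")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def site_rates(self, n_sites: int) -> np.ndarray:
        rates = np.atleast_1d(np.asarray(self.rate, dtype=float))
        if rates.size == 1:
            return np.full(n_sites, rates[0])
        if rates.size != n_sites:
            raise ValueError(f"profile has {rates.size} rates for {n_sites} sites")
        return rates


@dataclass(frozen=True)
class SpikeSpec:
    """A true variant planted at one (sample, site) with a known VAF."""

    site: GenomicSite
    sample_id: str
    true_vaf: float

    def __post_init__(self) -> None:
        if not 0.0 < self.true_vaf <= 1.0:
            raise ValueError(f"true_vaf must be in (0, 1], got {self.true_vaf}")


@dataclass
class SimTruth:
    """Ground-truth label per (sample_id, site key): true_variant or clean."""

    labels: dict = field(default_factory=dict)

    def label(self, sample_id: str, site_key: tuple) -> str:
        return self.labels.get((sample_id, site_key), "clean")

    @property
    def true_pairs(self) -> set:
        return {k for k, v in self.labels.items() if v == "true_variant"}


def default_sites(n_sites: int, chrom: str = "chr1", spacing: int = 10) -> list[GenomicSite]:
    """Deterministic panel of SNV sites: evenly spaced, alleles cycling."""
    sites = []
    for i in range(n_sites):
        ref = _BASES[i % 4]
        alt = _BASES[(i + 1) % 4]
        sites.append(GenomicSite(chrom, 1 + i * spacing, ref, alt))
    return sites


def simulate_cohort_counts(
    n_pairs: int,
    n_sites: int,
    mean_depth: float,
    profile: ErrorProfile,
    spikes: Sequence[SpikeSpec] = (),
    seed: int = 0,
    sites: Sequence[GenomicSite] | None = None,
    depth_shape: float = 10.0,
) -> tuple[SiteCountTable, SiteCountTable, SimTruth]:
    """Simulate tumor and normal error-corrected count tables plus truth.

    Per (sample, site): depth ~ NegativeBinomial around ``mean_depth``
    (clipped >= 1, shape ``depth_shape`` mimicking uneven coverage); alt
    counts ~ Binomial(depth, site error rate), beta-overdispersed across
    samples when ``profile.dispersion > 0``; spiked (sample, site) pairs
    add Binomial(depth, true_vaf) alt reads.  Sample ids are ``P##-T`` /
    ``P##-N``.
    """
    if n_pairs < 2:
        raise ValueError("background pooling needs at least 2 pairs")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    site_list = list(sites) if sites is not None else default_sites(n_sites)
    if len(site_list) != n_sites:
        raise ValueError("sites length disagrees with n_sites")
    site_keys = [s.key for s in site_list]
    site_index = {k: j for j, k in enumerate(site_keys)}
    sample_ids = []
    for i in range(n_pairs):
        sample_ids += [f"P{i:02d}-T", f"P{i:02d}-N"]
    sample_index = {s: i for i, s in enumerate(sample_ids)}

    spike_map: dict[tuple[int, int], float] = {}
    for spike in spikes:
        if spike.sample_id not in sample_index:
            raise ValueError(f"spike references unknown sample {spike.sample_id!r}")
        if spike.site.key not in site_index:
            raise ValueError(f"spike references unknown site {spike.site}")
        spike_map[(sample_index[spike.sample_id], site_index[spike.site.key])] = spike.true_vaf

    rates = profile.site_rates(n_sites)
    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(ss) for ss in root.spawn(len(sample_ids))]

    frames = []
    for i, sample_id in enumerate(sample_ids):
        rng = streams[i]
        p_nb = depth_shape / (depth_shape + mean_depth)
        depth = np.maximum(rng.negative_binomial(depth_shape, p_nb, size=n_sites), 1)
        if profile.dispersion > 0:
            a = rates * profile.dispersion
            b = (1.0 - rates) * profile.dispersion
            with np.errstate(divide="ignore", invalid="ignore"):
                p_err = np.where(rates > 0, rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12)), 0.0)
        else:
            p_err = rates
        alt = rng.binomial(depth, p_err)
        for (si, sj), vaf in spike_map.items():
            if si == i:
                alt[sj] = min(depth[sj], alt[sj] + rng.binomial(depth[sj], vaf))
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "chrom": [k[0] for k in site_keys],
                    "pos": [k[1] for k in site_keys],
                    "ref": [k[2] for k in site_keys],
                    "alt": [k[3] for k in site_keys],
                    "ref_count": depth - alt,
                    "alt_count": alt,
                    "other_count": 0,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    tumors = SiteCountTable(df[df["sample_id"].str.endswith("-T")])
    normals = SiteCountTable(df[df["sample_id"].str.endswith("-N")])
    truth = SimTruth(
        labels={
            (sample_ids[si], site_keys[sj]): "true_variant"
            for (si, sj) in spike_map
        }
    )
    return tumors, normals, truth


def simulate_read_families(
    n_families: int,
    family_size_dist: int | Callable,
    true_base: str = "A",
    error_rate: float = 0.01,
    seed: int = 0,
    chrom: str = "chr1",
    pos: int = 100,
) -> list[ReadFamily]:
    """Simulate UMI read families over a single site with per-read errors.

    ``family_size_dist`` is either a constant int or a callable
    ``rng -> int``.  Each member read carries ``true_base``, flipped
    independently with probability ``error_rate`` to a uniformly chosen
    other base.  UMIs are unique per family.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must satisfy 0 <= rate < 0.5")
    if true_base not in _BASES:
        raise ValueError(f"true_base must be one of {_BASES}")
    rng = np.random.default_rng(seed)
    others = [b for b in _BASES if b != true_base]
    position_key = (chrom, pos)
    families = []
    for i in range(n_families):
        size = family_size_dist if isinstance(family_size_dist, int) else int(family_size_dist(rng))
        if size < 1:
            raise ValueError("family sizes must be >= 1")
        umi = f"UMI{i:06d}"
        members = []
        for _ in range(size):
            base = true_base
            if error_rate > 0 and rng.random() < error_rate:
                base = others[rng.integers(3)]
            members.append(
                TaggedRead(
                    umi=umi,
                    position_key=position_key,
                    base_calls={(chrom, pos): base},
                    mapq=60,
                    mismatches=0,
                )
            )
        families.append(ReadFamily(key=(umi, position_key), members=members))
    return families


def simulate_gene_with_motifs(
    length: int,
    target_motif_fraction: float,
    seed: int = 0,
    tol: float = 0.02,
    max_tries: int = 50,
) -> str:
    """Generate a gene sequence whose WRC/GYW motif fraction is controlled.

    The sequence is a uniform random interleaving of WRC trigram blocks
    ("AAC": exactly one motif position each, and no G that could create a
    GYW match) with random A/T filler (which contains no C or G and hence
    no motif), so the realised motif count equals the block count exactly.
    The realised fraction (via :func:`~umivar.aid.scan_motifs`) is checked
    to within ``tol``; unattainable fractions (above ~1/3) raise.
    """
    if length < 3:
        raise ValueError("length must be >= 3")
    if not 0.0 <= target_motif_fraction <= 1.0 / 3.0 + tol:
        raise ValueError(f"target fraction {target_motif_fraction} unattainable (max ~1/3)")
    k = int(round(target_motif_fraction * length))
    if 3 * k > length:
        raise ValueError(
            f"could not realise motif fraction {target_motif_fraction} at length {length}"
        )
    root = np.random.SeedSequence(seed)
    for attempt_seq in root.spawn(max_tries):
        rng = np.random.default_rng(attempt_seq)
        filler = rng.choice(list("AT"), size=length - 3 * k).tolist()
        tokens = ["AAC"] * k + filler
        order = rng.permutation(len(tokens))
        seq = "".join(tokens[i] for i in order)
        realised = scan_motifs(seq).motif_fraction
        if abs(realised - target_motif_fraction) <= tol:
            return seq
    raise ValueError(
        f"could not realise motif fraction {target_motif_fraction} at length {length}"
    )


def simulate_aid_mutations(
    seq: str, n_mut: int, motif_bias: float = 1.0, seed: int = 0
) -> list[int]:
    """Place ``n_mut`` distinct mutations with elevated weight at motifs.

    Sampling is without replacement with weight ``motif_bias`` at WRC/GYW
    motif positions and 1 elsewhere; ``motif_bias=1`` is uniform
    placement.  Returns sorted 1-based positions.
    """
    if motif_bias < 1.0:
        raise ValueError("motif_bias must be >= 1")
    length = len(seq)
    if n_mut > length:
        raise ValueError(f"n_mut {n_mut} exceeds sequence length {length}")
    index = scan_motifs(seq)
    weights = np.ones(length)
    for p in index.motif_positions:
        weights[p - 1] = motif_bias
    rng = np.random.default_rng(seed)
    chosen = rng.choice(length, size=n_mut, replace=False, p=weights / weights.sum())
    return sorted(int(c) + 1 for c in chosen)
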