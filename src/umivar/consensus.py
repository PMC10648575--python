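"""UMI read-family grouping and consensus collapsing.

Reads sharing a unique molecular identifier (UMI) and alignment start
derive from one original DNA molecule.  Collapsing each family to a single
consensus read removes most polymerase/sequencer errors, which is what
makes sub-percent allele fractions detectable at all.  Reads below mapping
quality 10 or carrying more than 5 mismatches are excluded before
grouping, and families with fewer than 3 members are discarded rather than
collapsed (defaults; see :class:`~umivar.model.PipelineConfig`).

The consensus base at a site is the strict majority (> 50% of the calls
covering the site); anything less, including ties, yields ``N``, so the
collapse never invents an allele.  Base qualities do not enter the vote.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .model import GenomicSite

logger = logging.getLogger(__name__)

__all__ = [
    "TaggedRead",
    "ReadFamily",
    "ConsensusRead",
    "group_families",
    "collapse_family",
    "consensus_counts",
    "read_tagged_reads_sam",
]

#: (chrom, 1-based position) identifying a base call within a read.
SitePos = tuple


@dataclass
class TaggedRead:
    """One aligned read carrying its UMI barcode and quality attributes."""

    umi: str
    position_key: tuple  # (chrom, alignment start, 1-based)
    base_calls: dict  # {(chrom, pos): base}
    mapq: int = 60
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.mapq < 0 or self.mismatches < 0:
            raise ValueError("mapq and mismatches must be nonnegative")


@dataclass
class ReadFamily:
    """All reads sharing (UMI, alignment start): one original molecule."""

    key: tuple  # (umi, position_key)
    members: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a read family needs at least one member")
        for read in self.members:
            if (read.umi, read.position_key) != self.key:
                raise ValueError(f"member key {read.umi}/{read.position_key} != {self.key}")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ConsensusRead:
    """The error-corrected collapse of one read family."""

    key: tuple
    consensus_calls: dict  # {(chrom, pos): base or "N"}
    family_size: int


def group_families(
    reads: Iterable[TaggedRead], min_mapq: int = 10, max_mismatches: int = 5
) -> list[ReadFamily]:
    """Filter reads on quality, then group by (UMI, alignment start).

    Reads with ``mapq < min_mapq`` or ``mismatches > max_mismatches`` are
    excluded before grouping; reads lacking a UMI are excluded with a
    logged count.
    """
    missing_umi = 0
    grouped: dict[tuple, list[TaggedRead]] = defaultdict(list)
    for read in reads:
        if not read.umi:
            missing_umi += 1
            continue
        if read.mapq < min_mapq or read.mismatches > max_mismatches:
            continue
        grouped[(read.umi, read.position_key)].append(read)
    if missing_umi:
        logger.warning("%d reads lacked a UMI and were excluded", missing_umi)
    return [ReadFamily(key=key, members=members) for key, members in grouped.items()]


def collapse_family(family: ReadFamily, min_family_size: int = 3) -> ConsensusRead | None:
    """Collapse one family to a consensus read, or ``None`` if too small.

    Families with fewer than ``min_family_size`` members are removed.  Per
    site, the consensus base must win a strict majority of the calls
    covering that site; otherwise the consensus is ``N``.
    """
    if len(family) < min_family_size:
        return None
    sites: set = set()
    for read in family.members:
        sites.update(read.base_calls)
    consensus: dict = {}
    for site in sites:
        votes = Counter(
            read.base_calls[site] for read in family.members if site in read.base_calls
        )
        base, count = votes.most_common(1)[0]
        consensus[site] = base if count * 2 > sum(votes.values()) else "N"
    return ConsensusRead(key=family.key, consensus_calls=consensus, family_size=len(family))


def consensus_counts(
    consensus_reads: Sequence[ConsensusRead], sites: Sequence[GenomicSite]
) -> pd.DataFrame:
    """Tally per-site ref/alt/other consensus-read counts.

    ``N`` consensus calls are never counted as ref, alt, or other; depth is
    ``ref + alt + other``.  Sites covered by no consensus read get a depth-0
    row.  Only the first base of the ref/alt allele is compared, so the
    tally applies to SNV sites.
    """
    rows = []
    for site in sites:
        pos_key = (site.chrom, site.pos)
        ref = alt = other = 0
        for cread in consensus_reads:
            base = cread.consensus_calls.get(pos_key)
            if base is None or base == "N":
                continue
            if base == site.ref[0]:
                ref += 1
            elif base == site.alt[0]:
                alt += 1
            else:
                other += 1
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "ref_count": ref,
                "alt_count": alt,
                "other_count": other,
            }
        )
    return pd.DataFrame(rows)


def _umi_from_read(read: pysam.AlignedSegment) -> str:
    if read.has_tag("RX"):
        return str(read.get_tag("RX"))
    name = read.query_name or ""
    if "_" in name:
        return name.rsplit("_", 1)[1]
    return ""


def read_tagged_reads_sam(path, region_sites: Sequence[GenomicSite] | None = None) -> list[TaggedRead]:
    """Ingest tagged reads from SAM/BAM.

    The UMI is taken from the ``RX`` tag, falling back to the suffix after
    the final ``_`` in the read name; mismatches from the ``NM`` tag
    (0 when absent).  Base calls are recorded at aligned match positions,
    optionally restricted to ``region_sites``.
    """
    wanted = {(s.chrom, s.pos) for s in region_sites} if region_sites else None
    reads: list[TaggedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            calls: dict = {}
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                key = (aln.reference_name, rpos + 1)
                if wanted is not None and key not in wanted:
                    continue
                calls[key] = aln.query_sequence[qpos].upper()
            nm = int(aln.get_tag("NM")) if aln.has_tag("NM") else 0
            reads.append(
                TaggedRead(
                    umi=_umi_from_read(aln),
                    position_key=(aln.reference_name, aln.reference_start + 1),
                    base_calls=calls,
                    mapq=aln.mapping_quality,
                    mismatches=nm,
                )
            )
    return reads
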