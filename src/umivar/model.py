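"""Domain types and threshold configuration shared by every pipeline stage.

The pipeline validates ultra-low-VAF somatic variants discovered in bulk
tumor/normal deep sequencing of classical Hodgkin lymphoma biopsies.  The
malignant Hodgkin/Reed-Sternberg cells are rare (typically <5% of the
tissue), so true somatic variants sit at allele fractions of roughly
0.5-25% and must be separated from sequencing error using UMI consensus
counts and a pooled empirical background model.

Every numeric threshold used anywhere in the pipeline lives in
:class:`PipelineConfig`, so one auditable object documents an analysis run.
Positions are 1-based internally (VCF convention); the BED boundary in
:class:`TargetRegions` is the only place half-open 0-based coordinates
appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenomicSite",
    "VariantCall",
    "TargetRegions",
    "SampleMeta",
    "PipelineConfig",
    "SiteCountTable",
    "SiteKey",
]

_VALID_BASES = frozenset("ACGT")

#: Hashable identity of a site: (chrom, pos, ref, alt), pos 1-based.
SiteKey = tuple


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A candidate substitution or indel locus, 1-based, allele-anchored."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _VALID_BASES.issuperset(allele):
                raise ValueError(f"{name} allele {allele!r} not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantCall:
    """A site attributed to one sample, with tumor support statistics.

    ``tumor_vaf`` is a fraction in [0, 1]; ``alt_reads``/``tumor_depth`` are
    error-corrected (consensus) read counts when produced by this pipeline.
    ``gene`` and ``consequence`` are annotations taken as given input.
    """

    site: GenomicSite
    sample_id: str
    gene: str = ""
    consequence: str = ""
    tumor_vaf: float = 0.0
    tumor_depth: int = 0
    alt_reads: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_vaf <= 1.0:
            raise ValueError(f"tumor_vaf {self.tumor_vaf} outside [0, 1]")
        if self.alt_reads > self.tumor_depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} exceeds tumor_depth {self.tumor_depth}"
            )
        if self.tumor_depth > 0:
            implied = self.alt_reads / self.tumor_depth
            # Allow rounding slack: VAFs are often reported to 3-4 digits.
            if self.alt_reads and abs(implied - self.tumor_vaf) > 0.005 + 0.5 / self.tumor_depth:
                raise ValueError(
                    f"tumor_vaf {self.tumor_vaf} inconsistent with "
                    f"{self.alt_reads}/{self.tumor_depth}"
                )

    @property
    def key(self) -> tuple:
        return (self.sample_id, *self.site.key)


class TargetRegions:
    """Merged target intervals per chromosome (half-open, 0-based).

    Membership queries take 1-based positions, matching the rest of the
    pipeline: a 1-based position ``p`` is inside ``[start, end)`` iff
    ``start < p <= end``.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]], label: str = ""):
        self.label = label
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
            if start < 0:
                raise ValueError(f"negative start in {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._intervals: dict[str, np.ndarray] = {
            chrom: _merge(spans) for chrom, spans in per_chrom.items()
        }

    @property
    def chroms(self) -> list[str]:
        return sorted(self._intervals)

    def intervals(self, chrom: str) -> np.ndarray:
        """Merged ``(n, 2)`` array of [start, end) spans for ``chrom``."""
        return self._intervals.get(chrom, np.empty((0, 2), dtype=int))

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based ``pos`` falls inside a target span."""
        spans = self._intervals.get(chrom)
        if spans is None or not len(spans):
            return False
        p0 = pos - 1  # 0-based coordinate of the base
        i = int(np.searchsorted(spans[:, 0], p0, side="right")) - 1
        return i >= 0 and p0 < spans[i, 1]

    def total_span(self) -> int:
        return int(sum((s[:, 1] - s[:, 0]).sum() for s in self._intervals.values()))

    def __contains__(self, site: GenomicSite) -> bool:
        return self.contains(site.chrom, site.pos)


def _merge(spans: list[tuple[int, int]]) -> np.ndarray:
    spans = sorted(spans)
    merged = [list(spans[0])]
    for start, end in spans[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.asarray(merged, dtype=int)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata row: pairing, tissue, EBV status, burden."""

    sample_id: str
    patient_id: str
    tissue: str  # "tumor" | "normal"
    ebv_eber: str = "unknown"  # "positive" | "negative" | "unknown"
    relapse: bool = False
    mutation_count: int | None = None

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"tissue must be tumor|normal, got {self.tissue!r}")
        if self.ebv_eber not in ("positive", "negative", "unknown"):
            raise ValueError(f"bad ebv_eber {self.ebv_eber!r}")
        if self.mutation_count is not None and self.mutation_count < 0:
            raise ValueError("mutation_count must be nonnegative when known")


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline, in one place.

    SNV validation (iterative Fisher background test):

    * ``min_validation_depth`` — error-corrected depth required in tumor and
      normal before a site is evaluable (reads).
    * ``retain_alpha`` — Holm-adjusted p below which a site is retained (and
      excluded from later background pools) within an iteration round.
    * ``final_alpha`` — adjusted p at or below which a retained tumor site is
      carried forward; the matched normal must exceed ``normal_alpha``.

    UMI consensus: families smaller than ``min_family_size`` reads are
    discarded; reads below ``min_mapq`` or above ``max_mismatches`` (NM)
    never enter a family.

    Indel and de novo rule constants mirror the printed filter rules; the
    strict (``>``) versus inclusive (``>=``) reading of the paired-indel
    depth gate is switchable via ``indel_paired_depth_strict``.
    """

    # SNV background validation
    min_validation_depth: int = 100
    retain_alpha: float = 0.1
    final_alpha: float = 0.05
    normal_alpha: float = 0.05
    include_matched_normal_in_background: bool = True
    # UMI consensus
    min_family_size: int = 3
    min_mapq: int = 10
    max_mismatches: int = 5
    # Indel validation (consensus-read counts)
    indel_min_depth: int = 5          # paired path: depth > 5 (strict)
    indel_paired_depth_strict: bool = True
    indel_min_tumor_alt: int = 2      # "> 1 consensus tumor read" => >= 2
    indel_max_normal_alt: int = 20    # "< 20 consensus normal reads"
    indel_min_tumor_vaf: float = 0.0001   # "tumor VAF > 0.01%"
    indel_max_normal_vaf: float = 0.05    # "normal VAF < 5%"
    indel_tumor_only_min_alt: int = 1
    # De novo low-VAF filter
    denovo_min_depth: int = 5         # "< 5 consensus reads ... removed" => keep >= 5
    denovo_max_normal_vaf: float = 0.05   # "< 5%"
    denovo_min_tumor_vaf: float = 0.005   # "> 0.5%"
    denovo_max_normal_alt: int = 4    # "< 5 variant supporting reads" => <= 4
    denovo_min_tumor_alt: int = 2     # ">= 2 variant supporting reads"
    # EBV positivity from competitive alignment
    ebv_min_reads: int = 2
    ebv_min_mapq: int = 60
    # AID motif permutation test
    n_permutations: int = 100_000
    # Reproducibility
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, bool):
                continue
            if isinstance(value, (int, float)) and value < 0:
                raise ValueError(f"{f.name} must be nonnegative, got {value}")
        for name in ("retain_alpha", "final_alpha", "normal_alpha"):
            alpha = getattr(self, name)
            if not 0.0 < alpha < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {alpha}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


_COUNT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt",
    "ref_count", "alt_count", "other_count",
]


class SiteCountTable:
    """Error-corrected ref/alt/other read counts per (sample, site).

    The substrate of the Fisher background test.  Wraps a DataFrame with
    columns ``sample_id chrom pos ref alt ref_count alt_count other_count``;
    (sample, site) keys are unique and counts nonnegative.
    """

    columns = tuple(_COUNT_COLUMNS)

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        df = df.loc[:, _COUNT_COLUMNS].copy()
        for col in ("ref_count", "alt_count", "other_count"):
            df[col] = df[col].astype(int)
            if (df[col] < 0).any():
                raise ValueError(f"negative values in {col}")
        df["pos"] = df["pos"].astype(int)
        keys = df[["sample_id", "chrom", "pos", "ref", "alt"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (sample, site) key: {dup}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    @property
    def sites(self) -> list[SiteKey]:
        seen = self.df[["chrom", "pos", "ref", "alt"]].drop_duplicates()
        return sorted(map(tuple, seen.itertuples(index=False, name=None)))

    def get(self, sample_id: str, site: SiteKey) -> tuple[int, int, int]:
        """(ref_count, alt_count, other_count) for one (sample, site)."""
        chrom, pos, ref, alt = site
        m = (
            (self.df["sample_id"] == sample_id)
            & (self.df["chrom"] == chrom)
            & (self.df["pos"] == pos)
            & (self.df["ref"] == ref)
            & (self.df["alt"] == alt)
        )
        rows = self.df[m]
        if rows.empty:
            raise KeyError(f"no counts for {sample_id} at {site}")
        row = rows.iloc[0]
        return int(row.ref_count), int(row.alt_count), int(row.other_count)

    def depth(self, sample_id: str, site: SiteKey) -> int:
        r, a, o = self.get(sample_id, site)
        return r + a + o

    def has(self, sample_id: str, site: SiteKey) -> bool:
        try:
            self.get(sample_id, site)
            return True
        except KeyError:
            return False

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SiteCountTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    @classmethod
    def concat(cls, *tables: "SiteCountTable") -> "SiteCountTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))
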