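"""Deterministic rule engines for indel validation and de novo filtering.

Each decision is a pure function of consensus-read counts and the
configured thresholds, and carries the list of rules it failed so every
FAIL is fully explained.  Rule identifiers name the PipelineConfig
constant they test.

Indel validation (paired path, strict inequalities as printed): tumor and
normal consensus depth > 5, tumor alt reads > 1, normal alt reads < 20,
tumor VAF > 0.01%, normal VAF < 5%.  When the normal lacks depth, the
tumor-only path requires depth >= 5, >= 1 tumor alt read and tumor
VAF > 0.01%, yielding TUMOR_ONLY.

De novo filter: tumor and normal consensus depth >= 5, normal VAF < 5%,
tumor VAF > 0.5%, normal alt reads < 5, tumor alt reads >= 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import PipelineConfig, VariantCall

logger = logging.getLogger(__name__)

__all__ = [
    "IndelCounts",
    "FilterDecision",
    "validate_indel",
    "filter_denovo",
    "filter_consequence",
    "remove_known",
    "load_allowlist",
    "DEFAULT_KEEP_CLASSES",
]


@dataclass(frozen=True)
class IndelCounts:
    """Tumor/normal consensus-read support for one variant.

    Normal-side counts may be ``None`` when the matched normal could not be
    assayed.  VAFs default to ``alt/depth`` when not supplied.
    """

    tumor_depth: int
    tumor_alt: int
    normal_depth: int | None = None
    normal_alt: int | None = None
    tumor_vaf: float | None = None
    normal_vaf: float | None = None

    def __post_init__(self) -> None:
        if self.tumor_alt > self.tumor_depth:
            raise ValueError("tumor_alt exceeds tumor_depth")
        if (
            self.normal_depth is not None
            and self.normal_alt is not None
            and self.normal_alt > self.normal_depth
        ):
            raise ValueError("normal_alt exceeds normal_depth")

    @property
    def t_vaf(self) -> float:
        if self.tumor_vaf is not None:
            return self.tumor_vaf
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def n_vaf(self) -> float | None:
        if self.normal_vaf is not None:
            return self.normal_vaf
        if self.normal_depth is None or self.normal_alt is None:
            return None
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0


@dataclass
class FilterDecision:
    """Outcome of a rule engine: status plus the rules that failed."""

    status: str  # PASS | TUMOR_ONLY | FAIL | NOT_EVALUABLE
    failed_rules: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status == "PASS" and self.failed_rules:
            raise ValueError("PASS decisions cannot carry failed rules")


def validate_indel(c: IndelCounts, config: PipelineConfig | None = None) -> FilterDecision:
    """Apply the consensus-count indel rules; see module docstring.

    The paired path runs when the normal meets the depth gate (strict
    ``> 5`` by default, switchable to ``>= 5`` via
    ``indel_paired_depth_strict``); otherwise the tumor-only path runs.
    """
    cfg = config or PipelineConfig()

    def depth_ok(depth: int) -> bool:
        if cfg.indel_paired_depth_strict:
            return depth > cfg.indel_min_depth
        return depth >= cfg.indel_min_depth

    normal_evaluable = (
        c.normal_depth is not None and c.normal_alt is not None and depth_ok(c.normal_depth)
    )
    failed: list[str] = []
    if normal_evaluable:
        if not depth_ok(c.tumor_depth):
            failed.append("indel_min_depth.tumor")
        if c.tumor_alt < cfg.indel_min_tumor_alt:
            failed.append("indel_min_tumor_alt")
        if c.normal_alt >= cfg.indel_max_normal_alt:
            failed.append("indel_max_normal_alt")
        if not c.t_vaf > cfg.indel_min_tumor_vaf:
            failed.append("indel_min_tumor_vaf")
        if not c.n_vaf < cfg.indel_max_normal_vaf:
            failed.append("indel_max_normal_vaf")
        return FilterDecision("PASS" if not failed else "FAIL", failed)
    # Tumor-only path: inclusive depth gate as printed ("(5 consensus reads)").
    if c.tumor_depth < cfg.indel_min_depth:
        failed.append("indel_min_depth.tumor_only")
    if c.tumor_alt < cfg.indel_tumor_only_min_alt:
        failed.append("indel_tumor_only_min_alt")
    if not c.t_vaf > cfg.indel_min_tumor_vaf:
        failed.append("indel_min_tumor_vaf")
    return FilterDecision("TUMOR_ONLY" if not failed else "FAIL", failed)


def filter_denovo(c: IndelCounts, config: PipelineConfig | None = None) -> FilterDecision:
    """Apply the de novo low-VAF filter to tumor/normal consensus stats.

    All five quantities must be available; PASS iff tumor depth >= 5 and
    normal depth >= 5 and normal VAF < 5% and tumor VAF > 0.5% and normal
    alt < 5 and tumor alt >= 2.
    """
    cfg = config or PipelineConfig()
    if c.normal_depth is None or c.normal_alt is None:
        return FilterDecision("NOT_EVALUABLE", ["denovo.normal_missing"])
    failed: list[str] = []
    if c.tumor_depth < cfg.denovo_min_depth:
        failed.append("denovo_min_depth.tumor")
    if c.normal_depth < cfg.denovo_min_depth:
        failed.append("denovo_min_depth.normal")
    if not c.n_vaf < cfg.denovo_max_normal_vaf:
        failed.append("denovo_max_normal_vaf")
    if not c.t_vaf > cfg.denovo_min_tumor_vaf:
        failed.append("denovo_min_tumor_vaf")
    if c.normal_alt > cfg.denovo_max_normal_alt:
        failed.append("denovo_max_normal_alt")
    if c.tumor_alt < cfg.denovo_min_tumor_alt:
        failed.append("denovo_min_tumor_alt")
    return FilterDecision("PASS" if not failed else "FAIL", failed)


#: Protein-altering consequence classes kept by default.
DEFAULT_KEEP_CLASSES = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift",
        "inframe_insertion",
        "inframe_deletion",
        "splice_donor",
        "splice_acceptor",
    }
)

_KNOWN_CLASSES = DEFAULT_KEEP_CLASSES | {
    "synonymous",
    "intron",
    "intergenic",
    "utr_5_prime",
    "utr_3_prime",
    "upstream",
    "downstream",
    "non_coding",
}


def _normalise_consequence(term: str) -> str:
    term = term.strip().lower().replace(" ", "_")
    for suffix in ("_variant", "_mutation"):
        if term.endswith(suffix):
            term = term[: -len(suffix)]
    return term


def filter_consequence(
    variants: Sequence[VariantCall], keep_classes: Iterable[str] | None = None
) -> list[VariantCall]:
    """Keep protein-altering variants by consequence class.

    Unknown consequence terms are dropped with a warning (conservative:
    anything unrecognised is not carried into downstream analyses).
    """
    keep = frozenset(map(_normalise_consequence, keep_classes or DEFAULT_KEEP_CLASSES))
    kept = []
    for v in variants:
        term = _normalise_consequence(v.consequence)
        if term in keep:
            kept.append(v)
        elif term not in _KNOWN_CLASSES:
            logger.warning("unknown consequence %r on %s; dropped", v.consequence, v.site)
    return kept


def remove_known(
    variants: Sequence[VariantCall], known: Sequence[VariantCall]
) -> list[VariantCall]:
    """Drop variants already discovered elsewhere (exact key matches).

    Keys are (sample, chrom, pos, ref, alt); both lists must be normalised
    (left-aligned, decomposed) for exact matching to be meaningful.  Input
    order is preserved.
    """
    known_keys = {v.key for v in known}
    return [v for v in variants if v.key not in known_keys]


def load_allowlist(path) -> set:
    """Read an allowlist TSV (sample_id chrom pos ref alt) of rescued sites.

    Variants on the allowlist are kept regardless of filter outcome; this
    stands in for the manual review that rescued individual sites.
    """
    keys = set()
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            keys.add((parts[0], parts[1], int(parts[2]), parts[3], parts[4]))
    return keys
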