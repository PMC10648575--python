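"""Readers and writers for the standard formats the pipeline shares.

VCF 4.x in/out via pysam, BED target regions, TSV reports and sample
metadata, FASTA gene sequences via pyfaidx.  Internal positions are
1-based; BED is converted at this boundary only.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta

from .model import GenomicSite, SampleMeta, TargetRegions, VariantCall

logger = logging.getLogger(__name__)

__all__ = [
    "read_variants",
    "write_variants",
    "intersect_targets",
    "read_target_regions",
    "write_target_regions",
    "read_sample_metadata",
    "write_report",
    "read_report",
    "read_fasta",
    "write_fasta",
]


def _record_vaf_depth(rec: pysam.VariantRecord, alt_index: int) -> tuple[float, int, int]:
    """Extract (vaf, depth, alt_reads) from FORMAT of the first sample or INFO."""

    def _pick(container) -> tuple[float | None, int | None, int | None]:
        vaf = depth = alt_reads = None
        if "AF" in container:
            af = container["AF"]
            vaf = float(af[alt_index] if isinstance(af, tuple) else af)
        if "DP" in container:
            dp = container["DP"]
            depth = int(dp[0] if isinstance(dp, tuple) else dp)
        if "AD" in container:
            ad = container["AD"]
            if isinstance(ad, tuple):
                # VCF convention: AD = (ref, alt1, alt2, ...)
                alt_reads = int(ad[alt_index + 1]) if len(ad) > alt_index + 1 else int(ad[0])
            else:
                alt_reads = int(ad)
        return vaf, depth, alt_reads

    vaf = depth = alt_reads = None
    if rec.samples:
        vaf, depth, alt_reads = _pick(rec.samples[0])
    if vaf is None and depth is None and alt_reads is None:
        vaf, depth, alt_reads = _pick(rec.info)
    if depth is None:
        depth = 0
    if alt_reads is None:
        alt_reads = 0
    if vaf is None:
        vaf = alt_reads / depth if depth else 0.0
    return vaf, depth, alt_reads


def read_variants(path, sample_id: str, decompose: bool = True) -> list[VariantCall]:
    """Read a VCF into :class:`VariantCall` records for one sample.

    Multi-allelic records are decomposed into one call per alternate allele
    when ``decompose`` is true, and rejected otherwise.  Output is sorted by
    (chrom, pos, alt) for determinism.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) > 1 and not decompose:
                raise ValueError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos} requires decompose=True"
                )
            for i, alt in enumerate(alts):
                if alt is None or set(alt) - set("ACGT"):
                    logger.warning("skipping symbolic/non-ACGT alt %r at %s:%d",
                                   alt, rec.chrom, rec.pos)
                    continue
                site = GenomicSite(rec.chrom, rec.pos, rec.ref, alt)
                vaf, depth, alt_reads = _record_vaf_depth(rec, i)
                gene = str(rec.info.get("GENE", "") or "")
                csq = str(rec.info.get("CSQ", "") or "")
                calls.append(
                    VariantCall(
                        site=site,
                        sample_id=sample_id,
                        gene=gene,
                        consequence=csq,
                        tumor_vaf=vaf,
                        tumor_depth=depth,
                        alt_reads=alt_reads,
                    )
                )
    calls.sort(key=lambda v: (v.site.chrom, v.site.pos, v.site.alt))
    return calls


def write_variants(calls: Sequence[VariantCall], path, sample_id: str | None = None) -> None:
    """Write calls as a single-sample VCF 4.2 with AF/DP/AD in FORMAT."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">')
    header.add_line('##FORMAT=<ID=AF,Number=A,Type=Float,Description="Variant allele fraction">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for chrom in sorted({c.site.chrom for c in calls}):
        header.add_line(f"##contig=<ID={chrom}>")
    name = sample_id or (calls[0].sample_id if calls else "SAMPLE")
    header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda v: (v.site.chrom, v.site.pos, v.site.alt)):
            rec = out.new_record(
                contig=call.site.chrom,
                start=call.site.pos - 1,
                stop=call.site.pos - 1 + len(call.site.ref),
                alleles=(call.site.ref, call.site.alt),
            )
            if call.gene:
                rec.info["GENE"] = call.gene
            if call.consequence:
                rec.info["CSQ"] = call.consequence
            sample = rec.samples[name]
            sample["AF"] = (call.tumor_vaf,)
            sample["DP"] = call.tumor_depth
            sample["AD"] = (call.tumor_depth - call.alt_reads, call.alt_reads)
            out.write(rec)


def intersect_targets(
    variants: Sequence[VariantCall], regions: TargetRegions
) -> list[VariantCall]:
    """Keep variants whose position falls inside the target space.

    Variants on chromosomes absent from ``regions`` are dropped with a
    logged warning so that partial panels still run.
    """
    kept: list[VariantCall] = []
    known = set(regions.chroms)
    for v in variants:
        if v.site.chrom not in known:
            logger.warning("variant %s on chromosome absent from targets; dropped", v.site)
            continue
        if regions.contains(v.site.chrom, v.site.pos):
            kept.append(v)
    return kept


def read_target_regions(path, label: str = "") -> TargetRegions:
    """Read a BED3+ file into merged :class:`TargetRegions`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad BED coordinates") from exc
    return TargetRegions(intervals, label=label or Path(str(path)).stem)


def write_target_regions(regions: TargetRegions, path) -> None:
    with open(path, "w") as fh:
        for chrom in regions.chroms:
            for start, end in regions.intervals(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_sample_metadata(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    metas = []
    for row in df.itertuples(index=False):
        count = getattr(row, "mutation_count", "")
        metas.append(
            SampleMeta(
                sample_id=row.sample_id,
                patient_id=row.patient_id,
                tissue=row.tissue,
                ebv_eber=getattr(row, "ebv_eber", "unknown") or "unknown",
                relapse=str(getattr(row, "relapse", "")).lower() in ("1", "true", "yes"),
                mutation_count=int(count) if str(count).strip() else None,
            )
        )
    return metas


def _as_records(results: Iterable) -> list[dict]:
    records = []
    for item in results:
        if dataclasses.is_dataclass(item) and not isinstance(item, type):
            rec = {}
            for f in dataclasses.fields(item):
                value = getattr(item, f.name)
                rec[f.name] = str(value) if isinstance(value, (tuple, list, set)) else value
            records.append(rec)
        elif isinstance(item, dict):
            records.append(item)
        else:
            raise TypeError(f"cannot serialise {type(item).__name__} as a flat record")
    return records


def write_report(results, path) -> None:
    """Write any stage output as a TSV with header; round-trips losslessly."""
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        records = _as_records(results)
        df = pd.DataFrame.from_records(records)
    df.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    fa = Fasta(str(path), sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
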