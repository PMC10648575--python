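"""Iterative Fisher exact background-noise validation of candidate SNVs.

The core statistic of the pipeline.  At each candidate site, the
foreground sample's (alt, ref) error-corrected counts are compared by a
one-sided Fisher exact test against the pooled (alt, ref) counts at that
site across all other samples — the empirical background error of the
assay at that exact position, which absorbs context- and position-specific
error without an explicit noise model.

Testing is iterative: within each round every not-yet-retained candidate
is tested, the round's p values are Holm-adjusted as one family, and
candidates with adjusted p below ``retain_alpha`` (0.1) are retained and
excluded from later background pools (a true variant in one sample must
not inflate the background used to judge another).  Rounds repeat until
none is retained.  Retained candidates whose adjusted p is at or below
``final_alpha`` (0.05) are carried forward.

Final SNV status additionally gates on error-corrected depth (>= 100 in
tumor and normal) and requires the matched normal to be quiet (adjusted
p > 0.05); when the normal lacks depth, a significant tumor site is
classified "tumor-only".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .model import PipelineConfig, SiteCountTable, SiteKey

logger = logging.getLogger(__name__)

__all__ = [
    "FisherRecord",
    "ValidationOutcome",
    "fisher_site_test",
    "fisher_one_sided",
    "holm_adjust",
    "iterate_validation",
    "classify_snv",
    "validate_cohort",
]


@dataclass
class FisherRecord:
    """One Fisher test: foreground (alt, ref) vs pooled background."""

    sample_id: str
    site: SiteKey
    table: tuple  # ((alt_fg, ref_fg), (alt_bg, ref_bg))
    p_raw: float
    p_adj: float = float("nan")
    iteration: int = 1


@dataclass
class ValidationOutcome:
    """Final per-candidate status after classification.

    ``status`` is one of PASS, TUMOR_ONLY, FAIL, LOW_DEPTH, NOT_ASSAYED.
    """

    sample_id: str
    site: SiteKey
    status: str
    tumor_p_adj: float = float("nan")
    normal_p_adj: float = float("nan")
    tumor_depth: int = 0
    normal_depth: int | None = None


def fisher_one_sided(alt_fg: int, ref_fg: int, alt_bg: int, ref_bg: int) -> float:
    """One-sided Fisher exact p toward alt enrichment in the foreground.

    Equal to ``scipy.stats.fisher_exact([[alt_fg, ref_fg], [alt_bg, ref_bg]],
    alternative="greater")[1]`` but computed from the hypergeometric survival
    function so it vectorises.
    """
    return float(_fisher_greater(np.array([alt_fg]), np.array([ref_fg]),
                                 np.array([alt_bg]), np.array([ref_bg]))[0])


def _fisher_greater(alt_fg, ref_fg, alt_bg, ref_bg) -> np.ndarray:
    """Vectorised one-sided (greater) Fisher p over parallel count arrays."""
    alt_fg = np.asarray(alt_fg, dtype=np.int64)
    ref_fg = np.asarray(ref_fg, dtype=np.int64)
    alt_bg = np.asarray(alt_bg, dtype=np.int64)
    ref_bg = np.asarray(ref_bg, dtype=np.int64)
    total = alt_fg + ref_fg + alt_bg + ref_bg
    n_alt = alt_fg + alt_bg
    n_fg = alt_fg + ref_fg
    # P(X >= alt_fg) for X ~ Hypergeom(total, n_alt, n_fg); a foreground
    # with zero alt reads sits at the bottom of the one-sided tail (p = 1),
    # which also covers degenerate empty tables.
    p = hypergeom.sf(alt_fg - 1, total, n_alt, n_fg)
    return np.where(alt_fg == 0, 1.0, np.minimum(p, 1.0))


def _background(
    counts: SiteCountTable,
    sample_id: str,
    site: SiteKey,
    excluded: frozenset | set = frozenset(),
) -> tuple[int, int, int]:
    """(alt_bg, ref_bg, n_contributing) pooled over all other samples."""
    chrom, pos, ref, alt = site
    df = counts.df
    m = (
        (df["chrom"] == chrom)
        & (df["pos"] == pos)
        & (df["ref"] == ref)
        & (df["alt"] == alt)
        & (df["sample_id"] != sample_id)
    )
    rows = df[m]
    alt_bg = ref_bg = 0
    n = 0
    for row in rows.itertuples(index=False):
        if (row.sample_id, site) in excluded:
            continue
        alt_bg += row.alt_count
        ref_bg += row.ref_count
        n += 1
    return alt_bg, ref_bg, n


def fisher_site_test(
    counts: SiteCountTable,
    sample_id: str,
    site: SiteKey,
    excluded: frozenset | set = frozenset(),
    iteration: int = 1,
) -> FisherRecord:
    """Test one (sample, site) against the pooled background of all others.

    ``excluded`` (sample, site) pairs — previously retained variants — are
    omitted from the background pool.  Raises if no other sample
    contributes background at the site.
    """
    ref_fg, alt_fg, _ = counts.get(sample_id, site)
    alt_bg, ref_bg, n_contrib = _background(counts, sample_id, site, excluded)
    if n_contrib == 0:
        raise ValueError(f"empty background pool at site {site} for {sample_id}")
    p = fisher_one_sided(alt_fg, ref_fg, alt_bg, ref_bg)
    return FisherRecord(
        sample_id=sample_id,
        site=site,
        table=((alt_fg, ref_fg), (alt_bg, ref_bg)),
        p_raw=p,
        iteration=iteration,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p values, in the input order.

    Sort ascending; ``adj_(i) = max_{j<=i} (m - j + 1) * p_(j)`` capped at
    1; map back.  Adjusted values never fall below the raw ones.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    adj = np.empty(m, dtype=float)
    adj[order] = adj_sorted
    return adj.tolist()


class _CountMatrices:
    """Dense per-(sample, site) count matrices for fast round-wise testing."""

    def __init__(self, counts: SiteCountTable):
        df = counts.df
        self.samples = sorted(df["sample_id"].unique())
        site_keys = df[["chrom", "pos", "ref", "alt"]].apply(tuple, axis=1)
        self.sites = sorted(site_keys.unique())
        self.sample_idx = {s: i for i, s in enumerate(self.samples)}
        self.site_idx = {s: j for j, s in enumerate(self.sites)}
        n, k = len(self.samples), len(self.sites)
        self.alt = np.zeros((n, k), dtype=np.int64)
        self.ref = np.zeros((n, k), dtype=np.int64)
        self.other = np.zeros((n, k), dtype=np.int64)
        self.present = np.zeros((n, k), dtype=bool)
        rows = df.itertuples(index=False)
        for row, key in zip(rows, site_keys):
            i = self.sample_idx[row.sample_id]
            j = self.site_idx[key]
            self.alt[i, j] = row.alt_count
            self.ref[i, j] = row.ref_count
            self.other[i, j] = row.other_count
            self.present[i, j] = True
        self.alt_site_sum = self.alt.sum(axis=0)
        self.ref_site_sum = self.ref.sum(axis=0)
        self.present_site_sum = self.present.sum(axis=0)


def iterate_validation(
    counts: SiteCountTable,
    candidates: Sequence[tuple],
    retain_alpha: float = 0.1,
    final_alpha: float = 0.05,
) -> tuple[set, list[FisherRecord]]:
    """Run the iterative background test over all candidate (sample, site) pairs.

    Returns ``(carried_forward, log)``: the set of candidates retained with
    adjusted p <= ``final_alpha`` in the round where each was retained, and
    the full log of every Fisher test with its round index.

    Round ``r`` tests every not-yet-retained candidate against the pooled
    background excluding all previously retained (sample, site) pairs,
    Holm-adjusts within the round, and retains adjusted p < ``retain_alpha``.
    Iteration stops when a round retains nothing.  Termination is
    guaranteed (the retained set strictly grows, bounded by the candidate
    count); a guard raises beyond ``len(candidates)`` rounds.
    """
    candidates = list(dict.fromkeys(candidates))  # dedupe, keep order
    if not candidates:
        return set(), []
    mats = _CountMatrices(counts)
    for sample_id, site in candidates:
        if sample_id not in mats.sample_idx or site not in mats.site_idx:
            raise KeyError(f"candidate ({sample_id}, {site}) absent from count table")
        if not mats.present[mats.sample_idx[sample_id], mats.site_idx[site]]:
            raise KeyError(f"candidate ({sample_id}, {site}) absent from count table")
    if len(mats.samples) < 2:
        raise ValueError("background pooling requires at least 2 samples")

    # Per-site alt/ref removed from the pool by retained pairs.
    excl_alt = np.zeros(len(mats.sites), dtype=np.int64)
    excl_ref = np.zeros(len(mats.sites), dtype=np.int64)

    retained: dict[tuple, FisherRecord] = {}
    log: list[FisherRecord] = []
    max_rounds = len(candidates) + 1
    for round_idx in range(1, max_rounds + 1):
        remaining = [c for c in candidates if c not in retained]
        if not remaining:
            break
        si = np.array([mats.sample_idx[s] for s, _ in remaining])
        sj = np.array([mats.site_idx[site] for _, site in remaining])
        alt_fg = mats.alt[si, sj]
        ref_fg = mats.ref[si, sj]
        n_contrib = mats.present_site_sum[sj] - mats.present[si, sj].astype(int)
        if np.any(n_contrib == 0):
            bad = remaining[int(np.argmax(n_contrib == 0))]
            raise ValueError(f"empty background pool at site {bad[1]} for {bad[0]}")
        alt_bg = mats.alt_site_sum[sj] - alt_fg - excl_alt[sj]
        ref_bg = mats.ref_site_sum[sj] - ref_fg - excl_ref[sj]
        p_raw = _fisher_greater(alt_fg, ref_fg, alt_bg, ref_bg)
        p_adj = holm_adjust(p_raw)
        newly: list[tuple] = []
        for idx, cand in enumerate(remaining):
            rec = FisherRecord(
                sample_id=cand[0],
                site=cand[1],
                table=(
                    (int(alt_fg[idx]), int(ref_fg[idx])),
                    (int(alt_bg[idx]), int(ref_bg[idx])),
                ),
                p_raw=float(p_raw[idx]),
                p_adj=float(p_adj[idx]),
                iteration=round_idx,
            )
            log.append(rec)
            if rec.p_adj < retain_alpha:
                retained[cand] = rec
                newly.append(cand)
        if not newly:
            break
        for sample_id, site in newly:
            i, j = mats.sample_idx[sample_id], mats.site_idx[site]
            excl_alt[j] += mats.alt[i, j]
            excl_ref[j] += mats.ref[i, j]
    else:
        raise RuntimeError("iteration cap exceeded; retained set failed to stabilise")

    carried = {c for c, rec in retained.items() if rec.p_adj <= final_alpha}
    return carried, log


def classify_snv(
    sample_id: str,
    site: SiteKey,
    tumor_depth: int | None,
    tumor_p_adj: float,
    normal_depth: int | None,
    normal_p_adj: float | None,
    config: PipelineConfig | None = None,
) -> ValidationOutcome:
    """Classify one candidate SNV from its depths and adjusted p values.

    LOW_DEPTH if the tumor lacks the depth gate; NOT_ASSAYED if the tumor
    was not assayed at all.  With an evaluable normal (depth >= gate): PASS
    iff tumor adjusted p <= final_alpha and normal adjusted p >
    normal_alpha, else FAIL.  Without an evaluable normal: TUMOR_ONLY iff
    tumor adjusted p <= final_alpha, else FAIL.
    """
    cfg = config or PipelineConfig()
    if tumor_depth is None:
        return ValidationOutcome(sample_id, site, "NOT_ASSAYED")
    if tumor_depth < cfg.min_validation_depth:
        return ValidationOutcome(
            sample_id, site, "LOW_DEPTH",
            tumor_p_adj=tumor_p_adj, tumor_depth=tumor_depth, normal_depth=normal_depth,
        )
    normal_evaluable = (
        normal_depth is not None and normal_depth >= cfg.min_validation_depth
        and normal_p_adj is not None and not np.isnan(normal_p_adj)
    )
    tumor_significant = tumor_p_adj <= cfg.final_alpha
    if normal_evaluable:
        status = "PASS" if tumor_significant and normal_p_adj > cfg.normal_alpha else "FAIL"
    else:
        status = "TUMOR_ONLY" if tumor_significant else "FAIL"
    return ValidationOutcome(
        sample_id, site, status,
        tumor_p_adj=tumor_p_adj,
        normal_p_adj=float("nan") if not normal_evaluable else float(normal_p_adj),
        tumor_depth=tumor_depth,
        normal_depth=normal_depth,
    )


def validate_cohort(
    counts: SiteCountTable,
    candidates: Sequence[tuple],
    pair_map: dict,
    config: PipelineConfig | None = None,
) -> tuple[list[ValidationOutcome], list[FisherRecord]]:
    """End-to-end SNV validation: iterate, test matched normals, classify.

    ``candidates`` are (tumor_sample, site) pairs; ``pair_map`` maps each
    tumor sample to its matched normal (value ``None`` when no normal was
    sequenced).  The count table holds tumors and normals together so the
    background pool spans all samples.  After iteration, each candidate's
    matched normal is tested once against the background excluding all
    retained pairs, Holm-adjusted across those normal tests as one family.
    """
    cfg = config or PipelineConfig()
    carried, log = iterate_validation(
        counts, candidates, retain_alpha=cfg.retain_alpha, final_alpha=cfg.final_alpha
    )
    # Tumor adjusted p = the adjusted p from the last round each was tested.
    last_rec: dict[tuple, FisherRecord] = {}
    for rec in log:
        last_rec[(rec.sample_id, rec.site)] = rec
    retained_pairs = {
        (rec.sample_id, rec.site) for rec in log
        if rec.p_adj < cfg.retain_alpha
    }
    normal_tests: list[tuple[tuple, FisherRecord]] = []
    for cand in candidates:
        tumor_sample, site = cand
        normal_sample = pair_map.get(tumor_sample)
        if normal_sample is None or not counts.has(normal_sample, site):
            continue
        r, a, o = counts.get(normal_sample, site)
        if r + a + o < cfg.min_validation_depth:
            continue
        rec = fisher_site_test(counts, normal_sample, site, excluded=retained_pairs)
        normal_tests.append((cand, rec))
    if normal_tests:
        adj = holm_adjust([rec.p_raw for _, rec in normal_tests])
        for (cand, rec), p in zip(normal_tests, adj):
            rec.p_adj = p
    normal_by_cand = {cand: rec for cand, rec in normal_tests}

    outcomes = []
    for cand in candidates:
        tumor_sample, site = cand
        tumor_depth = counts.depth(tumor_sample, site) if counts.has(tumor_sample, site) else None
        tumor_rec = last_rec.get(cand)
        tumor_p = tumor_rec.p_adj if tumor_rec is not None else float("nan")
        normal_sample = pair_map.get(tumor_sample)
        normal_depth = (
            counts.depth(normal_sample, site)
            if normal_sample is not None and counts.has(normal_sample, site)
            else None
        )
        normal_rec = normal_by_cand.get(cand)
        normal_p = normal_rec.p_adj if normal_rec is not None else None
        outcomes.append(
            classify_snv(tumor_sample, site, tumor_depth, tumor_p, normal_depth, normal_p, cfg)
        )
    return outcomes, log
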