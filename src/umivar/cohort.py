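"""Cohort-level statistics: EBV status, burden comparison, co-occurrence.

EBV positivity is called from competitive-alignment read summaries (reads
aligned to the EBV reference at high mapping quality); the call is
compared with the clinical EBER in situ hybridisation label in a
concordance table.  Mutation burden is compared between groups with a
two-tailed t test.  Pairwise gene co-occurrence across samples is tested
with two-sided Fisher exact tests and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import PipelineConfig

__all__ = [
    "EbvCall",
    "PairAssociation",
    "classify_ebv",
    "concordance",
    "burden_test",
    "cooccurrence",
]


@dataclass(frozen=True)
class EbvCall:
    """EBV positivity call for one sample from alignment summaries."""

    sample_id: str
    positive: bool
    supporting_reads: int


@dataclass
class PairAssociation:
    """Pairwise gene association across samples.

    ``table`` is (both, a_only, b_only, neither); ``direction`` is
    "co-occurrence" when the odds ratio exceeds 1, "exclusivity" when it is
    below 1, "none" otherwise.
    """

    gene_a: str
    gene_b: str
    table: tuple
    p: float
    fdr: float = float("nan")
    direction: str = "none"


def classify_ebv(
    reads: Iterable[tuple] | pd.DataFrame,
    config: PipelineConfig | None = None,
    sample_id: str = "",
) -> EbvCall:
    """Call EBV positivity from per-read (reference_label, mapq) summaries.

    A sample is positive when at least ``ebv_min_reads`` (2) reads aligned
    to the EBV reference with mapping quality >= ``ebv_min_mapq`` (60).
    """
    cfg = config or PipelineConfig()
    if isinstance(reads, pd.DataFrame):
        pairs = zip(reads["reference_label"], reads["mapq"])
    else:
        pairs = iter(reads)
    supporting = sum(
        1 for label, mapq in pairs if label == "EBV" and mapq >= cfg.ebv_min_mapq
    )
    return EbvCall(
        sample_id=sample_id,
        positive=supporting >= cfg.ebv_min_reads,
        supporting_reads=supporting,
    )


def concordance(eber: Mapping[str, bool], alignment: Mapping[str, bool]) -> dict:
    """Confusion table between EBER ISH labels and alignment-based calls.

    Returns counts and per-cell sample lists for the four cells
    both_positive / eber_only / alignment_only / both_negative.
    """
    if set(eber) != set(alignment):
        raise ValueError("EBER and alignment labels cover different samples")
    cells = {
        "both_positive": [],
        "eber_only": [],
        "alignment_only": [],
        "both_negative": [],
    }
    for sample in sorted(eber):
        e, a = bool(eber[sample]), bool(alignment[sample])
        if e and a:
            cells["both_positive"].append(sample)
        elif e:
            cells["eber_only"].append(sample)
        elif a:
            cells["alignment_only"].append(sample)
        else:
            cells["both_negative"].append(sample)
    out = {f"n_{k}": len(v) for k, v in cells.items()}
    out.update(cells)
    return out


def burden_test(
    counts: Sequence[float], groups: Sequence, equal_var: bool = True
) -> tuple[float, float]:
    """Two-tailed two-sample t test of mutation burden between two groups.

    ``groups`` holds two distinct labels; each group needs >= 2 samples.
    Student's equal-variance t by default (``equal_var=False`` gives
    Welch).  Zero variance in both groups with equal means returns
    (0.0, 1.0) by convention; with different means the p is 0.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels}")
    a = counts[groups == labels[0]]
    b = counts[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def cooccurrence(matrix: pd.DataFrame) -> list[PairAssociation]:
    """Pairwise co-occurrence / mutual-exclusivity tests over a gene x sample matrix.

    ``matrix`` rows are genes, columns samples, entries truthy when the
    gene is mutated in the sample.  For each unordered gene pair a
    two-sided Fisher exact test is run on the 2x2 sample table, and
    Benjamini-Hochberg q values are computed across all pairs.  Degenerate
    margins (a gene mutated in no or all samples) give p = 1.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    m = matrix.astype(bool)
    results: list[PairAssociation] = []
    for gene_a, gene_b in combinations(m.index, 2):
        va, vb = m.loc[gene_a], m.loc[gene_b]
        both = int((va & vb).sum())
        a_only = int((va & ~vb).sum())
        b_only = int((~va & vb).sum())
        neither = int((~va & ~vb).sum())
        odds, p = stats.fisher_exact(
            [[both, a_only], [b_only, neither]], alternative="two-sided"
        )
        cross = both * neither
        anti = a_only * b_only
        direction = (
            "co-occurrence" if cross > anti else "exclusivity" if cross < anti else "none"
        )
        results.append(
            PairAssociation(
                gene_a=gene_a,
                gene_b=gene_b,
                table=(both, a_only, b_only, neither),
                p=float(p),
                direction=direction,
            )
        )
    if results:
        _, q, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.fdr = float(qv)
    return results
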