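"""AID hotspot motif scanning and random-placement enrichment tests.

Activation-induced cytidine deaminase (AID) preferentially mutates the C
of WRC trinucleotides (W = A/T, R = A/G) and, equivalently on the other
strand, the G of GYW trinucleotides (Y = C/T): GYW is the
reverse-complement image of WRC, so scanning both patterns on the forward
strand covers both strands.

Enrichment of observed mutations in these motifs is measured by an
empirical permutation test: each replicate places the gene's mutation
count uniformly at random (distinct positions) over the placement space
and counts how many land in motifs; the empirical tail p is the fraction
of replicates with at least the observed hit count.  A cohort-level test
sums hits across genes per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MotifIndex",
    "PermutationResult",
    "scan_motifs",
    "count_motif_hits",
    "permutation_test",
    "cohort_total_test",
    "restrict_to_cg",
]

_W = frozenset("AT")
_R = frozenset("AG")
_Y = frozenset("CT")


@dataclass(frozen=True)
class MotifIndex:
    """Motif positions of one gene sequence plus its placement space.

    ``motif_positions`` holds 1-based positions of the C of each WRC match
    and the G of each GYW match.  ``placement_space`` (sorted 1-based
    positions) restricts where simulated mutations may land — by default
    the whole sequence; ``motif_fraction`` is the motif density within it.
    """

    gene: str
    sequence: str
    motif_positions: frozenset
    placement_space: tuple
    motif_fraction: float


@dataclass(frozen=True)
class PermutationResult:
    """Empirical enrichment test result for one gene (or the cohort total)."""

    gene: str
    n_mut: int
    observed: int
    n_perm: int
    count_ge: int
    p_empirical: float
    mean_sim: float
    seed: int


def scan_motifs(
    sequence: str, gene: str = "", placement_space: Iterable[int] | None = None
) -> MotifIndex:
    """Scan a sequence for WRC/GYW motif positions.

    Position ``p`` (1-based) is a motif position iff ``sequence[p-3:p]``
    matches WRC (p is the C) or ``sequence[p-1:p+2]`` matches GYW (p is the
    G).  ``N`` never matches.  A position matching both patterns is counted
    once.  Sequences shorter than 3 yield an empty index.
    """
    seq = sequence.upper()
    positions: set[int] = set()
    for i in range(len(seq) - 2):
        a, b, c = seq[i], seq[i + 1], seq[i + 2]
        if c == "C" and a in _W and b in _R:
            positions.add(i + 3)  # the C, 1-based
        if a == "G" and b in _Y and c in _W:
            positions.add(i + 1)  # the G, 1-based
    if placement_space is None:
        space = tuple(range(1, len(seq) + 1))
    else:
        space = tuple(sorted(set(int(p) for p in placement_space)))
        if space and (space[0] < 1 or space[-1] > len(seq)):
            raise ValueError("placement_space positions outside the sequence")
    in_space = positions.intersection(space)
    fraction = len(in_space) / len(space) if space else 0.0
    return MotifIndex(
        gene=gene,
        sequence=seq,
        motif_positions=frozenset(positions),
        placement_space=space,
        motif_fraction=fraction,
    )


def restrict_to_cg(index: MotifIndex) -> MotifIndex:
    """Restrict the placement space to C/G base positions.

    Emulates testing C-to-T/G substitution enrichment specifically: both
    the simulated placements and the achievable motif hits are confined to
    cytosine/guanine positions.
    """
    cg = [p for p in index.placement_space if index.sequence[p - 1] in "CG"]
    return scan_motifs(index.sequence, gene=index.gene, placement_space=cg)


def count_motif_hits(positions: Iterable[int], index: MotifIndex) -> int:
    """Count how many of the given 1-based positions fall in motifs.

    Duplicates are counted per occurrence; positions outside the sequence
    raise.
    """
    total = 0
    length = len(index.sequence)
    for p in positions:
        if not 1 <= p <= length:
            raise ValueError(f"position {p} outside sequence of length {length}")
        if p in index.motif_positions:
            total += 1
    return total


def _simulate_hits(
    mask: np.ndarray, n_mut: int, n_perm: int, rng: np.random.Generator,
    batch_cells: int = 20_000_000,
) -> np.ndarray:
    """Hit counts of ``n_perm`` uniform distinct placements of ``n_mut``.

    Each replicate draws ``n_mut`` distinct indices uniformly from the
    space (random-key top-k over batches, memory-bounded) and counts how
    many land on masked (motif) positions.
    """
    n_space = mask.size
    if n_mut == n_space:
        return np.full(n_perm, int(mask.sum()), dtype=np.int64)
    hits = np.empty(n_perm, dtype=np.int64)
    batch = max(1, batch_cells // max(n_space, 1))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        keys = rng.random((b, n_space))
        idx = np.argpartition(keys, n_mut - 1, axis=1)[:, :n_mut]
        hits[done : done + b] = mask[idx].sum(axis=1)
        done += b
    return hits


def permutation_test(
    index: MotifIndex,
    n_mut: int,
    observed: int,
    n_perm: int = 100_000,
    seed: int = 0,
    add_one: bool = False,
) -> PermutationResult:
    """Empirical tail test of motif-hit enrichment for one gene.

    ``p_empirical = count_ge / n_perm`` (the fraction of replicates with at
    least ``observed`` hits); with ``add_one`` the
    ``(count_ge + 1) / (n_perm + 1)`` estimator is used instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed > n_mut:
        raise ValueError(f"observed hits {observed} exceed n_mut {n_mut}")
    space = np.asarray(index.placement_space, dtype=np.int64)
    if n_mut > space.size:
        raise ValueError(f"n_mut {n_mut} exceeds placement space size {space.size}")
    mask = np.isin(space, np.fromiter(index.motif_positions, dtype=np.int64, count=len(index.motif_positions)) if index.motif_positions else np.empty(0, dtype=np.int64))
    rng = np.random.default_rng(seed)
    hits = _simulate_hits(mask, n_mut, n_perm, rng)
    count_ge = int((hits >= observed).sum())
    p = (count_ge + 1) / (n_perm + 1) if add_one else count_ge / n_perm
    return PermutationResult(
        gene=index.gene,
        n_mut=n_mut,
        observed=observed,
        n_perm=n_perm,
        count_ge=count_ge,
        p_empirical=float(p),
        mean_sim=float(hits.mean()),
        seed=seed,
    )


def cohort_total_test(
    indexes: Mapping[str, MotifIndex],
    per_gene_n_mut: Mapping[str, int],
    observed_total: int,
    n_perm: int = 100_000,
    seed: int = 0,
    add_one: bool = False,
) -> PermutationResult:
    """Cohort-level test: place each gene's mutations independently, sum hits.

    ``mean_sim`` reports the expected total motif-hit count under random
    placement; ``p_empirical`` the fraction of replicates whose summed hits
    reach ``observed_total``.
    """
    missing = set(per_gene_n_mut) - set(indexes)
    if missing:
        raise KeyError(f"genes without a motif index: {sorted(missing)}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    totals = np.zeros(n_perm, dtype=np.int64)
    total_n_mut = 0
    for gene in sorted(per_gene_n_mut):
        n_mut = per_gene_n_mut[gene]
        if n_mut == 0:
            continue
        index = indexes[gene]
        space = np.asarray(index.placement_space, dtype=np.int64)
        if n_mut > space.size:
            raise ValueError(f"{gene}: n_mut {n_mut} exceeds placement space")
        mask = np.isin(space, np.fromiter(index.motif_positions, dtype=np.int64, count=len(index.motif_positions)) if index.motif_positions else np.empty(0, dtype=np.int64))
        totals += _simulate_hits(mask, n_mut, n_perm, rng)
        total_n_mut += n_mut
    if observed_total > total_n_mut:
        raise ValueError("observed_total exceeds the summed mutation count")
    count_ge = int((totals >= observed_total).sum())
    p = (count_ge + 1) / (n_perm + 1) if add_one else count_ge / n_perm
    return PermutationResult(
        gene="cohort_total",
        n_mut=total_n_mut,
        observed=observed_total,
        n_perm=n_perm,
        count_ge=count_ge,
        p_empirical=float(p),
        mean_sim=float(totals.mean()),
        seed=seed,
    )
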