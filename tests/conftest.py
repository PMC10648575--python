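import numpy as np
import pandas as pd
import pytest

from umivar.model import GenomicSite, PipelineConfig, SiteCountTable


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def site() -> GenomicSite:
    return GenomicSite("chr1", 100, "A", "T")


def make_count_table(rows):
    """rows: (sample_id, chrom, pos, ref, alt, ref_count, alt_count[, other])."""
    records = []
    for row in rows:
        other = row[7] if len(row) > 7 else 0
        records.append(
            dict(
                sample_id=row[0], chrom=row[1], pos=row[2], ref=row[3], alt=row[4],
                ref_count=row[5], alt_count=row[6], other_count=other,
            )
        )
    return SiteCountTable(pd.DataFrame.from_records(records))


@pytest.fixture
def count_table_factory():
    return make_count_table


def random_count_instance(rng: np.random.Generator, max_samples=5, max_sites=12, max_count=50):
    """A random small cohort for oracle-equivalence checks.

    Alt counts are mostly small (background-like) with occasional large
    values (variant-like) so both retention and rejection paths exercise.
    """
    n_samples = int(rng.integers(2, max_samples + 1))
    n_sites = int(rng.integers(1, max_sites + 1))
    samples = [f"S{i}" for i in range(n_samples)]
    sites = [("chr1", 10 * (j + 1), "A", "T") for j in range(n_sites)]
    records = []
    for s in samples:
        for site in sites:
            ref = int(rng.integers(5, max_count + 1))
            alt = int(rng.integers(0, 4)) if rng.random() < 0.8 else int(rng.integers(0, max_count // 2))
            records.append(
                dict(sample_id=s, chrom=site[0], pos=site[1], ref=site[2], alt=site[3],
                     ref_count=ref, alt_count=alt, other_count=0)
            )
    table = SiteCountTable(pd.DataFrame.from_records(records))
    pairs = [(s, site) for s in samples for site in sites]
    k = int(rng.integers(1, len(pairs) + 1))
    chosen = rng.choice(len(pairs), size=k, replace=False)
    candidates = [pairs[i] for i in sorted(chosen)]
    return table, candidates
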