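"""The iterative Fisher background test against independent oracles.

The brute-force oracle below recomputes every round from scratch with
scipy.stats.fisher_exact and statsmodels' Holm adjustment, sharing no code
with the implementation under test.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from umivar.model import PipelineConfig
from umivar.validation import (
    classify_snv,
    fisher_one_sided,
    fisher_site_test,
    holm_adjust,
    iterate_validation,
    validate_cohort,
)

from conftest import make_count_table, random_count_instance


def brute_force_retained(table, candidates, retain_alpha=0.1, final_alpha=0.05):
    """From-scratch reference implementation of the iterative validation."""
    df = table.df
    retained = {}
    while True:
        remaining = [c for c in candidates if c not in retained]
        if not remaining:
            break
        ps = []
        for sample_id, site in remaining:
            chrom, pos, ref, alt = site
            at_site = df[(df.chrom == chrom) & (df.pos == pos) & (df.ref == ref) & (df.alt == alt)]
            fg = at_site[at_site.sample_id == sample_id].iloc[0]
            alt_bg = ref_bg = 0
            for row in at_site[at_site.sample_id != sample_id].itertuples(index=False):
                if (row.sample_id, site) in retained:
                    continue
                alt_bg += row.alt_count
                ref_bg += row.ref_count
            _, p = fisher_exact(
                [[fg.alt_count, fg.ref_count], [alt_bg, ref_bg]], alternative="greater"
            )
            ps.append(p)
        adj = multipletests(ps, method="holm")[1]
        newly = [c for c, a in zip(remaining, adj) if a < retain_alpha]
        for c, a in zip(remaining, adj):
            if a < retain_alpha:
                retained[c] = a
        if not newly:
            break
    return {c for c, a in retained.items() if a <= final_alpha}


class TestFisherSiteTest:
    def test_zero_alt_gives_p_one(self, count_table_factory):
        table = count_table_factory(
            [("s1", "chr1", 10, "A", "T", 100, 0), ("s2", "chr1", 10, "A", "T", 500, 3)]
        )
        rec = fisher_site_test(table, "s1", ("chr1", 10, "A", "T"))
        assert rec.p_raw == pytest.approx(1.0)

    def test_enriched_foreground_is_significant(self, count_table_factory):
        table = count_table_factory(
            [("s1", "chr1", 10, "A", "T", 95, 5), ("s2", "chr1", 10, "A", "T", 2000, 2)]
        )
        rec = fisher_site_test(table, "s1", ("chr1", 10, "A", "T"))
        assert rec.p_raw < 1e-4
        assert rec.table == ((5, 95), (2, 2000))

    def test_background_level_foreground_not_significant(self, count_table_factory):
        table = count_table_factory(
            [("s1", "chr1", 10, "A", "T", 999, 1), ("s2", "chr1", 10, "A", "T", 9990, 10)]
        )
        rec = fisher_site_test(table, "s1", ("chr1", 10, "A", "T"))
        assert rec.p_raw > 0.3

    def test_empty_background_raises_naming_site(self, count_table_factory):
        table = count_table_factory(
            [("s1", "chr1", 10, "A", "T", 100, 2), ("s2", "chr1", 10, "A", "T", 200, 1),
             ("s1", "chr1", 20, "A", "T", 100, 2)]
        )
        with pytest.raises(ValueError, match="20"):
            fisher_site_test(table, "s1", ("chr1", 20, "A", "T"))

    def test_excluded_pairs_leave_background(self, count_table_factory):
        table = count_table_factory(
            [("s1", "chr1", 10, "A", "T", 100, 5),
             ("s2", "chr1", 10, "A", "T", 100, 50),
             ("s3", "chr1", 10, "A", "T", 1000, 1)]
        )
        site = ("chr1", 10, "A", "T")
        noisy = fisher_site_test(table, "s1", site)
        clean = fisher_site_test(table, "s1", site, excluded={("s2", site)})
        assert clean.table[1] == (1, 1000)
        assert clean.p_raw < noisy.p_raw

    @given(
        alt_fg=st.integers(0, 40), ref_fg=st.integers(0, 400),
        alt_bg=st.integers(0, 40), ref_bg=st.integers(0, 4000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_scipy_fisher_greater(self, alt_fg, ref_fg, alt_bg, ref_bg):
        ours = fisher_one_sided(alt_fg, ref_fg, alt_bg, ref_bg)
        _, ref_p = fisher_exact([[alt_fg, ref_fg], [alt_bg, ref_bg]], alternative="greater")
        assert ours == pytest.approx(ref_p, rel=1e-9, abs=1e-12)

    @given(extra=st.integers(1, 30))
    @settings(max_examples=50, derandomize=True)
    def test_adding_alt_reads_never_raises_p(self, extra):
        base = fisher_one_sided(3, 500, 10, 10_000)
        more = fisher_one_sided(3 + extra, 500, 10, 10_000)
        assert more <= base


class TestHolmAdjust:
    def test_hand_computed_step_down(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_cap_at_one(self):
        assert holm_adjust([1.0, 1.0]) == [1.0, 1.0]

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == [0.2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_matches_statsmodels_and_never_decreases(self, ps):
        ours = holm_adjust(ps)
        reference = multipletests(ps, method="holm")[1]
        assert np.allclose(ours, reference)
        assert all(a >= p for a, p in zip(ours, ps))


class TestIterateValidation:
    def test_no_alt_reads_retains_nothing(self, count_table_factory):
        table = count_table_factory(
            [(f"s{i}", "chr1", 10, "A", "T", 1000, 0) for i in range(4)]
        )
        retained, log = iterate_validation(table, [("s0", ("chr1", 10, "A", "T"))])
        assert retained == set()
        assert {rec.iteration for rec in log} == {1}

    def test_single_strong_variant_retained(self, count_table_factory):
        rows = [("s0", "chr1", 10, "A", "T", 1960, 40)]
        rows += [(f"s{i}", "chr1", 10, "A", "T", 2000, 0) for i in range(1, 30)]
        table = count_table_factory(rows)
        cand = [(f"s{i}", ("chr1", 10, "A", "T")) for i in range(30)]
        retained, _ = iterate_validation(table, cand)
        assert retained == {("s0", ("chr1", 10, "A", "T"))}

    def test_shared_variant_recovered_in_second_round(self, count_table_factory):
        """Two samples share a true variant; the weaker is masked in round 1
        because the stronger inflates its background, then recovered once the
        stronger is excluded from the pool."""
        site = ("chr1", 10, "A", "T")
        table = count_table_factory(
            [("s0", "chr1", 10, "A", "T", 1900, 100),
             ("s1", "chr1", 10, "A", "T", 1960, 40),
             ("s2", "chr1", 10, "A", "T", 2000, 1)]
        )
        candidates = [("s0", site), ("s1", site), ("s2", site)]
        retained, log = iterate_validation(table, candidates)
        assert ("s0", site) in retained and ("s1", site) in retained
        assert ("s2", site) not in retained
        rounds = {rec.sample_id: rec.iteration for rec in log if rec.p_adj < 0.1}
        assert rounds["s0"] == 1 and rounds["s1"] == 2
        # matches the from-scratch oracle
        assert retained == brute_force_retained(table, candidates)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(20_240_101)
        for _ in range(60):
            table, candidates = random_count_instance(rng)
            ours, _ = iterate_validation(table, candidates)
            assert ours == brute_force_retained(table, candidates)

    def test_unknown_candidate_rejected(self, count_table_factory):
        table = count_table_factory(
            [("s1", "chr1", 10, "A", "T", 10, 0), ("s2", "chr1", 10, "A", "T", 10, 0)]
        )
        with pytest.raises(KeyError):
            iterate_validation(table, [("s9", ("chr1", 10, "A", "T"))])


class TestClassifySnv:
    SITE = ("chr1", 10, "A", "T")

    @pytest.mark.parametrize(
        "tumor_depth,tumor_p,normal_depth,normal_p,expected",
        [
            (150, 0.01, 120, 0.9, "PASS"),
            (150, 0.01, 50, None, "TUMOR_ONLY"),
            (99, 0.01, 120, 0.9, "LOW_DEPTH"),
            (100, 0.05, 100, 0.9, "PASS"),        # boundary: tumor p <= 0.05
            (100, 0.051, 100, 0.9, "FAIL"),
            (150, 0.01, 120, 0.05, "FAIL"),       # normal p must exceed 0.05
            (150, 0.01, 120, 0.051, "PASS"),
            (150, 0.2, 50, None, "FAIL"),
            (150, 0.01, None, None, "TUMOR_ONLY"),
            (None, float("nan"), None, None, "NOT_ASSAYED"),
            (100, 0.01, 99, 0.9, "TUMOR_ONLY"),   # normal below depth gate
        ],
    )
    def test_status_truth_table(self, tumor_depth, tumor_p, normal_depth, normal_p, expected):
        outcome = classify_snv("s1", self.SITE, tumor_depth, tumor_p, normal_depth, normal_p)
        assert outcome.status == expected


class TestValidateCohort:
    def test_end_to_end_pass_and_tumor_only(self, count_table_factory):
        site = ("chr1", 10, "A", "T")
        rows = [("t0", "chr1", 10, "A", "T", 1960, 40),
                ("n0", "chr1", 10, "A", "T", 2000, 1)]
        rows += [(f"t{i}", "chr1", 10, "A", "T", 2000, 0) for i in range(1, 6)]
        rows += [(f"n{i}", "chr1", 10, "A", "T", 2000, 0) for i in range(1, 6)]
        table = count_table_factory(rows)
        pair_map = {f"t{i}": f"n{i}" for i in range(6)}
        outcomes, _ = validate_cohort(table, [("t0", site)], pair_map)
        assert outcomes[0].status == "PASS"
        # Shallow normal downgrades to TUMOR_ONLY
        rows[1] = ("n0", "chr1", 10, "A", "T", 50, 0)
        table = count_table_factory(rows)
        outcomes, _ = validate_cohort(table, [("t0", site)], pair_map)
        assert outcomes[0].status == "TUMOR_ONLY"

    def test_variant_in_normal_fails(self, count_table_factory):
        site = ("chr1", 10, "A", "T")
        rows = [("t0", "chr1", 10, "A", "T", 1960, 40),
                ("n0", "chr1", 10, "A", "T", 1955, 45)]
        rows += [(f"t{i}", "chr1", 10, "A", "T", 2000, 0) for i in range(1, 6)]
        rows += [(f"n{i}", "chr1", 10, "A", "T", 2000, 0) for i in range(1, 6)]
        table = count_table_factory(rows)
        pair_map = {f"t{i}": f"n{i}" for i in range(6)}
        outcomes, _ = validate_cohort(table, [("t0", site)], pair_map)
        assert outcomes[0].status == "FAIL"
        assert outcomes[0].normal_p_adj <= 0.05
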