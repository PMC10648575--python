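"""Boundary truth tables for the deterministic rule engines."""

import pytest

from umivar.filters import (
    DEFAULT_KEEP_CLASSES,
    FilterDecision,
    IndelCounts,
    filter_consequence,
    filter_denovo,
    load_allowlist,
    remove_known,
    validate_indel,
)
from umivar.model import GenomicSite, PipelineConfig, VariantCall


class TestValidateIndelPaired:
    def paired(self, tumor_depth=10, tumor_alt=2, normal_depth=10, normal_alt=0,
               tumor_vaf=None, normal_vaf=None):
        return IndelCounts(tumor_depth, tumor_alt, normal_depth, normal_alt,
                           tumor_vaf, normal_vaf)

    def test_clean_pair_passes(self):
        decision = validate_indel(self.paired(tumor_vaf=0.20))
        assert decision.status == "PASS" and decision.failed_rules == []

    @pytest.mark.parametrize(
        "kwargs,rule",
        [
            (dict(tumor_depth=5, tumor_alt=2), "indel_min_depth.tumor"),     # > 5 strict
            (dict(tumor_alt=1), "indel_min_tumor_alt"),                      # > 1 reads
            (dict(normal_depth=100, normal_alt=20), "indel_max_normal_alt"), # < 20 reads
            (dict(tumor_depth=10_000, tumor_alt=1), "indel_min_tumor_vaf"),  # VAF > 0.01%
            (dict(normal_depth=100, normal_alt=5), "indel_max_normal_vaf"),  # VAF < 5%
        ],
    )
    def test_each_rule_fails_at_its_boundary(self, kwargs, rule):
        decision = validate_indel(self.paired(**kwargs))
        assert decision.status == "FAIL"
        assert rule in decision.failed_rules

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(tumor_depth=6, tumor_alt=2),            # just above strict depth gate
            dict(normal_depth=1000, normal_alt=19),      # 19 < 20 normal reads
            dict(tumor_depth=9999, tumor_alt=2),         # vaf 2/9999 > 0.0001
            dict(normal_depth=101, normal_alt=5),        # 5/101 < 0.05
        ],
    )
    def test_just_inside_each_boundary_passes(self, kwargs):
        assert validate_indel(self.paired(**kwargs)).status == "PASS"

    def test_inclusive_depth_switch(self):
        cfg = PipelineConfig(indel_paired_depth_strict=False)
        c = self.paired(tumor_depth=5, tumor_alt=2, normal_depth=5, normal_alt=0)
        assert validate_indel(c, cfg).status == "PASS"
        assert validate_indel(c).status != "PASS"


class TestValidateIndelTumorOnly:
    def test_shallow_normal_routes_to_tumor_only(self):
        c = IndelCounts(tumor_depth=10, tumor_alt=1, normal_depth=3, normal_alt=0, tumor_vaf=0.10)
        assert validate_indel(c).status == "TUMOR_ONLY"

    def test_missing_normal_routes_to_tumor_only(self):
        c = IndelCounts(tumor_depth=10, tumor_alt=1)
        assert validate_indel(c).status == "TUMOR_ONLY"

    def test_tumor_only_depth_gate_is_inclusive(self):
        assert validate_indel(IndelCounts(5, 1)).status == "TUMOR_ONLY"
        decision = validate_indel(IndelCounts(4, 1))
        assert decision.status == "FAIL"
        assert "indel_min_depth.tumor_only" in decision.failed_rules

    def test_tumor_only_requires_one_alt_read(self):
        decision = validate_indel(IndelCounts(10, 0))
        assert decision.status == "FAIL"
        assert "indel_tumor_only_min_alt" in decision.failed_rules


class TestFilterDenovo:
    def counts(self, tumor_depth=200, tumor_alt=3, normal_depth=150, normal_alt=0,
               tumor_vaf=0.015, normal_vaf=None):
        return IndelCounts(tumor_depth, tumor_alt, normal_depth, normal_alt,
                           tumor_vaf, normal_vaf)

    def test_clean_variant_passes(self):
        decision = filter_denovo(self.counts())
        assert decision.status == "PASS" and decision.failed_rules == []

    @pytest.mark.parametrize(
        "kwargs,rule",
        [
            (dict(tumor_depth=4, tumor_alt=2), "denovo_min_depth.tumor"),
            (dict(normal_depth=4, normal_alt=0), "denovo_min_depth.normal"),
            (dict(normal_depth=100, normal_alt=5, normal_vaf=0.05), "denovo_max_normal_vaf"),
            (dict(tumor_vaf=0.005), "denovo_min_tumor_vaf"),   # strict > 0.5%
            (dict(tumor_vaf=0.004), "denovo_min_tumor_vaf"),
            (dict(normal_depth=1000, normal_alt=5), "denovo_max_normal_alt"),  # < 5 reads
            (dict(tumor_alt=1, tumor_vaf=0.01), "denovo_min_tumor_alt"),       # >= 2 reads
        ],
    )
    def test_each_rule_fails_at_its_boundary(self, kwargs, rule):
        decision = filter_denovo(self.counts(**kwargs))
        assert decision.status == "FAIL"
        assert rule in decision.failed_rules

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(tumor_depth=5, tumor_alt=2),              # depth gate inclusive
            dict(normal_depth=5, normal_alt=0),
            dict(tumor_vaf=0.0051),
            dict(normal_depth=1000, normal_alt=4),         # 4 < 5 normal reads
            dict(tumor_alt=2, tumor_vaf=0.01),
        ],
    )
    def test_just_inside_each_boundary_passes(self, kwargs):
        assert filter_denovo(self.counts(**kwargs)).status == "PASS"

    def test_missing_normal_not_evaluable(self):
        decision = filter_denovo(IndelCounts(tumor_depth=100, tumor_alt=5))
        assert decision.status == "NOT_EVALUABLE"

    def test_decisions_are_pure(self):
        c = self.counts(tumor_vaf=0.004, tumor_alt=1)
        first, second = filter_denovo(c), filter_denovo(c)
        assert first == second
        assert set(first.failed_rules) == {"denovo_min_tumor_vaf", "denovo_min_tumor_alt"}

    def test_pass_excludes_failed_rules(self):
        with pytest.raises(ValueError):
            FilterDecision("PASS", ["some_rule"])


def call(consequence, sample="s1", pos=100, alt="T"):
    return VariantCall(GenomicSite("chr1", pos, "A", alt), sample, consequence=consequence)


class TestFilterConsequence:
    def test_protein_altering_kept(self):
        kept = filter_consequence([call("missense"), call("stop_gained"), call("frameshift")])
        assert len(kept) == 3

    def test_silent_and_noncoding_dropped(self):
        assert filter_consequence([call("synonymous"), call("intergenic"), call("intron")]) == []

    def test_vep_style_suffix_normalised(self):
        assert len(filter_consequence([call("missense_variant")])) == 1

    def test_unknown_term_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            kept = filter_consequence([call("mystery_class")])
        assert kept == [] and "mystery_class" in caplog.text

    def test_custom_keep_set(self):
        kept = filter_consequence([call("synonymous"), call("missense")], keep_classes={"synonymous"})
        assert [v.consequence for v in kept] == ["synonymous"]


class TestRemoveKnown:
    def test_exact_match_removed_same_site_other_alt_kept(self):
        known = [call("missense", alt="T")]
        variants = [call("missense", alt="T"), call("missense", alt="G")]
        assert remove_known(variants, known) == [variants[1]]

    def test_empty_known_is_identity(self):
        variants = [call("missense"), call("synonymous", pos=200)]
        assert remove_known(variants, []) == variants

    def test_other_samples_unaffected(self):
        known = [call("missense", sample="s1")]
        variants = [call("missense", sample="s2")]
        assert remove_known(variants, known) == variants


class TestAllowlist:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "rescued.tsv"
        path.write_text(
            "sample_id\tchrom\tpos\tref\talt\n"
            "s1\tchr1\t100\tA\tT\n"
            "s2\tchr12\t55\tG\tC\n"
        )
        allow = load_allowlist(path)
        assert allow == {("s1", "chr1", 100, "A", "T"), ("s2", "chr12", 55, "G", "C")}
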