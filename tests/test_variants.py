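"""Variant-triage cascade: thresholds, gene summaries, and line overlap."""

import pytest

from teratopd.errors import DegenerateDesignError, ValidationError
from teratopd.simulate import VariantTruth, make_gene_list, simulate_variants
from teratopd.variants import (
    CancerGeneList,
    VariantRecord,
    filter_variants,
    line_overlap,
    per_line_gene_summary,
)

GENES = CancerGeneList.from_symbols(["TP53", "APC", "HLA-A", "Notch2"])

#: Published per-line gene lists (COSMIC-confirmed, high/moderate impact)
#: for the two hiPSC lines derived from the same parental fibroblasts.
GENES_201B7 = {
    "TNFRSF14", "SPEN", "NOTCH2", "PIK3CA", "TET2", "FAT1", "TERT", "DROSHA",
    "IL7R", "APC", "HLA-A", "NFKBIE", "KMT2C", "PCM1", "NCOA2", "OMD",
    "NOTCH1", "KAT6B", "CREB3L1", "MEN1", "MAML2", "ATM", "KCNJ5", "PTPRB",
    "SH2B3", "HNF1A", "NCOR2", "FLT3", "ERCC5", "FOXA1", "HIF1A", "ZFHX3",
    "TP53", "BRCA1", "AXIN2", "SETBP1", "MAP2K2", "JAK3", "EP300", "ZRSR2",
    "FANCB",
}
GENES_253G1 = (GENES_201B7 - {"MAP2K2", "ZRSR2"}) | {"CREB3L2", "AR"}


def rec(**kw):
    base = dict(
        line_id="L1", chrom="chr1", pos=100, ref="A", alt="T",
        gene_symbol="TP53", vaf=0.4, depth=100, impact="HIGH",
        cosmic_ids=("COSM1",),
    )
    base.update(kw)
    return VariantRecord(**base)


def brute_force_survivors(records, genes, vaf_min=0.09, depth_min=40,
                          impacts=("HIGH", "MODERATE"), require_cosmic=True):
    """Oracle: plain re-statement of each criterion, record by record."""
    out = []
    for r in records:
        if not r.gene_symbol:
            continue
        ok = (
            r.vaf > vaf_min
            and r.depth >= depth_min
            and r.impact in impacts
            and r.gene_symbol.upper() in {g.upper() for g in genes.symbols}
            and (not require_cosmic or len(r.cosmic_ids) > 0)
        )
        if ok:
            out.append(r)
    return out


class TestFilter:
    def test_vaf_boundary_is_strict(self):
        assert len(filter_variants([rec(vaf=0.09)], GENES).surviving) == 0
        assert len(filter_variants([rec(vaf=0.091)], GENES).surviving) == 1

    def test_depth_boundary_is_inclusive(self):
        assert len(filter_variants([rec(depth=40, impact="MODERATE")], GENES).surviving) == 1
        assert len(filter_variants([rec(depth=39)], GENES).surviving) == 0

    def test_impact_and_gene_and_cosmic_arms(self):
        assert len(filter_variants([rec(impact="LOW")], GENES).surviving) == 0
        assert len(filter_variants([rec(gene_symbol="MYC")], GENES).surviving) == 0
        assert len(filter_variants([rec(cosmic_ids=())], GENES).surviving) == 0

    def test_gene_matching_is_case_normalized(self):
        assert len(filter_variants([rec(gene_symbol="tp53")], GENES).surviving) == 1
        assert len(filter_variants([rec(gene_symbol="HLA-A")], GENES).surviving) == 1

    def test_unknown_impact_label_names_the_record(self):
        with pytest.raises(ValidationError, match="chr1:100"):
            rec(impact="SEVERE")

    def test_missing_gene_symbol_dropped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            result = filter_variants([rec(gene_symbol="")], GENES)
        assert len(result.surviving) == 0
        assert "missing gene symbol" in caplog.text

    def test_synthetic_table_matches_bruteforce_oracle(self):
        genes = make_gene_list(100)
        truth = VariantTruth(
            counts={
                "A": {"pass_all": 61, "fail_vaf": 20, "fail_depth": 20,
                      "fail_impact": 20, "fail_gene": 20, "fail_cosmic": 20},
                "B": {"pass_all": 70, "fail_vaf": 20, "fail_depth": 20,
                      "fail_impact": 20, "fail_gene": 20, "fail_cosmic": 20},
                "C": {"pass_all": 77, "fail_vaf": 19, "fail_depth": 19,
                      "fail_impact": 18, "fail_gene": 18, "fail_cosmic": 18},
            }
        )
        records = simulate_variants(truth, genes, seed=17)
        assert len(records) == 500
        result = filter_variants(records, genes)
        oracle = brute_force_survivors(records, genes)
        assert set(map(id, result.surviving)) == set(map(id, oracle))
        assert result.counts == {"A": 61, "B": 70, "C": 77}

    def test_filter_is_monotone_in_thresholds(self):
        genes = make_gene_list(50)
        truth = VariantTruth(counts={"A": {arm: 20 for arm in (
            "pass_all", "fail_vaf", "fail_depth", "fail_impact", "fail_gene", "fail_cosmic")}})
        records = simulate_variants(truth, genes, seed=3)
        strict = set(map(id, filter_variants(records, genes).surviving))
        relaxed_vaf = set(map(id, filter_variants(records, genes, vaf_min=0.0).surviving))
        relaxed_depth = set(map(id, filter_variants(records, genes, depth_min=0).surviving))
        relaxed_imp = set(map(id, filter_variants(
            records, genes, impacts=("HIGH", "MODERATE", "LOW", "MODIFIER")).surviving))
        no_cosmic = set(map(id, filter_variants(records, genes, require_cosmic=False).surviving))
        for relaxed in (relaxed_vaf, relaxed_depth, relaxed_imp, no_cosmic):
            assert strict <= relaxed

    def test_order_independence(self):
        genes = make_gene_list(50)
        truth = VariantTruth(counts={"A": {"pass_all": 10, "fail_vaf": 10}})
        records = simulate_variants(truth, genes, seed=5)
        a = filter_variants(records, genes).surviving
        b = filter_variants(records[::-1], genes).surviving
        assert set(a) == set(b)

    def test_cascade_decomposes_without_cosmic_and_impact_arms(self):
        genes = make_gene_list(50)
        truth = VariantTruth(counts={"A": {arm: 10 for arm in (
            "pass_all", "fail_vaf", "fail_depth", "fail_impact", "fail_gene", "fail_cosmic")}})
        records = simulate_variants(truth, genes, seed=8)
        result = filter_variants(
            records, genes,
            impacts=("HIGH", "MODERATE", "LOW", "MODIFIER"), require_cosmic=False,
        )
        expected = [
            r for r in records
            if r.vaf > 0.09 and r.depth >= 40 and r.gene_symbol in genes
        ]
        assert set(result.surviving) == set(expected)


class TestSummaries:
    def test_gene_deduplicated_per_line(self):
        result = filter_variants(
            [rec(pos=100), rec(pos=200), rec(pos=300, gene_symbol="APC")], GENES
        )
        assert per_line_gene_summary(result) == {"L1": ["APC", "TP53"]}

    def test_empty_surviving_set(self):
        result = filter_variants([rec(vaf=0.01)], GENES)
        assert per_line_gene_summary(result) == {}

    def test_jaccard_identical_and_disjoint(self):
        m = line_overlap({"a": ["TP53", "APC"], "b": ["TP53", "APC"], "c": ["KRAS"]})
        assert m.loc["a", "b"] == 1.0
        assert m.loc["a", "c"] == 0.0
        assert (m.values == m.values.T).all()
        assert (m.values.diagonal() == 1.0).all()

    def test_published_sibling_lines_jaccard(self):
        """The two lines reprogrammed from common fibroblasts share almost
        all triaged genes; the Jaccard index equals direct set arithmetic."""
        m = line_overlap({"201B7": sorted(GENES_201B7), "253G1": sorted(GENES_253G1)})
        expected = len(GENES_201B7 & GENES_253G1) / len(GENES_201B7 | GENES_253G1)
        assert m.loc["201B7", "253G1"] == pytest.approx(expected)
        assert expected > 0.9

    def test_two_empty_sets_defined_as_full_overlap(self):
        m = line_overlap({"a": [], "b": []})
        assert m.loc["a", "b"] == 1.0

    def test_single_line_rejected(self):
        with pytest.raises(DegenerateDesignError):
            line_overlap({"a": ["TP53"]})


class TestRecordValidation:
    def test_vaf_depth_pos_bounds(self):
        with pytest.raises(ValidationError):
            rec(vaf=1.2)
        with pytest.raises(ValidationError):
            rec(depth=-1)
        with pytest.raises(ValidationError):
            rec(pos=0)
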