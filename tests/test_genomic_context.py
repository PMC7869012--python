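"""Genomic-context classification rules, distance semantics, cis pairing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncnet.genomic_context import (
    CodingIndex,
    antisense_dysregulated_pairs,
    class_composition,
    classify_all,
    classify_lncrna,
    genomic_gap,
    nearby_dysregulated_pairs,
)
from lncnet.simulate import SimulationConfig, simulate_annotation

from conftest import de_frame, make_annotation

# one coding gene on chr1:+ spanning 1000..2999 with exons 1000..1499 and 2500..2999
GENE = ("gene1", "mRNA", "chr1", "+", 1000, 2999)
GENE_EXONS = {"gene1": [(1000, 1499), (2500, 2999)]}


def classify_one(lnc_tuple, genes=(GENE,), exons=GENE_EXONS, **kw):
    annot = make_annotation(list(genes) + [lnc_tuple], dict(exons))
    index = CodingIndex(annot.of_biotype("mRNA"))
    row = annot.table[annot.table["feature_id"] == lnc_tuple[0]].iloc[0]
    return classify_lncrna(row, index, **kw)


class TestClassifierRules:
    def test_empty_chromosome_is_intergenic(self, caplog):
        with caplog.at_level("WARNING"):
            cls = classify_one(("l", "lncRNA", "chr9", "+", 5, 50))
        assert cls == "intergenic"

    def test_exon_overlap_same_strand(self):
        assert classify_one(("l", "lncRNA", "chr1", "+", 1400, 1600)) == \
            "exon_sense_overlapping"

    def test_exon_overlap_opposite_strand_is_natural_antisense(self):
        assert classify_one(("l", "lncRNA", "chr1", "-", 1400, 1600)) == \
            "natural_antisense"

    def test_exact_exon_span_both_strands(self):
        assert classify_one(("l", "lncRNA", "chr1", "+", 1000, 1499)) == \
            "exon_sense_overlapping"
        assert classify_one(("l", "lncRNA", "chr1", "-", 1000, 1499)) == \
            "natural_antisense"

    def test_intronic_antisense_inside_span_no_exon(self):
        assert classify_one(("l", "lncRNA", "chr1", "-", 1600, 2400)) == \
            "intronic_antisense"

    def test_intronic_same_strand_is_intergenic(self):
        # sense-intronic has no class of its own here: falls through
        assert classify_one(("l", "lncRNA", "chr1", "+", 1600, 2400)) == "intergenic"

    def test_bidirectional_divergent_within_window(self):
        # gene TSS at 1000 (+); lncRNA on minus strand ending 500 before it
        assert classify_one(("l", "lncRNA", "chr1", "-", 100, 500)) == "bidirectional"

    def test_bidirectional_respects_window(self):
        assert classify_one(("l", "lncRNA", "chr1", "-", 100, 500),
                            bidir_window=400) == "intergenic"

    def test_convergent_neighbor_is_not_bidirectional(self):
        # lncRNA on minus strand past the gene end: tail-to-tail
        assert classify_one(("l", "lncRNA", "chr1", "-", 3100, 3500)) == "intergenic"

    def test_far_feature_is_intergenic(self):
        assert classify_one(("l", "lncRNA", "chr1", "+", 500_000, 500_800)) == \
            "intergenic"

    def test_precedence_sense_overlap_beats_antisense_to_other_gene(self):
        # overlaps gene1's exon on + strand AND a second minus-strand gene's exon
        genes = [GENE, ("gene2", "mRNA", "chr1", "-", 1300, 1700)]
        exons = {"gene1": GENE_EXONS["gene1"], "gene2": [(1300, 1700)]}
        assert classify_one(("l", "lncRNA", "chr1", "+", 1400, 1600),
                            genes=genes, exons=exons) == "exon_sense_overlapping"

    def test_classification_invariant_to_coding_order(self, rng):
        genes = [GENE, ("gene2", "mRNA", "chr1", "-", 5000, 8000),
                 ("gene3", "mRNA", "chr2", "+", 100, 900)]
        exons = {"gene1": GENE_EXONS["gene1"]}
        lncs = [("la", "lncRNA", "chr1", "-", 1400, 1600),
                ("lb", "lncRNA", "chr1", "-", 100, 500),
                ("lc", "lncRNA", "chr2", "-", 200, 300)]
        a1 = make_annotation(genes + lncs, dict(exons))
        a2 = make_annotation(genes[::-1] + lncs, dict(exons))
        c1 = classify_all(a1).sort_values("feature_id").reset_index(drop=True)
        c2 = classify_all(a2).sort_values("feature_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(c1, c2)


class TestGeneratorClosedLoop:
    def test_planted_classes_recovered(self):
        counts = {"intergenic": 8, "exon_sense_overlapping": 8,
                  "natural_antisense": 8, "intronic_antisense": 8, "bidirectional": 8}
        cfg = SimulationConfig(seed=4, n_mrna=60, n_lnc=40, planted_classes=counts)
        annot, truth = simulate_annotation(cfg)
        got = classify_all(annot)
        merged = got.merge(truth.classes, on="feature_id", suffixes=("_got", "_true"))
        assert (merged["lnc_class_got"] == merged["lnc_class_true"]).all()
        comp = class_composition(got)
        assert dict(zip(comp["lnc_class"], comp["count"])) == counts
        assert comp["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_intergenic_only_request(self):
        cfg = SimulationConfig(seed=1, n_mrna=10, n_lnc=5,
                               planted_classes={"intergenic": 5})
        annot, _ = simulate_annotation(cfg)
        assert (classify_all(annot)["lnc_class"] == "intergenic").all()


class TestGenomicGap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((1, 10), (5, 20), 0), ((1, 10), (11, 20), 0), ((1, 10), (12, 20), 1),
         ((12, 20), (1, 10), 1), ((1, 10), (10, 20), 0)],
    )
    def test_known_gaps(self, a, b, expected):
        assert genomic_gap(*a, *b) == expected

    @settings(deadline=None, max_examples=200)
    @given(st.integers(1, 60), st.integers(0, 20), st.integers(1, 60), st.integers(0, 20))
    def test_matches_base_counting_and_symmetry(self, s1, l1, s2, l2):
        e1, e2 = s1 + l1, s2 + l2
        gap = genomic_gap(s1, e1, s2, e2)
        assert gap == genomic_gap(s2, e2, s1, e1)
        a = set(range(s1, e1 + 1))
        b = set(range(s2, e2 + 1))
        overlap = bool(a & b)
        assert (gap == 0 and overlap) or not overlap or gap == 0
        if not overlap:
            between = {i for i in range(min(e1, e2) + 1, max(s1, s2))} - a - b
            assert gap == len(between)
        else:
            assert gap == 0


def _layout(gap_list):
    """One lncRNA per mRNA gene at the given gap downstream."""
    rows = []
    exons = {}
    for i, gap in enumerate(gap_list):
        s = 1_000_000 + i * 10_000_000
        rows.append((f"m{i}", "mRNA", "chr1", "+", s, s + 999))
        rows.append((f"l{i}", "lncRNA", "chr1", "+", s + 1000 + gap, s + 1500 + gap))
    return make_annotation(rows, exons)


class TestNearbyPairs:
    def test_inclusive_300kb_boundary(self):
        annot = _layout([300_000, 300_001])
        lncs = de_frame([("l0", 2.5, 0.01), ("l1", 2.5, 0.01)])
        mrnas = de_frame([("m0", -2.1, 0.02), ("m1", -2.1, 0.02)])
        pairs = nearby_dysregulated_pairs(lncs, mrnas, annot)
        assert list(pairs["lncRNA"]) == ["l0"]
        assert pairs["genomic_distance"].iloc[0] == 300_000

    def test_many_to_one_pairing_allowed(self):
        rows = [("m0", "mRNA", "chr1", "+", 1_000_000, 1_000_999),
                ("l0", "lncRNA", "chr1", "+", 1_100_000, 1_100_500),
                ("l1", "lncRNA", "chr1", "-", 900_000, 900_500)]
        annot = make_annotation(rows)
        lncs = de_frame([("l0", 2.4, 0.01), ("l1", 6.5, 0.001)])
        mrnas = de_frame([("m0", -2.3, 0.01)])
        pairs = nearby_dysregulated_pairs(lncs, mrnas, annot)
        assert sorted(pairs["lncRNA"]) == ["l0", "l1"]
        assert (pairs["mRNA"] == "m0").all()

    def test_pair_stats_mirror_de_tables(self):
        annot = _layout([1000])
        lncs = de_frame([("l0", 2.9, 0.0019)])
        mrnas = de_frame([("m0", 3.4, 0.0018)])
        pairs = nearby_dysregulated_pairs(lncs, mrnas, annot)
        rec = pairs.iloc[0]
        assert rec["lnc_fold_change"] == 2.9 and rec["mrna_fold_change"] == 3.4
        assert rec["lnc_direction"] == "up" and rec["mrna_direction"] == "up"

    def test_planted_layout_recovered(self):
        cfg = SimulationConfig(seed=8, n_mrna=40, n_lnc=20)
        from lncnet.simulate import CisSpec

        gaps = [5_000, 100_000, 299_999, 300_000, 300_001, 400_000, 500_000,
                650_000, 700_000, 800_000]
        cfg.planted_cis = [
            CisSpec(lnc=f"L{i+1:04d}", mrna=f"M{i+1:04d}", gap=g)
            for i, g in enumerate(gaps)
        ]
        cfg.planted_de = {c.lnc: 2.0 for c in cfg.planted_cis}
        cfg.planted_de.update({c.mrna: -2.0 for c in cfg.planted_cis})
        annot, truth = simulate_annotation(cfg)
        de_l = de_frame([(c.lnc, 4.0, 0.001) for c in cfg.planted_cis])
        de_m = de_frame([(c.mrna, -4.0, 0.001) for c in cfg.planted_cis])
        pairs = nearby_dysregulated_pairs(de_l, de_m, annot)
        assert len(pairs) == 4
        assert set(pairs["genomic_distance"]) == {5_000, 100_000, 299_999, 300_000}
        assert set(truth.cis[truth.cis["within"]]["lncRNA"]) == set(pairs["lncRNA"])


class TestAntisensePairs:
    def _annot(self):
        rows = [("m0", "mRNA", "chr1", "+", 1000, 2999),
                ("la", "lncRNA", "chr1", "-", 1200, 1400),
                ("lb", "lncRNA", "chr1", "+", 1200, 1400)]
        return make_annotation(rows, {"m0": [(1000, 1499), (2500, 2999)]})

    def test_planted_pair_both_dysregulated_returned(self):
        pairs = antisense_dysregulated_pairs(
            de_frame([("la", 2.2, 0.01)]), de_frame([("m0", -2.5, 0.02)]), self._annot()
        )
        assert len(pairs) == 1
        assert pairs.iloc[0]["relation"] == "antisense_overlap"
        assert pairs.iloc[0]["genomic_distance"] == 0

    def test_same_strand_overlap_not_antisense(self):
        pairs = antisense_dysregulated_pairs(
            de_frame([("lb", 2.2, 0.01)]), de_frame([("m0", -2.5, 0.02)]), self._annot()
        )
        assert pairs.empty

    def test_pair_requires_both_members_dysregulated(self):
        pairs = antisense_dysregulated_pairs(
            de_frame([("la", 2.2, 0.01)]), de_frame([]), self._annot()
        )
        assert pairs.empty

    def test_study_profile_has_no_antisense_pairs(self):
        from lncnet.simulate import study_config

        cfg = study_config(seed=0)
        annot, truth = simulate_annotation(cfg)
        de = truth  # planted truth: use all planted DE features as dysregulated
        lncs = de_frame([(f, 2.0, 0.01) for f in cfg.planted_de if f.startswith("L")])
        mrnas = de_frame([(f, 2.0, 0.01) for f in cfg.planted_de if f.startswith("M")])
        pairs = antisense_dysregulated_pairs(lncs, mrnas, annot)
        assert pairs.empty
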