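"""Cryptic junction rule, Boolean feature assembly, ranking and overlaps."""

import math

import numpy as np
import pandas as pd
import pytest

from irsig.alignment_counting import JunctionCountTable
from irsig.annotation_model import FlatFeature, JunctionKey
from irsig.ir_metrics import SSRatioRecord
from irsig.signature_scoring import (BooleanFeatureRow, assemble_features,
                                     detect_cryptic,
                                     intersect_significant_genes,
                                     rank_introns)


def _jtable(rows):
    """rows: {(chrom, donor, acceptor): {sample: count}}"""
    index = pd.MultiIndex.from_tuples(sorted(rows),
                                      names=["chrom", "donor", "acceptor"])
    samples = sorted({s for v in rows.values() for s in v})
    df = pd.DataFrame([[rows[k].get(s, 0) for s in samples] for k in index],
                      index=index, columns=samples)
    ann = pd.Series(False, index=index)
    strand = pd.Series(".", index=index)
    return JunctionCountTable(counts=df, annotated=ann, strand=strand)


INTRON = FlatFeature("g:intronic_part:000", "g", "intronic_part", "chr1",
                     1000, 2000, "+")


class TestDetectCryptic:
    def test_two_supported_junctions_flag_true(self):
        table = _jtable({("chr1", 1200, 1300): {"s1": 3},
                         ("chr1", 1500, 1600): {"s1": 3}})
        assert detect_cryptic(table, set(), INTRON).flag

    def test_single_junction_insufficient_however_deep(self):
        table = _jtable({("chr1", 1200, 1300): {"s1": 100}})
        assert not detect_cryptic(table, set(), INTRON).flag

    def test_each_junction_needs_three_reads(self):
        table = _jtable({("chr1", 1200, 1300): {"s1": 3},
                         ("chr1", 1500, 1600): {"s1": 2}})
        assert not detect_cryptic(table, set(), INTRON).flag

    def test_annotated_junctions_ignored(self):
        table = _jtable({("chr1", 1200, 1300): {"s1": 5},
                         ("chr1", 1500, 1600): {"s1": 5}})
        catalog = {JunctionKey("chr1", 1200, 1300, "+", annotated=True),
                   JunctionKey("chr1", 1500, 1600, "+", annotated=True)}
        assert not detect_cryptic(table, catalog, INTRON).flag

    def test_junction_must_end_strictly_inside(self):
        # the intron's own excision junction touches both boundaries exactly
        table = _jtable({("chr1", 1000, 2000): {"s1": 50},
                         ("chr1", 1100, 1200): {"s1": 4},
                         ("chr1", 1300, 1400): {"s1": 4}})
        rep = detect_cryptic(table, set(), INTRON)
        assert rep.flag and len(rep.junctions) == 2


def _diff(rows):
    """rows: {feature_id: (significant, padj)}"""
    return pd.DataFrame(
        {"significant": [v[0] for v in rows.values()],
         "fdr_adjusted_p": [v[1] for v in rows.values()]},
        index=list(rows))


def _jresults(rows):
    """rows: {(chrom, donor, acceptor): (significant, padj)}"""
    index = pd.MultiIndex.from_tuples(sorted(rows),
                                      names=["chrom", "donor", "acceptor"])
    return pd.DataFrame(
        {"significant": [rows[k][0] for k in index],
         "fdr_adjusted_p": [rows[k][1] for k in index]},
        index=index)


def _ssr(a3, b3, a5, b5):
    return SSRatioRecord("g:intronic_part:000", "g", "chr1", 1000, 2000, "+",
                         ratio_3ss={"A": a3, "B": b3},
                         ratio_5ss={"A": a5, "B": b5})


class TestAssembleFeatures:
    def test_all_six_indicators(self):
        ssr = _ssr(0.5, 0.05, 0.4, 0.02)
        diff = _diff({"g:exonic_part:001": (True, 0.01),
                      "g:intronic_part:000": (True, 0.02)})
        jres = _jresults({("chr1", 1000, 2000): (True, 0.005)})
        cryptic = detect_cryptic(
            _jtable({("chr1", 1200, 1300): {"s1": 3},
                     ("chr1", 1500, 1600): {"s1": 4}}), set(), INTRON)
        row = assemble_features(INTRON, ssr, diff, jres, cryptic,
                                flanking_exon_ids=["g:exonic_part:001"],
                                window_ids=[], condition_a="A", condition_b="B")
        assert row.score == 6
        assert row.min_adj_p == pytest.approx(0.005)

    def test_partial_pattern_scores_four(self):
        # high 3'/5' ratio deltas, significant intron, cryptics; exon and
        # junction tests quiet
        ssr = _ssr(0.5, 0.05, 0.4, 0.02)
        diff = _diff({"g:exonic_part:001": (False, 0.8),
                      "g:intronic_part:000": (True, 0.02)})
        jres = _jresults({("chr1", 1000, 2000): (False, 0.9)})
        cryptic = detect_cryptic(
            _jtable({("chr1", 1200, 1300): {"s1": 3},
                     ("chr1", 1500, 1600): {"s1": 4}}), set(), INTRON)
        row = assemble_features(INTRON, ssr, diff, jres, cryptic,
                                ["g:exonic_part:001"], [], "A", "B")
        assert (row.b_3ss_ratio, row.b_5ss_ratio, row.b_diff_exon,
                row.b_diff_intron, row.b_diff_junction, row.b_cryptic) == \
            (True, True, False, True, False, True)
        assert row.score == 4

    def test_quiet_intron_scores_zero(self):
        ssr = _ssr(0.05, 0.02, 0.01, 0.01)
        row = assemble_features(INTRON, ssr, _diff({}), None, None, [], [],
                                "A", "B")
        assert row.score == 0
        assert "junctions" in row.missing and "cryptic" in row.missing

    def test_window_significance_counts_as_intron_evidence(self):
        ssr = _ssr(0.0, 0.0, 0.0, 0.0)
        diff = _diff({"g:intronic_part:000:w001": (True, 0.03)})
        row = assemble_features(INTRON, ssr, diff, None, None, [],
                                ["g:intronic_part:000:w001"], "A", "B")
        assert row.b_diff_intron and row.score == 1

    def test_delta_threshold_is_inclusive(self):
        ssr = _ssr(0.2, 0.1, 0.0, 0.0)  # delta exactly 0.1
        row = assemble_features(INTRON, ssr, _diff({}), None, None, [], [],
                                "A", "B")
        assert row.b_3ss_ratio


def _row(score_bits, locus="1:100-200", min_p=math.nan, d3=math.nan, gene="g"):
    b = [bool(x) for x in score_bits]
    return BooleanFeatureRow(gene, locus, *b, min_adj_p=min_p, delta_3ss=d3)


class TestRanking:
    def test_descending_score(self):
        rows = [_row([1, 1, 1, 1, 0, 0], "1:1-2"),
                _row([1, 1, 1, 1, 1, 1], "1:3-4"),
                _row([1, 1, 1, 1, 1, 1], "1:5-6")]
        ranked = rank_introns(rows)
        assert [r.score for r in ranked] == [6, 6, 4]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_tie_broken_by_adjusted_p(self):
        rows = [_row([1, 1, 0, 0, 0, 0], "1:1-2", min_p=0.05),
                _row([1, 1, 0, 0, 0, 0], "1:3-4", min_p=0.001)]
        ranked = rank_introns(rows)
        assert ranked[0].locus == "1:3-4"

    def test_tie_broken_by_delta_then_locus(self):
        rows = [_row([1, 0, 0, 0, 0, 0], "2:1-2", d3=0.2),
                _row([1, 0, 0, 0, 0, 0], "1:9-10", d3=0.4),
                _row([1, 0, 0, 0, 0, 0], "1:5-6", d3=0.2)]
        ranked = rank_introns(rows)
        assert [r.locus for r in ranked] == ["1:9-10", "1:5-6", "2:1-2"]

    def test_single_row_rank_one(self):
        (r,) = rank_introns([_row([0] * 6)])
        assert r.rank == 1

    def test_score_equals_boolean_sum(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            bits = rng.integers(0, 2, size=6)
            assert _row(bits).score == bits.sum()


class TestVennPartition:
    def test_triple_overlap(self):
        part = intersect_significant_genes({"A", "B"}, {"B", "C"}, {"B"})
        assert part["all_three"] == {"B"}
        assert part["exon_only"] == {"A"}
        assert part["intron_only"] == {"C"}

    def test_disjoint_sets(self):
        part = intersect_significant_genes({"A"}, {"B"}, {"C"})
        assert part["all_three"] == set()
        assert part["exon_only"] == {"A"}

    def test_identical_sets(self):
        part = intersect_significant_genes({"A", "B"}, {"A", "B"}, {"A", "B"})
        assert part["all_three"] == {"A", "B"}
        assert all(not part[k] for k in part if k != "all_three")

    def test_partition_is_disjoint_and_complete(self):
        e, i, j = {"a", "b", "c"}, {"b", "d"}, {"c", "d", "e"}
        part = intersect_significant_genes(e, i, j)
        union = set().union(*part.values())
        assert union == e | i | j
        assert sum(len(v) for v in part.values()) == len(union)
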