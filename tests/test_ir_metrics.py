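"""Splice-site ratio computation, expression filter and summaries."""

import math

import numpy as np
import pytest

from irsig.alignment_counting import CountTable, CoverageTrack
from irsig.annotation_model import (FlatFeature, derive_intronic_parts,
                                    flatten_exonic_parts, intron_contexts)
from irsig.ir_metrics import (condition_ratio_difference, expressed_genes,
                              retention_distribution, ss_ratio,
                              ss_ratio_records, SSRatioRecord)

import pandas as pd

from conftest import make_gene, make_models


def _track(length, segments, chrom="chr1"):
    """Coverage track with constant-depth segments [(start, end, depth)]."""
    arr = np.zeros(length, dtype=np.int64)
    for s, e, d in segments:
        arr[s:e] = d
    return CoverageTrack(sample_id="t", arrays={chrom: arr})


def _features(strand="+"):
    up = FlatFeature("g:exonic_part:000", "g", "exonic_part", "chr1",
                     100, 200, strand)
    intron = FlatFeature("g:intronic_part:000", "g", "intronic_part", "chr1",
                         200, 300, strand)
    down = FlatFeature("g:exonic_part:001", "g", "exonic_part", "chr1",
                       300, 400, strand)
    return up, intron, down


class TestSSRatio:
    def test_uniform_intron_over_exon(self):
        up, intron, down = _features()
        cov = _track(500, [(100, 200, 100), (200, 300, 10), (300, 400, 100)])
        assert ss_ratio(intron, down, up, cov, "3ss") == pytest.approx(0.1)
        assert ss_ratio(intron, down, up, cov, "5ss") == pytest.approx(0.1)

    def test_zero_intron_coverage_gives_zero(self):
        up, intron, down = _features()
        cov = _track(500, [(100, 200, 50), (300, 400, 50)])
        assert ss_ratio(intron, down, up, cov, "3ss") == 0.0

    def test_fully_retained_intron_gives_one(self):
        up, intron, down = _features()
        cov = _track(500, [(100, 400, 80)])
        assert ss_ratio(intron, down, up, cov, "3ss") == pytest.approx(1.0)

    def test_empty_exon_window_is_missing_not_zero(self):
        up, intron, down = _features()
        cov = _track(500, [(200, 300, 10)])  # intron covered, exons silent
        assert math.isnan(ss_ratio(intron, down, up, cov, "3ss"))

    def test_minus_strand_windows_mirror(self):
        # on the minus strand the 3'SS window sits at the intron's genomic
        # start, next to the (genomically left) downstream exon
        up, intron, down = _features(strand="-")
        up, down = down, up  # transcription order reversed
        cov = _track(500, [(100, 200, 100), (200, 225, 30), (275, 300, 7),
                           (300, 400, 100)])
        # 3'SS: intron first 25 genomic bases (30x) over left exon last 25 (100x)
        assert ss_ratio(intron, down, up, cov, "3ss") == pytest.approx(0.3)
        # 5'SS: intron last 25 genomic bases (7x) over right exon first 25
        assert ss_ratio(intron, down, up, cov, "5ss") == pytest.approx(0.07)

    def test_ratio_invariant_to_depth_scaling(self):
        up, intron, down = _features()
        cov1 = _track(500, [(100, 200, 40), (200, 300, 12), (300, 400, 40)])
        cov5 = CoverageTrack("t5", {"chr1": cov1.arrays["chr1"] * 5})
        assert ss_ratio(intron, down, up, cov1, "3ss") == \
            pytest.approx(ss_ratio(intron, down, up, cov5, "3ss"))

    def test_records_pool_conditions_and_flag_truncation(self):
        models = make_models(make_gene("g", [[(100, 200), (210, 400)]]))
        exonic = flatten_exonic_parts(models)
        intronic = derive_intronic_parts(models, exonic)  # 10 bp intron
        ctxs = intron_contexts(exonic, intronic)
        cov = {"A": _track(500, [(100, 400, 10)])}
        (rec,) = ss_ratio_records(ctxs, cov)
        assert rec.truncated  # intron shorter than the 25 bp window
        assert rec.ratio_3ss["A"] == pytest.approx(10 * 10 / (25 * 10))


class TestExpressedGenes:
    def _table(self, n_reads, samples=("s1",)):
        counts = pd.DataFrame({s: [n_reads] for s in samples},
                              index=["g:exonic_part:000"])
        return CountTable(counts=counts, conditions={s: "A" for s in samples})

    def test_example_gene_passes(self):
        feats = [FlatFeature("g:exonic_part:000", "g", "exonic_part",
                             "chr1", 0, 2500, "+")]
        assert expressed_genes(self._table(500), feats, 125) == {"g"}

    def test_zero_reads_fails(self):
        feats = [FlatFeature("g:exonic_part:000", "g", "exonic_part",
                             "chr1", 0, 2500, "+")]
        assert expressed_genes(self._table(0), feats, 125) == set()

    def test_boundary_is_strict(self):
        # 400 reads x 125 bp / 2500 bp = exactly 20.0 -> not expressed
        feats = [FlatFeature("g:exonic_part:000", "g", "exonic_part",
                             "chr1", 0, 2500, "+")]
        assert expressed_genes(self._table(400), feats, 125) == set()


class TestRetentionDistribution:
    def test_summary_of_mixed_ratios(self):
        summary = retention_distribution([0.0, 0.02, 1.0])
        assert summary["median_ratio"] == pytest.approx(0.02)
        assert summary["frac_ratio_ge_0.5"] == pytest.approx(1 / 3)
        assert summary["frac_efficiency_gt_0.9"] == pytest.approx(2 / 3)

    def test_all_zero(self):
        summary = retention_distribution([0.0, 0.0])
        assert summary["median_ratio"] == 0.0
        assert summary["frac_ratio_ge_0.1"] == 0.0

    def test_nan_ratios_excluded(self):
        summary = retention_distribution([math.nan, 0.4])
        assert summary["n"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            retention_distribution([math.nan])


class TestConditionDifference:
    @pytest.mark.parametrize("a,b,delta", [
        (0.30, 0.05, 0.25), (0.30, 0.25, 0.05), (0.2, 0.2, 0.0),
    ])
    def test_absolute_difference(self, a, b, delta):
        rec = SSRatioRecord("i", "g", "chr1", 0, 100, "+",
                            ratio_3ss={"A": a, "B": b},
                            ratio_5ss={"A": a, "B": b})
        d3, d5 = condition_ratio_difference(rec, "A", "B")
        assert d3 == pytest.approx(delta)
        assert d5 == pytest.approx(delta)

    def test_undefined_ratio_propagates(self):
        rec = SSRatioRecord("i", "g", "chr1", 0, 100, "+",
                            ratio_3ss={"A": math.nan, "B": 0.3},
                            ratio_5ss={"A": 0.1, "B": 0.3})
        d3, d5 = condition_ratio_difference(rec, "A", "B")
        assert math.isnan(d3) and d5 == pytest.approx(0.2)


def test_distribution_median_recovers_truth_mixture(tmp_path):
    """On a simulated gene set with mixture-drawn retention fractions the
    estimated median 3'SS ratio lands within +-0.01 of the truth median."""
    from irsig.alignment_counting import coverage_track, pool_coverage
    from irsig.synthetic_data import SimConfig, generate_annotation, simulate_samples

    config = SimConfig(seed=51, n_genes=25, depth=150.0,
                       event_mix={"CNE": 1.0})
    models, truth = generate_annotation(config)
    alignments, conditions = simulate_samples(models, truth, str(tmp_path),
                                              seed=51, replicates=1)
    cov = {"A": pool_coverage([coverage_track(p) for s, p in
                               alignments.items() if conditions[s] == "A"])}
    exonic = flatten_exonic_parts(models)
    intronic = derive_intronic_parts(models, exonic)
    recs = ss_ratio_records(intron_contexts(exonic, intronic), cov)
    truth_r, est = [], []
    for rec in recs:
        r = truth.genes[rec.gene_id].intron_r.get((rec.start, rec.end), {}).get("A")
        if r is not None and not math.isnan(rec.ratio_3ss["A"]):
            truth_r.append(r)
            est.append(rec.ratio_3ss["A"])
    summary = retention_distribution(est)
    assert abs(summary["median_ratio"] - float(np.median(truth_r))) <= 0.01


def test_strand_mirror_leaves_ratios_unchanged():
    """Reversing a gene's strand and mirroring coordinates preserves ratios."""
    L = 500
    up, intron, down = _features("+")
    cov = _track(L, [(100, 200, 100), (200, 240, 20), (260, 300, 8),
                     (300, 400, 100)])
    r3 = ss_ratio(intron, down, up, cov, "3ss")
    r5 = ss_ratio(intron, down, up, cov, "5ss")

    def mirror(f, new_id):
        return FlatFeature(new_id, "g", f.kind, "chr1",
                           L - f.end, L - f.start, "-")
    m_up, m_intron, m_down = (mirror(up, "mu"), mirror(intron, "mi"),
                              mirror(down, "md"))
    m_cov = CoverageTrack("m", {"chr1": cov.arrays["chr1"][::-1].copy()})
    assert ss_ratio(m_intron, m_down, m_up, m_cov, "3ss") == pytest.approx(r3)
    assert ss_ratio(m_intron, m_down, m_up, m_cov, "5ss") == pytest.approx(r5)
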