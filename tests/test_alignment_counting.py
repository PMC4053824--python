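"""Read counting against hand-walked CIGARs and a brute-force oracle."""

import numpy as np
import pysam
import pytest

from irsig.alignment_counting import (count_features, count_junctions,
                                      coverage_track, mean_base_coverage)
from irsig.annotation_model import (FlatFeature, JunctionKey,
                                    derive_intronic_parts,
                                    flatten_exonic_parts, junction_catalog,
                                    window_introns)
from irsig.synthetic_data import SimConfig, generate_annotation, simulate_samples

from conftest import write_sam


def _feat(fid, start, end, kind="exonic_part", gene="g"):
    return FlatFeature(id=fid, gene_id=gene, kind=kind, chrom="chr1",
                       start=start, end=end, strand="+")


class TestCountFeatures:
    def test_contained_read_counts_once(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 100, "50M")])
        table = count_features({"s1": sam}, [_feat("f1", 100, 200)])
        assert table.counts.loc["f1", "s1"] == 1

    def test_spliced_read_skips_intron(self, tmp_path):
        # 25M100N25M starting at 175: aligned (175,200) + (300,325)
        sam = write_sam(tmp_path / "a.sam", [("r1", 175, "25M100N25M")])
        feats = [_feat("exL", 100, 200), _feat("intr", 200, 300, "intronic_part"),
                 _feat("exR", 300, 400)]
        table = count_features({"s1": sam}, feats)
        assert table.counts.loc["intr", "s1"] == 0
        assert table.counts.loc["exL", "s1"] == 1
        assert table.counts.loc["exR", "s1"] == 1

    def test_read_spanning_two_features_counts_for_both(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 180, "50M")])
        table = count_features({"s1": sam},
                               [_feat("f1", 100, 200), _feat("f2", 200, 300)])
        assert table.counts.loc["f1", "s1"] == 1
        assert table.counts.loc["f2", "s1"] == 1

    def test_secondary_and_unmapped_records_skipped(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [
            ("r1", 100, "50M"),
            ("r2", 100, "50M", 256),   # secondary
            ("r3", 100, "50M", 4),     # unmapped
        ])
        table = count_features({"s1": sam}, [_feat("f1", 100, 200)])
        assert table.counts.loc["f1", "s1"] == 1


class TestCountJunctions:
    def test_annotated_junction_counted(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 175, "25M100N25M")])
        catalog = {JunctionKey("chr1", 200, 300, "+", annotated=True)}
        table = count_junctions({"s1": sam}, catalog)
        assert table.counts.loc[("chr1", 200, 300), "s1"] == 1
        assert bool(table.annotated.loc[("chr1", 200, 300)])

    def test_uncataloged_junction_kept_as_unannotated(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 175, "25M100N25M")])
        table = count_junctions({"s1": sam}, set())
        assert table.counts.loc[("chr1", 200, 300), "s1"] == 1
        assert not bool(table.annotated.loc[("chr1", 200, 300)])

    def test_read_with_two_gaps_increments_both(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 100, "20M80N20M50N20M")])
        table = count_junctions({"s1": sam}, set())
        # gaps: (120,200) and (220,270)
        assert table.counts.loc[("chr1", 120, 200), "s1"] == 1
        assert table.counts.loc[("chr1", 220, 270), "s1"] == 1


class TestCoverage:
    def test_overlapping_reads_stack(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 100, "50M"), ("r2", 120, "50M")])
        cov = coverage_track(sam)
        assert cov.arrays["chr1"][130] == 2
        assert cov.arrays["chr1"][110] == 1

    def test_n_gap_bases_are_zero(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 175, "25M100N25M")])
        cov = coverage_track(sam)
        assert cov.arrays["chr1"][250] == 0
        assert cov.arrays["chr1"][180] == 1

    def test_empty_alignments_give_zero_track(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [])
        cov = coverage_track(sam)
        assert cov.arrays["chr1"].sum() == 0

    def test_region_outside_reference_rejected(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [], chrom_len=1000)
        with pytest.raises(ValueError, match="chr1:0-5000"):
            coverage_track(sam, regions=[("chr1", 0, 5000)])


class TestMeanBaseCoverage:
    @pytest.mark.parametrize("reads,rl,fl,expected", [
        (200, 125, 2500, 10.0), (0, 125, 1000, 0.0), (16, 125, 1000, 2.0),
    ])
    def test_arithmetic(self, reads, rl, fl, expected):
        assert mean_base_coverage(reads, rl, fl) == expected

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            mean_base_coverage(10, 125, 0)


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence on simulated reads
# ---------------------------------------------------------------------------

def _oracle_counts(sam_path, features):
    """Expand every read into its aligned base set and intersect features."""
    counts = {f.id: 0 for f in features}
    gap_counts = {}
    with pysam.AlignmentFile(sam_path, "r") as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary \
                    or read.mapping_quality < 1:
                continue
            bases = set()
            pos = read.reference_start
            for op, length in read.cigartuples:
                if op in (0, 7, 8):
                    bases.update(range(pos, pos + length))
                    pos += length
                elif op == 3:
                    key = (read.reference_name, pos, pos + length)
                    gap_counts[key] = gap_counts.get(key, 0) + 1
                    pos += length
                elif op == 2:
                    pos += length
            for f in features:
                if f.chrom == read.reference_name and \
                        bases & set(range(f.start, f.end)):
                    counts[f.id] += 1
    return counts, gap_counts


@pytest.fixture(scope="module")
def simulated_sample(tmp_path_factory):
    config = SimConfig(seed=17, n_genes=6, depth=40.0)
    models, truth = generate_annotation(config)
    out = tmp_path_factory.mktemp("oracle_sim")
    alignments, conditions = simulate_samples(models, truth, str(out),
                                              seed=17, replicates=1)
    exonic = flatten_exonic_parts(models)
    intronic = derive_intronic_parts(models, exonic)
    features = exonic + intronic + window_introns(intronic)
    return models, features, alignments


def test_feature_counts_match_base_set_oracle(simulated_sample):
    models, features, alignments = simulated_sample
    table = count_features(alignments, features)
    sample = next(iter(alignments))
    oracle, _ = _oracle_counts(alignments[sample], features)
    got = table.counts[sample].to_dict()
    assert got == oracle


def test_junction_counts_match_gap_oracle(simulated_sample):
    models, features, alignments = simulated_sample
    catalog = junction_catalog(models)
    table = count_junctions(alignments, catalog)
    sample = next(iter(alignments))
    _, gap_oracle = _oracle_counts(alignments[sample], features)
    for key, n in gap_oracle.items():
        assert table.counts.loc[key, sample] == n
    # rows absent from the oracle must be zero (catalog-only rows)
    observed = set(gap_oracle)
    for key in table.counts.index:
        if tuple(key) not in observed:
            assert table.counts.loc[key, sample] == 0


def test_coverage_sum_bounds_feature_counts(simulated_sample):
    models, features, alignments = simulated_sample
    sample = next(iter(alignments))
    table = count_features({sample: alignments[sample]}, features)
    cov = coverage_track(alignments[sample])
    for f in features:
        assert cov.window_sum(f.chrom, f.start, f.end) >= \
            table.counts.loc[f.id, sample]
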