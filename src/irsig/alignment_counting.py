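"""Read counting from spliced alignments.

Reads SAM/BAM with pysam and produces the three count structures the
pipeline consumes: per-feature read counts (a read counts once for every
flattened feature it overlaps by at least ``min_overlap`` aligned bases),
per-junction read counts (one increment per N-gap in the CIGAR), and
per-base coverage tracks (number of M-aligned reads covering each base;
N-gap bases contribute nothing).

Only primary, mapped records with mapping quality >= 1 are counted.
Paired-end input is accepted but each segment is treated independently
(the pipeline's semantics are single-end), with a one-time warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation_model import FlatFeature, JunctionKey

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Feature x sample integer counts plus the sample->condition map."""

    counts: pd.DataFrame  # index: feature ids, columns: sample ids
    conditions: dict[str, str] = field(default_factory=dict)

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]


@dataclass
class JunctionCountTable:
    """Junction x sample counts; index is (chrom, donor, acceptor)."""

    counts: pd.DataFrame  # MultiIndex (chrom, donor, acceptor), columns: samples
    annotated: pd.Series  # bool per junction row
    strand: pd.Series     # strand per junction row ("." if seen only in reads)
    conditions: dict[str, str] = field(default_factory=dict)

    def keys(self) -> list[JunctionKey]:
        return [
            JunctionKey(c, d, a, self.strand.loc[(c, d, a)],
                        annotated=bool(self.annotated.loc[(c, d, a)]))
            for c, d, a in self.counts.index
        ]


@dataclass
class CoverageTrack:
    """Per-base M-overlap coverage, one array per reference sequence."""

    sample_id: str
    arrays: dict[str, np.ndarray]

    def window_sum(self, chrom: str, start: int, end: int) -> int:
        arr = self.arrays.get(chrom)
        if arr is None:
            return 0
        return int(arr[start:end].sum())

    def add(self, other: "CoverageTrack") -> "CoverageTrack":
        """Pooled coverage of two tracks (replicate pooling)."""
        arrays = {c: a.copy() for c, a in self.arrays.items()}
        for c, a in other.arrays.items():
            if c in arrays:
                arrays[c] = arrays[c] + a
            else:
                arrays[c] = a.copy()
        return CoverageTrack(sample_id=f"{self.sample_id}+{other.sample_id}",
                             arrays=arrays)


def pool_coverage(tracks: list[CoverageTrack], label: str = "pooled") -> CoverageTrack:
    if not tracks:
        raise ValueError("no coverage tracks to pool")
    pooled = tracks[0]
    for t in tracks[1:]:
        pooled = pooled.add(t)
    pooled.sample_id = label
    return pooled


# ---------------------------------------------------------------------------
# CIGAR walking
# ---------------------------------------------------------------------------

_CONSUMES_REF = {0, 2, 3, 7, 8}  # M, D, N, =, X
_ALIGNED = {0, 7, 8}             # M, =, X


def aligned_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference intervals consumed by M/=/X operations (D and N excluded)."""
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in _ALIGNED:
            if blocks and blocks[-1][1] == pos:
                blocks[-1] = (blocks[-1][0], pos + length)
            else:
                blocks.append((pos, pos + length))
            pos += length
        elif op in _CONSUMES_REF:
            pos += length
    return blocks


def n_gaps(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """(gap_start, gap_end) reference intervals of every N operation."""
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op == 3:  # N
            gaps.append((pos, pos + length))
        if op in _CONSUMES_REF:
            pos += length
    return gaps


def _usable_reads(path: str):
    """Yield primary mapped records with a CIGAR and mapq >= 1."""
    warned_paired = False
    n_no_cigar = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < 1:
                continue
            if read.cigartuples is None:
                n_no_cigar += 1
                continue
            if read.is_paired and not warned_paired:
                logger.warning(
                    "%s: paired-end input; segments counted independently", path
                )
                warned_paired = True
            yield read
    if n_no_cigar:
        logger.warning("%s: skipped %d mapped records without CIGAR", path, n_no_cigar)


# ---------------------------------------------------------------------------
# Counting operations
# ---------------------------------------------------------------------------

def count_features(alignments: dict[str, str],
                   features: list[FlatFeature],
                   min_overlap: int = 1,
                   conditions: dict[str, str] | None = None) -> CountTable:
    """Count reads per flattened feature for each sample.

    ``alignments`` maps sample id to SAM/BAM path.  A read counts once for
    every feature it overlaps by at least ``min_overlap`` M-aligned bases
    (so it may count toward several features, including features of
    overlapping genes); N-gap bases never contribute overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f.id)
    ids = [f.id for f in features]
    data = {}
    for sample, path in alignments.items():
        counts: dict[str, int] = {}
        for read in _usable_reads(path):
            chrom = read.reference_name
            tree = trees.get(chrom)
            if tree is None:
                continue
            overlap_by_feature: dict[str, int] = {}
            for bs, be in aligned_blocks(read):
                for iv in tree.overlap(bs, be):
                    ov = min(be, iv.end) - max(bs, iv.begin)
                    if ov > 0:
                        overlap_by_feature[iv.data] = overlap_by_feature.get(iv.data, 0) + ov
            for fid, ov in overlap_by_feature.items():
                if ov >= min_overlap:
                    counts[fid] = counts.get(fid, 0) + 1
        data[sample] = [counts.get(fid, 0) for fid in ids]
    df = pd.DataFrame(data, index=pd.Index(ids, name="feature_id"), dtype=np.int64)
    return CountTable(counts=df, conditions=dict(conditions or {}))


def count_junctions(alignments: dict[str, str],
                    catalog: set[JunctionKey],
                    conditions: dict[str, str] | None = None) -> JunctionCountTable:
    """Count junction-spanning reads per sample.

    Each N gap of a read increments its junction once (a read spanning k
    junctions contributes to all k).  Junctions absent from the annotated
    catalog are retained as rows with ``annotated=False``.
    """
    lookup: dict[tuple[str, int, int], JunctionKey] = {
        (j.chrom, j.donor, j.acceptor): j for j in catalog
    }
    per_sample: dict[str, dict[tuple[str, int, int], int]] = {}
    seen: dict[tuple[str, int, int], str] = {}
    for sample, path in alignments.items():
        counts: dict[tuple[str, int, int], int] = {}
        for read in _usable_reads(path):
            chrom = read.reference_name
            for gs, ge in n_gaps(read):
                key = (chrom, gs, ge)
                counts[key] = counts.get(key, 0) + 1
                if key not in seen:
                    cat = lookup.get(key)
                    seen[key] = cat.strand if cat is not None else "."
        per_sample[sample] = counts
    # catalog junctions appear as zero-filled rows even if never observed
    for key, j in lookup.items():
        seen.setdefault(key, j.strand)
    index = pd.MultiIndex.from_tuples(
        sorted(seen), names=["chrom", "donor", "acceptor"]
    )
    df = pd.DataFrame(
        {s: [per_sample[s].get(k, 0) for k in index] for s in alignments},
        index=index, dtype=np.int64,
    )
    annotated = pd.Series([k in lookup for k in index], index=index, name="annotated")
    strand = pd.Series([seen[k] for k in index], index=index, name="strand")
    return JunctionCountTable(counts=df, annotated=annotated, strand=strand,
                              conditions=dict(conditions or {}))


def coverage_track(alignment_path: str,
                   reference_lengths: dict[str, int] | None = None,
                   regions: list[tuple[str, int, int]] | None = None,
                   sample_id: str = "") -> CoverageTrack:
    """Per-base M-overlap coverage across each reference sequence.

    Allocates one array per reference (lengths from the SAM header unless
    given); suitable for the desk-scale genomes this package targets.  If
    ``regions`` is given, each must lie within its reference bounds.
    """
    if reference_lengths is None:
        with pysam.AlignmentFile(alignment_path, "r", check_sq=False) as fh:
            reference_lengths = dict(zip(fh.references, fh.lengths))
    for chrom, start, end in regions or []:
        ref_len = reference_lengths.get(chrom)
        if ref_len is None or start < 0 or end > ref_len:
            raise ValueError(
                f"region {chrom}:{start}-{end} outside reference bounds"
            )
    arrays = {c: np.zeros(l, dtype=np.int64) for c, l in reference_lengths.items()}
    for read in _usable_reads(alignment_path):
        arr = arrays.get(read.reference_name)
        if arr is None:
            continue
        for bs, be in aligned_blocks(read):
            arr[bs:be] += 1
    return CoverageTrack(sample_id=sample_id or alignment_path, arrays=arrays)


def mean_base_coverage(read_count: int, read_length: int,
                       feature_length: int) -> float:
    """Mean per-base coverage: reads mapped x read length / feature length."""
    if feature_length <= 0:
        raise ValueError(f"feature_length must be positive, got {feature_length}")
    return read_count * read_length / feature_length


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

def write_counts_tsv(table: CountTable, path: str) -> None:
    table.counts.to_csv(path, sep="\t")


def write_junction_counts_tsv(table: JunctionCountTable, path: str) -> None:
    df = table.counts.copy()
    df.insert(0, "strand", table.strand)
    df.insert(1, "annotated", table.annotated.astype(int))
    df.to_csv(path, sep="\t")
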