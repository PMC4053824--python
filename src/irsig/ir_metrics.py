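"""Splice-site intron-retention ratios and expression filtering.

The retention estimate for an intron is the ratio of read coverage just
inside the intron to read coverage just inside the adjacent exon, summed
over a short window (default 25 bp) on each side of the splice site.  For a
fully spliced intron the intron-side window is empty and the ratio is 0;
for a fully retained intron coverage is equal on both sides and the ratio
is ~1; in between it estimates the fraction of polyadenylated transcripts
that still carry the intron.

The 3'SS ratio is taken at the intron's acceptor end (last ``window`` bp of
the intron over the first ``window`` bp of the downstream exon); the 5'SS
ratio at the donor end.  "First"/"last" follow transcription direction, so
on the minus strand the 3'SS window sits at the intron's genomic start.

"Reads in the window" is implemented as summed per-base coverage (robust to
read length); per-condition ratios pool replicate coverage before dividing;
ratios with an empty exon-side window are missing (NaN), never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment_counting import CountTable, CoverageTrack, mean_base_coverage
from .annotation_model import FlatFeature, IntronContext

DEFAULT_SS_WINDOW = 25
DEFAULT_EXPRESSION_THRESHOLD = 20.0


@dataclass
class SSRatioRecord:
    """Per-intron splice-site retention ratios, per condition."""

    intron_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    ratio_3ss: dict[str, float] = field(default_factory=dict)  # condition -> ratio (NaN if undefined)
    ratio_5ss: dict[str, float] = field(default_factory=dict)
    window_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    truncated: bool = False
    downstream_exon_id: str = ""
    upstream_exon_id: str = ""

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def _windows(intron: FlatFeature, exon_down: FlatFeature | None,
             exon_up: FlatFeature | None, side: str, window: int):
    """Genomic (intron_window, exon_window) intervals for one splice site.

    Returns (iv_intron, iv_exon, truncated) or None when the needed exon is
    absent.  Windows are truncated to the feature length when shorter.
    """
    w_i = min(window, intron.length)
    truncated = w_i < window
    plus = intron.strand != "-"
    if side == "3ss":
        if exon_down is None:
            return None
        w_e = min(window, exon_down.length)
        truncated = truncated or w_e < window
        if plus:
            iv_i = (intron.end - w_i, intron.end)
            iv_e = (exon_down.start, exon_down.start + w_e)
        else:
            iv_i = (intron.start, intron.start + w_i)
            iv_e = (exon_down.end - w_e, exon_down.end)
    elif side == "5ss":
        if exon_up is None:
            return None
        w_e = min(window, exon_up.length)
        truncated = truncated or w_e < window
        if plus:
            iv_i = (intron.start, intron.start + w_i)
            iv_e = (exon_up.end - w_e, exon_up.end)
        else:
            iv_i = (intron.end - w_i, intron.end)
            iv_e = (exon_up.start, exon_up.start + w_e)
    else:
        raise ValueError(f"side must be '3ss' or '5ss', got {side!r}")
    return iv_i, iv_e, truncated


def ss_ratio(intron: FlatFeature,
             downstream_exon: FlatFeature | None,
             upstream_exon: FlatFeature | None,
             coverage: CoverageTrack,
             side: str,
             window: int = DEFAULT_SS_WINDOW) -> float:
    """Coverage ratio across one splice site; NaN if the exon window is empty."""
    wins = _windows(intron, downstream_exon, upstream_exon, side, window)
    if wins is None:
        return math.nan
    (i_s, i_e), (e_s, e_e), _ = wins
    intron_sum = coverage.window_sum(intron.chrom, i_s, i_e)
    exon_sum = coverage.window_sum(intron.chrom, e_s, e_e)
    if exon_sum == 0:
        return math.nan
    return intron_sum / exon_sum


def ss_ratio_records(contexts: list[IntronContext],
                     coverage_by_condition: dict[str, CoverageTrack],
                     window: int = DEFAULT_SS_WINDOW) -> list[SSRatioRecord]:
    """Compute both splice-site ratios for every intron in every condition.

    ``coverage_by_condition`` maps condition name to replicate-pooled
    coverage.
    """
    records: list[SSRatioRecord] = []
    for ctx in contexts:
        intr = ctx.intron
        rec = SSRatioRecord(
            intron_id=intr.id, gene_id=intr.gene_id, chrom=intr.chrom,
            start=intr.start, end=intr.end, strand=intr.strand,
            downstream_exon_id=ctx.downstream.id if ctx.downstream else "",
            upstream_exon_id=ctx.upstream.id if ctx.upstream else "",
        )
        for side in ("3ss", "5ss"):
            wins = _windows(intr, ctx.downstream, ctx.upstream, side, window)
            if wins is not None and wins[2]:
                rec.truncated = True
        for cond, cov in coverage_by_condition.items():
            rec.ratio_3ss[cond] = ss_ratio(intr, ctx.downstream, ctx.upstream,
                                           cov, "3ss", window)
            rec.ratio_5ss[cond] = ss_ratio(intr, ctx.downstream, ctx.upstream,
                                           cov, "5ss", window)
            sums: dict[str, int] = {}
            for side, tag_i, tag_e in (("3ss", "intron_3ss", "exon_3ss"),
                                       ("5ss", "intron_5ss", "exon_5ss")):
                wins = _windows(intr, ctx.downstream, ctx.upstream, side, window)
                if wins is None:
                    sums[tag_i] = sums[tag_e] = 0
                    continue
                (i_s, i_e), (e_s, e_e), _ = wins
                sums[tag_i] = cov.window_sum(intr.chrom, i_s, i_e)
                sums[tag_e] = cov.window_sum(intr.chrom, e_s, e_e)
            rec.window_counts[cond] = sums
        records.append(rec)
    return records


def expressed_genes(counts: CountTable,
                    features: list[FlatFeature],
                    read_length: int,
                    threshold: float = DEFAULT_EXPRESSION_THRESHOLD) -> set[str]:
    """Genes whose mean exonic base coverage exceeds ``threshold`` (strict >).

    Coverage is computed per condition from the replicate-pooled exonic-part
    counts divided by the number of replicates; a gene must pass in every
    condition, so downstream condition contrasts are defined on both sides.
    Genes with zero exonic length are excluded.
    """
    lengths: dict[str, int] = {}
    ids_by_gene: dict[str, list[str]] = {}
    for f in features:
        if f.kind != "exonic_part":
            continue
        lengths[f.gene_id] = lengths.get(f.gene_id, 0) + f.length
        ids_by_gene.setdefault(f.gene_id, []).append(f.id)
    conditions = sorted(set(counts.conditions.values())) or [None]
    expressed: set[str] = set()
    for gene, total_len in lengths.items():
        if total_len <= 0:
            continue
        ok = True
        for cond in conditions:
            samples = (counts.condition_samples(cond) if cond is not None
                       else list(counts.counts.columns))
            if not samples:
                ok = False
                break
            pooled = int(counts.counts.loc[ids_by_gene[gene], samples].to_numpy().sum())
            mean_reads = pooled / len(samples)
            if mean_base_coverage(mean_reads, read_length, total_len) <= threshold:
                ok = False
                break
        if ok:
            expressed.add(gene)
    return expressed


def retention_distribution(ratios: list[float]) -> dict[str, float]:
    """Genome-wide summary of defined retention ratios.

    Splicing efficiency of an intron is ``1 - min(ratio, 1)``; the summary
    reports the median ratio, the fractions of introns with ratio >= 0.1 and
    >= 0.5, and the fraction with efficiency > 0.9.
    """
    defined = np.asarray([r for r in ratios if not math.isnan(r)], dtype=float)
    if defined.size == 0:
        raise ValueError("no defined retention ratios")
    eff = 1.0 - np.minimum(defined, 1.0)
    return {
        "n": int(defined.size),
        "median_ratio": float(np.median(defined)),
        "frac_ratio_ge_0.1": float(np.mean(defined >= 0.1)),
        "frac_ratio_ge_0.5": float(np.mean(defined >= 0.5)),
        "frac_efficiency_gt_0.9": float(np.mean(eff > 0.9)),
    }


def condition_ratio_difference(record: SSRatioRecord,
                               condition_a: str,
                               condition_b: str) -> tuple[float, float]:
    """Absolute per-condition ratio differences (3'SS, 5'SS); NaN propagates."""
    d3 = abs(record.ratio_3ss.get(condition_a, math.nan)
             - record.ratio_3ss.get(condition_b, math.nan))
    d5 = abs(record.ratio_5ss.get(condition_a, math.nan)
             - record.ratio_5ss.get(condition_b, math.nan))
    return d3, d5


def write_ratio_tsv(records: list[SSRatioRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("intron_id\tgene_id\tlocus\tcondition\tratio_3ss\tratio_5ss\t"
                 "intron_3ss\texon_3ss\tintron_5ss\texon_5ss\ttruncated\n")
        for rec in records:
            for cond in sorted(rec.ratio_3ss):
                w = rec.window_counts.get(cond, {})
                fh.write(
                    f"{rec.intron_id}\t{rec.gene_id}\t{rec.locus}\t{cond}\t"
                    f"{rec.ratio_3ss[cond]:.6g}\t{rec.ratio_5ss[cond]:.6g}\t"
                    f"{w.get('intron_3ss', 0)}\t{w.get('exon_3ss', 0)}\t"
                    f"{w.get('intron_5ss', 0)}\t{w.get('exon_5ss', 0)}\t"
                    f"{int(rec.truncated)}\n"
                )
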