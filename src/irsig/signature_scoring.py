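"""Cryptic-junction detection, the six-feature Boolean score and ranking.

Candidate regulator-dependent introns are ranked by summing six Boolean
indicators per intron:

1. the 3'SS retention ratio differs between conditions by >= 0.1;
2. the 5'SS ratio differs by >= 0.1;
3. a flanking exonic part shows significant differential usage;
4. the intron (its intronic part or any of its windows) shows significant
   differential usage;
5. a junction sharing a boundary with the intron, or skipping across it,
   shows significant differential junction usage;
6. the intron harbours cryptic junctions: at least two distinct unannotated
   junctions, each supported by >= 3 reads in at least one sample.

Score 0-6; ties in the ranking are broken by the smallest adjusted p among
the intron's differential tests, then by the larger 3'SS ratio difference,
then lexicographically by locus, giving a deterministic total order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .alignment_counting import JunctionCountTable
from .annotation_model import FlatFeature, JunctionKey
from .ir_metrics import SSRatioRecord, condition_ratio_difference

DEFAULT_RATIO_DELTA = 0.1
DEFAULT_CRYPTIC_MIN_READS = 3
DEFAULT_CRYPTIC_MIN_JUNCTIONS = 2


@dataclass
class CrypticJunctionReport:
    intron_id: str
    junctions: list[tuple[tuple[str, int, int], dict[str, int]]]  # key, per-sample counts
    flag: bool


@dataclass
class BooleanFeatureRow:
    """One intron's six indicators, their sum and (once ranked) its rank."""

    gene_id: str
    locus: str  # chrom:start-end, 1-based inclusive
    b_3ss_ratio: bool
    b_5ss_ratio: bool
    b_diff_exon: bool
    b_diff_intron: bool
    b_diff_junction: bool
    b_cryptic: bool
    rank: int = 0
    min_adj_p: float = math.nan   # tie-break 1
    delta_3ss: float = math.nan   # tie-break 2
    missing: list[str] = field(default_factory=list)
    intron_id: str = ""

    @property
    def score(self) -> int:
        return int(self.b_3ss_ratio) + int(self.b_5ss_ratio) \
            + int(self.b_diff_exon) + int(self.b_diff_intron) \
            + int(self.b_diff_junction) + int(self.b_cryptic)


def detect_cryptic(junctions: JunctionCountTable,
                   catalog: set[JunctionKey],
                   intron: FlatFeature,
                   min_reads: int = DEFAULT_CRYPTIC_MIN_READS,
                   min_junctions: int = DEFAULT_CRYPTIC_MIN_JUNCTIONS) -> CrypticJunctionReport:
    """Unannotated junctions attributable to one intron.

    A junction belongs to the intron when either endpoint falls strictly
    inside the intron interval.  The flag is true when at least
    ``min_junctions`` distinct unannotated junctions each reach
    ``min_reads`` reads in at least one sample.
    """
    annotated_coords = {(j.chrom, j.donor, j.acceptor) for j in catalog}
    hits: list[tuple[tuple[str, int, int], dict[str, int]]] = []
    n_supported = 0
    for key in junctions.counts.index:
        chrom, donor, acceptor = key
        if chrom != intron.chrom or key in annotated_coords:
            continue
        inside = (intron.start < donor < intron.end) or \
                 (intron.start < acceptor < intron.end)
        if not inside:
            continue
        row = junctions.counts.loc[key]
        hits.append((key, row.to_dict()))
        if int(row.max()) >= min_reads:
            n_supported += 1
    return CrypticJunctionReport(
        intron_id=intron.id, junctions=hits,
        flag=n_supported >= min_junctions,
    )


def _related_junction_mask(junction_results: pd.DataFrame,
                           intron: FlatFeature) -> pd.Series:
    """Junction rows touching either intron boundary or spanning the intron."""
    idx = junction_results.index
    chrom = idx.get_level_values("chrom")
    donor = idx.get_level_values("donor").to_numpy()
    acceptor = idx.get_level_values("acceptor").to_numpy()
    on_chrom = chrom == intron.chrom
    touches = (donor == intron.start) | (acceptor == intron.end)
    spans = (donor <= intron.start) & (acceptor >= intron.end)
    return pd.Series(on_chrom & (touches | spans), index=idx)


def assemble_features(intron: FlatFeature,
                      ssratio: SSRatioRecord | None,
                      diff_results: pd.DataFrame,
                      junction_results: pd.DataFrame | None,
                      cryptic: CrypticJunctionReport | None,
                      flanking_exon_ids: list[str],
                      window_ids: list[str],
                      condition_a: str,
                      condition_b: str,
                      ratio_delta: float = DEFAULT_RATIO_DELTA) -> BooleanFeatureRow:
    """Assemble the six Boolean indicators for one intron.

    ``diff_results`` holds adjusted exon/intron usage tests indexed by
    feature id; ``junction_results`` holds adjusted junction tests indexed
    by (chrom, donor, acceptor).  Missing inputs score their indicator
    false and are recorded in ``missing``.
    """
    missing: list[str] = []
    d3 = d5 = math.nan
    if ssratio is None:
        missing.append("ss_ratio")
    else:
        d3, d5 = condition_ratio_difference(ssratio, condition_a, condition_b)
        if math.isnan(d3):
            missing.append("ratio_3ss")
        if math.isnan(d5):
            missing.append("ratio_5ss")
    b_3 = (not math.isnan(d3)) and d3 >= ratio_delta
    b_5 = (not math.isnan(d5)) and d5 >= ratio_delta

    def _sig(feature_ids: list[str]) -> tuple[bool, float]:
        present = [f for f in feature_ids if f in diff_results.index]
        if not present:
            return False, math.nan
        sub = diff_results.loc[present]
        sig = bool(sub["significant"].any())
        padj = sub["fdr_adjusted_p"].min()
        return sig, float(padj) if pd.notna(padj) else math.nan

    b_exon, p_exon = _sig(flanking_exon_ids)
    if not flanking_exon_ids:
        missing.append("flanking_exons")
    b_intron, p_intron = _sig([intron.id, *window_ids])

    b_junc, p_junc = False, math.nan
    if junction_results is None or junction_results.empty:
        missing.append("junctions")
    else:
        mask = _related_junction_mask(junction_results, intron)
        sub = junction_results.loc[mask.to_numpy()]
        if not sub.empty:
            b_junc = bool(sub["significant"].any())
            pmin = sub["fdr_adjusted_p"].min()
            p_junc = float(pmin) if pd.notna(pmin) else math.nan

    if cryptic is None:
        missing.append("cryptic")
        b_cryptic = False
    else:
        b_cryptic = cryptic.flag

    ps = [p for p in (p_exon, p_intron, p_junc) if not math.isnan(p)]
    return BooleanFeatureRow(
        gene_id=intron.gene_id,
        locus=intron.locus,
        b_3ss_ratio=b_3, b_5ss_ratio=b_5,
        b_diff_exon=b_exon, b_diff_intron=b_intron,
        b_diff_junction=b_junc, b_cryptic=b_cryptic,
        min_adj_p=min(ps) if ps else math.nan,
        delta_3ss=d3,
        missing=missing,
        intron_id=intron.id,
    )


def _locus_sort_key(locus: str) -> tuple:
    chrom, _, span = locus.partition(":")
    start, _, end = span.partition("-")
    try:
        return (chrom, int(start), int(end))
    except ValueError:
        return (chrom, 0, 0)


def rank_introns(rows: list[BooleanFeatureRow]) -> list[BooleanFeatureRow]:
    """Assign ranks 1..N by descending score.

    Ties broken by smaller minimum adjusted p, then larger 3'SS delta, then
    locus order; NaNs sort last within their tier.
    """
    if not rows:
        raise ValueError("no rows to rank")

    def key(row: BooleanFeatureRow):
        p = row.min_adj_p if not math.isnan(row.min_adj_p) else math.inf
        d = -row.delta_3ss if not math.isnan(row.delta_3ss) else math.inf
        return (-row.score, p, d, _locus_sort_key(row.locus))

    ranked = sorted(rows, key=key)
    for i, row in enumerate(ranked, start=1):
        row.rank = i
    return ranked


def intersect_significant_genes(exon_sig: set[str],
                                intron_sig: set[str],
                                junction_sig: set[str]) -> dict[str, set[str]]:
    """Three-way Venn partition of significant gene sets (7 disjoint regions)."""
    e, i, j = set(exon_sig), set(intron_sig), set(junction_sig)
    return {
        "exon_only": e - i - j,
        "intron_only": i - e - j,
        "junction_only": j - e - i,
        "exon_intron": (e & i) - j,
        "exon_junction": (e & j) - i,
        "intron_junction": (i & j) - e,
        "all_three": e & i & j,
    }


SCORE_COLUMNS = ["gene", "locus", "b_3ss_ratio", "b_5ss_ratio", "b_diff_exon",
                 "b_diff_intron", "b_diff_junction", "b_cryptic", "score", "rank"]


def score_table(rows: list[BooleanFeatureRow]) -> pd.DataFrame:
    """Ranked rows as a table matching the published column order."""
    recs = [{
        "gene": r.gene_id, "locus": r.locus,
        "b_3ss_ratio": int(r.b_3ss_ratio), "b_5ss_ratio": int(r.b_5ss_ratio),
        "b_diff_exon": int(r.b_diff_exon), "b_diff_intron": int(r.b_diff_intron),
        "b_diff_junction": int(r.b_diff_junction), "b_cryptic": int(r.b_cryptic),
        "score": r.score, "rank": r.rank,
    } for r in rows]
    return pd.DataFrame(recs, columns=SCORE_COLUMNS)


def write_score_tsv(rows: list[BooleanFeatureRow], path: str) -> None:
    score_table(rows).to_csv(path, sep="\t", index=False)
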