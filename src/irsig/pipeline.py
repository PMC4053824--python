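"""End-to-end orchestration: flatten -> count -> ratios -> tests -> score -> enrich.

``analyze`` runs the whole analysis on in-memory inputs and returns every
intermediate table; ``run_pipeline`` is the file-level wrapper driven by a
:class:`RunConfig` (annotation path, sample sheet, output directory and the
method parameters, whose defaults are the published operating points: 25 bp
splice-site windows, 300 bp intron windows, expression threshold 20,
retention-selection threshold 0.1, ratio-difference threshold 0.1, FDR 0.1,
cryptic rule >= 2 junctions at >= 3 reads, 1,000 enrichment resamples).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import (alignment_counting as ac, annotation_model as am,
               differential_usage as du, event_enrichment as ee,
               ir_metrics as irm, signature_scoring as sc)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    annotation: str = ""
    sample_sheet: str = ""
    output_dir: str = "irsig_out"
    dialect: str = "gtf"
    ss_window: int = irm.DEFAULT_SS_WINDOW
    intron_window: int = am.DEFAULT_INTRON_WINDOW
    expression_threshold: float = irm.DEFAULT_EXPRESSION_THRESHOLD
    ir_threshold: float = ee.DEFAULT_SELECT_THRESHOLD
    fdr_alpha: float = du.DEFAULT_FDR_ALPHA
    min_count_exon_intron: int = du.MIN_COUNT_EXON_INTRON
    min_count_junction: int = du.MIN_COUNT_JUNCTION
    cryptic_min_reads: int = sc.DEFAULT_CRYPTIC_MIN_READS
    cryptic_min_junctions: int = sc.DEFAULT_CRYPTIC_MIN_JUNCTIONS
    ratio_delta: float = sc.DEFAULT_RATIO_DELTA
    resamples: int = ee.DEFAULT_RESAMPLES
    read_length: int = 125
    reference_condition: str = ""  # condition used for exon selection; default: first sorted
    seed: int = 0


@dataclass
class PipelineResult:
    models: am.GeneModelSet
    exonic: list[am.FlatFeature]
    intronic: list[am.FlatFeature]
    windows: list[am.FlatFeature]
    catalog: set[am.JunctionKey]
    feature_counts: ac.CountTable
    junction_counts: ac.JunctionCountTable
    expressed: set[str]
    ssratios: list[irm.SSRatioRecord]
    usage_results: pd.DataFrame          # exon + intron classes, FDR-adjusted
    junction_results: pd.DataFrame       # junction class, FDR-adjusted
    cryptic: dict[str, sc.CrypticJunctionReport]
    rows: list[sc.BooleanFeatureRow]     # ranked
    enrichment: ee.EnrichmentReport | None
    venn: dict[str, set[str]]
    condition_a: str
    condition_b: str
    stage_log: dict = field(default_factory=dict)


def read_sample_sheet(path: str) -> tuple[dict[str, str], dict[str, str]]:
    """Sample sheet TSV (sample_id, path, condition) -> (paths, conditions)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"sample sheet not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "path", "condition"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return (dict(zip(df["sample_id"], df["path"])),
            dict(zip(df["sample_id"], df["condition"])))


def _gene_of_junction(models: am.GeneModelSet):
    spans = [(g.chrom, *g.span, g.id) for g in models]

    def lookup(chrom: str, donor: int, acceptor: int) -> str:
        for c, lo, hi, gid in spans:
            if c == chrom and lo <= donor and acceptor <= hi:
                return gid
        return ""
    return lookup


def analyze(models: am.GeneModelSet,
            alignments: dict[str, str],
            conditions: dict[str, str],
            config: RunConfig | None = None) -> PipelineResult:
    """Run every stage on loaded inputs.

    ``alignments`` maps sample id to SAM/BAM path and ``conditions`` maps
    sample id to one of exactly two condition labels.
    """
    cfg = config or RunConfig()
    conds = sorted(set(conditions.values()))
    if len(conds) != 2:
        raise ValueError(f"exactly two conditions required, got {conds}")
    cond_a = cfg.reference_condition or conds[0]
    cond_b = next(c for c in conds if c != cond_a)
    log: dict = {}

    # --- flatten ---------------------------------------------------------
    exonic = am.flatten_exonic_parts(models)
    intronic = am.derive_intronic_parts(models, exonic)
    windows = am.window_introns(intronic, width=cfg.intron_window)
    catalog = am.junction_catalog(models)
    log["flatten"] = {"exonic_parts": len(exonic), "intronic_parts": len(intronic),
                      "intron_windows": len(windows), "annotated_junctions": len(catalog)}

    # --- count -----------------------------------------------------------
    all_features = exonic + intronic + windows
    counts = ac.count_features(alignments, all_features, conditions=conditions)
    jcounts = ac.count_junctions(alignments, catalog, conditions=conditions)
    log["count"] = {"features": len(counts.counts), "junctions": len(jcounts.counts)}

    # --- coverage / expression / ratios ----------------------------------
    ref_lengths = None
    cov_by_condition: dict[str, ac.CoverageTrack] = {}
    for cond in conds:
        tracks = [ac.coverage_track(alignments[s], reference_lengths=ref_lengths,
                                    sample_id=s)
                  for s in sorted(alignments) if conditions[s] == cond]
        cov_by_condition[cond] = ac.pool_coverage(tracks, label=cond)

    expressed = irm.expressed_genes(counts, exonic, cfg.read_length,
                                    threshold=cfg.expression_threshold)
    contexts = [ctx for ctx in am.intron_contexts(exonic, intronic)
                if ctx.intron.gene_id in expressed]
    ssratios = irm.ss_ratio_records(contexts, cov_by_condition,
                                    window=cfg.ss_window)
    log["ssratio"] = {"expressed_genes": len(expressed), "introns": len(ssratios)}

    # --- differential usage ----------------------------------------------
    exonic_ids = [f.id for f in exonic]
    gene_of = pd.Series({f.id: f.gene_id for f in all_features})
    gene_totals = counts.counts.loc[exonic_ids].groupby(
        gene_of.loc[exonic_ids]).sum()
    intron_ids = [f.id for f in intronic] + [f.id for f in windows]

    results = []
    for fclass, ids in (("exon", exonic_ids), ("intron", intron_ids)):
        sub = counts.counts.loc[ids]
        keep = du.filter_features(sub, fclass)
        if len(keep):
            results.append(du.test_usage(sub.loc[keep], gene_totals,
                                         gene_of, conditions, fclass,
                                         condition_a=cond_a, condition_b=cond_b))
    usage_results = du.adjust_fdr(pd.concat(results), alpha=cfg.fdr_alpha) \
        if results else pd.DataFrame()

    jlookup = _gene_of_junction(models)
    keep_j = du.filter_features(jcounts.counts, "junction")
    if len(keep_j):
        jsub = jcounts.counts.loc[keep_j]
        jgenes = pd.Series([jlookup(*key) for key in jsub.index], index=jsub.index)
        junction_results = du.adjust_fdr(
            du.test_usage(jsub, gene_totals, jgenes, conditions, "junction",
                          condition_a=cond_a, condition_b=cond_b),
            alpha=cfg.fdr_alpha)
    else:
        junction_results = pd.DataFrame()
    log["diff"] = {
        "tested_exon_intron": int(usage_results["p_value"].notna().sum())
        if not usage_results.empty else 0,
        "tested_junction": int(junction_results["p_value"].notna().sum())
        if not junction_results.empty else 0,
    }

    # --- cryptic + scoring -----------------------------------------------
    window_ids_of = {}
    for w in windows:
        window_ids_of.setdefault(w.parent_intron_id, []).append(w.id)
    cryptic: dict[str, sc.CrypticJunctionReport] = {}
    rows: list[sc.BooleanFeatureRow] = []
    ssr_by_intron = {r.intron_id: r for r in ssratios}
    for ctx in contexts:
        intr = ctx.intron
        rep = sc.detect_cryptic(jcounts, catalog, intr,
                                min_reads=cfg.cryptic_min_reads,
                                min_junctions=cfg.cryptic_min_junctions)
        cryptic[intr.id] = rep
        flanks = [e.id for e in (ctx.upstream, ctx.downstream) if e is not None]
        rows.append(sc.assemble_features(
            intr, ssr_by_intron.get(intr.id),
            usage_results if not usage_results.empty else pd.DataFrame(
                columns=["significant", "fdr_adjusted_p"]),
            junction_results if not junction_results.empty else None,
            rep, flanks, window_ids_of.get(intr.id, []),
            cond_a, cond_b, ratio_delta=cfg.ratio_delta,
        ))
    if rows:
        rows = sc.rank_introns(rows)
    log["score"] = {"scored_introns": len(rows)}

    # --- enrichment -------------------------------------------------------
    labels = ee.classify_events(models)
    exon_of_intron = map_intron_downstream_exons(models, intronic)
    selected = ee.select_high_ir_exons(ssratios, exon_of_intron, cond_a,
                                       threshold=cfg.ir_threshold)
    enrichment = None
    if selected:
        enrichment = ee.permutation_enrichment(
            selected, sorted(labels), labels,
            resamples=cfg.resamples, seed=cfg.seed)
    log["enrich"] = {"universe": len(labels), "selected": len(selected)}

    # --- gene-set overlap --------------------------------------------------
    def sig_genes(df: pd.DataFrame, fclass: str) -> set[str]:
        if df.empty:
            return set()
        sub = df[(df["feature_class"] == fclass) & df["significant"]]
        return set(sub["gene_id"].dropna()) - {""}

    venn = sc.intersect_significant_genes(
        sig_genes(usage_results, "exon"),
        sig_genes(usage_results, "intron"),
        sig_genes(junction_results, "junction"),
    )

    return PipelineResult(
        models=models, exonic=exonic, intronic=intronic, windows=windows,
        catalog=catalog, feature_counts=counts, junction_counts=jcounts,
        expressed=expressed, ssratios=ssratios, usage_results=usage_results,
        junction_results=junction_results, cryptic=cryptic, rows=rows,
        enrichment=enrichment, venn=venn,
        condition_a=cond_a, condition_b=cond_b, stage_log=log,
    )


def map_intron_downstream_exons(models: am.GeneModelSet,
                                intronic: list[am.FlatFeature]) -> dict[str, str]:
    """Intron feature id -> universe exon id of its downstream exon.

    "Downstream" follows transcription: the annotation exon starting at the
    intron's genomic end on the plus strand, or ending at the intron's
    genomic start on the minus strand.
    """
    by_gene: dict[str, set[tuple[int, int]]] = {}
    for gene in models:
        by_gene[gene.id] = {e for t in gene.transcripts for e in t.exons}
    mapping: dict[str, str] = {}
    for intr in intronic:
        exons = by_gene.get(intr.gene_id, set())
        for s, e in exons:
            if (intr.strand != "-" and s == intr.end) or \
               (intr.strand == "-" and e == intr.start):
                mapping[intr.id] = ee.exon_event_id(intr.gene_id, s, e)
                break
    return mapping


def run_pipeline(config: RunConfig) -> str:
    """Load inputs per ``config``, run :func:`analyze`, write all outputs.

    Returns the output directory.  Fails with the stage name on any stage
    error; the resolved configuration and a per-stage log are written next
    to the outputs.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    stage = "load"
    try:
        if not os.path.exists(config.annotation):
            raise FileNotFoundError(f"annotation not found: {config.annotation}")
        models = am.load_annotation(config.annotation, dialect=config.dialect)
        alignments, conditions = read_sample_sheet(config.sample_sheet)
        stage = "analyze"
        res = analyze(models, alignments, conditions, config)
        stage = "write"
        out = config.output_dir
        am.write_features_tsv(res.exonic + res.intronic + res.windows,
                              os.path.join(out, "features.tsv"))
        am.write_junctions_tsv(res.catalog, os.path.join(out, "junction_catalog.tsv"))
        ac.write_counts_tsv(res.feature_counts, os.path.join(out, "feature_counts.tsv"))
        ac.write_junction_counts_tsv(res.junction_counts,
                                     os.path.join(out, "junction_counts.tsv"))
        irm.write_ratio_tsv(res.ssratios, os.path.join(out, "ss_ratios.tsv"))
        defined = [r.ratio_3ss.get(res.condition_a) for r in res.ssratios]
        defined = [x for x in defined if x is not None and x == x]
        if defined:
            with open(os.path.join(out, "retention_summary.json"), "w") as fh:
                json.dump(irm.retention_distribution(defined), fh, indent=1)
        if not res.usage_results.empty:
            du.write_results_tsv(res.usage_results,
                                 os.path.join(out, "usage_results.tsv"))
        if not res.junction_results.empty:
            du.write_results_tsv(res.junction_results,
                                 os.path.join(out, "junction_usage_results.tsv"))
        sc.write_score_tsv(res.rows, os.path.join(out, "score_table.tsv"))
        if res.enrichment is not None:
            ee.write_enrichment_tsv(res.enrichment,
                                    os.path.join(out, "event_enrichment.tsv"))
        with open(os.path.join(out, "venn_partition.json"), "w") as fh:
            json.dump({k: sorted(v) for k, v in res.venn.items()}, fh, indent=1)
        with open(os.path.join(out, "resolved_config.yaml"), "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh)
        with open(os.path.join(out, "run_log.json"), "w") as fh:
            json.dump(res.stage_log, fh, indent=1)
        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
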