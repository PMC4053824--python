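"""Gene-model parsing and the flattened feature universe.

A gene annotation (GTF or GFF3) is reduced to per-gene *flattened* features:
non-overlapping exonic parts (the projection of all transcript exons, split
at every exon boundary used by any isoform), intronic parts (the complement
within the gene span, for multi-exon genes), and fixed-width windows tiling
each intronic part so that local retention signal inside long introns is not
diluted.  These parts are the counting and testing units of the whole
pipeline.  A catalog of annotated splice junctions (consecutive-exon pairs
over all transcripts) is derived alongside; junctions seen in reads but
absent from this catalog are "cryptic".

All internal coordinates are 0-based half-open; GTF/GFF I/O converts from
the 1-based inclusive convention on the way in and back on the way out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils

logger = logging.getLogger(__name__)

DEFAULT_INTRON_WINDOW = 300


class AnnotationParseError(ValueError):
    """A line of the annotation file could not be parsed."""


class AnnotationValidationError(ValueError):
    """The annotation parsed but violates a structural requirement."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    id: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class GeneModel:
    id: str
    chrom: str
    strand: str  # "+" or "-"
    transcripts: list[Transcript]

    @property
    def span(self) -> tuple[int, int]:
        starts = [e[0] for t in self.transcripts for e in t.exons]
        ends = [e[1] for t in self.transcripts for e in t.exons]
        return min(starts), max(ends)


@dataclass
class GeneModelSet:
    genes: list[GeneModel]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class FlatFeature:
    """A non-overlapping exonic part, intronic part or intron window."""

    id: str
    gene_id: str
    kind: str  # exonic_part | intronic_part | intron_window
    chrom: str
    start: int
    end: int
    strand: str
    parent_intron_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def locus(self) -> str:
        """1-based inclusive display form, e.g. ``1:140013603-140014330``."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class JunctionKey:
    """A splice junction: the gap between a donor and an acceptor boundary.

    ``donor`` is the genomic end of the upstream exon (= gap start) and
    ``acceptor`` the genomic start of the downstream exon (= gap end), both
    0-based half-open, so ``donor < acceptor`` always holds in genomic
    coordinates regardless of strand.  ``annotated`` is informational and
    excluded from equality/hashing so read-derived keys match the catalog.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str = "."
    annotated: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.donor >= self.acceptor:
            raise ValueError(
                f"junction donor must precede acceptor: {self.donor} >= {self.acceptor}"
            )


# ---------------------------------------------------------------------------
# Annotation loading
# ---------------------------------------------------------------------------

def _prevalidate(path: str) -> None:
    # cheap structural check so errors carry a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise AnnotationParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(parts)}"
                )
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from exc
            if parts[2] == "exon" and end < start:
                raise AnnotationValidationError(
                    f"line {lineno}: exon end {end} < start {start}"
                )


def load_annotation(path: str, dialect: str = "gtf") -> GeneModelSet:
    """Parse a GTF (Ensembl dialect) or GFF3 file into a :class:`GeneModelSet`.

    Coordinates are converted from the file's 1-based inclusive convention
    to internal 0-based half-open intervals; exons are sorted within each
    transcript.  Both multi- and single-exon genes are returned.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    _prevalidate(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # transcript_id -> (gene_id, chrom, strand, [exons])
    tx: dict[str, dict] = {}
    tx_order: list[str] = []
    for f in db.features_of_type("exon", order_by=("seqid", "start")):
        if dialect == "gtf":
            try:
                gene_id = f["gene_id"][0]
                tx_id = f["transcript_id"][0]
            except KeyError as exc:
                raise AnnotationValidationError(
                    f"exon at {f.seqid}:{f.start}-{f.end} lacks gene_id/transcript_id"
                ) from exc
        else:
            parent = f.attributes.get("Parent")
            if not parent:
                raise AnnotationValidationError(
                    f"exon at {f.seqid}:{f.start}-{f.end} has no Parent"
                )
            tx_id = parent[0]
            tx_feat = db[tx_id]
            gp = tx_feat.attributes.get("Parent")
            gene_id = gp[0] if gp else tx_feat.attributes.get("gene_id", [tx_id])[0]
        rec = tx.get(tx_id)
        if rec is None:
            rec = {"gene_id": gene_id, "chrom": f.seqid, "strand": f.strand, "exons": []}
            tx[tx_id] = rec
            tx_order.append(tx_id)
        rec["exons"].append((f.start - 1, f.end))  # to 0-based half-open

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tx_id in tx_order:
        rec = tx[tx_id]
        exons = sorted(rec["exons"])
        if not exons:
            raise AnnotationValidationError(f"transcript {tx_id} has zero exons")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise AnnotationValidationError(
                    f"transcript {tx_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )
        gid = rec["gene_id"]
        if gid not in genes:
            genes[gid] = GeneModel(gid, rec["chrom"], rec["strand"] or ".", [])
            gene_order.append(gid)
        genes[gid].transcripts.append(Transcript(tx_id, exons))
    return GeneModelSet([genes[g] for g in gene_order])


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------

def _elementary_parts(gene: GeneModel) -> list[tuple[int, int]]:
    """Split the exon union at every boundary; merge runs whose covering
    transcript set is identical (equivalent to per-base labeling by the set
    of transcripts covering the base, then taking maximal runs)."""
    bounds = sorted({b for t in gene.transcripts for e in t.exons for b in e})
    segs: list[tuple[int, int, frozenset]] = []
    for lo, hi in zip(bounds, bounds[1:]):
        cover = frozenset(
            t.id for t in gene.transcripts
            if any(s <= lo and hi <= e for s, e in t.exons)
        )
        if cover:
            segs.append((lo, hi, cover))
    merged: list[tuple[int, int, frozenset]] = []
    for lo, hi, cov in segs:
        if merged and merged[-1][1] == lo and merged[-1][2] == cov:
            merged[-1] = (merged[-1][0], hi, cov)
        else:
            merged.append((lo, hi, cov))
    return [(lo, hi) for lo, hi, _ in merged]


def _index_order(parts: list[tuple[int, int]], strand: str) -> list[tuple[int, int]]:
    """Transcription order: genomic order on +, reversed on -."""
    return parts if strand != "-" else list(reversed(parts))


def flatten_exonic_parts(models: GeneModelSet) -> list[FlatFeature]:
    """Project each gene's transcript exons onto non-overlapping exonic parts.

    Parts are split at every exon boundary of any isoform; their union is
    base-identical to the union of the transcript exons.  Overlapping genes
    are flattened independently per gene_id (a warning is logged); parts are
    indexed in transcription order.
    """
    out: list[FlatFeature] = []
    by_chrom_strand: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for gene in models:
        parts = _elementary_parts(gene)
        lo, hi = gene.span
        by_chrom_strand.setdefault((gene.chrom, gene.strand), []).append((lo, hi, gene.id))
        for idx, (s, e) in enumerate(_index_order(parts, gene.strand)):
            out.append(FlatFeature(
                id=f"{gene.id}:exonic_part:{idx:03d}",
                gene_id=gene.id, kind="exonic_part",
                chrom=gene.chrom, start=s, end=e, strand=gene.strand,
            ))
    for (chrom, strand), spans in by_chrom_strand.items():
        spans.sort()
        for (lo1, hi1, g1), (lo2, hi2, g2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                logger.warning(
                    "genes %s and %s overlap on %s%s; flattened independently",
                    g1, g2, chrom, strand,
                )
    return out


def derive_intronic_parts(models: GeneModelSet,
                          exonic: list[FlatFeature]) -> list[FlatFeature]:
    """Complement of the exonic parts within each multi-exon gene's span.

    Single-exon genes, and genes where some isoform's exon covers every
    intron (so the exonic parts tile the whole span), yield no intronic
    parts.
    """
    by_gene: dict[str, list[FlatFeature]] = {}
    for f in exonic:
        by_gene.setdefault(f.gene_id, []).append(f)
    out: list[FlatFeature] = []
    for gene in models:
        parts = sorted((f.start, f.end) for f in by_gene.get(gene.id, []))
        if len(parts) < 2:
            continue
        gaps = [
            (e1, s2) for (_, e1), (s2, _) in zip(parts, parts[1:]) if s2 > e1
        ]
        for idx, (s, e) in enumerate(_index_order(gaps, gene.strand)):
            out.append(FlatFeature(
                id=f"{gene.id}:intronic_part:{idx:03d}",
                gene_id=gene.id, kind="intronic_part",
                chrom=gene.chrom, start=s, end=e, strand=gene.strand,
            ))
    return out


def window_introns(intronic: list[FlatFeature],
                   width: int = DEFAULT_INTRON_WINDOW) -> list[FlatFeature]:
    """Tile each intronic part with consecutive ``width``-bp windows.

    Windows run from the part's genomic start; the final window keeps the
    remainder (length 1..width) rather than being merged, so window starts
    are deterministic.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    out: list[FlatFeature] = []
    for part in intronic:
        idx = 0
        for s in range(part.start, part.end, width):
            e = min(s + width, part.end)
            out.append(FlatFeature(
                id=f"{part.id}:w{idx:03d}",
                gene_id=part.gene_id, kind="intron_window",
                chrom=part.chrom, start=s, end=e, strand=part.strand,
                parent_intron_id=part.id,
            ))
            idx += 1
    return out


def junction_catalog(models: GeneModelSet) -> set[JunctionKey]:
    """All annotated junctions: one key per distinct consecutive-exon pair."""
    catalog: set[JunctionKey] = set()
    for gene in models:
        for t in gene.transcripts:
            for donor, acceptor in t.introns():
                catalog.add(JunctionKey(
                    gene.chrom, donor, acceptor, gene.strand, annotated=True,
                ))
    return catalog


# ---------------------------------------------------------------------------
# Adjacency helpers (used by the ratio and scoring stages)
# ---------------------------------------------------------------------------

@dataclass
class IntronContext:
    """An intronic part together with its flanking exonic parts.

    ``upstream``/``downstream`` follow transcription direction: upstream is
    the exon whose 3' end is the intron's donor side.
    """

    intron: FlatFeature
    upstream: FlatFeature | None
    downstream: FlatFeature | None


def intron_contexts(exonic: list[FlatFeature],
                    intronic: list[FlatFeature]) -> list[IntronContext]:
    """Pair each intronic part with its genomically adjacent exonic parts."""
    by_gene: dict[str, dict] = {}
    for f in exonic:
        g = by_gene.setdefault(f.gene_id, {"starts": {}, "ends": {}})
        g["starts"][f.start] = f
        g["ends"][f.end] = f
    out = []
    for intr in intronic:
        g = by_gene.get(intr.gene_id, {"starts": {}, "ends": {}})
        left = g["ends"].get(intr.start)     # exon ending where intron starts
        right = g["starts"].get(intr.end)    # exon starting where intron ends
        if intr.strand == "-":
            up, down = right, left
        else:
            up, down = left, right
        out.append(IntronContext(intron=intr, upstream=up, downstream=down))
    return out


# ---------------------------------------------------------------------------
# TSV / GTF export
# ---------------------------------------------------------------------------

def write_features_tsv(features: list[FlatFeature], path: str) -> None:
    """GFF-like TSV: chrom, start(1-based), end, strand, gene_id, feature_id, kind."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tgene_id\tfeature_id\tkind\n")
        for f in features:
            fh.write(f"{f.chrom}\t{f.start + 1}\t{f.end}\t{f.strand}\t"
                     f"{f.gene_id}\t{f.id}\t{f.kind}\n")


def write_junctions_tsv(catalog: set[JunctionKey], path: str,
                        gene_of: dict[JunctionKey, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tdonor\tacceptor\tstrand\tannotated\tgene_id\n")
        for j in sorted(catalog, key=lambda j: (j.chrom, j.donor, j.acceptor)):
            gene = (gene_of or {}).get(j, "")
            fh.write(f"{j.chrom}\t{j.donor}\t{j.acceptor}\t{j.strand}\t"
                     f"{int(j.annotated)}\t{gene}\n")


def write_gtf(models: GeneModelSet, path: str, source: str = "irsig") -> None:
    """Write a GeneModelSet back out as Ensembl-dialect GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in models:
            for t in gene.transcripts:
                for s, e in t.exons:
                    attrs = f'gene_id "{gene.id}"; transcript_id "{t.id}";'
                    fh.write(f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                             f"{gene.strand}\t.\t{attrs}\n")
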