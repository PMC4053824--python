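"""Synthetic annotations, ground truth and spliced reads.

Emulates oligo-dT-primed polyA+ RNA-seq as the analysis assumes it: most
transcript molecules are fully spliced, a minority retain specific introns
(a per-intron, per-condition retention fraction r in [0, 1]), cassette
exons are included with a per-condition fraction psi, reads are fixed
length and placed only in junction-consistent positions (within the exons
of the molecule, spanning its splice junctions with N-CIGARs, or inside
retained intron sequence), per-gene read counts are negative-binomially
dispersed around a target mean exonic coverage, and cryptic junctions can
be injected as reads spanning unannotated gaps.  No sequencing-error or
fragment-length model; quality strings are constant placeholders.

Every output is a pure function of the configuration seed.  Default
parameter values describe the regime the pipeline targets: 125 bp
single-end reads, two conditions with replicates, retention fractions
drawn from a mixture in which ~13% of introns are appreciably retained and
the rest are nearly fully spliced.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .annotation_model import GeneModel, GeneModelSet, Transcript, write_gtf

DEFAULT_READ_LENGTH = 125
DEFAULT_NB_DISPERSION = 0.05
_CHROM = "chrS"
_GENE_GAP = 500


@dataclass
class SimConfig:
    """Knobs of the generator; the seed fully determines all output."""

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_length: tuple[int, int] = (100, 250)
    intron_length: tuple[int, int] = (200, 800)
    conditions: tuple[str, str] = ("A", "B")
    depth: float = 100.0              # mean exonic coverage per sample
    read_length: int = DEFAULT_READ_LENGTH
    nb_dispersion: float = DEFAULT_NB_DISPERSION
    # event-type composition of the gene set
    event_mix: dict = field(default_factory=lambda: {
        "CNE": 0.4, "CE": 0.2, "MXE": 0.1, "IR": 0.1, "A3SS": 0.1, "A5SS": 0.1,
    })
    # retention-fraction mixture: most introns nearly spliced, a minority
    # appreciably retained (same r in both conditions unless a scenario
    # overrides it)
    retention_base_beta: tuple[float, float] = (0.5, 15.0)
    retention_high_frac: float = 0.13
    retention_high_beta: tuple[float, float] = (2.0, 6.0)
    psi_range: tuple[float, float] = (0.3, 0.9)
    boundary_shift: int = 30          # A3SS/A5SS alternative-boundary offset

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise ValueError("invalid exons_per_gene range")
        if self.exon_length[0] <= self.boundary_shift:
            raise ValueError("exons must be longer than the boundary shift")
        if not 0 <= self.retention_high_frac <= 1:
            raise ValueError("retention_high_frac must be in [0, 1]")


@dataclass
class GeneTruth:
    """Everything the simulator uses for one gene."""

    gene_id: str
    chrom: str
    strand: str
    event_type: str                       # CNE/CE/MXE/IR/A3SS/A5SS
    primary_chain: list[tuple[int, int]]  # exon chain of isoform 0
    alt_chain: list[tuple[int, int]] | None
    event_exon: tuple[int, int] | None
    depth: dict[str, float]               # condition -> mean exonic coverage
    psi: dict[str, float]                 # condition -> P(primary isoform)
    intron_r: dict[tuple[int, int], dict[str, float]]  # (donor, acceptor) -> cond -> r
    dispersion: float = DEFAULT_NB_DISPERSION

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.primary_chain)

    def set_intron_r(self, index: int, values: dict[str, float]) -> None:
        """Override r for the index-th gap of the primary chain."""
        gaps = [(self.primary_chain[i][1], self.primary_chain[i + 1][0])
                for i in range(len(self.primary_chain) - 1)]
        self.intron_r[gaps[index]] = dict(values)


@dataclass
class CrypticTruth:
    """An injected unannotated junction and its per-sample read support."""

    gene_id: str
    donor: int
    acceptor: int
    reads: dict[str, int]  # condition -> reads per replicate


@dataclass
class SimTruth:
    conditions: list[str]
    chrom_lengths: dict[str, int]
    read_length: int
    genes: dict[str, GeneTruth]
    cryptics: list[CrypticTruth] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Annotation + truth generation
# ---------------------------------------------------------------------------

def _event_assignment(config: SimConfig) -> list[str]:
    types, fracs = zip(*sorted(config.event_mix.items()))
    counts = [int(round(f * config.n_genes)) for f in fracs]
    while sum(counts) < config.n_genes:
        counts[int(np.argmax(fracs))] += 1
    while sum(counts) > config.n_genes:
        counts[int(np.argmax(counts))] -= 1
    out: list[str] = []
    for t, c in zip(types, counts):
        out.extend([t] * c)
    return out[: config.n_genes]


def _draw_r(rng: np.random.Generator, config: SimConfig) -> float:
    if rng.random() < config.retention_high_frac:
        a, b = config.retention_high_beta
    else:
        a, b = config.retention_base_beta
    return float(rng.beta(a, b))


def generate_annotation(config: SimConfig,
                        gtf_path: str | None = None) -> tuple[GeneModelSet, SimTruth]:
    """Build a deterministic gene set (with event-type isoforms) and truth.

    Genes are laid head-to-tail on one synthetic chromosome.  Genes of
    event type CE/MXE/IR/A3SS/A5SS get a second isoform realising the
    event, so their truth labels are recoverable from the annotation by
    ``classify_events``.  If ``gtf_path`` is given, the annotation is also
    written as GTF (byte-identical across runs with the same config).
    """
    rng = np.random.default_rng(config.seed)
    events = _event_assignment(config)
    genes: list[GeneModel] = []
    truths: dict[str, GeneTruth] = {}
    cursor = _GENE_GAP
    for gi, event in enumerate(events):
        gene_id = f"G{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        lo, hi = config.exons_per_gene
        n_exons = int(rng.integers(lo, hi + 1))
        min_needed = {"CE": 3, "IR": 2, "A3SS": 3, "A5SS": 3, "MXE": 4}.get(event, 1)
        n_exons = max(n_exons, min_needed)
        chain: list[tuple[int, int]] = []
        pos = cursor
        for _ in range(n_exons):
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            chain.append((pos, pos + elen))
            pos += elen + int(rng.integers(config.intron_length[0],
                                           config.intron_length[1] + 1))
        cursor = chain[-1][1] + _GENE_GAP

        alt_chain: list[tuple[int, int]] | None = None
        event_exon: tuple[int, int] | None = None
        mid = n_exons // 2
        if event == "CE":
            event_exon = chain[mid]
            alt_chain = chain[:mid] + chain[mid + 1:]
        elif event == "MXE":
            # primary keeps exon mid (skipping mid+1), the alternative
            # isoform swaps in exon mid+1 instead; both stay internal so
            # each isoform joins across the other's exon
            mid = min(mid, n_exons - 3)
            event_exon = chain[mid]
            alt_chain = chain[:mid] + chain[mid + 1:]
            chain = chain[:mid + 1] + chain[mid + 2:]
        elif event == "IR":
            # alternative isoform merges exon mid with the following intron
            event_exon = chain[mid]
            merged = (chain[mid][0], chain[mid + 1][1])
            alt_chain = chain[:mid] + [merged] + chain[mid + 2:]
        elif event == "A3SS":
            s, e = chain[mid]
            # shift the acceptor-side boundary (start on +, end on -)
            shifted = (s + config.boundary_shift, e) if strand == "+" \
                else (s, e - config.boundary_shift)
            event_exon = chain[mid]
            alt_chain = chain[:mid] + [shifted] + chain[mid + 1:]
        elif event == "A5SS":
            s, e = chain[mid]
            shifted = (s, e - config.boundary_shift) if strand == "+" \
                else (s + config.boundary_shift, e)
            event_exon = chain[mid]
            alt_chain = chain[:mid] + [shifted] + chain[mid + 1:]

        transcripts = [Transcript(f"{gene_id}.t0", list(chain))]
        if alt_chain is not None:
            transcripts.append(Transcript(f"{gene_id}.t1", list(alt_chain)))
        genes.append(GeneModel(gene_id, _CHROM, strand, transcripts))

        intron_r: dict[tuple[int, int], dict[str, float]] = {}
        for chain_ in [chain] + ([alt_chain] if alt_chain else []):
            for (s1, e1), (s2, e2) in zip(chain_, chain_[1:]):
                gap = (e1, s2)
                if gap not in intron_r:
                    r = _draw_r(rng, config)
                    intron_r[gap] = {c: r for c in config.conditions}
        psi = float(rng.uniform(*config.psi_range)) if alt_chain else 1.0
        truths[gene_id] = GeneTruth(
            gene_id=gene_id, chrom=_CHROM, strand=strand, event_type=event,
            primary_chain=chain, alt_chain=alt_chain, event_exon=event_exon,
            depth={c: config.depth for c in config.conditions},
            psi={c: psi for c in config.conditions},
            intron_r=intron_r,
            dispersion=config.nb_dispersion,
        )

    models = GeneModelSet(genes)
    truth = SimTruth(
        conditions=list(config.conditions),
        chrom_lengths={_CHROM: cursor + _GENE_GAP},
        read_length=config.read_length,
        genes=truths,
    )
    if gtf_path is not None:
        write_gtf(models, gtf_path)
    return models, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _molecule_blocks(gt: GeneTruth, condition: str,
                     rng: np.random.Generator) -> list[tuple[int, int]]:
    """One transcript molecule: exon chain choice, then per-gap retention."""
    chain = gt.primary_chain
    if gt.alt_chain is not None and rng.random() >= gt.psi[condition]:
        chain = gt.alt_chain
    blocks: list[tuple[int, int]] = [chain[0]]
    for (s1, e1), (s2, e2) in zip(chain, chain[1:]):
        r = gt.intron_r.get((e1, s2), {}).get(condition, 0.0)
        if r > 0 and rng.random() < r:
            blocks[-1] = (blocks[-1][0], e2)  # gap retained: merge through
        else:
            blocks.append((s2, e2))
    return blocks


def _read_from_molecule(blocks: list[tuple[int, int]], offset: int,
                        read_len: int) -> list[tuple[int, int]]:
    """Genomic M-segments of a read at molecule coordinate ``offset``."""
    segs: list[tuple[int, int]] = []
    remaining = read_len
    pos = offset
    for s, e in blocks:
        blen = e - s
        if pos >= blen:
            pos -= blen
            continue
        take = min(blen - pos, remaining)
        segs.append((s + pos, s + pos + take))
        remaining -= take
        pos = 0
        if remaining == 0:
            break
    return segs


def _cigar(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ops: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(segs):
        if i > 0:
            ops.append((3, s - segs[i - 1][1]))  # N
        ops.append((0, e - s))                   # M
    return ops


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with Var = mean + dispersion * mean^2."""
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def simulate_reads(models: GeneModelSet, truth: SimTruth, condition: str,
                   replicate: int, seed: int, path: str) -> str:
    """Write one sample's spliced alignments as SAM.

    Reads are placed uniformly along independently drawn molecules, so a
    gap in a molecule appears as an N-CIGAR junction and retained intron
    sequence receives M coverage; per-gene read counts are negative-
    binomial around depth * exonic_length / read_length.  Cryptic truth
    entries add their stated number of junction-spanning reads.
    """
    if condition not in truth.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = truth.conditions.index(condition)
    rng = np.random.default_rng([seed, cond_idx, replicate])
    read_len = truth.read_length
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)}
               for c, l in sorted(truth.chrom_lengths.items())],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        tid_of = {c: i for i, (c, _) in
                  enumerate(sorted(truth.chrom_lengths.items()))}
        for gene_id in sorted(truth.genes):
            gt = truth.genes[gene_id]
            mean_reads = gt.depth[condition] * gt.exonic_length() / read_len
            n_reads = _nb_draw(rng, mean_reads, gt.dispersion)
            # longest possible molecule: the primary chain with every gap
            # retained; molecules are accepted proportional to their number
            # of read start positions so per-base coverage is uniform over
            # the molecule population (reads sample bases, not molecules)
            max_positions = (gt.primary_chain[-1][1] - gt.primary_chain[0][0]
                             - read_len + 1)
            for ri in range(n_reads):
                for _ in range(100):
                    blocks = _molecule_blocks(gt, condition, rng)
                    mol_len = sum(e - s for s, e in blocks)
                    positions = mol_len - read_len + 1
                    if positions >= 1 and \
                       rng.random() * max_positions < positions:
                        break
                else:
                    continue
                offset = int(rng.integers(0, positions))
                segs = _read_from_molecule(blocks, offset, read_len)
                _emit(out, f"{gene_id}:{condition}:{replicate}:{ri}",
                      tid_of[gt.chrom], segs, read_len)
        for ci, cr in enumerate(truth.cryptics):
            n = cr.reads.get(condition, 0)
            gt = truth.genes[cr.gene_id]
            anchor = read_len // 2
            segs = [(cr.donor - anchor, cr.donor),
                    (cr.acceptor, cr.acceptor + read_len - anchor)]
            for ri in range(n):
                _emit(out, f"cryptic{ci}:{condition}:{replicate}:{ri}",
                      tid_of[gt.chrom], segs, read_len)
    return path


def _emit(out: pysam.AlignmentFile, name: str, tid: int,
          segs: list[tuple[int, int]], read_len: int) -> None:
    a = pysam.AlignedSegment(out.header)
    a.query_name = name
    a.reference_id = tid
    a.reference_start = segs[0][0]
    a.mapping_quality = 50
    a.cigartuples = _cigar(segs)
    a.query_sequence = "A" * read_len
    a.flag = 0
    out.write(a)


def simulate_samples(models: GeneModelSet, truth: SimTruth, out_dir: str,
                     seed: int, replicates: int = 2) -> tuple[dict[str, str], dict[str, str]]:
    """All condition x replicate SAMs plus a sample sheet.

    Returns (sample_id -> SAM path, sample_id -> condition); also writes
    ``sample_sheet.tsv`` in ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    alignments: dict[str, str] = {}
    conditions: dict[str, str] = {}
    for cond in truth.conditions:
        for rep in range(1, replicates + 1):
            sample = f"{cond}{rep}"
            path = os.path.join(out_dir, f"{sample}.sam")
            simulate_reads(models, truth, cond, rep, seed, path)
            alignments[sample] = path
            conditions[sample] = cond
    sheet = os.path.join(out_dir, "sample_sheet.tsv")
    with open(sheet, "w") as fh:
        fh.write("sample_id\tpath\tcondition\n")
        for sample in alignments:
            fh.write(f"{sample}\t{alignments[sample]}\t{conditions[sample]}\n")
    return alignments, conditions


# ---------------------------------------------------------------------------
# Truth round-trip
# ---------------------------------------------------------------------------

def _chain_str(chain: list[tuple[int, int]] | None) -> str:
    if chain is None:
        return ""
    return ",".join(f"{s}-{e}" for s, e in chain)


def _parse_chain(text: str) -> list[tuple[int, int]] | None:
    if not text:
        return None
    out = []
    for part in text.split(","):
        s, _, e = part.partition("-")
        out.append((int(s), int(e)))
    return out


def write_truth(truth: SimTruth, path: str) -> None:
    """Lossless TSV serialization of a :class:`SimTruth`."""
    with open(path, "w") as fh:
        fh.write("record\tgene_id\tfield\tcondition\tvalue\n")
        for c in truth.conditions:
            fh.write(f"meta\t\tcondition\t{c}\t\n")
        for chrom in sorted(truth.chrom_lengths):
            fh.write(f"meta\t\tchrom_length\t{chrom}\t{truth.chrom_lengths[chrom]}\n")
        fh.write(f"meta\t\tread_length\t\t{truth.read_length}\n")
        for gid in sorted(truth.genes):
            gt = truth.genes[gid]
            fh.write(f"gene\t{gid}\tchrom\t\t{gt.chrom}\n")
            fh.write(f"gene\t{gid}\tstrand\t\t{gt.strand}\n")
            fh.write(f"gene\t{gid}\tevent_type\t\t{gt.event_type}\n")
            fh.write(f"gene\t{gid}\tdispersion\t\t{gt.dispersion!r}\n")
            fh.write(f"gene\t{gid}\tprimary_chain\t\t{_chain_str(gt.primary_chain)}\n")
            fh.write(f"gene\t{gid}\talt_chain\t\t{_chain_str(gt.alt_chain)}\n")
            ee = _chain_str([gt.event_exon]) if gt.event_exon else ""
            fh.write(f"gene\t{gid}\tevent_exon\t\t{ee}\n")
            for c in truth.conditions:
                fh.write(f"depth\t{gid}\t\t{c}\t{gt.depth[c]!r}\n")
                fh.write(f"psi\t{gid}\t\t{c}\t{gt.psi[c]!r}\n")
            for (d, a) in sorted(gt.intron_r):
                for c in truth.conditions:
                    fh.write(f"intron_r\t{gid}\t{d}-{a}\t{c}\t{gt.intron_r[(d, a)][c]!r}\n")
        for cr in truth.cryptics:
            for c in truth.conditions:
                fh.write(f"cryptic\t{cr.gene_id}\t{cr.donor}-{cr.acceptor}\t{c}\t"
                         f"{cr.reads.get(c, 0)}\n")


def read_truth(path: str) -> SimTruth:
    conditions: list[str] = []
    chrom_lengths: dict[str, int] = {}
    read_length = DEFAULT_READ_LENGTH
    genes: dict[str, GeneTruth] = {}
    cryptics: dict[tuple[str, int, int], CrypticTruth] = {}

    def gene(gid: str) -> GeneTruth:
        if gid not in genes:
            genes[gid] = GeneTruth(gene_id=gid, chrom="", strand="+",
                                   event_type="CNE", primary_chain=[],
                                   alt_chain=None, event_exon=None,
                                   depth={}, psi={}, intron_r={})
        return genes[gid]

    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            record, gid, fieldname, cond, value = line.rstrip("\n").split("\t")
            if record == "meta":
                if fieldname == "condition":
                    conditions.append(cond)
                elif fieldname == "chrom_length":
                    chrom_lengths[cond] = int(value)
                elif fieldname == "read_length":
                    read_length = int(value)
            elif record == "gene":
                gt = gene(gid)
                if fieldname == "chrom":
                    gt.chrom = value
                elif fieldname == "strand":
                    gt.strand = value
                elif fieldname == "event_type":
                    gt.event_type = value
                elif fieldname == "dispersion":
                    gt.dispersion = float(value)
                elif fieldname == "primary_chain":
                    gt.primary_chain = _parse_chain(value) or []
                elif fieldname == "alt_chain":
                    gt.alt_chain = _parse_chain(value)
                elif fieldname == "event_exon":
                    parsed = _parse_chain(value)
                    gt.event_exon = parsed[0] if parsed else None
            elif record == "depth":
                gene(gid).depth[cond] = float(value)
            elif record == "psi":
                gene(gid).psi[cond] = float(value)
            elif record == "intron_r":
                d, _, a = fieldname.partition("-")
                gene(gid).intron_r.setdefault((int(d), int(a)), {})[cond] = float(value)
            elif record == "cryptic":
                d, _, a = fieldname.partition("-")
                key = (gid, int(d), int(a))
                if key not in cryptics:
                    cryptics[key] = CrypticTruth(gid, int(d), int(a), {})
                cryptics[key].reads[cond] = int(value)
    return SimTruth(conditions=conditions, chrom_lengths=chrom_lengths,
                    read_length=read_length, genes=genes,
                    cryptics=list(cryptics.values()))


# ---------------------------------------------------------------------------
# Scripted scenario: one engineered regulated intron
# ---------------------------------------------------------------------------

def thunder_scenario(seed: int,
                     n_background_cne: int = 14,
                     n_ce_retained: int = 24,
                     depth: float = 300.0) -> tuple[GeneModelSet, SimTruth, dict]:
    """A two-condition scenario with one engineered regulated intron.

    Condition A mimics cells where the regulator is active: gene ``G0000``
    has a cassette exon included at psi=0.2 whose flanking introns are
    retained at r=0.32, with two cryptic junctions injected inside the
    upstream flanking intron; in condition B the exon is included at
    psi=0.9 and the introns spliced (r=0.02).  ``G0001`` is the matched
    unregulated control (identical structure, no condition differences,
    r=0.02, no cryptics).  A further ``n_ce_retained`` cassette-exon genes
    carry non-differential retention (r=0.3 both conditions) so exons
    downstream of retained introns over-represent cassette exons, and
    ``n_background_cne`` single-isoform genes complete the universe.

    Returns (models, truth, info) where info names the engineered intron
    and its matched control.
    """
    n_genes = 2 + n_ce_retained + n_background_cne
    config = SimConfig(
        seed=seed, n_genes=n_genes, depth=depth,
        exons_per_gene=(5, 5), exon_length=(120, 200),
        intron_length=(250, 600),
        event_mix={"CE": (2 + n_ce_retained) / n_genes,
                   "CNE": n_background_cne / n_genes},
    )
    models, truth = generate_annotation(config)
    ce_genes = [g for g in sorted(truth.genes)
                if truth.genes[g].event_type == "CE"]
    regulated, control = ce_genes[0], ce_genes[1]

    def flanking_gaps(gt: GeneTruth) -> list[tuple[int, int]]:
        chain = gt.primary_chain
        mid = chain.index(gt.event_exon)
        return [(chain[mid - 1][1], chain[mid][0]),
                (chain[mid][1], chain[mid + 1][0])]

    # the engineered regulated gene
    gt = truth.genes[regulated]
    gt.psi = {"A": 0.2, "B": 0.9}
    up_gap, down_gap = flanking_gaps(gt)
    for gap in (up_gap, down_gap):
        gt.intron_r[gap] = {"A": 0.32, "B": 0.02}
    # compound skip gap: retaining it keeps exon + both introns
    skip_gap = (up_gap[0], down_gap[1])
    gt.intron_r[skip_gap] = {"A": 0.32, "B": 0.02}
    mid1 = up_gap[0] + (up_gap[1] - up_gap[0]) // 3
    mid2 = up_gap[0] + 2 * (up_gap[1] - up_gap[0]) // 3
    truth.cryptics.extend([
        CrypticTruth(regulated, mid1, mid1 + 60, {"A": 6, "B": 0}),
        CrypticTruth(regulated, mid2, mid2 + 60, {"A": 6, "B": 0}),
    ])

    # the matched unregulated control
    gt = truth.genes[control]
    gt.psi = {"A": 0.9, "B": 0.9}
    up_gap_c, down_gap_c = flanking_gaps(gt)
    for gap in (up_gap_c, down_gap_c, (up_gap_c[0], down_gap_c[1])):
        gt.intron_r[gap] = {"A": 0.02, "B": 0.02}

    # background cassette genes: retained in both conditions (high 3'SS
    # ratio in A, but no condition contrast)
    for g in ce_genes[2:]:
        bgt = truth.genes[g]
        bgt.psi = {"A": 0.5, "B": 0.5}
        u, d = flanking_gaps(bgt)
        for gap in (u, d, (u[0], d[1])):
            bgt.intron_r[gap] = {"A": 0.3, "B": 0.3}

    # everything else: nearly fully spliced, identically in both conditions
    for g, bgt in truth.genes.items():
        if g in (regulated, control) or g in ce_genes[2:]:
            continue
        for gap in bgt.intron_r:
            r = min(bgt.intron_r[gap]["A"], 0.03)
            bgt.intron_r[gap] = {"A": r, "B": r}

    info = {
        "regulated_gene": regulated,
        "regulated_intron_gap": up_gap,
        "control_gene": control,
        "control_intron_gap": up_gap_c,
    }
    return models, truth, info


# ---------------------------------------------------------------------------
# Direct count simulation (for testing the usage test at scale)
# ---------------------------------------------------------------------------

def simulate_usage_counts(n_features: int,
                          seed: int,
                          features_per_gene: int = 10,
                          replicates: int = 2,
                          mean_feature: float = 100.0,
                          mean_rest: float = 1000.0,
                          dispersion: float = DEFAULT_NB_DISPERSION,
                          usage_shift: dict[int, tuple[float, float]] | None = None):
    """Feature and gene-remainder counts straight from the noise model.

    Per feature and sample, the feature count and the rest-of-gene count
    are independent negative-binomial draws (Var = mu + dispersion mu^2);
    by default usage is identical in both conditions (a null data set).
    ``usage_shift`` maps feature row -> (usage_A, usage_B) to plant effects,
    scaling the feature mean while keeping the rest mean fixed.

    Returns (counts, gene_totals, feature_genes, conditions) ready for
    :func:`irsig.differential_usage.test_usage` with feature class
    ``intron``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    samples = [f"A{r}" for r in range(1, replicates + 1)] + \
              [f"B{r}" for r in range(1, replicates + 1)]
    conditions = {s: s[0] for s in samples}
    base_usage = mean_feature / (mean_feature + mean_rest)
    n = 1.0 / dispersion if dispersion > 0 else None

    def nb(mean, size):
        if n is None:
            return rng.poisson(mean, size=size)
        p = n / (n + mean)
        return rng.negative_binomial(n, p, size=size)

    n_genes = (n_features + features_per_gene - 1) // features_per_gene
    k = np.empty((n_features, len(samples)), dtype=np.int64)
    rest = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        cond = conditions[s]
        mu_k = np.full(n_features, mean_feature)
        for row, (ua, ub) in (usage_shift or {}).items():
            u = ua if cond == "A" else ub
            mu_k[row] = mean_rest * u / (1.0 - u)
        k[:, j] = nb(mu_k, n_features)
        rest[:, j] = nb(mean_rest, n_genes)  # one remainder draw per gene

    feature_ids = [f"f{i:05d}" for i in range(n_features)]
    gene_ids = [f"g{i // features_per_gene:05d}" for i in range(n_features)]
    counts = pd.DataFrame(k, index=pd.Index(feature_ids, name="feature_id"),
                          columns=samples)
    feature_genes = pd.Series(gene_ids, index=counts.index)
    gene_totals = pd.DataFrame(
        rest, index=pd.Index(sorted(set(gene_ids)), name="gene_id"),
        columns=samples,
    )
    return counts, gene_totals, feature_genes, conditions, base_usage
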