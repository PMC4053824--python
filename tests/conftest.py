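import textwrap

import pytest

from irsig.annotation_model import GeneModel, GeneModelSet, Transcript


def make_gene(gene_id, chains, chrom="chr1", strand="+"):
    """Build a GeneModel from a list of exon chains (one per transcript)."""
    transcripts = [Transcript(f"{gene_id}.t{i}", list(chain))
                   for i, chain in enumerate(chains)]
    return GeneModel(gene_id, chrom, strand, transcripts)


def make_models(*genes):
    return GeneModelSet(list(genes))


def write_sam(path, reads, chrom="chr1", chrom_len=100000):
    """Write a minimal SAM file.

    ``reads`` is a list of (qname, pos0, cigar) or (qname, pos0, cigar,
    flag, mapq) tuples; pos0 is 0-based.
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{chrom_len}"]
    for read in reads:
        qname, pos0, cigar = read[:3]
        flag = read[3] if len(read) > 3 else 0
        mapq = read[4] if len(read) > 4 else 50
        lines.append(f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}"
                     f"\t*\t0\t0\t*\t*")
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture
def two_exon_gtf(tmp_path):
    """One gene, one transcript, exons (101,200) and (301,400) 1-based."""
    gtf = tmp_path / "toy.gtf"
    gtf.write_text(textwrap.dedent("""\
        chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t0";
        chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t0";
    """))
    return str(gtf)
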