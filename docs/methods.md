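# Methods

## Model and rationale

Oligo-dT-primed RNA-seq captures polyadenylated transcripts; most introns
are already excised in this pool, so reads over an intron body indicate
molecules whose splicing was delayed past polyadenylation. The package
estimates, per intron, the fraction of such molecules from local coverage
at the splice sites rather than from whole-intron coverage: the last 25 bp
of the intron and the first 25 bp of the downstream exon see nearly the
same read population except for splicing status, so their coverage ratio
(the 3′SS ratio) estimates the retained fraction while being insensitive
to intron length, internal cryptic exons and coverage trends. The mirror
measure at the donor side is the 5′SS ratio. Ratios are computed on
replicate-pooled coverage per condition: splice-site windows are short, so
pooling stabilises low-coverage introns; the cost is that the ratio itself
carries no replicate variance estimate, which is why condition differences
in the ratio enter the final score only as a threshold indicator while
significance testing is delegated to the count-based usage tests.

An intron whose retention is controlled by a condition-specific regulator
should leave several independent traces: the ratio differs between
conditions at one or both splice sites, the intron's read share within its
gene changes, a flanking exon's share changes (retention flanks
alternatively spliced exons), junction usage around the intron changes,
and cryptic (unannotated) junctions appear inside it. No single trace is
reliable on its own; the package therefore scores each intron by how many
of the six Boolean indicators hold and ranks by that sum. The ranking is
deliberately non-parametric: a sum of thresholded indicators is robust to
the very different scales and error modes of its inputs.

## Feature universe

Transcript annotations are flattened per gene: exon boundaries of all
isoforms partition the exon union into non-overlapping exonic parts (the
per-base covering-isoform-set determines part boundaries); the complement
within the gene span gives intronic parts; intronic parts are tiled into
300-bp windows (final remainder window kept) so a localised change inside
a long intron is not averaged away. Overlapping genes are flattened
independently per gene id, and a read overlapping features of two genes
counts for both. Internally all coordinates are 0-based half-open;
GTF/GFF I/O converts from and to 1-based inclusive.

## Counting

A read counts once for every feature it overlaps by ≥ 1 aligned base
(CIGAR M/=/X operations only; N gaps contribute nothing), so exon-exon
junction reads never count toward the intervening intron. Each N gap
increments its junction, keyed by (chromosome, gap start, gap end); a
read spanning k junctions contributes to all k. Unmapped, secondary and
supplementary records and mapping quality 0 are excluded; paired-end
input is accepted with each segment treated independently (the targeted
libraries are single-end). Gene expression uses mean exonic base coverage
(reads × read length / exonic length, averaged over replicates), with a
strict > 20 threshold required in every condition so that downstream
condition contrasts are defined on both sides.

## Differential usage test

For feature *f* in gene *g* and sample *s*, the unit of analysis is
k<sub>fs</sub> successes out of m<sub>fs</sub> = k<sub>fs</sub> +
(rest-of-gene exonic reads); for exonic parts the feature's own count is
removed from the remainder so the contrast is "this feature vs the rest
of its gene", which also makes the proportion depth-free (per-sample
median-of-ratios size factors are computed only as a diagnostic).
Replicate variability beyond binomial sampling is modelled beta-binomially
with overdispersion ρ shared within a gene. ρ is estimated by the method
of moments from replicate proportion variances — Var(k/m) = p(1−p)/m ×
(1 + (m−1)ρ) inverted per feature and condition group, estimates averaged
unclipped so sampling noise cancels — and then shrunk toward the global
mean with a prior weight of 20 feature-level estimates. The shrinkage is
load-bearing: with two replicates per condition the raw per-gene moment
estimate has ~70% CV, and plugging it into the test inflated the
empirical type-I rate to 0.077 at nominal 0.05 on null simulations,
whereas the oracle (true ρ) test sat at 0.050; with moderation the rate
is ~0.047. The final ρ is clipped to [1e−8, 0.95]; at the floor the model
collapses to a plain binomial.

The test is a likelihood-ratio test of one common usage proportion
against one per condition, maximised per feature by vectorised
golden-section search on p ∈ (1e−9, 1−1e−9) (the beta-binomial likelihood
is unimodal in p at fixed ρ; 80 iterations shrink the bracket below any
practical tolerance), referred to χ²₁. Features are filtered before
testing: exonic/intronic features need ≥ 10 reads total over all samples,
junctions ≥ 2. Samples where the gene has no reads are dropped per
feature; a feature with an empty condition is reported untested (NaN).
FDR control is Benjamini–Hochberg within each feature class (exon,
intron, junction are reported as separate analyses), significant iff
adjusted p < 0.1.

## Scoring and ranking

The six indicators per intron: (1) |Δ 3′SS ratio| ≥ 0.1 between
conditions, (2) same for the 5′SS ratio, (3) a flanking exonic part
significant, (4) the intronic part or any of its 300-bp windows
significant, (5) a junction sharing either intron boundary or spanning
the intron significant, (6) ≥ 2 distinct unannotated junctions with an
endpoint strictly inside the intron, each supported by ≥ 3 reads in at
least one sample. The cryptic rule reads "supported by ≥ 3 reads" as
qualifying each junction individually — two junctions at 3 reads each
flag, one junction at 100 reads does not — since evidence for *distinct*
cryptic splice sites is what distinguishes a disturbed intron from one
noisy junction. Missing inputs score false and are annotated as missing.
Ranks are assigned by descending score with ties broken by the smallest
FDR-adjusted p among the intron's tests, then the larger 3′SS delta, then
locus order, giving a deterministic total order. The attribution of exon
and junction significance to an intron uses adjacency (flanking parts;
boundary-sharing or spanning junctions), the natural mapping when tests
are computed on flattened features.

## Event classification and enrichment

Each distinct annotated exon receives one label: MXE (disjoint exon pair,
isoforms carry exactly one of the two, each skipped-over in the other's
isoform), CE (present in some isoforms, skipped with flanks joined in
another), IR (the exon spans another isoform's entire intron, or another
isoform's exon engulfs this exon plus an adjacent intron), A3SS/A5SS
(overlapping exons sharing the donor-side resp. acceptor-side boundary,
strand-aware), CNE otherwise. When several definitions match, priority is
MXE > CE > IR > A3SS > A5SS (counts are reported per type without overlap
handling, so one primary label per exon).

Enrichment of a selected exon set (by default: exons whose upstream
intron has 3′SS ratio ≥ 0.1 in the reference condition; the threshold is
a parameter and 0.01 is equally valid) is assessed by drawing 1,000
equally sized exon sets from the universe without replacement; the
one-sided p is (1 + #resamples at least as extreme)/(resamples + 1),
direction "greater" for CE/MXE/IR/A3SS/A5SS and "less" for CNE. The floor
with 1,000 resamples is 1/1001, displayed as 0.001 (3-decimal rounding).
On universes small enough for exact enumeration the permutation p agrees
with the hypergeometric tail within ±0.01.

## Synthetic data

The generator emulates the targeted data regime: genes with 4–7 exons on
a synthetic chromosome, two isoforms where an event type (CE, MXE, IR,
A3SS, A5SS) is configured so truth labels are recoverable from the
annotation alone; per-intron retention fractions drawn from a mixture
(87% Beta(0.5, 15), 13% Beta(2, 6)) giving the strongly zero-skewed
genome-wide retention distribution the analysis assumes; cassette
inclusion ψ per condition; 125 bp single-end reads; per-gene read counts
negative-binomial around depth × exonic length / read length with
dispersion 0.05. Each read samples a fresh molecule (isoform choice by ψ,
then independent per-gap retention by r); molecules are accepted
proportional to their number of read start positions so that per-base
coverage is uniform over the molecule population — without this,
retained (longer) molecules are under-covered and the ratio
underestimates r. Reads are placed only junction-consistently, so at
r = 0 intronic coverage is exactly zero. Cryptic junctions are injected
as reads spanning an unannotated gap. Everything is a pure function of
the seed.

What the simulation does not model: sequencing errors and quality
strings, fragment-length and GC biases, positional (5′/3′) coverage bias,
multi-mapping ambiguity, more than two isoforms per gene, and coupling
between retention events within one molecule (gaps are retained
independently; a scenario can emulate coupling by assigning a retention
value to the compound gap left by a skipped exon, as the built-in
"thunder" scenario does). Passing tests therefore demonstrate the
estimators' correctness and calibration under the stated noise model, not
robustness to alignment artefacts or library-preparation bias in real
data.

The "thunder" scenario engineers one regulated cassette-exon gene
(ψ 0.2 vs 0.9; flanking-intron retention 0.32 vs 0.02; two injected
cryptic junctions in one flanking intron), one structurally matched
unregulated control, 23 cassette genes with condition-independent
retention 0.3 (so the high-retention exon selection over-represents
cassette exons without confounding the differential tests), and
constitutive background genes, at 300× exon depth with 2 replicates per
condition — sizes chosen so the full pipeline runs in seconds while every
indicator has decisive power.

## Defaults

| Parameter | Default | Meaning |
|---|---|---|
| splice-site window | 25 bp | coverage window on each side of a splice site |
| intron window | 300 bp | tiling width inside intronic parts |
| expression threshold | 20 | mean exonic base coverage, strict >, per condition |
| min feature count | 10 (exon/intron), 2 (junction) | total over all samples |
| FDR α | 0.1 | BH within feature class |
| ratio delta | 0.1 | |Δ ratio| scored true |
| IR selection threshold | 0.1 | 3′SS ratio selecting high-retention exons (0.01 accepted) |
| cryptic rule | ≥ 2 junctions × ≥ 3 reads | distinct unannotated junctions per intron |
| resamples | 1,000 | enrichment permutations (floor p = 0.001) |
| read length | 125 bp | single-end |
| NB dispersion | 0.05 | simulator count noise |

## Numerical and degenerate-input choices

Undefined ratios (empty exon-side window) propagate as missing, never 0,
so silent genes cannot masquerade as efficiently spliced; condition
deltas with a missing side score false. Windows truncate to feature
length when an intron or exon is shorter than 25 bp and the record is
flagged. The LRT statistic is clipped at 0 before χ² lookup. The
golden-section bracket endpoints (1e−9) bound proportions away from the
likelihood's singularities. Junction strand from unstranded reads is "."
and junctions are matched to the catalog by coordinates only. Zero-length
features, inverted exon coordinates and empty transcripts are rejected at
parse time with the offending line number.

## Known limitations

The usage test assumes exactly two conditions and benefits from ≥ 2
replicates per condition (with one replicate the dispersion falls back to
the global estimate). p-values are asymptotic (χ²₁) and the dispersion is
estimated, not profiled, so very low counts near the filter boundary are
only approximately calibrated. The ratio pools replicates and so provides
no per-intron variance; the 0.1 delta indicator inherits this. Event
classification is annotation-driven: unannotated isoforms make CE/MXE
labels incomplete, and the single-label priority undercounts overlapping
event memberships. Junction-to-gene attribution uses gene spans and picks
the first containing gene for nested loci.
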