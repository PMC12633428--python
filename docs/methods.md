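# Methods

This note documents the models and procedures `mosaikit` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show
about real data.

## Coordinates and inputs

All internal coordinates are 0-based half-open; VCF and GFF3 are
converted at the I/O boundary (BED/bedGraph are already half-open). The
toolkit consumes the *outputs* of read mapping and variant calling —
variant tables, callability masks, depth tracks, per-site modification
tables, transcript models — and never touches reads or alignments
itself. Only uncompressed text formats are read and written, so no file
ever needs an index.

## Windowed heterozygosity and divergence (`hetwin`)

Chromosomes are tiled with non-overlapping windows (default 10 kb,
anchored at 0; the last window may be short). Heterozygosity per window
is the number of qualifying heterozygous SNVs divided by the number of
alignable sites in the window; windows with fewer than 2,000 aligned
sites carry no value (`status=excluded`). The quality filter (default
minimum 60, matching typical maximum mapping quality) applies only when
a quality column is present; tables without one pass with a warning.

Two weighting modes are deliberately explicit rather than inferred from
the data. In *heterozygosity* mode every site counts 1 (a self-comparison
of two haplotypes only produces heterozygous sites). In *divergence*
mode, which compares a diploid strain's reads to an external reference, a
site where only one haplotype differs counts ½ and a site where both
differ counts 1, so the value estimates the haplotype-averaged distance.
The low-alignment exclusion threshold is applied in both modes.

Degeneracy classes are computed per CDS position under the standard
genetic code: class k means k nucleotides at that position preserve the
encoded amino acid, with the conventional exception that a position where
only the original base works is labeled 0 (so values are 0/2/3/4).
Codons containing ambiguous bases are labeled unknown and excluded;
internal stop codons are an error. Strand is handled by mapping CDS
order through the exon structure, so minus-strand genes report classes at
the correct genomic positions.

## LOH tract calling (`loh`)

Candidate tracts are the maximal intervals strictly between consecutive
heterozygous sites (and between chromosome ends and the outermost sites);
the flanking het sites themselves are excluded, making the definition
unambiguous at the boundary: consecutive het sites at 0-based positions p
and q delimit a candidate [p+1, q) of length q−p−1, emitted when that
interior length reaches `min_len` (default 1,000 bp). A chromosome with
no heterozygous site yields a single whole-chromosome tract. Tracts are
classed by end contact: left end only → `terminal_left`, right only →
`terminal_right`, both → `whole_chromosome`, neither → `interstitial`.

Because unalignable or highly diverged regions produce no het calls and
masquerade as homozygous, tracts must also contain at least
`min_callable_fraction` (default 0.5) callable bases; setting it to 0
recovers the pure spacing rule. Under background heterozygosity h per
base, the chance of a spurious ≥1-kb gap is ~e^(−1000·h) per site
(~e^(−27) at h=0.027), so false tracts are effectively absent in the
diverged-hybrid regime, and tract boundaries land within the local
inter-SNV spacing (median ≈ ln2/h ≈ 26 bp at 2.7%) of the true event
boundary.

Between-strain comparison matches tracts greedily by decreasing overlap,
requiring the overlap to cover at least `reciprocal_overlap` (default
0.5) of *both* tracts, each tract matched at most once — the standard
symmetric criterion used for CNV/LOH set comparison. Genome-wide
summaries report per-class counts, total/mean/max lengths and the
homozygous genome fraction, the latter also rounded to one decimal
percent as such figures are usually quoted.

## Parent-of-origin painting (`ancestry`)

A hybrid haplotype window whose divergence to parental reference P is at
within-species levels while its divergence to reference S is at
between-species levels derives from P, and vice versa. The decision
statistic is the signed difference d_S − d_P with a symmetric threshold
δ (default 0.01): P iff d_S − d_P ≥ δ, S iff d_P − d_S ≥ δ, ambiguous
between, unassigned when either comparison lacked aligned sites. δ sits
midway between the two regimes (0.6–1.4% within, ~2.7% between); at
10-kb windows the sampling noise of a divergence value is ~0.16%, so
mislabeling requires a ~12σ excursion, while a few percent of windows may
fall in the ambiguous band. δ and the smoothing parameters are plain
function arguments and are recorded in CLI output headers.

Segmentation merges runs of equal labels; ambiguous/unassigned runs
bounded by a single informative label join it, and informative runs
shorter than `min_run` (default 3 windows) flanked on both sides by the
same other label are flipped — removing isolated noise windows without
letting ambiguity seed segments. The smoothing iterates to a fixpoint
and is deterministic in input order.

Switch typing: boundaries on the two haplotypes within
`tolerance_windows` (default 1) of each other with opposite transitions
(P→S vs S→P) form one reciprocal crossover; an unpaired boundary that
enters or leaves a region where both haplotypes share a label, or that
lies in a called LOH tract, is non-reciprocal LOH; the rest are
unclassified. The A/B haplotype names are arbitrary phase labels;
painting never claims to identify which physical chromosome came from
which parent beyond each segment's label.

## Copy number from depth (`ploidy`)

Depth is averaged over non-overlapping 20-kb tiles (the resolution
karyotype plots use; an overlapping step is configurable but not the
default). The genome-wide baseline is the median of per-chromosome
median depths after one pruning round that drops chromosomes whose ratio
to the initial baseline falls outside [0.75, 1.25] — medians resist
partial events within a chromosome, and pruning stops whole-chromosome
aneuploidies from inflating the baseline. Copy number is
round(expected_copies × median/baseline) with ties rounded half away from
zero (symmetric and deterministic). `expected_copies` is explicit
because the same reads can be mapped to a phased diploid assembly
(normal haplotype chromosome = 1 copy) or a collapsed haploid reference
(normal = 2); nothing is inferred from the data. Each call carries a
confidence: the fraction of the chromosome's windows individually
implying the called integer.

Partial events are found by recursive binary segmentation on window
means: at each level the split maximizing the residual-sum-of-squares
reduction is found exhaustively and accepted only if both sides have at
least `min_seg_windows` (5) windows and the mean difference reaches
`min_effect` (0.25) × baseline — half the smallest real copy-number step
in phased mode, so Poisson noise at mean ≥ 30 per copy never splits a
flat chromosome while true steps of ≥ 1 copy always do. Segments then
receive integer calls as above. No GC or mappability correction is
applied and copy numbers are integers only; subclonal fractions are out
of scope.

## Methylation metaprofiles (`methprof`)

Sites with fewer than 5 mapped reads are removed. Offsets are anchored
with the TSS at 0 and downstream positive on both strands (offset =
pos − tss on +, tss − pos on −). The profile value at an offset is the
median modification fraction over all contributing (gene, site) pairs
pooled across genes; whether to pool or to take per-gene medians first is
genuinely open, so the pooled reading is the default and `per_gene=True`
gives the alternative. Duplicate TSS records are deduplicated so
re-annotated genes do not weight the median. Periodicity is estimated on
the downstream profile: missing offsets are linearly interpolated, the
profile mean-centered, and the normalized autocorrelation maximized over
lags 50–500 bp; the period is reported only when that autocorrelation
reaches 0.2, since a flat profile otherwise yields an arbitrary argmax.

## Transcript rules (`txrules`)

*Decoupling*: isoform-collapse pipelines merge neighboring genes whose
isoforms overlap on the same strand; genes are split into connected
components of pairwise same-strand CDS overlap (≥ 1 bp), and a
coding-free isoform inside a coding group joins the component with the
largest exonic overlap (logged).

*Isoform filter*: an isoform is kept iff it has ≥ 5 supporting reads and
≥ 5% of the gene's total reads, the total computed before any filtering
(the natural reading; computing it after would make the result depend on
filter order). If nothing survives, the most abundant isoform is rescued
so every gene keeps a model.

*Primary isoform cascade*: (1) if the longest-CDS isoform is also most
abundant, it wins (CDS-length ties go to the more abundant, remaining
ties to the lexicographically smaller id); (2) otherwise the longest-CDS
isoform wins if its reads reach 50% of the most abundant isoform's; (3)
otherwise the most abundant wins if its CDS reaches 80% of the longest;
(4) otherwise the longest-CDS isoform wins, so 5'-truncated isoforms —
overrepresented in long-read data — never win on abundance alone. The
branch taken is reported with each decision.

*Kozak model and ORF extension*: the start-codon context model is an
additive log-odds (base 2) position weight matrix over offsets
{−9…−1, +3…+5} relative to the A of the ATG (the ATG itself is
invariant and not scored; the window is configurable and recorded).
Counts use pseudocount 1; the background is the genomic nucleotide
frequency. Training uses primary transcripts whose ORF cannot be
extended — no in-frame upstream ATG reachable without an intervening
in-frame stop — on the assumption that their annotated starts are true.
A transcript is extended to an upstream in-frame, stop-free ATG whose
score exceeds the 25th percentile (linear interpolation) of the training
scores or the score of its own annotated start. Among multiple
qualifying candidates the 5'-most is chosen by default (maximal
extension; `choose="best"` takes the highest-scoring instead — the field
offers no consensus here). Extension never shortens a CDS, preserves
frame and stop-freedom by construction, and is idempotent.

*Antisense lncRNA calls*: a call requires antisense exonic overlap of at
least 30% of the coding transcript's length (the threshold is inclusive).
The promoter class reflects the lncRNA TSS: inside the mRNA gene body
with a same-gene sense TSS within 300 bp → `bidirectional_internal`;
inside the body otherwise → `unidirectional_internal`; within 300 bp of
the body → `adjacent`; farther → `distal` (a fourth label for overlap
calls whose TSS lies beyond the promoter window, which the three-way
scheme cannot express).

## Synthetic genomes (`synthdata`)

The generator exists because no public generative model accompanies this
class of analysis; its distributional choices are pragmatic stand-ins
with the statistical structure the analyses assume, not a claim about
mutational mechanism.

* **Sequences**: i.i.d. bases at the configured GC content (default
  0.64, a gene-dense microalgal value). Substitutions only — no indels
  or rearrangements — so ancestor, parents and hybrid share one
  coordinate system and windowed statistics operate on exactly aligned
  sites. Each parent is the ancestor mutated at its divergence rate
  (default 1.36% each, compounding to ~2.7% between parents, the
  hybrid's observed haplotype divergence); within-parent heterozygosity
  is a second independent substitution layer (defaults 0.6% and 1.35%,
  the within-species range) on one of the two parental haplotypes.
* **References**: the hybrid is founded from haplotypes P1 and S1; the
  *other* haplotype of each parent (P2, S2) is emitted as that parent's
  reference, so divergence of a hybrid window to its own species sits at
  within-species levels rather than zero — the regime real strain
  comparisons occupy.
* **Events**: crossovers reciprocally exchange suffixes; LOH copies the
  donor haplotype's interval onto the recipient; aneuploidy changes
  truth copy numbers only (an extra copy is sequence-identical), since
  depth is the only evidence the caller uses. Overlapping LOH intervals
  on one chromosome are rejected as conflicting.
* **Variant observable**: one heterozygous site per A≠B position,
  dropped at a configurable false-negative rate and augmented with
  uniform false positives — a stand-in for an upstream variant caller,
  not a model of any particular one.
* **Depth**: negative binomial with mean depth_mean × copies and
  dispersion parameter d (variance m + d·m²), exactly Poisson at d=0 —
  the standard overdispersion family for read depth.
* **Methylation**: promoters are hypomethylated (template ≈ 0 upstream
  and at the TSS); 6mA forms Gaussian peaks (σ = 20 bp) at one and two
  periods downstream (default period 180 bp, the nucleosome repeat
  length scale; default peak height 0.75), and 5mC rises in periodic
  bumps from three periods onward to a plateau (default 0.95), clipped
  to [0, 1]. Genes are spaced so no gene's profiled flank reaches a
  neighbor's, keeping each TSS profile uncontaminated. Site presence is
  Bernoulli per base (density 0.05), read counts Poisson (default mean
  30), modified counts binomial at the template fraction.
* **Transcripts**: single-exon genes on alternating strands in three
  designed classes — training genes (strong start context, clean 5'
  UTR), extension genes (weak annotated context plus a strong in-frame
  upstream ATG with a stop-free path, the true start), and negative
  controls that must never be extended (clean UTR, or an upstream ATG
  blocked by an in-frame stop). Strong contexts follow a fixed consensus
  with 85% per-base fidelity (planted true starts at 100%), giving a
  designed multi-bit score separation between strong and weak contexts.
  Most genes carry a 5'-truncated minor isoform; a subset of minors is
  designed to fall below the read-support filters. UTRs are scrubbed of
  accidental in-frame ATGs so the truth log enumerates every candidate.

Everything is driven by one seeded generator: identical config and seed
give byte-identical output files.

**What passing these tests shows — and does not.** Recovery on this
generator demonstrates the algorithms are correct at the documented
signal levels: i.i.d. substitution placement, ideal callability, no
alignment artifacts, no GC or mappability bias in depth, no indels or
rearrangements, and isolated single-exon transcript loci. Real data add
clustered variation, systematic coverage bias, mapping errors near
repeats, and multi-exon isoform complexity; the callability guard,
quality filters and configurable thresholds exist for exactly those
effects, but their efficacy on real libraries is not established by this
test suite.

## Benchmark problem sizes

The recovery benchmarks (`mosaikit.benchmarks`, also run by
`scripts/acceptance.py`) use: 10 Mb across 10 chromosomes with 20
planted LOH events for tract recovery; 5 Mb with 5 crossovers and 5 LOH
switches for painting; 100 simulated genomes (five 150-kb chromosomes
plus one 2-Mb chromosome with a 900-kb partial duplication each) for
copy-number calling; 2,000 genes for the methylation metaprofile; 500
genes plus a 65,536-point exhaustive rule grid for the transcript rules;
and all 61 sense codons for degeneracy. These sizes give tight binomial
error on every reported rate while keeping a full run around a minute on
one CPU.

## Known limitations

No indel/SV simulation or handling; no mechanistic classification of LOH
(gene conversion vs break-induced replication); no organelle ancestry;
no subclonal copy number; no 5hmC; multi-allelic and indel variant
records are skipped with a counter rather than modeled; the Kozak window
and δ/min_run painting parameters are conventions, not fitted values.
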