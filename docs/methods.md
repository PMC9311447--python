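# Methods

This note records the models, conventions and design choices behind each
stage of the pipeline, what the simulator does and does not emulate, and the
numerical details a user reproducing or extending the package should know.

## Library model and read anatomy

A library is a double restriction digest (default MspI `C^CGG` + NsiI
`ATGCA^T`) of genomic DNA, size-selected, ligated to adapters and sequenced
paired-end and directionally.  Each read starts with a 3-nt UMI, the sample
barcode (default 6 nt), one control nucleotide (CN) and the enzyme overhang
remnant, followed by the bisulfite-converted insert; inserts shorter than
the read run through into the reverse-complemented custom adapter of the
opposite end and then the standard Illumina adapter.

**Enzyme and end-repair model.** Each enzyme is reduced to its recognition
motif plus top- and bottom-strand cut offsets (bottom defaults to
`len(motif) − top`, exact for palindromes).  `digest()` places fragment
boundaries at top-strand cuts, so fragments tile the genome exactly.  The
*sequenced molecule* of a locus additionally models end repair at the right
end: a 5′ overhang is filled in to the bottom-strand cut (MspI: the fragment
gains `CG`), a 3′ overhang is trimmed back to it (NsiI: the fragment loses
`TGCA`).  Because fill-in uses 5-methyl-dCTP, filled bases are protected
from conversion on the strand that carries them; the simulator tracks
per-strand protection masks and reports protected cytosines as methylation
probability 1.0 in the truth tables.  This single blunt-duplex abstraction
makes every read begin with exactly the expected remnant on both strands and
makes the de novo reconstruction target well defined (the molecule, which is
what `loci.fasta` contains), at the cost of not representing sticky-end
chemistry explicitly.

**Conversion model.** Each unmethylated cytosine converts independently with
probability `conversion_efficiency` (default 1.0); methylated cytosines
never convert.  Methylation states are drawn per molecule from per-site
probabilities: CG sites from Beta(2, 2) by default, CHG fixed at 0.3, CHH at
0.05 — levels typical of a plant methylome.  Contexts are assigned on the
molecule (edge positions with missing neighbours fall through to CHH).

**Other simulator parameters.** Sample coverage is `coverage` read pairs per
locus per sample, each molecule Watson with probability `watson_fraction`
(0.5).  Diploid SNPs are placed uniformly outside the terminal motif-length
guard zones, with per-sample genotypes 0/0 : 0/1 : 1/1 drawn 0.4 : 0.4 : 0.2
at selected sites; molecules sample one haplotype per het site.  PCR
duplicates add Poisson(`pcr_duplicate_rate`) extra copies per molecule with
the same UMI and sequence; sequencing errors are uniform substitutions
applied last; base qualities are a constant phred 37.  All randomness flows
from one integer seed (byte-identical outputs per seed).

**What the simulator does not emulate.** Indels, adapter-synthesis errors,
quality decay along the read, UMI phasing artifacts, chimeras, incomplete
or over-conversion bias by context, and complementary (post-PCR) strands —
the library is strictly directional.  Passing tests therefore demonstrate
correctness of the pipeline's logic and estimators under the stated noise
models, not robustness to every failure mode of real sequencers.

## Demultiplexing

Clone removal keys on the exact tuple (UMI1, UMI2, fragment1, fragment2) —
equivalently the two full reads — keeping the first pair seen, then strips
UMIs.  Barcode expansion appends the Watson (T/C) and Crick (C/T) control
nucleotides to each sample's barcode pair; assignment requires both mate
prefixes to match exactly one expanded key (0 mismatches by default,
configurable per mate).  A sliding-window raw-quality filter (window
= ⌈0.15 × read length⌉, mean phred < 10 fails) drops the pair if either mate
fails; the order barcode → quality → overhang is a package choice.

**Overhang validation** tries both enzyme orders (fragment orientation is
unknown) and accepts at most one mismatch per mate.  When both orders are
acceptable — a converted MspI start `TGG` is also an exact match for a
T-remnant enzyme — the order requiring fewer rescues wins.  Two modes:

* `any_single_mismatch` (default): the mismatching base is **replaced** with
  the expected base.  This replicates widely used demultiplexer behaviour
  but can relabel a converted (unmethylated) overhang cytosine as
  methylated.  The first-base trim removes the only such position mate 1
  can contribute, but mate 2 reads the overhang cytosine of the far end,
  which matters for fragments longer than the mate-1 span.
* `ct_only`: only conversion-explainable mismatches (expected C read T,
  expected G read A) are rescuable, and the observed base is **kept**, so
  methylation at overhang cytosines stays unbiased.  This mode is used by
  the acceptance analyses.

## Trimming and directional merge

Per mate: locate the Illumina adapter (exact or mismatch-tolerant internal
occurrence, else the longest read-suffix/adapter-prefix overlap ≥ 3 at ≤10%
mismatches), truncate there; remove one 5′ base (the nick-translation
fill-in position); if an adapter was found, hard-trim a further 10 bp from
the 3′ end (the read-through copy of UMI + barcode + CN); drop the pair if
either mate ends below 20 bp.  Watson R1 is then pooled with Crick R2 as
mate 1 (top-strand sequence) and Watson R2 with Crick R1 as mate 2, giving
the conventional directional layout.

## De novo reference reconstruction

Read pairs (untrimmed, barcode/CN stripped) are assembled by sliding the
reverse-complemented mate 2 against mate 1 over candidate insert lengths
seeded by exact 16-mers at staggered offsets; the placement with the lowest
mismatch fraction (ties: longest overlap, then shortest insert) wins if the
overlap is ≥10 at ≤10% mismatches, and the consensus excludes read-through
tails.  Pairs without an acceptable overlap are joined with an 8-N spacer
(N's are excluded from identity scoring downstream).

Dereplication groups equal-length sequences by identical three-letter
encoding; the per-column majority over original letters is the consensus
(ties → N) and groups outside [min_depth, max_depth] = [10, 10000] are
discarded.  Watson/Crick pairing keys on the binary encoding of the
*encoded key* — equivalent to encoding the consensus but immune to tie N's —
greedily by descending depth.  The per-column merge restores the unconverted
sequence (T/C → C, G/A → G, N defers to the partner, other conflicts → N).
Unpaired strand clusters are discarded by default (`keep_unpaired` emits
them with conversion-ambiguous positions masked to N, since a single strand
cannot distinguish C from T).  Greedy centroid clustering processes
consensi in descending total depth; a sequence joins the first centroid with
global identity ≥ 0.99 (matches / alignment columns, N never matches,
Needleman–Wunsch alignment), else founds one.  Centroids are N-padded
(`NNNN…NNNN`) and numbered in processing order.

## Alignment

The aligner is a gapless three-letter seed-and-verify mapper: the reference
is converted twice (C→T, G→A), exact 16-mer seed tables index both copies
(N never seeds), and each candidate placement is scored over the full read
(match +1, mismatch −1; bases overhanging the cluster ends count as
mismatches and are soft-clipped from the stored record).  Directional mode
tries two orientations — original-top (mate 1 C→T forward) and
original-bottom (mate 1 G→A forward) — with mate 2 reverse-complemented in
the same space and required to land on the same cluster; nondirectional mode
adds the complementary orientations.  The unique best-scoring cluster wins
(MAPQ 40); equal best scores on different placements are ambiguous and
dropped; ties that agree on cluster and coordinates (reads with no
conversion-informative position) resolve to the first orientation; best
score < 0.6 × read length is unaligned.  Gap states are deliberately absent:
indels are out of scope end-to-end (simulator, consensus and caller), so a
gapped aligner would only add nondeterminism.  Output is coordinate-sorted
SAM with `@RG` per sample and an `XG` tag (`CT` = original top, `GA` =
original bottom).

## Methylation calling

At each reference C covered by an original-top read: read C increments the
methylated count, T the unmethylated count, other letters are ignored;
symmetrically G/A at reference G for original-bottom reads (a bottom-strand
C).  Where mates overlap, each position is counted from mate 1 only.
Context and trinucleotide come from the reference; windows containing N
(padding, join spacers, cluster edges) are reported as CHH with an
N-containing trinucleotide and flagged.  No base-quality threshold is
applied by default (`min_base_quality` available).  The CX report is a
7-column TSV (cluster, position, strand, methylated, unmethylated, context,
trinucleotide); M-bias tables give the methylated fraction per read cycle
split by mate and context, with mate-2 cycles counted from the record's 3′
end (records are stored reference-oriented).

## Variant calling

Double masking rewrites OT C/T over reference C to C and OB G/A over
reference G to G, keeping qualities (masking changes identity only, so site
depth is preserved).  The caller then works per site, independently across
sites and samples: observations need mapping quality ≥ 10 and base quality
≥ 1 (the deliberately permissive thresholds suited to this data type);
diploid genotype likelihoods use the symmetric error model P(b|a) = 1−ε if
b = a else ε/3 with ε from the base quality; the ML genotype is reported
with GQ = 10·(log₁₀L_best − log₁₀L_second); site QUAL is
Σ_samples −10·log₁₀ P(0/0 | data) under a uniform genotype prior, capped at
3000; sites need QUAL > 0 and ≥1 non-reference called genotype.  Indel-free
by construction; `filter_snps` additionally guards the VCF.

One refinement beyond reference-base masking: at sites whose candidate
alleles include **both** C and T, top-strand C/T observations cannot
distinguish the two alleles (a converted C reads T), so they are dropped
rather than counted as reference support; symmetrically for G/A on the
bottom strand.  Without this, a homozygous alternate T at a reference C is
dragged toward a heterozygous call by its own masked reads — the
heterozygous excess known from masking-based callers — and an alternate C
surfaces as a spurious T allele.  The consequence, shared with all
masking-based approaches, is that variants in the C/T (G/A) pair are
callable only where the opposite strand is covered; the evaluation module's
both-strand filter quantifies exactly this.

## Evaluation procedures

Cluster-vs-truth: each cluster (padding stripped) is matched to the locus
set; exact unique matches short-circuit, otherwise the unique best global
identity ≥ 0.9 counts as matched and contributes its mismatch count.
PR sweeps decompose multiallelic records and match calls to baseline by
(contig, position, alt); genotypes of shared samples must agree unless
squash-ploidy is on; candidate baselines can be pre-filtered to positions
covered by the call set's alignments and to positions with ≥1 read of each
strand.  CpG destranding merges the + strand C at p with the − strand C at
p+1 (counts summed, coordinate p).  Methylation R² is squared Pearson from
the least-squares fit over shared sites with coverage ≥ 10 in both sets
(identical to OLS R² for simple regression); accession-level aggregation
sums counts before taking proportions (coverage-weighted mean).  Ward
clustering uses scipy's linkage on correlation (1 − Pearson) or euclidean
distances with a Newick export.

## Problem sizes and numerical choices

The acceptance analyses use 200 loci of 120–350 bp, four samples and ~30
pairs per strand per locus per sample (~48 000 read pairs), which exercises
every stage in tens of seconds on one CPU.  Reads are simulated at 200 bp
for these analyses so that mate pairs span the largest fragments — a
requirement for the reconstruction identity check, since an unsequenced
interior can only be N-joined; the simulator default is 150 bp.  Methylation
recovery is tested as exact binomial consistency: each per-site count must
lie in its exact binomial region at a Bonferroni-corrected family-wise 99%
level across all site-sample tests (a per-site 99% region would be expected
to fail at ~1% of 10⁵ unbiased estimates by construction), and sites with
truth 0 or 1 must be exactly 0 or 1.  Seeds derive from a single integer
via numpy `SeedSequence`; all stage outputs are deterministic given the
seed, with deterministic tie-breaks throughout (first-seen clone wins,
descending-depth pairing and clustering order, first-orientation resolution
of placement-identical alignment ties).

## Known limitations

No indel support anywhere in the chain; no fuzzy UMI matching (exact UMIs
only, so UMI sequencing errors create false non-duplicates); identity
clustering keeps the centroid rather than re-consensusing members; the
reference branch assumes the provided FASTA uses the same coordinate
conventions as the de novo clusters (no N-padding is added); the caller has
no population prior and no haplotype window, which is adequate for SNP-only
output at reduced-representation scale but not for dense haplotypes;
quality-aware behaviour is limited because the simulator emits constant
base qualities.
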