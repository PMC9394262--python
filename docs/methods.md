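# Methods

This note documents the models, conventions and numerical choices behind
mitocomp, what the synthetic-data generator does and does not emulate, and
the known limitations of each stage.

## Record model and coordinates

A mitogenome is a circular DNA string plus typed features (core PCG, ORF,
intronic ORF, tRNA, rRNA, intron). Segment coordinates are 0-based
half-open internally and 1-based inclusive in files and reports (GenBank
convention). Multi-segment genes are stored in transcription order —
ascending for `+` strand, descending for `-` — so splicing is simple
concatenation (reverse-complemented per segment on the minus strand) and
an intron's insert offset is the cumulative exon length before it, counted
1-based in coding coordinates. Features crossing the circular origin are
stored pre-split into two segments with a wrap flag; splicing and offset
arithmetic treat the wrap transparently, with intron lengths computed
modulo the genome length.

Explicitly annotated intron features are cross-checked against the gaps of
multi-segment CDS joins; on conflict the join wins and the intron feature
is dropped with a log message, since joins are the operational definition
of exon structure. Gene symbols are normalized through a small synonym map
(cob/cytb, nad4L/nd4l, rnl/LSU, rns/SSU, …); unknown symbols pass through
lowercased. GFF3 reading/writing is a plain nine-column implementation
(multi-line CDS share an ID, `Is_circular` on the region line); GenBank
I/O goes through Biopython.

## Synthetic cohorts

The generator builds one ancestral genome — 15 core PCGs with realistic
lengths (cox1 1,593 nt … atp8 147 nt), rnl/rns, 26 tRNAs, per-gap
intergenic filler — and evolves every block along a user tree (or a star
tree at the given divergence) by an independent-site Kimura two-parameter
process. The per-branch rate is the branch length in expected
substitutions per site; transitions outnumber transversions by the
configurable ts/tv ratio (default 2). Because the process allows multiple
hits, the downstream K2P estimator recovers simulation rates without bias.
Protein-coding blocks keep their start/stop codons pinned and internal
codons that a substitution would turn into a stop (TAA/TAG under code 4)
revert to the parent codon.

Two calibration details matter for the composition contract (leaf GC
within ±2 points of the target for genomes ≥ 40 kb): the symmetric
substitution process has a 50% GC equilibrium, so ancestral GC is offset
by the expected drift given the mean tip depth; stop-codon avoidance in
coding regions still adds roughly +1 point, which stays inside the band.

Introns are planted at exact ancestral coding positions; orthologous
plants (same gene and position in several genomes) share one ancestral
intron body so their sequences are similar, and optional embedded ORFs are
labeled as LAGLIDADG/GIY-YIG homing endonucleases. Optional codon-level
indels (insert/delete whole codons at a per-codon rate, default off) are
applied per tip while tracking the host↔ancestor codon map, so planted
reference positions remain exact truth; the designated reference genome
receives no indels, keeping its coordinates identical to the ancestor's.
Repeats are planted as literal copies (direct, inverted or tandem) in
intergenic space with recorded intervals; free-standing ORF families are
ancestral coding blocks shared by a genome subset. A single seed drives
every draw and output is byte-identical across reruns.

What the generator does **not** emulate: intron secondary structure and
group I/II architecture, composition heterogeneity along the genome,
context-dependent mutation, rearrangement mechanics (orders are specified,
not evolved), and realistic intergenic turnover. Passing tests therefore
demonstrate algorithmic correctness against known truth, not performance
on the full messiness of real annotations.

The bundled 13-genome "study" cohort mirrors the observed conditions: two
shared arrangements (6 and 4 genomes) plus three private ones, a cox1
position class present in 12/13 and another in 10/13, a universal nad5
class, several single-genome classes, intron counts that drive genome-size
variation, and shared ORF families (RNA/DNA polymerase, hypothetical
proteins).

## Composition and correlation

Skews are computed on the deposited (direct) strand, N bases excluded;
zero denominators yield a null marker rather than an error. Codon usage
reads frame 0 of each spliced CDS and drops trailing partial codons with a
warning. The intron-count/genome-size correlation uses Pearson on raw
values and Spearman with midrank ties; p-values come from the t
approximation, replaced by exact permutation enumeration for n ≤ 8 (full
enumeration beyond that is impractically slow and the study scale is
n = 13). Constant inputs return NaN coefficients rather than raising.

## Repeats

Interspersed repeats: exact 12-mer seeds index the sequence against itself
and against its reverse complement; each new diagonal is extended gaplessly
in both directions under an x-drop of 20 (match +1, mismatch −2), keeping
the maximal-score window, and candidate pairs merge onto the longest
representative when both intervals overlap ≥ 50%. Defaults (min length
30 bp, min identity 80%) replace engine-specific E-value thresholds so the
contract is deterministic across machines. Gapped repeats longer than the
x-drop tolerance are split rather than joined — a known limitation.
Tandem repeats: for each period p ≤ 500 the lag-p self-match profile is
scanned for runs giving arrays of ≥ 2 copies and length > 10 bp; where
arrays overlap, the smallest explaining period wins. The repeat fraction
is the length of the interval union over all reported repeats divided by
genome length.

## Distances and selection

K2P excludes gap/ambiguous columns pairwise and raises a saturation error
when a log argument is non-positive. NG86 follows the original
site-counting convention: per codon position the synonymous fraction of
the three possible changes is counted, with mutations to stop codons
counted as nonsynonymous; site counts average over the two sequences.
Differences average over all substitution pathways with equal weights,
excluding pathways through a stop codon (falling back to all pathways if
every one is blocked); proportions get Jukes–Cantor correction, with
saturation at p ≥ 3/4. Ks = 0 pairs report a null ratio, are classified
"undefined", and are excluded from mean-ratio summaries.

For cross-genome gene pairs of unequal length, the K2P input is a global
DNA alignment (match +1, mismatch −1, gap open −5, extend −1); the NG86
input is instead built by aligning the translated proteins (BLOSUM62,
−11/−1) and back-mapping to codons, because nucleotide-level gaps need not
respect codon boundaries and a frame-shifted codon pairing would corrupt
site counts. Equal-length pairs are compared directly.

## Position classes and gain/loss

An intron's host offset is mapped onto the reference gene through a global
DNA alignment (match +2, mismatch −1, gap open −10, extend −0.5). If the
host position falls in a host-only insertion, the nearest
reference-aligned column to the left supplies the coordinate. Alignments
below 50% identity refuse projection, guarding against paralogs. Position
matching across genomes is exact — class names are integers — with an
optional ±k merge (off by default). rRNA-gene introns go through the same
machinery against the reference rRNA.

Under substitution-only divergence the projection is exact by
construction; under 5% codon indels about 98% of sites project exactly
(measured over 1,000 simulated gene pairs), the residue being co-optimal
gap placements that shift a site by a few nucleotides.

Gain/loss reconstruction offers Dollo parsimony (one gain at the stem of
the minimal clade containing all carriers, plus losses for each maximal
carrier-free subtree below it) and Fitch unordered binary parsimony with
deterministic tie-breaking: ambiguous nodes take the parent state and the
root prefers absence, so every reconstruction starts with a gain and
replays exactly to the observed leaf pattern.

## Gene arrangements

Orders cover the 17 arrangement genes (tRNAs excluded), sorted by the
start of the first transcribed segment and rotated to cox1, walking the
circle in cox1's annotated sense. Comparison is orientation-agnostic:
breakpoint distance is 17 minus the number of shared unordered circular
adjacencies, so full reversal — which preserves every adjacency — gives
distance 0, and arrangement grouping quotients reflection via a
lexicographic min(forward, reversed) canonical key. A circular chromosome
without strand information has no intrinsic direction, which motivates
both conventions; a signed comparison is not implemented.

## ORF clustering

Free-standing ORFs translate under code 4 (trailing stop removed, internal
stops are errors) and cluster by single linkage over all-vs-all global
protein alignment: a link requires identity ≥ 60% over mutually aligned
columns and coverage ≥ 70% of both proteins. Single linkage deliberately
lets length variants of one gene (e.g. a 429- vs 439-codon pair) share a
cluster. Entries are canonically sorted before linkage so clustering is
input-order independent; clusters are named orf<median protein length>
with letter suffixes on collision. Both thresholds are explicit knobs
since no canonical values exist for this analysis.

## Supermatrix and tree

The concatenated set holds the 14 core PCGs minus rps3, introns excluded
by construction (spliced CDS only). Per-gene multiple alignment is a star
alignment around the longest sequence — each other sequence aligns
pairwise to the center and merges on center columns, insertions padded to
the per-position maximum. This is adequate at the ≤ 15% divergence typical
within a genus but degrades where pairwise alignments of distant taxa
disagree about center gaps; the writers (FASTA, relaxed PHYLIP, NEXUS,
RAxML-style partitions) exist precisely so external ML/Bayesian tools can
rerun inference from the same matrix. Missing genes become gap rows and
partitions always tile the alignment.

Distances are K2P over shared non-gap columns; the tree is neighbor
joining (scikit-bio) with negative branch lengths clamped to zero, exact
on additive matrices. Bootstrap resamples supermatrix columns with
replacement, rebuilds the NJ tree per replicate, and reports for each
bipartition of the point tree the percentage of successful replicates
containing it; saturated replicates are skipped with a log entry, and an
alignment with no variable columns warns and reports zero support. An
optional outgroup re-roots the reported tree for display.

## Pipeline

`run_pipeline` executes stats → repeats → rates → pcl → order →
orfclusters → phylo over GenBank or GFF3+FASTA inputs; stage failures are
recorded while independent stages continue, and the process exits non-zero
on any failure. The Pcl stage requires a reference genome and refuses to
start without one. Every output file carries the tool version, seed and a
hash of the run configuration (output paths excluded), making reruns
byte-comparable. Problem sizes throughout the test suite and acceptance
script — 13-genome cohorts of ~30–50 kb, 100-replicate rate-ranking runs,
1,000-pair oracle comparisons — were chosen as the smallest sizes at which
the statistical claims concentrate.

## Known limitations

No gapped repeat alignment or repeat families; no E-value statistics; no
codon models beyond NG86 (no ML Ka/Ks, no confidence intervals); no
intron group typing or intron-sequence similarity clustering; star
alignment instead of progressive MSA; NJ instead of ML/Bayesian inference
(external writers provided); unsigned gene-order comparison only; de novo
annotation is out of scope — inputs must arrive annotated.
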