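# Methods

## Back-splice detection model

A circRNA junction read is modeled as the concatenation
`genome[e−k+1..e] + genome[s..s+(L−k)−1]` for a circle `[s, e]` (1-based
inclusive, `s < e`), read length `L` and junction offset `k`: the read's
first `k` bases come from the circle's tail, the rest from its head.
Detection triages reads that match the genome contiguously (either strand)
or an annotated spliced transcript, then takes the first and last
`anchor_length` bases (default 20 nt) of each remaining read and places them
with an exact k-mer index. Both anchors must place at a *unique* position
across both strands; ambiguous or missing anchors abort the read. A left
anchor downstream of the right anchor (reversed orientation) triggers
breakpoint search: all splits `k ∈ [anchor, L−anchor]` are tested for exact
two-block concordance, and a breakpoint is accepted only when the canonical
splice dinucleotides flank the circle on its annotated strand — AG
immediately 5′ of `s` and GT immediately 3′ of `e` for plus-strand circles,
which read AC/CT on the plus genome for minus-strand circles (the minus
pass simply reruns the plus logic on the reverse-complemented read). When
several breakpoints validate, the smallest start wins and the candidate is
flagged `multi_breakpoint`; determinism over biological plausibility, since
the alternatives describe the same junction shifted through a repeat.
A circRNA is called per sample when supported by at least
`min_distinct_reads` (default 2) distinct (read sequence, junction offset)
pairs.

Assumptions and limits: extension allows zero mismatches (configurable
through triage only), so junction reads carrying sequencing errors are
dropped rather than rescued — detection recall degrades smoothly with the
error rate while precision stays exact. Reads from circles shorter than
`read_length − anchor_length` place their anchors in non-reversed
orientation and are undetectable by this anchor scheme; the synthetic
defaults plant circles of ≥ 120 nt accordingly (the reassembly code still
accepts the full 51-nt floor).

## Classification

Exonic: the circle lies within one gene and overlaps ≥ 1 exon (endpoint
coincidence with splice sites is recorded as a flag but not required, a
permissive rule consistent with exon-dominant class mixes). Intronic:
entirely inside a single intron. Intergenic: no gene overlap. A circle
straddling a gene boundary has no defined parental relationship and is
classed intergenic with a warning — annotation dialects do not define this
case. Classification is order-independent because gene models are
non-overlapping.

## Expression and differential expression

circRNA abundance: TPM = junction reads × 10⁶ / total mapped reads of the
sample. mRNA abundance: FPKM = count × 10⁹ / (spliced length × total).
Features must be detected (abundance > 0) in at least two replicates of some
stage. Differential expression between two stages uses a two-sided Welch
t-test on log2(x + 1) with fold change = (mean_B + ε)/(mean_A + ε),
ε = 0.01 pseudo-abundance. Significance requires fold-change *magnitude*
(max of the ratio and its reciprocal) above threshold — 1.5 for circRNAs
with raw P < 0.05, 2 for mRNAs with Benjamini–Hochberg FDR < 0.05 computed
across features within each contrast. Negative-binomial shrinkage machinery
is deliberately not replicated: the thresholds, not the test internals,
define the DE sets, and the Welch surrogate is fully specified and
calibrated (null false-positive rate ≤ nominal under Poisson noise, see the
acceptance script). Identical groups give P = 1 by convention (the statistic
is undefined). The 2^−ΔΔCT helper accepts several reference genes and uses
their mean Ct.

## Back-splicing sequence reassembly and conservation

For circle length L > 200 the back-splicing sequence is the last 100 nt
followed by the first 100 nt (length 200, junction offset 100). For
51 ≤ L ≤ 200 the tail — the last ⌈L/2⌉ nt — is moved in front of the head,
preserving length with the junction at offset ⌈L/2⌉. "Over 200" is read as
strictly greater; at L = 200 both rules coincide. The ceiling split for odd
lengths is a logged constant (either convention centers the junction to
within one base).

Database search: subjects sharing no 11-mer with the query are skipped;
survivors receive a full local alignment (Biopython `PairwiseAligner`,
match +2, mismatch −3, gap open 5, gap extend 2 — a gap of length g costs
5 + 2g). E = m·n·2^(−bit), bit = (λS − ln K)/ln 2 with nucleotide
Karlin–Altschul constants λ = 0.625, K = 0.41 for +2/−3 scoring; m is the
query length and n the total database residues, with no effective-length
correction. Hits are kept below E = 1e−5 and sorted by E. A junction is
"spanned" when strictly interior to the aligned interval
(`start ≤ offset < end`): a junction touching the alignment edge provides no
cross-junction homology evidence. Tests verify the seeded search returns
exactly the full Smith–Waterman optimum (independent Gotoh DP oracle).

## Co-expression modules

The DE circRNA TPM and DE mRNA FPKM matrices are row-bound (feature-kind
tagged), dropping features with mean abundance < 0.001 or coefficient of
variation < 0.5. Unsigned adjacency a_ij = |pearson|^5; topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij); average-linkage
clustering of 1 − TOM. Module detection uses a static branch cut: descend
the dendrogram while both children hold ≥ 30 leaves, otherwise accept the
branch as a module; leftovers form the grey pool. This is a deliberate
simplification of the dynamic hybrid tree cut — it recovers well-separated
blocks exactly and keeps the procedure fully specified. Modules whose
eigengenes (first principal component of the standardized member rows,
sign-oriented to the mean profile, unit variance) are closer than 0.217
dissimilarity are merged iteratively to a fixed point (the count is
non-increasing, so at most the initial module count of iterations). Module
labels are WGCNA-style colors in descending size order; no meaning attaches
to a specific color. Traits are per-stage binary indicators; a module is
continuous-down / continuous-up when its eigengene stage means are monotone,
turn-point when they peak at the middle stage, otherwise the strongest
indicator correlation decides. Note an unsigned network cannot separate
perfectly anti-correlated profiles (|cor|⁵ = 1); Poisson noise around the
geometric stage profiles keeps the planted blocks separable in practice.

## miRNA target scoring and ceRNA networks

The reverse-complemented miRNA slides along the target; per aligned
position: complementary 0, G:U wobble 0.5, mismatch 1, gap 2, doubled at
miRNA positions 2–13 from the 5′ end. At most one gap per site is
considered (a bulged target base or an unpaired miRNA base); positions 5′
of a miRNA-side gap keep their index in the shortened sequence, a small
bookkeeping approximation. The best (lowest) site per miRNA–target pair is
kept when its expectation ≤ 5.0. Target-accessibility energies and
translation-inhibition calls are out of scope: scoring is
complementarity-only, so a zero expectation occurs exactly for a perfect
full-length complement. Genome-wide scans skip gapped sites by default for
speed; the single-site scorer allows them.

Per co-expression module, a miRNA is retained only with a qualifying site
on a module-member DE circRNA (sponge edge) *and* on a module-member DE
mRNA (crossover edge); unreachable nodes are dropped. Networks are
tripartite and module-pure by construction and are exported as a TSV edge
list plus GML.

## Synthetic data: what it emulates, and what it does not

The generator emulates the study design the pipeline targets: five stages ×
three replicates of single-end 100-nt rRNA-depleted reads; planted exonic /
intronic / intergenic circles (default 30/8/12, exon-heavy); stage profiles
acting multiplicatively on a base Poisson junction-read rate of 35
(geometric 8-fold span: down = decreasing, up = increasing, turn-point =
peak at FL3, flat = constant); genes carrying the same profile classes for
mRNA reads; a reference database seeded with 20 % of the planted circles'
reassemblies (divergence configurable, default 0) plus GC/length-matched
decoys sharing no 20-mer with any truth reassembly; 21-nt miRNAs with
designed sites embedded both in a non-flat circle and in a co-profiled mRNA.
Because sites are physical genome edits, a site inside an exonic circle is
necessarily also carried by the parental mRNA, and a site in a shared exon
can fall inside an overlapping circle — the truth table records these
induced sites explicitly.

Deliberately absent from the emulation: paired-end reads (anchors are
per-read in the detection scheme, so single-end halves complexity without
changing the algorithm), overdispersion beyond Poisson (DE truth stays
unambiguous), intron retention / alternative isoforms, indels and quality
score structure, rolling-circle junction reads over circles shorter than
half the read length, and genome repeats beyond what random sequence
produces. Passing tests therefore demonstrate algorithmic correctness under
the planted model, not performance on real libraries with error, bias and
repeat structure.

Determinism: every operation draws from a substream keyed on
(`seed`, stream id), so identical configurations give byte-identical
genomes, reads and truth tables regardless of call order.

## Problem sizes and defaults

Default study conditions: 4 chromosomes × 60 kb, 120 genes (2–5 exons of
120–350 nt, introns 90–400 nt), 50 circles spanning 120–1200 nt, 15 samples
× 20 000 reads, 8 miRNAs with 4 sponge triples, database of 10 homologs +
40 decoys. The full pipeline runs in well under a minute on one core; the
acceptance script (which additionally runs the detector-versus-oracle
comparison and the DE calibration) completes in a few minutes. Sizes were
chosen so every stage has enough features for its statistics (≥ 30-member
modules, ≥ 500-feature null calibration) while staying desk-scale.

## Known limitations

- Linear triage attributes ambiguous multi-transcript reads to the
  lexicographically smallest transcript id; gene-level counts are exact only
  because simulated genes do not share sequence.
- Anchor uniqueness is genome-wide and exact; a planted circle overlapping
  an embedded miRNA site can lose individual junction reads to anchor
  ambiguity (the calling threshold absorbs this at default depth).
- The E-value uses raw sequence lengths (no edge-effect correction), so
  values are slightly conservative for short queries.
- Module color labels depend on size rank only and are not stable across
  datasets.
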