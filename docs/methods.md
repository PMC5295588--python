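# Methods

## Scope and data model

All coordinates are 0-based half-open internally; GFF3/GTF I/O converts the
1-based closed convention at the boundary, and the converters are exact
inverses. SAM is parsed with pysam; only primary alignments are used, and
"uniquely mapped" means primary, NH absent or 1, and MAPQ at or above a
configurable floor (default 1). Libraries are strand-specific; the dialect
is configuration (`forward`, the default: the first-in-pair read maps to
the transcribed strand; or `reverse`), never inferred from data.

## Classification filters

The lncRNA filter suite requires, in order: spliced length ≥ 200 bp; at
least 2 raw fragments at some time point (replicates pooled per time
point, since the rule is stated per time point while counting is per
sample); non-zero standardised abundance at some time point; and no
tiling-path bridge to either flanking gene. The bridge test computes the
tiling path over the gap between the candidate span and each neighbour on
the candidate's strand: complete coverage of the gap (or a zero-length
gap) disqualifies. This operationalises "no tiling path to a neighbouring
gene" conservatively; a single uncovered base defeats a bridge.

Tiling paths use only properly paired reads whose CIGAR is a single
full-length match; the match length is taken from the record, not
hard-coded to 100. The antisense artifact rule removes a model when
(span − covered bases) / span exceeds 0.05 strictly, so a gap of exactly
5% is retained. The denominator is the model span; the alternative
read-count denominator is noted as ambiguous and the span form is the
implemented, configurable choice. Strand specificity is reported on the
composite region (the minimal interval containing both the sense gene and
the antisense model), pooling properly paired reads across all samples;
zero reads yield a missing value, not 0.

Coding potential is a three-forward-frame ATG→stop scan on the stranded
transcript sequence (minus-strand models are reverse-complemented first);
the default reporting threshold is 150 bp including the stop codon.

## Abundance

Counting is at the fragment level: a fragment contributes once to a model
when any of its reads overlaps the model's exons on the model's strand.
"Mappable length" is approximated by exonic length (the sum of exon
spans); a per-base mappability mask can be substituted through the same
argument. RPKM divides by the per-sample total of mapped fragments
excluding the ribosomal palindrome contig chrR, making values invariant to
rRNA carry-over on that contig. Sliding-window coverage uses per-base
depth, a per-window median, and log2(x + 1); the +1 pseudocount maps
zero-coverage windows to 0.

## Dynamics

Sample distance is D = 1 − SC over transcriptome profiles
(replicate-averaged per time point). D is symmetric with a zero diagonal
but violates the triangle inequality; classical (Torgerson) MDS —
double-centre −½·J·D²·J, eigendecompose, keep the top non-negative
eigenvalues — tolerates this, and axis signs are fixed by making
dimension 1 increase with time rank. On Euclidean-generated distances the
embedding reproduces the input to machine precision.

Spearman p-values: for n ≤ 13 without ties, the exact permutation null of
S = Σdᵢ² is enumerated once per n by a subset dynamic programme over the
generating function (cost n·2ⁿ, ~0.1 s at n = 13, cached). This matters
because Benjamini–Hochberg over thousands of transcript pairs rejects at
raw p ≈ 10⁻⁶, a tail where the t approximation is several-fold
anti-conservative at n = 13; with the exact null the measured null
false-report fraction sits at the nominal 0.01. Tied rows at n ≤ 13 are
mapped to the nearest attainable tie-free coefficient; for n ≤ 9 with ties
the null is enumerated directly; larger n uses the t approximation.
Multiple testing is Benjamini–Hochberg (configurable); the |SC| ≥ 0.85
display threshold is applied after FDR control.

Neighbour orientation for a lncRNA's 5′ neighbour: "converging" is a
co-oriented neighbour transcribing toward the lncRNA (read-through
scenario), "diverging" an opposite-strand neighbour transcribing away
(bidirectional-promoter scenario); 3′-side categories are reported
analogously. Group medians are compared against nearest-neighbour
correlations of 1000 randomly sampled genes (seeded) by two-sided
Mann–Whitney U. Clustering is complete linkage on D with exact optimal
leaf ordering; dendrograms export as Newick. Bootstrap support values are
out of scope.

## tRNA analysis

The reference collapses identical allele sequences to one contig per
unique sequence, retaining every genomic copy record. Reads are trimmed
65 bp from the 3′ end (100 → 35 bp) and treated single-end; pileups pool
all samples. The variant test is a one-sided binomial tail
P(X ≥ alt | coverage, e) against a fixed error rate e = 0.002, with
defaults min_alt_reads = 2, min_coverage = 8, and the lenient call
threshold p < 0.25 — calibrated so a planted 40% variant at coverage 200
is always called while null positions are called at well under 1%
(measured ≈ 0.6% at coverage 100). Anticodon coordinates come from gene
metadata (`wobble_index`), not structure prediction.

Decoding runs in the RNA alphabet with T↔U conversion at the boundary.
Anticodon positions 35/36 must pair Watson–Crick with codon positions 2/1;
position 34 (the wobble base) consults a decoding table
(G→{C,U}, U→{A,G}, A→{U}, C→{G}, I→{U,C,A}) that is data, not code, so
alternative rule sets are loadable. Wobble decoding additionally requires
matching amino-acid specificity, preventing near-cognate false positives.
A family counts as edited only on an observed A→G variant at the wobble
position, interpreted as A→I deamination (inosine reads as G). The
codon-rank correlation assigns zero abundance to codons without a cognate
family and uses average ranks, so the uncovered codons share tied bottom
ranks.

## Synthetic data

The generator emulates a compact AT-rich developmental study; its defaults
are the study conditions of every end-to-end test:

- **Genome**: 2 chromosomes × 200 kb; 150 coding genes, 50 intergenic
  lncRNA loci, 10 true asRNAs. Base composition 13% GC intergenic, 25% GC
  ORFs (stop-free codon sampling), 17% GC lncRNA exons; realised GC lands
  within ±0.02 of target for any class with ≥ 100 kb of sequence.
  Intergenic gaps are log-normal with a 700 bp median; when a requested
  complement cannot fit, gaps compress uniformly toward a 100 bp floor
  before a capacity error is raised. Coding exonic lengths are log-normal
  with an 1100 bp median (clipped 400–2200 bp) — compact transcripts chosen
  so the default complement fits the scaled genome — and lncRNA lengths
  log-normal with a 628 bp median. 70% of coding genes are spliced
  (introns uniform 70–500 bp).
- **Expression**: each transcript follows a Gaussian activation bump (peak
  time uniform over the course ± 2 hr, width 5 hr) multiplied by per-stage
  factors redrawn log-normally (σ = 0.5) at the stage boundaries (defaults
  6 and 9, i.e. leaps into the 12 hr and 18 hr time points). This yields
  gradual within-stage drift punctuated by larger boundary shifts, and a
  transcriptome trajectory near-collinear with time in MDS dimension 1.
  Per-transcript maxima are log-normal around class medians: 41 RPKM
  (mRNA, σ = 0.8), 1.0 RPKM (lncRNA, σ = 0.6), 8 RPKM (asRNA, σ = 0.5).
  Replicates add log-normal noise (σ = 0.1).
- **Reads**: emitted directly as SAM alignments (the aligner is out of
  scope, and this keeps tests hermetic); fragments are Poisson around
  RPKM × length × library_size / 10⁹ with a notional per-sample depth of
  5 × 10⁶ mapped fragments — a deliberately scaled-down depth at which the
  median lncRNA still yields ~6 fragments at its peak time point, so the
  2-fragment filter is informative rather than vacuous. Only fragments on
  simulated loci are emitted; the remaining notional depth represents the
  rest of a full transcriptome. Fragment lengths are N(300, 20), reads
  100 bp, SEQ/QUAL omitted (`*`) since no downstream step consumes read
  bases from the genomic SAM. At loci designated artifact-prone (spliced
  genes with intronic span fraction > 0.06), 10% of sense fragments are
  re-emitted with flipped strand flags — the strand-switch signature —
  so their antisense tiling gaps coincide with sense introns. Every read
  names its source model, enabling exact count-recovery tests.
- **tRNA**: 41 families with distinct anticodons (leaving 20 of 61 codons
  without a cognate), 1–2 unique alleles each, copies 1 + Poisson(3)
  capped at 22; family abundance factors are log-normal and independent of
  codon usage (so the synthetic abundance–codon-frequency correlation is
  ~0 by design). Designated A34 alleles carry an A→G fraction of 0.4 at
  the wobble position; sequencing error is positionally i.i.d. at 0.002.
  A separate deterministic "planted" complement misses exactly eight
  codons, four rescuable by wobble-position A→G variants (NNC codons whose
  only isoacceptor carries editable A34) and four not (NNA codons whose
  only isoacceptor carries C34).

What the generator does **not** emulate: base-call qualities, PCR
duplicates, mappability variation, multi-isoform loci, rRNA reads beyond
the notional library total, coupling of tRNA abundance to codon usage, and
the mitochondrial genome. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated statistical
structure, not performance on the full messiness of real libraries.

## Problem sizes

Defaults were chosen so the complete test suite runs in well under a
minute of simulation time: the classification study is 2 × 200 kb with
~0.5 M fragments across 26 samples; FDR calibration uses 100 null
replicates of 200 × 13 vs 50 × 13 matrices; the wobble oracle covers 1000
random complements × 61 codons; variant calibration uses 10⁴ null
positions at coverage 100.

## Known limitations

- The bridge test treats any fully covered flank gap as read-through;
  extremely deep intergenic noise could in principle disqualify a genuine
  lncRNA (no such noise source exists in the generator).
- Tied-rank Spearman p-values at 10 ≤ n ≤ 13 are approximated by the
  tie-free exact null.
- Counting attributes a fragment to every model whose exons it overlaps on
  its strand; no rescue of ambiguous assignments is attempted.
- `sample_intergenic` uses rejection sampling; pathologically fragmented
  intergenic space can exhaust the 10× attempt budget and error, reporting
  the achieved count.
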