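# Methods

## Coordinate and strand conventions

All internal coordinates are 0-based half-open; GFF input (1-based
inclusive) is converted on read, bedGraph/BED are used natively. Coverage is
strand-specific throughout: one depth array per sample per chromosome per
strand. Transcript-relative operations orient depth 5′→3′, so a minus-strand
gene's 3′ UTR extends toward smaller genomic coordinates and its summit
offsets map back through `transcript_to_genomic`.

## UTR extension

Walk outward from each ORF edge and include a base iff its depth ≥
`stop_fraction` × (median ORF depth). Choices where the procedure is
otherwise underdetermined:

- *Strictness.* A base exactly at the threshold is included; the walk stops
  at the first base strictly below it.
- *Even-count medians* use the mean of the two middle values; the consensus
  UTR length (median across the six input samples) is floored to an integer.
- *Silent genes.* A zero ORF median returns extension 0 — a threshold of 0
  would otherwise extend every silent gene to the 500-nt cap.
- *Adjacent ORFs.* The walk stops at the nearest same-strand ORF edge; the
  extension never includes a base of the neighboring ORF. Transcript
  intervals of two genes facing each other across a gap can still both
  extend into that gap; only ORFs bound the walk.
- The rule compares depth to a fraction of the same track's median, so it is
  invariant to rescaling a track — library size does not matter here.

## Peak-calling cascade

Windows are `window_len` = 100 nt at `window_step` = 50 nt from transcript
offset 0. When the transcript does not end on a full window, one trailing
window anchored at the 3′ end (length `min(window_len, L)`) is added so
3′-terminal sites are always scannable. Gates follow their wording exactly:
enrichment **>** 3, mean depth **>** 10, dependence ratio **≥** 1.75, log₂FC
**>** 0.8, p **<** 0.01.

- *Input subtraction* removes an IP window if it shares ≥ 1 base with any
  window passing the same gates in the paired (same genotype, same
  replicate) input sample — the strictest reading of "present in IP and not
  in input".
- *Merging* is transitive over overlapping **or book-ended** windows, since
  50-nt steps make adjacent signals exactly book-ended.
- *Per-genotype scores* for dependence are the mean of the three replicate
  enrichments of the merged interval, recomputed per sample. A cat score of
  0 yields ratio +∞: dependent, flagged (`cat_zero_flag`).
- *Summits* use pooled (summed) WT-IP depth; ties break leftmost in
  transcript orientation — deterministic and reproducible.
- *High-confidence test*: equal-variance Student t on per-replicate
  `log₂((IP mean + 1)/(input mean + 1))` over the peak interval. The log
  scale symmetrizes ratios; the pseudocount of 1 read guards zero-coverage
  inputs. High confidence additionally requires m⁶A dependence, mirroring
  the way the replicate test refines the dependent-site list.

## Expression statistics

Normalization is counts-per-million; the t test runs on `log₂(CPM + 1)` and
the fold change is `log₂((mean_a + 1)/(mean_b + 1))`. No multiple-testing
correction is applied — the analysis gates jointly on raw p < 0.01 and fold
change, which bounds the per-gene false-positive rate at α under the null;
a Benjamini–Hochberg column is available (`add_bh=True`) for users who want
it. Whether the original test operated on linear or log counts is not
derivable from the gates alone; log₂ is the package's standard and linear
results may differ marginally for skewed replicates.

CPM assumes roughly balanced libraries: when a large fraction of the panel
is truly up-regulated, library totals shift and every observed fold is
deflated (compositional bias). The tests therefore plant few DE genes
relative to the panel; users with globally shifted designs should prefer a
median-of-ratios normalization upstream.

## Motif and metagene

The motif anchor is the A of RGAC (third base) — the methylated position.
Searches are restricted to the summit's transcript on its own strand.
Consensus windows are 24 nt with the anchor A at index 13 (13 nt upstream,
10 nt downstream, window = [A−13, A+11) on the plus strand), reverse-
complemented for minus-strand genes; windows clipped by a chromosome edge
are flagged and excluded from consensus building. The IUPAC consensus letter
at each column is the smallest degeneracy class covering all bases with
frequency ≥ 0.25. The control comparison samples an equal-size set of
m⁶A-independent summits with a caller-supplied seed (default 0).

## Boolean epistasis

Models are linear chains only: one gene upstream of the other, the
downstream gene acting on replication; 2 orders × 2 × 2 edge signs = 8
models. Semantics: a gene is active iff present and unrepressed; the
upstream gene is active iff not deleted; the downstream gene is active iff
not deleted and its input edge leaves it on; replication follows the sign of
the downstream edge. Under these semantics exactly one model — double
repression with IME4 upstream — reproduces all four deletion phenotypes, and
an exhaustive truth-table oracle in the tests confirms every prediction.

## MazF model

Cleavage occurs immediately 5′ of the leading A of every ACA trimer whose
leading A is unmethylated (`cut_offset` is configurable; only
product presence/absence matters for the assay's readout). Overlapping
trimers (ACACA) are each evaluated; duplicate cut coordinates are
deduplicated, and a cut falling at position 0 cleaves no bond. A PCR product
requires both primer sites wholly within one fragment. Partial methylation
stoichiometry (mixed molecule populations, fractional band intensity) is not
modeled; the readout is binary.

## Synthetic-data generator

The generator emulates the structure of a 3 + 3 replicate design (WT and
catalytic-dead genotypes, IP and input fractions) that the analysis assumes:

- *Genome/annotation*: one chromosome, genes placed sequentially with 300-nt
  gaps on random strands, ORFs 600–2000 nt, true UTRs of 50 nt (5′) and
  150 nt (3′). A fraction (default 0.3) of genes is methylated: the
  transcript 4-mer around the planted A is set to GGAC, placed uniformly in
  the 3′-terminal third of the transcript but ≥ 20 nt from the 3′ end.
- *Coverage*: per-base negative-binomial draws (size 100) around a
  lognormal gene mean (median 30×, σ = 0.4), box-smoothed over 50 nt within
  each transcript. The smoothing models fragment-length autocorrelation:
  sequenced fragments span ~70–120 nt, so neighboring bases share most of
  their reads and real per-base depth cannot dip at a single base — with
  independent draws the UTR walk would stop spuriously at isolated low
  bases, truncating UTRs in a way real coverage does not. WT IP means are
  multiplied by the site effect (default 5×) within ±50 nt of each planted
  site; cat IP and all input tracks carry expression only.
- *Counts*: gene-level negative binomial, size 400 and lognormal means
  (σ = 0.5), corresponding to a replicate CV of ~5–9% for well-expressed
  genes — the low biological variability of isogenic yeast triplicates, and
  low enough that a true 2-fold change reliably clears the 0.8 log₂FC gate
  (a calibration the planted-analog design presumes). One methylated gene,
  the *RME1-analog*, has its cat mean multiplied by 2.0.
- *Determinism*: every stage draws from `default_rng([seed, stage])`, so a
  fixed seed gives byte-identical files.

What passing tests on this generator do **not** show about real data:
planted peaks are rectangular, so summits scatter ~uniformly over the
±50-nt plateau rather than concentrating on the site as real fragment
pileups do — the "summit within 5 nt of a motif" statistic is therefore not
reproduced structurally, and motif-window selection on synthetic data uses
the detector's resolution (25 nt, half a window step) instead. Coverage has
no positional biases (GC, 3′ bias, mappability), libraries are perfectly
balanced, and no gene is alternatively isoformed or overlapping on the
opposite strand.

## Problem sizes and runtime

Default study conditions are 50 genes, 12 tracks, 3 + 3 replicates; a full
simulate-plus-pipeline run takes well under a second, so the repeated-run
checks (25 seeded end-to-end runs, 100-seed gate calibration, 1000 random
MazF molecules) complete in seconds. These sizes are the package's reference
conditions for its published checks; all are configurable through
`SimConfig` and the parameter dataclasses.
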