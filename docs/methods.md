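# Methods

## Model and procedure

`meripeak` detects m6A regions as transcript windows whose read coverage in
an anti-m6A IP library exceeds, relative to sequencing depth, their coverage
in the matched input library.

1. **Gene models.** One transcript represents each gene. When an input GTF
   annotates several isoforms, the longest (by summed exon length, ties
   broken by transcript id) is kept: the common metagene convention, and it
   makes the window set deterministic. All internal coordinates are 0-based
   half-open; transcript coordinates run 5'→3', so position 0 of a
   minus-strand gene is its genomically rightmost exonic base.
2. **Windows.** Each transcript is tiled from its 5' end with discrete
   non-overlapping 25-nt windows (`floor(L/25)` of them; the trailing
   partial window is dropped). Windows are projected to genomic blocks so
   that genome-aligned reads can be counted against them.
3. **Counting.** A read increments a window when any of its aligned blocks
   overlaps any window block by ≥1 bp; a ~125-bp fragment therefore counts
   in ~5–6 consecutive windows, once each. Counting is strand-agnostic by
   default (plain interval intersection); duplicate-flagged SAM records are
   excluded. Library totals are alignment-record counts.
4. **Read filter.** Windows with fewer than 5 reads summed over *all*
   samples and replicates are dropped before testing. Pooling avoids biasing
   the filter toward IP-only signal; a per-library mode is available
   (`filter_windows(per_sample=True)`).
5. **Test.** Per replicate, the one-sided Fisher's exact test on
   [[k, K−k], [m, M−m]] with alternative "IP rate > input rate", computed as
   the upper hypergeometric tail (`scipy.stats.hypergeom.sf`). If either
   library is empty the window gets p = 1 (no evidence is possible).
6. **Replicates and FDR.** Per-replicate p-values are combined with
   Fisher's method; combined p-values are BH-adjusted over all retained
   windows transcriptome-wide; significance is q < α = 0.05. Combining raw
   p-values first and adjusting once yields a single coherent FDR-controlled
   decision per window; the alternative sequencing (BH per replicate, then
   combine the adjusted values and threshold at α) is available as
   `order="adjust-then-combine"`.
7. **Peaks.** Maximal runs of consecutive significant windows within one
   gene are merged; runs spanning <100 bp (fewer than 4 windows) are
   discarded, so every peak length is ≥100 and a multiple of 25.
   "Consecutive" is strict — a single non-significant window breaks a run —
   and runs never cross gene boundaries. A peak carries the pooled fold
   (Σk/ΣK)/(Σm/ΣM), the best member q, and score −log10 q (q floored at
   1e-300 so the score stays finite).

## Annotation

Region labels and metagene placement use the peak midpoint in transcript
coordinates, the standard proxy for a site position. Zones of ±100 nt
around the start and stop codons ("TSS", "Stop") take precedence over plain
5'UTR/CDS/3'UTR labels; the halfwidths are conventional choices, exposed in
`RegionScheme`. The metagene axis allocates 20/50/30 bins to
5'UTR/CDS/3'UTR, reflecting typical length ratios; each region of each
transcript is rescaled to its bin count and the histogram is normalized to
sum to 1. `compare_peak_sets(A, B)` treats A as the query: the fraction of
A's genes also methylated in B, and the fraction of A's peaks overlapping a
same-gene B peak by ≥1 nt.

## Synthetic data generator

The generator emulates fragment alignments from a polyA-selected
transcriptome so the whole pipeline is testable without sequencing data.

- **Transcriptome.** `n_genes` (default 200) non-overlapping genes on one
  pseudo-chromosome with 1-kb spacers, transcript lengths uniform on
  500–3000 nt, 1–3 exons with 200–500-nt introns, random strand, and a CDS
  spanning the central ~60% so all three regions are nonempty.
- **Abundance.** Per-gene relative abundance is log-normal(0, 1), shared by
  all libraries: fragments are multinomial over genes with these weights.
- **Truth.** 42.7% of genes (default) carry peaks; peak counts per gene are
  drawn from {1: .40, 2: .25, 3: .15, 4: .12, 5: .08} (65% of methylated
  genes get one or two peaks). Each peak is 150 nt; with probability
  `stop_bias` (default 0.6) its center is uniform within ±150 nt of the
  stop codon (clamped inside the transcript), otherwise uniform over the
  transcript. Peaks within a gene keep ≥100 nt between edges so distinct
  planted peaks remain distinct under the caller's merge definition; if a
  drawn count cannot be placed in 50 attempts the gene gets fewer peaks
  (logged).
- **Fragments.** Lengths are normal (125, 15) nt (150 for the low-input
  emulation), rounded and clipped to [30, L]. A fragment *center* is drawn
  uniformly (input) or from the piecewise-constant density that multiplies
  the baseline by `enrichment_fold` (default 8) inside planted intervals,
  renormalized (IP). Acting on centers rather than per-gene read counts
  keeps gene-level abundance identical between IP and input except through
  peaks — exactly the signal the window test targets. Fragments are clipped
  at transcript ends and projected to (possibly spliced) genomic blocks.
- **Randomness.** Everything derives from one `SeedSequence` rooted at the
  config seed, with fixed stream keys per stage and per (sample, replicate),
  so identical configs give byte-identical output files.

What the generator does **not** model: sequence content and motifs, base
quality or alignment error, positional coverage biases (fragmentation,
priming, GC), overlapping genes and isoform mixtures, or biological
replicate variability beyond sampling noise (replicates are i.i.d. draws).
Passing recovery tests therefore demonstrates correctness of the counting
and inference machinery under the stated sampling model, not performance on
real libraries with structured noise.

## Translation efficiency

Footprints are counted when their 5' end (strand-aware, in transcript
coordinates) lies in [cds_start + 20, cds_end − 20), trimming the
initiation and termination pile-ups; genes whose CDS is ≤40 nt are flagged
and excluded. TE = log2((ribo + 0.5)/(rna + 0.5)) after rescaling both
counts to the mean of the two library sizes. Rescaling to the mean (rather
than to a fixed per-million unit) keeps equal-depth libraries' counts
untouched, makes TE invariant to common depth scaling, and keeps the 0.5
pseudocount on the scale of raw counts. This TE is descriptive; differential
testing across conditions is out of scope.

## Numerical choices and edge cases

- Hypergeometric tails come from `scipy.stats.hypergeom.sf`; they agree
  with exact integer enumeration to <1e-9 for all tables with margins ≤30
  (tested exhaustively).
- Fisher's method clamps p = 0 inputs to the smallest positive double
  (logged); BH uses `statsmodels.stats.multitest.multipletests`.
- Empty inputs: zero genes → empty outputs; zero reads → valid empty BED;
  empty p-vector → empty q-vector; empty truth → recall undefined (`None`);
  empty peak set → undefined overlap fractions and 1–2-peak fraction.
- Peak-set evaluation: a planted peak is recovered when called peaks of the
  same gene cover ≥50% of its span; a called peak is a true positive when
  ≥50% of its span lies in planted intervals; both boundaries inclusive.

## Problem sizes

Default simulations use 200 genes and 100k–200k fragments per library —
roughly 14k tested windows — which gives the window test ample counts
(median ~50 input reads per covered window) while keeping any single run
under a few seconds and the full test suite near one minute. Error-control
runs average 20 independent seeds; the acceptance script averages 5.

## Known limitations

- One transcript per gene: peaks on minor isoforms' unique exons are
  invisible, as in any longest-isoform metagene analysis.
- The ≥5-read filter's pooling rule and the combine/adjust ordering are
  documented conventions of this implementation; both alternatives are
  flagged options.
- The fold estimate for a peak is a pooled ratio, not a shrunken estimator;
  it is reported for ranking, not inference.
- With dense multi-peak genes, physically close planted peaks can merge
  into one called region; the ≥50%-span matching rule absorbs modest
  merging but recall declines when many peaks crowd one transcript.
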