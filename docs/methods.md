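# Methods

## The assay this package models

Nuclease-mediated protein footprinting measures where proteins sit on RNA.
A cross-linked lysate is split in two: the *footprint* sample is digested
with an RNase while proteins are still bound, so protein-covered fragments
survive; the *digestion control* has its proteins stripped (SDS/proteinase
K) before digestion, so only intrinsically nuclease-resistant regions
survive. Both are sequenced strand-specifically. A protein-protected site
(PPS) is a region whose footprint coverage is higher than the control
predicts.

## The caller

Reads are deduplicated (identical chrom + block structure + strand collapse
to one representative) and turned into per-base, per-strand coverage.
For each base `i` with footprint depth `f_i` and control depth `c_i`, the
null is that footprint reads fall like control reads after depth
normalization. With `r = N_fp / N_ctl` the library-size ratio, the null
rate is

    lambda_i = r * max(c_i, lambda_min)

and the enrichment score is `s_i = -log10 P(X >= f_i)` for
`X ~ Poisson(lambda_i)`, set to 0 where `f_i = 0` and capped at 350.
`lambda_min` (default 0.5 reads) is a pseudo-rate floor so that bases with
zero control coverage cannot produce infinite scores. The tail is computed
through the regularized incomplete gamma function, switching to
`log1p` of the complementary CDF when the tail is near 1 and to a
log-space series (logsumexp over tail terms) below double underflow, so
the score is accurate across its whole range (checked against
arbitrary-precision summation to 1e-9 relative error).

Candidate regions are maximal runs of positive-score bases, with runs
separated by at most `max_gap` bases merged (default 0) and runs shorter
than `min_length` (default 15 nt) discarded. Each region is scored by its
maximum per-base score.

**FDR.** The null is a read-label permutation: footprint and control reads
are pooled and randomly relabeled, preserving both library sizes; the
score profile and candidate regions are recomputed. Over the grid of
distinct observed region scores, `FDR(t)` = mean permuted region count at
score ≥ t over the observed count at ≥ t, monotonized conservatively
(running maximum from the highest threshold downward). The working
threshold is the smallest grid score with `FDR(t) <=` the target (default
5%); all candidate regions whose score reaches it — ties included — are
reported with their full extent. Thresholding whole candidate regions by
their region score (rather than re-segmenting the per-base profile at the
working threshold) keeps a called site's boundaries at the edges of its
enriched run; re-segmentation would clip calls to their score peaks
whenever the permutation null pushes the threshold above the shoulder
scores, which misstates site sizes. Calling is per strand and per
chromosome; the threshold is global (one FDR table per experiment).

With 10 permutations the smallest non-zero estimate of the null count at
the top observed score is 0.1, so on signal-free data the caller emits
anything only when the observed maximum beats every permutation maximum —
about a 1-in-11 event; the measured any-call rate over 50 null
simulations is 6–8%.

## Downstream statistics

* **Genic regions.** Transcripts decompose into 5'UTR/CDS/3'UTR (coding
  exons, by CDS position and strand), proximal intron (the first and last
  500 nt of each intron; introns ≤ 1000 nt are wholly proximal, a
  distance-based reading), distal intron, lncRNA exon and a residual
  class. Decomposition is a per-transcript partition.
* **Annotation** is greedy: a PPS takes every (region class, transcript)
  label it overlaps by ≥ 1 base on the same strand, so summary
  distributions count labels, not PPSs, and isoform disagreement double
  counts by design. Per-region mean PPS counts are reported both over
  transcripts with ≥ 1 PPS in the region (default) and over all
  transcripts exposing the region, since either denominator is defensible.
* **Density** per region class = PPS base coverage / control reads in the
  class territory; undefined (reported missing) with zero control reads.
* **Expression dependence**: OLS of per-transcript PPS count on
  log10(control reads + 1); the expression proxy is the deduplicated
  control read count over exonic territory. Expression matching for the
  lncRNA vs 3'UTR comparison is greedy nearest-neighbor without
  replacement.
* **Profiles.** Metagene: regions rescaled to 100 bins, PPS bases
  accumulated with fractional bin overlap (regions shorter than the bin
  count are kept, not dropped), oriented 5'→3', normalized to the curve's
  own maximum; raw per-bin mass is kept so binned mass equals covered
  bases. End-anchored profiles count per-nt coverage frequency at offsets
  1..50 inward from each region end. PPS *bases* are counted (midpoints
  would sharpen but under-represent long sites).
* **Interval enrichment.** Background = transcribed segments of the
  control (coverage ≥ 10, gaps ≤ 10 merged, runs ≥ 15 kept). Shuffles
  preserve the PPS length multiset and place each interval uniformly
  inside a segment (segment chosen ∝ its valid start positions). The
  overlap unit is the query interval (≥ 1 nt counts once); the 2×2 table
  pools the ten shuffle sets; chi-squared is 1 df without continuity
  correction. Point events (e.g. T>C transversions) closer than 40 nt
  (closest-position distance) are single-linkage merged; the rule is
  idempotent on its own output.
* **Conservation.** Any per-base score track (bedGraph) is accepted;
  missing bases stay missing. Each PPS is compared to immediately
  adjacent flanks of its own length; significance is a chi-squared on the
  above/below-pooled-median dichotomy of per-interval means (a rank-sum
  alternative exists behind `rank_sum_pps_vs_flank`). Median split is the
  package's explicit convention for dichotomization.
* **Motif co-occurrence** is transcript-level: entry (a,b) counts
  transcripts where both motifs occur inside PPSs, regardless of
  multiplicity. k-means (k = 5 by default, 50 restarts, seeded) runs on
  raw count profiles; the 2-D map is classical (Torgerson) MDS of the
  overlap-coefficient complement `1 − n_ab / min(n_a, n_b)` — classical
  scaling is used because it reproduces Euclidean configurations exactly,
  which SMACOF-style solvers do not.
* **SNPs.** Background = territory of the same region classes the PPSs
  occupy, minus PPS bases (no self-contamination); tables are on base
  counts, unstranded. The synonymous/non-synonymous contrast is a 2×2 of
  class × stratum. Functional classes come from the input (no codon
  arithmetic is attempted).

## The simulator

The generator emulates the data-generating process, not sequence content:
reads carry coordinates only.

* ~50 transcripts (1–4 exons of 150–400 nt, introns 200–1500 nt, 15%
  lncRNA) laid on one synthetic chromosome; per-transcript abundance is
  log-normal (sigma 0.5, mean 1) — a modest spread so low-expression
  transcripts exist without dominating.
* Planted sites: Poisson(2) per transcript, lengths N(40, 5) truncated at
  15 nt, 25% intronic, ≥ 60 nt apart.
* Both libraries draw fragment starts uniformly along each transcript
  (coverage 30× × abundance exonic; half that intronic, emulating
  pre-mRNA); spliced fragments are projected through the exon chain.
  In the footprint sample a fragment touching a planted site survives *as
  its protected part* (trimmed to the site) — the nuclease removes the
  unprotected overhangs, which is why real called sites match footprint
  size — while fragments elsewhere survive whole with probability
  depletion/enrichment (default 0.1/8). Setting enrichment = depletion
  = 1 yields the exchangeable null (no trimming, identical processes).
* Conservation tracks are i.i.d. normal with an additive boost inside
  planted sites; SNPs and point events are placed over genic territory
  with configurable inside-site rate multipliers and class biases; motif
  occurrence tables carry a planted block structure over site-bearing
  transcripts with a configurable incidence-flip noise rate.

What the simulator does **not** model: sequence composition and mappability,
RNase structure specificity (ss vs ds), fragment-length biases, PCR
duplication, multi-mapping. Passing tests therefore demonstrate the
statistical machinery is correct under its stated model, not that any
particular biological dataset will behave this way.

## Problem sizes and numerical choices

Simulated experiments used in the test-suite and the acceptance script run
at ~20–40 transcripts (~50–120 kb of genome, 15k–40k reads), where a full
call — coverage, scores, 10 permutations, FDR — takes well under a second
and the whole suite a few minutes; the same code paths scale linearly in
genome size and read count. Scores are capped at 350; FDR grids above
1000 distinct region scores are thinned by quantiles with the upper tail
kept at full resolution; k-means ties are broken by the best of 50 seeded
restarts; degenerate 2×2 tables (a zero marginal) report statistic 0,
p = 1 rather than erroring.

## Known limitations

* The permutation null redistributes genuinely protected reads across the
  whole transcriptome, which inflates null region counts at low score
  thresholds; the caller is therefore conservative near the threshold
  floor (an FDR estimate near 1 at low thresholds even with real signal).
* Replicate-correlation window defaults (100 nt, non-overlapping) are a
  convention; published correlation figures depend on the original
  libraries and window choice and are not reproducible from synthetic
  data.
* Expression matching and the motif keep-list are heuristics standing in
  for manual curation steps that cannot be automated faithfully.
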