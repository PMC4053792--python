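# pipseq

Calling and analysis of protein-protected sites (PPSs) from RNase-mediated
protein footprint sequencing.

Footprint sequencing maps RNA–protein interactions transcriptome-wide: a
lysate is split into a **footprint** sample (RNase digestion with proteins
still bound, so protein-covered fragments survive) and an **RNase digestion
control** (proteins stripped first, so only intrinsically nuclease-resistant
RNA survives), and both are sequenced strand-specifically. Regions whose
footprint coverage exceeds what the control predicts are protein-protected
sites. This package is for computational biologists working with such
paired libraries: it takes aligned reads and produces called sites plus the
standard downstream analyses.

## The model

Per base *i*, with footprint depth *f<sub>i</sub>*, control depth
*c<sub>i</sub>* and library-size ratio *r* = *N*<sub>fp</sub>/*N*<sub>ctl</sub>:

> λ<sub>i</sub> = *r* · max(*c<sub>i</sub>*, λ<sub>min</sub>),  
> *s<sub>i</sub>* = −log₁₀ P(X ≥ *f<sub>i</sub>*),  X ~ Poisson(λ<sub>i</sub>)

Candidate regions are maximal runs of scored bases (gap-merged,
length-filtered, default ≥ 15 nt) scored by their maximum *s<sub>i</sub>*.
The score threshold is set by a permutation FDR: reads are pooled and
relabeled (library sizes preserved), region counts recomputed, and
FDR(*t*) = mean null count ≥ *t* / observed count ≥ *t*; sites are called
at the smallest threshold with FDR ≤ 5%.

Downstream modules cover greedy functional annotation over genic region
classes (5′UTR/CDS/3′UTR, proximal/distal intron, lncRNA), PPS density and
size statistics, metagene and end-anchored profiles, overlap enrichment
against external interval sets (CLIP-style) with size-preserving shuffles
over transcribed background segments, T>C-event merging and per-site event
counts, conservation versus equal-sized flanks, transcript-level motif
co-occurrence with k-means modules and classical MDS, SNP enrichment
against genic-region-matched backgrounds, and read-subsampling saturation
curves. A simulator generates complete synthetic experiments with known
planted truth for testing and calibration. See `docs/methods.md` for the
full model description.

## Worked example

Simulate an experiment, call sites, and annotate them:

```bash
pipseq simulate --seed 3 --outdir sim
# simulated 50 transcripts, 83 planted sites, 4720/40435 footprint/control reads -> sim/

pipseq call --footprint sim/footprint.bed --control sim/control.bed \
            --dialect bed --seed 1 --out-prefix pps
# 82 PPSs written to pps.bed

head -3 pps.bed
# chr1  1244  1293  PPS0  255  +  21.3334  69  65  3.969
# chr1  4278  4322  PPS1  194  +  16.0367  47  44  3.969
# chr1  5110  5156  PPS2   71  +   4.5145  26  65  3.969

pipseq annotate --pps pps.bed --annotation sim/annotation.gtf --out ann.tsv
# annotated 82 PPSs -> ann.tsv
```

The call output is BED6+ per site: the score column is min(1000,
round(10·score)); the extra columns are the mean per-base score, footprint
and control read counts over the site, and the FDR-derived score threshold
the run used (here 3.969 — every region whose maximum per-base score
reached 3.97 cleared the 5% permutation FDR). 82 of 83 planted sites are
recovered, at the ~40 nt sizes the simulator plants. The annotation step
labels each site with every overlapping (region class, transcript) pair —
PPS1 overlaps both the CDS and 5′UTR of tx1 and carries both labels, which
is the intended greedy double counting.

The same operations are importable (`pipseq.call_pps`,
`pipseq.annotate_pps`, …) for use from Python; the CLI subcommands
(`simulate`, `call`, `annotate`, `profile`, `enrich`, `conserve`,
`cooccur`, `snp`) are thin wrappers over them.

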