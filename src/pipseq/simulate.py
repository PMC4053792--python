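"""Synthetic footprint experiments with known truth.

The generator emulates the data-generating process of a nuclease
protection experiment: transcripts are laid out on a small synthetic
genome, protein-protected sites of ~40 nt are planted in exons and
introns, and two libraries are drawn from the same fragment-start process
— the control uniformly along each transcript, the footprint with
per-read acceptance proportional to ``enrichment`` inside planted sites
and ``depletion`` outside.  Digestion is thus modeled at the level of
which fragments survive, which is all the caller's coverage statistics
see.  Reads carry coordinates only (no sequence) and spliced reads are
projected through the exon structure.

Conservation tracks, SNP sets, T>C-style point events and FIMO-style
motif occurrence tables with planted structure are generated from the
same truth object so every downstream module has a closed testing loop.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import AlignedSegment, Library
from .model import (
    GenomicInterval,
    RegionMap,
    Strand,
    Transcript,
    build_region_map,
    merged_by_key,
)

CHROM = "chr1"


@dataclass
class SimConfig:
    """Study conditions of the synthetic experiment.

    Planted sites are ~40 nt (normal, sd 5), the footprint library keeps
    reads inside sites with 8-fold the acceptance of reads outside
    (enrichment 8, depletion 0.1), the control is uniform at 30x mean
    exonic depth, and reads are 50 nt single-end — matching the regime the
    caller is expected to operate in.  Intronic (pre-mRNA) signal runs at
    half the exonic depth.
    """

    n_transcripts: int = 50
    exon_count_range: tuple[int, int] = (1, 4)
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (200, 1500)
    lncrna_fraction: float = 0.15
    intergenic_gap: int = 500
    abundance_sigma: float = 0.5  # log-normal spread of per-transcript abundance
    pps_per_transcript: float = 2.0  # Poisson mean of planted sites per transcript
    pps_length_mean: float = 40.0
    pps_length_sd: float = 5.0
    pps_intron_fraction: float = 0.25  # planted sites placed in introns
    min_site_separation: int = 60
    enrichment: float = 8.0  # footprint acceptance multiplier inside sites (e)
    depletion: float = 0.1  # footprint survival outside sites (d)
    control_depth: float = 30.0  # mean exonic coverage of the control library
    intron_depth_fraction: float = 0.5
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        null_case = self.enrichment == 1.0 and self.depletion == 1.0
        if not null_case and not (self.enrichment > 1 > self.depletion >= 0):
            raise ValueError(
                "need enrichment > 1 > depletion >= 0 (or enrichment == depletion == 1 "
                "for the exchangeable null)"
            )
        if self.pps_length_mean <= 0 or self.read_length <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class SimTruth:
    """Ground truth of one synthetic experiment."""

    transcripts: list[Transcript]
    planted: list[GenomicInterval]
    abundance: dict[str, float]
    chrom_lengths: dict[str, int]
    files: dict[str, str] = field(default_factory=dict)

    def region_map(self, proximal_nt: int = 500) -> RegionMap:
        return build_region_map(self.transcripts, proximal_nt=proximal_nt)


# ---------------------------------------------------------------------------
# annotation + planted sites


def _make_transcript(rng: np.random.Generator, cfg: SimConfig, idx: int, cursor: int) -> Transcript:
    n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
    exons = []
    pos = cursor
    for i in range(n_exons):
        ln = int(rng.integers(*cfg.exon_length_range))
        exons.append((pos, pos + ln))
        pos += ln
        if i < n_exons - 1:
            pos += int(rng.integers(*cfg.intron_length_range))
    strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
    is_lnc = rng.random() < cfg.lncrna_fraction
    cds = None
    if not is_lnc:
        # UTR lengths in transcript (mature) coordinates
        total = sum(e - s for s, e in exons)
        utr5 = int(rng.integers(30, 100))
        utr3 = int(rng.integers(50, 200))
        if utr5 + utr3 + 30 > total:
            utr5, utr3 = 10, 10
        lo, hi = (utr5, total - utr3) if strand is Strand.PLUS else (utr3, total - utr5)
        cds = (_tx_to_genomic(exons, lo), _tx_to_genomic(exons, hi - 1) + 1)
    return Transcript(
        id=f"tx{idx}",
        gene_id=f"gene{idx}",
        biotype="lncRNA" if is_lnc else "mRNA",
        chrom=CHROM,
        strand=strand,
        exons=tuple(exons),
        cds=cds,
    )


def _tx_to_genomic(exons: list[tuple[int, int]], tpos: int) -> int:
    """Mature-transcript offset (genomic orientation) to genomic position."""
    for s, e in exons:
        if tpos < e - s:
            return s + tpos
        tpos -= e - s
    raise IndexError("transcript position beyond exonic length")


def _plant_sites(rng: np.random.Generator, cfg: SimConfig, t: Transcript) -> list[GenomicInterval]:
    n = int(rng.poisson(cfg.pps_per_transcript))
    sites: list[GenomicInterval] = []
    introns = t.introns()
    for _ in range(n):
        length = max(15, int(round(rng.normal(cfg.pps_length_mean, cfg.pps_length_sd))))
        in_intron = introns and rng.random() < cfg.pps_intron_fraction
        for _attempt in range(20):
            if in_intron:
                lens = np.array([e - s for s, e in introns], dtype=float)
                ok = lens >= length
                if not ok.any():
                    break
                i = int(rng.choice(len(introns), p=lens * ok / (lens * ok).sum()))
                s0, e0 = introns[i]
            else:
                lens = np.array([e - s for s, e in t.exons], dtype=float)
                ok = lens >= length
                if not ok.any():
                    break
                i = int(rng.choice(len(t.exons), p=lens * ok / (lens * ok).sum()))
                s0, e0 = t.exons[i]
            start = int(rng.integers(s0, e0 - length + 1))
            cand = GenomicInterval(t.chrom, start, start + length, t.strand)
            if all(
                cand.chrom != s.chrom
                or cand.start >= s.end + cfg.min_site_separation
                or s.start >= cand.end + cfg.min_site_separation
                for s in sites
            ):
                sites.append(cand)
                break
    return sites


def simulate_annotation(cfg: SimConfig, outdir: str | Path | None = None) -> tuple[list[Transcript], SimTruth]:
    """Lay out transcripts on a synthetic genome and plant true sites.

    When ``outdir`` is given, GTF, BED12, a biotype map and the truth BED
    are written there and recorded in ``truth.files``.
    """
    rng = np.random.default_rng(cfg.seed)
    transcripts: list[Transcript] = []
    cursor = cfg.intergenic_gap
    for i in range(cfg.n_transcripts):
        t = _make_transcript(rng, cfg, i, cursor)
        transcripts.append(t)
        cursor = t.exons[-1][1] + cfg.intergenic_gap
    planted: list[GenomicInterval] = []
    for t in transcripts:
        planted.extend(_plant_sites(rng, cfg, t))
    abundance = {
        t.id: float(v)
        for t, v in zip(
            transcripts,
            np.exp(rng.normal(0.0, cfg.abundance_sigma, size=len(transcripts))),
        )
    }
    truth = SimTruth(
        transcripts=transcripts,
        planted=planted,
        abundance=abundance,
        chrom_lengths={CHROM: cursor},
    )
    if outdir is not None:
        from . import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": outdir / "annotation.gtf",
            "bed12": outdir / "annotation.bed12",
            "biotypes": outdir / "biotypes.tsv",
            "truth_bed": outdir / "planted_sites.bed",
        }
        io.write_gtf(transcripts, paths["gtf"])
        io.write_bed12(transcripts, paths["bed12"])
        io.write_biotype_map(transcripts, paths["biotypes"])
        io.write_bed_intervals(planted, paths["truth_bed"], name="site")
        truth.files = {k: str(v) for k, v in paths.items()}
    return transcripts, truth


# ---------------------------------------------------------------------------
# libraries


def _project_read(exons: tuple[tuple[int, int], ...], tstart: int, rl: int) -> tuple[tuple[int, int], ...]:
    """Project a mature-transcript read [tstart, tstart+rl) to genomic blocks."""
    blocks: list[tuple[int, int]] = []
    remaining = rl
    pos = tstart
    for s, e in exons:
        ln = e - s
        if pos >= ln:
            pos -= ln
            continue
        take = min(remaining, ln - pos)
        blocks.append((s + pos, s + pos + take))
        remaining -= take
        pos = 0
        if remaining == 0:
            break
    return tuple(blocks)


def _candidate_reads(
    rng: np.random.Generator, cfg: SimConfig, truth: SimTruth
) -> list[AlignedSegment]:
    """Uniform fragment-start process along transcripts (exonic + intronic)."""
    reads: list[AlignedSegment] = []
    rl = cfg.read_length
    for t in truth.transcripts:
        ab = truth.abundance[t.id]
        L = t.exonic_length
        if L >= rl:
            n = rng.poisson(ab * cfg.control_depth * L / rl)
            for tstart in rng.integers(0, L - rl + 1, size=n):
                reads.append(AlignedSegment(t.chrom, _project_read(t.exons, int(tstart), rl), t.strand))
        for s, e in t.introns():
            if e - s < rl:
                continue
            n = rng.poisson(ab * cfg.control_depth * cfg.intron_depth_fraction * (e - s) / rl)
            for gstart in rng.integers(s, e - rl + 1, size=n):
                reads.append(AlignedSegment(t.chrom, ((int(gstart), int(gstart) + rl),), t.strand))
    return reads


def _intersect_blocks(
    blocks: tuple[tuple[int, int], ...], merged: list[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    out: list[tuple[int, int]] = []
    for s, e in blocks:
        for ms, me in merged:
            os_, oe = max(s, ms), min(e, me)
            if os_ < oe:
                out.append((os_, oe))
    return tuple(sorted(out))


def simulate_libraries(cfg: SimConfig, truth: SimTruth) -> tuple[Library, Library]:
    """Draw the footprint and digestion-control libraries.

    Both start from the same uniform fragment process.  In the footprint
    sample the nuclease degrades whatever is not protein-covered: a
    fragment touching a planted site survives as its protected part only
    (the read is trimmed to the site), while fragments elsewhere survive
    whole with probability depletion/enrichment.  The control sample keeps
    every fragment untrimmed.  Footprint:control coverage therefore
    contrasts by enrichment/depletion between protected and unprotected
    bases, and surviving footprint fragments have the ~site-sized lengths
    the assay actually sequences.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    ctl_reads = _candidate_reads(rng, cfg, truth)
    fp_candidates = _candidate_reads(rng, cfg, truth)
    if cfg.enrichment == 1.0 and cfg.depletion == 1.0:
        # exchangeable null: no protection, both libraries are the same process
        return (
            Library(name="sim_footprint", role="footprint", reads=fp_candidates),
            Library(name="sim_control", role="control", reads=ctl_reads),
        )
    planted = merged_by_key(truth.planted)
    fp_reads = []
    keep_out = cfg.depletion / cfg.enrichment
    for r in fp_candidates:
        merged = planted.get((r.chrom, r.strand), [])
        protected = _intersect_blocks(r.blocks, merged) if merged else ()
        if protected:
            fp_reads.append(AlignedSegment(r.chrom, protected, r.strand))
        elif rng.random() < keep_out:
            fp_reads.append(r)
    return (
        Library(name="sim_footprint", role="footprint", reads=fp_reads),
        Library(name="sim_control", role="control", reads=ctl_reads),
    )


# ---------------------------------------------------------------------------
# recovery evaluation


@dataclass
class RecoveryResult:
    sensitivity: float
    empirical_fdr: float | None  # None when there are no calls
    matches: list[tuple[GenomicInterval, GenomicInterval]]  # (planted, call)


def evaluate_recovery(called, truth: SimTruth, min_overlap: float = 0.5) -> RecoveryResult:
    """Sensitivity and empirical FDR of a call set against the planted truth.

    A planted site is recovered when some call overlaps it reciprocally by
    at least ``min_overlap`` of both lengths; a call is a false positive
    when it overlaps no planted site at all.
    """
    call_ivs = [c.interval if hasattr(c, "interval") else c for c in called]
    matches: list[tuple[GenomicInterval, GenomicInterval]] = []
    recovered = 0
    for site in truth.planted:
        hit = None
        for civ in call_ivs:
            ov = site.overlap_length(civ)
            if ov >= min_overlap * site.length and ov >= min_overlap * civ.length:
                hit = civ
                break
        if hit is not None:
            recovered += 1
            matches.append((site, hit))
    sensitivity = recovered / len(truth.planted) if truth.planted else 0.0
    if not call_ivs:
        return RecoveryResult(sensitivity, None, matches)
    fp = sum(
        1
        for civ in call_ivs
        if all(civ.overlap_length(site) == 0 for site in truth.planted)
    )
    return RecoveryResult(sensitivity, fp / len(call_ivs), matches)


# ---------------------------------------------------------------------------
# auxiliary truth-linked datasets


def simulate_conservation(
    truth: SimTruth,
    seed: int = 0,
    baseline_mean: float = 0.0,
    baseline_sd: float = 1.0,
    pps_boost: float = 2.0,
) -> dict[str, np.ndarray]:
    """I.i.d. normal per-base scores, elevated by ``pps_boost`` inside
    planted sites (a boost of 0 gives the null track)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    tracks: dict[str, np.ndarray] = {}
    for chrom, ln in truth.chrom_lengths.items():
        tracks[chrom] = rng.normal(baseline_mean, baseline_sd, size=ln)
    for site in truth.planted:
        tracks[site.chrom][site.start : site.end] += pps_boost
    return tracks


def _genic_bases(truth: SimTruth) -> dict[str, np.ndarray]:
    """Sorted unique genic (exonic + intronic) base positions per chromosome."""
    out: dict[str, np.ndarray] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for t in truth.transcripts:
        spans.setdefault(t.chrom, []).append((t.exons[0][0], t.exons[-1][1]))
    for chrom, pairs in spans.items():
        bases = np.concatenate([np.arange(s, e) for s, e in pairs])
        out[chrom] = np.unique(bases)
    return out


def simulate_snps(
    truth: SimTruth,
    n_snps: int = 500,
    pps_rate_multiplier: float = 1.0,
    syn_fraction_inside: float = 0.5,
    syn_fraction_outside: float = 0.5,
    set_label: str = "sim",
    seed: int = 0,
):
    """SNPs over genic territory, optionally concentrated inside planted
    sites (rate multiplier) and with a class bias inside vs outside."""
    from .snps import SNPRecord

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    planted = merged_by_key(iv.unstranded() for iv in truth.planted)
    out: list[SNPRecord] = []
    for chrom, bases in _genic_bases(truth).items():
        merged = planted.get((chrom, None), [])
        inside_mask = np.zeros(len(bases), dtype=bool)
        for s, e in merged:
            lo, hi = np.searchsorted(bases, [s, e])
            inside_mask[lo:hi] = True
        w = np.where(inside_mask, pps_rate_multiplier, 1.0)
        w = w / w.sum()
        idx = rng.choice(len(bases), size=n_snps, replace=False, p=w)
        for i in idx:
            pos = int(bases[i])
            syn_p = syn_fraction_inside if inside_mask[i] else syn_fraction_outside
            cls = "synonymous" if rng.random() < syn_p else "nonsynonymous"
            out.append(
                SNPRecord(
                    position=GenomicInterval(chrom, pos, pos + 1),
                    set_label=set_label,
                    functional_class=cls,
                )
            )
    return out


def simulate_events(
    truth: SimTruth,
    rate_inside: float = 0.1,
    rate_outside: float = 0.02,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Point events (T>C-transversion-like) at a higher per-base rate
    inside planted sites than elsewhere in genic territory."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    planted = merged_by_key(iv.unstranded() for iv in truth.planted)
    out: list[GenomicInterval] = []
    for chrom, bases in _genic_bases(truth).items():
        merged = planted.get((chrom, None), [])
        inside = np.zeros(len(bases), dtype=bool)
        for s, e in merged:
            lo, hi = np.searchsorted(bases, [s, e])
            inside[lo:hi] = True
        rates = np.where(inside, rate_inside, rate_outside)
        hit = rng.random(len(bases)) < rates
        for pos in bases[hit]:
            out.append(GenomicInterval(chrom, int(pos), int(pos) + 1))
    return out


def simulate_motif_occurrences(
    truth: SimTruth,
    n_motifs: int = 40,
    k: int = 5,
    noise: float = 0.1,
    motif_length: int = 8,
    seed: int = 0,
    path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """FIMO-style occurrence table with a planted block structure.

    Motifs are split into ``k`` blocks; transcripts carrying planted sites
    are partitioned into matching target groups, and each motif occurs on
    the transcripts of its own block (incidence flipped with probability
    ``noise``).  Occurrences are placed inside a planted site of the
    transcript, with the bedtools-getfasta style sequence name
    ``tx::chrom:start-end(strand)`` that the FIMO reader resolves.
    Returns the table and the true motif -> block assignment.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    sites_by_tx: dict[str, list[GenomicInterval]] = {}
    for site in truth.planted:
        for t in truth.transcripts:
            if site.strand is t.strand and t.exons[0][0] <= site.start and site.end <= t.exons[-1][1]:
                sites_by_tx.setdefault(t.id, []).append(site)
                break
    hosts = sorted(tx for tx, sites in sites_by_tx.items() if any(s.length > motif_length for s in sites))
    if len(hosts) < 2 * k:
        raise ValueError("too few transcripts with planted sites for the block design")
    blocks = {tx: i % k for i, tx in enumerate(hosts)}
    truth_labels = {f"motif{m}": m % k + 1 for m in range(n_motifs)}
    rows = []
    for m in range(n_motifs):
        motif = f"motif{m}"
        block = truth_labels[motif] - 1
        for tx in hosts:
            member = blocks[tx] == block
            if rng.random() < noise:
                member = not member
            if not member:
                continue
            sites = [s for s in sites_by_tx[tx] if s.length > motif_length]
            site = sites[int(rng.integers(0, len(sites)))]
            off = int(rng.integers(0, site.length - motif_length))
            seq_name = f"{tx}::{site.chrom}:{site.start}-{site.end}({site.strand.value})"
            rows.append(
                {
                    "motif_id": motif,
                    "sequence_name": seq_name,
                    "start": off + 1,  # FIMO is 1-based inclusive within the sequence
                    "stop": off + motif_length,
                    "strand": "+",
                    "score": float(rng.uniform(5, 15)),
                    "p-value": 1e-5,
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df, truth_labels
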