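"""Readers and writers for the text formats the pipeline consumes and emits.

Gene models come in as GTF (Ensembl-style attributes, parsed through
gffutils) or BED12; intervals as BED; per-base score tracks as bedGraph;
motif occurrences as FIMO-style TSV; SNP sets as BED or VCF.  Everything is
converted to 0-based half-open coordinates on the way in.
"""
from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import GenomicInterval, Strand, Transcript


class ParseError(ValueError):
    """Malformed record in an input file; carries the offending line number."""


# ---------------------------------------------------------------------------
# gene models


def _read_biotype_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{i}: expected two tab-separated columns")
        out[parts[0]] = parts[1]
    return out


def load_gene_models(
    path: str | Path,
    dialect: str = "gtf",
    biotype_map: str | Path | dict[str, str] | None = None,
) -> list[Transcript]:
    """Load transcripts from a GTF or BED12 file.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Biotypes come from, in order of precedence: an explicit ``biotype_map``
    (TSV of transcript_id, biotype, or a dict), the GTF ``transcript_biotype``
    attribute, then the GTF source column.  For BED12 without a map, a
    transcript with a thick (CDS) region is called mRNA and one without is
    called lncRNA.
    """
    if isinstance(biotype_map, (str, Path)):
        biotype_map = _read_biotype_map(biotype_map)
    if dialect == "gtf":
        return _load_gtf(path, biotype_map or {})
    if dialect == "bed12":
        return _load_bed12(path, biotype_map or {})
    raise ValueError(f"unknown gene-model dialect: {dialect!r}")


def _load_gtf(path: str | Path, biotype_map: dict[str, str]) -> list[Transcript]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils reports the line in its message
        raise ParseError(f"failed to parse GTF {path}: {exc}") from exc

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_ids = feat.attributes.get("transcript_id")
        if not tx_ids:
            raise ParseError(f"{path}: {feat.featuretype} record without transcript_id")
        tx_id = tx_ids[0]
        info = meta.setdefault(
            tx_id,
            {
                "gene_id": (feat.attributes.get("gene_id") or [tx_id])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "source": feat.source,
                "biotype_attr": (feat.attributes.get("transcript_biotype") or [None])[0],
            },
        )
        if feat.seqid != info["chrom"] or feat.strand != info["strand"]:
            raise ParseError(f"{path}: transcript {tx_id} spans chrom/strand boundaries")
        # GTF is 1-based inclusive
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tx_id, []).append((feat.start - 1, feat.end))

    out: list[Transcript] = []
    for tx_id, ex in exons.items():
        info = meta[tx_id]
        ex = sorted(ex)
        biotype = (
            biotype_map.get(tx_id)
            or info["biotype_attr"]
            or (info["source"] if info["source"] in ("mRNA", "lncRNA", "other") else None)
        )
        cds_span = None
        if tx_id in cds:
            pieces = sorted(cds[tx_id])
            cds_span = (pieces[0][0], pieces[-1][1])
            biotype = biotype or "mRNA"
        biotype = biotype or "other"
        try:
            out.append(
                Transcript(
                    id=tx_id,
                    gene_id=info["gene_id"],
                    biotype=biotype,
                    chrom=info["chrom"],
                    strand=Strand.from_symbol(info["strand"]),
                    exons=tuple(ex),
                    cds=cds_span,
                )
            )
        except ValueError as exc:
            warnings.warn(f"rejecting transcript {tx_id}: {exc}")
    return out


def _load_bed12(path: str | Path, biotype_map: dict[str, str]) -> list[Transcript]:
    out: list[Transcript] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise ParseError(f"{path}:{i}: BED12 needs 12 columns, got {len(f)}")
        try:
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = Strand.from_symbol(f[5])
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from exc
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise ParseError(f"{path}:{i}: blockCount disagrees with block lists")
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        if exons[-1][1] != end:
            raise ParseError(f"{path}:{i}: blocks do not reach chromEnd")
        cds_span = None if thick_start >= thick_end else (thick_start, thick_end)
        biotype = biotype_map.get(name) or ("mRNA" if cds_span else "lncRNA")
        try:
            out.append(
                Transcript(
                    id=name,
                    gene_id=biotype_map.get(name + "/gene", name),
                    biotype=biotype,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds=cds_span,
                )
            )
        except ValueError as exc:
            warnings.warn(f"rejecting transcript {name}: {exc}")
    return out


def write_gtf(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write transcripts as GTF (source column carries the biotype)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.id}"; transcript_biotype "{t.biotype}";'
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{t.biotype}\texon\t{s + 1}\t{e}\t.\t{t.strand.value}\t.\t{attrs}\n"
                )
            if t.cds is not None:
                cs, ce = t.cds
                for s, e in t.exons:
                    os_, oe = max(s, cs), min(e, ce)
                    if os_ < oe:
                        fh.write(
                            f"{t.chrom}\t{t.biotype}\tCDS\t{os_ + 1}\t{oe}\t.\t{t.strand.value}\t.\t{attrs}\n"
                        )


def write_bed12(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            start, end = t.exons[0][0], t.exons[-1][1]
            thick = t.cds if t.cds is not None else (start, start)
            sizes = ",".join(str(e - s) for s, e in t.exons)
            offsets = ",".join(str(s - start) for s, _ in t.exons)
            fh.write(
                f"{t.chrom}\t{start}\t{end}\t{t.id}\t0\t{t.strand.value}\t"
                f"{thick[0]}\t{thick[1]}\t0\t{len(t.exons)}\t{sizes}\t{offsets}\n"
            )


def write_biotype_map(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f"{t.id}\t{t.biotype}\n")


# ---------------------------------------------------------------------------
# intervals (BED)


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6 reader; strand taken from column 6 when present."""
    out: list[GenomicInterval] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise ParseError(f"{path}:{i}: BED needs at least 3 columns")
        try:
            strand = Strand.from_symbol(f[5]) if len(f) >= 6 and f[5] in "+-" else None
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from exc
    return out


def write_bed_intervals(intervals: Iterable[GenomicInterval], path: str | Path, name: str = "iv") -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            strand = iv.strand.value if iv.strand is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}{i}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# bedGraph score tracks


def read_bedgraph(
    path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-chromosome float arrays (NaN where absent)."""
    records: dict[str, list[tuple[int, int, float]]] = {}
    maxima: dict[str, int] = dict(chrom_lengths or {})
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ParseError(f"{path}:{i}: bedGraph needs 4 columns")
        try:
            chrom, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from exc
        records.setdefault(chrom, []).append((s, e, v))
        maxima[chrom] = max(maxima.get(chrom, 0), e)
    out: dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        arr = np.full(maxima[chrom], np.nan)
        for s, e, v in recs:
            arr[s:e] = v
        out[chrom] = arr
    return out


def write_bedgraph(values: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-chromosome arrays as bedGraph, skipping NaN bases."""
    with open(path, "w") as fh:
        for chrom in sorted(values):
            arr = np.asarray(values[chrom], dtype=float)
            finite = np.isfinite(arr)
            if not finite.any():
                continue
            # run-length encode constant stretches
            change = np.flatnonzero(np.diff(arr) != 0) + 1 if len(arr) > 1 else np.array([], int)
            bounds = np.concatenate(([0], change, [len(arr)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                if finite[s]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


# ---------------------------------------------------------------------------
# FIMO-style motif occurrence tables

_SEQNAME_RE = re.compile(r"^(?:(?P<tx>[^:]+)::)?(?P<chrom>[^:()]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)$")


def read_fimo(path: str | Path) -> pd.DataFrame:
    """Read a FIMO TSV into a normalized occurrence table.

    Sequence names of the form ``tx12::chr1:1040-1090(+)`` (bedtools
    getfasta -name style, as produced when FIMO scans extracted site
    sequences) are resolved to genomic coordinates: FIMO's 1-based inclusive
    start/stop within the sequence become 0-based half-open genomic
    positions.  The result has columns motif_id, transcript_id, chrom,
    start, end, strand, score.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower().replace(" ", "_") for c in df.columns]
    if "motif_id" not in df.columns and "pattern_name" in df.columns:
        df = df.rename(columns={"pattern_name": "motif_id"})
    required = {"motif_id", "sequence_name", "start", "stop"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: FIMO table missing columns {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        m = _SEQNAME_RE.match(str(rec.sequence_name))
        if not m:
            raise ParseError(
                f"{path}: cannot resolve sequence name {rec.sequence_name!r} to coordinates"
            )
        seq_start = int(m.group("start"))
        strand = Strand.from_symbol(m.group("strand"))
        rel_start, rel_stop = int(rec.start), int(rec.stop)
        if strand is Strand.PLUS:
            g_start = seq_start + rel_start - 1
            g_end = seq_start + rel_stop
        else:
            seq_end = int(m.group("end"))
            g_start = seq_end - rel_stop
            g_end = seq_end - rel_start + 1
        rows.append(
            {
                "motif_id": str(rec.motif_id),
                "transcript_id": m.group("tx") or "",
                "chrom": m.group("chrom"),
                "start": g_start,
                "end": g_end,
                "strand": strand.value,
                "score": float(getattr(rec, "score", 0.0)),
            }
        )
    return pd.DataFrame(rows, columns=["motif_id", "transcript_id", "chrom", "start", "end", "strand", "score"])


# ---------------------------------------------------------------------------
# SNP sets


def read_snps_bed(path: str | Path, set_label: str = "snp") -> list:
    from .snps import SNPRecord

    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise ParseError(f"{path}:{i}: BED needs at least 3 columns")
        start, end = int(f[1]), int(f[2])
        if end - start != 1:
            raise ParseError(f"{path}:{i}: SNP records must be single-base")
        func = f[6] if len(f) >= 7 and f[6] in ("synonymous", "nonsynonymous", "other") else None
        out.append(
            SNPRecord(
                position=GenomicInterval(f[0], start, end),
                set_label=set_label,
                functional_class=func,
            )
        )
    return out


def read_snps_vcf(path: str | Path, set_label: str = "snp", class_info_key: str | None = None) -> list:
    """Read SNPs from a VCF (POS base only; indel spans are not expanded)."""
    import pysam

    from .snps import SNPRecord

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            func = None
            if class_info_key and class_info_key in rec.info:
                val = rec.info[class_info_key]
                if isinstance(val, tuple):
                    val = val[0]
                if val in ("synonymous", "nonsynonymous", "other"):
                    func = val
            out.append(
                SNPRecord(
                    position=GenomicInterval(rec.chrom, rec.pos - 1, rec.pos),
                    set_label=set_label,
                    functional_class=func,
                )
            )
    return out


# ---------------------------------------------------------------------------
# PPS output


def write_pps_bed(pps_list: Sequence, path: str | Path) -> None:
    """PPSs as BED6+ with mean score, read counts and the FDR threshold used."""
    with open(path, "w") as fh:
        for i, p in enumerate(pps_list):
            iv = p.interval
            score_col = min(1000, round(10 * p.score))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tPPS{i}\t{score_col}\t{iv.strand.value}\t"
                f"{p.mean_score:.4f}\t{p.footprint_reads}\t{p.control_reads}\t{p.fdr_threshold_used:.4g}\n"
            )


def write_fdr_table(table, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "score_threshold": r.score_threshold,
                "observed_region_count": r.observed_region_count,
                "mean_null_region_count": r.mean_null_region_count,
                "estimated_fdr": r.estimated_fdr,
            }
            for r in table.rows
        ]
    )
    df.to_csv(path, sep="\t", index=False)
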