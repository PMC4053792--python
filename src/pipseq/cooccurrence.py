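"""Transcript-level motif co-occurrence, k-means modules, and MDS embedding.

Motif occurrences (FIMO output restricted to PPSs) are reduced to
transcript incidence sets; the co-occurrence matrix counts, for each motif
pair, the transcripts on which both occur (diagonal: transcripts with the
motif at all).  k-means on the rows of that weighted adjacency matrix
yields modules of co-binding motifs; a classical MDS of the overlap
dissimilarity gives the 2-D map.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .caller import PPS
from .model import GenomicInterval, Strand, merged_by_key, overlap_with_merged

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifOccurrence:
    motif_id: str
    transcript_id: str
    interval: GenomicInterval
    score: float = 0.0


def load_occurrences(path, pps_list: Sequence) -> list[MotifOccurrence]:
    """Read a FIMO-style TSV, keeping only occurrences inside a PPS.

    Occurrences with no PPS overlap (same strand) are dropped and counted.
    """
    from .io import read_fimo

    df = read_fimo(path)
    pps_merged = merged_by_key(p.interval if isinstance(p, PPS) else p for p in pps_list)
    kept: list[MotifOccurrence] = []
    dropped = 0
    for rec in df.itertuples(index=False):
        strand = Strand.from_symbol(rec.strand)
        if overlap_with_merged(pps_merged.get((rec.chrom, strand), []), rec.start, rec.end) > 0:
            kept.append(
                MotifOccurrence(
                    motif_id=rec.motif_id,
                    transcript_id=rec.transcript_id,
                    interval=GenomicInterval(rec.chrom, rec.start, rec.end, strand),
                    score=rec.score,
                )
            )
        else:
            dropped += 1
    if dropped:
        log.info("dropped %d motif occurrences outside PPSs", dropped)
    return kept


@dataclass
class CooccurrenceMatrix:
    """Symmetric motif x motif transcript-sharing counts (diagonal = incidence)."""

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if not np.array_equal(m, m.T):
            raise ValueError("co-occurrence matrix must be symmetric")

    @property
    def motifs(self) -> list[str]:
        return list(self.matrix.index)


def build_cooccurrence(occurrences: Sequence[MotifOccurrence]) -> CooccurrenceMatrix:
    """Count transcripts on which each motif pair jointly occurs.

    Co-occurrence is at the transcript level: multiplicity of occurrences
    on one transcript does not matter.
    """
    sets: dict[str, set[str]] = {}
    for occ in occurrences:
        sets.setdefault(occ.motif_id, set()).add(occ.transcript_id)
    motifs = sorted(sets)
    n = len(motifs)
    m = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(motifs):
        for j, b in enumerate(motifs[i:], start=i):
            m[i, j] = m[j, i] = len(sets[a] & sets[b])
    return CooccurrenceMatrix(pd.DataFrame(m, index=motifs, columns=motifs))


def cluster_motifs(
    m: CooccurrenceMatrix, k: int = 5, seed: int = 0, n_init: int = 50
) -> dict[str, int]:
    """k-means on raw co-occurrence profiles; labels 1..k, best of n_init restarts.

    Rows are keyed on sorted motif ids, so the assignment is invariant to
    the order occurrences were supplied in.
    """
    if k > len(m.motifs):
        raise ValueError("k cannot exceed the number of motifs")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(m.matrix.to_numpy(dtype=float))
    return {motif: int(lbl) + 1 for motif, lbl in zip(m.motifs, labels)}


def overlap_dissimilarity(m: CooccurrenceMatrix) -> pd.DataFrame:
    """1 - overlap coefficient: d(a,b) = 1 - n_ab / min(n_a, n_b)."""
    mat = m.matrix.to_numpy(dtype=float)
    diag = np.diag(mat)
    denom = np.minimum.outer(diag, diag)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(denom > 0, mat / denom, 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=m.motifs, columns=m.motifs)


def classical_mds(dissimilarity: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson scaling: double-center -squared distances and take the top
    eigenvectors.  Exact (to numerical precision) for Euclidean inputs."""
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    return coords - coords.mean(axis=0)


def mds_embed(m: CooccurrenceMatrix) -> pd.DataFrame:
    """2-D classical MDS of the overlap dissimilarity; columns x, y."""
    if len(m.motifs) < 2:
        raise ValueError("need at least two motifs to embed")
    coords = classical_mds(overlap_dissimilarity(m).to_numpy(), n_components=2)
    return pd.DataFrame(coords, index=m.motifs, columns=["x", "y"])


_DEGENERATE = set("RYSWKMBDHVN")


def flag_nondegenerate_long(consensus: dict[str, str], min_length: int = 18) -> list[str]:
    """Helper for motif pre-filtering: motifs whose consensus is at least
    ``min_length`` nt with zero degenerate (IUPAC ambiguity) positions —
    candidates for exclusion as likely repeats.  The keep-list itself is
    the user's decision."""
    flagged = []
    for motif, seq in consensus.items():
        seq = seq.upper()
        if len(seq) >= min_length and not (set(seq) & _DEGENERATE):
            if re.fullmatch(r"[ACGTU]+", seq):
                flagged.append(motif)
    return sorted(flagged)
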