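"""Summit characterization: RGAC motif distances, consensus extraction
windows, and metagene positions.

The m6A consensus core is the 4-mer RGAC (R = A or G) whose third base is the
methylated adenosine; distances are measured to that A. The search space is
the summit's own transcript on its own strand, since the modification is
transcript-borne.
"""
from __future__ import annotations

import re
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel

_RGAC = re.compile(r"(?=[AG]GAC)")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC degeneracy codes keyed by the base set they cover.
IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def transcript_sequence(genome: dict[str, str], gene: GeneModel) -> str:
    """The gene's transcript sequence 5'->3' (DNA alphabet)."""
    chrom = genome[gene.chrom]
    if gene.transcript_start < 0 or gene.transcript_end > len(chrom):
        raise ValueError(f"{gene.gene_id}: transcript outside chromosome bounds")
    seq = chrom[gene.transcript_start:gene.transcript_end].upper()
    return reverse_complement(seq) if gene.strand == "-" else seq


def rgac_anchor_offsets(seq: str) -> list[int]:
    """Transcript offsets of the methylatable A (3rd base) of every RGAC
    occurrence, overlapping matches included."""
    return [m.start() + 2 for m in _RGAC.finditer(seq.upper())]


def nearest_motif_distance(summit_offset: int, transcript_seq: str) -> Optional[int]:
    """Minimum |summit - anchor A| over the transcript's RGAC motifs, or None
    if the transcript contains no RGAC."""
    if not 0 <= summit_offset < len(transcript_seq):
        raise ValueError("summit outside transcript")
    anchors = rgac_anchor_offsets(transcript_seq)
    if not anchors:
        return None
    return min(abs(summit_offset - a) for a in anchors)


def nearest_motif_anchor(summit_offset: int, transcript_seq: str) -> Optional[int]:
    """Transcript offset of the nearest RGAC anchor A (smallest offset wins
    ties), or None."""
    anchors = rgac_anchor_offsets(transcript_seq)
    if not anchors:
        return None
    return min(anchors, key=lambda a: (abs(summit_offset - a), a))


def extract_motif_window(genome: dict[str, str], chrom: str, strand: str,
                         anchor: int, upstream: int = 13,
                         downstream: int = 11) -> tuple[str, bool]:
    """24-nt genomic window around a motif's anchor A, read 5'->3' on the
    motif strand with the A at index ``upstream`` (13 of 0..23 by default).

    On the plus strand the window covers [anchor-13, anchor+11); on the minus
    strand the equivalent genomic slice is taken and reverse-complemented.
    Windows running past a chromosome edge are clipped and flagged.
    """
    seq = genome[chrom]
    if strand == "+":
        lo, hi = anchor - upstream, anchor + downstream
    else:
        lo, hi = anchor - downstream + 1, anchor + upstream + 1
    clipped = lo < 0 or hi > len(seq)
    window = seq[max(lo, 0):min(hi, len(seq))].upper()
    if strand == "-":
        window = reverse_complement(window)
    return window, clipped


def extract_motif_windows(summit_rows: Sequence[dict], genome: dict[str, str],
                          max_distance: int = 5) -> list[str]:
    """Unclipped 24-nt windows for summits within ``max_distance`` nt of their
    nearest RGAC motif. Each row needs chrom, strand, motif_anchor_genomic,
    motif_distance."""
    windows = []
    for row in summit_rows:
        d = row.get("motif_distance")
        if d is None or (isinstance(d, float) and np.isnan(d)) or d > max_distance:
            continue
        window, clipped = extract_motif_window(
            genome, row["chrom"], row["strand"], int(row["motif_anchor_genomic"]))
        if not clipped:
            windows.append(window)
    return windows


def consensus_from_windows(windows: Sequence[str],
                           min_frequency: float = 0.25) -> tuple[pd.DataFrame, str]:
    """Position frequency matrix (rows A/C/G/T) and IUPAC consensus.

    The consensus letter at each position is the smallest degeneracy class
    covering all bases with frequency >= ``min_frequency``.
    """
    if not windows:
        raise ValueError("need at least one window")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("windows must all have the same length")
    bases = "ACGT"
    counts = np.zeros((4, length))
    for w in windows:
        for j, b in enumerate(w.upper()):
            if b in bases:
                counts[bases.index(b), j] += 1
    freq = counts / counts.sum(axis=0, keepdims=True)
    pfm = pd.DataFrame(freq, index=list(bases))
    consensus = "".join(
        IUPAC_CODES[frozenset(b for i, b in enumerate(bases) if freq[i, j] >= min_frequency)]
        for j in range(length))
    return pfm, consensus


def metagene_fraction(summit_offset: int, gene: GeneModel) -> float:
    """Summit position as a fraction of transcript length, 0 at the 5' end."""
    L = gene.transcript_length
    if not 0 <= summit_offset < L:
        raise ValueError("summit outside transcript")
    return summit_offset / L


def annotate_summits(peaks, genes: Sequence[GeneModel],
                     genome: dict[str, str]) -> pd.DataFrame:
    """Per-peak summit annotation: nearest-RGAC distance, within-5-nt flag,
    and metagene fraction."""
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for p in peaks:
        gene = by_id[p.gene_id]
        seq = transcript_sequence(genome, gene)
        d = nearest_motif_distance(p.summit, seq)
        anchor = nearest_motif_anchor(p.summit, seq)
        rows.append({
            "gene_id": p.gene_id,
            "chrom": gene.chrom,
            "strand": gene.strand,
            "summit": p.summit,
            "summit_genomic": p.summit_genomic,
            "dependence": p.dependence,
            "high_confidence": p.high_confidence,
            "motif_distance": d,
            "motif_anchor_genomic": (gene.transcript_to_genomic(anchor)
                                     if anchor is not None else None),
            "within5": d is not None and d <= 5,
            "metagene_fraction": metagene_fraction(p.summit, gene),
        })
    return pd.DataFrame(rows)


def sample_control_summits(independent: pd.DataFrame, n: int,
                           seed: int = 0) -> pd.DataFrame:
    """An equal-size random control drawn from m6A-independent summits, with
    a fixed RNG seed for reproducibility."""
    if n > len(independent):
        raise ValueError("cannot sample more control summits than available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(independent), size=n, replace=False)
    return independent.iloc[np.sort(idx)].reset_index(drop=True)


def metagene_histogram(fractions: Sequence[float], n_bins: int = 20) -> pd.DataFrame:
    """Counts of summit metagene fractions in equal-width bins over [0, 1]."""
    counts, edges = np.histogram(fractions, bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts})
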