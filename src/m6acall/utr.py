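"""Coverage-driven UTR extension.

Yeast genome annotation gives ORF coordinates only, but m6A peaks sit mostly
near 3' ends, often outside the ORF. UTRs are therefore inferred from the
input-sample (non-IP) RNA-seq coverage: each UTR is extended one base at a
time until per-base depth falls below a fraction of the ORF's median depth
(default 1/3), an adjacent same-strand ORF is reached, or a hard cap
(default 500 nt) is hit. The per-gene UTR length is the median across all
input samples (floored for even sample counts).
"""
from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .models import CoverageSet, GeneModel, SampleMeta, UtrParams


def median_orf_coverage(depth: np.ndarray, gene: GeneModel) -> float:
    """Median per-base depth over the gene's ORF.

    ``depth`` is the full-chromosome depth array on the gene's strand.
    Even-length ORFs use the mean-of-middle-two convention.
    """
    if gene.orf_start < 0 or gene.orf_end > depth.size:
        raise ValueError(f"{gene.gene_id}: ORF outside chromosome bounds")
    return float(np.median(depth[gene.orf_start:gene.orf_end]))


def extend_utr_one_sample(depth: np.ndarray, gene: GeneModel, side: str,
                          params: UtrParams = UtrParams(),
                          neighbor_bound: Optional[int] = None) -> int:
    """Number of bases one sample's coverage supports appending on one side.

    Walks outward from the ORF edge in transcript orientation (the 3' side of
    a minus-strand gene walks toward smaller coordinates). A base is included
    iff its depth >= stop_fraction * median ORF coverage; the walk stops at
    the first failing base, at ``neighbor_bound``, or at ``max_extension``.

    ``neighbor_bound`` is the adjacent ORF edge in walk direction as a
    half-open boundary: for an outward walk toward larger coordinates it is
    the neighbor's ``orf_start`` (positions must stay < bound); toward smaller
    coordinates it is the neighbor's ``orf_end`` (positions must stay >= bound).

    A zero ORF median returns 0: a threshold of 0 would otherwise extend
    silent genes to the cap.
    """
    if side not in ("5prime", "3prime"):
        raise ValueError("side must be '5prime' or '3prime'")
    med = median_orf_coverage(depth, gene)
    if med <= 0:
        return 0
    threshold = params.stop_fraction * med

    outward_right = (side == "3prime") == (gene.strand == "+")
    if outward_right:
        pos, step = gene.orf_end, 1
    else:
        pos, step = gene.orf_start - 1, -1

    n = 0
    while n < params.max_extension:
        if pos < 0 or pos >= depth.size:
            break
        if neighbor_bound is not None:
            if step > 0 and pos >= neighbor_bound:
                break
            if step < 0 and pos < neighbor_bound:
                break
        if depth[pos] < threshold:
            break
        n += 1
        pos += step
    return n


def consensus_utr_length(per_sample_lengths: Sequence[int]) -> int:
    """Median UTR length across samples; even counts floor the mean of the
    middle two values to an integer."""
    if len(per_sample_lengths) == 0:
        raise ValueError("need at least one per-sample length")
    return int(math.floor(float(np.median(per_sample_lengths))))


def neighbor_bounds(genes: Sequence[GeneModel]) -> dict[str, tuple[Optional[int], Optional[int]]]:
    """Per gene, the nearest same-strand ORF edge on each flank.

    Returns ``gene_id -> (left_bound, right_bound)`` where ``left_bound`` is
    the previous ORF's end (half-open; walk positions must stay >= it) and
    ``right_bound`` the next ORF's start (positions must stay < it), or None
    when no same-strand neighbor exists.
    """
    out: dict[str, tuple[Optional[int], Optional[int]]] = {}
    by_locus: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_locus.setdefault((g.chrom, g.strand), []).append(g)
    for group in by_locus.values():
        group = sorted(group, key=lambda g: g.orf_start)
        for i, g in enumerate(group):
            left = group[i - 1].orf_end if i > 0 else None
            right = group[i + 1].orf_start if i + 1 < len(group) else None
            out[g.gene_id] = (left, right)
    return out


def extend_utrs(genes: Sequence[GeneModel], coverage: CoverageSet,
                params: UtrParams = UtrParams(),
                samples: Optional[Sequence[SampleMeta]] = None) -> list[GeneModel]:
    """Extend every gene's UTRs from input-sample coverage.

    By default all input-fraction samples in ``coverage`` are used (the six
    input libraries of the full 3 WT + 3 cat design); the consensus length on
    each side is the median across samples.
    """
    if samples is None:
        samples = coverage.samples(fraction="input")
    if not samples:
        raise ValueError("no input samples available for UTR extension")
    bounds = neighbor_bounds(genes)
    extended: list[GeneModel] = []
    for gene in genes:
        left, right = bounds[gene.gene_id]
        if gene.strand == "+":
            bound5, bound3 = left, right
        else:
            bound5, bound3 = right, left
        len5, len3 = [], []
        for s in samples:
            depth = coverage.get(s, gene.chrom, gene.strand)
            len5.append(extend_utr_one_sample(depth, gene, "5prime", params, bound5))
            len3.append(extend_utr_one_sample(depth, gene, "3prime", params, bound3))
        extended.append(replace(gene,
                                utr5_len=consensus_utr_length(len5),
                                utr3_len=consensus_utr_length(len3)))
    return extended
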