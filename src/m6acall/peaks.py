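"""Three-stage m6A peak-calling cascade.

Methylation appears in m6A-seq as local IP-over-background coverage
enrichment. Detection proceeds per gene:

1. Scan each IP sample's transcript with 100-nt windows stepped by 50 nt;
   a window is a candidate peak when mean(window) / median(gene) > 3 and
   mean depth > 10 (both strict), for genes whose transcript median depth is
   > 0 in every IP sample.
2. Drop IP windows overlapping any window that passes the same thresholds in
   the paired input sample (same genotype and replicate).
3. Take windows retained in at least one of the six IP samples, merge
   overlapping or book-ended windows, recompute the enrichment of each merged
   interval per sample, and classify a peak as m6A-dependent when the mean WT
   enrichment divided by the mean cat (catalytic-dead) enrichment is >= 1.75.

The summit is the position of maximal pooled WT-IP depth (leftmost in
transcript orientation on ties). A replicate-level test then flags
high-confidence sites: Student's two-sample t on per-replicate
log2((IP mean + 1) / (input mean + 1)) over the peak interval, requiring
log2 fold change (WT minus cat) > 0.8 and p < 0.01.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sp_stats

from .models import CoverageSet, GeneModel, PeakCallingParams, SampleMeta

Interval = tuple[int, int]

M6A_DEPENDENT = "m6A_dependent"
M6A_INDEPENDENT = "m6A_independent"


@dataclass
class WindowScore:
    gene_id: str
    start: int      # transcript-relative, 0-based half-open
    end: int
    mean_depth: float
    enrichment: float


@dataclass
class MergedPeak:
    gene_id: str
    start: int                      # transcript-relative
    end: int
    genomic_start: int
    genomic_end: int
    sample_scores: dict[str, float] = field(default_factory=dict)
    wt_score: float = float("nan")
    cat_score: float = float("nan")
    dependence: str = M6A_INDEPENDENT
    cat_zero_flag: bool = False
    summit: int = -1                # transcript offset
    summit_genomic: int = -1
    hc_log2fc: Optional[float] = None
    hc_pvalue: Optional[float] = None
    high_confidence: bool = False


def window_spans(transcript_length: int, params: PeakCallingParams) -> list[Interval]:
    """Window layout over a transcript: full windows at offsets 0, step, 2*step,
    ... plus, when the transcript does not end on a full window, one trailing
    window anchored at the 3' end of length min(window_len, transcript length),
    so 3'-terminal signal is always scannable."""
    L = transcript_length
    if L < 1:
        raise ValueError("transcript length must be >= 1")
    win, step = params.window_len, params.window_step
    spans: list[Interval] = []
    start = 0
    while start + win <= L:
        spans.append((start, start + win))
        start += step
    trailing = (max(0, L - win), L)
    if not spans or spans[-1][1] < L:
        spans.append(trailing)
    return spans


def score_windows(tdepth: np.ndarray, gene_id: str,
                  params: PeakCallingParams = PeakCallingParams()) -> list[WindowScore]:
    """Score sliding windows over one sample's transcript depth (5'->3').

    Enrichment = mean(window) / median(transcript). The caller is expected to
    have excluded zero-median genes via :func:`gene_expression_filter`.
    """
    med = float(np.median(tdepth))
    if med <= 0:
        raise ValueError(f"{gene_id}: transcript median depth is 0; gene should "
                         "have been removed by the expression filter")
    out = []
    for s, e in window_spans(tdepth.size, params):
        mean = float(np.mean(tdepth[s:e]))
        out.append(WindowScore(gene_id, s, e, mean, mean / med))
    return out


def gene_expression_filter(coverage: CoverageSet, gene: GeneModel,
                           ip_samples: Optional[Sequence[SampleMeta]] = None) -> bool:
    """True iff the transcript's median depth is > 0 in every IP sample."""
    if ip_samples is None:
        ip_samples = coverage.samples(fraction="IP")
    for s in ip_samples:
        if np.median(coverage.transcript_depth(s, gene)) <= 0:
            return False
    return True


def call_sample_peaks(tdepth: np.ndarray, gene_id: str,
                      params: PeakCallingParams = PeakCallingParams()) -> list[Interval]:
    """Windows passing both gates (enrichment > 3, mean depth > 10; strict)."""
    return [(w.start, w.end) for w in score_windows(tdepth, gene_id, params)
            if w.enrichment > params.min_enrichment and w.mean_depth > params.min_depth]


def remove_input_peaks(ip_peaks: Sequence[Interval],
                       input_peaks: Sequence[Interval]) -> list[Interval]:
    """Retain IP windows sharing no base with any input-sample peak window."""
    def overlaps(a: Interval, b: Interval) -> bool:
        return a[0] < b[1] and b[0] < a[1]
    return [p for p in ip_peaks if not any(overlaps(p, q) for q in input_peaks)]


def merge_peaks(intervals: Sequence[Interval]) -> list[Interval]:
    """Transitive merge of overlapping or book-ended (gap 0) intervals.

    Output is sorted and pairwise disjoint with gaps >= 1 base.
    """
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [ordered[0]]
    for s, e in ordered[1:]:
        ps, pe = merged[-1]
        if s <= pe:  # overlap or book-ended
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def _interval_enrichment(tdepth: np.ndarray, interval: Interval) -> float:
    med = float(np.median(tdepth))
    if med <= 0:
        return 0.0
    return float(np.mean(tdepth[interval[0]:interval[1]])) / med


def classify_dependence(peak: MergedPeak, coverage: CoverageSet, gene: GeneModel,
                        params: PeakCallingParams = PeakCallingParams()) -> MergedPeak:
    """Recompute the merged interval's enrichment per IP sample and classify.

    The per-genotype score is the mean of the three replicate enrichments;
    dependent iff wt_score / cat_score >= dependence_ratio. A cat score of 0
    gives an infinite ratio: dependent, flagged.
    """
    interval = (peak.start, peak.end)
    scores: dict[str, list[float]] = {"WT": [], "cat": []}
    for s in coverage.samples(fraction="IP"):
        enr = _interval_enrichment(coverage.transcript_depth(s, gene), interval)
        peak.sample_scores[s.label] = enr
        scores[s.genotype].append(enr)
    peak.wt_score = float(np.mean(scores["WT"]))
    peak.cat_score = float(np.mean(scores["cat"]))
    if peak.cat_score == 0:
        peak.dependence = M6A_DEPENDENT
        peak.cat_zero_flag = True
    else:
        ratio = peak.wt_score / peak.cat_score
        peak.dependence = M6A_DEPENDENT if ratio >= params.dependence_ratio else M6A_INDEPENDENT
    return peak


def find_summit(peak: MergedPeak, coverage: CoverageSet, gene: GeneModel) -> int:
    """Transcript offset of maximal pooled WT-IP depth inside the peak
    (leftmost on ties)."""
    pooled = None
    for s in coverage.samples(genotype="WT", fraction="IP"):
        d = coverage.transcript_depth(s, gene)
        pooled = d.copy() if pooled is None else pooled + d
    if pooled is None:
        raise ValueError("no WT IP samples in coverage set")
    window = pooled[peak.start:peak.end]
    if window.size == 0:
        raise ValueError("empty peak interval")
    return peak.start + int(np.argmax(window))


def log_ratio_ttest(wt_ratios: Sequence[float], cat_ratios: Sequence[float]) -> tuple[float, float]:
    """log2 fold change and two-tailed equal-variance t p-value on log2 ratios.

    ``log2fc = mean(log2 wt) - mean(log2 cat)``.
    """
    if len(wt_ratios) < 2 or len(cat_ratios) < 2:
        raise ValueError("need at least 2 replicates per group for the t test")
    lw = np.log2(np.asarray(wt_ratios, dtype=float))
    lc = np.log2(np.asarray(cat_ratios, dtype=float))
    log2fc = float(lw.mean() - lc.mean())
    t = sp_stats.ttest_ind(lw, lc, equal_var=True)
    return log2fc, float(t.pvalue)


def high_confidence_test(peak: MergedPeak, coverage: CoverageSet, gene: GeneModel,
                         params: PeakCallingParams = PeakCallingParams(),
                         pseudocount: float = 1.0) -> MergedPeak:
    """Replicate-level IP/input test over the peak interval.

    Each replicate contributes one ratio (IP mean + pseudocount) /
    (input mean + pseudocount); the pseudocount guards zero-coverage inputs.
    The site is high-confidence iff it is m6A-dependent, log2fc > hc_log2fc
    and p < hc_alpha.
    """
    ratios: dict[str, list[float]] = {"WT": [], "cat": []}
    for genotype in ("WT", "cat"):
        for ip in coverage.samples(genotype=genotype, fraction="IP"):
            inp = SampleMeta(genotype, "input", ip.replicate)
            ip_mean = float(np.mean(coverage.transcript_depth(ip, gene)[peak.start:peak.end]))
            in_mean = float(np.mean(coverage.transcript_depth(inp, gene)[peak.start:peak.end]))
            ratios[genotype].append((ip_mean + pseudocount) / (in_mean + pseudocount))
    log2fc, pvalue = log_ratio_ttest(ratios["WT"], ratios["cat"])
    peak.hc_log2fc = log2fc
    peak.hc_pvalue = pvalue
    peak.high_confidence = (peak.dependence == M6A_DEPENDENT
                            and log2fc > params.hc_log2fc
                            and pvalue < params.hc_alpha)
    return peak


def call_gene_peaks(coverage: CoverageSet, gene: GeneModel,
                    params: PeakCallingParams = PeakCallingParams()) -> list[MergedPeak]:
    """Run the full cascade for one gene. Returns [] for genes failing the
    expression filter."""
    ip_samples = coverage.samples(fraction="IP")
    if not gene_expression_filter(coverage, gene, ip_samples):
        return []
    retained: list[Interval] = []
    for ip in ip_samples:
        ip_depth = coverage.transcript_depth(ip, gene)
        ip_peaks = call_sample_peaks(ip_depth, gene.gene_id, params)
        if not ip_peaks:
            continue
        inp = SampleMeta(ip.genotype, "input", ip.replicate)
        in_depth = coverage.transcript_depth(inp, gene)
        if np.median(in_depth) > 0:
            input_peaks = call_sample_peaks(in_depth, gene.gene_id, params)
        else:
            input_peaks = []
        retained.extend(remove_input_peaks(ip_peaks, input_peaks))

    peaks: list[MergedPeak] = []
    for s, e in merge_peaks(retained):
        if gene.strand == "+":
            gs, ge = gene.transcript_start + s, gene.transcript_start + e
        else:
            gs, ge = gene.transcript_end - e, gene.transcript_end - s
        peak = MergedPeak(gene.gene_id, s, e, gs, ge)
        classify_dependence(peak, coverage, gene, params)
        peak.summit = find_summit(peak, coverage, gene)
        peak.summit_genomic = gene.transcript_to_genomic(peak.summit)
        high_confidence_test(peak, coverage, gene, params)
        peaks.append(peak)
    return peaks
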