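"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes its quantity from first principles with explicit
loops and closed forms, sharing no code path with the package.
"""
from __future__ import annotations

import math

from scipy.special import stdtr


def brute_force_median(values) -> float:
    """Median by sorting: middle element, or mean of the middle two."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if n % 2 == 1:
        return v[n // 2]
    return (v[n // 2 - 1] + v[n // 2]) / 2.0


def brute_force_window_scores(tdepth, window_len=100, window_step=50):
    """Explicit loop over every window, recomputing mean and median from
    scratch. Returns (start, end, mean, enrichment) tuples."""
    L = len(tdepth)
    med = brute_force_median(tdepth)
    spans = []
    start = 0
    while start + window_len <= L:
        spans.append((start, start + window_len))
        start += window_step
    if not spans or spans[-1][1] < L:
        spans.append((max(0, L - window_len), L))
    out = []
    for s, e in spans:
        mean = sum(tdepth[s:e]) / (e - s)
        out.append((s, e, mean, mean / med))
    return out


def brute_force_utr_extension(chrom_depth, orf_start, orf_end, strand, side,
                              stop_fraction=1 / 3, max_extension=500,
                              neighbor_bound=None):
    """Naive per-base walk reimplementing the extension rule independently."""
    med = brute_force_median(chrom_depth[orf_start:orf_end])
    if med <= 0:
        return 0
    threshold = stop_fraction * med
    rightward = (side == "3prime") == (strand == "+")
    pos = orf_end if rightward else orf_start - 1
    step = 1 if rightward else -1
    n = 0
    while n < max_extension:
        if pos < 0 or pos >= len(chrom_depth):
            break
        if neighbor_bound is not None:
            if rightward and pos >= neighbor_bound:
                break
            if not rightward and pos < neighbor_bound:
                break
        if chrom_depth[pos] < threshold:
            break
        n += 1
        pos += step
    return n


def closed_form_ttest(a, b):
    """Equal-variance two-sample t statistic and two-tailed p-value via the
    closed-form pooled-variance formula and the t CDF."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    t = (ma - mb) / se
    p = 2.0 * stdtr(df, -abs(t))
    return t, p


def truth_table_epistasis():
    """Enumerate all 8 chain models x 4 genotypes by explicit truth tables.

    Returns {(upstream, e1, e2, deleted_tuple): replication}. Genotypes are
    sorted tuples of deleted genes.
    """
    table = {}
    for upstream in ("IME4", "RME1"):
        downstream = "RME1" if upstream == "IME4" else "IME4"
        for e1 in (True, False):          # True = activates
            for e2 in (True, False):
                for deleted in ((), ("IME4",), ("RME1",), ("IME4", "RME1")):
                    up_on = upstream not in deleted
                    if downstream in deleted:
                        down_on = False
                    else:
                        down_on = up_on if e1 else (not up_on)
                    rep = down_on if e2 else (not down_on)
                    table[(upstream,
                           "activates" if e1 else "represses",
                           "activates" if e2 else "represses",
                           deleted)] = rep
    return table
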