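"""Expression statistics: count normalization, differential expression
between genotypes, intersection with m6A targets, and RT-qPCR IP-enrichment
normalization.

Differential expression follows a joint gate rather than FDR control: a gene
is called up in the catalytic-dead mutant when log2 fold change > 0.8
(~1.75-fold) with a two-tailed Student t p < 0.01 on log2 counts; down is the
mirror image. An optional Benjamini-Hochberg column is exposed for users who
want it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

UP_IN_CAT = "up_in_cat"
DOWN_IN_CAT = "down_in_cat"
NS = "ns"


def normalize_counts(raw: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample (column sums 1e6)."""
    if (raw.values < 0).any():
        raise ValueError("count matrix must be non-negative")
    totals = raw.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero sample column(s): {bad}")
    return raw / totals * 1e6


def differential_expression(norm: pd.DataFrame,
                            group_a: Sequence[str],
                            group_b: Sequence[str],
                            lfc_threshold: float = 0.8,
                            alpha: float = 0.01,
                            pseudocount: float = 1.0,
                            add_bh: bool = False) -> pd.DataFrame:
    """Per-gene log2 fold change of group means (a over b) and t p-value.

    ``log2fc = log2((mean_a + pc) / (mean_b + pc))`` on normalized counts;
    the p-value is a two-tailed equal-variance Student t on log2(count + pc)
    per replicate. With group_a = cat and group_b = WT, classes are
    ``up_in_cat`` / ``down_in_cat`` / ``ns``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    a = norm[list(group_a)].to_numpy(dtype=float)
    b = norm[list(group_b)].to_numpy(dtype=float)
    log2fc = np.log2(a.mean(axis=1) + pseudocount) - np.log2(b.mean(axis=1) + pseudocount)
    t = sp_stats.ttest_ind(np.log2(a + pseudocount), np.log2(b + pseudocount),
                           axis=1, equal_var=True)
    pvalue = np.asarray(t.pvalue, dtype=float)
    cls = np.full(norm.shape[0], NS, dtype=object)
    cls[(log2fc > lfc_threshold) & (pvalue < alpha)] = UP_IN_CAT
    cls[(log2fc < -lfc_threshold) & (pvalue < alpha)] = DOWN_IN_CAT
    out = pd.DataFrame({"gene_id": norm.index, "log2fc": log2fc,
                        "pvalue": pvalue, "class": cls}).set_index("gene_id")
    if add_bh:
        out["bh_fdr"] = _benjamini_hochberg(pvalue)
    return out


def _benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    n = pvalues.size
    order = np.argsort(pvalues)
    ranked = pvalues[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def intersect_m6a_de(m6a_genes: Iterable[str],
                     de_up_genes: Iterable[str]) -> tuple[set[str], dict[str, int]]:
    """Set intersection plus the three Venn counts."""
    a, b = set(m6a_genes), set(de_up_genes)
    inter = a & b
    venn = {"m6a_only": len(a - b), "de_only": len(b - a), "intersection": len(inter)}
    return inter, venn


@dataclass
class QpcrMeasurement:
    """Abundances of a target and an internal-control transcript (e.g. PGK1)
    in IP and input fractions."""

    target_ip: float
    control_ip: float
    target_input: float
    control_input: float

    def __post_init__(self) -> None:
        for name in ("target_ip", "control_ip", "target_input", "control_input"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def qpcr_ip_enrichment(m: QpcrMeasurement) -> float:
    """Fold enrichment of IP over input, each first normalized to the
    internal control: (target/control)_IP / (target/control)_input."""
    return (m.target_ip / m.control_ip) / (m.target_input / m.control_input)
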