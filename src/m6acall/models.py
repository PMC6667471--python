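"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open throughout; GFF input (1-based inclusive)
is converted at parse time. Coverage is strand-specific: a depth array covers
one chromosome on one strand for one sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

GENOTYPES = ("WT", "cat")
FRACTIONS = ("IP", "input")


@dataclass(frozen=True, order=True)
class SampleMeta:
    """Identity of one sequencing sample: genotype x fraction x replicate."""

    genotype: str  # "WT" or "cat" (catalytically dead methyltransferase)
    fraction: str  # "IP" (anti-m6A immunoprecipitate) or "input"
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate numbers are 1-based positive integers")

    @property
    def label(self) -> str:
        return f"{self.genotype}_{self.fraction}_{self.replicate}"


@dataclass
class GeneModel:
    """An ORF plus data-derived UTR extensions defining a transcript interval.

    ``utr5_len``/``utr3_len`` are extension lengths in nt on the 5'/3' side of
    the ORF *in transcript orientation*; for a minus-strand gene the 3' UTR
    extends toward smaller genomic coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    orf_start: int
    orf_end: int
    utr5_len: int = 0
    utr3_len: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.orf_start < self.orf_end:
            raise ValueError(f"{self.gene_id}: orf_start must be < orf_end")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"{self.gene_id}: UTR lengths must be non-negative")

    @property
    def transcript_start(self) -> int:
        up = self.utr5_len if self.strand == "+" else self.utr3_len
        return self.orf_start - up

    @property
    def transcript_end(self) -> int:
        down = self.utr3_len if self.strand == "+" else self.utr5_len
        return self.orf_end + down

    @property
    def transcript_length(self) -> int:
        return self.transcript_end - self.transcript_start

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic coordinate to a 5'->3' transcript offset."""
        if not self.transcript_start <= pos < self.transcript_end:
            raise ValueError(f"position {pos} outside transcript of {self.gene_id}")
        if self.strand == "+":
            return pos - self.transcript_start
        return self.transcript_end - 1 - pos

    def transcript_to_genomic(self, offset: int) -> int:
        """Map a 5'->3' transcript offset to a genomic coordinate."""
        if not 0 <= offset < self.transcript_length:
            raise ValueError(f"offset {offset} outside transcript of {self.gene_id}")
        if self.strand == "+":
            return self.transcript_start + offset
        return self.transcript_end - 1 - offset


@dataclass
class CoverageTrack:
    """Per-base read depth for one sample over one chromosome, one strand."""

    chrom: str
    strand: str
    depth: np.ndarray
    sample: SampleMeta

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if np.any(self.depth < 0):
            raise ValueError("coverage depth must be non-negative")


class CoverageSet:
    """Collection of coverage tracks keyed by (sample, chrom, strand)."""

    def __init__(self) -> None:
        self._tracks: dict[tuple[SampleMeta, str, str], np.ndarray] = {}

    def add(self, sample: SampleMeta, chrom: str, strand: str, depth: np.ndarray) -> None:
        arr = np.asarray(depth, dtype=float)
        if np.any(arr < 0):
            raise ValueError("coverage depth must be non-negative")
        self._tracks[(sample, chrom, strand)] = arr

    def add_track(self, track: CoverageTrack) -> None:
        self.add(track.sample, track.chrom, track.strand, track.depth)

    def get(self, sample: SampleMeta, chrom: str, strand: str) -> np.ndarray:
        return self._tracks[(sample, chrom, strand)]

    def samples(self, genotype: Optional[str] = None,
                fraction: Optional[str] = None) -> list[SampleMeta]:
        seen = {key[0] for key in self._tracks}
        out = [s for s in seen
               if (genotype is None or s.genotype == genotype)
               and (fraction is None or s.fraction == fraction)]
        return sorted(out)

    def chroms(self) -> list[tuple[str, str]]:
        return sorted({(c, s) for (_, c, s) in self._tracks})

    def __iter__(self) -> Iterator[tuple[SampleMeta, str, str]]:
        return iter(sorted(self._tracks, key=lambda k: (k[0], k[1], k[2])))

    def transcript_depth(self, sample: SampleMeta, gene: GeneModel) -> np.ndarray:
        """Depth over the gene's transcript interval, oriented 5'->3'."""
        arr = self.get(sample, gene.chrom, gene.strand)
        if gene.transcript_start < 0 or gene.transcript_end > arr.size:
            raise ValueError(f"{gene.gene_id}: transcript outside chromosome bounds")
        window = arr[gene.transcript_start:gene.transcript_end]
        return window[::-1] if gene.strand == "-" else window

    def orf_depth(self, sample: SampleMeta, gene: GeneModel) -> np.ndarray:
        arr = self.get(sample, gene.chrom, gene.strand)
        if gene.orf_start < 0 or gene.orf_end > arr.size:
            raise ValueError(f"{gene.gene_id}: ORF outside chromosome bounds")
        return arr[gene.orf_start:gene.orf_end]


@dataclass
class UtrParams:
    """Stopping rule for coverage-driven UTR extension."""

    stop_fraction: float = 1.0 / 3.0   # stop when depth falls below this fraction of ORF median
    max_extension: int = 500           # hard cap in nt

    def __post_init__(self) -> None:
        if not 0 < self.stop_fraction < 1:
            raise ValueError("stop_fraction must lie in (0, 1)")
        if self.max_extension <= 0:
            raise ValueError("max_extension must be positive")


@dataclass
class PeakCallingParams:
    """Thresholds for the three-stage m6A peak-calling cascade.

    Defaults follow the sliding-window detection scheme: 100-nt windows with
    50-nt step, enrichment > 3 and mean depth > 10 (both strict), a WT/cat
    enrichment ratio of at least 1.75 (inclusive) for m6A dependence, and a
    replicate-level test gate of log2 fold change > 0.8 at p < 0.01.
    """

    window_len: int = 100
    window_step: int = 50
    min_enrichment: float = 3.0
    min_depth: float = 10.0
    dependence_ratio: float = 1.75
    hc_log2fc: float = 0.8
    hc_alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.window_step > self.window_len:
            raise ValueError("window_step must not exceed window_len")
        for name in ("min_enrichment", "min_depth", "dependence_ratio", "hc_log2fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hc_alpha < 1:
            raise ValueError("hc_alpha must lie in (0, 1)")
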