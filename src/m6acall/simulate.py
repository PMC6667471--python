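"""Synthetic genome, methylome, coverage, and count-matrix generator.

Emulates the structure of a 3 + 3 replicate m6A-seq design (WT and
catalytic-dead genotypes, IP and input fractions) on a toy single-chromosome
genome: non-overlapping genes on both strands, each with a true 5'/3' UTR
flanking the ORF; a planted methylome whose sites sit on RGAC motif A's in
the 3'-terminal third of their transcripts; per-base negative-binomial
coverage whose IP mean is multiplied by an enrichment effect inside a
rectangular window around each planted site in WT only; and a gene-level
count matrix in which one designated "RME1-analog" gene - methylated and
stabilized in the mutant - carries a fold change between genotypes.

All randomness derives from a single seed: substreams use
``default_rng([seed, stage])`` so each stage is independently reproducible
and the whole dataset is byte-identical for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .models import CoverageSet, GeneModel, SampleMeta

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    n_genes: int = 50
    orf_len_min: int = 600
    orf_len_max: int = 2000
    utr5_len: int = 50           # true UTR lengths written into the genome
    utr3_len: int = 150
    intergenic_gap: int = 300
    n_replicates: int = 3
    depth_mean: float = 30.0     # median per-base depth of a typical gene
    expr_sigma: float = 0.4      # lognormal sd of gene-level coverage means
    ip_effect: float = 5.0       # IP enrichment multiplier at planted sites
    peak_width: int = 100        # width of the planted enrichment window
    dispersion: float = 100.0    # NB size for per-base coverage
    fragment_smooth: int = 50    # box width (nt) emulating fragment-length autocorrelation
    counts_mean: float = 500.0
    counts_sigma: float = 0.5    # lognormal sd of gene-level count means
    counts_dispersion: float = 400.0  # NB size for gene-level counts
    frac_methylated: float = 0.3
    rme1_fold: float = 2.0       # cat/WT count ratio of the RME1-analog
    site_end_margin: int = 20    # planted sites stay this far from the 3' end
    chrom: str = "chrS"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        if self.ip_effect < 1:
            raise ValueError("ip_effect must be >= 1")
        if not 0 < self.frac_methylated <= 1:
            raise ValueError("frac_methylated must lie in (0, 1]")


@dataclass
class PlantedSite:
    gene_id: str
    offset: int          # transcript offset of the methylated A
    genomic: int
    effect: float


@dataclass
class MethylomeTruth:
    sites: list[PlantedSite]
    rme1_analog: str

    def by_gene(self) -> dict[str, PlantedSite]:
        return {s.gene_id: s for s in self.sites}


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]       # with true UTR lengths set
    truth: MethylomeTruth
    coverage: CoverageSet
    counts: pd.DataFrame
    count_samples: pd.DataFrame


def _stage_rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.rng_seed, stage])


def _set_transcript_bases(chrom: list[str], gene: GeneModel, offset: int, bases: str) -> None:
    """Write ``bases`` (transcript orientation) into the genome at the given
    transcript offset."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i, b in enumerate(bases):
        pos = gene.transcript_to_genomic(offset + i)
        chrom[pos] = b if gene.strand == "+" else comp[b]


def simulate_genome_and_annotation(cfg: SimConfig) -> tuple[dict[str, str], list[GeneModel], MethylomeTruth]:
    """Random genome with non-overlapping genes and a planted methylome.

    Every planted site's transcript 4-mer [A-2, A+2) is set to GGAC (an RGAC
    instance) on the gene's strand; sites are uniform in the 3'-terminal
    third of the transcript, at least ``site_end_margin`` nt from the 3' end.
    """
    rng = _stage_rng(cfg, 0)
    genes: list[GeneModel] = []
    pos = cfg.intergenic_gap
    chrom_parts = [rng.choice(_BASES, size=cfg.intergenic_gap)]
    for i in range(cfg.n_genes):
        orf_len = int(rng.integers(cfg.orf_len_min, cfg.orf_len_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tlen = cfg.utr5_len + orf_len + cfg.utr3_len
        if strand == "+":
            orf_start = pos + cfg.utr5_len
        else:
            orf_start = pos + cfg.utr3_len
        genes.append(GeneModel(f"g{i:03d}", cfg.chrom, strand,
                               orf_start, orf_start + orf_len,
                               utr5_len=cfg.utr5_len, utr3_len=cfg.utr3_len))
        chrom_parts.append(rng.choice(_BASES, size=tlen + cfg.intergenic_gap))
        pos += tlen + cfg.intergenic_gap
    chrom_arr = np.concatenate(chrom_parts)
    chrom = list(map(str, chrom_arr))

    n_meth = max(1, round(cfg.frac_methylated * cfg.n_genes))
    meth_idx = sorted(rng.choice(cfg.n_genes, size=n_meth, replace=False))
    sites: list[PlantedSite] = []
    for gi in meth_idx:
        gene = genes[gi]
        L = gene.transcript_length
        lo = max(2, (2 * L) // 3)
        hi = L - max(cfg.site_end_margin, 2)
        if hi <= lo:
            raise ValueError("transcript too short to place a 3'-biased site")
        offset = int(rng.integers(lo, hi))
        _set_transcript_bases(chrom, gene, offset - 2, "GGAC")
        sites.append(PlantedSite(gene.gene_id, offset,
                                 gene.transcript_to_genomic(offset), cfg.ip_effect))
    analog = sites[int(rng.integers(len(sites)))].gene_id
    genome = {cfg.chrom: "".join(chrom)}
    return genome, genes, MethylomeTruth(sites, analog)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial draws with the given per-element mean and NB size."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=float)
    nz = mean > 0
    if np.any(nz):
        p = size_param / (size_param + mean[nz])
        out[nz] = rng.negative_binomial(size_param, p)
    return out


def simulate_coverage_tracks(cfg: SimConfig, genes: list[GeneModel],
                             truth: MethylomeTruth, chrom_length: int) -> CoverageSet:
    """Per-base NB coverage for every sample over both strands.

    Input tracks reflect expression only; WT IP tracks multiply the gene mean
    by the site effect within +-peak_width/2 of planted sites; cat IP tracks
    carry no enrichment. Coverage outside transcripts is zero.

    Per-base NB draws are box-smoothed over ``fragment_smooth`` nt within
    each transcript: sequenced fragments are ~70-120 nt, so neighboring
    bases share most of their reads and real per-base depth is locally
    smooth, never dipping at a single base the way independent draws do.
    """
    rng = _stage_rng(cfg, 1)
    gene_means = cfg.depth_mean * np.exp(rng.normal(0.0, cfg.expr_sigma, size=len(genes)))
    site_by_gene = truth.by_gene()
    half = cfg.peak_width // 2

    cov = CoverageSet()
    for genotype in ("WT", "cat"):
        for fraction in ("IP", "input"):
            for rep in range(1, cfg.n_replicates + 1):
                sample = SampleMeta(genotype, fraction, rep)
                tracks = {"+": np.zeros(chrom_length), "-": np.zeros(chrom_length)}
                for gene, mu in zip(genes, gene_means):
                    L = gene.transcript_length
                    mean_vec = np.full(L, mu)
                    site = site_by_gene.get(gene.gene_id)
                    if site is not None and fraction == "IP" and genotype == "WT":
                        lo = max(0, site.offset - half)
                        hi = min(L, site.offset + half)
                        mean_vec[lo:hi] *= site.effect
                    depth = _nb_draw(rng, mean_vec, cfg.dispersion)
                    if cfg.fragment_smooth > 1 and L > 1:
                        depth = uniform_filter1d(depth, size=min(cfg.fragment_smooth, L),
                                                 mode="nearest")
                    if gene.strand == "-":
                        depth = depth[::-1]
                    tracks[gene.strand][gene.transcript_start:gene.transcript_end] = depth
                for strand, arr in tracks.items():
                    cov.add(sample, cfg.chrom, strand, arr)
    return cov


def simulate_counts(cfg: SimConfig, genes: list[GeneModel], truth: MethylomeTruth,
                    fold_overrides: Optional[dict[str, float]] = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level NB count matrix for the total-RNA fraction.

    The RME1-analog's cat mean is WT mean x ``rme1_fold``; all other genes
    have equal means across genotypes unless overridden via
    ``fold_overrides`` (gene_id -> cat/WT fold).
    """
    rng = _stage_rng(cfg, 2)
    base_means = cfg.counts_mean * np.exp(rng.normal(0.0, cfg.counts_sigma, size=len(genes)))
    folds = {truth.rme1_analog: cfg.rme1_fold}
    if fold_overrides:
        folds.update(fold_overrides)

    columns = [f"{g}_total_{r}" for g in ("WT", "cat")
               for r in range(1, cfg.n_replicates + 1)]
    data = {}
    for col in columns:
        genotype = col.split("_")[0]
        means = np.array([
            mu * (folds.get(gene.gene_id, 1.0) if genotype == "cat" else 1.0)
            for gene, mu in zip(genes, base_means)])
        data[col] = _nb_draw(rng, means, cfg.counts_dispersion)
    counts = pd.DataFrame(data, index=[g.gene_id for g in genes])
    counts.index.name = "gene_id"
    samples = pd.DataFrame({
        "sample": columns,
        "genotype": [c.split("_")[0] for c in columns],
        "fraction": ["total"] * len(columns),
        "replicate": [int(c.split("_")[2]) for c in columns],
    }).set_index("sample")
    return counts, samples


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate the full dataset: genome, annotation, truth, coverage, counts."""
    genome, genes, truth = simulate_genome_and_annotation(cfg)
    coverage = simulate_coverage_tracks(cfg, genes, truth, len(genome[cfg.chrom]))
    counts, count_samples = simulate_counts(cfg, genes, truth)
    return SimulatedDataset(cfg, genome, genes, truth, coverage, counts, count_samples)
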