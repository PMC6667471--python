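"""Readers and writers for the pipeline's file formats.

Genome: FASTA (Biopython). Annotation: GFF3/GTF, CDS features only
(gffutils, in-memory db); extended annotation is emitted as GFF3 with UTR
features and as BED12. Coverage: 4-column bedGraph, one file per sample per
strand, indexed by a sample sheet TSV. Counts and DE tables: TSV. Planted
methylome truth: BED6 with the effect size in the score column.

GFF is 1-based inclusive and converted to 0-based half-open on read;
bedGraph and BED are natively 0-based half-open.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import CoverageSet, GeneModel, SampleMeta
from .simulate import MethylomeTruth, PlantedSite, SimulatedDataset

SAMPLE_SHEET_COLUMNS = ["path", "genotype", "fraction", "replicate", "strand"]


# ---------------------------------------------------------------- genome

def read_genome(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------ annotation

def read_orf_annotation(path: str | Path) -> list[GeneModel]:
    """ORF coordinates from a GFF3/GTF file; only CDS features are consumed.
    Multi-segment CDS entries sharing an ID are merged to their span."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    spans: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("gene_id")
                   or feat.attributes.get("Parent") or [feat.id])[0]
        rec = spans.setdefault(gene_id, [feat.seqid, feat.strand, feat.start - 1, feat.end])
        rec[2] = min(rec[2], feat.start - 1)
        rec[3] = max(rec[3], feat.end)
    return [GeneModel(gid, chrom, strand, start, end)
            for gid, (chrom, strand, start, end) in spans.items()]


def write_annotation_gff3(genes: Sequence[GeneModel], path: str | Path,
                          with_utrs: bool = False) -> None:
    """GFF3 with one CDS per gene; with_utrs adds five_prime_UTR /
    three_prime_UTR features for non-zero extensions."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tm6acall\tCDS\t{g.orf_start + 1}\t{g.orf_end}\t."
                     f"\t{g.strand}\t0\tID={g.gene_id}\n")
            if not with_utrs:
                continue
            for kind, length in (("five_prime_UTR", g.utr5_len),
                                 ("three_prime_UTR", g.utr3_len)):
                if length == 0:
                    continue
                upstream = (kind == "five_prime_UTR") == (g.strand == "+")
                if upstream:
                    s, e = g.orf_start - length, g.orf_start
                else:
                    s, e = g.orf_end, g.orf_end + length
                fh.write(f"{g.chrom}\tm6acall\t{kind}\t{s + 1}\t{e}\t.\t{g.strand}\t."
                         f"\tID={g.gene_id}_{kind};Parent={g.gene_id}\n")


def write_annotation_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """BED12: transcript span with the ORF as the thick interval."""
    with open(path, "w") as fh:
        for g in genes:
            ts, te = g.transcript_start, g.transcript_end
            fh.write("\t".join(map(str, [
                g.chrom, ts, te, g.gene_id, 0, g.strand,
                g.orf_start, g.orf_end, "0,0,0", 1, te - ts, 0])) + "\n")


# -------------------------------------------------------------- coverage

def write_bedgraph(depth_by_chrom: dict[str, np.ndarray], path: str | Path) -> None:
    """Run-length-collapsed 4-column bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(depth_by_chrom):
            arr = np.asarray(depth_by_chrom[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr) != 0)
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    text = f"{v:g}" if v != int(v) else str(int(v))
                    fh.write(f"{chrom}\t{s}\t{e}\t{text}\n")


def read_bedgraph(path: str | Path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph into per-base arrays (unlisted chroms stay zero)."""
    arrays = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    if df.empty:
        return arrays
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom not in arrays:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
        arrays[chrom][int(start):int(end)] = float(value)
    return arrays


def write_sample_sheet(rows: pd.DataFrame, path: str | Path) -> None:
    rows[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str, "fraction": str,
                                            "strand": str, "path": str})
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def load_coverage(sheet: pd.DataFrame, chrom_lengths: dict[str, int],
                  base_dir: str | Path = ".") -> CoverageSet:
    """Build a CoverageSet from a sample sheet of bedGraph paths."""
    cov = CoverageSet()
    base = Path(base_dir)
    for row in sheet.itertuples(index=False):
        sample = SampleMeta(row.genotype, row.fraction, int(row.replicate))
        arrays = read_bedgraph(base / row.path, chrom_lengths)
        for chrom, arr in arrays.items():
            cov.add(sample, chrom, row.strand, arr)
    return cov


# ---------------------------------------------------------------- tables

def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_truth_bed(truth: MethylomeTruth, chrom: str,
                    strand_by_gene: dict[str, str], path: str | Path) -> None:
    """Planted sites as BED6 (score column = effect size)."""
    with open(path, "w") as fh:
        for s in truth.sites:
            fh.write(f"{chrom}\t{s.genomic}\t{s.genomic + 1}\t{s.gene_id}"
                     f"\t{s.effect:g}\t{strand_by_gene[s.gene_id]}\n")


def read_truth_bed(path: str | Path, genes: Sequence[GeneModel],
                   rme1_analog: str) -> MethylomeTruth:
    by_id = {g.gene_id: g for g in genes}
    sites = []
    with open(path) as fh:
        for line in fh:
            chrom, start, _end, gene_id, effect, _strand = line.rstrip("\n").split("\t")
            gene = by_id[gene_id]
            genomic = int(start)
            sites.append(PlantedSite(gene_id, gene.genomic_to_transcript(genomic),
                                     genomic, float(effect)))
    return MethylomeTruth(sites, rme1_analog)


# --------------------------------------------------------------- dataset

def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset to disk: FASTA, GFF3, bedGraphs + sample
    sheet, counts TSV, truth BED, and a JSON echo of the configuration."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out / "genome.fa"
    write_genome(ds.genome, paths["genome"])
    paths["annotation"] = out / "annotation.gff3"
    write_annotation_gff3(ds.genes, paths["annotation"])

    rows = []
    for sample in ds.coverage.samples():
        for strand, tag in (("+", "plus"), ("-", "minus")):
            fname = f"{sample.label}_{tag}.bedgraph"
            arrays = {chrom: ds.coverage.get(sample, chrom, strand)
                      for chrom, s in ds.coverage.chroms() if s == strand}
            write_bedgraph(arrays, out / fname)
            rows.append({"path": fname, "genotype": sample.genotype,
                         "fraction": sample.fraction, "replicate": sample.replicate,
                         "strand": strand})
    paths["sample_sheet"] = out / "samples.tsv"
    write_sample_sheet(pd.DataFrame(rows), paths["sample_sheet"])

    paths["counts"] = out / "counts.tsv"
    write_counts(ds.counts, paths["counts"])
    paths["truth"] = out / "truth.bed"
    write_truth_bed(ds.truth, ds.config.chrom,
                    {g.gene_id: g.strand for g in ds.genes}, paths["truth"])
    paths["config"] = out / "config.json"
    with open(paths["config"], "w") as fh:
        json.dump({**vars(ds.config), "rme1_analog": ds.truth.rme1_analog},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
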