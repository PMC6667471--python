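"""Generate a synthetic m6A-seq dataset with planted ground truth.

Builds a toy genome with 12 genes, a planted methylome (sites on RGAC motifs
in the 3'-terminal third of transcripts), 12 coverage tracks (2 genotypes x
2 fractions x 3 replicates), and a count matrix, then writes everything to
./sim_out/ in standard formats (FASTA, GFF3, bedGraph + sample sheet, TSV,
BED).
"""
from m6acall import SimConfig, simulate_dataset
from m6acall.io import write_dataset

cfg = SimConfig(n_genes=12, rng_seed=1)
ds = simulate_dataset(cfg)
paths = write_dataset(ds, "sim_out")

print(f"genome: 1 chromosome, {len(ds.genome[cfg.chrom]):,} bp")
print(f"genes: {len(ds.genes)}; planted m6A sites: {len(ds.truth.sites)}")
print(f"RME1-analog (methylated AND 2x up in cat): {ds.truth.rme1_analog}")
for name, path in paths.items():
    print(f"  {name}: {path}")
# Each planted site sits on an RGAC motif; the analog gene is the one gene
# that should survive the full m6A x differential-expression intersection.
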