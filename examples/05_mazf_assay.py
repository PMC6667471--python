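"""In-silico MazF methylation assay on an RME1-like 3' UTR site.

MazF cleaves ACA but not m6ACA. Primers flanking the probed ACA amplify only
when the site is methylated (template intact); control primers flanking no
ACA amplify regardless - mirroring the WT vs catalytic-dead readout.
"""
from m6acall import PrimerPair, RnaMolecule, assay

# a GGACA context: the methylatable A (index 17) starts the ACA trimer
utr = "GGUUCUGAUCCAAUUGGACAUUGGUCCAAGGUUCGGAUCCGG"
site = 17
primers = [
    PrimerPair((2, 10), (24, 32), "P1/P2 (flank m6A site)"),
    PrimerPair((33, 36), (38, 42), "P3/P4 (no ACA between)"),
]

for label, methylated in (("IME4 (methylated)", {site}), ("ime4-cat (unmethylated)", set())):
    print(f"{label}:")
    for row in assay(RnaMolecule(utr, methylated), primers):
        out = f"product, {row['length']} nt" if row["product"] else "no product"
        print(f"  {row['primer_pair']}: {out}")
# Expected: P1/P2 amplify only in the methylated (IME4) template; P3/P4
# amplify in both - the assay's positive control.
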