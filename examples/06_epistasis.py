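"""Order IME4 and RME1 genetically from deletion phenotypes.

Enumerates the eight ordered two-gene chain models acting on DNA
replication, predicts each deletion genotype's phenotype by Boolean
evaluation, and keeps the models consistent with the observations
(replication in WT, rme1-delta and the double deletion; none in ime4-delta).
"""
from m6acall import OBSERVED_PHENOTYPES, consistent_models, prediction_table

table = prediction_table()
print(table.to_string(index=False))

survivors = consistent_models(OBSERVED_PHENOTYPES)
print(f"\nconsistent models: {len(survivors)} of 8")
for m in survivors:
    print(f"  {m.describe()}")
# Only double repression survives: IME4 -| RME1 -| replication, i.e. the
# methyltransferase acts upstream by silencing the meiotic repressor.
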