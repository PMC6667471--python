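"""Boolean epistasis analysis of a two-gene linear pathway.

Given DNA-replication phenotypes of the wild type, the two single deletions
and the double deletion, enumerate the eight ordered two-gene chain models
(which gene is upstream x sign of each edge) and keep those whose Boolean
predictions match every observation. With the observed phenotypes
(replication in WT, rme1-delta and the double deletion; none in ime4-delta)
exactly one model survives: IME4 represses RME1, which represses replication,
placing the methyltransferase upstream of the repressor.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import FrozenSet, Iterable, Sequence

import pandas as pd

IME4 = "IME4"
RME1 = "RME1"
ACTIVATES = "activates"
REPRESSES = "represses"

GENOTYPES: tuple[FrozenSet[str], ...] = (
    frozenset(), frozenset({IME4}), frozenset({RME1}), frozenset({IME4, RME1}),
)


@dataclass(frozen=True)
class PathwayModel:
    """A linear chain upstream -> downstream -> replication with signed edges."""

    upstream: str
    downstream: str
    edge1_sign: str  # upstream -> downstream
    edge2_sign: str  # downstream -> replication

    def __post_init__(self) -> None:
        if {self.upstream, self.downstream} != {IME4, RME1}:
            raise ValueError("model must order IME4 and RME1")
        for sign in (self.edge1_sign, self.edge2_sign):
            if sign not in (ACTIVATES, REPRESSES):
                raise ValueError(f"invalid edge sign {sign!r}")

    def describe(self) -> str:
        a1 = "->" if self.edge1_sign == ACTIVATES else "-|"
        a2 = "->" if self.edge2_sign == ACTIVATES else "-|"
        return f"{self.upstream} {a1} {self.downstream} {a2} replication"


@dataclass(frozen=True)
class PhenotypeObservation:
    """Replication phenotype of one deletion genotype."""

    deleted: FrozenSet[str]
    replication: bool


#: Replication phenotypes reported for the four genotypes: wild type
#: replicates, ime4-delta does not, rme1-delta and the double deletion do.
OBSERVED_PHENOTYPES: tuple[PhenotypeObservation, ...] = (
    PhenotypeObservation(frozenset(), True),
    PhenotypeObservation(frozenset({IME4}), False),
    PhenotypeObservation(frozenset({RME1}), True),
    PhenotypeObservation(frozenset({IME4, RME1}), True),
)


def enumerate_models() -> list[PathwayModel]:
    """All 8 distinct ordered chain models, in a deterministic order."""
    return [PathwayModel(up, RME1 if up == IME4 else IME4, e1, e2)
            for up, e1, e2 in product((IME4, RME1),
                                      (ACTIVATES, REPRESSES),
                                      (ACTIVATES, REPRESSES))]


def predict_phenotype(model: PathwayModel, deleted: Iterable[str]) -> bool:
    """Boolean prediction of replication for a deletion genotype.

    A gene is active iff present (not deleted) and not repressed: the
    upstream gene is active iff present; the downstream gene is active iff
    present and its input edge leaves it on; replication follows the sign of
    the downstream edge.
    """
    deleted = frozenset(deleted)
    if not deleted <= {IME4, RME1}:
        raise ValueError(f"unknown genes in genotype: {sorted(deleted)}")
    upstream_active = model.upstream not in deleted
    if model.downstream in deleted:
        downstream_active = False
    elif model.edge1_sign == ACTIVATES:
        downstream_active = upstream_active
    else:
        downstream_active = not upstream_active
    if model.edge2_sign == ACTIVATES:
        return downstream_active
    return not downstream_active


def consistent_models(observations: Sequence[PhenotypeObservation]) -> list[PathwayModel]:
    """Models whose predictions match every observation."""
    if not observations:
        raise ValueError("need at least one observation")
    seen: dict[FrozenSet[str], bool] = {}
    for obs in observations:
        if obs.deleted in seen and seen[obs.deleted] != obs.replication:
            raise ValueError(f"contradictory observations for genotype {sorted(obs.deleted)}")
        seen[obs.deleted] = obs.replication
    return [m for m in enumerate_models()
            if all(predict_phenotype(m, o.deleted) == o.replication for o in observations)]


def prediction_table() -> pd.DataFrame:
    """Predicted replication phenotype of every model for every genotype,
    with a consistency flag against the observed phenotypes."""
    rows = []
    observed = {o.deleted: o.replication for o in OBSERVED_PHENOTYPES}
    for m in enumerate_models():
        row = {"model": m.describe()}
        consistent = True
        for g in GENOTYPES:
            label = "WT" if not g else "+".join(sorted(x + "Δ" for x in g))
            pred = predict_phenotype(m, g)
            row[label] = pred
            consistent &= pred == observed[g]
        row["consistent"] = consistent
        rows.append(row)
    return pd.DataFrame(rows)
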