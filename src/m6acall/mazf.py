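"""In-silico methylation-sensitive MazF digestion and PCR prediction.

MazF is a single-strand endoribonuclease that cleaves RNA at ACA trimers but
not when the first A carries m6A. Digesting mRNA and asking whether a primer
pair spanning the probed site still amplifies gives a binary, site-specific
methylation readout: a methylated ACA leaves the template intact (product),
an unmethylated ACA is cut (no product), and primer pairs that flank no ACA
amplify regardless.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

Interval = tuple[int, int]

_VALID = set("ACGU")


def _normalize_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class RnaMolecule:
    """An RNA sequence with a set of methylated A positions (0-based)."""

    sequence: str
    methylated: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize_rna(self.sequence))
        object.__setattr__(self, "methylated", frozenset(self.methylated))
        for pos in self.methylated:
            if not 0 <= pos < len(self.sequence) or self.sequence[pos] != "A":
                raise ValueError(f"methylated position {pos} does not index an A")


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primer binding sites on the molecule (half-open).
    The forward site must lie entirely upstream of the reverse site."""

    forward: Interval
    reverse: Interval
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.forward[0] < self.forward[1] <= self.reverse[0] < self.reverse[1]):
            raise ValueError("forward site must precede reverse site; intervals half-open")


def cleavage_positions(m: RnaMolecule, cut_offset: int = 0) -> list[int]:
    """Cut coordinates: one immediately 5' of the first A of every ACA trimer
    whose leading A is unmethylated. Overlapping ACA trimers (e.g. ACACA) are
    each evaluated; duplicate coordinates are deduplicated.

    ``cut_offset`` shifts the cut relative to the leading A (0 = 5' of it).
    """
    seq = m.sequence
    cuts = set()
    for i in range(len(seq) - 2):
        if seq[i:i + 3] == "ACA" and i not in m.methylated:
            pos = i + cut_offset
            if 0 < pos < len(seq):
                cuts.add(pos)
    return sorted(cuts)


def mazf_digest(m: RnaMolecule, cut_offset: int = 0) -> list[Interval]:
    """Fragments after complete MazF digestion; they partition the sequence."""
    edges = [0] + cleavage_positions(m, cut_offset) + [len(m.sequence)]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def pcr_product(fragments: Sequence[Interval],
                primers: PrimerPair) -> tuple[bool, Optional[int]]:
    """Whether a PCR product forms from the digested template, and its length.

    A product exists iff both primer sites lie wholly within a single
    fragment; its length is reverse end minus forward start.
    """
    for s, e in fragments:
        if s <= primers.forward[0] and primers.forward[1] <= e \
                and s <= primers.reverse[0] and primers.reverse[1] <= e:
            return True, primers.reverse[1] - primers.forward[0]
    return False, None


def assay(m: RnaMolecule, primer_pairs: Sequence[PrimerPair],
          cut_offset: int = 0) -> list[dict]:
    """Digest once and report product presence/length per primer pair."""
    fragments = mazf_digest(m, cut_offset)
    report = []
    for pp in primer_pairs:
        present, length = pcr_product(fragments, pp)
        report.append({"primer_pair": pp.name, "product": present, "length": length})
    return report
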