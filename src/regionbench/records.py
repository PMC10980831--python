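"""Sequence record type shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")

#: Expansion of IUPAC nucleotide codes into the plain bases they cover.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One DNA sequence with an identifier and a genome of origin.

    ``genome_id`` defaults to ``id``; it differs when a genome carries
    several 16S copies (e.g. ids ``g1_rrnA``/``g1_rrnB`` for genome ``g1``).
    """

    id: str
    seq: str
    genome_id: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genome_id:
            self.genome_id = self.id

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.seq),
                              self.genome_id, self.description)
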