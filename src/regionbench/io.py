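"""FASTA and newick readers/writers.

FASTA handling is delegated to Biopython's SeqIO; this layer adds the checks
the rest of the package relies on (unique ids, IUPAC alphabet, uppercase
normalization) and converts to :class:`~regionbench.records.SequenceRecord`.

Header convention: ``>genome_id[ description]``.  For multi-copy 16S input
the id may carry a copy suffix (``g1_rrnA``); the genome of origin is then
the part before the last ``_rrn`` marker, falling back to the full id.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import DataError
from .records import IUPAC_DNA, SequenceRecord
from .tree import Tree, parse_newick, write_newick_string

log = logging.getLogger("regionbench")

__all__ = ["read_fasta", "write_fasta", "read_newick", "write_newick",
           "read_panel_tsv", "genome_id_from_header"]


def genome_id_from_header(seq_id: str) -> str:
    if "_rrn" in seq_id:
        return seq_id.rsplit("_rrn", 1)[0]
    return seq_id


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    lowercased = False
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            lowercased = True
            seq = seq.upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise DataError(
                f"non-IUPAC character {seq[pos]!r} at position {pos + 1} "
                f"of record {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, seq,
                                      genome_id_from_header(rec.id), desc))
    if lowercased:
        log.info("read_fasta(%s): lowercase input uppercased", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_newick(path: str | Path) -> Tree:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    return parse_newick(path.read_text())


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(write_newick_string(tree) + "\n")


def read_panel_tsv(path: str | Path) -> list["PrimerPair"]:
    """Read a primer panel table (region_label, forward, reverse,
    max_mismatch) into :class:`~regionbench.regions.PrimerPair` objects."""
    from .regions import PrimerPair

    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    pairs: list[PrimerPair] = []
    lines = path.read_text().splitlines()
    if not lines:
        raise DataError(f"empty panel file: {path}")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["region_label", "forward", "reverse", "max_mismatch"]
    if [h.strip() for h in header] != expected:
        raise DataError(
            f"panel header must be {expected}, got {header} in {path}")
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise DataError(f"line {i} of {path}: expected 4 fields")
        label, fwd, rev, mm = (f.strip() for f in fields)
        pairs.append(PrimerPair(label, fwd, rev, int(mm)))
    labels = [p.region_label for p in pairs]
    if len(labels) != len(set(labels)):
        raise DataError(f"duplicate region labels in panel {path}")
    return pairs


def write_panel_tsv(pairs: Sequence["PrimerPair"], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region_label\tforward\treverse\tmax_mismatch\n")
        for p in pairs:
            fh.write(f"{p.region_label}\t{p.forward}\t{p.reverse}"
                     f"\t{p.max_mismatch}\n")
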