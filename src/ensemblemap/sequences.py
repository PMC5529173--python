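"""Sequence records and the maximally disruptive single point mutant panel.

The map of conformational space is built not from the wild-type sequence
alone but from a panel of single point mutants designed to disturb base
pairing as much as possible.  Transversions that swap a base for its
Watson-Crick complement (A<->U, C<->G) destroy every pair the original base
could form while creating the complementary pairing potential, and were
identified as maximally structure-disruptive in mutate-and-map experiments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

#: The maximally disruptive substitution for each base: swap for the
#: Watson-Crick complement so every original pairing partner is lost.
DISRUPTIVE_MUTATION = {"A": "U", "U": "A", "C": "G", "G": "C"}


class SequenceError(ValueError):
    """Raised for malformed or non-RNA sequence input."""


def _normalize(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, convert T to U, and validate against the RNA alphabet."""
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise SequenceError(
            f"{context}: non-nucleotide character(s) {sorted(bad)!r}; "
            "only A, C, G, U (or T) are accepted"
        )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """An RNA sequence with an identifier.

    Input is normalized on construction: case-folded to uppercase and DNA
    thymine converted to uracil.  IUPAC ambiguity codes are rejected because
    the disruptive-mutation rule is undefined for them.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize(self.sequence, context=self.id))
        if len(self.sequence) < 1:
            raise SequenceError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MutantRecord:
    """A single point mutant of a parent sequence.

    ``position`` is 1-based, matching CT and SHAPE file conventions.
    """

    parent_id: str
    position: int
    original_base: str
    mutant_base: str
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.parent_id}_pos{self.position}{self.original_base}{self.mutant_base}"


def read_fasta(path: Union[str, Path]) -> List[SequenceRecord]:
    """Read a (multi-)FASTA file into normalized :class:`SequenceRecord`\\ s.

    Raises :class:`SequenceError` naming the offending line for content that
    precedes the first header, and for non-nucleotide characters.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise SequenceError(
                f"{path}: line {lineno}: expected a FASTA header ('>') "
                "before sequence data"
            )
        break
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[Union[SequenceRecord, MutantRecord]],
                path: Union[str, Path]) -> None:
    """Write records as FASTA (uses ``.id`` for headers; 60-column wrap)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def generate_point_mutants(seq: SequenceRecord) -> List[MutantRecord]:
    """Generate the disruptive single point mutant panel, one per position.

    Each mutant differs from the parent at exactly one position, applying
    A->U, U->A, C->G, G->C.  Mutants are ordered by position (1-based).
    """
    mutants = []
    chars = list(seq.sequence)
    for pos0, base in enumerate(chars):
        new_base = DISRUPTIVE_MUTATION[base]
        mutated = chars.copy()
        mutated[pos0] = new_base
        mutants.append(
            MutantRecord(
                parent_id=seq.id,
                position=pos0 + 1,
                original_base=base,
                mutant_base=new_base,
                sequence="".join(mutated),
            )
        )
    return mutants


def write_mutant_panel(seq: SequenceRecord, path: Union[str, Path]) -> List[MutantRecord]:
    """Export the mutant panel as multi-FASTA; returns the panel."""
    mutants = generate_point_mutants(seq)
    write_fasta(mutants, path)
    return mutants
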