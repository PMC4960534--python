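"""Protein records for limited-proteolysis analysis.

A :class:`ProteinRecord` holds a mature-chain sequence with 1-based residue
numbering and an explicit cysteine state.  Three cysteine states are
supported:

``reduced``
    free thiols (the state of a TCEP-reduced sample);
``disulfide``
    intact bridges given as a list of (i, j) cysteine position pairs; a
    fragment loses 2 H (≈2.016 Da) for every bridge fully contained in it;
``carbamidomethyl``
    reduced and alkylated thiols, +57.051 Da (average) per cysteine.  This
    is the state that reproduces published MALDI tables produced by
    standard in-silico digestion software with a fixed Cys modification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._config import AMINO_ACIDS

CYS_STATES = ("reduced", "disulfide", "carbamidomethyl")


@dataclass(frozen=True)
class ProteinRecord:
    """A mature protein chain with 1-based residue numbering.

    Parameters
    ----------
    id : str
        Identifier (FASTA header word).
    sequence : str
        One-letter amino-acid sequence restricted to the 20 standard
        residues.
    numbering_offset : int
        Added to the 1-based index to obtain the displayed residue number;
        0 means residue 1 is the first mature residue.
    cys_state : str
        One of ``reduced``, ``disulfide``, ``carbamidomethyl``.
    disulfides : tuple of (int, int)
        Cysteine pairs (1-based positions), only meaningful when
        ``cys_state == "disulfide"``.
    """

    id: str
    sequence: str
    numbering_offset: int = 0
    cys_state: str = "reduced"
    disulfides: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
        if self.cys_state not in CYS_STATES:
            raise ValueError(f"cys_state must be one of {CYS_STATES}")
        seen: set[int] = set()
        for i, j in self.disulfides:
            for p in (i, j):
                if not 1 <= p <= len(self.sequence):
                    raise ValueError(f"disulfide position {p} out of bounds")
                if self.sequence[p - 1] != "C":
                    raise ValueError(f"residue {p} is not cysteine")
            if i == j or i in seen or j in seen:
                raise ValueError("disulfide pairs must reference distinct cysteines")
            seen.update((i, j))

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """One-letter code at 1-based position *pos*."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"residue position {pos} out of range 1..{len(self)}")
        return self.sequence[pos - 1]

    def with_cys_state(self, state: str, disulfides: Iterable[tuple[int, int]] = ()) -> "ProteinRecord":
        return replace(self, cys_state=state, disulfides=tuple(disulfides))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read all records from a FASTA file as reduced-state proteins."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records: Iterator[SeqRecord] = (
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    )
    SeqIO.write(seq_records, str(path), "fasta")
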