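"""FASTA input/output and RNA alphabet normalization.

Sequences are analyzed as RNA: under the ``normalize`` policy DNA input is
accepted and T is mapped to U, lowercase is uppercased. Ambiguity codes
(N and other IUPAC letters) are rejected under ``strict``; under
``normalize`` they are retained but the record is flagged so downstream
counting can skip affected windows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

from .errors import AlphabetError, FastaParseError

RNA_ALPHABET = frozenset("ACGU")

AlphabetPolicy = Literal["strict", "normalize"]


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA record: identifier plus residues over {A,C,G,U}.

    ``has_ambiguity`` is True when normalization retained non-ACGU
    characters (e.g. N); such positions contribute no kmer counts.
    """

    id: str
    residues: str
    has_ambiguity: bool = field(default=False, compare=False)

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Uppercase and map T->U. Idempotent."""
    return raw.upper().replace("T", "U")


def _validate_strict(record_id: str, residues: str) -> None:
    for i, ch in enumerate(residues, start=1):
        if ch not in RNA_ALPHABET:
            raise AlphabetError(record_id, i, ch)


def make_sequence(
    record_id: str, raw: str, policy: AlphabetPolicy = "normalize"
) -> RnaSequence:
    """Build a validated :class:`RnaSequence` from raw residues."""
    residues = normalize_residues(raw)
    if policy == "strict":
        _validate_strict(record_id, residues)
        return RnaSequence(record_id, residues)
    if policy != "normalize":
        raise ValueError(f"unknown alphabet policy: {policy!r}")
    ambiguous = any(ch not in RNA_ALPHABET for ch in residues)
    return RnaSequence(record_id, residues, has_ambiguity=ambiguous)


def _check_fasta_shape(handle: io.TextIOBase) -> None:
    # SeqIO silently skips junk before the first header; reject it with a
    # line number instead.
    for lineno, line in enumerate(handle, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError(
                f"expected FASTA header, got {stripped[:20]!r}", line=lineno
            )
        return


def read_fasta(
    path: str | Path, policy: AlphabetPolicy = "normalize"
) -> list[RnaSequence]:
    """Read a FASTA file into an ordered list of :class:`RnaSequence`.

    Parameters
    ----------
    path:
        FASTA file, wrapped or unwrapped, DNA or RNA alphabet.
    policy:
        ``"normalize"`` maps T->U and uppercases, retaining (but flagging)
        ambiguity codes; ``"strict"`` raises :class:`AlphabetError` on any
        non-ACGU residue after normalization.

    Returns
    -------
    list of RnaSequence, in file order. An empty file yields an empty list.
    """
    path = Path(path)
    with open(path) as handle:
        _check_fasta_shape(handle)
    out: list[RnaSequence] = []
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            out.append(make_sequence(record.id, str(record.seq), policy))
    return out


def write_fasta(
    seqs: Iterable[RnaSequence], path: str | Path, width: int = 60
) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns.

    Round-trips exactly through :func:`read_fasta` on (id, residues).
    """
    path = Path(path)
    with open(path, "w") as handle:
        for seq in seqs:
            handle.write(f">{seq.id}\n")
            for start in range(0, len(seq.residues), width):
                handle.write(seq.residues[start : start + width] + "\n")
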