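"""Reading, validating, and writing protein sequences in FASTA.

Only the 20 canonical amino acids are admitted into a :class:`ProteinRecord`.
Sequences carrying ambiguity codes or non-standard residues (B, J, O, U, X,
Z, ``*``, gap characters, ...) are, by default, dropped at ingestion and
counted in a skip report — encoders downstream are then total over their
input domain.  A strict mode that raises instead is available for pipelines
that must not lose records silently.
"""

from __future__ import annotations

import dataclasses
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import (
    AlphabetError,
    DuplicateIdError,
    EmptyInputError,
    ValidationError,
)

#: The 20 canonical amino acids, alphabetically ordered.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)


class AlphabetPolicy(str, Enum):
    """What to do with sequences containing non-canonical characters."""

    #: Drop the offending record and count it in the skip report (default).
    REJECT_RECORD = "reject_record"
    #: Raise :class:`~pprkit.errors.AlphabetError` on the first bad record.
    ERROR = "error"


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence.

    Parameters
    ----------
    id:
        Non-empty identifier token, unique within a collection.
    residues:
        Uppercase string over the 20-letter canonical alphabet, length >= 1.
    description:
        Free-text remainder of the FASTA header.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or self.id.split() != [self.id]:
            raise ValidationError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.residues:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - ALPHABET_SET
        if bad:
            raise AlphabetError(
                f"record {self.id!r} contains non-canonical characters: "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass(frozen=True)
class SkipReport:
    """Records dropped during ingestion under ``reject_record``."""

    skipped_ids: tuple[str, ...] = ()

    @property
    def count(self) -> int:
        return len(self.skipped_ids)


def read_fasta(
    path: str | Path,
    policy: AlphabetPolicy = AlphabetPolicy.REJECT_RECORD,
) -> tuple[list[ProteinRecord], SkipReport]:
    """Read a multi-record protein FASTA file.

    Returns records in file order plus a :class:`SkipReport` counting the
    sequences rejected for non-canonical characters.  Lowercase residues are
    uppercased; duplicate ids raise; a file from which no record survives
    raises :class:`~pprkit.errors.EmptyInputError`.
    """
    policy = AlphabetPolicy(policy)
    path = Path(path)
    records: list[ProteinRecord] = []
    skipped: list[str] = []
    seen: set[str] = set()
    with open(path) as handle:
        for raw in SeqIO.parse(handle, "fasta"):
            if raw.id in seen:
                raise DuplicateIdError(f"duplicate record id {raw.id!r} in {path}")
            seen.add(raw.id)
            description = raw.description[len(raw.id):].strip()
            try:
                record = ProteinRecord(raw.id, str(raw.seq), description)
            except AlphabetError:
                if policy is AlphabetPolicy.ERROR:
                    raise
                skipped.append(raw.id)
                continue
            records.append(record)
    if not records:
        raise EmptyInputError(f"no usable records in {path} ({len(skipped)} skipped)")
    return records, SkipReport(tuple(skipped))


def write_fasta(
    records: Sequence[ProteinRecord] | Iterable[ProteinRecord],
    path: str | Path,
    line_width: int = 60,
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``line_width``.

    Round-trips with :func:`read_fasta`: ids and residues are preserved
    exactly.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("refusing to write an empty FASTA file")
    if line_width < 1:
        raise ValueError(f"line_width must be >= 1, got {line_width}")
    path = Path(path)
    with open(path, "w") as handle:
        for record in records:
            header = record.id if not record.description else f"{record.id} {record.description}"
            handle.write(f">{header}\n")
            seq = record.residues
            for start in range(0, len(seq), line_width):
                handle.write(seq[start : start + line_width] + "\n")
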