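"""Amino-acid physicochemical property tables.

Two kinds of table are shipped as plain-text data files and can equally be
supplied by the user in the same format:

* **indices** — one real-valued score per amino acid (hydrophobicity,
  hydrophilicity, side-chain mass), the raw material for the auto-cross
  covariance and pseudo amino acid composition encoders.  Before use they
  are standardized to mean 0 and unit population standard deviation over
  the 20 amino acids, which removes any dependence on the published scale.
* **groupings** — a partition of the 20 amino acids into three classes per
  physicochemical property (eight properties), the basis of the
  composition/transition/distribution blocks of the 188-feature descriptor.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import DegenerateIndexError, ValidationError
from .sequence_io import ALPHABET, ALPHABET_SET

_STD_TOL = 1e-9


def _check_scores(name: str, scores: Mapping[str, float]) -> dict[str, float]:
    if set(scores) != ALPHABET_SET:
        missing = ALPHABET_SET - set(scores)
        extra = set(scores) - ALPHABET_SET
        raise ValidationError(
            f"index {name!r} must score exactly the 20 canonical amino acids "
            f"(missing {sorted(missing)}, extra {sorted(extra)})"
        )
    return {aa: float(scores[aa]) for aa in ALPHABET}


@dataclasses.dataclass(frozen=True)
class AAIndex:
    """Raw per-amino-acid property scores on their published scale."""

    name: str
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        scores = _check_scores(self.name, self.scores)
        if len(set(scores.values())) == 1:
            raise DegenerateIndexError(
                f"index {self.name!r} assigns the same score to all amino acids"
            )
        object.__setattr__(self, "scores", scores)


@dataclasses.dataclass(frozen=True)
class NormalizedIndex:
    """Standardized property scores: mean 0, population SD 1 over the 20 amino acids."""

    name: str
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        scores = _check_scores(self.name, self.scores)
        values = list(scores.values())
        mean = sum(values) / 20.0
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / 20.0)
        if abs(mean) > _STD_TOL or abs(sd - 1.0) > _STD_TOL:
            raise ValidationError(
                f"index {self.name!r} is not standardized (mean={mean:.3g}, pop SD={sd:.3g})"
            )
        object.__setattr__(self, "scores", scores)


@dataclasses.dataclass(frozen=True)
class GroupingScheme:
    """An ordered 3-way partition of the amino-acid alphabet for one property."""

    property_name: str
    groups: tuple[frozenset[str], frozenset[str], frozenset[str]]

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.groups)
        if len(groups) != 3:
            raise ValidationError(f"{self.property_name!r}: exactly 3 groups required")
        union = groups[0] | groups[1] | groups[2]
        if union != ALPHABET_SET or sum(map(len, groups)) != 20:
            raise ValidationError(
                f"{self.property_name!r}: groups must partition the 20-letter alphabet"
            )
        object.__setattr__(self, "groups", groups)

    def group_of(self, residue: str) -> int:
        """Return the 0-based group index holding ``residue``."""
        for g, members in enumerate(self.groups):
            if residue in members:
                return g
        raise KeyError(residue)


def normalize_index(index: AAIndex) -> NormalizedIndex:
    """Standardize raw scores: subtract the mean over the 20 amino acids and
    divide by the population standard deviation (denominator 20).

    Idempotent up to floating-point tolerance; raises
    :class:`~pprkit.errors.DegenerateIndexError` for an all-equal index.
    """
    values = list(index.scores.values())
    mean = sum(values) / 20.0
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / 20.0)
    if sd == 0.0:
        raise DegenerateIndexError(f"index {index.name!r} has zero variance")
    return NormalizedIndex(
        index.name, {aa: (s - mean) / sd for aa, s in index.scores.items()}
    )


def load_index(path: str | Path, name: str | None = None) -> AAIndex:
    """Load a raw index from a two-column (amino acid, score) text file.

    Lines starting with ``#`` are comments; whitespace-delimited.
    """
    path = Path(path)
    scores: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split()
        scores[aa.upper()] = float(value)
    return AAIndex(name or path.stem, scores)


def load_grouping(path: str | Path, name: str | None = None) -> GroupingScheme:
    """Load a 3-group partition from a two-column (group number, members) file."""
    path = Path(path)
    groups: dict[int, frozenset[str]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, members = line.split()
        groups[int(label)] = frozenset(members.upper())
    if sorted(groups) != [1, 2, 3]:
        raise ValidationError(f"{path}: expected groups labelled 1, 2, 3")
    return GroupingScheme(name or path.stem, (groups[1], groups[2], groups[3]))


def _data_dir(kind: str) -> Path:
    return Path(str(resources.files("pprkit").joinpath("data", kind)))


def builtin_indices() -> dict[str, AAIndex]:
    """The three shipped property indices: hydrophobicity, hydrophilicity,
    and side-chain mass — the classical triple for covariance and pseudo
    amino acid composition encodings."""
    directory = _data_dir("indices")
    return {p.stem: load_index(p) for p in sorted(directory.glob("*.tsv"))}


def builtin_normalized_indices() -> list[NormalizedIndex]:
    """The builtin indices standardized, in the fixed order
    (hydrophobicity, hydrophilicity, mass)."""
    indices = builtin_indices()
    return [normalize_index(indices[n]) for n in ("hydrophobicity", "hydrophilicity", "mass")]


def builtin_groupings() -> list[GroupingScheme]:
    """The eight shipped 3-group partitions, in fixed file order:
    hydrophobicity, van der Waals volume, polarity, polarizability, charge,
    secondary-structure propensity, solvent accessibility, surface tension."""
    directory = _data_dir("groupings")
    schemes = [load_grouping(p, name=p.stem.split("_", 1)[1]) for p in sorted(directory.glob("*.tsv"))]
    if len(schemes) != 8:
        raise ValidationError(f"expected 8 grouping schemes, found {len(schemes)}")
    return schemes
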