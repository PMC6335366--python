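"""The 188-dimensional composition/transition/distribution descriptor.

The vector concatenates four blocks computed from a protein sequence of
length ``L``:

* 20 amino-acid frequencies (count / L);
* 24 group-composition features — for each of 8 physicochemical
  3-group partitions, the fraction of residues in each group;
* 120 group-distribution features — for each partition and group, the
  relative sequence positions of the first, 25%, 50%, 75%, and last
  occurrence of that group (ceil-quantile occurrence index divided by L;
  an absent group contributes five zeros);
* 24 group-transition features — for each partition, the frequency of
  adjacent residue pairs crossing between group pairs (1,2), (1,3), (2,3),
  direction-insensitive, normalized by L - 1.

20 + 24 + 120 + 24 = 188 features, all in [0, 1].
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .errors import SequenceTooShortError, ValidationError
from .property_tables import GroupingScheme, builtin_groupings
from .sequence_io import ALPHABET, ProteinRecord

N_FEATURES = 188
_PAIRS = ((0, 1), (0, 2), (1, 2))
_ANCHORS = ("first", "q25", "q50", "q75", "last")


@dataclasses.dataclass(frozen=True)
class Descriptor188:
    """One sequence's 188-feature vector with stable feature names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_FEATURES,) or len(self.names) != N_FEATURES:
            raise ValidationError(f"descriptor must have exactly {N_FEATURES} features")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValidationError("descriptor values must be finite and non-negative")
        if abs(values[:20].sum() - 1.0) > 1e-9:
            raise ValidationError("amino-acid frequency block must sum to 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))


def _check_schemes(schemes: Sequence[GroupingScheme]) -> Sequence[GroupingScheme]:
    if len(schemes) != 8:
        raise ValidationError(f"exactly 8 grouping schemes required, got {len(schemes)}")
    return schemes


def composition_aa(record: ProteinRecord) -> np.ndarray:
    """Frequencies of the 20 amino acids, alphabetical order; sums to 1."""
    seq = record.residues
    length = len(seq)
    return np.array([seq.count(aa) for aa in ALPHABET], dtype=float) / length


def _group_indices(record: ProteinRecord, scheme: GroupingScheme) -> np.ndarray:
    lut = np.zeros(26, dtype=np.int8)
    for g, members in enumerate(scheme.groups):
        for aa in members:
            lut[ord(aa) - 65] = g
    codes = np.frombuffer(record.residues.encode("ascii"), dtype=np.uint8) - 65
    return lut[codes]


def composition_groups(
    record: ProteinRecord, schemes: Sequence[GroupingScheme]
) -> np.ndarray:
    """Per-scheme fractions of residues in each of the 3 groups (24 values)."""
    _check_schemes(schemes)
    length = len(record)
    out = np.empty(24, dtype=float)
    for s, scheme in enumerate(schemes):
        groups = _group_indices(record, scheme)
        out[3 * s : 3 * s + 3] = np.bincount(groups, minlength=3) / length
    return out


def distribution_groups(
    record: ProteinRecord, schemes: Sequence[GroupingScheme]
) -> np.ndarray:
    """Relative positions of the 1st, 25%, 50%, 75%, and last occurrence of
    each group under each scheme (120 values).

    For a group occurring ``n`` times, the quantile anchors are the
    ceil(q * n)-th occurrences (1-based), divided by sequence length; a
    group with no occurrence contributes five zeros.
    """
    _check_schemes(schemes)
    length = len(record)
    out = np.zeros(120, dtype=float)
    for s, scheme in enumerate(schemes):
        groups = _group_indices(record, scheme)
        for g in range(3):
            positions = np.flatnonzero(groups == g) + 1  # 1-based
            n = len(positions)
            base = (s * 3 + g) * 5
            if n == 0:
                continue
            for a, q in enumerate((0.0, 0.25, 0.50, 0.75, 1.0)):
                occ = max(1, math.ceil(q * n))
                out[base + a] = positions[occ - 1] / length
    return out


def transition_groups(
    record: ProteinRecord, schemes: Sequence[GroupingScheme]
) -> np.ndarray:
    """Frequencies of adjacent residue pairs crossing between group pairs
    (1,2), (1,3), (2,3), direction-insensitive, normalized by L - 1
    (24 values)."""
    _check_schemes(schemes)
    length = len(record)
    if length < 2:
        raise SequenceTooShortError(
            f"transitions undefined for length-1 sequence {record.id!r}"
        )
    out = np.empty(24, dtype=float)
    for s, scheme in enumerate(schemes):
        groups = _group_indices(record, scheme)
        left, right = groups[:-1], groups[1:]
        for p, (a, b) in enumerate(_PAIRS):
            crossings = np.count_nonzero(
                ((left == a) & (right == b)) | ((left == b) & (right == a))
            )
            out[3 * s + p] = crossings / (length - 1)
    return out


def feature_names(schemes: Sequence[GroupingScheme]) -> tuple[str, ...]:
    """Stable names for the 188 features, block by block."""
    _check_schemes(schemes)
    names = [f"ctd.aac.{aa}" for aa in ALPHABET]
    names += [f"ctd.comp.{s.property_name}.g{g + 1}" for s in schemes for g in range(3)]
    names += [
        f"ctd.dist.{s.property_name}.g{g + 1}.{anchor}"
        for s in schemes
        for g in range(3)
        for anchor in _ANCHORS
    ]
    names += [
        f"ctd.trans.{s.property_name}.g{a + 1}g{b + 1}"
        for s in schemes
        for (a, b) in _PAIRS
    ]
    return tuple(names)


def extract_188d(
    record: ProteinRecord, schemes: Sequence[GroupingScheme] | None = None
) -> Descriptor188:
    """Compute the full 188-feature descriptor for one sequence (L >= 2)."""
    if schemes is None:
        schemes = builtin_groupings()
    _check_schemes(schemes)
    values = np.concatenate(
        [
            composition_aa(record),
            composition_groups(record, schemes),
            distribution_groups(record, schemes),
            transition_groups(record, schemes),
        ]
    )
    return Descriptor188(values, feature_names(schemes))
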