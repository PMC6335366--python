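"""Kmer, auto-cross covariance (ACC), and parallel-correlation pseudo
amino acid composition (PC-PseAAC) encoders.

All three map a variable-length protein sequence to a fixed-length vector:

* **kmer** — frequencies of all 20^k length-k windows (count divided by the
  number of windows, L - k + 1).
* **ACC** — lagged covariances of standardized physicochemical property
  profiles.  AC terms correlate one property with itself at gap g; CC terms
  correlate an ordered pair of distinct properties.  With N properties and
  maximum gap lg the vector has N*lg + N*(N-1)*lg entries.
* **PC-PseAAC** — 20 composition features plus lambda sequence-order
  correlation factors theta_k, where theta_k is the average over all
  gap-k residue pairs of the mean squared standardized property
  difference.  Two output conventions are supported: the classical
  weighted normalization x_u = f_u / (sum f + w * sum theta) (all 20+lambda
  entries then sum to 1) and a literal mode with raw frequencies and
  unweighted theta values.
"""

from __future__ import annotations

import dataclasses
from enum import Enum
from itertools import product
from typing import Sequence

import numpy as np

from .errors import ConfigError, SequenceTooShortError, ValidationError
from .property_tables import NormalizedIndex, builtin_normalized_indices
from .sequence_io import ALPHABET, ProteinRecord

_KMER_CEILING = 3


@dataclasses.dataclass(frozen=True)
class KmerParams:
    """Window length k for the kmer encoder (default 2 → 400 features)."""

    k: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.k <= _KMER_CEILING:
            raise ConfigError(f"k must be in [1, {_KMER_CEILING}], got {self.k}")


@dataclasses.dataclass(frozen=True)
class ACCParams:
    """Properties and maximum gap for ACC (defaults: 3 builtin properties, lg=2)."""

    indices: tuple[NormalizedIndex, ...] = ()
    lg: int = 2

    def __post_init__(self) -> None:
        indices = tuple(self.indices) or tuple(builtin_normalized_indices())
        if len(indices) < 2:
            raise ConfigError("ACC needs at least 2 properties for cross terms")
        if self.lg < 1:
            raise ConfigError(f"lg must be >= 1, got {self.lg}")
        object.__setattr__(self, "indices", indices)

    @property
    def dimension(self) -> int:
        n = len(self.indices)
        return n * self.lg + n * (n - 1) * self.lg


class PseAACMode(str, Enum):
    #: Classical weighted normalization; the 20+lambda entries sum to 1.
    CHOU_NORMALIZED = "chou_normalized"
    #: Raw amino-acid frequencies followed by unweighted theta values.
    LITERAL_FREQUENCY = "literal_frequency"


@dataclasses.dataclass(frozen=True)
class PseAACParams:
    """Properties, sequence-order depth lambda, and weight w for PC-PseAAC."""

    indices: tuple[NormalizedIndex, ...] = ()
    lam: int = 2
    weight: float = 0.05
    mode: PseAACMode = PseAACMode.CHOU_NORMALIZED

    def __post_init__(self) -> None:
        indices = tuple(self.indices) or tuple(builtin_normalized_indices())
        if not indices:
            raise ConfigError("PC-PseAAC needs at least 1 property")
        if self.lam < 1:
            raise ConfigError(f"lambda must be >= 1, got {self.lam}")
        if self.weight <= 0:
            raise ConfigError(f"weight must be > 0, got {self.weight}")
        object.__setattr__(self, "indices", indices)
        object.__setattr__(self, "mode", PseAACMode(self.mode))

    @property
    def dimension(self) -> int:
        return 20 + self.lam


def kmer_names(k: int) -> tuple[str, ...]:
    return tuple("kmer." + "".join(w) for w in product(ALPHABET, repeat=k))


def extract_kmer(record: ProteinRecord, params: KmerParams = KmerParams()) -> np.ndarray:
    """Frequencies of all 20^k words in lexicographic order; sums to 1."""
    seq = record.residues
    length = len(seq)
    if length < params.k:
        raise SequenceTooShortError(
            f"sequence {record.id!r} of length {length} is shorter than k={params.k}"
        )
    k = params.k
    index = {aa: i for i, aa in enumerate(ALPHABET)}
    counts = np.zeros(20**k, dtype=float)
    code = 0
    for j, aa in enumerate(seq):
        code = (code * 20 + index[aa]) % (20**k)
        if j >= k - 1:
            counts[code] += 1
    return counts / (length - k + 1)


def _profile(record: ProteinRecord, index: NormalizedIndex) -> np.ndarray:
    return np.array([index.scores[aa] for aa in record.residues], dtype=float)


def ac_value(record: ProteinRecord, index: NormalizedIndex, gap: int) -> float:
    """Auto covariance of one property at the given gap.

    AC(i, g) = (1 / (L - g)) * sum_{j=1..L-g} (S_{i,j} - Sbar_i)(S_{i,j+g} - Sbar_i),
    where S_{i,j} is the standardized score of residue j and Sbar_i the mean
    score over the whole sequence.
    """
    length = len(record)
    if length <= gap:
        raise SequenceTooShortError(
            f"sequence {record.id!r} of length {length} cannot support gap {gap}"
        )
    s = _profile(record, index)
    if np.ptp(s) == 0.0:  # constant profile: deviations are exactly zero
        return 0.0
    d = s - s.mean()
    return float(d[:-gap] @ d[gap:]) / (length - gap)


def cc_value(
    record: ProteinRecord,
    index1: NormalizedIndex,
    index2: NormalizedIndex,
    gap: int,
) -> float:
    """Cross covariance of an ordered pair of distinct properties at the
    given gap; each property is centered on its own sequence mean."""
    if index1.name == index2.name:
        raise ValidationError("cc_value requires two distinct properties; use ac_value")
    length = len(record)
    if length <= gap:
        raise SequenceTooShortError(
            f"sequence {record.id!r} of length {length} cannot support gap {gap}"
        )
    s1 = _profile(record, index1)
    s2 = _profile(record, index2)
    if np.ptp(s1) == 0.0 or np.ptp(s2) == 0.0:
        return 0.0
    d1 = s1 - s1.mean()
    d2 = s2 - s2.mean()
    return float(d1[:-gap] @ d2[gap:]) / (length - gap)


def acc_names(params: ACCParams) -> tuple[str, ...]:
    names = [
        f"acc.ac.{idx.name}.{gap}"
        for idx in params.indices
        for gap in range(1, params.lg + 1)
    ]
    names += [
        f"acc.cc.{i1.name}.{i2.name}.{gap}"
        for i1 in params.indices
        for i2 in params.indices
        if i1.name != i2.name
        for gap in range(1, params.lg + 1)
    ]
    return tuple(names)


def extract_acc(record: ProteinRecord, params: ACCParams = ACCParams()) -> np.ndarray:
    """The full ACC vector: AC terms (property-major, gap-minor) followed by
    CC terms (ordered-pair-major, gap-minor).  Defaults give 3*2 + 3*2*2 = 18
    features."""
    values = [
        ac_value(record, idx, gap)
        for idx in params.indices
        for gap in range(1, params.lg + 1)
    ]
    values += [
        cc_value(record, i1, i2, gap)
        for i1 in params.indices
        for i2 in params.indices
        if i1.name != i2.name
        for gap in range(1, params.lg + 1)
    ]
    return np.array(values, dtype=float)


def theta_k(
    record: ProteinRecord, indices: Sequence[NormalizedIndex], k: int
) -> float:
    """Sequence-order correlation factor at gap k.

    theta_k = (1 / (L - k)) * sum_{i=1..L-k} Theta(A_i, A_{i+k}) with
    Theta(a, b) = (1 / T) * sum_j (I_j(a) - I_j(b))^2 over the T properties;
    always >= 0 and invariant under sequence reversal.
    """
    length = len(record)
    if length <= k:
        raise SequenceTooShortError(
            f"sequence {record.id!r} of length {length} cannot support gap {k}"
        )
    profiles = np.stack([_profile(record, idx) for idx in indices])
    diff = profiles[:, :-k] - profiles[:, k:]
    return float(np.mean(diff**2, axis=0).sum()) / (length - k)


def pseaac_names(params: PseAACParams) -> tuple[str, ...]:
    return tuple(
        [f"pse.aa.{aa}" for aa in ALPHABET]
        + [f"pse.theta.{k}" for k in range(1, params.lam + 1)]
    )


def extract_pc_pseaac(
    record: ProteinRecord, params: PseAACParams = PseAACParams()
) -> np.ndarray:
    """The 20+lambda PC-PseAAC vector (defaults: lambda=2 → 22 features)."""
    length = len(record)
    if length <= params.lam:
        raise SequenceTooShortError(
            f"sequence {record.id!r} of length {length} cannot support lambda={params.lam}"
        )
    freqs = np.array([record.residues.count(aa) for aa in ALPHABET], dtype=float) / length
    thetas = np.array(
        [theta_k(record, params.indices, k) for k in range(1, params.lam + 1)]
    )
    if params.mode is PseAACMode.LITERAL_FREQUENCY:
        return np.concatenate([freqs, thetas])
    denom = freqs.sum() + params.weight * thetas.sum()
    return np.concatenate([freqs, params.weight * thetas]) / denom
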