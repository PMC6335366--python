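"""Balanced-run dataset construction and synthetic PPR-like data.

The study design this module implements: a small positive class (PPR
proteins, 196-1,863 residues, built from tandem degenerate 35-amino-acid
repeat motifs) faces a ~20x larger negative pool with a far wider length
range.  To keep the length distribution of sampled negatives representative,
the pool is split at its length quartiles and each balanced run draws
negatives from the four bins in proportion to bin size (largest-remainder
apportionment), pairing them with the full positive set.  Ten such runs,
each independently seeded, are evaluated and averaged.

The synthetic generator emulates that data shape: positives embed a block of
tandem, independently point-mutated copies of a dataset-level 35-residue
consensus motif inside background sequence; negatives are pure background.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ConfigError, ValidationError
from .sequence_io import ALPHABET, ProteinRecord

#: Average amino-acid frequencies of well-characterized proteins
#: (Swiss-Prot composition statistics), alphabetical order; renormalized.
BACKGROUND_FREQUENCIES: np.ndarray = np.array(
    [
        0.0825, 0.0138, 0.0545, 0.0675, 0.0386, 0.0707, 0.0227, 0.0596,
        0.0584, 0.0966, 0.0242, 0.0406, 0.0470, 0.0393, 0.0553, 0.0656,
        0.0534, 0.0687, 0.0108, 0.0292,
    ]
)
BACKGROUND_FREQUENCIES = BACKGROUND_FREQUENCIES / BACKGROUND_FREQUENCIES.sum()


@dataclasses.dataclass(frozen=True)
class LengthStrata:
    """The negative pool split into 4 bins at its length quartiles."""

    boundaries: tuple[int, int, int]
    bins: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...], tuple[str, ...]]

    @property
    def pool_size(self) -> int:
        return sum(len(b) for b in self.bins)


@dataclasses.dataclass(frozen=True)
class BalancedRun:
    """One balanced dataset: all positives plus an equal-size negative sample."""

    run_index: int
    positive_ids: tuple[str, ...]
    negative_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.negative_ids) != len(self.positive_ids):
            raise ValidationError("balanced run must pair equal-size classes")
        if len(set(self.negative_ids)) != len(self.negative_ids):
            raise ValidationError("sampled negative ids must be unique")


def length_quartiles(negatives: Sequence[ProteinRecord]) -> LengthStrata:
    """Split records into 4 bins at the nearest-rank 25/50/75 length
    percentiles; every record lands in exactly one bin."""
    if len(negatives) < 4:
        raise ValidationError(f"need at least 4 records to stratify, got {len(negatives)}")
    lengths = sorted(len(r) for r in negatives)
    n = len(lengths)
    bounds = tuple(lengths[math.ceil(q * n) - 1] for q in (0.25, 0.50, 0.75))
    bins: list[list[str]] = [[], [], [], []]
    for record in negatives:
        length = len(record)
        if length <= bounds[0]:
            bins[0].append(record.id)
        elif length <= bounds[1]:
            bins[1].append(record.id)
        elif length <= bounds[2]:
            bins[2].append(record.id)
        else:
            bins[3].append(record.id)
    if any(not b for b in bins[1:]) and bounds[0] == bounds[2]:
        warnings.warn("degenerate length distribution: all records in one bin",
                      stacklevel=2)
    return LengthStrata(bounds, tuple(tuple(b) for b in bins))


def largest_remainder_quotas(sizes: Sequence[int], total: int) -> list[int]:
    """Apportion ``total`` across bins proportionally to ``sizes`` by the
    largest-remainder rule; quotas sum exactly to ``total`` and each quota
    is within 1 of its exact proportional share (before capacity capping)."""
    pool = sum(sizes)
    if total > pool:
        raise ValidationError(f"cannot draw {total} from a pool of {pool}")
    shares = [total * s / pool for s in sizes]
    quotas = [math.floor(sh) for sh in shares]
    remainders = sorted(
        range(len(sizes)), key=lambda i: (shares[i] - quotas[i], -i), reverse=True
    )
    for i in remainders[: total - sum(quotas)]:
        quotas[i] += 1
    # cap at bin capacity; push any excess into bins with headroom
    excess = 0
    for i, s in enumerate(sizes):
        if quotas[i] > s:
            excess += quotas[i] - s
            quotas[i] = s
    while excess > 0:
        for i, s in enumerate(sizes):
            if excess and quotas[i] < s:
                quotas[i] += 1
                excess -= 1
    return quotas


def proportional_sample(strata: LengthStrata, total: int, seed: int) -> list[str]:
    """Draw ``total`` ids from the strata, each bin contributing its
    largest-remainder quota, uniformly without replacement within bins."""
    sizes = [len(b) for b in strata.bins]
    quotas = largest_remainder_quotas(sizes, total)
    rng = np.random.default_rng(seed)
    sample: list[str] = []
    for bin_ids, quota in zip(strata.bins, quotas):
        if quota:
            picks = rng.choice(len(bin_ids), size=quota, replace=False)
            sample.extend(bin_ids[i] for i in sorted(picks))
    return sample


def make_runs(
    positives: Sequence[ProteinRecord],
    negatives: Sequence[ProteinRecord],
    n_runs: int = 10,
    base_seed: int = 0,
) -> list[BalancedRun]:
    """Build ``n_runs`` balanced runs: each keeps all positives and draws an
    equal number of negatives by length-stratified proportional sampling
    with seed = base_seed + run_index."""
    if len(negatives) < len(positives):
        raise ValidationError("negative pool smaller than the positive set")
    strata = length_quartiles(negatives)
    positive_ids = tuple(r.id for r in positives)
    runs = []
    for run_index in range(1, n_runs + 1):
        seed = base_seed + run_index
        sample = proportional_sample(strata, len(positives), seed)
        runs.append(BalancedRun(run_index, positive_ids, tuple(sample), seed))
    return runs


def kfold_indices(
    n: int,
    k: int = 10,
    stratified: bool = False,
    seed: int | None = None,
    labels: Sequence[int] | None = None,
) -> list[np.ndarray]:
    """Shuffled k-fold test-index sets partitioning range(n); fold sizes
    differ by at most 1.  Stratified mode (requires ``labels``) preserves
    the class ratio per fold to within one instance."""
    if n < k:
        raise ValidationError(f"cannot split {n} instances into {k} folds")
    if stratified:
        if labels is None:
            raise ValidationError("stratified folds require labels")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n), np.asarray(labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    return [test for _, test in split]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Shape parameters of the synthetic PPR-like dataset.

    Defaults mirror the study's data: ~1:20 class imbalance, positives of
    196-1,863 residues carrying 5-20 tandem copies of a degenerate
    35-residue motif (each copy point-mutated at rate 0.2), negatives of
    background composition between 11 and 5,000 residues (the ceiling is
    kept below the real pool's extreme maximum and is configurable).
    """

    n_pos: int = 50
    n_neg: int = 1000
    motif_length: int = 35
    repeats_range: tuple[int, int] = (5, 20)
    mutation_rate: float = 0.2
    pos_length_range: tuple[int, int] = (196, 1863)
    neg_length_range: tuple[int, int] = (11, 5000)
    background_frequencies: tuple[float, ...] = tuple(BACKGROUND_FREQUENCIES)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("n_pos and n_neg must be positive")
        for lo, hi, what in (
            (*self.repeats_range, "repeats_range"),
            (*self.pos_length_range, "pos_length_range"),
            (*self.neg_length_range, "neg_length_range"),
        ):
            if lo > hi or lo < 1:
                raise ConfigError(f"{what} {lo, hi} is empty or non-positive")
        if not 0 <= self.mutation_rate < 1:
            raise ConfigError(f"mutation_rate must be in [0, 1), got {self.mutation_rate}")
        freqs = np.asarray(self.background_frequencies, dtype=float)
        if freqs.shape != (20,) or abs(freqs.sum() - 1.0) > 1e-9 or np.any(freqs < 0):
            raise ConfigError("background_frequencies must be 20 probabilities summing to 1")
        if self.motif_length * self.repeats_range[0] > self.pos_length_range[1]:
            raise ConfigError(
                "minimum repeat block exceeds the maximum positive length "
                f"({self.motif_length} x {self.repeats_range[0]} > {self.pos_length_range[1]})"
            )


def _background(rng: np.random.Generator, length: int, freqs: np.ndarray) -> str:
    letters = rng.choice(20, size=length, p=freqs)
    return "".join(ALPHABET[i] for i in letters)


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> str:
    if rate == 0.0:
        return motif
    out = list(motif)
    hits = np.flatnonzero(rng.random(len(motif)) < rate)
    for i in hits:
        choices = ALPHABET.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_dataset(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Generate (positives, negatives), fully reproducible from the seed.

    One 35-residue consensus motif is drawn per dataset.  Each positive
    embeds r tandem copies (r uniform in ``repeats_range``, capped so the
    block fits), every copy independently point-mutated at
    ``mutation_rate``, at a random offset inside a background sequence of
    length drawn from ``pos_length_range``; negatives are pure background.
    """
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.background_frequencies, dtype=float)
    consensus = _background(rng, config.motif_length, freqs)

    positives = []
    lo_r, hi_r = config.repeats_range
    lo_l, hi_l = config.pos_length_range
    for i in range(config.n_pos):
        r_cap = min(hi_r, hi_l // config.motif_length)
        r = int(rng.integers(lo_r, r_cap + 1))
        block = "".join(_mutate(rng, consensus, config.mutation_rate) for _ in range(r))
        length = int(rng.integers(max(lo_l, len(block)), hi_l + 1))
        offset = int(rng.integers(0, length - len(block) + 1))
        tail = length - len(block) - offset
        seq = _background(rng, offset, freqs) + block + _background(rng, tail, freqs)
        positives.append(ProteinRecord(f"pos_{i + 1:05d}", seq, "synthetic repeat protein"))

    negatives = []
    lo_n, hi_n = config.neg_length_range
    for i in range(config.n_neg):
        length = int(rng.integers(lo_n, hi_n + 1))
        negatives.append(
            ProteinRecord(f"neg_{i + 1:05d}", _background(rng, length, freqs),
                          "synthetic background protein")
        )
    return positives, negatives
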