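# Methods

## Problem setting

Pentatricopeptide-repeat (PPR) proteins consist of tandem arrays of a
degenerate 35-amino-acid helical motif. Given a curated set of positive
sequences and a much larger pool of non-PPR proteins, the task is binary
sequence classification from primary structure alone. The toolkit encodes
each sequence as a fixed-length feature vector, optionally fuses and
selects features, and evaluates standard classifiers under a resampling
protocol designed for a ~1:20 class imbalance.

Only the 20 canonical amino acids are admitted. Sequences containing
ambiguity codes or non-standard residues are dropped at ingestion (and
counted), keeping every encoder total over its input domain; a strict
error mode exists for pipelines that must not lose records.

## Encoders

**188D.** Four blocks in fixed order. (1) Amino-acid frequencies
count(a)/L, alphabetical. (2) For each of 8 physicochemical properties, the
alphabet is partitioned into 3 groups and the per-group residue fractions
recorded (24 features). (3) Distribution: for each property and group with
n occurrences, the 1-based positions of the 1st, ⌈0.25n⌉-th, ⌈0.50n⌉-th,
⌈0.75n⌉-th and n-th occurrence, divided by L (120 features). The ceiling
rule is the standard convention for these descriptors: it is monotone,
lands exactly on the first/last occurrence at the extremes, and needs no
interpolation. A group absent from the sequence contributes five zeros.
(4) Transition: frequencies of adjacent pairs crossing group pairs (1,2),
(1,3), (2,3), direction-insensitive — the three-pair reading is forced by
the 3×8 = 24 feature count — normalized by L−1 so the block is
length-independent like the others.

The 8 partitions (hydrophobicity, normalized van der Waals volume,
polarity, polarizability, charge, secondary-structure propensity, solvent
accessibility, surface tension) are the standard three-group divisions
from the composition/transition/distribution descriptor literature,
shipped as versioned plain-text data files; users can substitute their own
in the same format.

**kmer.** Frequencies of all 20^k windows, normalized by the window count
L−k+1 so the vector sums to 1. k is capped at 3 (20^4 = 160,000 columns
serves no purpose at these dataset sizes).

**ACC.** Property profiles are built from standardized amino-acid indices
(below). AC(i,g) = (1/(L−g)) Σ_{j≤L−g} (S_{i,j}−S̄_i)(S_{i,j+g}−S̄_i),
centered on the *sequence-specific* mean S̄_i; CC terms are the analogous
lagged cross-covariances for ordered pairs of distinct properties, as the
N(N−1)·lg dimension requires. The per-term prefactor is 1/(L−g): the sum
has L−g terms, and the number of properties cannot enter a per-property
average. Defaults: the three classical properties and lg = 2, giving 18
features.

**PC-PseAAC.** θ_k averages the mean squared standardized property
difference over all gap-k residue pairs; the default output applies the
classical weighted normalization x_u = f_u/(Σf + w·Σθ) with w = 0.05 (the
long-standing default of pseudo-amino-acid tooling), under which all 20+λ
entries sum to 1. A `literal_frequency` mode exposes raw frequencies and
unweighted θ values for users who want the unnormalized quantities.
Defaults: 3 properties, λ = 2 → 22 features.

## Property tables

Three indices ship with the package: hydrophobicity (Tanford-type transfer
free energies as tabulated in the classical pseudo-amino-acid literature),
Hopp–Woods hydrophilicity, and side-chain mass. Before use each index is
standardized over the 20 amino acids — subtract the mean, divide by the
*population* standard deviation (denominator 20) — which removes all
dependence on the published scale; consequently the exact choice of raw
scale affects nothing but the sign conventions of individual covariance
terms. Degenerate (all-equal) indices are rejected.

## MRMD feature selection

Relevance MRᵢ = |Pearson(featureᵢ, labels)| ∈ [0,1]. Redundancy is
penalized through distance: columns are min-max scaled to [0,1], MDᵢ is
the mean Euclidean distance from column i to every other column, and the
MD vector is divided by its maximum. The scaling choices matter: raw
Euclidean distances grow with instance count and feature scale, and an
unnormalized MD would dominate MR arbitrarily; after normalization the two
terms are commensurate and the combined score MRᵢ + MDᵢ is scale-invariant
(verified by property test). Constant columns receive MR = 0 with a
warning instead of an error, so real matrices with degenerate columns
survive end-to-end. Ranking is descending by score with stable ties.

Selection is always a rank prefix. `fixed_n` takes the top n. `auc_scan`
evaluates candidate prefix sizes by seeded stratified cross-validation of
an internal 50-tree random forest and keeps the size with the best mean
AUC, preferring the smaller size on ties. In the full pipeline the scan is
run on every balanced run and the single best-scanning subset is applied
to all runs, mirroring a select-once-apply-everywhere protocol.

## Imbalance protocol

The negative pool is split at its nearest-rank 25/50/75 length percentiles
into four bins (nearest-rank rather than interpolated percentiles: bin
membership must be integral). Each balanced run draws |positives|
negatives, apportioned across bins by the largest-remainder rule — the
standard apportionment that guarantees quotas summing exactly to the total
with each quota within one of its proportional share — and sampled
uniformly without replacement within bins. Runs are independently seeded
(seed = base + run index); overlap between runs' samples is allowed.
Default: 10 runs, all averaged.

## Evaluation

Folds are stratified and shuffled (fold sizes differ by ≤ 1; class ratio
preserved to within one instance). Classifiers are scikit-learn estimators
behind the `ClassifierSpec` contract: random forest (the primary
classifier), an entropy-criterion decision tree (an approximation of
C4.5-style trees — gain ratio and confidence pruning are not replicated),
and Gaussian naive Bayes. Continuous positive-class probabilities (vote
fractions for the forest) feed a rank-based (Mann–Whitney) AUC with ties
counted half; confusion counts use a fixed 0.5 threshold. F-measure is
(α²+1)PR/(α²P+R) with α = 1; because which class's F a WEKA-style toolkit
reports is convention-dependent, reports carry both the positive-class F1
and the support-weighted two-class variant. The public `f_measure` raises
on degenerate counts rather than silently returning 0; inside
cross-validation a fold that predicts no positives scores F = 0 (the
conventional limit) so one bad fold cannot abort a run. Cross-run
aggregation reports the mean and population SD of per-run means (SD 0 for
a single run).

## Synthetic data generator

The generator emulates the shape of the real study data, and its defaults
are the study conditions: positives of 196–1,863 residues containing 5–20
tandem copies of a dataset-level random 35-residue consensus, each copy
independently point-mutated at rate 0.2 (the repeats are degenerate, not
exact); negatives are i.i.d. background sequences of 11–5,000 residues.
The negative length ceiling is kept at 5,000 — far above the positive
range, low enough for desk-scale runs — and is configurable. Background
residue frequencies follow average Swiss-Prot composition. A ~1:20
imbalance (50 positives, 1,000 negatives) is the default dataset shape.

What the generator does *not* emulate: real PPR motifs have a conserved
helix-turn-helix structure and position-specific conservation patterns (a
profile HMM would be the faithful model); real negatives contain other
repeat families, low-complexity regions, and homology structure removed
here by construction. Passing signal-recovery tests therefore shows that
the pipeline detects compositional and autocorrelation signal injected by
tandem repeats — not that it reproduces published performance on curated
UniProt data, which is outside this package's scope.

## Numerical choices and degenerate inputs

* Standardization tolerance for property indices: 1e-9 on mean and SD.
* Homopolymer sequences: covariance and θ terms return exactly 0 (constant
  profiles short-circuit before floating-point cancellation can leave
  ~1e-32 residue).
* Duplicate-only matrices: all pairwise distances 0 → MD left at 0 (0/0
  guard).
* Sequences shorter than a gap/λ/k raise a too-short error naming both
  quantities; length-1 sequences have no transitions and raise.
* All seeds below 2^31; one master seed derives module seeds by SHA-256
  hashing of (seed, context tokens), so partial re-runs reproduce exactly.

## Problem sizes in the shipped checks

The test suite and the reproduction script run at desk scale, chosen as
the smallest sizes at which each claim is comfortably demonstrated:
dimension checks on 2+2 sequences; oracle-equivalence on 100–200 random
fixtures; signal recovery on a balanced 200+200 dataset; the balanced-run
protocol on 30 positives against a 300-negative pool (10 runs × 10 folds =
100 fold records).

## Known limitations

* The decision-tree backend is not a faithful C4.5; J48-style numbers will
  differ in the second decimal on small data.
* MRMD's distance normalization is one reasonable convention among
  several; rankings can differ from implementations that sum raw distances.
* The AUC scan inherits the variance of its internal cross-validation; on
  small matrices the chosen subset size can vary between seeds even though
  the informative features themselves are stably recovered.
* No profile-HMM or alignment-based features; the toolkit is deliberately
  sequence-composition-based.
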