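# Methods

## Problem and model

Biopanning output from the Ph.D.-7 phage display library mixes true target
binders with target-unrelated peptides. The propagation-related subset
(PrTUPs) rides on clones that amplify faster than average; their displayed
peptide sequences are the only observable this package uses. `prtup`
frames PrTUP detection as supervised binary classification of 7-mer
peptide sequences: positives are fast-growing clones, negatives
regular-growing clones, and the classifier is an RBF-kernel support vector
machine over a composition-based sequence encoding. The model therefore
assumes the displayed peptide carries a sequence signal correlated with
propagation speed; clones that propagate fast purely through regulatory
mutations elsewhere in the phage genome (a documented phenomenon — e.g.
the HAIYPRH clone's gene II 5′-UTR mutation) carry no such signal, and no
sequence-based classifier can detect them. The same holds for display
censorship effects; both are out of scope.

## Dataset construction

Peptides are validated against the 20 standard residues (records with
ambiguous residues such as X/B/Z are rejected or skipped). Redundancy is
removed with a greedy Hamming-distance filter: scanning in file order, a
peptide is kept iff its distance to every previously kept peptide exceeds
`h` (default 2, i.e. "within distance 2" is removed). The greedy
keep-first rule is a deliberate choice — the removal rule alone does not
determine *which* member of a close pair survives — and makes the filter
deterministic and idempotent, at the cost of order dependence. Filtering
defaults to per-class application; a joint mode exists
(`--joint-filter`) since the alternative reading is defensible. When
negatives outnumber positives they are subsampled without replacement
under a recorded seed, and class disjointness is enforced.

## Encoding

Each peptide becomes `8000 + nλ` features: tripeptide composition
(lexicographic index over the alphabetical residue order) plus PseAAC
sequence-order correlation factors from `n = 9` physicochemical property
profiles at gaps `1…λ`, ordered tier-major (all properties at gap 1, then
gap 2, …). The weighted normalization makes the vector sum to one.

**Property standardization.** Raw scales are centred on their 20-residue
mean and divided by the root of the **sum** of squared deviations (unit
Euclidean norm per property), not by the population SD. This is not
cosmetic: with z-scored properties the correlation sum `Στ` of an ordinary
7-mer reaches ≈ −3, so the normalizer `1 + wΣτ` becomes non-positive
within the `w ≤ 0.70` tuning grid and the encoding is undefined there.
With unit-norm scales `|Στ|` stays ≲ 0.15 and the normalizer is positive
across the entire grid (covered by a test). Because standardization is
affine-invariant, adding a constant to or rescaling a raw property scale
leaves the encoding unchanged.

**Property table provenance.** The nine scales ship in
`src/prtup/data/properties.tsv` with a source per row: Eisenberg consensus
hydrophobicity, Hopp–Woods hydrophilicity, side-chain mass, CRC
pK1/pK2/pI, Bhaskaran–Ponnuswamy flexibility, the Charton steric
parameter as a rigidity proxy, and — because no published numeric
irreplaceability scale could be pinned — a clearly labelled synthetic
stand-in (−log₂ synonymous-codon fraction under the standard genetic
code). The table is versioned, embedded into every model archive, and
swappable (`PropertyTable.from_tsv`); conclusions that depend on exact
property values should treat the default table as one reasonable pinning,
not ground truth.

## Feature selection

F-scores use the between/within-class variability ratio (the definition
of the widely used LIBSVM `fselect.py` tool; the per-class variances are
unbiased, n−1). A feature constant within both classes but different
between them has zero within-class variance and scores +∞, which sorts
first; identical class means score exactly 0. Ranking is a stable
descending sort (ties → ascending feature index). Incremental feature
selection evaluates nested prefixes of the ranking with seeded stratified
k-fold CV, reusing the same folds at every subset size (paired
comparison), and keeps the first accuracy maximum (parsimony under ties).
The canonical protocol is stride 1 over all 8,027 subsets; the `stride`
parameter gives a coarse curve for desk-scale runs — tests and the
acceptance script use strides of 10–25 on 120-sample synthetic datasets,
sizes at which the full scan is unnecessary to recover a planted signal.
SVM hyperparameters are held fixed during IFS and `(C, γ)` re-tuned on
the selected subset afterwards; a nested per-subset search would multiply
cost ~100-fold for little benefit at these sample sizes.

## Classifier and tuning

The SVM is scikit-learn's libsvm-backed `SVC` (RBF kernel) with sigmoid
probability calibration (`probability=True`, seeded — calibration uses
internal CV, so the seed is part of the model's provenance). The default
`(C, γ)` grid is the conventional log₂ grid `C = 2⁻⁵…2¹⁵`, `γ = 2⁻¹⁵…2³`,
exponent step 2 (11 × 10 = 110 points); ties break toward smaller C, then
smaller γ. The encoding parameters `(λ, w)` are tuned on the 84-point
grid `λ ∈ {1..6}`, `w ∈ {0.05..0.70}` by CV accuracy of the
full-feature-set model (no selection), matching the staging of the
original protocol. Classification thresholds the calibrated positive
probability at `tp` (default 0.5); a probability exactly equal to `tp` is
positive — a documented, testable convention.

## Evaluation

Sn, Sp, Acc and MCC are computed from the confusion matrix; MCC returns 0
when a denominator factor vanishes. Headline CV numbers are pooled over
the concatenated held-out predictions of all folds (per-fold metrics are
retained); folds are stratified and seeded. ROC points come from
threshold sweeping over unique scores, AUC by the trapezoidal rule —
equal to pair-counting concordance, which the tests verify exhaustively
on small instances. The permutation test shuffles labels uniformly,
re-runs the CV per shuffle and reports `p = (#shuffles with accuracy >
observed)/N`, displayed as `p < 1/N` when the count is 0 (a permutation p
cannot claim 0). The permutation reuses the already-selected feature
mask instead of redoing selection per shuffle; this is anti-conservative
in principle (the selection step's optimism is not re-simulated) but is
the computationally standard choice and mirrors the staged protocol.

## Synthetic data

The generator emulates the statistical shape of the benchmark: two
classes of 7-mers over the 20 residues. Negatives are i.i.d. from the
background (uniform by default; an NNK-codon background reproducing the
real library's residue bias is available but off by default, so that
tests exercise the cleanest null). Positives either match the background
(null), carry an enriched tripeptide motif inserted with probability
`min(1, effect_size)`, or are drawn from an exponentially tilted residue
distribution along chosen property profiles. Sequences colliding with a
negative are redrawn so class disjointness holds. What the generator does
**not** emulate: the NNK codon bias of real Ph.D.-7 data (unless enabled),
positional composition structure, the Hamming-clustered redundancy of
amplified libraries, and any linkage between sequence and phage genotype.
Passing tests on synthetic data therefore demonstrate that the pipeline
recovers planted composition signals and is calibrated under a clean
null — not that the shipped default model matches the published
benchmark's accuracy, which requires the original training FASTA files.

## Numerical choices and conventions

- Encoding normalizer ≤ 0 raises (possible only for exotic property
  tables or w outside the grid; impossible on the default table within
  the grid, by test).
- Feature-vector sum-to-one is asserted to 1e−9; standardization
  invariants to 1e−12.
- Infinite F-scores are propagated as `inf` sentinels, not clipped.
- Stratified folds differ by at most one sample per class; fold
  assignment, SVM calibration, subsampling and the permutation stream all
  derive from explicit integer seeds.
- Problem sizes in tests and the acceptance script (60+60 planted,
  100+100 null, 100 permutation shuffles, IFS stride 10–25, 4–5 folds)
  are desk-scale choices that keep the full suite under ~2 minutes while
  leaving every statistical conclusion comfortably powered.

## Known limitations

- The exact property scales behind the original nine-property encoding
  are not recoverable; metrics obtained with the shipped table on real
  data may differ from published values by a property-table-dependent
  margin.
- Sequence-blind PrTUPs (genomic-mutation propagators) are undetectable
  by construction.
- The model archive embeds a fitted scikit-learn estimator via joblib;
  archives are not guaranteed portable across major scikit-learn
  versions (the format version field guards against silent drift).
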