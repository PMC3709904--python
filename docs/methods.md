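# Methods

## Model and assumptions

`tfpartner` treats the functional classification of a TF's binding partner as
two cascaded binary problems over composition-averaged sequence features.

**Featurization.** For an amino-acid index $I$ (one value per standard
residue) and a sequence of length $L$, the feature is the arithmetic mean of
$I$ over all residues. This is a sufficient statistic of residue composition:
any permutation of the sequence yields the same vector, and multiplying an
index by a constant scales the feature by the same constant. The
representation assumes that bulk composition — not residue order, position,
or domain architecture — carries the class signal. A pair of interacting
proteins is the concatenation of the two per-protein vectors (TF first), so
the design matrix has width $2k$ for $k$ indices.

**Why dual sub-models.** The pair representation is ordered, but for TF–TF
instances the order is a curation artifact. Training a single forest on
TF-first rows would bake that artifact into the decision function. Instead
each task trains a forward sub-model (all rows TF-first) and a reverse
sub-model (TF–TF rows half-swapped; TF–TcoF and TF–other rows are genuinely
asymmetric and stay TF-first), and the reported confidence is the mean of the
two sub-model scores. This approximates order invariance; exact invariance is
available as the `strict_symmetric` scoring mode, which averages the four
scores obtained from both sub-models on both orderings. The four floats are
summed in sorted order, so the symmetry is bit-exact, not approximate.

**Classifier.** Random Forests (scikit-learn) behind a pluggable sub-model
surface. A forest's confidence score for a pair is the average positive-class
probability over its trees. Defaults: 100 trees, `sqrt` feature sampling
(≈ √(2k) candidates per split), unlimited depth, seeds 1 and 2 for the
forward/reverse sub-models. The defaults are standard Random Forest practice;
nothing in the method depends on them and all are configurable. No feature
scaling is applied: forests are invariant to monotone transformations of
individual features.

**Cascade.** MODEL1 scores TF-or-TcoF (positive) vs other. A pair scoring
below the threshold (default 0.5) is called OTHER with MODEL1's score; a pair
at or above it is forwarded to MODEL2, which scores TcoF (positive) vs TF.
A score exactly at the threshold is called positive — a deterministic
tie-break that must be fixed somewhere. Treating TcoF as MODEL2's positive
class is likewise a fixed reporting convention (sensitivity = TcoF recall);
it can be read in reverse for the TF class.

## Data handling

- **AAindex1 dialect.** Only the per-residue dialect is supported. `NA`
  values are handled before featurization by either dropping the affected
  index (default — a mean over undefined values is undefined) or imputing the
  index's mean over its defined residues. The reduced-feature configuration
  is expressed as a plain accession list file, not a hard-coded set.
- **Index-set signature.** A hash of the ordered accession list travels with
  every feature vector and model artifact; models refuse inputs built under a
  different index configuration. The NA policy is recorded in the
  featurization manifest rather than the signature, since imputation changes
  values but not the accession list.
- **Sequences.** FASTA via Biopython; UniProt `db|ACC|name` headers reduce to
  the accession. Nonstandard letters (B, Z, X, U, O, J) are tolerated at
  parse time; during averaging the default `skip` policy excludes them from
  both numerator and denominator (an `error` policy is available for strict
  pipelines). A sequence with no standard residues cannot be featurized.
- **Pair tables.** TSV with the known TF first. Exact duplicate rows collapse
  with a warning; the same pair under two labels is an error. Self-pairs
  (homodimeric TFs) are allowed.

## Evaluation

Stratified k-fold cross-validation retrains both sub-models in every fold;
per-protein featurization is label-free and computed once, so no information
leaks between folds. Fold assignment shuffles each class with a seeded,
class-indexed RNG stream and deals members round-robin with a rolling offset:
class proportions per fold are within ±1, global fold sizes are within ±1
(so leave-one-out works), and the assignment depends only on the pair
identities, labels and seed — never on input file order. Pairs are also
canonically sorted before training because Random Forest bootstrap sampling
is row-order sensitive. Rates (accuracy, sensitivity, specificity) are
computed from pooled confusion counts across folds (micro-averaging) using
exact rational arithmetic; a rate with a zero denominator is reported as
undefined rather than zero. Pooling rather than fold-averaging was chosen
because it is deterministic and denominator-safe on small folds. Stratified
percentage splits (e.g. 2/3–1/3, 90/10) use per-class largest-remainder
rounding so the realized train size equals round(n·fraction).

## Synthetic data generator

The generator emulates a curated TF-interaction training set: labeled pairs
of three kinds (TF–TcoF, TF–TF, TF–other) whose partner classes differ only
in residue composition. Each role's residue-frequency profile is a mixture
`(1−δ)·base + δ·extreme` of a shared near-uniform base profile
(Dirichlet(50·**1**)) and a role-specific random extreme profile
(Dirichlet(**1**)), so the pairwise total-variation distance between role
profiles grows linearly in the separation δ, and δ = 0 is an exact null.
Individual proteins draw their own profile from Dirichlet(c·role profile)
— the concentration c models within-class compositional heterogeneity — and
residues i.i.d. from it; lengths are uniform on a range. The fixture
amino-acid indices are random values in [−5, 5] (3 decimals, so flat-file
round-trips are exact) rather than copies of database content.

Reference configuration (the generator defaults): 200 pairs per class
(600 total), δ = 0.5, concentration 100 (tight within-class scatter —
"well-separated"), lengths 50–200, 40 indices, seed 42. The choices code for
a regime in which composition clearly separates the classes, mirroring the
performance regime reported for the method on curated human data; the null
configuration (δ = 0) differs only in separation.

What the generator does **not** emulate: interaction-network topology (hub
TFs appearing in many pairs — instances here are exchangeable by design, which
is what makes plain CV valid), sequence evolution and phylogenetic
correlation, domain structure, and class-dependent length distributions.
Passing the planted-signal tests therefore shows the pipeline recovers
compositional signal when present and invents none when absent; it does not
certify the accuracy figures achievable on real curated data.

## Numerical choices

- Confidence scores combine by exact arithmetic means; the strict-symmetric
  mean sorts the four addends before `fsum`, making argument-swap symmetry
  exact.
- Threshold 0.5, ties positive; both configurable per call.
- Model archives embed a 20-row probe matrix with the model's own scores;
  loading recomputes and requires bit-identical agreement, so a corrupt or
  library-incompatible artifact fails loudly instead of predicting quietly.
- Problem sizes in the test suite: the end-to-end checks run the full
  600-pair reference configuration at 10-fold CV; the δ-monotonicity sweep
  (4 separations × 3 generator seeds × 2 tasks) uses 5-fold CV, which halves
  training cost without affecting the monotonicity property being checked.

## Known limitations

- Composition averaging discards all positional and structural information by
  construction; two proteins with identical composition are indistinguishable.
- The prediction-time convention in `dual_average` scoring mode feeds the pair as
  given (TF first) to both sub-models; only `strict_symmetric` guarantees
  exact order invariance.
- Class-probability scores are uncalibrated ensemble vote fractions; the
  0.5 threshold is a convention, not an optimized operating point.
- No redundancy reduction (sequence clustering) is applied; with real data,
  homologous pairs on both sides of a CV split would inflate estimates.
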