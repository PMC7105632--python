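# Methods

## Problem and model

`phagehydro` predicts whether a phage protein is an enzyme, and if so
whether it is a hydrolase, from primary sequence alone. The model is a
cascade of two independent binary classifiers. Stage 1 (enzyme vs
non-enzyme) and stage 2 (hydrolase vs other enzyme) are trained on their
own labelled sets; the cascade is composed only at prediction time, where
stage 2 is applied exclusively to stage-1 positives. This mirrors the
experimental design the benchmark datasets encode: the hydrolase-labelled
set is a relabelling of the enzyme class, not an independent sample.

The underlying assumption is that enzymatic function leaves compositional
and short-to-medium-range correlational signatures in the sequence that
survive the loss of detectable homology. No alignment, structure or
annotation is used.

## Sequence descriptors

All encoders require the 20 standard amino acids; records with other
characters are rejected at parse time (or skipped with `drop_invalid`).
Feature names are deterministic and carry their block prefix, so selected
subsets persist as plain-text name lists.

**GGDC** (400-D). For gap `g` (default 2), entry (a, b) is the count of
positions i with residues a at i and b at i+g+1, divided by the number of
gap pairs `L − g − 1`; the block sums to 1. Requires `L ≥ g + 2`.

**PseAAC** (150-D). For lag j = 1..λ (default 15) and each of 10 property
scales, `τ(j,p)` is the sequence average of `h_p(s_k) · h_p(s_{k+j})`,
where `h_p` is the scale z-scored to mean 0 / unit variance over the 20
residues. The product-correlation form is the default; a squared-difference
form (`correlation="squared-diff"`) is available because the correlation
function is a genuinely open choice in this descriptor family. The 20
plain composition terms are deliberately excluded (composition is covered
by the CTD block), giving exactly λ × 10 features and the block totals
400+150 = 550 and 714 that the two schemes rely on. Requires `L ≥ λ + 1`.

The 10 scales (hydrophobicity, hydrophilicity, side-chain mass, pK1, pK2,
isoelectric point, rigidity, flexibility, irreplaceability, polarity) ship
as an auditable TSV (`data/property_scales.tsv`) populated from standard
published sources documented in its header: Kyte–Doolittle hydropathy,
Hopp–Woods hydrophilicity, residue side-chain masses, CRC dissociation
constants and pI values, the Charton steric parameter (as the rigidity
scale), the Bhaskaran–Ponnuswamy flexibility index, a sign-inverted
Dayhoff relative mutability (as irreplaceability — the least replaceable
residues are the least mutable), and Grantham polarity. Every correctness
test is invariant to the specific numbers; swapping the TSV re-defines the
encoder without code changes.

**GTPC** (125-D). Residues map into 5 classes (aliphatic GAVLMI, aromatic
FYW, positive KRH, negative DE, uncharged STCPNQ); entry (r, s, t) is the
count of overlapping tripeptides with that class triple divided by the
tripeptide count `L − 2`, so the block sums to 1. A `denominator="n-1"`
switch reproduces pipelines that normalize by `L − 1` instead (such a
vector sums to `(L−2)/(L−1)`, not 1, which is why the tripeptide count is
the default here). Requires `L ≥ 3`.

**CTDC** (39-D). Thirteen groupings (seven hydrophobicity scales, van der
Waals volume, polarity, polarizability, charge, secondary structure,
solvent accessibility), each partitioning the residues into 3 classes,
shipped as `data/ctd_groupings.tsv` following the iFeature toolkit's
partitions; entries are class fractions `N_r / L`, so each triple sums to
1 and the block to 13. Transition and distribution descriptors are out of
scope — composition only.

## Feature selection

Each feature's one-way ANOVA F-value is the between-class mean square
(1 df) over the within-class mean square (n − 2 df) for the two label
groups. Conventions: a feature constant everywhere scores 0; identical
class means score 0 regardless of spread; zero within-class variance with
distinct means is a perfect separator and scores +∞, ordering before all
finite values. Ties keep original column order, so the ranking is
deterministic. F is invariant under affine rescaling of a feature, which
is property-tested.

Incremental feature selection evaluates a classifier by cross-validation
on growing prefixes of the F-ranked list (every size 1..D by default; a
stride, or an explicit size grid, for 714-D sweeps) and returns the full
accuracy-vs-size curve plus the smallest size achieving the maximum.
Hyperparameters are searched once on the full feature set and reused
across subset sizes; a per-size re-search would nest a grid search inside
every prefix evaluation at prohibitive and hard-to-justify cost.

## Classification and evaluation

The primary classifier is an RBF-kernel SVM (scikit-learn SVC). SVM, KNN
and MLP inputs are min–max scaled to [0, 1] with statistics from the
training fold only (a Pipeline step, so cross-validation cannot leak);
random forests take raw features. Defaults, as documented configuration
rather than literature claims: SVM C = 8 and γ = sklearn's `"scale"`;
KNN k = 5; RF 200 trees; MLP one hidden layer of 100 units, 500
iterations; stochastic kinds take an explicit seed that the reports
record. The C = 8 default matters: at n ≈ 60 a heavily regularized SVM
degenerates under leave-one-out into voting for the training majority,
which on exchangeable balanced data is systematically the held-out
sample's *opposite* class (accuracy far below chance); a larger C restores
chance-level null behaviour without affecting separable problems.

Grid search maximizes cross-validated accuracy over log₂-spaced grids
(C ∈ 2⁻⁵..2¹⁵, γ ∈ 2⁻¹⁵..2³, steps of 2²); ties go to the smallest C,
then the smallest γ, favouring the smoother model deterministically.

The jackknife test trains n models, each leaving one sample out, and
pools the held-out predictions into a single confusion matrix. Metrics
are the standard Sn = TP/(TP+FN), Sp = TN/(TN+FP), Ac = (TP+TN)/n, and
MCC = (TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)) with MCC ≡ 0 when a
denominator factor vanishes; MCC equals the Pearson correlation of the
predicted and true label vectors, which the tests verify on random
confusion matrices. AUC is the rank statistic over per-sample decision
scores (signed margin for SVM, positive-class probability otherwise),
ties counting one half.

## Cascade training and persistence

Per stage: encode with the stage's scheme → optional grid search → ANOVA
ranking → IFS (or a pinned subset size that bypasses the sweep) → final
fit on all stage data restricted to the selected features. Models persist
as a directory of human-auditable text (config JSON, feature-name list,
per-feature scaling min/max TSV) plus the fitted estimator via joblib;
loading re-asserts that each stage's features lie inside its scheme's
name universe, so a tampered feature list fails fast. Calls are hard
thresholds at the classifier's native decision boundary; no probability
calibration is applied between stages, as there is no principled
threshold to calibrate against without a validation set.

## Synthetic data

The generator emulates two-class protein sets with controllable,
channel-targeted class separation. Sequences are emitted left to right
from a background residue model (uniform by default; a Swiss-Prot-like
frequency option exists so tests cannot silently depend on the
background). For positives, each emission step produces, with probability
`effect_size`, one planted motif — a g-gap residue pair, a tripeptide over
the 5 GTPC classes, or a residue from a chosen CTD class — and otherwise
one background residue; the motif target is drawn uniformly from the
configured list. `effect_size = 0` makes the classes exchangeable by
construction. Everything derives from a single integer seed; identical
seeds give byte-identical FASTA.

Default study conditions: 60 samples per class, lengths 50–150 (minimum
17, the λ = 15 PseAAC precondition), effect size 0.3, planted 2-gap A··A
pair. These sizes keep a full jackknife SVM evaluation under a second
while leaving enough samples for stable leave-one-out estimates.
`generate_cascade_datasets` builds the nested two-stage design: enzymes
carry the A··A motif, hydrolases additionally a K··E motif (emitted at
combined rate so each motif appears at its stage's rate when the two
rates are equal), and the stage-2 set is exactly the enzyme class
relabelled — so the two stages separate on different feature channels and
a hydrolase-like query is in-distribution for both.

What the generator does **not** emulate: homology structure between
samples, realistic phage proteome composition, domain architecture, or
length–class correlation. Passing recovery tests therefore shows that the
pipeline detects and selects the kind of compositional/correlational
signal it was designed for at realistic sample sizes — not that real
phage enzymes are separable at any particular accuracy. The published
benchmark of 255 curated phage proteins is an optional external
validation, not bundled here.

## Numerical choices and edge cases

- Encoders raise a length error naming the record when a sequence is too
  short; dataset-level encoding aggregates all failing ids into one error
  (prediction instead records a per-sample error entry and proceeds).
- IFS optima and grid-search winners break ties toward the smallest
  size / smallest (C, γ), making every reported optimum deterministic.
- Feature tables round-trip exactly: values are written with pandas'
  shortest-repr float formatting and parsed with `float_precision=
  "round_trip"`.
- Leave-one-out folds are checked for single-class training splits and
  fail with the fold index (reachable at very small n or extreme
  imbalance).

## Known limitations

- The exact published values behind the original predictor's 10 property
  scales are not identifiable; different but equally standard scales give
  a numerically different (not necessarily worse) PseAAC block, so
  external-benchmark accuracies are not expected to replicate digit for
  digit.
- Jackknife evaluation is O(n) model fits per configuration; IFS over all
  714 prefix sizes at n in the hundreds is minutes of compute. Use the
  stride/k-fold options for exploration.
- Stage-2 training sees only curated enzyme labels; prediction-time
  composition with an imperfect stage 1 means stage-2 operating
  characteristics on raw queries differ from its jackknife estimates.
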