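# Methods

This note records the modeling choices, defaults, and numerical conventions
behind `rnaiface`, and what its synthetic benchmarks do and do not
demonstrate.

## Interface definition and structure handling

A protein residue is an interface residue iff the minimum Euclidean distance
between any of its atoms and any atom of any RNA chain in the same complex
is **≤ 5.0 Å**. The comparison is inclusive at the boundary: distances of
exactly 5.0 Å count as interface, a convention fixed for determinism.
All recorded atoms participate, including hydrogens when present —
restricting to heavy atoms is a defensible alternative, but the all-atom
rule is simpler and the 5 Å cutoff was historically applied to deposited
coordinates as-is. Ions, ligands and waters never participate. The distance
scan uses a KD-tree over RNA atoms; tests verify exact agreement with an
all-pairs double loop.

Parsing policies: the first alternate location of each atom is kept;
residues are ordered by author sequence order; nonstandard amino acids map
to `X` but keep their position, so sequence, label string and structure
stay aligned (an `X` row receives the neutral all-zero profile row
downstream). Only standard ribonucleotides (A/C/G/U) populate RNA chains.

Dataset admission (applied per protein chain): resolution strictly below
3.5 Å (missing resolution rejects the chain with its own reason code),
chain length ≥ 40, at least one RNA chain of ≥ 5 nucleotides in the
complex, and ≥ 3 interface residues. Each rejected chain is tallied under
the first criterion it fails, in that order. The 30 % redundancy criterion
is served by a deliberately simple greedy filter — longest-first, keep iff
global-alignment identity (BLOSUM62, gap open −10, extend −0.5; identity =
matches / alignment length) to every kept sequence is ≤ 0.30. It is
plumbing, not a clustering-tool replacement, and is documented as such.

## Profiles and distances

PSI-BLAST runs 3 iterations at e-value 0.001 (used both for reporting and
profile inclusion), returning the final-iteration ASCII PSSM; the final
iteration's hit count is recorded. When the binary is unavailable, or a
search returns no hits, the *pseudo-profile* supplies the BLOSUM62 score
row of each residue in the canonical 20-column order — exactly the backing
PSI-BLAST itself uses in the no-hit case — keeping the downstream pipeline
runnable and testable offline.

Normalization is the elementwise logistic f(x) = 1/(1+e⁻ˣ), mapping raw
log-odds into (0,1) with f(0) = 0.5 as the no-information point.

Profile distances operate on normalized profiles only (enforced by type):

* NSSD(P₁,P₂) = (1/(20·L)) Σᵢ Σⱼ (P₁(i,j) − P₂(i,j))², bounded by 1 on
  (0,1)-valued entries;
* NKL(P₁,P₂) = (1/(2·20·L)) Σᵢ Σⱼ [P₁ log(P₁/P₂) + P₂ log(P₂/P₁)].

NKL uses **natural logarithms** and is applied entrywise to the logistic
values without row renormalization — the symmetrized-KL form is evaluated
verbatim on positive entries rather than on per-row probability
distributions. Entries must be strictly positive, which the logistic
guarantees; raw log-odds are rejected. Both distances are symmetric,
non-negative, and zero exactly on identical inputs.

## Window encoding

Each residue is the centre of a 25-residue window (12 neighbours per side);
the window's normalized 20-value rows concatenate to 500 features. Window
positions beyond either terminus contribute the pad value 0.5 in all 20
slots — the logistic image of a raw score of 0, i.e. "no information".
Terminus handling is not dictated by the published pipeline description;
0.5 is this package's declared default and is configurable. No class
rebalancing is applied at encoding time.

## Classifiers

* **NB** — Gaussian naive Bayes (features are continuous in (0,1); the
  event model is this package's choice).
* **RF100** — random forest, 100 trees.
* **SVML / SVMRBF** — support vector machines with C = 1.0 and, for the RBF
  kernel, γ = 1/n_features; probability outputs come from sigmoid (Platt)
  calibration fitted on internal cross-validated decision values. C and γ
  are not prescribed by the source pipeline and are configurable.
* **CONSENSUS** — the elementwise arithmetic mean of the SVMRBF and RF100
  interface probabilities. The consensus always lies between its members.

Thresholding: label 1 iff p ≥ threshold (default 0.5; ties positive). No
feature scaling beyond the logistic normalization. All fits are
reproducible given data and seed; model files embed a format-version header
and the hyperparameter spec.

## Evaluation

ACC = (TP+TN)/N, Sn = TP/(TP+FN), Sp = TN/(TN+FP),
MCC = (TP·TN − FP·FN)/√((TN+FN)(TN+FP)(TP+FN)(TP+FP)). Degenerate cases: a
zero MCC denominator yields MCC = 0; a zero Sn/Sp denominator yields NaN,
excluded from averages. AUC is the rank-sum probability with half-credit
ties, equal to the trapezoidal area under the ROC curve; tests verify
agreement with exhaustive pair enumeration.

Cross-validation is **chain-level**: whole chains are assigned to folds, so
train and test never share a chain. Folds balance residue counts (not chain
counts) by greedy longest-first placement into the lightest fold after a
seeded shuffle. Both per-fold and pooled (concatenated-prediction) reports
are emitted; the pooled report is the headline, since it weighs every
residue equally, and the fold-mean AUC is reported alongside.

## Database subsampling

A k % sample keeps **ceil(n·k/100)** records — the unique simple rounding
rule consistent with the printed sizes of the published 1 %, 5 % and 10 %
samples of a 50,371,270-record database (503,713; 2,518,564; 5,037,127).
The size is computed in exact rational arithmetic to avoid float boundary
errors at scale. Sampling is uniform without replacement via reservoir
sampling (algorithm R), so memory is proportional to the sample, not the
database; the output preserves source record order and records are written
byte-identically, with a manifest (source hash, seed, counts) alongside.
Order preservation is this package's choice; the published procedure does
not state one.

## Synthetic data: what it emulates, and what it does not

`synth_complex` places single-atom protein residues on a line at 10 Å
spacing and RNA atoms 3 Å from each planted interface position, padding the
RNA chain to 5 nucleotides with atoms 1000 Å away. Interface distances are
≤ 4 Å and non-interface distances ≥ 8 Å, a ≥ 4 Å margin around the 5 Å
cutoff that makes annotation immune to the 10⁻³ Å PDB coordinate
round-off. Single-atom residues are the minimal geometry exercising the
all-atom distance scan; nothing about the construction is physically
realistic.

`synth_profile_dataset` draws per-residue labels Bernoulli(0.15) — roughly
the interface rate of structure-derived RNA-binding benchmarks — and raw
scores N(0, 1), adding `effect_size` (default 3.0, a clearly separable
signal on the raw-score scale) to the first five columns of interface
residues *before* logistic normalization, so the effect size keeps a stable
meaning in score units. Setting `effect_size = 0` gives an exact null:
labels independent of features.

Passing tests on these fixtures demonstrate that the pipeline is wired
correctly — labels propagate, windows align, folds do not leak, the
classifiers detect signal exactly where it was planted and find none where
it was not. They say nothing about predictive accuracy on real protein–RNA
complexes, where signal is weaker, correlated along the chain, and
entangled with homology between chains; the published-scale benchmarks
(multi-gigabyte databases, days of profile search) are out of scope here.

## Problem sizes and numerical conventions

The cross-validation benchmarks use 20 chains × 100 residues (≈ 2,000
windows of 500 features), a size at which chain-level 5-fold CV with the
calibrated SVM and the consensus completes in well under a minute while
leaving the null band [0.40, 0.60] comfortably wide relative to AUC
sampling error (≈ 0.03 at ~300 positives). Sampling uniformity is checked
over 2,000 seeded draws of 5-of-20 (standard error ≈ 0.0097 on an
inclusion probability of 0.25). Distance and consensus contracts are
asserted to 10⁻¹² absolute — comfortably above float64 accumulation error
at these sizes, far below anything scientifically meaningful.

## Known limitations

* The greedy identity filter is order-dependent plumbing, not CD-HIT.
* mmCIF input, biological-assembly expansion and missing-residue modeling
  are unsupported.
* SVM calibration internals are delegated to scikit-learn; probability
  values (not ranks) therefore depend on its calibration implementation.
* Classifier implementations and defaults are modern library versions;
  exact reproduction of scores from older Java-based toolkits is not
  attempted.
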