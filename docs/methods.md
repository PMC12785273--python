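# Methods

## Problem and model

The package addresses directional multi-target classification in
chemical space: given a compound structure, predict for each of five
epigenetic regulator modules (miR-34a, DNMT3a, HDAC, miR-125b, miR-135a)
whether the compound up-regulates (label 1) or down-regulates (label 0)
that regulator, and rank compounds by how many modules they push in the
direction that mitigates ethanol-induced neural-crest-cell impairment —
down for miR-34a, DNMT3a, and HDAC; up for miR-125b and miR-135a. Each
module is an independent binary QSAR problem; the coupling between
modules happens only at the ranking stage, where the equal-weight rank
score is the mean of the five binary mitigation indicators.

## Curation rules

Input records are canonicalized with RDKit; the structure key is a SHA-256
prefix of the canonical SMILES, so identical structures collide regardless
of input notation. Rejection reasons are applied in a fixed precedence so
each record gets exactly one: unparseable > missing structure >
multicomponent (any `.` in the canonical SMILES — salts and mixtures are
dropped, not stripped to a parent) > isotope-labeled > inorganic (no
carbon atom; a deliberately simple, testable definition) > duplicate
(first occurrence kept) > ambiguous label (copies of one structure that
disagree on a module label are all dropped). The report always balances:
n_input = n_kept + Σ rejects.

## Descriptor sets and providers

Featurization goes through a provider registry so alternative calculators
can be plugged in; the shipped provider is RDKit-native. The six sets are:
binarized E-state fingerprints (79 bits), MACCS keys (167), an 881-bit
hashed circular fingerprint with substructure-presence semantics, a
2048-bit path fingerprint computed with bond orders ignored (pure graph
topology), a curated ~95-key SMARTS substructure fingerprint in the
Klekota–Roth style, and the RDKit 1D/2D descriptor block (~210 real-valued
columns; width is provider-dependent and recorded in the provenance of
every matrix). Bit-exact agreement with any external fingerprint software
is explicitly out of scope — the grid only needs six stable, named
semantics. Constant and missing-value columns are dropped by a cleaner
fitted on training rows only; the real-valued block is z-scored (again fit
on training rows); binary fingerprints are left unscaled.

## Splitting, balancing, cross-validation

Splits are stratified 4:1 (per class: round(0.8·count) training rows,
seeded permutation), giving exactly 200/50 for a 250-compound module and
guaranteeing both classes in the test set. SMOTE is hand-rolled to the
textbook contract: each synthetic sample is x + u·(x′−x) for a minority
row x, a uniformly drawn one of its k = 5 (capped at minority−1) nearest
minority neighbors x′, and u ~ U[0,1]; for binary fingerprints synthetic
coordinates are rounded to {0,1}, for the descriptor block they are left
continuous. Balancing is applied to training data only — inside each CV
fold during cross-validation — because balancing before splitting would
leak synthetic copies of test information into training. Cross-validation
is stratified ten-fold with the entire preprocessing (clean → scale →
SMOTE) refitted per fold.

## Algorithms and selection

Default hyperparameters (all overridable per config): MLP with one
100-unit hidden layer, max 500 iterations; k-NN with k = 5; Gaussian
naive Bayes; random forest with 500 trees; RBF-kernel SVC (C = 1,
gamma = scale) scored by decision function; XGBoost with 300 rounds,
depth 6, learning rate 0.1. AUC uses the native class-1 probability where
available and the decision function otherwise — AUC only needs a score
monotone in the probability. Degenerate metric denominators yield 0 plus
a flag rather than NaN so grid tables stay numeric. The best model per
module is the config maximizing the mean of (ACC, AUC, F1, MCC), each
averaged over the CV mean and the external test value; ties break by MCC,
then AUC, then enumeration order. Weighting CV and test equally is a
documented design choice — selection criteria weighting internal versus
external evidence was genuinely open.

## Applicability domain

The domain statistic is the mean Euclidean distance to the k = 5 nearest
training compounds in the descriptor space of the module's selected
model. Normalization anchors are the min and max of the same statistic
computed leave-one-out over the training set; normalized values are
clipped below at 0 and a query is in-domain iff its raw distance does not
exceed the training maximum (normalized ≤ 1). Training-only statistics
(rather than pooling with the prediction set) keep the domain fixed as
new libraries are screened. When all training distances coincide
(d_min = d_max) any query at or below that distance normalizes to 0.

## Ranking

Out-of-domain module predictions contribute indicator 0 and are flagged,
so an unreliable model can only withhold credit, never grant it (a config
option to exclude the module and renormalize was considered and rejected
as less conservative). Rank tables sort by descending score with
alphabetical id tie-breaks; coverage percentages are rounded half-up to
two decimals, and the microRNA umbrella counts compounds favorable for at
least one of the three miR modules once (a union, not a sum).

## Alert mining

Fragments are generated by recursively breaking every acyclic,
non-directional single bond (rings stay whole) and collecting every
connected fragment between 2 and 18 heavy atoms, canonicalized and
deduplicated, with a 5000-fragment-per-molecule cap. Open valences are
matched as plain substructure queries without explicit attachment points.
The likelihood ratio uses Haldane–Anscombe smoothing,
LR = ((a+½)/(P+1))/((b+½)/(N+1)), so alerts absent from inactives rank
finitely and comparably; information gain is the entropy drop of the
label given match status, in bits. Selection is greedy by descending LR
(ties: higher IG, fewer heavy atoms, lexicographic); after a rule is
selected the actives it matches stop counting toward later rules'
support, which removes redundant sub/super-structure variants. As a
performance screen, only fragments appearing in the fragment pools of at
least `min_support` library molecules enter the matching pass; reported
counts always come from true substructure matching, so a + b equals the
number of molecules matched. Permutation importance is the mean accuracy
drop over seeded independent shuffles of one column at a time.

## Synthetic benchmark

The generator emulates the study's data shape: per module, 250 compounds
(≈200 train / 50 test after the 4:1 split), binary labels with mild
imbalance, an unlabeled ~200-compound screening library, and labels
driven by substructural motifs plus noise. Molecules are concatenations
of 2–5 valence-safe grammar units (alkyl, aryl, ether, ester, amine,
alkene); about 40% of compounds per module carry that module's planted
motif spliced at a random chain position (acyl chain for miR-34a, amide
for DNMT3a, hexyl ether for HDAC, conjugated diene for miR-125b,
gem-dimethyl carbinol for miR-135a — the motif vocabulary of interest for
these target families). The hexyl ether was preferred over the shorter
C–N motif for HDAC because a two-atom amine pattern also matches the
grammar's amine units and would make the module unlearnable. At noise 0
the module label equals the favorable-direction value iff the compound
carries the motif — rejection sampling enforces this exactly — and labels
are then flipped independently with probability 0.1 by default. The
alkene grammar unit ensures proper sub-fragments of the diene motif occur
in both classes, so mining ranks the full planted motif above its
fragments on likelihood ratio rather than by tie-break.

What the generator does **not** emulate: realistic drug-likeness or
property distributions, ring-system diversity, tautomers and charge
states, correlated multi-module activity within one compound, and
assay-style label noise that depends on structure. Passing tests
demonstrate that the pipeline's machinery (splitting, balancing,
leakage-free evaluation, domain scoring, directional ranking, alert
recovery) behaves to contract on data with a known planted signal — they
do not certify predictive performance on real bioactivity data.

## Problem sizes and numerics

The default benchmark (5 modules × 250 compounds, 180 grid configs,
ten-fold CV) runs in roughly ten minutes on one CPU; alert mining over
all five modules takes under a minute with the pool pre-screen. Metric
implementations are validated against independent direct-formula
evaluation to 1e-12 and the rank-statistic AUC against trapezoidal ROC
integration to 1e-12. The garbled printed form of the MCC denominator in
the source material is implemented as the standard
√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). All randomness flows through explicit
integer seeds (NumPy `default_rng`, scikit-learn/XGBoost `random_state`);
identical seeds reproduce byte-identical artifacts, which the run
manifest's checksums make checkable.

## Known limitations

- The 1D/2D descriptor block is ~210 columns, not the ~1613 of the
  external calculator the descriptor family is modeled on; provenance
  records the actual width.
- The curated SMARTS key set is ~95 patterns, a compact stand-in for the
  4860-key Klekota–Roth definition, chosen for coverage of the functional
  groups the planted-motif benchmark exercises.
- Alert mining breaks only acyclic single bonds; ring-bond fragmentation
  and fragment recombination are out of scope.
- The pool pre-screen in `mine_alerts` can miss a fragment whose matches
  are dominated by molecules that do not generate it during
  fragmentation (possible with ring-internal matches); for the linear
  grammar used in testing, pool membership and substructure matching
  coincide.
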