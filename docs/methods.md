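# Methods

## The encoding

A reaction SMILES `REACTANTS>REAGENTS>PRODUCTS` is parsed into three
dot-separated molecule lists; atom-map numbers, if present, are
stripped (mapped corpora remain usable, and the fingerprint never
depends on a mapping). Reagents are concatenated onto the reactants,
giving a left side L and a right side P. Each side becomes a set of
fragment SMILES:

* for every heavy atom and every bond radius ρ ∈ {0, …, r}, the
  circular environment — all bonds within ρ steps of the root atom,
  plus their atoms; ρ = 0 is the bare atom — rendered as canonical
  SMILES with the parent's aromaticity perception and any stereo
  descriptors the fragment's atoms carry;
* every SSSR ring, rendered from its ring atoms and ring bonds only
  (no exocyclic substituents).

Set semantics throughout: duplicate fragments collapse, so copy-number
on one side carries no signal, and an environment that stops growing
once ρ exceeds the molecule's extent simply reproduces a smaller
fragment that the set absorbs. The differential set S = L Δ P is
hashed fragment-by-fragment — the first 4 bytes of the SHA-256 digest
of the UTF-8 string, read as a big-endian unsigned 32-bit integer — and
folded to d bits by k mod d. Bit i of the output is set iff some hash
is ≡ i (mod d); each set bit records the fragments that produced it,
which is what makes individual features chemically interpretable.

Two numerical choices matter for reproducibility. First, Python's
built-in string hash is process-salted, so a fixed cryptographic digest
is used instead; identical inputs give byte-identical fingerprints
across processes and platforms. Second, RDKit's fragment writer
(`MolFragmentToSmiles`) is *not* invariant to the parent molecule's
atom order (e.g. an aryl-ether fragment of aspirin renders as `COc` or
`cOC` depending on input ordering), so every parent is canonically
renumbered (`CanonicalRankAtoms` + `RenumberAtoms`) before extraction.
With that normalisation, randomized SMILES renderings of the same
molecule produce identical fragment sets; this is tested directly.

Direct consequences of the set algebra, kept as tested laws rather
than special cases: identity reactions give the zero vector; a
reaction and its reverse are indistinguishable (a known degeneracy of
the symmetric difference — callers who need directionality must add
it); molecule order and reactant/reagent placement are irrelevant;
popcount ≤ |S|, with folding only ever merging bits; and for nested
dimensions d | d', the popcount at d' is at least that at d.

Parameters: radius r (default 3; 2–4 are the usual range — smaller
radii produce fewer fragments and fewer fold collisions at small d,
larger radii more context), dimension d (default 2048; 16–2048 are all
supported, with collision rates growing as d shrinks), and
`include_rings` (default on). 32-bit hash collisions before folding
are vanishingly rare at these set sizes and are deliberately left
merged in the provenance maps.

## Downstream harnesses

**5-NN classification.** Exact brute-force nearest-neighbour search.
On binary vectors, Hamming distance and squared Euclidean distance
induce the same neighbour ranking, so the metric choice is benign;
Hamming counts are reported. The vote is made deterministic: majority,
then smaller summed neighbour distance among tied classes, then
first-seen order in the neighbour list. k larger than the training set
is clipped with a warning.

**MLP classification.** Input d → dense tanh layer of 1664 units →
softmax, cross-entropy loss, Adam at learning rate 0.001 (the
optimizer's conventional default), batch size 64, exactly 10 epochs, no
early stopping. Implemented over scikit-learn's `MLPClassifier`, whose
multinomial output layer is exactly softmax + cross-entropy; weight
initialisation and shuffling derive from a single seed, making runs
bit-reproducible.

**Yield regression.** XGBoost with a fixed hyperparameter set used for
every run: n_estimators 999 999 (effectively unbounded),
learning_rate 0.01, max_depth 15, min_child_weight 8,
colsample_bytree 0.2125, subsample 1. A seeded 10% of the training
rows is removed as a validation set; boosting stops after 20 rounds
without validation improvement and the best-round model is kept. The
validation split RNG is a dedicated stream keyed by the user seed, and
validation rows never enter the boosting rows (asserted in tests).

**Metrics.** Accuracy; multiclass Matthews correlation in Gorodkin's
confusion-matrix form (clipped to [−1, 1] against float round-off, 0
when undefined); confusion entropy (CEN) with per-class
misclassification probabilities normalised by the class's total
involvement, logarithm base 2(N−1), and involvement-weighted
aggregation — 0 for a diagonal matrix, and degenerate single-class or
empty matrices return 0; R² = 1 − SS_res/SS_tot, undefined (error) for
constant truth.

## The synthetic corpus

`fixtures` instantiates five textbook templates — Fischer
esterification, amide coupling, amine N-alkylation, Williamson ether
synthesis, Suzuki-type biaryl coupling — by string substitution of
alkyl/aryl substituents from small pools, with reject-and-resample
validation and within-class distinctness. Each template designates a
reagent (catalyst/base), which the reagent-merge law needs. Template
labels give a classification task whose classes are separable by
construction; the suite asserts the inter-class mean Hamming distance
exceeds the intra-class mean.

Yields live on the percent scale. The generator computes, per
reaction, yield = clip(50 + Σ effects of fragments present in the
reaction's differential set S + N(0, σ), 0, 100). Effects are summed
over membership in S deliberately: S is exactly what the fingerprint
encodes, so at σ = 0 the structure→yield rule is fully representable
from the input features and regression recovery isolates the model
pipeline rather than representation loss.

The default effect map is a fixed rule, not a seeded draw — it plays
the role of the (single, fixed) chemistry underlying a yield dataset.
It mirrors how real yield corpora behave, where reaction/reagent
family dominates and substrate modulates: each class's shortest
*marker* fragment (a fragment present in the differential set of every
member of that class and of no other — e.g. the newly formed amide
bond's environment) carries a family effect of +18, −15, +12, −10 or
+15 percentage points (classes in name order), and the four
cross-cutting fragments closest to 50% prevalence carry ±7.5-point
substituent effects. Marker-fragment signals are redundantly encoded
(whole groups of correlated bits change together), which matters
because the fixed colsample_bytree = 0.2125 means most boosting trees
never see any one given column; an isolated cross-cutting fragment
with no correlated support is recovered noticeably less stably. With
σ = 5 this design gives signal variance ≈ 250 against noise variance
25, i.e. an R² ceiling ≈ 0.92; seeded 70/30 runs land at 0.86–0.91.
The noiseless single-fragment benchmark places one −20 effect on a
class marker and recovers R² ≥ 0.999.

What the fixtures do *not* emulate: chemically realistic reactivity,
reagent incompatibilities, the heavy class imbalance and label noise of
patent-derived corpora, and out-of-distribution splits that hold out
whole reagent families. Passing tests therefore demonstrate the
correctness of the encoding and the harness plumbing, not benchmark
performance on real reaction corpora.

## Problem sizes and numerical notes

The test suite and the acceptance script run the classification and
regression recoveries at 5 classes × 100 reactions with 70/30 splits,
and the law checks on batches of 100 molecules/reactions — sizes at
which every quantity is stable across seeds while the whole suite
stays fast on a single CPU. Degenerate inputs are errors, not silent
defaults: empty reaction sides, single-class MLP fits, regression on
constant truth, and validation splits that would be empty all raise
typed exceptions. Strict parsing is the default everywhere; lenient
modes skip-and-report and are opt-in.

## Known limitations

* Reverse reactions and identity reactions are indistinguishable from
  their forward/degenerate forms by design.
* Copy-number (stoichiometry) is invisible: a fragment present on both
  sides in different multiplicities cancels.
* The "subtraction"-style variant of differential fingerprints (kept
  bits signed by side) is not implemented.
* Fragment SMILES canonicalisation is delegated to RDKit; a different
  RDKit major version could render some fragments differently and
  change individual bit positions (not the algebraic laws).
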