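# Methods

This note documents the models and procedures implemented in `simtransfer`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Fingerprints and similarity

Structural similarity between two drugs is the Tanimoto coefficient
`T(A, B) = |A ∩ B| / |A ∪ B|` over binary circular-fingerprint bit sets
(set semantics, no counts), with radius 2 and width 1024 bits as defaults.

SMILES parsing, aromaticity perception and salt stripping are delegated to
RDKit; stereochemistry is ignored and only the largest covalent fragment is
kept, since the analysis is purely 2D/topological.  The parsed graph is
converted to a light-weight `Molecule` (atoms with element, charge,
attached-H count, ring and aromatic flags; undirected bonds with order
single/double/triple/aromatic).

The circular fingerprint itself is a native implementation of the
ECFP procedure:

1. **Initial invariant** per atom from (element, formal charge, heavy
   degree, attached-H count, ring membership), hashed with a fixed,
   seedless 32-bit FNV-1a mix.  Aromaticity is carried by the aromatic
   *bond* type in the iterations, not by the atom invariant.
2. **Neighborhood iterations** 1..radius: each atom's new identifier hashes
   (round, own identifier, sorted list of (bond-order code, neighbor
   identifier)).
3. **Duplicate-environment removal**: an environment covering a bond set
   already emitted at a smaller radius, or emitted at the same radius by
   another atom (smaller identifier wins), contributes nothing — the
   canonical ECFP convention.
4. **Folding**: every retained identifier maps to bit `id mod width`.

On the embedded 20-drug panel this reproduces RDKit's Morgan environment
partition *exactly*: before folding, the native and RDKit similarity
matrices agree to machine precision.  After folding to 1024 bits the two
implementations necessarily diverge slightly, because hash-dependent
folding collisions add noise: on this panel RDKit's own folded matrix
agrees with its unfolded one only at Spearman ρ ≈ 0.92, which caps the
achievable agreement between any two independently hashed folded
implementations near ρ² ≈ 0.85.  Rank agreement of the production folded
matrix is therefore validated against the toolkit's *exact* (unfolded)
similarity — the collision-free reference — where it reaches ρ ≈ 0.95.

The fixture panel's SMILES are standard public structures for the 20
drugs; they are not canonical to any specific registry, and fingerprint
values at 1024 bits are sensitive to small provenance differences.  On
both the native and reference matrices the structurally closest pair is
diclofenac-furosemide (Voltaren-Lasix), in a near-tie with
flunitrazepam-etizolam; folding can swap the two.

## Corpus model

Documents carry a drug query, free text and one of four labels: NC-u/m
(noncompliant use or mention), NC-s (noncompliant sales), G-u (general
use), G-m (general mention).  The subcorpus `D_i` of drug *i* is the set of
documents retrieved by that drug's query.

Splitting uses largest-remainder rounding so part sizes are exact (1000
documents at 80:10:10 give exactly 800/100/100), with label stratification
on by default: per-label allocations are largest-remainder too, then
corrected toward the exact global sizes one document at a time, keeping
each label's share of each part within one document of ideal.  All
randomized operations require a seed.

Random oversampling balances a training set to the size of its *largest*
label class by resampling each minority class with replacement — no data
is discarded.  Oversampled copies receive derived ids (`<orig>#os<k>`) so
corpora keep unique ids while provenance stays traceable; the leakage guard
and the feature cache resolve a copy to its source document.  Oversampling
is applied to the training part only, after splitting, in both experiment
designs (class imbalance is identical in both).

## Classifier

The default backend is deliberately light: hashed token counts (stateless
feature hashing, 2^14 features, whitespace tokens; a character 2-3-gram
mode exists for unsegmented text such as Japanese) into a multinomial
logistic model trained by epochs of stochastic gradient descent
(scikit-learn `SGDClassifier`, log loss, L2 α = 1e-5).  After each epoch
the development-set cross-entropy is recorded; training stops when the dev
loss has not improved for `patience` (default 3) consecutive epochs or at
`max_epochs` (default 12), and the parameters of the minimum-dev-loss epoch
are kept (earliest epoch on ties).  Documents with no active features at
prediction time fall back to the training-majority label.

The experiment harness accepts any backend exposing the same
`fit(train, dev, config)` / `predict(corpus)` contract — e.g. a fine-tuned
transformer encoder classifying from its CLS representation.  The analysis
measures *relative* transfer performance, which is defined for any backend;
absolute scores depend on the backend and are not the point.

## Transfer experiment designs

**Single-subcorpus transfer.**  For i ≠ j: split `D_i` 90:10 into
train/dev, oversample the training part, fit, and score macro-F1 (and
accuracy) on all of `D_j`.  For i = j: split 80:10:10 and score on the held
out tenth.  All n² ordered cells form the transfer matrix.

**Incremental learning (Sim vs Rnd).**  For target *j* and source count
*X*: take the first *X* drugs of an ordering of the other n−1 drugs —
descending Tanimoto similarity to *j* (ties broken by ascending drug name)
for SIM, or a uniform random permutation for RND — pool their subcorpora
`D_K`, split 90:10 train/dev, oversample, fit, and score plain accuracy on
all of `D_j`.  The dev set comes from `D_K` itself, never from the target.
RND is averaged over `n_rnd_reps` (default 10) independent orderings and
reported with the standard error of per-target means; SIM is deterministic
given the similarity matrix, so one run suffices.

Two guards hold everywhere: the target drug's documents never enter
training or development sets (asserted at document-id level on every run),
and every cell/replicate derives its own seed from the master seed via a
splitmix64-style mixer keyed on (purpose, drug, X, replicate), making whole
result tables byte-identical under a fixed master seed and safe to
parallelize.

Reported metrics follow the designs they summarize: macro-F1 for the
transfer matrix (robust to the strong label imbalance), accuracy for the
incremental curves; both are computed everywhere.

## Statistics

Accuracy, macro-F1 and Cohen's kappa delegate to scikit-learn behind the
module surface, with two conventions pinned down: a label absent from both
truth and prediction is excluded from the macro-F1 mean (classes that occur
but earn no credit contribute 0), and kappa of two identical constant
annotations (p_e = 1) is defined as 1.  The similarity-F1 correlation
z-scores both axes (population variance) before Pearson's r — which is
invariant to that affine rescaling, a fact asserted at run time — with a
two-sided p from the exact n−2-df reference distribution.  The correlation
is computed over off-diagonal (i ≠ j) pairs only: diagonal pairs are forced
(T = 1, high F1) and would inflate r.

Pair categorization buckets ordered (train, test) pairs into OTC_rel
(either drug is over-the-counter-relevant), antipsycho (both drugs
hypnotic/anxiolytic or antipsychotic) and other, and into similarity bands
high (T > 0.15) / low (T < 0.03) / mid.

## Synthetic-data generator

The generator emulates the statistical shape of a drug-mention
pharmacovigilance corpus; defaults are 20 drugs in 4 classes, 1000
documents per drug, and label proportions NC-u/m 0.21, NC-s 0.07, G-u 0.38,
G-m 0.34.

*Structure layer*: drugs are assigned round-robin to classes; each class
has a random 64-bit-prototype over 1024 positions and each drug's
fingerprint is its class prototype with independent per-bit flips (rate
0.02), giving within-class Tanimoto ≈ 0.6 against between-class ≈ 0.03.
Flip rates ≥ 0.5 would erase the class structure and are rejected.

*Text layer*: each document is the drug-name token plus ~Poisson(20)
tokens drawn i.i.d. from the mixture
`κ · θ(class, label) + (1 − κ) · θ(drug, label)`, where each θ is a
Dirichlet-weighted distribution over its own disjoint 40-token block plus
a shared 30-token function-word block at weight 0.3 (preventing degenerate
perfect separability at κ = 0).  Tokens are abstract (`w0042`-style): the
harness is language-independent by construction.

The coupling κ is the package's experimental knob: at κ = 1 same-class
drugs have identical generating distributions, so structural similarity is
maximally informative about text; at κ = 0 every drug's informative
vocabulary is private and structure carries no information.  No published
effect size exists for how much more similar same-class drug texts are, so
the default κ = 0.7 is a repository choice, documented as such.

The two layers draw from child-seeded, mutually independent random streams.
This matters: an earlier revision seeded both layers with the same stream,
which coupled fingerprint-flip noise to text-distribution noise and
produced a small spurious positive similarity-F1 correlation even at
κ = 0.  The κ = 0 ablation is exactly what caught it.

**What passing tests show — and don't.**  The generator reproduces the
corpus features the analysis logically depends on: grouped structures,
label imbalance, drug-conditional text, and a controllable
structure-to-text coupling.  It does not emulate natural language
(morphology, negation, sarcasm), annotator disagreement, near-duplicate
spam, or realistic vocabulary overlap between therapeutic classes, and its
class separation is far cleaner than real tweets.  Results on it validate
the *machinery* (ordering, leakage-free evaluation, metric wiring) and the
*qualitative* behavior of similarity-guided transfer under a known ground
truth — not absolute performance on real social-media text.

## Problem sizes

Synthetic experiments are sized for a desk-scale single-CPU run: the
Sim-vs-Rnd acceptance experiment uses 20 drugs × 500 documents at
κ ∈ {1, 0} over 5 harness seeds with 10 RND replicates; correlation
recovery uses 10 drugs × 300 documents over 5 seeds; diagonal dominance
uses 5 drugs × 300 documents.  The acceptance script runs slightly smaller
replicas (12 drugs × 400 documents, 3 seeds, 5 RND replicates for
Sim-vs-Rnd; 10 × 300, 3 seeds for correlation) — sizes at which the
qualitative effects are far outside noise, as the per-seed standard errors
reported by `sim_vs_rnd_summary` show.

## Known limitations

- Absolute classifier scores come from a linear bag-of-tokens backend and
  do not transfer to transformer-scale models; only relative comparisons
  are meaningful.
- Fingerprint bit patterns are hash-specific; only similarity *rankings*
  are comparable across implementations, and folded 1024-bit values carry
  irreducible collision noise (see above).
- The fixture panel's SMILES provenance is "standard public structures",
  not a pinned registry export; near-tied similarity rankings can differ
  under other provenances.
- Cohen's kappa is exercised on constructed label vectors; annotator
  behavior is not simulated.
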