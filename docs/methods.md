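# Methods

This note records the models implemented in `murzyme`, the choices made
where the design was genuinely open, and what the synthetic generators do
and do not emulate.

## Parsimony screening of mechanistic models

A mechanistic proposal is reduced to eight attributes: five binary
complexity markers (conformational change, serial course, irreducible
complexity, long-range electron transfer, obligatory E·S complex), two
counts (minimal steps, molecularity of the key transient), and an event
scheme. The probability index of a scheme treats every
association/dissociation event as an unbiased half-probability outcome and
every one-of-*k* partner/route selection as a further 1/*k*:
`P = (1/2)^n · Π 1/k_i`, computed exactly as a `Fraction`. Affinities are
deliberately not modelled — the index is a combinatorial parsimony measure,
not a thermodynamic quantity. For schemes with `parallel_modes > 1` the
serial product is reported as a flagged lower bound rather than combined by
an invented union rule: any admissible combination rule could only raise the
value, so the floor is the defensible statement.

Scoring is +1 per attribute to the simpler model (lower binaries, fewer
steps, lower molecularity, *higher* probability index), ties award nothing,
and the verdict follows the 0–8 totals; equal totals are reported as a tie,
never broken. This is the plainest reading of a binary per-attribute
increment scheme, and it makes the comparison antisymmetric by construction.

Packaged encodings: the haloperoxidase classical scheme has three
half-events (index 1/8); the CYP classical cycle five half-events plus a
one-of-five selection (1/160); the cyclooxygenase classical cycle six
half-events and two one-of-three selections (1/576 — this decomposition is a
reconstruction consistent with the printed value, and the data file says
so); oxidative phosphorylation and hemoglobin carry no published numeric
index, so their encodings are chosen only to preserve the qualitative
ordering and are asserted nowhere as exact values. The two classical
controls (DNA polymerase, ribosome) pair a plausible classical encoding with
a deliberately contrived DRS account of high-fidelity copying; they exist to
exercise the classical branch of the label gate.

## Consistency rules and the label gate

The rule engine is a fixed table: four mutual-incompatibility pairs and four
standalone inadmissible assertions over an 11-code vocabulary, evaluated
with set semantics (order- and duplicate-insensitive, monotone under
supersets). The k_cat threshold is 1×10⁹ M⁻¹s⁻¹; a numeric qualifier, when
given, must exceed it for the code to be admitted at all. Only the classical
proposal is screened — the DRS account admits a larger event set by design
and has no analogous exclusions.

Gate semantics: `classical` requires both a classical comparison win and a
clean consistency report; either a murburn win or any violation yields
`murzyme`; a tie with a clean report is `unresolved`. Inconsistency alone
sufficing for `murzyme` is a one-directional choice: the screening exists to
disqualify active-site accounts, not to validate DRS ones.

## Trend-rule classifier

Each of the 28 criteria has per-class trend tokens, a strength tier and a
weight, shipped as an editable CSV. Matching: definite tokens (`yes`, `no`,
`low`, `moderate`, `high`) match exactly; `usually-*` tokens match their
majority direction; `some-yes` matches only an affirmative answer (a
negative is uninformative for that class), while `rare` matches its majority
direction *no*; `sometimes-high` matches `high`; `mixed`, `sometimes` and
`need-not-be` have no direction, so those rows score only toward the class
whose trend is definite. Weights default to 2.0 / 1.0 / 0.5
(salient / definite / soft); the four salient criteria are heme presence,
DRS involvement, non-integral stoichiometry and substrate non-selectivity,
the features the feature-table classifiers themselves rank as most
informative.

Confidence is a deliberate design point. The margin `|Δ| = |score_m −
score_c|` is normalised by the **total** table weight (equivalently: margin
per answered weight × coverage) and mapped to tiers at ≥ 0.5 high, ≥ 0.25
medium, > 0 low. Normalising by answered weight alone would let a single
answered criterion claim high confidence; scaling by coverage makes sparse
profiles honest. Thresholds are constants in `trendclass` and the weights
are user-editable, so the tiers are tunable plumbing, not calibrated
probabilities.

## Feature-table learning

The decision tree is a deliberately deterministic ID3 variant: greedy
maximum information gain (`IG = H(Y) − Σ_v p(v) H(Y|X=v)`, base-2; Gini
available), ties broken toward the lowest-numbered feature, each feature
used at most once per path, growth stopped only by leaf purity or feature
exhaustion. Zero-gain splits are still taken at impure nodes — this is what
lets XOR-style tables be learned exactly and guarantees that training
accuracy reaches the per-feature-vector majority bound (verified against a
brute-force oracle in the tests, and cross-checked against scikit-learn's
entropy tree). Leaf and vote ties resolve to the lexicographically smaller
label; unseen branch values fall back to the parent majority. The forest
bags bootstrap row samples with √p features per split, 100 trees by default,
fully reproducible under a seed.

Evaluation uses stratified random splits (class proportions preserved —
plain random splits of a 39-row table can starve a class), 20 repetitions of
60/40 by default, averaging accuracy and per-class precision/recall/F1;
a class never predicted in a repetition contributes precision 0 with a
warning.

## PDB text pipeline

Record parsing follows the fixed 80-column layout: HEADER classification in
columns 11–50 and entry id in 63–66, TITLE/COMPND/KEYWDS continuations
(numeral in columns 9–10) joined with a space, MOLECULE sub-fields collected
from the semicolon-separated COMPND specification, KEYWDS comma-split, HET
and HETNAM codes recorded separately. Cleaning lowercases, strips
punctuation and collapses whitespace; the embedded text is the cleaned
concatenation of classification + title + molecules + keywords (HET codes
are parsed but not embedded). The parser is record-level by design: generic
header parsers drop the space at COMPND continuation boundaries, which
corrupts tokens for text mining.

The built-in embedder hashes each token (stable blake2b) into one of
`dimension` buckets (default 384, the dimensionality typical of small
sentence-transformer models), counts, and L2-normalises; it is deterministic
across runs and platforms, and an external sentence-embedding callable can
be plugged in through `EmbedderConfig`. Class imbalance is handled by seeded
random oversampling of the minority class to parity — applied strictly to
the training partition of each repetition (undersampling available by flag).
The classifiers are scikit-learn's SVC (linear kernel by default, C = 1.0 —
text embeddings are near-linearly separable; RBF by flag), logistic
regression, and a 100-tree random forest, evaluated over repeated stratified
4:1 splits.

## Synthetic generators

The feature-table generator maps each trend token to a class-conditional
probability of an affirmative answer: definite trends are followed with
probability 1.0, `usually-*` 0.8, `some-yes` 0.4, `rare` 0.1, and the
direction-free tokens are a coin flip — an adherence map that keeps definite
trends clean while making soft trends genuinely noisy. The default cohort is
22 murzymes and 17 classical systems (39 rows), the size of a curated
expert-annotated collection for this problem; holdouts use the same process
on a disjoint seed. Because the structural block contains a definite trend
(heme), structural-only evaluation is also perfectly separable under the
default adherence; sub-unit structural accuracy appears only if definite
adherence is lowered.

The corpus generator writes valid 80-column PDB text with class-correlated
vocabularies (oxidoreductase-flavoured for murzymes, hydrolase/transferase-
flavoured for classical enzymes) and a HEM HET record on every murzyme file.
With probability `overlap` (default 0.3) a file draws all descriptive tokens
from a class-neutral shared vocabulary, making it unclassifiable from text;
this bounds achievable accuracy at about `1 − overlap · P(minority)` ≈ 0.92
for the default 56/144 corpus of 200 records, whose imbalance (~28%
murzyme) mirrors annotated structure collections.

What the generators do **not** emulate: real PDB annotation is far messier
(multi-chain COMPND blocks, inconsistent keyword vocabularies, organism and
method text), class-correlated vocabulary is cleaner than real functional
annotation overlap, and the feature tables have conditionally independent
features given the class, unlike correlated real biochemistry. Passing tests
therefore demonstrate the correctness and calibration of the machinery on
trend-faithful data, not field performance on curated structure corpora;
published text-classification accuracies obtained with pretrained
transformer embeddings on hand-labeled corpora are expected to differ and
are not asserted here.

## Numerical and degenerate-input choices

Probability indices are exact rationals; float values are derived, never
compared for ties (index ties are genuine ties). Empty event schemes have
index 1. Single-class training tables yield a warned one-leaf tree. Empty
embedding text maps to the zero vector. Splits that cannot stratify (a class
with one member) fall back to plain random splitting with a warning.
`test_frac` must lie strictly in (0, 1). All stochastic routines take
explicit integer seeds and derive per-repetition seeds from a
`numpy.random.default_rng` stream, so every reported number is reproducible
byte-for-byte.

## Problem sizes

Default experiment sizes — 39-row cohorts, 20 split repetitions, 200-record
corpora, 10-seed sweeps — were chosen as the natural scale of this problem:
expert-curated mechanism annotations number in the dozens, and the corpus
generator's ceiling is set by vocabulary overlap rather than corpus size, so
larger synthetic corpora only flatten variance without changing any
conclusion.
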