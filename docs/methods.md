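# Methods

## The model

`dkppi` extracts binary protein–protein interaction (PPI) relations from
annotated sentences. Every unordered pair of protein mentions in a sentence
is one *instance*; the task is to classify each instance as interacting
(positive) or not (negative). Instances are represented by 44 features and
classified with random forests.

The central idea is the *dominant keyword*. Interaction trigger words
("interact", "bind", ...) are strong evidence for the positive class, but
whether a given occurrence of a trigger actually decides the label depends on
its context: the same word can be decisive in one sentence and incidental in
another. The package therefore carries a per-instance binary flag DK
(1 = this instance's keyword is dominant) and uses it, together with the
keyword's position relative to the pair, to split the training set into four
subsets — II (DK=1, infix), IP (DK=1, prefix/postfix), NI (DK=0, infix),
NP (DK=0, prefix/postfix) — each with its own classifier. Prediction routes
an unlabeled instance to the classifier of its (predicted) subset.

### Feature set (44 dimensions)

* **Lexical (25)** — the selected keyword stem; three word distances
  (P1–K, P2–K, P1–P2); the keyword-position indicator triple
  (infix/prefix/postfix); 1-based sentence positions of P1 and P2; the
  two-letter comma pattern over the ordered anchors; negation, conjunction,
  "which", "but" and condition flags; the preposition following the keyword
  within word distance 3; a multiple-keyword flag; seven individual
  "second keyword" flags (bind, interact, regulate, induce, stimulate,
  associate, known); a parallel-expression flag.
* **Parse (6)** — for P1, P2 and K: the height in the constituent tree and
  the comma-joined part-of-speech path from just below the root down to the
  token's preterminal. Height counts the labels on that root-exclusive,
  preterminal-inclusive path; this is the only convention reproducing the
  worked example (heights 2/5/3 with paths "NP,NN" / "VP,VP,PP,NP,NN" /
  "VP,VP,VBN" for "P1 is driven by P2").
* **Patterns (13)** — thirteen fixed lexical structure patterns over the
  blinded token sequence (e.g. `P1 * iVerb * P2`, `iNoun between * P1 * and
  * P2`, `between P1 and P2`). A wildcard `*` matches 0–5 word tokens;
  literals and the iVerb/iNoun classes match by Porter stem.

Counting conventions. Word distances count word tokens strictly between the
anchors; standalone punctuation (commas, semicolons, parentheses, slashes)
forms non-word tokens that never enter distances, and the pair's own protein
tokens are likewise not counted as intervening words. A multi-word protein
name is collapsed to a single word token. The keyword of an instance is the
lexicon word minimizing the summed distance to the two proteins (leftmost on
ties — within the infix zone all candidates tie, so the tie-break matters);
when no lexicon word occurs, keyword-dependent features take their sentinels
(−1 for distances, "none" for nominals, false for flags).

Wildcards match zero to five words (rather than one to five) so that
`P1 * iVerb * P2` covers the bare S-V-O archetype; the limit is exposed as a
parameter and the tests check the matcher against an independent oracle
under both limits.

### Dominant-keyword refinement

The unbalance degree of a keyword stem K over a labeled instance set is
U(K) = (#positives with keyword K) / (#instances with keyword K), where "with
keyword K" means K is the instance's *selected* keyword. Initially DK(i) = 1
iff min(U(K_i), 1 − U(K_i)) < T (strict inequality; default T = 0.15);
keyword-less instances start at DK = 0.

The assumption is refined for m iterations of k-fold cross-validation inside
the training set. On each fold, classifiers C0 (trained on current DK=0
instances of the other folds) and C1 (DK=1 side) predict the held-out
instances, and for each instance:

1. **Predictions differ** — DK is set to follow whichever classifier was
   correct, overriding the current value.
2. **Both correct** — nothing changes, except that a true-negative instance
   flips its DK with mutation probability α (escape from local stable
   states). Positives are never mutated: the positive class is small, and
   random corruption there is costly.
3. **Both wrong** — a gold-negative instance is removed from the training
   set entirely; gold positives are never removed.

Removals take effect immediately within the pass; removed instances are
excluded from all subsequent training (C0/C1, the DK-classifier, the four
subset classifiers) but still count as ordinary instances when they fall in
an outer evaluation fold. Defaults: k = 10, m = 5, α = 0.05. Fold assignment
is stratified by gold label with a seeded shuffle and re-drawn every
iteration (a config switch can freeze one partition); mutation draws come
from a dedicated seeded stream so setting α = 0 does not shift the fold
randomness, and with α = 0 the whole refinement is deterministic. C0/C1 are
trained on all 44 features; the per-subset masks below apply only to the
four final classifiers. If one DK side is empty or single-class, that
classifier degrades to a majority-label stub (logged).

Because the refined DK values exist only for training instances, a
*DK-classifier* is trained with the final DK values as class labels and
assigns DK to unlabeled instances at prediction time.

### Feature masks

Within a subset the keyword position is fixed, which makes some patterns
dead weight: the K-P1-P2-shaped patterns 7, 8, 9 and the pair-only pattern
13 are removed for the infix subsets (II, NI), and the S-V-O-shaped patterns
1, 2, 10, 12 for the prefix/postfix subsets (IP, NP). Masking is manual and
fixed; no data-driven feature selection is performed.

### Method variants

* **SC** — single classifier, all features, no partition.
* **MC** — partition by the *initial* DK rule only; prediction-time DK is
  1 iff the instance's keyword stem is in the dominant-stem set derived from
  training (MC has no DK-classifier, so this lexicon lookup is the only
  consistent routing).
* **DK-MC** — partition by refined DK; DK-classifier routes at prediction.
* **FS-MC** / **DK-FS-MC** — the same two with the per-subset masks.

### Evaluation

Recall = TP/(TP+FN), Precision = TP/(TP+FP), F = 2RP/(R+P); a zero
denominator yields 0 with a degeneracy flag. The harness runs outer
stratified 10-fold cross-validation at instance level; DK refinement runs
strictly inside each training side. Headline numbers pool the fold counts
(micro); macro averages are reported alongside. Instance-level
stratification is a choice, not a given — document-level splitting (relevant
when the same abstract contributes near-duplicate instances) is a known
caveat and is not performed here.

## Synthetic data

Real benchmark corpora require external downloads and a specific constituent
parser, so the package ships a generator that emulates the statistical
structure the method assumes. Each sentence is built from a hand-written
template (a data file, ~6 per keyword-position family) carrying a fixed
bracketed parse tree whose leaves align 1:1 with the word tokens. A sentence
holds two protein mentions and one keyword slot filled either with the
designated dominant keyword (probability `dominant_share`, default 0.4 —
trigger words are very frequent in PPI-bearing sentences) or with one of
`n_distractor_keywords` = 4 distractors.

Labels: if the dominant keyword is present, the pair is positive with
probability `dominance` and the instance's ground-truth flag `planted_dk` is
1 — the keyword caused the label. Otherwise the label is Bernoulli
(`positive_rate`, default 0.3) independent of the keyword and `planted_dk`
is 0; the label is then *surfaced* through non-keyword cues: negative labels
use a negation-cue template ("does not …", "but not …") with probability
`signal_fidelity` (default 0.85), positives with probability
1 − `signal_fidelity`. This reflects the modelling premise that instances
without a dominant keyword are classifiable from features other than the
keyword; were their labels pure noise, DK recovery would be ill-posed and no
classifier could beat the base rate on them. With `dominance` = 1.0 the
unbalance degree of the dominant keyword is exactly 1 and the planted flags
are exact ground truth for parameter-recovery tests.

What the generator does **not** emulate: real biomedical syntax and
vocabulary breadth, multi-word and nested protein names, more than two
mentions per sentence, document structure (all sentences are independent),
parser errors, and annotation noise. Passing tests therefore demonstrate
that the pipeline recovers the structure it models — not benchmark-corpus
performance.

## Numerical and design choices

* **Classifier** — scikit-learn `RandomForestClassifier`, 100 trees (the
  library default; no hyperparameters are prescribed for the method),
  `n_jobs=1`, seeded. The learner is a pluggable factory; any object with
  `fit`/`predict` works.
* **Encoding** — nominal features (keyword stem, comma pattern, preposition,
  the three POS paths) are ordinal-encoded with a vocabulary learned from
  the training split; unseen categories map to −1. Trees only need a
  consistent partitioning of category codes, so ordinal encoding is adequate
  at these dimensionalities.
* **Stemming** — an in-package transcription of the Porter algorithm; all
  lexicon membership is stem-level.
* **Lexicon** — the shipped trigger lexicon (134 distinct stems from ~190
  surface words of the interaction-verb/noun vocabulary) is a versioned data
  file and fully configurable; published results in this area use unpublished
  lexicons of similar size (~180 stems), so the file is a package choice, not
  a reproduction.
* **Degenerate inputs** — sentences with <2 mentions yield no instances;
  missing parse trees degrade to sentinel parse features; fold counts shrink
  when survivors or class counts are too small (logged); an empty or
  single-class training subset yields a majority-label stub.
* **Problem sizes** — the parameter-recovery suite uses 500 sentences
  (dominance 1.0) and the method-comparison suite 600 sentences at
  dominance 0.9 over five seeds; both are large enough for stable estimates
  at these effect sizes while keeping a full test run on one CPU
  comfortable.

## Known limitations

* The preposition window ("within 3") is measured in raw word tokens after
  the keyword; no example constrains whether protein tokens count there, and
  the package counts them.
* MC/FS-MC routing of a prediction-time keyword unseen in training falls to
  DK=0 (not in the dominant-stem set), which is the conservative choice.
* Instances whose pair spans overlap are enumerated but share collapsed
  tokens; distances involving nested mentions are edge-case territory and
  only lightly exercised.
* The refinement's convergence is empirical, not proven; with α > 0 the
  procedure is stochastic by design.
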