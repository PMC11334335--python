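# Methods

This note documents the models, parameter choices, and known limits of
the `morallex` pipeline. It covers what each stage assumes, which knobs
matter, what the synthetic corpus does and does not emulate, and the
numerical conventions used at degenerate inputs and ties.

## Corpus ingestion and seed matching

CHAT transcripts are parsed at the main-tier level only: dependent tiers
(`%mor`, `%gra`) and headers other than `@Participants`/`@ID` are
ignored, because the analysis operates on surface text. The target
child's age is read from the `@ID` header in `y;m.d` notation and stored
in whole months; analyses bin it as integer years, `floor(months/12)`,
since CHAT ages are exact and flooring never promotes a child into an
older bin. Utterances without a recorded age are dropped and counted.
By default the `CHI` participant is the child and every other declared
participant is a caretaker; an explicit tier→role map can override this.
Whole sub-corpora can be excluded by name (the analysis excludes
corpora collected under controlled demographic designs).

Preprocessing lowercases, splits on terminal punctuation, strips
punctuation except word-internal apostrophes, and lemmatizes. The
default lemmatizer is a deterministic irregulars-table + suffix-rule
backend; it is intentionally pluggable behind a `str -> str` contract so
a heavier NLP pipeline can be swapped in, and tests that need
backend-independent output pin a lookup table. Contractions stay
attached ("don't", "it's") because the negation analysis counts the
*n't* clitic on raw text.

Lexicon matching follows LIWC conventions: a trailing `*` gives a
pattern prefix semantics; all other patterns require exact lemma
equality. The default age window is 1–6 years inclusive. When an
utterance matches several categories, its *initial* category is the
first match in token order; the survey stage overrides it anyway, and
the initial category only matters for band-rule and tie-break decisions.

## Sentence encoding and reduction

The clustering and neighbour-search stages need a sentence encoder with
one contract: any string maps deterministically to a fixed-length finite
vector. The default is a seeded feature-hashing encoder — each token
and bigram hashes (MD5) to a fixed pseudo-random unit vector, summed and
L2-normalized. It requires no trained weights, is bitwise reproducible
across processes, and separates the synthetic corpus's category
vocabularies geometrically. A transformer sentence encoder satisfies
the same contract and can be plugged in for real corpora; no result in
this repository depends on any particular encoder's weights.

PCA keeps the minimal number of components reaching 95% cumulative
explained variance (configurable; 1.0 keeps the full rank). It is
fitted per clustering cell, on that cell's utterances, because
clustering is per-cell; a joint fit is a config switch away. Reduced
vectors are mean-centred, so a sentence can land exactly at the origin;
such vectors get proximity 0 during prototype selection (they are
neither prototypical nor peripheral) while `proximity()` itself treats
zero vectors as errors.

Static token embeddings come in four variants used by the model grid:
two corpus-trained tables — skip-gram with negative sampling (plain
numpy SGD; window 2, 5 negatives, 5 epochs, seeded) and a PPMI +
truncated-SVD factorization (the same count-based family as GloVe) —
and two corpus-independent hash-derived tables in which every token gets
a fixed pseudo-random unit vector. The hash tables are synthetic
stand-ins playing the structural role of large general-purpose
pretrained embeddings: unlimited vocabulary, no corpus knowledge. They
use 100 dimensions (the corpus tables use 32) because ten linearly
separable classes need headroom among random directions. Sentence
features are arithmetic means over in-vocabulary tokens; all-OOV
sentences yield a flagged zero vector and are excluded from classifier
training but counted.

## Clustering and survey selection

Each (foundation-polarity × speaker-role) cell is fitted with full-
covariance Gaussian mixtures (regularization 1e-4, 2 initializations,
fixed seed) for k = 2..10; the model maximizing the Euclidean silhouette
wins, ties to the smaller k. Cells with fewer points than k+1 truncate
the grid; fewer than 3 points, or degenerate duplicates, fall back to a
flagged single cluster with undefined silhouette. Cosine silhouette is
available by config; the metric choice is recorded on the model.

Prototypes and peripherals (10 each at most, per cluster) are ranked by
cosine proximity to the cluster's member-mean vector and de-duplicated
globally by sentence text, so repeated utterances are surveyed once.

## Annotation aggregation

The aggregation thresholds are: moral share ≥ 0.75 → moral with the
majority-vote foundation; share < 0.5 → nonmoral; the band in between →
moral only if the majority foundation equals the initial one. Exactly
0.5 falls in the band (the nonmoral rule is strictly "less than 50%").
Multi-select annotations contribute one vote per selected category.
Foundation-vote ties resolve to the initial foundation when it is among
the tied categories, else lexicographically; cluster-level relevance
ties resolve to nonmoral. Both tie-breaks are logged. The one-word
blacklist (kin terms, "food", "trash", …) applies only to single-token
utterances. With 7 annotators at per-annotator accuracy 0.95 these
rules recover ground truth on ≥ 99% of unambiguous utterances; the band
rule is what makes 4-of-7 splits recoverable when the majority
foundation confirms the seed.

## Propagation

Seeded-but-unsurveyed utterances take the majority of three votes —
their cluster's label and their two nearest surveyed neighbours by
cosine — with a three-way foundation tie resolving to the initial
foundation if it is among the votes, else the cluster's. Neighbour
search runs in the cell's reduced space (the space the cluster lives
in); cells with fewer than two surveyed members fall back to the cluster
label alone, flagged. Unseeded utterances were never clustered, so they
take their three nearest surveyed neighbours in the full contextual
space, with rank-1 breaking three-way ties. Exact cosine ties order by
utterance id so reruns are stable.

The unseeded route inherits the survey pool's composition: when nearly
all surveyed sentences are moral, nearest-neighbour voting over-labels
mundane sentences as moral. For that reason the headline emergence
time-courses and all classifier training use the seed-matched
(survey-anchored) labels; the unseeded labels feed only the
lexical-subset analyses, and their precision should be validated before
being given weight on real data.

## Emergence analyses

Two normalizations are emitted: share-of-moral-language per (age, role),
which sums to 1 across the ten categories wherever moral language
exists, and per-total-sentence rates, which are comparable across roles
with different volubility. Ages above the 1–6 window can be pooled into
one bin. MLU counts words, not morphemes.

Word-level significance uses a bootstrap over moral sentences: resample
with replacement at the original size, count the word's frequency and
the mean frequency over all seed words present, and estimate
p = (1 + #{resamples with freq ≥ mean}) / (n_perm + 1), one-sided with
"≥" at the boundary. A word is flagged when p < α (default 0.01),
i.e. its usage sits significantly below the average moral word's.
Identical sentence count-profiles are collapsed before resampling (sums
of multinomial blocks are multinomial — an exact speedup). Calibration:
under exchangeable word frequencies the flagged rate matches α in the
large-count regime (measured 0.009–0.011 at roughly 1,000 expected
tokens per word, n_perm = 2,000); at small counts (tens of tokens per
word) the one-sided percentile bootstrap is anti-conservative — we
measured a flagged rate of about 0.016 at 40 tokens/word — so per-word
flags at sparse ages should be read as ordering evidence, not exact
error rates. The calibration suite therefore checks the estimator at
50,000 sentences per replicate.

Negation classification is a pure text predicate: standalone *no* or
*not*, or the substring *n't* (curly apostrophes normalized). Lexical
subsets (property words, obligation modals) match patterns exactly as
listed with word boundaries — *must* does not match *mustn't* — and the
CS-vs-CDS comparison is a one-way ANOVA over per-age rates with role as
the factor, run per category.

## Generalization grid

Targets per task: binary moral relevance (nonmoral examples are the
utterances labelled nonmoral in the training pool — ambiguous seed uses
that the survey rejected); 10-class foundation-polarity; 5-class
foundation with polarity collapsed. Labels from corpora that split
Fairness into Equality/Proportionality collapse to Fairness. The
classifier is scikit-learn multinomial logistic regression, C = 1.0,
max_iter = 2000, balanced class weights (without reweighting, the
planted — and empirically real — Care dominance collapses fine-grained
models to majority prediction), seeded. Multi-sentence documents are
labelled by sentence-majority vote with summed-probability tie-breaks.

Evaluation uses ten balanced test sets per task (minority-class size,
sampled without replacement within a set), mean micro-F1 — which equals
accuracy for single-label prediction — and a 95% CI of
mean ± 1.96·SD/√n over the sets. Random controls resample same-size
training sets from seedless utterances with uniformly random class
assignments, 20 times per configuration, and land at chance (1/K) by
construction; the moral-label models beating them is the signal check.

## The synthetic corpus: what it does and does not show

The generator is the study-conditions oracle: staggered onsets (Care
from age 1, Fairness and Purity from 2, Authority from 3, Loyalty from
4), Care receiving 76–97% of moral language depending on age, role
asymmetries (caretakers stress Fairness-virtue and Degradation, children
Cheating), per-category negation rates roughly three times higher for
Fairness/Authority in child speech, utterance length growing with age,
an overall moral rate of 15% of utterances (far denser than real
transcripts, to keep desk-scale cells populated), ambiguous nonmoral
senses planted on three polysemous seed words, annotators with accuracy
0.9 (0.95 in the recovery checks) and a 1-in-6 attention-failure rate
matching a 300-participant, 40-utterances-each survey design.

Sentences are deliberately simple frames over category-specific
vocabularies, so the hash encoder separates categories essentially
perfectly. Passing tests therefore demonstrate that the machinery —
matching, clustering, aggregation rules, propagation votes, counting,
and the evaluation harness — is correct and recovers planted structure;
they say nothing about how well any particular sentence encoder
disambiguates real child speech, where senses overlap, categories share
vocabulary, and annotators disagree for reasons other than noise. Real
agreement ratios and grid scores will be substantially lower than the
near-ceiling values seen here.

## Problem sizes

Defaults were chosen so the full study stays comfortably interactive on
one core: 500 sentences per age × role cell (6,000 utterances) for the
analysis scripts and the emergence-ordering check; 300 per cell for the
grid-bearing runs; 2,000 points for the propagation-recovery geometry;
200,000 draws for Monte-Carlo chance baselines; 10,000 random vote
configurations for the rule-oracle checks; 100 replicates × 2,000
bootstrap resamples for permutation calibration. The complete test
suite runs in about two minutes; the acceptance script in about two.
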