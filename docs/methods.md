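# Methods

## Pipeline model

`lexdec` constructs lexical-decision vocabulary tests from a plain-text
corpus in five stages: frequency estimation, rare-word selection,
pseudoword synthesis, real↔pseudo pairing, and block assembly; a sixth
component scores response tables. The stages and the choices behind
them are documented here.

### Tokenization and cleaning

Tokens are maximal runs of Unicode letters, optionally containing
internal apostrophes (ASCII `'` or typographic `’`) or hyphens; digits
and punctuation break tokens. Cleaning removes tokens containing
digits, tokens whose casefolded form is shorter than 2 or longer than
20 characters, and tokens mixing characters from more than one Unicode
script (a cheap guard against boilerplate — URLs, foreign quotations —
in multilingual corpora; the script of a character is approximated by
the leading word of its Unicode name). The surviving tokens are fully
casefolded (so `Straße → strasse`). All bounds are parameters.
Casing statistics (`CasingStats`) are collected from the raw tokens
*before* casefolding, because the proper-noun filter needs them.

The cleaning rules are deliberately conservative and language-agnostic;
no lemmatization, affix stripping, or diacritic normalization is
attempted. For languages with rich prefixing morphology this means
some inflected forms survive as "words", a known limitation.

### Frequency table and rare-word selection

Counts are exact multiset multiplicities; `total_tokens` is the number
of cleaned tokens, so conservation holds by construction. A word's
per-million frequency is `count / total_tokens × 10⁶`.

Real test items are sampled uniformly without replacement from the
band `f_pm ∈ [5, 20]`, and the sample is redrawn (up to 1,000
attempts) until its mean per-million frequency lies within ±30% of the
target mean of **10 per million**. The target pitches the test at
proficient speakers; the band and target are both parameters, and
raising or lowering the target is the intended way to make the test
easier or harder. Selection excludes every word removed by a filter:
dictionary non-membership (treated as likely misspellings), a
capitalized-occurrence fraction above 0.5 (proper nouns — a heuristic
stand-in for a part-of-speech tagger, overridable by an external
predicate for languages like German that capitalize all nouns), and
optionally transparent compounds (both parts ≥ 4 characters and
≥ 50 per million; off by default because compounding rules are
language-specific).

### Pseudoword synthesis

A character n-gram model of order k = 5 (four context symbols predict
the fifth) is fitted on the cleaned lexicon: each word is padded with
k−1 start symbols and one end symbol, and every k-window contributes
one count. Two deliberate choices:

- **Type counting.** Each lexicon word counts once, regardless of its
  corpus frequency, so a handful of very frequent words cannot
  dominate the transition statistics.
- **No smoothing.** Sampling only ever draws from observed contexts,
  which guarantees that every k-window of a sampled string is attested
  in real words — the property that makes pseudowords look wordlike.
  The cost is that the model cannot score strings containing unseen
  windows; the scorer returns NaN for those.

Sampling draws symbols from the fitted conditional distributions until
the end symbol, then rejects the candidate unless it (a) decodes (when
a transliteration scheme is in use), (b) has surface length within
bounds, (c) is not itself a lexicon word, and (d) is not within one
Damerau–Levenshtein edit of a dictionary entry — a string one typo
away from a real word would test spelling, not vocabulary. The
one-edit threshold is a design choice; it is exposed as
`typo_max_distance`. Rejection sampling is capped (default 10,000
attempts) and reports per-reason rejection tallies on exhaustion.
Set generation spawns one child random stream per candidate slot from
the master seed, so results are reproducible and independent of how
many rejections each slot consumed.

The Damerau–Levenshtein implementation is the unrestricted
(Lowrance–Wagner) variant, under which transposed characters may be
edited further. Unlike the common optimal-string-alignment shortcut it
is a true metric (e.g. distance("ca","abc") = 2, not 3), so
triangle-inequality-based reasoning about near-neighbours is sound.
The distance-≤1 test used in the hot path is a closed-form neighbour
check, property-tested against the full distance.

Character-based scripts are handled by an invertible
`TransliterationScheme` (encode to letters, decode back); the model is
fitted and sampled in letter space. A scheme must pass
`roundtrip_check` (decode∘encode = identity on the training lexicon)
before use. The package ships the identity scheme and an invertible
toy syllabary for tests; real romanizers (e.g. Pinyin) are plug-ins.

### Pairing

"Low-level statistics" for matching are the feature pair
(character length, mean log transition probability). Features of both
pools are standardized jointly (union mean/variance) so neither
dimension dominates; real words are visited in seeded random order and
each greedily claims the nearest unused pseudoword by Euclidean
distance. Greedy matching is near-optimal at these pool sizes (tested
against a random-bijection baseline) and trivially deterministic; an
optimal-assignment solver could be substituted without changing any
interface. Pseudowords are filtered for typo-proximity *before*
pairing, so no pair is discarded afterwards.

### Test assembly

Default layout: two blocks of 30 items. Each block is half real, half
pseudo — chance level is then exactly 50% — and all items within a
block come from distinct pairs; with more than one block, the real and
pseudo member of a pair are placed in different blocks (pair group g
contributes reals to block g and pseudos to block g+1 cyclically).
With a single block this separation is impossible and both members
share the block. Item order is a seeded shuffle. The repeat design
(`repeat_items=True`, used with 20-item blocks) appends each block's
items again in a fresh seeded order, enabling item-level response
consistency. The answer key is serialized separately from the
participant-facing spec so the shown file leaks no labels.

### Scoring

- **Accuracy**: fraction of responses matching the key; the primary
  score. Balanced accuracy (mean of per-class accuracies) is also
  reported since conventions differ between published tests.
  When a design contains repeats, accuracy uses first presentations
  only, so items are not double-weighted.
- **Confidence intervals**: percentile bootstrap, n = 1,000 resamples
  by default, seeded, resampling items (for accuracy) or participants
  (for reliability). Percentile rather than BCa: simple, adequate for
  these sample sizes, and exactly reproducible.
- **Repetition consistency**: over items presented twice, the fraction
  answered identically. For a responder answering independently with
  per-presentation correctness p the expected value is p² + (1−p)²;
  a responder who copies their first answer scores 1 regardless of
  accuracy, which is what makes consistency a lexicality-free
  reliability measure.
- **Test–retest reliability**: Pearson r between per-participant
  scores on two parallel blocks (scipy's estimator; the bootstrap is
  vectorized in numpy).
- **Group contrasts**: Cohen's d with pooled (n−1) SD; paired Wilcoxon
  signed-rank with zero differences dropped, exact null distribution
  for ≤ 25 untied pairs, normal approximation with continuity
  correction otherwise (ties take average ranks and force the
  approximation).

Degenerate inputs error loudly rather than returning NaN: zero-variance
score vectors, all-zero difference vectors, zero pooled SD, responses
referencing unknown item ids, and more than two presentations of an
item are all rejected.

## Synthetic data

`synthlang` generates the study conditions for every test:

- **Languages**: V distinct words from a consonant–vowel template
  grammar (lengths 4–10, 20-letter alphabet, occasional closed
  syllables), with Zipfian sampling weights w_r ∝ r^(−s), s = 1 by
  default. This reproduces the two features of real corpora the
  pipeline depends on — a rank–frequency power law and recurrent
  character structure — and nothing else: no morphology, no semantics,
  no real phonotactics. Passing tests therefore demonstrate the
  pipeline's mechanics, not the psycholinguistic validity of items in
  any natural language.
- **Corpora**: i.i.d. draws from the Zipf weights (real text is
  burstier; irrelevant for frequency-marginal behaviour).
- **Responders**: answer each presentation correctly with a
  class-specific probability; `sticky` responders copy their first
  answer on repeats. This emulates the native/non-native performance
  gap as a pure accuracy difference.

Problem sizes: the calibration corpus is V = 50,000 types / 2,000,000
tokens — at Zipf s = 1 the ranks whose expected frequency falls in the
5–20 per-million band span roughly 4,400–17,500, comfortably inside
the vocabulary, and the in-band pool holds ≈ 15,000 types. The general
unit fixture is V = 20,000 / 600k tokens for the same reason (band
ranks ≈ 4,800–19,000); a smaller V = 5,000 language serves the n-gram
and dictionary tests, where frequency plays no role. A vocabulary much
below ~20,000 types cannot support the default band at s = 1: the
in-band ranks fall outside the lexicon and only the Poisson lower tail
of common words lands in the band, clustered at its upper edge.

## Numerical and degenerate-case choices

- All randomness flows through `numpy.random.Generator`; composite
  operations spawn child streams via `SeedSequence(seed, spawn_key)`.
- Fitted transition probabilities per context sum to 1 to within
  1e−12 (they are ratios of integer counts).
- Standardization with a zero-variance feature sets that SD to 1,
  neutralizing the dimension instead of dividing by zero.
- Frequency-table TSV rows are ordered by descending count with
  lexicographic tie-break, making output diffable.
- `select_rare_words` errors (naming the pool size) when the in-band
  pool is smaller than requested, and errors after the resample cap if
  the mean target is unreachable — it never silently widens the band.

## Known limitations

- The proper-noun heuristic fails for all-noun-capitalizing languages
  (German) without an external predicate, and for scripts without case.
- The compound rule is a generic stand-in, not a morphological
  analyzer.
- Greedy pairing is not globally optimal (observed cost is well below
  the random-bijection baseline, which is the property that matters
  for item matching).
- Pseudoword "wordlikeness" is purely orthographic n-gram likelihood;
  no pronunciation or syllable-structure modeling.
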