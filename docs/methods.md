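# Methods

## Task and model

Entity linking is staged: mention detection, candidate generation, and
disambiguation.  This package inserts a semantic-type stage between the
last two.  For a mention `m` with candidate set `C`, a predictor estimates
the coarse semantic group(s) of `m` from its textual context, and a filter
keeps only candidates whose own type set is compatible, yielding `C′ ⊆ C`
with ranks preserved; the final prediction is the top-ranked member of
`C′`.  An empty predicted group set marks the mention as the *None* type
(a spurious span) and, under the default `drop` policy, removes it from the
output entirely — which is how type prediction doubles as a false-positive
filter for upstream NER.

### The type scheme

UMLS concepts carry one or more of 127 fine semantic types.  Fine types are
poor direct prediction targets: multi-valued per concept and extremely
skewed in frequency.  The packaged scheme (`src/medlink/data/
semantic_groups.tsv`) maps the 127 types onto 24 coarse groups used as the
label space.  The table is pinned: type-name matching is exact after outer
whitespace trimming, with no case folding, so transcription drift surfaces
as an error rather than a silent mismap.  A strict-cardinality flag
(default on) enforces 127/24; custom typologies can be loaded with it off.
The label `None` is reserved: never a group, never a fine type.

### Context featurization

The context of a mention is `k` whitespace tokens on each side (punctuation
stripped at token edges), with the mention bracketed by the marker tokens
`[men]` and `[/men]` that carry its position.  `k` defaults to 64
(reasonable choices are 48–128 for running text; the synthetic fixtures are
fully informative already at k≈8).  The default encoder hashes token bags
in three namespaces (left context, mention, right context) into 2^18
dimensions, plus distance-tagged features for the two tokens nearest the
mention on each side — the immediate collocates carry most of the type
signal, and a pure bag representation would dilute them.  One-vs-rest
L2-regularized logistic scorers (liblinear, fixed seed) produce one
probability per group.  The encoder is deliberately CPU-scale; the
featurize/score contract is the interface, and a contextual transformer
encoder can replace it without touching any other stage.

A group with no positive (or no negative) training example gets a constant
scorer equal to its clipped empirical rate, so the probability vector is
always complete.

### Thresholds

Multi-label decisions use per-group thresholds: predict group `g` iff
`P(g) ≥ τ_g`.  Thresholds are tuned by exhaustive grid search on a
validation split, by default 100 evenly spaced values in [0.001, 0.999].
The selection criterion is per-group F1 — the standard threshold-dependent
surrogate; the area under the PR curve, which we report alongside, is
threshold-free and therefore cannot itself pick a threshold.  Ties break
toward the smallest maximizing threshold; a group absent from the
validation labels defaults to τ = 0.5 with a warning.

### Filtering semantics

Candidates and predictions are both *sets* (concepts are multi-typed,
prediction is multi-label), so the filter keeps a candidate iff its type
set intersects the predicted set; at coarse granularity the candidate's
fine types are first mapped to groups.  Intersection is the unique rule
with the oracle-safety property: filtering on the gold concept's own types
(the fine or coarse *oracle*) can never remove a gold candidate.  Because
grouping coarsens types, fine-oracle-filtered sets are always subsets of
coarse-oracle-filtered sets.  When filtering empties a candidate list the
`drop` policy (default) leaves it empty and the mention is excluded from
predictions; `passthrough` restores the unfiltered list for
recall-sensitive uses.

### Candidate generation

The built-in generator is a dictionary: preferred names and synonyms,
normalized by lowercasing and whitespace collapsing (the normalizer is
pluggable), mapped to their concepts.  A form shared by `n` concepts yields
`n` candidates each scored `1/n`, ordered by CUI — ambiguity is preserved,
not resolved, here.  Lists are capped at 5 candidates by default, the cap
common to off-the-shelf dictionary linkers.  Candidate lists produced by
external tools can be imported as JSON-lines instead.

## Evaluation conventions

**Exact** mention+ID F1 counts a prediction as a true positive only when
span and CUI both match a gold annotation exactly.  **Partial** mention+ID
F1 gives overlapping same-CUI spans fractional credit
`w = overlap_chars / max(len_pred, len_gold)`, matched greedily one-to-one
by descending weight (ties: earlier gold start, then earlier prediction
start).  The normalization by the longer span is this package's documented
convention: it is symmetric-penalizing, bounded by 1, reduces to the exact
metric on exact spans, and therefore guarantees partial ≥ exact
component-wise.  Other conventions (normalizing by prediction length, gold
length, or span union) exist; the weight function is pluggable.

Mentions whose gold CUI lies outside the working inventory are *unlinkable*
and are excluded from both numerators and denominators, with counts
reported.  Abstentions and None-type suppressions are non-predictions: they
cost recall, never precision.

Type predictions are scored one-vs-rest per group; the micro average pools
all (example, group) decisions, the macro average means per-group F1.
PR-AUC is the area under the precision-recall step curve (average
precision), micro-averaged by pooling (example, group) pairs.  Confusion
analysis counts (gold group, predicted group) pairs where the predicted
group is not in the gold set.

The reduction report records, per mention, the candidate-set sizes before
and after filtering, whether the gold concept was present and retained, and
whether the predicted groups intersected the gold groups; it summarizes the
fraction of mentions with a strictly smaller set and the fraction fully
disambiguated (singleton set retaining gold, among gold-present mentions).

## Distant supervision

Documents indexed with MeSH headers support weak annotation: a detected
mention is linked iff its surface exactly matches one of its own document's
headers, with the header resolved to a CUI and fine types through a
crosswalk table.  "Exactly matches" defaults to case-insensitive comparison
after whitespace collapsing, because headers are Title Case while running
text is not — a strictly literal mode is available.  Headers are tried in
order, first match wins; a matching header absent from the crosswalk is
skipped and counted.  Quality is assessed against gold annotations on
shared documents: a weak link is correct iff a gold mention with identical
span and CUI exists (a relaxed overlap mode is reported separately).  The
exact-match rule trades recall for precision by design; on fixtures with
unambiguous headers precision is exactly 1.

## Synthetic study conditions

The generators are pure functions of (config, seed).  Defaults, fixed once
as the package's study conditions: 60 concepts over 6 of the 24 groups,
`ambiguity_rate = 0.5` (half of all surface forms are names of two concepts
in different groups — the "cold" structure), 120 documents × 4 mentions,
`cue_strength = 1.0`, one spurious extra candidate per mention, and a
MeSH-linkable fraction of 0.2.  Oracle-safety measurements use 2,000
documents × 5 mentions = 10,000 mentions.  These sizes keep the whole suite
and the acceptance script in the tens of seconds while leaving every rate
measurable with negligible sampling noise.

Each mention's immediately preceding token is its group's cue word with
probability `cue_strength`, else a uniformly drawn other group's cue; at
`cue_strength = 1/n_groups` the cue is independent of the group and
context-based prediction collapses toward baseline.  Cue words and filler
tokens are nonsense strings disjoint from mention surfaces, so the
learnability ceiling is analytic: at `cue_strength = 1` the context
determines the group exactly.

What the fixtures do **not** emulate: real token statistics, morphological
variation, multi-word mention boundaries that cross tokenization,
inventory scale (millions of concepts), fine-type frequency skew, or
annotation noise.  Passing tests therefore demonstrate the correctness of
the machinery — filtering semantics, metric arithmetic, threshold search,
determinism, and the *direction* of the filtering benefit under ambiguity —
not performance on clinical or literature text.

## Numerical and design notes

- Determinism: every library API takes explicit seeds/configs; the CLI
  threads one root seed, and re-runs are byte-identical (the output
  manifests isolate their timestamp in a single field).
- Logistic scorers use liblinear with fixed `random_state`, C = 1.0,
  max_iter = 200; hashed features make training independent of vocabulary
  order.
- Readers repair nothing: offset mismatches, duplicate keys, increasing
  candidate scores, and unknown labels raise typed errors (an explicit
  `allow_unsorted` flag re-sorts imported candidates with a warning).
- Degenerate inputs: empty gold sets make recall-bearing metrics raise
  rather than return 0/0; PR-AUC requires at least one positive; an all
  empty-label training set is a degenerate-training error.
- Mentions whose span cuts through a token are featurized with the raw
  surface as the mention token rather than erroring.

## Limitations

- The default encoder is linear over hashed bags; it cannot model cue-word
  order beyond the distance-tagged nearest tokens, and real-text accuracy
  will trail contextual encoders.
- Coarse groups can be qualitatively broad (symptoms and findings sit in
  different groups, but e.g. all drugs share one), and fine-granularity
  filtering is only available through the oracle or imported type
  predictions.
- The dictionary generator requires exact normalized-form matches; no
  approximate string matching is included, and no disambiguation model
  beyond rank-1 selection of the filtered list.
- Weak annotation assumes detected spans are given; no NER model ships with
  the package.
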