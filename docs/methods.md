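# Methods

This note documents the models and procedures implemented in
`ontoalign`, their assumptions, the tunable parameters, the numerical
and design choices that were genuinely open, and what the synthetic
fixtures do and do not show about real ontologies.

## Lexical model

Every class annotation is reduced to one of four lexical categories —
`localName`, `label`, `exactSynonym`, `otherSynonym` — through an
editable property table (`ontoalign.config.DEFAULT_PROPERTY_CATEGORIES`)
that covers OBO flat-file tags, the oboInOwl/SKOS properties and the
NCI-style `FULLSYN`.  Annotation properties outside the table are
ignored with a logged count.  Local names are indexed only when they are
word-like; OBO-style alphanumeric codes (`UBERON_0000948`, `C68500`)
carry no lexical signal and are excluded (rule: a local name is a code
when it matches letters-plus-digits or contains no letters).

Names are normalized before indexing: underscores and all characters
other than letters, digits, parentheses and dash become spaces, a space
is inserted at internal capitalization boundaries (`hasPart` → `has
part`), everything is lower-cased and whitespace is collapsed.  The
function is idempotent, which the entry invariant relies on.  Names
detected as formulas are exempt — for them only underscores are
replaced — because word normalization would corrupt chemical notation
(`Fe(III)`).  The formula pattern (configurable) flags an intra-token
letter/digit boundary or an opening parenthesis glued to the preceding
token; it is deliberately conservative: a false positive merely leaves a
name unnormalized.

### Category weights

Weights are scores in (0, 1] per category: localName 1.0, label 1.0,
exactSynonym 0.95, otherSynonym 0.85 by default, configurable.  Only
their order matters qualitatively — it must mirror the decreasing
reliability of the annotation types so that label-to-label matches
outrank synonym matches and homonym ties break correctly.  The 0.05/0.10
gaps were chosen so that one category step stays smaller than the
derivation penalty step (below): an original exact-synonym match (0.95)
still outranks a derived label match (0.9), keeping "original evidence
beats derived evidence" within one category step.

### Derived synonyms

Stop-word removal (default list: of, the, a, an, structure, entire, set,
region, portion), parenthetical removal, thesaurus substitution and
background-knowledge expansion all create entries at the source weight
multiplied by a derivation penalty of 0.9 per step.  Derived names are
less reliable than originals; the penalty keeps a derived label match
(0.9 per endpoint) below an original label match while leaving the
resulting mapping scores (≥ 0.81 for label-derived pairs) above the
0.5 storage threshold.  Stop-word removal strips internal stop words as
well as leading ones by default; a `leading_stopwords_only` flag
restricts it, since both behaviours are defensible readings of the
SNOMED-style "structure of X" convention.

The thesaurus is induced per class: two multi-word names with the same
word count differing in exactly one position contribute that word pair.
Names of different lengths are not compared — without positional
anchoring the differing-word criterion is ambiguous, so that case is
excluded.  Substitution replaces all occurrences of one pair's word in
one source entry; derived names never chain through a second pair, which
bounds the noise the thesaurus can inject.

## Matchers

* `lexical_match` probes the name index of the larger lexicon with every
  name of the smaller one; a shared name yields a mapping scored by the
  product of the endpoint weights (maximized over shared names).  The
  product (rather than the mean) was chosen so that two mediocre
  annotations never outrank one perfect pair; the choice is exposed to
  sensitivity testing through the fixture suite.
* `quadratic_lexical_match` is the pairwise-comparison oracle: same
  output, |A|·|B| equality comparisons, used to validate the hash-based
  matcher and to exhibit the linear-vs-quadratic comparison-count
  scaling without relying on wall-clock time.  Its equality comparisons
  are vectorised over integer name codes purely for speed; no index is
  consulted.
* `word_match` scores candidate pairs (found through a word-keyed
  inverted index) by the Jaccard overlap of the best name pair's word
  sets, times the entry weights.  Uniform word weights are the default;
  this is the simplest formula consistent with "word overlap" —
  information-content word weighting would be a drop-in refinement.
* `string_match_global` / `string_match_local` score class pairs by the
  best weighted ISub over their name pairs.  The local variant
  restricts candidates to the neighbourhoods (radius 2 hops, subclass
  and part-of edges in both directions) of seed mappings.  Radius 2 over
  both hierarchies reflects that part-of forms a second hierarchical
  backbone in anatomical ontologies; radius 1 misses sibling classes,
  radius ≥ 3 erodes the precision advantage of locality.
* `thesaurus_match` equals lexical matching on thesaurus-augmented
  lexica, restricted to mappings that involve a thesaurus-origin entry,
  so the (noisier) derived synonyms are quarantined in their own matcher
  and enter the combination late.

### ISub

ISub scores two strings as `comm − diff + winkler`: `comm` is twice the
total length of greedily removed longest common substrings over the
summed lengths; `diff` combines the two unmatched fractions through a
Hamacher product with p = 0.6; `winkler` adds `0.1 · prefix · (1 −
comm)` for a shared prefix of up to 4 characters.  Common substrings of
any positive length are removed — this is what makes the metric tolerant
of word order ("hepatic artery" vs "artery, hepatic") — and the raw
value in [−1, 1] is clamped to [0, 1] because every downstream contract
expects that range.  One consequence is that unequal strings whose
characters fully cover each other (block anagrams) can reach a raw 1.0;
the exact score 1.0 is reserved for equality, so such pairs are capped
at 0.999.

### Combination order

Preliminary alignments are combined hierarchically, most precise matcher
first: lexical ≻ cross-reference/mediating ≻ logical definitions ≻
thesaurus ≻ word overlap ≻ local string.  A less precise matcher only
contributes mappings whose endpoints are still unmapped.  Union
combination (per-pair maximum) is used when merging alternative
background sources into a baseline.

## Background knowledge

Anchoring both inputs to a third ontology and intersecting the anchor
alignments (similarity = min of the two anchor scores, maximized over
mediating classes) is the mediator strategy.  When the background
ontology carries curated cross-references into the inputs these are used
as anchors instead, at weight 0.99 — they are essentially manually
curated mappings, more reliable than literal lexical matches but not
formally exact.  Lexical anchors supplement the cross-references for one
input ontology only when they cover at least twice as many of its
classes, covering sources whose cross-references reach only one side or
only part of one.  Lexical expansion imports the background names as
expansion-origin synonyms (penalty 0.9) of anchored classes; it can
recover partial matches the mediator cannot, at a documented precision
risk because indirect matches are put on par with direct ones.

Logical definitions (genus + differentia pointing at external
ontologies) are compared as sets after rewriting every filler through a
cross-reference bridge (union-find over all xref pairs, lexicographic
minimum as representative); equal definitions yield mappings at a fixed
similarity of 0.90 — below lexical evidence, reflecting the measured
unreliability of composite definitions, but above the word/string
matchers' typical scores.

**Mapping gain** of a candidate alignment over a baseline is the number
of candidate mappings whose *source class* is unmapped in the baseline,
divided by the baseline size.  Counting unmapped source classes rather
than unseen pairs prevents conflicting alternatives to existing mappings
from inflating the gain; the alternative denominator (candidate size) is
available as a config switch (`gain_denominator`) since the definition's
wording admits both.  An empty baseline degenerates to the raw candidate
count.  Selection is two-stage and greedy: preselect candidates with
individual gain ≥ 0.02 over the lexical baseline, then walk them in
descending individual gain, re-computing the gain over the running
baseline and adding a source (unioning its alignment in) when the
recomputed gain is ≥ 0.02.  The small nonzero thresholds quantify
"significant" gain; candidate input order never affects the outcome
(ties break on source name).

## Filtering

### Selection

Mappings are ordered totally: score descending, then matcher precision
rank, then lexicographic (source, target) — reproducibility demands a
total order.  A strict 1:1 core is selected greedily in that order.
`strict` returns the core; `permissive` additionally admits mappings all
of whose conflicts with the core are exact score ties; `hybrid` also
admits mappings whose every core conflict has both scores above 0.75
(configurable).  Evaluating the tie/0.75 rules against the fixed strict
core (rather than during a single destructive sweep) is an
interpretation choice: it makes the permissive and hybrid outputs
supersets of the strict output by construction, which a per-sweep rule
does not guarantee in corner cases where an admitted tie would block a
lower-scored mapping the strict core accepts.

### Coherence repair

The merged ontologies plus alignment are projected to propositional
logic: subclass edges and (bidirectional) equivalence mappings become
implications; disjointness axioms become mutual-exclusion clauses.
Part-of and other object properties are excluded from the projection —
the propositional simplification keeps repair tractable and matches how
disjointness is asserted in practice (over the subclass hierarchy).  A
class is unsatisfiable when it implies both members of a disjoint pair.

Modularization restricts the satisfiability tests to the *search list*:
classes with more than one parent under the projection (counting mapping
edges), mapped classes, and classes in disjointness clauses.  This is
verdict-preserving: if any class is unsatisfiable, the node where its
two implication paths to the disjoint pair diverge has out-degree ≥ 2
(or is itself in a disjointness clause) and is likewise unsatisfiable,
so testing the search list suffices.  The property suite checks the
modularized verdict against the full, unmodularized oracle.

For each unsatisfiable class, a conflict set is extracted from the
mapping edges on BFS shortest implication paths to the two disjoint
classes and then minimized by greedy single-removal (entailment is
monotone in the active mapping set, so the result is irreducible:
removing any one mapping breaks the entailment).  Repair repeatedly
removes the mapping occurring in the most conflict sets — lowest score
first on ties, then provenance, then lexicographic — and recomputes,
until coherent.  This greedy weighted-vertex-cover heuristic is the
standard approximation for minimal-removal repair; only mappings are
ever removed, never ontology axioms.

## Synthetic fixtures

The generator renders a shared concept backbone (random recursive
subclass tree, ~15 % part-of edges, two-word names from a bundled
anatomical vocabulary) into two ontologies with OBO-style numeric
identifiers, so code detection is exercised.  A configurable fraction of
concepts is shared and forms the 1:1 reference alignment.  Each variant
operation hides a shared concept from literal matching in a way exactly
one strategy recovers: stop-word prefixes (reduced synonyms),
parenthetical insertions (reduced synonyms), CamelCase rendering
(normalization), planted word-pair swaps with a helper class carrying
both spellings (thesaurus matcher), single-character typos (local string
matcher), and label/synonym shuffles with an ambiguous related synonym
matching a distractor class (synonym use and category weights).
Background flags emit a mediator ontology carrying both sides' names,
cross-references into both inputs, and logical definitions whose fillers
are bridged by the mediator's xrefs.  Incoherence planting replaces a
parent link in ontology B with a disjointness axiom against the old
parent, so each input stays individually coherent and the conflict
arises only through the two reference mappings.

What the fixtures do **not** emulate: the term-length and synonym-count
distributions of real ontologies (FMA labels are far longer and more
compositional), real homonymy density, multi-hierarchy modelling
differences, non-1:1 correspondences, and noise in reference alignments.
Passing fixture tests therefore demonstrates the correctness and the
qualitative direction of each strategy (e.g. synonym use raises recall,
weighting protects precision under ambiguity), not the absolute
precision/recall one would measure on OAEI corpora.

## Problem sizes and numerics

The test and acceptance workloads use fixture sizes of 40–100 classes
for behavioural checks, 1000 randomized pairs (n ≤ 100) for the
hash-vs-pairwise oracle equivalence, sizes 100–1600 for the
comparison-count scaling regressions, and 100 fixtures of 50 classes at
incoherence rate 0.2 for repair soundness — large enough for stable
log-log slopes and conflict structure, small enough that the whole suite
runs in minutes on one core.  Scores are serialized with up to four
decimals (trailing zeros trimmed) and files are UTF-8 with deterministic
row order, so outputs are byte-reproducible.  All randomness flows
through a single integer seed per fixture.

## Known limitations

* No OWL 2 reasoning: coherence is propositional; existential
  restrictions, property chains and conservativity violations are out of
  scope.
* The OWL reader covers the lexical/structural subset needed for
  matching (named classes, labels, oboInOwl synonyms, subClassOf,
  disjointWith, hasDbXref).
* Word overlap uses uniform word weights; no evidence-content weighting
  is shipped.
* Single-threaded by design; the natural extension points for
  parallelism are the per-seed loop of `string_match_local` and the
  per-class pair scoring of `string_match_global`, both embarrassingly
  parallel over disjoint candidate sets.
* No remote background-knowledge discovery; candidate sources are local
  files.
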