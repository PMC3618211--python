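# Methods

This note documents the models and procedures implemented in
`ppirules`, the design choices made where the method description left
room, and what the bundled tests do and do not establish.

## Extraction model

The extractor is a deterministic binary classifier over candidate
protein pairs in single sentences. Eight rules are evaluated in
ascending id; the first match returns positive, otherwise the pair is
negative (also the fallback when no dependency parse is available —
then only the purely lexical rules 5, 7 and 8 run). The rule engine is
deliberately order-insensitive at the *label* level: the rules are
individually sufficient conditions, so the positive/negative decision
equals the disjunction of the single-rule decisions, and the order only
determines which rule id is reported. This is property-tested.

### Dependency dialect

All syntactic rules are written against collapsed-Stanford-style
labels: `prep_X` for preposition-folded modifiers, `conj_and` for
coordination, `neg` for negation. `collapse_ud` converts Universal
Dependencies input (`nmod:X`/`obl:X`, or bare `nmod`/`obl` plus a
`case` child; `conj` plus `cc`; `advmod` on *not/never*; `det` on
*no*; `obj` → `dobj`) and is idempotent, so pre-collapsed input passes
through. Conjunction propagation copies the first conjunct's incoming
`nsubj`/`dobj`/`prep_*` edges to each conjunct as flagged extra edges;
queries treat them like ordinary edges (this is what lets the
subject–verb–preposition rule extract both "P0–P1" and "P0–P2" from
"P0 interacts … with P1 and P2"), while tree-walking operations (root
paths for chain features) use only non-propagated edges, which form a
tree.

### Keyword lexicon

67 interaction lemmas in five categories (Activation 12, Deactivation
12, Creating bond 19, Breaking bond 10, Signaling 14), shipped as a
TSV data file whose checksum is asserted in tests. Tokens are matched
through a deterministic suffix-stripping normalizer (one inflectional/
derivational suffix, trailing-*e* drop, final-consonant undoubling)
applied identically to lexicon lemmas and input tokens, plus a small
exception table (*induction*→*induce*, *reduction*→*reduce*,
*cleavage*→*cleave*, *recognition*→*recognize*, …). *bound* is its own
lemma in the table, distinct from *bind*, so the surface form "bound"
resolves to it. The method description does not state whether nominal
forms were matched by stemming or listing; matching is centralized in
`match_keyword` so the policy can be revised in one place. A
~180-word common-English/biomedical negative list guards against
accidental stem collisions.

### Precision constraints

Two locality constraints apply to the syntactic rules 1–4
(`RuleConfig`, overridable):

* `window_tokens = 7` — maximum surface span, both proteins inclusive.
  Rule 8 also enforces this (its example spans exactly 7 tokens);
  rules 5 and 7 are adjacent by construction; rule 6 is exempt.
* `max_dep_words = 3` — maximum number of *dependency-bearing* words
  strictly between the proteins. Operationalized as: a token counts
  when it participates in at least one edge whose label is outside
  {case, cc, punct, det, mark, aux, auxpass, cop} and its POS is not
  ADP/CCONJ/PUNCT/DET/AUX/PART. This makes prepositions and
  coordinators ("with", "and") not count, as the method prescribes.
  The source figure sentence is not printed in full, so the bundled
  figure-style fixture is a marked reconstruction ("PROTEIN0 interacts
  directly with PROTEIN1 and PROTEIN2") chosen so the documented count
  of exactly three dependency-bearing words holds for the P0–P2 pair.

Negation vetoes: rule 1 and 4 check the verb and its subject; rules 2,
3 and 5 check the relation noun and its governing verb (nearest verbal
ancestor); rule 6 checks the role noun, linking verb and subject;
rules 7 and 8 need no check by construction. A vetoed structural match
is recorded (`MatchResult.negated`) for auditability. Rule 2's second
prepositional slot accepts {to, by, with, on, for} by default
(whitelist induced from the documented examples; a wildcard mode
exists). Rule 4 rejects when the keyword verb has any `dobj`/`prep_*`
dependent — the one exemption is *form* with `dobj` lemma *complex*.
Pairs of co-referent mentions (same entity key) are never positive;
unclassifiable instances default to negative.

## Preprocessing

Masking assigns `PROTEINk` in order of first appearance and is
invertible (`unmask ∘ mask = id`, property-tested). Parenthetical
removal deletes maximal `(...)` groups containing no protein mask and
treats unbalanced parentheses as literals. Clause splitting has no
published procedure; because it precedes parsing, the implementation is
parse-free and conservative: split at sentence-medial semicolons, and
at a comma + coordinating conjunction only when both sides contain at
least two protein masks. It is disableable, conserves tokens and
mentions, and drops-and-reports gold pairs that straddle a boundary
(how such pairs were originally scored is unknowable; both orders of
filtering are supported downstream). Overlapping entity spans keep the
longest span. Character spans are 0-based half-open; inclusive XML
`charOffset` ranges are converted on read.

## Evaluation

Precision, recall and F are computed from TP/FP/FN with the 0/0 → 0
convention. Relation identity is the corpus-wide unordered pair of
normalized entity keys (case-folded, whitespace/hyphen-normalized
surface by default; corpus-provided ids override). Aggregation is the
simple rule: one positive instance makes the relation positive, on
both the gold and the predicted side. More elaborate vote-based
aggregation is explicitly out of scope. MIpR filtering keeps relations
with ≥ k instances; gold-positive relations additionally need ≥ k
gold-positive instances (negative relations are filtered on total
count only, having no positives). Reports round to 3 decimals
(round-half-even); `EvalResult.f_score` is the exact harmonic mean of
the exact precision and recall — published tables that derive F from
already-rounded P/R can therefore differ in the third decimal, which
the acceptance tests absorb with a 2·10⁻³ tolerance.

One caveat discovered while testing: the intuitive bound
"relation-level TP ≤ instance-level TP" is *not* universal under
simple aggregation — a gold-positive relation whose only
predicted-positive instance is a gold-negative instance produces a
relation TP without any instance TP. The bound does hold whenever
predicted positives fall only on gold-positive instances (the regime
of a perfect-precision extractor), and is tested under that condition.

## Two-tier pipelining

`pipeline(tier1, tier2, instances)` implements the cascade: tier-2
only sees tier-1 rejections, and the final positive set is the union.
Consequences tested as properties: tier-1 positives are never flipped;
an always-negative tier reduces the pipeline to the other tier; labels
equal a brute-force union oracle. A tier that raises on an instance
leaves the tier-1 label in place (logged). External systems are
spliced in as label files (`ExternalLabelTier`) — their internals are
not reimplemented.

Chain features for learned tiers: the forward (root → first protein)
and backward (root → second protein) dependency chains, rendered as
(label, lemma) elements per edge; adjacent-element bigrams are the
features. Element rendering keeps both label and lemma
(`label/lemma`), restrictable to either, since the original choice is
unstated. Top-n selection (default n = 100 per direction) sorts by the
difference between forward- and backward-chain occurrence counts; ties
break by higher same-direction raw count, then lexicographic string,
so selection is deterministic and permutation-invariant. Optional
extras: the two chain lengths (counted in edges; the alternative —
tokens — is a constant offset) and the surface offset distance
(second minus first token index; adjacent proteins → 1). The shipped
reference classifier thresholds the active-bigram count, fitting the
threshold by exhaustive search for maximal training F (ties → smallest
threshold); it is a transparent, fully deterministic plug-in — any
scikit-learn estimator satisfies the same contract and is exercised in
tests, but is not required at runtime.

## Synthetic data

The generator emulates the statistical structure of an exhaustively
annotated PPI benchmark at reduced scale, not its lexical diversity or
parser-error distribution. Defaults (chosen once): 62 positive and 231
negative relations — one tenth of the reference corpus's 618/2312 —
with positive relations drawing 1 + Poisson(0.6) positive and
Poisson(1.5) negative instances (matching the reported averages of
~1.6 and ~1.5) and negative relations 1 + Poisson(0.7) instances.
Positive instances are realized from rule-matching templates (rule mix
configurable) except for a `miss_rate = 0.6` fraction phrased outside
the rule inventory, so the stand-alone extractor shows the intended
profile: perfect precision, modest instance recall, higher relation
recall. Negative instances are negated keyword sentences
(`negation_rate = 0.3`), keyword-free distractors
(`distractor_rate = 0.5`) or plain co-occurrences. Explicit
multiplicity lists override sampling so MIpR strata are exact.
Generation is byte-reproducible from the mandatory seed.

Because templates instantiate hand-built trees, passing tests show the
rules behave as specified on well-formed parses; they do not quantify
robustness to real parser errors or to annotation idiosyncrasies of
any particular corpus — experiments on external benchmark corpora
remain an optional, non-bundled exercise.

## Problem sizes

The test suite and the acceptance script run synthetic corpora of a
few hundred sentences (the default generator configuration yields
~600) and property checks over a few hundred instances; these sizes
exercise every code path while keeping the full suite in well under a
minute of compute.

## Known limitations

* No named-entity recognition and no cross-sentence relations (out of
  scope by design).
* Interaction *type* categories are recorded for reporting, never
  predicted; directionality is not modeled.
* The clause splitter is a stand-in heuristic (disableable); the
  original procedure is undocumented.
* Whether propagated conjunction edges counted toward the
  dependency-word constraint originally is unstated; counting is over
  surface tokens as operationalized above.
* Rule 6's verb slot accepts any verb by default (copula-only mode via
  config); the original formulation writes only "VERB".
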