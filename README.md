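# ppirules

High-precision rule-based extraction of protein–protein interactions
(PPIs) from biomedical sentences, with per-relation evaluation and a
two-tier classifier pipelining framework.

## The problem

Text-mining pipelines that feed interaction databases or network models
need extractors whose *false positives* are rare: one wrong edge
pollutes every downstream inference, while a missed restatement of a
known interaction costs little — the same relation is usually described
many times across a large corpus. Mainstream PPI extractors optimize
per-instance F-score and are poor fits for this regime. `ppirules`
implements the opposite design point: a small set of auditable
lexical/syntactic rules tuned for precision, an evaluation methodology
that scores *distinct relations* rather than sentence instances, and a
pipelining mechanism that lets the rules complement any existing
extractor.

## The method

Sentences are preprocessed the standard way: protein names are masked
(`PROTEIN0`, `PROTEIN1`, …), parentheticals without a protein are
removed, multi-clause sentences are split, and only sentences/clauses
with ≥ 2 proteins are parsed. Each candidate pair (Pᵢ, Pⱼ) is then
tested against eight rules in order (REL = one of 67 interaction
keywords such as *activate, bind, phosphorylate, interact*; matching
covers inflections and nominalizations):

| # | Pattern | Example |
|---|---------|---------|
| 1 | Pᵢ –nsubj→ REL ←dobj/prep\*– Pⱼ | "P0 interacts with P1" |
| 2 | REL –prep_of→ Pᵢ, –prep\*→ Pⱼ | "binding of P0 to P1" |
| 3 | REL –prep_between/of→ Pᵢ –conj_and→ Pⱼ | "interaction between P0 and P1" |
| 4 | (Pᵢ and Pⱼ) –nsubj→ REL | "P0 and P1 interact" |
| 5 | Pᵢ{-,/}Pⱼ {interaction, complex, heterodimer, product, assembly} | "P0-P1 complex" |
| 6 | Pᵢ VERB {receptor, ligand, substrate, binding protein} {for, of} Pⱼ | "P0 is a receptor for P1" |
| 7 | Pᵢ {receptor, ligand, substrate, binding protein} ( Pⱼ ) | "erythropoietin receptor (EPOR)" |
| 8 | Pᵢ {binding domain, binding site} {in, within, on, of} Pⱼ | "CD30L binding domain on … CD30" |

The first match labels the pair positive; otherwise it is negative.
Precision is protected by negation vetoes (a `neg` dependency on the
relation word, its subject, or its governing verb kills the match for
rules 1–6) and by locality constraints on the syntactic rules: the pair
must lie within a seven-word window and have at most three
dependency-bearing words between the proteins. Rules are matched on
collapsed-Stanford-style dependency labels (`prep_of`, `conj_and`,
`neg`); Universal Dependencies parses are converted internally.

**Per-relation evaluation.** Let T̂P, F̂P, F̂N count *distinct protein
pairs* (relations) predicted correctly, where one predicted-positive
instance makes a relation positive. Then

    Precision = T̂P / (T̂P + F̂P)      Recall = T̂P / (T̂P + F̂N)
    F = 2 · Precision · Recall / (Precision + Recall)

The same equations over instance counts give the conventional
per-instance metrics. Corpora can be stratified by **MIpR** — the
minimum number of instances per relation (positive relations must also
have ≥ k positive instances).

**Two-tier pipelining.** `pipeline(tier1, tier2, instances)` runs any
classifier over all instances and re-screens tier-1 rejections with the
second one; positives of either tier are final. Tiers can be the rule
engine, precomputed labels from an external system, or a model over
dependency-chain features (top-100 forward/backward root-to-protein
path bigrams, selected by cross-direction occurrence contrast).

## Worked example

```python
from ppirules.fixtures import worked_examples
from ppirules.corpus import enumerate_candidates
from ppirules.rules import classify_pair

case = worked_examples()[0]          # "PROTEIN0 interacts directly with PROTEIN1 and PROTEIN2"
for pair in enumerate_candidates(case.sentence):
    res = classify_pair(pair, case.sentence, case.tree)
    print(pair.first.mention_id, pair.second.mention_id,
          "positive" if res.matched else "negative", res.rule_id)
```

prints

```
e0 e1 positive 1
e0 e2 positive 1
e1 e2 negative None
```

— the subject–verb–preposition rule extracts both pairs involving the
subject (the second conjunct is reached through conjunction
propagation), while the conjunct pair P1–P2 itself carries no asserted
interaction. Running `python examples/02_per_relation_evaluation.py`
on a seeded synthetic corpus prints

```
instance-level: TP=34  FP=0   FN=61  P=1.000 R=0.358 F=0.527
relation-level: TP=29  FP=0   FN=33  P=1.000 R=0.468 F=0.637
```

same predictions, two views: relation-level recall is higher because a
single extracted instance per relation suffices, and the extractor's
false-positive count stays at zero in both.

The `examples/` directory holds one short script per capability
(rule extraction, per-relation evaluation, MIpR stratification,
two-tier pipelining, synthetic corpus generation); a thin CLI
(`ppirules extract|evaluate|pipeline|synth`) exposes the same
operations for file-based workflows.

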