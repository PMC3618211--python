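"""Classify the bundled worked-example sentences with the eight rules.

Each candidate protein pair is tested against the rules in order; the
first match labels it positive.  The output lists, per sentence, which
pair matched which rule, or why it stayed negative (including recorded
negation vetoes).
"""

from ppirules.corpus import enumerate_candidates
from ppirules.fixtures import worked_examples
from ppirules.rules import classify_pair

for case in worked_examples():
    print(f"\n{case.name}: {case.sentence.masked_text}")
    for pair in enumerate_candidates(case.sentence):
        res = classify_pair(pair, case.sentence, case.tree)
        a, b = pair.first.mention_id, pair.second.mention_id
        if res.matched:
            print(f"  ({a}, {b}) -> POSITIVE via rule {res.rule_id}")
        elif res.negated:
            print(f"  ({a}, {b}) -> negative (negation veto)")
        else:
            print(f"  ({a}, {b}) -> negative")

print(
    "\nA POSITIVE line means the rule engine asserts a protein-protein "
    "interaction for that pair; negation vetoes show where a structural "
    "match was suppressed by a 'not'/'no' cue."
)
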