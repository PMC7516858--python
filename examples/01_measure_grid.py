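"""Score a 2x2 sample with every confirmation measure.

A sample of 1000 observations of a rare hypothesis (prevalence 0.2) with
very few counterexamples: a=20 positive examples of e1->h1, c=8
counterexamples, and the rest test-negative.
"""

from confirmlab import ContingencyTable, Rule, measure_value
from confirmlab.properties import ALL_MEASURES

table = ContingencyTable(a=20, b=180, c=8, d=792)
rule = Rule.parse("e1->h1")

print(f"counts (a, b, c, d) = {table.as_tuple()},  rule {rule}")
for name in ALL_MEASURES:
    value, defined = measure_value(name, table, rule)
    print(f"  {name:>4s} = {value:+.3f}" if defined else f"  {name:>4s} = undefined")

print()
print("L, F and b* are large because counterexamples are rare relative to")
print("positive examples (the likelihood ratio is 10); c* = 0.6 reflects the")
print("correct rate of the prediction itself, P(h1|e1) = 20/28.")
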