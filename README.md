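# confirmlab

Confirmation measures for 2×2 evidence: how strongly does a sample
support an uncertain rule *e → h*, such as "if the test is positive, the
patient is infected" or "if it is a raven, it is black"?

The package is aimed at biostatisticians evaluating diagnostic tests and
at anyone studying inductive-logic desiderata computationally.  Evidence
is a 2×2 contingency table of example counts

|        | e1 (positive) | e0 (negative) |
|--------|---------------|---------------|
| **h1** | a             | b             |
| **h0** | c             | d             |

and a confirmation measure is a function *f(a, b, c, d)* in [−1, 1].

## What it computes

**Classical measures.**  D = P(h1|e1) − P(h1), M, R, C, Z, S,
N = P(e1|h1) − P(e1|h0), L = log₂ LR⁺, and
F = (LR⁺ − 1)/(LR⁺ + 1), with directional variants, the certainty-factor
alias CF(h→e) = Z(e→h), and logs in base 2 throughout.

**Channel confirmation b\*.**  Derived by maximizing the average semantic
information of the test result over the believable proportion of its
truth function:

    b*(e1→h1) = [P(e1|h1) − P(e1|h0)] / max(P(e1|h1), P(e1|h0))
              = (LR⁺ − 1) / max(LR⁺, 1)

b\* scores the *testing means* (the channel), like the likelihood ratio
but normalized to [−1, 1].  Probability prediction under a new prevalence
is one line: P(h1|θ_e1) = P(h1)/[1 − b\*·P(h0)].

**Prediction confirmation c\*.**  The same shape applied to the counts
sharing the rule's antecedent:

    c*(e1→h1) = (a − c) / max(a, c)

c\* scores the *probability prediction* (a transform of the correct rate,
CR = 1/(2 − c\*)).  Because it ignores e0-examples entirely it satisfies
the Nicod–Fisher criterion — a black raven raises it, a white piece of
chalk does not — which dissolves the raven paradox.

Around the measures: a property lab (symmetries HS/ES/CS/TS,
monotonicity, normalization, logicality, Nicod–Fisher, with concrete
counterexample witnesses), semantic-information machinery (truth
functions, logical probability, the optimization yielding b\*, a
maximum-mutual-information classifier), a two-test diagnosis engine, and
a seeded multinomial simulator.

## Worked example

Two COVID-19 tests disagree: the nucleic-acid test (sensitivity 0.5,
specificity 0.95) reads negative, chest CT (sensitivity 0.8, specificity
0.75) reads positive.  Which do you believe?

```python
from confirmlab import TestProfile, evaluate_test, two_test_decision

nat = TestProfile(sensitivity=0.5, specificity=0.95, prior=0.25)
ct = TestProfile(sensitivity=0.8, specificity=0.75, prior=0.25)
print(evaluate_test(nat, ["b*"])["b*"])
grid = two_test_decision(nat, ct, measure="b*")
print(grid[("-", "+")].final)
```

Running `python examples/02_two_test_diagnosis.py` prints:

```
b*(NAT+) = 0.90   b*(NAT-) = 0.47
b*(CT+) = 0.69   b*(CT-) = 0.73

decision grid (NAT result, CT result) -> final call:
  NAT+ CT+: positive
  NAT+ CT-: positive
  NAT- CT+: positive  <- overridden by CT
  NAT- CT-: negative
```

NAT's positive is extremely well confirmed (b\* = 0.90: almost no false
positives) but its negative is weak (b\* = 0.47: half the infected test
negative), so a CT positive (b\* = 0.69) overrides a NAT negative — the
call clinicians converged on in practice.  Most posterior-based measures
(Z, S, C, N, and c\*) get this decision wrong; only likelihood-ratio
measures (F, b\*) are reliable here, while conversely only c\* behaves
correctly in the raven-paradox experiment
(`examples/04_raven_paradox.py`).

Each script in `examples/` demonstrates one capability and prints a short
interpretation.  A thin CLI mirrors the library:

```sh
confirmlab measures --counts 20,180,8,792 --measures D,F,b*,c* --decimals 3
confirmlab diagnose --profile-a nat.json --profile-b ct.json
confirmlab raven --base 20,10,10,20
confirmlab reproduce test_measure_grid --check
```

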