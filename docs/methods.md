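# Methods

## Evidence model

All measures consume a 2×2 contingency table of counts (a, b, c, d) over
the four example types (e1,h1), (e0,h1), (e1,h0), (e0,h0).  Counts are
stored as non-negative reals so that expected tables implied by a test
profile (sensitivity s, specificity t, prior p, size n) are exact:
a = nps, b = np(1−s), c = n(1−p)(1−t), d = n(1−p)t.  A half-up integer
rounding view exists for export only.  All probabilities are plug-in
count ratios with no smoothing — the published grids are all computed
this way, and smoothing would silently destroy the logicality property
(±1 at zero counts).  A conditional with an empty conditioning event is
returned as `None` and propagates to an explicit `defined=False` report,
never an exception: degenerate tables must stay visible to the property
lab.  Signed infinities are reserved for genuine limits (log of zero in
R and L, infinite likelihood ratios) and are never clamped, so
monotonicity checks remain meaningful at the boundary.

## Rules and measure resolution

A rule is a directed implication between one value of the evidence
variable and one value of the hypothesis variable.  Classical measures
(D, M, R, C, Z, S, N, L, F) are defined for e-side antecedents; any such
rule is evaluated by substituting its antecedent/consequent into the
canonical e1→h1 formula shape (this is the convention that reproduces
every published test-negative value).  Z takes the confirmation branch on
ties (posterior = prior gives 0 either way).  The certainty factor of an
h→e inference is the Z of the mirrored e→h rule.

The starred measures resolve every one of the 16
(family × directed-rule) combinations through a single pair:

* **b\*** (channel): positive = P(ant|cons), counter = P(ant|¬cons),
  value = (pos − neg)/max(pos, neg).  This one formula covers the e→h
  forms, the converse h→e forms, and — because negating the consequent
  swaps the pair — Consequent Symmetry is an algebraic identity rather
  than a bolted-on sign rule.
* **c\*** (prediction): positive and counter are the two *counts* sharing
  the rule's antecedent, value = (pos − neg)/max.  Using counts rather
  than conditionals makes scale invariance and antecedent-only dependence
  explicit.
* **bF\*/cF\***: the same pairs with a sum denominator; bF\* is measure F
  exactly (checked against the four count identities
  (ad−bc)/(ad+bc+2·{ac,ab,bd,cd}) in the tests).

When both members of a pair are zero the value is undefined, not 0: a
0/0 must surface in property checks.  b\* is computed from conditionals
(so test profiles work without choosing n), with the count identity kept
as a test-side cross-check.

The negative likelihood ratio here is LR⁻ = P(e0|h0)/P(e0|h1), the
*reciprocal* of the clinical convention, so that both ratios exceed 1 for
an informative test and b\* maps them through the same transform
(LR − 1)/max(LR, 1).

## Semantic information and the derivation of b\*

A test result's meaning is a truth function over the hypothesis states.
Supported families: Gaussian bumps exp[−(x−c)²/(2σ²)] ("about c"),
logistic thresholds, explicit tabular values, and the mixture
T = b′ + (1−b′)·1[believable]: a crisp believable part plus a
tautological part of proportion b′.  The logical probability
T(θ) = Σ P(x)T(θ|x) is deliberately not normalized across labels.
Semantic information is the log-normalized truth value
I(x;θ) = log₂[T(θ|x)/T(θ)], negative for misleading predictions; its
average under a sampling distribution is a generalized KL quantity equal
to the sub-sample log-likelihood up to an additive constant (asserted to
1e−9 in the tests).  **All logs in the package are base 2**; the choice
is a convention (the published grids print R and L in bits) and affects
only R, L and the information quantities, none of the bounded measures.

Maximizing the average semantic information of the test-positive over
b′ ∈ [0, 1] has the stationary point
b′ = [P(h0|e1)/P(h0)] / [P(h1|e1)/P(h1)] = P(e1|h0)/P(e1|h1) = 1/LR⁺
(the grouping is fixed by the 1/LR⁺ identity).  The objective increases
up to that point, so the constrained argmax is min(1/LR⁺, 1) — the
clipping matters for anti-informative tables (LR⁺ < 1), where the
unconstrained stationary point leaves the unit interval.  `optimize_bprime`
returns this closed form; a numeric mode (grid step 1e−4 by default,
then a bounded scalar refinement) exists as an independent check and is
required to agree to 1e−4.  b\* = 1 − b′\* links the derivation to the
measure.  The matched truth function of a label is its transition-
probability column scaled to peak 1, which for the medical test is
exactly the mixture (1, b′\*).

## Probability prediction

`predict_from_b(prior, b*)` implements P(h1|θ) = P(h1)/[1 − b\*·P(h0)]
for b\* ≥ 0 and the consequent-symmetric branch
P(h0|θ) = P(h0)/[1 − |b\*|·P(h1)] for b\* < 0.  It takes (prior, b\*)
rather than a table because the use case is transporting a test's b\* to
populations with different prevalence.  Fed back with the sample's own
prior it reproduces P(h1|e1) exactly (a property test, both branches).
`predict_from_c` inverts c\* to the correct rate CR = 1/(2 − c\*) with
the mirrored negative branch; `predict_from_cF` is the linear map
(1 + cF\*)/2.  All prediction functions return the full {h1, h0}
distribution with P(h1|θ) as the scalar accessor, because the negative
branches naturally produce P(h0|θ).

## Maximum-mutual-information classifier

For a discrete feature x with prior P(x) and posteriors P(h1|x), a
labeling x → {e0, e1} induces a 2×2 channel.  The assignment rule scores
each x by Σᵢ P(hᵢ|x)·I(hᵢ;θ_ej) with ties to e1, and alternates with
channel/truth re-estimation.  Re-estimation makes the average semantic
information equal the Shannon mutual information of the labeling, and the
assignment step maximizes a lower bound of the next labeling's mutual
information, so the trajectory is a monotone ascent.  The ascent can
stall in local optima (observed on ~10% of random setups from a single
start).  Because the MI-optimal binary quantizer of a binary-input
channel is a likelihood-ratio threshold, the default starting set is all
|X|+1 threshold labelings in P(h1|x) order plus the max-posterior
labeling; the best fixed point reached is returned.  Iterations are
capped at 100 with cycle detection (finite alphabets converge in a
handful of steps).  An unused label re-enters via a zero information row
rather than locking out.  Continuous features are supported only through
a user-supplied discretization.  A brute-force oracle over all 2^|X|
labelings backs the tests for |X| ≤ 8.

## Property lab

Symmetry, monotonicity, normalization, logicality and Nicod–Fisher are
checked empirically — seeded random tables plus exhaustive unit-increment
grids with zero-count edges — and every `False` verdict carries a
concrete witness table; no algebraic proof is attempted.  Commutativity
Symmetry needs a converse (h→e) form and is therefore only checkable for
F and the starred measures.  Nicod–Fisher is operationalized as the
four-part condition for e1→h1: Δa=1 strictly increases the measure,
Δc=1 strictly decreases it, and Δb=1, Δd=1 leave it unchanged.  The raven
experiment reports, per measure, the base value, the value after one more
positive example, the value after one more irrelevant non-example, and
their difference.

One deliberate divergence from the received classification: measure
N = P(e1|h1) − P(e1|h0) is often listed among the non-monotone measures,
but its partial derivatives (b/(a+b)², −a/(a+b)², −d/(c+d)², c/(c+d)²)
all carry the allowed sign, so no unit-increment counterexample exists on
positive counts; exhaustive search over {0..12}⁴ confirms this.  The
suite asserts N monotone; D and M are falsified with witnesses as
expected.

## Diagnosis engine

Each test contributes two rules (test+ → infected, test− → uninfected)
scored on the expected table implied by its profile.  In a discordant
cell of the two-test grid the positive-supporting degree of one test is
compared with the negative-supporting degree of the other; the strictly
larger wins and ties are reported as undecided.  An optional belief
threshold (off by default; 0.2 reproduces the published refinement)
demands that a counted result's degree exceed the threshold, including in
concordant cells — a concordant call backed by no believed result becomes
undecided, which is what disqualifies the posterior-difference measure D.
The simulator draws multinomially from the profile's joint with a seeded
generator; an exact mode returns expected counts n·p.

## Worked-example fixtures and errata

The fixtures encode the published grids with per-cell printed precision
(comparisons use half-up rounding ± one unit in the last place, since the
sources round inconsistently, e.g. 0.69 for 0.6875).  Four printed cells
are flagged as errata and excluded from reproduction checks rather than
matched: the first comparison example's c\* (printed 0.8, formula 0.6),
the third example's N (printed 0.091, formula 0.909), the S/N values
after Δa=1 in the increment table (printed 0.334, formula 0.344), and the
two low-prevalence cells of the prediction sweep (inconsistent with
b\* = 0.9).  The implementation is never tuned toward an erratum.

## Problem sizes and numerical choices

Default check sizes — 10,000 random tables for symmetry screening,
{1..10}⁴ for monotonicity, 1,000 random tables for the optimizer
equivalence, 100 random setups (alphabet ≤ 8) for the classifier oracle,
one multinomial sample of 10⁶ for estimator convergence — were chosen so
the full battery runs in seconds while exercising the degenerate edges
(zero counts, ties, empty labels).  Symmetry identities are asserted to
1e−9, exact algebraic identities (count forms vs conditional forms,
Consequent Symmetry, round-trip predictions) to 1e−12.

## Limitations

Random-table screening can only falsify, not prove, a universal claim;
witnesses make failures reproducible but green symmetry flags are
evidence, not proof.  The synthetic evidence model is an idealized i.i.d.
multinomial world: expected tables are exact, samples are independent and
representative, and there are no covariates (the two-test engine assumes
identical symptoms across patients) — so passing tests say nothing about
stratified populations, correlated tests, or small-sample uncertainty.
Degrees of confirmation from small samples are point values here;
interval-valued confirmation and hypothesis-testing extensions are out of
scope, as are k×k tables, confidence intervals for rates, ROC analysis,
and general m×n channel algebra beyond what the 2×2 test and the finite
classifier need.
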