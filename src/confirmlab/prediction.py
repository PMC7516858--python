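"""Probability predictions from degrees of confirmation and semantic channels.

A degree of confirmation summarizes what a sample taught us about a rule;
these functions transport that summary back to probabilities:

* from b* and a (possibly new) prior:  P(h1|th_e1) = P(h1)/[1 - b* P(h0)]
  for b* >= 0, with the Consequent-Symmetry branch for b* < 0.  This is the
  use case where the prevalence changes but the test's channel quality
  does not.
* from c*: the correct rate CR = 1/(2 - c*) for c* >= 0, and the mirrored
  branch for c* < 0.
* from cF*: CR = (1 + cF*)/2.
* the semantic Bayes rule: posterior_i ∝ prior_i * truth_i for a truth
  function over a finite outcome set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Union

from .star import StarValue

Number = Union[float, StarValue]


def _scalar(x: Number, name: str) -> float:
    v = float(x)
    if isinstance(x, StarValue) and not x.defined:
        raise ValueError(f"{name} is undefined")
    if math.isnan(v):
        raise ValueError(f"{name} is undefined (NaN)")
    if abs(v) > 1 + 1e-12:
        raise ValueError(f"{name} must lie in [-1, 1], got {v}")
    return min(1.0, max(-1.0, v))


@dataclass(frozen=True)
class Prediction:
    """A predicted distribution over {h1, h0}."""

    p_h1: float
    p_h0: float

    def __float__(self) -> float:
        return float(self.p_h1)

    def as_dict(self) -> dict:
        return {"p_h1": self.p_h1, "p_h0": self.p_h0}


def predict_from_b(prior: float, bstar: Number) -> Prediction:
    """P(h|th_e1) from the prior P(h1) and a channel confirmation b*(e1->h1).

    b* = 0 returns the prior unchanged; b* = 1 returns certainty in h1.
    For b* < 0 the consequent-symmetric rule e1->h0 has degree |b*| and
    the same formula predicts P(h0|th_e1).
    """
    if not 0 < prior < 1:
        raise ValueError(f"prior must be in (0,1), got {prior}")
    b = _scalar(bstar, "b*")
    if b >= 0:
        p1 = prior / (1 - b * (1 - prior))
    else:
        p0 = (1 - prior) / (1 - abs(b) * prior)
        p1 = 1 - p0
    p1 = min(1.0, max(0.0, p1))
    return Prediction(p_h1=p1, p_h0=1 - p1)


def predict_from_c(cstar: Number) -> Prediction:
    """The correct rate implied by a prediction confirmation c*(e1->h1).

    CR = P(h1|th_e1) = 1/(2 - c*) for c* >= 0 (c* = 0 gives the
    uninformative 0.5; c* = 1 gives certainty).  For c* < 0 the mirrored
    rule gives P(h0|th_e1) = 1/(2 - |c*|).
    """
    c = _scalar(cstar, "c*")
    if c >= 0:
        p1 = 1.0 / (2.0 - c)
    else:
        p0 = 1.0 / (2.0 - abs(c))
        p1 = 1 - p0
    return Prediction(p_h1=p1, p_h0=1 - p1)


def predict_from_cF(cf: Number) -> Prediction:
    """Correct rate from cF*: CR = (1 + cF*)/2 (sum-denominator variant)."""
    v = _scalar(cf, "cF*")
    p1 = (1 + v) / 2
    return Prediction(p_h1=p1, p_h0=1 - p1)


def semantic_bayes(prior: Mapping, truth: Mapping) -> dict:
    """Posterior over a finite outcome set from a prior and a truth function.

    posterior_i = prior_i * truth_i / sum_k prior_k * truth_k.  Truth values
    must lie in [0, 1]; the result sums to 1.  Raises if every outcome with
    positive prior has zero truth value.
    """
    missing = set(prior) - set(truth)
    if missing:
        raise ValueError(f"truth values missing for outcomes {sorted(missing)}")
    weights = {}
    for outcome, p in prior.items():
        t = truth[outcome]
        if not 0 <= t <= 1:
            raise ValueError(f"truth value for {outcome!r} must be in [0,1], got {t}")
        weights[outcome] = p * t
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all prior-weighted truth values are zero; posterior undefined")
    return {outcome: w / total for outcome, w in weights.items()}
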