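"""Truth functions, logical probability, and semantic information.

A hypothesis's semantic meaning is represented by a *truth function*
T(th|x) in [0, 1] over outcomes x.  Its prior-weighted average
T(th) = sum_i P(x_i) T(th|x_i) is the *logical probability* — unlike a
statistical probability it need not normalize across hypotheses.  The
semantic information conveyed about an outcome is the log-normalized
truth value

    I(x; th) = log2[ T(th|x) / T(th) ]   (bits; negative for misleading
                                          predictions)

and averaging it under a sampling distribution gives a generalized
Kullback-Leibler quantity whose maximization over the truth function's
free parameter is equivalent to maximum likelihood.

For a binary medical test the positive result's truth function is a
*mixture*: truth 1 on the believable part (infected) and a tautological
floor b1' on the counter-instance (uninfected).  Maximizing the average
semantic information of the test-positive over b1' in [0, 1] has the
closed-form solution b1'* = P(e1|h0)/P(e1|h1) = 1/LR+ (clipped to 1 when
the test is anti-informative), the disconfirmation degree from which
b* = 1 - b1'*.

All logarithms in this package are base 2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .contingency import ContingencyTable
from .outcomes import E0, E1, H0, H1


@dataclass(frozen=True)
class TruthFunction:
    """A parametric map from outcomes (or feature values) to truth values.

    Families:

    * ``gaussian`` — exp[-(x - center)^2 / (2 sigma^2)], peaking at 1;
      models "x is about center".
    * ``logistic`` — 1/[1 + exp(-rate (x - midpoint))], monotone; models
      threshold predicates such as "x is elderly".
    * ``mixture`` — a crisp believable part (truth 1 on ``believable``
      outcomes) plus a tautological part of proportion ``b_prime``:
      T = b' + (1 - b') 1[x in believable].
    * ``tabular`` — explicit truth values per outcome.
    """

    family: str
    params: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "logistic", "mixture", "tabular"):
            raise ValueError(f"unknown truth-function family {self.family!r}")
        if self.family == "mixture":
            b = self.params.get("b_prime")
            if b is None or not 0 <= b <= 1:
                raise ValueError("mixture requires b_prime in [0,1]")
            if "believable" not in self.params:
                raise ValueError("mixture requires a 'believable' outcome collection")
        if self.family == "tabular":
            values = self.params.get("values")
            if not values:
                raise ValueError("tabular requires a non-empty 'values' mapping")
            bad = {k: v for k, v in values.items() if not 0 <= v <= 1}
            if bad:
                raise ValueError(f"tabular truth values outside [0,1]: {bad}")

    def __call__(self, x):
        if self.family == "gaussian":
            center, sigma = self.params["center"], self.params["sigma"]
            return math.exp(-((x - center) ** 2) / (2 * sigma**2))
        if self.family == "logistic":
            rate, midpoint = self.params["rate"], self.params["midpoint"]
            return 1.0 / (1.0 + math.exp(-rate * (x - midpoint)))
        if self.family == "mixture":
            b = self.params["b_prime"]
            return b + (1 - b) * (1.0 if x in self.params["believable"] else 0.0)
        return self.params["values"][x]

    # JSON schema: {"family": ..., "params": {...}}
    def to_json(self) -> str:
        params = dict(self.params)
        if self.family == "mixture":
            params["believable"] = sorted(params["believable"])
        return json.dumps({"family": self.family, "params": params})

    @classmethod
    def from_json(cls, text: str) -> "TruthFunction":
        obj = json.loads(text)
        params = dict(obj["params"])
        if obj["family"] == "mixture":
            params["believable"] = frozenset(params["believable"])
        return cls(obj["family"], params)


def mixture_truth(believable, b_prime: float) -> TruthFunction:
    """Convenience constructor for the believable-part mixture."""
    return TruthFunction("mixture", {"believable": frozenset(believable), "b_prime": b_prime})


def logical_probability(prior: Mapping, truth: TruthFunction) -> float:
    """T(th) = sum_i P(x_i) T(th|x_i); equals 1 for a tautology."""
    total = sum(prior.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"prior must sum to 1, got {total}")
    return sum(p * truth(x) for x, p in prior.items())


def semantic_information(outcome, truth: TruthFunction, prior: Mapping) -> float:
    """I(x; th) = log2[T(th|x)/T(th)] in bits; -inf when the truth value is 0."""
    t_theta = logical_probability(prior, truth)
    if t_theta <= 0:
        raise ValueError("logical probability is zero; information undefined")
    t = truth(outcome)
    if t == 0:
        return -math.inf
    return math.log2(t / t_theta)


def avg_semantic_information(sampling: Mapping, truth: TruthFunction, prior: Mapping) -> float:
    """Expectation of I(x; th) under a sampling distribution.

    When the implied likelihood matches the sampling distribution this is
    the Kullback-Leibler divergence of the sampling distribution from the
    prior; a tautological truth function gives 0.
    """
    total = sum(sampling.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"sampling distribution must sum to 1, got {total}")
    out = 0.0
    for x, w in sampling.items():
        if w == 0:
            continue
        out += w * semantic_information(x, truth, prior)
    return out


# ---------------------------------------------------------------------------
# The believable-proportion objective for the test-positive rule


def mixture_information(table: ContingencyTable, b_prime) -> np.ndarray | float:
    """Average semantic information of the test-positive truth mixture.

    I(h; th_e1) = P(h0|e1) log2[b'/T] + P(h1|e1) log2[1/T] with
    T = P(h1) + b' P(h0).  Vectorized over ``b_prime`` (scalar or array).
    """
    p_h1 = table.prob(H1)
    p_h0 = table.prob(H0)
    p1 = table.cond(H1, E1)
    if p1 is None:
        raise ValueError("table has no positive test results; objective undefined")
    p0 = 1.0 - p1
    b = np.asarray(b_prime, dtype=float)
    t_theta = p_h1 + b * p_h0
    with np.errstate(divide="ignore"):
        term0 = np.where(p0 > 0, p0 * (np.log2(np.maximum(b, 0.0)) - np.log2(t_theta)), 0.0)
    term1 = -p1 * np.log2(t_theta)
    out = term0 + term1
    if np.isscalar(b_prime):
        return float(out)
    return out


def optimize_bprime(
    table: ContingencyTable,
    method: str = "closed",
    grid_step: float = 1e-4,
) -> float:
    """The believable-part proportion b1'* maximizing the information objective.

    ``method="closed"`` returns the stationary point
    [P(h0|e1)/P(h0)] / [P(h1|e1)/P(h1)] = P(e1|h0)/P(e1|h1) = 1/LR+,
    clipped to [0, 1] (the objective is increasing below the stationary
    point, so the clipped value is the constrained argmax when LR+ < 1).
    ``method="grid"`` maximizes the objective numerically on a grid of the
    given step followed by a bounded local refinement; the two must agree.
    """
    p1e1 = table.cond(E1, H1)
    p1e0 = table.cond(E1, H0)
    if p1e1 is None or p1e0 is None or p1e1 == 0:
        raise ValueError("rule e1->h1 has no positive examples; b'* undefined")
    if method == "closed":
        return min(1.0, p1e0 / p1e1)
    if method != "grid":
        raise ValueError("method must be 'closed' or 'grid'")
    grid = np.arange(0.0, 1.0 + grid_step, grid_step)
    grid = np.clip(grid, 0.0, 1.0)
    values = mixture_information(table, grid)
    best = float(grid[int(np.nanargmax(values))])
    lo = max(0.0, best - grid_step)
    hi = min(1.0, best + grid_step)
    res = minimize_scalar(
        lambda b: -mixture_information(table, float(b)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    refined = float(res.x)
    return refined if mixture_information(table, refined) >= mixture_information(table, best) else best


def optimize_truth_function(table: ContingencyTable, label: str) -> TruthFunction:
    """The matched (tabular) truth function of a test result over {h1, h0}.

    Truth values are the label's transition probabilities scaled so the
    maximum is 1: T*(th|h) = P(label|h)/max_h P(label|h).  For the
    test-positive of an informative test this is the mixture (1, b'*).
    """
    if label not in (E1, E0):
        raise ValueError(f"label must be e1 or e0, got {label!r}")
    col = {h: table.cond(label, h) for h in (H1, H0)}
    if any(v is None for v in col.values()):
        raise ValueError("table is degenerate in h; truth function undefined")
    peak = max(col.values())
    if peak == 0:
        raise ValueError(f"label {label} never occurs; truth function undefined")
    return TruthFunction("tabular", {"values": {h: v / peak for h, v in col.items()}})


def conditional_log_likelihood(table: ContingencyTable, truth: TruthFunction) -> float:
    """Log-likelihood (base 2) of the e1-conditioned sub-sample under P(h|th_e1).

    With N1 = a + c positive results, L = sum_i N_1i log2 P(h_i|th_e1) where
    the predicted posterior comes from the semantic Bayes rule.  Linked to
    the average semantic information by
    L/N1 = I(h; th_e1) + sum_i P(h_i|e1) log2 P(h_i).
    """
    from .prediction import semantic_bayes

    prior = {H1: table.prob(H1), H0: table.prob(H0)}
    posterior = semantic_bayes(prior, {H1: truth(H1), H0: truth(H0)})
    out = 0.0
    for h, count in ((H1, table.a), (H0, table.c)):
        if count == 0:
            continue
        p = posterior[h]
        if p == 0:
            return -math.inf
        out += count * math.log2(p)
    return out
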