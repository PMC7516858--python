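"""Maximum-mutual-information binary labeling of a discrete feature.

Setup: a feature x with finite alphabet, prior P(x), and posteriors
P(h1|x) linking it to a binary ground truth h.  A labeling f: x -> {e0, e1}
induces a 2x2 channel P(e|h).  The label-assignment rule scores each
feature value by its expected semantic information under each label's
matched truth function,

    e*(x) = argmax_j  P(h0|x) I(h0; th_ej) + P(h1|x) I(h1; th_ej),

and alternating assignment with channel/truth re-estimation is a monotone
ascent on the Shannon mutual information I(E; H): re-estimation makes the
average semantic information equal the mutual information, and the
assignment step can only increase it.  The ascent can stall in a local
optimum, so :func:`optimize_classifier` runs a small deterministic set of
starting labelings and returns the best fixed point reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

E0_LABEL = 0
E1_LABEL = 1


def _validate(px: np.ndarray, ph1_given_x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    px = np.asarray(px, dtype=float)
    ph1 = np.asarray(ph1_given_x, dtype=float)
    if px.ndim != 1 or px.size == 0:
        raise ValueError("feature alphabet must be non-empty")
    if px.shape != ph1.shape:
        raise ValueError("P(x) and P(h1|x) must have the same length")
    if np.any(px < 0) or not math.isclose(px.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("P(x) must be a distribution")
    if np.any((ph1 < 0) | (ph1 > 1)):
        raise ValueError("P(h1|x) must lie in [0,1]")
    return px, ph1


def channel_from_labels(px: np.ndarray, ph1_given_x: np.ndarray, labels: Sequence[int]) -> np.ndarray:
    """P(e|h) as a 2x2 array indexed [h (0/1), e (0/1)] for a labeling."""
    px, ph1 = _validate(px, ph1_given_x)
    labels = np.asarray(labels, dtype=int)
    joint_h1 = px * ph1  # P(x, h1)
    joint_h0 = px * (1 - ph1)
    p_h1 = joint_h1.sum()
    p_h0 = joint_h0.sum()
    out = np.zeros((2, 2))
    for e in (E0_LABEL, E1_LABEL):
        mask = labels == e
        out[1, e] = joint_h1[mask].sum() / p_h1 if p_h1 > 0 else 0.0
        out[0, e] = joint_h0[mask].sum() / p_h0 if p_h0 > 0 else 0.0
    return out


def mutual_information(px: np.ndarray, ph1_given_x: np.ndarray, labels: Sequence[int]) -> float:
    """Shannon mutual information I(E; H) in bits for a labeling."""
    px, ph1 = _validate(px, ph1_given_x)
    labels = np.asarray(labels, dtype=int)
    joint = np.zeros((2, 2))  # [h, e]
    for e in (E0_LABEL, E1_LABEL):
        mask = labels == e
        joint[1, e] = (px * ph1)[mask].sum()
        joint[0, e] = (px * (1 - ph1))[mask].sum()
    ph = joint.sum(axis=1)
    pe = joint.sum(axis=0)
    mi = 0.0
    for i in (0, 1):
        for j in (0, 1):
            p = joint[i, j]
            if p > 0:
                mi += p * math.log2(p / (ph[i] * pe[j]))
    return mi


def _semantic_info_matrix(channel: np.ndarray, ph: np.ndarray) -> np.ndarray:
    """I(h_i; th_ej) from a channel via matched truth functions.

    Truth values are each label's column scaled to peak 1; the logical
    probability is the prior-weighted truth.  An unused label (all-zero
    column) conveys no information: its row of the matrix is 0, so it can
    be re-entered by the assignment step.
    """
    info = np.zeros((2, 2))  # [h, e]
    for e in (0, 1):
        col = channel[:, e]
        peak = col.max()
        if peak == 0:
            continue
        truth = col / peak
        t_theta = float(ph @ truth)
        for i in (0, 1):
            info[i, e] = math.log2(truth[i] / t_theta) if truth[i] > 0 else -math.inf
    return info


def classify(
    px: np.ndarray,
    ph1_given_x: np.ndarray,
    info: np.ndarray,
) -> np.ndarray:
    """Assign each feature value the label with larger expected information.

    ``info`` is the 2x2 matrix I(h_i; th_ej) indexed [h, e].  Ties go to
    the positive label e1.
    """
    px, ph1 = _validate(px, ph1_given_x)
    score = np.empty((px.size, 2))
    for e in (0, 1):
        score[:, e] = (1 - ph1) * info[0, e] + ph1 * info[1, e]
    # nan from 0 * -inf means "impossible h under this label but P(h|x)=0"
    score = np.nan_to_num(score, nan=0.0, neginf=-1e18)
    return np.where(score[:, 1] >= score[:, 0], E1_LABEL, E0_LABEL)


@dataclass
class ClassifierResult:
    labels: Tuple[int, ...]
    mutual_information: float
    trajectory: List[float]
    iterations: int
    converged: bool
    cycle_detected: bool = False


def _ascend(px, ph1, labels: np.ndarray, ph: np.ndarray, max_iter: int) -> ClassifierResult:
    seen = {tuple(labels)}
    trajectory = [mutual_information(px, ph1, labels)]
    converged = False
    cycle = False
    it = 0
    for it in range(1, max_iter + 1):
        channel = channel_from_labels(px, ph1, labels)
        info = _semantic_info_matrix(channel, ph)
        new_labels = classify(px, ph1, info)
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        trajectory.append(mutual_information(px, ph1, labels))
        key = tuple(labels)
        if key in seen:
            cycle = True
            break
        seen.add(key)
    return ClassifierResult(
        labels=tuple(int(v) for v in labels),
        mutual_information=trajectory[-1],
        trajectory=trajectory,
        iterations=it,
        converged=converged,
        cycle_detected=cycle,
    )


def optimize_classifier(
    px: Sequence[float],
    ph1_given_x: Sequence[float],
    max_iter: int = 100,
    starts: Optional[Sequence[Sequence[int]]] = None,
) -> ClassifierResult:
    """Best fixed point of the assignment/re-estimation alternation.

    Default starts are the |X| + 1 threshold labelings in P(h1|x) order
    (for a binary ground truth the mutual-information-optimal binary
    quantizer is a likelihood-ratio threshold, so this set contains a
    globally optimal labeling) plus the maximum-posterior labeling.  Each
    start runs the monotone ascent; the fixed point with the largest
    mutual information is returned, with its non-decreasing trajectory.
    """
    px, ph1 = _validate(px, ph1_given_x)
    ph = np.array([float((px * (1 - ph1)).sum()), float((px * ph1).sum())])
    if starts is None:
        order = np.argsort(ph1)
        starts = []
        for k in range(px.size + 1):
            labels = np.zeros(px.size, dtype=int)
            labels[order[k:]] = E1_LABEL
            starts.append(labels)
        starts.append(np.where(ph1 >= 0.5, E1_LABEL, E0_LABEL))
    best: Optional[ClassifierResult] = None
    for start in starts:
        result = _ascend(px, ph1, np.asarray(start, dtype=int), ph, max_iter)
        if best is None or result.mutual_information > best.mutual_information:
            best = result
    assert best is not None
    return best


def exhaustive_max_mutual_information(
    px: Sequence[float], ph1_given_x: Sequence[float]
) -> Tuple[float, Tuple[int, ...]]:
    """Brute-force maximum of I(E; H) over all 2^|X| labelings (oracle)."""
    px, ph1 = _validate(px, ph1_given_x)
    m = px.size
    if m > 20:
        raise ValueError("exhaustive search is limited to small alphabets")
    best_mi, best_labels = -1.0, None
    for code in range(2**m):
        labels = [(code >> k) & 1 for k in range(m)]
        mi = mutual_information(px, ph1, labels)
        if mi > best_mi:
            best_mi, best_labels = mi, tuple(labels)
    return best_mi, best_labels
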