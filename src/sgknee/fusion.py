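"""Decision-level fusion of per-view confidence scores.

Each view's model emits a class-confidence vector (softmax output).  For a
class j the three views' confidences are compared against the *ideal
solution*: the all-ones vector a perfectly confident ensemble would emit.
Three dissimilarity measures — Euclidean, Manhattan and cosine distance —
are multiplied into a single fuzzy distance

    I_j = ||1 - S_j||_2  *  sum|1 - S_j|  *  (1 - cos<(S_aj, S_cj, S_sj), 1>)

and the predicted class is argmin_j I_j: the class whose scores sit closest
to unanimous certainty.

The product form has one degenerate corner: if every view emits *exactly*
the same confidence for class j, the score triple is perfectly collinear
with the ideal direction and the cosine factor — hence the whole product —
vanishes for that class no matter how low the confidence is.  Generic
softmax outputs never tie exactly, but to keep the rule deterministic and
sensible there, ties in the argmin fall back to the cosine-free product
(Euclidean x Manhattan) and only then to the lowest class index.

Single-view mode degenerates gracefully: the cosine term of a scalar
against the scalar ideal is identically 0, so every I_j collapses to 0 and
the rule falls back to argmax of the score vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FusionInput", "DistanceTriple", "distance_vector", "fuse", "fused_positive_score"]


@dataclass
class FusionInput:
    """Per-view confidence scores for one sample, rows = views.

    ``scores`` has shape (V, J): V views (3 for axial/coronal/sagittal,
    1 in single-view mode) by J classes; every row sums to 1.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2:
            raise ValueError("scores must be a (views, classes) matrix")
        if s.shape[1] < 2:
            raise ValueError("need at least 2 classes")
        if np.any(s < -1e-9):
            raise ValueError("scores must be nonnegative")
        if not np.allclose(s.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each view's score vector must sum to 1")
        self.scores = s

    @property
    def n_views(self) -> int:
        return self.scores.shape[0]

    @property
    def n_classes(self) -> int:
        return self.scores.shape[1]


@dataclass
class DistanceTriple:
    """Per-class distances to the ideal vector and their product I_j."""

    P_E: np.ndarray
    P_M: np.ndarray
    P_C: np.ndarray

    @property
    def I(self) -> np.ndarray:
        return self.P_E * self.P_M * self.P_C


def distance_vector(inp: FusionInput, j: int) -> np.ndarray:
    """P_j = (1 - S_vj) across views: component-wise distance to the ideal."""
    if not 0 <= j < inp.n_classes:
        raise IndexError(f"class index {j} out of range [0, {inp.n_classes})")
    return 1.0 - inp.scores[:, j]


def _cosine_distance_to_ideal(v: np.ndarray) -> float:
    """1 - cosine similarity between a score vector and the all-ones vector.

    A degenerate all-zero vector has no direction and is treated as
    maximally distant (distance 1).
    """
    n = np.linalg.norm(v)
    if n < 1e-12:
        return 1.0
    d = float(1.0 - np.sum(v) / (n * np.sqrt(len(v))))
    # snap float noise so an exactly collinear triple gives exactly 0
    return 0.0 if abs(d) < 1e-12 else d


def fuse(inp: FusionInput) -> tuple[int, DistanceTriple]:
    """Fuzzy-distance fusion: predicted class = argmin_j I_j.

    Ties break by the cosine-free product P_E * P_M, then by lowest class
    index.  In single-view mode the cosine term is 0 for every class, so
    the rule falls back to argmax of the score vector.
    """
    if inp.n_views == 1:
        y = int(np.argmax(inp.scores[0]))
        zeros = np.zeros(inp.n_classes)
        return y, DistanceTriple(P_E=zeros, P_M=zeros, P_C=zeros)

    J = inp.n_classes
    P_E = np.empty(J)
    P_M = np.empty(J)
    P_C = np.empty(J)
    for j in range(J):
        p = distance_vector(inp, j)
        P_E[j] = np.linalg.norm(p)
        P_M[j] = np.sum(np.abs(p))
        P_C[j] = _cosine_distance_to_ideal(inp.scores[:, j])
    triple = DistanceTriple(P_E=P_E, P_M=P_M, P_C=P_C)
    I = triple.I
    y = min(range(J), key=lambda j: (I[j], P_E[j] * P_M[j], j))
    return int(y), triple


def fused_positive_score(inp: FusionInput) -> float:
    """Continuous tear score in [0, 1] for ROC analysis (binary only).

    I_j is a distance (smaller = closer to the ideal for class j), so the
    normalized complement I_0 / (I_0 + I_1) rises toward 1 as the views
    collectively favour the tear class.  This is an artifact convention for
    threshold-free evaluation of the argmin rule, not part of the rule.
    """
    if inp.n_classes != 2:
        raise ValueError("fused_positive_score is defined for binary problems")
    if inp.n_views == 1:
        return float(inp.scores[0, 1])
    _, triple = fuse(inp)
    I0, I1 = triple.I
    if I0 + I1 < 1e-300:
        d0 = triple.P_E[0] * triple.P_M[0]
        d1 = triple.P_E[1] * triple.P_M[1]
        return 0.5 if d0 + d1 < 1e-300 else float(d0 / (d0 + d1))
    return float(I0 / (I0 + I1))
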