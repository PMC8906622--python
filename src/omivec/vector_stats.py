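"""Discriminant-plane vector statistics.

The geometry of condition clusters on the 2D LDA plane is summarized by

* the Dissimilarity Coefficient ``r = sqrt((x2-x1)^2 + (y2-y1)^2)`` --
  the Euclidean distance between two condition centroids, measuring how
  far disease state has moved between conditions;
* ratios of such distances between condition pairs;
* trajectories -- polylines through condition centroids in temporal
  order, whose segment lengths are Dissimilarity Coefficients; and
* the Disease Severity Index ``D = sum rho_x * rho_y * r_xy`` over all
  cross-condition sample pairs (x in A, y in B), where ``rho`` is each
  point's distance from a reference center (the grand mean of all
  embedded samples by default) and ``r_xy`` the distance between the two
  points.  D grows when both conditions sit far from the center AND far
  from each other, i.e. with overall displacement of the disease state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .discriminant import Embedding2D
from .model import ConditionKey, DegenerateInputError


@dataclass(frozen=True)
class PlanePoint:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite plane point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _as_xy(p) -> np.ndarray:
    if isinstance(p, PlanePoint):
        return p.as_array()
    arr = np.asarray(p, dtype=float)
    if arr.shape != (2,):
        raise ValueError(f"expected a 2D point, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"non-finite plane point {arr}")
    return arr


def dissimilarity_coefficient(p1, p2) -> float:
    """Euclidean distance between two points on the discriminant plane."""
    a, b = _as_xy(p1), _as_xy(p2)
    return float(np.hypot(*(b - a)))


def dissimilarity_ratio(
    e: Embedding2D,
    pair_numerator: tuple[ConditionKey, ConditionKey],
    pair_denominator: tuple[ConditionKey, ConditionKey],
) -> float:
    """Ratio of centroid distances r(numerator pair) / r(denominator pair)."""
    num = dissimilarity_coefficient(e.centroid(pair_numerator[0]), e.centroid(pair_numerator[1]))
    den = dissimilarity_coefficient(
        e.centroid(pair_denominator[0]), e.centroid(pair_denominator[1])
    )
    if den == 0.0:
        raise DegenerateInputError(f"zero centroid distance for denominator pair {pair_denominator}")
    return num / den


@dataclass
class SeverityTerms:
    """Decomposition of the Disease Severity Index for inspection.

    ``rho_a``/``rho_b`` are each sample's distance from the center;
    ``pair_distances`` is the full cross-pair distance matrix (A x B).
    """

    center: np.ndarray
    rho_a: np.ndarray
    rho_b: np.ndarray
    pair_distances: np.ndarray

    @property
    def total(self) -> float:
        return float(np.sum(self.rho_a[:, None] * self.rho_b[None, :] * self.pair_distances))


def severity_terms(
    e: Embedding2D,
    cond_a: ConditionKey,
    cond_b: ConditionKey,
    center="global-mean",
) -> SeverityTerms:
    """Compute the per-pair terms of the Disease Severity Index."""
    for cond in (cond_a, cond_b):
        if cond not in e.groups:
            raise KeyError(f"condition {cond} not in embedding")
        if not e.groups[cond]:
            raise KeyError(f"condition {cond} has no samples")
    if isinstance(center, str):
        if center != "global-mean":
            raise ValueError(f"unknown center rule {center!r}")
        c = e.coordinates.to_numpy().mean(axis=0)
    else:
        c = _as_xy(center)
    A = e.coordinates.loc[e.groups[cond_a]].to_numpy()
    B = e.coordinates.loc[e.groups[cond_b]].to_numpy()
    return SeverityTerms(
        center=c,
        rho_a=np.linalg.norm(A - c, axis=1),
        rho_b=np.linalg.norm(B - c, axis=1),
        pair_distances=cdist(A, B),
    )


def disease_severity_index(
    e: Embedding2D,
    cond_a: ConditionKey,
    cond_b: ConditionKey,
    center="global-mean",
) -> float:
    """D = sum over cross pairs (x in A, y in B) of rho_x * rho_y * r_xy.

    Symmetric in the two conditions; zero when all points coincide with
    the center; scales as s^3 under uniform scaling about the center.
    """
    return severity_terms(e, cond_a, cond_b, center=center).total


@dataclass
class Trajectory:
    """Ordered polyline of condition centroids with per-segment lengths."""

    points: list[tuple[ConditionKey, np.ndarray]]
    segment_lengths: list[float]


def trajectory(e: Embedding2D, ordered_conditions: Sequence[ConditionKey]) -> Trajectory:
    """Centroid polyline through ``ordered_conditions`` (length >= 2)."""
    conds = list(ordered_conditions)
    if len(conds) < 2:
        raise ValueError("trajectory needs at least 2 conditions")
    pts = [(c, e.centroid(c)) for c in conds]  # KeyError if unknown
    lengths = [
        dissimilarity_coefficient(pts[i][1], pts[i + 1][1]) for i in range(len(pts) - 1)
    ]
    return Trajectory(points=pts, segment_lengths=lengths)
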