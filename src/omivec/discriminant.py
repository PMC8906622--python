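"""Multi-class Fisher LDA ordination, robust to p >> n.

Samples are projected onto the top-2 discriminant axes of the Fisher
criterion (between-class vs within-class scatter).  With only 3 replicates
per condition against hundreds or thousands of features the within-class
scatter is singular, so it is shrunk toward a scaled identity
(Ledoit-Wolf intensity by default) before solving the generalized
eigenproblem.  Axis signs follow a fixed convention -- the
largest-magnitude loading of each axis is positive -- so trajectories are
reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.covariance import ledoit_wolf

from .model import (
    ConditionKey,
    DegenerateInputError,
    FeatureTable,
    InsufficientReplicationError,
    group_samples,
)


@dataclass
class Embedding2D:
    """Per-sample 2D discriminant-plane coordinates plus condition geometry.

    ``coordinates`` is indexed by sample id with columns LD1/LD2;
    ``loadings`` maps each (scaled) feature to its 2-vector of axis
    weights; ``explained_ratio`` gives each axis's share of the positive
    discriminant eigenvalue mass.
    """

    coordinates: pd.DataFrame
    groups: dict[ConditionKey, list[str]]
    loadings: pd.DataFrame
    explained_ratio: np.ndarray

    def centroid(self, cond: ConditionKey) -> np.ndarray:
        if cond not in self.groups:
            raise KeyError(f"condition {cond} not in embedding")
        return self.coordinates.loc[self.groups[cond]].to_numpy().mean(axis=0)


def centroids(e: Embedding2D) -> dict[ConditionKey, np.ndarray]:
    """Arithmetic mean of member coordinates per condition."""
    return {cond: e.centroid(cond) for cond in e.groups}


def _scatter_matrices(X: np.ndarray, labels: np.ndarray):
    """Between-class and (pooled) within-class covariance of rows of X."""
    n, p = X.shape
    classes = np.unique(labels)
    g = len(classes)
    grand = X.mean(axis=0)
    Sb = np.zeros((p, p))
    Sw = np.zeros((p, p))
    within_centered = np.empty_like(X)
    for c in classes:
        mask = labels == c
        mu = X[mask].mean(axis=0)
        d = (mu - grand)[:, None]
        Sb += mask.sum() * (d @ d.T)
        within_centered[mask] = X[mask] - mu
        Sw += within_centered[mask].T @ within_centered[mask]
    Sb /= max(g - 1, 1)
    Sw /= max(n - g, 1)
    return Sb, Sw, within_centered


def lda_project(
    t: FeatureTable,
    groups: dict[ConditionKey, list[str]] | None = None,
    shrinkage: float | str = "auto",
    scale: bool = True,
) -> Embedding2D:
    """Project samples of ``t`` onto the 2D Fisher discriminant plane.

    Parameters
    ----------
    groups
        Condition -> sample-id partition; defaults to grouping by the
        table's metadata.
    shrinkage
        Within-scatter shrinkage intensity in [0, 1], or ``"auto"`` for a
        Ledoit-Wolf estimate.  The regularized within-class covariance is
        ``(1 - g) * Sw + g * (tr(Sw)/p) * I``.
    scale
        Center and unit-variance scale features first (constant features
        are left centered only).
    """
    if groups is None:
        groups = group_samples(t)
    if len(groups) < 3:
        raise DegenerateInputError(
            f"need >= 3 condition groups for a 2D discriminant plane, got {len(groups)}"
        )
    for cond, ids in groups.items():
        if len(ids) < 2:
            raise InsufficientReplicationError(f"group {cond} has {len(ids)} sample(s); need >= 2")

    order = [sid for ids in groups.values() for sid in ids]
    X = t.values.loc[order].to_numpy(dtype=float)
    labels = np.concatenate(
        [np.full(len(ids), i) for i, ids in enumerate(groups.values())]
    )
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)

    Sb, Sw, within_centered = _scatter_matrices(X, labels)
    if not np.any(np.abs(Sb) > 1e-12):
        raise DegenerateInputError("zero between-class scatter (all group means identical)")

    p = X.shape[1]
    if shrinkage == "auto":
        _, gamma = ledoit_wolf(within_centered, assume_centered=True)
        gamma = float(gamma)
    else:
        gamma = float(shrinkage)
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("shrinkage must be in [0, 1] or 'auto'")
    nu = np.trace(Sw) / p
    if nu <= 0:
        nu = 1.0  # no within-class variation at all; identity target
    Sw_reg = (1.0 - gamma) * Sw + gamma * nu * np.eye(p)

    try:
        eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw_reg)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as err:
        raise DegenerateInputError(
            "singular within-class scatter; increase shrinkage (e.g. 'auto')"
        ) from err
    # eigh returns ascending order; take top 2 discriminant axes
    idx = np.argsort(eigvals)[::-1][:2]
    W = eigvecs[:, idx]
    lams = np.clip(eigvals, 0.0, None)
    total = lams.sum()
    explained = lams[idx] / total if total > 0 else np.zeros(2)

    # sign convention: largest-magnitude loading of each axis is positive
    for j in range(W.shape[1]):
        k = int(np.argmax(np.abs(W[:, j])))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]

    coords = X @ W
    coordinates = pd.DataFrame(coords, index=order, columns=["LD1", "LD2"])
    loadings = pd.DataFrame(W, index=t.feature_ids, columns=["LD1", "LD2"])
    return Embedding2D(
        coordinates=coordinates,
        groups={c: list(ids) for c, ids in groups.items()},
        loadings=loadings,
        explained_ratio=np.asarray(explained, dtype=float),
    )
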