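"""Differential-feature shortlisting between two conditions.

A feature is shortlisted when it is statistically significantly altered
(Welch two-sample t-test on natural-log values, Benjamini-Hochberg
adjusted) AND its fold change passes the 1.5-fold cutoff in either
direction.  Zeros are replaced by half the smallest positive value in the
table before log transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ConditionKey, FeatureTable, InsufficientReplicationError, group_samples


@dataclass
class DifferentialResult:
    feature_id: str
    mean_a: float
    mean_b: float
    fold_change: float  # b over a
    p_value: float
    adjusted_p: float
    selected: bool


def _pseudo_value(values: np.ndarray) -> float:
    pos = values[values > 0]
    if pos.size == 0:
        return 1.0  # all-zero table; any positive constant keeps logs finite
    return float(pos.min()) / 2.0


def differential_test(
    t: FeatureTable,
    a: ConditionKey,
    b: ConditionKey,
    alpha: float = 0.05,
    fc_cutoff: float = 1.5,
) -> list[DifferentialResult]:
    """Welch t + BH + two-sided fold-change shortlisting of ``b`` vs ``a``.

    ``selected`` is True iff adjusted p <= ``alpha`` and fold change
    (mean_b / mean_a, computed after zero replacement) is >= ``fc_cutoff``
    or <= 1/``fc_cutoff``.
    """
    if fc_cutoff < 1:
        raise ValueError("fc_cutoff must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    groups = group_samples(t)
    for cond in (a, b):
        if cond not in groups:
            raise KeyError(f"condition {cond} not present in table")
        if len(groups[cond]) < 2:
            raise InsufficientReplicationError(
                f"condition {cond} has {len(groups[cond])} sample(s); need >= 2"
            )
    pseudo = _pseudo_value(t.values.to_numpy(dtype=float))
    xa = t.values.loc[groups[a]].to_numpy(dtype=float)
    xb = t.values.loc[groups[b]].to_numpy(dtype=float)
    la = np.log(np.where(xa > 0, xa, pseudo))
    lb = np.log(np.where(xb > 0, xb, pseudo))

    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(la, lb, axis=0, equal_var=False)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # zero-variance features
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    adjusted = np.maximum(adjusted, pvals)

    mean_a = np.where(xa > 0, xa, pseudo).mean(axis=0)
    mean_b = np.where(xb > 0, xb, pseudo).mean(axis=0)
    fc = mean_b / mean_a
    selected = (adjusted <= alpha) & ((fc >= fc_cutoff) | (fc <= 1.0 / fc_cutoff))

    return [
        DifferentialResult(
            feature_id=str(fid),
            mean_a=float(mean_a[j]),
            mean_b=float(mean_b[j]),
            fold_change=float(fc[j]),
            p_value=float(pvals[j]),
            adjusted_p=float(adjusted[j]),
            selected=bool(selected[j]),
        )
        for j, fid in enumerate(t.feature_ids)
    ]


def selected_features(results: list[DifferentialResult]) -> set[str]:
    return {r.feature_id for r in results if r.selected}


def shortlist_matrix(
    t: FeatureTable,
    contrasts: list[tuple[ConditionKey, ConditionKey]],
    alpha: float = 0.05,
    fc_cutoff: float = 1.5,
) -> dict[tuple[ConditionKey, ConditionKey], set[str]]:
    """Apply :func:`differential_test` to each contrast; map contrast -> selected set."""
    return {
        (a, b): selected_features(differential_test(t, a, b, alpha=alpha, fc_cutoff=fc_cutoff))
        for a, b in contrasts
    }


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Tabular view of differential results for TSV export."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "fold_change": [r.fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "selected": [r.selected for r in results],
        }
    ).set_index("feature_id")
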