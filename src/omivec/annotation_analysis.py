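"""Annotation-driven analytics: pro/anti-inflammatory ratios, overlap
(Venn) counts, the clinical disease-severity score, and condition-level
correlation between inflammation markers, taxa and metabolic categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (
    AnnotationError,
    AnnotationTable,
    ClinicalRecord,
    ConditionKey,
    FeatureTable,
    group_samples,
)


@dataclass
class RatioEntry:
    """Pro/anti/neutral counts of a shortlist plus the pro:anti ratio.

    ``ratio`` is None (serialized as the explicit string "undefined") when
    no anti-labelled feature was shortlisted.
    """

    n_pro: int
    n_anti: int
    n_neutral: int
    ratio: float | None

    @property
    def undefined(self) -> bool:
        return self.ratio is None

    @property
    def total(self) -> int:
        return self.n_pro + self.n_anti + self.n_neutral


def pro_anti_ratio(selected: Iterable[str], annotation: AnnotationTable) -> RatioEntry:
    """Count shortlisted features by inflammation label and form n_pro/n_anti."""
    feats = list(selected)
    missing = [f for f in feats if f not in annotation.labels.index]
    if missing:
        raise AnnotationError(f"unannotated features: {sorted(missing)}")
    labels = [annotation.label_of(f) for f in feats]
    n_pro = labels.count("pro")
    n_anti = labels.count("anti")
    n_neutral = labels.count("neutral")
    ratio = (n_pro / n_anti) if n_anti > 0 else None
    return RatioEntry(n_pro=n_pro, n_anti=n_anti, n_neutral=n_neutral, ratio=ratio)


@dataclass
class OverlapReport:
    """Common/unique cardinalities of two feature sets (a two-set Venn)."""

    n_common: int
    n_unique_left: int
    n_unique_right: int


def overlap_counts(left: Iterable[str], right: Iterable[str]) -> OverlapReport:
    ls, rs = set(left), set(right)
    return OverlapReport(
        n_common=len(ls & rs),
        n_unique_left=len(ls - rs),
        n_unique_right=len(rs - ls),
    )


@dataclass
class SeverityScore:
    """Component grades (0-4 each) and total (0-12) per sample."""

    sample_id: str
    weight_grade: int
    stool_grade: int
    blood_grade: int

    @property
    def total(self) -> int:
        return self.weight_grade + self.stool_grade + self.blood_grade


def _weight_grade(weight_change: float, bands: list[dict]) -> int:
    loss = max(0.0, -float(weight_change))
    for band in bands:
        if loss < float(band["upper"]):
            return int(band["grade"])
    return int(bands[-1]["grade"])


def clinical_severity_score(
    records: list[ClinicalRecord], rubric: Mapping
) -> list[SeverityScore]:
    """Grade clinical records on the disease-activity rubric.

    The rubric maps percent weight-loss bands to 0-4 grades
    (``weight_loss_bands``: list of {upper, grade}, applied as
    loss < upper); stool and blood grades pass through.
    """
    bands = rubric["weight_loss_bands"]
    out = []
    for r in records:
        if not np.isfinite(r.weight_change):
            raise ValueError(f"non-finite weight change for {r.sample_id!r}")
        out.append(
            SeverityScore(
                sample_id=r.sample_id,
                weight_grade=_weight_grade(r.weight_change, bands),
                stool_grade=int(r.stool_grade),
                blood_grade=int(r.blood_grade),
            )
        )
    return out


@dataclass
class CorrelationMatrix:
    """Pairwise correlations between two condition-level blocks.

    ``r`` and ``p_adjusted`` are row-variable x column-variable frames;
    cells whose correlation is undefined (constant input) are NaN with the
    reason recorded in ``missing``.
    """

    r: pd.DataFrame
    p_adjusted: pd.DataFrame
    method: str
    missing: dict[tuple[str, str], str]


def correlate_blocks(
    x_block: pd.DataFrame, y_block: pd.DataFrame, method: str = "spearman"
) -> CorrelationMatrix:
    """Correlate every x variable with every y variable across conditions.

    Both blocks must share the same condition index (>= 3 conditions);
    p-values are Benjamini-Hochberg adjusted over all defined cells.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    if not x_block.index.equals(y_block.index):
        common = x_block.index.intersection(y_block.index)
        if len(common) < len(x_block.index) or len(common) < len(y_block.index):
            raise ValueError("blocks must be indexed by the same condition set")
        y_block = y_block.loc[x_block.index]
    if len(x_block.index) < 3:
        raise ValueError("need >= 3 conditions for correlation")

    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rvals = pd.DataFrame(np.nan, index=x_block.columns, columns=y_block.columns)
    pvals = pd.DataFrame(np.nan, index=x_block.columns, columns=y_block.columns)
    missing: dict[tuple[str, str], str] = {}
    for xc in x_block.columns:
        xv = x_block[xc].to_numpy(dtype=float)
        for yc in y_block.columns:
            yv = y_block[yc].to_numpy(dtype=float)
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                missing[(xc, yc)] = "constant input"
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = corr_fn(xv, yv)
            rvals.loc[xc, yc] = float(res.statistic)
            pvals.loc[xc, yc] = float(res.pvalue)

    flat = pvals.to_numpy().ravel()
    ok = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        _, adj[ok], _, _ = multipletests(flat[ok], method="fdr_bh")
    p_adj = pd.DataFrame(adj.reshape(pvals.shape), index=pvals.index, columns=pvals.columns)
    return CorrelationMatrix(r=rvals, p_adjusted=p_adj, method=method, missing=missing)


def category_score(
    t: FeatureTable,
    categories: pd.Series,
    condition: ConditionKey,
    pseudo: float | None = None,
) -> dict[str, float]:
    """Per-category mean log fold change of a condition vs its strain's day-0 control.

    ``categories`` maps feature id -> category label; unmapped features are
    excluded, and categories with no features in the table are dropped
    with a warning.
    """
    groups = group_samples(t)
    if condition not in groups:
        raise KeyError(f"condition {condition} not in table")
    ref = ConditionKey(condition.strain, 0, "control")
    if ref not in groups:
        raise KeyError(f"reference condition {ref} not in table")
    if pseudo is None:
        vals = t.values.to_numpy(dtype=float)
        pos = vals[vals > 0]
        pseudo = float(pos.min()) / 2.0 if pos.size else 1.0
    mean_c = t.values.loc[groups[condition]].mean(axis=0).clip(lower=pseudo)
    mean_r = t.values.loc[groups[ref]].mean(axis=0).clip(lower=pseudo)
    lfc = np.log(mean_c / mean_r)

    out: dict[str, float] = {}
    for cat in pd.unique(categories):
        feats = [f for f in categories.index[categories == cat] if f in t.values.columns]
        if not feats:
            warnings.warn(f"category {cat!r} has no features in the table; dropped")
            continue
        out[str(cat)] = float(lfc.loc[feats].mean())
    return out
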