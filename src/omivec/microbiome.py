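"""OTU filtering, relative-abundance scaling, taxonomic aggregation and
the Evenness Index.

The Evenness Index ``E = -sum_i E_i ln E_i`` on a composition (taxon or
metabolite proportions) is Shannon entropy, bounded by ``ln k`` for k
categories; a community dominated by one phylum (e.g. Proteobacteria at
peak colitis) has low E, an even community high E.  Treated/control E
ratios per (strain, day) summarize diversity loss over the disease
course.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ConditionKey, DegenerateInputError, FeatureTable, TaxonomyMap, group_samples


@dataclass
class AbundanceProfile:
    """Per-sample proportion vectors over features or taxa.

    ``proportions`` rows sum to 1 (within 1e-9); ``rank`` labels the
    column unit (otu | phylum | genus | metabolite).  ``metadata`` carries
    the sample design columns through the pipeline.
    """

    proportions: pd.DataFrame
    rank: str
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if arr.size:
            if (arr < 0).any():
                raise ValueError("negative proportion")
            sums = arr.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                sid = self.proportions.index[bad][0]
                raise ValueError(f"sample {sid!r} proportions sum to {sums[bad][0]}, not 1")

    def condition_of(self, sample_id: str) -> ConditionKey:
        row = self.metadata.loc[sample_id]
        return ConditionKey(str(row["strain"]), int(row["day"]), str(row["arm"]))

    def groups(self) -> dict[ConditionKey, list[str]]:
        out: dict[ConditionKey, list[str]] = {}
        for sid in self.proportions.index:
            out.setdefault(self.condition_of(sid), []).append(sid)
        return out

    def condition_mean(self, cond: ConditionKey) -> pd.Series:
        """Pooled composition of a condition: mean of member proportion rows."""
        ids = self.groups().get(cond)
        if not ids:
            raise KeyError(f"condition {cond} not in profile")
        return self.proportions.loc[ids].mean(axis=0)


def filter_otus(t: FeatureTable, min_count: int = 2, prevalence: float = 0.2) -> FeatureTable:
    """Keep an OTU iff count >= ``min_count`` in >= ceil(prevalence * n) samples.

    The sample set is unchanged; the result may have zero features.
    """
    if t.layer != "otu":
        raise ValueError(f"filter_otus expects the otu layer, got {t.layer!r}")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    needed = math.ceil(prevalence * t.n_samples)
    hits = (t.values.to_numpy() >= min_count).sum(axis=0)
    keep = [fid for fid, h in zip(t.feature_ids, hits) if h >= needed]
    return FeatureTable(t.values[keep], t.layer, t.metadata)


def total_sum_scale(t: FeatureTable) -> AbundanceProfile:
    """Total-sum scaling: divide each sample's values by its total.

    Raises :class:`DegenerateInputError` naming any all-zero sample.
    """
    totals = t.values.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateInputError(f"all-zero sample(s): {list(zero.index)}")
    props = t.values.div(totals, axis=0)
    rank = "otu" if t.layer == "otu" else "metabolite"
    return AbundanceProfile(proportions=props, rank=rank, metadata=t.metadata)


def aggregate_taxa(p: AbundanceProfile, tax: TaxonomyMap, rank: str) -> AbundanceProfile:
    """Sum proportions within ``rank`` groups (phylum, genus, ...).

    Per-sample totals are conserved at 1; features missing from the
    taxonomy aggregate into ``"unclassified"``.
    """
    if rank not in tax.ranks:
        raise ValueError(f"unknown rank {rank!r}; taxonomy has {tax.ranks}")
    assignment = tax.assignments(p.proportions.columns, rank)
    agg = p.proportions.T.groupby(pd.Index(assignment, name=rank), sort=True).sum().T
    return AbundanceProfile(proportions=agg, rank=rank, metadata=p.metadata)


def evenness_index(proportions) -> float:
    """E = -sum over entries with p > 0 of p * ln p (0 ln 0 := 0)."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("negative proportion")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum())


@dataclass
class EvennessReport:
    """Per-condition Evenness Index plus treated/control ratios.

    ``per_condition`` maps each condition to its E (computed on the
    pooled, i.e. condition-mean, composition); ``ratios`` is a DataFrame
    indexed by (strain, day) with columns E_control, E_treated, ratio.
    """

    per_condition: dict[ConditionKey, float]
    ratios: pd.DataFrame


def evenness_by_condition(p: AbundanceProfile, pooled: bool = True) -> dict[ConditionKey, float]:
    """Evenness per condition, on pooled composition or averaged per-sample."""
    out = {}
    for cond, ids in p.groups().items():
        if pooled:
            out[cond] = evenness_index(p.condition_mean(cond).to_numpy())
        else:
            out[cond] = float(
                np.mean([evenness_index(p.proportions.loc[s].to_numpy()) for s in ids])
            )
    return out


def evenness_ratio_report(p: AbundanceProfile, pooled: bool = True) -> EvennessReport:
    """Treated/control Evenness ratio per (strain, day).

    Requires both arms present for each (strain, day); raises
    :class:`DegenerateInputError` when a control E is 0.
    """
    per_cond = evenness_by_condition(p, pooled=pooled)
    cells = sorted({(c.strain, c.day) for c in per_cond}, key=lambda x: (x[0], x[1]))
    rows = []
    for strain, day in cells:
        ctrl = ConditionKey(strain, day, "control")
        trt = ConditionKey(strain, day, "treated")
        if ctrl not in per_cond or trt not in per_cond:
            raise KeyError(f"missing arm for ({strain}, day {day})")
        if per_cond[ctrl] == 0.0:
            raise DegenerateInputError(f"control evenness is 0 for ({strain}, day {day})")
        rows.append(
            {
                "strain": strain,
                "day": day,
                "E_control": per_cond[ctrl],
                "E_treated": per_cond[trt],
                "ratio": per_cond[trt] / per_cond[ctrl],
            }
        )
    return EvennessReport(
        per_condition=per_cond, ratios=pd.DataFrame(rows).set_index(["strain", "day"])
    )


def count_detected_features(
    t: FeatureTable, condition: ConditionKey, detect_threshold: float = 0.0
) -> int:
    """Number of features whose condition-mean exceeds ``detect_threshold``."""
    groups = group_samples(t)
    if condition not in groups:
        raise KeyError(f"condition {condition} not in table")
    means = t.values.loc[groups[condition]].mean(axis=0)
    return int((means > detect_threshold).sum())
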