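"""Shared data model for the multi-omics colitis analysis.

All omics layers (transcripts, serum metabolites, cecal "meta-metabolites",
OTU counts) share one in-memory currency: a :class:`FeatureTable` holding a
samples x features matrix of non-negative reals plus per-sample design
metadata.  Every sample belongs to exactly one experimental *condition* --
a (strain, day, arm) cell of the 2-strain x 3-day x 2-arm design -- and all
downstream statistics are computed at condition level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

#: Recognised omics layers.
LAYERS = ("transcript", "serum_metabolite", "cecal_metabolite", "otu")

#: Treatment arms of the design.
ARMS = ("control", "treated")

#: Inflammation annotation labels.
ANNOTATION_LABELS = ("pro", "anti", "neutral")


class FormatError(ValueError):
    """A delimited file violates the table format (e.g. duplicated ids)."""


class MetadataError(ValueError):
    """A sample lacks design metadata, or metadata is malformed."""


class AnnotationError(ValueError):
    """A feature lacks an inflammation annotation label."""


class InsufficientReplicationError(ValueError):
    """A condition group has too few samples for the requested statistic."""


class DegenerateInputError(ValueError):
    """Input geometry/data is degenerate (zero scatter, all-zero sample...)."""


class ConditionKey(NamedTuple):
    """One cell of the experimental design.

    Attributes
    ----------
    strain : str
        Mouse strain label, e.g. ``"C57BL/6"`` or ``"BALB/c"``.
    day : int
        Days since treatment start (0, 7 or 15 in the default design).
    arm : str
        ``"control"`` or ``"treated"``.
    """

    strain: str
    day: int
    arm: str

    def label(self) -> str:
        return f"{self.strain}|d{self.day}|{self.arm}"


def condition_from_row(row: Mapping) -> ConditionKey:
    """Build a ConditionKey from a metadata row with strain/day/arm fields."""
    arm = str(row["arm"])
    if arm not in ARMS:
        raise MetadataError(f"unknown arm {arm!r}; expected one of {ARMS}")
    day = int(row["day"])
    if day < 0:
        raise MetadataError(f"negative day {day}")
    return ConditionKey(str(row["strain"]), day, arm)


@dataclass
class FeatureTable:
    """Samples x features matrix of finite non-negative reals with metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are samples, columns features.  Counts (OTU layer) or
        concentrations / expression levels (other layers).
    layer : str
        One of :data:`LAYERS`.
    metadata : pandas.DataFrame
        Indexed by sample id with columns ``strain``, ``day``, ``arm``;
        must cover every sample in ``values``.
    """

    values: pd.DataFrame
    layer: str
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            bad = self._first_bad_cell(lambda v: not _is_number(v))
            raise ValueError(f"non-numeric value at sample {bad[0]!r}, feature {bad[1]!r}")
        if arr.size:
            farr = arr.astype(float)
            if not np.isfinite(farr).all():
                bad = self._first_bad_cell(lambda v: not np.isfinite(float(v)))
                raise ValueError(f"non-finite value at sample {bad[0]!r}, feature {bad[1]!r}")
            if (farr < 0).any():
                bad = self._first_bad_cell(lambda v: float(v) < 0)
                raise ValueError(f"negative value at sample {bad[0]!r}, feature {bad[1]!r}")
        missing = idx.difference(self.metadata.index)
        if len(missing):
            raise MetadataError(f"samples without metadata: {missing.tolist()}")
        for col in ("strain", "day", "arm"):
            if col not in self.metadata.columns:
                raise MetadataError(f"metadata missing column {col!r}")
        bad_arms = set(self.metadata["arm"]) - set(ARMS)
        if bad_arms:
            raise MetadataError(f"unknown arm labels: {sorted(bad_arms)}")

    def _first_bad_cell(self, pred) -> tuple[str, str]:
        for sid, row in self.values.iterrows():
            for fid, v in row.items():
                try:
                    bad = pred(v)
                except (TypeError, ValueError):
                    bad = True
                if bad:
                    return str(sid), str(fid)
        raise AssertionError("no offending cell found")

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def condition_of(self, sample_id: str) -> ConditionKey:
        if sample_id not in self.metadata.index:
            raise MetadataError(f"sample {sample_id!r} has no metadata")
        return condition_from_row(self.metadata.loc[sample_id])

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(self.values.loc[ids], self.layer, self.metadata.loc[ids])


def group_samples(t: FeatureTable) -> dict[ConditionKey, list[str]]:
    """Partition samples of ``t`` into condition groups.

    Returns a mapping whose groups are disjoint and jointly cover every
    sample, in order of first appearance.
    """
    groups: dict[ConditionKey, list[str]] = {}
    for sid in t.sample_ids:
        groups.setdefault(t.condition_of(sid), []).append(sid)
    return groups


@dataclass
class TaxonomyMap:
    """feature id -> ranked lineage lookup for OTU aggregation.

    ``lineages`` is indexed by feature id with one column per rank
    (at minimum ``phylum`` and ``genus``).  Unknown assignments are the
    explicit string ``"unclassified"``, never missing.
    """

    lineages: pd.DataFrame

    UNCLASSIFIED = "unclassified"

    def __post_init__(self) -> None:
        if self.lineages.index.has_duplicates:
            raise FormatError("duplicate feature ids in taxonomy")
        for rank in ("phylum", "genus"):
            if rank not in self.lineages.columns:
                raise FormatError(f"taxonomy missing rank column {rank!r}")
        self.lineages = self.lineages.fillna(self.UNCLASSIFIED)

    @property
    def ranks(self) -> list[str]:
        return list(self.lineages.columns)

    def assignment(self, feature_id: str, rank: str) -> str:
        if rank not in self.lineages.columns:
            raise ValueError(f"unknown rank {rank!r}; have {self.ranks}")
        if feature_id not in self.lineages.index:
            return self.UNCLASSIFIED
        return str(self.lineages.loc[feature_id, rank])

    def assignments(self, feature_ids: Iterable[str], rank: str) -> list[str]:
        return [self.assignment(f, rank) for f in feature_ids]


@dataclass
class AnnotationTable:
    """feature id -> {pro, anti, neutral} inflammation label for one layer."""

    labels: pd.Series
    layer: str

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise FormatError("duplicate feature ids in annotation")
        bad = set(self.labels.unique()) - set(ANNOTATION_LABELS)
        if bad:
            raise AnnotationError(
                f"labels must be in {ANNOTATION_LABELS}; found {sorted(bad)}"
            )

    def label_of(self, feature_id: str) -> str:
        if feature_id not in self.labels.index:
            raise AnnotationError(f"feature {feature_id!r} has no annotation")
        return str(self.labels.loc[feature_id])

    def features_with(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass
class ClinicalRecord:
    """Per-sample clinical observations feeding the disease severity score.

    ``weight_change`` is percent body-weight change relative to day 0
    (negative = loss); stool and blood observations are integer grades on
    the 0-4 disease-activity rubric.
    """

    sample_id: str
    weight_change: float
    stool_grade: int
    blood_grade: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight_change):
            raise ValueError(f"non-finite weight change for {self.sample_id!r}")
        for name, g in (("stool", self.stool_grade), ("blood", self.blood_grade)):
            if not (0 <= int(g) <= 4):
                raise ValueError(f"{name} grade {g} outside 0-4 for {self.sample_id!r}")


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False
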