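"""Readers and writers for the tab-separated table formats.

All files are plain TSV with a header row.  Feature tables have samples in
rows (first column = sample id, first row = feature ids); metadata,
taxonomy, annotation and clinical tables are long-format TSV.  Ids are
case-sensitive exact strings; cells must be numeric (a missing value must
be written as 0, not left blank).
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    AnnotationTable,
    ClinicalRecord,
    FeatureTable,
    FormatError,
    MetadataError,
    TaxonomyMap,
)

_SEP = "\t"
_INDEX_LABEL = "sample_id"


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"duplicate {what} id {lab!r}")
        seen.add(lab)


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (columns sample_id, strain, day, arm)."""
    meta = pd.read_csv(path, sep=_SEP, dtype={"sample_id": str, "strain": str, "arm": str})
    for col in ("sample_id", "strain", "day", "arm"):
        if col not in meta.columns:
            raise MetadataError(f"metadata file {path} missing column {col!r}")
    _check_unique(meta["sample_id"], "sample")
    meta = meta.set_index("sample_id")
    meta["day"] = meta["day"].astype(int)
    return meta


def read_feature_table(path, layer: str, metadata_path) -> FeatureTable:
    """Read a samples x features TSV plus its metadata into a FeatureTable.

    The first header cell is ignored (conventionally ``sample_id``); the
    remaining header cells are feature ids and the first column holds
    sample ids.  Raises :class:`FormatError` on duplicated ids,
    :class:`MetadataError` when a sample has no metadata row, and
    ``ValueError`` naming the offending cell for negative or non-numeric
    values.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_SEP)
    _check_unique(header[1:], "feature")
    df = pd.read_csv(path, sep=_SEP, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "sample")
    meta = read_metadata(metadata_path)
    return FeatureTable(values=df, layer=layer, metadata=meta.loc[list(df.index)])


def write_feature_table(t: FeatureTable, path) -> None:
    """Write ``t.values`` as TSV, re-readable by :func:`read_feature_table`."""
    t.values.to_csv(path, sep=_SEP, index_label=_INDEX_LABEL)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep=_SEP, index_label=_INDEX_LABEL)


def read_taxonomy(path) -> TaxonomyMap:
    """Read a taxonomy TSV (columns feature_id, phylum, genus, ...)."""
    df = pd.read_csv(path, sep=_SEP, dtype=str)
    if "feature_id" not in df.columns:
        raise FormatError(f"taxonomy file {path} missing column 'feature_id'")
    _check_unique(df["feature_id"], "feature")
    return TaxonomyMap(df.set_index("feature_id"))


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    tax.lineages.to_csv(path, sep=_SEP, index_label="feature_id")


def read_annotation(path, layer: str) -> AnnotationTable:
    """Read an annotation TSV (columns feature_id, label)."""
    df = pd.read_csv(path, sep=_SEP, dtype=str)
    for col in ("feature_id", "label"):
        if col not in df.columns:
            raise FormatError(f"annotation file {path} missing column {col!r}")
    _check_unique(df["feature_id"], "feature")
    return AnnotationTable(df.set_index("feature_id")["label"], layer=layer)


def write_annotation(ann: AnnotationTable, path) -> None:
    ann.labels.rename("label").to_csv(path, sep=_SEP, index_label="feature_id")


def read_clinical(path) -> list[ClinicalRecord]:
    """Read clinical records TSV (sample_id, weight_change, stool_grade, blood_grade)."""
    df = pd.read_csv(path, sep=_SEP, dtype={"sample_id": str})
    _check_unique(df["sample_id"], "sample")
    return [
        ClinicalRecord(
            sample_id=str(r["sample_id"]),
            weight_change=float(r["weight_change"]),
            stool_grade=int(r["stool_grade"]),
            blood_grade=int(r["blood_grade"]),
        )
        for _, r in df.iterrows()
    ]


def write_clinical(records: list[ClinicalRecord], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "weight_change": [r.weight_change for r in records],
            "stool_grade": [r.stool_grade for r in records],
            "blood_grade": [r.blood_grade for r in records],
        }
    )
    df.to_csv(path, sep=_SEP, index=False)


def table_to_tsv_bytes(df: pd.DataFrame, index_label: str = _INDEX_LABEL) -> bytes:
    """Serialize a DataFrame to the canonical TSV byte representation."""
    buf = _stdio.StringIO()
    df.to_csv(buf, sep=_SEP, index_label=index_label)
    return buf.getvalue().encode()
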