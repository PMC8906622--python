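"""Synthetic multi-omics study generator.

Generates complete datasets with the statistical structure the downstream
analysis assumes: a 2-strain x 3-day x 2-arm x 3-replicate design with

* an OTU count table drawn Dirichlet-multinomially from genus-level
  composition profiles (overdispersed counts; the plain multinomial is
  recovered as the infinite-concentration limit),
* log-normal transcript / serum-metabolite / cecal-metabolite tables whose
  pro- and anti-inflammatory features shift on the log scale with a
  strain-specific severity trajectory, and
* clinical records (weight change, stool and blood grades) tied to the
  same trajectory.

All condition-level parameters live in a YAML calibration file
(:data:`DEFAULT_CALIBRATION`); the shipped defaults encode the study
conditions: Proteobacteria peaking at 32% of total abundance on day 15 in
treated C57BL/6 and 29% on day 7 in treated BALB/c, pro-inflammatory
shifts monotone over days in C57BL/6 and peaked at day 7 in BALB/c.

Randomness is one global seed split deterministically per layer and
condition, so regenerating one layer never perturbs another.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    ARMS,
    AnnotationTable,
    ClinicalRecord,
    ConditionKey,
    FeatureTable,
    TaxonomyMap,
)

DEFAULT_CALIBRATION = "default_calibration.yaml"


def load_calibration(path=None) -> dict:
    """Load a calibration config; default is the packaged study calibration."""
    if path is None:
        text = resources.files("omivec.data").joinpath(DEFAULT_CALIBRATION).read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def _child_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-layer/per-condition stream from one global seed."""
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class CompositionProfile:
    """Genus-level gut composition per condition.

    ``taxa`` is an ordered list of (genus, phylum); ``proportions`` maps each
    condition to a vector over that taxon order summing to 1.
    ``concentration`` controls Dirichlet overdispersion of replicate samples;
    ``None`` means the multinomial (infinite-concentration) limit.
    """

    taxa: list[tuple[str, str]]
    proportions: dict[ConditionKey, np.ndarray]
    concentration: float | None = 200.0

    def __post_init__(self) -> None:
        if self.concentration is not None and not self.concentration > 0:
            raise ValueError(f"concentration must be > 0, got {self.concentration}")
        k = len(self.taxa)
        for cond, p in self.proportions.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (k,):
                raise ValueError(f"{cond}: expected {k} proportions, got {p.shape}")
            if (p < 0).any():
                raise ValueError(f"{cond}: negative proportion")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{cond}: proportions sum to {p.sum()}, not 1")
            self.proportions[cond] = p


@dataclass
class EffectProfile:
    """Log-normal generative parameters for one feature layer.

    Each feature value is ``exp(baseline_log_mean + shift(label, condition)
    + N(0, log_sd))``; shifts are per-condition log-scale offsets applied by
    inflammation label.
    """

    layer: str
    baseline_log_mean: pd.Series
    log_sd: float
    shifts: dict[ConditionKey, dict[str, float]]
    n_per_group: int = 3

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.log_sd >= 0:
            raise ValueError("log_sd must be >= 0")


def _sample_ids(cond: ConditionKey, n: int) -> list[str]:
    s = cond.strain.replace("/", "").replace(" ", "")
    return [f"{s}_d{cond.day}_{cond.arm}_r{i + 1}" for i in range(n)]


def _metadata_for(conds_and_ids: list[tuple[ConditionKey, list[str]]]) -> pd.DataFrame:
    rows = []
    for cond, ids in conds_and_ids:
        for sid in ids:
            rows.append({"sample_id": sid, "strain": cond.strain, "day": cond.day, "arm": cond.arm})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_otu_table(
    profile: CompositionProfile,
    n_per_group: int,
    depth: int,
    seed: int,
    otus_per_genus: int = 3,
    otu_split: Sequence[float] = (0.6, 0.3, 0.1),
) -> tuple[FeatureTable, TaxonomyMap]:
    """Draw an OTU count table from genus-level composition profiles.

    Each genus is split into ``otus_per_genus`` OTUs at fixed within-genus
    ratios, and each sample's counts are Dirichlet-multinomial:
    ``p ~ Dirichlet(concentration * proportions)``, ``counts ~
    Multinomial(depth, p)``.  Every sample's counts sum to ``depth``
    exactly.  Returns the table and a taxonomy map covering all OTUs.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    split = np.asarray(otu_split, dtype=float)[:otus_per_genus]
    split = split / split.sum()
    otu_ids, phyla, genera = [], [], []
    for genus, phylum in profile.taxa:
        for k in range(otus_per_genus):
            otu_ids.append(f"OTU_{genus}_{k + 1}")
            phyla.append(phylum)
            genera.append(genus)
    if depth < len(otu_ids):
        warnings.warn(f"depth {depth} below number of OTUs {len(otu_ids)}")

    rows, conds_ids = [], []
    for cond, genus_p in profile.proportions.items():
        otu_p = np.concatenate([gp * split for gp in genus_p])
        rng = _child_rng(seed, "otu", cond.label())
        ids = _sample_ids(cond, n_per_group)
        conds_ids.append((cond, ids))
        for _ in ids:
            if profile.concentration is None:
                p = otu_p
            else:
                pos = otu_p > 0
                p = np.zeros_like(otu_p)
                p[pos] = rng.dirichlet(profile.concentration * otu_p[pos])
            rows.append(rng.multinomial(depth, p / p.sum()))

    all_ids = [sid for _, ids in conds_ids for sid in ids]
    values = pd.DataFrame(np.array(rows, dtype=int), index=all_ids, columns=otu_ids)
    table = FeatureTable(values, layer="otu", metadata=_metadata_for(conds_ids))
    tax = TaxonomyMap(
        pd.DataFrame({"phylum": phyla, "genus": genera}, index=pd.Index(otu_ids, name="feature_id"))
    )
    return table, tax


def simulate_feature_layer(
    effects: EffectProfile, annotation: AnnotationTable, seed: int
) -> FeatureTable:
    """Draw a log-normal feature table from an effect profile.

    Deterministic given ``seed``; requires every baseline feature to carry
    an inflammation label.
    """
    features = list(effects.baseline_log_mean.index)
    labels = [annotation.label_of(f) for f in features]  # AnnotationError if absent
    base = effects.baseline_log_mean.to_numpy(dtype=float)

    rows, conds_ids = [], []
    for cond, shift_by_label in effects.shifts.items():
        shift = np.array([shift_by_label.get(lab, 0.0) for lab in labels])
        rng = _child_rng(seed, effects.layer, cond.label())
        ids = _sample_ids(cond, effects.n_per_group)
        conds_ids.append((cond, ids))
        for _ in ids:
            noise = rng.normal(0.0, effects.log_sd, size=len(features)) if effects.log_sd > 0 else 0.0
            rows.append(np.exp(base + shift + noise))

    all_ids = [sid for _, ids in conds_ids for sid in ids]
    values = pd.DataFrame(np.array(rows), index=all_ids, columns=features)
    return FeatureTable(values, layer=effects.layer, metadata=_metadata_for(conds_ids))


def simulate_clinical(
    design: Sequence[ConditionKey],
    severity_map: Mapping[ConditionKey, tuple[float, int, int]],
    seed: int,
    n_per_group: int = 3,
    grade_noise: int = 1,
    weight_sd: float = 1.0,
) -> list[ClinicalRecord]:
    """Draw clinical records around per-condition (weight%, stool, blood) targets.

    Grades are jittered by at most ``grade_noise`` (integer), clamped to the
    0-4 rubric; weight change gets gaussian noise of sd ``weight_sd``.
    """
    for cond in design:
        _, stool, blood = severity_map[cond]
        for g in (stool, blood):
            if not (0 <= int(g) <= 4):
                raise ValueError(f"grade {g} outside 0-4 for {cond}")
    records = []
    for cond in design:
        weight, stool, blood = severity_map[cond]
        rng = _child_rng(seed, "clinical", cond.label())
        for sid in _sample_ids(cond, n_per_group):
            jitters = rng.integers(-grade_noise, grade_noise + 1, size=2) if grade_noise else (0, 0)
            records.append(
                ClinicalRecord(
                    sample_id=sid,
                    weight_change=float(weight + (rng.normal(0.0, weight_sd) if weight_sd else 0.0)),
                    stool_grade=int(np.clip(stool + jitters[0], 0, 4)),
                    blood_grade=int(np.clip(blood + jitters[1], 0, 4)),
                )
            )
    return records


@dataclass
class StudyBundle:
    """Complete synthetic dataset: one FeatureTable per layer plus side tables."""

    tables: dict[str, FeatureTable]
    taxonomy: TaxonomyMap
    annotations: dict[str, AnnotationTable]
    clinical: list[ClinicalRecord]
    category_map: pd.Series
    design: list[ConditionKey]
    config: dict = field(repr=False, default_factory=dict)


def _design_conditions(cfg: dict) -> list[ConditionKey]:
    d = cfg["design"]
    return [
        ConditionKey(strain, int(day), arm)
        for strain in d["strains"]
        for day in d["days"]
        for arm in d["arms"]
    ]


def composition_profile_from_config(cfg: dict) -> CompositionProfile:
    """Build the genus-level CompositionProfile from a calibration dict."""
    otu_cfg = cfg["otu"]
    taxa = [(t["genus"], t["phylum"]) for t in otu_cfg["taxa"]]
    comps = otu_cfg["compositions"]
    proportions: dict[ConditionKey, np.ndarray] = {}
    for cond in _design_conditions(cfg):
        if cond.arm == "control":
            arm_cfg = comps["control"]
            vec = arm_cfg.get(cond.strain, {}).get(cond.day) if isinstance(
                arm_cfg.get(cond.strain), dict
            ) else None
            if vec is None:
                vec = arm_cfg["default"]
        else:
            vec = comps["treated"][cond.strain][cond.day]
        proportions[cond] = np.asarray(vec, dtype=float)
    return CompositionProfile(
        taxa=taxa, proportions=proportions, concentration=otu_cfg.get("concentration")
    )


def _layer_annotation(layer: str, layer_cfg: dict) -> AnnotationTable:
    prefix = {"transcript": "gene", "serum_metabolite": "ser", "cecal_metabolite": "cec"}[layer]
    ids, labels = [], []
    for label in ("pro", "anti", "neutral"):
        n = int(layer_cfg[f"n_{label}"])
        for i in range(n):
            ids.append(f"{prefix}_{label}{i + 1:03d}")
            labels.append(label)
    return AnnotationTable(pd.Series(labels, index=pd.Index(ids, name="feature_id")), layer=layer)


def _severity(cfg: dict, cond: ConditionKey) -> float:
    if cond.arm == "control":
        return 0.0
    return float(cfg["severity"][cond.strain][cond.day])


def default_study(seed: int = 0, config=None, n_per_group: int | None = None,
                  depth: int | None = None) -> StudyBundle:
    """Generate the full default synthetic study.

    ``config`` may be a calibration dict or a path to a YAML file; the
    packaged defaults are used when omitted.  ``n_per_group`` and ``depth``
    override the config values (useful for power studies).
    """
    cfg = config if isinstance(config, dict) else load_calibration(config)
    n = int(n_per_group if n_per_group is not None else cfg["design"]["n_per_group"])
    dep = int(depth if depth is not None else cfg["otu"]["depth"])
    design = _design_conditions(cfg)

    profile = composition_profile_from_config(cfg)
    otu_table, taxonomy = simulate_otu_table(
        profile,
        n_per_group=n,
        depth=dep,
        seed=seed,
        otus_per_genus=int(cfg["otu"].get("otus_per_genus", 3)),
        otu_split=cfg["otu"].get("otu_split", (0.6, 0.3, 0.1)),
    )

    tables: dict[str, FeatureTable] = {"otu": otu_table}
    annotations: dict[str, AnnotationTable] = {}
    cat_ids, cat_vals = [], []
    for layer, layer_cfg in cfg["layers"].items():
        ann = _layer_annotation(layer, layer_cfg)
        annotations[layer] = ann
        lo, hi = layer_cfg["baseline_log_mean_range"]
        rng = _child_rng(seed, layer, "baseline")
        baseline = pd.Series(
            rng.uniform(lo, hi, size=len(ann.labels)), index=ann.labels.index
        )
        shifts = {}
        for cond in design:
            sev = _severity(cfg, cond)
            shifts[cond] = {
                "pro": float(layer_cfg["pro_max_log_fc"]) * sev,
                "anti": -float(layer_cfg["anti_max_log_fc"]) * sev,
                "neutral": 0.0,
            }
        effects = EffectProfile(
            layer=layer, baseline_log_mean=baseline,
            log_sd=float(layer_cfg["log_sd"]), shifts=shifts, n_per_group=n,
        )
        tables[layer] = simulate_feature_layer(effects, ann, seed)
        if layer != "transcript":
            cats = cfg.get("categories", {})
            for j, fid in enumerate(ann.labels.index):
                lab = ann.labels.loc[fid]
                if lab in cats:
                    cat_ids.append(fid)
                    cat_vals.append(cats[lab][j % len(cats[lab])])

    clin_cfg = cfg.get("clinical", {})
    severity_map = {}
    for cond in design:
        sev = _severity(cfg, cond)
        grade = int(round(4 * sev))
        severity_map[cond] = (-float(clin_cfg.get("max_weight_loss", 18.0)) * sev, grade, grade)
    clinical = simulate_clinical(
        design,
        severity_map,
        seed=seed,
        n_per_group=n,
        grade_noise=int(clin_cfg.get("grade_noise", 1)),
        weight_sd=float(clin_cfg.get("weight_sd", 1.0)),
    )

    return StudyBundle(
        tables=tables,
        taxonomy=taxonomy,
        annotations=annotations,
        clinical=clinical,
        category_map=pd.Series(cat_vals, index=pd.Index(cat_ids, name="feature_id"), dtype=object),
        design=design,
        config=cfg,
    )
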