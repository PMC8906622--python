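"""End-to-end pipeline: simulate -> shortlist -> project -> vector stats ->
microbiome profiles -> annotation analytics, with a reproducibility manifest.

The pipeline is file-based: every stage reads the TSV outputs of its
upstream stages and writes plain TSV, so any stage can be inspected or
re-run in isolation.  A content-addressed stage state makes runs
restartable: a stage is skipped when its recorded configuration, input
file hashes and output file hashes all still match; deleting a stage's
outputs forces just that stage (and any dependent whose inputs then
change) to be recomputed.  Manifests contain no wall-clock timestamps, so
two runs with the same configuration and seed produce byte-identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from importlib import resources

from . import __version__
from . import io as ovio
from .annotation_analysis import (
    category_score,
    clinical_severity_score,
    correlate_blocks,
    overlap_counts,
    pro_anti_ratio,
)
from .discriminant import lda_project
from .microbiome import (
    aggregate_taxa,
    evenness_by_condition,
    evenness_ratio_report,
    filter_otus,
    total_sum_scale,
)
from .model import ConditionKey, FeatureTable, group_samples
from .shortlist import differential_test, results_frame, selected_features
from .simulate import default_study, load_calibration
from .vector_stats import (
    disease_severity_index,
    dissimilarity_coefficient,
    trajectory,
)

log = logging.getLogger("omivec")

FEATURE_LAYERS = ("transcript", "serum_metabolite", "cecal_metabolite")


def load_default_rubric() -> dict:
    text = resources.files("omivec.data").joinpath("default_rubric.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    alpha: float = 0.05
    fc_cutoff: float = 1.5
    shrinkage: float | str = "auto"
    center: str = "global-mean"
    min_count: int = 2
    prevalence: float = 0.2
    calibration: str | None = None  # path to a calibration YAML; packaged default if None
    rubric: str | None = None       # path to a clinical rubric YAML
    n_per_group: int | None = None
    depth: int | None = None

    def validate(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.fc_cutoff < 1:
            raise ValueError(f"fc_cutoff must be >= 1, got {self.fc_cutoff}")
        if not 0 <= self.prevalence <= 1:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if isinstance(self.shrinkage, str):
            if self.shrinkage != "auto":
                raise ValueError("shrinkage must be 'auto' or a number in [0, 1]")
        elif not 0 <= float(self.shrinkage) <= 1:
            raise ValueError("shrinkage must be in [0, 1]")
        if self.center != "global-mean":
            raise ValueError("center must be 'global-mean'")
        for p in (self.calibration, self.rubric):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _slug(strain: str) -> str:
    return strain.replace("/", "").replace(" ", "")


def _cond_cols(conds: list[ConditionKey]) -> pd.DataFrame:
    return pd.DataFrame(
        {"strain": [c.strain for c in conds], "day": [c.day for c in conds],
         "arm": [c.arm for c in conds]}
    )


def _read_layer(outdir: Path, layer: str) -> FeatureTable:
    return ovio.read_feature_table(
        outdir / "simulated" / f"{layer}.tsv", layer, outdir / "simulated" / "metadata.tsv"
    )


def _strains_days(meta: pd.DataFrame) -> tuple[list[str], list[int]]:
    return list(pd.unique(meta["strain"])), sorted(pd.unique(meta["day"]).tolist())


# ---------------------------------------------------------------- stages

def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    bundle = default_study(
        seed=cfg.seed, config=cfg.calibration, n_per_group=cfg.n_per_group, depth=cfg.depth
    )
    d = outdir / "simulated"
    d.mkdir(parents=True, exist_ok=True)
    out = []
    meta = next(iter(bundle.tables.values())).metadata
    ovio.write_metadata(meta, d / "metadata.tsv")
    out.append(d / "metadata.tsv")
    for layer, table in bundle.tables.items():
        ovio.write_feature_table(table, d / f"{layer}.tsv")
        out.append(d / f"{layer}.tsv")
    ovio.write_taxonomy(bundle.taxonomy, d / "taxonomy.tsv")
    out.append(d / "taxonomy.tsv")
    for layer, ann in bundle.annotations.items():
        ovio.write_annotation(ann, d / f"annotation_{layer}.tsv")
        out.append(d / f"annotation_{layer}.tsv")
    ovio.write_clinical(bundle.clinical, d / "clinical.tsv")
    out.append(d / "clinical.tsv")
    bundle.category_map.rename("category").to_csv(
        d / "categories.tsv", sep="\t", index_label="feature_id"
    )
    out.append(d / "categories.tsv")
    return out


def _contrasts_for(strain: str, days: list[int]) -> list[tuple[ConditionKey, ConditionKey]]:
    base = ConditionKey(strain, days[0], "control")
    return [(base, ConditionKey(strain, day, "treated")) for day in days if day != days[0]]


def _stage_shortlist(cfg: RunConfig, outdir: Path) -> list[Path]:
    d = outdir / "shortlist"
    d.mkdir(parents=True, exist_ok=True)
    out = []
    for layer in FEATURE_LAYERS:
        t = _read_layer(outdir, layer)
        strains, days = _strains_days(t.metadata)
        for strain in strains:
            for a, b in _contrasts_for(strain, days):
                res = differential_test(t, a, b, alpha=cfg.alpha, fc_cutoff=cfg.fc_cutoff)
                path = d / f"{layer}_{_slug(strain)}_d{b.day}.tsv"
                results_frame(res).to_csv(path, sep="\t")
                out.append(path)
    return out


def _stage_project(cfg: RunConfig, outdir: Path) -> list[Path]:
    d = outdir / "embedding"
    d.mkdir(parents=True, exist_ok=True)
    out = []
    for layer in FEATURE_LAYERS:
        t = _read_layer(outdir, layer)
        strains, _ = _strains_days(t.metadata)
        for strain in strains:  # strain-wise ordination
            ids = list(t.metadata.index[t.metadata["strain"] == strain])
            sub = t.subset_samples(ids)
            emb = lda_project(sub, shrinkage=cfg.shrinkage)
            cpath = d / f"{layer}_{_slug(strain)}_coords.tsv"
            emb.coordinates.to_csv(cpath, sep="\t", index_label="sample_id")
            out.append(cpath)
            conds = list(emb.groups)
            cent = _cond_cols(conds)
            cent[["LD1", "LD2"]] = np.array([emb.centroid(c) for c in conds])
            gpath = d / f"{layer}_{_slug(strain)}_centroids.tsv"
            cent.to_csv(gpath, sep="\t", index=False)
            out.append(gpath)
    return out


def _stage_vectorstats(cfg: RunConfig, outdir: Path) -> list[Path]:
    d = outdir / "vectorstats"
    d.mkdir(parents=True, exist_ok=True)
    out = []
    for layer in FEATURE_LAYERS:
        t = _read_layer(outdir, layer)
        strains, days = _strains_days(t.metadata)
        for strain in strains:
            ids = list(t.metadata.index[t.metadata["strain"] == strain])
            emb = lda_project(t.subset_samples(ids), shrinkage=cfg.shrinkage)
            conds = list(emb.groups)
            rows = []
            for i, ca in enumerate(conds):
                for cb in conds[i + 1:]:
                    rows.append(
                        {"stat": "r", "a": ca.label(), "b": cb.label(),
                         "value": dissimilarity_coefficient(emb.centroid(ca), emb.centroid(cb))}
                    )
            for day in days:
                ca = ConditionKey(strain, day, "control")
                cb = ConditionKey(strain, day, "treated")
                rows.append(
                    {"stat": "D", "a": ca.label(), "b": cb.label(),
                     "value": disease_severity_index(emb, ca, cb, center=cfg.center)}
                )
            treated = [ConditionKey(strain, day, "treated") for day in days]
            traj = trajectory(emb, treated)
            for (a, _), (b, _), seg in zip(traj.points, traj.points[1:], traj.segment_lengths):
                rows.append({"stat": "trajectory_segment", "a": a.label(), "b": b.label(),
                             "value": seg})
            base, mid, last = treated[0], treated[1], treated[-1]
            r_last = dissimilarity_coefficient(emb.centroid(base), emb.centroid(last))
            r_mid = dissimilarity_coefficient(emb.centroid(base), emb.centroid(mid))
            if r_mid > 0:
                rows.append({"stat": "ratio", "a": f"{base.label()}->{last.label()}",
                             "b": f"{base.label()}->{mid.label()}", "value": r_last / r_mid})
            path = d / f"{layer}_{_slug(strain)}.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            out.append(path)
    return out


def _stage_microbiome(cfg: RunConfig, outdir: Path) -> list[Path]:
    d = outdir / "microbiome"
    d.mkdir(parents=True, exist_ok=True)
    out = []
    t = _read_layer(outdir, "otu")
    tax = ovio.read_taxonomy(outdir / "simulated" / "taxonomy.tsv")
    prof = total_sum_scale(filter_otus(t, min_count=cfg.min_count, prevalence=cfg.prevalence))
    for rank in ("phylum", "genus"):
        agg = aggregate_taxa(prof, tax, rank)
        path = d / f"{rank}.tsv"
        agg.proportions.to_csv(path, sep="\t", index_label="sample_id")
        out.append(path)

    # evenness: phylum-level for microbiota, per-metabolite for the two pools
    rows = []
    phylum = aggregate_taxa(prof, tax, "phylum")
    rep = evenness_ratio_report(phylum)
    for (strain, day), r in rep.ratios.iterrows():
        rows.append({"block": "microbiota_phylum", "strain": strain, "day": day,
                     "E_control": r["E_control"], "E_treated": r["E_treated"],
                     "ratio": r["ratio"]})
    for layer in ("serum_metabolite", "cecal_metabolite"):
        mt = _read_layer(outdir, layer)
        mprof = total_sum_scale(mt)
        mrep = evenness_ratio_report(mprof)
        for (strain, day), r in mrep.ratios.iterrows():
            rows.append({"block": layer, "strain": strain, "day": day,
                         "E_control": r["E_control"], "E_treated": r["E_treated"],
                         "ratio": r["ratio"]})
    path = d / "evenness.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    out.append(path)
    return out


def _stage_annotation(cfg: RunConfig, outdir: Path) -> list[Path]:
    d = outdir / "annotation"
    d.mkdir(parents=True, exist_ok=True)
    out = []

    # pro/anti ratios per shortlist, overlap between the two strains per contrast
    ratio_rows, overlap_rows = [], []
    sets: dict[tuple[str, str, int], set[str]] = {}
    for layer in FEATURE_LAYERS:
        ann = ovio.read_annotation(outdir / "simulated" / f"annotation_{layer}.tsv", layer)
        t = _read_layer(outdir, layer)
        strains, days = _strains_days(t.metadata)
        for strain in strains:
            for day in days[1:]:
                sl = pd.read_csv(
                    outdir / "shortlist" / f"{layer}_{_slug(strain)}_d{day}.tsv", sep="\t"
                )
                sel = set(sl.loc[sl["selected"], "feature_id"].astype(str))
                sets[(layer, strain, day)] = sel
                entry = pro_anti_ratio(sel, ann)
                ratio_rows.append(
                    {"layer": layer, "strain": strain, "day": day,
                     "n_pro": entry.n_pro, "n_anti": entry.n_anti,
                     "n_neutral": entry.n_neutral,
                     "ratio": "undefined" if entry.undefined else entry.ratio}
                )
        for day in days[1:]:
            left, right = strains[0], strains[1]
            rep = overlap_counts(sets[(layer, left, day)], sets[(layer, right, day)])
            overlap_rows.append(
                {"layer": layer, "day": day, "left": left, "right": right,
                 "n_common": rep.n_common, "n_unique_left": rep.n_unique_left,
                 "n_unique_right": rep.n_unique_right}
            )
    p = d / "ratios.tsv"
    pd.DataFrame(ratio_rows).to_csv(p, sep="\t", index=False)
    out.append(p)
    p = d / "overlap.tsv"
    pd.DataFrame(overlap_rows).to_csv(p, sep="\t", index=False)
    out.append(p)

    # clinical severity scores
    rubric = load_default_rubric() if cfg.rubric is None else yaml.safe_load(
        Path(cfg.rubric).read_text()
    )
    records = ovio.read_clinical(outdir / "simulated" / "clinical.tsv")
    scores = clinical_severity_score(records, rubric)
    p = d / "clinical_scores.tsv"
    pd.DataFrame(
        {"sample_id": [s.sample_id for s in scores],
         "weight_grade": [s.weight_grade for s in scores],
         "stool_grade": [s.stool_grade for s in scores],
         "blood_grade": [s.blood_grade for s in scores],
         "total": [s.total for s in scores]}
    ).to_csv(p, sep="\t", index=False)
    out.append(p)

    # condition-level correlation: inflammation markers vs phyla + categories
    tt = _read_layer(outdir, "transcript")
    ann_t = ovio.read_annotation(outdir / "simulated" / "annotation_transcript.tsv", "transcript")
    groups = group_samples(tt)
    conds = list(groups)
    labels = [c.label() for c in conds]
    logv = np.log(tt.values.clip(lower=tt.values.to_numpy()[tt.values.to_numpy() > 0].min() / 2))
    x_rows = []
    for c in conds:
        m = logv.loc[groups[c]].mean(axis=0)
        x_rows.append(
            {"pro_inflammation": m.loc[ann_t.features_with("pro")].mean(),
             "anti_inflammation": m.loc[ann_t.features_with("anti")].mean()}
        )
    x_block = pd.DataFrame(x_rows, index=labels)

    phylum = pd.read_csv(outdir / "microbiome" / "phylum.tsv", sep="\t", index_col=0)
    meta = ovio.read_metadata(outdir / "simulated" / "metadata.tsv")
    y_rows = []
    cats = pd.read_csv(outdir / "simulated" / "categories.tsv", sep="\t", index_col=0)["category"]
    ct = _read_layer(outdir, "cecal_metabolite")
    for c in conds:
        ids = [s for s in phylum.index if
               (meta.loc[s, "strain"], int(meta.loc[s, "day"]), meta.loc[s, "arm"]) == c]
        row = phylum.loc[ids].mean(axis=0).to_dict()
        row.update(category_score(ct, cats, c))
        y_rows.append(row)
    y_block = pd.DataFrame(y_rows, index=labels)

    cm = correlate_blocks(x_block, y_block, method="spearman")
    p = d / "correlation_r.tsv"
    cm.r.to_csv(p, sep="\t", index_label="marker")
    out.append(p)
    p = d / "correlation_p.tsv"
    cm.p_adjusted.to_csv(p, sep="\t", index_label="marker")
    out.append(p)
    return out


STAGES: list[tuple[str, object, list[str]]] = [
    ("simulate", _stage_simulate, []),
    ("shortlist", _stage_shortlist, ["simulate"]),
    ("project", _stage_project, ["simulate"]),
    ("vectorstats", _stage_vectorstats, ["simulate"]),
    ("microbiome", _stage_microbiome, ["simulate"]),
    ("annotation", _stage_annotation, ["simulate", "shortlist", "microbiome"]),
]


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(cfg: RunConfig, force: bool = False) -> dict:
    """Run all stages in dependency order and write ``manifest.json``.

    Returns the manifest dict.  Stages whose recorded inputs and outputs
    are unchanged are skipped unless ``force``.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state_path = outdir / "stage_state.json"
    state = json.loads(state_path.read_text()) if state_path.exists() else {}
    chash = _config_hash(cfg)

    stage_records: dict[str, dict] = {}
    outputs_by_stage: dict[str, list[Path]] = {}
    for name, fn, deps in STAGES:
        inputs: dict[str, str] = {}
        for dep in deps:
            for p in outputs_by_stage[dep]:
                inputs[str(p.relative_to(outdir))] = _sha256(p)
        rec = state.get(name)
        reusable = (
            not force
            and rec is not None
            and rec.get("config") == chash
            and rec.get("inputs") == inputs
            and all(
                (outdir / rel).exists() and _sha256(outdir / rel) == h
                for rel, h in rec.get("outputs", {}).items()
            )
        )
        if reusable:
            log.info("stage %-12s skipped (up to date)", name)
            outs = [outdir / rel for rel in rec["outputs"]]
        else:
            t0 = time.perf_counter()
            try:
                outs = fn(cfg, outdir)
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
            log.info("stage %-12s wrote %d file(s) in %.2fs", name, len(outs),
                     time.perf_counter() - t0)
        outputs_by_stage[name] = outs
        rec = {
            "config": chash,
            "inputs": inputs,
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outs},
        }
        stage_records[name] = rec
        state[name] = rec
        state_path.write_text(json.dumps(state, sort_keys=True, indent=1))

    manifest = {
        "software": {"name": "omivec", "version": __version__},
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": {
            name: {"inputs": r["inputs"], "outputs": r["outputs"]}
            for name, r in stage_records.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
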