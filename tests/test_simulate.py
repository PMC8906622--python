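"""Synthetic-data generator: determinism, conservation, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from omivec.model import AnnotationTable, ConditionKey, group_samples
from omivec.simulate import (
    CompositionProfile,
    EffectProfile,
    composition_profile_from_config,
    default_study,
    load_calibration,
    simulate_clinical,
    simulate_feature_layer,
    simulate_otu_table,
)

COND = ConditionKey("C57BL/6", 0, "control")
TRT = ConditionKey("C57BL/6", 15, "treated")


def _profile(props, taxa=None, conc=50.0):
    taxa = taxa or [(f"g{i}", f"p{i}") for i in range(len(props))]
    return CompositionProfile(taxa=taxa, proportions={COND: np.asarray(props)},
                              concentration=conc)


class TestOtuSimulator:
    def test_counts_sum_to_depth(self):
        t, _ = simulate_otu_table(_profile([0.5, 0.3, 0.2]), n_per_group=4,
                                  depth=777, seed=1)
        assert (t.values.sum(axis=1) == 777).all()

    def test_single_taxon_conservation(self):
        t, tax = simulate_otu_table(_profile([1.0]), n_per_group=2, depth=500,
                                    seed=2, otus_per_genus=1)
        assert (t.values.iloc[:, 0] == 500).all()
        assert tax.assignment(t.feature_ids[0], "phylum") == "p0"

    def test_multinomial_limit(self):
        # infinite concentration = plain multinomial at the exact proportions
        t, _ = simulate_otu_table(_profile([0.5, 0.5], conc=None), n_per_group=1,
                                  depth=1000, seed=3, otus_per_genus=1)
        # 5 sigma of Binomial(1000, 0.5)
        assert abs(t.values.iloc[0, 0] - 500) < 5 * np.sqrt(1000 * 0.25)

    def test_determinism(self):
        a, _ = simulate_otu_table(_profile([0.6, 0.4]), n_per_group=3, depth=100, seed=9)
        b, _ = simulate_otu_table(_profile([0.6, 0.4]), n_per_group=3, depth=100, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_mean_proportions_recovered(self):
        # Monte-Carlo oracle: empirical means within 3 SE of (0.6, 0.3, 0.1)
        props = np.array([0.6, 0.3, 0.1])
        t, _ = simulate_otu_table(_profile(props, conc=50.0), n_per_group=200,
                                  depth=2000, seed=4, otus_per_genus=1)
        obs = (t.values / 2000).to_numpy()
        se = obs.std(axis=0, ddof=1) / np.sqrt(obs.shape[0])
        assert (np.abs(obs.mean(axis=0) - props) < 3 * se + 1e-12).all()

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            _profile([0.7, 0.7])
        with pytest.raises(ValueError):
            _profile([0.5, 0.5], conc=-1.0)

    def test_shallow_depth_warns(self):
        with pytest.warns(UserWarning):
            simulate_otu_table(_profile([0.5, 0.5]), n_per_group=1, depth=3, seed=0)


def _effects(shift, log_sd, n=3, features=("pro1", "neu1"), labels=("pro", "neutral")):
    ann = AnnotationTable(pd.Series(labels, index=list(features)), layer="transcript")
    baseline = pd.Series(2.0, index=list(features))
    shifts = {COND: {"pro": 0.0, "anti": 0.0, "neutral": 0.0},
              TRT: {"pro": shift, "anti": 0.0, "neutral": 0.0}}
    return EffectProfile(layer="transcript", baseline_log_mean=baseline,
                         log_sd=log_sd, shifts=shifts, n_per_group=n), ann


class TestFeatureLayerSimulator:
    def test_noise_free_limit(self):
        eff, ann = _effects(shift=0.0, log_sd=0.0)
        t = simulate_feature_layer(eff, ann, seed=0)
        np.testing.assert_allclose(t.values.to_numpy(), np.exp(2.0))

    def test_determinism(self):
        eff, ann = _effects(shift=0.5, log_sd=0.3)
        a = simulate_feature_layer(eff, ann, seed=5)
        b = simulate_feature_layer(eff, ann, seed=5)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_mean_fold_change_recovered(self):
        # pro shift ln 4 -> treated/control mean ratio ~ 4 within 3 SE
        eff, ann = _effects(shift=np.log(4.0), log_sd=0.3, n=1000)
        t = simulate_feature_layer(eff, ann, seed=6)
        groups = group_samples(t)
        ctrl = t.values.loc[groups[COND], "pro1"].to_numpy()
        trt = t.values.loc[groups[TRT], "pro1"].to_numpy()
        ratio = trt.mean() / ctrl.mean()
        rel_se = np.sqrt(
            (trt.std(ddof=1) / trt.mean()) ** 2 / len(trt)
            + (ctrl.std(ddof=1) / ctrl.mean()) ** 2 / len(ctrl)
        )
        assert abs(ratio - 4.0) < 3 * 4.0 * rel_se

    def test_missing_annotation_rejected(self):
        eff, _ = _effects(shift=0.0, log_sd=0.1)
        ann = AnnotationTable(pd.Series(["pro"], index=["pro1"]), layer="transcript")
        from omivec.model import AnnotationError

        with pytest.raises(AnnotationError):
            simulate_feature_layer(eff, ann, seed=0)


class TestClinicalSimulator:
    def test_zero_noise_exact(self):
        sm = {COND: (0.0, 0, 0), TRT: (-12.0, 3, 4)}
        recs = simulate_clinical([COND, TRT], sm, seed=0, n_per_group=2,
                                 grade_noise=0, weight_sd=0.0)
        assert [(r.stool_grade, r.blood_grade) for r in recs] == [(0, 0), (0, 0), (3, 4), (3, 4)]
        assert recs[2].weight_change == -12.0

    def test_jitter_bounded_and_clamped(self):
        sm = {TRT: (-15.0, 4, 4)}
        recs = simulate_clinical([TRT], sm, seed=1, n_per_group=500, grade_noise=1)
        assert all(r.stool_grade in (3, 4) and r.blood_grade in (3, 4) for r in recs)

    def test_grade_out_of_rubric_rejected(self):
        with pytest.raises(ValueError):
            simulate_clinical([TRT], {TRT: (0.0, 5, 0)}, seed=0)


class TestDefaultStudy:
    def test_bundle_shape_and_invariants(self, bundle):
        assert set(bundle.tables) == {"otu", "transcript", "serum_metabolite",
                                      "cecal_metabolite"}
        for t in bundle.tables.values():
            t.validate()
            groups = group_samples(t)
            assert len(groups) == 12
            assert all(len(v) == 3 for v in groups.values())
        # taxonomy covers all OTUs
        otu = bundle.tables["otu"]
        assert all(f in bundle.taxonomy.lineages.index for f in otu.feature_ids)

    def test_pro_shift_kinetics(self, bundle):
        # C57BL/6-treated pro means rise monotonically over days; BALB/c peaks d7
        t = bundle.tables["transcript"]
        pro = bundle.annotations["transcript"].features_with("pro")
        groups = group_samples(t)

        def pro_mean(strain, day):
            ids = groups[ConditionKey(strain, day, "treated")]
            return np.log(t.values.loc[ids, pro]).mean().mean()

        c57 = [pro_mean("C57BL/6", d) for d in (0, 7, 15)]
        balb = [pro_mean("BALB/c", d) for d in (0, 7, 15)]
        assert c57[0] < c57[1] < c57[2]
        assert balb[1] > balb[0] and balb[1] > balb[2]

    def test_calibrated_proteobacteria_recovery(self):
        # seed-averaged treated C57BL/6 d15 Proteobacteria ~ calibration value
        from omivec.microbiome import aggregate_taxa, filter_otus, total_sum_scale

        cfg = load_calibration()
        taxa = cfg["otu"]["taxa"]
        target = sum(
            p for p, tx in zip(cfg["otu"]["compositions"]["treated"]["C57BL/6"][15], taxa)
            if tx["phylum"] == "Proteobacteria"
        )
        vals = []
        for seed in range(10):
            b = default_study(seed=seed)
            ph = aggregate_taxa(total_sum_scale(filter_otus(b.tables["otu"])),
                                b.taxonomy, "phylum")
            vals.append(ph.condition_mean(ConditionKey("C57BL/6", 15, "treated"))
                        ["Proteobacteria"])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - target) < 3 * se + 0.005

    def test_profile_from_config_matches_design(self):
        cfg = load_calibration()
        profile = composition_profile_from_config(cfg)
        assert len(profile.proportions) == 12
        ck = ConditionKey("BALB/c", 7, "treated")
        taxa = [t["genus"] for t in cfg["otu"]["taxa"]]
        heli = profile.proportions[ck][taxa.index("Helicobacter")]
        assert heli == pytest.approx(0.29)
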