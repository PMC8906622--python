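"""OTU filtering, total-sum scaling, taxon aggregation, Evenness Index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omivec.microbiome import (
    AbundanceProfile,
    aggregate_taxa,
    count_detected_features,
    evenness_index,
    evenness_ratio_report,
    filter_otus,
    total_sum_scale,
)
from omivec.model import ConditionKey, DegenerateInputError, TaxonomyMap
from conftest import make_table

CTRL = ConditionKey("C57BL/6", 0, "control")
TRT = ConditionKey("C57BL/6", 0, "treated")


def otu_table(values, **kw):
    return make_table(values, layer="otu", **kw)


def taxonomy(mapping):
    rows = {fid: {"phylum": ph, "genus": ge} for fid, (ph, ge) in mapping.items()}
    return TaxonomyMap(pd.DataFrame.from_dict(rows, orient="index"))


class TestFilterOtus:
    def test_single_hit_meets_20_percent_of_five(self):
        t = otu_table(np.array([[2], [0], [0], [0], [0]]))
        assert filter_otus(t, min_count=2, prevalence=0.2).feature_ids == ["f1"]

    def test_below_min_count_removed(self):
        t = otu_table(np.ones((5, 1)))
        assert filter_otus(t, min_count=2, prevalence=0.2).n_features == 0

    def test_identity_filter(self):
        t = otu_table(np.arange(12.0).reshape(4, 3))
        kept = filter_otus(t, min_count=0, prevalence=0.0)
        assert kept.feature_ids == t.feature_ids
        assert kept.sample_ids == t.sample_ids

    def test_prevalence_ceiling(self):
        # 4 samples at prevalence 0.3 -> need ceil(1.2) = 2 hitting samples
        t = otu_table(np.array([[5, 5], [5, 0], [0, 0], [0, 0]]))
        assert filter_otus(t, min_count=2, prevalence=0.3).feature_ids == ["f1"]

    def test_wrong_layer_rejected(self):
        with pytest.raises(ValueError):
            filter_otus(make_table(np.ones((2, 2))))


class TestTotalSumScale:
    def test_proportions(self):
        prof = total_sum_scale(otu_table([[2.0, 3.0, 5.0]]))
        np.testing.assert_allclose(prof.proportions.to_numpy(), [[0.2, 0.3, 0.5]])

    def test_single_feature_all_ones(self):
        prof = total_sum_scale(otu_table([[7.0], [3.0]]))
        np.testing.assert_allclose(prof.proportions.to_numpy(), 1.0)

    def test_idempotent(self):
        t = otu_table(np.random.default_rng(0).integers(1, 50, (4, 5)).astype(float))
        once = total_sum_scale(t).proportions
        twice = total_sum_scale(
            otu_table(once.to_numpy(), sample_ids=list(once.index))
        ).proportions
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_all_zero_sample_named(self):
        t = otu_table(np.array([[1.0, 2.0], [0.0, 0.0]]))
        with pytest.raises(DegenerateInputError, match="s2"):
            total_sum_scale(t)


class TestAggregateTaxa:
    def test_phylum_conservation(self):
        prof = total_sum_scale(otu_table([[4.0, 6.0]]))
        tax = taxonomy({"f1": ("P", "g1"), "f2": ("P", "g2")})
        agg = aggregate_taxa(prof, tax, "phylum")
        np.testing.assert_allclose(agg.proportions.to_numpy(), [[1.0]])

    def test_identity_taxonomy_unchanged(self):
        prof = total_sum_scale(otu_table([[1.0, 3.0]]))
        tax = taxonomy({"f1": ("p1", "f1"), "f2": ("p2", "f2")})
        agg = aggregate_taxa(prof, tax, "genus")
        np.testing.assert_allclose(
            np.sort(agg.proportions.to_numpy()), np.sort(prof.proportions.to_numpy())
        )

    def test_unknown_rank_rejected(self):
        prof = total_sum_scale(otu_table([[1.0]]))
        with pytest.raises(ValueError):
            aggregate_taxa(prof, taxonomy({"f1": ("P", "g")}), "family")

    def test_unmapped_feature_goes_unclassified(self):
        prof = total_sum_scale(otu_table([[1.0, 1.0]]))
        agg = aggregate_taxa(prof, taxonomy({"f1": ("P", "g")}), "phylum")
        assert "unclassified" in agg.proportions.columns
        np.testing.assert_allclose(agg.proportions.sum(axis=1), 1.0)

    def test_default_study_mass_conservation(self, bundle):
        prof = total_sum_scale(filter_otus(bundle.tables["otu"]))
        phylum = aggregate_taxa(prof, bundle.taxonomy, "phylum")
        genus = aggregate_taxa(prof, bundle.taxonomy, "genus")
        np.testing.assert_allclose(phylum.proportions.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(genus.proportions.sum(axis=1), 1.0, atol=1e-12)


class TestEvennessIndex:
    def test_uniform_is_ln_k(self):
        for k in range(2, 11):
            assert evenness_index(np.full(k, 1.0 / k)) == pytest.approx(np.log(k),
                                                                        abs=1e-12)

    def test_single_category_zero(self):
        assert evenness_index([1.0]) == 0.0

    def test_direct_evaluation(self):
        assert evenness_index([0.5, 0.25, 0.25]) == pytest.approx(1.5 * np.log(2),
                                                                  abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            evenness_index([0.5, -0.1, 0.6])
        with pytest.raises(ValueError):
            evenness_index([0.5, 0.4])

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=12),
           st.integers(0, 1000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_permutation_invariance_and_bound(self, weights, seed):
        p = np.array(weights) / np.sum(weights)
        p = p / p.sum()
        e = evenness_index(p)
        assert 0 <= e <= np.log(len(p)) + 1e-9
        perm = np.random.default_rng(seed).permutation(p)
        assert evenness_index(perm / perm.sum()) == pytest.approx(e, abs=1e-9)

    def test_zero_category_neutral(self):
        p = np.array([0.5, 0.5])
        assert evenness_index(np.append(p, 0.0)) == pytest.approx(evenness_index(p))

    @given(st.lists(st.floats(0.01, 10.0), min_size=3, max_size=10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_merging_categories_decreases_evenness(self, weights):
        p = np.array(weights) / np.sum(weights)
        p = p / p.sum()
        merged = np.append(p[2:], p[0] + p[1])
        assert evenness_index(merged / merged.sum()) < evenness_index(p) + 1e-12


class TestEvennessRatioReport:
    def _profile(self, ctrl_rows, trt_rows):
        values = np.vstack([ctrl_rows, trt_rows])
        conds = [CTRL] * len(ctrl_rows) + [TRT] * len(trt_rows)
        t = otu_table(values, conditions=conds)
        return total_sum_scale(t)

    def test_identical_arms_ratio_one(self):
        prof = self._profile([[1.0, 1.0, 2.0]], [[1.0, 1.0, 2.0]])
        rep = evenness_ratio_report(prof)
        assert rep.ratios.loc[("C57BL/6", 0), "ratio"] == pytest.approx(1.0)

    def test_collapsed_treated_ratio_zero(self):
        prof = self._profile([[1.0, 1.0]], [[5.0, 0.0]])
        rep = evenness_ratio_report(prof)
        assert rep.ratios.loc[("C57BL/6", 0), "ratio"] == 0.0

    def test_degenerate_control_rejected(self):
        prof = self._profile([[5.0, 0.0]], [[1.0, 1.0]])
        with pytest.raises(DegenerateInputError):
            evenness_ratio_report(prof)

    def test_missing_arm_rejected(self):
        t = otu_table([[1.0, 1.0]], conditions=[CTRL])
        with pytest.raises(KeyError):
            evenness_ratio_report(total_sum_scale(t))

    def test_diversity_falls_with_severity_on_default_study(self):
        # seed-averaged treated/control phylum evenness ratio is lower at
        # day 15 than at day 0 for C57BL/6 (calibrated severity)
        from omivec.simulate import default_study

        r0, r15 = [], []
        for seed in range(20):
            b = default_study(seed=seed)
            prof = total_sum_scale(filter_otus(b.tables["otu"]))
            phylum = aggregate_taxa(prof, b.taxonomy, "phylum")
            rep = evenness_ratio_report(phylum)
            r0.append(rep.ratios.loc[("C57BL/6", 0), "ratio"])
            r15.append(rep.ratios.loc[("C57BL/6", 15), "ratio"])
        assert np.mean(r15) < np.mean(r0)


class TestCountDetected:
    def test_zero_threshold_counts_all_positive(self):
        t = make_table(np.full((2, 4), 3.0))
        assert count_detected_features(t, CTRL, 0.0) == 4

    def test_threshold_above_max(self):
        t = make_table(np.full((2, 4), 3.0))
        assert count_detected_features(t, CTRL, 10.0) == 0

    def test_constructed_count(self):
        vals = np.ones((2, 10))
        vals[:, :7] = 5.0
        t = make_table(vals)
        assert count_detected_features(t, CTRL, 2.0) == 7
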