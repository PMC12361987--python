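"""DMS discovery: rank-sum, BH, thresholds, subgroups, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methdx as m
from methdx.dms import DMSThresholds, dichotomize_age
from methdx.dms import test_all_sites as rank_test_all_sites
from oracles import bh_by_hand, exact_rank_sum_p


class TestRankSum:
    def test_extreme_separation_small_n(self):
        assert m.rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.10)

    def test_identical_samples_give_p_one(self):
        assert m.rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_symmetry(self):
        x, y = [0.1, 0.4, 0.2, 0.8], [0.3, 0.9, 0.5]
        assert m.rank_sum_test(x, y) == pytest.approx(m.rank_sum_test(y, x))

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            m.rank_sum_test([1.0], [2.0, 3.0])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.data())
    def test_matches_exact_enumeration_oracle(self, data):
        """On tie-free pooled samples of total size <= 12 the p value
        equals full enumeration over rank assignments."""
        n1 = data.draw(st.integers(2, 5))
        n2 = data.draw(st.integers(2, 5))
        pooled = data.draw(st.lists(st.integers(0, 10 ** 6), min_size=n1 + n2,
                                    max_size=n1 + n2, unique=True))
        x, y = pooled[:n1], pooled[n1:]
        assert m.rank_sum_test(x, y) == pytest.approx(exact_rank_sum_p(x, y))


class TestBHAdjust:
    def test_hand_worked_example(self):
        out = m.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert m.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_cap_at_one(self):
        assert (m.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            m.bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_hand_formula(self, pvals):
        assert np.allclose(m.bh_adjust(pvals), bh_by_hand(pvals))


class TestDiscoverDMS:
    def test_null_cohort_no_discoveries(self):
        design = m.SynthDesign(n_cases=40, n_controls=30, n_sites=500, n_dms=0, seed=11)
        counts, metadata, _ = m.simulate_cohort(design)
        matrix = m.call_betas(counts, e=0.99)
        records = m.discover_dms(matrix, metadata["class"], DMSThresholds.tissue())
        assert len(records) == 0
        assert records.attrs["empty_after_filter"]

    def test_planted_recovery(self):
        design = m.SynthDesign(n_cases=40, n_controls=30, n_sites=2000, n_dms=50,
                               delta_target=0.3, seed=7)
        counts, metadata, truth = m.simulate_cohort(design)
        matrix = m.call_betas(counts, e=0.99)
        records = m.discover_dms(matrix, metadata["class"], DMSThresholds.tissue())
        hits = set(records["site_id"]) & set(truth.planted_sites)
        assert len(hits) >= 45
        unplanted = len(records) - len(hits)
        assert unplanted <= 0.05 * max(len(records), 1)

    def test_delta_boundary_is_inclusive(self):
        """A site whose delta equals the cutoff exactly is retained."""
        n = 12
        case_cols = [f"c{i}" for i in range(n)]
        ctrl_cols = [f"b{i}" for i in range(n)]
        matrix = pd.DataFrame(
            [[0.65] * n + [0.50] * n, [0.30] * n + [0.30] * n],
            index=["chr1:100", "chr1:200"], columns=case_cols + ctrl_cols)
        labels = pd.Series({**{c: "malignant" for c in case_cols},
                            **{c: "benign" for c in ctrl_cols}})
        records = m.discover_dms(matrix, labels, DMSThresholds.tissue())
        assert list(records["site_id"]) == ["chr1:100"]
        assert records["delta"].iloc[0] >= 0.15

    def test_records_satisfy_thresholds(self, small_matrix):
        matrix, metadata, _ = small_matrix
        thresholds = DMSThresholds.tissue()
        records = m.discover_dms(matrix, metadata["class"], thresholds)
        assert len(records) > 0
        assert (records["fdr"] < thresholds.max_fdr).all()
        assert (records["delta"].abs() >= thresholds.min_abs_delta).all()
        assert (records["detect_case"] >= thresholds.min_detect).all()
        assert (records["detect_control"] >= thresholds.min_detect).all()
        assert (records["fdr"] >= records["p_value"] - 1e-12).all()

    def test_order_invariance(self, small_matrix):
        matrix, metadata, _ = small_matrix
        rng = np.random.default_rng(0)
        shuffled = matrix.iloc[rng.permutation(matrix.shape[0]),
                               rng.permutation(matrix.shape[1])]
        a = m.discover_dms(matrix, metadata["class"]).sort_values("site_id").reset_index(drop=True)
        b = m.discover_dms(shuffled, metadata["class"]).sort_values("site_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_bh_universe_is_post_filter(self, small_matrix):
        """FDR values change with the tested universe, so BH must run on
        exactly the detection-passing sites."""
        matrix, metadata, _ = small_matrix
        tested = rank_test_all_sites(matrix, metadata["class"], min_detect=0.65)
        refdr = m.bh_adjust(tested["p_value"].to_numpy())
        assert np.allclose(tested["fdr"].to_numpy(), refdr)


class TestSubgroupDMS:
    def test_class_factor_reproduces_discover(self, small_matrix):
        matrix, metadata, _ = small_matrix
        a = m.discover_dms(matrix, metadata["class"])
        b = m.subgroup_dms(matrix, metadata["class"], levels=("malignant", "benign"))
        pd.testing.assert_frame_equal(a, b)

    def test_independent_factor_finds_nothing(self):
        design = m.SynthDesign(n_cases=25, n_controls=25, n_sites=400, n_dms=10, seed=13)
        counts, metadata, _ = m.simulate_cohort(design)
        matrix = m.call_betas(counts, e=0.99)
        rng = np.random.default_rng(13)
        factor = pd.Series(np.where(rng.random(len(metadata)) < 0.5, "A", "B"),
                           index=metadata.index)
        records = m.subgroup_dms(matrix, factor, DMSThresholds.tissue())
        assert len(records) == 0

    def test_age_boundary_in_younger_group(self):
        ages = pd.Series({"s1": 54.0, "s2": 55.0, "s3": 56.0})
        groups = dichotomize_age(ages, cutoff=55)
        assert groups["s2"] == "younger" and groups["s3"] == "older"


class TestAnnotationEnrichment:
    def _annotation(self, n_sites, props, seed=5):
        ann, _, _ = m.simulate_annotations(n_sites, props, 5, seed=seed)
        return ann

    def test_matched_proportions_give_fold_one(self):
        from methdx.calling import site_id
        ann = self._annotation(100, {"promoter": 0.5})
        background = [site_id("chr1", 1001 + 50 * i) for i in range(100)]
        promoters = {f"{r.chrom}:{r.end}" for r in ann.itertuples()}
        dms_sites = [s for s in background if s in promoters][:10] \
            + [s for s in background if s not in promoters][:10]
        result = m.annotation_enrichment(dms_sites, background, ann)
        fold = result.set_index("category").loc["promoter", "fold"]
        assert fold == pytest.approx(1.0)

    def test_direct_fold_ratio(self):
        from methdx.calling import site_id
        background = [site_id("chr1", 1001 + 50 * i) for i in range(100)]
        # 2 background sites annotated promoter; 10-site DMS set contains 1
        ann = pd.DataFrame({"chrom": ["chr1", "chr1"],
                            "start": [1000, 1050], "end": [1001, 1051],
                            "category": ["promoter", "promoter"]})
        dms_sites = background[:10]  # includes both promoter sites? only first two
        result = m.annotation_enrichment(dms_sites, background, ann)
        row = result.set_index("category").loc["promoter"]
        assert row["fold"] == pytest.approx((row["k"] / 10) / (2 / 100))

    def test_planted_promoter_enrichment_recovered(self):
        from methdx.calling import site_id
        rng = np.random.default_rng(5)
        ann = self._annotation(1000, {"promoter": 0.2}, seed=5)
        background = [site_id("chr1", 1001 + 50 * i) for i in range(1000)]
        promoters = {f"{r.chrom}:{r.end}" for r in ann.itertuples()}
        prom = [s for s in background if s in promoters]
        rest = [s for s in background if s not in promoters]
        # construct a DMS set whose promoter rate is 3x the background's 20%
        dms_sites = (list(rng.choice(prom, 60, replace=False))
                     + list(rng.choice(rest, 40, replace=False)))
        result = m.annotation_enrichment(dms_sites, background, ann)
        fold = result.set_index("category").loc["promoter", "fold"]
        assert abs(fold - 3.0) < 0.5

    def test_dms_must_be_subset_of_background(self):
        ann = self._annotation(10, {"promoter": 0.5})
        with pytest.raises(ValueError):
            m.annotation_enrichment(["chrX:1"], ["chr1:1001"], ann)
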