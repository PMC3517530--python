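"""Cross-validation loops, adjusted rates and derived metrics."""

import numpy as np
import pytest

from surfwave.validation import (ClassifierConfig, EmptySelectionError,
                                 adjusted_rates, iterative_three_way, loo,
                                 round_half_up, sens_spec_ppv, split_half,
                                 validate_cohort)

from conftest import make_feature_matrix


def separable_cohort(n_per=10, p=20, gap=10.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(0, 1, (n_per, p)),
                        rng.normal(gap, 1, (n_per, p))])
    labels = ["patient"] * n_per + ["control"] * n_per
    return make_feature_matrix(x, labels)


class TestAdjustedRates:
    def test_worked_example_one(self):
        rate, clipped = adjusted_rates(0.024, 0.11, 0.07)
        assert round_half_up(rate, 3) == 0.064
        assert not clipped

    def test_worked_example_two(self):
        rate, _ = adjusted_rates(0.0952, 0.16, 0.14)
        assert round_half_up(rate, 3) == 0.115

    def test_zero_inputs(self):
        assert adjusted_rates(0.0, 0.0, 0.0) == (0.0, False)

    def test_clipping_flagged(self):
        rate, clipped = adjusted_rates(0.01, 0.0, 0.5)
        assert rate == 0.0
        assert clipped

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rates(1.5, 0.0, 0.0)

    def test_round_half_up_behaves_like_printed_tables(self):
        assert round_half_up(0.0685, 3) == 0.069
        assert round_half_up(0.1152, 3) == 0.115


class TestSensSpecPPV:
    def test_adhd_row_reproduces_published_metrics(self):
        m = sens_spec_ppv(0.064, 0.115, 41, 42)
        assert round(100 * m["sensitivity"], 1) == 93.6
        assert round(100 * m["specificity"], 1) == 88.5
        assert abs(m["ppv"] - 0.89) < 0.005

    def test_perfect_classification(self):
        m = sens_spec_ppv(0.0, 0.0, 10, 10)
        assert m["sensitivity"] == m["specificity"] == m["ppv"] == 1.0

    def test_degenerate_denominator_flagged(self):
        m = sens_spec_ppv(1.0, 0.0, 10, 10)
        assert not m["ppv_defined"]


class TestLOO:
    def test_separable_cohort_has_zero_rates(self):
        fm = separable_cohort()
        res = loo(fm, cfg=ClassifierConfig(alpha=1e-4))
        assert res.per_class == {"control": 0.0, "patient": 0.0}

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(0)
        rates = []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=(20, 30))
            labels = list(rng.permutation(["a"] * 10 + ["b"] * 10))
            fm = make_feature_matrix(x, labels)
            rates.append(loo(fm, cfg=ClassifierConfig(alpha=1.0)).overall)
        assert 0.35 < np.mean(rates) < 0.65

    def test_minimal_cohort_rate_granularity(self):
        fm = separable_cohort(n_per=3, gap=20.0)
        res = loo(fm, cfg=ClassifierConfig(alpha=1.0))
        for rate in res.per_class.values():
            assert rate in {0.0, 1 / 3, 2 / 3, 1.0}

    def test_selection_rerun_inside_folds(self):
        """A fold with no surviving feature raises instead of silently
        reusing a whole-cohort selection."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 10))
        fm = make_feature_matrix(x, ["a"] * 6 + ["b"] * 6)
        with pytest.raises(EmptySelectionError):
            loo(fm, cfg=ClassifierConfig(alpha=1e-10))

    def test_too_small_class_rejected(self):
        fm = separable_cohort(n_per=2)
        with pytest.raises(ValueError):
            loo(fm)


class TestSplitHalf:
    def test_separable_cohort_all_zero(self):
        fm = separable_cohort()
        res = split_half(fm, cfg=ClassifierConfig(alpha=1e-4), seed=1)
        assert res.split_mean == {"control": 0.0, "patient": 0.0}
        assert res.loo_split_mean == {"control": 0.0, "patient": 0.0}

    def test_seeded_reproducibility_and_schema(self):
        fm = separable_cohort(seed=2)
        cfg = ClassifierConfig(alpha=1e-3)
        r1 = split_half(fm, cfg=cfg, n_splits=4, seed=5)
        r2 = split_half(fm, cfg=cfg, n_splits=4, seed=5)
        assert r1 == r2
        r3 = split_half(fm, cfg=cfg, n_splits=4, seed=6)
        assert r3.n_splits == 4

    def test_requested_number_of_replicates(self):
        """10 splits produce 10 test-half estimates and 20 half-cohort LOO
        estimates per class (visible through the sd denominators)."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(16, 5))
        x[:8] += 6.0
        fm = make_feature_matrix(x, ["a"] * 8 + ["b"] * 8)
        res = split_half(fm, cfg=ClassifierConfig(alpha=1.0), n_splits=10,
                         seed=0)
        assert res.n_splits == 10
        for c in ("a", "b"):
            assert np.isfinite(res.split_sd[c])
            assert np.isfinite(res.loo_split_sd[c])


class TestValidateCohort:
    def test_perfect_cohort_report(self):
        fm = separable_cohort()
        rep = validate_cohort(fm, patient_class="patient",
                              cfg=ClassifierConfig(alpha=1e-4), seed=0)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 1.0
        assert rep.ppv == 1.0
        assert rep.adjusted == {"control": 0.0, "patient": 0.0}

    def test_report_serializes(self):
        import json

        fm = separable_cohort(n_per=6)
        rep = validate_cohort(fm, cfg=ClassifierConfig(alpha=1.0), seed=0)
        blob = json.dumps(rep.to_dict())
        assert "sensitivity" in blob


class TestNoLeakage:
    def test_canary_feature_does_not_beat_chance_on_shuffled_labels(self):
        """A feature equal to the (shuffled) training labels is selected in
        every fold, but held-out error stays at chance because selection
        happens strictly inside the fold."""
        rng = np.random.default_rng(4)
        rates = []
        for seed in range(15):
            r = np.random.default_rng(100 + seed)
            x = r.normal(size=(20, 10))
            labels = list(r.permutation(["a"] * 10 + ["b"] * 10))
            x[:, 0] = [1.0 if l == "a" else 0.0 for l in labels]  # canary
            fm = make_feature_matrix(x, labels)
            rates.append(loo(fm, cfg=ClassifierConfig(alpha=1.0)).overall)
        # chance is 0.5; the canary makes training folds separable but the
        # held-out subject's label is independent of the training split
        assert np.mean(rates) > 0.3


class TestIterativeThreeWay:
    def test_three_separated_classes_fully_recovered(self):
        # both patient classes deviate from HA on a shared feature set, and
        # differ from each other on a second set (the regime in which the
        # iterative two-way strategy is designed to work)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(18, 12))
        x[6:, :3] += 15.0       # SZ and BD vs HA
        x[6:12, 6:9] += 15.0    # SZ vs BD
        labels = ["HA"] * 6 + ["SZ"] * 6 + ["BD"] * 6
        fm = make_feature_matrix(x, labels)
        out = iterative_three_way(fm, merge_pair=("SZ", "BD"),
                                  cfg=ClassifierConfig(alpha=1e-3))
        assert out["per_class"] == {"BD": 0.0, "HA": 0.0, "SZ": 0.0}

    def test_stage_feature_sets_selected_independently(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(18, 12))
        # features 0-2 separate (SZ,BD) from HA; features 6-8 separate SZ/BD
        x[6:, :3] += 12.0
        x[6:12, 6:9] += 12.0
        labels = ["HA"] * 6 + ["SZ"] * 6 + ["BD"] * 6
        fm = make_feature_matrix(x, labels)
        out = iterative_three_way(fm, merge_pair=("SZ", "BD"),
                                  cfg=ClassifierConfig(alpha=1e-4))
        assert set(out["stage2_features"]) != set(out["stage1_features"])
        assert {6, 7, 8} <= set(out["stage2_features"])

    def test_indistinguishable_pair_fails_only_at_stage_two(self):
        rng = np.random.default_rng(7)
        far = rng.normal(20, 1, (6, 6))
        same_a = rng.normal(0, 1, (6, 6))
        same_b = rng.normal(0, 1, (6, 6))
        x = np.concatenate([far, same_a, same_b])
        labels = ["HA"] * 6 + ["SZ"] * 6 + ["BD"] * 6
        fm = make_feature_matrix(x, labels)
        out = iterative_three_way(fm, merge_pair=("SZ", "BD"),
                                  cfg=ClassifierConfig(alpha=1.0))
        assert out["per_class"]["HA"] == 0.0
        assert out["per_class"]["SZ"] + out["per_class"]["BD"] > 0.5

    def test_missing_merge_pair_rejected(self):
        fm = separable_cohort(n_per=3)
        with pytest.raises(ValueError):
            iterative_three_way(fm, merge_pair=None)
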