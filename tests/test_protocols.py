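"""Offline leave-one-out and online incremental protocols, plus
per-class sensitivity/specificity."""

import numpy as np
import pytest

from vennose import (ConfusionTable, Dataset, ExperimentConfig,
                     InvalidInputError, default_class_means,
                     generate_feature_table, offline_loo, online_run,
                     sensitivity_specificity)


class TestOfflineLOO:
    @pytest.mark.parametrize("method, mode", [("nb", "loo"), ("vm-nb", "loo"),
                                              ("platt", "loo")])
    def test_separable_data_classified_perfectly(self, separable_data, method, mode):
        # vm methods use the leave-one-out taxonomy here: the "induct"
        # shortcut can degenerate to a pure-category identity matrix on
        # noise-free data, which honestly reports an uninformative [0,1]
        cfg = ExperimentConfig(method=method, mode=mode, scale=False, seed=0)
        res = offline_loo(separable_data, cfg)
        assert res.classification_rate == 1.0

    def test_minimal_dataset_runs(self):
        d = generate_feature_table([2, 1, 1], default_class_means(3, 2, 8.0), 1.0, seed=0)
        cfg = ExperimentConfig(method="nb", scale=False)
        res = offline_loo(d, cfg)
        assert 0.0 <= res.classification_rate <= 1.0
        assert len(res.records) == 4

    def test_label_shuffled_data_near_chance(self, rng):
        d = generate_feature_table(20, default_class_means(3, 4, 2.0), 1.0, seed=3)
        shuffled = Dataset(d.X, d.y[rng.permutation(d.n)], d.labels)
        cfg = ExperimentConfig(method="nb", scale=False)
        res = offline_loo(shuffled, cfg)
        # null rate 1/3; 3-sigma binomial band at n=60 is about +/-0.18
        assert abs(res.classification_rate - 1 / 3) < 0.19

    def test_rate_equals_sensitivity_weighted_sum(self, three_class_data):
        cfg = ExperimentConfig(method="nb", scale=False)
        res = offline_loo(three_class_data, cfg)
        sens, _ = sensitivity_specificity(res.confusion)
        weights = res.confusion.counts.sum(axis=1) / three_class_data.n
        assert res.classification_rate == pytest.approx(float(weights @ sens))

    def test_row_order_invariance(self, three_class_data):
        cfg = ExperimentConfig(method="nb", scale=True)
        base = offline_loo(three_class_data, cfg)
        perm = np.random.default_rng(0).permutation(three_class_data.n)
        shuffled = offline_loo(three_class_data.subset(perm), cfg)
        by_id_base = {r.sample_id: (r.predicted_label, r.p_lower) for r in base.records}
        by_id_perm = {r.sample_id: (r.predicted_label, r.p_lower) for r in shuffled.records}
        assert set(by_id_base) == set(by_id_perm)
        for sid, (lab, p) in by_id_base.items():
            assert by_id_perm[sid][0] == lab
            # probabilities agree up to float summation order
            assert by_id_perm[sid][1] == pytest.approx(p, abs=1e-9)

    def test_venn_records_carry_intervals(self, three_class_data):
        cfg = ExperimentConfig(method="vm-nb", mode="induct", scale=False)
        res = offline_loo(three_class_data.subset(np.arange(24)), cfg)
        assert all(0 <= r.p_lower <= r.p_upper <= 1 for r in res.records)
        assert any(r.p_upper > r.p_lower for r in res.records)

    def test_too_small_dataset_rejected(self):
        d = generate_feature_table(1, default_class_means(3, 2, 5.0), 1.0, seed=0)
        with pytest.raises(InvalidInputError):
            offline_loo(d, ExperimentConfig(method="nb"))


class TestOnlineRun:
    def test_deterministic_given_seed(self, three_class_data):
        cfg = ExperimentConfig(method="vm-nb", mode="induct", scale=False, seed=42)
        a = online_run(three_class_data, cfg)
        b = online_run(three_class_data, cfg)
        assert [(r.sample_id, r.p_lower, r.p_upper, r.correct) for r in a.records] == \
               [(r.sample_id, r.p_lower, r.p_upper, r.correct) for r in b.records]
        assert a.test_order == b.test_order

    def test_consumes_every_noninitial_sample_once(self, three_class_data):
        cfg = ExperimentConfig(method="nb", scale=False, seed=1,
                               online_init_per_class=4)
        res = online_run(three_class_data, cfg)
        assert len(res.records) == three_class_data.n - 3 * 4
        assert len(set(r.sample_id for r in res.records)) == len(res.records)

    def test_interval_width_narrows_on_separable_data(self):
        d = generate_feature_table(40, default_class_means(3, 4, 8.0), 1.0, seed=21)
        cfg = ExperimentConfig(method="vm-nb", mode="induct", scale=False, seed=21)
        res = online_run(d, cfg)
        widths = np.array([r.p_upper - r.p_lower for r in res.records])
        q = len(widths) // 4
        assert widths[-q:].mean() < widths[:q].mean()

    def test_online_validity_bounds_hold_throughout(self, three_class_data):
        cfg = ExperimentConfig(method="vm-nb", mode="induct", scale=False, seed=9)
        res = online_run(three_class_data, cfg)
        rep = res.report
        N = np.arange(1, rep.n + 1)
        slack = 3 * np.sqrt(N)
        assert np.all(rep.cn >= rep.cp_lower - slack)
        assert np.all(rep.cn <= rep.cp_upper + slack)

    def test_class_too_small_rejected(self):
        d = generate_feature_table(3, default_class_means(3, 2, 5.0), 1.0, seed=0)
        cfg = ExperimentConfig(method="nb", online_init_per_class=3)
        with pytest.raises(InvalidInputError):
            online_run(d, cfg)


class TestSensitivitySpecificity:
    def test_diagonal_table_is_perfect(self):
        table = ConfusionTable(np.diag([5, 7, 9]), ("a", "b", "c"))
        sens, spec = sensitivity_specificity(table)
        assert np.allclose(sens, 1.0) and np.allclose(spec, 1.0)

    def test_two_class_hand_case(self):
        table = ConfusionTable(np.array([[8, 2], [1, 9]]), ("a", "b"))
        sens, spec = sensitivity_specificity(table)
        np.testing.assert_allclose(sens, [0.8, 0.9])
        np.testing.assert_allclose(spec, [0.9, 0.8])

    def test_everything_predicted_to_first_class(self):
        table = ConfusionTable(np.array([[10, 0, 0], [10, 0, 0], [10, 0, 0]]),
                               ("a", "b", "c"))
        sens, spec = sensitivity_specificity(table)
        np.testing.assert_allclose(sens, [1.0, 0.0, 0.0])
        np.testing.assert_allclose(spec, [0.0, 1.0, 1.0])

    def test_empty_class_row_is_nan_not_zero(self):
        table = ConfusionTable(np.array([[4, 1], [0, 0]]), ("a", "b"))
        sens, _ = sensitivity_specificity(table)
        assert np.isnan(sens[1])


class TestConfig:
    def test_unknown_method_rejected_with_list(self):
        with pytest.raises(InvalidInputError, match="vm-svm"):
            ExperimentConfig(method="vm-svn")

    def test_retuning_runs_in_online_mode(self):
        d = generate_feature_table(12, default_class_means(3, 2, 6.0), 1.0, seed=2)
        cfg = ExperimentConfig(method="platt", scale=False, tune=True, seed=2,
                               retune_interval=10, online_init_per_class=3)
        res = online_run(d, cfg)  # must tune once counts allow, and finish
        assert res.config.svm_c in [2.0 ** k for k in range(2, 15, 2)]
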