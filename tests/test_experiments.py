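"""Protocol mechanics, leakage audit, ablations, and paired comparison."""

import numpy as np
import pytest
from scipy import stats

from dbfn.core_data import DEAP_EEG_CHANNELS, RegionMask
from dbfn.experiments import (
    ProtocolSpec,
    band_pair_ablation,
    extract_study_features,
    region_ablation,
    restrict_band_pair,
    run_loso,
    run_protocol,
    run_subject_dependent,
    run_subject_trial_independent,
    wilcoxon_compare,
)
from dbfn.model import ClassifierProtocolConfig
from dbfn.synthetic_data import CouplingSpec, generate_study, two_class_fixture

CFG = ClassifierProtocolConfig(n_repeats=2, seed=0, c_grid=(0.5, 4.0))
SPEC = ProtocolSpec(dimension="valence", window_s=10.0, k_features=32, seed=5)


class TestFeatureExtraction:
    def test_shapes_and_layout(self, small_feats):
        n_ch = 8
        expected = 12 * 6 * (1 + 2 * n_ch)  # 12 signals x 6 windows of 10 s
        assert small_feats.X.shape == (24, expected)
        assert len(small_feats.layout) == expected
        assert small_feats.subject_index.max() == 2

    def test_band_pair_restriction(self, small_feats):
        sub = restrict_band_pair(small_feats, "gamma_beta")
        assert sub.X.shape[1] == 2 * 6 * (1 + 2 * 8)
        assert all(c.startswith("gamma_beta:") for c in sub.layout)
        assert restrict_band_pair(small_feats, "ALL") is small_feats
        with pytest.raises(KeyError):
            restrict_band_pair(small_feats, "theta_gamma")

    def test_labels_match_fixture_classes(self, small_feats, small_study):
        y = small_feats.labels("valence")
        flat_classes = [c for cl in small_study.classes for c in cl]
        np.testing.assert_array_equal(
            y, np.array([c == "high" for c in flat_classes], dtype=int))


class TestProtocolMechanics:
    def test_subject_dependent_one_accuracy_per_subject(self, small_feats):
        res = run_subject_dependent(small_feats, SPEC, CFG)
        assert len(res.per_subject_accuracy) == 3
        assert all(0.0 <= a <= 1.0 for a in res.per_subject_accuracy)
        # mean/std recomputable from the per-subject list
        assert res.mean == pytest.approx(
            np.mean(res.per_subject_accuracy), abs=1e-12)
        assert res.std == pytest.approx(
            np.std(res.per_subject_accuracy), abs=1e-12)

    def test_single_subject_study(self):
        study = two_class_fixture(seed=8, n_subjects=1, n_trials=8,
                                  n_channels=6)
        feats = extract_study_features(study, window_s=10.0)
        res = run_subject_dependent(feats, SPEC, CFG)
        assert len(res.per_subject_accuracy) == 1

    def test_loso_two_subjects(self):
        study = two_class_fixture(seed=9, n_subjects=2, n_trials=8,
                                  n_channels=6)
        feats = extract_study_features(study, window_s=10.0)
        res = run_loso(feats, SPEC, CFG)
        assert len(res.per_subject_accuracy) == 2
        assert all(0.0 <= a <= 1.0 for a in res.per_subject_accuracy)

    def test_loso_single_subject_rejected(self):
        study = two_class_fixture(seed=8, n_subjects=1, n_trials=8,
                                  n_channels=6)
        feats = extract_study_features(study, window_s=10.0)
        with pytest.raises(ValueError, match="subjects"):
            run_loso(feats, SPEC, CFG)

    def test_subject_trial_partition_disjoint_and_seeded(self, small_feats):
        res1 = run_subject_trial_independent(small_feats, SPEC, CFG)
        res2 = run_subject_trial_independent(small_feats, SPEC, CFG)
        assert len(res1.per_subject_accuracy) == 3
        for f1, f2 in zip(res1.folds, res2.folds):
            # same seed -> identical partitions
            assert f1.train_rows == f2.train_rows
            assert f1.test_rows == f2.test_rows
            # no trial index on both sides of a fold
            tr_trials = {int(small_feats.trial_index[r]) for r in f1.train_rows}
            te_trials = {int(small_feats.trial_index[r]) for r in f1.test_rows}
            assert not tr_trials & te_trials
            # test half of 8 shared trial indices
            assert len(te_trials) == 4

    def test_no_training_stage_reads_test_rows(self, small_feats):
        for runner in (run_subject_dependent, run_loso,
                       run_subject_trial_independent):
            res = runner(small_feats, SPEC, CFG)
            assert res.folds, "protocols must emit fold audits"
            for fold in res.folds:
                assert fold.training_stages_clean()
                assert fold.log.rows_for(("mrmr",)) <= fold.train_rows

    def test_run_protocol_dispatch(self, small_feats):
        res = run_protocol(small_feats,
                           ProtocolSpec(mode="subject_independent",
                                        dimension="arousal", window_s=10.0,
                                        k_features=32, seed=5), CFG)
        assert len(res.per_subject_accuracy) == 3
        assert res.config["mode"] == "subject_independent"


@pytest.fixture(scope="module")
def deap_named_study():
    specs = {
        "low": CouplingSpec(32, frozenset({(0, 16)}), 0.9, "alpha", 0.2),
        "high": CouplingSpec(
            32, frozenset({(0, 16), (2, 18), (4, 20), (6, 22)}),
            0.9, "alpha", 0.2),
    }
    return generate_study(
        2, 6, specs, {"low": (2.5, 2.5), "high": (7.5, 7.5)}, seed=21,
        channel_names=DEAP_EEG_CHANNELS)


class TestAblations:
    def test_region_runs_shrink_feature_blocks(self, deap_named_study):
        spec = ProtocolSpec(mode="subject_dependent", dimension="valence",
                            window_s=30.0, k_features=16, seed=2)
        masks = [RegionMask.from_map(r) for r in ("LT", "F")]
        out = region_ablation(deap_named_study, spec, masks, CFG)
        assert set(out) == {"LT", "F"}
        for res in out.values():
            assert len(res.per_subject_accuracy) == 2

    def test_region_with_too_few_channels_rejected(self, deap_named_study):
        spec = ProtocolSpec(window_s=30.0, seed=2)
        with pytest.raises(ValueError, match="2 channels"):
            region_ablation(deap_named_study, spec,
                            [RegionMask("tiny", ("Fp1",))], CFG)

    def test_band_pair_ablation_feature_count(self, small_feats):
        res = band_pair_ablation(small_feats, SPEC, "beta_alpha", CFG)
        assert res.config["band_pair"] == "beta_alpha"
        assert len(res.per_subject_accuracy) == 3

    def test_coupled_band_pair_carries_more_mi_than_disjoint_pair(
            self, small_study):
        # coupling is planted in the alpha band: difference signals involving
        # alpha must show higher planted-edge MI than the gamma_beta pair,
        # which contains no coupled band.
        from dbfn.connectivity import mi_matrix_stack
        from dbfn.spectral import segment_windows, trial_difference_signals

        dense_edges = list(small_study.truth["high"].planted_edges)
        wins_mi = {}
        for s, subject in enumerate(small_study.subjects[:2]):
            for t, tr in enumerate(subject.trials):
                if small_study.classes[s][t] != "high":
                    continue
                for d in trial_difference_signals(tr):
                    if d.mode != "amplitude":
                        continue
                    name = f"{d.pair[0]}_{d.pair[1]}"
                    if name not in ("alpha_theta", "gamma_beta"):
                        continue
                    mi = mi_matrix_stack(
                        segment_windows(d.values, 10.0, tr.fs))
                    vals = [mi[:, i, j].mean() for i, j in dense_edges]
                    wins_mi.setdefault(name, []).append(np.mean(vals))
        assert np.mean(wins_mi["alpha_theta"]) > np.mean(wins_mi["gamma_beta"])


class TestWilcoxon:
    def test_identical_samples_flagged_degenerate(self):
        res = wilcoxon_compare([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert res.degenerate and res.p_value == 1.0

    def test_uniform_shift_significant_at_n32(self, rng):
        b = rng.uniform(0.5, 0.9, 32)
        res = wilcoxon_compare(b + 0.1, b)
        assert res.p_value < 0.05
        assert not res.degenerate

    def test_null_p_values_uniform(self, rng):
        ps = []
        for _ in range(200):
            a = rng.standard_normal(12)
            b = rng.standard_normal(12)
            ps.append(wilcoxon_compare(a, b).p_value)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([0.1, 0.2], [0.1])
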