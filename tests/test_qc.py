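import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from metaboline.qc import (
    average_biological_replicates,
    batch_plate_filter,
    correct_confluency,
    correct_injection_drift,
    drop_low_intensity_injections,
    replicate_roc_auc,
    zscore_features,
)
from metaboline.synthetic import StudyConfig, generate_study
from metaboline.types import PreconditionError, Stage

from conftest import make_matrix, make_meta, quiet_config


def auc_oracle(pos, neg):
    """Brute-force pairwise comparison AUC with 0.5 for ties."""
    wins = sum(1.0 if p < n else (0.5 if p == n else 0.0) for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestReplicateRocAuc:
    def test_perfect_separation(self):
        # two identical bio replicates per line, lines far apart
        vals = [[1, 1], [1, 1], [100, 100], [100, 100]]
        meta = make_meta(4, ["A", "A", "B", "B"], bio_reps=[1, 2, 1, 2])
        m = make_matrix(vals)
        assert replicate_roc_auc(m, meta, "biological") == 1.0

    def test_all_ties_gives_half(self):
        vals = [[1.0, 2.0]] * 4
        meta = make_meta(4, ["A", "A", "B", "B"], bio_reps=[1, 2, 1, 2])
        assert replicate_roc_auc(make_matrix(vals), meta, "biological") == 0.5

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(2, 1, size=(8, 5)))
        lines = ["A", "A", "A", "A", "B", "B", "B", "B"]
        bio = [1, 1, 2, 2, 1, 1, 2, 2]
        meta = make_meta(8, lines, bio_reps=bio, tech_reps=[1, 2] * 4)
        m = make_matrix(vals)
        logv = np.log10(vals)
        dist = {}
        for i, j in itertools.combinations(range(8), 2):
            dist[(i, j)] = np.linalg.norm(logv[i] - logv[j])
        for level, posrule in [
            ("technical", lambda i, j: lines[i] == lines[j] and bio[i] == bio[j]),
            ("biological", lambda i, j: lines[i] == lines[j] and bio[i] != bio[j]),
        ]:
            pos = [d for (i, j), d in dist.items() if posrule(i, j)]
            neg = [d for (i, j), d in dist.items() if lines[i] != lines[j]]
            assert replicate_roc_auc(m, meta, level) == pytest.approx(auc_oracle(pos, neg))

    def test_no_negative_pairs_errors(self):
        meta = make_meta(4, ["A"] * 4, bio_reps=[1, 1, 2, 2])
        with pytest.raises(PreconditionError):
            replicate_roc_auc(make_matrix(np.ones((4, 3))), meta, "biological")

    def test_unknown_level_errors(self, small_study):
        matrix, meta, _ = small_study
        with pytest.raises(ValueError):
            replicate_roc_auc(matrix, meta, "nope")


class TestInjectionDrift:
    def test_flat_input_unchanged(self):
        # zero-drift, zero-noise input: every feature constant over injections,
        # so the lowess fit is exactly that constant and correction is identity
        matrix, meta, _ = generate_study(quiet_config(n_features=8))
        out = correct_injection_drift(matrix, meta)
        assert out.stage == Stage.drift_corrected
        assert np.allclose(np.log(out.data), np.log(matrix.data), atol=1e-8)

    def test_constant_feature_returned_unchanged(self):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.normal(3, 0.3, size=(20, 3)))
        vals[:, 0] = 5.0
        meta = make_meta(20, [f"L{i}" for i in range(20)])
        out = correct_injection_drift(make_matrix(vals), meta)
        assert np.allclose(out.data.iloc[:, 0], 5.0)

    def test_planted_linear_drift_removed(self):
        matrix, meta, _ = generate_study(
            StudyConfig(seed=5, n_cell_lines=15, n_tissues=3, n_features=40,
                        drift_amplitude=1.0, confluency_effect=0.0,
                        batch_frac=0.0, global_bio_sd=0.0, global_tech_sd=0.0)
        )
        inj = meta["injection_index"].to_numpy()
        pre = [abs(pearsonr(np.log(matrix.data[f]), inj).statistic) for f in matrix.feature_ids]
        out = correct_injection_drift(matrix, meta)
        post = [abs(pearsonr(np.log(out.data[f]), inj).statistic) for f in out.feature_ids]
        assert np.median(pre) > 0.3
        assert np.median(post) < 0.1

    def test_too_few_injections_error(self):
        meta = make_meta(5, list("ABCDE"))
        with pytest.raises(PreconditionError, match="10"):
            correct_injection_drift(make_matrix(np.ones((5, 3))), meta)


class TestLowIntensityRemoval:
    def test_exact_threshold_arithmetic(self):
        vals = np.full((4, 1), 2.0**30)
        vals[2, 0] = 2.0**24  # log2 sum 24 < 25
        out, removed = drop_low_intensity_injections(make_matrix(vals), 25.0)
        assert removed == ["s2"]
        assert out.n_samples == 3

    def test_nothing_removed_when_above(self):
        vals = np.full((3, 2), 2.0**25)
        out, removed = drop_low_intensity_injections(make_matrix(vals), 25.0)
        assert removed == []

    def test_threshold_zero_removes_nothing(self, small_study):
        matrix, _, _ = small_study
        _, removed = drop_low_intensity_injections(matrix, 0.0)
        assert removed == []

    def test_all_removed_errors(self):
        with pytest.raises(PreconditionError):
            drop_low_intensity_injections(make_matrix(np.ones((3, 2))), 100.0)


class TestConfluencyCorrection:
    def test_independent_input_nearly_unchanged(self):
        matrix, meta, _ = generate_study(quiet_config(between_line_sd=0.5, n_features=10))
        out = correct_confluency(matrix, meta)
        # confluency plays no role in the generated values; correction factors
        # come only from smoothing the line structure and stay bounded
        assert out.stage == Stage.confluency_corrected
        ratio = np.log(out.data.to_numpy() / matrix.data.to_numpy())
        assert np.abs(ratio).max() < 1.0

    def test_planted_confluency_dependence_removed(self):
        matrix, meta, _ = generate_study(
            StudyConfig(seed=4, n_cell_lines=15, n_tissues=3, n_features=30,
                        confluency_effect=2.0, drift_amplitude=0.0, batch_frac=0.0,
                        global_bio_sd=0.0, global_tech_sd=0.0)
        )
        conf = meta["confluency"].to_numpy()
        pre = spearmanr(matrix.data.sum(axis=1), conf).statistic
        out = correct_confluency(matrix, meta)
        post = spearmanr(out.data.sum(axis=1), conf).statistic
        assert abs(pre) > 0.5
        assert abs(post) < 0.1

    def test_constant_confluency_identity(self, caplog):
        meta = make_meta(6, list("ABCDEF"), confluency=[0.5] * 6)
        m = make_matrix(np.exp(np.random.default_rng(0).normal(2, 1, (6, 4))))
        out = correct_confluency(m, meta)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_two_samples_error(self):
        meta = make_meta(2, ["A", "B"], confluency=[0.4, 0.8])
        with pytest.raises(PreconditionError):
            correct_confluency(make_matrix(np.ones((2, 2))), meta)


class TestBatchPlateFilter:
    def test_no_batch_structure_precondition(self):
        meta = make_meta(6, ["A", "A", "B", "B", "C", "C"], bio_reps=[1, 2] * 3)
        m = make_matrix(np.exp(np.random.default_rng(0).normal(2, 1, (6, 5))))
        with pytest.raises(PreconditionError, match="batch"):
            batch_plate_filter(m, meta, max_remove=2)

    def test_sweep_starts_at_zero(self, small_study):
        matrix, meta, _ = small_study
        _, report = batch_plate_filter(matrix, meta, max_remove=10)
        assert report.sweep_curve[0][0] == 0

    def test_max_remove_zero_is_identity(self, small_study):
        matrix, meta, _ = small_study
        out, report = batch_plate_filter(matrix, meta, max_remove=0)
        assert out.feature_ids == matrix.feature_ids
        assert report.removed_features == []

    def test_max_remove_too_large_errors(self, small_study):
        matrix, meta, _ = small_study
        with pytest.raises(PreconditionError):
            batch_plate_filter(matrix, meta, max_remove=matrix.n_features)

    def test_anova_pvalues_cover_all_features(self, small_study):
        matrix, meta, _ = small_study
        _, report = batch_plate_filter(matrix, meta, max_remove=5)
        assert list(report.anova_pvalues.index) == matrix.feature_ids
        assert set(report.anova_pvalues.columns) == {"p_batch", "p_plate"}


class TestZscore:
    def test_three_values(self):
        m = make_matrix([[1.0], [2.0], [3.0]])
        z = zscore_features(m.with_data(m.data, Stage.cellline_avg))
        assert np.allclose(z.data.iloc[:, 0], [-1, 0, 1])  # sample SD (n-1) = 1

    def test_constant_feature_dropped(self):
        m = make_matrix([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]], stage=Stage.cellline_avg)
        z = zscore_features(m)
        assert z.feature_ids == ["f0"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(10, 4)), stage=Stage.cellline_avg)
        z1 = zscore_features(m)
        z2 = zscore_features(z1)
        assert np.allclose(z1.data, z2.data, atol=1e-12)

    def test_moments(self, averaged_z):
        assert np.allclose(averaged_z.data.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(averaged_z.data.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_single_sample_error(self):
        with pytest.raises(PreconditionError):
            zscore_features(make_matrix([[1.0, 2.0]], stage=Stage.cellline_avg))


class TestAverageBiologicalReplicates:
    def test_bio_rep_mean(self):
        vals = [[2.0], [4.0], [6.0]]
        meta = make_meta(3, ["A", "A", "A"], bio_reps=[1, 2, 3])
        out = average_biological_replicates(make_matrix(vals), meta)
        assert out.data.loc["A", "f0"] == 4.0
        assert out.stage == Stage.cellline_avg

    def test_identical_tech_reps(self):
        vals = [[7.0], [7.0]]
        meta = make_meta(2, ["A", "A"], bio_reps=[1, 1], tech_reps=[1, 2])
        out = average_biological_replicates(make_matrix(vals), meta)
        assert out.data.loc["A", "f0"] == 7.0

    def test_unbalanced_tech_reps_equal_bio_weight(self):
        # bio rep 1 has three tech reps of 0, bio rep 2 one tech rep of 6:
        # equal bio-rep weighting gives (0 + 6)/2 = 3, not the sample mean 1.5
        vals = [[0.0], [0.0], [0.0], [6.0]]
        meta = make_meta(4, ["A"] * 4, bio_reps=[1, 1, 1, 2], tech_reps=[1, 2, 3, 1])
        out = average_biological_replicates(make_matrix(vals), meta)
        assert out.data.loc["A", "f0"] == 3.0
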