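"""Linear-SVM decoding: training contract, split designs, significance,
rank-sum z."""

import numpy as np
import pandas as pd
import pytest

from obmix.decoding import (
    DecodingResult,
    _ranksum_z,
    accuracy_significance,
    balanced_accuracy,
    cross_generalization_accuracy,
    random_split_accuracy,
    ranksum_z_timecourse,
    train_linear_decoder,
)
from obmix.exceptions import (
    InsufficientReplicatesError,
    InvalidDesignError,
    InvalidTrainingSetError,
)
from obmix.transients import time_resolved_matrices
from tests.test_similarity import matrix_from


def separable_matrix(n_per_class=10, n_rois=20, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.normal(size=n_rois)
    pos = w + rng.normal(0, noise, (n_per_class, n_rois))
    neg = -w + rng.normal(0, noise, (n_per_class, n_rois))
    amps = np.vstack([pos, neg])
    labels = [True] * n_per_class + [False] * n_per_class
    return matrix_from(amps, labels)


class TestTrainLinearDecoder:
    def test_separable_through_origin_perfect_training_accuracy(self):
        rm = separable_matrix()
        dec = train_linear_decoder(rm)
        pred = dec.predict(rm.amplitudes)
        assert balanced_accuracy(rm.labels["target_present"], pred) == 1.0
        assert dec.weights.shape == (rm.n_rois,)

    def test_class_swap_flips_weights(self):
        rm = separable_matrix(seed=1)
        y = rm.labels["target_present"].to_numpy()
        w1 = train_linear_decoder(rm, labels=y).weights
        w2 = train_linear_decoder(rm, labels=~y).weights
        cos = np.dot(w1, w2) / (np.linalg.norm(w1) * np.linalg.norm(w2))
        assert cos == pytest.approx(-1.0, abs=1e-3)

    def test_all_zero_features_chance(self):
        rm = matrix_from(np.zeros((10, 5)), [True] * 5 + [False] * 5)
        dec = train_linear_decoder(rm)
        pred = dec.predict(rm.amplitudes)
        assert balanced_accuracy(rm.labels["target_present"], pred) == 0.5

    def test_single_class_rejected(self):
        rm = matrix_from(np.random.default_rng(2).normal(size=(6, 5)), [True] * 6)
        with pytest.raises(InvalidTrainingSetError):
            train_linear_decoder(rm)

    def test_roi_permutation_invariance(self):
        rm = separable_matrix(seed=3, noise=0.3)
        rng = np.random.default_rng(4)
        perm = rng.permutation(rm.n_rois)
        test = rng.normal(size=(20, rm.n_rois))
        dec = train_linear_decoder(rm)
        rm_p = matrix_from(rm.amplitudes[:, perm],
                           rm.labels["target_present"].tolist())
        dec_p = train_linear_decoder(rm_p)
        assert np.array_equal(dec.predict(test), dec_p.predict(test[:, perm]))

    def test_regularization_decade_stable_on_separable_data(self):
        rm = separable_matrix(seed=5, noise=0.2)
        test = separable_matrix(seed=6, noise=0.2)
        y = test.labels["target_present"].to_numpy()
        accs = [
            balanced_accuracy(y, train_linear_decoder(rm, C=c).predict(test.amplitudes))
            for c in (0.3, 1.0, 3.0)
        ]
        assert max(accs) - min(accs) < 0.1


class TestSplitDesigns:
    def test_post_onset_separable_pre_onset_near_chance(self, anaesthetised_session):
        """Post-onset windows decode essentially perfectly; pre-onset windows
        carry no stimulus information (near chance, up to the small-sample
        pessimism of held-out decoding on noise-only features)."""
        rms = time_resolved_matrices(
            anaesthetised_session, target="EB", t_start=-2.0, t_end=1.5, step_s=0.5
        )
        res = random_split_accuracy(rms, n_splits=20, seed=1)
        tc = dict(zip(res.time_points, res.mean_timecourse()))
        assert tc[1.5] > 0.9
        assert abs(tc[-2.0] - 0.5) < 0.15
        assert tc[1.5] - tc[-2.0] > 0.3

    def test_label_shuffle_at_chance(self, anaesthetised_session):
        """Freshly shuffled labels destroy all decodable structure."""
        rms = time_resolved_matrices(
            anaesthetised_session, target="EB", t_start=1.0, t_end=1.0, step_s=1.0
        )
        rng = np.random.default_rng(2)
        rm = rms[0][1]
        accs = []
        for rep in range(20):
            shuffled = rm.labels.copy()
            shuffled["target_present"] = rng.permutation(
                shuffled["target_present"].to_numpy()
            )
            rm_s = type(rm)(
                amplitudes=rm.amplitudes, labels=shuffled, window=rm.window,
                fov_id=rm.fov_id, state=rm.state, stimuli=rm.stimuli,
            )
            res = random_split_accuracy([(1.0, rm_s)], n_splits=5, seed=rep)
            accs.append(res.mean_timecourse()[0])
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_cross_generalization_on_linear_low_noise_session(self, panel):
        """With linear summation and little noise, mixture patterns are the
        sums of their components, so single-trained decoders generalize."""
        from obmix.synthetic import (
            STATE_PRESETS, StateProfile, SyntheticConfig, make_trial_list,
            simulate_session,
        )

        state = StateProfile(name="linear_quiet", gain=1.0, trial_noise_sd=0.2,
                             decay_tau_s=6.0)
        cfg = SyntheticConfig(
            trial_list=make_trial_list(panel, 6, seed=51), seed=52
        )
        trials = simulate_session(panel, state, cfg)
        rms = time_resolved_matrices(
            trials, target="EB", t_start=1.0, t_end=1.0, step_s=1.0
        )
        res = cross_generalization_accuracy(rms, n_splits=10, seed=4)
        assert res.split_spec == "train_single_test_mixture"
        assert res.accuracy.shape == (10, 1)
        # mixtures resemble their components well above chance, but
        # target+masker mixtures sit near the single-odour boundary
        # (w·(target+x) ≈ margin+ − margin−), so cross-generalization stays
        # below the within-design accuracy
        cross = res.mean_timecourse()[0]
        within = random_split_accuracy(rms, n_splits=10, seed=4).mean_timecourse()[0]
        assert 0.55 < cross <= within + 0.05

    def test_no_mixtures_invalid_design(self):
        rm = separable_matrix()
        with pytest.raises(InvalidDesignError):
            cross_generalization_accuracy([(0.0, rm)], n_splits=2, seed=1)


class TestAccuracySignificance:
    def _result(self, accs, fov):
        accs = np.asarray(accs, dtype=float)[None, :]
        return DecodingResult(
            time_points=np.arange(accs.shape[1], dtype=float),
            accuracy=accs,
            split_spec="random_80_20",
            n_splits=1,
            seed=0,
            fov_id=fov,
        )

    def test_all_at_chance_never_significant(self):
        results = [self._result([0.5, 0.5, 0.5], f"f{i}") for i in range(4)]
        out = accuracy_significance(results)
        assert not out["significant"].any()
        assert out["earliest_significant_time"] is None

    def test_all_perfect_significant_from_first_window(self):
        rng = np.random.default_rng(5)
        results = [
            self._result(1.0 - rng.uniform(0, 0.02, 3), f"f{i}") for i in range(5)
        ]
        out = accuracy_significance(results)
        assert out["significant"].all()
        assert out["earliest_significant_time"] == 0.0

    def test_too_few_fields_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            accuracy_significance([self._result([0.5], "a")])

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(6)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            results = [
                self._result(rng.normal(0.5, 0.05, 1).clip(0, 1), f"f{i}")
                for i in range(6)
            ]
            out = accuracy_significance(results, alpha=0.05)
            hits += int(out["significant"][0])
        rate = hits / n_sim
        assert 0.02 < rate < 0.09


class TestRanksumZ:
    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert _ranksum_z(x, x) == 0.0

    def test_separated_groups_match_closed_form(self):
        # complete separation at (5, 5): W = 40, mu = 27.5,
        # sigma = sqrt(5*5*11/12) -> z = 12.5 / 4.7871 = 2.6112
        x = np.array([6.0, 7.0, 8.0, 9.0, 10.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert _ranksum_z(x, y) == pytest.approx(12.5 / np.sqrt(275 / 12))

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=5), rng.normal(size=6)
        assert _ranksum_z(x, y) == pytest.approx(-_ranksum_z(y, x))

    def test_timecourse_sign_convention(self):
        def result(level, fov):
            return DecodingResult(
                time_points=np.array([0.0]),
                accuracy=np.array([[level]]),
                split_spec="random_80_20",
                n_splits=1,
                seed=0,
                fov_id=fov,
            )

        high = [result(0.9 + 0.01 * i, f"h{i}") for i in range(4)]
        low = [result(0.5 + 0.01 * i, f"l{i}") for i in range(4)]
        z = ranksum_z_timecourse(high, low)["z"].iloc[0]
        assert z > 2.0
        z_swapped = ranksum_z_timecourse(low, high)["z"].iloc[0]
        assert z_swapped == pytest.approx(-z)
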