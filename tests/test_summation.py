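"""Mixture-summation statistics: pairs, deviations, medians, masking,
noise robustness."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from obmix.exceptions import (
    EmptyFieldError,
    InsufficientTrialsError,
    NoReferenceGlomeruliError,
)
from obmix.summation import (
    SummationPair,
    classify_linearity,
    deviation_from_linearity,
    fractional_deviation,
    linear_sum_pairs,
    masking_index,
    median_fractional_deviation,
    noise_robustness,
)
from obmix.synthetic import (
    STATE_PRESETS,
    SyntheticConfig,
    make_trial_list,
    simulate_session,
)
from obmix.transients import ResponseMatrix, build_response_matrix


def pair(r_obs, r_lin, sem_obs=0.1, sem_lin=0.1, fov="fov0"):
    return SummationPair(
        roi_id=0,
        r_observed=r_obs,
        r_linear=r_lin,
        sem_observed=sem_obs,
        sem_linear=sem_lin,
        n_trials_mixture=4,
        n_trials_components=4,
        fov_id=fov,
    )


def toy_matrix(stim_amps: dict, n_rois=1, fov="fov0"):
    """ResponseMatrix from {stimulus tuple: list of per-trial amplitudes}."""
    amps, stimuli = [], []
    for stim, values in stim_amps.items():
        for v in values:
            amps.append(np.atleast_1d(np.asarray(v, dtype=float)))
            stimuli.append(tuple(stim) if isinstance(stim, tuple) else (stim,))
    labels = pd.DataFrame(
        {
            "stimulus": ["+".join(s) for s in stimuli],
            "n_components": [len(s) for s in stimuli],
            "target_present": ["EB" in s for s in stimuli],
            "masker_present": ["MB" in s for s in stimuli],
            "rewarded": [None] * len(stimuli),
        }
    )
    return ResponseMatrix(
        amplitudes=np.stack(amps),
        labels=labels,
        window=(0.0, 1.0),
        fov_id=fov,
        stimuli=stimuli,
    )


class TestLinearSumPairs:
    def test_noiseless_linear_session_observed_equals_linear(self, noiseless_rm):
        pairs = linear_sum_pairs(noiseless_rm, "EB", "MB")
        for p in pairs:
            assert p.r_observed == pytest.approx(p.r_linear, abs=1e-9)

    def test_mean_arithmetic(self):
        rm = toy_matrix({"EB": [1.0], "MB": [2.0], ("EB", "MB"): [2.0]})
        (p,) = linear_sum_pairs(rm, "EB", "MB")
        assert (p.r_observed, p.r_linear) == (2.0, 3.0)

    def test_joint_sem_is_sum_of_component_sems(self):
        # component SEMs 0.3 and 0.2 -> joint 0.5 (two points +/- d have sem d)
        a = [1.0 - 0.3, 1.0 + 0.3]
        b = [2.0 - 0.2, 2.0 + 0.2]
        rm = toy_matrix({"EB": a, "MB": b, ("EB", "MB"): [3.0, 3.0]})
        (p,) = linear_sum_pairs(rm, "EB", "MB")
        assert p.sem_linear == pytest.approx(0.5)

    def test_missing_trial_type_names_stimulus(self):
        rm = toy_matrix({"EB": [1.0], "MB": [2.0]})
        with pytest.raises(InsufficientTrialsError, match="EB\\+MB"):
            linear_sum_pairs(rm, "EB", "MB")


class TestFractionalDeviation:
    @pytest.mark.parametrize(
        "r_obs,r_lin,expected",
        [
            (1.0, 1.0, 0.0),
            (0.61, 1.0, -0.39),
            (2.0, -1.0, 3.0),  # sign oracle: (2 - (-1))/|-1|
        ],
    )
    def test_formula(self, r_obs, r_lin, expected):
        assert fractional_deviation(pair(r_obs, r_lin)) == pytest.approx(expected)

    def test_exclusion_floor_marks_roi(self):
        assert math.isnan(fractional_deviation(pair(1.0, 0.01)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        k=st.floats(0.5, 50.0),
        r_obs=st.floats(-5, 5),
        r_lin=st.floats(0.2, 5.0),
    )
    def test_scale_invariance(self, k, r_obs, r_lin):
        d1 = fractional_deviation(pair(r_obs, r_lin), floor=0.0)
        d2 = fractional_deviation(pair(k * r_obs, k * r_lin), floor=0.0)
        assert d2 == pytest.approx(d1, rel=1e-9)


class TestDeviationFromLinearity:
    def test_arithmetic(self):
        assert deviation_from_linearity(pair(3.0, 1.0, 0.5, 0.5)) == pytest.approx(2.0)

    def test_zero_when_equal(self):
        assert deviation_from_linearity(pair(2.0, 2.0, 0.7, 0.1)) == 0.0

    def test_zero_joint_sem_undefined(self):
        assert math.isnan(deviation_from_linearity(pair(1.0, 2.0, 0.0, 0.0)))

    def test_classification_matches_bruteforce_tally(self):
        rng = np.random.default_rng(21)
        pairs = [
            pair(rng.normal(0, 2), rng.normal(0, 2), rng.uniform(0.1, 0.5),
                 rng.uniform(0.1, 0.5))
            for _ in range(200)
        ]
        table = classify_linearity(pairs, threshold=2.0)
        devs = np.array([deviation_from_linearity(p) for p in pairs])
        assert (table["label"] == "sublinear").sum() == np.sum(devs < -2)
        assert (table["label"] == "supralinear").sum() == np.sum(devs > 2)
        assert (table["label"] == "linear").sum() == np.sum(np.abs(devs) <= 2)

    def test_joint_sem_shrinks_sqrt_n(self, panel):
        """Doubling trial counts shrinks the joint SEM by ~sqrt(2)."""
        sems = {}
        for n, seed in ((20, 31), (40, 32)):
            cfg = SyntheticConfig(
                trial_list=[("EB",), ("MB",), ("EB", "MB")] * n, seed=seed
            )
            trials = simulate_session(panel, STATE_PRESETS["anaesthetised"], cfg)
            rm = build_response_matrix(trials, (0.0, 1.0), target="EB", masker="MB")
            pairs = linear_sum_pairs(rm, "EB", "MB")
            sems[n] = np.mean([p.sem_observed + p.sem_linear for p in pairs])
        assert sems[20] / sems[40] == pytest.approx(math.sqrt(2), rel=0.15)


class TestMedianFractionalDeviation:
    def test_known_median(self):
        pairs = [pair(1 + d, 1.0) for d in (-0.5, -0.39, 0.1)]
        out = median_fractional_deviation(pairs)
        assert out["pooled_median"] == pytest.approx(-0.39)

    def test_single_roi(self):
        out = median_fractional_deviation([pair(0.5, 1.0)])
        assert out["pooled_median"] == pytest.approx(-0.5)

    def test_even_count_midpoint_matches_sort_oracle(self):
        devs = [-0.6, -0.2, 0.1, 0.3]
        pairs = [pair(1 + d, 1.0) for d in devs]
        out = median_fractional_deviation(pairs)
        s = sorted(devs)
        assert out["pooled_median"] == pytest.approx((s[1] + s[2]) / 2)

    def test_per_field_then_pooled(self):
        pairs = [pair(0.5, 1.0, fov="A"), pair(0.9, 1.0, fov="B"),
                 pair(1.3, 1.0, fov="C")]
        out = median_fractional_deviation(pairs)
        assert out["field_medians"] == {"A": -0.5, "B": pytest.approx(-0.1),
                                        "C": pytest.approx(0.3)}
        assert out["pooled_median"] == pytest.approx(-0.1)

    def test_all_excluded_raises(self):
        with pytest.raises(EmptyFieldError):
            median_fractional_deviation([pair(1.0, 0.0)])

    def test_linear_noiseless_all_linear_and_median_zero(self, noiseless_rm):
        pairs = linear_sum_pairs(noiseless_rm, "EB", "MB")
        table = classify_linearity(pairs)
        assert (table["label"] == "linear").all()
        out = median_fractional_deviation(pairs)
        assert out["pooled_median"] == pytest.approx(0.0, abs=1e-9)

    def test_saturating_sessions_negative_linear_sessions_zero(self, panel):
        """Sign recovery: saturating summation -> median < 0; linear -> ~0."""
        results = {}
        for name in ("anaesthetised", "behaving"):
            cfg = SyntheticConfig(
                trial_list=make_trial_list(panel, 8, seed=41), seed=42
            )
            trials = simulate_session(panel, STATE_PRESETS[name], cfg)
            rm = build_response_matrix(trials, (0.0, 1.0), target="EB", masker="MB")
            pairs = linear_sum_pairs(rm, "EB", "MB")
            devs = np.array([fractional_deviation(p) for p in pairs])
            devs = devs[~np.isnan(devs)]
            results[name] = devs
        sat = results["anaesthetised"]
        # sign test: overwhelmingly negative under saturation
        p_sign = stats.binomtest(int((sat < 0).sum()), sat.size, 0.5).pvalue
        assert np.median(sat) < -0.2 and p_sign < 1e-6
        assert abs(np.median(results["behaving"])) < 0.2


class TestNoiseRobustness:
    def test_zero_sd_identical_to_unperturbed(self, anaesthetised_rm):
        df = noise_robustness(anaesthetised_rm, "EB", "MB", [0.0], n_repeats=3,
                              seed=1)
        assert df["median"].nunique() == 1

    def test_iqr_broadens_median_stable(self, anaesthetised_rm):
        df = noise_robustness(
            anaesthetised_rm, "EB", "MB", [0.0, 0.5, 1.0], n_repeats=100, seed=2
        )
        g = df.groupby("noise_sd")
        iqr = g["iqr"].mean()
        assert iqr.is_monotonic_increasing
        med0 = g["median"].mean().loc[0.0]
        for sd in (0.5, 1.0):
            shift = abs(g["median"].mean().loc[sd] - med0)
            mc_se = g["median"].std().loc[sd]
            assert shift < 2 * mc_se

    def test_negative_sd_rejected(self, anaesthetised_rm):
        from obmix.exceptions import InvalidArgumentError

        with pytest.raises(InvalidArgumentError):
            noise_robustness(anaesthetised_rm, "EB", "MB", [-0.1])


class TestMaskingIndex:
    def _glomerular_matrix(self, target_pattern, bg_pattern):
        return toy_matrix(
            {
                "EB": [target_pattern] * 3,
                "MB": [bg_pattern] * 3,
            },
            n_rois=len(target_pattern),
        )

    # one dominant glomerulus out of 12 clears the z > 2 responsiveness cut
    TARGET = np.array([8.0, 6.0] + [0.1] * 10)

    def test_identical_background_gives_one(self):
        rm = self._glomerular_matrix(self.TARGET, self.TARGET)
        (res,) = masking_index(rm, "EB")
        assert res.masking_index == pytest.approx(1.0)
        assert res.n_target_glomeruli >= 1

    def test_orthogonal_background_gives_zero(self):
        b = np.array([0.0, 0.0] + [3.0] * 10)
        rm = self._glomerular_matrix(self.TARGET, b)
        (res,) = masking_index(rm, "EB")
        assert res.masking_index == pytest.approx(0.0)

    def test_half_scaled_background_gives_half(self):
        rm = self._glomerular_matrix(self.TARGET, 0.5 * self.TARGET)
        (res,) = masking_index(rm, "EB")
        assert res.masking_index == pytest.approx(0.5)

    def test_no_responsive_glomeruli_raises(self):
        t = np.ones(8)  # zero variance across glomeruli -> no z > 2
        rm = self._glomerular_matrix(t + np.arange(8) * 1e-9, t)
        with pytest.raises(NoReferenceGlomeruliError):
            masking_index(rm, "EB")

    def test_graded_panel_tracks_overlap_spectrum(self):
        """On a sparse glomerular-level panel, masking indices rank with the
        generating tuning overlaps (the most similar odour masks most)."""
        from obmix.synthetic import (
            DEFAULT_OVERLAPS, StateProfile, SyntheticConfig, make_panel,
            simulate_session,
        )

        glom_panel = make_panel(400, 11, DEFAULT_OVERLAPS, seed=77,
                                amp_mean=0.5, amp_sd=1.5)
        state = StateProfile(name="glomerular", gain=1.0, trial_noise_sd=0.1)
        cfg = SyntheticConfig(
            n_rois=400,
            trial_list=[(o,) for o in glom_panel.odour_ids] * 3,
            seed=78,
        )
        trials = simulate_session(glom_panel, state, cfg)
        rm = build_response_matrix(trials, (0.0, 1.0), target="EB")
        results = masking_index(rm, "EB")
        overlaps = [glom_panel.overlap_spectrum[r.odour_id] for r in results]
        indices = [r.masking_index for r in results]
        rho = stats.spearmanr(overlaps, indices).statistic
        assert rho > 0.7
        ranked = sorted(results, key=lambda r: -r.masking_index)
        assert "MB" in [r.odour_id for r in ranked[:3]]
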