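"""POR probabilities, paired intensity tests, neural-behavioral regression."""

import numpy as np
import pandas as pd
import pytest

import odoradapt as oa
from odoradapt.errors import AlignmentError, PairingError, UsageError


def _table(rows):
    return pd.DataFrame(rows, columns=["animal_id", "trial_id", "stimulus_label", "por"])


class TestPORProbability:
    def test_all_respond(self):
        t = _table([(f"a{i}", 1, "hex_H", True) for i in range(4)])
        assert oa.por_probability(t, "hex_H").p_por[0] == 1.0

    def test_three_of_four(self):
        t = _table([("a1", 1, "hex_H", True), ("a2", 1, "hex_H", True),
                    ("a3", 1, "hex_H", True), ("a4", 1, "hex_H", False)])
        s = oa.por_probability(t, "hex_H")
        assert s.p_por[0] == 0.75
        assert s.n_animals == 4

    def test_absent_stimulus_rejected(self):
        with pytest.raises(UsageError):
            oa.por_probability(_table([("a1", 1, "hex_H", True)]), "oct_H")

    def test_unbiased_against_generative_curve(self):
        proto = oa.StimulusProtocol(n_trials_per_block=10, odor_window_s=(0, 4),
                                    block_sequence=["hex_H", "hex_L"])
        model = oa.BehaviorModel(p0=0.2, p_inf_high=0.8, p_inf_low=0.55,
                                 tau_trials=2, n_animals=500)
        table = oa.simulate_behavior(model, proto, seed=77)
        for stim in ("hex_H", "hex_L"):
            s = oa.por_probability(table, stim)
            p_true = model.p_curve(stim, s.trial_ids)
            se = np.sqrt(p_true * (1 - p_true) / 500)
            assert np.all(np.abs(s.p_por - p_true) < 3 * se)


class TestIntensityTTest:
    def _paired_table(self, low, high):
        rows = []
        for i, (lo, hi) in enumerate(zip(low, high)):
            rows.append((f"a{i}", 1, "hex_L", bool(lo)))
            rows.append((f"a{i}", 1, "hex_H", bool(hi)))
        return _table(rows)

    def test_identical_samples_center_the_null(self):
        t = self._paired_table([1, 0, 1, 0], [1, 0, 1, 0])
        res = oa.intensity_ttest(t, "hex")
        assert res.t_statistic == 0.0
        assert res.p_value == 0.5

    def test_hand_computed_t_statistic(self):
        # per-animal means over 2 trials: low (0.5, 0, 1, 0.5), high (1, 0.5, 1, 1)
        rows = []
        lows = [(1, 0), (0, 0), (1, 1), (1, 0)]
        highs = [(1, 1), (1, 0), (1, 1), (1, 1)]
        for i, (lo, hi) in enumerate(zip(lows, highs)):
            for trial, (l, h) in enumerate(zip(lo, hi), start=1):
                rows.append((f"a{i}", trial, "hex_L", bool(l)))
                rows.append((f"a{i}", trial, "hex_H", bool(h)))
        res = oa.intensity_ttest(_table(rows), "hex")
        d = np.array([0.5, 0.0, 1.0, 0.5]) - np.array([1.0, 0.5, 1.0, 1.0])
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        from scipy import stats

        assert res.t_statistic == pytest.approx(t_manual, abs=1e-12)
        assert res.p_value == pytest.approx(stats.t.cdf(t_manual, df=3), abs=1e-12)
        assert res.n_pairs == 4

    def test_unpaired_animal_rejected_with_ids(self):
        t = self._paired_table([1, 0], [1, 1])
        t = pd.concat([t, _table([("a9", 1, "hex_L", True)])], ignore_index=True)
        with pytest.raises(PairingError, match="a9"):
            oa.intensity_ttest(t, "hex")

    def test_lower_low_intensity_gives_small_p(self):
        proto = oa.StimulusProtocol(n_trials_per_block=10, odor_window_s=(0, 4),
                                    block_sequence=["hex_H", "hex_L"])
        model = oa.BehaviorModel(p0=0.1, p_inf_high=0.9, p_inf_low=0.3,
                                 tau_trials=2, n_animals=40)
        table = oa.simulate_behavior(model, proto, seed=5)
        res = oa.intensity_ttest(table, "hex")
        assert res.t_statistic < 0
        assert res.p_value < 0.01


class TestEarlyLate:
    def test_power_grows_after_divergence(self):
        """Intensities share early probabilities and diverge late: the late
        test must reject more often across replicates."""
        proto = oa.StimulusProtocol(n_trials_per_block=10, odor_window_s=(0, 4),
                                    block_sequence=["hex_H", "hex_L"])
        # fast facilitation to distinct plateaus: early trials overlap at p0
        model = oa.BehaviorModel(p0=0.3, p_inf_high=0.9, p_inf_low=0.4,
                                 tau_trials=3, n_animals=40)
        early_p, late_p = [], []
        for seed in range(30):
            table = oa.simulate_behavior(model, proto, seed=seed)
            early, late = oa.early_late_comparison(table, "hex", split_trial=5)
            early_p.append(early.p_value)
            late_p.append(late.p_value)
        # stochastically smaller late p-values = more power after divergence
        assert np.mean(late_p) < np.mean(early_p)
        assert np.mean(np.asarray(late_p) < 0.05) >= np.mean(np.asarray(early_p) < 0.05)

    def test_split_beyond_block_rejected(self, protocol):
        model = oa.BehaviorModel(n_animals=5)
        table = oa.simulate_behavior(model, protocol, seed=0)
        with pytest.raises(UsageError):
            oa.early_late_comparison(table, "hex", split_trial=10)


class TestNeuralBehaviorRegression:
    def test_exact_negative_line(self):
        counts = np.array([100.0, 80, 60, 40, 20])
        p = 1.0 - 0.005 * counts
        fit = oa.neural_behavior_regression(counts, p)
        assert fit.slope == pytest.approx(-0.005)
        assert fit.r_squared == pytest.approx(1.0)

    def test_normal_equations_oracle(self):
        counts = np.array([120.0, 100.0, 90.0, 70.0, 50.0])
        p = np.array([0.2, 0.45, 0.5, 0.6, 0.8])
        x = np.column_stack([np.ones(5), counts])
        beta = np.linalg.solve(x.T @ x, x.T @ p)
        fit = oa.neural_behavior_regression(counts, p)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_slope_sign_invariant_to_count_rescaling(self):
        counts = np.array([120.0, 100.0, 90.0, 70.0, 50.0])
        p = np.array([0.2, 0.45, 0.5, 0.6, 0.8])
        s1 = oa.neural_behavior_regression(counts, p).slope
        s2 = oa.neural_behavior_regression(3.7 * counts + 11, p).slope
        assert np.sign(s1) == np.sign(s2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            oa.neural_behavior_regression(np.arange(4.0), np.arange(5.0) / 10)

    def test_joint_simulation_gives_negative_slope(self):
        proto = oa.StimulusProtocol(n_trials_per_block=25, odor_window_s=(0, 4),
                                    block_sequence=["hex_H"])
        neg = 0
        reps = 10
        for seed in range(reps):
            model = oa.make_population_model(odors=("hex",), protocol=proto,
                                             n_units=40, seed=seed)
            events = oa.simulate_session(model, proto, seed=seed)
            tensor = oa.bin_spikes(events, proto, unit_labels=model.unit_labels())
            counts = oa.ensemble_count_timecourse(tensor)
            bmodel = oa.BehaviorModel(n_animals=36, seed=seed)
            table = oa.simulate_behavior(bmodel, proto, seed=seed + 1000)
            p = oa.por_probability(table, "hex_H")
            if oa.neural_behavior_regression(counts, p).slope < 0:
                neg += 1
        assert neg == reps


class TestBonferroni:
    def test_adjusts_and_caps(self):
        adj = oa.bonferroni([0.01, 0.4], n_tests=4)
        assert np.allclose(adj, [0.04, 1.0])


class TestCatchPOR:
    def _catch_setup(self, p0_catch):
        proto = oa.StimulusProtocol(
            n_trials_per_block=15, odor_window_s=(0, 4), block_sequence=["bza_H"],
            catch_trial_index=9, catch_stimulus="iaa_H",
        )
        model = oa.BehaviorModel(p0=0.25, p_inf_high=0.85, tau_trials=2,
                                 n_animals=400, p0_catch=p0_catch)
        return proto, model

    def test_no_contrast_catch_has_no_drop(self):
        proto, model = self._catch_setup(p0_catch=None)
        table = oa.simulate_behavior(model, proto, seed=9)
        report = oa.catch_trial_por(table, proto)
        assert abs(report["catch_drop"]) < 0.08  # binomial noise only, n=400

    def test_catch_p_matches_unadapted_deviant_level(self):
        proto, model = self._catch_setup(p0_catch=0.25)
        table = oa.simulate_behavior(model, proto, seed=9)
        report = oa.catch_trial_por(table, proto)
        se = np.sqrt(0.25 * 0.75 / 400)
        assert abs(report["catch_p"] - 0.25) < 3 * se
        assert report["catch_drop"] < -0.3

    def test_large_contrast_drop_in_every_replicate(self):
        proto, model = self._catch_setup(p0_catch=0.1)
        drops = []
        for seed in range(10):
            table = oa.simulate_behavior(model, proto, seed=seed)
            drops.append(oa.catch_trial_por(table, proto)["catch_drop"])
        assert max(drops) < 0

    def test_requires_catch_protocol(self, protocol):
        model = oa.BehaviorModel(n_animals=5)
        table = oa.simulate_behavior(model, protocol, seed=0)
        with pytest.raises(UsageError):
            oa.catch_trial_por(table, protocol)
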