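"""Trajectories, trial correlations, clustering, classification, catch profiles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import adjusted_rand_score

import odoradapt as oa
from odoradapt.errors import UndefinedCorrelationError, UsageError
from odoradapt.geometry import TrialCorrelationMatrix


def brute_force_complete_linkage(d):
    """Oracle: agglomerate by exhaustively scanning all cluster pairs for the
    minimum complete-linkage (max pairwise) distance; ties by lowest index."""
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            h = max(d[a, b] for a in clusters[i] for b in clusters[j])
            if best is None or h < best[0] - 1e-12:
                best = (h, i, j)
        h, i, j = best
        merges.append((h, sorted(clusters[i] + clusters[j])))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merges[-1][1])
    return merges


def _tensor_from_vectors(vectors, stimuli=None):
    """Single-bin tensor whose per-trial population vectors are given rows."""
    vectors = np.asarray(vectors, dtype=float)
    n_trials, n_units = vectors.shape
    counts = vectors.T[:, None, :]
    return oa.TrialTensor(
        counts=counts,
        bin_edges_s=[0.0, 4.0],
        unit_labels=[f"u{i}" for i in range(n_units)],
        trial_labels=list(range(1, n_trials + 1)),
        stimulus_labels=stimuli or ["hex_H"] * n_trials,
    )


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = rng.random(30)
        assert oa.pearson_trial_correlation(x, x) == pytest.approx(1.0)

    @pytest.mark.parametrize("a", [2.5, -3.0])
    def test_affine_invariance(self, rng, a):
        x = rng.random(20)
        assert oa.pearson_trial_correlation(x, a * x + 1.7) == pytest.approx(np.sign(a))

    def test_hand_arithmetic_oracle(self):
        # direct covariance / (sigma_i sigma_j) arithmetic on printed vectors
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 5.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert oa.pearson_trial_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            oa.pearson_trial_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelationMatrix:
    def test_duplicated_trials_correlate_perfectly(self, rng):
        v = rng.integers(0, 20, 12).astype(float)
        t = _tensor_from_vectors([v, v, v + rng.integers(0, 3, 12)])
        m = oa.trial_correlation_matrix(t)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self, tensor):
        m = oa.trial_correlation_matrix(tensor)
        assert np.array_equal(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_reductions_agree(self, tensor):
        a = oa.trial_correlation_matrix(tensor, "sum_window").values
        b = oa.trial_correlation_matrix(tensor, "mean_per_bin").values
        assert np.allclose(a, b)

    def test_within_odor_exceeds_between_odor(self):
        proto = oa.StimulusProtocol(n_trials_per_block=8, odor_window_s=(0, 4),
                                    block_sequence=["hex_H", "oct_H"])
        model = oa.make_population_model(odors=("hex", "oct"), protocol=proto, seed=6)
        events = oa.simulate_session(model, proto, seed=6)
        t = oa.bin_spikes(events, proto, unit_labels=model.unit_labels())
        m = oa.trial_correlation_matrix(t).values
        n = 8
        within = np.concatenate([m[:n, :n][np.triu_indices(n, 1)],
                                 m[n:, n:][np.triu_indices(n, 1)]])
        between = m[:n, n:].ravel()
        assert within.mean() > between.mean() + 0.2

    def test_zero_variance_trial_identified(self):
        t = _tensor_from_vectors([[1, 2, 3], [5, 5, 5]])
        with pytest.raises(UndefinedCorrelationError, match="trial 2"):
            oa.trial_correlation_matrix(t)

    @given(st.integers(0, 10_000))
    def test_invariance_to_per_trial_positive_rescaling(self, seed):
        """Pearson depends only on vector direction: scaling any trial's
        vector by a positive constant leaves the matrix unchanged — the
        level at which amplitude adaptation provably cannot corrupt
        identity/intensity information."""
        r = np.random.default_rng(seed)
        vecs = r.random((5, 15)) * 10
        scales = r.uniform(0.1, 5.0, 5)
        a = oa.trial_correlation_matrix(_tensor_from_vectors(vecs)).values
        b = oa.trial_correlation_matrix(
            _tensor_from_vectors(vecs * scales[:, None])
        ).values
        assert np.allclose(a, b, atol=1e-12)


class TestDendrogram:
    def test_two_identical_groups(self):
        vecs = [[10, 0, 0, 1], [10, 0, 0, 1], [0, 10, 1, 0], [0, 10, 1, 0]]
        m = oa.trial_correlation_matrix(_tensor_from_vectors(vecs))
        tree = oa.cluster_dendrogram(m)
        heights = tree.linkage[:, 2]
        assert heights[0] == pytest.approx(0.0, abs=1e-12)
        assert heights[1] == pytest.approx(0.0, abs=1e-12)
        assert heights[2] > 1.0  # anticorrelated groups merge last

    def test_matches_brute_force_linkage_oracle(self):
        # hand-specified correlations among 4 trials
        r = np.array(
            [
                [1.0, 0.9, 0.2, 0.1],
                [0.9, 1.0, 0.3, 0.2],
                [0.2, 0.3, 1.0, 0.7],
                [0.1, 0.2, 0.7, 1.0],
            ]
        )
        m = TrialCorrelationMatrix(r, [1, 2, 3, 4], ["a"] * 4)
        tree = oa.cluster_dendrogram(m)
        oracle = brute_force_complete_linkage(1.0 - r)
        assert np.allclose(sorted(tree.linkage[:, 2]), sorted(h for h, _ in oracle))
        # the first two merges pair (0,1) and (2,3)
        assert set(map(int, tree.linkage[0, :2])) == {0, 1}
        assert set(map(int, tree.linkage[1, :2])) == {2, 3}

    def test_determinism(self, tensor):
        m = oa.trial_correlation_matrix(tensor)
        t1 = oa.cluster_dendrogram(m)
        t2 = oa.cluster_dendrogram(m)
        assert np.array_equal(t1.linkage, t2.linkage)
        assert t1.leaf_order() == t2.leaf_order()
        assert t1.to_newick() == t2.to_newick()

    def test_cuts_recover_odor_then_intensity(self):
        proto = oa.StimulusProtocol(n_trials_per_block=12, odor_window_s=(0, 4),
                                    block_sequence=["hex_H", "hex_L", "oct_H", "oct_L"])
        model = oa.make_population_model(odors=("hex", "oct"), protocol=proto, seed=14)
        events = oa.simulate_session(model, proto, seed=14)
        t = oa.bin_spikes(events, proto, unit_labels=model.unit_labels())
        tree = oa.cluster_dendrogram(oa.trial_correlation_matrix(t))
        odor = [s.split("_")[0] for s in t.stimulus_labels]
        assert adjusted_rand_score(odor, tree.cut(2)) == 1.0
        assert adjusted_rand_score(t.stimulus_labels, tree.cut(4)) == 1.0

    def test_newick_is_parseable(self, tensor):
        from io import StringIO

        from Bio import Phylo

        tree = oa.cluster_dendrogram(oa.trial_correlation_matrix(tensor))
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert parsed.count_terminals() == tensor.n_trials


class TestClassification:
    def test_perfectly_separated_classes(self):
        vecs = [[50, 0, 1, 0], [45, 1, 0, 0], [48, 0, 0, 1],
                [0, 50, 0, 1], [1, 47, 0, 0], [0, 52, 1, 0]]
        stims = ["hex_H"] * 3 + ["oct_H"] * 3
        rep = oa.classify_trials(_tensor_from_vectors(vecs, stims))
        assert rep.overall_accuracy == 1.0
        assert rep.confusion.loc["hex_H", "hex_H"] == 3

    def test_shuffled_labels_at_chance(self, rng):
        n_per, n_classes = 40, 2
        vecs = rng.poisson(10, (n_per * n_classes, 30)).astype(float)
        stims = list(rng.permutation(["a"] * n_per + ["b"] * n_per))
        rep = oa.classify_trials(_tensor_from_vectors(vecs, stims))
        chance = 1 / n_classes
        se = np.sqrt(chance * (1 - chance) / (n_per * n_classes))
        assert abs(rep.overall_accuracy - chance) < 3 * se

    def test_simulator_above_chance(self, tensor):
        rep = oa.classify_trials(tensor)
        assert rep.overall_accuracy > 0.5
        assert set(rep.per_class_accuracy) == {"hex_H", "hex_L"}

    def test_single_trial_class_rejected(self):
        t = _tensor_from_vectors([[1, 2], [2, 1], [3, 1]], ["a", "a", "b"])
        with pytest.raises(UsageError, match="single trial"):
            oa.classify_trials(t)


class TestCatchCorrelation:
    def test_reference_position_is_one(self, tensor):
        corr = oa.catch_trial_correlation(tensor, 0)
        assert corr[0] == pytest.approx(1.0)
        assert len(corr) == tensor.n_trials

    def test_direction_preservation_keeps_noncatch_high(self):
        proto = oa.default_catch_protocol(repeated="hex_H", catch="iaa_H")
        model = oa.make_population_model(odors=("hex",), protocol=proto,
                                         extra_stimuli=("iaa_H",), seed=23)
        events = oa.simulate_catch_session(model, proto, seed=23)
        t = oa.bin_spikes(events, proto, unit_labels=model.unit_labels())
        corr = oa.catch_trial_correlation(t, 0)
        catch_idx = proto.catch_trial_index - 1
        non_catch = np.delete(corr, catch_idx)
        assert non_catch.min() >= 0.8
        assert corr[catch_idx] < non_catch.min() - 0.3


class TestTrajectories:
    def _fit(self, tensor, f=3):
        return oa.cp_als(tensor, f, restarts=3, seed=0)

    def test_constant_activity_collapses_to_origin(self):
        counts = np.ones((6, 10, 4), dtype=int)
        t = oa.TrialTensor(counts, np.linspace(0, 0.5, 11), [f"u{i}" for i in range(6)],
                           [1, 2, 3, 4], ["hex_H"] * 4)
        model = self._fit(t, f=1)
        trajs = oa.trial_trajectories(model)
        for tr in trajs:
            assert np.allclose(tr.points, 0.0, atol=1e-8)

    def test_planar_data_has_vanishing_third_component(self, rng):
        # activity confined to a 2-D subspace of unit space
        basis = rng.random((2, 12))
        coords = rng.random((2, 10 * 6)) * 5
        series = (basis.T @ coords).reshape(12, 10, 6, order="F")
        counts = np.round(series * 10).astype(int)
        t = oa.TrialTensor(counts, np.linspace(0, 0.5, 11), [f"u{i}" for i in range(12)],
                           list(range(1, 7)), ["hex_H"] * 6)
        # the third factor mops up rounding noise; geometry stays planar
        model = oa.cp_als(t, 3, restarts=3, seed=0)
        trajs = oa.trial_trajectories(model, smooth_points=1)
        assert trajs[0].explained_variance[2] < 0.01
        assert np.abs(np.asarray([tr.points[:, 2] for tr in trajs])).max() < (
            0.05 * np.abs(trajs[0].points[:, 0]).max()
        )

    def test_projection_contracts_distances(self, tensor):
        model = self._fit(tensor)
        trajs = oa.trial_trajectories(model, smooth_points=1)
        xhat = oa.reconstruct_tensor(model)
        series = np.moveaxis(xhat, 2, 1).reshape(tensor.n_units, -1)
        centered = series - series.mean(axis=1, keepdims=True)
        pts = np.vstack([tr.points for tr in trajs])
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = rng.integers(0, pts.shape[0], 2)
            d_low = np.linalg.norm(pts[i] - pts[j])
            d_full = np.linalg.norm(centered[:, i] - centered[:, j])
            assert d_low <= d_full + 1e-9

    def test_adaptation_shrinks_but_does_not_rotate_trajectories(self):
        proto = oa.StimulusProtocol(n_trials_per_block=25, odor_window_s=(0, 4),
                                    block_sequence=["hex_H"])
        model = oa.make_population_model(odors=("hex",), protocol=proto, n_units=80, seed=4)
        events = oa.simulate_session(model, proto, seed=4)
        t = oa.bin_spikes(events, proto, unit_labels=model.unit_labels())
        cp = oa.cp_als(t, 3, restarts=3, seed=0)
        trajs = oa.trial_trajectories(cp)
        first, last = trajs[0], trajs[-1]
        # loop size scales with the adaptation multiplier ...
        m25 = 0.4 + 0.6 * np.exp(-24 / 5)
        assert last.diameter() / first.diameter() == pytest.approx(m25, rel=0.15)
        # ... while the raw-space direction of the trial mean is preserved
        m1 = first.mean_point(centered=False)
        mlast = last.mean_point(centered=False)
        cos = m1 @ mlast / (np.linalg.norm(m1) * np.linalg.norm(mlast))
        assert cos >= 0.95

    def test_smoothing_window_shrinks_at_edges(self):
        pts = np.arange(15, dtype=float).reshape(5, 3)
        from odoradapt.geometry import _running_average

        sm = _running_average(pts, 3)
        assert np.allclose(sm[0], pts[:2].mean(axis=0))   # 2-point edge window
        assert np.allclose(sm[2], pts[1:4].mean(axis=0))  # full 3-point interior
        assert np.allclose(sm[-1], pts[-2:].mean(axis=0))
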