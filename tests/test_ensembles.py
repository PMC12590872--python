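"""Ensemble vectors, shuffle-normalized similarity, fate, bias, separability."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from locopop.ensembles import (action_bias, activation_matrix,
                               activation_vector, bout_activation_proportions,
                               ensemble_similarity, fate_overlap,
                               separability_matrix, separability_score,
                               similarity_by_day)

from oracles import exact_shuffle_jaccard_mean, exact_shuffle_jaccard_sd

RATE = 25.0


class TestActivationVector:
    def test_subthreshold_population_all_zero(self, rng):
        dff = rng.uniform(-2, 2, (5, 1000))
        assert activation_vector(dff, 500, RATE).sum() == 0

    def test_suprathreshold_peak_at_event(self):
        dff = np.zeros((3, 1000))
        dff[1, 505] = 5.0
        vec = activation_vector(dff, 500, RATE)
        assert list(vec) == [0, 1, 0]

    def test_edge_event_rejected_and_dropped(self):
        dff = np.zeros((2, 100))
        with pytest.raises(ValueError, match="edge"):
            activation_vector(dff, 10, RATE)
        mat, kept = activation_matrix(dff, np.array([10, 50]), RATE)
        assert mat.shape == (1, 2)
        assert list(kept) == [50]


class TestBoutActivationProportions:
    def test_fully_active_population(self):
        dff = np.zeros((4, 6000))
        events = np.arange(8) * 600 + 400
        for e in events:
            dff[:, e] = 5.0
        curve = bout_activation_proportions(dff, events, RATE)
        assert np.allclose(curve, 1.0)

    def test_dropout_after_third_bout(self):
        # half the population is active only on bouts 1-3: the curve steps
        # from 1.0 down to 0.5, exactly, in noise-free data
        dff = np.zeros((4, 6000))
        events = np.arange(8) * 600 + 400
        for e in events:
            dff[:2, e] = 5.0
        for e in events[:3]:
            dff[2:, e] = 5.0
        curve = bout_activation_proportions(dff, events, RATE)
        assert np.allclose(curve, [1, 1, 1, 0.5, 0.5, 0.5, 0.5, 0.5])

    def test_silent_population_zero_curve(self):
        dff = np.zeros((4, 6000))
        events = np.arange(8) * 600 + 400
        assert np.allclose(bout_activation_proportions(dff, events, RATE), 0.0)

    def test_truncated_session_warns(self):
        dff = np.zeros((2, 3000))
        with pytest.warns(UserWarning, match="requested bouts"):
            curve = bout_activation_proportions(dff, np.array([500, 1500]), RATE)
        assert len(curve) == 2


class TestEnsembleSimilarity:
    def test_identical_vectors_raw_one(self):
        v = np.array([1, 0, 1, 1, 0, 0])
        r = ensemble_similarity(v, v, 200, 0)
        assert r.raw == 1.0
        assert r.normalized > 1.0

    def test_disjoint_vectors_zero(self):
        r = ensemble_similarity(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1]),
                                200, 0)
        assert r.raw == 0.0
        assert r.normalized == 0.0

    def test_four_neuron_worked_example(self):
        # raw = 1/3; exact shuffle expectation over the hypergeometric
        # overlap is 7/18, so the normalized index is ~6/7
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        r = ensemble_similarity(a, b, 1000, 3)
        assert r.raw == pytest.approx(1 / 3)
        exact = exact_shuffle_jaccard_mean(4, 2, 2)
        assert exact == pytest.approx(7 / 18)
        se = exact_shuffle_jaccard_sd(4, 2, 2) / np.sqrt(1000)
        assert abs(r.shuffle_mean - exact) < 3 * se
        assert r.normalized == pytest.approx((1 / 3) / exact, rel=0.05)

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ensemble_similarity(np.zeros(5), np.zeros(5), 10, 0)

    def test_one_empty_vector_undefined_normalization(self):
        r = ensemble_similarity(np.array([1, 0, 0]), np.zeros(3), 100, 0)
        assert r.raw == 0.0
        assert np.isnan(r.normalized)

    @given(st.integers(2, 10), st.data())
    def test_shuffle_mean_matches_hypergeometric_oracle(self, n, data):
        na = data.draw(st.integers(1, n))
        nb = data.draw(st.integers(1, n))
        a = np.zeros(n, int)
        a[:na] = 1
        b = np.zeros(n, int)
        b[n - nb:] = 1
        r = ensemble_similarity(a, b, 1000, 0)
        exact = exact_shuffle_jaccard_mean(n, na, nb)
        se = exact_shuffle_jaccard_sd(n, na, nb) / np.sqrt(1000)
        assert abs(r.shuffle_mean - exact) <= max(3 * se, 1e-12)


class TestSimilarityByDay:
    def test_repeated_deterministic_ensemble_uniform_and_maximal(self):
        mat = np.tile(np.array([1, 1, 0, 0, 1, 0, 0, 0], np.int8), (4, 1))
        res = similarity_by_day({1: mat, 2: mat}, "within_day", 400, 0)
        assert set(res) == {1, 2}
        vals = np.array(list(res.values()))
        # identical bouts: raw 1 for all pairs; normalization is the only
        # source of spread
        assert np.all(vals > 1.0)
        assert np.ptp(vals) < 0.2
        across = similarity_by_day({1: mat, 2: mat}, "across_adjacent_days",
                                   400, 0)
        assert list(across) == [(1, 2)]

    def test_independent_random_ensembles_near_chance(self, rng):
        mats = {d: (rng.random((6, 40)) < 0.3).astype(np.int8)
                for d in (1, 2, 3)}
        res = similarity_by_day(mats, "within_day", 500, rng)
        assert np.mean(list(res.values())) == pytest.approx(1.0, abs=0.35)

    def test_insufficient_bouts_skipped(self):
        mats = {1: np.ones((1, 5), np.int8), 2: np.ones((3, 5), np.int8)}
        res = similarity_by_day(mats, "within_day", 100, 0)
        assert 1 not in res and 2 in res


class TestFateOverlap:
    def test_worked_overlap_example(self):
        # late set {0,1,2,3}, early set {0,1,4}: two of four late neurons
        # were active early -> 50%
        n = 8
        late = np.zeros((2, n), bool)
        late[:, [0, 1, 2, 3]] = True
        early = np.zeros((2, n), bool)
        early[:, [0, 1, 4]] = True
        r = fate_overlap(early, late, 400, 0)
        assert r.observed_pct == pytest.approx(50.0)
        assert r.n_late == 4

    def test_late_subset_of_early_full_overlap(self):
        n = 10
        late = np.zeros((2, n), bool)
        late[:, [2, 3]] = True
        early = np.zeros((2, n), bool)
        early[:, [1, 2, 3, 4]] = True
        assert fate_overlap(early, late, 200, 0).observed_pct == 100.0

    def test_active_requires_both_days(self):
        n = 6
        late = np.zeros((2, n), bool)
        late[0, [0, 1]] = True  # only one day: no late neuron
        late[1, [1, 2]] = True  # neuron 1 active both days
        early = np.ones((2, n), bool)
        r = fate_overlap(early, late, 100, 0)
        assert r.n_late == 1

    def test_independent_vectors_match_shuffle_null(self, rng):
        n = 200
        early = rng.random((2, n)) < 0.4
        late = rng.random((2, n)) < 0.4
        r = fate_overlap(early, late, 1000, rng)
        # observed is itself a draw from the null here
        assert abs(r.observed_pct - r.shuffle_mean_pct) < 20.0
        assert 0.0 <= r.p_value <= 1.0

    def test_relabeling_invariance(self, rng):
        n = 30
        early = rng.random((2, n)) < 0.5
        late = rng.random((2, n)) < 0.5
        perm = rng.permutation(n)
        r1 = fate_overlap(early, late, 10, 0)
        r2 = fate_overlap(early[:, perm], late[:, perm], 10, 0)
        assert r1.observed_pct == pytest.approx(r2.observed_pct)

    def test_empty_late_set_rejected(self):
        with pytest.raises(ValueError, match="late"):
            fate_overlap(np.ones((2, 4), bool), np.zeros((2, 4), bool), 10, 0)


class TestActionBias:
    def test_worked_example_quarter(self):
        # two onset-only, one offset-only, one both: (1+1-1+0)/4 = 0.25
        on = np.array([1, 1, 0, 1], bool)
        off = np.array([0, 0, 1, 1], bool)
        assert action_bias(np.arange(4), on, off) == pytest.approx(0.25)

    def test_pure_onset_ensemble(self):
        on = np.ones(5, bool)
        off = np.zeros(5, bool)
        assert action_bias(np.arange(5), on, off) == 1.0

    def test_balanced_ensemble_zero(self):
        on = np.array([1, 1, 0, 0], bool)
        off = np.array([0, 0, 1, 1], bool)
        assert action_bias(np.arange(4), on, off) == 0.0

    def test_antisymmetric_under_role_swap(self, rng):
        on = rng.random(20) < 0.5
        off = rng.random(20) < 0.5
        members = np.flatnonzero(on | off)
        assert action_bias(members, on, off) == pytest.approx(
            -action_bias(members, off, on))

    def test_inactive_members_omitted_and_all_inactive_rejected(self):
        on = np.array([1, 0, 0], bool)
        off = np.zeros(3, bool)
        assert action_bias(np.arange(3), on, off) == 1.0  # 2 omitted
        with pytest.raises(ValueError, match="inactive"):
            action_bias(np.array([1, 2]), on, off)


class TestSeparability:
    def test_matrix_layout(self, rng):
        dff = rng.standard_normal((3, 4000))
        mat, labs = separability_matrix(dff, np.array([500, 1500]),
                                        np.array([2500, 3500]), RATE)
        assert mat.shape == (4, 3 * 101)
        assert list(labs) == ["onset", "onset", "offset", "offset"]

    def test_separated_clusters_high_silhouette(self, rng):
        # two point-clouds 10x their spread apart stay separable through
        # PCA + t-SNE for any reasonable embedding seed
        a = rng.standard_normal((8, 40)) * 0.1
        b = rng.standard_normal((8, 40)) * 0.1 + 1.0
        mat = np.vstack([a, b])
        labs = np.array(["onset"] * 8 + ["offset"] * 8, object)
        for seed in (0, 1):
            assert separability_score(mat, labs, tsne_seed=seed) > 0.9

    def test_shuffled_labels_near_zero(self, rng):
        mat = rng.standard_normal((20, 40))
        labs = np.array(["onset", "offset"] * 10, object)
        scores = [separability_score(mat, labs, tsne_seed=s) for s in (0, 1, 2)]
        assert abs(np.mean(scores)) < 0.25

    def test_single_label_rejected(self, rng):
        mat = rng.standard_normal((6, 10))
        labs = np.array(["onset"] * 6, object)
        with pytest.raises(ValueError, match="label"):
            separability_score(mat, labs)
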