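"""NMF fitting, VAF/MSE order criterion, pattern matching, fixed-W NNLS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from stsforecast import synergy
from stsforecast.preprocess import ActivationMatrix
from stsforecast.synthgen import SynthConfig

from conftest import aggregated_activation


class TestVafMse:
    def test_vaf_examples(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert synergy.vaf(A, A, np.eye(2)) == pytest.approx(100.0)
        assert synergy.vaf(A, np.zeros((2, 2)), np.zeros((2, 2))) == pytest.approx(0.0)
        WH = np.array([[1.0, 2.0], [3.0, 0.0]])
        # residual energy 16, signal energy 30
        assert synergy.vaf(A, WH, np.eye(2)) == pytest.approx(100 * (1 - 16 / 30))
        with pytest.raises(ValueError):
            synergy.vaf(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))

    def test_mse_examples(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert synergy.mse(A, A, np.eye(2)) == 0.0
        r = 0.2
        assert synergy.mse(A, A + r, np.eye(2)) == pytest.approx(r * r)
        WH = A - np.array([[0.0, 0.0], [0.1, 0.3]])
        assert synergy.mse(A, WH, np.eye(2)) == pytest.approx(0.025)
        with pytest.raises(ValueError):
            synergy.mse(np.empty((0, 0)), np.empty((0, 0)), np.empty((0, 0)))


class TestFitNmf:
    def test_rank_one_exact(self):
        rng = np.random.default_rng(0)
        A = np.outer(rng.uniform(0.1, 1, 6), rng.uniform(0.1, 1, 200))
        m = synergy.fit_nmf(A, 1, restarts=3, seed=0)
        assert m.vaf_percent >= 99.9
        assert np.all(m.W >= 0) and np.all(m.H >= 0)
        assert m.W.max(axis=0) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(0, 1, (5, 80))
        m1 = synergy.fit_nmf(A, 2, restarts=4, seed=9)
        m2 = synergy.fit_nmf(A, 2, restarts=4, seed=9)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.H, m2.H)

    def test_input_validation(self):
        A = np.ones((3, 10))
        with pytest.raises(ValueError):
            synergy.fit_nmf(A, 0)
        with pytest.raises(ValueError):
            synergy.fit_nmf(A, 4)
        with pytest.raises(ValueError):
            synergy.fit_nmf(-A, 1)

    def test_matches_reference_solver_quality(self):
        """Independent NMF (sklearn coordinate descent) as residual oracle."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(3)
        A = rng.uniform(0.1, 1, (6, 40)) @ np.eye(40)
        ours = synergy.fit_nmf(A, 3, restarts=8, seed=1)
        ref = sklearn.NMF(3, init="nndsvda", solver="cd", max_iter=3000, tol=1e-10)
        Wr = ref.fit_transform(A)
        ref_mse = float(np.mean((A - Wr @ ref.components_) ** 2))
        assert ours.mse <= ref_mse * 1.1 + 1e-12


class TestConcat:
    def test_concat_and_split_are_inverse(self):
        rng = np.random.default_rng(0)
        a = ActivationMatrix(rng.uniform(0, 1, (4, 100)), 100.0, ("a", "b", "c", "d"))
        b = ActivationMatrix(rng.uniform(0, 1, (4, 50)), 100.0, ("a", "b", "c", "d"))
        cat = synergy.concat_trials([a, b])
        assert cat.n_samples == 150
        assert cat.trial_boundaries == (100,)
        pa, pb = synergy.split_trials(cat)
        np.testing.assert_array_equal(pa, a.values)
        np.testing.assert_array_equal(pb, b.values)
        assert synergy.concat_trials([a]).n_samples == 100

    def test_mismatched_muscles_raise(self):
        a = ActivationMatrix(np.ones((2, 10)), 100.0, ("a", "b"))
        b = ActivationMatrix(np.ones((2, 10)), 100.0, ("a", "c"))
        with pytest.raises(ValueError):
            synergy.concat_trials([a, b])


class TestSelectOrder:
    def test_rank_one_selects_one(self):
        rng = np.random.default_rng(1)
        A = np.outer(rng.uniform(0.1, 1, 5), rng.uniform(0.1, 1, 300))
        sel = synergy.select_order(A / A.max(), restarts=3, seed=0)
        assert sel.n == 1 and sel.satisfied

    def test_order_monotone_in_noise(self):
        """More envelope noise never lowers the selected model order."""
        from stsforecast.synthgen import generate_trial
        from stsforecast.preprocess import downsample_pool, normalize_per_muscle

        orders = []
        for sigma in (0.001, 0.01):
            ns = []
            for seed in range(3):
                cfg = SynthConfig(
                    cycles_per_strategy=2, rng_seed=seed, envelope_noise_sigma=sigma
                )
                tr = generate_trial(cfg, "momentum")
                env = downsample_pool(tr.true_envelopes, tr.fs, 100.0)
                vals, _ = normalize_per_muscle(env)
                ns.append(synergy.select_order(vals, restarts=5, seed=seed).n)
            orders.append(ns)
        for low, high in zip(*orders):
            assert high >= low


class TestCosineAndMatching:
    def test_cosine_examples(self):
        assert synergy.cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert synergy.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert synergy.cosine_similarity([1, 0, 1], [1, 1, 0]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            synergy.cosine_similarity([0, 0], [1, 0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        arrays(float, 5, elements=st.floats(0.01, 1.0)),
        arrays(float, 5, elements=st.floats(0.01, 1.0)),
    )
    def test_cosine_symmetric_unit_range(self, u, v):
        s1 = synergy.cosine_similarity(u, v)
        assert s1 == pytest.approx(synergy.cosine_similarity(v, u))
        assert 0.0 <= s1 <= 1.0 + 1e-12

    def test_match_recovers_permutation(self):
        rng = np.random.default_rng(4)
        W = rng.uniform(0, 1, (6, 4))
        perm = [2, 0, 3, 1]
        match = synergy.match_synergies(W, W[:, perm])
        assert [j for _, j, _ in match.pairs] == [perm.index(i) for i in range(4)]
        assert all(s == pytest.approx(1.0) for _, _, s in match.pairs)

    def test_optimal_beats_greedy_on_crafted_case(self):
        # column 0 of A matches both B0 (0.99) and B1 (0.98); greedy takes
        # B0 first and forces a bad pairing downstream
        Wa = np.array([[1.0, 0.9, 0.0], [0.1, 0.6, 0.1], [0.0, 0.0, 1.0]])
        Wb = np.array([[0.95, 1.0, 0.0], [0.3, 0.05, 0.0], [0.05, 0.0, 1.0]])
        match = synergy.match_synergies(Wa, Wb)
        S = match.similarity_matrix
        # brute force over all 6 assignments is the oracle
        from itertools import permutations

        best = max(sum(S[i, p[i]] for i in range(3)) for p in permutations(range(3)))
        assert match.total == pytest.approx(best)
        # greedy best-first choice
        greedy, used = 0.0, set()
        for i in np.argsort(-S.max(axis=1)):
            j = max((j for j in range(3) if j not in used), key=lambda j: S[i, j])
            used.add(j)
            greedy += S[i, j]
        assert match.total >= greedy

    def test_mismatched_muscle_dim_raises(self):
        with pytest.raises(ValueError):
            synergy.match_synergies(np.ones((4, 2)), np.ones((5, 2)))


class TestEstimateTemporal:
    def test_exact_recovery_on_consistent_system(self):
        rng = np.random.default_rng(5)
        W = rng.uniform(0, 1, (8, 4))
        H = rng.uniform(0, 1, (4, 60))
        Hhat = synergy.estimate_temporal(W @ H, W)
        np.testing.assert_allclose(Hhat, H, atol=1e-8)

    def test_zero_activation_gives_zero(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        np.testing.assert_array_equal(
            synergy.estimate_temporal(np.zeros((3, 5)), W), np.zeros((2, 5))
        )

    def test_single_frame_overdetermined_solution(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        h = synergy.estimate_temporal(np.array([[1.0], [2.0], [3.0]]), W)
        np.testing.assert_allclose(h[:, 0], [1.0, 2.0], atol=1e-12)

    def test_rank_deficient_w_raises(self):
        W = np.ones((4, 2))
        with pytest.raises(ValueError):
            synergy.estimate_temporal(np.ones((4, 3)), W)

    def test_nonnegativity_under_model_mismatch(self):
        rng = np.random.default_rng(6)
        W = rng.uniform(0, 1, (6, 3))
        A = rng.standard_normal((6, 30))  # even signed data yields H >= 0
        assert np.all(synergy.estimate_temporal(np.abs(A), W) >= 0)


def test_spatial_recovery_small_corpus(small_corpus):
    """NMF at the true order recovers the generator's spatial patterns."""
    vals, scale, cfg = aggregated_activation(small_corpus)
    Wt = cfg.true_spatial / scale[:, None]
    Wt = Wt / Wt.max(axis=0)
    m = synergy.fit_nmf(vals, 4, restarts=8, seed=0)
    match = synergy.match_synergies(Wt, m.W)
    assert all(s >= 0.95 for _, _, s in match.pairs)


def test_vaf_nondecreasing_in_order(small_corpus):
    """Best-of-restarts VAF should not drop as the order grows (0.5 pp slack)."""
    vals, _, _ = aggregated_activation(small_corpus)
    vafs = [
        synergy.fit_nmf(vals, n, restarts=5, seed=0).vaf_percent for n in (1, 2, 3, 4, 5)
    ]
    for a, b in zip(vafs, vafs[1:]):
        assert b >= a - 0.5
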