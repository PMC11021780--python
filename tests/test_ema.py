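import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cascadeseg import Tensor
from cascadeseg.ema import (BasisSet, EmaConfig, EMAttention3d, e_step,
                            em_iterate, init_bases, init_bases_from_data,
                            m_step, reconstruct, update_global_bases)


def brute_force_m_step(x_flat, attention, epsilon=1e-6):
    """Independent per-basis weighted-mean loop (the oracle)."""
    d, n = x_flat.shape
    k = attention.shape[1]
    mu = np.zeros((d, k))
    for kk in range(k):
        num = np.zeros(d)
        den = 0.0
        for nn in range(n):
            num += attention[nn, kk] * x_flat[:, nn]
            den += attention[nn, kk]
        mu[:, kk] = num / (den + epsilon)
    norms = np.linalg.norm(mu, axis=0, keepdims=True)
    return mu / np.maximum(norms, 1e-12)


def make_clusters(rng, d=16, k=4, per=16, scale=16.0):
    """Noise-free mixture: k orthogonal centers of norm `scale`, repeated."""
    q, _ = np.linalg.qr(rng.normal(size=(d, k)))
    centers = (q * scale).T
    x = np.repeat(centers, per, axis=0).T.astype(np.float32)
    labels = np.repeat(np.arange(k), per)
    return x, labels


class TestESteps:
    def test_singleton_basis_gives_all_ones(self, rng):
        x = rng.normal(size=(4, 10)).astype(np.float32)
        basis = init_bases(4, 1, rng)
        a = e_step(x, basis)
        np.testing.assert_allclose(a, 1.0)

    def test_hand_computed_softmax_row(self):
        x = np.array([[1.0], [0.0]], dtype=np.float32)
        basis = BasisSet(mu=np.array([[1.0, 0.0], [0.0, 1.0]], dtype=np.float32))
        a = e_step(x, basis)
        np.testing.assert_allclose(a[0], [0.731059, 0.268941], atol=1e-5)

    def test_rows_sum_to_one(self, rng):
        x = rng.normal(size=(8, 50)).astype(np.float32)
        a = e_step(x, init_bases(8, 6, rng))
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(a >= 0)

    def test_shift_invariance_via_scaled_bases(self, rng):
        # adding a constant to every inner product of a row leaves it unchanged
        x = rng.normal(size=(4, 12)).astype(np.float32)
        basis = init_bases(4, 3, rng)
        logits = x.T @ basis.mu
        shifted = logits + 5.0
        a = np.exp(shifted - shifted.max(axis=1, keepdims=True))
        a /= a.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(a, e_step(x, basis), atol=1e-5)

    def test_nonfinite_input_rejected(self, rng):
        x = np.full((4, 3), np.nan, dtype=np.float32)
        with pytest.raises(FloatingPointError):
            e_step(x, init_bases(4, 2, rng))


class TestMStep:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            d, n, k = rng.integers(2, 17, size=3)
            x = rng.normal(size=(d, n)).astype(np.float32)
            a = rng.uniform(size=(n, k)).astype(np.float32)
            a /= a.sum(axis=1, keepdims=True)
            got = m_step(x, a).mu
            want = brute_force_m_step(x, a)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_one_hot_attention_gives_cluster_means(self, rng):
        x = rng.normal(size=(5, 8)).astype(np.float32)
        assign = np.array([0, 0, 1, 1, 1, 0, 1, 0])
        a = np.eye(2, dtype=np.float32)[assign]
        mu = m_step(x, a).mu
        for k in range(2):
            mean = x[:, assign == k].mean(axis=1)
            np.testing.assert_allclose(mu[:, k], mean / np.linalg.norm(mean),
                                       atol=1e-5)

    def test_uniform_attention_collapses_to_global_mean(self, rng):
        x = rng.normal(size=(6, 20)).astype(np.float32)
        a = np.full((20, 2), 0.5, dtype=np.float32)
        mu = m_step(x, a).mu
        g = x.mean(axis=1)
        g /= np.linalg.norm(g)
        np.testing.assert_allclose(mu[:, 0], g, atol=1e-4)
        np.testing.assert_allclose(mu[:, 1], g, atol=1e-4)

    def test_columns_unit_norm(self, rng):
        x = rng.normal(size=(7, 30)).astype(np.float32)
        a = e_step(x, init_bases(7, 4, rng))
        mu = m_step(x, a).mu
        np.testing.assert_allclose(np.linalg.norm(mu, axis=0), 1.0, atol=1e-5)

    def test_dead_basis_keeps_previous_value(self, rng):
        x = rng.normal(size=(4, 6)).astype(np.float32)
        prev = init_bases(4, 2, rng)
        a = np.zeros((6, 2), dtype=np.float32)
        a[:, 0] = 1.0   # basis 1 receives nothing
        mu = m_step(x, a, prev=prev).mu
        np.testing.assert_allclose(mu[:, 1], prev.mu[:, 1], atol=1e-6)


class TestEmIterate:
    def test_t1_equals_manual_composition(self, rng):
        x = rng.normal(size=(6, 24)).astype(np.float32)
        basis0 = init_bases(6, 3, rng)
        basis, a = em_iterate(x, basis0, t=1)
        a_manual = e_step(x, basis0)
        basis_manual = m_step(x, a_manual, prev=basis0)
        np.testing.assert_allclose(basis.mu, basis_manual.mu, atol=1e-6)
        np.testing.assert_allclose(a, a_manual, atol=1e-6)

    def test_deterministic(self, rng):
        x = rng.normal(size=(6, 24)).astype(np.float32)
        basis0 = init_bases(6, 3, rng)
        b1, a1 = em_iterate(x, basis0, t=3)
        b2, a2 = em_iterate(x, basis0, t=3)
        assert np.array_equal(b1.mu, b2.mu) and np.array_equal(a1, a2)

    def test_cluster_recovery_with_spread_init(self):
        x, labels = make_clusters(np.random.default_rng(0))
        basis0 = init_bases_from_data(x, 4, np.random.default_rng(1))
        basis, _ = em_iterate(x, basis0, t=3)
        a = e_step(x, basis)
        for k in range(4):
            mass = a[labels == k].sum(axis=0)
            assert mass.max() / mass.sum() >= 0.95

    def test_reconstruction_error_non_increasing(self):
        x, _ = make_clusters(np.random.default_rng(2))
        basis = init_bases_from_data(x, 4, np.random.default_rng(3))
        errs = []
        for _ in range(3):
            a = e_step(x, basis)
            basis = m_step(x, a, prev=basis)
            recon = reconstruct(basis, e_step(x, basis))
            errs.append(float(((x - recon) ** 2).sum()))
        for e0, e1 in zip(errs, errs[1:]):
            assert e1 <= e0 * (1 + 1e-5) + 1e-6

    def test_rejects_zero_iterations(self, rng):
        x = rng.normal(size=(4, 4)).astype(np.float32)
        with pytest.raises(ValueError):
            em_iterate(x, init_bases(4, 2, rng), t=0)


class TestReconstruct:
    def test_single_basis_broadcasts(self):
        basis = BasisSet(mu=np.array([[1.0], [0.0]], dtype=np.float32))
        a = np.ones((5, 1), dtype=np.float32)
        recon = reconstruct(basis, a)
        np.testing.assert_allclose(recon, [[1.0] * 5, [0.0] * 5])

    def test_rank_bounded_by_n_bases(self, rng):
        x = rng.normal(size=(12, 64)).astype(np.float32)
        basis, a = em_iterate(x, init_bases(12, 4, rng), t=3)
        recon = reconstruct(basis, a)
        s = np.linalg.svd(recon, compute_uv=False)
        assert np.all(s[4:] < 1e-5)

    def test_recon_lies_in_basis_span(self, rng):
        x = rng.normal(size=(8, 40)).astype(np.float32)
        basis, a = em_iterate(x, init_bases(8, 3, rng), t=2)
        recon = reconstruct(basis, a)
        proj = basis.mu @ np.linalg.lstsq(basis.mu, recon, rcond=None)[0]
        assert np.abs(recon - proj).max() < 1e-5

    def test_one_hot_attention_copies_bases(self, rng):
        basis = init_bases(6, 3, rng)
        assign = np.array([0, 2, 1, 1])
        a = np.eye(3, dtype=np.float32)[assign]
        recon = reconstruct(basis, a)
        for n, k in enumerate(assign):
            np.testing.assert_allclose(recon[:, n], basis.mu[:, k], atol=1e-6)


class TestGlobalBases:
    def test_momentum_one_keeps_state(self, rng):
        state, conv = init_bases(5, 3, rng), init_bases(5, 3, rng)
        out = update_global_bases(state, conv, momentum=1.0)
        np.testing.assert_allclose(out.mu, state.mu, atol=1e-6)

    def test_momentum_zero_replaces_state(self, rng):
        state, conv = init_bases(5, 3, rng), init_bases(5, 3, rng)
        out = update_global_bases(state, conv, momentum=0.0)
        np.testing.assert_allclose(out.mu, conv.mu, atol=1e-6)

    def test_output_columns_unit_norm(self, rng):
        for _ in range(5):
            state, conv = init_bases(6, 4, rng), init_bases(6, 4, rng)
            out = update_global_bases(state, conv, momentum=rng.uniform())
            np.testing.assert_allclose(np.linalg.norm(out.mu, axis=0), 1.0,
                                       atol=1e-5)


class TestEmaForward:
    @given(st.sampled_from([8, 16]), st.sampled_from([2, 4]), st.integers(0, 100))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_shape_preserved(self, channels, side, seed):
        rng = np.random.default_rng(seed)
        module = EMAttention3d(EmaConfig(channels=channels, n_bases=4), rng)
        x = rng.normal(size=(channels, side, side, side)).astype(np.float32)
        out = module.forward(Tensor(x))
        assert out.data.shape == x.shape

    def test_zeroed_convs_give_residual_identity(self, rng):
        module = EMAttention3d(EmaConfig(channels=8, n_bases=4), rng)
        module.w_in.data[:] = 0
        module.w_out.data[:] = 0
        x = rng.normal(size=(8, 4, 4, 4)).astype(np.float32)
        out = module.forward(Tensor(x))
        np.testing.assert_array_equal(out.data, x)

    def test_inference_is_deterministic_and_state_preserving(self, rng):
        module = EMAttention3d(EmaConfig(channels=8, n_bases=4), rng)
        x = rng.normal(size=(8, 4, 4, 4)).astype(np.float32)
        mu_before = module.global_bases.mu.copy()
        a = module.forward(Tensor(x), training=False)
        b = module.forward(Tensor(x), training=False)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(module.global_bases.mu, mu_before)

    def test_training_updates_global_bases(self, rng):
        module = EMAttention3d(EmaConfig(channels=8, n_bases=4), rng)
        x = rng.normal(size=(8, 4, 4, 4)).astype(np.float32)
        mu_before = module.global_bases.mu.copy()
        module.forward(Tensor(x), training=True)
        assert not np.array_equal(module.global_bases.mu, mu_before)

    def test_channel_mismatch_rejected(self, rng):
        module = EMAttention3d(EmaConfig(channels=8, n_bases=4), rng)
        with pytest.raises(ValueError, match="channels"):
            module.forward(Tensor(np.zeros((4, 4, 4, 4), dtype=np.float32)))
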