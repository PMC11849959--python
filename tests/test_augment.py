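import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylomix import (
    AugmentConfig,
    LabeledDataset,
    draw_mixing_weight,
    phylomix_augment,
    phylomix_pair,
    random_binary_tree,
    sample_exchange_set,
    vanilla_mixup,
)


def toy_dataset(tree, n, seed, mode="count"):
    rng = np.random.default_rng(seed)
    X = rng.integers(1, 60, size=(n, tree.n_leaves)).astype(float)
    if mode == "relative":
        X = X / X.sum(axis=1, keepdims=True)
    y = (np.arange(n) % 2).astype(float)
    return LabeledDataset(X=X, y=y, taxa=tree.taxa, mode=mode)


class TestMixingWeight:
    def test_beta22_mean(self, rng):
        draws = np.array([draw_mixing_weight(2.0, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(0.5, abs=0.01)

    def test_beta22_variance_oracle(self, rng):
        # Beta(a,a) variance = 1 / (8a + 4)
        draws = np.array([draw_mixing_weight(2.0, rng) for _ in range(100_000)])
        assert draws.var() == pytest.approx(1.0 / 20.0, abs=0.005)

    def test_beta_half_u_shaped(self, rng):
        draws = np.array([draw_mixing_weight(0.5, rng) for _ in range(20_000)])
        edges = ((draws < 0.1) | (draws > 0.9)).mean()
        middle = ((draws > 0.45) & (draws < 0.55)).mean()
        assert edges > middle

    def test_invalid_alpha(self, rng):
        with pytest.raises(ValueError):
            draw_mixing_weight(0.0, rng)


class TestExchangeSet:
    def test_lambda_one_empty(self, rng):
        tree = random_binary_tree(16, seed=0)
        assert sample_exchange_set(tree, 1.0, rng) == set()

    def test_lambda_zero_full(self, rng):
        tree = random_binary_tree(16, seed=0)
        assert sample_exchange_set(tree, 0.0, rng) == set(range(1, 16))

    def test_stopping_rule_monte_carlo(self, rng):
        tree = random_binary_tree(64, seed=1)
        target = math.ceil(0.5 * 63)  # 32
        sizes = []
        for _ in range(1000):
            e = sample_exchange_set(tree, 0.5, rng)
            assert len(e) >= target
            assert len(e) <= 63
            sizes.append(len(e))
        assert target <= np.mean(sizes) <= 63
        assert np.mean(sizes) > 31.5

    def test_no_duplicates_and_subtree_closure(self, rng):
        tree = random_binary_tree(40, seed=3)
        e = sample_exchange_set(tree, 0.4, rng)
        assert len(e) == len(set(e))


class TestPhylomixPair:
    def test_lambda_one_identity(self, quartet, rng):
        xi = np.array([5.0, 3.0, 2.0, 6.0])
        xj = np.array([1.0, 1.0, 8.0, 2.0])
        s = phylomix_pair(xi, 1.0, xj, 0.0, quartet, AugmentConfig(), rng, lam=1.0)
        np.testing.assert_allclose(s.abundance, xi, atol=1e-9)
        assert s.label == 1.0

    def test_lambda_zero_partner_composition_base_total(self, quartet, rng):
        xi = np.array([5.0, 3.0, 2.0, 6.0])  # S = 16
        xj = np.array([1.0, 1.0, 8.0, 2.0])  # composition 1/12,1/12,8/12,2/12
        s = phylomix_pair(xi, 1.0, xj, 0.0, quartet, AugmentConfig(), rng, lam=0.0)
        np.testing.assert_allclose(s.abundance, xj / xj.sum() * 16.0, atol=1e-9)
        assert s.label == 0.0
        assert s.abundance.sum() == pytest.approx(16.0)

    def test_unexchanged_subtree_keeps_base_subcomposition(self, rng):
        tree = random_binary_tree(32, seed=7)
        gen = np.random.default_rng(1)
        xi = gen.integers(1, 50, 32).astype(float)
        xj = gen.integers(1, 50, 32).astype(float)
        s = phylomix_pair(xi, 1.0, xj, 0.0, tree, AugmentConfig(), rng)
        for v in range(1, tree.n_internal + 1):
            if set(tree.subtree_internal(v).tolist()) & s.exchanged:
                continue
            leaves = tree.leaf_indices(v)
            got = s.abundance[leaves]
            if got.sum() == 0:
                continue
            np.testing.assert_allclose(
                got / got.sum(), xi[leaves] / xi[leaves].sum(), atol=1e-9
            )

    def test_misaligned_rejected(self, quartet, rng):
        with pytest.raises(ValueError, match="aligned"):
            phylomix_pair(
                np.ones(3), 1.0, np.ones(4), 0.0, quartet, AugmentConfig(), rng
            )


class TestPhylomixAugment:
    def test_beta3_count(self):
        tree = random_binary_tree(12, seed=0)
        ds = toy_dataset(tree, 10, seed=1)
        synth = phylomix_augment(ds, tree, AugmentConfig(ratio=3.0, seed=0))
        assert synth.n == 30

    def test_label_convexity(self):
        tree = random_binary_tree(12, seed=0)
        ds = toy_dataset(tree, 5, seed=1)
        synth = phylomix_augment(ds, tree, AugmentConfig(ratio=1.0, seed=0))
        assert synth.n == 5
        assert np.all(synth.y >= ds.y.min()) and np.all(synth.y <= ds.y.max())
        for rec in synth.provenance:
            lo, hi = sorted([ds.y[rec.i], ds.y[rec.j]])
            assert lo <= rec.label <= hi

    def test_determinism(self):
        tree = random_binary_tree(20, seed=0)
        ds = toy_dataset(tree, 8, seed=2)
        cfg = AugmentConfig(seed=123)
        a = phylomix_augment(ds, tree, cfg)
        b = phylomix_augment(ds, tree, cfg)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)

    def test_total_conservation_count_mode(self):
        tree = random_binary_tree(20, seed=0)
        ds = toy_dataset(tree, 8, seed=2)
        synth = phylomix_augment(ds, tree, AugmentConfig(seed=3))
        for rec in synth.provenance:
            assert rec.abundance.sum() == pytest.approx(
                ds.X[rec.i].sum(), rel=1e-6
            )

    def test_relative_mode_simplex(self):
        tree = random_binary_tree(20, seed=0)
        ds = toy_dataset(tree, 8, seed=2, mode="relative")
        synth = phylomix_augment(
            ds, tree, AugmentConfig(seed=3, mode="relative")
        )
        assert np.all(synth.X >= 0)
        np.testing.assert_allclose(synth.X.sum(axis=1), 1.0, atol=1e-9)

    def test_exchange_quota_in_provenance(self):
        tree = random_binary_tree(30, seed=0)
        ds = toy_dataset(tree, 6, seed=2)
        synth = phylomix_augment(ds, tree, AugmentConfig(seed=9))
        for rec in synth.provenance:
            assert len(rec.exchanged) >= math.ceil((1 - rec.lam) * 29)

    def test_too_few_samples(self):
        tree = random_binary_tree(8, seed=0)
        ds = toy_dataset(tree, 2, seed=0)
        phylomix_augment(ds, tree, AugmentConfig(seed=0))  # n=2 ok
        one = LabeledDataset(ds.X[:1], ds.y[:1], ds.taxa)
        with pytest.raises(ValueError, match="at least 2"):
            phylomix_augment(one, tree, AugmentConfig(seed=0))


class TestVanillaMixup:
    def test_midpoint(self):
        X = np.array([[2.0, 0.0], [0.0, 2.0]])
        ds = LabeledDataset(X, np.array([1.0, 0.0]), ("a", "b"))
        synth = vanilla_mixup(ds, AugmentConfig(ratio=50.0, seed=0))
        mid = synth.X[np.isclose(synth.y, 0.5, atol=0.02)]
        assert len(mid) > 0
        np.testing.assert_allclose(mid.sum(axis=1), 2.0, atol=1e-9)

    def test_componentwise_envelope(self):
        tree = random_binary_tree(10, seed=0)
        ds = toy_dataset(tree, 6, seed=4)
        synth = vanilla_mixup(ds, AugmentConfig(seed=5))
        for rec in synth.provenance:
            lo = np.minimum(ds.X[rec.i], ds.X[rec.j])
            hi = np.maximum(ds.X[rec.i], ds.X[rec.j])
            assert np.all(rec.abundance >= lo - 1e-12)
            assert np.all(rec.abundance <= hi + 1e-12)

    @given(ratio=st.floats(0.3, 4.0), n=st.integers(2, 12))
    @settings(max_examples=20, deadline=None)
    def test_synthetic_count_ceiling(self, ratio, n):
        tree = random_binary_tree(6, seed=0)
        ds = toy_dataset(tree, n, seed=0)
        synth = vanilla_mixup(ds, AugmentConfig(ratio=ratio, seed=0))
        assert synth.n == math.ceil(ratio * n)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"alpha": 0.0}, {"ratio": -1.0}, {"mode": "x"}, {"rounding": "up"}]
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            AugmentConfig(**kwargs)
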