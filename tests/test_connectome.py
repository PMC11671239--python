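import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from sfcoupling import (
    ConfigError,
    DataError,
    functional_connectivity,
    symmetrize_structural,
    consistency_threshold,
)


class TestFunctionalConnectivity:
    def test_matches_pairwise_oracle(self, rng):
        ts = rng.standard_normal((200, 5))
        z = functional_connectivity(ts)
        np.testing.assert_allclose(z, oracles.fisher_z_matrix(ts), atol=1e-12)
        assert np.allclose(z, z.T) and np.all(np.diagonal(z) == 0)

    def test_constructed_half_correlation(self, rng):
        # build two series with exact sample correlation 0.5 by Gram-Schmidt
        a = rng.standard_normal(300)
        b = rng.standard_normal(300)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b = b - (b @ a) / (a @ a) * a  # orthogonal to a
        b = b / b.std()
        y = 0.5 * a + np.sqrt(1 - 0.25) * b
        z = functional_connectivity(np.column_stack([a, y, rng.standard_normal(300)]))
        assert z[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-10)

    def test_affine_rescaling_of_columns_is_irrelevant(self, rng):
        ts = rng.standard_normal((80, 4))
        scaled = ts * np.array([3.0, 0.2, 7.5, 1.0]) + np.array([5.0, -2.0, 0.0, 100.0])
        np.testing.assert_allclose(
            functional_connectivity(ts), functional_connectivity(scaled), atol=1e-10
        )

    def test_degenerate_inputs_raise(self, rng):
        ts = rng.standard_normal((50, 3))
        dup = np.column_stack([ts[:, 0], ts[:, 0], ts[:, 1]])
        with pytest.raises(DataError, match="perfectly correlated"):
            functional_connectivity(dup)
        const = ts.copy()
        const[:, 2] = 4.2
        with pytest.raises(DataError, match="ROI index 2"):
            functional_connectivity(const)
        with pytest.raises(DataError, match=">= 10 timepoints"):
            functional_connectivity(ts[:5])


class TestSymmetrizeStructural:
    def test_matches_elementwise_loop_oracle(self, rng):
        n = 6
        counts = rng.integers(0, 400, (n, n))
        np.fill_diagonal(counts, 0)
        vols = rng.uniform(50, 600, n)
        w = symmetrize_structural(counts, vols, 5000)
        np.testing.assert_allclose(w, oracles.symmetrize_loop(counts, vols, 5000), atol=1e-12)
        assert np.allclose(w, w.T) and np.all(np.diagonal(w) == 0)

    def test_forced_values(self):
        counts = np.array([[0, 2500], [2500, 0]])
        w = symmetrize_structural(counts, np.array([1.0, 1.0]), 5000)
        assert w[0, 1] == pytest.approx(0.5)
        assert symmetrize_structural(np.zeros((2, 2), int), np.ones(2), 5000)[0, 1] == 0.0

    def test_literal_multiply_mode(self):
        counts = np.array([[0, 10], [30, 0]])
        vols = np.array([2.0, 3.0])
        w = symmetrize_structural(counts, vols, 5000, normalization="multiply_by_volumes")
        assert w[0, 1] == pytest.approx((10 + 30) / 5000 * (2 + 3))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_commutes_with_roi_permutation(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        counts = rng.integers(0, 100, (n, n))
        np.fill_diagonal(counts, 0)
        vols = rng.uniform(10, 100, n)
        perm = rng.permutation(n)
        direct = symmetrize_structural(counts, vols, 5000)[np.ix_(perm, perm)]
        permuted = symmetrize_structural(counts[np.ix_(perm, perm)], vols[perm], 5000)
        np.testing.assert_allclose(direct, permuted, atol=1e-14)

    def test_invalid_inputs_raise(self):
        with pytest.raises(DataError, match="positive"):
            symmetrize_structural(np.zeros((2, 2), int), np.array([1.0, 0.0]), 5000)
        with pytest.raises(DataError, match="nonnegative"):
            symmetrize_structural(np.array([[0, -1], [0, 0]]), np.ones(2), 5000)
        with pytest.raises(DataError, match="diagonal"):
            symmetrize_structural(np.eye(2, dtype=int), np.ones(2), 5000)


def _stack_with_planted_edges(n_sub=20, n=8, planted=3, seed=0):
    """Symmetric stack with 10 candidate edges, `planted` of which appear in
    only one subject (huge coefficient of variation)."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    edges = rng.choice(iu.size, size=10, replace=False)
    stack = np.zeros((n_sub, n, n))
    stable, rare = edges[planted:], edges[:planted]
    for s in range(n_sub):
        for e in stable:
            v = 1.0 + 0.05 * rng.standard_normal()
            stack[s, iu[e], ju[e]] = stack[s, ju[e], iu[e]] = v
    for e in rare:
        stack[0, iu[e], ju[e]] = stack[0, ju[e], iu[e]] = 0.8
    return stack, iu, ju, stable, rare


class TestConsistencyThreshold:
    def test_planted_high_cv_edges_are_removed_exactly(self):
        stack, iu, ju, stable, rare = _stack_with_planted_edges()
        # independent check that the planted edges really have the top CVs
        cvs = {e: oracles.edge_cv(stack, iu[e], ju[e]) for e in np.concatenate([stable, rare])}
        worst = sorted(cvs, key=cvs.get, reverse=True)[:3]
        assert set(worst) == set(rare)
        mask, thresh = consistency_threshold(stack, 0.30)
        for e in rare:
            assert not mask[iu[e], ju[e]]
            assert np.all(thresh[:, iu[e], ju[e]] == 0)
        for e in stable:
            assert mask[iu[e], ju[e]]
            np.testing.assert_array_equal(thresh[:, iu[e], ju[e]], stack[:, iu[e], ju[e]])

    def test_zero_fraction_keeps_everything(self):
        stack, iu, ju, stable, rare = _stack_with_planted_edges()
        mask, thresh = consistency_threshold(stack, 0.0)
        assert mask[iu, ju].sum() == 10
        np.testing.assert_array_equal(thresh, stack)

    def test_removal_count_uses_ceiling(self, rng):
        n_sub, n = 15, 10
        base = rng.uniform(0.5, 1.5, (n, n))
        base = np.triu(base, 1)
        stack = np.array(
            [np.triu(base * rng.uniform(0.8, 1.2, (n, n)), 1) for _ in range(n_sub)]
        )
        stack = stack + np.transpose(stack, (0, 2, 1))
        iu, ju = np.triu_indices(n, k=1)
        e = int(np.any(stack[:, iu, ju] != 0, axis=0).sum())
        for frac in (0.30, 0.17, 0.5):
            mask, _ = consistency_threshold(stack, frac)
            assert mask[iu, ju].sum() == e - int(np.ceil(frac * e))

    def test_keep_bottom_mode_retains_lowest_cv_fraction(self):
        stack, iu, ju, stable, rare = _stack_with_planted_edges()
        mask, _ = consistency_threshold(stack, 0.30, mode="keep_bottom")
        assert mask[iu, ju].sum() == int(np.floor(0.30 * 10))
        for e in rare:
            assert not mask[iu[e], ju[e]]

    def test_invalid_fraction_raises(self):
        stack = np.zeros((3, 4, 4))
        with pytest.raises(ConfigError):
            consistency_threshold(stack, 1.0)
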