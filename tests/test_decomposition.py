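"""Ensemble construction and eigen-microstate decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainmodes.decomposition import (
    ActivityMatrix,
    build_ensemble,
    decompose,
    mode_timecourse,
    zscore_time_courses,
)
from brainmodes.errors import AlignmentError, ContractError, ZeroVarianceNode

from conftest import random_zscored_session


class TestZscore:
    def test_unit_sd_row(self):
        m = ActivityMatrix(values=[[1.0, 2.0, 3.0]], node_ids=["a"])
        z = zscore_time_courses(m)
        np.testing.assert_allclose(z.values, [[-1.0, 0.0, 1.0]], atol=1e-12)
        assert z.zscored

    def test_hand_computed_four_points(self):
        # sample sd of (2,4,6,8) is sqrt(20/3)
        m = ActivityMatrix(values=[[2.0, 4.0, 6.0, 8.0]], node_ids=["a"])
        z = zscore_time_courses(m)
        np.testing.assert_allclose(
            z.values, [[-1.1619, -0.3873, 0.3873, 1.1619]], atol=5e-5
        )

    def test_constant_row_names_node(self):
        m = ActivityMatrix(values=[[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], node_ids=["a", "b"])
        with pytest.raises(ZeroVarianceNode, match="'b'"):
            zscore_time_courses(m)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_standardized(self, seed):
        rng = np.random.default_rng(seed)
        z = random_zscored_session(rng, n_nodes=5, n_time=11)
        assert np.abs(z.values.mean(axis=1)).max() < 1e-8
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-6)


class TestBuildEnsemble:
    def test_concatenation_shape(self, rng):
        a = random_zscored_session(rng, n_nodes=3, n_time=5, label="s1")
        b = random_zscored_session(rng, n_nodes=3, n_time=5, label="s2")
        ens = build_ensemble([a, b])
        assert ens.values.shape == (3, 10)
        assert ens.segment_index == (("s1", 0, 5), ("s2", 5, 10))

    def test_normalization_constant(self):
        sess = ActivityMatrix(
            values=[[-1.0, 0.0, 1.0], [1.0, 0.0, -1.0]],
            node_ids=["a", "b"],
            zscored=True,
        )
        ens = build_ensemble([sess])
        assert ens.S == pytest.approx(2.0)  # root-sum-square of {1,0,1,1,0,1}
        np.testing.assert_allclose(ens.values, sess.values / 2.0)
        assert np.sum(ens.values**2) == pytest.approx(1.0, abs=1e-10)

    def test_rejects_permuted_node_ids(self, rng):
        a = random_zscored_session(rng, n_nodes=3, n_time=5)
        b = ActivityMatrix(
            values=a.values, node_ids=list(a.node_ids)[::-1], zscored=True
        )
        with pytest.raises(AlignmentError):
            build_ensemble([a, b])

    def test_rejects_raw_input(self, rng):
        raw = ActivityMatrix(values=rng.normal(size=(3, 5)), node_ids=list("abc"))
        with pytest.raises(ContractError):
            build_ensemble([raw])


class TestDecompose:
    def test_rank_one_antisymmetric(self):
        sess = ActivityMatrix(
            values=[[-1.0, 0.0, 1.0], [1.0, 0.0, -1.0]],
            node_ids=["a", "b"],
            zscored=True,
        )
        ms = decompose(build_ensemble([sess]))
        np.testing.assert_allclose(ms.weights, [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(ms.modes[:, 0], [0.7071, -0.7071], atol=1e-4)

    def test_rank_one_symmetric(self):
        sess = ActivityMatrix(
            values=[[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]],
            node_ids=["a", "b"],
            zscored=True,
        )
        ms = decompose(build_ensemble([sess]))
        np.testing.assert_allclose(ms.weights, [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(ms.modes[:, 0], [0.7071, 0.7071], atol=1e-4)

    def test_weights_sum_to_one(self, random_modeset):
        ms, _ = random_modeset
        assert ms.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_modes_orthogonal_norms_equal_weights(self, random_modeset):
        ms, _ = random_modeset
        gram = ms.modes.T @ ms.modes
        np.testing.assert_allclose(gram, np.diag(ms.weights), atol=1e-8)

    def test_oracle_gram_eigendecomposition(self):
        """Weights/modes must match a dense eigendecomposition of AA^T."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            n, m = rng.integers(3, 11), rng.integers(12, 31)
            sess = random_zscored_session(rng, n_nodes=int(n), n_time=int(m))
            ens = build_ensemble([sess])
            ms = decompose(ens)
            lam, U = np.linalg.eigh(ens.values @ ens.values.T)
            lam, U = lam[::-1], U[:, ::-1]
            np.testing.assert_allclose(ms.weights, np.clip(lam, 0, None), atol=1e-10)
            for i in range(int(n)):
                if ms.weights[i] < 1e-8:
                    continue
                u = ms.modes[:, i] / ms.singular_values[i]
                r = abs(float(u @ U[:, i]))
                assert r == pytest.approx(1.0, abs=1e-8)

    def test_node_relabeling_equivariance(self, rng):
        sess = random_zscored_session(rng, n_nodes=7, n_time=25)
        perm = rng.permutation(7)
        permuted = ActivityMatrix(
            values=sess.values[perm],
            node_ids=[sess.node_ids[i] for i in perm],
            zscored=True,
        )
        ms1 = decompose(build_ensemble([sess]))
        ms2 = decompose(build_ensemble([permuted]))
        np.testing.assert_allclose(ms1.weights, ms2.weights, atol=1e-10)
        np.testing.assert_allclose(
            np.abs(ms1.modes[perm]), np.abs(ms2.modes), atol=1e-8
        )

    def test_duplicate_columns_leave_weights_unchanged(self, rng):
        """S-normalization makes the weights scale invariant."""
        sess = random_zscored_session(rng, n_nodes=5, n_time=15)
        doubled = ActivityMatrix(
            values=np.hstack([sess.values, sess.values]),
            node_ids=sess.node_ids,
            zscored=True,
        )
        w1 = decompose(build_ensemble([sess])).weights
        w2 = decompose(build_ensemble([doubled])).weights
        np.testing.assert_allclose(w1, w2, atol=1e-10)


class TestModeTimecourse:
    def test_unit_norm(self, random_modeset):
        ms, _ = random_modeset
        for i in (1, ms.rank):
            assert np.linalg.norm(mode_timecourse(ms, i)) == pytest.approx(
                1.0, abs=1e-10
            )

    def test_rank_one_series(self):
        sess = ActivityMatrix(
            values=[[-1.0, 0.0, 1.0], [1.0, 0.0, -1.0]],
            node_ids=["a", "b"],
            zscored=True,
        )
        ms = decompose(build_ensemble([sess]))
        series = mode_timecourse(ms, 1)
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2)
        assert np.allclose(series, expected) or np.allclose(series, -expected)

    def test_out_of_range(self, random_modeset):
        ms, _ = random_modeset
        with pytest.raises(IndexError):
            mode_timecourse(ms, ms.rank + 1)
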