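"""Cross-state matching, system aggregation, permutation + FDR, surrogates."""

import numpy as np
import pytest

from brainmodes.decomposition import build_ensemble, decompose, zscore_time_courses
from brainmodes.errors import AlignmentError, ContractError, UndefinedSimilarity
from brainmodes.simulate import (
    CohortManifest,
    generate_session,
    generate_two_state,
    random_coords,
)
from brainmodes.states import (
    SystemPartition,
    amplitude_difference_test,
    coactivation_difference_test,
    match_modes,
    similarity_with_sa_surrogates,
    system_amplitudes,
    system_pair_means,
    variogram_surrogates,
)


@pytest.fixture(scope="module")
def modeset_pair(small_basis):
    sess = generate_session(small_basis, M=200, noise_sd=0.1, seed=51)
    ms = decompose(build_ensemble([zscore_time_courses(sess)]))
    return ms


class TestSystemAmplitudes:
    def test_block_means(self):
        part = SystemPartition(labels=["A", "A", "B", "B"])
        amps = system_amplitudes(np.array([1.0, 3.0, -2.0, -4.0]), part)
        assert amps == {"A": 2.0, "B": -3.0}

    def test_zero_mode(self):
        part = SystemPartition(labels=["A", "A", "B"])
        amps = system_amplitudes(np.zeros(3), part)
        assert set(amps.values()) == {0.0}

    def test_empty_system_rejected(self):
        with pytest.raises(ContractError):
            SystemPartition(labels=["A", "A", "B"], systems=("A", "B", "C"))

    def test_partition_mismatch(self):
        part = SystemPartition(labels=["A", "B"])
        with pytest.raises(AlignmentError):
            system_amplitudes(np.zeros(5), part)


class TestMatchModes:
    def test_identity(self, modeset_pair):
        corr = match_modes(modeset_pair, modeset_pair, 3, 3)
        for i in range(1, 4):
            j, sign, r = corr.assignment[i]
            assert (j, sign) == (i, 1)
            assert r == pytest.approx(1.0)

    def test_planted_swap(self, modeset_pair):
        import dataclasses

        swapped_modes = modeset_pair.modes.copy()
        swapped_modes[:, [1, 2]] = swapped_modes[:, [2, 1]]
        other = dataclasses.replace(modeset_pair, modes=swapped_modes)
        corr = match_modes(modeset_pair, other, 3, 3)
        assert corr.assignment[2][0] == 3
        assert corr.assignment[3][0] == 2

    def test_negation_flips_signs(self, modeset_pair):
        import dataclasses

        other = dataclasses.replace(modeset_pair, modes=-modeset_pair.modes)
        corr = match_modes(modeset_pair, other, 3, 3)
        for i in range(1, 4):
            _, sign, r = corr.assignment[i]
            assert sign == -1
            assert abs(r) == pytest.approx(1.0)

    def test_optimal_beats_identity(self, modeset_pair):
        """The assignment's total |r| is at least that of the identity."""
        import dataclasses

        rng = np.random.default_rng(8)
        noisy = modeset_pair.modes + 0.1 * rng.normal(size=modeset_pair.modes.shape)
        other = dataclasses.replace(modeset_pair, modes=noisy)
        corr = match_modes(modeset_pair, other, 5, 5)
        total = sum(abs(r) for _, _, r in corr.assignment.values())
        identity = sum(abs(corr.correlation[i, i]) for i in range(5))
        assert total >= identity - 1e-12


class TestSystemPairMeans:
    def test_seven_systems_give_28_entries(self):
        labels = [f"s{i % 7}" for i in range(21)]
        part = SystemPartition(labels=labels)
        names, means = system_pair_means(np.ones((21, 21)), part)
        assert len(names) == 28
        np.testing.assert_allclose(means, 1.0)


@pytest.fixture(scope="module")
def paired_states(default_basis):
    man = CohortManifest(
        n_subjects=10, n_runs=1, n_timepoints=150, noise_sd=0.2,
        subject_effect=0.1, state_effect=0.0, seed=61,
    )
    two = generate_two_state(default_basis, man)
    sess = [two.state_a.sessions[(s, 0)] for s in range(10)]
    return sess


class TestAmplitudeDifference:
    def test_identical_states_find_nothing(self, paired_states):
        """With literally identical data the observed and all null
        differences vanish, so every p value is 1."""
        rep = amplitude_difference_test(
            paired_states, paired_states, mode_rank=1, n_perm=30, seed=5
        )
        assert rep.significant.sum() == 0
        np.testing.assert_allclose(rep.p_values, 1.0)

    def test_p_floor_is_add_one(self, paired_states):
        rep = amplitude_difference_test(
            paired_states, paired_states, mode_rank=1, n_perm=99, seed=5
        )
        assert np.all(rep.p_values >= 1.0 / 100)

    def test_q_dominates_p(self, default_basis):
        man = CohortManifest(
            n_subjects=6, n_runs=1, n_timepoints=150, noise_sd=0.2,
            subject_effect=0.1, state_effect=0.6, seed=62,
        )
        two = generate_two_state(default_basis, man)
        sa = [two.state_a.sessions[(s, 0)] for s in range(6)]
        sb = [two.state_b.sessions[(s, 0)] for s in range(6)]
        rep = amplitude_difference_test(sa, sb, mode_rank=1, n_perm=50, seed=6)
        assert np.all(rep.q_values >= rep.p_values - 1e-12)
        assert np.array_equal(rep.significant, rep.q_values < rep.fdr_level)

    def test_unpaired_subjects_rejected(self, paired_states):
        with pytest.raises(AlignmentError):
            amplitude_difference_test(
                paired_states, paired_states[:-1], mode_rank=1, n_perm=5, seed=0
            )


class TestCoactivationDifference:
    def test_identical_states_find_nothing(self, paired_states, default_basis):
        part = SystemPartition(labels=default_basis.partition)
        rep = coactivation_difference_test(
            paired_states, paired_states, mode_rank=1, partition=part,
            n_perm=30, seed=5,
        )
        assert rep.significant.sum() == 0
        assert len(rep.labels) == 28  # 7 systems: 7 within + 21 between


class TestSurrogates:
    def test_self_similarity_minimal_p(self, small_basis):
        m1 = small_basis.modes[:, 0]
        r, p = similarity_with_sa_surrogates(
            m1, m1, small_basis.coords, n_surr=99, seed=1
        )
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.01)

    def test_variogram_preserved_known_kernel(self):
        """On a map with a known squared-exponential covariance the
        surrogates reproduce the binned variogram: within 15% in the
        typical well-populated bin (sparse bins carry sampling noise)."""
        from scipy.spatial.distance import pdist, squareform

        from brainmodes.states import _VariogramWorkspace

        rng = np.random.default_rng(12)
        coords = random_coords(150, seed=4)
        D = squareform(pdist(coords))
        K = np.exp(-(D**2) / (2 * 20.0**2))
        K /= K.sum(axis=1, keepdims=True)
        x = K @ rng.normal(size=150) + 0.05 * rng.normal(size=150)
        surr = variogram_surrogates(x, coords, n_surr=15, seed=5)
        ws = _VariogramWorkspace(coords, 25)
        gamma_obs = ws.gamma(x)
        gamma_surr = np.nanmean([ws.gamma(s) for s in surr], axis=0)
        ok = ws.counts >= 30
        rel = np.abs(gamma_surr[ok] - gamma_obs[ok]) / gamma_obs[ok]
        assert np.median(rel) <= 0.15
        assert np.nanmax(rel) <= 0.40

    def test_mode_map_variogram_roughly_preserved(self, default_basis):
        """The surrogate null for a real basic-mode map keeps its
        spatial autocorrelation profile (median bin error small)."""
        m1 = default_basis.modes[:, 0]
        surr = variogram_surrogates(m1, default_basis.coords, n_surr=15, seed=2)
        from brainmodes.states import _VariogramWorkspace

        ws = _VariogramWorkspace(default_basis.coords, 25)
        gamma_obs = ws.gamma(m1)
        gamma_surr = np.nanmean([ws.gamma(s) for s in surr], axis=0)
        ok = ws.counts >= 30
        rel = np.abs(gamma_surr[ok] - gamma_obs[ok]) / gamma_obs[ok]
        assert np.median(rel) <= 0.20

    def test_rank_remap_preserves_value_multiset(self, small_basis):
        m1 = small_basis.modes[:, 0]
        surr = variogram_surrogates(
            m1, small_basis.coords, n_surr=3, seed=3, resample=True
        )
        for s in surr:
            np.testing.assert_allclose(np.sort(s), np.sort(m1), atol=1e-12)

    def test_calibration_under_independence(self, small_basis):
        """Against an independent target the surrogate p is roughly
        uniform: rejections at alpha=0.05 stay near the nominal rate."""
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            target = rng.normal(size=small_basis.n_nodes)
            _, p = similarity_with_sa_surrogates(
                small_basis.modes[:, 0], target, small_basis.coords,
                n_surr=99, seed=int(rng.integers(2**31 - 1)),
            )
            hits += p < 0.05
        # binomial(40, 0.05): central 99% well below 8
        assert hits <= 8

    def test_constant_map_rejected(self, small_basis):
        with pytest.raises(UndefinedSimilarity):
            similarity_with_sa_surrogates(
                np.ones(50), np.arange(50.0), small_basis.coords, n_surr=5, seed=0
            )
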