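"""Synthetic multi-subject cohorts with planted low-dimensional mode structure.

Every downstream stage of the package (decomposition, leading-mode
selection, FC reconstruction, fingerprinting, state comparison) is
exercised on data generated here, where the ground truth is known by
construction.  A cohort is built from a :class:`PlantedBasis`: K
orthonormal, spatially smooth, functional-system-dependent patterns over
N nodes with a strictly decreasing strength spectrum.  A session is the
mixture ``sum_k spectrum_k * mode_k * t_k(t)`` plus i.i.d. Gaussian
noise, where the temporal loadings ``t_k`` are band-limited (smoothed
white noise), exactly zero-mean, mutually orthogonal, and of unit sample
variance.

A deliberate design feature: the basis construction finishes with a
sequence of Givens rotations that equalizes the spectrum-weighted energy
of every node (an equal-norm frame with prescribed spectrum).  Each
node's noiseless signal variance is then identical, so the node-wise
z-scoring applied downstream is a single global rescale and the planted
modes are *exactly* the modes of the standardized data — noiseless
sessions decompose back onto the planted basis to machine precision.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .decomposition import ActivityMatrix
from .errors import ContractError

__all__ = [
    "PlantedBasis",
    "CohortManifest",
    "Cohort",
    "TwoStateCohort",
    "default_partition",
    "random_coords",
    "generate_basis",
    "generate_session",
    "generate_cohort",
    "generate_two_state",
]

#: Geometric decay of planted mode strengths.  Descending with clear
#: gaps so a scree elbow exists, and sized so that at the default
#: observation noise (sd 0.2) the weakest of five planted modes carries
#: several times the weight of the largest pure-noise mode.
DEFAULT_SPECTRUM_BASE = 1.2
DEFAULT_SPECTRUM_RATIO = 0.84


@dataclass(frozen=True)
class PlantedBasis:
    """Ground-truth spatial basis shared by a synthetic cohort.

    modes : (N, K) orthonormal columns; spectrum : (K,) strictly
    positive, non-increasing mode strengths; partition : length-N system
    labels; coords : (N, 3) node coordinates; seed : generator seed.
    """

    modes: np.ndarray
    spectrum: np.ndarray
    partition: tuple
    coords: np.ndarray
    seed: int

    def __post_init__(self):
        modes = np.asarray(self.modes, dtype=float)
        spectrum = np.asarray(self.spectrum, dtype=float)
        gram = modes.T @ modes
        if not np.allclose(gram, np.eye(modes.shape[1]), atol=1e-10):
            raise ContractError("basis modes are not orthonormal")
        if np.any(spectrum <= 0) or np.any(np.diff(spectrum) > 0):
            raise ContractError("spectrum must be positive and non-increasing")
        if len(self.partition) != modes.shape[0]:
            raise ContractError("partition does not cover the node set")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape[0] != modes.shape[0]:
            raise ContractError("coords do not cover the node set")
        object.__setattr__(self, "modes", modes)
        object.__setattr__(self, "spectrum", spectrum)
        object.__setattr__(self, "partition", tuple(self.partition))
        object.__setattr__(self, "coords", coords)

    @property
    def n_nodes(self) -> int:
        return self.modes.shape[0]

    @property
    def k_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def node_ids(self) -> tuple:
        return tuple(f"node{i:04d}" for i in range(self.n_nodes))


@dataclass(frozen=True)
class CohortManifest:
    """Study-design parameters of a synthetic cohort.

    Defaults are the package's standard synthetic study conditions:
    20 subjects, two runs (the classic test-retest fingerprinting
    design), 300 time points per run, observation noise sd 0.2, and a
    subject-specific basis perturbation of scale 0.3.
    """

    n_subjects: int = 20
    n_runs: int = 2
    n_timepoints: int = 300
    noise_sd: float = 0.2
    subject_effect: float = 0.3
    state_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.n_runs, self.n_timepoints) < 1:
            raise ContractError("counts must be >= 1")
        if min(self.noise_sd, self.subject_effect) < 0:
            raise ContractError("scales must be >= 0")
        if not 0.0 <= self.state_effect <= 1.0:
            raise ContractError("state_effect must lie in [0, 1]")


@dataclass(frozen=True)
class Cohort:
    """Generated sessions plus the ground truth that produced them."""

    sessions: dict  # (subject, run) -> ActivityMatrix
    subject_bases: dict  # subject -> (N, K) modes actually used
    basis: PlantedBasis
    manifest: CohortManifest

    def runs(self, run: int):
        """Sessions of one run, ordered by subject."""
        subjects = sorted({s for s, _ in self.sessions})
        return [self.sessions[(s, run)] for s in subjects]


@dataclass(frozen=True)
class TwoStateCohort:
    """Paired state-A / state-B sessions for the same subjects."""

    state_a: Cohort
    state_b: Cohort
    basis_b: PlantedBasis


def default_partition(n_nodes: int, n_systems: int = 7) -> tuple:
    """Contiguous assignment of nodes to ``n_systems`` labelled systems."""
    labels = [f"sys{j + 1}" for j in range(n_systems)]
    return tuple(labels[(i * n_systems) // n_nodes] for i in range(n_nodes))


def random_coords(n_nodes: int, seed: int, extent: float = 100.0) -> np.ndarray:
    """Uniform random 3-D node coordinates in a cube of the given extent."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, extent, size=(n_nodes, 3))


def clustered_coords(
    partition, seed: int, extent: float = 100.0, spread: float = 18.0
) -> np.ndarray:
    """System-clustered 3-D node coordinates.

    Each system's nodes scatter (sd ``spread``) around a random cluster
    center, so the node-to-system assignment is spatially coherent and
    system-dependent patterns are spatially autocorrelated — the
    geometry the surrogate machinery assumes.
    """
    partition = list(partition)
    rng = np.random.default_rng(seed)
    centers = {
        name: rng.uniform(0.15 * extent, 0.85 * extent, size=3)
        for name in dict.fromkeys(partition)
    }
    return np.array(
        [centers[name] + rng.normal(scale=spread, size=3) for name in partition]
    )


def _orthonormalize(X: np.ndarray) -> np.ndarray:
    """QR-based orthonormalization with deterministic column signs."""
    Q, R = np.linalg.qr(X)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


def _balance_rows(modes: np.ndarray, spectrum: np.ndarray) -> np.ndarray:
    """Equalize spectrum-weighted row energies with left Givens rotations.

    Left rotations preserve the column Gram matrix (orthonormality and
    the effective spectrum) while redistributing energy across rows.
    Each step rotates the most- and least-energetic rows so that one of
    them lands exactly on the target energy; at most N - 1 steps.
    """
    B = modes * spectrum  # (N, K)
    r = np.einsum("ij,ij->i", B, B)
    target = r.mean()
    order = []  # rows already fixed at target
    active = np.ones(len(r), dtype=bool)
    for _ in range(len(r) - 1):
        idx = np.flatnonzero(active)
        if idx.size < 2:
            break
        hi = idx[np.argmax(r[idx])]
        lo = idx[np.argmin(r[idx])]
        if r[hi] - target <= 1e-15 and target - r[lo] <= 1e-15:
            break
        # rotate rows (hi, lo) so the new hi-row energy equals target
        p = B[hi] @ B[lo]
        a = 0.5 * (r[hi] - r[lo])
        m = 0.5 * (r[hi] + r[lo])
        R_amp = np.hypot(a, p)
        phi = np.arctan2(p, a)
        theta = 0.5 * (phi + np.arccos(np.clip((target - m) / R_amp, -1, 1)))
        c, s = np.cos(theta), np.sin(theta)
        bh, bl = B[hi].copy(), B[lo].copy()
        B[hi] = c * bh + s * bl
        B[lo] = -s * bh + c * bl
        r[hi] = B[hi] @ B[hi]
        r[lo] = B[lo] @ B[lo]
        active[hi] = False
        order.append(hi)
    return B / spectrum


def generate_basis(
    n_nodes: int,
    k_modes: int,
    partition=None,
    coords: np.ndarray | None = None,
    smoothness: float = 10.0,
    seed: int = 0,
    spectrum: np.ndarray | None = None,
    balance: bool = True,
) -> PlantedBasis:
    """Build K orthonormal, smooth, system-structured spatial patterns.

    Each raw pattern is a random per-system offset (system-dependence)
    plus spatially autocorrelated noise obtained by smoothing white
    noise with a squared-exponential kernel of the given length scale on
    the node coordinates.  Patterns are then orthonormalized and, if
    ``balance`` is set (default), rotated so every node carries the same
    spectrum-weighted signal energy (see module docstring).

    Raises
    ------
    ValueError
        If ``k_modes >= n_nodes`` (rank deficiency) or the partition has
        fewer than two systems.
    """
    if k_modes >= n_nodes:
        raise ValueError(
            f"k_modes ({k_modes}) must be smaller than n_nodes ({n_nodes})"
        )
    if partition is None:
        partition = default_partition(n_nodes)
    partition = tuple(partition)
    if len(partition) != n_nodes:
        raise ValueError("partition length does not match n_nodes")
    systems = sorted(set(partition))
    if len(systems) < 2:
        raise ValueError("partition must define at least two systems")
    rng = np.random.default_rng(seed)
    if coords is None:
        coords = clustered_coords(partition, seed=int(rng.integers(2**31 - 1)))
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != n_nodes:
        raise ValueError("coords length does not match n_nodes")
    if spectrum is None:
        spectrum = DEFAULT_SPECTRUM_BASE * DEFAULT_SPECTRUM_RATIO ** np.arange(
            k_modes
        )
    spectrum = np.asarray(spectrum, dtype=float)

    D = squareform(pdist(coords))
    kernel = np.exp(-(D**2) / (2.0 * smoothness**2))
    kernel /= kernel.sum(axis=1, keepdims=True)

    sys_index = {name: np.flatnonzero([p == name for p in partition]) for name in systems}
    raw = np.empty((n_nodes, k_modes))
    for k in range(k_modes):
        pattern = np.empty(n_nodes)
        offsets = rng.normal(size=len(systems))
        for name, off in zip(systems, offsets):
            pattern[sys_index[name]] = off
        pattern = pattern + kernel @ rng.normal(size=n_nodes)
        raw[:, k] = pattern
    modes = _orthonormalize(raw)
    if balance:
        modes = _balance_rows(modes, spectrum)
    return PlantedBasis(
        modes=modes, spectrum=spectrum, partition=partition, coords=coords, seed=seed
    )


def _temporal_loadings(M: int, K: int, rng, window: int = 5) -> np.ndarray:
    """Band-limited loadings: exactly zero-mean, orthogonal, unit sample sd.

    White noise is smoothed with a moving-average window (mimicking the
    low-pass character of hemodynamic time series), then orthogonalized
    against the constant vector and against each other (QR), and scaled
    to unit sample variance.  Returns shape (K, M).
    """
    noise = rng.normal(size=(M, K))
    k = np.ones(window) / window
    smooth = np.column_stack(
        [np.convolve(noise[:, j], k, mode="same") for j in range(K)]
    )
    basis = np.column_stack([np.ones(M), smooth])
    Q = _orthonormalize(basis)[:, 1:]  # drop the constant direction
    return (Q * np.sqrt(M - 1)).T


def generate_session(
    basis: PlantedBasis,
    M: int,
    noise_sd: float,
    seed: int,
    label: str = "",
) -> ActivityMatrix:
    """One session: planted mixture plus i.i.d. Gaussian observation noise.

    Returns the raw (not yet z-scored) N x M activity matrix
    ``modes @ diag(spectrum) @ loadings + noise``.
    """
    if M < 3:
        raise ValueError("a session needs at least 3 time points")
    if M <= basis.n_nodes:
        warnings.warn(
            f"M={M} <= n_nodes={basis.n_nodes}: the decomposition will be "
            "rank-limited by time points",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    T = _temporal_loadings(M, basis.k_modes, rng)
    X = (basis.modes * basis.spectrum) @ T
    if noise_sd > 0:
        X = X + rng.normal(scale=noise_sd, size=X.shape)
    return ActivityMatrix(values=X, node_ids=basis.node_ids, label=label)


def _perturb_basis(basis: PlantedBasis, scale: float, rng) -> np.ndarray:
    """Subject-specific basis: add a random tangent pattern to each mode,
    re-orthonormalize, re-balance.  scale 0 returns the basis unchanged."""
    if scale == 0:
        return basis.modes
    tangent = rng.normal(size=basis.modes.shape) / np.sqrt(basis.n_nodes)
    modes = _orthonormalize(basis.modes + scale * tangent)
    return _balance_rows(modes, basis.spectrum)


def generate_cohort(basis: PlantedBasis, manifest: CohortManifest) -> Cohort:
    """Multi-subject, multi-run cohort with stable subject signatures.

    Each subject receives a fixed perturbed copy of the planted basis
    (scale ``manifest.subject_effect``) reused across all of its runs;
    temporal loadings and observation noise are redrawn per run.
    """
    root = np.random.SeedSequence(manifest.seed)
    subject_seeds = root.spawn(manifest.n_subjects)
    sessions = {}
    subject_bases = {}
    for s, sseq in enumerate(subject_seeds):
        srng = np.random.default_rng(sseq)
        modes = _perturb_basis(basis, manifest.subject_effect, srng)
        subject_bases[s] = modes
        sub_basis = PlantedBasis(
            modes=modes,
            spectrum=basis.spectrum,
            partition=basis.partition,
            coords=basis.coords,
            seed=basis.seed,
        )
        for r in range(manifest.n_runs):
            run_seed = int(srng.integers(2**31 - 1))
            sessions[(s, r)] = generate_session(
                sub_basis,
                manifest.n_timepoints,
                manifest.noise_sd,
                seed=run_seed,
                label=f"sub-{s:03d}/run-{r + 1}",
            )
    return Cohort(
        sessions=sessions, subject_bases=subject_bases, basis=basis, manifest=manifest
    )


def flatten_to_system_means(pattern: np.ndarray, partition) -> np.ndarray:
    """Replace each node's value by its system mean (contrast removal)."""
    partition = np.asarray(partition)
    out = np.empty_like(np.asarray(pattern, dtype=float))
    for name in np.unique(partition):
        idx = partition == name
        out[idx] = pattern[idx].mean()
    return out


def state_b_basis(basis: PlantedBasis, state_effect: float) -> PlantedBasis:
    """Perturbed-state basis: mode 1 shrunk toward its system means.

    Mode 1 becomes ``(1 - e) * mode1 + e * flattened(mode1)``, emulating
    a state that reduces the spatial inhomogeneity of the dominant
    activity pattern; the basis is then re-orthonormalized (mode 1
    first, so the flattening is preserved exactly up to normalization)
    and re-balanced.
    """
    if not 0.0 <= state_effect <= 1.0:
        raise ContractError("state_effect must lie in [0, 1]")
    if state_effect == 0:
        return basis
    modes = basis.modes.copy()
    flat = flatten_to_system_means(modes[:, 0], basis.partition)
    modes[:, 0] = (1 - state_effect) * modes[:, 0] + state_effect * flat
    modes = _orthonormalize(modes)
    modes = _balance_rows(modes, basis.spectrum)
    return PlantedBasis(
        modes=modes,
        spectrum=basis.spectrum,
        partition=basis.partition,
        coords=basis.coords,
        seed=basis.seed,
    )


def generate_two_state(basis: PlantedBasis, manifest: CohortManifest) -> TwoStateCohort:
    """Paired two-state cohort: every subject scanned in both states.

    State A uses the planted basis; state B uses :func:`state_b_basis`
    with ``manifest.state_effect``.  The same subject-specific tangent
    perturbation is applied to both state bases so subjects are paired.
    """
    basis_b = state_b_basis(basis, manifest.state_effect)
    root = np.random.SeedSequence(manifest.seed)
    subject_seeds = root.spawn(manifest.n_subjects)
    sessions_a, sessions_b = {}, {}
    bases_a, bases_b = {}, {}
    for s, sseq in enumerate(subject_seeds):
        srng = np.random.default_rng(sseq)
        tangent = srng.normal(size=basis.modes.shape) / np.sqrt(basis.n_nodes)
        for which, state_basis, sessions, bases in (
            ("A", basis, sessions_a, bases_a),
            ("B", basis_b, sessions_b, bases_b),
        ):
            if manifest.subject_effect > 0:
                modes = _orthonormalize(
                    state_basis.modes + manifest.subject_effect * tangent
                )
                modes = _balance_rows(modes, state_basis.spectrum)
            else:
                modes = state_basis.modes
            bases[s] = modes
            sub_basis = PlantedBasis(
                modes=modes,
                spectrum=state_basis.spectrum,
                partition=state_basis.partition,
                coords=state_basis.coords,
                seed=state_basis.seed,
            )
            for r in range(manifest.n_runs):
                run_seed = int(srng.integers(2**31 - 1))
                sessions[(s, r)] = generate_session(
                    sub_basis,
                    manifest.n_timepoints,
                    manifest.noise_sd,
                    seed=run_seed,
                    label=f"sub-{s:03d}/state-{which}/run-{r + 1}",
                )
    cohort_a = Cohort(
        sessions=sessions_a, subject_bases=bases_a, basis=basis, manifest=manifest
    )
    cohort_b = Cohort(
        sessions=sessions_b, subject_bases=bases_b, basis=basis_b, manifest=manifest
    )
    return TwoStateCohort(state_a=cohort_a, state_b=cohort_b, basis_b=basis_b)
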