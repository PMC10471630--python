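"""Cross-state mode comparison, system aggregation, and surrogate testing.

Modes from two conditions are put in correspondence by maximizing total
absolute spatial correlation (Hungarian assignment), which makes order
inversions and sign flips between conditions explicit.  State
differences in a mode's node amplitudes or in its system-level
coactivation pattern are tested with a paired permutation scheme —
each subject's state labels are flipped independently — with
Benjamini-Hochberg FDR over nodes or system pairs.  Because the SVD
fixes neither order nor sign, every group mode recomputed inside the
permutation loop is re-matched and sign-aligned to the fixed state-A
reference before differencing.

Map-to-map association is tested against spatial-autocorrelation-
preserving surrogates: permute the map's values, smooth with a
distance kernel over a grid of length scales, and rescale to match the
original map's binned variogram, so the null keeps the map's smoothness
but destroys its alignment with the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .decomposition import build_ensemble, decompose, zscore_time_courses
from .errors import AlignmentError, ContractError, UndefinedSimilarity
from .fc import mode_coactivation

__all__ = [
    "SystemPartition",
    "ModeCorrespondence",
    "StateDifferenceReport",
    "system_amplitudes",
    "match_modes",
    "amplitude_difference_test",
    "coactivation_difference_test",
    "system_pair_means",
    "binned_variogram",
    "variogram_surrogates",
    "similarity_with_sa_surrogates",
]


@dataclass(frozen=True)
class SystemPartition:
    """Node-to-functional-system assignment.

    ``labels`` has one system name per node (in node order); ``systems``
    is the ordered list of distinct names (e.g. the seven canonical
    cortical systems: default-mode, frontoparietal, limbic,
    ventral/dorsal attention, somatomotor, visual).
    """

    labels: tuple
    systems: tuple = ()

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        systems = tuple(self.systems) or tuple(dict.fromkeys(labels))
        if len(systems) < 2:
            raise ContractError("partition must define at least 2 systems")
        if set(labels) - set(systems):
            raise ContractError("labels contain systems not in the system list")
        missing = set(systems) - set(labels)
        if missing:
            raise ContractError(f"empty systems: {sorted(missing)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "systems", systems)

    def indices(self, system: str) -> np.ndarray:
        return np.flatnonzero([lab == system for lab in self.labels])

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ModeCorrespondence:
    """One-to-one spatial correspondence between two mode sets.

    ``correlation`` is the kA x kB signed Pearson matrix over nodes;
    ``assignment`` maps 1-based rank in A to ``(rank in B, sign, r)``.
    """

    correlation: np.ndarray
    assignment: dict
    unmatched_a: tuple
    unmatched_b: tuple


@dataclass(frozen=True)
class StateDifferenceReport:
    """Permutation + FDR test of state differences on one basic mode."""

    labels: tuple  # node ids or system-pair names
    observed: np.ndarray  # state B minus state A
    p_values: np.ndarray
    q_values: np.ndarray
    significant: np.ndarray
    reference: np.ndarray  # state-A reference values for the same labels
    mode_rank: int
    matched_rank_b: int
    matched_sign_b: int
    n_perm: int
    seed: int
    fdr_level: float


def system_amplitudes(mode: np.ndarray, partition: SystemPartition) -> dict:
    """Mean fluctuation amplitude of a mode within each system."""
    mode = np.asarray(mode, dtype=float)
    if mode.shape[0] != partition.n_nodes:
        raise AlignmentError("mode and partition cover different node sets")
    return {
        name: float(mode[partition.indices(name)].mean())
        for name in partition.systems
    }


def match_modes(set_a, set_b, k_a: int | None = None, k_b: int | None = None) -> ModeCorrespondence:
    """Optimal one-to-one mode correspondence between two conditions.

    Computes the Pearson correlation over nodes between the first
    ``k_a`` modes of A and ``k_b`` modes of B, then solves the
    assignment maximizing total |r| (Hungarian method).  Signs of the
    matched correlations are recorded so inversions and flips are
    explicit.
    """
    if set_a.node_ids != set_b.node_ids:
        raise AlignmentError("mode sets are over different node sets")
    k_a = set_a.rank if k_a is None else int(k_a)
    k_b = set_b.rank if k_b is None else int(k_b)
    A = set_a.modes[:, :k_a]
    B = set_b.modes[:, :k_b]
    corr = np.corrcoef(A.T, B.T)[:k_a, k_a:]
    rows, cols = linear_sum_assignment(-np.abs(corr))
    assignment = {}
    for i, j in zip(rows, cols):
        r = float(corr[i, j])
        assignment[i + 1] = (j + 1, 1 if r >= 0 else -1, r)
    unmatched_a = tuple(i + 1 for i in range(k_a) if i not in rows)
    unmatched_b = tuple(j + 1 for j in range(k_b) if j not in cols)
    return ModeCorrespondence(
        correlation=corr,
        assignment=assignment,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
    )


def _group_modes(sessions):
    """Group-level mode set from per-subject sessions (z-scored, concatenated)."""
    z = [s if s.zscored else zscore_time_courses(s) for s in sessions]
    return decompose(build_ensemble(z))


def _gram_modes_from_gram(norm_gram: np.ndarray, S: float, M: int, node_ids):
    """Spatial modes from the normalized N x N Gram matrix ``A A^T``.

    Equivalent to :func:`decompose` for everything the permutation loop
    uses (modes, singular values, weights) but much faster when M >> N;
    temporal coefficients are not computed.
    """
    from .decomposition import EigenModeSet, _fix_signs

    lam, U = np.linalg.eigh(norm_gram)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    U = U[:, order]
    U, _ = _fix_signs(U, np.zeros((U.shape[1], 0)))
    sigma = np.sqrt(lam)
    return EigenModeSet(
        modes=U * sigma,
        singular_values=sigma,
        weights=lam,
        temporal_coeffs=np.zeros((0, M)),
        S=S,
        M=M,
        node_ids=tuple(node_ids),
    )


def _match_to_reference(modeset, reference: np.ndarray, n_candidates: int):
    """Best match (by |r| over nodes) to a fixed reference pattern among
    the top ``n_candidates`` modes; returns (aligned E, 1-based rank, sign)."""
    k = min(n_candidates, modeset.rank)
    E = modeset.modes[:, :k]
    ref = reference - reference.mean()
    cen = E - E.mean(axis=0, keepdims=True)
    denom = np.linalg.norm(cen, axis=0) * np.linalg.norm(ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cen.T @ ref / denom, 0.0)
    idx = int(np.argmax(np.abs(r)))
    sign = 1 if r[idx] >= 0 else -1
    return sign * modeset.modes[:, idx], idx + 1, sign


def system_pair_means(fc_values: np.ndarray, partition: SystemPartition):
    """Within- and between-system means of an interregional matrix.

    Averages off-diagonal entries within each system and all entries
    between each pair of distinct systems.  Returns ``(names, means)``
    with 7 systems giving 28 entries (7 within + 21 between).
    """
    names, means = [], []
    systems = partition.systems
    for a_i, a in enumerate(systems):
        ia = partition.indices(a)
        for b in systems[a_i:]:
            ib = partition.indices(b)
            block = fc_values[np.ix_(ia, ib)]
            if a == b:
                off = ~np.eye(len(ia), dtype=bool)
                if not off.any():
                    raise ContractError(f"system {a!r} has a single node")
                means.append(float(block[off].mean()))
            else:
                means.append(float(block.mean()))
            names.append(f"{a}~{b}")
    return tuple(names), np.asarray(means)


def _state_difference(
    state_a_sessions,
    state_b_sessions,
    mode_rank: int,
    stat_fn,
    n_perm: int,
    seed: int,
    fdr_level: float,
    n_candidates: int,
):
    """Shared permutation engine for the two state-difference tests.

    ``stat_fn(modeset, aligned_mode, rank)`` maps a group decomposition
    (with its reference-aligned mode) to the statistic vector.  The null
    flips each subject's state labels independently and recomputes both
    group statistics with re-matching against the fixed state-A
    reference.
    """
    a_sessions = list(state_a_sessions)
    b_sessions = list(state_b_sessions)
    if len(a_sessions) != len(b_sessions):
        raise AlignmentError("states have different numbers of subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_sub = len(a_sessions)
    za = [zscore_time_courses(s) if not s.zscored else s for s in a_sessions]
    zb = [zscore_time_courses(s) if not s.zscored else s for s in b_sessions]
    for a, b in zip(za, zb):
        if a.node_ids != za[0].node_ids or b.node_ids != za[0].node_ids:
            raise AlignmentError("sessions are over different node sets")
    node_ids = za[0].node_ids

    # per-subject Gram blocks: the Gram of any state mixture is a sum of
    # blocks, which makes each permutation an O(n_sub * N^2) update
    ga = [s.values @ s.values.T for s in za]
    gb = [s.values @ s.values.T for s in zb]
    ma = [s.n_timepoints for s in za]
    mb = [s.n_timepoints for s in zb]

    def mixture_modes(take_b):
        gram = sum(gb[i] if t else ga[i] for i, t in enumerate(take_b))
        M = sum(mb[i] if t else ma[i] for i, t in enumerate(take_b))
        ssq = float(np.trace(gram))  # z-scored rows: total sum of squares
        S = np.sqrt(ssq)
        return _gram_modes_from_gram(gram / ssq, S, M, node_ids)

    modes_a = mixture_modes([False] * n_sub)
    if not 1 <= mode_rank <= modes_a.rank:
        raise IndexError(f"mode_rank {mode_rank} outside 1..{modes_a.rank}")
    reference = modes_a.modes[:, mode_rank - 1]
    stat_a = stat_fn(modes_a, reference, mode_rank)

    modes_b = mixture_modes([True] * n_sub)
    aligned_b, rank_b, sign_b = _match_to_reference(modes_b, reference, n_candidates)
    stat_b = stat_fn(modes_b, aligned_b, rank_b)
    observed = stat_b - stat_a

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, observed.size))
    for p in range(n_perm):
        flips = rng.random(n_sub) < 0.5
        ms_a = mixture_modes(flips)
        al_a, rk_a, _ = _match_to_reference(ms_a, reference, n_candidates)
        ms_b = mixture_modes(~flips)
        al_b, rk_b, _ = _match_to_reference(ms_b, reference, n_candidates)
        null[p] = stat_fn(ms_b, al_b, rk_b) - stat_fn(ms_a, al_a, rk_a)

    p_values = (1 + np.sum(np.abs(null) >= np.abs(observed), axis=0)) / (1 + n_perm)
    _, q_values, _, _ = multipletests(p_values, method="fdr_bh")
    return observed, p_values, q_values, stat_a, rank_b, sign_b


def amplitude_difference_test(
    state_a_sessions,
    state_b_sessions,
    mode_rank: int,
    n_perm: int = 500,
    seed: int = 0,
    fdr_level: float = 0.05,
    n_candidates: int = 10,
    use_unit_modes: bool = False,
) -> StateDifferenceReport:
    """Node-wise state difference in a basic mode's fluctuation amplitudes.

    The observed statistic is the per-node difference between the
    state-B and state-A group modes at ``mode_rank`` (state B matched
    and sign-aligned to the state-A reference).  By default the
    sigma-scaled patterns ``E_i`` are compared; ``use_unit_modes``
    switches to the unit-norm patterns ``u_i``.
    """

    def stat(modeset, aligned, rank):
        if use_unit_modes:
            sigma = modeset.singular_values[rank - 1]
            return aligned / sigma if sigma > 0 else aligned
        return aligned

    observed, p, q, ref, rank_b, sign_b = _state_difference(
        state_a_sessions,
        state_b_sessions,
        mode_rank,
        stat,
        n_perm,
        seed,
        fdr_level,
        n_candidates,
    )
    node_ids = tuple(list(state_a_sessions)[0].node_ids)
    return StateDifferenceReport(
        labels=node_ids,
        observed=observed,
        p_values=p,
        q_values=q,
        significant=q < fdr_level,
        reference=ref,
        mode_rank=mode_rank,
        matched_rank_b=rank_b,
        matched_sign_b=sign_b,
        n_perm=n_perm,
        seed=seed,
        fdr_level=fdr_level,
    )


def coactivation_difference_test(
    state_a_sessions,
    state_b_sessions,
    mode_rank: int,
    partition: SystemPartition,
    n_perm: int = 500,
    seed: int = 0,
    fdr_level: float = 0.05,
    n_candidates: int = 10,
) -> StateDifferenceReport:
    """System-pair state difference in a mode's coactivation pattern.

    The statistic is the within/between-system mean of the matched
    mode's rank-1 coactivation matrix; FDR is applied across the system
    pairs (7 systems -> 28 entries).
    """
    first = list(state_a_sessions)[0]
    if len(first.node_ids) != partition.n_nodes:
        raise AlignmentError("partition does not cover the session node set")
    names_box = {}

    def stat(modeset, aligned, rank):
        coact = mode_coactivation(modeset, rank)
        names, means = system_pair_means(coact.values, partition)
        names_box["names"] = names
        return means

    observed, p, q, ref, rank_b, sign_b = _state_difference(
        state_a_sessions,
        state_b_sessions,
        mode_rank,
        stat,
        n_perm,
        seed,
        fdr_level,
        n_candidates,
    )
    return StateDifferenceReport(
        labels=names_box["names"],
        observed=observed,
        p_values=p,
        q_values=q,
        significant=q < fdr_level,
        reference=ref,
        mode_rank=mode_rank,
        matched_rank_b=rank_b,
        matched_sign_b=sign_b,
        n_perm=n_perm,
        seed=seed,
        fdr_level=fdr_level,
    )


def binned_variogram(values: np.ndarray, coords: np.ndarray, n_bins: int = 25):
    """Isotropic binned semivariogram over all node pairs.

    Returns ``(bin_centers, gamma)`` where ``gamma[k]`` is half the mean
    squared value difference of node pairs whose distance falls in bin
    ``k``; empty bins give NaN.
    """
    values = np.asarray(values, dtype=float)
    d = pdist(np.asarray(coords, dtype=float))
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, d.max(), n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    gamma = np.full(n_bins, np.nan)
    for k in range(n_bins):
        mask = which == k
        if mask.any():
            gamma[k] = sq[mask].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, gamma


#: nugget-to-smooth amplitude ratios scanned when matching variograms
_NUGGET_RATIOS = np.concatenate([[0.0], np.geomspace(0.02, 2.0, 25)])


class _VariogramWorkspace:
    """Precomputed pair/bin structure for repeated variogram evaluation."""

    def __init__(self, coords: np.ndarray, n_bins: int):
        d = pdist(np.asarray(coords, dtype=float))
        edges = np.linspace(0.0, d.max(), n_bins + 1)
        self.which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
        self.counts = np.bincount(self.which, minlength=n_bins).astype(float)
        self.n_bins = n_bins
        n = coords.shape[0]
        self.rows, self.cols = np.triu_indices(n, k=1)

    def _bin_mean(self, pair_values: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.bincount(
                self.which, weights=pair_values, minlength=self.n_bins
            ) / np.where(self.counts > 0, self.counts, np.nan)

    def gamma(self, values: np.ndarray) -> np.ndarray:
        diff = values[self.rows] - values[self.cols]
        return self._bin_mean(0.5 * diff**2)

    def cross_gamma(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        du = u[self.rows] - u[self.cols]
        dv = v[self.rows] - v[self.cols]
        return self._bin_mean(0.5 * du * dv)


def variogram_surrogates(
    values: np.ndarray,
    coords: np.ndarray,
    n_surr: int,
    seed: int,
    n_bins: int = 25,
    n_scales: int = 12,
    resample: bool = False,
) -> np.ndarray:
    """Spatial-autocorrelation-preserving surrogate maps.

    Each surrogate permutes the map's values (destroying alignment with
    any other map), mixes a squared-exponential kernel smoothing of the
    permutation (length scale from a geometric grid) with a small
    unsmoothed "nugget" component, and applies the affine rescaling
    minimizing the squared error between the candidate's and the
    original map's binned variograms; the best (scale, nugget) pair
    wins.  With ``resample`` the surrogate's values are rank-remapped
    onto the original value multiset.  Returns shape ``(n_surr, N)``.
    """
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if x.std() == 0:
        raise UndefinedSimilarity("constant map has no variogram structure")
    rng = np.random.default_rng(seed)
    D = squareform(pdist(coords))
    pos = D[D > 0]
    scales = np.geomspace(np.percentile(pos, 2), D.max() / 2.0, n_scales)
    kernels = []
    for ell in scales:
        K = np.exp(-(D**2) / (2.0 * ell**2))
        kernels.append(K / K.sum(axis=1, keepdims=True))
    ws = _VariogramWorkspace(coords, n_bins)
    gamma_obs = ws.gamma(x)
    valid = np.isfinite(gamma_obs)
    sorted_x = np.sort(x)
    out = np.empty((n_surr, x.size))

    def standardize(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    ok0 = valid & (gamma_obs > 0)
    # relative-error metric, weighted by pair counts: a bin's empirical
    # variogram has sampling sd roughly gamma/sqrt(count)
    wt = ws.counts[ok0] / gamma_obs[ok0] ** 2
    g_o = gamma_obs[ok0]
    for b in range(n_surr):
        perm = rng.permutation(x)
        nug = standardize(perm)
        g_nug = ws.gamma(nug)[ok0]
        best, best_err = None, np.inf
        for K in kernels:
            sm = K @ perm
            if sm.std() == 0:
                continue
            sm = standardize(sm)
            g_sm = ws.gamma(sm)[ok0]
            g_x = ws.cross_gamma(sm, nug)[ok0]
            # the candidate a*(sm + t*nug) has binned variogram
            # a^2 * (g_sm + 2 t g_x + t^2 g_nug): fit a analytically for
            # each nugget ratio t and keep the best relative match
            for t in _NUGGET_RATIOS:
                g_c = g_sm + 2.0 * t * g_x + t * t * g_nug
                denom = np.sum(wt * g_c**2)
                if denom <= 0:
                    continue
                a2 = max(np.sum(wt * g_c * g_o) / denom, 0.0)
                err = np.sum(wt * (a2 * g_c - g_o) ** 2)
                if err < best_err:
                    best_err = err
                    a = np.sqrt(a2)
                    cand = sm + t * nug
                    best = a * cand + (x.mean() - a * cand.mean())
        if best is None:  # degenerate: fall back to the raw permutation
            best = perm
        if resample:
            best = sorted_x[np.argsort(np.argsort(best))]
        out[b] = best
    return out


def similarity_with_sa_surrogates(
    mode_map: np.ndarray,
    target_map: np.ndarray,
    coords: np.ndarray,
    n_surr: int = 500,
    seed: int = 0,
    resample: bool = False,
):
    """Spatial similarity with an autocorrelation-corrected permutation p.

    ``r`` is the Pearson correlation over nodes between the mode map and
    the target map; ``p`` is the two-sided add-one rank of |r| against
    the |r| of variogram-matched surrogates of the mode map correlated
    with the fixed target.
    """
    x = np.asarray(mode_map, dtype=float)
    y = np.asarray(target_map, dtype=float)
    if x.shape != y.shape:
        raise AlignmentError("maps have different lengths")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedSimilarity("constant map")
    r = float(np.corrcoef(x, y)[0, 1])
    surr = variogram_surrogates(x, coords, n_surr, seed, resample=resample)
    ys = (y - y.mean()) / y.std()
    cen = surr - surr.mean(axis=1, keepdims=True)
    sd = cen.std(axis=1)
    sd[sd == 0] = np.inf
    r_null = (cen / sd[:, None] * ys).mean(axis=1)
    p = float((1 + np.sum(np.abs(r_null) >= abs(r))) / (1 + n_surr))
    return r, p
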