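"""Leading-mode selection: scree elbow, mean-weight threshold, permutation test.

A basic mode is *leading* when it satisfies all three criteria:

(i)  it lies strictly before the elbow of the weight-vs-rank curve
     (Cattell's scree test, located with the Kneedle algorithm);
(ii) its weight exceeds the mean weight over all N possible modes, 1/N;
(iii) its weight is significantly larger than expected under a spatial
     null in which the node labels of every time column are shuffled
     independently, destroying spatial organization while preserving
     each column's value multiset (and hence the total variance).

The leading set is reported as the longest prefix of the weight ordering
passing all three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import EigenModeSet, EnsembleMatrix

__all__ = [
    "LeadingModeSelection",
    "find_elbow",
    "permutation_null_weights",
    "mode_p_value",
    "select_leading_modes",
]


@dataclass(frozen=True)
class ModeCriteria:
    """Criterion outcomes for one mode."""

    rank: int
    weight: float
    passes_elbow: bool
    passes_threshold: bool
    p_value: float
    is_leading: bool


@dataclass(frozen=True)
class LeadingModeSelection:
    """Outcome of the three-criterion leading-mode selection."""

    per_mode: tuple  # of ModeCriteria
    elbow_rank: int | None
    mean_threshold: float
    n_leading: int
    n_perm: int
    alpha: float
    seed: int
    prefix_weight_p: float  # significance of the leading modes' total weight

    def __post_init__(self):
        leading = [m.rank for m in self.per_mode if m.is_leading]
        if leading != list(range(1, self.n_leading + 1)):
            raise AssertionError("leading modes are not a prefix of the ordering")


def find_elbow(weights, n_top: int = 30, sensitivity: float = 1.0) -> int | None:
    """Locate the scree elbow of a descending weight curve (Kneedle).

    Runs the Kneedle knee-point detector for a convex decreasing curve
    on ranks ``1..n_top``: normalize to the unit square, flip to concave
    increasing, and find where the difference from the diagonal peaks,
    subject to the sensitivity threshold.  Returns the 1-based elbow
    rank, or ``None`` when the curve is flat (no elbow).  Modes strictly
    before the returned rank pass the scree criterion.
    """
    w = np.asarray(weights, dtype=float)[: int(n_top)]
    if w.size < 3:
        raise ValueError("need at least 3 weights to locate an elbow")
    if np.any(np.diff(w) > 1e-12):
        raise ValueError("weights must be non-increasing")
    if np.ptp(w) == 0:
        return None
    x = np.linspace(0.0, 1.0, w.size)
    y = (w - w.min()) / np.ptp(w)
    y_t = 1.0 - y  # convex decreasing -> concave increasing
    y_d = y_t - x
    # local maxima of the difference curve
    lmx = [
        i
        for i in range(1, w.size - 1)
        if y_d[i] >= y_d[i - 1] and y_d[i] >= y_d[i + 1]
    ]
    if not lmx:
        return None
    threshold_drop = sensitivity * np.mean(np.diff(x))
    for j, i in enumerate(lmx):
        threshold = y_d[i] - threshold_drop
        stop = lmx[j + 1] if j + 1 < len(lmx) else w.size
        if np.any(y_d[i + 1 : stop + 1] < threshold) or j == len(lmx) - 1:
            return i + 1  # 1-based rank
    return None


def _pipeline_weights(blocks, r: int) -> np.ndarray:
    """Weight spectrum of shuffled blocks after re-applying the
    pipeline normalization (row z-scoring, then unit total energy)."""
    zs = []
    for P in blocks:
        mean = P.mean(axis=1, keepdims=True)
        sd = P.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        zs.append((P - mean) / sd)
    Z = np.hstack(zs) if len(zs) > 1 else zs[0]
    sigma = np.linalg.svd(Z, compute_uv=False)
    w = sigma**2
    return w[:r] / w.sum()


def permutation_null_weights(
    ensemble: EnsembleMatrix,
    n_perm: int,
    seed: int,
    n_top: int | None = None,
    sessions=None,
) -> np.ndarray:
    """Null weight spectra under column-wise node-label shuffling.

    For each of ``n_perm`` instances the node entries of every time
    column are permuted independently, destroying spatial organization,
    and the instance is pushed through the same pipeline as the
    observed data — row z-scoring, unit-energy normalization, weight
    spectrum.  Re-applying the normalization matters: the observed
    ensemble has exactly unit-variance rows, and comparing it against
    shuffles that violate that constraint biases the null upward.

    When the original (pre-z-scoring) ``sessions`` are supplied the
    shuffle acts on the raw values, which makes the permutation
    distribution exactly exchangeable with the observed statistic for
    spatially unstructured data; otherwise the z-scored ensemble is
    shuffled, which is very slightly conservative.

    Returns an array of shape ``(n_perm, r)`` of descending weights
    (``r = n_top`` or full rank); each row sums to 1 over the full rank.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if sessions is not None:
        blocks = [np.asarray(s.values, dtype=float) for s in sessions]
    else:
        blocks = [ensemble.values]
    r = min(sum(b.shape[1] for b in blocks), blocks[0].shape[0])
    if n_top is not None:
        r = min(r, int(n_top))
    out = np.empty((n_perm, r))
    for b in range(n_perm):
        shuffled = [rng.permuted(B, axis=0) for B in blocks]
        out[b] = _pipeline_weights(shuffled, r)
    return out


def mode_p_value(observed_weight: float, null_weights) -> float:
    """Add-one permutation p-value: ``(1 + #{null >= obs}) / (1 + B)``.

    Ties count as exceedances; the estimator never returns zero.
    """
    null = np.asarray(null_weights, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null >= observed_weight)) / (1 + null.size))


def select_leading_modes(
    modeset: EigenModeSet,
    ensemble: EnsembleMatrix,
    alpha: float = 0.05,
    n_perm: int = 1000,
    n_top: int = 30,
    seed: int = 0,
    sensitivity: float = 1.0,
    sessions=None,
) -> LeadingModeSelection:
    """Apply the three leading-mode criteria and return the longest
    passing prefix.

    The permutation null is rank-matched: the observed weight of the
    mode at rank ``i`` is compared to the null distribution of rank-``i``
    weights.  Passing the raw ``sessions`` sharpens the null's
    calibration (see :func:`permutation_null_weights`).  In addition to the per-mode tests, the total weight of the
    selected prefix is tested against the matching prefix sums of the
    null spectra (``prefix_weight_p``); this aggregate test is an
    interpretation layered on the same null, not a selection criterion.
    """
    n_top = int(min(n_top, modeset.rank))
    weights = modeset.weights[:n_top]
    elbow = find_elbow(modeset.weights, n_top=n_top, sensitivity=sensitivity)
    threshold = 1.0 / modeset.modes.shape[0]
    null = permutation_null_weights(
        ensemble, n_perm=n_perm, seed=seed, n_top=n_top, sessions=sessions
    )
    per_mode = []
    n_leading = 0
    prefix_open = True
    for i, w in enumerate(weights, start=1):
        passes_elbow = elbow is not None and i < elbow
        passes_threshold = w > threshold
        p = mode_p_value(w, null[:, i - 1])
        leading = prefix_open and passes_elbow and passes_threshold and p < alpha
        if leading:
            n_leading += 1
        else:
            prefix_open = False
        per_mode.append(
            ModeCriteria(
                rank=i,
                weight=float(w),
                passes_elbow=passes_elbow,
                passes_threshold=passes_threshold,
                p_value=p,
                is_leading=leading,
            )
        )
    if n_leading > 0:
        obs_total = float(weights[:n_leading].sum())
        null_total = null[:, :n_leading].sum(axis=1)
        prefix_p = mode_p_value(obs_total, null_total)
    else:
        prefix_p = 1.0
    return LeadingModeSelection(
        per_mode=tuple(per_mode),
        elbow_rank=elbow,
        mean_threshold=threshold,
        n_leading=n_leading,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
        prefix_weight_p=prefix_p,
    )
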