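"""Ensemble matrix construction and eigen-microstate decomposition.

The central object of the analysis is the ensemble matrix ``A`` (nodes x
time): z-scored nodal time courses, concatenated over sessions and divided
by the root-sum-square of all elements (the dataset constant ``S``) so
that the squared singular values of ``A`` sum to one.  Each basic mode
(eigen-microstate) is ``E_i = sigma_i * u_i`` where ``u_i`` is the i-th
left singular vector; its weight ``w_i = sigma_i**2`` is the fraction of
ensemble variance it carries.  The right singular vectors ``v_i`` give the
per-time-point contribution of each mode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    AlignmentError,
    ContractError,
    NumericalError,
    ZeroVarianceNode,
)

__all__ = [
    "ActivityMatrix",
    "EnsembleMatrix",
    "EigenModeSet",
    "zscore_time_courses",
    "build_ensemble",
    "decompose",
    "mode_timecourse",
]


@dataclass(frozen=True)
class ActivityMatrix:
    """One session's node x time activity matrix.

    Parameters
    ----------
    values : ndarray, shape (n_nodes, n_timepoints)
        Activity amplitudes (arbitrary units).
    node_ids : tuple of str
        Ordered node identifiers; row ``i`` of ``values`` belongs to
        ``node_ids[i]``.
    zscored : bool
        Whether each row has been standardized over time.
    ddof : int
        Delta degrees of freedom used when standardizing (1 = sample
        standard deviation, which makes node-pair inner products divided
        by ``M - 1`` equal Pearson correlation exactly).
    label : str
        Free-form provenance tag, e.g. ``"sub-03/run-1"``.
    """

    values: np.ndarray
    node_ids: tuple
    zscored: bool = False
    ddof: int = 1
    label: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ContractError("activity matrix must be 2-D (nodes x time)")
        if not np.all(np.isfinite(values)):
            raise NumericalError("activity matrix contains non-finite values")
        object.__setattr__(self, "values", values)
        node_ids = tuple(str(n) for n in self.node_ids)
        if len(node_ids) != values.shape[0]:
            raise AlignmentError(
                f"{len(node_ids)} node ids for {values.shape[0]} rows"
            )
        if len(set(node_ids)) != len(node_ids):
            raise AlignmentError("duplicate node ids")
        object.__setattr__(self, "node_ids", node_ids)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EnsembleMatrix:
    """Concatenated, S-normalized ensemble matrix.

    ``values`` is the z-scored concatenation divided by ``S`` (the
    root-sum-square of the un-normalized concatenation), so the sum of
    its squared elements is exactly one.  ``segment_index`` maps each
    block of time columns back to the session it came from as
    ``(label, start, stop)`` tuples.
    """

    values: np.ndarray
    S: float
    node_ids: tuple
    segment_index: tuple = ()

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EigenModeSet:
    """Result of the eigen-microstate decomposition.

    Attributes
    ----------
    modes : ndarray, shape (n_nodes, rank)
        Basic modes; column ``i`` is ``E_i = sigma_i * u_i``.
    singular_values : ndarray, shape (rank,)
        Singular values of the normalized ensemble, descending.
    weights : ndarray, shape (rank,)
        ``sigma_i**2``; sums to 1 at full rank.
    temporal_coeffs : ndarray, shape (rank, n_timepoints)
        Right singular vectors (rows); ``temporal_coeffs[i, t]`` is the
        contribution of the microstate at time ``t`` to mode ``i``.
    S : float
        Normalization constant carried from the ensemble.
    M : int
        Number of time points of the ensemble.
    node_ids : tuple of str
    """

    modes: np.ndarray
    singular_values: np.ndarray
    weights: np.ndarray
    temporal_coeffs: np.ndarray
    S: float
    M: int
    node_ids: tuple

    @property
    def rank(self) -> int:
        return self.modes.shape[1]

    def unit_modes(self) -> np.ndarray:
        """Left singular vectors ``u_i = E_i / sigma_i`` (unit norm)."""
        sigma = np.where(self.singular_values > 0, self.singular_values, 1.0)
        return self.modes / sigma


def zscore_time_courses(matrix: ActivityMatrix) -> ActivityMatrix:
    """Standardize each node's time course to zero mean, unit variance.

    Uses the sample (``ddof``) standard deviation so that downstream
    functional connectivity equals Pearson correlation exactly.

    Raises
    ------
    ZeroVarianceNode
        If any node's time course is constant, naming the node.
    """
    X = matrix.values
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=matrix.ddof, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ZeroVarianceNode(matrix.node_ids[flat[0]])
    return replace(matrix, values=(X - mean) / sd, zscored=True)


def build_ensemble(sessions) -> EnsembleMatrix:
    """Concatenate z-scored sessions and normalize by root-sum-square S.

    All sessions must share the same node ids in the same order and must
    already be z-scored.  ``S`` is computed on the concatenated matrix;
    the stored values are divided by it so their squared sum is one.
    """
    sessions = list(sessions)
    if not sessions:
        raise ContractError("no sessions given")
    ref = sessions[0].node_ids
    for s in sessions:
        if not s.zscored:
            raise ContractError(
                f"session {s.label!r} is not z-scored; call zscore_time_courses first"
            )
        if s.node_ids != ref:
            raise AlignmentError(
                f"session {s.label!r} node ids do not match the first session"
            )
    concat = np.hstack([s.values for s in sessions])
    S = float(np.sqrt(np.sum(concat**2)))
    if S == 0:
        raise NumericalError("ensemble is identically zero")
    segments = []
    start = 0
    for s in sessions:
        stop = start + s.n_timepoints
        segments.append((s.label, start, stop))
        start = stop
    return EnsembleMatrix(
        values=concat / S, S=S, node_ids=ref, segment_index=tuple(segments)
    )


def _fix_signs(U, Vt):
    """Deterministic sign convention: the largest-|.| element of each
    left singular vector is made positive; ties break to the lowest node
    index (argmax returns the first maximum)."""
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    return U * flip, Vt * flip[:, None]


def decompose(ensemble: EnsembleMatrix, rank: int | None = None) -> EigenModeSet:
    """Economy-size SVD of the normalized ensemble.

    Returns modes ordered by descending singular value under the
    deterministic sign convention.  ``rank`` truncates the retained
    modes (default: full ``min(N, M)``); weights are always those of the
    retained modes.
    """
    A = ensemble.values
    if not np.all(np.isfinite(A)):
        raise NumericalError("ensemble contains non-finite values")
    U, sigma, Vt = np.linalg.svd(A, full_matrices=False)
    U, Vt = _fix_signs(U, Vt)
    if rank is not None:
        if not 0 < rank <= sigma.size:
            raise IndexError(f"rank {rank} outside 1..{sigma.size}")
        U, sigma, Vt = U[:, :rank], sigma[:rank], Vt[:rank]
    return EigenModeSet(
        modes=U * sigma,
        singular_values=sigma,
        weights=sigma**2,
        temporal_coeffs=Vt,
        S=ensemble.S,
        M=ensemble.n_timepoints,
        node_ids=ensemble.node_ids,
    )


def mode_timecourse(modeset: EigenModeSet, i: int) -> np.ndarray:
    """Temporal coefficient series of mode ``i`` (1-based rank).

    The returned length-M vector is the i-th right singular vector; its
    entries quantify how much the microstate at each time point
    contributes to the mode.  Unit Euclidean norm.
    """
    if not 1 <= i <= modeset.rank:
        raise IndexError(f"mode rank {i} outside 1..{modeset.rank}")
    return modeset.temporal_coeffs[i - 1]
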