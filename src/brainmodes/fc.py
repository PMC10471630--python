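"""Functional connectivity: original, mode-wise, and low-rank reconstructed.

On z-scored data with sample scaling, the FC between nodes i and j,
``FC_ij = (1/(M-1)) * sum_t A_it A_jt``, is exactly the Pearson
correlation of their time courses.  Substituting the eigen-microstate
decomposition turns FC into a superposition of rank-1 mode coactivation
patterns, ``FC_ij = (S^2/(M-1)) * sum_k E_ik E_jk``, where the ``S^2``
factor undoes the root-sum-square normalization applied before the SVD.
Truncating the sum at k modes gives the reconstructed FC; at full rank
the identity is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import ActivityMatrix, EigenModeSet
from .errors import AlignmentError, ContractError, UndefinedSimilarity

__all__ = [
    "FCMatrix",
    "compute_fc",
    "reconstruct_fc",
    "mode_coactivation",
    "fc_similarity",
]


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric N x N connectivity matrix with provenance tag.

    ``kind`` is ``"original"``, ``"reconstructed(k)"`` or
    ``"coactivation(k)"``.
    """

    values: np.ndarray
    node_ids: tuple
    kind: str = "original"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ContractError("FC matrix must be square")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ContractError("FC matrix must be symmetric")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def compute_fc(session: ActivityMatrix) -> FCMatrix:
    """Original FC: ``A A^T / (M - 1)`` on a z-scored session.

    Equals the Pearson correlation matrix of the node time courses.
    """
    if not session.zscored:
        raise ContractError("compute_fc requires a z-scored session")
    if session.n_timepoints < 3:
        raise ContractError("need at least 3 time points for FC")
    M = session.n_timepoints
    fc = session.values @ session.values.T / (M - 1)
    return FCMatrix(values=fc, node_ids=session.node_ids, kind="original")


def reconstruct_fc(modeset: EigenModeSet, k: int) -> FCMatrix:
    """FC reconstructed from the first ``k`` basic modes.

    ``FC = (S^2/(M-1)) * sum_{k'<=k} E_k' E_k'^T``; ``k = 0`` gives the
    zero matrix and ``k = rank`` reproduces the original FC of the
    underlying concatenated data exactly.
    """
    if not 0 <= k <= modeset.rank:
        raise IndexError(f"k={k} outside 0..{modeset.rank}")
    E = modeset.modes[:, :k]
    scale = modeset.S**2 / (modeset.M - 1)
    fc = scale * (E @ E.T) if k > 0 else np.zeros((modeset.modes.shape[0],) * 2)
    return FCMatrix(values=fc, node_ids=modeset.node_ids, kind=f"reconstructed({k})")


def mode_coactivation(modeset: EigenModeSet, k: int) -> FCMatrix:
    """Rank-1 coactivation pattern of mode ``k`` (1-based).

    ``(S^2/(M-1)) * E_k E_k^T`` — mode k's additive contribution to FC.
    """
    if not 1 <= k <= modeset.rank:
        raise IndexError(f"mode rank {k} outside 1..{modeset.rank}")
    e = modeset.modes[:, k - 1]
    scale = modeset.S**2 / (modeset.M - 1)
    return FCMatrix(
        values=scale * np.outer(e, e),
        node_ids=modeset.node_ids,
        kind=f"coactivation({k})",
    )


def fc_similarity(a: FCMatrix, b: FCMatrix) -> float:
    """Pearson correlation across strictly-lower-triangle entries.

    The diagonal is excluded: original FC diagonals are constant 1 and
    would contribute no variance.
    """
    if a.node_ids != b.node_ids:
        raise AlignmentError("FC matrices are over different node sets")
    n = a.n_nodes
    if n < 3:
        raise ContractError("similarity needs at least 3 nodes")
    rows, cols = np.tril_indices(n, k=-1)
    x = a.values[rows, cols]
    y = b.values[rows, cols]
    if x.std() == 0 or y.std() == 0:
        raise UndefinedSimilarity("an FC lower triangle has zero variance")
    return float(np.corrcoef(x, y)[0, 1])
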