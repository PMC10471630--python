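"""scikit-learn-compatible estimator facade over the functional core.

`EigenMicrostates` is a decomposition in the sklearn sense: ``fit(X)``
on a time x node matrix learns the basic modes; ``transform`` projects
new data onto them; ``inverse_transform`` reconstructs.  Both follow
sklearn conventions (``get_params``/``set_params``, trailing-underscore
fitted attributes, ``check_array`` validation) and compose with
pipelines and model selection.

Note the axis convention: sklearn's rows are samples, so ``X`` here is
``(n_timepoints, n_nodes)`` — the transpose of the node x time matrices
used by the functional API.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .decomposition import ActivityMatrix, build_ensemble, decompose, zscore_time_courses
from .selection import select_leading_modes

__all__ = ["EigenMicrostates", "LeadingModeSelector"]


class EigenMicrostates(TransformerMixin, BaseEstimator):
    """Eigen-microstate decomposition of multivariate time series.

    Parameters
    ----------
    n_modes : int or None
        Number of basic modes to keep (None = full rank).
    zscore : bool
        Standardize each node's time course before decomposing
        (default True; set False when the input is already z-scored).

    Attributes
    ----------
    components_ : ndarray, shape (n_modes, n_nodes)
        Basic modes ``E_i = sigma_i u_i`` (rows, sklearn convention).
    singular_values_ : ndarray
    weights_ : ndarray
        ``sigma_i**2``, fractions of ensemble variance (sum to 1 at
        full rank).
    normalization_ : float
        Root-sum-square constant S of the fitted ensemble.
    temporal_coeffs_ : ndarray, shape (n_modes, n_timepoints)
        Right singular vectors of the fitted ensemble.
    """

    def __init__(self, n_modes=None, zscore=True):
        self.n_modes = n_modes
        self.zscore = zscore

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        session = ActivityMatrix(
            values=X.T,
            node_ids=[f"n{j}" for j in range(X.shape[1])],
            zscored=not self.zscore,
        )
        if self.zscore:
            session = zscore_time_courses(session)
        ensemble = build_ensemble([session])
        modeset = decompose(ensemble, rank=self.n_modes)
        self.modeset_ = modeset
        self.components_ = modeset.modes.T
        self.singular_values_ = modeset.singular_values
        self.weights_ = modeset.weights
        self.normalization_ = modeset.S
        self.temporal_coeffs_ = modeset.temporal_coeffs
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Project time points onto the unit modes ``u_i``."""
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        U = self.modeset_.unit_modes()
        return X @ U

    def inverse_transform(self, Xt):
        check_is_fitted(self, "components_")
        Xt = check_array(Xt, dtype=float)
        return Xt @ self.modeset_.unit_modes().T


class LeadingModeSelector(BaseEstimator):
    """Fit the decomposition and select the leading basic modes.

    Applies the three-criterion rule (scree elbow, mean-weight
    threshold 1/N, rank-matched permutation significance) to a
    time x node matrix.

    Attributes
    ----------
    n_leading_ : int
    elbow_rank_ : int or None
    p_values_ : ndarray
    selection_ : LeadingModeSelection
        The full per-mode criterion table.
    """

    def __init__(self, alpha=0.05, n_perm=200, n_top=30, seed=0, zscore=True):
        self.alpha = alpha
        self.n_perm = n_perm
        self.n_top = n_top
        self.seed = seed
        self.zscore = zscore

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        session = ActivityMatrix(
            values=X.T,
            node_ids=[f"n{j}" for j in range(X.shape[1])],
            zscored=not self.zscore,
        )
        if self.zscore:
            session = zscore_time_courses(session)
        ensemble = build_ensemble([session])
        modeset = decompose(ensemble)
        selection = select_leading_modes(
            modeset,
            ensemble,
            alpha=self.alpha,
            n_perm=self.n_perm,
            n_top=self.n_top,
            seed=self.seed,
        )
        self.modeset_ = modeset
        self.selection_ = selection
        self.n_leading_ = selection.n_leading
        self.elbow_rank_ = selection.elbow_rank
        self.p_values_ = np.array([m.p_value for m in selection.per_mode])
        self.leading_modes_ = modeset.modes[:, : selection.n_leading].T
        self.n_features_in_ = X.shape[1]
        return self
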