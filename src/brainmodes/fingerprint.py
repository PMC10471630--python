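"""Connectome fingerprinting: how individual-specific are FC matrices?

Given per-subject FC matrices from two runs, the similarity table holds
the FC similarity of every subject's run-1 matrix with every subject's
run-2 matrix.  Identification is correct when a subject's most similar
run-2 matrix is their own; differential identifiability summarizes the
margin as ``I_diff = (I_self - I_others) * 100``, the gap between mean
intra- and inter-subject similarity in percentage points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .decomposition import build_ensemble, decompose, zscore_time_courses
from .errors import AlignmentError, ContractError
from .fc import compute_fc, fc_similarity, reconstruct_fc

__all__ = [
    "IdentifiabilityReport",
    "similarity_matrix",
    "identification_accuracy",
    "differential_identifiability",
    "intra_inter_by_k",
    "session_fc",
    "session_modes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Fingerprinting summary for one similarity table.

    ``accuracy`` is the run1->run2 identification rate;
    ``accuracy_reverse`` queries in the other direction;
    ``accuracy_mean`` averages the two.  ``per_subject`` holds
    ``(intra_similarity, mean_inter_similarity)`` pairs.
    """

    per_subject: tuple
    accuracy: float
    accuracy_reverse: float
    accuracy_mean: float
    I_self: float
    I_others: float
    I_diff: float


def similarity_matrix(run1_fcs, run2_fcs) -> np.ndarray:
    """Cross-run FC similarity table: entry (i, j) compares subject i's
    run-1 FC with subject j's run-2 FC."""
    run1_fcs, run2_fcs = list(run1_fcs), list(run2_fcs)
    if len(run1_fcs) != len(run2_fcs):
        raise AlignmentError("runs have different numbers of subjects")
    n = len(run1_fcs)
    table = np.empty((n, n))
    for i, a in enumerate(run1_fcs):
        for j, b in enumerate(run2_fcs):
            table[i, j] = fc_similarity(a, b)
    return table


def identification_accuracy(table: np.ndarray) -> float:
    """Fraction of subjects whose own run-2 FC is their best match.

    Exact ties at the argmax are counted incorrect (they indicate a
    degenerate configuration) and logged.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ContractError("similarity table must be square")
    n = table.shape[0]
    correct = 0
    for i in range(n):
        row = table[i]
        best = row.max()
        winners = np.flatnonzero(row == best)
        if winners.size > 1:
            logger.warning("tie at argmax for subject %d; counted incorrect", i)
            continue
        if winners[0] == i:
            correct += 1
    return correct / n


def differential_identifiability(table: np.ndarray):
    """``(I_self, I_others, I_diff)`` of a similarity table.

    ``I_self`` is the mean diagonal (intra-subject) similarity,
    ``I_others`` the mean off-diagonal similarity, and
    ``I_diff = (I_self - I_others) * 100``.
    """
    table = np.asarray(table, dtype=float)
    n = table.shape[0]
    if table.ndim != 2 or table.shape[1] != n:
        raise ContractError("similarity table must be square")
    if n < 2:
        raise ContractError("need at least 2 subjects")
    i_self = float(np.mean(np.diag(table)))
    off = ~np.eye(n, dtype=bool)
    i_others = float(np.mean(table[off]))
    return i_self, i_others, (i_self - i_others) * 100.0


def report(table: np.ndarray) -> IdentifiabilityReport:
    """Full fingerprinting report for one similarity table."""
    i_self, i_others, i_diff = differential_identifiability(table)
    n = table.shape[0]
    off = ~np.eye(n, dtype=bool)
    per_subject = tuple(
        (float(table[i, i]), float(np.mean(table[i][off[i]])))
        for i in range(n)
    )
    acc = identification_accuracy(table)
    acc_rev = identification_accuracy(table.T)
    return IdentifiabilityReport(
        per_subject=per_subject,
        accuracy=acc,
        accuracy_reverse=acc_rev,
        accuracy_mean=(acc + acc_rev) / 2.0,
        I_self=i_self,
        I_others=i_others,
        I_diff=i_diff,
    )


def session_fc(session) -> "FCMatrix":
    """Original FC of one raw session (z-scores internally)."""
    return compute_fc(zscore_time_courses(session))


def session_modes(session):
    """Individual-level mode set from a single session."""
    z = zscore_time_courses(session)
    return decompose(build_ensemble([z]))


def intra_inter_by_k(run1_sessions, run2_sessions, k_grid):
    """Fingerprinting summaries of reconstructed FC across mode counts.

    For each k in ``k_grid``, reconstructs every subject-run FC from its
    individual-level mode set truncated at k modes, builds the cross-run
    similarity table, and tabulates mean intra-subject similarity, mean
    inter-subject similarity, identification accuracy (run1->run2), and
    I_diff.  Returns a dict ``k -> (intra, inter, accuracy, I_diff)``.
    """
    run1_sessions, run2_sessions = list(run1_sessions), list(run2_sessions)
    if len(run1_sessions) != len(run2_sessions):
        raise AlignmentError("runs have different numbers of subjects")
    modes1 = [session_modes(s) for s in run1_sessions]
    modes2 = [session_modes(s) for s in run2_sessions]
    out = {}
    for k in k_grid:
        k = int(k)
        for idx, ms in enumerate(modes1 + modes2):
            if k > ms.rank:
                raise IndexError(
                    f"k={k} exceeds rank {ms.rank} of subject "
                    f"{idx % len(modes1)}"
                )
        fcs1 = [reconstruct_fc(ms, k) for ms in modes1]
        fcs2 = [reconstruct_fc(ms, k) for ms in modes2]
        table = similarity_matrix(fcs1, fcs2)
        i_self, i_others, i_diff = differential_identifiability(table)
        out[k] = (i_self, i_others, identification_accuracy(table), i_diff)
    return out
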