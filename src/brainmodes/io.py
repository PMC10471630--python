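"""File formats, configuration, and the end-to-end pipeline driver.

All matrices travel as TSV with a node-id header column (human-diffable
and language-neutral); every written artifact gets a JSON provenance
sidecar recording parameters and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fingerprint as fp
from .decomposition import (
    ActivityMatrix,
    build_ensemble,
    decompose,
    zscore_time_courses,
)
from .errors import ConfigError, ParseError
from .fc import compute_fc, fc_similarity, reconstruct_fc
from .selection import select_leading_modes
from .simulate import (
    CohortManifest,
    generate_basis,
    generate_cohort,
    generate_two_state,
)
from .states import (
    SystemPartition,
    amplitude_difference_test,
    coactivation_difference_test,
)

__all__ = [
    "RunConfig",
    "read_session",
    "write_session",
    "read_partition",
    "write_partition",
    "read_coords",
    "write_coords",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: repr round-trip float format for TSV output
FLOAT_FORMAT = "%.17g"


def read_session(path) -> ActivityMatrix:
    """Read a nodes x time TSV (first column = node ids) as a session."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser types
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate node id {dup!r}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[
            [not np.issubdtype(t, np.number) for t in df.dtypes]
        ][0]
        raise ParseError(f"{path}: non-numeric values in column {bad!r}")
    return ActivityMatrix(
        values=values, node_ids=tuple(map(str, df.index)), label=path.stem
    )


def write_session(session: ActivityMatrix, path) -> None:
    """Write a session as TSV with repr round-trip precision."""
    df = pd.DataFrame(
        session.values,
        index=list(session.node_ids),
        columns=[f"t{j}" for j in range(session.n_timepoints)],
    )
    df.index.name = "node_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_partition(path) -> SystemPartition:
    """Read a node-to-system table (columns: node_id, system)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"node_id", "system"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns node_id, system")
    if df["node_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate node id")
    return SystemPartition(labels=tuple(df["system"]))


def write_partition(node_ids, labels, path) -> None:
    pd.DataFrame({"node_id": list(node_ids), "system": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_coords(path) -> np.ndarray:
    """Read node coordinates (columns: node_id, x, y, z)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if not cols:
        raise ParseError(f"{path}: expected coordinate columns x, y, z")
    return df[cols].to_numpy(dtype=float)


def write_coords(node_ids, coords, path) -> None:
    coords = np.asarray(coords)
    df = pd.DataFrame(coords, columns=["x", "y", "z"][: coords.shape[1]])
    df.insert(0, "node_id", list(node_ids))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end synthetic run.

    Every stochastic stage derives its seed from ``seed``; the config
    round-trips through JSON losslessly.
    """

    out_dir: str = "brainmodes-out"
    n_nodes: int = 100
    k_modes: int = 5
    n_subjects: int = 20
    n_runs: int = 2
    n_timepoints: int = 300
    noise_sd: float = 0.2
    subject_effect: float = 0.3
    state_effect: float = 0.0
    smoothness: float = 10.0
    alpha: float = 0.05
    n_perm: int = 200
    n_top: int = 30
    k_grid: tuple = (1, 2, 3, 4, 5)
    fdr_level: float = 0.05
    compare_states: bool = False
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        if "k_grid" in data:
            data["k_grid"] = tuple(data["k_grid"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sidecar(path: Path, payload: dict) -> None:
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(payload, indent=2, default=str)
    )


def write_modes(modeset, path, k: int | None = None) -> None:
    """Write basic modes as a nodes x modes TSV plus a JSON sidecar."""
    k = modeset.rank if k is None else k
    df = pd.DataFrame(
        modeset.modes[:, :k],
        index=list(modeset.node_ids),
        columns=[f"mode{i + 1}" for i in range(k)],
    )
    df.index.name = "node_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    _sidecar(
        Path(path),
        {
            "S": modeset.S,
            "M": modeset.M,
            "rank": modeset.rank,
            "weights": modeset.weights[:k].tolist(),
        },
    )


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a cohort and run every analysis stage, writing artifacts.

    Stages: simulate -> z-score -> ensemble -> decompose -> select ->
    FC-reconstruction sweep -> fingerprint -> (optional) compare-states.
    Returns the key scalars of each stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(config.seed)
    s_basis, s_cohort, s_select, s_states = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng.spawn(4)
    )

    logger.info("stage simulate: N=%d K=%d", config.n_nodes, config.k_modes)
    basis = generate_basis(
        config.n_nodes, config.k_modes, smoothness=config.smoothness, seed=s_basis
    )
    manifest = CohortManifest(
        n_subjects=config.n_subjects,
        n_runs=config.n_runs,
        n_timepoints=config.n_timepoints,
        noise_sd=config.noise_sd,
        subject_effect=config.subject_effect,
        state_effect=config.state_effect,
        seed=s_cohort,
    )
    cohort = generate_cohort(basis, manifest)
    write_partition(basis.node_ids, basis.partition, out / "partition.tsv")
    write_coords(basis.node_ids, basis.coords, out / "coords.tsv")
    for (s, r), sess in sorted(cohort.sessions.items()):
        write_session(sess, out / f"sub-{s:03d}_run-{r + 1}.tsv")

    zsessions = [
        zscore_time_courses(cohort.sessions[key])
        for key in sorted(cohort.sessions)
    ]
    ensemble = build_ensemble(zsessions)
    modeset = decompose(ensemble)
    logger.info("stage decompose: S=%.4f rank=%d", ensemble.S, modeset.rank)
    write_modes(modeset, out / "modes.tsv", k=min(config.n_top, modeset.rank))

    raw_sessions = [cohort.sessions[key] for key in sorted(cohort.sessions)]
    selection = select_leading_modes(
        modeset,
        ensemble,
        alpha=config.alpha,
        n_perm=config.n_perm,
        n_top=config.n_top,
        seed=s_select,
        sessions=raw_sessions,
    )
    logger.info("stage select: n_leading=%d", selection.n_leading)
    sel_rows = [dataclasses.asdict(m) for m in selection.per_mode]
    pd.DataFrame(sel_rows).to_csv(out / "selection.tsv", sep="\t", index=False)
    _sidecar(
        out / "selection.tsv",
        {
            "elbow_rank": selection.elbow_rank,
            "n_leading": selection.n_leading,
            "prefix_weight_p": selection.prefix_weight_p,
            "n_perm": selection.n_perm,
            "seed": selection.seed,
        },
    )

    original_fc = compute_fc(
        ActivityMatrix(
            values=np.hstack([z.values for z in zsessions]),
            node_ids=zsessions[0].node_ids,
            zscored=True,
        )
    )
    sweep = []
    for k in config.k_grid:
        rec = reconstruct_fc(modeset, int(k))
        sweep.append((int(k), fc_similarity(rec, original_fc)))
    pd.DataFrame(sweep, columns=["k", "similarity"]).to_csv(
        out / "fc_reconstruction.tsv", sep="\t", index=False
    )

    results = {
        "S": ensemble.S,
        "rank": modeset.rank,
        "n_leading": selection.n_leading,
        "fc_similarity_by_k": dict(sweep),
    }

    if config.n_runs >= 2:
        run1 = [fp.session_fc(s) for s in cohort.runs(0)]
        run2 = [fp.session_fc(s) for s in cohort.runs(1)]
        table = fp.similarity_matrix(run1, run2)
        rep = fp.report(table)
        pd.DataFrame(table).to_csv(out / "similarity_table.tsv", sep="\t")
        _sidecar(
            out / "similarity_table.tsv",
            {
                "accuracy": rep.accuracy,
                "accuracy_reverse": rep.accuracy_reverse,
                "I_diff": rep.I_diff,
            },
        )
        logger.info(
            "stage fingerprint: accuracy=%.3f I_diff=%.2f", rep.accuracy, rep.I_diff
        )
        results["accuracy"] = rep.accuracy
        results["I_diff"] = rep.I_diff

    if config.compare_states:
        if config.state_effect is None:
            raise ConfigError("compare_states requires state_effect")
        two = generate_two_state(basis, manifest)
        sess_a = [two.state_a.sessions[(s, 0)] for s in range(config.n_subjects)]
        sess_b = [two.state_b.sessions[(s, 0)] for s in range(config.n_subjects)]
        amp = amplitude_difference_test(
            sess_a, sess_b, mode_rank=1, n_perm=config.n_perm, seed=s_states,
            fdr_level=config.fdr_level,
        )
        partition = SystemPartition(labels=basis.partition)
        coact = coactivation_difference_test(
            sess_a, sess_b, mode_rank=1, partition=partition,
            n_perm=config.n_perm, seed=s_states, fdr_level=config.fdr_level,
        )
        pd.DataFrame(
            {
                "node_id": amp.labels,
                "observed": amp.observed,
                "p": amp.p_values,
                "q": amp.q_values,
                "significant": amp.significant,
            }
        ).to_csv(out / "state_amplitude_diff.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "pair": coact.labels,
                "observed": coact.observed,
                "p": coact.p_values,
                "q": coact.q_values,
                "significant": coact.significant,
            }
        ).to_csv(out / "state_coactivation_diff.tsv", sep="\t", index=False)
        results["n_significant_nodes"] = int(amp.significant.sum())
        results["n_significant_pairs"] = int(coact.significant.sum())

    (out / "run_config.json").write_text(config.to_json())
    (out / "results.json").write_text(json.dumps(results, indent=2, default=float))
    return results
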