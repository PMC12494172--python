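"""End-to-end study pipeline: gaze -> phenotype -> connectivity -> CPM.

Operates on in-memory study objects (typically from
:mod:`gazecpm.synthetic`); the file-based driver in :mod:`gazecpm.io`
wraps these functions for CLI use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectivity as _connectivity_module  # noqa: F401
from .connectivity import (
    ConnectivityMatrix,
    RunData,
    clean_timecourses,
    connectivity,
    edge_index,
    exclude_run,
    flag_spikes,
)
from . import cpm as cpm_mod
from . import gaze as gz
from . import phenotype as ph
from .synthetic import SyntheticStudy

__all__ = [
    "GazeParams",
    "participant_phenotypes",
    "run_connectivity",
    "run_cpm",
    "run_study",
    "planted_edge_vector_indices",
]


@dataclass
class GazeParams:
    velocity_threshold: float = gz.DEFAULT_VELOCITY_THRESHOLD
    min_fixation_ms: float = gz.DEFAULT_MIN_FIXATION_MS
    window_ms: float = gz.DEFAULT_WINDOW_MS
    qc_threshold: float = gz.DEFAULT_QC_THRESHOLD
    keep_per_cs_type: int = gz.DEFAULT_KEEP_PER_CS_TYPE
    min_trials_for_slope: int = 24


def participant_phenotypes(
    study: SyntheticStudy,
    params: GazeParams | None = None,
) -> pd.DataFrame:
    """Gaze QC, I-VT classification, trial summaries and ST/GT slopes.

    Returns one row per participant with gaze-sample quality, QC status,
    the CS-value regression slope of the gaze index, and group labels
    (assigned over QC-passing participants only).
    """
    p = params or GazeParams()
    rows = []
    for i, (sched, stream) in enumerate(zip(study.schedules, study.gaze)):
        quality = gz.gaze_sample_quality(stream)
        row: dict = {
            "participant": study.covariates["participant"].iloc[i],
            "gaze_quality": quality,
            "qc_pass": quality >= p.qc_threshold,
            "stgt_slope": np.nan,
            "intercept": np.nan,
            "n_trials_used": 0,
        }
        if row["qc_pass"]:
            fixations = gz.classify_fixations(
                stream, p.velocity_threshold, p.min_fixation_ms
            )
            summaries = gz.summarize_trials(sched, fixations, study.config.layout, p.window_ms)
            kept = gz.apply_exclusions(summaries, p.keep_per_cs_type)
            res = ph.stgt_coefficient(
                np.array([s.trial.cs_value for s in kept]),
                np.array([s.gaze_index for s in kept]),
                min_trials=p.min_trials_for_slope,
            )
            row.update(
                stgt_slope=res.stgt_slope,
                intercept=res.intercept,
                n_trials_used=res.n_trials_used,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df["group"] = "excluded"
    ok = df["qc_pass"] & df["stgt_slope"].notna()
    if ok.sum() >= 5:
        df.loc[ok, "group"] = ph.assign_groups(df.loc[ok, "stgt_slope"].to_numpy())
    return df


def run_connectivity(
    study: SyntheticStudy,
    run_label: str,
    drop_nodes: tuple[int, ...] = (),
) -> tuple[list[ConnectivityMatrix | None], pd.DataFrame]:
    """Clean and correlate every participant's run; apply motion exclusion.

    Returns (matrices, qc table); an excluded run's entry is None.
    """
    mats: list[ConnectivityMatrix | None] = []
    qc_rows = []
    for i, (X, confounds) in enumerate(study.runs[run_label]):
        run = RunData(timecourses=X, confounds=confounds, run_label=run_label)
        flags = flag_spikes(run.fd)
        excluded = exclude_run(flags)
        qc_rows.append(
            {
                "participant": study.covariates["participant"].iloc[i],
                "run": run_label,
                "spike_fraction": float(flags.mean()),
                "excluded": excluded,
            }
        )
        if excluded:
            mats.append(None)
            continue
        cleaned = clean_timecourses(run, flags)
        mats.append(
            connectivity(
                cleaned,
                drop_nodes=drop_nodes,
                n_volumes_used=int(len(flags) - flags.sum()),
            )
        )
    return mats, pd.DataFrame(qc_rows)


def run_cpm(
    matrices: list[ConnectivityMatrix | None],
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    config: cpm_mod.CPMConfig,
    with_permutations: bool = True,
) -> tuple[cpm_mod.CPMResult, np.ndarray]:
    """CPM over subjects that passed gaze QC and run exclusion.

    Returns (result, included-subject index array into the study order).
    """
    ok = (
        phenotypes["qc_pass"].to_numpy()
        & phenotypes["stgt_slope"].notna().to_numpy()
        & np.array([m is not None for m in matrices])
    )
    idx = np.flatnonzero(ok)
    if len(idx) < 10:
        raise ValueError(f"only {len(idx)} usable subjects; LOOCV needs >= 10")
    X = cpm_mod.stack_matrices([matrices[i] for i in idx])
    y = phenotypes["stgt_slope"].to_numpy(dtype=float)[idx]
    C = covariates.iloc[idx][list(config.covariates)].to_numpy(dtype=float)
    result = cpm_mod.loocv_predict(X, y, C, config)
    if with_permutations:
        result = cpm_mod.permutation_test(X, y, C, config, result=result)
    return result, idx


def planted_edge_vector_indices(edges: tuple[tuple[int, int], ...], n_nodes: int) -> np.ndarray:
    """Vector-order indices of node-pair edges (strict upper triangle, row-major)."""
    iu, ju = edge_index(n_nodes)
    lookup = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(iu, ju))}
    return np.array([lookup[(min(i, j), max(i, j))] for i, j in edges], dtype=int)


def run_study(
    study: SyntheticStudy,
    cpm_config: cpm_mod.CPMConfig,
    gaze_params: GazeParams | None = None,
    run_labels: tuple[str, ...] | None = None,
    with_permutations: bool = True,
) -> dict:
    """Complete analysis bundle for a (synthetic) study.

    Runs gaze phenotyping, the adjusted WHR/BMI association models, and a
    CPM per run label; reports planted-edge recall against the study's
    ground truth.
    """
    phen = participant_phenotypes(study, gaze_params)
    merged = phen.merge(study.covariates, on="participant")
    bundle: dict = {"phenotypes": phen, "cpm": {}}

    fit_df = merged[merged["qc_pass"] & merged["stgt_slope"].notna()]
    for adip in ("whr", "bmi"):
        try:
            bundle[f"{adip}_model"] = ph.adiposity_model(fit_df, predictor=adip)
        except ValueError as e:  # pragma: no cover - tiny studies only
            warnings.warn(f"{adip} model skipped: {e}", stacklevel=2)

    planted_idx = planted_edge_vector_indices(study.truth.true_edges, study.config.n_nodes)
    for label in run_labels or study.config.run_labels:
        mats, qc = run_connectivity(study, label)
        result, idx = run_cpm(mats, phen, study.covariates, cpm_config, with_permutations)
        recall = (
            len(np.intersect1d(result.consensus["pos"], planted_idx)) / len(planted_idx)
            if len(planted_idx)
            else float("nan")
        )
        bundle["cpm"][label] = {
            "result": result,
            "run_qc": qc,
            "included_subjects": idx,
            "planted_edge_recall": recall,
        }
    return bundle
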