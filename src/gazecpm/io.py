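"""File formats, configuration, and the file-based pipeline driver.

All tabular artifacts are delimited text with headers (gaze streams and
event logs as TSV, covariates and phenotypes as CSV, timecourses/confounds
and connectivity matrices as TSV); matrices additionally get a compact
``.npy`` binary sidecar for fast reloading. A JSON manifest records the
seed, parameter echo and every exclusion decision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import ConnectivityMatrix, edge_index
from . import cpm as cpm_mod
from .gaze import AOILayout, AOIRect, GazeStream, TrialRecord
from .pipeline import GazeParams, run_study
from .synthetic import StudyConfig, SyntheticStudy, TRIAL_TIMING_MS, simulate_study

__all__ = [
    "read_gaze_table",
    "write_gaze_table",
    "read_events",
    "write_events",
    "read_matrix",
    "write_matrix",
    "write_study",
    "load_study",
    "PipelineConfig",
    "load_config",
    "run_pipeline",
]

GAZE_COLUMNS = ["timestamp_ms", "x_deg", "y_deg", "valid"]
EVENT_COLUMNS = ["onset", "duration", "trial_type", "cs_value", "orientation", "shaping"]


def write_gaze_table(stream: GazeStream, path: Path | str) -> None:
    pd.DataFrame(
        {
            "timestamp_ms": stream.t,
            "x_deg": stream.x,
            "y_deg": stream.y,
            "valid": stream.valid.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gaze_table(path: Path | str) -> GazeStream:
    """Read a tab-separated gaze stream; validates columns and monotone time."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty gaze table")
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in GAZE_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise ValueError(f"{path}: unparseable value in row {int(bad.idxmax()) + 2}")
    t = df["timestamp_ms"].to_numpy(dtype=float)
    if len(t) > 1:
        nonmono = np.flatnonzero(np.diff(t) <= 0)
        if nonmono.size:
            raise ValueError(f"{path}: non-monotone timestamp at row {int(nonmono[0]) + 3}")
    return GazeStream(
        t=t,
        x=df["x_deg"].to_numpy(dtype=float),
        y=df["y_deg"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy().astype(bool),
    )


def write_events(schedule: list[TrialRecord], path: Path | str) -> None:
    """Write a trial log as a BIDS-events-like TSV (onset/duration in s)."""
    pd.DataFrame(
        {
            "onset": [tr.cs_onset / 1000.0 for tr in schedule],
            "duration": [(tr.cs_offset - tr.cs_onset) / 1000.0 for tr in schedule],
            "trial_type": [f"cs{tr.cs_type}" for tr in schedule],
            "cs_value": [tr.cs_value for tr in schedule],
            "orientation": [tr.orientation for tr in schedule],
            "shaping": [int(tr.shaping) for tr in schedule],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path: Path | str) -> list[TrialRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for k, row in enumerate(df.itertuples(index=False), start=1):
        onset_ms = float(row.onset) * 1000.0
        records.append(
            TrialRecord(
                index=k,
                cs_type=int(str(row.trial_type).lstrip("cs")),
                cs_value=float(row.cs_value),
                cs_onset=onset_ms,
                cs_offset=onset_ms + float(row.duration) * 1000.0,
                orientation=str(row.orientation),
                shaping=bool(row.shaping),
            )
        )
    return records


def write_matrix(mat: ConnectivityMatrix, path: Path | str) -> None:
    """TSV with node ids as header plus a .npy binary sidecar."""
    path = Path(path)
    pd.DataFrame(mat.z, columns=[str(i) for i in mat.node_ids]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    np.save(path.with_suffix(".npy"), mat.z)


def read_matrix(path: Path | str, n_volumes_used: int = 0) -> ConnectivityMatrix:
    path = Path(path)
    sidecar = path.with_suffix(".npy")
    if sidecar.exists():
        z = np.load(sidecar)
        node_ids = pd.read_csv(path, sep="\t", nrows=0).columns.astype(int).to_numpy()
    else:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        z = df.to_numpy(dtype=float)
        node_ids = df.columns.astype(int).to_numpy()
    return ConnectivityMatrix(z=z, node_ids=node_ids, n_volumes_used=n_volumes_used)


def write_study(study: SyntheticStudy, out_dir: Path | str) -> Path:
    """Serialize a simulated study (all text formats + ground-truth JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.covariates.to_csv(out / "covariates.csv", index=False)
    for i in range(study.config.n_participants):
        pid = study.covariates["participant"].iloc[i]
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        write_gaze_table(study.gaze[i], pdir / "gaze.tsv")
        write_events(study.schedules[i], pdir / "events.tsv")
        for label, runs in study.runs.items():
            X, confounds = runs[i]
            pd.DataFrame(X, columns=[f"node_{k}" for k in range(X.shape[1])]).to_csv(
                pdir / f"timecourses_{label}.tsv", sep="\t", index=False, float_format="%.17g"
            )
            confounds.to_csv(pdir / f"confounds_{label}.tsv", sep="\t", index=False, float_format="%.17g")
    truth = {
        "theta": study.truth.theta.tolist(),
        "true_edges": [list(e) for e in study.truth.true_edges],
        "true_whr_slope": study.truth.true_whr_slope,
        "seed": study.config.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    cfg = asdict(study.config)
    cfg["layout"] = {
        "cs": asdict(study.config.layout.cs),
        "ucs": asdict(study.config.layout.ucs),
    }
    (out / "study_config.yaml").write_text(yaml.safe_dump(cfg))
    return out


def _config_from_dict(d: dict) -> StudyConfig:
    d = dict(d)
    layout = d.pop("layout", None)
    if isinstance(layout, dict):
        d["layout"] = AOILayout(cs=AOIRect(**layout["cs"]), ucs=AOIRect(**layout["ucs"]))
    for key in ("cs_values", "run_labels", "planted_runs", "bout_ms"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if d.get("planted_edges") is not None:
        d["planted_edges"] = tuple(tuple(e) for e in d["planted_edges"])
    return StudyConfig(**d)


def load_study(study_dir: Path | str) -> SyntheticStudy:
    """Reload a serialized study from disk (regenerates nothing)."""
    from .gaze import GazeStream  # noqa: F401 (type reference)
    from .synthetic import GroundTruth

    d = Path(study_dir)
    cfg = _config_from_dict(yaml.safe_load((d / "study_config.yaml").read_text()))
    covariates = pd.read_csv(d / "covariates.csv")
    truth_d = json.loads((d / "ground_truth.json").read_text())
    truth = GroundTruth(
        theta=np.asarray(truth_d["theta"], dtype=float),
        true_edges=tuple(tuple(e) for e in truth_d["true_edges"]),
        true_whr_slope=float(truth_d["true_whr_slope"]),
    )
    gaze, schedules = [], []
    runs: dict[str, list] = {label: [] for label in cfg.run_labels}
    for pid in covariates["participant"]:
        pdir = d / pid
        gaze.append(read_gaze_table(pdir / "gaze.tsv"))
        schedules.append(read_events(pdir / "events.tsv"))
        for label in cfg.run_labels:
            X = pd.read_csv(pdir / f"timecourses_{label}.tsv", sep="\t", float_precision="round_trip").to_numpy(dtype=float)
            confounds = pd.read_csv(pdir / f"confounds_{label}.tsv", sep="\t", float_precision="round_trip")
            runs[label].append((X, confounds))
    return SyntheticStudy(
        config=cfg, truth=truth, schedules=schedules, gaze=gaze,
        covariates=covariates, runs=runs,
    )


@dataclass
class PipelineConfig:
    """Root configuration for the file-based pipeline."""

    study_dir: str
    out_dir: str
    gaze: GazeParams = field(default_factory=GazeParams)
    cpm: cpm_mod.CPMConfig = field(default_factory=cpm_mod.CPMConfig)
    run_labels: tuple[str, ...] | None = None
    seed: int = 0


def load_config(path: Path | str) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text())
    gaze = GazeParams(**d.pop("gaze", {}))
    cpm_d = d.pop("cpm", {})
    if "covariates" in cpm_d:
        cpm_d["covariates"] = tuple(cpm_d["covariates"])
    cpm = cpm_mod.CPMConfig(**cpm_d)
    if d.get("run_labels") is not None:
        d["run_labels"] = tuple(d["run_labels"])
    return PipelineConfig(gaze=gaze, cpm=cpm, **d)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain on a serialized study and write all outputs.

    Writes the phenotype CSV, association-model tables, per-run CPM
    results (consensus edge lists, degree tables, pair-count matrix,
    accuracy/permutation JSON) and a manifest with one terminal status per
    participant.
    """
    study = load_study(config.study_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle = run_study(
        study, config.cpm, gaze_params=config.gaze, run_labels=config.run_labels
    )
    phen = bundle["phenotypes"]
    phen.to_csv(out / "phenotypes.csv", index=False)
    stats: dict = {}
    for adip in ("whr", "bmi"):
        fit = bundle.get(f"{adip}_model")
        if fit is not None:
            fit.as_frame().to_csv(out / f"model_{adip}.csv", index=False)
            stats[f"{adip}_model"] = {
                "r_squared": fit.r_squared,
                "adj_r_squared": fit.adj_r_squared,
                "n": fit.n,
            }

    atlas = cpm_mod.CanonicalAtlas.blocks(study.config.n_nodes)
    manifest_participants = {}
    for _, row in phen.iterrows():
        if not row["qc_pass"]:
            status = "excluded:gaze_quality"
        elif not np.isfinite(row["stgt_slope"]):
            status = "excluded:no_slope"
        else:
            status = "completed"
        manifest_participants[row["participant"]] = {
            "status": status,
            "gaze_quality": float(row["gaze_quality"]),
        }

    cpm_json: dict = {}
    for label, res_d in bundle["cpm"].items():
        result = res_d["result"]
        iu, ju = edge_index(study.config.n_nodes)
        for sign in ("pos", "neg"):
            sel = result.consensus[sign]
            pd.DataFrame(
                {"node_i": iu[sel], "node_j": ju[sel], "sign": sign}
            ).to_csv(out / f"consensus_{label}_{sign}.csv", index=False)
        nodes, pair = cpm_mod.degree_summary(
            result.consensus["pos"], study.config.n_nodes, atlas
        )
        nodes.to_csv(out / f"degrees_{label}_pos.csv", index=False)
        pair.to_csv(out / f"paircounts_{label}_pos.tsv", sep="\t")
        res_d["run_qc"].to_csv(out / f"run_qc_{label}.csv", index=False)
        cpm_json[label] = {
            "accuracy": result.accuracy,
            "permutation_p": result.permutation_p,
            "n_subjects": result.n_subjects,
            "consensus_edges_pos": int(len(result.consensus["pos"])),
            "consensus_edges_neg": int(len(result.consensus["neg"])),
            "planted_edge_recall": res_d["planted_edge_recall"],
        }
        for _, qrow in res_d["run_qc"].iterrows():
            if qrow["excluded"]:
                entry = manifest_participants[qrow["participant"]]
                if entry["status"] == "completed":
                    entry["status"] = f"excluded:motion_{label}"

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "gaze_params": asdict(config.gaze),
        "cpm_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config.cpm).items()
        },
        "participants": manifest_participants,
        "cpm": cpm_json,
        "stats": stats,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
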