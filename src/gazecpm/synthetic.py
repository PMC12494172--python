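"""Synthetic study generator with known ground truth.

Emulates a food Pavlovian conditioning study: each participant carries a
latent sign-tracking propensity theta (standard normal scaled by
``propensity_sd``). Theta drives (i) how strongly gaze is attracted to the
reward-predicting CS image in the late window of CS presentation, via a
logistic allocation probability; (ii) waist-to-hip ratio, via a linear
coupling; and (iii) functional coupling on a planted set of node pairs in
the simulated fMRI node timecourses. Every downstream stage of the
pipeline (I-VT filtering, phenotyping, connectivity, CPM) can therefore be
validated against recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .gaze import AOILayout, DEFAULT_LAYOUT, GazeStream, TrialRecord

__all__ = [
    "StudyConfig",
    "GroundTruth",
    "SyntheticStudy",
    "TRIAL_TIMING_MS",
    "gen_trial_schedule",
    "gen_gaze_session",
    "gen_covariates",
    "gen_run_timecourses",
    "simulate_study",
    "default_planted_edges",
]

# Per-trial event timing (ms): fixation cross, CS image, double fixation
# cross, reward delivery (UCS), inter-trial interval.
TRIAL_TIMING_MS = {
    "fixation": 1500.0,
    "cs": 3000.0,
    "double_fixation": 1500.0,
    "ucs": 3000.0,
    "iti": 7500.0,
}
TRIAL_LEN_MS = sum(TRIAL_TIMING_MS.values())  # 16.5 s

SAMPLE_DT_MS = 20.0  # 50 Hz tracker

CONFOUND_MOTION = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
CONFOUND_COLUMNS = (
    CONFOUND_MOTION
    + [f"d_{c}" for c in CONFOUND_MOTION]
    + ["global_signal", "csf", "white_matter", "framewise_displacement"]
)


def default_planted_edges(n_nodes: int, n_edges: int = 10, spacing: int | None = None) -> list[tuple[int, int]]:
    """Evenly spread node pairs spanning different factor blocks.

    Pairs (i, j) with j - i = n_nodes // 2 sit in different latent-factor
    blocks, so their baseline correlation is near zero and the planted
    coupling dominates.
    """
    half = n_nodes // 2
    edges = [(i, i + half) for i in range(min(n_edges, half))]
    return edges


@dataclass
class StudyConfig:
    """Parameters of a simulated study.

    The defaults mirror the task design: 4 CS types with reward values
    (2, 1, 0, 0), 16 experimental trials per type in pseudorandomized
    blocks of four, orientation switch after 32 experimental trials, 50 Hz
    gaze sampling, 220-node parcellation.
    """

    n_participants: int = 47
    n_nodes: int = 220
    n_volumes: int = 200
    trial_counts: int = 16
    cs_values: tuple[float, ...] = (2.0, 1.0, 0.0, 0.0)
    propensity_sd: float = 1.0
    whr_slope: float = 0.05
    whr_intercept: float = 0.865
    whr_noise_sd: float = 0.04
    planted_edges: tuple[tuple[int, int], ...] | None = None
    planted_effect: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0
    # gaze generator
    cs_attract_slope: float = 1.5  # logistic scale of theta -> P(fixate CS)
    blink_rate_hz: float = 0.15
    bout_ms: tuple[float, float] = (200.0, 400.0)
    jitter_deg: float = 0.12
    layout: AOILayout = field(default_factory=lambda: DEFAULT_LAYOUT)
    # timecourse generator
    n_factors: int = 10
    fd_spike_fraction: float = 0.05
    run_labels: tuple[str, ...] = ("sweet", "savory")
    planted_runs: tuple[str, ...] = ("sweet",)

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_nodes, self.n_volumes, self.trial_counts) <= 0:
            raise ValueError("counts must be positive")
        vals = np.asarray(self.cs_values, dtype=float)
        if not ((vals == 0).any() and (vals > 0).any()):
            raise ValueError("cs_values needs at least one zero and one positive value")
        if self.planted_edges is None:
            self.planted_edges = tuple(default_planted_edges(self.n_nodes))
        seen = set()
        for i, j in self.planted_edges:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes) or i == j:
                raise ValueError(f"invalid planted edge ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate planted edge ({i}, {j})")
            seen.add(key)

    @property
    def n_cs_types(self) -> int:
        return len(self.cs_values)


@dataclass
class GroundTruth:
    """Latent quantities of a simulated study, kept for recovery checks."""

    theta: np.ndarray  # latent sign-tracking propensity per participant
    true_edges: tuple[tuple[int, int], ...]
    true_whr_slope: float


@dataclass
class SyntheticStudy:
    config: StudyConfig
    truth: GroundTruth
    schedules: list[list[TrialRecord]]  # per participant
    gaze: list[GazeStream]  # per participant
    covariates: pd.DataFrame
    # runs[label][participant] = (timecourses T×N, confounds DataFrame)
    runs: dict[str, list[tuple[np.ndarray, pd.DataFrame]]]


def gen_trial_schedule(config: StudyConfig, rng: np.random.Generator | None = None) -> list[TrialRecord]:
    """Build one session's trial sequence.

    8 shaping trials present the CS types first in descending then
    ascending reward-value order; 16 blocks of 4 experimental trials
    follow, each block a permutation of the 4 CS types so every pairing
    appears once per block. The screen/dispenser orientation switches from
    CS-left to CS-right after experimental trial 32.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    k = config.n_cs_types
    order_desc = list(np.argsort(-np.asarray(config.cs_values), kind="stable") + 1)
    shaping_types = order_desc + order_desc[::-1]
    exp_types: list[int] = []
    for _ in range(config.trial_counts):
        exp_types.extend(rng.permutation(k) + 1)

    records: list[TrialRecord] = []
    t = 0.0
    switch_at = (config.trial_counts * k) // 2  # experimental trial after which orientation flips
    for idx, cs_type in enumerate(shaping_types + exp_types, start=1):
        shaping = idx <= len(shaping_types)
        exp_idx = idx - len(shaping_types)
        orientation = "CS-left" if (shaping or exp_idx <= switch_at) else "CS-right"
        cs_onset = t + TRIAL_TIMING_MS["fixation"]
        records.append(
            TrialRecord(
                index=idx,
                cs_type=int(cs_type),
                cs_value=float(config.cs_values[cs_type - 1]),
                cs_onset=cs_onset,
                cs_offset=cs_onset + TRIAL_TIMING_MS["cs"],
                orientation=orientation,
                shaping=shaping,
            )
        )
        t += TRIAL_LEN_MS
    return records


def _aoi_centers(layout: AOILayout, orientation: str) -> dict[str, tuple[float, float]]:
    lay = layout.oriented(orientation)
    return {
        "CS": ((lay.cs.x0 + lay.cs.x1) / 2, (lay.cs.y0 + lay.cs.y1) / 2),
        "UCS": ((lay.ucs.x0 + lay.ucs.x1) / 2, (lay.ucs.y0 + lay.ucs.y1) / 2),
        "BG": (0.0, 0.0),
    }


def gen_gaze_session(
    schedule: Sequence[TrialRecord],
    theta: float,
    layout: AOILayout,
    seed: int | np.random.SeedSequence,
    config: StudyConfig | None = None,
) -> GazeStream:
    """Simulate a 50 Hz gaze stream for one session.

    During the late half of each CS presentation gaze alternates between
    fixation bouts whose AOI is drawn from a categorical distribution: on
    rewarding trials P(CS) = logistic(cs_attract_slope * theta) with the
    remainder split toward the reward location; on zero-value trials gaze
    favors the UCS/background regardless of theta. Outside that window
    gaze rests near screen center (plus a brief orienting response at CS
    onset). Bout changes produce saccadic jumps well above the I-VT
    velocity threshold; blinks appear as invalid-sample runs of 60-200 ms
    at Poisson times.
    """
    cfg = config if config is not None else StudyConfig()
    rng = np.random.default_rng(seed)
    session_end = schedule[-1].cs_onset - TRIAL_TIMING_MS["fixation"] + TRIAL_LEN_MS
    t = np.arange(0.0, session_end, SAMPLE_DT_MS)
    n = len(t)
    tx = np.zeros(n)
    ty = np.zeros(n)

    def _slice(t0: float, t1: float) -> slice:
        # samples with t0 <= t < t1 on the uniform 20 ms grid
        return slice(
            min(n, max(0, int(np.ceil(t0 / SAMPLE_DT_MS)))),
            min(n, max(0, int(np.ceil(t1 / SAMPLE_DT_MS)))),
        )

    p_cs_reward = float(expit(cfg.cs_attract_slope * theta))
    aoi_names = ("CS", "UCS", "BG")
    for tr in schedule:
        centers = _aoi_centers(layout, tr.orientation)
        # orienting response: first half of CS presentation on the CS image
        half = (tr.cs_onset + tr.cs_offset) / 2.0
        sel = _slice(tr.cs_onset, half)
        tx[sel], ty[sel] = centers["CS"]
        # late window: theta-driven allocation in fixation bouts
        pos = half
        while pos < tr.cs_offset:
            dur = rng.uniform(*cfg.bout_ms)
            if tr.cs_value > 0:
                p = np.array([p_cs_reward, (1 - p_cs_reward) * 0.7, (1 - p_cs_reward) * 0.3])
            else:
                p = np.array([0.05, 0.55, 0.40])
            aoi = aoi_names[rng.choice(3, p=p / p.sum())]
            sel = _slice(pos, min(pos + dur, tr.cs_offset))
            cx, cy = centers[aoi]
            tx[sel], ty[sel] = cx, cy
            pos += dur

    x = tx + rng.normal(0.0, cfg.jitter_deg, n)
    y = ty + rng.normal(0.0, cfg.jitter_deg, n)

    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(cfg.blink_rate_hz * session_end / 1000.0)
    starts = rng.uniform(0, session_end, n_blinks)
    durs = rng.uniform(60.0, 200.0, n_blinks)
    for s, d in zip(starts, durs):
        valid[_slice(s, s + d)] = False

    return GazeStream(t=t, x=x, y=y, valid=valid)


def gen_covariates(
    config: StudyConfig,
    truth: GroundTruth,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """One covariate row per participant.

    WHR is linearly coupled to the latent propensity
    (``whr_intercept + whr_slope * theta + noise``); the remaining
    covariates (age, sex, pre-task hunger, BMI, scanner, run order) are
    independent draws with marginals typical of a young-adult sample.
    """
    rng = np.random.default_rng(seed)
    n = config.n_participants
    theta = truth.theta
    whr = config.whr_intercept + config.whr_slope * theta + rng.normal(0, config.whr_noise_sd, n)
    df = pd.DataFrame(
        {
            "participant": [f"sub-{i + 1:03d}" for i in range(n)],
            "age": np.round(rng.uniform(18, 41, n), 1),
            "sex": rng.integers(0, 2, n),  # 1 = female
            "hunger": np.round(rng.uniform(0, 100, n), 1),
            "whr": np.round(whr, 4),
            "bmi": np.round(rng.normal(25.2, 3.6, n).clip(18.5, 40), 1),
            "scanner": rng.integers(0, 2, n),
            "run_order": rng.integers(0, 2, n),  # 1 = sweet first
        }
    )
    return df


def gen_run_timecourses(
    config: StudyConfig,
    truth: GroundTruth,
    participant: int,
    seed: int | np.random.SeedSequence,
    planted: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one run's node-timecourse matrix and confound table.

    Timecourses follow a latent-factor model: nodes are grouped into
    ``n_factors`` contiguous blocks mimicking canonical-network structure,
    each node loading mostly on its block factor plus observation noise.
    For every planted edge (i, j), node j additionally receives a copy of
    node i's standardized series with weight
    ``planted_effect * standardized(theta)``, so the (i, j) correlation
    increases monotonically with the participant's propensity. Confounds
    comprise 6 motion parameters (random walks), their derivatives,
    global/CSF/white-matter signals and framewise displacement with a
    configurable fraction of FD > 0.5 spike volumes; small motion and
    linear-drift components leak into the node signals so confound
    regression has real work to do.
    """
    rng = np.random.default_rng(seed)
    T, N, k = config.n_volumes, config.n_nodes, config.n_factors
    blocks = np.minimum((np.arange(N) * k) // N, k - 1)
    loadings = rng.normal(0, 0.1, (N, k))
    loadings[np.arange(N), blocks] += 0.8
    factors = rng.normal(0, 1, (T, k))
    X = factors @ loadings.T + rng.normal(0, config.noise_sd, (T, N))

    theta_std = (truth.theta[participant] - np.mean(truth.theta)) / (np.std(truth.theta) + 1e-12)
    if planted and config.planted_effect != 0:
        w = config.planted_effect * theta_std
        for i, j in truth.true_edges:
            xi = X[:, i]
            xi = (xi - xi.mean()) / (xi.std() + 1e-12)
            X[:, j] = X[:, j] + w * xi

    motion = np.cumsum(rng.normal(0, 0.02, (T, 6)), axis=0)
    deriv = np.vstack([np.zeros(6), np.diff(motion, axis=0)])
    fd = np.abs(deriv).sum(axis=1)
    fd = 0.4 * fd / (fd.max() + 1e-12)  # sub-threshold baseline
    n_spikes = int(round(config.fd_spike_fraction * T))
    if n_spikes:
        spikes = rng.choice(T, n_spikes, replace=False)
        fd[spikes] = 0.5 + rng.exponential(0.3, n_spikes)

    # mild contamination of node signals by motion and scanner drift
    drift = np.linspace(-1, 1, T)
    X = X + 0.3 * np.outer(drift, rng.normal(0, 1, N)) + 0.2 * motion[:, [0]] * rng.normal(0, 1, N)

    conf = pd.DataFrame(
        np.column_stack(
            [
                motion,
                deriv,
                X.mean(axis=1) + rng.normal(0, 0.05, T),
                rng.normal(0, 1, T),
                rng.normal(0, 1, T),
                fd,
            ]
        ),
        columns=CONFOUND_COLUMNS,
    )
    return X, conf


def simulate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a complete study: schedules, gaze, covariates, timecourses.

    All randomness flows from ``config.seed`` through spawned seed
    sequences, so identical configs give identical studies. The planted
    connectivity effect is applied only to runs listed in
    ``config.planted_runs`` (the remaining run labels act as null runs).
    """
    root = np.random.SeedSequence(config.seed)
    ss_theta, ss_cov, ss_sched, ss_gaze, ss_runs = root.spawn(5)
    rng = np.random.default_rng(ss_theta)
    theta = rng.normal(0, config.propensity_sd, config.n_participants)
    truth = GroundTruth(
        theta=theta,
        true_edges=tuple(config.planted_edges),
        true_whr_slope=config.whr_slope,
    )

    sched_seeds = ss_sched.spawn(config.n_participants)
    gaze_seeds = ss_gaze.spawn(config.n_participants)
    schedules = [
        gen_trial_schedule(config, np.random.default_rng(s)) for s in sched_seeds
    ]
    gaze = [
        gen_gaze_session(schedules[i], theta[i], config.layout, gaze_seeds[i], config)
        for i in range(config.n_participants)
    ]
    covariates = gen_covariates(config, truth, ss_cov)

    runs: dict[str, list[tuple[np.ndarray, pd.DataFrame]]] = {}
    run_seeds = ss_runs.spawn(len(config.run_labels) * config.n_participants)
    for r, label in enumerate(config.run_labels):
        planted = label in config.planted_runs
        runs[label] = [
            gen_run_timecourses(
                config, truth, i, run_seeds[r * config.n_participants + i], planted=planted
            )
            for i in range(config.n_participants)
        ]
    return SyntheticStudy(
        config=config,
        truth=truth,
        schedules=schedules,
        gaze=gaze,
        covariates=covariates,
        runs=runs,
    )
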