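"""Connectome-based predictive modeling (CPM).

Given per-subject Fisher-z connectivity matrices and a behavioral target
(the sign-/goal-tracking slope), CPM runs leave-one-out cross-validation:
in each training fold every edge is correlated with behavior by partial
Spearman rank correlation (controlling for covariates such as age, sex,
run order, pre-scan hunger, WHR and scanner), edges with |rho| above a
threshold form positive and negative networks, each training subject's
summed strength over a network feeds a univariate linear model of
behavior, and the held-out subject's strength yields their prediction.
Prediction accuracy is the Spearman correlation of predicted vs observed
behavior; significance comes from permuting behavior against the matrices
and re-running the whole pipeline.

Edges are indexed in the package's fixed order: 0-based node indices,
strict upper triangle, row-major.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .connectivity import ConnectivityMatrix, edge_index

__all__ = [
    "CPMConfig",
    "CPMResult",
    "CanonicalAtlas",
    "CANONICAL_NETWORKS",
    "partial_spearman",
    "select_edges",
    "network_strength",
    "loocv_predict",
    "permutation_test",
    "consensus_network",
    "degree_summary",
    "top_nodes",
    "stack_matrices",
]

CANONICAL_NETWORKS = ("MF", "FP", "DMN", "Mot", "VI", "VII", "VAs", "SAL", "SC", "CBL")


@dataclass
class CPMConfig:
    """Tunable parameters of the CPM pipeline."""

    selection_threshold: float = 0.3
    covariates: tuple[str, ...] = ("age", "sex", "run_order", "hunger", "whr", "scanner")
    n_permutations: int = 10_000
    consensus_fraction: float = 0.90
    seed: int = 0
    add_one_smoothing: bool = False
    permute_covariates: bool = False  # Freedman-Lane-style option

    def __post_init__(self) -> None:
        if not (0 < self.selection_threshold < 1):
            raise ValueError("selection_threshold must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.consensus_fraction <= 1):
            raise ValueError("consensus_fraction must be in (0, 1]")


@dataclass
class CanonicalAtlas:
    """Node -> canonical-network label (one of the ten reference networks)."""

    labels: np.ndarray  # length n_nodes, entries in CANONICAL_NETWORKS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        unknown = set(self.labels) - set(CANONICAL_NETWORKS)
        if unknown:
            raise ValueError(f"unknown network labels: {sorted(unknown)}")

    @classmethod
    def blocks(cls, n_nodes: int) -> "CanonicalAtlas":
        """Contiguous-block assignment (matches the synthetic factor blocks)."""
        k = len(CANONICAL_NETWORKS)
        blocks = np.minimum((np.arange(n_nodes) * k) // n_nodes, k - 1)
        return cls(labels=np.asarray(CANONICAL_NETWORKS, dtype=object)[blocks])


@dataclass
class CPMResult:
    """Everything LOOCV produces, per network sign ('pos'/'neg')."""

    fold_edges: dict[str, list[np.ndarray]]
    strengths: dict[str, np.ndarray]  # held-out strength per subject
    predictions: dict[str, np.ndarray]
    observed: np.ndarray
    accuracy: dict[str, float]
    consensus: dict[str, np.ndarray]  # edge indices
    consensus_fraction: float
    n_subjects: int
    n_edges: int
    permutation_p: dict[str, float] = field(default_factory=dict)
    null_accuracy: dict[str, np.ndarray] = field(default_factory=dict)


def _residualize(M: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, M, rcond=None)
    return M - design @ beta


def partial_spearman(
    edge: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """Partial Spearman rank correlation of one edge with behavior.

    Edge values and behavior are rank-transformed (average ranks for
    ties), each is residualized on the covariate design (plus intercept;
    covariates enter unranked, categoricals should arrive
    indicator-coded), and the residuals are Pearson-correlated. With no
    covariates this reduces to the plain Spearman rho.
    """
    e = np.asarray(edge, dtype=float)
    b = np.asarray(behavior, dtype=float)
    if np.ptp(e) == 0 or np.ptp(b) == 0:
        raise ValueError("rho undefined for a constant edge or behavior vector")
    n = len(e)
    D = np.ones((n, 1))
    if covariates is not None and np.size(covariates) > 0:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if n < C.shape[1] + 3:
            raise ValueError("too few subjects for the covariate design")
        D = np.column_stack([D, C])
    re = _residualize(rankdata(e), D)
    rb = _residualize(rankdata(b), D)
    denom = np.linalg.norm(re) * np.linalg.norm(rb)
    if denom == 0:
        raise ValueError("rho undefined: residuals have zero variance")
    return float(re @ rb / denom)


def select_edges(rho: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Strict-threshold split into positive and negative edge sets."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.flatnonzero(rho > threshold), np.flatnonzero(rho < -threshold)


def network_strength(matrix: ConnectivityMatrix | np.ndarray, edges: np.ndarray) -> float:
    """Summed Fisher-z connectivity over an edge set.

    ``matrix`` may be a ConnectivityMatrix or an already-vectorized edge
    array in the fixed edge order.
    """
    vec = matrix.edges() if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)
    edges = np.asarray(edges, dtype=int)
    if edges.size and edges.max() >= len(vec):
        raise ValueError("edge index out of range (dropped node?)")
    return float(vec[edges].sum())


def stack_matrices(matrices: list[ConnectivityMatrix]) -> np.ndarray:
    """Subjects x edges array of Fisher-z values in the fixed edge order."""
    n_nodes = matrices[0].n_nodes
    if any(m.n_nodes != n_nodes for m in matrices):
        raise ValueError("all matrices must share the node set")
    return np.vstack([m.edges() for m in matrices])


class _FoldCache:
    """Per-fold quantities that do not depend on the behavior vector.

    Edge ranks and their covariate residuals are fixed given matrices and
    covariates, so the permutation test can reuse them; only the behavior
    ranks are re-residualized per permutation. This is algebraically
    identical to re-running the full pipeline for every permutation.
    """

    def __init__(self, X: np.ndarray, covariates: np.ndarray | None):
        n = X.shape[0]
        self.n = n
        self.train_idx: list[np.ndarray] = []
        self.designs: list[np.ndarray] = []
        self.edge_resid: list[np.ndarray] = []
        self.edge_norm: list[np.ndarray] = []
        all_idx = np.arange(n)
        for i in range(n):
            tr = np.delete(all_idx, i)
            D = np.ones((n - 1, 1))
            if covariates is not None and np.size(covariates) > 0:
                D = np.column_stack([D, covariates[tr]])
            R = rankdata(X[tr], axis=0)
            Rr = _residualize(R, D)
            norms = np.linalg.norm(Rr, axis=0)
            self.train_idx.append(tr)
            self.designs.append(D)
            self.edge_resid.append(Rr)
            self.edge_norm.append(norms)

    def fold_rho(self, fold: int, behavior: np.ndarray) -> np.ndarray:
        tr = self.train_idx[fold]
        rb = _residualize(rankdata(behavior[tr]), self.designs[fold])
        nb = np.linalg.norm(rb)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = (self.edge_resid[fold].T @ rb) / (self.edge_norm[fold] * nb)
        return rho


def _loocv(
    cache: _FoldCache,
    X: np.ndarray,
    behavior: np.ndarray,
    threshold: float,
    collect_edges: bool = False,
    warn_empty: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, list[np.ndarray]]]:
    """One full LOOCV pass; returns per-sign predictions and fold edge sets."""
    n = cache.n
    preds = {"pos": np.empty(n), "neg": np.empty(n)}
    strengths = {"pos": np.empty(n), "neg": np.empty(n)}
    fold_edges: dict[str, list[np.ndarray]] = {"pos": [], "neg": []}
    for i in range(n):
        tr = cache.train_idx[i]
        rho = cache.fold_rho(i, behavior)
        pos, neg = select_edges(rho, threshold)
        if collect_edges:
            fold_edges["pos"].append(pos)
            fold_edges["neg"].append(neg)
        yb = behavior[tr]
        for sign, sel in (("pos", pos), ("neg", neg)):
            s_test = X[i, sel].sum()
            strengths[sign][i] = s_test
            if sel.size == 0:
                if warn_empty:
                    warnings.warn(
                        f"fold {i}: empty {sign} edge set; predicting training mean",
                        stacklevel=3,
                    )
                preds[sign][i] = yb.mean()
                continue
            s_train = X[tr][:, sel].sum(axis=1)
            sm_, ym_ = s_train.mean(), yb.mean()
            var = np.dot(s_train - sm_, s_train - sm_)
            if var == 0:
                preds[sign][i] = ym_
                continue
            b1 = np.dot(s_train - sm_, yb - ym_) / var
            preds[sign][i] = ym_ + b1 * (s_test - sm_)
    return {"pred": preds, "strength": strengths}, fold_edges


def _spearman_accuracy(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return float("nan")
    return float(spearmanr(pred, obs).statistic)


def loocv_predict(
    matrices: list[ConnectivityMatrix] | np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None,
    config: CPMConfig,
) -> CPMResult:
    """Run the full leave-one-out CPM pipeline.

    ``matrices`` is a list of ConnectivityMatrix or a pre-stacked
    subjects x edges array. Selection and model fitting in each fold use
    only the training subjects; the held-out subject contributes only its
    network strength at prediction time.
    """
    X = matrices if isinstance(matrices, np.ndarray) else stack_matrices(matrices)
    y = np.asarray(behavior, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("LOOCV needs at least 10 subjects")
    if len(y) != n:
        raise ValueError("behavior length must match number of subjects")
    C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else covariates

    cache = _FoldCache(X, C)
    out, fold_edges = _loocv(cache, X, y, config.selection_threshold, collect_edges=True, warn_empty=True)
    preds = out["pred"]
    accuracy = {s: _spearman_accuracy(preds[s], y) for s in ("pos", "neg")}
    consensus = {
        s: consensus_network(fold_edges[s], config.consensus_fraction, X.shape[1])
        for s in ("pos", "neg")
    }
    return CPMResult(
        fold_edges=fold_edges,
        strengths=out["strength"],
        predictions=preds,
        observed=y,
        accuracy=accuracy,
        consensus=consensus,
        consensus_fraction=config.consensus_fraction,
        n_subjects=n,
        n_edges=X.shape[1],
    )


def permutation_test(
    matrices: list[ConnectivityMatrix] | np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None,
    config: CPMConfig,
    result: CPMResult | None = None,
) -> CPMResult:
    """Permutation inference for LOOCV prediction accuracy.

    The behavior vector is shuffled against the connectivity matrices
    (covariates stay aligned with the matrices by default;
    ``permute_covariates`` shuffles them with behavior) and the entire
    LOOCV pipeline is re-run per permutation. The p-value per network sign
    is the proportion of permuted accuracies greater than or equal to the
    observed accuracy (optionally add-one smoothed). Permuted accuracies
    that are undefined (constant predictions) never count as exceeding.
    """
    X = matrices if isinstance(matrices, np.ndarray) else stack_matrices(matrices)
    y = np.asarray(behavior, dtype=float)
    C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else covariates

    if result is None:
        result = loocv_predict(X, y, C, config)

    cache = _FoldCache(X, C)
    rng = np.random.default_rng(config.seed)
    B = config.n_permutations
    null = {"pos": np.empty(B), "neg": np.empty(B)}
    for b in range(B):
        perm = rng.permutation(len(y))
        yb = y[perm]
        if config.permute_covariates and C is not None:
            cache_b = _FoldCache(X, C[perm])
            out, _ = _loocv(cache_b, X, yb, config.selection_threshold)
        else:
            out, _ = _loocv(cache, X, yb, config.selection_threshold)
        for s in ("pos", "neg"):
            null[s][b] = _spearman_accuracy(out["pred"][s], yb)

    for s in ("pos", "neg"):
        obs = result.accuracy[s]
        if np.isnan(obs):
            result.permutation_p[s] = float("nan")
        else:
            count = int(np.count_nonzero(null[s] >= obs))
            if config.add_one_smoothing:
                result.permutation_p[s] = (count + 1) / (B + 1)
            else:
                result.permutation_p[s] = count / B
        result.null_accuracy[s] = null[s]
    return result


def consensus_network(
    fold_edge_sets: list[np.ndarray],
    fraction: float,
    n_edges: int,
) -> np.ndarray:
    """Edges selected in at least ``fraction`` of all folds."""
    counts = np.zeros(n_edges, dtype=int)
    for sel in fold_edge_sets:
        counts[sel] += 1
    need = fraction * len(fold_edge_sets)
    return np.flatnonzero(counts >= need)


def degree_summary(
    consensus_edges: np.ndarray,
    n_nodes: int,
    atlas: CanonicalAtlas | None = None,
    node_ids: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node degrees and the canonical-network pair-count matrix.

    Returns (node table, 10x10 pair-count table). Degree is the number of
    consensus edges incident to the node; the degree proportion divides by
    the total consensus edge count. Each edge increments the unordered
    pair of its endpoints' canonical-network labels.
    """
    iu, ju = edge_index(n_nodes)
    ei, ej = iu[consensus_edges], ju[consensus_edges]
    deg = np.bincount(np.concatenate([ei, ej]), minlength=n_nodes)
    n_edges = len(consensus_edges)
    ids = np.arange(n_nodes) if node_ids is None else np.asarray(node_ids)
    labels = atlas.labels if atlas is not None else np.asarray(["?"] * n_nodes, dtype=object)
    nodes = pd.DataFrame(
        {
            "node": ids,
            "network": labels,
            "degree": deg,
            "degree_proportion": deg / n_edges if n_edges else np.zeros(n_nodes),
        }
    )
    pair = pd.DataFrame(
        np.zeros((len(CANONICAL_NETWORKS), len(CANONICAL_NETWORKS)), dtype=int),
        index=list(CANONICAL_NETWORKS),
        columns=list(CANONICAL_NETWORKS),
    )
    if atlas is not None:
        order = {lab: i for i, lab in enumerate(CANONICAL_NETWORKS)}
        for a, b in zip(labels[ei], labels[ej]):
            i, j = sorted((order[a], order[b]))
            pair.iat[i, j] += 1
    return nodes, pair


def top_nodes(node_table: pd.DataFrame, top_fraction: float = 0.10) -> pd.DataFrame:
    """Highest-degree nodes: the top ``top_fraction`` of nodes by degree.

    Ties at the cutoff degree are all included, so the returned count can
    exceed round(top_fraction * N).
    """
    n = len(node_table)
    k = int(round(top_fraction * n))
    ranked = node_table.sort_values("degree", ascending=False, kind="stable").reset_index(drop=True)
    if k >= n:
        return ranked
    cut = ranked["degree"].iloc[k - 1] if k > 0 else np.inf
    out = ranked[ranked["degree"] >= cut]
    if len(out) > k:
        warnings.warn(f"degree ties at the top-{top_fraction:.0%} cutoff: returning {len(out)} nodes", stacklevel=2)
    return out.reset_index(drop=True)
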