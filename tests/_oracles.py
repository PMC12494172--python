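"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (explicit loops, textbook formulas,
general-purpose library calls) and shares no code with gazecpm internals.
"""

from __future__ import annotations

import numpy as np
import scipy.stats as st

from gazecpm.gaze import GazeStream


def welch_formula(a, b):
    """Textbook Welch t statistic and Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * st.t.sf(abs(t), df)
    return t, df, p


def ols_slope(x, y):
    """Brute-force OLS slope via the normal equations."""
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    return beta[1]


def naive_partial_spearman(edge, behavior, covariates=None):
    """Explicit rank + residual computation, one edge at a time."""
    re = st.rankdata(edge)
    rb = st.rankdata(behavior)
    n = len(re)
    D = np.ones((n, 1))
    if covariates is not None:
        D = np.column_stack([D, np.atleast_2d(np.asarray(covariates, float)).reshape(n, -1)])
    # OLS residuals via pseudo-inverse
    P = D @ np.linalg.pinv(D)
    ee = re - P @ re
    bb = rb - P @ rb
    return float(st.pearsonr(ee, bb).statistic)


def naive_cpm_loocv(X, y, C, threshold):
    """Step-by-step LOOCV CPM: per-fold selection, strengths, predictions.

    Returns dicts keyed 'pos'/'neg' of (fold edge lists, predictions).
    """
    n, _ = X.shape
    preds = {"pos": np.empty(n), "neg": np.empty(n)}
    folds = {"pos": [], "neg": []}
    for i in range(n):
        tr = [k for k in range(n) if k != i]
        rhos = np.array(
            [naive_partial_spearman(X[tr, e], y[tr], C[tr] if C is not None else None)
             for e in range(X.shape[1])]
        )
        pos = np.flatnonzero(rhos > threshold)
        neg = np.flatnonzero(rhos < -threshold)
        folds["pos"].append(pos)
        folds["neg"].append(neg)
        for sign, sel in (("pos", pos), ("neg", neg)):
            if len(sel) == 0:
                preds[sign][i] = np.mean(y[tr])
                continue
            s_train = np.array([X[k, sel].sum() for k in tr])
            if np.ptp(s_train) == 0:
                preds[sign][i] = np.mean(y[tr])
                continue
            b1, b0 = np.polyfit(s_train, y[tr], 1)
            preds[sign][i] = b0 + b1 * X[i, sel].sum()
    return folds, preds


def planted_fixation_stream(rng, n_segments=None, dt_ms=20.0):
    """Noise-free gaze stream with known fixation segments.

    Segments are stationary clusters at positions at least 5 degrees apart,
    joined either by a fast multi-sample sweep (every inter-sample velocity
    far above 30 deg/s) or by a run of invalid samples. Returns
    (stream, [(start_ms, end_ms), ...]).
    """
    n_segments = int(rng.integers(1, 8)) if n_segments is None else n_segments
    t, x, y, valid = [], [], [], []
    segments = []
    clock = 0.0
    pos = np.array([0.0, 0.0])

    def emit(px, py, ok=True):
        nonlocal clock
        t.append(clock)
        x.append(px)
        y.append(py)
        valid.append(ok)
        clock += dt_ms

    for _ in range(int(rng.integers(2, 6))):  # lead-in saccade samples
        pos = pos + rng.uniform(3, 6, 2)
        emit(*pos)
    for _ in range(n_segments):
        target = pos + rng.uniform(5, 12, 2) * rng.choice([-1, 1], 2)
        n_samp = int(rng.integers(5, 31))  # 80-600 ms span
        start = clock
        for _ in range(n_samp):
            emit(*target)
        segments.append((start, clock - dt_ms))
        pos = target
        if rng.random() < 0.5:  # saccade gap
            for _ in range(int(rng.integers(2, 5))):
                pos = pos + rng.uniform(3, 6, 2) * rng.choice([-1, 1], 2)
                emit(*pos)
        else:  # blink gap
            for _ in range(int(rng.integers(3, 8))):
                emit(0.0, 0.0, ok=False)
            pos = pos + rng.uniform(5, 10, 2)
            emit(*pos)  # single valid saccade landing sample
    stream = GazeStream(
        t=np.array(t), x=np.array(x), y=np.array(y), valid=np.array(valid)
    )
    keep = [(s, e) for s, e in segments if e - s >= 50.0]
    return stream, keep
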