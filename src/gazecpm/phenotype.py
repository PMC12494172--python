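"""Sign-/goal-tracking phenotyping and behavioral statistics.

The per-participant phenotype is the ordinary-least-squares slope of the
trial-level gaze index on the reward value of the CS (2, 1, 0, 0): a more
positive slope means gaze was drawn to the reward-predicting cue
(sign-tracking), a more negative slope means gaze went to the reward
location itself (goal-tracking). Post-hoc groups take the most positive
2/5 of slopes as sign-trackers (ST), the most negative 2/5 as
goal-trackers (GT), and the middle 1/5 as intermediates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from scipy.linalg import helmert

__all__ = [
    "PhenotypeResult",
    "AssociationFit",
    "stgt_coefficient",
    "assign_groups",
    "adiposity_model",
    "welch_t",
    "rm_anova",
    "trend_over_trials",
]


@dataclass
class PhenotypeResult:
    """Per-participant CS-value regression of the gaze index."""

    stgt_slope: float
    intercept: float
    n_trials_used: int
    group: str | None = None  # "ST" | "GT" | "intermediate" | "excluded"


@dataclass
class AssociationFit:
    """An adjusted OLS association model (one row per design term)."""

    terms: list[str]
    estimates: np.ndarray
    std_estimates: np.ndarray  # from the refit with z-scored outcome/continuous terms
    conf_int: np.ndarray  # (k, 2)
    pvalues: np.ndarray
    r_squared: float
    adj_r_squared: float
    n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "std_estimate": self.std_estimates,
                "ci_low": self.conf_int[:, 0],
                "ci_high": self.conf_int[:, 1],
                "p": self.pvalues,
            }
        )


def stgt_coefficient(
    cs_values: np.ndarray,
    gaze_indices: np.ndarray,
    min_trials: int = 24,
) -> PhenotypeResult:
    """OLS slope of gaze index on CS reward value.

    Trials with a missing gaze index (no valid fixation time in the
    analysis window) are dropped. Requires at least two distinct CS values
    among the retained trials; the slope is otherwise undefined.
    ``min_trials`` gates group assignment downstream (participants with
    fewer usable trials keep their slope but are marked excluded).
    """
    x = np.asarray(cs_values, dtype=float)
    y = np.asarray(gaze_indices, dtype=float)
    keep = ~np.isnan(y)
    x, y = x[keep], y[keep]
    if len(np.unique(x)) < 2:
        raise ValueError("slope undefined: fewer than 2 distinct CS values")
    slope, intercept = np.polyfit(x, y, 1)
    res = PhenotypeResult(
        stgt_slope=float(slope), intercept=float(intercept), n_trials_used=int(len(y))
    )
    if res.n_trials_used < min_trials:
        res.group = "excluded"
    return res


def assign_groups(
    slopes: np.ndarray,
    fractions: tuple[float, float, float] = (0.4, 0.2, 0.4),
) -> np.ndarray:
    """Split participants into ST / intermediate / GT by ranked slope.

    The top ``round(fractions[0] * n)`` slopes (round half up) are labeled
    ST and the bottom ``round(fractions[2] * n)`` GT, so a sample of 47
    yields groups of 19/9/19. Ties are broken by stable input order.
    """
    slopes = np.asarray(slopes, dtype=float)
    if not np.all(np.isfinite(slopes)):
        raise ValueError("all slopes must be finite")
    n = len(slopes)
    if n < 5:
        raise ValueError("need at least 5 participants for a 2/5-1/5-2/5 split")
    n_st = int(math.floor(fractions[0] * n + 0.5))
    n_gt = int(math.floor(fractions[2] * n + 0.5))
    order = np.argsort(-slopes, kind="stable")  # most positive first
    labels = np.array(["intermediate"] * n, dtype=object)
    labels[order[:n_st]] = "ST"
    labels[order[n - n_gt :]] = "GT"
    return labels


def adiposity_model(
    data: pd.DataFrame,
    predictor: str,
    outcome: str = "stgt_slope",
    covariates: tuple[str, ...] = ("age", "sex", "hunger"),
    binary: tuple[str, ...] = ("sex",),
) -> AssociationFit:
    """Adjusted linear association between the ST/GT slope and an adiposity measure.

    Fits ``outcome ~ predictor + covariates`` by OLS with classical 95%
    confidence intervals. Standardized estimates come from refitting with
    the outcome and every continuous term z-scored; binary indicators
    (sex by default) are left on their original scale in that refit.
    """
    cols = [outcome, predictor, *covariates]
    df = data[cols].dropna()
    k = len(cols)
    if len(df) < k + 2:
        raise ValueError("too few complete cases")
    X = sm.add_constant(df[[predictor, *covariates]].astype(float))
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(df[outcome].astype(float), X).fit()

    zdf = df.astype(float).copy()
    for c in cols:
        if c not in binary:
            sd = zdf[c].std(ddof=1)
            zdf[c] = (zdf[c] - zdf[c].mean()) / sd
    zfit = sm.OLS(zdf[outcome], sm.add_constant(zdf[[predictor, *covariates]])).fit()

    return AssociationFit(
        terms=list(X.columns),
        estimates=fit.params.values,
        std_estimates=zfit.params.values,
        conf_int=fit.conf_int().values,
        pvalues=fit.pvalues.values,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        n=int(len(df)),
    )


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df (two-sided)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = st.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def rm_anova(cells: np.ndarray) -> dict[str, float]:
    """Two-way repeated-measures ANOVA for the AOI x CS-type interaction.

    ``cells`` has shape (n_subjects, n_aoi, n_cs) of percent-fixation
    values. Returns the interaction F statistic with
    Greenhouse-Geisser-corrected degrees of freedom; epsilon is computed
    from the covariance matrix of the orthonormal interaction contrasts
    (Kronecker product of Helmert contrasts for the two factors).
    """
    Y = np.asarray(cells, dtype=float)
    if Y.ndim != 3:
        raise ValueError("cells must be (subjects, aoi, cs_type)")
    if np.isnan(Y).any():
        raise ValueError("missing cells not allowed in repeated-measures ANOVA")
    n, p, q = Y.shape
    m = Y.mean()
    m_a = Y.mean(axis=(0, 2))  # per AOI
    m_b = Y.mean(axis=(0, 1))  # per CS
    m_ab = Y.mean(axis=0)  # p×q
    m_sa = Y.mean(axis=2)  # n×p
    m_sb = Y.mean(axis=1)  # n×q
    m_s = Y.mean(axis=(1, 2))  # n

    inter = m_ab - m_a[:, None] - m_b[None, :] + m
    ss_ab = n * np.sum(inter**2)
    resid = (
        Y
        - m_ab[None, :, :]
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - m
    )
    ss_err = np.sum(resid**2)
    df1 = (p - 1) * (q - 1)
    df2 = (n - 1) * df1
    if ss_err == 0:
        F = 0.0 if ss_ab == 0 else float("inf")
    else:
        F = (ss_ab / df1) / (ss_err / df2)

    C = np.kron(helmert(p), helmert(q))  # orthonormal interaction contrasts
    Z = Y.reshape(n, p * q) @ C.T
    S = np.cov(Z, rowvar=False)
    if np.trace(S) == 0:  # degenerate: no interaction-contrast variance
        eps = 1.0
    else:
        eps = float(np.trace(S) ** 2 / (df1 * np.sum(S * S)))
    eps = min(eps, 1.0)
    df1c, df2c = eps * df1, eps * df2
    pval = float(st.f.sf(F, df1c, df2c)) if np.isfinite(F) else 0.0
    if F == 0.0:
        pval = 1.0
    return {
        "F": float(F),
        "df1": df1c,
        "df2": df2c,
        "p": pval,
        "epsilon": eps,
        "df1_uncorrected": float(df1),
        "df2_uncorrected": float(df2),
    }


def trend_over_trials(values: np.ndarray, trial_numbers: np.ndarray | None = None) -> tuple[float, float]:
    """Change of a per-trial measure over the session, across participants.

    A two-stage summary-statistics test: each participant's values are
    regressed on trial number by OLS, and the slopes are tested against
    zero with a one-sample t-test. When the slopes have zero variance the
    t statistic is undefined; p is 1 when the common slope is 0 and 0
    otherwise.
    """
    V = np.asarray(values, dtype=float)
    if V.ndim != 2 or V.shape[1] < 3:
        raise ValueError("need at least 3 trials per participant")
    tn = np.arange(1, V.shape[1] + 1, dtype=float) if trial_numbers is None else np.asarray(trial_numbers, float)
    slopes = np.array([np.polyfit(tn[~np.isnan(row)], row[~np.isnan(row)], 1)[0] for row in V])
    slopes[np.abs(slopes) < 1e-10] = 0.0  # snap float noise from exactly flat series
    mean_slope = float(np.mean(slopes))
    if np.std(slopes, ddof=1) == 0:
        return mean_slope, 1.0 if mean_slope == 0 else 0.0
    _, pval = st.ttest_1samp(slopes, 0.0)
    return mean_slope, float(pval)
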