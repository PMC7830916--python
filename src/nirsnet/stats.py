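"""Developmental-trajectory statistics for network metrics.

The central model regresses a per-subject network outcome ``Y`` (typically a
sparsity-AUC value of a global or nodal metric) on diagnosis and age:

    Y = b0 + b1*group + b2*age + b3*age^2 + b4*age:group + b5*age^2:group + e

with age centered on the full-sample mean and the quadratic term computed as
the square of the centered age (which keeps it nearly orthogonal to the
linear term). Group is coded TD = 0, ASD = 1, so b4/b5 measure how the ASD
group's linear/quadratic age trend departs from the TD trend. Standardized
coefficients are obtained by z-scoring the outcome and each constructed
predictor column (including the interaction columns) before fitting; this
leaves t statistics and p-values identical to the unstandardized fit.

Alongside the trajectory fit the module provides Benjamini-Hochberg FDR
correction over channel families, age-controlled partial correlations
between network metrics and ADOS symptom scores (defined for the ASD group
only), and the pooled two-sample t test used for demographic tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Model terms in design order; b1..b5 in the trajectory model.
TERMS = ("group", "age", "age2", "age_group", "age2_group")

_TERM_ALIASES = {
    "group": "group",
    "age": "age",
    "age2": "age2",
    "age^2": "age2",
    "age:group": "age_group",
    "age_group": "age_group",
    "age2:group": "age2_group",
    "age^2:group": "age2_group",
    "age2_group": "age2_group",
}


def canonical_term(term: str) -> str:
    try:
        return _TERM_ALIASES[term.lower()]
    except KeyError:
        raise ValueError(f"unknown trajectory term {term!r}") from None


def trajectory_design(
    age: np.ndarray,
    is_asd: np.ndarray,
    *,
    standardize: bool = False,
    zscore_age_first: bool = False,
) -> pd.DataFrame:
    """Build the five-column trajectory design matrix (without intercept).

    ``zscore_age_first`` switches the standardization convention: when True
    the age variable itself is z-scored before the quadratic and interaction
    columns are constructed (instead of z-scoring the constructed columns).
    """
    age = np.asarray(age, dtype=float)
    g = np.asarray(is_asd, dtype=float)
    age_c = age - age.mean()
    if zscore_age_first and standardize:
        age_c = age_c / age_c.std(ddof=1)
    cols = {
        "group": g,
        "age": age_c,
        "age2": age_c**2,
        "age_group": age_c * g,
        "age2_group": age_c**2 * g,
    }
    design = pd.DataFrame(cols)
    if standardize and not zscore_age_first:
        design = (design - design.mean()) / design.std(ddof=1)
    return design


@dataclass
class TrajectoryFit:
    """OLS fit of the six-term developmental-trajectory model."""

    beta_std: dict[str, float]
    beta_raw: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    intercept: float
    r_squared: float
    nobs: int
    resid: np.ndarray = field(repr=False)


def fit_trajectory(
    y: np.ndarray,
    age: np.ndarray,
    is_asd: np.ndarray,
    *,
    min_per_group: int = 10,
    zscore_age_first: bool = False,
) -> TrajectoryFit:
    """Fit the trajectory model for one outcome via statsmodels OLS."""
    y = np.asarray(y, dtype=float)
    is_asd = np.asarray(is_asd, dtype=bool)
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains missing/non-finite values")
    n_asd = int(is_asd.sum())
    n_td = int((~is_asd).sum())
    if min(n_asd, n_td) < min_per_group:
        raise ValueError(
            f"need at least {min_per_group} subjects per group, got "
            f"ASD={n_asd}, TD={n_td}"
        )
    design_raw = trajectory_design(age, is_asd)
    X = sm.add_constant(design_raw)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient trajectory design; check age spread and group mix"
        )
    fit_raw = sm.OLS(y, X).fit()

    design_std = trajectory_design(
        age, is_asd, standardize=True, zscore_age_first=zscore_age_first
    )
    y_sd = y.std(ddof=1)
    y_std = (y - y.mean()) / y_sd if y_sd > 0 else y - y.mean()
    fit_std = sm.OLS(y_std, sm.add_constant(design_std)).fit()

    return TrajectoryFit(
        beta_std={t: float(fit_std.params[t]) for t in TERMS},
        beta_raw={t: float(fit_raw.params[t]) for t in TERMS},
        tvalues={t: float(fit_raw.tvalues[t]) for t in TERMS},
        pvalues={t: float(fit_raw.pvalues[t]) for t in TERMS},
        intercept=float(fit_raw.params["const"]),
        r_squared=float(fit_raw.rsquared),
        nobs=int(fit_raw.nobs),
        resid=np.asarray(fit_raw.resid, dtype=float),
    )


def fit_trajectory_table(
    Y: np.ndarray,
    age: np.ndarray,
    is_asd: np.ndarray,
) -> dict[str, np.ndarray]:
    """Vectorized trajectory fits for many outcomes sharing one design.

    Parameters
    ----------
    Y : (n_subjects, n_outcomes) array.

    Returns dict with keys ``beta_std`` (5 × p), ``t`` (5 × p), ``p`` (5 × p),
    ``r_squared`` (p,), rows ordered as :data:`TERMS`.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    design = trajectory_design(age, is_asd, standardize=True).to_numpy()
    sd = Y.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Yz = (Y - Y.mean(axis=0)) / sd
    X = np.column_stack([np.ones(n), design])
    k = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Yz  # (k, p)
    resid = Yz - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(t), dof)
    ss_tot = (Yz**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - (resid**2).sum(axis=0) / ss_tot
    return {
        "beta_std": beta[1:],
        "t": t[1:],
        "p": pvals[1:],
        "r_squared": r2,
        "terms": list(TERMS),
    }


def fdr_correct(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level *q* → (reject flags, adjusted p)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class PartialCorrelationResult:
    """Correlation of two variables after regressing out a covariate."""

    r: float
    p: float
    n: int
    undefined: bool = False


def partial_correlation(x, y, covariate) -> PartialCorrelationResult:
    """Age-controlled partial correlation via the residual method.

    Both *x* and *y* are regressed on ``[1, covariate]``; the Pearson
    correlation of the residuals is returned with a two-sided p-value from
    ``t = r * sqrt((n - 3) / (1 - r^2))`` on n − 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(c))):
        raise ValueError("inputs must be finite")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    Z = np.column_stack([np.ones(n), c])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    # residual variance at numerical-noise level means x or y is an exact
    # function of the covariate: the partial correlation is undefined
    tol_x = 1e-10 * max(x.std(), 1e-300)
    tol_y = 1e-10 * max(y.std(), 1e-300)
    if sx <= tol_x or sy <= tol_y:
        return PartialCorrelationResult(r=np.nan, p=np.nan, n=n, undefined=True)
    r = float(np.clip((rx @ ry) / (n * sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return PartialCorrelationResult(r=r, p=0.0, n=n)
    t = r * np.sqrt((n - 3) / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), n - 3))
    return PartialCorrelationResult(r=r, p=p, n=n)


@dataclass
class GroupComparison:
    """Pooled-variance two-sample t test between ASD and TD summaries."""

    variable: str
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    t: float
    p: float
    df: int


def pooled_t_test(
    n1=None, mean1=None, sd1=None, n2=None, mean2=None, sd2=None,
    *, sample1=None, sample2=None, variable: str = "",
) -> GroupComparison:
    """Student's pooled two-sample t from summaries or raw samples."""
    if sample1 is not None or sample2 is not None:
        a = np.asarray(sample1, dtype=float)
        b = np.asarray(sample2, dtype=float)
        n1, mean1, sd1 = a.size, a.mean(), a.std(ddof=1)
        n2, mean2, sd2 = b.size, b.mean(), b.std(ddof=1)
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean1 - mean2
    if pooled_var == 0:
        if diff == 0:
            t_stat, p = 0.0, 1.0
        else:
            warnings.warn("zero pooled variance with unequal means", RuntimeWarning)
            t_stat, p = float(np.sign(diff)) * np.inf, 0.0
    else:
        se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        t_stat = float(diff / se)
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
    return GroupComparison(
        variable=variable, n1=int(n1), mean1=float(mean1), sd1=float(sd1),
        n2=int(n2), mean2=float(mean2), sd2=float(sd2), t=t_stat, p=p, df=df,
    )


def demographic_comparisons(subjects: pd.DataFrame) -> pd.DataFrame:
    """ASD-vs-TD pooled t tests for age and the three IQ scales."""
    asd = subjects[subjects["group"] == "ASD"]
    td = subjects[subjects["group"] == "TD"]
    rows = []
    for var in ("age", "viq", "piq", "fsiq"):
        cmp = pooled_t_test(
            sample1=asd[var].to_numpy(), sample2=td[var].to_numpy(), variable=var
        )
        rows.append(
            {"variable": var, "n_asd": cmp.n1, "mean_asd": cmp.mean1,
             "sd_asd": cmp.sd1, "n_td": cmp.n2, "mean_td": cmp.mean2,
             "sd_td": cmp.sd2, "t": cmp.t, "p": cmp.p}
        )
    return pd.DataFrame(rows)


def trajectory_analysis(
    metrics: pd.DataFrame,
    subjects: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Fit the trajectory model for every outcome in a tidy metric table.

    *metrics* has columns ``subject_id, chromophore, metric, channel, auc``
    (channel ``"global"`` for network-level metrics). FDR correction is
    applied within each (metric, chromophore, term) family across channels.
    """
    subj = subjects.set_index("subject_id")
    rows = []
    for (metric, chrom), grp in metrics.groupby(["metric", "chromophore"], sort=True):
        wide = grp.pivot_table(index="subject_id", columns="channel", values="auc")
        wide = wide.reindex(index=[s for s in subj.index if s in wide.index])
        age = subj.loc[wide.index, "age"].to_numpy()
        is_asd = (subj.loc[wide.index, "group"] == "ASD").to_numpy()
        res = fit_trajectory_table(wide.to_numpy(), age, is_asd)
        for it, term in enumerate(TERMS):
            flags, p_adj = fdr_correct(res["p"][it], q=q)
            for ic, channel in enumerate(wide.columns):
                rows.append(
                    {"metric": metric, "chromophore": chrom, "channel": channel,
                     "term": term, "beta_std": res["beta_std"][it, ic],
                     "t": res["t"][it, ic], "p": res["p"][it, ic],
                     "p_fdr": p_adj[ic], "fdr_significant": bool(flags[ic]),
                     "r_squared": res["r_squared"][ic], "n": len(wide)}
                )
    return pd.DataFrame(rows)


def brain_behavior(
    metrics: pd.DataFrame,
    subjects: pd.DataFrame,
    scores: tuple[str, ...] = ("ados_communication", "ados_social"),
) -> pd.DataFrame:
    """Age-controlled partial correlations with ADOS scores, ASD group only."""
    asd = subjects[subjects["group"] == "ASD"].set_index("subject_id")
    rows = []
    for (metric, chrom, channel), grp in metrics.groupby(
        ["metric", "chromophore", "channel"], sort=True
    ):
        vals = grp.set_index("subject_id")["auc"]
        common = [s for s in asd.index if s in vals.index]
        if len(common) < 4:
            continue
        x = vals.loc[common].to_numpy()
        age = asd.loc[common, "age"].to_numpy()
        for score in scores:
            y = asd.loc[common, score].to_numpy(dtype=float)
            res = partial_correlation(x, y, age)
            rows.append(
                {"metric": metric, "chromophore": chrom, "channel": channel,
                 "ados_scale": score, "r": res.r, "p": res.p, "n": res.n,
                 "undefined": res.undefined}
            )
    return pd.DataFrame(rows)
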