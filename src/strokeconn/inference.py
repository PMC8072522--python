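"""Treatment-effect and brain-behaviour inference on connectivity indices.

The treatment effect on an index is the session-by-arm interaction from a
linear mixed model over the two sessions of a contrast (e.g. T1->T2):
fixed effects session, arm, session x arm, plus optional age and
session-averaged mean FD covariates, and a per-subject random intercept
(REML).  The sign convention is (sensorimotor change) - (motor change).
With complete data and no covariates the interaction estimate coincides
exactly with the difference of arm-mean change scores; that change-score
least-squares model is also the documented fallback when the mixed model
fails to converge.

Brain-behaviour associations are Spearman partial correlations: x, y and
the covariates are rank-transformed, the ranked x and y are residualized
on the ranked covariates, and rho is the Pearson correlation of the
residuals with p from the t distribution on n - 2 - n_covariates degrees
of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ARM_LEVELS = ("sensorimotor", "motor")


@dataclass
class BonferroniThreshold:
    raw: float
    rounded: float
    n_tests: int


def bonferroni_threshold(
    alpha: float = 0.05, n_indices: int = 6, n_time_contrasts: int = 3
) -> BonferroniThreshold:
    """Per-test threshold alpha / (n_indices * n_time_contrasts)."""
    if alpha <= 0 or n_indices <= 0 or n_time_contrasts <= 0:
        raise ValueError("alpha and counts must be positive")
    n_tests = n_indices * n_time_contrasts
    raw = alpha / n_tests
    return BonferroniThreshold(raw=raw, rounded=round(raw, 3), n_tests=n_tests)


@dataclass
class TreatmentEffect:
    index_name: str
    contrast: tuple[str, str]
    estimate: float  # (sensorimotor change) - (motor change), Fisher-z units
    se: float
    p: float
    n_sensorimotor: int
    n_motor: int
    covariates: list[str]
    method: str  # "mixed" or "change_score"
    converged: bool
    df: int = 0
    significant: bool | None = None


def _complete_contrast(
    data: pd.DataFrame, contrast: tuple[str, str]
) -> pd.DataFrame:
    """Keep subjects with finite values at both contrast sessions."""
    d = data[data["session"].isin(contrast)].copy()
    d = d[np.isfinite(d["value"])]
    counts = d.groupby("subject_id")["session"].nunique()
    keep = counts[counts == 2].index
    return d[d["subject_id"].isin(keep)].copy()


def _covariate_columns(
    d: pd.DataFrame, use_age: bool, use_fd: bool
) -> list[str]:
    cols = []
    if use_age and "age" in d.columns:
        cols.append("age")
    if use_fd and "mean_fd" in d.columns:
        cols.append("mean_fd")
    return [c for c in cols if np.ptp(d[c].to_numpy(dtype=float)) > 0]


def change_score_effect(
    data: pd.DataFrame,
    contrast: tuple[str, str] = ("T1", "T2"),
    use_age: bool = True,
    use_fd: bool = True,
    index_name: str = "",
) -> TreatmentEffect:
    """Between-arm difference of per-subject change scores (OLS).

    The cross-check / fallback model: delta ~ arm (+ covariates), with the
    arm coefficient carrying the (sensorimotor - motor) convention.
    """
    d = _complete_contrast(data, contrast)
    wide = d.pivot_table(index="subject_id", columns="session", values="value")
    meta = d.groupby("subject_id").first()
    delta = (wide[contrast[1]] - wide[contrast[0]]).loc[meta.index]
    arm = (meta["arm"] == "sensorimotor").astype(float).to_numpy()
    n_sm, n_mo = int(arm.sum()), int((1 - arm).sum())
    if n_sm < 2 or n_mo < 2:
        raise ValueError("need at least 2 complete subjects per arm")
    covs = _covariate_columns(meta, use_age, use_fd)
    x = np.column_stack(
        [np.ones_like(arm), arm] + [meta[c].to_numpy(dtype=float) for c in covs]
    )
    y = delta.to_numpy(dtype=float)
    df = len(y) - x.shape[1]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    sigma2 = float(resid @ resid) / df if df > 0 else np.nan
    se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
    est = float(beta[1])
    if se == 0:
        t, p = (0.0, 1.0) if est == 0 else (np.inf * np.sign(est), 0.0)
    else:
        t = est / se
        p = float(2 * stats.t.sf(abs(t), df))
    return TreatmentEffect(
        index_name=index_name,
        contrast=contrast,
        estimate=est,
        se=se,
        p=p,
        n_sensorimotor=n_sm,
        n_motor=n_mo,
        covariates=covs,
        method="change_score",
        converged=True,
        df=df,
    )


def treatment_effect(
    data: pd.DataFrame,
    contrast: tuple[str, str] = ("T1", "T2"),
    use_age: bool = True,
    use_fd: bool = True,
    index_name: str = "",
    method: str = "mixed",
) -> TreatmentEffect:
    """Session-by-arm interaction for one index over one session contrast.

    Parameters
    ----------
    data:
        Tidy frame with columns ``subject_id``, ``session``, ``value``,
        ``arm`` (\"sensorimotor\"/\"motor\") and optionally ``age`` and
        ``mean_fd`` (the per-subject mean FD averaged over the contrast's
        sessions).  Only subjects complete for the contrast enter.
    """
    if method == "change_score":
        return change_score_effect(data, contrast, use_age, use_fd, index_name)
    if method != "mixed":
        raise ValueError("method must be 'mixed' or 'change_score'")
    d = _complete_contrast(data, contrast)
    arms = set(d["arm"].unique())
    if not arms <= set(ARM_LEVELS):
        raise ValueError(f"unknown arm labels {arms - set(ARM_LEVELS)}")
    n_per_arm = d.groupby("arm")["subject_id"].nunique()
    n_sm = int(n_per_arm.get("sensorimotor", 0))
    n_mo = int(n_per_arm.get("motor", 0))
    if n_sm < 2 or n_mo < 2:
        raise ValueError("need at least 2 complete subjects per arm")
    d["post"] = (d["session"] == contrast[1]).astype(float)
    d["arm_sm"] = (d["arm"] == "sensorimotor").astype(float)
    d["post_x_arm"] = d["post"] * d["arm_sm"]
    covs = _covariate_columns(d, use_age, use_fd)
    exog_cols = ["post", "arm_sm", "post_x_arm"] + covs
    import statsmodels.api as sm

    exog = sm.add_constant(d[exog_cols].to_numpy(dtype=float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                d["value"].to_numpy(dtype=float),
                exog,
                groups=d["subject_id"].to_numpy(),
            )
            fit = model.fit(reml=True)
        k = 1 + exog_cols.index("post_x_arm")
        est = float(fit.params[k])
        se = float(fit.bse[k])
        # t reference with between-subject denominator df: the interaction
        # is a between-subject contrast of change scores, so the normal
        # (Wald) reference would be anti-conservative at these sample sizes
        df = n_sm + n_mo - 2 - len(covs)
        if se > 0 and df > 0:
            p = float(2 * stats.t.sf(abs(est / se), df))
        else:
            p = float(fit.pvalues[k])
        converged = bool(getattr(fit, "converged", True)) and np.isfinite(se)
    except (np.linalg.LinAlgError, ValueError):
        converged = False
    if not converged:
        fb = change_score_effect(data, contrast, use_age, use_fd, index_name)
        fb.converged = False
        return fb
    return TreatmentEffect(
        index_name=index_name,
        contrast=contrast,
        estimate=est,
        se=se,
        p=p,
        n_sensorimotor=n_sm,
        n_motor=n_mo,
        covariates=covs,
        method="mixed",
        converged=True,
        df=df,
    )


@dataclass
class BrainBehaviourResult:
    rho: float
    p: float
    df: int
    n: int
    index_name: str = ""
    behaviour: str = ""
    covariates: list[str] = field(default_factory=list)


def partial_spearman(
    x,
    y,
    covariates=None,
    index_name: str = "",
    behaviour: str = "",
    covariate_names: list[str] | None = None,
) -> BrainBehaviourResult:
    """Rank-based partial correlation of x and y given covariates.

    Rows with any missing value are dropped listwise.  With no (or
    constant) covariates this reduces to the ordinary Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    x, y, cov = x[keep], y[keep], cov[keep]
    # constant covariates carry no rank information
    if cov.shape[1]:
        cov = cov[:, np.ptp(cov, axis=0) > 0]
    n, k = len(x), cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need more than {k + 2} complete observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("x and y must not be constant")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = np.column_stack([stats.rankdata(c) for c in cov.T]) if k else np.empty((n, 0))
    design = np.column_stack([np.ones(n), rc])
    beta_x = np.linalg.lstsq(design, rx, rcond=None)[0]
    beta_y = np.linalg.lstsq(design, ry, rcond=None)[0]
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    rho = float(np.clip(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)), -1.0, 1.0))
    df = n - 2 - k
    rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return BrainBehaviourResult(
        rho=rho,
        p=p,
        df=df,
        n=n,
        index_name=index_name,
        behaviour=behaviour,
        covariates=covariate_names or [f"cov{i}" for i in range(k)],
    )
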