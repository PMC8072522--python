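"""Data-driven selection of aberrant connections (stroke vs. control).

Each connection's Fisher-z values at baseline are regressed on group
(healthy = 0, stroke = 1) with mean frame-wise displacement as nuisance
regressor; the two-sided p value of the group coefficient feeds a
seed-level Benjamini-Hochberg correction applied independently within each
ROI's row of the p matrix.  A connection is selected when it survives in at
least one of its two seed rows (configurable to require both), and is
classed hypo- (stroke < healthy, negative coefficient) or hyper-connected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import RoiLabel, pair_compartment

DEFAULT_ALPHA = 0.01
COMPARTMENTS = ("inter", "ipsi_intra", "contra_intra")
CLASSES = ("hypo", "hyper")


@dataclass
class ConnectionTestResult:
    roi_i: int
    roi_j: int
    coefficient: float  # stroke - healthy, Fisher-z units
    t: float
    p: float
    n: int
    df: int


def _design(groups: np.ndarray, mean_fd: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(groups, dtype=float), groups.astype(float)]
    if mean_fd is not None and np.ptp(mean_fd) > 0:
        cols.append(mean_fd.astype(float))
    return np.column_stack(cols)


def _ols_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """Closed-form OLS; returns (coef, t, p, df) for column 1 (group)."""
    n, p = x.shape
    df = n - p
    if df <= 0:
        raise ValueError("not enough subjects for the connection-wise model")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0))
    coef = float(beta[1])
    if se == 0:
        t = 0.0 if coef == 0 else np.inf * np.sign(coef)
        pval = 1.0 if coef == 0 else 0.0
    else:
        t = coef / se
        pval = 2 * stats.t.sf(abs(t), df)
    return coef, float(t), float(pval), df


def test_connection(
    z_values: np.ndarray,
    groups: np.ndarray,
    mean_fd: np.ndarray | None = None,
    roi_i: int = -1,
    roi_j: int = -1,
) -> ConnectionTestResult:
    """Group contrast for one connection with mean FD as nuisance regressor.

    Subjects with missing z are excluded pairwise.  A zero-variance FD
    covariate is dropped, in which case the t statistic reduces to the
    ordinary pooled two-sample t.
    """
    z = np.asarray(z_values, dtype=float)
    groups = np.asarray(groups)
    if mean_fd is not None:
        mean_fd = np.asarray(mean_fd, dtype=float)
    keep = np.isfinite(z)
    if mean_fd is not None:
        keep &= np.isfinite(mean_fd)
    z, groups = z[keep], groups[keep]
    fd = None if mean_fd is None else mean_fd[keep]
    if (groups == 0).sum() == 0 or (groups == 1).sum() == 0:
        raise ValueError("one group has no subjects with data for this connection")
    x = _design(groups, fd)
    coef, t, pval, df = _ols_t(x, z)
    return ConnectionTestResult(
        roi_i=roi_i, roi_j=roi_j, coefficient=coef, t=t, p=pval, n=len(z), df=df
    )


def test_all_connections(
    z_stack: np.ndarray,
    groups: np.ndarray,
    mean_fd: np.ndarray | None = None,
    min_per_group: int = 3,
) -> dict[str, np.ndarray]:
    """Connection-wise group contrast over a (n_subjects, R, R) z stack.

    Returns ROI x ROI matrices of coefficients, t statistics and two-sided
    p values (NaN on the diagonal and for pairs lacking ``min_per_group``
    subjects per group after pairwise exclusion).  When no entries are
    missing the fit is fully vectorized: the design is shared, so the hat
    matrix is computed once for all pairs.
    """
    z_stack = np.asarray(z_stack, dtype=float)
    n_subj, n_rois, _ = z_stack.shape
    groups = np.asarray(groups)
    fd = None if mean_fd is None else np.asarray(mean_fd, dtype=float)
    coef = np.full((n_rois, n_rois), np.nan)
    tmat = np.full((n_rois, n_rois), np.nan)
    pmat = np.full((n_rois, n_rois), np.nan)
    ii, jj = np.triu_indices(n_rois, k=1)
    flat = z_stack[:, ii, jj]  # (n_subj, n_pairs)
    complete = np.all(np.isfinite(flat), axis=0)
    if complete.any():
        x = _design(groups, fd)
        n, p = x.shape
        df = n - p
        xtx_inv = np.linalg.inv(x.T @ x)
        pinv = xtx_inv @ x.T
        y = flat[:, complete]
        beta = pinv @ y
        resid = y - x @ beta
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta[1] / se, 0.0)
        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        coef[ii[complete], jj[complete]] = beta[1]
        tmat[ii[complete], jj[complete]] = tvals
        pmat[ii[complete], jj[complete]] = pvals
    for k in np.flatnonzero(~complete):
        zk = flat[:, k]
        keep = np.isfinite(zk)
        if (groups[keep] == 0).sum() < min_per_group:
            continue
        if (groups[keep] == 1).sum() < min_per_group:
            continue
        res = test_connection(zk, groups, fd)
        coef[ii[k], jj[k]] = res.coefficient
        tmat[ii[k], jj[k]] = res.t
        pmat[ii[k], jj[k]] = res.p
    for m in (coef, tmat, pmat):
        m[jj, ii] = m[ii, jj]
    return {"coefficient": coef, "t": tmat, "p": pmat}


def seed_level_fdr(
    p_matrix: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "any",
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg within each seed's row of the p matrix.

    Each row is corrected independently over its finite entries.  A
    connection is selected if it survives in at least one of its two rows
    (``mode="any"``, default) or in both (``mode="both"``).  Returns the
    symmetric boolean selection mask and the matrix of per-pair adjusted p
    values (the smaller of the two row-wise adjusted values).
    """
    p = np.asarray(p_matrix, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("p matrix must be square")
    if mode not in ("any", "both"):
        raise ValueError("mode must be 'any' or 'both'")
    n = p.shape[0]
    reject_rows = np.zeros((n, n), dtype=bool)
    p_adj_rows = np.full((n, n), np.nan)
    for i in range(n):
        finite = np.isfinite(p[i])
        finite[i] = False
        if not finite.any():
            continue
        rej, p_adj, _, _ = multipletests(p[i, finite], alpha=alpha, method="fdr_bh")
        reject_rows[i, finite] = rej
        p_adj_rows[i, finite] = p_adj
    if mode == "any":
        selected = reject_rows | reject_rows.T
    else:
        selected = reject_rows & reject_rows.T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_adj = np.fmin(p_adj_rows, p_adj_rows.T)
    np.fill_diagonal(selected, False)
    return selected, p_adj


@dataclass
class ConnectionSet:
    """Selected connections-of-interest with class and compartment labels."""

    table: pd.DataFrame  # roi_i, roi_j (positions), cls, compartment, coefficient, p, p_fdr

    def counts(self) -> dict[tuple[str, str], int]:
        out = {(c, comp): 0 for c in CLASSES for comp in COMPARTMENTS}
        for _, row in self.table.iterrows():
            out[(row["cls"], row["compartment"])] += 1
        return out

    def members(self, cls: str, compartment: str) -> list[tuple[int, int]]:
        sub = self.table[
            (self.table["cls"] == cls) & (self.table["compartment"] == compartment)
        ]
        return [(int(r.roi_i), int(r.roi_j)) for r in sub.itertuples()]

    def __len__(self) -> int:
        return len(self.table)


def classify_and_compartment(
    coefficient: np.ndarray,
    selected: np.ndarray,
    p: np.ndarray,
    p_fdr: np.ndarray,
    labels: list[RoiLabel],
    canonical_side: str = "right",
) -> ConnectionSet:
    """Label selected connections hypo/hyper and assign compartments.

    Pairs touching midline ROIs belong to no compartment and are excluded;
    a selected pair with coefficient exactly 0 cannot be classed and is
    dropped with a warning.
    """
    rows = []
    n = coefficient.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if not selected[i, j]:
                continue
            comp = pair_compartment(labels, i, j, canonical_side=canonical_side)
            if comp is None:
                continue
            c = coefficient[i, j]
            if c == 0 or not np.isfinite(c):
                warnings.warn(
                    f"selected pair ({i}, {j}) has zero/undefined coefficient; dropped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "roi_i": i,
                    "roi_j": j,
                    "cls": "hypo" if c < 0 else "hyper",
                    "compartment": comp,
                    "coefficient": c,
                    "p": p[i, j],
                    "p_fdr": p_fdr[i, j],
                }
            )
    table = pd.DataFrame(
        rows, columns=["roi_i", "roi_j", "cls", "compartment", "coefficient", "p", "p_fdr"]
    )
    return ConnectionSet(table=table)


def select_connections(
    z_stack: np.ndarray,
    groups: np.ndarray,
    mean_fd: np.ndarray | None,
    labels: list[RoiLabel],
    alpha: float = DEFAULT_ALPHA,
    mode: str = "any",
    canonical_side: str = "right",
    min_per_group: int = 3,
) -> tuple[ConnectionSet, dict[str, np.ndarray]]:
    """Full selection stage: contrast, seed-level FDR, classification."""
    res = test_all_connections(z_stack, groups, mean_fd, min_per_group=min_per_group)
    selected, p_adj = seed_level_fdr(res["p"], alpha=alpha, mode=mode)
    conn = classify_and_compartment(
        res["coefficient"], selected, res["p"], p_adj, labels, canonical_side
    )
    res["selected"] = selected
    res["p_fdr"] = p_adj
    return conn, res
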