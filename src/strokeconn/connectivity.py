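"""ROI-to-ROI Fisher z-transformed correlation matrices."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: correlations are clipped to 1 - CLIP before atanh so perfectly correlated
#: pairs stay finite
CLIP = 1e-7
MIN_FRAMES = 3


def fisher_z(r):
    """Fisher z transform atanh(r), with |r| clipped to 1 - 1e-7.

    Accepts scalars or arrays; NaNs pass through.  Values outside [-1, 1]
    (beyond numerical tolerance) raise.
    """
    arr = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = np.abs(arr) > 1 + 1e-12
    if np.any(bad & np.isfinite(arr)):
        raise ValueError("correlations must lie in [-1, 1]")
    clipped = np.clip(arr, -1 + CLIP, 1 - CLIP)
    out = np.arctanh(clipped)
    if np.isscalar(r):
        return float(out)
    return out


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z matrix for one subject-session.

    The diagonal and any entry touching an unavailable ROI are NaN.
    """

    z: np.ndarray
    n_frames_used: int
    roi_availability: np.ndarray
    subject_id: str | None = None
    session: str | None = None
    roi_ids: list[int] | None = None

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]


def compute_matrix(
    roi_series: np.ndarray,
    censor_mask: np.ndarray | None = None,
    availability: np.ndarray | None = None,
    subject_id: str | None = None,
    session: str | None = None,
    roi_ids: list[int] | None = None,
) -> ConnectivityMatrix:
    """Pearson correlation over uncensored frames, Fisher z-transformed.

    Censored frames are excluded outright.  ROIs flagged unavailable (or
    whose series are NaN / have zero variance over the retained frames)
    yield NaN rows and columns.
    """
    series = np.asarray(roi_series, dtype=float)
    if series.ndim != 2:
        raise ValueError("roi_series must be (n_frames, n_rois)")
    n_frames, n_rois = series.shape
    if censor_mask is not None:
        censor_mask = np.asarray(censor_mask, dtype=bool)
        if censor_mask.shape != (n_frames,):
            raise ValueError("censor mask length mismatch")
        series = series[~censor_mask]
    n_used = series.shape[0]
    if n_used < MIN_FRAMES:
        raise ValueError(
            f"only {n_used} uncensored frames; need at least {MIN_FRAMES}"
        )
    if availability is None:
        avail = np.ones(n_rois, dtype=bool)
    else:
        avail = np.asarray(availability, dtype=bool).copy()
    avail &= np.all(np.isfinite(series), axis=0)
    spread = np.zeros(n_rois)
    spread[avail] = np.ptp(series[:, avail], axis=0)
    degenerate = avail & (spread == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} ROI(s) with zero variance; entries set missing",
            RuntimeWarning,
            stacklevel=2,
        )
        avail &= ~degenerate
    z = np.full((n_rois, n_rois), np.nan)
    idx = np.flatnonzero(avail)
    if idx.size >= 2:
        r = np.corrcoef(series[:, idx], rowvar=False)
        r = (r + r.T) / 2  # corrcoef can be asymmetric at the last ulp
        z_sub = fisher_z(r)
        z[np.ix_(idx, idx)] = z_sub
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(
        z=z,
        n_frames_used=n_used,
        roi_availability=avail,
        subject_id=subject_id,
        session=session,
        roi_ids=roi_ids,
    )


def matrix_to_long(cm: ConnectivityMatrix) -> pd.DataFrame:
    """Long-format table of the upper triangle (roi_i, roi_j, z)."""
    ids = cm.roi_ids if cm.roi_ids is not None else list(range(1, cm.n_rois + 1))
    ii, jj = np.triu_indices(cm.n_rois, k=1)
    return pd.DataFrame(
        {
            "roi_i": [ids[i] for i in ii],
            "roi_j": [ids[j] for j in jj],
            "z": cm.z[ii, jj],
        }
    )


def write_matrix_tsv(cm: ConnectivityMatrix, path) -> None:
    ids = cm.roi_ids if cm.roi_ids is not None else list(range(1, cm.n_rois + 1))
    pd.DataFrame(cm.z, index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="roi"
    )


def read_matrix_tsv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="roi")
    z = df.to_numpy(dtype=float)
    # availability: a row that is NaN everywhere off-diagonal is unavailable
    off = ~np.eye(len(z), dtype=bool)
    avail = np.array([np.isfinite(z[i][off[i]]).any() for i in range(len(z))])
    return ConnectivityMatrix(
        z=z,
        n_frames_used=-1,
        roi_availability=avail,
        roi_ids=[int(c) for c in df.columns],
    )
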