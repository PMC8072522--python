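"""Nuisance regression and band-pass filtering of BOLD time series.

The denoising chain is: (1) least-squares regression of an ordered confound
design (intercept, six realignment parameters, one indicator per censored
frame, k anatomical-noise principal components per tissue), then
(2) a hard FFT band-pass of the residuals.  Both steps are linear, so the
chain commutes with spatial averaging: denoising ROI-mean series equals
averaging denoised voxel series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_LOW_HZ = 0.009
DEFAULT_HIGH_HZ = 0.08
DEFAULT_N_COMPONENTS = 5


def _voxel_by_time(data, tissue_mask) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim == 4:
        if tissue_mask is None:
            raise ValueError("tissue_mask required for 4D input")
        mask = np.asarray(tissue_mask, dtype=bool)
        if mask.shape != data.shape[:3]:
            raise ValueError("tissue mask shape does not match BOLD grid")
        return data[mask]
    if data.ndim == 2:
        return data
    raise ValueError("expected 4D volume or 2D voxel-by-time matrix")


def compcor_components(data, tissue_mask=None, k: int = DEFAULT_N_COMPONENTS) -> np.ndarray:
    """Top-k principal-component time series of a tissue compartment (aCompCor).

    ``data`` is a 4D volume (with ``tissue_mask``) or a voxel-by-time matrix.
    Each voxel series is demeaned over time before the SVD, which makes the
    returned (n_frames, k) components exactly zero-mean; they are mutually
    orthonormal.  The sign of each component is fixed by making its
    largest-magnitude spatial loading positive.
    """
    x = _voxel_by_time(data, tissue_mask)
    n_vox, n_frames = x.shape
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return np.empty((n_frames, 0))
    if n_vox <= k:
        raise ValueError(f"tissue mask has {n_vox} voxels; need more than k={k}")
    if n_frames < k + 1:
        raise ValueError(f"need at least k+1={k + 1} frames, got {n_frames}")
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    comps = vt[:k].T.copy()  # (n_frames, k), orthonormal
    for j in range(k):
        i_max = int(np.argmax(np.abs(u[:, j])))
        if u[i_max, j] < 0:
            comps[:, j] = -comps[:, j]
    return comps


@dataclass
class ConfoundDesign:
    """Ordered confound regressors for one run."""

    matrix: np.ndarray  # (n_frames, n_columns)
    names: list[str]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def build_confound_design(
    n_frames: int,
    realignment=None,
    censor_mask=None,
    wm_components: np.ndarray | None = None,
    csf_components: np.ndarray | None = None,
) -> ConfoundDesign:
    """Assemble intercept + motion + censored-frame indicators + tissue PCs."""
    cols: list[np.ndarray] = [np.ones(n_frames)]
    names: list[str] = ["intercept"]
    if realignment is not None:
        from .motion import _as_params

        params = _as_params(realignment)
        if params.shape[0] != n_frames:
            raise ValueError("realignment frame count does not match n_frames")
        for j, name in enumerate(
            ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        ):
            cols.append(params[:, j])
            names.append(name)
    if censor_mask is not None:
        censor_mask = np.asarray(censor_mask, dtype=bool)
        if censor_mask.shape != (n_frames,):
            raise ValueError("censor mask length does not match n_frames")
        for t in np.flatnonzero(censor_mask):
            indicator = np.zeros(n_frames)
            indicator[t] = 1.0
            cols.append(indicator)
            names.append(f"spike_{t:04d}")
    for label, comps in (("wm", wm_components), ("csf", csf_components)):
        if comps is None:
            continue
        comps = np.asarray(comps, dtype=float)
        if comps.shape[0] != n_frames:
            raise ValueError(f"{label} components frame count mismatch")
        for j in range(comps.shape[1]):
            cols.append(comps[:, j])
            names.append(f"{label}_pc{j + 1}")
    return ConfoundDesign(matrix=np.column_stack(cols), names=names)


def regress_confounds(series: np.ndarray, design: ConfoundDesign) -> np.ndarray:
    """Residualize each column of ``series`` on the confound design.

    Columns that are entirely NaN (unavailable ROIs) are passed through
    unchanged.  Rank-deficient designs are handled by the pseudo-inverse with
    a warning; residuals are orthogonal to every design column either way.
    """
    series = np.asarray(series, dtype=float)
    one_d = series.ndim == 1
    if one_d:
        series = series[:, None]
    x = design.matrix
    if x.shape[0] != series.shape[0]:
        raise ValueError(
            f"design has {x.shape[0]} rows but series has {series.shape[0]} frames"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn(
            f"confound design is rank deficient ({rank}/{x.shape[1]}); "
            "using pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
    finite = np.all(np.isfinite(series), axis=0)
    resid = series.copy()
    if finite.any():
        beta = np.linalg.pinv(x) @ series[:, finite]
        resid[:, finite] = series[:, finite] - x @ beta
    return resid[:, 0] if one_d else resid


def _interpolate_censored(series: np.ndarray, censor_mask: np.ndarray) -> np.ndarray:
    """Linear interpolation across censored frames, per column."""
    keep = ~censor_mask
    if keep.sum() < 2:
        raise ValueError("need at least 2 uncensored frames to interpolate")
    t = np.arange(series.shape[0], dtype=float)
    out = series.copy()
    for j in range(series.shape[1]):
        col = series[:, j]
        if not np.all(np.isfinite(col)):
            continue
        out[censor_mask, j] = np.interp(t[censor_mask], t[keep], col[keep])
    return out


def bandpass(
    series: np.ndarray,
    tr: float,
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    censor_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Hard FFT band-pass keeping frequencies in [low, high] Hz.

    Censored frames are linearly interpolated before the transform so that
    artefactual frames do not leak into the pass band; callers keep the
    censor mask and continue to exclude those frames downstream.  The DC
    component is outside the band whenever ``low > 0``, so outputs are
    zero-mean per column.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    nyquist = 0.5 / tr
    if not (0 <= low < high < nyquist):
        raise ValueError(
            f"invalid band [{low}, {high}] Hz for Nyquist {nyquist:.4f} Hz"
        )
    series = np.asarray(series, dtype=float)
    one_d = series.ndim == 1
    if one_d:
        series = series[:, None]
    n = series.shape[0]
    work = series
    if censor_mask is not None:
        censor_mask = np.asarray(censor_mask, dtype=bool)
        if censor_mask.shape != (n,):
            raise ValueError("censor mask length mismatch")
        if censor_mask.any():
            work = _interpolate_censored(series, censor_mask)
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    finite = np.all(np.isfinite(work), axis=0)
    out = work.copy()
    if finite.any():
        spec = np.fft.rfft(work[:, finite], axis=0)
        spec[~keep] = 0.0
        out[:, finite] = np.fft.irfft(spec, n=n, axis=0)
    if low == 0:
        out[:, finite] -= out[:, finite].mean(axis=0, keepdims=True)
    return out[:, 0] if one_d else out


def denoise_series(
    series: np.ndarray,
    design: ConfoundDesign,
    tr: float,
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    censor_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Full chain: confound regression, then band-pass filtering."""
    resid = regress_confounds(series, design)
    return bandpass(resid, tr, low=low, high=high, censor_mask=censor_mask)
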