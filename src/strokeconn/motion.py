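"""Head-motion metrics and frame censoring ("scrubbing").

Frame-wise displacement (FD) is the Power composite: the sum of absolute
frame-to-frame changes of the three translations (mm) plus the three
rotations (radians) projected onto a sphere of radius 50 mm.  Frames are
censored when FD exceeds 0.5 mm or when the global percent BOLD change
exceeds 50 Δ%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical realignment-parameter column order (translations in mm,
#: rotations in radians)
REALIGNMENT_COLUMNS = [
    "trans_x_mm",
    "trans_y_mm",
    "trans_z_mm",
    "rot_x_rad",
    "rot_y_rad",
    "rot_z_rad",
]

DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_BOLD_THRESHOLD_PCT = 50.0
DEFAULT_SPHERE_RADIUS_MM = 50.0


def _as_params(realignment) -> np.ndarray:
    if isinstance(realignment, pd.DataFrame):
        missing = [c for c in REALIGNMENT_COLUMNS if c not in realignment.columns]
        if missing:
            if realignment.shape[1] == 6:
                arr = realignment.to_numpy(dtype=float)
            else:
                raise ValueError(
                    f"realignment table missing columns {missing}; "
                    f"expected {REALIGNMENT_COLUMNS}"
                )
        else:
            arr = realignment[REALIGNMENT_COLUMNS].to_numpy(dtype=float)
    else:
        arr = np.asarray(realignment, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(
            f"realignment parameters must be (n_frames, 6), got {arr.shape}"
        )
    if arr.shape[0] < 2:
        raise ValueError("FD requires at least 2 frames")
    if not np.all(np.isfinite(arr)):
        raise ValueError("realignment parameters contain non-finite entries")
    return arr


def compute_fd(
    realignment,
    radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
    degrees: bool = False,
) -> np.ndarray:
    """Frame-wise displacement in mm (Power composite), first frame = 0.

    Parameters
    ----------
    realignment:
        (n_frames, 6) array or DataFrame with columns
        ``trans_{x,y,z}_mm`` and ``rot_{x,y,z}_rad``.
    radius_mm:
        Sphere radius converting rotation angles to arc displacement.
    degrees:
        If the rotation columns are in degrees, convert them first.
    """
    params = _as_params(realignment)
    if degrees:
        params = params.copy()
        params[:, 3:] = np.deg2rad(params[:, 3:])
    diffs = np.abs(np.diff(params, axis=0))
    fd = diffs[:, :3].sum(axis=1) + radius_mm * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def compute_global_change(bold: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Per-frame global percent BOLD change, first frame = 0.

    Defined as ``100 * |g_t - g_{t-1}| / mean(g)`` where ``g_t`` is the
    mean intensity within ``brain_mask`` at frame t.  Scale-invariant.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4:
        raise ValueError(f"expected 4D BOLD volume, got shape {bold.shape}")
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != bold.shape[:3]:
        raise ValueError("brain mask shape does not match BOLD grid")
    if not mask.any():
        raise ValueError("brain mask is empty")
    g = bold[mask].mean(axis=0)
    g_mean = g.mean()
    if g_mean <= 0:
        raise ValueError("mean within-mask intensity must be positive")
    change = 100.0 * np.abs(np.diff(g)) / g_mean
    return np.concatenate([[0.0], change])


@dataclass
class MotionSummary:
    """Scrubbing summary for one run.

    ``censor_mask[t]`` is True when frame t is censored.  ``mean_fd`` is the
    arithmetic mean of FD over *all* frames (censored included) and is the
    value used downstream as nuisance regressor.
    """

    fd: np.ndarray
    global_change: np.ndarray
    censor_mask: np.ndarray
    mean_fd: float
    censored_fraction: float
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM
    bold_threshold: float = DEFAULT_BOLD_THRESHOLD_PCT

    @property
    def n_frames(self) -> int:
        return self.fd.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "fd": self.fd,
                "global_change": self.global_change,
                "censored": self.censor_mask.astype(int),
            }
        )


def build_censor_mask(
    fd: np.ndarray,
    global_change: np.ndarray | None = None,
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
    bold_threshold: float = DEFAULT_BOLD_THRESHOLD_PCT,
    pad: int = 0,
) -> MotionSummary:
    """Censor frames with FD > fd_threshold or |Δ%BOLD| > bold_threshold.

    ``pad > 0`` additionally censors that many neighbours on each side of
    every flagged frame (off by default).
    """
    fd = np.asarray(fd, dtype=float)
    if global_change is None:
        global_change = np.zeros_like(fd)
    global_change = np.asarray(global_change, dtype=float)
    if fd.shape != global_change.shape:
        raise ValueError("fd and global_change must have equal length")
    if fd.ndim != 1:
        raise ValueError("fd must be one-dimensional")
    mask = (fd > fd_threshold) | (np.abs(global_change) > bold_threshold)
    if pad > 0:
        flagged = np.flatnonzero(mask)
        for t in flagged:
            mask[max(0, t - pad) : t + pad + 1] = True
    return MotionSummary(
        fd=fd,
        global_change=global_change,
        censor_mask=mask,
        mean_fd=float(fd.mean()),
        censored_fraction=float(mask.mean()),
        fd_threshold=fd_threshold,
        bold_threshold=bold_threshold,
    )


def summarize_motion(
    realignment,
    bold: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
    bold_threshold: float = DEFAULT_BOLD_THRESHOLD_PCT,
    radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
    degrees: bool = False,
    pad: int = 0,
) -> MotionSummary:
    """Convenience chain: FD + global change + censor mask in one call."""
    fd = compute_fd(realignment, radius_mm=radius_mm, degrees=degrees)
    if bold is not None:
        if brain_mask is None:
            raise ValueError("brain_mask required when BOLD data are supplied")
        gc = compute_global_change(bold, brain_mask)
        if gc.shape != fd.shape:
            raise ValueError("BOLD frame count does not match realignment table")
    else:
        gc = None
    return build_censor_mask(
        fd, gc, fd_threshold=fd_threshold, bold_threshold=bold_threshold, pad=pad
    )


def read_realignment(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"realignment TSV {path} missing columns {missing}")
    return df[REALIGNMENT_COLUMNS]


def write_motion_summary(summary: MotionSummary, path) -> None:
    summary.to_frame().to_csv(path, sep="\t", index=False)


def read_motion_summary(path) -> MotionSummary:
    df = pd.read_csv(path, sep="\t")
    fd = df["fd"].to_numpy(dtype=float)
    gc = df["global_change"].to_numpy(dtype=float)
    mask = df["censored"].to_numpy(dtype=bool)
    return MotionSummary(
        fd=fd,
        global_change=gc,
        censor_mask=mask,
        mean_fd=float(fd.mean()),
        censored_fraction=float(mask.mean()),
    )
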