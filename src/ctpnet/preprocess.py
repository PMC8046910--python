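"""Temporal-domain preprocessing and motion quality control.

Spatial registration steps (slice timing, motion correction, template
normalisation) are assumed done upstream: inputs are already-aligned
volumes. The stages here are the temporal ones: leading-volume discard,
linear detrend + 0.01-0.08 Hz band-pass, nuisance regression (Friston-24
motion expansion plus white-matter and CSF mean signals), Gaussian spatial
smoothing, task-run high-pass filtering, and the 1.5 mm / 1.5 deg motion
exclusion rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, ndimage, signal

from .base import BoldRun, MaskVolume

logger = logging.getLogger(__name__)

MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                  "rot_x_deg", "rot_y_deg", "rot_z_deg"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MotionSummary:
    """Motion QC result: per-axis maxima, exclusion flag, Friston-24 matrix."""

    max_abs_translation_mm: np.ndarray
    max_abs_rotation_deg: np.ndarray
    excluded: bool
    friston24: np.ndarray
    threshold_mm: float = 1.5
    threshold_deg: float = 1.5


def discard_initial_volumes(run: BoldRun, n: int) -> BoldRun:
    """Drop the first ``n`` volumes (signal-equilibrium period)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= run.n_volumes:
        raise ValueError(f"cannot discard {n} of {run.n_volumes} volumes")
    if n == 0:
        return run
    return replace(run, data=run.data[..., n:], n_discarded=run.n_discarded + n)


def friston24(params: np.ndarray) -> np.ndarray:
    """Friston-24 expansion: [p, p(t-1), p^2, p(t-1)^2], lag row zero-filled."""
    p = np.asarray(params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion parameters must be a t x 6 array")
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, lag, p ** 2, lag ** 2])


def motion_qc(motion_table, threshold_mm: float = 1.5,
              threshold_deg: float = 1.5) -> MotionSummary:
    """Apply the strict > 1.5 mm / > 1.5 deg exclusion rule and build Friston-24.

    ``motion_table`` is a DataFrame with the six rigid-body columns
    (translations in mm then rotations in degrees) or an equivalent array.
    A value of exactly 1.5 does not exclude ("larger than" is strict).
    """
    if isinstance(motion_table, pd.DataFrame):
        missing = [c for c in MOTION_COLUMNS if c not in motion_table.columns]
        if not missing:
            params = motion_table[MOTION_COLUMNS].to_numpy(dtype=float)
        elif motion_table.shape[1] == 6:
            params = motion_table.to_numpy(dtype=float)
        else:
            raise ValueError(f"motion table must have 6 columns, missing {missing}")
    else:
        params = np.asarray(motion_table, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6 or params.shape[0] < 1:
        raise ValueError("motion table must have shape (t, 6) with t >= 1")
    max_trans = np.abs(params[:, :3]).max(axis=0)
    max_rot = np.abs(params[:, 3:]).max(axis=0)
    excluded = bool((max_trans > threshold_mm).any() or (max_rot > threshold_deg).any())
    return MotionSummary(max_abs_translation_mm=max_trans,
                         max_abs_rotation_deg=max_rot,
                         excluded=excluded,
                         friston24=friston24(params),
                         threshold_mm=threshold_mm,
                         threshold_deg=threshold_deg)


def detrend_bandpass(run: BoldRun, low_hz: float = 0.01,
                     high_hz: float = 0.08, order: int = 2) -> BoldRun:
    """Remove per-voxel mean and linear trend, then band-pass filter.

    The band-pass is a zero-phase (forward-backward) Butterworth filter, so
    the timing of transient events is not shifted.
    """
    nyquist = 0.5 / run.tr_s
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist {nyquist}")
    if run.n_volumes < 16:
        raise ValueError("band-pass needs at least 16 volumes")
    shape3 = run.shape3d
    y = run.data.reshape(-1, run.n_volumes)
    y = signal.detrend(y, axis=1, type="linear")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / run.tr_s, output="sos")
    y = signal.sosfiltfilt(sos, y, axis=1)
    return run.with_data(y.reshape(*shape3, run.n_volumes))


def nuisance_regress(run: BoldRun, regressors: np.ndarray) -> BoldRun:
    """Replace every voxel by its least-squares residual against the design.

    The design is [intercept | regressors]; collinear columns are dropped
    with a warning so the fit stays well posed.
    """
    R = np.asarray(regressors, dtype=float)
    if R.ndim != 2 or R.shape[0] != run.n_volumes:
        raise ValueError("regressors must be (t, k) matching the run length")
    if R.shape[1] >= run.n_volumes:
        raise ValueError("more regressors than time points")
    if not np.all(np.isfinite(R)):
        raise ValueError("regressors must be finite")
    X = np.hstack([np.ones((run.n_volumes, 1)), R])
    X = _drop_collinear(X)
    y = run.data.reshape(-1, run.n_volumes).T  # (t, V)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return run.with_data(resid.T.reshape(run.data.shape))


def _drop_collinear(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    keep_rank = int((diag > tol * max(diag[0], 1.0)).sum())
    if keep_rank < X.shape[1]:
        dropped = sorted(piv[keep_rank:])
        warnings.warn(f"dropping {X.shape[1] - keep_rank} collinear design "
                      f"column(s): {dropped}")
        keep = sorted(piv[:keep_rank])
        X = X[:, keep]
    return X


def smooth_gaussian(data: np.ndarray, fwhm_mm: float,
                    voxel_size_mm) -> np.ndarray:
    """Separable Gaussian smoothing of a 3D volume or 4D run (per volume).

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, converted from mm to voxels.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return np.array(data, dtype=float, copy=True)
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
    arr = np.asarray(data, dtype=float)
    # truncate at 6 sigma so the discrete kernel matches the analytic
    # Gaussian to well below 1e-6
    if arr.ndim == 3:
        return ndimage.gaussian_filter(arr, sigma=sigma_vox, truncate=6.0)
    if arr.ndim == 4:
        return ndimage.gaussian_filter(arr, sigma=(*sigma_vox, 0.0), truncate=6.0)
    raise ValueError("expected a 3D volume or 4D run")


def smooth_run(run: BoldRun, fwhm_mm: float = 4.0) -> BoldRun:
    return run.with_data(smooth_gaussian(run.data, fwhm_mm, run.voxel_size_mm))


def dct_drift_basis(n_volumes: int, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine basis spanning fluctuations slower than ``cutoff_s``.

    Columns are cos(pi k (t + 1/2) / T) for k = 1..K with K chosen so the
    slowest excluded frequency is 1/cutoff_s; may be empty for short runs.
    """
    duration = n_volumes * tr_s
    k_max = int(np.floor(2.0 * duration / cutoff_s))
    t = np.arange(n_volumes)
    basis = [np.cos(np.pi * k * (t + 0.5) / n_volumes) for k in range(1, k_max + 1)]
    return np.column_stack(basis) if basis else np.empty((n_volumes, 0))


def highpass_task(run: BoldRun, cutoff_s: float = 128.0) -> BoldRun:
    """Project out slow drift via the discrete-cosine basis (task runs)."""
    if run.provenance != "task":
        raise ValueError("highpass_task expects a task-provenance run")
    if cutoff_s <= 2.0 * run.tr_s:
        raise ValueError("cutoff_s must exceed twice the TR")
    basis = dct_drift_basis(run.n_volumes, run.tr_s, cutoff_s)
    if basis.shape[1] == 0:
        # nothing slower than the cutoff fits in the run; remove the mean only
        return run.with_data(run.data - run.data.mean(axis=3, keepdims=True))
    return nuisance_regress(run, basis)


def extract_mask_mean(run: BoldRun, mask: MaskVolume) -> np.ndarray:
    """Mean time course over a mask (e.g. white matter or CSF compartment)."""
    return run.data[mask.data].mean(axis=0)
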