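"""Minimal resting-state preprocessing.

Temporal high-pass filtering by a Gaussian-weighted running-line fit
(sigma given in seconds), spatial smoothing by a Gaussian kernel of given
FWHM with mask renormalization, framewise displacement from rigid-body
motion parameters, and nuisance handling by partial correlation.  The
default pipeline runs without nuisance regression; the partial-correlation
path is an opt-in validation route.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import BoldRun, warn_undefined

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def running_line_matrix(n_timepoints: int, sigma_samples: float) -> np.ndarray:
    """Hat matrix of the Gaussian-weighted running-line smoother.

    Row t0 gives the fitted value at t0 of a straight line fit to the whole
    series under Gaussian weights of SD ``sigma_samples`` centred at t0.
    """
    t = np.arange(n_timepoints, dtype=float)
    d = t[None, :] - t[:, None]                      # (t0, i)
    w = np.exp(-0.5 * (d / sigma_samples) ** 2)
    s0 = w.sum(axis=1, keepdims=True)
    s1 = (w * d).sum(axis=1, keepdims=True)
    s2 = (w * d * d).sum(axis=1, keepdims=True)
    det = s0 * s2 - s1 ** 2
    return w * (s2 - s1 * d) / det


def highpass_filter(series, sigma_s: float, tr_s: float) -> np.ndarray:
    """High-pass a time series by subtracting a Gaussian-weighted running line.

    At each timepoint a line is fit to the series under Gaussian weights of
    SD ``sigma_s / tr_s`` samples centred there; the fitted value is
    subtracted and the series mean added back.  Accepts a 1D series or an
    array with time on the last axis; the operation is linear in its input.
    """
    if not sigma_s > 0:
        raise ValueError("sigma_s must be > 0")
    if not tr_s > 0:
        raise ValueError("tr_s must be > 0")
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    if n < 3:
        raise ValueError("series length must be >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    smoother = running_line_matrix(n, sigma_s / tr_s)
    trend = x @ smoother.T
    return x - trend + x.mean(axis=-1, keepdims=True)


def spatial_smooth(volume, fwhm_mm: float, voxel_mm, mask=None,
                   mode: str = "constant") -> np.ndarray:
    """Gaussian spatial smoothing, sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    3D volumes are smoothed directly; 4D volumes per timepoint (the time axis
    is untouched).  The volume is zero-padded outside the mask (the full grid
    when no mask is given) and renormalized by the smoothed mask, which
    preserves constants and avoids edge darkening inside small brain masks;
    out-of-mask voxels are returned as zero.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    vol = np.asarray(volume)
    if vol.ndim not in (3, 4):
        raise ValueError("volume must be 3D or 4D")
    voxel_mm = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    if np.any(voxel_mm <= 0):
        raise ValueError("voxel sizes must be > 0")
    if fwhm_mm == 0:
        return vol.copy()
    sigma = tuple(fwhm_mm * FWHM_TO_SIGMA / voxel_mm)
    if vol.ndim == 4:
        sigma = sigma + (0.0,)
    dtype = np.promote_types(vol.dtype, np.float32)
    vol = vol.astype(dtype, copy=False)
    if mask is None:
        mask = np.ones(vol.shape[:3], dtype=bool)
    m = mask.astype(dtype)
    num = vol * (m[..., None] if vol.ndim == 4 else m)
    num = gaussian_filter(num, sigma=sigma, mode=mode)
    den = gaussian_filter(m, sigma=sigma[:3], mode=mode)
    out = np.zeros_like(num)
    if vol.ndim == 3:
        out[mask] = num[mask] / den[mask]
    else:
        out[mask, :] = num[mask, :] / den[mask][:, None]
    return out


def framewise_displacement(motion_params, head_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement (Power variant) from 6 rigid-body parameters.

    Columns are three rotations (radians) then three translations (mm);
    FD_t = sum |delta translations| + radius * sum |delta rotations|, with
    FD_0 = 0.  Invariant to constant offsets in the parameters.
    """
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValueError(f"motion parameters must be (t, 6), got {mp.shape}")
    if mp.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    d = np.abs(np.diff(mp, axis=0))
    fd = d[:, 3:].sum(axis=1) + head_radius_mm * d[:, :3].sum(axis=1)
    return np.concatenate([[0.0], fd])


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_correlation(x, y, nuisance=()) -> float:
    """Pearson correlation of x and y after projecting out nuisance series.

    Residuals are taken against the nuisance set plus an intercept, so an
    empty nuisance set reduces to the plain Pearson correlation.  A series
    that is constant after projection yields NaN with an
    :class:`~roifc.core.UndefinedResultWarning` (flagged undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nuis = [np.asarray(n, dtype=float) for n in nuisance]
    n = x.shape[0]
    if y.shape[0] != n or any(v.shape[0] != n for v in nuis):
        raise ValueError("all series must have the same length")
    if n <= len(nuis) + 2:
        raise ValueError("series too short for the number of nuisance regressors")
    design = np.column_stack([np.ones(n)] + nuis)
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = rx.std(), ry.std()
    if sx < 1e-12 * max(1.0, np.abs(x).max()) or \
       sy < 1e-12 * max(1.0, np.abs(y).max()) or sx == 0 or sy == 0:
        warn_undefined("partial correlation undefined: a series is constant "
                       "after nuisance projection")
        return float("nan")
    return float(np.dot(rx, ry) / (n * sx * sy))


def preprocess_run(run: BoldRun, mask=None, hp_sigma_s: float = 100.0,
                   fwhm_mm: float = 4.0) -> BoldRun:
    """High-pass filter then smooth one run; returns a new BoldRun (float32)."""
    from .core import voxel_sizes
    data = run.data.astype(np.float32)
    if hp_sigma_s:
        shape = data.shape
        flat = data.reshape(-1, shape[3])
        smoother = running_line_matrix(shape[3], hp_sigma_s / run.tr_s).astype(np.float32)
        mean = flat.mean(axis=1, keepdims=True)
        flat = flat - flat @ smoother.T + mean
        data = flat.reshape(shape)
    if fwhm_mm:
        data = spatial_smooth(data, fwhm_mm, voxel_sizes(run.affine),
                              mask=mask).astype(np.float32)
    return BoldRun(data=data, affine=run.affine, tr_s=run.tr_s,
                   subject_id=run.subject_id)
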