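"""Post-processing of component time courses.

The cleaning chain applied to every ICA component time course before
connectivity analysis, in fixed order:

1. polynomial detrending (linear, quadratic and cubic trends removed),
2. nuisance regression of the six rigid-motion parameters and their
   temporal derivatives,
3. despiking (bounded compression of outliers around a running-median
   baseline, standing in for AFNI 3dDespike),
4. zero-phase low-pass Butterworth filtering at 0.15 Hz.

Framewise displacement from the motion parameters is provided for
motion screening (Power-style sum of absolute derivatives with a 50 mm
head radius).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from scipy.ndimage import median_filter

from .cohort import ComponentTimeSeriesSet
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "detrend_poly",
    "regress_nuisance",
    "despike",
    "lowpass",
    "framewise_displacement",
    "postprocess_subject",
    "postprocess_cohort",
]

_MAD_SCALE = 1.4826  # consistency factor: MAD -> Gaussian sigma


def detrend_poly(series: np.ndarray, order: int = 3) -> np.ndarray:
    """Residual of an OLS polynomial fit (with intercept) in the time index.

    Works on the last axis; batch dimensions are supported.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < order + 2:
        raise InvalidInputError(f"series of length {n} too short for order-{order} detrend")
    t = np.arange(n, dtype=float)
    t = (t - t.mean()) / t.std()  # conditioning only; span unchanged
    design = np.vander(t, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, np.moveaxis(series, -1, 0).reshape(n, -1), rcond=None)
    fit = design @ coef
    resid = np.moveaxis(series, -1, 0).reshape(n, -1) - fit
    return np.moveaxis(resid.reshape((n,) + series.shape[:-1]), 0, -1)


def _motion_design(motion: np.ndarray) -> np.ndarray:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise InvalidInputError("motion parameters must be a (time, 6) array")
    if not np.all(np.isfinite(motion)):
        raise InvalidInputError("non-finite motion parameters")
    deriv = np.vstack([np.zeros(6), np.diff(motion, axis=0)])  # backward difference
    n = motion.shape[0]
    return np.column_stack([np.ones(n), motion, deriv])


def regress_nuisance(series: np.ndarray, motion: np.ndarray) -> np.ndarray:
    """Residualize against [intercept, 6 motion params, their derivatives].

    Rank-deficient designs are solved by pseudoinverse with a warning.
    """
    series = np.asarray(series, dtype=float)
    design = _motion_design(motion)
    n = design.shape[0]
    if series.shape[-1] != n:
        raise InvalidInputError(
            f"motion rows ({n}) do not match series length ({series.shape[-1]})"
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("rank-deficient nuisance design; using pseudoinverse", stacklevel=2)
    y = np.moveaxis(series, -1, 0).reshape(n, -1)
    coef = np.linalg.pinv(design) @ y
    resid = y - design @ coef
    return np.moveaxis(resid.reshape((n,) + series.shape[:-1]), 0, -1)


def despike(
    series: np.ndarray,
    c1: float = 2.5,
    c2: float = 4.0,
    window: int = 7,
) -> np.ndarray:
    """Compress outliers around a running-median baseline.

    Residuals from a window-7 running median whose magnitude exceeds
    ``c1 * (1.4826 * MAD)`` are squashed by a tanh map saturating at
    ``c2 * (1.4826 * MAD)``; everything else is untouched.  A constant
    residual profile (MAD = 0) returns the input unchanged.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 11:
        raise InvalidInputError("despike requires at least 11 time points")
    if not (c2 > c1 > 0):
        raise InvalidParameterError("need 0 < c1 < c2")
    if series.ndim == 1:
        return _despike_1d(series, c1, c2, window)
    out = np.empty_like(series)
    flat = series.reshape(-1, series.shape[-1])
    oflat = out.reshape(-1, series.shape[-1])
    for idx in range(flat.shape[0]):
        oflat[idx] = _despike_1d(flat[idx], c1, c2, window)
    return out


def _despike_1d(x: np.ndarray, c1: float, c2: float, window: int) -> np.ndarray:
    base = median_filter(x, size=window, mode="nearest")
    resid = x - base
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = _MAD_SCALE * mad
    if sigma == 0.0:
        return x.copy()
    lo, hi = c1 * sigma, c2 * sigma
    absr = np.abs(resid)
    flagged = absr > lo
    compressed = np.sign(resid) * (lo + (hi - lo) * np.tanh((absr - lo) / (hi - lo)))
    return np.where(flagged, base + compressed, x)


def lowpass(series: np.ndarray, cutoff: float = 0.15, tr: float = 3.0) -> np.ndarray:
    """Zero-phase (forward-backward) order-4 Butterworth low-pass filter."""
    series = np.asarray(series, dtype=float)
    nyquist = 1.0 / (2.0 * tr)
    if not 0.0 < cutoff < nyquist:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist = {nyquist:.4f} Hz) at tr = {tr}"
        )
    b, a = signal.butter(4, cutoff / nyquist)
    return signal.filtfilt(b, a, series, axis=-1)


def framewise_displacement(motion: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Power-style FD: sum of absolute parameter derivatives, rotations
    converted to arc length on a sphere of ``radius`` mm.

    Returns one value per transition (length = rows - 1), nonnegative.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise InvalidInputError("motion must be (>=2, 6)")
    d = np.abs(np.diff(motion, axis=0))
    return d[:, :3].sum(axis=1) + radius * d[:, 3:].sum(axis=1)


def postprocess_subject(
    data: np.ndarray,
    motion: np.ndarray | None = None,
    tr: float = 3.0,
    cutoff: float = 0.15,
    detrend_order: int = 3,
    despike_c1: float = 2.5,
    despike_c2: float = 4.0,
) -> np.ndarray:
    """Detrend -> nuisance-regress -> despike -> low-pass one subject's
    (components x time) matrix.  ``motion=None`` skips the regression
    (synthetic cohorts carry no motion files)."""
    x = detrend_poly(data, order=detrend_order)
    if motion is not None:
        x = regress_nuisance(x, motion)
    x = despike(x, c1=despike_c1, c2=despike_c2)
    return lowpass(x, cutoff=cutoff, tr=tr)


def postprocess_cohort(
    tsset: ComponentTimeSeriesSet,
    motions: list[np.ndarray] | None = None,
    **kwargs,
) -> ComponentTimeSeriesSet:
    """Apply :func:`postprocess_subject` to every subject of a cohort."""
    if motions is not None and len(motions) != tsset.n_subjects:
        raise InvalidInputError("one motion-parameter array per subject required")
    out = np.empty_like(tsset.data)
    for s in range(tsset.n_subjects):
        motion = motions[s] if motions is not None else None
        out[s] = postprocess_subject(tsset.data[s], motion=motion, tr=tsset.tr, **kwargs)
    return ComponentTimeSeriesSet(
        data=out,
        labels=tsset.labels,
        tr=tsset.tr,
        subject_ids=list(tsset.subject_ids),
        component_names=list(tsset.component_names),
        networks=list(tsset.networks),
    )
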