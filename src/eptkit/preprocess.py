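"""Per-voxel time-course cleaning.

Extreme-time-point selection is sensitive to noise: a spike or a slow drift
can change which frames survive a threshold or appear as local extrema.  The
cleaning chain therefore runs, in fixed order:

1. polynomial detrending (linear, quadratic and cubic trends),
2. nuisance regression against six motion parameters and their first
   derivatives,
3. outlier (spike) replacement — frames more than ``c1`` robust standard
   deviations from the voxel median (median absolute deviation criterion,
   c1 = 2.5) are replaced by a third-order spline fit to the clean frames,
4. zero-phase fifth-order Butterworth band-pass, 0.01-0.15 Hz.

All steps are ordinary least squares / standard DSP; they are applied to
voxel courses before any node averaging or time-point selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .core import BoldRun, NuisanceSet

__all__ = [
    "CleaningConfig",
    "detrend_poly",
    "regress_nuisance",
    "despike_mad",
    "bandpass",
    "clean_run",
]

MAD_SCALE = 1.4826  # consistency factor: 1/Phi^-1(3/4), MAD -> Gaussian sigma


@dataclass
class CleaningConfig:
    """Cleaning parameters; defaults are the standard pipeline values."""

    detrend: bool = True
    detrend_orders: tuple = (1, 2, 3)
    nuisance: bool = True
    despike: bool = True
    spike_threshold: float = 2.5      # c1, in robust-sigma units
    spline_order: int = 3
    filter: bool = True
    band: tuple = (0.01, 0.15)        # Hz
    filter_order: int = 5

    def validate(self, tr: float) -> None:
        low, high = self.band
        nyq = 0.5 / tr
        if not (0 < low < high < nyq):
            raise ValueError(
                f"band {self.band} invalid for Nyquist {nyq:.3f} Hz (TR={tr})"
            )


def _poly_design(n_frames: int, orders: tuple = (1, 2, 3)) -> np.ndarray:
    u = np.linspace(-1.0, 1.0, n_frames)
    cols = [np.ones(n_frames)] + [u**o for o in orders]
    return np.column_stack(cols)


def detrend_poly(tc: np.ndarray, orders: tuple = (1, 2, 3)) -> np.ndarray:
    """Residual of a least-squares fit against {1, t, t^2, t^3}.

    Accepts a single course (length T) or a stack (V x T); the residual is
    orthogonal to the polynomial regressors.
    """
    tc = np.asarray(tc, dtype=float)
    squeeze = tc.ndim == 1
    X = np.atleast_2d(tc)
    T = X.shape[1]
    if T < 8:
        raise ValueError("need at least 8 frames to fit cubic trends")
    D = _poly_design(T, orders)
    beta, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    res = X - (D @ beta).T
    return res[0] if squeeze else res


def regress_nuisance(data: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """OLS-residualise each voxel course on nuisance columns + intercept.

    Collinear nuisance columns are dropped (with a warning) so the design
    is full rank.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    squeeze = np.asarray(data).ndim == 1
    if nuisance.n_frames != X.shape[1]:
        raise ValueError(
            f"nuisance has {nuisance.n_frames} rows but data has {X.shape[1]} frames"
        )
    D = np.column_stack([np.ones(X.shape[1]), nuisance.matrix])
    # drop collinear columns, keeping the earliest of each dependent group
    q, r = np.linalg.qr(D)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        dropped = [nuisance.columns[i - 1] for i in np.flatnonzero(~keep) if i > 0]
        warnings.warn(f"dropping collinear nuisance columns: {dropped}")
        D = D[:, keep]
    beta, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    res = X - (D @ beta).T
    return res[0] if squeeze else res


def despike_mad(
    tc: np.ndarray, c1: float = 2.5, spline_order: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Flag and replace spikes by the median-absolute-deviation rule.

    Frame *t* is flagged iff ``|tc(t) - median| > c1 * 1.4826 * MAD``.
    Flagged frames are replaced by a spline of order ``spline_order`` fit to
    the unflagged frames (boundary outliers by extrapolation); unflagged
    frames are returned unchanged.  Returns ``(cleaned, flagged_indices)``.
    """
    tc = np.asarray(tc, dtype=float).ravel()
    T = tc.size
    if T < 10:
        raise ValueError("need at least 10 frames to despike")
    med = np.median(tc)
    mad = np.median(np.abs(tc - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers flagged")
        return tc.copy(), np.empty(0, dtype=int)
    flagged = np.flatnonzero(np.abs(tc - med) > c1 * MAD_SCALE * mad)
    if flagged.size > 0.3 * T:
        raise ValueError(
            f"{flagged.size}/{T} frames flagged as outliers (> 30%); "
            "refusing to despike a signal of this quality"
        )
    if flagged.size == 0:
        return tc.copy(), flagged
    clean_idx = np.setdiff1d(np.arange(T), flagged)
    if spline_order == 3:
        spline = CubicSpline(clean_idx, tc[clean_idx], extrapolate=True)
    else:
        from scipy.interpolate import make_interp_spline

        spline = make_interp_spline(clean_idx, tc[clean_idx], k=spline_order)
    out = tc.copy()
    out[flagged] = spline(flagged)
    return out, flagged


def _butter_sos(tr: float, band: tuple, order: int):
    nyq = 0.5 / tr
    return sps.butter(order, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")


def bandpass(
    tc: np.ndarray,
    tr: float,
    low: float = 0.01,
    high: float = 0.15,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass.

    Works on a single course or a V x T stack (filtered along the last
    axis).  Forward-backward application doubles the effective order and
    cancels phase distortion.
    """
    tc = np.asarray(tc, dtype=float)
    nyq = 0.5 / tr
    if not (0 < low < high < nyq):
        raise ValueError(f"band [{low}, {high}] invalid for Nyquist {nyq:.3f} Hz")
    sos = _butter_sos(tr, (low, high), order)
    # sosfiltfilt default padding: 3 * (2 * n_sections + 1 - min(...)) ~ 3*(order+1)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if tc.shape[-1] <= padlen:
        raise ValueError(
            f"time course of length {tc.shape[-1]} too short for filtering; "
            f"need more than {padlen} frames"
        )
    return sps.sosfiltfilt(sos, tc, axis=-1)


def clean_run(
    run: BoldRun,
    nuisance: NuisanceSet | None = None,
    cfg: CleaningConfig | None = None,
) -> tuple[BoldRun, dict]:
    """Apply the full cleaning chain to every voxel of a run.

    Order is fixed: detrend -> nuisance regression -> despike -> band-pass.
    Returns the cleaned run and a QC log with per-voxel outlier counts and
    the applied configuration.
    """
    cfg = cfg or CleaningConfig()
    cfg.validate(run.tr)
    X = run.data.copy()
    qc: dict = {
        "order": ["detrend", "nuisance", "despike", "bandpass"],
        "steps_applied": [],
        "outlier_counts": np.zeros(run.n_voxels, dtype=int),
    }
    if cfg.detrend:
        X = detrend_poly(X, cfg.detrend_orders)
        qc["steps_applied"].append("detrend")
    if cfg.nuisance and nuisance is not None:
        X = regress_nuisance(X, nuisance)
        qc["steps_applied"].append("nuisance")
    if cfg.despike:
        counts = qc["outlier_counts"]
        # vectorised MAD screen; spline infill only where something is flagged
        med = np.median(X, axis=1, keepdims=True)
        mad = np.median(np.abs(X - med), axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            hits = np.abs(X - med) > cfg.spike_threshold * MAD_SCALE * np.where(mad == 0, np.inf, mad)
        for v in np.flatnonzero(hits.any(axis=1)):
            try:
                X[v], flagged = despike_mad(X[v], cfg.spike_threshold, cfg.spline_order)
            except ValueError as err:
                raise ValueError(f"voxel {v}: {err}") from err
            counts[v] = flagged.size
        qc["steps_applied"].append("despike")
    if cfg.filter:
        X = bandpass(X, run.tr, cfg.band[0], cfg.band[1], cfg.filter_order)
        qc["steps_applied"].append("bandpass")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values after cleaning")
    qc["outlier_counts"] = qc["outlier_counts"].tolist()
    from .core import config_hash

    qc["config_hash"] = config_hash(
        {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    )
    return run.with_data(X), qc
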