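"""Vascular-reactivity normalization, HR characterization, fSNR, univariate
contrasts.

Differences in BOLD amplitude between groups can reflect vascular rather
than neural differences.  The hypercapnic breath-hold response provides a
per-voxel estimate of vascular reactivity: dividing task-evoked percent
signal change by breath-hold-evoked percent signal change discounts
reactivity differences (the normalization is scale-equivariant by
construction).  A reversing-checkerboard run characterises the hemodynamic
response's peak latency and amplitude, and the functional SNR is the mean
task-evoked percent signal change across an ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hrf import convolve_regressor, double_gamma_hrf
from .mvpa import TrialDataset

logger = logging.getLogger(__name__)

__all__ = ["CalibrationResult", "percent_signal_change",
           "breath_hold_normalize", "hr_characterize", "univariate_contrast",
           "fsnr"]


def _as_timeseries(data) -> np.ndarray:
    """Accept a nibabel image or array; return float array with time last."""
    try:
        import nibabel as nib

        if isinstance(data, nib.spatialimages.SpatialImage):
            return np.asarray(data.dataobj, float)
    except ImportError:                      # pragma: no cover
        pass
    return np.asarray(data, float)


@dataclass
class CalibrationResult:
    breath_hold_pct: np.ndarray | None = None    # per-voxel %BOLD
    selected_fraction: float = float("nan")
    hr_peak_latency_s: float = float("nan")
    hr_peak_amplitude_pct: float = float("nan")
    fsnr: float = float("nan")


def percent_signal_change(timeseries, onsets_s, tr_s: float = 1.5,
                          window_s: float = 30.0,
                          n_baseline: int = 2) -> np.ndarray:
    """Trial-averaged percent BOLD change relative to the pre-stimulus mean.

    ``timeseries`` is (T,) or (T, V) (or 4-D with time last, flattened to
    voxels); for each event the baseline is the mean of the ``n_baseline``
    pre-stimulus time points and the epoch is expressed in percent of it.
    Events lacking a full baseline are dropped with a log entry.
    """
    ts = _as_timeseries(timeseries)
    if ts.ndim > 2:
        ts = ts.reshape(-1, ts.shape[-1]).T       # (T, V)
    if ts.ndim == 1:
        ts = ts[:, None]
    n_vol = len(ts)
    wlen = int(round(window_s / tr_s))
    epochs = []
    dropped = 0
    for t0 in np.atleast_1d(onsets_s):
        v0 = int(round(float(t0) / tr_s))
        if v0 - n_baseline < 0 or v0 + wlen > n_vol:
            dropped += 1
            continue
        base = ts[v0 - n_baseline:v0].mean(axis=0)
        epochs.append(100.0 * (ts[v0:v0 + wlen] - base) / base)
    if dropped:
        logger.info("dropped %d event(s) without full baseline/window", dropped)
    if not epochs:
        raise ValueError("no usable events")
    out = np.mean(epochs, axis=0)                 # (wlen, V)
    return out.squeeze()


def _breath_hold_glm(bh_ts: np.ndarray, onsets_s, tr_s: float,
                     block_s: float = 10.0):
    """Per-voxel regression of the breath-hold boxcar convolved with the HRF.

    Returns (beta, p) per voxel; p is one-sided for a positive response.
    """
    n_vol = len(bh_ts)
    box = np.zeros(n_vol)
    for t0 in np.atleast_1d(onsets_s):
        v0 = int(round(float(t0) / tr_s))
        box[v0:v0 + int(round(block_s / tr_s))] = 1.0
    reg = convolve_regressor(box, double_gamma_hrf(tr_s))
    X = np.column_stack([np.ones(n_vol), reg])
    beta, *_ = np.linalg.lstsq(X, bh_ts, rcond=None)
    resid = bh_ts - X @ beta
    dof = n_vol - 2
    mse = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / np.sqrt(mse * xtx_inv)
    p = stats.t.sf(t, df=dof)
    return beta[1], p


def breath_hold_normalize(task_pct: np.ndarray, bh_timeseries, bh_onsets_s,
                          tr_s: float = 1.5, alpha: float = 0.05,
                          block_s: float = 10.0, eps: float = 1e-3):
    """Divide task %BOLD by breath-hold %BOLD at reactive voxels.

    Voxels with a significant positive breath-hold response (per-voxel GLM,
    p < alpha uncorrected) are selected; the task signal is divided by the
    peak breath-hold %BOLD per voxel.  Returns ``(normalized, info)`` where
    non-selected or near-zero-denominator voxels are NaN and ``info``
    reports the selected fraction and the per-voxel breath-hold %BOLD.
    """
    task_pct = np.asarray(task_pct, float)
    shape = task_pct.shape
    bh_ts = _as_timeseries(bh_timeseries)
    if bh_ts.ndim > 2:
        bh_ts = bh_ts.reshape(-1, bh_ts.shape[-1]).T
    _, p = _breath_hold_glm(bh_ts, bh_onsets_s, tr_s, block_s)
    psc = percent_signal_change(bh_ts, bh_onsets_s, tr_s,
                                window_s=block_s + 15.0)
    bh_amp = np.atleast_2d(psc).max(axis=0) if psc.ndim > 1 else \
        np.atleast_1d(psc.max())
    selected = p < alpha
    guarded = selected & (np.abs(bh_amp) < eps)
    if guarded.any():
        logger.info("%d voxel(s) excluded by division guard", int(guarded.sum()))
    usable = selected & ~guarded
    flat = task_pct.reshape(-1)
    norm = np.full(flat.shape, np.nan)
    norm[usable] = flat[usable] / bh_amp[usable]
    info = CalibrationResult(
        breath_hold_pct=bh_amp.reshape(shape),
        selected_fraction=float(selected.mean()),
    )
    return norm.reshape(shape), info


def hr_characterize(timeseries, onsets_s, tr_s: float = 1.5,
                    window_s: float = 20.0,
                    roi_mask: np.ndarray | None = None) -> CalibrationResult:
    """Peak latency and amplitude of the trial-averaged hemodynamic response.

    The response is the trial-averaged percent signal change (ROI-averaged
    when a mask is given); peak amplitude is its maximum and latency the
    time of that maximum.  A non-positive response is flagged.
    """
    ts = _as_timeseries(timeseries)
    if ts.ndim > 2:
        if roi_mask is not None:
            if not roi_mask.any():
                raise ValueError("empty ROI")
            ts = ts[roi_mask].T
        else:
            ts = ts.reshape(-1, ts.shape[-1]).T
    curve = percent_signal_change(ts, onsets_s, tr_s, window_s)
    if curve.ndim > 1:
        curve = curve.mean(axis=1)
    peak_idx = int(np.argmax(curve))
    amp = float(curve[peak_idx])
    if amp <= 0:
        logger.warning("non-positive hemodynamic response (peak %.3f%%)", amp)
    return CalibrationResult(hr_peak_latency_s=peak_idx * tr_s,
                             hr_peak_amplitude_pct=amp)


def univariate_contrast(data: TrialDataset,
                        roi_voxels: np.ndarray | None = None) -> dict:
    """Per-voxel and ROI-mean t-statistics for radial vs concentric.

    Pattern-mode contrast: a two-sample t-test per voxel between the two
    categories' trial patterns, plus a t-test on the across-voxel mean
    signal (the univariate ROI response).  A distributed, sign-balanced
    category code yields a null univariate contrast even when decoding is
    far above chance.
    """
    stim = data.stimulus_mask()
    rad = data.patterns[stim & (data.labels == "radial")]
    con = data.patterns[stim & (data.labels == "concentric")]
    if len(rad) == 0 or len(con) == 0:
        raise ValueError("both categories required")
    if roi_voxels is not None:
        rad, con = rad[:, roi_voxels], con[:, roi_voxels]
    t_vox, p_vox = stats.ttest_ind(rad, con, axis=0)
    t_roi, p_roi = stats.ttest_ind(rad.mean(axis=1), con.mean(axis=1))
    return {
        "t_voxel": t_vox, "p_voxel": p_vox,
        "t_roi": float(t_roi), "p_roi": float(p_roi),
        "mean_diff_roi": float(rad.mean() - con.mean()),
    }


def fsnr(task_timeseries, onsets_s, roi_mask: np.ndarray | None = None,
         tr_s: float = 1.5, window_s: float = 12.0) -> float:
    """Functional SNR: mean task-evoked % signal change across ROI voxels."""
    ts = _as_timeseries(task_timeseries)
    if ts.ndim > 2:
        ts = ts[roi_mask].T if roi_mask is not None else \
            ts.reshape(-1, ts.shape[-1]).T
    curve = percent_signal_change(ts, onsets_s, tr_s, window_s)
    if curve.ndim > 1:
        curve = curve.mean(axis=1)
    return float(curve.max())
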