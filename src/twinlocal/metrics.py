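"""Voxelwise local resting-state metrics and their preprocessing steps.

Implements the per-run chain: framewise displacement (Power convention,
50 mm head radius) and the motion exclusion rule, FD-based scrubbing,
nuisance (confound) regression with a Friston-24 helper, linear detrending,
ideal DFT bandpass, KCC-ReHo (Kendall's coefficient of concordance over the
3x3x3 voxel neighborhood), fALFF (amplitude-spectrum ratio of the
0.01-0.08 Hz band to 0-0.25 Hz), Z-standardization within the brain mask,
masked Gaussian smoothing, atlas ROI means, and AP/PA run averaging.

Pipeline order: confound regression -> detrend -> scrub -> bandpass (ReHo
only; fALFF is computed on unfiltered, detrended data) -> metric -> Z-score
-> smooth -> ROI means.  :func:`process_subject` enforces this order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .synthetic import FmriRun

__all__ = [
    "compute_fd",
    "scrub_mask",
    "friston24",
    "regress_confounds",
    "detrend_linear",
    "bandpass",
    "compute_reho",
    "compute_falff",
    "zscore_map",
    "smooth_gaussian",
    "extract_roi_means",
    "average_runs",
    "apply_motion_exclusion",
    "process_run",
    "process_subject",
]


# --------------------------------------------------------------------------
# motion
# --------------------------------------------------------------------------

def compute_fd(motion: np.ndarray, head_radius: float = 50.0):
    """Power-style framewise displacement from 6 rigid-body parameters.

    ``motion`` is (t, 6): 3 translations in mm then 3 rotations in radians.
    FD(i) = sum |delta translation| + head_radius * sum |delta rotation|,
    with FD(1) = 0.  Returns (per-volume FD, mean FD over volumes 2..t).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion parameters must be (t, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return fd, float(fd[1:].mean())


def scrub_mask(
    fd: np.ndarray,
    threshold: float = 0.5,
    extend_before: int = 1,
    extend_after: int = 2,
) -> np.ndarray:
    """Boolean keep-mask censoring FD spikes and their neighbors.

    Volumes with FD > ``threshold`` are censored together with
    ``extend_before`` preceding and ``extend_after`` following volumes.
    """
    fd = np.asarray(fd, dtype=float)
    if not np.all(np.isfinite(fd)):
        raise ValueError("FD values must be finite")
    bad = fd > threshold
    censor = bad.copy()
    for i in np.flatnonzero(bad):
        censor[max(0, i - extend_before): i + extend_after + 1] = True
    return ~censor


def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston 24-parameter motion design: params, one-volume lags, both squared."""
    motion = np.asarray(motion, dtype=float)
    lag = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, lag, motion**2, lag**2])


# --------------------------------------------------------------------------
# time-series cleaning
# --------------------------------------------------------------------------

def _apply_voxelwise(run: FmriRun, fun) -> FmriRun:
    flat = run.data[run.mask]  # (v, t)
    out = np.array(run.data, copy=True)
    out[run.mask] = fun(flat)
    return FmriRun(data=out, tr=run.tr, mask=run.mask, phase_dir=run.phase_dir)


def regress_confounds(run: FmriRun, confounds: np.ndarray) -> FmriRun:
    """Per-voxel OLS residuals against a confound matrix; voxel mean restored.

    An intercept column is appended if absent.  Collinear columns are
    handled by the minimum-norm least-squares solution with a warning.
    """
    X = np.asarray(confounds, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    t = run.data.shape[-1]
    if X.shape[0] != t:
        raise ValueError(f"confounds have {X.shape[0]} rows, run has {t} volumes")
    if not np.any(np.ptp(X, axis=0) == 0):
        X = np.hstack([X, np.ones((t, 1))])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("confound design is rank-deficient; dropping collinear "
                      "directions via least squares", stacklevel=2)

    def clean(Y):
        mean = Y.mean(axis=1, keepdims=True)
        beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        return Y - (X @ beta).T + mean

    return _apply_voxelwise(run, clean)


def detrend_linear(run: FmriRun) -> FmriRun:
    """Remove the per-voxel best-fit line, keeping the voxel mean."""
    t = run.data.shape[-1]
    if t < 3:
        raise ValueError("need at least 3 volumes to detrend")
    x = np.arange(t, dtype=float)
    x = (x - x.mean()) / x.std()

    def clean(Y):
        mean = Y.mean(axis=1, keepdims=True)
        slope = (Y - mean) @ x / t
        return Y - slope[:, None] * x[None, :]

    return _apply_voxelwise(run, clean)


def bandpass(run: FmriRun, low: float = 0.01, high: float = 0.08) -> FmriRun:
    """Ideal DFT-domain bandpass: bins with low <= f <= high kept, DC removed."""
    if low >= high:
        raise ValueError(f"low ({low}) must be below high ({high})")
    t = run.data.shape[-1]
    nyq = 0.5 / run.tr
    if high >= nyq:
        raise ValueError(f"high ({high}) must be below Nyquist ({nyq:.4g})")
    freqs = np.fft.rfftfreq(t, d=run.tr)
    keep = (freqs >= low) & (freqs <= high)

    def clean(Y):
        spec = np.fft.rfft(Y, axis=1)
        spec[:, ~keep] = 0.0
        return np.fft.irfft(spec, n=t, axis=1)

    return _apply_voxelwise(run, clean)


def censor_volumes(run: FmriRun, keep: np.ndarray) -> FmriRun:
    """Drop censored volumes (scrubbing) from the time axis."""
    keep = np.asarray(keep, dtype=bool)
    if keep.shape[0] != run.data.shape[-1]:
        raise ValueError("keep-mask length must equal volume count")
    if keep.sum() < 3:
        raise ValueError("fewer than 3 volumes survive scrubbing")
    return FmriRun(
        data=run.data[..., keep], tr=run.tr, mask=run.mask, phase_dir=run.phase_dir
    )


# --------------------------------------------------------------------------
# ReHo
# --------------------------------------------------------------------------

def compute_reho(run: FmriRun, tie_correction: bool = False) -> np.ndarray:
    """Kendall's coefficient of concordance over each voxel's 3x3x3 neighborhood.

    Per in-mask voxel with K in-mask neighbors (itself included, K <= 27):

        W = 12 * sum_i (R_i - Rbar)^2 / (K^2 (n^3 - n))

    where n is the number of time points, R_i the across-voxel sum of
    within-voxel temporal ranks at time i, and Rbar = K (n + 1) / 2.  Ranks
    use midranks for ties; by default no tie-correction term is applied to
    the denominator (``tie_correction`` adds the standard correction).
    Voxels with K < 2 get NaN.
    """
    n = run.data.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 time points for ReHo")
    mask = run.mask
    ranks = np.zeros_like(run.data)
    ranks[mask] = stats.rankdata(run.data[mask], axis=-1)

    # neighborhood rank sums and counts via 27 shifted accumulations
    rank_sum = np.zeros_like(ranks)
    count = np.zeros(mask.shape)
    tie_term = np.zeros(mask.shape)
    if tie_correction:
        T = np.zeros(mask.shape)
        flat = run.data[mask]
        corr = np.zeros(flat.shape[0])
        for v in range(flat.shape[0]):
            _, counts = np.unique(flat[v], return_counts=True)
            corr[v] = float(np.sum(counts**3 - counts))
        T_full = np.zeros(mask.shape)
        T_full[mask] = corr
        T = T_full
    m = mask.astype(float)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                shifted_r = np.roll(ranks, (dx, dy, dz), axis=(0, 1, 2))
                shifted_m = np.roll(m, (dx, dy, dz), axis=(0, 1, 2))
                # zero out wrap-around
                sl = _edge_slices(mask.shape, dx, dy, dz)
                if sl is not None:
                    shifted_r = shifted_r.copy()
                    shifted_m = shifted_m.copy()
                    for s in sl:
                        shifted_r[s] = 0.0
                        shifted_m[s] = 0.0
                rank_sum += shifted_r * shifted_m[..., None]
                count += shifted_m
                if tie_correction:
                    shifted_t = np.roll(T, (dx, dy, dz), axis=(0, 1, 2))
                    if sl is not None:
                        shifted_t = shifted_t.copy()
                        for s in sl:
                            shifted_t[s] = 0.0
                    tie_term += shifted_t * shifted_m

    out = np.full(mask.shape, np.nan)
    K = count
    with np.errstate(invalid="ignore", divide="ignore"):
        rbar = K[..., None] * (n + 1) / 2.0
        S = np.sum((rank_sum - rbar) ** 2, axis=-1)
        denom = K**2 * (n**3 - n)
        if tie_correction:
            denom = denom - K * tie_term
        W = 12.0 * S / denom
    valid = mask & (K >= 2)
    out[valid] = W[valid]
    return out


def _edge_slices(shape, dx, dy, dz):
    slices = []
    for axis, d in enumerate((dx, dy, dz)):
        if d == 0:
            continue
        idx = [slice(None)] * 3
        idx[axis] = slice(0, 1) if d > 0 else slice(-1, None)
        slices.append(tuple(idx))
    return slices or None


# --------------------------------------------------------------------------
# fALFF
# --------------------------------------------------------------------------

def compute_falff(
    run: FmriRun,
    band: tuple = (0.01, 0.08),
    full_range: tuple = (0.0, 0.25),
    mode: str = "amplitude",
) -> np.ndarray:
    """Fraction of spectral mass in the low-frequency band.

    ``mode='amplitude'`` (default) sums square-rooted periodogram values,
    the originating method's convention; ``mode='power'`` sums the
    periodogram itself.  The numerator covers band[0] <= f <= band[1]; the
    denominator covers full_range[0] < f <= full_range[1] (DC excluded).
    Zero-variance voxels get NaN.  Input should be detrended, not bandpassed.
    """
    if mode not in ("amplitude", "power"):
        raise ValueError("mode must be 'amplitude' or 'power'")
    t = run.data.shape[-1]
    freqs = np.fft.rfftfreq(t, d=run.tr)
    num_bins = (freqs >= band[0]) & (freqs <= band[1])
    den_bins = (freqs > full_range[0]) & (freqs <= full_range[1])
    Y = run.data[run.mask]
    spec = np.abs(np.fft.rfft(Y, axis=1))
    if mode == "power":
        spec = spec**2
    num = spec[:, num_bins].sum(axis=1)
    den = spec[:, den_bins].sum(axis=1)
    vals = np.full(Y.shape[0], np.nan)
    ok = (den > 0) & (Y.std(axis=1) > 0)
    vals[ok] = num[ok] / den[ok]
    out = np.full(run.mask.shape, np.nan)
    out[run.mask] = vals
    return out


# --------------------------------------------------------------------------
# map post-processing
# --------------------------------------------------------------------------

def zscore_map(map3d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-standardize within the mask (population-SD convention)."""
    vals = map3d[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite in-mask values")
    sd = vals.std()
    if sd == 0:
        raise ValueError("constant map cannot be Z-standardized")
    out = np.full(map3d.shape, np.nan)
    out[mask] = (map3d[mask] - vals.mean()) / sd
    return out


def smooth_gaussian(
    map3d: np.ndarray, mask: np.ndarray, fwhm: float = 6.0, voxel_size: float = 2.0
) -> np.ndarray:
    """Masked separable Gaussian smoothing with kernel width given as FWHM (mm).

    Out-of-mask and NaN voxels are excluded and the kernel weights
    renormalized over the contributing voxels.
    """
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / voxel_size
    vals = np.where(mask & np.isfinite(map3d), map3d, 0.0)
    weights = (mask & np.isfinite(map3d)).astype(float)
    num = ndimage.gaussian_filter(vals, sigma)
    den = ndimage.gaussian_filter(weights, sigma)
    out = np.full(map3d.shape, np.nan)
    ok = mask & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return out


def extract_roi_means(map3d: np.ndarray, atlas: np.ndarray,
                      roi_ids=None) -> np.ndarray:
    """Mean map value per atlas label; NaN voxels excluded, empty ROI -> NaN."""
    if roi_ids is None:
        roi_ids = sorted(int(v) for v in np.unique(atlas) if v > 0)
    out = np.full(len(roi_ids), np.nan)
    for i, roi in enumerate(roi_ids):
        sel = (atlas == roi) & np.isfinite(map3d)
        if sel.any():
            out[i] = float(map3d[sel].mean())
    return out


def average_runs(v_ap: np.ndarray | None, v_pa: np.ndarray | None,
                 policy: str = "exclude") -> np.ndarray | None:
    """Elementwise mean of the AP and PA ROI vectors.

    With the default ``policy='exclude'`` a missing run makes the subject's
    vector missing (None); ``policy='single'`` falls back to the available run.
    """
    if v_ap is None or v_pa is None:
        if policy == "single":
            return v_pa if v_ap is None else v_ap
        return None
    return (np.asarray(v_ap) + np.asarray(v_pa)) / 2.0


def apply_motion_exclusion(table, threshold: float = 0.3):
    """Flag acquisitions whose mean FD strictly exceeds the threshold (mm).

    Works on a DataFrame with per-run mean-FD columns (any column starting
    with ``mean_fd``); a subject-wave is excluded if either run exceeds the
    threshold.  Returns a copy with the ``excluded`` column set.
    """
    out = table.copy()
    fd_cols = [c for c in out.columns if c.startswith("mean_fd")]
    if not fd_cols:
        raise ValueError("no mean_fd columns found")
    out["excluded"] = (out[fd_cols] > threshold).any(axis=1)
    return out


# --------------------------------------------------------------------------
# per-run / per-subject drivers
# --------------------------------------------------------------------------

@dataclass
class MetricParams:
    """Tunables of the metric chain."""

    band_low: float = 0.01          # Hz
    band_high: float = 0.08         # Hz
    falff_full_hi: float = 0.25     # Hz
    falff_mode: str = "amplitude"
    fwhm: float = 6.0               # mm
    voxel_size: float = 2.0         # mm
    scrub_threshold: float = 0.5    # mm
    fd_threshold: float = 0.3       # mm, acquisition exclusion
    smooth: bool = True


def process_run(
    run: FmriRun,
    motion: np.ndarray,
    atlas: np.ndarray,
    params: MetricParams | None = None,
    confounds: np.ndarray | None = None,
) -> dict:
    """Full single-run chain; returns ROI means for both metrics plus QC.

    The driver enforces the processing order: bandpass strictly precedes
    ReHo and is never applied before fALFF.
    """
    params = params or MetricParams()
    fd, mean_fd = compute_fd(motion)
    design = friston24(motion)
    if confounds is not None:
        design = np.hstack([design, confounds])
    cleaned = regress_confounds(run, design)
    cleaned = detrend_linear(cleaned)
    keep = scrub_mask(fd, threshold=params.scrub_threshold)
    cleaned = censor_volumes(cleaned, keep)

    banded = bandpass(cleaned, params.band_low, params.band_high)
    reho = compute_reho(banded)
    falff = compute_falff(
        cleaned,
        band=(params.band_low, params.band_high),
        full_range=(0.0, params.falff_full_hi),
        mode=params.falff_mode,
    )
    out = {}
    for name, m in (("ReHo", reho), ("fALFF", falff)):
        z = zscore_map(m, run.mask)
        if params.smooth:
            z = smooth_gaussian(z, run.mask, params.fwhm, params.voxel_size)
        out[name] = extract_roi_means(z, atlas)
    out["mean_fd"] = mean_fd
    out["n_kept"] = int(keep.sum())
    return out


def process_subject(
    runs: dict,
    motions: dict,
    atlas: np.ndarray,
    params: MetricParams | None = None,
) -> dict:
    """AP + PA chain with run averaging and the motion exclusion rule."""
    params = params or MetricParams()
    per_run = {ph: process_run(runs[ph], motions[ph], atlas, params)
               for ph in ("AP", "PA")}
    mean_fds = {ph: per_run[ph]["mean_fd"] for ph in per_run}
    excluded = any(v > params.fd_threshold for v in mean_fds.values())
    out = {"mean_fd_ap": mean_fds["AP"], "mean_fd_pa": mean_fds["PA"],
           "mean_fd": float(np.mean(list(mean_fds.values()))),
           "excluded": excluded}
    for name in ("ReHo", "fALFF"):
        out[name] = average_runs(per_run["AP"][name], per_run["PA"][name])
    return out
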