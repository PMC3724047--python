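"""Temporal preprocessing and frame censoring for one BOLD run.

Pipeline order contract (enforced via the run's history):
``drop_initial -> smooth_spatial -> bandpass -> regress_nuisance -> scrub``.
Frame metrics (framewise displacement and frame-to-frame global-signal
change) are computed on the post-smoothing, pre-bandpass signal, which
still carries the raw baseline the percent change is referenced to.
Censoring uses the AND rule: a frame is flagged only when *both* the
displacement and the global-signal change reach their thresholds; the
flagged frame, the one before and the two after are removed.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from ._filters import sosfiltfilt
from .containers import BoldRun, MotionTrace, ScrubReport

_ORDER = ["drop_initial", "smooth_spatial", "bandpass", "regress_nuisance", "scrub"]


def _check_order(run: BoldRun, step: str) -> None:
    if step in run.history:
        raise ValueError(f"step {step!r} already applied")
    later = _ORDER[_ORDER.index(step) + 1:]
    done_later = [s for s in later if s in run.history]
    if done_later:
        raise ValueError(
            f"cannot apply {step!r} after {done_later[0]!r}: pipeline order is "
            + " -> ".join(_ORDER)
        )


# ---------------------------------------------------------------------------
# temporal steps
# ---------------------------------------------------------------------------

def drop_initial(run: BoldRun, n: int = 10) -> BoldRun:
    """Discard the first ``n`` frames (magnetization equilibration)."""
    _check_order(run, "drop_initial")
    if n < 0:
        raise ValueError("n must be >= 0")
    if run.n_frames <= n:
        raise ValueError(f"run has {run.n_frames} frames, cannot drop {n}")
    return run.with_data(run.data[..., n:], "drop_initial")


def fwhm_to_sigma(fwhm_mm: float, voxel_mm: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_mm


def smooth_spatial(run: BoldRun, fwhm_mm: float = 8.0) -> BoldRun:
    """Isotropic Gaussian smoothing of every volume (reflective edges)."""
    _check_order(run, "smooth_spatial")
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return run.with_data(run.data.copy(), "smooth_spatial")
    sigmas = [fwhm_to_sigma(fwhm_mm, v) for v in run.voxel_size]
    out = run.data.astype(np.float32, copy=True)
    for axis, s in enumerate(sigmas):
        ndimage.gaussian_filter1d(out, s, axis=axis, mode="reflect", output=out)
    return run.with_data(out, "smooth_spatial")


def butter_bandpass_sos(low_hz: float, high_hz: float, tr: float, order: int = 4):
    nyq = 0.5 / tr
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"band must satisfy 0 <= low < high < Nyquist ({nyq:g} Hz)"
        )
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr,
                      output="sos")


def bandpass_series(
    series: np.ndarray, tr: float, low_hz: float = 0.008, high_hz: float = 0.08,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band-pass along the last axis (forward-backward)."""
    sos = butter_bandpass_sos(low_hz, high_hz, tr, order)
    out = sosfiltfilt(sos, series)
    return out.astype(series.dtype) if series.dtype == np.float32 else out


def bandpass(run: BoldRun, low_hz: float = 0.008, high_hz: float = 0.08,
             order: int = 4) -> BoldRun:
    """Zero-phase Butterworth band-pass of every voxel series."""
    _check_order(run, "bandpass")
    out = np.zeros_like(run.data, dtype=np.float32)
    mask = run.brain_mask
    out[mask] = bandpass_series(run.data[mask], run.tr, low_hz, high_hz, order)
    return run.with_data(out, "bandpass")


def build_nuisance_design(
    run: BoldRun, motion: MotionTrace | None = None, global_signal: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Default design: intercept, WM, CSF, global mean, 6 motion params.

    Tissue and global regressors are means of the (current) voxel data
    over their masks; with global_signal=False the global column is
    omitted (the no-GSR variant).
    """
    cols, names = [np.ones(run.n_frames)], ["intercept"]
    if run.wm_mask is not None and run.wm_mask.any():
        cols.append(run.data[run.wm_mask].mean(axis=0))
        names.append("wm")
    if run.csf_mask is not None and run.csf_mask.any():
        cols.append(run.data[run.csf_mask].mean(axis=0))
        names.append("csf")
    if global_signal:
        cols.append(run.data[run.brain_mask].mean(axis=0))
        names.append("global")
    if motion is not None:
        if motion.n_frames != run.n_frames:
            raise ValueError("motion trace length does not match run")
        for i in range(6):
            cols.append(motion.params[:, i])
            names.append(f"motion_{i}")
    return np.column_stack(cols).astype(np.float64), names


def regress_series(series: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each row of ``series`` on ``design``."""
    if design.shape[0] != series.shape[-1]:
        raise ValueError("regressor rows must equal run length")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # drop the dependent directions, keep an orthonormal basis
        warnings.warn(
            f"rank-deficient nuisance design ({rank}/{design.shape[1]}); "
            "dependent columns dropped"
        )
        u, s, _ = np.linalg.svd(design, full_matrices=False)
        basis = u[:, s > s[0] * 1e-10]
    else:
        basis, _ = np.linalg.qr(design, mode="reduced")
    fitted = (series @ basis) @ basis.T
    return series - fitted


def regress_nuisance(
    run: BoldRun,
    motion: MotionTrace | None = None,
    design: np.ndarray | None = None,
    global_signal: bool = True,
) -> BoldRun:
    """Project nuisance signals out of every in-mask voxel series."""
    _check_order(run, "regress_nuisance")
    if design is None:
        design, _ = build_nuisance_design(run, motion, global_signal)
    out = np.zeros_like(run.data, dtype=np.float32)
    mask = run.brain_mask
    out[mask] = regress_series(run.data[mask].astype(np.float64), design)
    return run.with_data(out, "regress_nuisance")


# ---------------------------------------------------------------------------
# censoring
# ---------------------------------------------------------------------------

def framewise_displacement(
    params: np.ndarray, rotation_radius_mm: float = 50.0
) -> np.ndarray:
    """Power-style FD: |dtranslations| + radius * |drotations| (frame 0 = 0)."""
    d = np.abs(np.diff(params, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def global_signal_change_pct(run: BoldRun) -> np.ndarray:
    """|GS(t) - GS(t-1)| / mean(GS) * 100 over the brain mask (frame 0 = 0)."""
    gs = run.data[run.brain_mask].mean(axis=0, dtype=np.float64)
    mean = gs.mean()
    if abs(mean) < 1e-12:
        raise ValueError("zero mean global signal; metrics need the raw baseline")
    change = np.abs(np.diff(gs)) / mean * 100.0
    return np.concatenate([[0.0], change])


def compute_frame_metrics(run: BoldRun, motion: MotionTrace,
                          rotation_radius_mm: float = 50.0) -> MotionTrace:
    """Fill the derived FD and global-signal-change series."""
    if motion.n_frames != run.n_frames:
        raise ValueError("motion trace length does not match run")
    return MotionTrace(
        params=motion.params,
        fd=framewise_displacement(motion.params, rotation_radius_mm),
        gs_pct=global_signal_change_pct(run),
    )


def scrub_windows(flagged: np.ndarray, n_frames: int) -> np.ndarray:
    """Removal window per flag: {t-1, t, t+1, t+2}, clipped and merged."""
    removed: set[int] = set()
    for t in np.asarray(flagged, dtype=int):
        for dt in (-1, 0, 1, 2):
            u = t + dt
            if 0 <= u < n_frames:
                removed.add(u)
    return np.array(sorted(removed), dtype=int)


def scrub(
    run: BoldRun,
    metrics: MotionTrace,
    gs_thresh: float = 0.5,
    disp_thresh: float = 0.5,
    exclusion_n: int = 60,
) -> tuple[BoldRun, ScrubReport]:
    """Censor motion-contaminated frames (AND rule, 4-frame windows)."""
    _check_order(run, "scrub")
    if metrics.fd is None or metrics.gs_pct is None:
        raise ValueError("frame metrics not computed; run compute_frame_metrics")
    if len(metrics.fd) != run.n_frames:
        raise ValueError("metrics length does not match run")
    flagged = np.where(
        (metrics.fd >= disp_thresh) & (metrics.gs_pct >= gs_thresh)
    )[0]
    removed = scrub_windows(flagged, run.n_frames)
    keep = np.setdiff1d(np.arange(run.n_frames), removed)
    report = ScrubReport(
        flagged=flagged,
        removed=removed,
        n_removed=len(removed),
        excluded=len(removed) > exclusion_n,
    )
    return run.with_data(run.data[..., keep], "scrub"), report


# ---------------------------------------------------------------------------
# convenience: the whole per-run pipeline
# ---------------------------------------------------------------------------

def preprocess_run(
    run: BoldRun,
    motion: MotionTrace,
    n_drop: int = 10,
    fwhm_mm: float = 8.0,
    low_hz: float = 0.008,
    high_hz: float = 0.08,
    global_signal: bool = True,
    gs_thresh: float = 0.5,
    disp_thresh: float = 0.5,
    exclusion_n: int = 60,
) -> tuple[BoldRun, ScrubReport]:
    """drop -> smooth -> (metrics) -> bandpass -> regress -> scrub."""
    run = drop_initial(run, n_drop)
    motion = motion.trimmed(n_drop)
    run = smooth_spatial(run, fwhm_mm)
    metrics = compute_frame_metrics(run, motion)
    run = bandpass(run, low_hz, high_hz)
    run = regress_nuisance(run, motion=motion, global_signal=global_signal)
    return scrub(run, metrics, gs_thresh, disp_thresh, exclusion_n)
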