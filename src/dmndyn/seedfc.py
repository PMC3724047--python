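"""Seed-based whole-brain connectivity maps and group significance.

The seed is an 8 mm-radius sphere centered on the posterior cingulate
(MNI 0, -53, 26 by default).  Per subject and state the seed mean time
course is correlated against every in-mask voxel, Fisher-Z transformed,
and the per-state group map is a two-tailed one-sample t-test over
subjects with FDR control (Benjamini-Yekutieli by default, which is
valid under arbitrary dependence).  The state's network map — the set
entering the four-state union mask — is the significant positive-t
voxels; significant negative-t voxels are kept separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BoldRun

Z_CLIP = 1.0 - 1e-7


@dataclass
class SeedSpec:
    """Spherical seed region in scanner (mm) coordinates."""

    center_mm: tuple[float, float, float] = (0.0, -53.0, 26.0)
    radius_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("seed radius must be > 0")


@dataclass
class ConnectivityMap:
    """One subject x state Fisher-Z seed-connectivity volume (in-mask)."""

    subject: str
    state: str
    z: np.ndarray  # flat over brain-mask voxels
    mask: np.ndarray  # boolean volume


@dataclass
class GroupStateMap:
    """Group-level t/p volumes and FDR mask for one state."""

    state: str
    t: np.ndarray
    p: np.ndarray
    sig_pos: np.ndarray  # significant positive-t voxels (the network map)
    sig_neg: np.ndarray
    mask: np.ndarray
    n_subjects: int
    q: float
    fdr_method: str


def seed_mask(seed: SeedSpec, affine: np.ndarray, shape, brain_mask=None) -> np.ndarray:
    """Voxels whose centers lie within the seed sphere."""
    ijk = np.indices(shape).reshape(3, -1)
    xyz = affine[:3, :3] @ ijk + affine[:3, 3:4]
    d2 = ((xyz - np.asarray(seed.center_mm)[:, None]) ** 2).sum(axis=0)
    mask = (d2 <= seed.radius_mm**2).reshape(shape)
    if brain_mask is not None:
        mask &= brain_mask
    if not mask.any():
        raise ValueError("seed sphere does not intersect the brain mask")
    return mask


def extract_seed_timecourse(run: BoldRun, seed: SeedSpec) -> np.ndarray:
    """Unweighted mean series over the seed sphere's in-mask voxels."""
    mask = seed_mask(seed, run.affine, run.data.shape[:3], run.brain_mask)
    return run.data[mask].mean(axis=0, dtype=np.float64)


def voxelwise_correlation(run: BoldRun, seed_tc: np.ndarray) -> np.ndarray:
    """Pearson r of each in-mask voxel with the seed series (flat array)."""
    if run.n_frames < 3:
        raise ValueError("need at least 3 surviving frames")
    s = np.asarray(seed_tc, dtype=np.float64)
    if s.std() == 0:
        raise ValueError("seed time course is constant")
    x = run.data[run.brain_mask].astype(np.float64)
    x = x - x.mean(axis=1, keepdims=True)
    s = s - s.mean()
    xn = np.sqrt((x**2).sum(axis=1))
    const = xn == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant voxel series; r set to 0")
        xn[const] = 1.0
    r = (x @ s) / (xn * np.sqrt((s**2).sum()))
    r[const] = 0.0
    return np.clip(r, -1.0, 1.0)


def fisher_z(r) -> np.ndarray:
    """Variance-stabilizing z = atanh(r); |r| = 1 clipped with a warning."""
    r = np.asarray(r, dtype=np.float64)
    if (np.abs(r) > 1).any():
        raise ValueError("correlations must lie in [-1, 1]")
    if (np.abs(r) >= 1).any():
        warnings.warn("|r| = 1 clipped to 1 - 1e-7 before Fisher-Z")
    return np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))


def connectivity_map(run: BoldRun, seed: SeedSpec, subject: str | None = None
                     ) -> ConnectivityMap:
    tc = extract_seed_timecourse(run, seed)
    z = fisher_z(voxelwise_correlation(run, tc))
    return ConnectivityMap(
        subject=subject or run.subject, state=run.state, z=z,
        mask=run.brain_mask,
    )


def fdr_correct(p_values, q: float = 0.05, method: str = "by") -> np.ndarray:
    """FDR step-up rejection mask (Benjamini-Yekutieli or -Hochberg)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"by": "fdr_by", "bh": "fdr_bh"}[method.lower()]
    reject, *_ = multipletests(p.ravel(), alpha=q, method=sm_method)
    return reject.reshape(p.shape)


def group_significance(
    z_maps: list[ConnectivityMap], q: float = 0.05, fdr_method: str = "by"
) -> GroupStateMap:
    """One-sample t against 0 per voxel, two-tailed, FDR within the mask."""
    if len(z_maps) < 2:
        raise ValueError("need at least 2 subjects")
    state = z_maps[0].state
    mask = z_maps[0].mask
    for m in z_maps:
        if m.state != state or m.mask.shape != mask.shape or not (m.mask == mask).all():
            raise ValueError("all maps must share state and mask")
    data = np.stack([m.z for m in z_maps])  # (n, v)
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{zero_var.sum()} zero-variance voxels in group t-test")
    sd_safe = np.where(zero_var, 1.0, sd)
    t = mean / (sd_safe / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[zero_var] = np.where(mean[zero_var] != 0, 0.0, 1.0)
    t[zero_var] = np.where(mean[zero_var] != 0, np.inf, 0.0)
    sig = fdr_correct(p, q=q, method=fdr_method)
    return GroupStateMap(
        state=state, t=t, p=p,
        sig_pos=sig & (t > 0), sig_neg=sig & (t < 0),
        mask=mask, n_subjects=n, q=q, fdr_method=fdr_method,
    )
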