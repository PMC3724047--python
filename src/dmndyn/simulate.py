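"""Synthetic multi-subject four-state BOLD cohort generator.

Latent construction: for each state, innovations are drawn from a
multivariate Gaussian with the (subject-perturbed) target correlation,
passed through an identical AR(1) filter per channel, and standardized.
Because every channel sees the same filter, the cross-correlations of
the latent signals equal the target matrix exactly in expectation.
Region voxels ride on their region's latent plus voxel-private white
noise; all brain voxels additionally carry a baseline (~1000 units), a
shared global fluctuation (what global-signal regression removes), a
slow scanner drift below the analysis band, and optional motion spikes
that exceed both censoring thresholds simultaneously.

Between-subject heterogeneity is applied on the Fisher-Z scale as one
shared deviate per (subject, state, system-block): the whole
stable-decreasing block of a subject's matrix moves together, which is
what gives system-level mean connectivity a between-subject SD of
exactly ``subject_sd`` (matching the published SEMs) and gives the
latent dFC the variance the behavior coupling requires.  The group
Fisher-Z offsets are mean-matched so that the *population mean on the r
scale* equals the scenario's target correlations despite the tanh
nonlinearity.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .containers import STATES, TASK_STATES, BoldRun, Cohort, MotionTrace, SubjectData
from .scenario import (
    PlantedRegion,
    ScenarioError,
    SynthScenario,
    repair_psd,
    save_scenario,
    load_scenario,
)

_BURN = 50  # AR(1) burn-in frames discarded before use


# ---------------------------------------------------------------------------
# latent machinery
# ---------------------------------------------------------------------------

def _ar1(innov: np.ndarray, phi: float) -> np.ndarray:
    """AR(1)-filter innovations along the last axis, unit stationary SD."""
    if abs(phi) >= 1:
        raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
    x = sps.lfilter([1.0], [1.0, -phi], innov, axis=-1)
    return x * np.sqrt(1.0 - phi**2)


def _correlated_latents(
    rng: np.random.Generator, corr: np.ndarray, n_frames: int, phi: float
) -> np.ndarray:
    """(k, n_frames) latent signals with the given correlation matrix."""
    k = corr.shape[0]
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    innov = factor @ rng.standard_normal((k, n_frames + _BURN))
    return _ar1(innov, phi)[:, _BURN:]


def _mean_matched_z(r: np.ndarray, sigma: float) -> np.ndarray:
    """Fisher-Z offsets z0 with E[tanh(z0 + N(0, sigma^2))] = r.

    Solved by Newton iteration on Gauss-Hermite quadrature; with
    sigma = 0 this is plain atanh.  Keeps the population mean of the
    subject-level correlations equal to the group target on the r scale,
    which is the scale the published group means are printed on.
    """
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-9, 1 - 1e-9)
    z = np.arctanh(r)
    if sigma == 0:
        return z
    # near-saturated entries (|r| ~ 1, e.g. the diagonal) keep plain atanh
    sat = np.abs(r) > 0.999
    nodes, weights = np.polynomial.hermite_e.hermegauss(31)
    for _ in range(50):
        zz = z[..., None] + sigma * nodes
        t = np.tanh(zz)
        mean = (t * weights).sum(axis=-1) / weights.sum()
        grad = ((1 - t**2) * weights).sum(axis=-1) / weights.sum()
        step = np.clip((mean - r) / np.maximum(grad, 1e-12), -0.5, 0.5)
        step[sat] = 0.0
        z = z - step
        if np.max(np.abs(step)) < 1e-12:
            break
    return z


# ---------------------------------------------------------------------------
# GSR compensation
# ---------------------------------------------------------------------------
#
# The published group means are measured AFTER global-signal regression,
# and GSR subtracts the network's own share of the brain mean from every
# voxel, deflating all mutual correlations (the classic GSR bias).  The
# generator therefore plants correlations such that the post-GSR
# measurement equals the target, using a first-order analytic model of
# the regression: region mean = cbar*amp*latent + global; brain mean =
# global + sum_i f_i * amp * latent_i, with cbar (mean smoothed
# indicator inside the region) and f (smoothed region mass / brain
# voxels) computed exactly from the scenario's geometry and smoothing
# kernel.  This mirrors the tanh mean-matching: the printed values are
# observed group statistics, and the generator is calibrated so the
# observation — not the hidden latent — hits them.

def _region_geometry(scenario: SynthScenario, fwhm_mm: float = 8.0):
    """(cbar, f): smoothed-indicator mean inside each region and its
    mass fraction of the brain mean."""
    from scipy import ndimage

    from .preprocess import fwhm_to_sigma

    brain = scenario.brain_mask()
    n = brain.sum()
    k = scenario.n_latents
    cbar = np.zeros(k)
    f = np.zeros(k)
    sig = fwhm_to_sigma(fwhm_mm, scenario.voxel_size)
    for reg in scenario.region_layout:
        ind = np.zeros(scenario.grid_shape)
        ind[tuple(reg.voxels.T)] = 1.0
        sm = ndimage.gaussian_filter(ind, sig, mode="reflect")
        cbar[reg.latent_index] += sm[tuple(reg.voxels.T)].mean()
        f[reg.latent_index] += sm[brain].sum() / n
    return cbar, f


def predict_post_gsr(
    rho: np.ndarray, cbar: np.ndarray, f: np.ndarray, amp: float, amp_g: float
) -> np.ndarray:
    """First-order post-GSR correlation matrix of the region means."""
    u = rho @ f
    w = float(f @ rho @ f)
    beta = (amp_g**2 + amp**2 * cbar * u) / (amp_g**2 + amp**2 * w)
    cov = (
        amp**2
        * (
            np.outer(cbar, cbar) * rho
            - np.outer(cbar * u, beta)
            - np.outer(beta, cbar * u)
            + np.outer(beta, beta) * w
        )
        + np.outer(beta - 1, beta - 1) * amp_g**2
    )
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def gsr_compensated_covariance(scenario: SynthScenario) -> dict[str, np.ndarray]:
    """Per-state planted matrices whose post-GSR measurement = targets."""
    cbar, f = _region_geometry(scenario)
    amp = scenario.noise.signal_sd
    amp_g = scenario.noise.global_sd
    out = {}
    for state, target in scenario.state_covariance.items():
        rho = target.copy()
        for _ in range(40):
            pred = predict_post_gsr(rho, cbar, f, amp, amp_g)
            step = target - pred
            np.fill_diagonal(step, 0.0)
            rho = np.clip(rho + step, -0.99, 0.99)
            np.fill_diagonal(rho, 1.0)
            if np.max(np.abs(step)) < 1e-10:
                break
        if np.linalg.eigvalsh(rho).min() < -1e-10:
            rho = repair_psd(rho)
        out[state] = rho
    return out


def latent_systems(scenario: SynthScenario) -> list[str]:
    """System label of each latent row (from its first region)."""
    out = [""] * scenario.n_latents
    for reg in scenario.region_layout:
        if not out[reg.latent_index]:
            out[reg.latent_index] = reg.system
    return out


def _block_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def scenario_fingerprint(scenario: SynthScenario) -> str:
    """Hash of everything the observation-scale calibration depends on."""
    payload = {
        "grid_shape": list(scenario.grid_shape),
        "voxel_size": scenario.voxel_size,
        "n_volumes": scenario.n_volumes,
        "tr": scenario.tr,
        "origin_mm": list(scenario.origin_mm),
        "layout": [
            [r.name, r.system, r.voxels.tolist(), r.latent_index]
            for r in scenario.region_layout
        ],
        "noise": {k: round(float(v), 9) if isinstance(v, (int, float)) else v
                  for k, v in vars(scenario.noise).items()},
        "targets": {
            s: np.round(m, 9).tolist()
            for s, m in sorted(scenario.state_covariance.items())
        },
        "motion_spike_rate": scenario.motion_spike_rate,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()


_PACKAGED_CALIBRATION = Path(__file__).parent / "data" / "default_calibration.json"


def _load_packaged_calibration(scenario: SynthScenario):
    if not _PACKAGED_CALIBRATION.exists():
        return None
    with open(_PACKAGED_CALIBRATION) as fh:
        payload = json.load(fh)
    if payload.get("fingerprint") != scenario_fingerprint(scenario):
        return None
    return {s: np.asarray(m) for s, m in payload["matrices"].items()}


def planted_covariance(scenario: SynthScenario) -> dict[str, np.ndarray]:
    """Group matrices the image-level generator actually plants.

    With ``compensate_gsr`` (the default) the planted matrices are
    observation-scale calibrated so the post-pipeline measurement
    reproduces the targets: the packaged simulation-based calibration
    table is used when the scenario matches its fingerprint (the
    packaged default study), otherwise the analytic first-order GSR
    compensation.  The region-level fast path (no images, no GSR)
    always plants the raw targets.
    """
    if not getattr(scenario, "compensate_gsr", True):
        return scenario.state_covariance
    cache = scenario.__dict__.get("_planted_cov_cache")
    if cache is None:
        cache = _load_packaged_calibration(scenario)
        if cache is None:
            cache = gsr_compensated_covariance(scenario)
        scenario.__dict__["_planted_cov_cache"] = cache
    return cache


def calibrate_planted_covariance(
    scenario: SynthScenario,
    n_runs: int = 48,
    n_iter: int = 3,
    rng_seed: int = 31_415,
    verbose: bool = False,
) -> dict[str, np.ndarray]:
    """Simulation-based observation-scale calibration of the planted matrices.

    Iteratively adjusts the planted system-block correlations so that
    the *measured* block means — planted-region time courses through the
    default preprocessing (smoothing, band-pass, nuisance + global
    regression, censoring) — equal the scenario's targets.  This folds
    in every systematic measurement effect at once (GSR network-mean
    subtraction, tanh/Jensen bias of finite-sample correlations,
    regression losses), which the analytic first-order model only
    approximates.  The measurement masks are the planted regions plus a
    one-voxel dilation: the group statistics recover each region
    together with its high-SNR smoothing halo, and the halo's diluted
    signal amplifies the additive global-regression residue, so the
    calibration must emulate the extent that is actually measured.
    Noise-free in expectation only: each block retains a residual of
    about 0.075/sqrt(n_runs) from the calibration runs.
    """
    from scipy import ndimage as ndi

    from .pipeline import PipelineConfig, preprocess_series

    cfg = PipelineConfig()
    brain = scenario.brain_mask()
    wm, csf = scenario.tissue_masks()
    systems = latent_systems(scenario)
    k = scenario.n_latents
    masks = []
    for reg in scenario.region_layout:
        m = np.zeros(scenario.grid_shape, dtype=bool)
        m[tuple(reg.voxels.T)] = True
        m = ndi.binary_dilation(m, structure=np.ones((3, 3, 3), bool)) & brain
        masks.append(m[brain])
    blocks: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i in range(k):
        for j in range(i + 1, k):
            blocks.setdefault(_block_key(systems[i], systems[j]), []).append((i, j))

    planted = {s: m.copy() for s, m in gsr_compensated_covariance(scenario).items()}
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    for it in range(n_iter):
        for state in STATES:
            acc = np.zeros((k, k))
            for _ in range(n_runs):
                data, params = _simulate_run(
                    scenario, planted[state], rng, brain, wm, csf
                )
                run = BoldRun(
                    subject="cal", state=state, data=data, tr=scenario.tr,
                    affine=scenario.affine, brain_mask=brain, wm_mask=wm,
                    csf_mask=csf,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    series, _ = preprocess_series(
                        run, MotionTrace(params=params), cfg
                    )
                x = np.stack(
                    [series[m].mean(axis=0, dtype=np.float64) for m in masks]
                )
                x -= x.mean(axis=1, keepdims=True)
                nrm = np.sqrt((x**2).sum(axis=1))
                nrm[nrm == 0] = 1.0
                acc += (x @ x.T) / np.outer(nrm, nrm) / n_runs
            z = np.arctanh(
                np.clip(planted[state], -1 + 1e-9, 1 - 1e-9)
            )
            for key, pairs in blocks.items():
                target = np.mean(
                    [scenario.state_covariance[state][i, j] for i, j in pairs]
                )
                measured = np.mean([acc[i, j] for i, j in pairs])
                delta = np.arctanh(np.clip(target, -0.999, 0.999)) - np.arctanh(
                    np.clip(measured, -0.999, 0.999)
                )
                for i, j in pairs:
                    z[i, j] += delta
                    z[j, i] = z[i, j]
                if verbose:
                    print(f"iter {it} {state} {key}: measured {measured:+.3f} "
                          f"target {target:+.3f}")
            p = np.tanh(z)
            np.fill_diagonal(p, 1.0)
            if np.linalg.eigvalsh(p).min() < -1e-10:
                p = repair_psd(p)
            planted[state] = p
    return planted


def save_calibration(scenario: SynthScenario, matrices, path=None) -> None:
    path = Path(path) if path else _PACKAGED_CALIBRATION
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(
            {
                "fingerprint": scenario_fingerprint(scenario),
                "matrices": {s: np.asarray(m).tolist() for s, m in matrices.items()},
            },
            fh,
        )


def sample_subject_matrices(
    scenario: SynthScenario,
    rng: np.random.Generator,
    covariance: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Per-state subject correlation matrices: group mean + block deviates.

    Each unordered system-block gets a Gaussian deviate on the Fisher-Z
    scale with total SD ``subject_sd``, decomposed into a stable
    per-subject offset (shared by all four states, SD
    sqrt(subject_sd^2 - state_sd^2)) plus an independent state-specific
    part (SD ``state_sd``).  The shared part models trait-like
    individual connectivity differences — it widens the group SEMs but
    cancels in within-subject contrasts; the state part is what the
    repeated-measures error term and the dFC variance see.  Perturbed
    matrices are clipped back to (-1, 1) on the r scale and PSD-repaired
    if the perturbation left the cone.
    """
    systems = latent_systems(scenario)
    k = scenario.n_latents
    state_sd = min(scenario.state_sd, scenario.subject_sd)
    shared_sd = np.sqrt(max(scenario.subject_sd**2 - state_sd**2, 0.0))
    block_keys = sorted(
        {_block_key(systems[i], systems[j]) for i in range(k) for j in range(i + 1, k)}
    )
    shared = {key: rng.normal(0.0, shared_sd) for key in block_keys}
    cov = covariance if covariance is not None else scenario.state_covariance
    z0_cache = scenario.__dict__.setdefault("_z0_cache", {})
    out: dict[str, np.ndarray] = {}
    for state in STATES:
        group = cov[state]
        ck = (state, id(cov), scenario.subject_sd)
        if ck not in z0_cache:
            z0_cache[ck] = _mean_matched_z(group, scenario.subject_sd)
        z = z0_cache[ck].copy()
        blocks = {
            key: shared[key] + rng.normal(0.0, state_sd) for key in block_keys
        }
        for i in range(k):
            for j in range(i + 1, k):
                z[i, j] += blocks[_block_key(systems[i], systems[j])]
                z[j, i] = z[i, j]
        r = np.tanh(z)
        np.fill_diagonal(r, 1.0)
        if np.linalg.eigvalsh(r).min() < -1e-10:
            r = repair_psd(r)
        out[state] = r
    return out


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------

def _as_seedseq(rng_stream) -> np.random.SeedSequence:
    if rng_stream is None:
        raise ValueError(
            "rng_stream is required: the generator's reproducibility "
            "contract is identical seeds -> identical output"
        )
    if isinstance(rng_stream, np.random.SeedSequence):
        return rng_stream
    return np.random.SeedSequence(int(rng_stream))


def _spike_frames(
    rng: np.random.Generator, rate: float, n_frames: int, min_gap: int = 5
) -> np.ndarray:
    """Poisson number of spike frames, pairwise >= min_gap apart."""
    count = rng.poisson(rate)
    lo, hi = 11, n_frames - 3  # survive the first-10 drop, keep windows inside
    if hi <= lo:
        return np.empty(0, dtype=int)
    frames: list[int] = []
    for _ in range(count):
        for _try in range(200):
            t = int(rng.integers(lo, hi))
            if all(abs(t - f) >= min_gap for f in frames):
                frames.append(t)
                break
    return np.array(sorted(frames), dtype=int)


def _simulate_run(
    scenario: SynthScenario,
    corr: np.ndarray,
    rng: np.random.Generator,
    brain: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One run's raw 4D data and motion parameters for given latents."""
    nm = scenario.noise
    T = scenario.n_volumes
    nb = int(brain.sum())
    t_idx = np.arange(T)
    lat = _correlated_latents(rng, corr, T, nm.ar_coeff)
    g = _ar1(rng.standard_normal(T + _BURN), nm.ar_coeff)[_BURN:]
    wm_sig = _ar1(rng.standard_normal(T + _BURN), nm.ar_coeff)[_BURN:]
    csf_sig = _ar1(rng.standard_normal(T + _BURN), nm.ar_coeff)[_BURN:]

    series = rng.standard_normal((nb, T), dtype=np.float32)
    series *= nm.white_sd
    series += nm.baseline
    series += (nm.global_sd * g).astype(np.float32)[None, :]
    # slow scanner drift, below the 0.008 Hz band edge
    drift = np.sin(
        2 * np.pi * nm.drift_freq_hz * scenario.tr * t_idx
        + rng.uniform(0, 2 * np.pi)
    ).astype(np.float32)
    amp = rng.uniform(-nm.drift_sd, nm.drift_sd, nb).astype(np.float32)
    series += amp[:, None] * drift[None, :]

    spikes = _spike_frames(rng, scenario.motion_spike_rate, T)
    for t0 in spikes:
        s = rng.choice([-1.0, 1.0])
        series[:, t0:] += np.float32(s * nm.gs_spike_pct / 100.0 * nm.baseline)

    data = np.zeros(scenario.grid_shape + (T,), dtype=np.float32)
    data[brain] = series
    for reg in scenario.region_layout:
        data[tuple(reg.voxels.T)] += (
            nm.signal_sd * lat[reg.latent_index]
        ).astype(np.float32)
    data[wm] += (nm.nuisance_sd * wm_sig).astype(np.float32)
    data[csf] += (nm.nuisance_sd * csf_sig).astype(np.float32)

    params = np.cumsum(rng.normal(0.0, 0.002, (T, 6)), axis=0)
    for t0 in spikes:
        axis = int(rng.integers(0, 3))
        params[t0:, axis] += nm.spike_translation_mm * rng.choice([-1, 1])
        params[t0:, 3 + axis] += nm.spike_rotation_rad * rng.choice([-1, 1])
    return data, params


def simulate_subject(
    scenario: SynthScenario, subject_index: int, rng_stream
) -> SubjectData:
    """Simulate all four runs (and motion traces) of one subject."""
    if subject_index >= scenario.n_subjects:
        raise ValueError("subject_index out of range")
    ss = _as_seedseq(rng_stream)
    rng = np.random.default_rng(ss)
    brain = scenario.brain_mask()
    wm, csf = scenario.tissue_masks()
    true_corr = sample_subject_matrices(
        scenario, rng, covariance=planted_covariance(scenario)
    )
    runs: dict[str, BoldRun] = {}
    motion: dict[str, MotionTrace] = {}
    subject = f"sub-{subject_index:02d}"
    for state in STATES:
        data, params = _simulate_run(
            scenario, true_corr[state], rng, brain, wm, csf
        )
        runs[state] = BoldRun(
            subject=subject,
            state=state,
            data=data,
            tr=scenario.tr,
            affine=scenario.affine,
            brain_mask=brain,
            wm_mask=wm,
            csf_mask=csf,
        )
        motion[state] = MotionTrace(params=params)
    return SubjectData(subject=subject, runs=runs, motion=motion, true_corr=true_corr)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def system_block_pairs(systems: list[str], sys_a: str, sys_b: str):
    ia = [i for i, s in enumerate(systems) if s == sys_a]
    ib = [i for i, s in enumerate(systems) if s == sys_b]
    return [(i, j) for i in ia for j in ib if i != j]


def _block_mean_z(mat: np.ndarray, pairs) -> float:
    z = np.arctanh(np.clip(mat, -1 + 1e-9, 1 - 1e-9))
    return float(np.mean([z[i, j] for i, j in pairs]))


def latent_dfc_from_matrices(
    scenario: SynthScenario, per_subject: list[dict[str, np.ndarray]]
) -> dict[tuple[str, str], np.ndarray]:
    """Per-subject Fisher-Z latent dFC for both system pairings and tasks."""
    systems = latent_systems(scenario)
    out: dict[tuple[str, str], np.ndarray] = {}
    for sysname in ("decreasing", "increasing"):
        pairs = system_block_pairs(systems, "stable", sysname)
        if not pairs:
            continue
        for task in TASK_STATES:
            vals = [
                _block_mean_z(m[task], pairs) - _block_mean_z(m["R1"], pairs)
                for m in per_subject
            ]
            out[(sysname, task)] = np.asarray(vals)
    return out


def effective_samples(
    n_frames: int, tr: float, low_hz: float = 0.008, high_hz: float = 0.08,
    ar_coeff: float = 0.3, order: int = 4,
) -> float:
    """Effective temporal dof of a band-passed AR(1) run.

    A zero-phase Butterworth band-pass leaves roughly 2*bandwidth*duration
    independent samples; this computes it exactly for the generator's
    process via Bartlett's formula: n_eff = n / sum_tau rho(tau)^2 with
    rho the theoretical autocorrelation of the filtered process.
    """
    from scipy import signal as sps

    nfft = 4096
    freqs = np.fft.rfftfreq(nfft, d=tr)
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr,
                     output="sos")
    _, h = sps.sosfreqz(sos, worN=freqs, fs=1.0 / tr)
    # forward-backward filtering squares the magnitude response
    gain2 = np.abs(h) ** 4
    ar_psd = 1.0 / np.abs(1.0 - ar_coeff * np.exp(-2j * np.pi * freqs * tr)) ** 2
    psd = gain2 * ar_psd
    acov = np.fft.irfft(psd, n=nfft)
    rho = acov / acov[0]
    m = min(n_frames, nfft // 2)
    s = rho[0] ** 2 + 2.0 * np.sum(rho[1:m] ** 2)
    return float(n_frames / s)


def _os_cov_r(r: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Olkin-Siotani asymptotic n*cov(r_ij, r_kl) for jointly normal data."""
    return (
        0.5 * r[i, j] * r[k, l]
        * (r[i, k] ** 2 + r[i, l] ** 2 + r[j, k] ** 2 + r[j, l] ** 2)
        + r[i, k] * r[j, l] + r[i, l] * r[j, k]
        - (r[i, j] * r[i, k] * r[i, l] + r[j, i] * r[j, k] * r[j, l]
           + r[k, i] * r[k, j] * r[k, l] + r[l, i] * r[l, j] * r[l, k])
    )


def block_z_error_sd(corr: np.ndarray, pairs, n_eff: float) -> float:
    """Sampling SD of a block-mean Fisher-Z estimate over n_eff samples."""
    tot = 0.0
    for (i, j) in pairs:
        for (k, l) in pairs:
            cov = _os_cov_r(corr, i, j, k, l) / n_eff
            tot += cov / ((1 - corr[i, j] ** 2) * (1 - corr[k, l] ** 2))
    return float(np.sqrt(max(tot, 0.0))) / len(pairs)


def dfc_estimation_sd(scenario: SynthScenario, sysname: str, task: str,
                      covariance: dict[str, np.ndarray] | None = None) -> float:
    """Analytic sampling SD of the estimated system-mean Fisher-Z dFC.

    The measured dFC is a difference of two independent-run block means,
    each carrying the finite-frame sampling error of a band-limited
    5-minute run; this is the noise floor the behavior-coupling
    calibration must account for.
    """
    cov = covariance if covariance is not None else scenario.state_covariance
    systems = latent_systems(scenario)
    pairs = system_block_pairs(systems, "stable", sysname)
    if not pairs:
        return 0.0
    n_eff = effective_samples(
        scenario.n_volumes - 10, scenario.tr, ar_coeff=scenario.noise.ar_coeff
    )
    v = (block_z_error_sd(cov["R1"], pairs, n_eff) ** 2
         + block_z_error_sd(cov[task], pairs, n_eff) ** 2)
    return float(np.sqrt(v))


def dfc_attenuation(
    scenario: SynthScenario,
    sysname: str,
    task: str,
    covariance: dict[str, np.ndarray] | None = None,
    n_pilot: int = 1200,
) -> float:
    """Pilot-measured attenuation of the observed dFC-behavior coupling.

    The correlation between the latent per-subject dFC and the dFC a
    5-minute band-limited run lets anyone *measure* is < 1; couplings
    calibrated on the observed scale must be inflated by 1/alpha.  The
    asymptotic value from :func:`dfc_estimation_sd` under-estimates the
    error at ~40 effective samples, so alpha is measured directly by a
    deterministic pilot simulation of the generator's own latent process
    (fixed internal seed); one pilot pass serves all system pairings and
    task states and is cached per scenario.
    """
    cov = covariance if covariance is not None else scenario.state_covariance
    cache = scenario.__dict__.setdefault("_alpha_cache", {})
    ck = id(cov)
    if ck not in cache:
        cache[ck] = _pilot_alpha_table(scenario, cov, n_pilot)
    return cache[ck].get((sysname, task), 1.0)


def _pilot_alpha_table(
    scenario: SynthScenario, cov: dict[str, np.ndarray], n_pilot: int
) -> dict[tuple[str, str], float]:
    from .preprocess import bandpass_series

    systems = latent_systems(scenario)
    combos = {
        (sysname, task): system_block_pairs(systems, "stable", sysname)
        for sysname in ("decreasing", "increasing")
        for task in TASK_STATES
    }
    combos = {k: v for k, v in combos.items() if v}
    if not combos:
        return {}
    rng = np.random.default_rng(np.random.SeedSequence(202306))
    nm = scenario.noise
    nvox = np.zeros(scenario.n_latents)
    for reg in scenario.region_layout:
        nvox[reg.latent_index] += len(reg.voxels)
    lat = {k: [] for k in combos}
    obs = {k: [] for k in combos}
    for _ in range(n_pilot):
        mats = sample_subject_matrices(scenario, rng, covariance=cov)
        block_obs = {}
        for state in STATES:
            x = nm.signal_sd * _correlated_latents(
                rng, mats[state], scenario.n_volumes, nm.ar_coeff
            )
            x += rng.standard_normal(x.shape) * (
                nm.white_sd / np.sqrt(nvox)
            )[:, None]
            x = bandpass_series(x[:, 10:], scenario.tr)
            x = x - x.mean(axis=1, keepdims=True)
            nrm = np.sqrt((x**2).sum(axis=1))
            c = (x @ x.T) / np.outer(nrm, nrm)
            block_obs[state] = {
                k: np.mean([c[i, j] for i, j in pairs])
                for k, pairs in combos.items()
            }
        for k, pairs in combos.items():
            _, task = k
            lat[k].append(
                _block_mean_z(mats[task], pairs) - _block_mean_z(mats["R1"], pairs)
            )
            obs[k].append(block_obs[task][k] - block_obs["R1"][k])
    return {
        k: float(np.clip(np.corrcoef(lat[k], obs[k])[0, 1], 1e-3, 1.0))
        for k in combos
    }


def _censored_sd_factor(mu: float, sd: float, cap: float = 100.0):
    """Moments of min(X, cap) for X ~ N(mu, sd^2): (sd_clipped, cov_factor).

    cov(min(X, cap), D) = rho * sd * sd_D * Phi(z0) for any D jointly
    normal with X, so the correlation of the delivered clipped value is
    rho * sd * Phi(z0) / sd_clipped.
    """
    z0 = (cap - mu) / sd
    p = stats.norm.cdf(z0)
    phi0 = stats.norm.pdf(z0)
    ea = mu * p - sd * phi0 + cap * (1 - p)
    ea2 = (mu**2 + sd**2) * p - sd * (mu + cap) * phi0 + cap**2 * (1 - p)
    var = max(ea2 - ea**2, 1e-12)
    return np.sqrt(var), p


def simulate_behavior(
    scenario: SynthScenario,
    latent_dfc: dict[tuple[str, str], np.ndarray],
    rng_stream,
    covariance: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """RT / accuracy records coupled to the latent per-subject dFC.

    RT couples to dFC(stable, decreasing) and accuracy to
    dFC(stable, increasing) of the same task state.  The coupling
    targets are the *observed* correlations the study reports — between
    behavior and the pipeline-estimated dFC, which carries the
    finite-frame sampling noise of band-limited 5-minute runs.  The
    latent coupling is therefore inflated analytically by the predicted
    attenuation factor (latent dFC SD over total observed dFC SD, with
    the estimation noise from :func:`dfc_estimation_sd`); accuracy is
    additionally inflated for the [0, 100] clipping (censored-normal
    moments).  Both calibrations are deterministic functions of the
    scenario.
    """
    rng = np.random.default_rng(_as_seedseq(rng_stream))
    cov = covariance if covariance is not None else scenario.state_covariance
    n = scenario.n_subjects
    for key, vals in latent_dfc.items():
        if len(vals) != n:
            raise ValueError(f"latent dFC for {key} has wrong length")
    beh = scenario.behavior
    # the shared per-subject offset cancels in dFC = z(task) - z(R1)
    sd_lat = np.sqrt(2.0) * min(scenario.state_sd, scenario.subject_sd)
    records = []
    for task in TASK_STATES:
        # standardized latent dFC (exact population moments)
        def standardized(sysname: str) -> np.ndarray:
            if sd_lat == 0 or (sysname, task) not in latent_dfc:
                return np.zeros(n)
            systems = latent_systems(scenario)
            pairs = system_block_pairs(systems, "stable", sysname)
            z0 = _mean_matched_z(cov[task], scenario.subject_sd)
            z0r = _mean_matched_z(cov["R1"], scenario.subject_sd)
            mu = np.mean([z0[i, j] - z0r[i, j] for i, j in pairs])
            return (latent_dfc[(sysname, task)] - mu) / sd_lat

        x_rt = standardized("decreasing")
        x_acc = standardized("increasing")

        def latent_rho(rho_obs: float, sysname: str) -> float:
            """Observed coupling target -> latent slope (deattenuation)."""
            if sd_lat == 0 or rho_obs == 0:
                return 0.0
            alpha = dfc_attenuation(scenario, sysname, task, covariance=cov)
            # the printed target is a sample correlation at n_ref; the
            # ensemble-mean sample r underestimates the population value
            # by the standard Fisher bias factor
            fisher = 1.0 + (1.0 - rho_obs**2) / (2.0 * max(beh.n_ref - 1, 1))
            rho_l = rho_obs * fisher / alpha
            if abs(rho_l) > 0.99:
                warnings.warn(
                    f"coupling target {rho_obs} for {sysname}/{task} exceeds "
                    "the estimation-noise ceiling; capped at 0.99"
                )
                rho_l = np.sign(rho_l) * 0.99
            return rho_l

        rho = latent_rho(beh.rho_rt[task], "decreasing")
        sd_rt = beh.rt_sd(task)
        rt = (
            beh.rt_mean[task]
            + rho * sd_rt * x_rt
            + np.sqrt(max(1 - rho**2, 0.0)) * sd_rt * rng.standard_normal(n)
        )
        rt = np.maximum(rt, 1.0)

        mu_a, sd_a = beh.acc_mean[task], beh.acc_sd(task)
        sd_clip, pmass = _censored_sd_factor(mu_a, sd_a)
        rho_a = latent_rho(beh.rho_acc[task], "increasing")
        rho_pre = rho_a * sd_clip / (sd_a * pmass)
        if abs(rho_pre) > 0.99:
            warnings.warn("accuracy coupling target unreachable after clipping")
            rho_pre = np.sign(rho_pre) * 0.99
        acc = (
            mu_a
            + rho_pre * sd_a * x_acc
            + np.sqrt(max(1 - rho_pre**2, 0.0)) * sd_a * rng.standard_normal(n)
        )
        acc = np.clip(acc, 0.0, 100.0)
        for i in range(n):
            records.append(
                {
                    "subject": f"sub-{i:02d}",
                    "state": task,
                    "rt_ms": rt[i],
                    "accuracy_pct": acc[i],
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(scenario: SynthScenario, seed: int | None = None) -> Cohort:
    """Full image-level cohort: every subject, all four states, behavior."""
    entropy = scenario.seed if seed is None else seed
    root = np.random.SeedSequence(entropy)
    children = root.spawn(scenario.n_subjects + 1)
    subjects = [
        simulate_subject(scenario, i, children[i]) for i in range(scenario.n_subjects)
    ]
    latent = latent_dfc_from_matrices(scenario, [s.true_corr for s in subjects])
    behavior = simulate_behavior(
        scenario, latent, children[-1], covariance=planted_covariance(scenario)
    )
    return Cohort(
        scenario=scenario, subjects=subjects, behavior=behavior, latent_dfc=latent
    )


@dataclass
class RegionCohort:
    """Region-time-course cohort (no images): the fast generation mode.

    Mathematically this is the region-mean of the image-level simulation
    without the spatial steps: each region series is its latent plus
    region-averaged voxel noise.  Used where only region/system-level
    statistics are needed (e.g. the behavior arm at many replicates).
    """

    scenario: SynthScenario
    series: list[dict[str, np.ndarray]]  # per subject: state -> (k, T)
    true_corr: list[dict[str, np.ndarray]]
    behavior: pd.DataFrame
    latent_dfc: dict[tuple[str, str], np.ndarray]


def simulate_region_cohort(scenario: SynthScenario, seed: int | None = None) -> RegionCohort:
    entropy = scenario.seed if seed is None else seed
    root = np.random.SeedSequence(entropy)
    children = root.spawn(scenario.n_subjects + 1)
    nm = scenario.noise
    nvox = np.zeros(scenario.n_latents)
    for reg in scenario.region_layout:
        nvox[reg.latent_index] += len(reg.voxels)
    series: list[dict[str, np.ndarray]] = []
    mats: list[dict[str, np.ndarray]] = []
    for i in range(scenario.n_subjects):
        rng = np.random.default_rng(children[i])
        true_corr = sample_subject_matrices(scenario, rng)
        per_state = {}
        for state in STATES:
            lat = _correlated_latents(rng, true_corr[state], scenario.n_volumes, nm.ar_coeff)
            noise = rng.standard_normal(lat.shape) * (
                nm.white_sd / np.sqrt(nvox)
            )[:, None]
            per_state[state] = nm.signal_sd * lat + noise
        series.append(per_state)
        mats.append(true_corr)
    latent = latent_dfc_from_matrices(scenario, mats)
    behavior = simulate_behavior(scenario, latent, children[-1])
    return RegionCohort(
        scenario=scenario,
        series=series,
        true_corr=mats,
        behavior=behavior,
        latent_dfc=latent,
    )


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixtures(cohort: Cohort, out_dir) -> dict:
    """Write a cohort as NIfTI + text fixtures; returns the manifest."""
    if not cohort.subjects:
        raise ValueError("refusing to write an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc: SynthScenario = cohort.scenario
    files: dict[str, str] = {}

    def _save_img(arr, name):
        img = nib.Nifti1Image(np.asarray(arr), sc.affine)
        path = out / name
        nib.save(img, path)
        files[name] = _sha256(path)

    brain = sc.brain_mask()
    wm, csf = sc.tissue_masks()
    _save_img(brain.astype(np.uint8), "mask_brain.nii.gz")
    _save_img(wm.astype(np.uint8), "mask_wm.nii.gz")
    _save_img(csf.astype(np.uint8), "mask_csf.nii.gz")
    _save_img(sc.region_label_volume(), "planted_regions.nii.gz")
    for sub in cohort.subjects:
        for state in STATES:
            name = f"{sub.subject}_{state}_bold.nii.gz"
            if name in files:
                raise ValueError(f"manifest collision for {name}")
            _save_img(sub.runs[state].data, name)
            mpath = out / f"{sub.subject}_{state}_motion.txt"
            np.savetxt(mpath, sub.motion[state].params, fmt="%.17g")
            files[mpath.name] = _sha256(mpath)
    bpath = out / "behavior.tsv"
    cohort.behavior.to_csv(bpath, sep="\t", index=False)
    files[bpath.name] = _sha256(bpath)
    save_scenario(sc, out / "scenario.yaml")
    files["scenario.yaml"] = _sha256(out / "scenario.yaml")
    manifest = {"n_subjects": cohort.n_subjects, "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_fixtures(fix_dir):
    """Read back a fixture directory written by :func:`write_fixtures`.

    Returns (scenario, subjects) where subjects mirror
    :class:`SubjectData` minus the generator truth.
    """
    fix = Path(fix_dir)
    sc = load_scenario(fix / "scenario.yaml")
    brain = np.asarray(nib.load(fix / "mask_brain.nii.gz").dataobj).astype(bool)
    wm = np.asarray(nib.load(fix / "mask_wm.nii.gz").dataobj).astype(bool)
    csf = np.asarray(nib.load(fix / "mask_csf.nii.gz").dataobj).astype(bool)
    subjects = []
    for i in range(sc.n_subjects):
        subject = f"sub-{i:02d}"
        runs, motion = {}, {}
        for state in STATES:
            img = nib.load(fix / f"{subject}_{state}_bold.nii.gz")
            runs[state] = BoldRun(
                subject=subject,
                state=state,
                data=np.asarray(img.dataobj, dtype=np.float32),
                tr=sc.tr,
                affine=img.affine,
                brain_mask=brain,
                wm_mask=wm,
                csf_mask=csf,
            )
            motion[state] = MotionTrace(
                params=np.loadtxt(fix / f"{subject}_{state}_motion.txt")
            )
        subjects.append(
            SubjectData(subject=subject, runs=runs, motion=motion, true_corr={})
        )
    behavior = pd.read_csv(fix / "behavior.tsv", sep="\t")
    return sc, subjects, behavior
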