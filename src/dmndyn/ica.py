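"""Group spatial ICA validation arm.

Simplified GIFT-style chain: per-subject temporal PCA reduction,
temporal concatenation, group PCA, infomax ICA (logistic nonlinearity,
natural gradient), MDL model-order selection from the eigenvalue
spectrum, DMN component selection by template matching (mean z inside
the template minus mean z outside), and GICA back-projection of the
group decomposition to subject-specific maps and time courses.  The
subject DMN maps feed the same repeated-measures ANOVA + paired-t
region statistics as the seed arm.

Subject data enter as (frames x voxels) matrices over the analysis
mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import STATES
from .seedfc import ConnectivityMap, group_significance
from .regions import detect_regions, RegionSet


# ---------------------------------------------------------------------------
# model order
# ---------------------------------------------------------------------------

def mdl_order(data: np.ndarray, subsample_correction: bool = False) -> int:
    """Minimum-description-length model order from the data eigenspectrum.

    ``data`` is (frames x voxels): channels are frames (p), samples are
    voxels (N).  MDL(k) = -log L(k) + 0.5 k (2p - k) log N, with
    log L(k) = N (p - k) log(GM / AM) of the trailing eigenvalues.
    ``subsample_correction`` divides N by the smoothness-implied
    subsampling factor 2 (rough independent-sample correction); the
    default uses the raw sample count.
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (frames >= 2, voxels) matrix")
    p, n = x.shape
    x = x - x.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / n
    ev = np.linalg.eigvalsh(cov)[::-1]
    ev = np.clip(ev, 1e-300, None)
    if ev[0] / ev[-1] > 1e12:
        warnings.warn("near-degenerate eigenvalue spectrum in MDL")
    n_eff = n / 2.0 if subsample_correction else float(n)
    best_k, best = 0, np.inf
    for k in range(0, p):
        tail = ev[k:]
        gm = np.exp(np.mean(np.log(tail)))
        am = np.mean(tail)
        loglik = n_eff * (p - k) * np.log(gm / am)
        crit = -loglik + 0.5 * k * (2 * p - k) * np.log(n_eff)
        if crit < best:
            best, best_k = crit, k
    return best_k


# ---------------------------------------------------------------------------
# reduction + concatenation
# ---------------------------------------------------------------------------

@dataclass
class ReducedData:
    """Two-stage PCA reduction of a concatenated multi-subject dataset."""

    reduced: np.ndarray            # (k_group, voxels)
    subject_bases: list[np.ndarray]  # U_i: (frames, k_subject)
    group_basis: np.ndarray        # G: (n * k_subject, k_group)
    subject_variance: list[float]  # variance fraction retained per subject
    group_variance: float
    subject_means: list[np.ndarray]


def _temporal_pca(x: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Top-k temporal eigenvectors of (frames x voxels) data."""
    t = x.shape[0]
    if k > t:
        raise ValueError(f"requested {k} PCs from {t} frames")
    cov = (x @ x.T) / x.shape[1]
    w, v = np.linalg.eigh(cov)
    w, v = w[::-1], v[:, ::-1]
    retained = float(w[:k].sum() / max(w.sum(), 1e-300))
    return v[:, :k], retained


def reduce_and_concatenate(
    runs: list[np.ndarray], n_pc_subject: int, n_pc_group: int
) -> ReducedData:
    """Subject-wise temporal PCA, concatenation, group-level PCA."""
    bases, variances, reduced_rows, means = [], [], [], []
    for x in runs:
        x = np.asarray(x, dtype=np.float64)
        mean = x.mean(axis=0, keepdims=True)
        xc = x - mean
        u, retained = _temporal_pca(xc, n_pc_subject)
        bases.append(u)
        variances.append(retained)
        reduced_rows.append(u.T @ xc)
        means.append(mean)
    y = np.concatenate(reduced_rows, axis=0)  # (n*k1, v)
    if n_pc_group > y.shape[0]:
        raise ValueError("group PCs exceed concatenated rank")
    g, g_var = _temporal_pca(y, n_pc_group)
    return ReducedData(
        reduced=g.T @ y,
        subject_bases=bases,
        group_basis=g,
        subject_variance=variances,
        group_variance=g_var,
        subject_means=means,
    )


def reconstruct_subject(reduced: ReducedData, runs: list[np.ndarray], i: int
                        ) -> np.ndarray:
    """Back-project subject i through its temporal PCA basis (no ICA)."""
    x = np.asarray(runs[i], dtype=np.float64) - reduced.subject_means[i]
    u = reduced.subject_bases[i]
    return u @ (u.T @ x)


# ---------------------------------------------------------------------------
# infomax
# ---------------------------------------------------------------------------

@dataclass
class IcaDecomposition:
    """Group spatial ICA result plus back-reconstruction machinery."""

    order: int
    maps: np.ndarray          # (order, voxels), z-scored
    mixing: np.ndarray        # (k_group, order): reduced ~ mixing @ raw_maps
    unmixing: np.ndarray      # (order, k_group)
    reduced: ReducedData
    map_scales: np.ndarray    # per-component raw SD removed by z-scoring
    map_means: np.ndarray
    converged: bool = True
    subject_maps: list[np.ndarray] = field(default_factory=list)
    subject_timecourses: list[np.ndarray] = field(default_factory=list)


def infomax(
    x: np.ndarray,
    rng,
    lr: float = None,
    max_iter: int = 600,
    tol: float = 1e-6,
    anneal: float = 0.97,
) -> tuple[np.ndarray, bool]:
    """Natural-gradient infomax with logistic nonlinearity.

    ``x`` is (k, samples), assumed whitened.  Returns the (k, k)
    unmixing matrix W (sources = W x) and a convergence flag.  The
    learning rate anneals on oscillation, standard Bell-Sejnowski
    batch-mode behavior.
    """
    k, n = x.shape
    rng = np.random.default_rng(rng)
    w = np.eye(k) + 0.01 * rng.standard_normal((k, k))
    if lr is None:
        lr = 0.01 / np.log(k + 2.0)
    ident = np.eye(k)
    last_delta = None
    # small stochastic blocks, the standard infomax schedule
    block = int(min(max(8, np.floor(np.sqrt(n / 3.0))), n))
    for it in range(max_iter):
        perm = rng.permutation(n)
        w_old = w.copy()
        for start in range(0, n, block):
            sel = perm[start:start + block]
            u = w @ x[:, sel]
            y = 1.0 / (1.0 + np.exp(-u))
            grad = ident + (1.0 - 2.0 * y) @ u.T / len(sel)
            w = w + lr * grad @ w
            if not np.isfinite(w).all():
                # blow-up: restart smaller
                w = np.eye(k) + 0.01 * rng.standard_normal((k, k))
                lr *= 0.5
                break
        delta = np.max(np.abs(w - w_old))
        if last_delta is not None and delta > last_delta:
            lr *= anneal  # oscillation: cool down
        lr *= 0.99        # fixed annealing schedule
        last_delta = delta
        if delta < tol:
            return w, True
    warnings.warn("infomax did not converge; returning best iterate")
    return w, False


def group_infomax(
    reduced: ReducedData, order: int, rng=None
) -> IcaDecomposition:
    """Run infomax on the (whitened) group-reduced data."""
    r = reduced.reduced
    if order > r.shape[0]:
        raise ValueError("order exceeds reduced rank")
    x = r[:order] if order < r.shape[0] else r
    # whiten rows
    xc = x - x.mean(axis=1, keepdims=True)
    cov = (xc @ xc.T) / xc.shape[1]
    w_ev, v_ev = np.linalg.eigh(cov)
    w_ev = np.clip(w_ev, 1e-12, None)
    whiten = (v_ev / np.sqrt(w_ev)) @ v_ev.T
    xw = whiten @ xc
    w, converged = infomax(xw, rng)
    unmix_total = w @ whiten  # maps = unmix_total @ x
    raw_maps = unmix_total @ xc
    scales = raw_maps.std(axis=1, ddof=0)
    means = raw_maps.mean(axis=1)
    maps = (raw_maps - means[:, None]) / np.maximum(scales, 1e-30)[:, None]
    mixing = np.linalg.pinv(unmix_total)  # (k_used, order)
    if x.shape[0] < r.shape[0]:
        pad = np.zeros((r.shape[0], order))
        pad[:order] = mixing
        mixing = pad
        unmix_full = np.zeros((order, r.shape[0]))
        unmix_full[:, :order] = unmix_total
        unmix_total = unmix_full
    return IcaDecomposition(
        order=order,
        maps=maps,
        mixing=mixing,
        unmixing=unmix_total,
        reduced=reduced,
        map_scales=scales,
        map_means=means,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# template matching and back-reconstruction
# ---------------------------------------------------------------------------

@dataclass
class TemplateMatch:
    component: int
    score: float
    scores: np.ndarray
    flipped: bool


def template_match(maps: np.ndarray, template: np.ndarray) -> TemplateMatch:
    """Pick the component best matching a binary template.

    Goodness of fit = mean z inside the template minus mean z outside;
    the winning component is sign-flipped if its inside-mean is
    negative, so the returned orientation has positive template loading.
    """
    template = np.asarray(template, dtype=bool).ravel()
    if template.sum() == 0:
        raise ValueError("empty template")
    if template.all():
        raise ValueError("template covers the whole mask")
    inside = maps[:, template].mean(axis=1)
    outside = maps[:, ~template].mean(axis=1)
    gof = inside - outside
    best = int(np.argmax(np.abs(gof)))
    return TemplateMatch(
        component=best,
        score=float(np.abs(gof[best])),
        scores=gof,
        flipped=bool(gof[best] < 0),
    )


def back_reconstruct(
    decomposition: IcaDecomposition, runs: list[np.ndarray], subject: int
) -> tuple[np.ndarray, np.ndarray]:
    """GICA back-projection of one subject: (maps, time courses).

    Subject mixing = U_i G_i pinv(W_total); subject maps are the
    pseudo-inverse projection of the subject's (centered) data through
    that composed transform.  Maps are returned in the group z-scoring
    convention (same per-component scale/offset as the group maps).
    """
    red = decomposition.reduced
    if subject >= len(red.subject_bases):
        raise ValueError("subject did not participate in the decomposition")
    k1 = red.subject_bases[0].shape[1]
    g_i = red.group_basis[subject * k1:(subject + 1) * k1]  # (k1, k_group)
    u_i = red.subject_bases[subject]                        # (t, k1)
    a_i = u_i @ g_i @ decomposition.mixing                  # (t, order)
    x = np.asarray(runs[subject], dtype=np.float64) - red.subject_means[subject]
    maps_raw = np.linalg.pinv(a_i) @ x                      # (order, v)
    maps = (maps_raw - decomposition.map_means[:, None]) / np.maximum(
        decomposition.map_scales, 1e-30
    )[:, None]
    return maps, a_i


def back_reconstruct_all(
    decomposition: IcaDecomposition, runs: list[np.ndarray]
) -> IcaDecomposition:
    maps, tcs = [], []
    for i in range(len(runs)):
        m, a = back_reconstruct(decomposition, runs, i)
        maps.append(m)
        tcs.append(a)
    decomposition.subject_maps = maps
    decomposition.subject_timecourses = tcs
    return decomposition


def map_spatial_correlation(map_a: np.ndarray, map_b: np.ndarray,
                            mask: np.ndarray | None = None) -> float:
    """Pearson r between two maps over the (optional) mask."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        a, b = a[m], b[m]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant map")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# state-wise chain
# ---------------------------------------------------------------------------

def run_state_ica(
    runs: list[np.ndarray],
    template: np.ndarray,
    order: int | None = None,
    n_pc_subject: int = 30,
    rng=None,
) -> tuple[IcaDecomposition, TemplateMatch, np.ndarray]:
    """Reduce, decompose, select the DMN component for one state.

    Returns (decomposition with subject maps filled, template match,
    per-subject DMN maps (n x voxels), sign-aligned to the template).
    """
    if order is None:
        order = max(mdl_order(np.concatenate(runs, axis=0)), 2)
    k1 = min(n_pc_subject, min(r.shape[0] for r in runs))
    k_group = min(max(order, 2), k1 * len(runs))
    red = reduce_and_concatenate(runs, k1, k_group)
    dec = group_infomax(red, order, rng=rng)
    match = template_match(dec.maps, template)
    dec = back_reconstruct_all(dec, runs)
    sign = -1.0 if match.flipped else 1.0
    subject_dmn = np.stack(
        [sign * m[match.component] for m in dec.subject_maps]
    )
    return dec, match, subject_dmn


def ica_state_statistics(
    subject_maps: dict[str, np.ndarray],
    brain_mask: np.ndarray,
    seed_mask_vol: np.ndarray | None = None,
    q: float = 0.05,
    fdr_method_maps: str = "by",
    fdr_method_tests: str = "bh",
    connectivity: int = 26,
    min_size_exclusive: int = 5,
) -> RegionSet:
    """Seed-arm region statistics applied to ICA subject DMN maps.

    ``subject_maps[state]`` is (n_subjects x voxels) over the brain
    mask; the maps play the role of the seed arm's Fisher-Z maps in the
    union-mask / RM-ANOVA / paired-t chain.
    """
    for s in STATES:
        if s not in subject_maps:
            raise ValueError(f"missing state {s}")
    n = subject_maps["R1"].shape[0]
    z_maps = {
        s: [
            ConnectivityMap(subject=f"sub-{i:02d}", state=s,
                            z=subject_maps[s][i], mask=brain_mask)
            for i in range(n)
        ]
        for s in STATES
    }
    group_maps = {
        s: group_significance(z_maps[s], q=q, fdr_method=fdr_method_maps)
        for s in STATES
    }
    regset, _, _ = detect_regions(
        z_maps, group_maps, seed_mask_vol, q, fdr_method_tests, connectivity,
        min_size_exclusive,
    )
    return regset
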