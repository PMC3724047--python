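"""State-dependent region detection and classification.

Within the union of the four states' significant connectivity maps, a
one-way repeated-measures ANOVA (states within subjects) finds voxels
whose seed connectivity changes across R1/T1/T2/R2; surviving clusters
(size > 5, 26-connectivity by default) are classified by a retrospective
paired t-test of mean(T1, T2) against mean(R1, R2) into decreasing and
increasing regions.  Stable regions are voxels significant in *all*
four state maps that show no ANOVA change, split into connected
components; the component containing the seed is tagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .containers import STATES
from .seedfc import ConnectivityMap, GroupStateMap, fdr_correct


@dataclass
class UnionMask:
    """Union of the four state network maps, with per-state membership."""

    mask: np.ndarray  # boolean volume
    membership: dict[str, np.ndarray]  # state -> boolean volume

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Region:
    name: str
    kind: str  # stable | decreasing | increasing
    mask: np.ndarray
    is_seed_region: bool = False

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    @property
    def peak_voxel(self) -> tuple[int, int, int]:
        idx = np.argwhere(self.mask)
        return tuple(np.round(idx.mean(axis=0)).astype(int))


@dataclass
class RegionSet:
    regions: list[Region] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[Region]:
        return [r for r in self.regions if r.kind == kind]

    def __len__(self) -> int:
        return len(self.regions)


def union_mask(maps: dict[str, GroupStateMap]) -> UnionMask:
    """Voxels significant (positive network map) in >= 1 of the 4 states."""
    missing = [s for s in STATES if s not in maps]
    if missing:
        raise ValueError(f"missing state map(s): {missing}")
    shapes = {maps[s].sig_pos.shape for s in STATES}
    if len(shapes) != 1:
        raise ValueError("state maps on different grids")
    membership = {s: _to_volume(maps[s]) for s in STATES}
    mask = np.zeros_like(membership["R1"])
    for s in STATES:
        mask |= membership[s]
    return UnionMask(mask=mask, membership=membership)


def _to_volume(gmap: GroupStateMap) -> np.ndarray:
    vol = np.zeros(gmap.mask.shape, dtype=bool)
    vol[gmap.mask] = gmap.sig_pos
    return vol


def rm_anova_1way(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way repeated-measures ANOVA.

    ``data`` has shape (n_subjects, k_states, ...); subjects are the
    blocking factor.  Returns (F, p) with df (k-1, (k-1)(n-1)).
    """
    n, k = data.shape[0], data.shape[1]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = data.mean(axis=(0, 1))
    state_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_state = n * ((state_means - grand) ** 2).sum(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum(axis=0)
    ss_total = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_err = np.maximum(ss_total - ss_state - ss_subj, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_state = ss_state / df1
    ms_err = ss_err / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_err > 0, ms_state / np.maximum(ms_err, 1e-300), np.inf)
        f = np.where((ms_err == 0) & (ms_state == 0), 0.0, f)
    p = stats.f.sf(f, df1, df2)
    p = np.where(np.isinf(f), 0.0, p)
    p = np.where(f == 0, 1.0, p)
    return f, p


def voxelwise_rm_anova(
    z_maps: dict[str, list[ConnectivityMap]],
    union: UnionMask,
    q: float = 0.05,
    fdr_method: str = "bh",
):
    """RM-ANOVA of Fisher-Z connectivity over union-mask voxels.

    ``z_maps[state]`` must be subject-aligned lists (only subjects with
    all four states).  Returns (F, p, significant) as flat arrays over
    the union-mask voxels plus the boolean significance volume.
    """
    ns = {len(z_maps[s]) for s in STATES}
    if len(ns) != 1:
        raise ValueError("every subject must have all four states")
    n = ns.pop()
    if n < 2:
        raise ValueError("need at least 2 subjects")
    brain = z_maps["R1"][0].mask
    sel = union.mask[brain]  # union voxels as index into flat in-mask arrays
    data = np.stack(
        [[z_maps[s][i].z[sel] for s in STATES] for i in range(n)]
    )  # (n, 4, v)
    f, p = rm_anova_1way(data)
    sig = fdr_correct(p, q=q, method=fdr_method)
    sig_vol = np.zeros(brain.shape, dtype=bool)
    sig_vol[union.mask] = sig
    return f, p, sig_vol


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def cluster_filter(
    sig_voxels: np.ndarray, min_size_exclusive: int = 5, connectivity: int = 26
) -> list[np.ndarray]:
    """Connected components with more than ``min_size_exclusive`` voxels."""
    labels, nlab = ndimage.label(sig_voxels, structure=_STRUCTURES[connectivity])
    out = []
    for lab in range(1, nlab + 1):
        comp = labels == lab
        if comp.sum() > min_size_exclusive:
            out.append(comp)
    return out


def classify_voxels(
    z_maps: dict[str, list[ConnectivityMap]],
    clusters: list[np.ndarray],
    q: float = 0.05,
    fdr_method: str = "bh",
) -> dict[str, np.ndarray]:
    """Paired t of mean(T1,T2) vs mean(R1,R2) per ANOVA-significant voxel.

    Returns boolean volumes keyed 'decreasing', 'increasing',
    'unclassified'.  ANOVA-significant voxels whose retrospective test
    does not reach significance are reported as unclassified (with a
    warning) and excluded from the region set.
    """
    shape = z_maps["R1"][0].mask.shape
    out = {k: np.zeros(shape, dtype=bool) for k in
           ("decreasing", "increasing", "unclassified")}
    if not clusters:
        return out
    allvox = np.zeros(shape, dtype=bool)
    for c in clusters:
        allvox |= c
    brain = z_maps["R1"][0].mask
    sel = allvox[brain]
    n = len(z_maps["R1"])
    stack = {s: np.stack([m.z[sel] for m in z_maps[s]]) for s in STATES}
    task = 0.5 * (stack["T1"] + stack["T2"])
    rest = 0.5 * (stack["R1"] + stack["R2"])
    diff = task - rest  # (n, v)
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    degenerate = sd == 0
    sd = np.where(degenerate, 1.0, sd)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[degenerate] = np.where(mean[degenerate] != 0, 0.0, 1.0)
    sig = fdr_correct(p, q=q, method=fdr_method)
    dec = sig & (mean < 0)
    inc = sig & (mean > 0)
    uncl = ~sig
    if uncl.any():
        warnings.warn(
            f"{uncl.sum()} ANOVA-significant voxels not significant in the "
            "retrospective paired test; labeled unclassified"
        )
    vol = np.zeros(shape, dtype=bool)
    for key, flat in (("decreasing", dec), ("increasing", inc),
                      ("unclassified", uncl)):
        vol = np.zeros(shape, dtype=bool)
        flat_vol = np.zeros(brain.sum(), dtype=bool)
        flat_vol[sel] = flat
        vol[brain] = flat_vol
        out[key] = vol
    return out


def define_regions(
    labels: dict[str, np.ndarray],
    union: UnionMask,
    anova_sig: np.ndarray,
    seed_mask_vol: np.ndarray | None = None,
    connectivity: int = 26,
    min_size_exclusive: int = 5,
) -> RegionSet:
    """Assemble the final stable / decreasing / increasing region set.

    Stable voxels are those present in all four state maps and not
    ANOVA-significant; they are split into connected components and
    auto-named by their peak coordinate.  Decreasing/increasing regions
    are the classified clusters (re-labeled per class so the retained
    voxels stay size-filtered).

    Stable regions are additionally required to be spatially distinct
    from the detected changing clusters: voxels within the smoothing
    support (2-voxel dilation) of a changing cluster are removed from
    stable candidacy.  A voxel-level test has partial power, so a
    detected changing region is typically surrounded by voxels of the
    same underlying signal that individually missed the threshold;
    without this guard those remnants masquerade as tiny "stable"
    regions carrying changing-system connectivity.
    """
    regions: list[Region] = []
    changing = np.zeros_like(union.mask)
    for kind in ("decreasing", "increasing"):
        comps = cluster_filter(labels[kind], min_size_exclusive, connectivity)
        for i, comp in enumerate(comps):
            regions.append(Region(name=f"{kind[:3]}_{i:02d}", kind=kind, mask=comp))
            changing |= comp
    stable = np.ones_like(union.mask)
    for s in STATES:
        stable &= union.membership[s]
    stable &= ~anova_sig
    if changing.any():
        # a stable region must be spatially distinct from the detected
        # changing clusters: a voxel-level test has partial power, so a
        # detected cluster is typically surrounded by same-signal voxels
        # that individually missed the threshold, and without this guard
        # those remnants masquerade as small "stable" regions
        support = ndimage.binary_dilation(
            changing, structure=_STRUCTURES[connectivity], iterations=2
        )
        stable &= ~support
    if not stable.any():
        warnings.warn("no stable voxels found")
    # the same noise-suppressing size filter applies to stable components
    comps = cluster_filter(stable, min_size_exclusive, connectivity)
    for comp in comps:
        idx = np.argwhere(comp)
        peak = tuple(np.round(idx.mean(axis=0)).astype(int))
        is_seed = bool(
            seed_mask_vol is not None and (comp & seed_mask_vol).any()
        )
        regions.append(
            Region(
                name=f"stable_{peak[0]}_{peak[1]}_{peak[2]}",
                kind="stable",
                mask=comp,
                is_seed_region=is_seed,
            )
        )
    return RegionSet(regions=regions)


def detect_regions(
    z_maps: dict[str, list[ConnectivityMap]],
    group_maps: dict[str, GroupStateMap],
    seed_mask_vol: np.ndarray | None = None,
    q: float = 0.05,
    fdr_method: str = "bh",
    connectivity: int = 26,
    min_size_exclusive: int = 5,
) -> tuple[RegionSet, UnionMask, np.ndarray]:
    """Full detection chain: union -> RM-ANOVA -> clusters -> classes."""
    union = union_mask(group_maps)
    _, _, anova_sig = voxelwise_rm_anova(z_maps, union, q, fdr_method)
    clusters = cluster_filter(anova_sig, min_size_exclusive, connectivity)
    labels = classify_voxels(z_maps, clusters, q, fdr_method)
    regset = define_regions(
        labels, union, anova_sig, seed_mask_vol, connectivity,
        min_size_exclusive,
    )
    return regset, union, anova_sig
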