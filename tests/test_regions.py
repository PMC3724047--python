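"""Union mask, repeated-measures ANOVA, clustering, classification."""

import numpy as np
import pytest
from scipy import ndimage

import dmndyn as dd
from dmndyn.containers import STATES
from dmndyn.regions import (
    UnionMask,
    classify_voxels,
    cluster_filter,
    define_regions,
    rm_anova_1way,
    union_mask,
    voxelwise_rm_anova,
)
from dmndyn.seedfc import ConnectivityMap, GroupStateMap


def _gmap(state, sig, mask):
    flat = sig[mask]
    return GroupStateMap(
        state=state, t=np.where(flat, 5.0, 0.0), p=np.where(flat, 1e-6, 0.9),
        sig_pos=flat, sig_neg=np.zeros_like(flat), mask=mask,
        n_subjects=16, q=0.05, fdr_method="by",
    )


class TestUnionMask:
    def test_identical_masks_union_is_that_mask(self):
        mask = np.ones((4, 4, 4), bool)
        sig = np.zeros((4, 4, 4), bool)
        sig[:2] = True
        maps = {s: _gmap(s, sig, mask) for s in STATES}
        u = union_mask(maps)
        assert np.array_equal(u.mask, sig)

    def test_disjoint_masks_sizes_add(self):
        mask = np.ones((4, 4, 10), bool)
        maps = {}
        for i, s in enumerate(STATES):
            sig = np.zeros((4, 4, 10), bool)
            sig[:, i, 1] = True  # 4 voxels each, disjoint columns
            maps[s] = _gmap(s, sig, mask)
        u = union_mask(maps)
        assert u.n_voxels == 16

    def test_random_overlap_equals_elementwise_or(self, rng):
        mask = np.ones((5, 5, 5), bool)
        sigs = {s: rng.random((5, 5, 5)) < 0.3 for s in STATES}
        u = union_mask({s: _gmap(s, sigs[s], mask) for s in STATES})
        expected = sigs["R1"] | sigs["T1"] | sigs["T2"] | sigs["R2"]
        assert np.array_equal(u.mask, expected)

    def test_missing_state_raises(self):
        mask = np.ones((3, 3, 3), bool)
        maps = {s: _gmap(s, mask.copy(), mask) for s in ("R1", "T1")}
        with pytest.raises(ValueError, match="missing state"):
            union_mask(maps)


def _anova_oracle(table):
    """Brute-force two-way (subject x state) sum-of-squares decomposition."""
    table = np.asarray(table, float)
    n, k = table.shape
    grand = table.mean()
    ss_state = n * ((table.mean(0) - grand) ** 2).sum()
    ss_subj = k * ((table.mean(1) - grand) ** 2).sum()
    ss_tot = ((table - grand) ** 2).sum()
    ss_err = ss_tot - ss_state - ss_subj
    return (ss_state / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestRmAnova:
    def test_matches_sum_of_squares_oracle(self):
        table = np.array([[0.40, 0.31, 0.22, 0.44],
                          [0.52, 0.38, 0.30, 0.49],
                          [0.47, 0.30, 0.21, 0.50]])
        f, p = rm_anova_1way(table[:, :, None])
        assert f[0] == pytest.approx(_anova_oracle(table), rel=1e-10)

    def test_matches_pingouin_reference(self, rng):
        """Cross-check against an independent RM-ANOVA implementation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        table = rng.normal(size=(8, 4))
        f, p = rm_anova_1way(table[:, :, None])
        df = pd.DataFrame({
            "y": table.ravel(),
            "subject": np.repeat(np.arange(8), 4),
            "state": np.tile(np.arange(4), 8),
        })
        ref = pingouin.rm_anova(data=df, dv="y", within="state",
                                subject="subject")
        assert f[0] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert p[0] == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_identical_states_give_f_zero_p_one(self):
        table = np.tile(np.arange(5.0)[:, None], (1, 4))
        f, p = rm_anova_1way(table[:, :, None])
        assert f[0] == 0.0 and p[0] == 1.0

    def test_calibrated_effect_significant_in_most_replicates(self, rng):
        """The published state profile at n=16 is detected reliably
        (subject noise 0.1, 200 replicates, BH-FDR over a small mask)."""
        means = np.array([0.43, 0.35, 0.24, 0.45])
        hits = 0
        reps = 200
        for _ in range(reps):
            data = means[None, :, None] + rng.normal(0, 0.1, size=(16, 4, 20))
            f, p = rm_anova_1way(data)
            rej = dd.fdr_correct(p, q=0.05, method="bh")
            hits += rej.mean() > 0.5
        assert hits / reps > 0.95

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError):
            rm_anova_1way(np.zeros((1, 4, 3)))


class TestClusterFilter:
    def test_size_threshold_is_exclusive(self):
        vol = np.zeros((10, 10, 10), bool)
        vol[1, 1, 1:6] = True           # 5-voxel blob: removed
        vol[5, 5, 2:8] = True           # 6-voxel blob: kept
        out = cluster_filter(vol, 5)
        assert len(out) == 1 and out[0].sum() == 6

    def test_empty_input_empty_output(self):
        assert cluster_filter(np.zeros((4, 4, 4), bool)) == []

    def test_vertex_touching_blobs_depend_on_connectivity(self):
        vol = np.zeros((12, 12, 12), bool)
        vol[2:4, 2:4, 2:4] = True
        vol[4:6, 4:6, 4:6] = True       # touches only at the corner voxel
        assert len(cluster_filter(vol, 5, connectivity=26)) == 1
        assert len(cluster_filter(vol, 5, connectivity=6)) == 2

    def test_matches_flood_fill_oracle(self, rng):
        vol = rng.random((8, 8, 8)) < 0.25
        for conn, struct in ((6, ndimage.generate_binary_structure(3, 1)),
                             (26, np.ones((3, 3, 3), bool))):
            ours = cluster_filter(vol, 0, connectivity=conn)
            labels, n = ndimage.label(vol, structure=struct)
            sizes = sorted(int((labels == i).sum()) for i in range(1, n + 1))
            assert sorted(c.sum() for c in ours) == sizes


def _zmaps_from_profiles(profiles, n_sub, noise, rng, shape=(6, 6, 6)):
    """Per-state subject maps whose voxels follow per-voxel state profiles."""
    mask = np.ones(shape, bool)
    nvox = int(np.prod(shape))
    out = {s: [] for s in STATES}
    for i in range(n_sub):
        for si, s in enumerate(STATES):
            z = np.zeros(nvox)
            for vox, prof in profiles.items():
                z[vox] = prof[si]
            z += rng.normal(0, noise, nvox)
            out[s].append(
                ConnectivityMap(subject=f"s{i}", state=s, z=z, mask=mask)
            )
    return out, mask


class TestClassifyVoxels:
    def test_deterministic_decrease_and_increase(self, rng):
        profiles = {0: (0.5, 0.3, 0.3, 0.5),    # decreasing
                    1: (0.05, 0.30, 0.34, 0.03)}  # increasing (printed values)
        z_maps, mask = _zmaps_from_profiles(profiles, 16, 0.02, rng)
        cluster = np.zeros(mask.shape, bool)
        cluster.flat[[0, 1]] = True
        labels = classify_voxels(z_maps, [cluster])
        assert labels["decreasing"].flat[0]
        assert labels["increasing"].flat[1]

    def test_no_task_rest_difference_is_unclassified(self, rng):
        profiles = {0: (0.2, 0.4, 0.0, 0.2)}  # task mean == rest mean
        z_maps, mask = _zmaps_from_profiles(profiles, 12, 0.01, rng)
        cluster = np.zeros(mask.shape, bool)
        cluster.flat[0] = True
        with pytest.warns(UserWarning, match="unclassified"):
            labels = classify_voxels(z_maps, [cluster])
        assert labels["unclassified"].flat[0]
        assert not labels["decreasing"].flat[0]

    def test_empty_cluster_list(self, rng):
        z_maps, _ = _zmaps_from_profiles({}, 4, 0.1, rng)
        labels = classify_voxels(z_maps, [])
        assert not any(v.any() for v in labels.values())


class TestDefineRegions:
    def _membership(self, shape, spec):
        mem = {}
        for s in STATES:
            vol = np.zeros(shape, bool)
            for vox, states in spec.items():
                if s in states:
                    vol[vox] = True
            mem[s] = vol
        mask = np.zeros(shape, bool)
        for v in mem.values():
            mask |= v
        return UnionMask(mask=mask, membership=mem)

    def test_voxel_in_three_of_four_maps_not_stable(self):
        shape = (8, 8, 8)
        always = [(2, 2, z) for z in range(2, 8)]
        mostly = [(5, 5, z) for z in range(2, 8)]
        spec = {v: STATES for v in always}
        spec.update({v: ("R1", "T1", "T2") for v in mostly})
        union = self._membership(shape, spec)
        anova = np.zeros(shape, bool)
        labels = {k: np.zeros(shape, bool)
                  for k in ("decreasing", "increasing", "unclassified")}
        regset = define_regions(labels, union, anova)
        stable = regset.of_kind("stable")
        assert len(stable) == 1
        assert stable[0].size == len(always)

    def test_anova_significant_voxel_never_stable(self):
        shape = (8, 8, 8)
        vox = [(2, 2, z) for z in range(2, 8)]
        union = self._membership(shape, {v: STATES for v in vox})
        anova = np.zeros(shape, bool)
        for v in vox:
            anova[v] = True
        labels = {"decreasing": anova.copy(),
                  "increasing": np.zeros(shape, bool),
                  "unclassified": np.zeros(shape, bool)}
        regset = define_regions(labels, union, anova)
        assert regset.of_kind("stable") == []
        assert len(regset.of_kind("decreasing")) == 1

    def test_stable_and_changing_regions_exclusive(self):
        """Region classes are disjoint by construction."""
        shape = (8, 8, 8)
        vox = [(2, 2, z) for z in range(1, 8)]
        union = self._membership(shape, {v: STATES for v in vox})
        anova = np.zeros(shape, bool)
        anova[2, 2, 1:4] = True
        labels = {"decreasing": anova.copy(),
                  "increasing": np.zeros(shape, bool),
                  "unclassified": np.zeros(shape, bool)}
        regset = define_regions(labels, union, anova, min_size_exclusive=2)
        cover = np.zeros(shape, int)
        for reg in regset.regions:
            cover += reg.mask
        assert cover.max() <= 1


def test_voxelwise_rm_anova_runs_within_union_only(rng):
    shape = (5, 5, 5)
    mask = np.ones(shape, bool)
    z_maps, _ = _zmaps_from_profiles(
        {0: (0.6, 0.2, 0.2, 0.6)}, 10, 0.05, rng, shape
    )
    union_vol = np.zeros(shape, bool)
    union_vol.flat[:10] = True
    union = UnionMask(mask=union_vol, membership={s: union_vol for s in STATES})
    f, p, sig = voxelwise_rm_anova(z_maps, union)
    assert len(f) == 10
    assert sig.flat[0]
    assert not sig[~union_vol].any()
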