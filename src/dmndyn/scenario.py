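"""Scenario definitions for the synthetic four-state BOLD cohort generator.

A :class:`SynthScenario` fixes everything the generator needs: the grid,
the planted region layout (stable / decreasing / increasing systems),
one inter-region correlation matrix per experimental state, the
between-subject heterogeneity, the noise model, the motion-spike rate
and the behavior coupling.  The packaged default scenario plants the
study's layout — a seed-bearing stable region (PCC) plus five further
stable regions (MPFC, bilateral IPL, bilateral LTC), four decreasing
regions (precuneus, bilateral angular gyrus, vermis) and four increasing
regions (bilateral insula/IFC, ACC, MCC) — with the group-level
system-block correlations set to the published four-state trajectory:

* stable-decreasing: 0.43, 0.35, 0.24, 0.45 over (R1, T1, T2, R2)
* stable-increasing: 0.05, 0.30, 0.34, 0.03 over (R1, T1, T2, R2)

Non-published blocks (within-system and decreasing-increasing) are set
to values consistent with the qualitative within-system trajectories:
stable connectivity high and flat, decreasing-system cohesion dropping
under task, increasing-system cohesion rising under task.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .containers import STATES

SYSTEMS = ("stable", "decreasing", "increasing")
VALID_SYSTEMS = SYSTEMS + ("background",)


class ScenarioError(ValueError):
    """Raised for invalid scenario configurations."""


@dataclass
class PlantedRegion:
    """A labelled voxel set driven by one latent signal."""

    name: str
    system: str
    voxels: np.ndarray  # (n, 3) integer voxel coordinates
    latent_index: int

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
            raise ScenarioError(f"region {self.name}: voxels must be (n, 3)")
        if len(self.voxels) < 1:
            raise ScenarioError(f"region {self.name}: empty voxel set")
        if self.system not in VALID_SYSTEMS:
            raise ScenarioError(
                f"region {self.name}: unknown system {self.system!r}"
            )


@dataclass
class NoiseModel:
    """Amplitudes of the signal/noise components, in image units.

    The baseline is ~1000 units, so ``signal_sd = 2`` means BOLD
    fluctuations of 0.2% — a realistic resting-state amplitude.  The
    global component is shared by every brain voxel and is what global
    signal regression removes.
    """

    ar_coeff: float = 0.3
    white_sd: float = 1.0
    drift_sd: float = 1.0
    drift_freq_hz: float = 0.003
    baseline: float = 1000.0
    signal_sd: float = 2.0
    global_sd: float = 2.0
    nuisance_sd: float = 1.0  # WM / CSF private components
    gs_spike_pct: float = 1.0  # global-signal step size of a motion spike
    spike_translation_mm: float = 0.35
    spike_rotation_rad: float = 0.005


@dataclass
class BehaviorCoupling:
    """Calibration of the simulated RT / accuracy records.

    Means and SEMs are the published group values at n=19; between-
    subject SDs are SEM * sqrt(n_ref).  ``rho_rt`` couples RT to the
    latent dFC(stable, decreasing) of each task state; ``rho_acc``
    couples accuracy to dFC(stable, increasing).
    """

    rt_mean: dict = field(default_factory=lambda: {"T1": 1864.0, "T2": 1310.0})
    rt_sem: dict = field(default_factory=lambda: {"T1": 152.8, "T2": 65.6})
    acc_mean: dict = field(default_factory=lambda: {"T1": 97.8, "T2": 94.5})
    acc_sem: dict = field(default_factory=lambda: {"T1": 0.46, "T2": 0.99})
    rho_rt: dict = field(default_factory=lambda: {"T1": 0.6018, "T2": 0.5745})
    rho_acc: dict = field(default_factory=lambda: {"T1": 0.4899, "T2": 0.5876})
    n_ref: int = 19

    def rt_sd(self, state: str) -> float:
        return self.rt_sem[state] * np.sqrt(self.n_ref)

    def acc_sd(self, state: str) -> float:
        return self.acc_sem[state] * np.sqrt(self.n_ref)


@dataclass
class SynthScenario:
    """Fully resolved parameters of one synthetic study."""

    grid_shape: tuple[int, int, int]
    voxel_size: float
    n_subjects: int
    n_volumes: int
    tr: float
    region_layout: list[PlantedRegion]
    state_covariance: dict[str, np.ndarray]
    #: total between-subject SD of a planted block correlation per state
    #: (Fisher-Z scale); sets the group-level SEMs
    subject_sd: float
    #: state-specific part of subject_sd: the component that does NOT
    #: cancel within subject across states.  It drives both the
    #: repeated-measures error term and the between-subject variance of
    #: dFC; the remainder (sqrt(subject_sd^2 - state_sd^2)) is a stable
    #: per-subject offset shared by all four states.
    state_sd: float
    noise: NoiseModel
    motion_spike_rate: float
    behavior: BehaviorCoupling
    seed: int
    origin_mm: tuple[float, float, float] = (-45.0, -74.0, -19.0)
    seed_center_mm: tuple[float, float, float] = (0.0, -53.0, 26.0)
    seed_radius_mm: float = 8.0
    #: plant image-level correlations pre-corrected for the global-signal-
    #: regression bias so the post-GSR measurement matches the targets
    compensate_gsr: bool = True

    def __post_init__(self) -> None:
        if self.n_volumes < 11:
            raise ScenarioError("n_volumes must be >= 11 (first-10 drop)")
        if not 0 <= self.state_sd <= self.subject_sd:
            raise ScenarioError("state_sd must lie in [0, subject_sd]")
        validate_covariances(self.state_covariance, len_latents(self))
        _check_disjoint(self.region_layout, self.grid_shape)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    @property
    def n_latents(self) -> int:
        return len_latents(self)

    def brain_mask(self) -> np.ndarray:
        """Ellipsoidal brain mask, guaranteed to cover every region."""
        nx, ny, nz = self.grid_shape
        c = (np.array(self.grid_shape) - 1) / 2.0
        semi = np.array([nx, ny * 1.03, nz]) / 2.0 + 0.5
        ix, iy, iz = np.indices(self.grid_shape)
        d = (
            ((ix - c[0]) / semi[0]) ** 2
            + ((iy - c[1]) / semi[1]) ** 2
            + ((iz - c[2]) / semi[2]) ** 2
        )
        mask = d <= 1.0
        for reg in self.region_layout:
            mask[tuple(reg.voxels.T)] = True
        return mask

    def tissue_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """(WM, CSF) masks: small cubes away from the planted regions."""
        wm = np.zeros(self.grid_shape, dtype=bool)
        csf = np.zeros(self.grid_shape, dtype=bool)
        cx = self.grid_shape[0] // 2
        wm_c = (cx, int(self.grid_shape[1] * 0.33), int(self.grid_shape[2] * 0.9) - 2)
        csf_c = (cx, int(self.grid_shape[1] * 0.61), int(self.grid_shape[2] * 0.23))
        for mask, c in ((wm, wm_c), (csf, csf_c)):
            sl = tuple(slice(max(v - 1, 0), v + 2) for v in c)
            mask[sl] = True
        return wm, csf

    def region_label_volume(self) -> np.ndarray:
        lab = np.zeros(self.grid_shape, dtype=np.int32)
        for i, reg in enumerate(self.region_layout, start=1):
            lab[tuple(reg.voxels.T)] = i
        return lab


def len_latents(scenario: SynthScenario) -> int:
    return 1 + max(r.latent_index for r in scenario.region_layout)


def validate_covariances(
    cov: dict[str, np.ndarray], k: int, allow_repair: bool = False
) -> None:
    """Check each state matrix is a PSD correlation matrix of size k."""
    for state in STATES:
        if state not in cov:
            raise ScenarioError(f"missing state {state!r} in state_covariance")
    extra = set(cov) - set(STATES)
    if extra:
        raise ScenarioError(f"unknown state label(s) {sorted(extra)}")
    for state, m in cov.items():
        m = np.asarray(m, dtype=float)
        if m.shape != (k, k):
            raise ScenarioError(f"{state}: matrix must be {k}x{k}")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ScenarioError(f"{state}: matrix not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ScenarioError(f"{state}: diagonal must be 1")
        w = np.linalg.eigvalsh(m)
        if w.min() < -1e-8 and not allow_repair:
            raise ScenarioError(
                f"{state}: matrix not positive semidefinite "
                f"(min eigenvalue {w.min():.3g}); set psd_repair to allow "
                "eigenvalue clipping"
            )


def _check_disjoint(layout: list[PlantedRegion], grid: tuple[int, int, int]) -> None:
    seen: set[tuple[int, int, int]] = set()
    for reg in layout:
        if (reg.voxels < 0).any() or (reg.voxels >= np.array(grid)).any():
            raise ScenarioError(f"region {reg.name}: voxels outside the grid")
        vox = set(map(tuple, reg.voxels))
        if vox & seen:
            raise ScenarioError(f"region {reg.name} overlaps another region")
        seen |= vox


# ---------------------------------------------------------------------------
# default scenario
# ---------------------------------------------------------------------------

#: published four-state system-block correlations (R1, T1, T2, R2) plus
#: field-realistic values for the non-published blocks
DEFAULT_BLOCK_CORR: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("stable", "stable"): (0.55, 0.55, 0.55, 0.55),
    ("stable", "decreasing"): (0.43, 0.35, 0.24, 0.45),
    ("stable", "increasing"): (0.05, 0.30, 0.34, 0.03),
    ("decreasing", "decreasing"): (0.50, 0.40, 0.30, 0.50),
    ("increasing", "increasing"): (0.10, 0.32, 0.36, 0.08),
    ("decreasing", "increasing"): (0.02, 0.10, 0.12, 0.02),
}

#: (name, system, cube center in voxels, cube half-width)
DEFAULT_LAYOUT: list[tuple[str, str, tuple[int, int, int], int]] = [
    ("PCC", "stable", (15, 7, 15), 2),      # seed-bearing region
    ("MPFC", "stable", (15, 33, 15), 1),
    ("IPL_L", "stable", (6, 10, 22), 1),
    ("IPL_R", "stable", (24, 10, 22), 1),
    ("LTC_L", "stable", (5, 16, 10), 1),
    ("LTC_R", "stable", (25, 16, 10), 1),
    ("PCS", "decreasing", (15, 5, 23), 1),
    ("ANG_L", "decreasing", (5, 4, 16), 1),
    ("ANG_R", "decreasing", (25, 4, 16), 1),
    ("VER", "decreasing", (15, 3, 7), 1),
    ("IIFC_L", "increasing", (5, 24, 13), 1),
    ("IIFC_R", "increasing", (25, 24, 13), 1),
    ("ACC", "increasing", (15, 26, 15), 1),
    ("MCC", "increasing", (15, 17, 20), 1),
]


def _cube(center: tuple[int, int, int], half: int) -> np.ndarray:
    r = np.arange(-half, half + 1)
    dx, dy, dz = np.meshgrid(r, r, r, indexing="ij")
    off = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    return off + np.asarray(center)


def block_correlation_matrices(
    systems: list[str],
    block_corr: dict[tuple[str, str], tuple[float, ...]] = DEFAULT_BLOCK_CORR,
) -> dict[str, np.ndarray]:
    """Expand per-system-block correlations into full latent matrices."""
    k = len(systems)
    out: dict[str, np.ndarray] = {}
    for si, state in enumerate(STATES):
        m = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                key = (systems[i], systems[j])
                if key not in block_corr:
                    key = (systems[j], systems[i])
                m[i, j] = m[j, i] = block_corr.get(key, (0.0,) * 4)[si]
        out[state] = m
    return out


def default_scenario(**overrides) -> SynthScenario:
    """The packaged default study: 19 subjects, published calibration."""
    layout = [
        PlantedRegion(name, system, _cube(center, half), idx)
        for idx, (name, system, center, half) in enumerate(DEFAULT_LAYOUT)
    ]
    systems = [r.system for r in layout]
    base = dict(
        grid_shape=(30, 36, 30),
        voxel_size=3.0,
        n_subjects=19,
        n_volumes=150,
        tr=2.0,
        region_layout=layout,
        state_covariance=block_correlation_matrices(systems),
        subject_sd=0.15,
        state_sd=0.09,
        noise=NoiseModel(),
        motion_spike_rate=0.5,
        behavior=BehaviorCoupling(),
        seed=0,
    )
    base.update(overrides)
    if "subject_sd" in overrides and "state_sd" not in overrides:
        # keep the default shared/state variance split
        base["state_sd"] = base["subject_sd"] * (0.09 / 0.15)
    return SynthScenario(**base)


def null_scenario(**overrides) -> SynthScenario:
    """No-dynamics control: the R1 correlation structure in all states."""
    sc = default_scenario(**overrides)
    r1 = sc.state_covariance["R1"]
    sc.state_covariance = {s: r1.copy() for s in STATES}
    return sc


# ---------------------------------------------------------------------------
# config-dict / YAML interface
# ---------------------------------------------------------------------------

_SCHEMA_KEYS = {
    "grid_shape", "voxel_size", "n_subjects", "n_volumes", "tr",
    "region_layout", "state_covariance", "subject_sd", "state_sd", "noise",
    "motion_spike_rate", "behavior", "seed", "origin_mm",
    "seed_center_mm", "seed_radius_mm", "psd_repair", "compensate_gsr",
}


def make_scenario(config: dict) -> SynthScenario:
    """Build a scenario from a (possibly partial) config mapping.

    Unspecified keys fall back to the packaged default scenario.  State
    covariance matrices must be PSD; a non-PSD matrix raises unless the
    config sets ``psd_repair: true``, in which case eigenvalues are
    clipped at zero and the diagonal renormalized.
    """
    unknown = set(config) - _SCHEMA_KEYS
    if unknown:
        raise ScenarioError(f"unknown config key(s): {sorted(unknown)}")
    cfg = dict(config)
    repair = bool(cfg.pop("psd_repair", False))

    if "region_layout" in cfg and not isinstance(
        next(iter(cfg["region_layout"]), None), PlantedRegion
    ):
        cfg["region_layout"] = [
            PlantedRegion(
                name=r["name"],
                system=r["system"],
                voxels=np.asarray(r["voxels"]),
                latent_index=int(r["latent_index"]),
            )
            for r in cfg["region_layout"]
        ]
    if "noise" in cfg and isinstance(cfg["noise"], dict):
        cfg["noise"] = NoiseModel(**cfg["noise"])
    if "behavior" in cfg and isinstance(cfg["behavior"], dict):
        cfg["behavior"] = BehaviorCoupling(**cfg["behavior"])
    if "state_covariance" in cfg:
        cov = {s: np.asarray(m, dtype=float) for s, m in cfg["state_covariance"].items()}
        layout = cfg.get("region_layout")
        k = (1 + max(r.latent_index for r in layout)) if layout else None
        if k is None:
            k = next(iter(cov.values())).shape[0]
            # a bare covariance override implies a matching trivial layout
            if k != default_scenario().n_latents:
                cfg["region_layout"] = _auto_layout(k)
        validate_covariances(cov, k, allow_repair=repair)
        if repair:
            cov = {s: repair_psd(m) for s, m in cov.items()}
        cfg["state_covariance"] = cov
    for key in ("grid_shape", "origin_mm", "seed_center_mm"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return default_scenario(**cfg)


def _auto_layout(k: int) -> list[PlantedRegion]:
    """k small stable cubes on a lattice, for bare-covariance configs."""
    xs, ys, zs = [4, 11, 18, 25], [4, 11, 18, 25, 32], [4, 11, 18, 25]
    centers = [(x, y, z) for z in zs for y in ys for x in xs]
    if k > len(centers):
        raise ScenarioError(f"cannot auto-place {k} regions on the default grid")
    return [
        PlantedRegion(f"region_{i}", "stable", _cube(centers[i], 1), i)
        for i in range(k)
    ]


def repair_psd(m: np.ndarray, floor: float = 1e-9) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone and renormalize."""
    w, v = np.linalg.eigh(m)
    w = np.clip(w, floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def scenario_to_dict(sc: SynthScenario) -> dict:
    return {
        "grid_shape": list(sc.grid_shape),
        "voxel_size": sc.voxel_size,
        "n_subjects": sc.n_subjects,
        "n_volumes": sc.n_volumes,
        "tr": sc.tr,
        "region_layout": [
            {
                "name": r.name,
                "system": r.system,
                "voxels": r.voxels.tolist(),
                "latent_index": r.latent_index,
            }
            for r in sc.region_layout
        ],
        "state_covariance": {s: m.tolist() for s, m in sc.state_covariance.items()},
        "subject_sd": sc.subject_sd,
        "state_sd": sc.state_sd,
        "noise": dataclasses.asdict(sc.noise),
        "motion_spike_rate": sc.motion_spike_rate,
        "behavior": dataclasses.asdict(sc.behavior),
        "seed": sc.seed,
        "origin_mm": list(sc.origin_mm),
        "seed_center_mm": list(sc.seed_center_mm),
        "seed_radius_mm": sc.seed_radius_mm,
        "compensate_gsr": sc.compensate_gsr,
    }


def save_scenario(sc: SynthScenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(sc), fh, sort_keys=False)


def load_scenario(path) -> SynthScenario:
    with open(path) as fh:
        return make_scenario(yaml.safe_load(fh))
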