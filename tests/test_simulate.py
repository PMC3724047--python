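"""Generator fidelity, determinism, behavior coupling, fixtures."""

import numpy as np
import pytest

import dmndyn as dd
from dmndyn.containers import STATES, TASK_STATES
from dmndyn.simulate import (
    _correlated_latents,
    _mean_matched_z,
    dfc_attenuation,
    latent_dfc_from_matrices,
    sample_subject_matrices,
    planted_covariance,
)
from conftest import small_scenario


class TestLatents:
    def test_noise_free_unit_correlation(self):
        """Planted r = 1 with no noise yields empirical r = 1 exactly."""
        sc = small_scenario(
            subject_sd=0.0,
            state_covariance={
                s: np.full((7, 7), 1.0) + 0.0 * np.eye(7) for s in STATES
            },
            noise=dd.NoiseModel(white_sd=0.0, drift_sd=0.0, global_sd=0.0),
            motion_spike_rate=0.0,
            compensate_gsr=False,
        )
        sub = dd.simulate_subject(sc, 0, np.random.SeedSequence(3))
        run = sub.runs["R1"]
        a = run.data[tuple(sc.region_layout[0].voxels.T)].mean(axis=0)
        b = run.data[tuple(sc.region_layout[3].voxels.T)].mean(axis=0)
        assert abs(np.corrcoef(a, b)[0, 1] - 1.0) < 1e-5

    def test_generator_fidelity_monte_carlo(self):
        """Planted r = 0.5 recovered within Monte-Carlo error, pre-pipeline."""
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        rng = np.random.default_rng(11)
        vals = [
            np.corrcoef(_correlated_latents(rng, corr, 140, 0.3))[0, 1]
            for _ in range(500)
        ]
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_latent_fidelity_any_psd_matrix(self, rng):
        """Noise-free latents reproduce an arbitrary PSD target matrix."""
        base = rng.normal(size=(4, 6))
        cov = base @ base.T
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        est = np.zeros((4, 4))
        n_rep = 100
        for _ in range(n_rep):
            est += np.corrcoef(_correlated_latents(rng, corr, 400, 0.3)) / n_rep
        assert np.abs(est - corr).max() < 3 / np.sqrt(400)

    def test_mean_matching_compensates_tanh_jensen(self):
        """E[tanh(z0 + d)] equals the target r despite the nonlinearity."""
        r = np.array([0.43, 0.24, 0.05])
        z0 = _mean_matched_z(r, sigma=0.15)
        d = np.random.default_rng(0).normal(0, 0.15, (200_000, 1))
        emp = np.tanh(z0 + d).mean(axis=0)
        assert np.abs(emp - r).max() < 0.002
        assert np.allclose(_mean_matched_z(r, 0.0), np.arctanh(r))


class TestSubjectSimulation:
    def test_seed_determinism_bit_for_bit(self, tiny_scenario):
        a = dd.simulate_subject(tiny_scenario, 1, np.random.SeedSequence(42))
        b = dd.simulate_subject(tiny_scenario, 1, np.random.SeedSequence(42))
        for s in STATES:
            assert np.array_equal(a.runs[s].data, b.runs[s].data)
            assert np.array_equal(a.motion[s].params, b.motion[s].params)

    def test_missing_rng_stream_raises(self, tiny_scenario):
        with pytest.raises(ValueError, match="rng_stream"):
            dd.simulate_subject(tiny_scenario, 0, None)

    def test_subject_index_bounds(self, tiny_scenario):
        with pytest.raises(ValueError, match="subject_index"):
            dd.simulate_subject(
                tiny_scenario, tiny_scenario.n_subjects,
                np.random.SeedSequence(0),
            )

    def test_zero_spike_rate_never_flags(self):
        sc = small_scenario(motion_spike_rate=0.0)
        sub = dd.simulate_subject(sc, 0, np.random.SeedSequence(5))
        for s in STATES:
            run, _ = dd.preprocess_run(sub.runs[s], sub.motion[s])
        # preprocess_run scrubs: nothing should have been removed
        _, report = dd.preprocess_run(sub.runs["R1"], sub.motion["R1"])
        assert report.n_removed == 0

    def test_spikes_exceed_both_censoring_thresholds(self):
        sc = small_scenario(motion_spike_rate=4.0, n_subjects=1)
        sub = dd.simulate_subject(sc, 0, np.random.SeedSequence(9))
        flagged_any = 0
        for s in STATES:
            _, report = dd.preprocess_run(sub.runs[s], sub.motion[s])
            flagged_any += len(report.flagged)
            # every removal window is the AND-rule 4-frame pattern
            if len(report.flagged):
                assert report.n_removed <= 4 * len(report.flagged)
        assert flagged_any > 0

    def test_subject_matrices_unbiased_on_r_scale(self, tiny_scenario):
        rng = np.random.default_rng(2)
        acc = np.zeros_like(tiny_scenario.state_covariance["R1"])
        n = 400
        for _ in range(n):
            acc += sample_subject_matrices(tiny_scenario, rng)["R1"] / n
        target = tiny_scenario.state_covariance["R1"]
        off = ~np.eye(len(acc), dtype=bool)
        assert np.abs(acc - target)[off].max() < 0.03


class TestBehavior:
    def test_null_coupling_gives_null_correlation(self):
        beh = dd.BehaviorCoupling(
            rho_rt={"T1": 0.0, "T2": 0.0}, rho_acc={"T1": 0.0, "T2": 0.0}
        )
        sc = small_scenario(behavior=beh, n_subjects=19)
        rs = []
        for seed in range(60):
            rc = dd.simulate_region_cohort(sc, seed=seed)
            x = rc.latent_dfc[("decreasing", "T1")]
            y = rc.behavior.query("state == 'T1'")["rt_ms"].to_numpy()
            rs.append(np.corrcoef(x, y)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    @staticmethod
    def _centered_latents(sc, n, rng):
        """Latent dFC draws centered on the analytic block-mean offsets."""
        from dmndyn.simulate import (
            _mean_matched_z, latent_systems, system_block_pairs,
        )

        systems = latent_systems(sc)
        sd_lat = np.sqrt(2) * sc.state_sd
        out = {}
        for sysname in ("decreasing", "increasing"):
            pairs = system_block_pairs(systems, "stable", sysname)
            for t in TASK_STATES:
                z_t = _mean_matched_z(sc.state_covariance[t], sc.subject_sd)
                z_r = _mean_matched_z(sc.state_covariance["R1"], sc.subject_sd)
                mu = np.mean([z_t[i, j] - z_r[i, j] for i, j in pairs])
                out[(sysname, t)] = mu + rng.normal(0, sd_lat, n)
        return out

    def test_rt_group_mean_matches_configuration(self):
        """Simulated group mean RT stays within 2% of the configured mean."""
        sc = small_scenario(n_subjects=1000)
        lat = self._centered_latents(sc, 1000, np.random.default_rng(0))
        beh = dd.simulate_behavior(sc, lat, np.random.SeedSequence(8))
        for t in TASK_STATES:
            rt = beh.query("state == @t")["rt_ms"].mean()
            assert abs(rt - sc.behavior.rt_mean[t]) / sc.behavior.rt_mean[t] < 0.02
            acc = beh.query("state == @t")["accuracy_pct"]
            assert (acc <= 100).all() and (acc >= 0).all()

    def test_latent_coupling_recovery_against_oracle(self):
        """corr(latent dFC, RT) matches the calibrated latent slope.

        The observed-scale targets are deattenuated internally; on the
        latent scale the realized correlation must equal that slope.
        """
        sc = small_scenario(n_subjects=4000)
        cov = sc.state_covariance
        alpha = dfc_attenuation(sc, "decreasing", "T1", covariance=cov)
        rho_obs = sc.behavior.rho_rt["T1"]
        fisher = 1 + (1 - rho_obs**2) / (2 * (sc.behavior.n_ref - 1))
        expected = min(rho_obs * fisher / alpha, 0.99)
        rng = np.random.default_rng(3)
        lat = TestBehavior._centered_latents(sc, 4000, rng)
        beh = dd.simulate_behavior(sc, lat, np.random.SeedSequence(4))
        rt = beh.query("state == 'T1'")["rt_ms"].to_numpy()
        got = np.corrcoef(lat[("decreasing", "T1")], rt)[0, 1]
        assert abs(got - expected) < 0.04

    def test_length_mismatch_raises(self, tiny_scenario):
        lat = {("decreasing", "T1"): np.zeros(3)}
        with pytest.raises(ValueError, match="wrong length"):
            dd.simulate_behavior(tiny_scenario, lat, np.random.SeedSequence(0))


class TestFixtures:
    def test_write_read_round_trip(self, tmp_path):
        sc = small_scenario(n_subjects=2)
        cohort = dd.simulate_cohort(sc, seed=1)
        manifest = dd.write_fixtures(cohort, tmp_path / "fix")
        # 2 subjects x 4 states images + motion, masks, labels, tables
        images = [f for f in manifest["files"] if f.endswith("_bold.nii.gz")]
        assert len(images) == 2 * 4
        sc2, subjects, behavior = dd.load_fixtures(tmp_path / "fix")
        orig = cohort.subjects[0].runs["T2"].data
        back = subjects[0].runs["T2"].data
        assert np.array_equal(orig, back)
        assert np.array_equal(
            cohort.subjects[1].motion["R2"].params,
            subjects[1].motion["R2"].params,
        )
        assert len(behavior) == len(cohort.behavior)

    def test_empty_cohort_rejected(self, tmp_path, tiny_scenario):
        empty = dd.Cohort(scenario=tiny_scenario, subjects=[],
                          behavior=None, latent_dfc={})
        with pytest.raises(ValueError, match="empty cohort"):
            dd.write_fixtures(empty, tmp_path)


def test_gsr_compensation_raises_planted_values():
    """Compensated matrices sit above the targets (GSR deflates them back)."""
    sc = dd.default_scenario()
    comp = planted_covariance(sc)
    raw = sc.state_covariance
    kinds = [r.system for r in sc.region_layout]
    i, j = kinds.index("stable"), kinds.index("decreasing")
    for s in STATES:
        assert comp[s][i, j] > raw[s][i, j]
        assert np.linalg.eigvalsh(comp[s]).min() > -1e-10


def test_latent_dfc_from_matrices_elementwise():
    sc = small_scenario(n_subjects=2)
    mats = [
        sample_subject_matrices(sc, np.random.default_rng(k)) for k in (0, 1)
    ]
    out = latent_dfc_from_matrices(sc, mats)
    kinds = [r.system for r in sc.region_layout]
    pairs = [(i, j) for i in range(7) for j in range(7)
             if kinds[i] == "stable" and kinds[j] == "decreasing"]
    z = lambda m: np.mean([np.arctanh(m[i, j]) for i, j in pairs])
    expect = z(mats[0]["T1"]) - z(mats[0]["R1"])
    assert np.isclose(out[("decreasing", "T1")][0], expect)


def test_block_z_error_matches_single_pair_closed_form():
    """For a single pair the Olkin-Siotani block error reduces to the
    standard var(atanh r) = 1/n form."""
    from dmndyn.simulate import block_z_error_sd

    for r in (0.0, 0.3, 0.6):
        corr = np.array([[1.0, r], [r, 1.0]])
        got = block_z_error_sd(corr, [(0, 1)], n_eff=40.0)
        assert got == pytest.approx(1.0 / np.sqrt(40.0), rel=1e-9)


def test_effective_samples_below_band_limit():
    """Band-passing a 140-frame run leaves ~2*BW*T effective samples."""
    from dmndyn.simulate import effective_samples

    n_eff = effective_samples(140, 2.0)
    assert 25 < n_eff < 2 * (0.08 - 0.008) * 140 * 2.0 + 2
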