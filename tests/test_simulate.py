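"""Two-state transient-trapping simulator: dynamics, observation model,
fragmentation, and ground-truth bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from sptmotion import (
    GroundTruth,
    SimConfig,
    estimate_switching_probability,
    render_observed,
    simulate_ground_truth,
)
from sptmotion.errors import DataError, DomainError


def _small(**kw):
    base = dict(n_walkers=10, n_frames=50, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_invalid_config_lists_all_violations(self):
        cfg = SimConfig(n_walkers=0, p_switch=2.0, substeps=0)
        with pytest.raises(DataError) as err:
            cfg.validate()
        msg = str(err.value)
        assert "n_walkers" in msg and "p_switch" in msg and "substeps" in msg

    def test_json_round_trip(self, tmp_path):
        cfg = SimConfig(n_walkers=3, seed=9, box=(1e-6, 2e-6, 3e-6))
        cfg.to_json(tmp_path / "c.json")
        assert SimConfig.from_json(tmp_path / "c.json") == cfg


class TestGroundTruthDynamics:
    def test_seed_reproducibility_and_divergence(self):
        a = simulate_ground_truth(_small(seed=1))
        b = simulate_ground_truth(_small(seed=1))
        c = simulate_ground_truth(_small(seed=2))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.states, b.states)
        assert not np.array_equal(a.positions, c.positions)

    def test_no_switching_keeps_state_constant(self):
        truth = simulate_ground_truth(_small(p_switch=0.0))
        assert np.all(truth.states == truth.states[:, :1])

    def test_zero_diffusion_keeps_paths_constant(self):
        truth = simulate_ground_truth(_small(D1=0.0, D2=0.0))
        assert np.allclose(truth.positions, truth.positions[:, :1, :])

    def test_mobile_substep_variance(self):
        # per-axis substep displacement variance = 2 D2 dt / substeps
        cfg = _small(n_walkers=100, n_frames=134, D1=1e-12, D2=1e-12, p_switch=0.0)
        truth = simulate_ground_truth(cfg)
        disp = np.diff(truth.positions, axis=1)
        var = disp.var()
        expected = 2 * cfg.D2 * cfg.dt / cfg.substeps
        assert var == pytest.approx(expected, rel=0.01)  # ~2e5 samples/axis

    def test_mean_squared_frame_displacement(self):
        # 3-D frame displacement: E|dx|^2 = 6 D2 dt
        cfg = SimConfig(
            n_walkers=500, n_frames=200, D1=1e-12, D2=1e-12, p_switch=0.0, seed=8
        )
        truth = simulate_ground_truth(cfg)
        S = cfg.substeps
        frame_pos = truth.positions[:, ::S, :]
        msd = (np.diff(frame_pos, axis=1) ** 2).sum(axis=2).mean()
        assert msd == pytest.approx(6 * cfg.D2 * cfg.dt, rel=0.02)

    def test_state_occupancy_is_symmetric(self):
        cfg = SimConfig(n_walkers=300, n_frames=400, seed=12)
        truth = simulate_ground_truth(cfg)
        frac2 = np.mean(truth.states == 2)
        assert frac2 == pytest.approx(0.5, abs=0.03)

    def test_dwell_times_are_geometric(self):
        # long sequences so that censoring of interior dwells is negligible
        cfg = SimConfig(
            n_walkers=50, n_frames=20000, substeps=1, D1=0.0, D2=0.0, seed=4
        )
        truth = simulate_ground_truth(cfg)
        dwells = []
        for row in truth.states:
            change = np.flatnonzero(np.diff(row) != 0)
            if len(change) >= 2:  # interior (uncensored) dwells only
                dwells.extend(np.diff(change))
        dwells = np.asarray(dwells)
        # chi-square goodness of fit against the geometric pmf (discrete
        # data, so a continuous KS test is not applicable); pool the tail
        kmax = 120
        edges = np.arange(1, kmax + 1)
        observed = np.array([(dwells == k).sum() for k in edges], float)
        observed = np.append(observed, (dwells > kmax).sum())
        pmf = stats.geom(cfg.p_switch).pmf(edges)
        expected = len(dwells) * np.append(pmf, 1 - pmf.sum())
        keep = expected >= 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01


class TestRenderObserved:
    def test_unfragmented_noise_free_observation_matches_truth(self):
        cfg = _small(
            D1=1e-12,
            D2=1e-12,
            z_visible=np.inf,
            sigma0=0.0,
            sigma_z=0.0,
            blur="last-substep",
        )
        truth = simulate_ground_truth(cfg)
        obs = render_observed(truth, cfg)
        assert len(obs) == cfg.n_walkers  # one track per walker
        for w in range(cfg.n_walkers):
            (tid,) = truth.observed_ids[w]
            traj = obs[tid]
            expected = truth.positions[w, cfg.substeps :: cfg.substeps, :2]
            np.testing.assert_array_equal(traj.coords, expected)

    def test_always_visible_immobile_walker_with_zero_noise_is_constant(self):
        cfg = _small(D1=0.0, D2=0.0, z_visible=np.inf, sigma0=0.0, sigma_z=0.0)
        obs = render_observed(simulate_ground_truth(cfg), cfg)
        for traj in obs:
            assert np.allclose(traj.coords, traj.coords[0])

    def test_out_of_focus_walker_emits_nothing(self):
        # immobile walkers: visible iff their fixed z is inside the slab
        cfg = _small(n_walkers=200, D1=0.0, D2=0.0, p_switch=0.0, sigma0=0, sigma_z=0)
        truth = simulate_ground_truth(cfg)
        obs = render_observed(truth, cfg)
        z = truth.positions[:, 0, 2] % cfg.box[2]
        out = np.abs(z - cfg.box[2] / 2) > cfg.z_visible
        for w in np.flatnonzero(out):
            assert truth.observed_ids[w] == []
        assert len(obs) == int((~out).sum())

    def test_fragments_are_maximal_visible_runs(self, default_sim):
        truth, observed, _ = default_sim
        cfg = truth.config
        for traj in observed.trajectories:
            assert np.all(np.diff(traj.frames) == 1)  # consecutive frames
        # fragments of one walker never overlap and are separated by gaps
        for w, ids in truth.observed_ids.items():
            frames = [observed[i].frames for i in ids]
            for a, b in zip(frames, frames[1:]):
                assert b[0] > a[-1] + 1

    def test_ground_truth_labels_partition_and_match_states(self, default_sim):
        truth, observed, _ = default_sim
        assert set(observed.labels) == set(observed.ids)
        for w, ids in truth.observed_ids.items():
            for tid in ids:
                st = truth.states[w, observed[tid].frames]
                lab = observed.labels[tid]
                expected = (
                    "immobile"
                    if np.all(st == 1)
                    else "mobile" if np.all(st == 2) else "hybrid"
                )
                assert lab == expected

    def test_hybrid_tracks_longer_than_mobile_on_average(self, default_sim):
        _, observed, _ = default_sim
        lens = {"mobile": [], "hybrid": []}
        for t in observed:
            lab = observed.labels[t.id]
            if lab in lens:
                lens[lab].append(t.n_points)
        assert np.mean(lens["hybrid"]) > np.mean(lens["mobile"])

    def test_rendering_is_reproducible(self):
        cfg = _small()
        a = render_observed(simulate_ground_truth(cfg), cfg)
        b = render_observed(simulate_ground_truth(cfg), cfg)
        assert a.ids == b.ids
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert np.array_equal(ta.coords, tb.coords)


class TestSwitchingEstimate:
    def test_direct_count(self):
        cfg = _small(n_walkers=1, n_frames=6)
        truth = GroundTruth(
            cfg,
            np.zeros((1, 6 * cfg.substeps + 1, 3)),
            np.array([[1, 1, 2, 2, 2, 1]], dtype=np.int8),
        )
        assert estimate_switching_probability(truth) == pytest.approx(0.4)

    def test_zero_switching(self):
        truth = simulate_ground_truth(_small(p_switch=0.0))
        assert estimate_switching_probability(truth) == 0.0

    def test_single_frame_is_domain_error(self):
        truth = simulate_ground_truth(_small(n_frames=1))
        with pytest.raises(DomainError):
            estimate_switching_probability(truth)
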