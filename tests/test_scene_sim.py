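"""Agent simulation: dynamics, conservation laws and the density model."""

import dataclasses
import math

import numpy as np
import pytest

import spherotox as st
from spherotox.scene_sim import AgentState, density_for_count


def _cfg(**kw):
    base = st.SceneConfig(**{k: v for k, v in kw.items() if k != "n_agents"})
    n = kw.get("n_agents", 100)
    return dataclasses.replace(base, effector_density=density_for_count(base, n))


class TestConfigValidation:
    def test_spheroid_must_fit_inside_domain(self):
        with pytest.raises(ValueError, match="inside domain"):
            st.SceneConfig(spheroids=(st.Spheroid((50.0, 300.0, 140.0), 120.0),))

    @pytest.mark.parametrize(
        "field,value",
        [("speed", -1.0), ("bias_strength", 1.5), ("n_frames", 1), ("kill_rate", -0.1)],
    )
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            st.SceneConfig(**{field: value})

    def test_bias_without_spheroid_is_an_error(self):
        cfg = dataclasses.replace(
            _cfg(n_agents=10), spheroids=(), bias_strength=0.5
        )
        with pytest.raises(ValueError, match="spheroid"):
            st.simulate_agents(cfg)

    def test_agent_count_follows_density_times_volume(self):
        cfg = st.SceneConfig(effector_density=2e6)  # 600x600x400 um = 1.44e-4 mL
        assert cfg.n_effectors == round(2e6 * 600 * 600 * 400 / 1e12)


class TestDynamics:
    def test_frozen_scene_has_no_motion_attachment_or_death(self):
        cfg = _cfg(n_agents=60, n_frames=10, speed=0.0)
        truth = st.simulate_agents(cfg)
        assert np.array_equal(truth.agent_positions[0], truth.agent_positions[-1])
        assert truth.death_events == []
        assert (truth.agent_states == AgentState.FREE).all()

    def test_no_kill_channel_means_no_deaths(self):
        cfg = _cfg(n_agents=100, n_frames=20, kill_rate=0.0, uniform_kill_rate=0.0)
        truth = st.simulate_agents(cfg)
        assert truth.death_events == []

    def test_ballistic_attachment_time_matches_distance_over_speed(self):
        # full bias, infinite persistence: straight-line approach at `speed`
        cfg = _cfg(
            n_agents=50,
            n_frames=40,
            frame_interval=0.5,
            speed=20.0,
            bias_strength=1.0,
            persistence_time=float("inf"),
            sensing_range=1e6,
        )
        truth = st.simulate_agents(cfg)
        c = np.array(cfg.spheroids[0].center)
        d0 = (
            np.linalg.norm(truth.agent_positions[0] - c, axis=1)
            - cfg.spheroids[0].radius
            - cfg.attachment_radius
        )
        t_pred = np.maximum(d0, 0.0) / cfg.speed
        t_obs = truth.first_attachment_times()
        ok = np.isfinite(t_obs)
        assert ok.all()
        # recorded on the frame grid: observed time is within one frame above truth
        assert np.all(t_obs[ok] - t_pred[ok] > -1e-9)
        assert np.all(t_obs[ok] - t_pred[ok] <= cfg.frame_interval + 1e-9)

    def test_top_seeding_initializes_on_upper_face(self):
        cfg = _cfg(n_agents=80, n_frames=5, seeding_mode="top")
        truth = st.simulate_agents(cfg)
        assert np.allclose(truth.agent_positions[0][:, 2], cfg.domain_extent[2])

    def test_gel_seeding_excludes_spheroid_interior(self):
        cfg = _cfg(n_agents=300, n_frames=2)
        truth = st.simulate_agents(cfg)
        d = np.linalg.norm(
            truth.agent_positions[0] - np.array(cfg.spheroids[0].center), axis=1
        )
        assert (d >= cfg.spheroids[0].radius).all()


class TestInvariants:
    def test_determinism_bit_identical(self):
        cfg = _cfg(n_agents=80, n_frames=12, kill_rate=0.05, infiltration_rate=0.1)
        t1, t2 = st.simulate_agents(cfg), st.simulate_agents(cfg)
        assert np.array_equal(t1.agent_positions, t2.agent_positions)
        assert np.array_equal(t1.agent_states, t2.agent_states)
        assert t1.death_events == t2.death_events
        s1 = st.render_frames(t1, cfg)
        s2 = st.render_frames(t2, cfg)
        assert np.array_equal(s1.pixels, s2.pixels)

    def test_agents_conserved_and_states_monotone(self):
        cfg = _cfg(n_agents=120, n_frames=24, kill_rate=0.05, infiltration_rate=0.1)
        truth = st.simulate_agents(cfg)
        assert truth.agent_positions.shape[1] == cfg.n_effectors
        assert (np.diff(truth.agent_states.astype(int), axis=0) >= 0).all()
        assert set(np.unique(truth.agent_states)) <= {0, 1, 2}

    def test_each_tumor_cell_dies_at_most_once_within_time_span(self):
        cfg = _cfg(n_agents=150, n_frames=24, kill_rate=0.2, uniform_kill_rate=0.01)
        truth = st.simulate_agents(cfg)
        ids = [cid for cid, _, _ in truth.death_events]
        assert len(ids) == len(set(ids))
        t_end = (cfg.n_frames - 1) * cfg.frame_interval + cfg.frame_interval
        assert all(0 <= t <= t_end for _, t, _ in truth.death_events)

    def test_doubling_density_doubles_attachments(self):
        # no feedback: expected attached count is linear in seeding density
        n1 = n2 = 0
        for s in range(20):
            c1 = _cfg(n_agents=100, n_frames=25, rng_seed=s)
            c2 = _cfg(n_agents=200, n_frames=25, rng_seed=1000 + s)
            n1 += (st.simulate_agents(c1).agent_states[-1] >= 1).sum()
            n2 += (st.simulate_agents(c2).agent_states[-1] >= 1).sum()
        assert abs(n2 / n1 - 2.0) < 0.2

    def test_attachment_time_distribution_density_invariant(self):
        from scipy.stats import ks_2samp

        samples = {}
        for n_agents in (500, 1000):
            cfg = _cfg(n_agents=n_agents, n_frames=36, rng_seed=5 + n_agents)
            f = st.simulate_agents(cfg).first_attachment_times()
            samples[n_agents] = f[np.isfinite(f)]
        d = ks_2samp(samples[500], samples[1000]).statistic
        assert d < 0.1

    def test_top_seeding_reaches_spheroids_later_than_gel(self):
        # per-agent arrival: top seeding starts every effector a slab away,
        # so mean first-attachment time is later; the dispersion ordering is
        # asserted at the per-spheroid recruitment-time level (where the
        # measurement is defined) in the acceptance suite
        times = {}
        for mode in ("gel", "top"):
            ts = []
            for s in range(5):
                cfg = _cfg(n_agents=150, n_frames=40, seeding_mode=mode, rng_seed=s)
                f = st.simulate_agents(cfg).first_attachment_times()
                ts.append(f[np.isfinite(f)])
            times[mode] = np.concatenate(ts)
        assert times["top"].mean() > times["gel"].mean() + 5.0


class TestUnitRatioDensity:
    def test_zero_targets_zero_density(self):
        assert st.effector_density_for_unit_ratio(0, 200.0, 300.0) == 0.0

    def test_closed_form_shell_volume(self):
        # V = (4/3) pi (500^3 - 200^3) um^3 = 4.90e8 um^3 = 4.90e-4 mL
        v_ml = 4.0 / 3.0 * math.pi * (500.0**3 - 200.0**3) / 1e12
        expect = 2000.0 / v_ml
        got = st.effector_density_for_unit_ratio(2000, 200.0, 300.0)
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(4.1e6, rel=0.02)

    def test_experimental_radius_range_lands_at_upper_end_of_seeded_range(self):
        dens = [
            st.effector_density_for_unit_ratio(2000, r, 300.0)
            for r in np.linspace(150, 400, 11)
        ]
        assert min(dens) > 2e5
        assert max(dens) < 8e6

    def test_invalid_shell_rejected(self):
        with pytest.raises(ValueError):
            st.effector_density_for_unit_ratio(2000, 200.0, 0.0)
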