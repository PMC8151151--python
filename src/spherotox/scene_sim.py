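"""Agent-based synthetic co-culture scenes with ground truth.

Generates time-lapse scenes of killer lymphocytes (effector agents) attacking
tumor spheroids embedded in a 3D gel slab, and renders them into calibrated
multi-channel image stacks (brightfield, effector dye, nuclear dye).  Every
scene carries its full ground truth (agent trajectories and states, tumor-cell
death events, spheroid masks, fragmented-signal area) so that each downstream
image-analysis stage can be validated against known answers.

The motility model is a persistent random walk whose heading relaxes with
timescale ``persistence_time`` and is blended toward the nearest spheroid
surface (weight ``bias_strength``) once the agent is within ``sensing_range``.
There is deliberately no density feedback: agents never interact with each
other, so recruitment scales linearly with seeding density and the per-agent
arrival-time distribution is density-invariant by construction.

Killing is contact-mediated: agents that reach a spheroid surface attach, may
infiltrate inward, and trigger apoptosis of the nearest tumor cell at a fixed
rate.  A separate uniform kill rate emulates a drug control (agent-free
cytotoxicity).  Dead cells are rendered as a handful of small bright apoptotic
bodies whose signal decays with timescale ``fragment_decay`` (~24 h); the
effector live dye bleaches with timescale ``bleach_decay`` (~72 h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import CalibratedStack

__all__ = [
    "Spheroid",
    "SceneConfig",
    "SceneGroundTruth",
    "AgentState",
    "simulate_agents",
    "render_frames",
    "simulate_and_render",
    "effector_density_for_unit_ratio",
    "density_for_count",
]

UM3_PER_ML = 1e12  # 1 mL = 1 cm^3 = 1e12 um^3


class AgentState(IntEnum):
    FREE = 0
    ATTACHED = 1
    INFILTRATED = 2


@dataclass(frozen=True)
class Spheroid:
    """A spherical tumor aggregate: center (x, y, z) in um, radius in um."""

    center: tuple[float, float, float]
    radius: float
    n_cells: int = 200


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic co-culture scene.

    Lengths in um, times in h, rates in 1/h.  ``effector_density`` is in
    cells/mL of gel; the agent count is its product with the slab volume.
    ``seeding_mode`` 'gel' seeds agents uniformly in the slab volume, 'top'
    seeds them on the upper gel-liquid interface (z = domain_extent[2]).
    """

    domain_extent: tuple[float, float, float] = (600.0, 600.0, 400.0)
    pixel_size: float = 4.0
    frame_interval: float = 1.0
    n_frames: int = 48
    spheroids: tuple[Spheroid, ...] = (Spheroid((300.0, 300.0, 140.0), 120.0, 200),)
    effector_density: float = 2e6
    seeding_mode: str = "gel"
    speed: float = 30.0
    persistence_time: float = 0.5
    bias_strength: float = 0.5
    sensing_range: float = 100.0
    attachment_radius: float = 8.0
    infiltration_rate: float = 0.0
    kill_rate: float = 0.0
    uniform_kill_rate: float = 0.0
    fragment_decay: float = 24.0
    bleach_decay: float = 72.0
    noise_sd: float = 0.02
    rng_seed: int = 0
    # rendering geometry (um); kept on the config so truth and render agree
    nucleus_radius: float = 5.0
    effector_radius: float = 5.0

    def __post_init__(self) -> None:
        if len(self.domain_extent) != 3 or any(L <= 0 for L in self.domain_extent):
            raise ValueError("domain_extent must be three positive lengths (um)")
        for name in (
            "pixel_size",
            "frame_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "speed",
            "persistence_time",
            "sensing_range",
            "attachment_radius",
            "infiltration_rate",
            "kill_rate",
            "uniform_kill_rate",
            "fragment_decay",
            "bleach_decay",
            "noise_sd",
            "effector_density",
            "nucleus_radius",
            "effector_radius",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.seeding_mode not in ("gel", "top"):
            raise ValueError("seeding_mode must be 'gel' or 'top'")
        Lx, Ly, Lz = self.domain_extent
        for s in self.spheroids:
            cx, cy, cz = s.center
            if s.radius <= 0:
                raise ValueError("spheroid radius must be > 0")
            if not (
                s.radius <= cx <= Lx - s.radius
                and s.radius <= cy <= Ly - s.radius
                and s.radius <= cz <= Lz - s.radius
            ):
                raise ValueError("every spheroid sphere must lie inside domain_extent")

    @property
    def times(self) -> np.ndarray:
        """Frame times in hours; t=0 is the moment effectors are added."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def slab_volume_ml(self) -> float:
        Lx, Ly, Lz = self.domain_extent
        return Lx * Ly * Lz / UM3_PER_ML

    @property
    def n_effectors(self) -> int:
        return int(round(self.effector_density * self.slab_volume_ml))

    @property
    def frame_shape(self) -> tuple[int, int]:
        Lx, Ly, _ = self.domain_extent
        return (int(round(Ly / self.pixel_size)), int(round(Lx / self.pixel_size)))

    def with_seed(self, rng_seed: int) -> "SceneConfig":
        return replace(self, rng_seed=rng_seed)


def density_for_count(config: SceneConfig, n_agents: int) -> float:
    """Effector density (cells/mL) that seeds ``n_agents`` in this slab."""
    return n_agents / config.slab_volume_ml


@dataclass
class SceneGroundTruth:
    """Per-frame truth of a simulated scene; the oracle for all analysis stages."""

    config: SceneConfig
    times: np.ndarray  # (T,) h
    agent_positions: np.ndarray  # (T, N, 3) um
    agent_states: np.ndarray  # (T, N) AgentState codes
    cell_positions: np.ndarray  # (M, 3) um, all tumor cells of all spheroids
    cell_spheroid: np.ndarray  # (M,) spheroid index per tumor cell
    death_events: list[tuple[int, float, tuple[float, float, float]]]
    fragment_offsets: dict[int, np.ndarray]  # cell id -> (n_frag, 3) um offsets
    per_frame_masks: np.ndarray  # (T, S, H, W) bool, spheroid disk masks
    per_frame_frag_area: np.ndarray  # (T, S) px^2 true fragmented-signal area

    @property
    def n_agents(self) -> int:
        return self.agent_positions.shape[1]

    def first_attachment_times(self) -> np.ndarray:
        """Per-agent time of first attachment (NaN if never attached)."""
        attached = self.agent_states >= AgentState.ATTACHED  # (T, N)
        any_att = attached.any(axis=0)
        first_idx = attached.argmax(axis=0)
        out = np.full(self.n_agents, np.nan)
        out[any_att] = self.times[first_idx[any_att]]
        return out

    def n_dead(self, time_h: float) -> int:
        return sum(1 for _, t, _ in self.death_events if t <= time_h)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n[n == 0] = 1.0
    return v / n


def _sample_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform points in a ball of given radius (rejection-free)."""
    u = rng.standard_normal((n, 3))
    u = _unit(u)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return u * r[:, None]


def simulate_agents(config: SceneConfig) -> SceneGroundTruth:
    """Run the agent-based co-culture simulation.

    Fully deterministic given ``config.rng_seed``.  Agents are conserved
    (no division, no death) and their state can only progress
    free -> attached -> infiltrated.
    """
    if config.bias_strength > 0 and len(config.spheroids) == 0:
        raise ValueError("bias_strength > 0 requires at least one spheroid to bias toward")

    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0]))
    Lx, Ly, Lz = config.domain_extent
    L = np.array([Lx, Ly, Lz])
    n_agents = config.n_effectors
    spheroids = config.spheroids
    S = len(spheroids)
    centers = np.array([s.center for s in spheroids]).reshape(S, 3)
    radii = np.array([s.radius for s in spheroids])

    # tumor cells, uniform within each sphere
    cell_pos_parts = []
    cell_sph = []
    for si, s in enumerate(spheroids):
        cell_pos_parts.append(s.center + _sample_in_sphere(rng, s.n_cells, s.radius))
        cell_sph.append(np.full(s.n_cells, si, dtype=int))
    cell_positions = (
        np.concatenate(cell_pos_parts) if cell_pos_parts else np.empty((0, 3))
    )
    cell_spheroid = np.concatenate(cell_sph) if cell_sph else np.empty(0, dtype=int)
    alive = np.ones(len(cell_positions), dtype=bool)

    # effector seeding
    pos = rng.random((n_agents, 3)) * L
    if config.seeding_mode == "top":
        pos[:, 2] = Lz
    elif S:
        # resample agents that land inside a spheroid (gel excludes the tumor mass)
        for _ in range(50):
            d = np.linalg.norm(pos[:, None, :] - centers[None], axis=2)
            inside = (d < radii[None]).any(axis=1)
            if not inside.any():
                break
            pos[inside] = rng.random((inside.sum(), 3)) * L
    heading = _unit(rng.standard_normal((n_agents, 3)))
    state = np.zeros(n_agents, dtype=np.int8)

    T = config.n_frames
    positions_out = np.empty((T, n_agents, 3))
    states_out = np.empty((T, n_agents), dtype=np.int8)
    positions_out[0] = pos
    states_out[0] = state

    death_events: list[tuple[int, float, tuple[float, float, float]]] = []
    fragment_offsets: dict[int, np.ndarray] = {}
    # per-agent infiltration target radius (fraction of spheroid radius), drawn on entry
    infil_target = np.full(n_agents, np.nan)
    agent_sph = np.full(n_agents, -1, dtype=int)

    # substep small enough to resolve attachment shells and heading relaxation
    dt = config.frame_interval
    if config.speed > 0:
        dt = min(dt, max(config.attachment_radius, 2.0) / config.speed)
    if math.isfinite(config.persistence_time) and config.persistence_time > 0:
        dt = min(dt, config.persistence_time / 2.0)
    n_sub = max(1, int(math.ceil(config.frame_interval / dt)))
    dt = config.frame_interval / n_sub

    def record_death(cid: int, t: float) -> None:
        alive[cid] = False
        p = cell_positions[cid]
        death_events.append((int(cid), float(t), (float(p[0]), float(p[1]), float(p[2]))))
        n_frag = int(rng.integers(3, 7))
        # apoptotic bodies scatter within about one nucleus diameter of the cell
        fragment_offsets[int(cid)] = _sample_in_sphere(rng, n_frag, 2.0 * config.nucleus_radius)

    p_infil = -np.expm1(-config.infiltration_rate * dt)
    p_kill = -np.expm1(-config.kill_rate * dt)
    p_ukill = -np.expm1(-config.uniform_kill_rate * dt)
    sigma_rot = (
        math.sqrt(2.0 * dt / config.persistence_time)
        if math.isfinite(config.persistence_time) and config.persistence_time > 0
        else 0.0
    )

    for fi in range(1, T):
        t0 = config.times[fi - 1]
        for sub in range(n_sub):
            t_now = t0 + (sub + 1) * dt
            free = state == AgentState.FREE
            if free.any() and config.speed > 0:
                h = heading[free]
                if sigma_rot > 0:
                    h = _unit(h + sigma_rot * rng.standard_normal(h.shape))
                if S and config.bias_strength > 0:
                    d = np.linalg.norm(pos[free][:, None, :] - centers[None], axis=2)
                    nearest = d.argmin(axis=1)
                    surf_dist = d[np.arange(len(nearest)), nearest] - radii[nearest]
                    sensed = surf_dist <= config.sensing_range
                    if sensed.any():
                        toward = _unit(centers[nearest[sensed]] - pos[free][sensed])
                        h[sensed] = _unit(
                            (1.0 - config.bias_strength) * h[sensed]
                            + config.bias_strength * toward
                        )
                newpos = pos[free] + config.speed * dt * h
                # reflecting slab boundaries
                for ax in range(3):
                    lo = newpos[:, ax] < 0
                    hi = newpos[:, ax] > L[ax]
                    newpos[lo, ax] = -newpos[lo, ax]
                    newpos[hi, ax] = 2 * L[ax] - newpos[hi, ax]
                    h[lo | hi, ax] *= -1.0
                pos[free] = newpos
                heading[free] = h
            elif sigma_rot > 0 and free.any():
                heading[free] = _unit(
                    heading[free] + sigma_rot * rng.standard_normal((int(free.sum()), 3))
                )

            # attachment: free agents within attachment_radius of a surface
            if S and free.any() and config.speed > 0:
                idx = np.flatnonzero(free)
                d = np.linalg.norm(pos[idx][:, None, :] - centers[None], axis=2)
                nearest = d.argmin(axis=1)
                surf = d[np.arange(len(idx)), nearest] - radii[nearest]
                hit = surf <= config.attachment_radius
                if hit.any():
                    ids = idx[hit]
                    sph = nearest[hit]
                    state[ids] = AgentState.ATTACHED
                    agent_sph[ids] = sph
                    # snap to the surface point on the agent's radial ray
                    radial = _unit(pos[ids] - centers[sph])
                    pos[ids] = centers[sph] + radial * radii[sph][:, None]

            # infiltration: attached agents start moving inward at rate infiltration_rate
            att = state == AgentState.ATTACHED
            if att.any() and p_infil > 0:
                go = rng.random(int(att.sum())) < p_infil
                ids = np.flatnonzero(att)[go]
                if len(ids):
                    state[ids] = AgentState.INFILTRATED
                    # lymphocytes penetrate a few cell layers; most stay on
                    # outer shells, deeper stops are rarer
                    infil_target[ids] = rng.uniform(0.4, 0.95, len(ids))
            inf_mask = state == AgentState.INFILTRATED
            if inf_mask.any() and config.speed > 0:
                ids = np.flatnonzero(inf_mask)
                sph = agent_sph[ids]
                rel = pos[ids] - centers[sph]
                rcur = np.linalg.norm(rel, axis=1)
                rtarget = infil_target[ids] * radii[sph]
                step = 0.3 * config.speed * dt  # crawling through tissue is slower
                rnew = np.maximum(rcur - step, rtarget)
                scale = np.where(rcur > 0, rnew / np.maximum(rcur, 1e-12), 0.0)
                pos[ids] = centers[sph] + rel * scale[:, None]

            # contact killing: attached or infiltrated agents fire at kill_rate
            engaged = state >= AgentState.ATTACHED
            if engaged.any() and p_kill > 0 and alive.any():
                fire = rng.random(int(engaged.sum())) < p_kill
                for aid in np.flatnonzero(engaged)[fire]:
                    si = agent_sph[aid]
                    cand = np.flatnonzero(alive & (cell_spheroid == si))
                    if len(cand) == 0:
                        continue
                    dd = np.linalg.norm(cell_positions[cand] - pos[aid], axis=1)
                    record_death(int(cand[dd.argmin()]), t_now)

            # drug-control killing, independent of agents
            if p_ukill > 0 and alive.any():
                hit = rng.random(int(alive.sum())) < p_ukill
                for cid in np.flatnonzero(alive)[hit]:
                    record_death(int(cid), t_now)

        positions_out[fi] = pos
        states_out[fi] = state

    masks = _spheroid_masks(config)
    per_frame_masks = np.broadcast_to(masks[None], (T,) + masks.shape).copy()
    frag_area = _true_frag_area(config, death_events, fragment_offsets, cell_spheroid)

    return SceneGroundTruth(
        config=config,
        times=config.times.copy(),
        agent_positions=positions_out,
        agent_states=states_out,
        cell_positions=cell_positions,
        cell_spheroid=cell_spheroid,
        death_events=death_events,
        fragment_offsets=fragment_offsets,
        per_frame_masks=per_frame_masks,
        per_frame_frag_area=frag_area,
    )


def _spheroid_masks(config: SceneConfig) -> np.ndarray:
    """(S, H, W) boolean disk masks of each spheroid's 2D projection."""
    H, W = config.frame_shape
    yy, xx = np.mgrid[0:H, 0:W]
    px = config.pixel_size
    masks = np.zeros((len(config.spheroids), H, W), dtype=bool)
    for si, s in enumerate(config.spheroids):
        cx, cy, _ = s.center
        rr2 = ((xx + 0.5) * px - cx) ** 2 + ((yy + 0.5) * px - cy) ** 2
        masks[si] = rr2 <= s.radius**2
    return masks


def _true_frag_area(
    config: SceneConfig,
    death_events: Sequence[tuple[int, float, tuple[float, float, float]]],
    fragment_offsets: dict[int, np.ndarray],
    cell_spheroid: np.ndarray,
) -> np.ndarray:
    """Analytic fragmented-signal area (px^2) per frame and spheroid.

    Each apoptotic body has footprint pi*r_frag^2 with r_frag a quarter of the
    intact-nucleus diameter; the footprint is weighted by the same exponential
    amplitude decay the renderer applies.
    """
    T = config.n_frames
    S = len(config.spheroids)
    out = np.zeros((T, S))
    r_frag_px = (config.nucleus_radius / 2.0) / config.pixel_size
    foot = math.pi * r_frag_px**2
    times = config.times
    for cid, t_death, _ in death_events:
        si = int(cell_spheroid[cid])
        nf = len(fragment_offsets[cid])
        dt = times - t_death
        w = np.where(dt >= 0, np.exp(-np.maximum(dt, 0) / config.fragment_decay), 0.0)
        out[:, si] += nf * foot * w
    return out


# ---------------------------------------------------------------------------
# rendering


def _splat(
    shape: tuple[int, int], xy_um: np.ndarray, weights: np.ndarray, pixel_size: float
) -> np.ndarray:
    """Bilinear deposition of weighted points onto a pixel grid."""
    H, W = shape
    img = np.zeros((H + 2, W + 2))
    if len(xy_um) == 0:
        return img[1:-1, 1:-1]
    c = xy_um[:, 0] / pixel_size - 0.5
    r = xy_um[:, 1] / pixel_size - 0.5
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    r0 = np.clip(r0, -1, H - 1) + 1
    c0 = np.clip(c0, -1, W - 1) + 1
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        np.add.at(img, (r0 + dr, c0 + dc), weights * w)
    return img[1:-1, 1:-1]


def render_frames(
    truth: SceneGroundTruth,
    config: SceneConfig | None = None,
    *,
    effector_amplitude: float = 0.5,
    nucleus_amplitude: float = 1.2,
    fragment_amplitude: float = 0.5,
    z_section: tuple[float, float] | None = None,
) -> CalibratedStack:
    """Render a simulated scene into a calibrated BF/EFF/NUC image stack.

    Fluorescence channels are formed by depositing one blurred point spread
    per emitter and integrating along z (widefield-like additive projection),
    so total effector intensity is conserved up to bleaching and noise.
    Amplitudes are the integrated (summed-pixel) intensity per emitter before
    decay; intensities are normalized to [0, 1] full scale and additive
    Gaussian noise of sd ``noise_sd`` is applied then clipped.

    ``z_section`` emulates a confocal optical section: only emitters whose z
    coordinate lies within the given (low, high) slab are rendered.  Use a
    slab through the spheroid center plane to obtain rim-resolved radial
    profiles; the default (None) integrates the full slab thickness as a
    widefield acquisition does.
    """
    if config is None:
        config = truth.config
    if truth.agent_positions.shape[0] != config.n_frames:
        raise ValueError("truth and config disagree on frame count")
    H, W = config.frame_shape
    px = config.pixel_size
    for s in config.spheroids:
        if 2 * s.radius / px < 3:
            raise ValueError(
                f"pixel_size {px} um too coarse: spheroid of radius {s.radius} um "
                "spans fewer than 3 pixels"
            )

    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    T = config.n_frames
    stack = np.zeros((T, 3, H, W), dtype=np.float32)

    # --- brightfield: bright background, dark textured spheroid interior
    masks = truth.per_frame_masks[0] if len(config.spheroids) else np.zeros((0, H, W), bool)
    union = masks.any(axis=0) if len(masks) else np.zeros((H, W), bool)
    texture = gaussian_filter(rng.standard_normal((H, W)), 1.0)
    tex_sd = texture.std() or 1.0
    bf_static = np.full((H, W), 0.85)
    bf_static[union] = 0.40 + 0.12 * (texture[union] / tex_sd)

    sig_eff_px = max(config.effector_radius / px, 0.6)
    sig_nuc_px = max(config.nucleus_radius / px, 0.6)
    sig_frag_px = max(sig_nuc_px / 4.0, 0.4)

    deaths_by_cell = {cid: t for cid, t, _ in truth.death_events}
    times = config.times

    def in_section(z: np.ndarray) -> np.ndarray:
        if z_section is None:
            return np.ones(len(z), dtype=bool)
        lo, hi = z_section
        return (z >= lo) & (z <= hi)

    for fi in range(T):
        t = times[fi]
        bf = bf_static.copy()

        # effector channel: one PSF per agent, bleaching with bleach_decay
        apos = truth.agent_positions[fi]
        apos = apos[in_section(apos[:, 2])]
        decay = math.exp(-t / config.bleach_decay) if math.isfinite(config.bleach_decay) else 1.0
        eff = _splat((H, W), apos[:, :2], np.full(len(apos), effector_amplitude * decay), px)
        eff = gaussian_filter(eff, sig_eff_px)

        # nuclear channel: intact nuclei for live cells, apoptotic bodies for dead
        live_ids = [
            i for i in range(len(truth.cell_positions))
            if deaths_by_cell.get(i, np.inf) > t
            and in_section(truth.cell_positions[i, 2:3])[0]
        ]
        live_xy = truth.cell_positions[live_ids][:, :2] if live_ids else np.empty((0, 2))
        nuc = _splat((H, W), live_xy, np.full(len(live_xy), nucleus_amplitude), px)
        nuc = gaussian_filter(nuc, sig_nuc_px)

        frag_xy = []
        frag_w = []
        for cid, t_death in deaths_by_cell.items():
            if t_death <= t:
                offs = truth.fragment_offsets[cid]
                amp = fragment_amplitude * math.exp(-(t - t_death) / config.fragment_decay)
                base = truth.cell_positions[cid]
                for o in offs:
                    p = base + o
                    if in_section(p[2:3])[0]:
                        frag_xy.append(p[:2])
                        frag_w.append(amp)
        if frag_xy:
            fimg = _splat((H, W), np.array(frag_xy), np.array(frag_w), px)
            nuc = nuc + gaussian_filter(fimg, sig_frag_px)

        stack[fi, 0] = bf
        stack[fi, 1] = eff
        stack[fi, 2] = nuc

    # amplitudes are fixed in [0,1] full-scale units (no per-stack rescaling),
    # so intensities are comparable across scenes and linear in emitter count
    if config.noise_sd > 0:
        stack += rng.normal(0.0, config.noise_sd, size=stack.shape).astype(np.float32)
    np.clip(stack, 0.0, 1.0, out=stack)

    return CalibratedStack(
        pixels=stack,
        channel_roles=("BF", "EFF", "NUC"),
        times=times.astype(float),
        pixel_size=px,
        metadata={"rng_seed": config.rng_seed, "frame_interval_h": config.frame_interval},
    )


def simulate_and_render(config: SceneConfig) -> tuple[SceneGroundTruth, CalibratedStack]:
    truth = simulate_agents(config)
    return truth, render_frames(truth, config)


def effector_density_for_unit_ratio(
    n_target_cells: int = 2000,
    spheroid_radius: float = 200.0,
    shell_thickness: float = 300.0,
) -> float:
    """Effector density (cells/mL) giving a theoretical 1:1 E:T ratio.

    Places ``n_target_cells`` effectors in the spherical shell of the given
    thickness surrounding a spheroid of the given radius:
    N / V_shell with V_shell = (4/3)*pi*((r+d)^3 - r^3).
    """
    if n_target_cells < 0:
        raise ValueError("n_target_cells must be >= 0")
    if spheroid_radius <= 0:
        raise ValueError("spheroid_radius must be > 0")
    if shell_thickness <= 0:
        raise ValueError("shell_thickness must be > 0")
    v_um3 = (4.0 / 3.0) * math.pi * (
        (spheroid_radius + shell_thickness) ** 3 - spheroid_radius**3
    )
    return n_target_cells / (v_um3 / UM3_PER_ML)
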