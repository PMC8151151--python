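"""End-to-end analysis orchestration with deterministic reporting.

``run_pipeline`` executes simulate (optional) -> segment -> track ->
recruitment -> sigmoid fit -> cytotoxicity -> (optional) specific lysis ->
infiltration -> coupling, writes every stage output as CSV with explicit
units in the column names, and records provenance (config hash, seed,
package version) so an identical config + seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cytotox import (
    FragmentationParams,
    FragmentationSeries,
    coupling_curve,
    fragmentation_series,
    specific_lysis,
)
from .infiltration import infiltration_depth, radial_profile
from .io import CalibratedStack, read_stack, write_stack
from .kinetics import fit_sigmoid, measure_recruitment
from .scene_sim import SceneConfig, Spheroid, simulate_agents, render_frames
from .segmentation import SegmentationParams, segment_spheroids, track_labels

log = logging.getLogger("spherotox")

__all__ = ["AnalysisConfig", "ResultsBundle", "run_pipeline", "scene_config_from_dict"]


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs: input, parameters, seed, output dir.

    Exactly one of ``stack_path`` (analyze an existing calibrated stack) or
    ``scene`` (simulate a synthetic scene first) must be provided.
    """

    out_dir: str | Path
    stack_path: str | Path | None = None
    scene: SceneConfig | None = None
    control_scene: SceneConfig | None = None  # effector-free control for lysis
    channel_map: tuple[str, ...] | None = None
    rng_seed: int = 0
    min_area_um2: float = float(np.pi * 25.0**2)
    max_link_distance_um: float = 50.0
    guard_band_um: float = 20.0
    frag_method: str = "lowres_threshold"
    nucleus_diameter_um: float = 10.0
    radial_bin_um: float = 10.0

    def __post_init__(self) -> None:
        if (self.stack_path is None) == (self.scene is None):
            raise ValueError("provide exactly one of stack_path or scene")

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "out_dir": str(self.out_dir),
            "stack_path": str(self.stack_path) if self.stack_path else None,
            "scene": _scene_to_dict(self.scene) if self.scene else None,
            "control_scene": _scene_to_dict(self.control_scene)
            if self.control_scene
            else None,
            "channel_map": list(self.channel_map) if self.channel_map else None,
            "rng_seed": self.rng_seed,
            "min_area_um2": self.min_area_um2,
            "max_link_distance_um": self.max_link_distance_um,
            "guard_band_um": self.guard_band_um,
            "frag_method": self.frag_method,
            "nucleus_diameter_um": self.nucleus_diameter_um,
            "radial_bin_um": self.radial_bin_um,
        }
        return d


def _scene_to_dict(sc: SceneConfig) -> dict:
    d = dataclasses.asdict(sc)
    d["spheroids"] = [
        {"center": list(s.center), "radius": s.radius, "n_cells": s.n_cells}
        for s in sc.spheroids
    ]
    d["domain_extent"] = list(sc.domain_extent)
    return d


def scene_config_from_dict(d: dict) -> SceneConfig:
    d = dict(d)
    sph = tuple(
        Spheroid(
            tuple(float(c) for c in s["center"]),
            float(s["radius"]),
            int(s.get("n_cells", 200)),
        )
        for s in d.pop("spheroids", [])
    )
    if "domain_extent" in d:
        d["domain_extent"] = tuple(float(x) for x in d["domain_extent"])
    for key, val in d.items():
        # YAML writes scientific notation like 1.8e6 as a string; coerce
        if isinstance(val, str) and key not in ("seeding_mode",):
            d[key] = float(val)
    if "n_frames" in d:
        d["n_frames"] = int(d["n_frames"])
    if "rng_seed" in d:
        d["rng_seed"] = int(d["rng_seed"])
    return SceneConfig(spheroids=sph, **d)


@dataclass
class ResultsBundle:
    """All pipeline outputs plus the provenance record."""

    out_dir: Path
    stack: CalibratedStack
    tracks: list
    curves: list
    fits: list
    frag_series: list[FragmentationSeries]
    lysis: Any = None
    profiles: list = field(default_factory=list)
    couplings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _config_hash(cfg: AnalysisConfig) -> str:
    blob = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")


def run_pipeline(config: AnalysisConfig) -> ResultsBundle:
    """Run every analysis stage and write CSV outputs + provenance.

    Any stage failure aborts with the stage name in the exception message;
    outputs of completed stages are preserved in ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # --- acquire stack
        stage = "simulate"
        truth = None
        if config.scene is not None:
            scene = dataclasses.replace(config.scene, rng_seed=config.rng_seed)
            truth = simulate_agents(scene)
            stack = render_frames(truth, scene)
            write_stack(stack, out / "stack.tif")
            _write_truth(truth, out)
        else:
            stage = "read_stack"
            stack = read_stack(config.stack_path, config.channel_map)

        # --- segmentation + tracking
        stage = "segment"
        seg_params = SegmentationParams(
            pixel_size=stack.pixel_size, min_area_um2=config.min_area_um2
        )
        bf = stack.channel("BF")
        labels = [segment_spheroids(bf[fi], seg_params) for fi in range(stack.n_frames)]
        stage = "track"
        tracks = track_labels(labels, config.max_link_distance_um, stack.pixel_size)
        full = [t for t in tracks if len(t.entries) == stack.n_frames]
        if full:
            tracks = full
        else:
            log.warning("no track spans all %d frames; keeping partial tracks", stack.n_frames)
        rows = []
        for tr in tracks:
            for e in tr.entries:
                rows.append(
                    {
                        "spheroid_id": tr.id,
                        "frame": e.frame,
                        "time_h": stack.times[e.frame],
                        "centroid_row_px": e.centroid[0],
                        "centroid_col_px": e.centroid[1],
                        "area_um2": e.area_um2(stack.pixel_size),
                        "eq_diameter_um": e.equivalent_diameter_um(stack.pixel_size),
                    }
                )
        _write_csv(pd.DataFrame(rows), out / "tracks.csv")
        if not tracks:
            raise RuntimeError("segmentation found no spheroids")

        # --- recruitment
        stage = "recruitment"
        curves = measure_recruitment(stack, tracks, "EFF", config.guard_band_um)
        crows = []
        for c in curves:
            for t, v in zip(c.times, c.values):
                crows.append({"spheroid_id": c.spheroid_id, "time_h": t, "value_au": v})
        _write_csv(pd.DataFrame(crows), out / "recruitment.csv")

        stage = "fit"
        fits = []
        for c in curves:
            if np.isfinite(c.values).sum() >= 4:
                fits.append(fit_sigmoid(c))
        _write_csv(
            pd.DataFrame(
                [
                    {
                        "spheroid_id": f.spheroid_id,
                        "a_au": f.a,
                        "b_au": f.b,
                        "k_per_h": f.k,
                        "tau_h": f.tau,
                        "rss": f.rss,
                        "converged": f.converged,
                        "identifiable": f.identifiable,
                    }
                    for f in fits
                ]
            ),
            out / "fits.csv",
        )

        # --- cytotoxicity
        stage = "cytotox"
        fparams = FragmentationParams(
            pixel_size=stack.pixel_size, nucleus_diameter_um=config.nucleus_diameter_um
        )
        nuc = stack.channel("NUC")
        frag_series_list = []
        for tr in tracks:
            masks = [tr.entry_at(fi).mask if tr.entry_at(fi) else np.zeros(stack.frame_shape, bool) for fi in range(stack.n_frames)]
            frag_series_list.append(
                fragmentation_series(
                    nuc, masks, stack.times, tr.id, config.frag_method, fparams
                )
            )
        frows = []
        for fs in frag_series_list:
            for t, v in zip(fs.times, fs.frag_fraction):
                frows.append(
                    {
                        "spheroid_id": fs.spheroid_id,
                        "time_h": t,
                        "frag_fraction": v,
                        "method": fs.method,
                    }
                )
        _write_csv(pd.DataFrame(frows), out / "fragmentation.csv")

        # --- optional control run -> specific lysis
        lysis = None
        if config.control_scene is not None and frag_series_list:
            stage = "lysis"
            ctrl_cfg = AnalysisConfig(
                out_dir=out / "control",
                scene=config.control_scene,
                rng_seed=config.rng_seed + 1,
                min_area_um2=config.min_area_um2,
                frag_method=config.frag_method,
                nucleus_diameter_um=config.nucleus_diameter_um,
            )
            ctrl = run_pipeline(ctrl_cfg)
            if ctrl.frag_series:
                mean_ctrl = _mean_series(ctrl.frag_series)
                mean_treat = _mean_series(frag_series_list)
                lysis = specific_lysis(mean_treat, mean_ctrl)
                _write_csv(
                    pd.DataFrame(
                        {
                            "time_h": lysis.times,
                            "specific_lysis_pct": lysis.specific_lysis,
                        }
                    ),
                    out / "specific_lysis.csv",
                )

        # --- infiltration
        stage = "infiltration"
        profiles = []
        prows = []
        for tr in tracks:
            prof = radial_profile(stack, tr, "EFF", config.radial_bin_um)
            profiles.append(prof)
            for ti in range(len(prof.times)):
                for bi, bc in enumerate(prof.bin_centers):
                    prows.append(
                        {
                            "spheroid_id": prof.spheroid_id,
                            "time_h": prof.times[ti],
                            "bin_center_um": bc,
                            "mean_intensity_au": prof.per_time_means[ti, bi],
                            "n_pixels": prof.per_time_counts[ti, bi],
                            "boundary_radius_um": prof.boundary_radius[ti],
                        }
                    )
        _write_csv(pd.DataFrame(prows), out / "radial_profiles.csv")

        # --- coupling
        stage = "coupling"
        couplings = []
        lrows = []
        fs_by_id = {fs.spheroid_id: fs for fs in frag_series_list}
        for c in curves:
            fs = fs_by_id.get(c.spheroid_id)
            if fs is None or np.isfinite(c.values).sum() < 4:
                continue
            if np.isfinite(fs.frag_fraction).sum() < 4:
                continue
            pairs, lag = coupling_curve(c, fs)
            couplings.append((c.spheroid_id, pairs, lag))
            lrows.append({"spheroid_id": c.spheroid_id, "lag_h": lag})
        _write_csv(pd.DataFrame(lrows), out / "coupling_lags.csv")

        # --- diagnostic figures
        stage = "plots"
        from .plots import plot_coupling, plot_fits, plot_profile_heatmap

        plot_fits(curves, fits, out / "fits.png")
        if profiles:
            plot_profile_heatmap(profiles[0], out / "radial_profile.png")
        plot_coupling(couplings, out / "coupling.png")

        # --- provenance
        stage = "provenance"
        prov = {
            "config": config.to_dict(),
            "config_sha256": _config_hash(config),
            "rng_seed": config.rng_seed,
            "spherotox_version": __version__,
            "n_tracks": len(tracks),
            "n_fits": len(fits),
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return ResultsBundle(
        out_dir=out,
        stack=stack,
        tracks=tracks,
        curves=curves,
        fits=fits,
        frag_series=frag_series_list,
        lysis=lysis,
        profiles=profiles,
        couplings=couplings,
        provenance=prov,
    )


def _mean_series(series: list[FragmentationSeries]) -> FragmentationSeries:
    times = series[0].times
    vals = np.nanmean(np.stack([s.frag_fraction for s in series]), axis=0)
    return FragmentationSeries(
        spheroid_id=0, times=times, frag_fraction=np.clip(vals, 0, 1),
        method=series[0].method,
    )


def _write_truth(truth, out: Path) -> None:
    """Ground-truth sidecars: agent table and death-event table as CSV."""
    T, N, _ = truth.agent_positions.shape
    rows = []
    for fi in range(T):
        for ai in range(N):
            x, y, z = truth.agent_positions[fi, ai]
            rows.append(
                {
                    "frame": fi,
                    "time_h": truth.times[fi],
                    "agent_id": ai,
                    "x_um": x,
                    "y_um": y,
                    "z_um": z,
                    "state": int(truth.agent_states[fi, ai]),
                }
            )
    _write_csv(pd.DataFrame(rows), out / "truth_agents.csv")
    _write_csv(
        pd.DataFrame(
            [
                {"cell_id": cid, "time_h": t, "x_um": p[0], "y_um": p[1], "z_um": p[2]}
                for cid, t, p in truth.death_events
            ],
            columns=["cell_id", "time_h", "x_um", "y_um", "z_um"],
        ),
        out / "truth_death_events.csv",
    )
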