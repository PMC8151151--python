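"""Diagnostic figures for pipeline outputs (PNG, headless backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_fits", "plot_profile_heatmap", "plot_coupling"]


def plot_fits(curves, fits, path: str | Path) -> Path:
    """Recruitment curves with their sigmoid fits, one panel per spheroid."""
    path = Path(path)
    n = max(len(curves), 1)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3), squeeze=False)
    fit_by_id = {f.spheroid_id: f for f in fits}
    for ax, c in zip(axes[0], curves):
        ax.plot(c.times, c.values, "o", ms=3, label="measured")
        f = fit_by_id.get(c.spheroid_id)
        if f is not None and np.isfinite(f.tau):
            tt = np.linspace(c.times[0], c.times[-1], 200)
            ax.plot(tt, f.predict(tt), "-",
                    label=f"fit: k={f.k:.2f}/h, tau={f.tau:.1f} h")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("recruitment (a.u.)")
        ax.set_title(f"spheroid {c.spheroid_id}")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_profile_heatmap(profile, path: str | Path) -> Path:
    """Time x radius heat map of a radial profile with the boundary line."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    m = np.ma.masked_invalid(profile.per_time_means)
    im = ax.pcolormesh(profile.bin_centers, profile.times, m, shading="nearest")
    ax.plot(profile.boundary_radius, profile.times, "w--", lw=1,
            label="spheroid boundary")
    ax.set_xlabel("distance from centroid (um)")
    ax.set_ylabel("time (h)")
    ax.set_title(f"spheroid {profile.spheroid_id} radial profile")
    fig.colorbar(im, ax=ax, label="mean intensity (a.u.)")
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_coupling(couplings, path: str | Path) -> Path:
    """Recruitment vs cytotoxicity scatter, colored by time, per spheroid."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for sid, pairs, lag in couplings:
        sc = ax.scatter(pairs[:, 1], pairs[:, 2], c=pairs[:, 0], s=8,
                        label=f"spheroid {sid} (lag {lag:.1f} h)")
    ax.set_xlabel("recruitment (a.u.)")
    ax.set_ylabel("fragmentation fraction")
    if couplings:
        fig.colorbar(sc, ax=ax, label="time (h)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
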