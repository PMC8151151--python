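"""Effector recruitment quantification and sigmoid kinetics.

Recruitment on a spheroid is the mean effector-channel fluorescence inside its
mask minus the image background, estimated as the median intensity over pixels
outside all spheroid masks dilated by a guard band.  Each spheroid's curve is
fitted with the four-parameter sigmoid

    y(t) = a + b * exp(k (t - tau)) / (1 + exp(k (t - tau)))

where ``a`` is the baseline, ``b`` the maximum recruitment amplitude, ``k``
the recruitment rate (1/h) and ``tau`` the recruitment time (delay, h); the
curve passes through a + b/2 exactly at t = tau.  Fitting uses bounded
nonlinear least squares with a multi-start grid over tau and k.

Two cohort-level analyses accompany the fit: the density response (ordinary
least squares of amplitude b against effector density, plus two-sample KS
distances between recruitment-time distributions across densities) and a
spatial clustering control based on the pair-correlation function with a
Monte-Carlo complete-spatial-randomness envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.ndimage import binary_dilation
from scipy.special import expit

from .io import CalibratedStack
from .segmentation import SpheroidTrack

__all__ = [
    "RecruitmentCurve",
    "SigmoidFit",
    "sigmoid_model",
    "measure_recruitment",
    "fit_sigmoid",
    "summarize_recruitment",
    "density_response",
    "clustering_scale",
]


@dataclass
class RecruitmentCurve:
    """Background-subtracted mean effector intensity on one spheroid vs time."""

    spheroid_id: int
    times: np.ndarray  # h, strictly increasing
    values: np.ndarray  # a.u., NaN where the mask was missing at a frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def dropna(self) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(self.values)
        return self.times[ok], self.values[ok]


@dataclass
class SigmoidFit:
    """Fitted sigmoid parameters with diagnostics.

    ``identifiable`` is False when the amplitude is not resolved above the
    residual noise (b < 3 residual sd) or tau falls outside the observation
    span; parameters are still reported.
    """

    spheroid_id: int
    a: float
    b: float
    k: float
    tau: float
    rss: float
    converged: bool
    identifiable: bool
    n_points: int = 0

    def predict(self, t: np.ndarray) -> np.ndarray:
        return sigmoid_model(np.asarray(t, dtype=float), self.a, self.b, self.k, self.tau)


def sigmoid_model(t: np.ndarray, a: float, b: float, k: float, tau: float) -> np.ndarray:
    """y = a + b * e^{k(t-tau)} / (1 + e^{k(t-tau)}); equals a + b/2 at t = tau."""
    return a + b * expit(k * (np.asarray(t, dtype=float) - tau))


def measure_recruitment(
    stack: CalibratedStack,
    tracks: Sequence[SpheroidTrack],
    effector_channel: str = "EFF",
    guard_band_um: float = 20.0,
) -> list[RecruitmentCurve]:
    """Per-spheroid background-subtracted mean effector intensity over time.

    Background per frame is the median intensity outside the union of all
    spheroid masks dilated by ``guard_band_um``.  Frames where a track has no
    mask yield NaN (missing), never zero.
    """
    if not tracks:
        raise ValueError("tracks must be nonempty")
    eff = stack.channel(effector_channel)
    T = stack.n_frames
    guard_px = max(1, int(round(guard_band_um / stack.pixel_size)))
    struct = np.ones((2 * guard_px + 1, 2 * guard_px + 1), dtype=bool)

    backgrounds = np.empty(T)
    for fi in range(T):
        union = np.zeros(stack.frame_shape, dtype=bool)
        for tr in tracks:
            e = tr.entry_at(fi)
            if e is not None:
                union |= e.mask
        outside = ~binary_dilation(union, structure=struct) if union.any() else np.ones_like(union)
        backgrounds[fi] = (
            float(np.median(eff[fi][outside])) if outside.any() else float("nan")
        )

    curves = []
    for tr in tracks:
        vals = np.full(T, np.nan)
        for fi in range(T):
            e = tr.entry_at(fi)
            if e is not None and e.mask.any():
                vals[fi] = float(eff[fi][e.mask].mean()) - backgrounds[fi]
        curves.append(RecruitmentCurve(spheroid_id=tr.id, times=stack.times, values=vals))
    return curves


_K_GRID = (0.05, 0.2, 1.0)


def fit_sigmoid(curve: RecruitmentCurve) -> SigmoidFit:
    """Fit the four-parameter sigmoid to one recruitment curve.

    Bounded least squares (a free, b >= 0, k >= 0, tau within one observation
    span of the sampled window), multi-started over every observed time as a
    tau seed and k in {0.05, 0.2, 1} / h.  Best residual sum of squares wins;
    ties go to the smaller k, then the smaller tau.  A flat (zero-variance)
    curve returns a degenerate, non-identifiable fit rather than raising.
    """
    t, y = curve.dropna()
    if len(t) < 4:
        raise ValueError(f"need >= 4 finite points to fit, have {len(t)}")
    span = float(t[-1] - t[0])
    if np.ptp(y) == 0.0:
        return SigmoidFit(
            spheroid_id=curve.spheroid_id,
            a=float(y[0]), b=0.0, k=float("nan"), tau=float("nan"),
            rss=0.0, converged=True, identifiable=False, n_points=len(t),
        )

    lo = np.array([y.min() - np.ptp(y), 0.0, 0.0, t[0] - span])
    hi = np.array([y.max() + np.ptp(y), 4.0 * np.ptp(y), 50.0, t[-1] + span])

    def resid(p: np.ndarray) -> np.ndarray:
        return sigmoid_model(t, *p) - y

    best = None
    a0 = float(y[: max(1, len(y) // 4)].mean())
    b0 = max(float(y.max() - a0), 1e-6)
    # tau seeds: every observed time for short series, evenly subsampled otherwise
    tau_seeds = t if len(t) <= 16 else t[np.linspace(0, len(t) - 1, 12).round().astype(int)]
    for tau0 in tau_seeds:
        for k0 in _K_GRID:
            p0 = np.clip(np.array([a0, b0, k0, tau0]), lo, hi)
            try:
                sol = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            rss = float(2.0 * sol.cost)
            key = (round(rss, 12), sol.x[2], sol.x[3])
            if best is None or key < best[0]:
                best = (key, sol, rss)
    if best is None:
        return SigmoidFit(
            spheroid_id=curve.spheroid_id,
            a=float(y.mean()), b=0.0, k=float("nan"), tau=float("nan"),
            rss=float(np.sum((y - y.mean()) ** 2)),
            converged=False, identifiable=False, n_points=len(t),
        )
    _, sol, rss = best
    a, b, k, tau = (float(v) for v in sol.x)
    resid_sd = math.sqrt(rss / max(len(t) - 4, 1))
    identifiable = (b >= 3.0 * resid_sd) and (t[0] <= tau <= t[-1])
    return SigmoidFit(
        spheroid_id=curve.spheroid_id,
        a=a, b=b, k=k, tau=tau, rss=rss,
        converged=bool(sol.success), identifiable=identifiable, n_points=len(t),
    )


def summarize_recruitment(
    fits: Sequence[SigmoidFit], groups: Sequence[object] | None = None
) -> dict:
    """Per-group sample mean and sd of tau, k and b over identifiable fits.

    Groups with fewer than two identifiable fits are omitted (with a count of
    exclusions reported).  Returns {group: {"tau": (mean, sd), "k": ...,
    "b": ..., "n": n_used, "n_excluded": n_dropped}}.
    """
    if groups is None:
        groups = ["all"] * len(fits)
    if len(groups) != len(fits):
        raise ValueError("groups must parallel fits")
    out: dict = {}
    for g in dict.fromkeys(groups):  # preserve order
        sel = [f for f, gg in zip(fits, groups) if gg == g]
        ok = [f for f in sel if f.identifiable]
        n_exc = len(sel) - len(ok)
        if len(ok) < 2:
            import warnings

            warnings.warn(
                f"group {g!r} has {len(ok)} identifiable fits (<2); omitted", stacklevel=2
            )
            continue
        entry = {"n": len(ok), "n_excluded": n_exc}
        for name in ("tau", "k", "b"):
            vals = np.array([getattr(f, name) for f in ok], dtype=float)
            entry[name] = (float(vals.mean()), float(vals.std(ddof=1)))
        out[g] = entry
    return out


def density_response(fits_by_density: Mapping[float, Sequence[SigmoidFit]]) -> dict:
    """Amplitude-vs-density line and recruitment-time distribution comparison.

    Ordinary least squares of the per-density mean fitted amplitude b on
    effector density (slope, intercept, R^2) — the form in which direct
    proportionality between recruitment and density is reported — plus the
    per-fit regression R^2 (``r2_fits``) and pairwise two-sample
    Kolmogorov-Smirnov distances between the tau samples (identifiable fits)
    of each density.  Requires >= 3 densities with >= 3 fits each.
    """
    densities = sorted(fits_by_density)
    if len(densities) < 3:
        raise ValueError(f"need >= 3 distinct densities, have {len(densities)}")
    for d in densities:
        if len(fits_by_density[d]) < 3:
            raise ValueError(f"density {d} has < 3 fits")
    xs, ys = [], []
    for d in densities:
        for f in fits_by_density[d]:
            xs.append(d)
            ys.append(f.b)
    lr_fits = stats.linregress(xs, ys)
    mean_b = [float(np.mean([f.b for f in fits_by_density[d]])) for d in densities]
    lr = stats.linregress(densities, mean_b)
    ks: dict[tuple[float, float], float] = {}

    def taus(d: float) -> np.ndarray:
        t = np.array([f.tau for f in fits_by_density[d] if f.identifiable])
        if len(t) < 2:  # fall back to every finite tau if too few identifiable
            t = np.array([f.tau for f in fits_by_density[d] if np.isfinite(f.tau)])
        return t

    for i, d1 in enumerate(densities):
        for d2 in densities[i + 1 :]:
            ks[(d1, d2)] = float(stats.ks_2samp(taus(d1), taus(d2)).statistic)
    return {
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
        "r2": float(lr.rvalue**2),
        "r2_fits": float(lr_fits.rvalue**2),
        "mean_b": dict(zip(densities, mean_b)),
        "ks_tau": ks,
        "max_ks_tau": max(ks.values()) if ks else 0.0,
    }


def clustering_scale(
    points: np.ndarray,
    window: tuple[float, float],
    n_null: int = 99,
    rng_seed: int = 0,
    bin_width: float = 5.0,
    r_max: float | None = None,
) -> tuple[float, dict]:
    """Characteristic clustering length of a 2D point pattern (um).

    Computes the pair-correlation g(r) on ``bin_width`` bins and compares it
    against a pointwise 95% Monte-Carlo envelope from ``n_null`` uniform
    (complete spatial randomness) resamplings of the same intensity in the
    same window.  The clustering length is the outer edge of the contiguous
    run of significant bins starting at r = 0 (excess correlation at short
    range is what defines a clustered pattern; an isolated significant bin at
    large r is the expected 5% false-positive rate of the pointwise
    envelope), or 0 when the first bin is not significant.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of um coordinates")
    n = len(pts)
    if n < 30:
        raise ValueError(f"need >= 30 points for a stable statistic, have {n}")
    wx, wy = window
    if r_max is None:
        r_max = min(wx, wy) / 4.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def pcf(p: np.ndarray) -> np.ndarray:
        d = np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(-1))
        iu = np.triu_indices(len(p), k=1)
        counts, _ = np.histogram(d[iu], bins=edges)
        lam = len(p) / (wx * wy)
        # expected pair count in each annulus under CSR (ignoring edge effects,
        # which cancel against the null simulated in the identical window)
        shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        expected = 0.5 * len(p) * lam * shell
        return counts / np.maximum(expected, 1e-12)

    g_obs = pcf(pts)
    rng = np.random.default_rng(rng_seed)
    g_null = np.empty((n_null, len(centers)))
    for i in range(n_null):
        q = rng.random((n, 2)) * np.array([wx, wy])
        g_null[i] = pcf(q)
    env = np.quantile(g_null, 0.95, axis=0)
    exceed = g_obs > env
    if exceed[0]:
        run_end = int(np.argmin(exceed)) if not exceed.all() else len(exceed)
        length = float(edges[run_end])
    else:
        length = 0.0
    return length, {"r": centers, "g": g_obs, "envelope_95": env, "exceed": exceed}
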