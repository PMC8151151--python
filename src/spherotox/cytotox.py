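"""Cytotoxicity scoring from nuclear-channel images.

Nuclear fragmentation is the apoptosis proxy: dying tumor cells collapse into
a few small bright apoptotic bodies, so the fraction of nuclear signal that
sits in small punctate objects tracks killing.  Two scorers share one output
(a fragmentation fraction in [0, 1]):

* ``fragmentation_highres`` — resolves individual nuclei; decomposes the
  in-mask nuclear signal into connected bright objects and classifies objects
  with equivalent diameter below a cutoff (default: half the intact-nucleus
  diameter) and high solidity as fragments; returns fragmented area over
  total nuclear area.
* ``fragmentation_lowres`` — for magnifications too coarse to resolve nuclei;
  unsharp-mask sharpening enhances the punctate apoptotic-body signal, a
  robust median + z*MAD threshold in standardized units picks up positive
  pixels, and the positive area over the spheroid mask area is the proxy.

Both thresholds are defined in standardized (data-relative) units, so the
scores are invariant to multiplicative intensity rescaling.

Because the fragment signal itself decays (timescale ~24 h), both scorers
measure the *instantaneous* fragmented area, not cumulative deaths.

``specific_lysis`` converts treated vs control fragmentation into the
control-normalized killing surrogate (fully fragmented spheroid = 100%), and
``coupling_curve`` pairs a recruitment curve with a fragmentation series and
reports the lag between their half-maximum crossings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .kinetics import RecruitmentCurve

__all__ = [
    "FragmentationParams",
    "FragmentationSeries",
    "LysisSeries",
    "fragmentation_highres",
    "fragmentation_lowres",
    "specific_lysis",
    "coupling_curve",
    "half_crossing_time",
]


@dataclass(frozen=True)
class FragmentationParams:
    """Shared scorer settings (all lengths in um unless noted).

    ``nucleus_diameter_um`` is the expected intact-nucleus diameter; the
    high-res fragment-size cutoff defaults to half of it.  ``z_thresh`` is
    the low-res threshold in robust standardized units (lower-side MAD
    scale) above the median of the sharpened in-mask values.
    ``min_nuclear_area_px`` is the floor on total nuclear
    area below which the high-res score is reported missing.
    """

    pixel_size: float = 4.0
    nucleus_diameter_um: float = 10.0
    fragment_cutoff_um: float | None = None  # default: nucleus_diameter / 2
    min_solidity: float = 0.8
    z_thresh: float = 3.0
    min_nuclear_area_px: int = 20

    @property
    def cutoff_um(self) -> float:
        return (
            self.fragment_cutoff_um
            if self.fragment_cutoff_um is not None
            else self.nucleus_diameter_um / 2.0
        )


@dataclass
class FragmentationSeries:
    """Fraction of fragmented nuclear signal on one spheroid vs time."""

    spheroid_id: int
    times: np.ndarray  # h
    frag_fraction: np.ndarray  # in [0, 1], NaN = missing
    method: str = "lowres_threshold"  # or "highres_region"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frag_fraction = np.asarray(self.frag_fraction, dtype=float)
        if self.times.shape != self.frag_fraction.shape:
            raise ValueError("times and frag_fraction must have equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        finite = self.frag_fraction[np.isfinite(self.frag_fraction)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("frag_fraction must lie in [0, 1]")


@dataclass
class LysisSeries:
    """Control-normalized specific-lysis surrogate (%) vs time."""

    times: np.ndarray
    specific_lysis: np.ndarray  # percent in [0, 100], NaN = undefined

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.specific_lysis = np.asarray(self.specific_lysis, dtype=float)
        finite = self.specific_lysis[np.isfinite(self.specific_lysis)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 100 + 1e-9):
            raise ValueError("specific_lysis must lie in [0, 100]")


def fragmentation_highres(
    nuclear_frame: np.ndarray,
    spheroid_mask: np.ndarray,
    params: FragmentationParams | None = None,
) -> float:
    """High-resolution fragmentation fraction: fragmented / total nuclear area.

    Nuclear-signal pixels inside the mask are segmented by Otsu thresholding
    in normalized units, decomposed into connected objects, and each object
    is classed as a fragment when its equivalent diameter is below the
    fragment-size cutoff and its solidity exceeds ``min_solidity`` (compact
    bright dots), else as intact.  Returns NaN (missing) on an empty mask,
    an all-dark frame, or when total nuclear area is below the floor.
    """
    params = params or FragmentationParams()
    frame = np.asarray(nuclear_frame, dtype=float)
    mask = np.asarray(spheroid_mask, dtype=bool)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask must share shape")
    if not mask.any():
        return float("nan")
    inside = frame[mask]
    peak = inside.max()
    if peak <= 0:
        return float("nan")
    norm = frame / peak  # multiplicative-rescaling invariance
    vals = norm[mask]
    if np.ptp(vals) <= 1e-12:
        return float("nan")
    thr = threshold_otsu(vals)
    fg = (norm > thr) & mask
    if fg.sum() < params.min_nuclear_area_px:
        return float("nan")

    cutoff_px = params.cutoff_um / params.pixel_size
    lab = cc_label(fg, connectivity=2)
    frag_area = 0.0
    total_area = 0.0
    for p in regionprops(lab):
        total_area += p.area
        if p.equivalent_diameter_area < cutoff_px and p.solidity >= params.min_solidity:
            frag_area += p.area
    return float(frag_area / total_area)


def fragmentation_lowres(
    nuclear_frame: np.ndarray,
    spheroid_mask: np.ndarray,
    params: FragmentationParams | None = None,
) -> float:
    """Low-resolution fragmentation proxy: positive-pixel area / mask area.

    Unsharp masking (subtract a Gaussian blur with sigma equal to the
    intact-nucleus radius, gain 1) enhances punctate apoptotic-body signal;
    pixels whose sharpened value exceeds median + z * (lower-side MAD scale)
    of in-mask sharpened values count as positive.  Bounded in [0, 1] by
    construction; returns NaN on an empty mask.
    """
    params = params or FragmentationParams()
    frame = np.asarray(nuclear_frame, dtype=float)
    mask = np.asarray(spheroid_mask, dtype=bool)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask must share shape")
    if not mask.any():
        return float("nan")
    sigma_px = (params.nucleus_diameter_um / 2.0) / params.pixel_size
    sharp = frame - ndimage.gaussian_filter(frame, sigma_px)
    vals = sharp[mask]
    # standardized units from the lower half of the sharpened distribution:
    # apoptotic bodies only add positive residuals, so the negative side stays
    # an uncontaminated estimate of the background scale and the positive area
    # can grow with fragment load instead of being renormalized away
    med = np.median(vals)
    neg = vals[vals < med]
    scale = 1.4826 * float(np.median(med - neg)) if len(neg) else float(vals.std())
    if scale <= 0:
        scale = float(vals.std())
    if scale <= 0:
        return 0.0
    thr = med + params.z_thresh * scale
    return float(((sharp > thr) & mask).sum() / mask.sum())


def fragmentation_series(
    nuclear_frames: np.ndarray,
    masks: Sequence[np.ndarray],
    times: np.ndarray,
    spheroid_id: int = 1,
    method: str = "lowres_threshold",
    params: FragmentationParams | None = None,
) -> FragmentationSeries:
    """Score every frame of one spheroid with the chosen method."""
    scorer = fragmentation_highres if method == "highres_region" else fragmentation_lowres
    vals = np.array(
        [scorer(f, m, params) for f, m in zip(nuclear_frames, masks)], dtype=float
    )
    return FragmentationSeries(
        spheroid_id=spheroid_id, times=np.asarray(times, float),
        frag_fraction=vals, method=method,
    )


def specific_lysis(
    treated: FragmentationSeries, control: FragmentationSeries
) -> LysisSeries:
    """Control-normalized specific-lysis surrogate.

    L(t) = 100 * clamp[(F_T(t) - F_C(t)) / (1 - F_C(t)), 0, 1], under the
    convention that a fully fragmented spheroid corresponds to 100% lysis.
    The control is linearly interpolated onto the treated time grid; times
    where F_C = 1 are reported missing.  Disjoint time ranges are an error.
    """
    tt, ft = treated.times, treated.frag_fraction
    ok = np.isfinite(control.frag_fraction)
    tc, fc_raw = control.times[ok], control.frag_fraction[ok]
    if len(tc) == 0 or tt.max() < tc.min() or tt.min() > tc.max():
        raise ValueError("treated and control time ranges do not overlap")
    fc = np.interp(tt, tc, fc_raw)
    with np.errstate(invalid="ignore", divide="ignore"):
        L = 100.0 * np.clip((ft - fc) / (1.0 - fc), 0.0, 1.0)
    L[np.isclose(fc, 1.0)] = np.nan
    L[~np.isfinite(ft)] = np.nan
    return LysisSeries(times=tt.copy(), specific_lysis=L)


def half_crossing_time(times: np.ndarray, values: np.ndarray) -> float:
    """First time a series crosses half of its own maximum rise.

    The series is baseline-corrected by its initial value first, so a nonzero
    noise floor (e.g. the false-positive floor of a fragmentation scorer)
    does not trigger the landmark at t=0.  Linear interpolation between
    samples; NaN when the series never rises to half its maximum or is
    degenerate (non-positive maximum rise).
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    ok = np.isfinite(v)
    t, v = t[ok], v[ok]
    if len(v) == 0:
        return float("nan")
    v = v - v[0]
    vmax = v.max()
    if vmax <= 0:
        return float("nan")
    half = vmax / 2.0
    if v[0] >= half:
        return float(t[0])
    above = v >= half
    if not above.any():
        return float("nan")
    i = int(above.argmax())
    t0, t1, v0, v1 = t[i - 1], t[i], v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (half - v0) * (t1 - t0) / (v1 - v0))


def coupling_curve(
    recruitment: RecruitmentCurve, fragmentation: FragmentationSeries
) -> tuple[np.ndarray, float]:
    """Pair recruitment with cytotoxicity on a common grid; report the lag.

    Both series are linearly interpolated onto the union of their time points
    restricted to the overlap window.  Returns an (n, 3) array of
    (time, recruitment, frag_fraction) rows ordered by time, and the lag
    t_half(fragmentation) - t_half(recruitment) in hours (NaN when either
    series never reaches half its maximum).
    """
    tr, vr = recruitment.dropna()
    tf = fragmentation.times[np.isfinite(fragmentation.frag_fraction)]
    vf = fragmentation.frag_fraction[np.isfinite(fragmentation.frag_fraction)]
    if len(tr) < 4 or len(tf) < 4:
        raise ValueError("both series need >= 4 finite points")
    lo, hi = max(tr.min(), tf.min()), min(tr.max(), tf.max())
    if lo >= hi:
        raise ValueError("recruitment and fragmentation time ranges do not overlap")
    grid = np.unique(np.concatenate([tr, tf]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    ri = np.interp(grid, tr, vr)
    fi = np.interp(grid, tf, vf)
    pairs = np.column_stack([grid, ri, fi])
    lag = half_crossing_time(tf, vf) - half_crossing_time(tr, vr)
    return pairs, float(lag)
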