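"""Spheroid segmentation from brightfield, frame-to-frame tracking, size stats.

Spheroids appear in brightfield as dark, strongly textured disks on a bright,
smooth background, so local intensity variance separates them robustly without
any trained model.  Two interchangeable backends share one output contract
(an integer label map, background 0):

* ``segment_spheroids`` — deterministic texture segmentation: local-variance
  map, Otsu threshold, morphological closing, hole filling, minimum-area
  filter.  The default backend.
* :class:`PixelClassifier` — a trainable pixel classifier (random forest on a
  fixed feature bank: Gaussian-smoothed intensity, gradient magnitude and
  local variance at three scales) fit from labeled scribbles, mirroring the
  interactive pixel-classification workflow common in this field.

Tracking is greedy nearest-centroid linking; spheroids are essentially
stationary in gel, so a disappearing object signals a segmentation failure
and deliberately terminates its track (no gap closing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "SegmentationParams",
    "segment_spheroids",
    "PixelClassifier",
    "SpheroidTrack",
    "track_labels",
    "size_statistics",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Settings for brightfield spheroid segmentation.

    ``min_area_um2`` defaults to the area of a 50 um-diameter disk: smaller
    objects are debris, not spheroids.
    """

    pixel_size: float = 4.0  # um / px
    min_area_um2: float = float(np.pi * 25.0**2)
    variance_window_um: float = 12.0
    closing_radius_um: float = 8.0

    @property
    def min_area_px(self) -> float:
        return self.min_area_um2 / self.pixel_size**2


def _local_variance(frame: np.ndarray, size: int) -> np.ndarray:
    m = ndimage.uniform_filter(frame, size)
    m2 = ndimage.uniform_filter(frame * frame, size)
    return np.maximum(m2 - m * m, 0.0)


def _cleanup(fg: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Morphological closing, hole filling and minimum-area filtering."""
    rad = max(1, int(round(params.closing_radius_um / params.pixel_size)))
    fg = ndimage.binary_closing(fg, structure=disk(rad))
    fg = ndimage.binary_fill_holes(fg)
    lab = cc_label(fg, connectivity=2)
    if lab.max():
        areas = np.bincount(lab.ravel())
        small = np.flatnonzero(areas < params.min_area_px)
        fg = fg & ~np.isin(lab, small[small > 0])
    return fg


def segment_spheroids(
    brightfield_frame: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Segment spheroids in one brightfield frame; returns an integer label map.

    Deterministic texture backend: threshold the local-variance map (Otsu),
    close, fill holes, drop objects below the minimum area.  A frame with no
    texture contrast (e.g. uniform intensity) yields an empty label map.
    """
    frame = np.asarray(brightfield_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2D single-channel frame, got shape {frame.shape}")
    params = params or SegmentationParams()

    uniq = np.unique(frame)
    if len(uniq) == 1:
        return np.zeros(frame.shape, dtype=np.int32)
    if len(uniq) == 2:
        # an already-binary frame is a mask rendering: label the minority class
        # directly (no morphology) so segmentation is idempotent on its output
        counts = [(frame == u).sum() for u in uniq]
        fg = frame == uniq[int(np.argmin(counts))]
        lab = cc_label(fg, connectivity=2)
        areas = np.bincount(lab.ravel())
        small = np.flatnonzero(areas < params.min_area_px)
        fg &= ~np.isin(lab, small[small > 0])
        return cc_label(fg, connectivity=2).astype(np.int32)

    win = max(3, int(round(params.variance_window_um / params.pixel_size)) | 1)
    # local SD, then a second smoothing pass so the textured interior becomes a
    # homogeneous plateau that Otsu separates cleanly from the flat background
    sd = ndimage.uniform_filter(np.sqrt(_local_variance(frame, win)), win)
    if sd.max() < 1e-6 or sd.max() - sd.min() <= 0:
        return np.zeros(frame.shape, dtype=np.int32)
    thr = threshold_otsu(sd)
    fg = sd > thr
    if fg.all() or not fg.any():
        return np.zeros(frame.shape, dtype=np.int32)
    # Otsu always returns a split; require genuine texture contrast before trusting it
    if sd[fg].mean() < 2.0 * sd[~fg].mean():
        return np.zeros(frame.shape, dtype=np.int32)
    fg = _cleanup(fg, params)
    return cc_label(fg, connectivity=2).astype(np.int32)


class PixelClassifier:
    """Trainable pixel classifier on a fixed feature bank.

    Features per pixel: Gaussian-smoothed intensity, gradient magnitude and
    local variance, each at three scales (default 1, 2.5 and 6 px).  Trained
    from scribble annotations (0 = unlabeled, 1 = background, 2 = spheroid)
    and applied to whole frames; output passes through the same morphological
    cleanup as the deterministic backend.
    """

    SCALES = (1.0, 2.5, 6.0)

    def __init__(self, params: SegmentationParams | None = None, random_state: int = 0):
        self.params = params or SegmentationParams()
        self._clf = RandomForestClassifier(
            n_estimators=50, max_depth=12, random_state=random_state, n_jobs=1
        )
        self._fitted = False

    def _features(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=float)
        feats = []
        for s in self.SCALES:
            sm = ndimage.gaussian_filter(frame, s)
            gx = ndimage.sobel(sm, axis=0)
            gy = ndimage.sobel(sm, axis=1)
            feats.append(sm)
            feats.append(np.hypot(gx, gy))
            feats.append(_local_variance(frame, max(3, int(2 * s) | 1)))
        return np.stack([f.ravel() for f in feats], axis=1)

    def fit(self, frame: np.ndarray, scribbles: np.ndarray) -> "PixelClassifier":
        scribbles = np.asarray(scribbles)
        if scribbles.shape != np.asarray(frame).shape:
            raise ValueError("scribbles must share the frame's shape")
        X = self._features(frame)
        y = scribbles.ravel()
        sel = y > 0
        if not sel.any() or len(np.unique(y[sel])) < 2:
            raise ValueError("scribbles must label both background (1) and spheroid (2)")
        self._clf.fit(X[sel], y[sel])
        self._fitted = True
        return self

    def segment(self, frame: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("classifier not fitted; call fit() first")
        frame = np.asarray(frame, dtype=float)
        if frame.ndim != 2:
            raise ValueError("expected a 2D frame")
        pred = self._clf.predict(self._features(frame)).reshape(frame.shape)
        fg = _cleanup(pred == 2, self.params)
        return cc_label(fg, connectivity=2).astype(np.int32)


@dataclass
class TrackEntry:
    frame: int
    mask: np.ndarray  # boolean
    centroid: tuple[float, float]  # (row, col), px
    area_px: float

    def area_um2(self, pixel_size: float) -> float:
        return self.area_px * pixel_size**2

    def equivalent_diameter_um(self, pixel_size: float) -> float:
        return 2.0 * np.sqrt(self.area_px / np.pi) * pixel_size


@dataclass
class SpheroidTrack:
    """One spheroid followed through time (frame-indexed masks and centroids)."""

    id: int
    pixel_size: float
    entries: list[TrackEntry] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [e.frame for e in self.entries]

    def entry_at(self, frame: int) -> TrackEntry | None:
        for e in self.entries:
            if e.frame == frame:
                return e
        return None

    def equivalent_diameters_um(self) -> np.ndarray:
        return np.array([e.equivalent_diameter_um(self.pixel_size) for e in self.entries])


def track_labels(
    per_frame_labels: Sequence[np.ndarray],
    max_link_distance: float,
    pixel_size: float = 1.0,
) -> list[SpheroidTrack]:
    """Link label maps across frames by greedy nearest-centroid matching.

    ``max_link_distance`` is in um.  A link farther than that starts a new
    track; an object missing in a frame terminates its track (no gap closing).
    """
    shapes = {lm.shape for lm in per_frame_labels}
    if len(shapes) > 1:
        raise ValueError(f"label maps must share one shape, got {sorted(shapes)}")

    tracks: list[SpheroidTrack] = []
    active: dict[int, SpheroidTrack] = {}  # track id -> track, alive last frame
    next_id = 1

    for fi, lm in enumerate(per_frame_labels):
        props = regionprops(lm)
        objs = [
            TrackEntry(
                frame=fi,
                mask=lm == p.label,
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                area_px=float(p.area),
            )
            for p in props
        ]
        new_active: dict[int, SpheroidTrack] = {}
        # greedy matching: smallest centroid distance first
        pairs = []
        for tid, tr in active.items():
            last = tr.entries[-1].centroid
            for oi, ob in enumerate(objs):
                d = np.hypot(last[0] - ob.centroid[0], last[1] - ob.centroid[1]) * pixel_size
                if d <= max_link_distance:
                    pairs.append((d, tid, oi))
        used_t: set[int] = set()
        used_o: set[int] = set()
        for d, tid, oi in sorted(pairs, key=lambda x: x[0]):
            if tid in used_t or oi in used_o:
                continue
            active[tid].entries.append(objs[oi])
            new_active[tid] = active[tid]
            used_t.add(tid)
            used_o.add(oi)
        for oi, ob in enumerate(objs):
            if oi in used_o:
                continue
            tr = SpheroidTrack(id=next_id, pixel_size=pixel_size, entries=[ob])
            next_id += 1
            tracks.append(tr)
            new_active[tr.id] = tr
        active = new_active

    return tracks


def size_statistics(
    tracks: Sequence[SpheroidTrack], frame: int = 0
) -> tuple[float, float, float]:
    """Cohort size statistics at one frame: (mean diameter um, sd, dispersion %).

    Relative dispersion is 100 * sample sd / mean of equivalent diameters, the
    standard uniformity figure for spheroid batches.
    """
    diams = []
    for tr in tracks:
        e = tr.entry_at(frame)
        if e is not None:
            diams.append(e.equivalent_diameter_um(tr.pixel_size))
    if len(diams) < 2:
        raise ValueError(
            f"size dispersion needs >= 2 spheroids at frame {frame}, found {len(diams)}"
        )
    diams = np.asarray(diams)
    mean = float(diams.mean())
    sd = float(diams.std(ddof=1))
    return mean, sd, 100.0 * sd / mean
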