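"""Detection and linking of particles in reconstructed volume series.

The observation geometry is a 4D intensity series (time, z, y, x) such
as a holographic-microscopy reconstruction stack.  Particles are found
by maximum-intensity projecting each time point — along z for lateral
(XY) motion, along y for axial (XZ) motion — thresholding the projected
image, and taking intensity-weighted centroids of connected components.
Detections are joined frame-to-frame by greedy nearest-neighbour linking
with optional gap closing.

Lateral drift common to all particles (stage or bulk-fluid motion) can
be estimated as the ensemble-mean per-frame displacement and subtracted;
axial drift is the sedimentation signal and is deliberately never
subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "Track",
    "Detection",
    "project_xyt",
    "project_xzt",
    "detect_particles",
    "detect_series",
    "link_detections",
    "estimate_drift",
    "subtract_drift",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """Time-ordered positions of one particle.

    Coordinates are SI metres; ``z`` increases downward so that sinking
    produces a positive axial velocity.  Planar tracks (e.g. from an XZ
    projection) may leave ``y`` as ``None``; purely lateral tracks may
    leave ``z`` as ``None``.
    """

    track_id: int
    frames: np.ndarray
    dt: float
    x: np.ndarray
    y: np.ndarray | None = None
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"frame interval must be > 0 s, got {self.dt}")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")
        for name in ("x", "y", "z"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != self.frames.shape:
                raise ValueError(
                    f"track coordinate {name} has {arr.shape}, frames "
                    f"{self.frames.shape}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def t(self) -> np.ndarray:
        """Time stamps in seconds."""
        return self.frames * self.dt


@dataclass(frozen=True)
class Detection:
    """A candidate particle in one projected frame: in-plane coordinates
    (m; ``(x, y)`` for XY projections, ``(x, z)`` for XZ projections,
    stored as ``u``/``v``) and total intensity weight."""

    frame: int
    u: float
    v: float
    weight: float


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------

def _check_volumes(volumes: np.ndarray) -> np.ndarray:
    volumes = np.asarray(volumes)
    if volumes.ndim != 4 or any(s == 0 for s in volumes.shape):
        raise ValueError(
            f"expected non-empty (t, z, y, x) volume series, got shape "
            f"{volumes.shape}")
    return volumes


def project_xyt(volumes: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along z: (t, z, y, x) -> (t, y, x)."""
    return _check_volumes(volumes).max(axis=1)


def project_xzt(volumes: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along y: (t, z, y, x) -> (t, z, x)."""
    return _check_volumes(volumes).max(axis=2)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_particles(image: np.ndarray, pixel_size: tuple[float, float],
                     frame: int = 0,
                     threshold: str | float = "otsu",
                     min_area: int = 1) -> list[Detection]:
    """Detect bright spots in one projected frame.

    The image is thresholded (Otsu by default, or an absolute intensity
    if a number is given), connected components of the binary mask are
    labelled, and each component's background-subtracted
    intensity-weighted centroid is returned in metres.  ``pixel_size``
    is ``(row, col)`` metre-per-pixel, i.e. ``(dy, dx)`` for an XY
    projection or ``(dz, dx)`` for an XZ projection.  A blank (constant)
    frame yields no detections.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected 2D image, got shape {image.shape}")
    lo = float(image.min())
    if image.max() == lo:
        return []
    if threshold == "otsu":
        thr = float(threshold_otsu(image))
    else:
        thr = float(threshold)
    mask = image > thr
    if not mask.any():
        return []
    labels = cc_label(mask)
    # weight centroids by intensity above the local floor, so the flat
    # background inside large components does not pull the centroid
    out: list[Detection] = []
    for prop in regionprops(labels, intensity_image=image - lo):
        if prop.area < min_area:
            continue
        r_c, c_c = prop.centroid_weighted
        out.append(Detection(frame=frame,
                             u=c_c * pixel_size[1],
                             v=r_c * pixel_size[0],
                             weight=float(prop.image_intensity.sum())))
    return out


def detect_series(images: np.ndarray, pixel_size: tuple[float, float],
                  threshold: str | float = "otsu",
                  min_area: int = 1) -> list[list[Detection]]:
    """Run :func:`detect_particles` on every frame of a (t, rows, cols)
    projected series."""
    images = np.asarray(images)
    if images.ndim != 3:
        raise ValueError(f"expected (t, rows, cols) series, got {images.shape}")
    return [detect_particles(img, pixel_size, frame=i, threshold=threshold,
                             min_area=min_area)
            for i, img in enumerate(images)]


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def link_detections(frames: list[list[Detection]], max_disp: float,
                    dt: float, gap_max: int = 2,
                    plane: str = "xy") -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Candidate (track-end, detection) pairs within ``max_disp`` are
    accepted in order of increasing distance (ties broken by lowest track
    id); unmatched detections start new tracks; a track may skip up to
    ``gap_max`` frames before being retired.  ``plane`` selects how the
    planar coordinates map onto :class:`Track` axes: ``"xy"`` fills
    (x, y), ``"xz"`` fills (x, z).

    Greedy matching suits the sparse fields this pipeline targets (tens
    of particles per ~350 µm field); globally optimal assignment is used
    only as a test oracle.
    """
    if max_disp <= 0:
        raise ValueError(f"max_disp must be > 0 m, got {max_disp}")
    if plane not in ("xy", "xz"):
        raise ValueError(f"plane must be 'xy' or 'xz', got {plane!r}")

    # active track state: id -> (frames list, u list, v list, last_frame)
    active: dict[int, list] = {}
    finished: list[list] = []
    next_id = 0

    for f_idx, dets in enumerate(frames):
        # retire stale tracks
        for tid in [t for t, st in active.items()
                    if f_idx - st[3] > gap_max + 1]:
            finished.append(active.pop(tid))
        # candidate pairs sorted by (distance, track id, detection index)
        pairs = []
        for tid, st in active.items():
            for d_idx, det in enumerate(dets):
                dist = float(np.hypot(det.u - st[1][-1], det.v - st[2][-1]))
                if dist <= max_disp:
                    pairs.append((dist, tid, d_idx))
        pairs.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, tid, d_idx in pairs:
            if tid in used_tracks or d_idx in used_dets:
                continue
            st = active[tid]
            st[0].append(f_idx)
            st[1].append(dets[d_idx].u)
            st[2].append(dets[d_idx].v)
            st[3] = f_idx
            used_tracks.add(tid)
            used_dets.add(d_idx)
        for d_idx, det in enumerate(dets):
            if d_idx in used_dets:
                continue
            active[next_id] = [[f_idx], [det.u], [det.v], f_idx]
            next_id += 1
    finished.extend(active.values())

    tracks = []
    for tid, st in enumerate(sorted(finished, key=lambda s: (s[0][0], s[1][0]))):
        frames_arr = np.array(st[0], dtype=int)
        u = np.array(st[1])
        v = np.array(st[2])
        if plane == "xy":
            tracks.append(Track(tid, frames_arr, dt, x=u, y=v, z=None))
        else:
            tracks.append(Track(tid, frames_arr, dt, x=u, y=None, z=v))
    return tracks


# ---------------------------------------------------------------------------
# Drift
# ---------------------------------------------------------------------------

def estimate_drift(tracks: list[Track]) -> np.ndarray:
    """Ensemble lateral drift per frame interval.

    Returns an (n_frames - 1, 2) array of the mean (dx, dy) displacement
    from frame f to f+1 over all tracks present in both frames; frame
    intervals with no concurrent track get zero drift.  With a single
    short track the drift is statistically meaningless: a warning is
    emitted and zeros are returned.
    """
    if not tracks:
        raise ValueError("need at least one track to estimate drift")
    n_frames = int(max(tr.frames.max() for tr in tracks)) + 1
    sums = np.zeros((max(n_frames - 1, 1), 2))
    counts = np.zeros(max(n_frames - 1, 1), dtype=int)
    for tr in tracks:
        if tr.y is None:
            continue
        consecutive = np.flatnonzero(np.diff(tr.frames) == 1)
        for i in consecutive:
            f = tr.frames[i]
            sums[f, 0] += tr.x[i + 1] - tr.x[i]
            sums[f, 1] += tr.y[i + 1] - tr.y[i]
            counts[f] += 1
    if counts.sum() == 0 or (len(tracks) == 1 and len(tracks[0]) < 3):
        warnings.warn("drift poorly defined (single very short track); "
                      "returning zeros", stacklevel=2)
        return np.zeros_like(sums)
    drift = np.zeros_like(sums)
    has = counts > 0
    drift[has] = sums[has] / counts[has, None]
    return drift


def subtract_drift(tracks: list[Track], drift: np.ndarray) -> list[Track]:
    """Remove the cumulative lateral drift from each track.

    The cumulative drift trajectory is anchored at frame 0; subtracting
    it leaves the ensemble-mean per-frame lateral displacement at zero.
    Axial (z) positions are never altered — axial drift is the
    sedimentation signal.
    """
    drift = np.asarray(drift, dtype=float)
    cum = np.vstack([np.zeros(2), np.cumsum(drift, axis=0)])
    out = []
    for tr in tracks:
        idx = np.clip(tr.frames, 0, len(cum) - 1)
        out.append(Track(
            tr.track_id, tr.frames.copy(), tr.dt,
            x=tr.x - cum[idx, 0],
            y=None if tr.y is None else tr.y - cum[idx, 1],
            z=None if tr.z is None else tr.z.copy()))
    return out
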