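"""Quantitative-phase dry-mass segmentation, tracking and motion metrics.

A phase-shift stack (optical path difference per pixel) is converted to dry
mass through the specific refractive increment, cells are segmented with a
tiled local-Otsu threshold, linked over time by greedy nearest-neighbour
assignment, and each track yields per-interval net displacement, percent
mass fluctuation (internal mass redistribution after centroid alignment)
and a mass accumulation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

__all__ = [
    "PhaseStack",
    "QPMConfig",
    "CellTrack",
    "MotionMetrics",
    "DEFAULT_ALPHA_UM3_PER_PG",
    "segment_frame",
    "phase_to_mass",
    "link_tracks",
    "motion_metrics",
]

log = logging.getLogger(__name__)

#: specific refractive increment, µm^3/pg (common literature value)
DEFAULT_ALPHA_UM3_PER_PG = 0.18


@dataclass
class PhaseStack:
    """Time-lapse of phase-shift images.

    ``frames`` holds optical path difference in nm per pixel, shape
    (T, H, W); ``pixel_size_um`` and ``frame_interval_min`` calibrate space
    and time; ``wavelength_nm`` records the illumination (660 nm LED by
    default) for provenance.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    wavelength_nm: float = 660.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class QPMConfig:
    """Segmentation / linking parameters."""

    tile_px: int = 64            # local-Otsu tile size
    min_area_px: int = 50        # connected components below this are dropped
    alpha: float = DEFAULT_ALPHA_UM3_PER_PG
    max_link_um: float = 20.0    # linking gate
    subpixel_align: bool = False  # bilinear shift before mass differencing


@dataclass
class CellTrack:
    """One linked cell trajectory.

    ``observations`` rows: (frame index, mask label, centroid (y, x) in µm,
    total mass pg).
    """

    track_id: int
    observations: list[tuple[int, int, tuple[float, float], float]] = \
        field(default_factory=list)

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def frames(self) -> list[int]:
        return [o[0] for o in self.observations]


@dataclass
class MotionMetrics:
    """Per-interval motion and mass-redistribution metrics for one track."""

    track_id: int
    net_displacement_um: np.ndarray
    pct_mass_fluctuation: np.ndarray
    unreliable: np.ndarray          # intervals with empty mask intersection
    mass_accumulation_rate_pg_per_h: float

    @property
    def mean_displacement_um(self) -> float:
        return float(np.mean(self.net_displacement_um)) \
            if self.net_displacement_um.size else np.nan

    @property
    def mean_pct_mass_fluctuation(self) -> float:
        ok = self.pct_mass_fluctuation[~self.unreliable]
        return float(np.mean(ok)) if ok.size else np.nan


def segment_frame(frame: np.ndarray, config: QPMConfig | None = None
                  ) -> np.ndarray:
    """Label cells with a tiled local-Otsu threshold.

    The frame is tiled, an Otsu threshold is computed per tile (tiles
    without contrast fall back to the global threshold), the tile grid is
    bilinearly interpolated to a per-pixel threshold surface, and connected
    foreground components smaller than ``min_area_px`` are removed.
    """
    config = config or QPMConfig()
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if np.ptp(frame) == 0:
        log.warning("flat frame: empty mask")
        return np.zeros(frame.shape, dtype=np.int32)

    global_thr = threshold_otsu(frame)
    t = config.tile_px
    ny = max(1, int(np.ceil(frame.shape[0] / t)))
    nx = max(1, int(np.ceil(frame.shape[1] / t)))
    grid = np.full((ny, nx), global_thr)
    for iy in range(ny):
        for ix in range(nx):
            tile = frame[iy * t : (iy + 1) * t, ix * t : (ix + 1) * t]
            # low-contrast tiles (pure background) keep the global threshold
            if np.ptp(tile) > 0.2 * np.ptp(frame):
                grid[iy, ix] = threshold_otsu(tile)

    if ny == 1 and nx == 1:
        surface = np.full(frame.shape, grid[0, 0])
    else:
        cy = (np.arange(ny) + 0.5) * t
        cx = (np.arange(nx) + 0.5) * t
        yy = np.clip(np.arange(frame.shape[0]), cy[0], cy[-1])
        xx = np.clip(np.arange(frame.shape[1]), cx[0], cx[-1])
        iy = np.clip(np.searchsorted(cy, yy) - 1, 0, max(ny - 2, 0))
        ix = np.clip(np.searchsorted(cx, xx) - 1, 0, max(nx - 2, 0))
        if ny > 1:
            wy = (yy - cy[iy]) / (cy[iy + 1] - cy[iy])
        else:
            wy = np.zeros_like(yy, dtype=float)
            iy = np.zeros_like(iy)
        if nx > 1:
            wx = (xx - cx[ix]) / (cx[ix + 1] - cx[ix])
        else:
            wx = np.zeros_like(xx, dtype=float)
            ix = np.zeros_like(ix)
        iy2 = np.minimum(iy + 1, ny - 1)
        ix2 = np.minimum(ix + 1, nx - 1)
        surface = ((1 - wy)[:, None] * (1 - wx)[None, :] * grid[iy][:, ix]
                   + (1 - wy)[:, None] * wx[None, :] * grid[iy][:, ix2]
                   + wy[:, None] * (1 - wx)[None, :] * grid[iy2][:, ix]
                   + wy[:, None] * wx[None, :] * grid[iy2][:, ix2])

    fg = frame > surface
    labels, _ = ndimage.label(fg)
    sizes = np.bincount(labels.ravel())
    small = np.nonzero(sizes < config.min_area_px)[0]
    if small.size:
        labels[np.isin(labels, small)] = 0
    # relabel consecutively
    out, _ = ndimage.label(labels > 0)
    if out.max() == 0:
        log.warning("empty foreground after size filtering")
    return out.astype(np.int32)


def phase_to_mass(frame: np.ndarray, pixel_size_um: float,
                  alpha: float = DEFAULT_ALPHA_UM3_PER_PG) -> np.ndarray:
    """Convert an OPD image (nm) to dry mass per pixel (pg).

    mass = OPD * pixel_area / alpha with alpha the specific refractive
    increment (µm^3/pg).  Negative OPD (noise) is clipped to zero; the
    clipped fraction is logged.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    frame = np.asarray(frame, dtype=float)
    neg = frame < 0
    if neg.any():
        frac = neg.mean()
        if frac > 0.5:
            log.warning("%.0f%% of pixels carry negative OPD", 100 * frac)
        else:
            log.debug("clipped %.2f%% negative-OPD pixels", 100 * frac)
    opd_um = np.clip(frame, 0.0, None) * 1e-3
    return opd_um * pixel_size_um**2 / alpha


def _frame_objects(mask: np.ndarray, mass: np.ndarray, pixel_size_um: float):
    """(label, centroid µm (y, x), total mass pg) per object, mass-weighted."""
    out = []
    for rp in regionprops(mask, intensity_image=mass):
        m = rp.image_intensity[rp.image].sum()
        cy, cx = rp.centroid_weighted
        out.append((rp.label, (cy * pixel_size_um, cx * pixel_size_um),
                    float(m)))
    return out


def link_tracks(
    masks: list[np.ndarray],
    mass_images: list[np.ndarray],
    pixel_size_um: float,
    config: QPMConfig | None = None,
) -> list[CellTrack]:
    """Greedy nearest-neighbour linking of segmented objects over time.

    Candidate links between consecutive frames are sorted by centroid
    distance (ties broken by smallest relative mass difference) and accepted
    greedily under the ``max_link_um`` gate; unmatched objects terminate or
    start tracks.  No merging or splitting.
    """
    config = config or QPMConfig()
    if len(masks) < 2:
        raise ValueError("need at least 2 frames to link")
    per_frame = [_frame_objects(m, mi, pixel_size_um)
                 for m, mi in zip(masks, mass_images)]

    tracks: list[CellTrack] = []
    active: dict[int, CellTrack] = {}  # index into per_frame[t] -> track
    for i, (lbl, c, m) in enumerate(per_frame[0]):
        tr = CellTrack(track_id=len(tracks))
        tr.observations.append((0, lbl, c, m))
        tracks.append(tr)
        active[i] = tr

    for t in range(1, len(per_frame)):
        prev, curr = per_frame[t - 1], per_frame[t]
        cands = []
        for i, (_, ci, mi) in enumerate(prev):
            if i not in active:
                continue
            for j, (_, cj, mj) in enumerate(curr):
                dist = float(np.hypot(ci[0] - cj[0], ci[1] - cj[1]))
                if dist <= config.max_link_um:
                    rel_dm = abs(mi - mj) / max(mi, 1e-12)
                    cands.append((dist, rel_dm, i, j))
        cands.sort()
        used_i, used_j = set(), set()
        next_active: dict[int, CellTrack] = {}
        for dist, _, i, j in cands:
            if i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            tr = active[i]
            lbl, c, m = curr[j]
            tr.observations.append((t, lbl, c, m))
            next_active[j] = tr
        for j, (lbl, c, m) in enumerate(curr):
            if j not in used_j:
                tr = CellTrack(track_id=len(tracks))
                tr.observations.append((t, lbl, c, m))
                tracks.append(tr)
                next_active[j] = tr
        active = next_active

    if all(len(tr) == 1 for tr in tracks):
        log.warning("all assignments exceeded the gate: tracks of length 1")
    return tracks


def _aligned_diff(
    m0: np.ndarray, m1: np.ndarray, shift: tuple[int, int]
) -> tuple[float, bool]:
    """Sum |m1 shifted onto m0 - m0| over the union support."""
    s0, s1 = int(shift[0]), int(shift[1])
    h, w = m0.shape
    m1s = np.zeros_like(m0)
    y0, y1 = max(0, -s0), min(h, h - s0)
    x0, x1 = max(0, -s1), min(w, w - s1)
    if y1 > y0 and x1 > x0:
        m1s[y0:y1, x0:x1] = m1[y0 + s0 : y1 + s0, x0 + s1 : x1 + s1]
    support0 = m0 > 0
    support1 = m1s > 0
    union = support0 | support1
    overlap = bool((support0 & support1).any())
    return float(np.abs(m1s[union] - m0[union]).sum()), overlap


def motion_metrics(
    track: CellTrack,
    masks: list[np.ndarray],
    mass_images: list[np.ndarray],
    pixel_size_um: float,
    frame_interval_min: float,
    config: QPMConfig | None = None,
) -> MotionMetrics:
    """Per-interval displacement and percent mass fluctuation for a track.

    Displacement is the Euclidean centroid step (µm).  Percent mass
    fluctuation aligns the two frames' cell masses by the integer-pixel
    shift of the centroids, then sums absolute pixelwise differences over
    the union of the aligned supports, normalised by the earlier frame's
    cell mass.  Integer alignment avoids interpolation-induced phantom
    fluctuation; translation by whole pixels cancels exactly.
    """
    config = config or QPMConfig()
    if len(track) < 2:
        raise ValueError("track length must be >= 2")
    obs = track.observations
    n_int = len(obs) - 1
    disp = np.zeros(n_int)
    fluct = np.zeros(n_int)
    unreliable = np.zeros(n_int, dtype=bool)

    for i in range(n_int):
        (f0, l0, c0, m0_tot) = obs[i]
        (f1, l1, c1, _) = obs[i + 1]
        disp[i] = float(np.hypot(c1[0] - c0[0], c1[1] - c0[1]))
        m0 = np.where(masks[f0] == l0, mass_images[f0], 0.0)
        m1 = np.where(masks[f1] == l1, mass_images[f1], 0.0)
        shift_px = (
            int(round((c1[0] - c0[0]) / pixel_size_um)),
            int(round((c1[1] - c0[1]) / pixel_size_um)),
        )
        if config.subpixel_align:
            m1 = ndimage.shift(
                m1,
                (-(c1[0] - c0[0]) / pixel_size_um + shift_px[0],
                 -(c1[1] - c0[1]) / pixel_size_um + shift_px[1]),
                order=1, mode="constant",
            )
        total_abs, overlap = _aligned_diff(m0, m1, shift_px)
        fluct[i] = 100.0 * total_abs / m0_tot if m0_tot > 0 else np.nan
        if not overlap:
            unreliable[i] = True
            log.warning("track %d interval %d: empty mask intersection",
                        track.track_id, i)

    times_h = np.array([o[0] for o in obs]) * frame_interval_min / 60.0
    masses = np.array([o[3] for o in obs])
    if np.ptp(times_h) > 0:
        rate = float(stats.linregress(times_h, masses).slope)
    else:
        rate = np.nan
    return MotionMetrics(
        track_id=track.track_id,
        net_displacement_um=disp,
        pct_mass_fluctuation=fluct,
        unreliable=unreliable,
        mass_accumulation_rate_pg_per_h=rate,
    )
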