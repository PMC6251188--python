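"""Phase-singularity detection by topological charge, tracking, rotor
classification, and density maps.

The charge at a pixel is the sum of wrapped phase differences taken
counter-clockwise around the closed ring of its 8 neighbours; pixels whose
charge is within a tolerance of +/-2 pi are singularity candidates, and a
candidate is an actual singularity when at least three of its eight
neighbours are same-sign candidates and it is the closest of that cluster
to +/-2 pi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .movie_io import RunConfig
from .phase_analysis import PhaseMovie, wrap_phase

__all__ = [
    "PSPoint",
    "PSTrack",
    "DensityMap",
    "topological_charge",
    "detect_ps",
    "detect_ps_movie",
    "track_ps",
    "count_rotations",
    "ps_density_maps",
    "ps_rate",
]

log = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi

# closed 8-neighbour ring, counter-clockwise for row-down image coordinates
# (ordered by increasing atan2(drow, dcol))
RING = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
NEIGHBOURS_8 = RING


@dataclass
class PSPoint:
    """One singularity detection: frame, sub-pixel position, chirality.

    ``seed_row``/``seed_col`` hold the integer winning pixel (the residual
    minimum of its candidate cluster) before centroid refinement.
    """

    frame: int
    row: float
    col: float
    chirality: int
    charge_residual: float = 0.0
    seed_row: int = -1
    seed_col: int = -1

    @property
    def pixel(self) -> tuple[int, int]:
        return int(round(self.row)), int(round(self.col))


@dataclass
class PSTrack:
    """A time-ordered chain of same-chirality singularity detections."""

    points: list[PSPoint] = field(default_factory=list)
    rotations: float = 0.0
    is_rotor: bool = False
    rotations_flagged: bool = False  # True when the DF fallback was used

    @property
    def birth_frame(self) -> int:
        return self.points[0].frame

    @property
    def death_frame(self) -> int:
        return self.points[-1].frame

    @property
    def chirality(self) -> int:
        return self.points[0].chirality

    @property
    def lifetime_frames(self) -> int:
        return self.death_frame - self.birth_frame + 1

    def position_at(self, frame: int) -> tuple[float, float] | None:
        for pt in self.points:
            if pt.frame == frame:
                return (pt.row, pt.col)
        return None


@dataclass
class DensityMap:
    """H x W event-count surface with normalization metadata."""

    counts: np.ndarray
    kind: str  # trajectory | initiation | annihilation | nwf_origin
    duration_ms: float = 0.0
    area_cm2: float = 0.0

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def topological_charge(phase_frame: np.ndarray,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Loop integral of wrapped phase differences around every interior pixel.

    Returns an ``H x W`` map; boundary pixels (and pixels whose ring
    touches a masked-out pixel) are 0.  A counter-clockwise +1 vortex
    yields approximately ``+2 pi`` next to its core.
    """
    phase_frame = np.asarray(phase_frame, float)
    h, w = phase_frame.shape
    charge = np.zeros((h, w), float)
    interior = np.zeros((h, w), bool)
    interior[1:-1, 1:-1] = True
    if mask is not None:
        mask = np.asarray(mask, bool)
        padded = np.pad(mask, 1, constant_values=False)
        ring_ok = np.ones((h, w), bool)
        for dr, dc in RING:
            ring_ok &= padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
        interior &= mask & ring_ok

    core = phase_frame[1:-1, 1:-1]
    acc = np.zeros_like(core)
    ring = RING + [RING[0]]
    for k in range(len(RING)):
        (r0, c0), (r1, c1) = ring[k], ring[k + 1]
        a = phase_frame[1 + r0:h - 1 + r0, 1 + c0:w - 1 + c0]
        b = phase_frame[1 + r1:h - 1 + r1, 1 + c1:w - 1 + c1]
        d = b - a
        acc += d - TWO_PI * np.round(d / TWO_PI)
    charge[1:-1, 1:-1] = acc
    charge[~interior] = 0.0
    return charge


def detect_ps(phase_frame: np.ndarray, ps_tol_rad: float = 3.0,
              mask: np.ndarray | None = None, frame: int = 0) -> list[PSPoint]:
    """Detect actual phase singularities in one frame.

    Candidates have ``|charge - sign * 2 pi| <= ps_tol_rad``; an actual PS
    additionally needs >= 3 of its 8 neighbours to be same-sign candidates
    and must be the residual minimum among itself and those neighbours.
    Position is refined to the residual-weighted centroid of the local
    candidate cluster; ties on the minimum go to the row-major first pixel.
    """
    charge = topological_charge(phase_frame, mask)
    sign = np.sign(charge).astype(int)
    residual = np.abs(np.abs(charge) - TWO_PI)
    candidate = (residual <= ps_tol_rad) & (sign != 0)

    h, w = charge.shape
    points: list[PSPoint] = []
    for r, c in zip(*np.nonzero(candidate)):
        s = sign[r, c]
        nbrs = [(r + dr, c + dc) for dr, dc in NEIGHBOURS_8
                if 0 <= r + dr < h and 0 <= c + dc < w
                and candidate[r + dr, c + dc] and sign[r + dr, c + dc] == s]
        if len(nbrs) < 3:
            continue
        res_here = residual[r, c]
        cluster = [(r, c)] + nbrs
        best = min(cluster, key=lambda p: (residual[p], p))
        if best != (r, c):
            continue
        weights = np.array([max(ps_tol_rad - residual[p], 1e-9) for p in cluster])
        rows = np.array([p[0] for p in cluster], float)
        cols = np.array([p[1] for p in cluster], float)
        points.append(PSPoint(frame=frame,
                              row=float(np.sum(weights * rows) / weights.sum()),
                              col=float(np.sum(weights * cols) / weights.sum()),
                              chirality=int(s),
                              charge_residual=float(res_here),
                              seed_row=int(r), seed_col=int(c)))
    return points


def detect_ps_movie(phase: PhaseMovie, ps_tol_rad: float = 3.0) -> list[list[PSPoint]]:
    """Per-frame singularity lists for a whole phase movie."""
    return [detect_ps(phase.phase[t], ps_tol_rad, phase.mask, frame=t)
            for t in range(phase.n_frames)]


def track_ps(per_frame: list[list[PSPoint]], link_px: float = 5.0,
             gap_frames: int = 0) -> list[PSTrack]:
    """Greedy nearest-neighbour linking of singularities across frames.

    Same-chirality detections within ``link_px`` are linked by ascending
    pair distance; unmatched detections open tracks, and a track dies after
    going unmatched for more than ``gap_frames`` frames.
    """
    open_tracks: list[PSTrack] = []
    done: list[PSTrack] = []
    for t, pts in enumerate(per_frame):
        # retire tracks that have been silent too long
        still_open = []
        for tr in open_tracks:
            if t - tr.death_frame > gap_frames + 1:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        pairs = []
        for ti, tr in enumerate(open_tracks):
            last = tr.points[-1]
            for pi, pt in enumerate(pts):
                if pt.chirality != last.chirality:
                    continue
                d = float(np.hypot(pt.row - last.row, pt.col - last.col))
                if d <= link_px:
                    pairs.append((d, ti, pi))
        pairs.sort()
        used_tracks: set[int] = set()
        used_pts: set[int] = set()
        for d, ti, pi in pairs:
            if ti in used_tracks or pi in used_pts:
                continue
            open_tracks[ti].points.append(pts[pi])
            used_tracks.add(ti)
            used_pts.add(pi)
        for pi, pt in enumerate(pts):
            if pi not in used_pts:
                open_tracks.append(PSTrack(points=[pt]))
    done.extend(open_tracks)
    done.sort(key=lambda tr: (tr.birth_frame, tr.points[0].row, tr.points[0].col))
    return done


def _probe_offset(track: PSTrack) -> tuple[int, int]:
    """Probe direction: perpendicular to net motion; (0, +2) when static."""
    dr = track.points[-1].row - track.points[0].row
    dc = track.points[-1].col - track.points[0].col
    n = np.hypot(dr, dc)
    if n < 1e-9:
        return (0, 2)
    # rotate motion by 90 degrees, scale to 2 px
    pr, pc = -dc / n, dr / n
    return (int(round(2 * pr)), int(round(2 * pc)))


def count_rotations(track: PSTrack, phase: PhaseMovie,
                    local_df_hz: float | None = None) -> float:
    """Rotations completed over a track's life, by probe-pixel phase unwrap.

    The probe sits 2 px from the per-frame core position (fixed offset
    direction relative to net motion); rotations are the absolute
    temporally-unwrapped phase change there divided by 2 pi.  Tracks whose
    probe never lands on valid tissue fall back to lifetime x local DF and
    are flagged.  Sets ``track.rotations`` / ``track.is_rotor``.
    """
    h, w = phase.mask.shape
    off = _probe_offset(track)
    samples = []
    for pt in track.points:
        r = int(round(pt.row)) + off[0]
        c = int(round(pt.col)) + off[1]
        if 0 <= r < h and 0 <= c < w and phase.mask[r, c]:
            samples.append(phase.phase[pt.frame, r, c])
    if len(samples) >= 2:
        unwrapped = np.unwrap(np.asarray(samples))
        rotations = float(abs(unwrapped[-1] - unwrapped[0]) / TWO_PI)
        track.rotations_flagged = False
    else:
        lifetime_s = track.lifetime_frames * phase.dt / 1000.0
        rotations = float(lifetime_s * (local_df_hz or 0.0))
        track.rotations_flagged = True
        log.warning("track at frame %d: probe off-grid, DF fallback used",
                    track.birth_frame)
    track.rotations = rotations
    track.is_rotor = rotations > 1.0
    return rotations


def ps_density_maps(tracks: list[PSTrack], shape: tuple[int, int],
                    duration_ms: float = 0.0, area_cm2: float = 0.0
                    ) -> tuple[DensityMap, DensityMap, DensityMap]:
    """(trajectory, initiation, annihilation) count maps from tracks."""
    traj = np.zeros(shape, float)
    init = np.zeros(shape, float)
    annih = np.zeros(shape, float)
    for tr in tracks:
        for pt in tr.points:
            traj[pt.pixel] += 1
        init[tr.points[0].pixel] += 1
        annih[tr.points[-1].pixel] += 1
    mk = lambda a, k: DensityMap(a, k, duration_ms=duration_ms, area_cm2=area_cm2)
    return mk(traj, "trajectory"), mk(init, "initiation"), mk(annih, "annihilation")


def ps_rate(tracks: list[PSTrack], mask: np.ndarray, duration_ms: float,
            pitch_mm: float, dt_ms: float = 1.0) -> dict[str, float]:
    """Mean coexisting singularity count per cm^2 per ms, by lifetime class.

    ``short`` covers tracks lasting <= 1 rotation, ``long`` those > 1
    rotation (rotors); ``all`` is their sum.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    area = float(mask.sum()) * (pitch_mm / 10.0) ** 2
    if area <= 0:
        raise ValueError("mask area is zero")
    n_frames = int(round(duration_ms / dt_ms))
    per_frame_short = np.zeros(n_frames)
    per_frame_long = np.zeros(n_frames)
    for tr in tracks:
        target = per_frame_long if tr.rotations > 1.0 else per_frame_short
        for pt in tr.points:
            if pt.frame < n_frames:
                target[pt.frame] += 1
    short = float(per_frame_short.mean() / area / dt_ms)
    long_ = float(per_frame_long.mean() / area / dt_ms)
    return {"short": short, "long": long_, "all": short + long_}
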