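"""Isophase wavefront extraction, new-wavefront detection/classification,
and new-wavefront density maps and preferential sites.

Active pixels are those on the isophase line of a chosen value theta
(default -pi/2, tracking the depolarization upstroke): the pixel phase
lies in ``[theta - band, theta]`` and between one and three of its four
adjacent neighbours have phase greater than theta.  An active pixel is
*new* when no active pixel existed within a square neighbourhood of it in
the previous frame; whole 8-connected components are classified as
propagated, new during existing activity, or new after a fully quiescent
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .movie_io import RunConfig
from .phase_analysis import PhaseMovie
from .singularities import DensityMap

__all__ = [
    "WavefrontEvent",
    "NWFSite",
    "CLASS_PROPAGATED",
    "CLASS_NEW_EXISTING",
    "CLASS_NEW_QUIESCENCE",
    "isophase_pixels",
    "label_wavefronts",
    "detect_new_wavefronts",
    "classify_wavefront",
    "extract_events",
    "nwf_density_map",
    "find_nwf_sites",
    "site_cycle_lengths",
]

CLASS_PROPAGATED = "propagated"
CLASS_NEW_EXISTING = "new_existing_AF"
CLASS_NEW_QUIESCENCE = "new_after_quiescence"

FOUR_NEIGHBOURS = [(-1, 0), (1, 0), (0, -1), (0, 1)]


@dataclass
class WavefrontEvent:
    """One labeled wavefront component in one frame."""

    frame: int
    pixels: set[tuple[int, int]]
    origin: tuple[float, float]
    wf_class: str
    component_id: int

    @property
    def origin_pixel(self) -> tuple[int, int]:
        return int(round(self.origin[0])), int(round(self.origin[1]))

    @property
    def is_new(self) -> bool:
        return self.wf_class != CLASS_PROPAGATED


@dataclass
class NWFSite:
    """A high-density new-wavefront initiation region."""

    pixels: set[tuple[int, int]]
    centroid: tuple[float, float]
    event_count: int = 0
    cycle_lengths: list[float] = field(default_factory=list)
    event_frames: list[int] = field(default_factory=list)


def isophase_pixels(phase_frame: np.ndarray, theta: float = -np.pi / 2,
                    band: float = 0.5, mask: np.ndarray | None = None) -> np.ndarray:
    """Boolean map of pixels on the theta isophase line.

    Active iff ``theta - band <= phase <= theta`` and the count of in-mask
    4-neighbours with ``phase > theta`` is 1, 2 or 3.  ``theta`` must sit
    at least ``band`` away from the +/-pi branch cut; crossing it would
    need circular comparisons the rule does not define.
    """
    if np.pi - abs(theta) < band:
        raise ValueError(f"theta={theta} is within {band} of the branch cut")
    phase_frame = np.asarray(phase_frame, float)
    h, w = phase_frame.shape
    if mask is None:
        mask = np.ones((h, w), bool)
    mask = np.asarray(mask, bool)

    in_band = (phase_frame >= theta - band) & (phase_frame <= theta) & mask
    greater = (phase_frame > theta) & mask
    padded = np.pad(greater, 1, constant_values=False)
    count = np.zeros((h, w), int)
    for dr, dc in FOUR_NEIGHBOURS:
        count += padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
    return in_band & (count >= 1) & (count <= 3)


def label_wavefronts(active: np.ndarray, min_component_px: int = 1
                     ) -> list[set[tuple[int, int]]]:
    """8-connected components of the active mask, small ones discarded."""
    labels = measure.label(np.asarray(active, bool), connectivity=2)
    comps = []
    for lab in range(1, labels.max() + 1):
        px = set(zip(*np.nonzero(labels == lab)))
        if len(px) >= min_component_px:
            comps.append({(int(r), int(c)) for r, c in px})
    return comps


def detect_new_wavefronts(active_t: np.ndarray, active_prev: np.ndarray,
                          radius_px: int = 3) -> np.ndarray:
    """Per-pixel labels for the current frame: True = new, False = propagated.

    An active pixel is propagated when any previously-active pixel lies in
    the ``(2 radius + 1)^2`` square around it (dilation of the previous
    frame's active mask); returned array is True only at new active pixels.
    """
    active_t = np.asarray(active_t, bool)
    active_prev = np.asarray(active_prev, bool)
    if active_t.shape != active_prev.shape:
        raise ValueError("frame shapes differ")
    size = 2 * radius_px + 1
    reachable = ndimage.binary_dilation(active_prev, np.ones((size, size), bool))
    return active_t & ~reachable


def classify_wavefront(component: set[tuple[int, int]], new_labels: np.ndarray,
                       prev_frame_active_count: int) -> str:
    """Three-way class of one component by pixel majority (ties count as new)."""
    n_new = sum(1 for p in component if new_labels[p])
    if 2 * n_new < len(component):
        return CLASS_PROPAGATED
    if prev_frame_active_count == 0:
        return CLASS_NEW_QUIESCENCE
    return CLASS_NEW_EXISTING


def extract_events(phase: PhaseMovie, config: RunConfig | None = None
                   ) -> tuple[list[WavefrontEvent], np.ndarray]:
    """Run the isophase + new-wavefront chain over a whole phase movie.

    Returns all per-frame wavefront events plus the per-frame active-pixel
    counts.  Frame 0 has no predecessor: its components are reported as
    propagated (their novelty is undefined).
    """
    cfg = config or RunConfig()
    t_n = phase.n_frames
    active_counts = np.zeros(t_n, int)
    events: list[WavefrontEvent] = []
    prev_active = np.zeros(phase.mask.shape, bool)
    next_id = 0
    for t in range(t_n):
        active = isophase_pixels(phase.phase[t], cfg.iso_theta, cfg.iso_band,
                                 phase.mask)
        active_counts[t] = int(active.sum())
        comps = label_wavefronts(active, cfg.min_component_px)
        if t == 0:
            new_labels = np.zeros_like(active)
        else:
            new_labels = detect_new_wavefronts(active, prev_active, cfg.nwf_radius_px)
        prev_count = int(prev_active.sum())
        for comp in comps:
            rows = [p[0] for p in comp]
            cols = [p[1] for p in comp]
            wf_class = (CLASS_PROPAGATED if t == 0 else
                        classify_wavefront(comp, new_labels, prev_count))
            events.append(WavefrontEvent(
                frame=t, pixels=comp,
                origin=(float(np.mean(rows)), float(np.mean(cols))),
                wf_class=wf_class, component_id=next_id))
            next_id += 1
        prev_active = active
    return events, active_counts


def nwf_density_map(events: list[WavefrontEvent], shape: tuple[int, int],
                    duration_ms: float = 0.0, area_cm2: float = 0.0,
                    per_pixel: bool = False) -> DensityMap:
    """Count map of new-wavefront origins (one count per event by default).

    With ``per_pixel=True`` every pixel of each new component is
    incremented instead (large fronts then dominate; the event-count
    invariant no longer holds).
    """
    counts = np.zeros(shape, float)
    for ev in events:
        if not ev.is_new:
            continue
        if per_pixel:
            for p in ev.pixels:
                counts[p] += 1
        else:
            counts[ev.origin_pixel] += 1
    return DensityMap(counts, "nwf_origin", duration_ms=duration_ms,
                      area_cm2=area_cm2)


def find_nwf_sites(density: DensityMap, mask: np.ndarray | None = None,
                   events: list[WavefrontEvent] | None = None,
                   dt_ms: float = 1.0, n_sd: float = 2.0,
                   min_site_events: int = 3, merge_px: int = 3) -> list[NWFSite]:
    """Threshold the (3x3-smoothed) density map into preferential sites.

    Supra-threshold pixels (mean + ``n_sd`` SD over the mask, with a floor
    of ``min_site_events`` events within the 3x3 smoothing support so that
    chance coincidences of isolated events never qualify) form 8-connected
    sites; fragments closer than ``merge_px`` are merged by morphological
    closing, since events jitter by a few pixels around a physiological
    source.  New events are assigned by origin containment and each site's
    inter-event cycle lengths are recorded.  An empty list is a valid
    outcome (no preferential site).
    """
    counts = density.counts
    if mask is None:
        mask = np.ones(counts.shape, bool)
    smooth = ndimage.uniform_filter(counts, size=3, mode="constant")
    vals = smooth[mask]
    thr = float(vals.mean() + n_sd * vals.std())
    thr = max(thr, (min_site_events - 0.5) / 9.0)
    supra = (smooth > thr) & mask
    if merge_px > 0 and supra.any():
        st = np.ones((2 * merge_px + 1, 2 * merge_px + 1), bool)
        supra = ndimage.binary_closing(supra, st) & mask
    sites: list[NWFSite] = []
    labels = measure.label(supra, connectivity=2)
    for lab in range(1, labels.max() + 1):
        px = {(int(r), int(c)) for r, c in zip(*np.nonzero(labels == lab))}
        rows = [p[0] for p in px]
        cols = [p[1] for p in px]
        site = NWFSite(pixels=px, centroid=(float(np.mean(rows)), float(np.mean(cols))))
        sites.append(site)
    if events is not None:
        for site in sites:
            frames = sorted(ev.frame for ev in events
                            if ev.is_new and ev.origin_pixel in site.pixels)
            site.event_count = len(frames)
            site.event_frames = frames
            site.cycle_lengths = [float((b - a) * dt_ms)
                                  for a, b in zip(frames, frames[1:])]
    return sites


def site_cycle_lengths(site: NWFSite, events: list[WavefrontEvent],
                       dt_ms: float = 1.0) -> list[float]:
    """Intervals (ms) between successive new events originating in a site."""
    frames = sorted(ev.frame for ev in events
                    if ev.is_new and ev.origin_pixel in site.pixels)
    return [float((b - a) * dt_ms) for a, b in zip(frames, frames[1:])]
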