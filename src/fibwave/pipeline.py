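"""End-to-end orchestration: voltage movie -> phase -> singularities ->
wavefront events -> mechanism report."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditioning import DFMap, condition, dominant_frequency
from .mechanisms import (MechanismReport, MechanismThresholds, activity_series,
                         classify_mechanism)
from .movie_io import RunConfig, VoltageMovie
from .phase_analysis import PhaseMovie, compute_phase
from .singularities import (DensityMap, PSTrack, count_rotations, detect_ps_movie,
                            ps_density_maps, ps_rate, track_ps)
from .wavefronts import (NWFSite, WavefrontEvent, extract_events, find_nwf_sites,
                         nwf_density_map)

__all__ = ["AnalysisResult", "analyze_phase", "analyze"]


@dataclass
class AnalysisResult:
    phase: PhaseMovie
    dfmap: DFMap | None
    tracks: list[PSTrack]
    events: list[WavefrontEvent]
    active_counts: np.ndarray
    nwf_map: DensityMap
    ps_maps: tuple[DensityMap, DensityMap, DensityMap]
    sites: list[NWFSite]
    report: MechanismReport
    rates: dict[str, float] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.report.label


def analyze_phase(phase: PhaseMovie, config: RunConfig | None = None,
                  dfmap: DFMap | None = None,
                  thresholds: MechanismThresholds | None = None) -> AnalysisResult:
    """Run singularity + wavefront + mechanism analysis on a phase movie."""
    cfg = config or RunConfig()
    per_frame = detect_ps_movie(phase, cfg.ps_tol_rad)
    tracks = track_ps(per_frame, cfg.track_link_px, cfg.track_gap_frames)
    local_df = dfmap.mean_df if dfmap is not None else None
    for tr in tracks:
        count_rotations(tr, phase, local_df_hz=local_df)
    events, active_counts = extract_events(phase, cfg)
    duration = phase.n_frames * phase.dt
    area = float(phase.mask.sum()) * (phase.pitch / 10.0) ** 2
    nwf_map = nwf_density_map(events, phase.mask.shape, duration_ms=duration,
                              area_cm2=area)
    ps_maps = ps_density_maps(tracks, phase.mask.shape, duration_ms=duration,
                              area_cm2=area)
    sites = find_nwf_sites(nwf_map, phase.mask, events, dt_ms=phase.dt)
    report = activity_series(phase.n_frames, tracks, active_counts)
    classify_mechanism(report, sites, events, dt_ms=phase.dt,
                       thresholds=thresholds)
    rates = ps_rate(tracks, phase.mask, duration, phase.pitch, phase.dt)
    return AnalysisResult(phase=phase, dfmap=dfmap, tracks=tracks, events=events,
                          active_counts=active_counts, nwf_map=nwf_map,
                          ps_maps=ps_maps, sites=sites, report=report, rates=rates)


def analyze(movie: VoltageMovie, config: RunConfig | None = None,
            precondition: bool = True,
            thresholds: MechanismThresholds | None = None) -> AnalysisResult:
    """Full pipeline from a raw voltage movie."""
    cfg = config or RunConfig()
    if precondition:
        movie, dfmap = condition(movie, cfg)
    else:
        dfmap = dominant_frequency(movie, cfg.df_band_hz)
    phase = compute_phase(movie, cfg, mean_cycle_ms=dfmap.mean_cycle_ms)
    return analyze_phase(phase, cfg, dfmap, thresholds)
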