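"""Mechanism inference: per-frame activity summaries, the sustained-by
rotor vs sustained-by-new-wavefront rule, map correlation, and the
two-sample median test used for cycle-length comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .singularities import DensityMap, PSTrack
from .wavefronts import NWFSite, WavefrontEvent

__all__ = [
    "MechanismReport",
    "MechanismThresholds",
    "activity_series",
    "classify_mechanism",
    "map_correlation",
    "moods_median_test",
]

LABEL_ROTOR = "rotor_sustained"
LABEL_NWF = "nwf_sustained"
LABEL_MIXED = "mixed"


@dataclass
class MechanismThresholds:
    """Knobs of the mechanism rule (defaults formalize the qualitative
    criteria: most quiescence exits re-initiated from a preferential site
    vs a rotor present essentially all the time)."""

    site_exit_frac: float = 0.5     # fraction of exits attributed to sites
    attribution_ms: float = 20.0    # window after an exit to credit a new event
    rotor_presence_frac: float = 0.8
    quiescent_frac: float = 0.01


@dataclass
class MechanismReport:
    n_ps_series: np.ndarray
    n_rotor_series: np.ndarray
    active_px_series: np.ndarray
    quiescent_frames: list[int]
    restart_attributions: dict[str, float] = field(default_factory=dict)
    label: str = ""

    @property
    def quiescent_frac(self) -> float:
        return len(self.quiescent_frames) / max(1, len(self.active_px_series))

    @property
    def rotor_presence_frac(self) -> float:
        return float((self.n_rotor_series > 0).mean())


def activity_series(n_frames: int, tracks: list[PSTrack],
                    active_counts: np.ndarray) -> MechanismReport:
    """Per-frame counts of singularities, rotors and active pixels.

    A track contributes to the rotor series from the frame at which it has
    completed its first full rotation (approximated by pro-rating its
    total rotations over its lifetime) until its death.
    """
    n_ps = np.zeros(n_frames, int)
    n_rotor = np.zeros(n_frames, int)
    for tr in tracks:
        for pt in tr.points:
            if pt.frame < n_frames:
                n_ps[pt.frame] += 1
        if tr.rotations > 1.0 and tr.lifetime_frames > 0:
            frames_per_rotation = tr.lifetime_frames / tr.rotations
            start = min(tr.birth_frame + int(np.ceil(frames_per_rotation)),
                        tr.death_frame)
            for pt in tr.points:
                if start <= pt.frame < n_frames:
                    n_rotor[pt.frame] += 1
    active = np.asarray(active_counts[:n_frames], int)
    quiescent = [int(t) for t in np.flatnonzero(active == 0)]
    return MechanismReport(n_ps_series=n_ps, n_rotor_series=n_rotor,
                           active_px_series=active, quiescent_frames=quiescent)


def _quiescence_exits(active: np.ndarray) -> list[int]:
    """Frames at which activity resumes after >= 1 quiescent frame."""
    quiet = active == 0
    return [t for t in range(1, len(active)) if quiet[t - 1] and not quiet[t]]


def classify_mechanism(report: MechanismReport,
                       sites: list[NWFSite],
                       events: list[WavefrontEvent] | None = None,
                       dt_ms: float = 1.0,
                       thresholds: MechanismThresholds | None = None) -> str:
    """Label a recording rotor-sustained, NWF-sustained, or mixed.

    NWF-sustained: the recording shows quiescence (> ``quiescent_frac`` of
    frames) and at least ``site_exit_frac`` of quiescence exits are
    credited to a new-wavefront event from a detected preferential site
    within ``attribution_ms`` of the exit.  Rotor-sustained: a rotor is
    present in at least ``rotor_presence_frac`` of frames and quiescence is
    rare.  Everything else is mixed.  Sets ``report.label`` and
    ``report.restart_attributions``.
    """
    th = thresholds or MechanismThresholds()
    active = report.active_px_series
    exits = _quiescence_exits(active)
    attributions: dict[str, float] = {}
    site_frac = 0.0
    if exits and sites and events is not None:
        win = max(1, int(round(th.attribution_ms / dt_ms)))
        site_events = [sorted(f for f in s.event_frames) for s in sites]
        hits = np.zeros(len(sites), int)
        for ex in exits:
            for si, frames in enumerate(site_events):
                if any(ex <= f < ex + win or ex - 1 <= f <= ex for f in frames):
                    hits[si] += 1
                    break
        for si, h in enumerate(hits):
            attributions[f"site_{si}"] = float(h / len(exits))
        site_frac = float(hits.sum() / len(exits))
    report.restart_attributions = attributions

    q_frac = report.quiescent_frac
    if site_frac >= th.site_exit_frac and q_frac > th.quiescent_frac:
        report.label = LABEL_NWF
    elif (report.rotor_presence_frac >= th.rotor_presence_frac
          and q_frac <= th.quiescent_frac):
        report.label = LABEL_ROTOR
    else:
        report.label = LABEL_MIXED
    return report.label


def map_correlation(map_a: DensityMap | np.ndarray, map_b: DensityMap | np.ndarray,
                    mask: np.ndarray | None = None) -> float:
    """Pearson correlation between two maps over mask-true pixels.

    Returns NaN (flagged degenerate) when either map has zero variance.
    """
    a = map_a.counts if isinstance(map_a, DensityMap) else np.asarray(map_a, float)
    b = map_b.counts if isinstance(map_b, DensityMap) else np.asarray(map_b, float)
    if a.shape != b.shape:
        raise ValueError("map shapes differ")
    if mask is None:
        mask = np.ones(a.shape, bool)
    x = a[mask].ravel()
    y = b[mask].ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def moods_median_test(x, y) -> tuple[float, float]:
    """Mood's median test for equality of two medians.

    Pools both samples, drops values equal to the grand median, cross-
    tabulates above-median counts per group, and tests the 2x2 table with
    a 1-df chi-square statistic; when any expected cell count is below 5
    the p-value comes from exact enumeration of tables with fixed margins
    (two-sided, by table probability).  Identical or fully tied samples
    give (0.0, 1.0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    grand = float(np.median(np.concatenate([x, y])))
    ax, bx = int((x > grand).sum()), int((x < grand).sum())
    ay, by = int((y > grand).sum()), int((y < grand).sum())
    table = np.array([[ax, ay], [bx, by]], float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or \
       (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = float(np.nansum((table - expected) ** 2 / expected))
    if (expected < 5).any():
        _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
        return chi2, float(p)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p
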