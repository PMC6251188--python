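"""Instantaneous phase from conditioned voltage traces.

Each pixel trace is centred by envelope normalization (sliding-window
extrema joined with cubic splines), converted to phase with the Hilbert
transform, and the resulting phase field is spatially smoothed in its
complex-exponential form so averaging never crosses the branch cut.

Phase convention: 0 at signal maxima, -pi/2 mid-upstroke, so the -pi/2
isophase tracks the depolarization wavefront.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import CubicSpline

from .movie_io import RunConfig, VoltageMovie

__all__ = [
    "ExtremaSet",
    "PhaseMovie",
    "detect_extrema",
    "envelope_normalize",
    "hilbert_phase",
    "smooth_phase",
    "compute_phase",
    "wrap_phase",
]


def wrap_phase(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the half-open interval (-pi, pi]."""
    out = np.angle(np.exp(1j * np.asarray(theta, dtype=float)))
    # np.angle returns [-pi, pi]; fold the closed lower end onto +pi
    return np.where(out == -np.pi, np.pi, out) if np.ndim(out) else (
        np.pi if out == -np.pi else float(out))


@dataclass
class ExtremaSet:
    """Alternating maxima/minima of one trace after pair rejection."""

    maxima: list[tuple[int, float]]
    minima: list[tuple[int, float]]
    window_frames: int
    amp_threshold: float

    @property
    def n_maxima(self) -> int:
        return len(self.maxima)

    @property
    def n_minima(self) -> int:
        return len(self.minima)


@dataclass
class PhaseMovie:
    """``T x H x W`` phase angles in (-pi, pi] plus inherited geometry."""

    phase: np.ndarray
    mask: np.ndarray
    dt: float = 1.0
    pitch: float = 0.44

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, float)
        self.mask = np.asarray(self.mask, bool)

    @property
    def n_frames(self) -> int:
        return self.phase.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.phase.shape


def _windowed_flags(trace: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean maps of samples that are the max/min of their centred window."""
    mx = ndimage.maximum_filter1d(trace, size=window, mode="nearest")
    mn = ndimage.minimum_filter1d(trace, size=window, mode="nearest")
    is_max = trace >= mx
    is_min = trace <= mn
    # samples flat across the whole window satisfy both; they are not extrema
    flat = is_max & is_min
    is_max &= ~flat
    is_min &= ~flat
    # record endpoints and monotone tails are not validatable extrema:
    # require an immediate-neighbour local extremum as well
    local_max = np.zeros_like(is_max)
    local_min = np.zeros_like(is_min)
    local_max[1:-1] = (trace[1:-1] >= trace[:-2]) & (trace[1:-1] >= trace[2:])
    local_min[1:-1] = (trace[1:-1] <= trace[:-2]) & (trace[1:-1] <= trace[2:])
    return is_max & local_max, is_min & local_min


def _dedupe_plateaus(idx: np.ndarray, window: int) -> list[int]:
    """Collapse runs of flagged samples closer than half a window."""
    if len(idx) == 0:
        return []
    keep = [int(idx[0])]
    for i in idx[1:]:
        if i - keep[-1] >= max(1, window // 2):
            keep.append(int(i))
    return keep


def _enforce_alternation(merged: list[tuple[int, float, int]]
                         ) -> list[tuple[int, float, int]]:
    """Keep the more extreme member of any same-type run (type: +1 max, -1 min)."""
    out: list[tuple[int, float, int]] = []
    for item in merged:
        if out and out[-1][2] == item[2]:
            prev = out[-1]
            if item[2] == 1:  # two maxima in a row: keep the larger
                if item[1] > prev[1]:
                    out[-1] = item
            else:             # two minima: keep the smaller
                if item[1] < prev[1]:
                    out[-1] = item
        else:
            out.append(item)
    return out


def detect_extrema(trace: np.ndarray, window_frames: int,
                   amp_reject_frac: float = 0.15) -> ExtremaSet:
    """Sliding-window extrema with small-amplitude pair rejection.

    A sample is a maximum (minimum) if it is the extremum of the centred
    window of length ``window_frames``.  Consecutive (max, min) pairs whose
    amplitude ``|v_max - v_min|`` falls below ``amp_reject_frac`` times the
    median pair amplitude are removed (both members), and alternation is
    restored by keeping the more extreme member of any same-type run.
    """
    if window_frames < 3:
        raise ValueError(f"window_frames must be >= 3, got {window_frames}")
    trace = np.asarray(trace, float)
    is_max, is_min = _windowed_flags(trace, window_frames)
    max_idx = _dedupe_plateaus(np.flatnonzero(is_max), window_frames)
    min_idx = _dedupe_plateaus(np.flatnonzero(is_min), window_frames)

    merged = sorted([(i, trace[i], 1) for i in max_idx]
                    + [(i, trace[i], -1) for i in min_idx])
    merged = _enforce_alternation(merged)

    # consecutive (max, min) pairs in time, either order of occurrence
    def pairs(seq):
        return [(seq[k], seq[k + 1]) for k in range(len(seq) - 1)
                if seq[k][2] == 1 and seq[k + 1][2] == -1]

    amp_threshold = 0.0
    pr = pairs(merged)
    if pr:
        amps = np.array([abs(a[1] - b[1]) for a, b in pr])
        # floor guards against degenerate medians when most pairs are
        # near-flat wiggles (long quiescent stretches between deflections)
        amp_threshold = max(amp_reject_frac * float(np.median(amps)),
                            0.01 * float(np.ptp(trace)))
        drop: set[int] = set()
        for (a, b) in pr:
            if abs(a[1] - b[1]) < amp_threshold:
                drop.add(a[0])
                drop.add(b[0])
        merged = _enforce_alternation([m for m in merged if m[0] not in drop])

    maxima = [(i, v) for i, v, t in merged if t == 1]
    minima = [(i, v) for i, v, t in merged if t == -1]
    return ExtremaSet(maxima=maxima, minima=minima,
                      window_frames=window_frames, amp_threshold=amp_threshold)


def envelope_normalize(trace: np.ndarray, extrema: ExtremaSet) -> np.ndarray:
    """Rescale a trace into [-1, 1] between its spline envelopes.

    The upper/lower envelopes interpolate the surviving maxima/minima with
    cubic splines; beyond the first/last extremum they extend at the
    nearest extremum's value.  Output is ``2 (s - L) / (U - L) - 1``,
    forced to 0 wherever the envelopes pinch together.
    """
    trace = np.asarray(trace, float)
    if extrema.n_maxima < 2 or extrema.n_minima < 2:
        raise ValueError("need at least two maxima and two minima to build envelopes")
    t = np.arange(len(trace))

    def env(points: list[tuple[int, float]]) -> np.ndarray:
        idx = np.array([p[0] for p in points], float)
        val = np.array([p[1] for p in points], float)
        spline = CubicSpline(idx, val)
        out = spline(np.clip(t, idx[0], idx[-1]))
        out[t < idx[0]] = val[0]
        out[t > idx[-1]] = val[-1]
        return out

    upper = env(extrema.maxima)
    lower = env(extrema.minima)
    span = upper - lower
    eps = 1e-6 * float(np.ptp(trace) or 1.0)
    out = np.where(span > eps, 2.0 * (trace - lower) / np.where(span > eps, span, 1.0) - 1.0,
                   0.0)
    return out


def hilbert_phase(trace: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal, wrapped to (-pi, pi].

    ``cos(w t)`` maps to phase ``w t``: 0 at maxima, -pi/2 mid-upstroke.
    """
    trace = np.asarray(trace, float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    analytic = signal.hilbert(trace, axis=0)
    return wrap_phase(np.angle(analytic))


def smooth_phase(phase: PhaseMovie, bin_px: int = 9) -> PhaseMovie:
    """Circular spatial smoothing: argument of the boxcar mean of e^{i theta}.

    Mask-aware (invalid pixels neither contribute nor change); magnitude of
    the complex mean is discarded.
    """
    if bin_px < 1 or bin_px % 2 == 0:
        raise ValueError(f"bin size must be odd and >= 1, got {bin_px}")
    if bin_px == 1:
        return PhaseMovie(phase.phase.copy(), phase.mask, phase.dt, phase.pitch)
    z = np.exp(1j * phase.phase)
    m = phase.mask.astype(float)
    size = (1, bin_px, bin_px)
    re = ndimage.uniform_filter(z.real * m, size=size, mode="constant")
    im = ndimage.uniform_filter(z.imag * m, size=size, mode="constant")
    sm = wrap_phase(np.arctan2(im, re))
    sm = np.where(phase.mask, sm, phase.phase)
    return PhaseMovie(sm, phase.mask, phase.dt, phase.pitch)


def compute_phase(movie: VoltageMovie, config: RunConfig | None = None,
                  mean_cycle_ms: float | None = None) -> PhaseMovie:
    """Voltage movie -> smoothed phase movie (per-pixel envelope + Hilbert).

    Pixels where extrema detection fails (flat or degenerate traces) are
    dropped from the output mask.
    """
    cfg = config or RunConfig()
    if mean_cycle_ms is None:
        from .conditioning import dominant_frequency

        mean_cycle_ms = dominant_frequency(movie, cfg.df_band_hz).mean_cycle_ms
    window = max(3, int(round(cfg.extrema_window_frac * mean_cycle_ms / movie.dt)))

    t, h, w = movie.shape
    phase = np.zeros((t, h, w), float)
    mask = movie.mask.copy()
    centred = np.zeros((t, h, w), float)
    for r, c in zip(*np.nonzero(movie.mask)):
        trace = movie.data[:, r, c]
        try:
            ext = detect_extrema(trace, window, cfg.amp_reject_frac)
            centred[:, r, c] = envelope_normalize(trace, ext)
        except ValueError:
            mask[r, c] = False
    sel = np.nonzero(mask)
    if len(sel[0]):
        analytic = signal.hilbert(centred[:, sel[0], sel[1]], axis=0)
        phase[:, sel[0], sel[1]] = wrap_phase(np.angle(analytic))
    pm = PhaseMovie(phase, mask, movie.dt, movie.pitch)
    return smooth_phase(pm, cfg.spatial_bin)
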