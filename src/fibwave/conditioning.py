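"""Signal conditioning: spatial filtering, dominant frequency, band-pass,
drift removal and normalization.

The standard chain is spatial filter -> drift removal -> dominant-frequency
estimate -> zero-phase FIR band-pass (2 Hz to 125 % of the mean DF) ->
min-max normalization, wrapped by :func:`condition`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .movie_io import RunConfig, VoltageMovie

__all__ = [
    "DFMap",
    "spatial_filter",
    "dominant_frequency",
    "design_bandpass",
    "temporal_bandpass",
    "remove_baseline_normalize",
    "condition",
]

log = logging.getLogger(__name__)


@dataclass
class DFMap:
    """Per-pixel dominant frequency (Hz) with the search band used."""

    values: np.ndarray          # H x W, NaN outside mask
    band: tuple[float, float]   # (low, high) Hz searched
    mean_df: float              # mask-restricted mean, Hz

    @property
    def mean_cycle_ms(self) -> float:
        return 1000.0 / self.mean_df


def _masked_boxcar(frames: np.ndarray, mask: np.ndarray, bin_px: int) -> np.ndarray:
    """Mask-aware uniform filter over the last two axes.

    Each valid pixel is replaced by the mean of valid pixels within its
    ``bin x bin`` window; invalid pixels pass through untouched and never
    contribute to neighbours.
    """
    m = mask.astype(float)
    size = ((1,) * (frames.ndim - 2)) + (bin_px, bin_px)
    num = ndimage.uniform_filter(frames * m, size=size, mode="constant")
    den = ndimage.uniform_filter(np.broadcast_to(m, frames.shape).copy(),
                                 size=size, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out = np.where(mask, out, frames)
    return out


def spatial_filter(movie: VoltageMovie, bin_px: int | None = None) -> VoltageMovie:
    """Frame-wise mask-aware uniform (boxcar) spatial filter.

    ``bin_px`` must be odd; the default 9 matches the published chain.
    """
    if bin_px is None:
        bin_px = 9
    if bin_px < 1 or bin_px % 2 == 0:
        raise ValueError(f"bin size must be odd and >= 1, got {bin_px}")
    if bin_px == 1:
        return movie.with_data(movie.data.copy(), spatial_bin=1)
    out = _masked_boxcar(movie.data, movie.mask, bin_px)
    return movie.with_data(out, spatial_bin=bin_px)


def dominant_frequency(movie: VoltageMovie,
                       band: tuple[float, float] = (2.0, 50.0)) -> DFMap:
    """Per-pixel dominant frequency from a Hann-tapered periodogram.

    The DF of a pixel is the frequency of maximal power spectral density
    within ``band``; the per-movie ``mean_df`` is the mask mean.
    """
    low, high = band
    fs = movie.fs_hz
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got {band}")
    if high >= fs / 2:
        raise ValueError(f"band top {high} Hz is at/above Nyquist ({fs / 2} Hz)")
    if movie.duration_ms < 2 * 1000.0 / low:
        raise ValueError("movie shorter than two cycles of the band low edge")

    t, h, w = movie.shape
    traces = movie.data.reshape(t, -1)
    freqs, psd = signal.periodogram(traces, fs=fs, window="hann",
                                    detrend="constant", axis=0)
    sel = (freqs >= low) & (freqs <= high)
    if not sel.any():
        raise ValueError("no spectral bins inside the search band")
    idx = np.argmax(psd[sel], axis=0)
    df = freqs[sel][idx].reshape(h, w).astype(float)
    df[~movie.mask] = np.nan
    mean_df = float(np.nanmean(df[movie.mask]))
    return DFMap(values=df, band=(low, high), mean_df=mean_df)


def design_bandpass(low: float, high: float, fs: float, *,
                    trans_hz: float = 1.0, min_atten_db: float = 20.0,
                    max_taps: int | None = None) -> np.ndarray:
    """Design an equiripple (Parks-McClellan) FIR band-pass.

    Stop bands end at ``low - trans_hz`` and start at ``high + trans_hz``;
    a Kaiser-window design is the fallback if the exchange algorithm fails
    to converge.  Returned taps are applied forward-backward, so effective
    stop-band attenuation is doubled.  When ``max_taps`` is given the
    transition width is widened as needed so the filter fits short records
    (at the cost of low-edge selectivity).
    """
    nyq = fs / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"need 0 < low < high < Nyquist, got {(low, high, nyq)}")
    trans = min(trans_hz, low / 2, (nyq - high) / 2)
    # Kaiser estimate for the required length at the narrowest transition.
    numtaps, beta = signal.kaiserord(min_atten_db + 6, trans / nyq)
    while max_taps is not None and numtaps > max_taps:
        trans *= 1.25
        numtaps, beta = signal.kaiserord(min_atten_db + 6, trans / nyq)
    numtaps |= 1  # odd length -> symmetric, integer group delay
    low_stop = max(low / 4, low - trans)
    high_stop = min(high + trans, nyq * 0.999)
    bands = [0, low_stop, low, high, high_stop, nyq]
    try:
        taps = signal.remez(numtaps, bands, [0, 1, 0], fs=fs, maxiter=50)
        if not np.all(np.isfinite(taps)):
            raise ValueError("remez produced non-finite taps")
    except Exception:  # pragma: no cover - convergence fallback
        taps = signal.firwin(numtaps, [low, high], window=("kaiser", beta),
                             pass_zero=False, fs=fs)
    return taps


def temporal_bandpass(movie: VoltageMovie, low: float, high: float,
                      taps: np.ndarray | None = None,
                      fit_to_length: bool = False) -> VoltageMovie:
    """Zero-phase (forward-backward) FIR band-pass applied per pixel.

    Raises a length error when the movie is shorter than three filter
    lengths, where edge transients would dominate; ``fit_to_length``
    instead widens the transition band so the filter fits.
    """
    if taps is None:
        max_taps = movie.n_frames // 3 if fit_to_length else None
        taps = design_bandpass(low, high, movie.fs_hz, max_taps=max_taps)
    t = movie.n_frames
    if t < 3 * len(taps):
        raise ValueError(
            f"movie length {t} < 3 x filter length {len(taps)}; "
            "record longer or relax the transition width")
    flat = movie.data.reshape(t, -1)
    out = signal.filtfilt(taps, [1.0], flat, axis=0, padtype="even")
    return movie.with_data(out.reshape(movie.shape), bandpass_hz=(low, high))


def remove_baseline_normalize(movie: VoltageMovie,
                              cycle_ms: float | None = None) -> VoltageMovie:
    """Remove the moving-mean trend and min-max rescale each pixel to [0, 1].

    The detrending window is two mean cycle lengths (``cycle_ms``; default
    estimated from the DF band default when not given).  Pixels with a
    constant trace cannot be normalized and are masked out with a warning.
    """
    if cycle_ms is None:
        cycle_ms = 1000.0 / dominant_frequency(movie).mean_df
    win = max(3, int(round(2 * cycle_ms / movie.dt)))
    win = min(win, movie.n_frames)
    t = movie.n_frames
    flat = movie.data.reshape(t, -1)
    trend = ndimage.uniform_filter1d(flat, size=win, axis=0, mode="nearest")
    detrended = flat - trend
    lo = detrended.min(axis=0)
    hi = detrended.max(axis=0)
    rng = hi - lo
    eps = 1e-12 + 1e-9 * np.abs(flat).max()
    degenerate = (rng <= eps)
    mask = movie.mask.copy()
    bad = degenerate.reshape(movie.shape[1:]) & mask
    if bad.any():
        log.warning("masking %d constant-trace pixel(s) during normalization",
                    int(bad.sum()))
        mask &= ~bad
    rng = np.where(degenerate, 1.0, rng)
    out = (detrended - lo) / rng
    out = out.reshape(movie.shape)
    return VoltageMovie(out, dt=movie.dt, pitch=movie.pitch, mask=mask,
                        meta={**movie.meta, "normalized": True})


def condition(movie: VoltageMovie, config: RunConfig | None = None
              ) -> tuple[VoltageMovie, DFMap]:
    """Full conditioning chain; returns the cleaned movie and its DF map."""
    cfg = config or RunConfig()
    m = spatial_filter(movie, cfg.spatial_bin)
    dfmap = dominant_frequency(m, cfg.df_band_hz)
    m = remove_baseline_normalize(m, cycle_ms=dfmap.mean_cycle_ms)
    high = min(cfg.band_high_frac * dfmap.mean_df, 0.45 * movie.fs_hz)
    m = temporal_bandpass(m, cfg.band_low_hz, high, fit_to_length=True)
    # band-pass shifts the range; re-normalize without re-detrending
    flat = m.data.reshape(m.n_frames, -1)
    lo, hi = flat.min(axis=0), flat.max(axis=0)
    rng = np.where(hi - lo <= 0, 1.0, hi - lo)
    m = m.with_data(((flat - lo) / rng).reshape(m.shape))
    return m, dfmap
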