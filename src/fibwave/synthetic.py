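"""Ground-truth movie generators.

Four families, in increasing fidelity:

* analytic phase films (rigid/meandering spirals, plane waves) with exact
  core trajectories;
* a stylized focal-source generator with guaranteed inter-beat quiescence;
* a two-variable excitable-media reaction-diffusion solver (cubic
  activation with slow recovery, 5-point Laplacian, no-flux boundaries)
  supporting cross-field spiral initiation and point pacing;
* a two-layer generator coupling two reaction-diffusion sheets at discrete
  connection sites, with stochastic anisotropic edge removal ("fibrosis")
  and recovery-shortening islands, emitting breakthrough ground truth.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .movie_io import VoltageMovie
from .phase_analysis import PhaseMovie, wrap_phase

__all__ = [
    "GroundTruth",
    "RDParams",
    "TwoLayerSpec",
    "analytic_spiral_movie",
    "plane_wave_movie",
    "focal_movie",
    "rd_simulate",
    "two_layer_simulate",
    "add_optical_noise",
    "random_smooth_phase",
]

TWO_PI = 2.0 * np.pi


@dataclass
class GroundTruth:
    """What a generator actually put into a movie."""

    regime: str  # spiral | focal | plane | rd | two_layer
    ps_trajectories: list[tuple[int, float, float, int]] = field(default_factory=list)
    focal_events: list[tuple[int, int, int]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def core_at(self, frame: int) -> tuple[float, float] | None:
        for f, r, c, _ in self.ps_trajectories:
            if f == frame:
                return (r, c)
        return None


# ---------------------------------------------------------------------------
# analytic films
# ---------------------------------------------------------------------------

def analytic_spiral_movie(freq_hz: float, core: tuple[float, float] | np.ndarray,
                          duration_ms: float, grid: tuple[int, int] = (128, 80),
                          dt: float = 1.0, pitch: float = 0.44,
                          wavenumber: float = 0.0, spiral_sign: int = 1,
                          ) -> tuple[PhaseMovie, VoltageMovie, GroundTruth]:
    """Rigidly rotating (optionally meandering) Archimedean-spiral phase film.

    ``phase(t, r, c) = wrap(2 pi f t - s * atan2(r - r0(t), c - c0(t))
    - k * dist)``; voltage is ``cos(phase)``.  ``core`` is a fixed
    ``(row, col)`` or a ``(T, 2)`` trajectory.  The detected chirality of
    the core is ``-spiral_sign`` under the counter-clockwise loop
    convention used by the singularity detector.
    """
    h, w = grid
    n = int(round(duration_ms / dt))
    fs = 1000.0 / dt
    if freq_hz >= fs / 8:
        raise ValueError(f"freq {freq_hz} Hz too high for {fs} Hz sampling")
    traj = np.asarray(core, float)
    if traj.ndim == 1:
        traj = np.tile(traj, (n, 1))
    if traj.shape != (n, 2):
        raise ValueError(f"core trajectory must be (T, 2), got {traj.shape}")
    if not ((0 <= traj[:, 0]).all() and (traj[:, 0] < h).all()
            and (0 <= traj[:, 1]).all() and (traj[:, 1] < w).all()):
        raise ValueError("core leaves the grid")

    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    phase = np.empty((n, h, w))
    for t in range(n):
        r0, c0 = traj[t]
        ang = np.arctan2(rr - r0, cc - c0)
        dist = np.hypot(rr - r0, cc - c0)
        phase[t] = TWO_PI * freq_hz * (t * dt / 1000.0) - spiral_sign * ang \
            - wavenumber * dist
    phase = wrap_phase(phase)
    mask = np.ones((h, w), bool)
    pm = PhaseMovie(phase, mask, dt, pitch)
    vm = VoltageMovie(np.cos(phase), dt=dt, pitch=pitch, mask=mask,
                      meta={"generator": "analytic_spiral", "freq_hz": freq_hz})
    chir = -int(spiral_sign)
    truth = GroundTruth(
        regime="spiral",
        ps_trajectories=[(t, float(traj[t, 0]), float(traj[t, 1]), chir)
                         for t in range(n)],
        params={"freq_hz": freq_hz, "duration_ms": duration_ms, "grid": grid,
                "dt": dt, "wavenumber": wavenumber, "spiral_sign": spiral_sign})
    return pm, vm, truth


def plane_wave_movie(freq_hz: float, wavelength_px: float, duration_ms: float,
                     grid: tuple[int, int] = (128, 80), dt: float = 1.0,
                     pitch: float = 0.44) -> tuple[PhaseMovie, VoltageMovie, GroundTruth]:
    """Plane wave travelling along columns; contains no singularities."""
    h, w = grid
    n = int(round(duration_ms / dt))
    cc = np.arange(w, dtype=float)
    t_idx = np.arange(n, dtype=float)[:, None]
    ph = TWO_PI * freq_hz * (t_idx * dt / 1000.0) - TWO_PI * cc[None, :] / wavelength_px
    phase = wrap_phase(np.repeat(ph[:, None, :], h, axis=1))
    mask = np.ones((h, w), bool)
    pm = PhaseMovie(phase, mask, dt, pitch)
    vm = VoltageMovie(np.cos(phase), dt=dt, pitch=pitch, mask=mask,
                      meta={"generator": "plane_wave", "freq_hz": freq_hz})
    return pm, vm, GroundTruth(regime="plane",
                               params={"freq_hz": freq_hz,
                                       "wavelength_px": wavelength_px})


# ---------------------------------------------------------------------------
# focal source with guaranteed quiescence
# ---------------------------------------------------------------------------

def _ap_waveform(tau: np.ndarray, upstroke_ms: float, apd_ms: float) -> np.ndarray:
    """Stylized action potential: linear upstroke, raised-cosine repolarization."""
    v = np.zeros_like(tau)
    up = (tau >= 0) & (tau < upstroke_ms)
    v[up] = tau[up] / upstroke_ms
    rep = (tau >= upstroke_ms) & (tau < upstroke_ms + apd_ms)
    v[rep] = 0.5 * (1 + np.cos(np.pi * (tau[rep] - upstroke_ms) / apd_ms))
    return v


def focal_movie(origin: tuple[int, int], cycle_ms: float, cv_mm_per_ms: float,
                apd_ms: float, duration_ms: float, grid: tuple[int, int] = (128, 80),
                dt: float = 1.0, pitch: float = 0.44, upstroke_ms: float = 2.0,
                cycle_jitter_ms: float = 0.0, rng: np.random.Generator | None = None,
                n_beats: int | None = None) -> tuple[VoltageMovie, GroundTruth]:
    """Periodic focal source with full repolarization between beats.

    Each beat launches a circular wave from ``origin``; a pixel at distance
    ``d`` mm activates ``d / cv`` ms after the beat.  Raises when the wave
    cannot clear the field (transit + upstroke + APD) within one cycle,
    which would break the quiescence guarantee.
    """
    h, w = grid
    r0, c0 = origin
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("origin outside grid")
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dist_mm = np.hypot(rr - r0, cc - c0) * pitch
    transit = float(dist_mm.max() / cv_mm_per_ms)
    if cycle_ms - cycle_jitter_ms <= transit + upstroke_ms + apd_ms:
        raise ValueError(
            f"cycle {cycle_ms} ms too short for quiescence: transit {transit:.1f}"
            f" + upstroke {upstroke_ms} + APD {apd_ms} ms")

    n = int(round(duration_ms / dt))
    max_beats = int(np.floor((duration_ms - transit - upstroke_ms - apd_ms)
                             / cycle_ms)) + 1
    n_beats = max_beats if n_beats is None else min(n_beats, max_beats)
    if cycle_jitter_ms > 0:
        rng = rng or np.random.default_rng(0)
        beat_times = np.arange(n_beats) * cycle_ms + \
            rng.uniform(-cycle_jitter_ms, cycle_jitter_ms, n_beats)
        beat_times[0] = max(beat_times[0], 0.0)
    else:
        beat_times = np.arange(n_beats) * cycle_ms

    t_ms = np.arange(n, dtype=float) * dt
    data = np.zeros((n, h, w))
    act = dist_mm / cv_mm_per_ms
    for bt in beat_times:
        tau = t_ms[:, None, None] - bt - act[None, :, :]
        data += _ap_waveform(tau, upstroke_ms, apd_ms)
    mask = np.ones((h, w), bool)
    vm = VoltageMovie(data, dt=dt, pitch=pitch, mask=mask,
                      meta={"generator": "focal", "cycle_ms": cycle_ms})
    truth = GroundTruth(
        regime="focal",
        focal_events=[(int(round(bt / dt)), r0, c0) for bt in beat_times
                      if bt / dt < n],
        params={"origin": origin, "cycle_ms": cycle_ms, "cv": cv_mm_per_ms,
                "apd_ms": apd_ms, "duration_ms": duration_ms, "grid": grid})
    return vm, truth


# ---------------------------------------------------------------------------
# reaction-diffusion excitable medium
# ---------------------------------------------------------------------------

@dataclass
class RDParams:
    """Two-variable excitable kinetics (cubic activation, slow recovery)."""

    k: float = 8.0
    a: float = 0.15
    eps0: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    diffusion: float = 0.2
    dt: float = 0.05          # model time units per step
    ms_per_unit: float = 1.0  # model time unit -> ms mapping for output


@dataclass
class Stimulus:
    """Rectangular current injection in model time units."""

    t_start: float
    duration: float
    rows: slice
    cols: slice
    amplitude: float = 2.0


def _edge_laplacian(u: np.ndarray, wh: np.ndarray, wv: np.ndarray) -> np.ndarray:
    """Flux-form 5-point Laplacian with per-edge conductances (no-flux edges)."""
    lap = np.zeros_like(u)
    dv = wv * (u[1:, :] - u[:-1, :])
    lap[:-1, :] += dv
    lap[1:, :] -= dv
    dh = wh * (u[:, 1:] - u[:, :-1])
    lap[:, :-1] += dh
    lap[:, 1:] -= dh
    return lap


def fibrotic_edges(shape: tuple[int, int], fraction: float, longitudinal_bias: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Edge-conductance maps with a random ``fraction`` of edges removed.

    The longitudinal (horizontal) direction is ``longitudinal_bias`` times
    more likely to be selected, emulating interstitial fibrosis laid along
    fibres.
    """
    h, w = shape
    wh = np.ones((h, w - 1))
    wv = np.ones((h - 1, w))
    n_edges = wh.size + wv.size
    n_remove = int(round(fraction * n_edges))
    if n_remove == 0:
        return wh, wv
    # sample edges with bias on the horizontal class
    probs = np.concatenate([np.full(wh.size, longitudinal_bias),
                            np.full(wv.size, 1.0)])
    probs /= probs.sum()
    chosen = rng.choice(n_edges, size=n_remove, replace=False, p=probs)
    flat_h = chosen[chosen < wh.size]
    flat_v = chosen[chosen >= wh.size] - wh.size
    wh.ravel()[flat_h] = 0.0
    wv.ravel()[flat_v] = 0.0
    return wh, wv


def _check_stability(params: RDParams) -> None:
    limit = 1.0 / (4.0 * params.diffusion)
    if params.dt >= limit:
        raise ValueError(
            f"dt={params.dt} unstable for D={params.diffusion}; "
            f"use dt < {limit:.3f}")


def spiral_initial_state(shape: tuple[int, int],
                         front_col: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Broken-front initial condition that curls into a single spiral.

    A half-height excited strip with a refractory tail on its left; the
    free end at mid-height curls into the recovered region.
    """
    h, w = shape
    c0 = front_col if front_col is not None else w // 2
    u = np.zeros(shape)
    v = np.zeros(shape)
    u[: h // 2, c0:c0 + 4] = 1.0
    v[: h // 2, max(0, c0 - 8):c0] = 1.5
    return u, v


def rd_simulate(shape: tuple[int, int], duration_units: float,
                stimuli: Sequence[Stimulus], params: RDParams | None = None,
                wh: np.ndarray | None = None, wv: np.ndarray | None = None,
                eps_scale: np.ndarray | float = 1.0,
                sample_every: int | None = None, pitch: float = 0.44,
                record_u: bool = True,
                initial_state: tuple[np.ndarray, np.ndarray] | None = None,
                coupling: Callable[[np.ndarray, float], np.ndarray] | None = None,
                ) -> VoltageMovie:
    """Explicit integration of the excitable medium; returns the sampled movie.

    ``eps_scale`` locally multiplies the recovery rate (values > 1 shorten
    the action potential, modelling acetylcholine islands).  ``coupling``
    may inject an extra per-pixel current ``I(u, t_units)``.
    """
    p = params or RDParams()
    _check_stability(p)
    h, w = shape
    if wh is None:
        wh = np.ones((h, w - 1))
    if wv is None:
        wv = np.ones((h - 1, w))
    if sample_every is None:
        sample_every = max(1, int(round(1.0 / (p.dt * p.ms_per_unit))))
    n_steps = int(round(duration_units / p.dt))
    if initial_state is not None:
        u = np.array(initial_state[0], float)
        v = np.array(initial_state[1], float)
    else:
        u = np.zeros(shape)
        v = np.zeros(shape)
    frames = []
    eps_arr = np.asarray(eps_scale, float)
    for step in range(n_steps):
        t_units = step * p.dt
        current = np.zeros(shape)
        for s in stimuli:
            if s.t_start <= t_units < s.t_start + s.duration:
                current[s.rows, s.cols] += s.amplitude
        if coupling is not None:
            current = current + coupling(u, t_units)
        lap = _edge_laplacian(u, wh, wv)
        du = p.k * u * (u - p.a) * (1.0 - u) - u * v + p.diffusion * lap + current
        eps = (p.eps0 * eps_arr + p.mu1 * v / (u + p.mu2))
        dv = eps * (-v - p.k * u * (u - p.a - 1.0))
        u = u + p.dt * du
        v = v + p.dt * dv
        np.clip(u, -0.1, 1.5, out=u)
        if record_u and step % sample_every == 0:
            frames.append(u.copy())
    dt_ms = sample_every * p.dt * p.ms_per_unit
    return VoltageMovie(np.stack(frames), dt=dt_ms, pitch=pitch,
                        meta={"generator": "rd", "params": vars(p).copy()})


def cross_field_stimuli(shape: tuple[int, int], s2_time: float = 15.0,
                        amplitude: float = 2.0) -> list[Stimulus]:
    """S1 plane wave from the left edge plus a half-field S2 -> one spiral."""
    h, w = shape
    return [
        Stimulus(t_start=0.0, duration=0.5, rows=slice(0, h), cols=slice(0, 3),
                 amplitude=amplitude),
        Stimulus(t_start=s2_time, duration=0.5, rows=slice(0, h // 2),
                 cols=slice(0, w), amplitude=amplitude),
    ]


# ---------------------------------------------------------------------------
# two-layer breakthrough generator
# ---------------------------------------------------------------------------

@dataclass
class TwoLayerSpec:
    """Configuration of the coupled endo/epi sheet pair."""

    shape: tuple[int, int] = (96, 64)
    n_connections: int = 1
    connection_sites: list[tuple[int, int]] | None = None
    fibrosis_fraction: float = 0.0        # driven layer (A)
    fibrosis_fraction_b: float = 0.0      # receiving layer (B)
    longitudinal_bias: float = 4.0
    n_islands: int = 0
    island_radius_px: float = 5.5         # approx 2.4 mm at 0.44 mm pitch
    island_eps_factor: float = 3.0        # recovery speed-up inside islands
    apd_gradient: bool = False            # shorter recovery on layer B
    coupling_strength: float = 4.0
    duration_units: float = 120.0
    drive: str = "spiral"                 # spiral | pacing
    pacing_cycle_units: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fibrosis_fraction <= 0.166:
            raise ValueError("fibrosis_fraction outside [0, 0.166]")
        if not 0 <= self.fibrosis_fraction_b <= 0.166:
            raise ValueError("fibrosis_fraction_b outside [0, 0.166]")


def _island_map(shape: tuple[int, int], n_islands: int, radius: float,
                factor: float, rng: np.random.Generator) -> np.ndarray:
    eps = np.ones(shape)
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    for _ in range(n_islands):
        r0 = rng.uniform(0, h)
        c0 = rng.uniform(0, w)
        eps[np.hypot(rr - r0, cc - c0) <= radius] = factor
    return eps


def two_layer_simulate(spec: TwoLayerSpec, params: RDParams | None = None
                       ) -> tuple[VoltageMovie, VoltageMovie, GroundTruth]:
    """Two excitable sheets coupled resistively at discrete connection sites.

    Layer A is driven (cross-field spiral or corner pacing); layer B starts
    quiescent and can only be excited through the connections.  Ground
    truth records every upward 0.5-crossing of layer B at a connection site
    as a breakthrough (focal) event on the receiving layer.  With zero
    connections layer B is asserted silent.
    """
    p = params or RDParams()
    _check_stability(p)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape

    sites = spec.connection_sites
    if sites is None:
        sites = [(int(rng.integers(h // 8, h - h // 8)),
                  int(rng.integers(w // 8, w - w // 8)))
                 for _ in range(spec.n_connections)]
    if len(set(sites)) != len(sites):
        raise ValueError("connection sites must be distinct")

    wh_a, wv_a = fibrotic_edges(spec.shape, spec.fibrosis_fraction,
                                spec.longitudinal_bias, rng)
    wh_b, wv_b = fibrotic_edges(spec.shape, spec.fibrosis_fraction_b,
                                spec.longitudinal_bias, rng)
    eps_a = _island_map(spec.shape, spec.n_islands, spec.island_radius_px,
                        spec.island_eps_factor, rng)
    eps_b = _island_map(spec.shape, spec.n_islands, spec.island_radius_px,
                        spec.island_eps_factor, rng)
    if spec.apd_gradient:
        eps_b = eps_b * 2.0  # faster recovery -> shorter APD on layer B

    if spec.drive == "spiral":
        stims = []
        u_init, v_init = spiral_initial_state(spec.shape)
    else:
        u_init = v_init = None
        stims = [Stimulus(t_start=i * spec.pacing_cycle_units, duration=0.5,
                          rows=slice(0, 5), cols=slice(0, 5))
                 for i in range(int(spec.duration_units / spec.pacing_cycle_units))]
        u_init = v_init = None

    site_rows = np.array([s[0] for s in sites], int)
    site_cols = np.array([s[1] for s in sites], int)

    sample_every = max(1, int(round(1.0 / (p.dt * p.ms_per_unit))))
    n_steps = int(round(spec.duration_units / p.dt))
    if u_init is not None:
        u_a = u_init.copy()
        v_a = v_init.copy()
    else:
        u_a = np.zeros(spec.shape)
        v_a = np.zeros(spec.shape)
    u_b = np.zeros(spec.shape)
    v_b = np.zeros(spec.shape)
    frames_a, frames_b = [], []
    breakthroughs: list[tuple[int, int, int]] = []
    above = np.zeros(len(sites), bool)

    for step in range(n_steps):
        t_units = step * p.dt
        cur_a = np.zeros(spec.shape)
        for s in stims:
            if s.t_start <= t_units < s.t_start + s.duration:
                cur_a[s.rows, s.cols] += s.amplitude
        cur_b = np.zeros(spec.shape)
        if sites:
            diff = u_a[site_rows, site_cols] - u_b[site_rows, site_cols]
            cur_b[site_rows, site_cols] += spec.coupling_strength * diff
            cur_a[site_rows, site_cols] -= spec.coupling_strength * diff

        for (u, v, wh, wv, eps, cur) in ((u_a, v_a, wh_a, wv_a, eps_a, cur_a),
                                         (u_b, v_b, wh_b, wv_b, eps_b, cur_b)):
            lap = _edge_laplacian(u, wh, wv)
            du = p.k * u * (u - p.a) * (1.0 - u) - u * v + p.diffusion * lap + cur
            eps_t = p.eps0 * eps + p.mu1 * v / (u + p.mu2)
            dv = eps_t * (-v - p.k * u * (u - p.a - 1.0))
            u += p.dt * du
            v += p.dt * dv
            np.clip(u, -0.1, 1.5, out=u)

        if sites:
            now_above = u_b[site_rows, site_cols] > 0.5
            frame_idx = step // sample_every
            for i in np.flatnonzero(now_above & ~above):
                breakthroughs.append((frame_idx, sites[i][0], sites[i][1]))
            above = now_above

        if step % sample_every == 0:
            frames_a.append(u_a.copy())
            frames_b.append(u_b.copy())

    if not sites:
        assert np.max(np.abs(np.stack(frames_b))) < 1e-6, \
            "unconnected layer B became active"

    dt_ms = sample_every * p.dt * p.ms_per_unit
    meta = {"generator": "two_layer", "seed": spec.seed, "sites": sites}
    vm_a = VoltageMovie(np.stack(frames_a), dt=dt_ms, pitch=0.44, meta=meta)
    vm_b = VoltageMovie(np.stack(frames_b), dt=dt_ms, pitch=0.44, meta=meta)
    truth = GroundTruth(regime="two_layer", focal_events=breakthroughs,
                        params={"spec": vars(spec).copy(), "sites": sites,
                                "dt_ms": dt_ms})
    return vm_a, vm_b, truth


# ---------------------------------------------------------------------------
# measurement artefacts and random fields
# ---------------------------------------------------------------------------

def add_optical_noise(movie: VoltageMovie, snr_db: float, drift_amp: float = 0.0,
                      drift_hz: float = 0.3, seed: int = 0) -> VoltageMovie:
    """Add Gaussian noise at the requested SNR plus per-pixel sinusoidal drift."""
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    rng = np.random.default_rng(seed)
    sig_power = float(np.var(movie.data[:, movie.mask]))
    noise_power = sig_power / (10.0 ** (snr_db / 10.0))
    noise = rng.normal(0.0, np.sqrt(noise_power), movie.shape)
    out = movie.data + noise
    if drift_amp > 0:
        t = np.arange(movie.n_frames) * movie.dt / 1000.0
        phases = rng.uniform(0, TWO_PI, movie.shape[1:])
        out = out + drift_amp * np.sin(
            TWO_PI * drift_hz * t[:, None, None] + phases[None])
    return movie.with_data(out, snr_db=snr_db, drift_amp=drift_amp)


def random_smooth_phase(shape: tuple[int, int], sigma: float = 4.0,
                        seed: int = 0) -> np.ndarray:
    """Smooth random phase field in (-pi, pi] (argument of filtered noise).

    Contains vortices wherever the underlying complex field winds through
    zero, making it a natural stress input for charge-based detectors.
    """
    rng = np.random.default_rng(seed)
    zr = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    zi = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return wrap_phase(np.arctan2(zi, zr))
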