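"""Gridded optical-mapping movie I/O and run configuration.

A movie is a ``T x H x W`` stack of voltage/fluorescence samples with a
boolean valid-tissue mask, a frame interval ``dt`` (ms) and a pixel pitch
(mm).  Movies round-trip through multi-page TIFF, an HDF5 container, or a
NumPy ``.npz`` archive; derived products (singularity tracks, wavefront
events, density maps) are written as delimited tables and gridded arrays.

Coordinate convention: 0-based ``(frame, row, col)``; time in ms is
``frame * dt``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VoltageMovie",
    "RunConfig",
    "FormatError",
    "read_movie",
    "write_movie",
    "write_products",
    "read_density_map",
]

#: dataset/attribute names used in the HDF5 container
H5_DATA = "frames"
H5_MASK = "mask"
H5_ATTRS = ("dt_ms", "pitch_mm")

PRODUCT_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised when an input file does not parse as a valid movie."""


@dataclass
class VoltageMovie:
    """A ``T x H x W`` voltage movie plus acquisition metadata.

    Parameters
    ----------
    data:
        Samples, arbitrary units before normalization, in ``[0, 1]`` after.
    dt:
        Frame interval in ms (must be positive).
    pitch:
        Pixel edge length in mm (must be positive).
    mask:
        ``H x W`` boolean valid-tissue map; ``None`` means all-true.
    meta:
        Free-form provenance record.
    """

    data: np.ndarray
    dt: float = 1.0
    pitch: float = 0.44
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"movie must be T x H x W, got shape {self.data.shape}")
        t, h, w = self.data.shape
        if t < 2 or h < 3 or w < 3:
            raise FormatError(f"movie too small: T={t}, H={h}, W={w} (need T>=2, H,W>=3)")
        if not self.dt > 0:
            raise FormatError(f"dt must be positive, got {self.dt}")
        if not self.pitch > 0:
            raise FormatError(f"pitch must be positive, got {self.pitch}")
        if self.mask is None:
            self.mask = np.ones((h, w), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (h, w):
                raise FormatError(
                    f"mask shape {self.mask.shape} does not match frame shape {(h, w)}"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.dt

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt

    @property
    def area_cm2(self) -> float:
        """Mask area in cm^2 (valid pixels x pitch^2)."""
        return int(self.mask.sum()) * (self.pitch / 10.0) ** 2

    def with_data(self, data: np.ndarray, **meta: Any) -> "VoltageMovie":
        """Copy carrying new samples (same geometry/metadata)."""
        m = dict(self.meta)
        m.update(meta)
        return VoltageMovie(np.asarray(data, float), dt=self.dt, pitch=self.pitch,
                            mask=self.mask.copy(), meta=m)

    def with_mask(self, mask: np.ndarray) -> "VoltageMovie":
        return VoltageMovie(self.data, dt=self.dt, pitch=self.pitch,
                            mask=np.asarray(mask, bool), meta=dict(self.meta))


@dataclass
class RunConfig:
    """Pipeline parameters.

    Defaults reproduce the published processing chain: 9x9 spatial bin,
    2 Hz high-pass edge, band-pass top at 125 % of the mean dominant
    frequency, extrema window at 90 % of the mean cycle length, amplitude
    pair rejection at 15 % of the median pair amplitude, singularity
    charge tolerance 3.0 rad, isophase value -pi/2 with band 0.5 rad.
    """

    spatial_bin: int = 9
    band_low_hz: float = 2.0
    band_high_frac: float = 1.25
    extrema_window_frac: float = 0.9
    amp_reject_frac: float = 0.15
    ps_tol_rad: float = 3.0
    iso_theta: float = -np.pi / 2
    iso_band: float = 0.5
    nwf_radius_px: int = 3
    min_component_px: int = 1
    track_link_px: float = 5.0
    track_gap_frames: int = 0
    df_band_hz: tuple[float, float] = (2.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_bin < 1 or self.spatial_bin % 2 == 0:
            raise ValueError(f"spatial_bin must be odd and >= 1, got {self.spatial_bin}")
        if not 0 < self.iso_band < np.pi:
            raise ValueError(f"iso_band must be in (0, pi), got {self.iso_band}")
        if not 0 < self.ps_tol_rad < 2 * np.pi:
            raise ValueError(f"ps_tol_rad must be in (0, 2*pi), got {self.ps_tol_rad}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["df_band_hz"] = list(self.df_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        kwargs = dict(d)
        if "df_band_hz" in kwargs:
            kwargs["df_band_hz"] = tuple(kwargs["df_band_hz"])
        return cls(**kwargs)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# movie readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix == ".npz":
        return "npz"
    raise FormatError(f"cannot infer movie format from suffix {suffix!r}")


def read_movie(path: str | os.PathLike, fmt: str | None = None, *,
               dt: float | None = None, pitch: float | None = None) -> VoltageMovie:
    """Read a movie from TIFF, HDF5 or NPZ.

    ``dt``/``pitch`` overrides take precedence over file metadata; TIFF
    carries no metadata, so both must be supplied for TIFF input.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file: {p}")
    fmt = _infer_format(p, fmt)
    mask = None
    meta: dict = {"source": str(p), "format": fmt}

    if fmt == "tiff":
        import tifffile

        data = np.asarray(tifffile.imread(p))
        if data.ndim == 2:
            data = data[None]
        file_dt = file_pitch = None
    elif fmt == "hdf5":
        import h5py

        with h5py.File(p, "r") as fh:
            if H5_DATA not in fh:
                raise FormatError(f"missing dataset {H5_DATA!r} in {p}")
            data = fh[H5_DATA][...]
            mask = fh[H5_MASK][...].astype(bool) if H5_MASK in fh else None
            file_dt = fh.attrs.get("dt_ms")
            file_pitch = fh.attrs.get("pitch_mm")
    elif fmt == "npz":
        with np.load(p, allow_pickle=False) as arc:
            if "frames" not in arc:
                raise FormatError(f"missing array 'frames' in {p}")
            data = arc["frames"]
            mask = arc["mask"].astype(bool) if "mask" in arc else None
            file_dt = float(arc["dt_ms"]) if "dt_ms" in arc else None
            file_pitch = float(arc["pitch_mm"]) if "pitch_mm" in arc else None
    else:
        raise FormatError(f"unknown format {fmt!r}")

    dt = dt if dt is not None else (float(file_dt) if file_dt is not None else None)
    pitch = pitch if pitch is not None else (
        float(file_pitch) if file_pitch is not None else None)
    if dt is None:
        raise FormatError(f"{p}: frame interval (dt) absent from file and not supplied")
    if pitch is None:
        raise FormatError(f"{p}: pixel pitch absent from file and not supplied")
    return VoltageMovie(np.asarray(data, float), dt=dt, pitch=pitch, mask=mask, meta=meta)


def write_movie(movie: VoltageMovie, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a movie to TIFF (float32 pages), HDF5 or NPZ."""
    p = Path(path)
    fmt = _infer_format(p, fmt)
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(p, movie.data.astype(np.float32))
    elif fmt == "hdf5":
        import h5py

        with h5py.File(p, "w") as fh:
            fh.create_dataset(H5_DATA, data=movie.data)
            fh.create_dataset(H5_MASK, data=movie.mask)
            fh.attrs["dt_ms"] = movie.dt
            fh.attrs["pitch_mm"] = movie.pitch
    elif fmt == "npz":
        np.savez(p, frames=movie.data, mask=movie.mask,
                 dt_ms=movie.dt, pitch_mm=movie.pitch)
    else:
        raise FormatError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# derived-product tables
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ["track_id", "frame", "row", "col", "chirality", "rotations", "is_rotor"]
EVENT_COLUMNS = ["frame", "component_id", "wf_class", "centroid_row", "centroid_col",
                 "n_pixels"]


def tracks_to_frame(tracks: Iterable) -> pd.DataFrame:
    """Flatten ``PSTrack`` objects to one row per (track, frame)."""
    rows = []
    for tid, tr in enumerate(tracks):
        for pt in tr.points:
            rows.append((tid, pt.frame, pt.row, pt.col, pt.chirality,
                         tr.rotations, tr.is_rotor))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def events_to_frame(events: Iterable) -> pd.DataFrame:
    rows = [(ev.frame, ev.component_id, ev.wf_class, ev.origin[0], ev.origin[1],
             len(ev.pixels)) for ev in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_products(tracks: Sequence, events: Sequence, maps: Sequence,
                   path: str | os.PathLike, config: RunConfig | None = None) -> None:
    """Write tracks/events as CSV, density maps as text grids, plus a manifest.

    Layout under ``path``: ``tracks.csv``, ``events.csv``,
    ``map_<kind>.txt`` (one per map, plain ``numpy.savetxt`` grid with a
    JSON header line), and ``manifest.json``.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    tracks_to_frame(tracks).to_csv(out / "tracks.csv", index=False)
    events_to_frame(events).to_csv(out / "events.csv", index=False)
    map_files = []
    for i, m in enumerate(maps):
        name = f"map_{m.kind}_{i}.txt"
        header = json.dumps({"kind": m.kind, "duration_ms": m.duration_ms,
                             "area_cm2": m.area_cm2})
        np.savetxt(out / name, m.counts, header=header)
        map_files.append(name)
    manifest = {
        "schema_version": PRODUCT_SCHEMA_VERSION,
        "n_tracks": len(tracks),
        "n_events": len(events),
        "maps": map_files,
        "config": config.to_dict() if config is not None else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_density_map(path: str | os.PathLike):
    """Read back a density map written by :func:`write_products`."""
    from .singularities import DensityMap

    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = json.loads(header)
    counts = np.loadtxt(path)
    return DensityMap(counts=counts, kind=meta["kind"],
                      duration_ms=meta["duration_ms"], area_cm2=meta["area_cm2"])
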