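"""Core data model for TCSPC FLIM cubes and container-format I/O.

A FLIM acquisition is stored as a 3D photon-count cube indexed
``(row, col, time_channel)``: each pixel holds a fluorescence decay
histogram of photon arrival times.  Time channel ``k`` spans
``[k*dt, (k+1)*dt)`` picoseconds (half-open bins).  The canonical
interchange container is HDF5 (dataset ``/counts`` plus attributes);
multi-page TIFF with a JSON metadata sidecar is supported for exchange
with image tools.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

__all__ = [
    "DecayCube",
    "IntensityImage",
    "read_cube",
    "write_cube",
    "intensity_image",
    "rebin_time",
    "DEFAULT_CHANNEL_WIDTH_PS",
    "DEFAULT_N_CHANNELS",
]

# TCSPC module default calibration: 1024 time channels of 19.97 ps.
DEFAULT_CHANNEL_WIDTH_PS = 19.97
DEFAULT_N_CHANNELS = 1024


@dataclass
class DecayCube:
    """Per-pixel photon-count decay histograms with time calibration.

    Parameters
    ----------
    counts
        Non-negative integer array of shape ``(n_rows, n_cols, n_channels)``.
    channel_width
        Width of one time channel in picoseconds.
    meta
        Free-form acquisition metadata (string keys and values).
    """

    counts: np.ndarray
    channel_width: float = DEFAULT_CHANNEL_WIDTH_PS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError(
                f"decay cube must be 3D (row, col, channel); got {self.counts.ndim}D"
            )
        if self.counts.shape[2] < 1:
            raise ValueError("decay cube needs at least 1 time channel")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("photon counts must be integral")
            self.counts = as_int
        if self.counts.min(initial=0) < 0:
            raise ValueError("photon counts must be non-negative")
        if self.channel_width <= 0:
            raise ValueError("channel_width must be positive (picoseconds)")

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def total_photons(self) -> int:
        return int(self.counts.sum())

    def pixel_totals(self) -> np.ndarray:
        """Total counts per pixel, shape ``(n_rows, n_cols)``."""
        return self.counts.sum(axis=2)

    def time_axis_ps(self) -> np.ndarray:
        """Left bin edges of the time channels in picoseconds."""
        return np.arange(self.n_channels) * self.channel_width


@dataclass
class IntensityImage:
    """Per-pixel total photon counts (decay cube summed over time)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("intensity image must be 2D")
        if self.values.min(initial=0) < 0:
            raise ValueError("intensities must be non-negative")

    def total_photons(self) -> int:
        return int(self.values.sum())


def intensity_image(cube: DecayCube) -> IntensityImage:
    """Sum the cube over time channels; photon counts are conserved."""
    return IntensityImage(cube.pixel_totals())


def rebin_time(cube: DecayCube, b: int) -> DecayCube:
    """Aggregate the time axis into ``b`` contiguous bins.

    When ``n_channels`` is not divisible by ``b`` the last bin absorbs the
    remainder channels, so the total photon count is always conserved.
    ``channel_width`` is scaled by the nominal bin size.
    """
    n = cube.n_channels
    if not 1 <= b <= n:
        raise ValueError(f"b must be in [1, {n}]; got {b}")
    if b == n:
        return DecayCube(cube.counts.copy(), cube.channel_width, dict(cube.meta))
    size = n // b
    edges = np.arange(1, b) * size  # split points; tail goes to the last bin
    parts = np.split(cube.counts, edges, axis=2)
    out = np.stack([p.sum(axis=2) for p in parts], axis=2)
    return DecayCube(out, cube.channel_width * size, dict(cube.meta))


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

_HDF5_EXT = {".h5", ".hdf5", ".hdf"}
_TIFF_EXT = {".tif", ".tiff"}


def _resolve_format(path: str, hint: str) -> str:
    if hint != "auto":
        return hint
    ext = os.path.splitext(path)[1].lower()
    if ext in _HDF5_EXT:
        return "hdf5"
    if ext in _TIFF_EXT:
        return "tiff"
    if ext == ".sdt":
        return "sdt"
    raise ValueError(f"cannot infer FLIM container format from extension {ext!r}")


def read_cube(path: str, format_hint: str = "auto") -> DecayCube:
    """Read a decay cube from HDF5, multi-page TIFF (+ JSON sidecar) or SDT.

    SDT (Becker & Hickl) support requires the optional ``sdtfile`` package.
    """
    if not os.path.exists(path):
        raise IOError(f"FLIM input file not found: {path}")
    fmt = _resolve_format(path, format_hint)
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt == "tiff":
        return _read_tiff(path)
    if fmt == "sdt":
        return _read_sdt(path)
    raise ValueError(f"unknown format {fmt!r}; expected hdf5, tiff, sdt or auto")


def write_cube(cube: DecayCube, path: str, format: str = "auto") -> str:
    """Write a decay cube; returns the path written.

    HDF5 layout: dataset ``/counts`` (row, col, channel) unsigned integer with
    attribute ``channel_width_ps`` and one ``meta/<key>`` attribute per
    metadata entry.  TIFF layout: one 16-bit page per time channel plus a
    ``<path>.json`` sidecar carrying the calibration and metadata.
    """
    fmt = _resolve_format(path, format)
    if fmt == "hdf5":
        return _write_hdf5(cube, path)
    if fmt == "tiff":
        return _write_tiff(cube, path)
    raise ValueError(f"unsupported output format {fmt!r}; use hdf5 or tiff")


def _write_hdf5(cube: DecayCube, path: str) -> str:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("counts", data=cube.counts.astype(np.uint32))
        ds.attrs["channel_width_ps"] = float(cube.channel_width)
        for key, val in cube.meta.items():
            ds.attrs[f"meta/{key}"] = str(val)
    return path


def _read_hdf5(path: str) -> DecayCube:
    try:
        with h5py.File(path, "r") as f:
            ds = f["counts"]
            counts = np.asarray(ds[...])
            width = float(ds.attrs.get("channel_width_ps", DEFAULT_CHANNEL_WIDTH_PS))
            meta = {
                key[len("meta/"):]: str(ds.attrs[key])
                for key in ds.attrs
                if key.startswith("meta/")
            }
    except OSError as exc:
        raise IOError(f"unreadable HDF5 file {path}: {exc}") from exc
    if counts.ndim != 3:
        raise ValueError(f"{path}: /counts must be 3D (row, col, channel)")
    return DecayCube(counts.astype(np.int64), width, meta)


def _write_tiff(cube: DecayCube, path: str) -> str:
    if cube.counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise OverflowError(
            "counts exceed the 16-bit TIFF range (65535); write HDF5 instead"
        )
    # pages are (row, col) planes, one per time channel
    pages = np.moveaxis(cube.counts.astype(np.uint16), 2, 0)
    tifffile.imwrite(path, pages)
    sidecar = {"channel_width_ps": float(cube.channel_width),
               "meta": {k: str(v) for k, v in cube.meta.items()}}
    with open(path + ".json", "w") as f:
        json.dump(sidecar, f, indent=1, sort_keys=True)
    return path


def _read_tiff(path: str) -> DecayCube:
    try:
        pages = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise IOError(f"unreadable TIFF file {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2D planes")
    counts = np.moveaxis(pages, 0, 2).astype(np.int64)
    width = DEFAULT_CHANNEL_WIDTH_PS
    meta: dict = {}
    sidecar_path = path + ".json"
    if os.path.exists(sidecar_path):
        with open(sidecar_path) as f:
            sidecar = json.load(f)
        width = float(sidecar.get("channel_width_ps", width))
        meta = dict(sidecar.get("meta", {}))
    return DecayCube(counts, width, meta)


def _read_sdt(path: str) -> DecayCube:
    try:
        import sdtfile  # optional adapter for the instrument's native format
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading Becker & Hickl .sdt files requires the optional "
            "'sdtfile' package; convert to HDF5 or install sdtfile"
        ) from exc
    sdt = sdtfile.SdtFile(path)  # pragma: no cover
    data = np.asarray(sdt.data[0])  # pragma: no cover
    times = np.asarray(sdt.times[0])  # pragma: no cover
    width = float(np.mean(np.diff(times))) * 1e12  # pragma: no cover
    return DecayCube(data.astype(np.int64), width)  # pragma: no cover
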