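"""Image I/O, calibration handling, and shared preprocessing.

Every stage of the pipeline consumes a :class:`MovieStack`: a 5-D intensity
array with fixed axis order ``(t, c, z, y, x)`` plus physical calibration
(voxel size in micrometres, frame interval in seconds).  Fixed volumes are
movies with a single time point.  All voxel indices are 0-based and all
region bounds are half-open; physical positions are micrometres with the
origin at the centre of voxel (0, 0, 0).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import AsymdivError, MissingCalibrationError

__all__ = [
    "MovieStack",
    "RegionBox",
    "Annotation",
    "read_movie",
    "write_movie",
    "read_sidecar",
    "max_intensity_projection",
    "butterworth_lowpass",
    "subtract_background",
]

_AXES = "TCZYX"


@dataclass
class RegionBox:
    """Axis-aligned box in voxel coordinates, half-open on every axis."""

    lower: tuple[int, ...]
    upper: tuple[int, ...]

    def __post_init__(self):
        if len(self.lower) != len(self.upper):
            raise ValueError("lower and upper must have the same length")
        self.lower = tuple(int(v) for v in self.lower)
        self.upper = tuple(int(v) for v in self.upper)
        for lo, hi in zip(self.lower, self.upper):
            if not lo < hi:
                raise ValueError(f"empty region: lower {self.lower} !< upper {self.upper}")

    @property
    def ndim(self) -> int:
        return len(self.lower)

    def slices(self) -> tuple[slice, ...]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))

    def validate_within(self, shape: tuple[int, ...]) -> None:
        if len(shape) != self.ndim:
            raise ValueError(f"region is {self.ndim}-D but image is {len(shape)}-D")
        for lo, hi, n in zip(self.lower, self.upper, shape):
            if lo < 0 or hi > n:
                raise ValueError(f"region {self.lower}..{self.upper} outside image shape {shape}")

    @classmethod
    def from_dict(cls, d: dict) -> "RegionBox":
        return cls(tuple(d["lower"]), tuple(d["upper"]))

    def to_dict(self) -> dict:
        return {"lower": list(self.lower), "upper": list(self.upper)}


@dataclass
class Annotation:
    """Manual annotations supplied alongside a movie.

    ``anterior_direction`` is a unit vector in image ``(y, x)`` coordinates
    pointing from anterior to posterior reference anatomy; it disambiguates
    the polarity of the centrosome axis, which is not inferable from the
    image alone.
    """

    anaphase_frame: int | None = None
    anterior_direction: np.ndarray | None = None
    blank_region: RegionBox | None = None
    notes: str = ""

    def __post_init__(self):
        if self.anterior_direction is not None:
            v = np.asarray(self.anterior_direction, dtype=float)
            n = float(np.linalg.norm(v))
            if abs(n - 1.0) > 1e-6:
                if n == 0:
                    raise ValueError("anterior_direction must be nonzero")
                v = v / n
            self.anterior_direction = v


@dataclass
class MovieStack:
    """Multi-channel time-lapse (or fixed) image with physical calibration."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]  # (z, y, x) in um
    frame_interval: float  # seconds
    channel_labels: list[str] = field(default_factory=list)
    bit_depth_hint: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"data must be 5-D (t, c, z, y, x), got {self.data.ndim}-D")
        if min(self.data.shape) < 1:
            raise ValueError("all axis lengths must be >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive values (z, y, x) in um")
        self.frame_interval = float(self.frame_interval)
        if self.n_frames > 1 and self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 for time-lapse data")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal the c-axis length")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise ValueError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_labels.index(channel)
        except ValueError:
            raise ValueError(
                f"unknown channel {channel!r}; available: {self.channel_labels}"
            ) from None


def read_sidecar(path: str | Path) -> dict:
    """Load a YAML/JSON sidecar config."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def annotation_from_sidecar(sidecar: dict) -> Annotation:
    ann = sidecar.get("annotations") or {}
    direction = ann.get("anterior_direction")
    blank = ann.get("blank_region")
    return Annotation(
        anaphase_frame=ann.get("anaphase_frame"),
        anterior_direction=np.asarray(direction, float) if direction is not None else None,
        blank_region=RegionBox.from_dict(blank) if blank else None,
        notes=ann.get("notes", ""),
    )


def _parse_ome(xml_str: str) -> dict:
    """Extract calibration from OME-XML, tolerating namespaces."""
    out: dict = {}
    try:
        root = ET.fromstring(xml_str)
    except ET.ParseError:
        return out
    pixels = root.find(".//{*}Pixels")
    if pixels is None:
        return out
    sizes = []
    for key in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX"):
        v = pixels.get(key)
        sizes.append(float(v) if v is not None else None)
    if all(s is not None for s in sizes):
        out["voxel_size_um"] = sizes
    ti = pixels.get("TimeIncrement")
    if ti is not None:
        out["frame_interval_s"] = float(ti)
    names = [c.get("Name") for c in pixels.findall("{*}Channel")]
    if names and all(n is not None for n in names):
        out["channels"] = names
    return out


def read_movie(path: str | Path, sidecar: str | Path | dict | None = None) -> MovieStack:
    """Read a TIFF/OME-TIFF into a :class:`MovieStack`.

    Axes are normalized to ``(t, c, z, y, x)``; axes absent from the file
    are inserted with length 1.  Calibration comes from OME metadata when
    present; a sidecar config (path or dict) overrides / supplements it.

    Raises
    ------
    MissingCalibrationError
        If the voxel size (or, for time-lapse data, the frame interval)
        is available from neither the file metadata nor the sidecar.
    """
    path = Path(path)
    if isinstance(sidecar, (str, Path)):
        sidecar = read_sidecar(sidecar)
    sidecar = dict(sidecar or {})

    try:
        tif = tifffile.TiffFile(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise AsymdivError(f"cannot read image file {path}: {exc}") from exc
    with tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        meta = _parse_ome(tif.ome_metadata) if tif.ome_metadata else {}

    # Normalize axes: squeeze unknown singleton axes, then insert missing ones.
    known = ""
    arr = data
    drop = []
    for i, ax in enumerate(axes):
        if ax in _AXES:
            known += ax
        elif data.shape[i] == 1:
            drop.append(i)
        else:
            # unlabeled stack axis (plain TIFF): take the first vacant slot,
            # preferring z (an un-annotated plane stack is usually a volume)
            for guess in "ZTC":
                if guess not in axes and guess not in known:
                    known += guess
                    break
            else:
                raise AsymdivError(f"unsupported non-singleton axis {ax!r} in {path}")
    for i in reversed(drop):
        arr = np.squeeze(arr, axis=i)
    # Insert missing known axes at canonical positions
    for target_pos, ax in enumerate(_AXES):
        if ax not in known:
            arr = np.expand_dims(arr, axis=target_pos)
            known = known[:target_pos] + ax + known[target_pos:]
    # Reorder to TCZYX
    order = [known.index(ax) for ax in _AXES]
    arr = np.transpose(arr, order)

    voxel = sidecar.get("voxel_size_um", meta.get("voxel_size_um"))
    if voxel is None:
        raise MissingCalibrationError(
            "voxel_size",
            f"{path} has no voxel size in its metadata and the sidecar "
            "provides no 'voxel_size_um' — cannot calibrate",
        )
    interval = sidecar.get("frame_interval_s", meta.get("frame_interval_s"))
    if interval is None:
        if arr.shape[0] > 1:
            raise MissingCalibrationError(
                "frame_interval",
                f"{path} is a time-lapse but no 'frame_interval_s' is available",
            )
        interval = 0.0
    channels = sidecar.get("channels", meta.get("channels")) or []
    return MovieStack(
        data=arr,
        voxel_size=tuple(voxel),
        frame_interval=float(interval),
        channel_labels=list(channels),
    )


def write_movie(movie: MovieStack, path: str | Path) -> None:
    """Write a MovieStack as OME-TIFF with full calibration metadata."""
    vz, vy, vx = movie.voxel_size
    metadata = {
        "axes": _AXES,
        "PhysicalSizeZ": vz,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeY": vy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeX": vx,
        "PhysicalSizeXUnit": "µm",
        "Channel": {"Name": list(movie.channel_labels)},
    }
    if movie.frame_interval > 0:
        metadata["TimeIncrement"] = movie.frame_interval
        metadata["TimeIncrementUnit"] = "s"
    tifffile.imwrite(path, movie.data, ome=True, metadata=metadata)


def max_intensity_projection(
    movie: MovieStack,
    channel: int | str,
    z_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Maximum intensity projection along z.

    Parameters
    ----------
    z_range
        Half-open ``(z_lo, z_hi)`` interval of planes to project; defaults
        to the full z extent.

    Returns
    -------
    ndarray with shape ``(t, y, x)``.
    """
    c = movie.channel_index(channel)
    nz = movie.data.shape[2]
    if z_range is None:
        z_range = (0, nz)
    z_lo, z_hi = int(z_range[0]), int(z_range[1])
    if not (0 <= z_lo < z_hi <= nz):
        raise ValueError(f"empty or out-of-range z_range {z_range} for {nz} planes")
    return movie.data[:, c, z_lo:z_hi].max(axis=1)


def butterworth_lowpass(image: np.ndarray, cutoff_fraction: float, order: int) -> np.ndarray:
    """Frequency-domain Butterworth low-pass filter, applied per 2-D plane.

    The gain is ``1 / (1 + (f / fc)**(2*order))`` with ``f`` the radial
    spatial frequency in cycles/pixel and ``fc = cutoff_fraction``.  The DC
    gain is exactly 1, so the mean intensity is preserved.  Leading axes
    (time, z) are treated as a stack of independent planes.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if not 0 < cutoff_fraction <= 0.5:
        raise ValueError("cutoff_fraction must be in (0, 0.5]")
    if order < 1:
        raise ValueError("order must be >= 1")
    ny, nx = image.shape[-2:]
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    f = np.hypot(fy, fx)
    gain = 1.0 / (1.0 + (f / cutoff_fraction) ** (2 * order))
    spec = np.fft.fft2(image, axes=(-2, -1))
    return np.real(np.fft.ifft2(spec * gain, axes=(-2, -1)))


def subtract_background(image: np.ndarray, blank: RegionBox) -> np.ndarray:
    """Subtract the mean intensity of a blank region; clip negatives to 0.

    The blank box indexes the trailing axes of ``image`` (so a 2-D box
    applies to every plane of a stack).
    """
    image = np.asarray(image, dtype=float)
    nd = blank.ndim
    if nd > image.ndim:
        raise ValueError("blank region has more dimensions than the image")
    blank.validate_within(image.shape[-nd:])
    region = image[(Ellipsis,) + blank.slices()]
    if region.size == 0:
        raise ValueError("blank region is empty")
    return np.clip(image - region.mean(), 0.0, None)
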