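"""Dynamic readouts of registered tracks: kymographs, positions, velocities,
and the asymmetry index with its three-way classification.

The asymmetry index of a daughter-cell pair is

    X = (sum_post - sum_ant) / (sum_post + sum_ant)

where the sums are background-subtracted total fluorescence intensities in
the posterior and anterior daughter.  X = 0 is perfect symmetry and
X = +1 / -1 absolute posterior / anterior asymmetry.  |X| >= 0.2 — one
daughter holding at least 50% more signal than the other — is classified
asymmetric.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np

from .errors import AsymdivError, DegenerateGeometryError
from .io_core import MovieStack, RegionBox, max_intensity_projection, subtract_background
from .registration import CellRegistration, project_onto_axis
from .tracking import Track

__all__ = [
    "Kymograph",
    "AsymmetryResult",
    "VelocityResult",
    "build_kymograph",
    "telophase_position",
    "average_velocity",
    "asymmetry_index",
    "classify_asymmetry",
    "daughter_intensity_sums",
    "compute_asymmetry",
]


@dataclass
class Kymograph:
    """Occupancy-probability matrix over (time window, axial position bins).

    Each row is one frame in the window [t0 - W, t0 + W]; each cell holds
    the probability of finding a tracked endosome in that position bin, so
    every row with at least one endosome sums to 1.
    """

    values: np.ndarray  # (n_rows, n_bins)
    frames: np.ndarray  # absolute frame indices, one per row
    bin_edges: np.ndarray  # n_bins + 1 edges over clamped s in [0, 1]
    t0: int
    frame_interval_s: float
    truncated: bool = False

    def to_png(self, path) -> None:
        """8-bit grayscale image: probability scaled to [0, 255]."""
        import imageio.v3 as iio

        img = np.round(np.clip(self.values, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(path, img)


@dataclass
class AsymmetryResult:
    """Asymmetry of one cell's daughter pair for one channel."""

    sum_ant: float
    sum_post: float
    index: float
    label: str
    threshold: float = 0.2


@dataclass
class VelocityResult:
    """Per-cell endosome motion summary over a time window (um/min)."""

    speed_um_min: float  # mean unsigned step speed
    axial_um_min: float  # mean signed axial velocity (posterior positive)
    n_steps: int


def _clamped_s(track: Track, registration: CellRegistration, frame: int) -> float | None:
    spot = track.spot_at(frame)
    if spot is None:
        return None
    s = project_onto_axis(spot.position_um, registration, frame)
    return float(np.clip(s, 0.0, 1.0))


def build_kymograph(
    tracks: list[Track],
    registration: CellRegistration,
    window_frames: int = 20,
    n_bins: int = 50,
) -> Kymograph:
    """Histogram tracked endosome positions per frame around anaphase.

    Positions are normalized axial coordinates clamped to [0, 1], binned
    into ``n_bins`` equal bins, and each row is normalized by the number
    of endosomes present in that frame.  A window reaching beyond the
    registered frames is truncated with a warning.
    """
    if registration.t0 is None:
        raise AsymdivError("registration has no anaphase frame t0")
    lo = registration.t0 - window_frames
    hi = registration.t0 + window_frames
    truncated = lo < 0 or hi > registration.n_frames - 1
    if truncated:
        _warnings.warn("kymograph window exceeds the movie extent; truncating")
        lo, hi = max(lo, 0), min(hi, registration.n_frames - 1)
    frames = np.arange(lo, hi + 1)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    values = np.zeros((frames.size, n_bins))
    for row, f in enumerate(frames):
        ss = [s for tr in tracks if (s := _clamped_s(tr, registration, int(f))) is not None]
        if ss:
            hist, _ = np.histogram(ss, bins=edges)
            values[row] = hist / len(ss)
    return Kymograph(values=values, frames=frames, bin_edges=edges,
                     t0=registration.t0, frame_interval_s=registration.frame_interval_s,
                     truncated=truncated)


def telophase_position(
    tracks: list[Track],
    registration: CellRegistration,
    t_query_min: float = 4.0,
) -> float:
    """Mean clamped axial coordinate of all endosomes at one time point.

    ``t_query_min`` is minutes relative to anaphase onset; the nearest
    frame is used (telophase is T = +4 min by convention).
    """
    frame = registration.frame_at_minutes(t_query_min)
    frame = int(np.clip(frame, 0, registration.n_frames - 1))
    ss = [s for tr in tracks if (s := _clamped_s(tr, registration, frame)) is not None]
    if not ss:
        raise AsymdivError(f"no endosomes present at frame {frame}")
    return float(np.mean(ss))


def average_velocity(
    tracks: list[Track],
    registration: CellRegistration,
    window_minutes: tuple[float, float] = (-4.0, 4.0),
    per_track: bool = False,
) -> VelocityResult:
    """Mean endosome speed (um/min) over a window around anaphase.

    One step's speed is the Euclidean displacement between consecutive
    observed spots divided by the elapsed time (gap-closed steps span
    more than one frame interval).  The per-cell value averages over all
    steps of all tracks by default; ``per_track`` averages track means
    instead.  The signed axial component (posterior positive) is reported
    alongside.
    """
    f_lo = registration.frame_at_minutes(window_minutes[0])
    f_hi = registration.frame_at_minutes(window_minutes[1])
    speeds, axials, per_track_speeds = [], [], []
    for tr in tracks:
        tr_speeds = []
        for s0, s1 in zip(tr.spots[:-1], tr.spots[1:]):
            if s0.frame < f_lo or s1.frame > f_hi:
                continue
            dt_min = (s1.frame - s0.frame) * registration.frame_interval_s / 60.0
            disp = s1.position_um[-2:] - s0.position_um[-2:]
            speed = float(np.linalg.norm(disp)) / dt_min
            u = registration.unit(s1.frame)
            axials.append(float(disp @ u) / dt_min)
            speeds.append(speed)
            tr_speeds.append(speed)
        if tr_speeds:
            per_track_speeds.append(float(np.mean(tr_speeds)))
    if not speeds:
        raise AsymdivError("no track steps inside the velocity window")
    mean_speed = float(np.mean(per_track_speeds if per_track else speeds))
    return VelocityResult(speed_um_min=mean_speed,
                          axial_um_min=float(np.mean(axials)),
                          n_steps=len(speeds))


def asymmetry_index(sum_post: float, sum_ant: float) -> float:
    """Normalized intensity ratio X = (post - ant) / (post + ant) in [-1, 1]."""
    if sum_post < 0 or sum_ant < 0:
        raise ValueError("intensity sums must be nonnegative")
    total = sum_post + sum_ant
    if total == 0:
        raise AsymdivError("asymmetry index undefined: both intensity sums are zero")
    return (sum_post - sum_ant) / total


def classify_asymmetry(index: float, threshold: float = 0.2) -> str:
    """Three-way label: posterior if X >= threshold, anterior if X <= -threshold.

    The boundary cases X = +-threshold count as asymmetric (non-strict
    inequalities).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if index >= threshold:
        return "posterior"
    if index <= -threshold:
        return "anterior"
    return "symmetric"


def daughter_intensity_sums(
    movie: MovieStack,
    registration: CellRegistration,
    channel: int | str,
    t_frame: int,
    blank: RegionBox | None = None,
    z_range: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Background-subtracted intensity sums (anterior, posterior) at a frame.

    The daughters are delimited by the splitting plane: the plane through
    the centrosome midpoint perpendicular to the A-P axis at ``t_frame``;
    the anterior side is the one holding the anterior centrosome.
    """
    mip = max_intensity_projection(movie, channel, z_range)[t_frame]
    if blank is not None:
        mip = subtract_background(mip, blank)
    u = registration.unit(t_frame)
    mid = registration.origin(t_frame)
    if registration.axis_lengths()[t_frame] == 0:
        raise DegenerateGeometryError(f"degenerate axis at frame {t_frame}")
    _, vy, vx = movie.voxel_size
    yy = np.arange(mip.shape[0])[:, None] * vy
    xx = np.arange(mip.shape[1])[None, :] * vx
    axial = (yy - mid[0]) * u[0] + (xx - mid[1]) * u[1]
    # pixels exactly on the plane are shared half-half, so axis reversal
    # maps (ant, post) -> (post, ant) exactly
    on_plane = 0.5 * float(mip[axial == 0].sum())
    sum_post = float(mip[axial > 0].sum()) + on_plane
    sum_ant = float(mip[axial < 0].sum()) + on_plane
    return sum_ant, sum_post


def compute_asymmetry(
    movie: MovieStack,
    registration: CellRegistration,
    channel: int | str,
    t_frame: int,
    blank: RegionBox | None = None,
    threshold: float = 0.2,
) -> AsymmetryResult:
    """Daughter intensity sums -> asymmetry index -> class label."""
    sum_ant, sum_post = daughter_intensity_sums(movie, registration, channel,
                                                t_frame, blank)
    x = asymmetry_index(sum_post, sum_ant)
    return AsymmetryResult(sum_ant=sum_ant, sum_post=sum_post, index=x,
                           label=classify_asymmetry(x, threshold), threshold=threshold)
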