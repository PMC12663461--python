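"""Spatial and temporal registration of a dividing cell.

The two centrosomes define the cell's anterior–posterior (A-P) axis: the
anterior centrosome gets normalized coordinate 0 and the posterior one 1,
and every tracked object is projected onto this axis.  The midpoint
between the centrosomes is the spatial origin.  Temporal registration
sets T = 0 at anaphase onset, operationally the first appearance of the
cleavage furrow.

Axis polarity is biological (it comes from embryo anatomy) and cannot be
inferred from the image alone, so anterior/posterior assignment requires
an explicit anatomical direction vector from the annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AsymdivError, DegenerateGeometryError
from .io_core import Annotation, MovieStack, max_intensity_projection
from .tracking import Spot, detect_centrosome_pair, detect_movie_spots

__all__ = [
    "CellRegistration",
    "assign_anterior_posterior",
    "detect_anaphase_onset",
    "project_onto_axis",
    "register_movie",
]


@dataclass
class CellRegistration:
    """Per-frame A-P axis from the centrosome pair plus the anaphase frame."""

    anterior_um: np.ndarray  # (n_frames, 2) (y, x) um
    posterior_um: np.ndarray
    frame_interval_s: float
    t0: int | None = None

    def __post_init__(self):
        self.anterior_um = np.atleast_2d(np.asarray(self.anterior_um, float))
        self.posterior_um = np.atleast_2d(np.asarray(self.posterior_um, float))
        if self.anterior_um.shape != self.posterior_um.shape:
            raise ValueError("anterior and posterior position arrays must match")
        if np.any(self.axis_lengths() <= 0):
            raise DegenerateGeometryError("centrosome axis has zero length in some frame")

    @property
    def n_frames(self) -> int:
        return self.anterior_um.shape[0]

    def axis_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.posterior_um - self.anterior_um, axis=1)

    def unit(self, frame: int) -> np.ndarray:
        d = self.posterior_um[frame] - self.anterior_um[frame]
        n = np.linalg.norm(d)
        if n == 0:
            raise DegenerateGeometryError(f"degenerate axis at frame {frame}")
        return d / n

    def origin(self, frame: int) -> np.ndarray:
        return 0.5 * (self.anterior_um[frame] + self.posterior_um[frame])

    def time_minutes(self, frame: int) -> float:
        if self.t0 is None:
            raise AsymdivError("anaphase frame t0 is not set")
        return (frame - self.t0) * self.frame_interval_s / 60.0

    def frame_at_minutes(self, t_min: float) -> int:
        if self.t0 is None:
            raise AsymdivError("anaphase frame t0 is not set")
        return int(round(self.t0 + t_min * 60.0 / self.frame_interval_s))


def _pair_positions(pair) -> tuple[np.ndarray, np.ndarray]:
    a, b = pair
    pa = a.position_um if isinstance(a, Spot) else np.asarray(a, float)
    pb = b.position_um if isinstance(b, Spot) else np.asarray(b, float)
    return np.asarray(pa, float)[-2:], np.asarray(pb, float)[-2:]


def assign_anterior_posterior(
    pairs_by_frame: dict[int, tuple],
    anterior_direction: np.ndarray,
    frame_interval_s: float,
    n_frames: int | None = None,
    tol: float = 1e-9,
) -> CellRegistration:
    """Label the centrosome pair anterior/posterior and build a registration.

    Pair identity is kept consistent across frames by nearest-neighbour
    matching; the centrosome whose *mean* position projects lower onto
    ``anterior_direction`` is anterior, and labels never flip mid-movie.
    Frames without a detected pair are filled by linear interpolation
    (edge frames by extension).
    """
    if not pairs_by_frame:
        raise ValueError("no centrosome pairs provided")
    direction = np.asarray(anterior_direction, float)
    direction = direction / np.linalg.norm(direction)

    frames = sorted(pairs_by_frame)
    track1: list[np.ndarray] = []
    track2: list[np.ndarray] = []
    for f in frames:
        pa, pb = _pair_positions(pairs_by_frame[f])
        if not track1:
            track1.append(pa)
            track2.append(pb)
            continue
        straight = np.linalg.norm(pa - track1[-1]) + np.linalg.norm(pb - track2[-1])
        swapped = np.linalg.norm(pb - track1[-1]) + np.linalg.norm(pa - track2[-1])
        if swapped < straight:
            pa, pb = pb, pa
        track1.append(pa)
        track2.append(pb)

    p1 = float(np.mean([p @ direction for p in track1]))
    p2 = float(np.mean([p @ direction for p in track2]))
    if abs(p1 - p2) <= tol:
        raise DegenerateGeometryError(
            "mean centrosome projections onto the anterior direction are equal; "
            "label the pair manually"
        )
    ant_sparse, post_sparse = (track1, track2) if p1 < p2 else (track2, track1)

    n = n_frames if n_frames is not None else frames[-1] + 1
    all_frames = np.arange(n)
    ant = np.empty((n, 2))
    post = np.empty((n, 2))
    for k in range(2):
        ant[:, k] = np.interp(all_frames, frames, [p[k] for p in ant_sparse])
        post[:, k] = np.interp(all_frames, frames, [p[k] for p in post_sparse])
    return CellRegistration(ant, post, frame_interval_s)


def detect_anaphase_onset(
    movie: MovieStack,
    registration: CellRegistration,
    membrane_channel: int | str = "membrane",
    slab_halfwidth_um: float = 0.5,
    factor: float = 2.0,
    min_consecutive: int = 2,
    annotation: Annotation | None = None,
) -> int:
    """Find T = 0: the first sustained appearance of the cleavage furrow.

    Per frame, the mean membrane intensity is measured in a thin slab
    through the centrosome midpoint perpendicular to the A-P axis; t0 is
    the first frame where this midline signal exceeds the baseline (the
    median over the first quartile of frames) by ``factor`` and stays
    above it for ``min_consecutive`` frames.  A manual annotation
    overrides detection.
    """
    if annotation is not None and annotation.anaphase_frame is not None:
        return int(annotation.anaphase_frame)

    mip = max_intensity_projection(movie, membrane_channel)
    _, vy, vx = movie.voxel_size
    ny, nx = mip.shape[1:]
    yy = np.arange(ny)[:, None] * vy
    xx = np.arange(nx)[None, :] * vx

    n = movie.n_frames
    signal = np.empty(n)
    for t in range(n):
        u = registration.unit(min(t, registration.n_frames - 1))
        mid = registration.origin(min(t, registration.n_frames - 1))
        axial = (yy - mid[0]) * u[0] + (xx - mid[1]) * u[1]
        slab = np.abs(axial) <= slab_halfwidth_um
        if not slab.any():
            raise DegenerateGeometryError("midline slab misses the image entirely")
        signal[t] = mip[t][slab].mean()

    q = max(1, n // 4)
    baseline = float(np.median(signal[:q]))
    threshold = factor * baseline if baseline > 0 else np.inf
    above = signal >= threshold
    for t in range(n - min_consecutive + 1):
        if above[t:t + min_consecutive].all():
            return t
    raise AsymdivError(
        "no sustained cleavage-furrow signal found; provide the anaphase frame "
        "manually in the annotations"
    )


def project_onto_axis(position_um: np.ndarray, registration: CellRegistration,
                      frame: int) -> float:
    """Normalized axial coordinate s of a point at one frame.

    s = 0 at the anterior centrosome, s = 1 at the posterior one; the
    perpendicular component is discarded.  Values outside [0, 1] (beyond
    a centrosome) are returned unclamped; clamping happens only when
    binning into histograms.
    """
    p = np.asarray(position_um, float)[-2:]
    ant = registration.anterior_um[frame]
    axis = registration.posterior_um[frame] - ant
    length = np.linalg.norm(axis)
    if length == 0:
        raise DegenerateGeometryError(f"degenerate axis at frame {frame}")
    return float((p - ant) @ (axis / length) / length)


def register_movie(
    movie: MovieStack,
    annotation: Annotation,
    centrosome_channel: int | str = "centrosome",
    membrane_channel: int | str = "membrane",
    sigma_um: float = 0.3,
    min_score: float = 5.0,
    min_pair_separation_um: float = 1.0,
) -> CellRegistration:
    """Full registration pipeline: detect centrosomes, label A-P, find t0."""
    if annotation.anterior_direction is None:
        raise AsymdivError("annotation must provide anterior_direction")
    spots = detect_movie_spots(movie, centrosome_channel, sigma_um,
                               min_score, min_separation_um=min_pair_separation_um / 2)
    pairs = {}
    for t, frame_spots in spots.items():
        try:
            pairs[t] = detect_centrosome_pair(frame_spots, min_pair_separation_um)
        except Exception:
            continue  # missing frames are interpolated
    if not pairs:
        raise AsymdivError("centrosome pair not found in any frame")
    reg = assign_anterior_posterior(pairs, annotation.anterior_direction,
                                    movie.frame_interval, n_frames=movie.n_frames)
    reg.t0 = detect_anaphase_onset(movie, reg, membrane_channel,
                                   annotation=annotation)
    return reg
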