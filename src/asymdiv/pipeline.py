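"""High-level analysis flows combining the individual stages.

These are the entry points the CLI wraps: one for live division movies
(register, track, kymograph, velocity, asymmetry) and one for fixed-cell
composition volumes (nuclei, zones, endosome categories).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import (
    EndosomeRecord,
    assign_zone,
    category_table,
    classify_composition,
    nuclei_s_edges,
    registration_from_nuclei,
    segment_endosomes,
    segment_nuclei,
)
from .colocalization import blank_threshold
from .io_core import Annotation, MovieStack, RegionBox, max_intensity_projection
from .kinematics import (
    AsymmetryResult,
    Kymograph,
    VelocityResult,
    build_kymograph,
    compute_asymmetry,
    telophase_position,
)
from .registration import CellRegistration, register_movie
from .tracking import Track, detect_movie_spots, link_tracks

__all__ = ["DivisionAnalysis", "FixedCellAnalysis", "analyze_division", "analyze_fixed_cell"]


@dataclass
class DivisionAnalysis:
    registration: CellRegistration
    tracks: list[Track]
    kymograph: Kymograph
    asymmetry: AsymmetryResult
    velocity: VelocityResult
    telophase_mean_s: float


@dataclass
class FixedCellAnalysis:
    records: list[EndosomeRecord]
    table: pd.DataFrame
    registration: CellRegistration
    nuclei_masks: tuple[np.ndarray, np.ndarray]
    zone_edges: tuple[float, float]
    label_image: np.ndarray
    thresholds: dict = field(default_factory=dict)


def analyze_division(
    movie: MovieStack,
    annotation: Annotation,
    endosome_channel: int | str = "endosome",
    sigma_um: float = 0.25,
    min_score: float = 5.0,
    min_separation_um: float = 0.3,
    max_disp_um: float = 1.0,
    max_gap_frames: int = 1,
    measure_frame: int | None = None,
    window_frames: int = 20,
) -> DivisionAnalysis:
    """Full live-movie analysis of one dividing cell."""
    reg = register_movie(movie, annotation)
    spots = detect_movie_spots(movie, endosome_channel, sigma_um, min_score,
                               min_separation_um)
    tracks = link_tracks(spots, max_disp_um, max_gap_frames)
    kymo = build_kymograph(tracks, reg, window_frames=window_frames)
    t_frame = measure_frame if measure_frame is not None else movie.n_frames - 1
    asym = compute_asymmetry(movie, reg, endosome_channel, t_frame,
                             blank=annotation.blank_region)
    vel = average_velocity_safe(tracks, reg)
    telo = telophase_position(tracks, reg, 4.0)
    return DivisionAnalysis(registration=reg, tracks=tracks, kymograph=kymo,
                            asymmetry=asym, velocity=vel, telophase_mean_s=telo)


def average_velocity_safe(tracks, reg) -> VelocityResult:
    from .kinematics import average_velocity

    try:
        return average_velocity(tracks, reg)
    except Exception:
        return VelocityResult(speed_um_min=float("nan"),
                              axial_um_min=float("nan"), n_steps=0)


def analyze_fixed_cell(
    movie: MovieStack,
    ap_direction: tuple[float, float],
    reference: str = "Dld",
    markers: tuple[str, ...] = ("Par3", "Dlic1"),
    dapi_channel: str = "DAPI",
    blank: RegionBox | None = None,
    min_overlap_fraction: float = 0.1,
) -> FixedCellAnalysis:
    """Composition analysis of one fixed anaphase cell."""
    pixel_yx = movie.voxel_size[1:]
    if blank is None:
        blank = RegionBox((0, 0), (16, 16))  # image corner, off-sample by design
    dapi_mip = max_intensity_projection(movie, dapi_channel)[0]
    nuclei = segment_nuclei(dapi_mip, ap_direction)
    reg = registration_from_nuclei(nuclei, pixel_yx)
    edges = nuclei_s_edges(nuclei, reg, pixel_yx)
    ref_mip = max_intensity_projection(movie, reference)[0]
    labels = segment_endosomes(ref_mip)
    marker_mips = {m: max_intensity_projection(movie, m)[0] for m in markers}
    thresholds = {m: blank_threshold(marker_mips[m], blank) for m in markers}
    records = classify_composition(labels, marker_mips, thresholds,
                                   min_overlap_fraction, pixel_size_um=pixel_yx)
    for r in records:
        r.zone = assign_zone(r.centroid_um, reg, edges)
    return FixedCellAnalysis(records=records, table=category_table(records, markers),
                             registration=reg, nuclei_masks=nuclei, zone_edges=edges,
                             label_image=labels, thresholds=thresholds)
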