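"""Fixed-cell endosome composition analysis.

Endosomes are segmented on a reference-channel MIP with the fixed 8-bit
display threshold (100 of 255 after percentile rescaling), assigned to a
zone along the A-P axis (central between the two anaphase nuclei, or the
anterior/posterior surround), and scored for marker composition: a marker
is present on an endosome when it covers at least a minimum fraction of
the endosome footprint.  Cargo metrics normalize intensity to DAPI or
report the fraction of the marker-demarcated endosome area occupied by
the cargo signal, a channel-independent measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import AsymdivError, DegenerateGeometryError
from .registration import CellRegistration, project_onto_axis

__all__ = [
    "EndosomeRecord",
    "segment_nuclei",
    "segment_endosomes",
    "registration_from_nuclei",
    "nuclei_s_edges",
    "assign_zone",
    "classify_composition",
    "cargo_metrics",
    "division_orientation",
    "category_table",
]

ZONES = ("central", "anterior_surround", "posterior_surround")


@dataclass
class EndosomeRecord:
    """One segmented endosome and its composition scores."""

    endosome_id: int
    centroid_um: np.ndarray  # (y, x)
    area_um2: float
    combo: tuple[str, ...] = ()
    presence: dict = field(default_factory=dict)
    overlap_areas_um2: dict = field(default_factory=dict)
    zone: str | None = None
    normalized_intensity: float | None = None
    area_fractions: dict = field(default_factory=dict)


def segment_nuclei(
    dapi: np.ndarray,
    ap_direction: tuple[float, float],
    smooth_sigma_px: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment the two anaphase nuclei from a DAPI image.

    Otsu threshold on the smoothed MIP, connected components, two largest
    components returned ordered along the A-P direction (anterior first).
    """
    dapi = np.asarray(dapi, float)
    if dapi.ndim == 3:
        dapi = dapi.max(axis=0)
    if dapi.max() == dapi.min():
        raise AsymdivError("DAPI image is constant; cannot segment nuclei")
    smooth = ndimage.gaussian_filter(dapi, smooth_sigma_px)
    mask = smooth > threshold_otsu(smooth)
    labels = cc_label(mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    if np.count_nonzero(sizes) < 2:
        raise AsymdivError("fewer than two nuclei found in the DAPI channel")
    top = np.argsort(sizes)[-2:]
    u = np.asarray(ap_direction, float)
    u = u / np.linalg.norm(u)
    masks = [labels == l for l in top]
    projs = [np.argwhere(m).mean(axis=0) @ u for m in masks]
    order = np.argsort(projs)
    return masks[order[0]], masks[order[1]]


def registration_from_nuclei(
    nuclei_masks: tuple[np.ndarray, np.ndarray],
    pixel_size_um: tuple[float, float],
) -> CellRegistration:
    """A-P registration for a fixed cell, anchored at the nucleus centroids.

    Fixed cells carry no centrosome channel, so the nucleus centroids act
    as the axis anchors: the anterior nucleus centroid gets coordinate 0
    and the posterior one 1.
    """
    vy, vx = pixel_size_um
    cents = [np.argwhere(m).mean(axis=0) * [vy, vx] for m in nuclei_masks]
    return CellRegistration(anterior_um=cents[0][None, :],
                            posterior_um=cents[1][None, :],
                            frame_interval_s=0.0)


def segment_endosomes(
    reference_mip: np.ndarray,
    low_percentile: float = 0.1,
    high_percentile: float = 99.9,
    threshold_8bit: int = 100,
    min_area_px: int = 4,
) -> np.ndarray:
    """Segment endosomes on a reference-channel MIP.

    The image is rescaled to 8-bit by percentile scaling, thresholded at
    the fixed display value (100 of 255), and connected components below
    the minimum area are removed.  Labels are sorted by descending area
    (label 1 = largest).  Touching endosomes merge into one component;
    no watershed splitting is attempted.
    """
    img = np.asarray(reference_mip, float)
    lo, hi = np.percentile(img, [low_percentile, high_percentile])
    if hi <= lo:
        if lo == 0:  # truly blank image: nothing to segment
            return np.zeros(img.shape, dtype=int)
        raise AsymdivError("reference image is saturated/constant; cannot rescale")
    img8 = np.clip((img - lo) / (hi - lo), 0, 1) * 255.0
    mask = img8 >= threshold_8bit
    labels = cc_label(mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = np.flatnonzero(sizes >= min_area_px)
    order = keep[np.argsort(-sizes[keep], kind="stable")]
    out = np.zeros_like(labels)
    for new_id, old in enumerate(order, start=1):
        out[labels == old] = new_id
    return out


def nuclei_s_edges(
    nuclei_masks: tuple[np.ndarray, np.ndarray],
    registration: CellRegistration,
    pixel_size_um: tuple[float, float],
    frame: int = 0,
) -> tuple[float, float]:
    """Inner edges (in s) of the anterior and posterior nucleus masks."""
    vy, vx = pixel_size_um
    spans = []
    for m in nuclei_masks:
        coords = np.argwhere(m) * [vy, vx]
        ss = np.array([project_onto_axis(c, registration, frame) for c in coords])
        spans.append((ss.min(), ss.max()))
    spans.sort(key=lambda t: t[0] + t[1])
    edge_lo = spans[0][1]  # posterior edge of the anterior nucleus
    edge_hi = spans[1][0]  # anterior edge of the posterior nucleus
    if edge_hi <= edge_lo:
        raise DegenerateGeometryError("nuclei overlap along the axis; no central zone")
    return edge_lo, edge_hi


def assign_zone(
    centroid_um: np.ndarray,
    registration: CellRegistration,
    edges: tuple[float, float],
    frame: int = 0,
) -> str:
    """Zone of an endosome centroid: central / anterior_surround / posterior_surround.

    Central means the normalized axial coordinate lies strictly between
    the inner nucleus edges; otherwise the side of the gap midpoint
    decides.  The surround zones include the nuclear footprints.
    """
    edge_lo, edge_hi = edges
    if edge_hi <= edge_lo:
        raise DegenerateGeometryError("degenerate zone geometry")
    s = project_onto_axis(centroid_um, registration, frame)
    if edge_lo < s < edge_hi:
        return "central"
    return "anterior_surround" if s < (edge_lo + edge_hi) / 2 else "posterior_surround"


def classify_composition(
    label_image: np.ndarray,
    marker_channels: dict[str, np.ndarray],
    marker_thresholds: dict[str, float],
    min_overlap_fraction: float = 0.1,
    pixel_size_um: tuple[float, float] = (1.0, 1.0),
) -> list[EndosomeRecord]:
    """Score marker presence on each segmented endosome.

    Marker m is present on endosome e when the area of (m above its
    threshold) within e's footprint reaches ``min_overlap_fraction`` of
    the footprint area.  The combo tuple lists present markers in the
    order of ``marker_channels``.
    """
    label_image = np.asarray(label_image)
    for name, ch in marker_channels.items():
        if np.shape(ch) != label_image.shape:
            raise ValueError(f"marker channel {name!r} shape mismatch with label image")
    marker_masks = {
        name: np.asarray(ch, float) > marker_thresholds[name]
        for name, ch in marker_channels.items()
    }
    pixel_area_um2 = float(pixel_size_um[0] * pixel_size_um[1])
    records = []
    for lab in range(1, int(label_image.max()) + 1):
        fp = label_image == lab
        area_px = int(fp.sum())
        if area_px == 0:
            continue
        presence, overlaps = {}, {}
        for name, mmask in marker_masks.items():
            overlap_px = int((fp & mmask).sum())
            overlaps[name] = overlap_px * pixel_area_um2
            presence[name] = overlap_px >= min_overlap_fraction * area_px
        combo = tuple(name for name in marker_channels if presence[name])
        centroid_px = np.argwhere(fp).mean(axis=0)
        records.append(EndosomeRecord(
            endosome_id=lab,
            centroid_um=centroid_px * np.asarray(pixel_size_um, float),
            area_um2=area_px * pixel_area_um2,
            combo=combo, presence=presence, overlap_areas_um2=overlaps,
        ))
    return records


def cargo_metrics(
    footprint: np.ndarray,
    cargo: np.ndarray,
    cargo_threshold: float,
    dapi: np.ndarray,
    dapi_mask: np.ndarray,
    marker_footprints: dict[str, np.ndarray],
) -> tuple[float, dict[str, float]]:
    """Normalized cargo intensity and per-marker cargo area fractions.

    normalized_intensity = mean cargo over the endosome footprint divided
    by the mean DAPI over the cell's DAPI mask; area_fraction(m) = area of
    (cargo above threshold) within marker m's footprint over that
    footprint's area.
    """
    cargo = np.asarray(cargo, float)
    dapi = np.asarray(dapi, float)
    fp = np.asarray(footprint, bool)
    dmask = np.asarray(dapi_mask, bool)
    if not dmask.any() or dapi[dmask].mean() == 0:
        raise AsymdivError("zero DAPI mean; normalization undefined")
    norm_int = float(cargo[fp].mean() / dapi[dmask].mean()) if fp.any() else 0.0
    fractions = {}
    cargo_mask = cargo > cargo_threshold
    for name, mfp in marker_footprints.items():
        mfp = np.asarray(mfp, bool)
        if not mfp.any():
            raise AsymdivError(f"marker footprint {name!r} is empty")
        fractions[name] = float((cargo_mask & mfp).sum() / mfp.sum())
    return norm_int, fractions


def division_orientation(
    cleavage_plane_normal: np.ndarray,
    surface_normal: np.ndarray,
    bin_edges: tuple[float, float] = (30.0, 60.0),
) -> tuple[float, str]:
    """Angle between the cleavage plane and the apical surface, with class.

    The plane–surface angle is 90 degrees minus the angle between the two
    normals (folded into [0, 90]); classes are the three angle bins
    [0, 30) / [30, 60) / [60, 90] by default.
    """
    n1 = np.asarray(cleavage_plane_normal, float)
    n2 = np.asarray(surface_normal, float)
    if np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise ValueError("normals must be nonzero")
    cosang = abs(n1 @ n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    normal_angle = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    angle = 90.0 - normal_angle
    e1, e2 = bin_edges
    if angle < e1:
        cls = f"0-{e1:g}"
    elif angle < e2:
        cls = f"{e1:g}-{e2:g}"
    else:
        cls = f"{e2:g}-90"
    return float(angle), cls


def category_table(records: list[EndosomeRecord], markers: tuple[str, ...]) -> pd.DataFrame:
    """Counts of endosomes per composition category per zone."""
    def name(combo: tuple[str, ...]) -> str:
        if not combo:
            return "neither"
        if len(combo) == len(markers):
            return "both" if len(markers) == 2 else "all"
        return "+".join(combo)

    rows = [{"zone": r.zone or "unassigned", "category": name(r.combo)} for r in records]
    if not rows:
        return pd.DataFrame(columns=["zone", "category", "count"])
    df = pd.DataFrame(rows).value_counts().rename("count").reset_index()
    return df.sort_values(["zone", "category"]).reset_index(drop=True)
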