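"""Thresholded Manders colocalization with Costes automatic thresholding
and Costes block-randomization significance.

Thresholds come either from a blank (sample-free) image region
(mean + k*SD) or from the Costes procedure: an orthogonal regression of
channel 2 on channel 1 defines candidate threshold pairs (T1, a*T1 + b),
and T1 is lowered from the intensity maximum until the correlation of the
*below*-threshold pixels drops to zero — above the returned thresholds
the two channels carry all of their correlated signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AsymdivError, DegenerateGeometryError
from .io_core import RegionBox
from .registration import CellRegistration

__all__ = [
    "ColocResult",
    "CostesThresholds",
    "select_central_zone",
    "blank_threshold",
    "costes_auto_threshold",
    "manders_coefficients",
    "costes_randomization",
]


@dataclass
class CostesThresholds:
    t1: float
    t2: float
    slope: float
    intercept: float
    converged: bool  # False when below-threshold correlation never crossed 0


@dataclass
class ColocResult:
    region: dict | None
    t1: float
    t2: float
    threshold_source: str  # "manual-blank" or "costes"
    m1: float
    m2: float
    pearson_r: float
    p_value: float | None = None
    n_iterations: int = 0
    extras: dict = field(default_factory=dict)


def select_central_zone(
    nuclei_masks: tuple[np.ndarray, np.ndarray],
    registration: CellRegistration,
    pixel_size_um: float,
    frame: int = 0,
    width_px: int = 50,
    height_px: int = 100,
    reference_pixel_um: float = 0.126,
) -> RegionBox:
    """Rectangle between the two anaphase nuclei, centred on the axis midpoint.

    The physical footprint is fixed (``width_px x height_px`` at the
    reference pixel size, i.e. 6.3 x 12.6 um by default) with the long
    side along the A-P axis, rescaled to the image's actual pixel size
    and clipped along the axis to the inter-nuclear gap.
    """
    mask_a, mask_b = nuclei_masks
    ny, nx = mask_a.shape
    u = registration.unit(frame)
    mid = registration.origin(frame) / pixel_size_um  # px

    half_long = height_px * reference_pixel_um / pixel_size_um / 2.0
    half_short = width_px * reference_pixel_um / pixel_size_um / 2.0
    # long side along the dominant image axis of u
    long_axis = 0 if abs(u[0]) >= abs(u[1]) else 1
    half = [0.0, 0.0]
    half[long_axis] = half_long
    half[1 - long_axis] = half_short

    # inter-nuclear gap along the axis, in px coordinates
    coords_a = np.argwhere(mask_a)
    coords_b = np.argwhere(mask_b)
    if coords_a.size == 0 or coords_b.size == 0:
        raise ValueError("empty nucleus mask")
    proj_a = coords_a @ u
    proj_b = coords_b @ u
    if proj_a.mean() > proj_b.mean():
        proj_a, proj_b = proj_b, proj_a
    # the gap starts one pixel beyond the anterior nucleus' last pixel
    gap_lo, gap_hi = float(proj_a.max()) + 1.0, float(proj_b.min())
    if gap_hi <= gap_lo:
        raise DegenerateGeometryError("nuclei touch or overlap: no inter-nuclear gap")

    center = mid.copy()
    lo = center - half
    hi = center + half
    # Clip the long side to the inter-nuclear gap.  The gap bounds are
    # projections onto u; convert to coordinates along the long image axis
    # (the axis is assumed near-aligned with an image axis).
    sign = 1.0 if u[long_axis] >= 0 else -1.0
    gl, gh = sorted([gap_lo * sign, gap_hi * sign])
    lo[long_axis] = max(lo[long_axis], gl)
    hi[long_axis] = min(hi[long_axis], gh)
    lo = np.clip(np.floor(lo).astype(int), 0, [ny - 1, nx - 1])
    hi = np.clip(np.ceil(hi).astype(int), 1, [ny, nx])
    if np.any(hi <= lo):
        raise DegenerateGeometryError("central zone collapsed to an empty box")
    return RegionBox(tuple(lo), tuple(hi))


def blank_threshold(channel: np.ndarray, blank: RegionBox, k: float = 3.0) -> float:
    """Threshold from a blank region: mean + k * SD of its intensities."""
    channel = np.asarray(channel, float)
    blank.validate_within(channel.shape[-blank.ndim:])
    vals = channel[(Ellipsis,) + blank.slices()].ravel()
    if vals.size == 0:
        raise ValueError("blank region is empty")
    return float(vals.mean() + k * vals.std())


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return np.nan
    return float((x * y).sum() / denom)


def _orthogonal_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line y = a*x + b via the principal covariance axis."""
    cov = np.cov(np.stack([x, y]))
    if cov[0, 0] == 0:
        raise AsymdivError("channel 1 has zero variance; regression undefined")
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if major[0] == 0:
        raise AsymdivError("orthogonal regression slope undefined (vertical axis)")
    a = major[1] / major[0]
    b = float(y.mean() - a * x.mean())
    return float(a), b


def costes_auto_threshold(
    ch1: np.ndarray,
    ch2: np.ndarray,
    step: float | None = None,
) -> CostesThresholds:
    """Costes automatic threshold pair for two channels of the same shape.

    Starting from the maximum of channel 1, the candidate threshold T1 is
    decremented (T2 = a*T1 + b from the orthogonal regression) until the
    Pearson correlation of the pixels *below both* thresholds falls to
    <= 0; the last pair before crossing is returned.  The search step is
    one intensity quantization unit (1 for integer data).  If the
    correlation never crosses 0, the minimum thresholds are returned with
    ``converged=False``.
    """
    ch1 = np.asarray(ch1)
    ch2 = np.asarray(ch2)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must have the same shape")
    x = ch1.ravel().astype(float)
    y = ch2.ravel().astype(float)
    if x.std() == 0 or y.std() == 0:
        raise AsymdivError("constant channel; Costes regression undefined")
    a, b = _orthogonal_fit(x, y)
    if step is None:
        step = 1.0 if np.issubdtype(ch1.dtype, np.integer) else float(x.max() - x.min()) / 255.0
    if step <= 0:
        raise ValueError("step must be positive")

    t1 = float(x.max())
    prev = (t1, a * t1 + b)
    x_min = float(x.min())
    while t1 >= x_min:
        t2 = a * t1 + b
        mask = (x < t1) & (y < t2)
        if mask.sum() >= 2:
            r = _pearson(x[mask], y[mask])
            if not np.isnan(r) and r <= 0:
                return CostesThresholds(prev[0], prev[1], a, b, converged=True)
        prev = (t1, t2)
        t1 -= step
    return CostesThresholds(x_min, a * x_min + b, a, b, converged=False)


def manders_coefficients(
    ch1: np.ndarray,
    ch2: np.ndarray,
    t1: float,
    t2: float,
    region: RegionBox | np.ndarray | None = None,
    thresholded: bool = True,
) -> tuple[float, float]:
    """Thresholded Manders coefficients (M1, M2).

    M1 is the fraction of channel-1 intensity above t1 that lies in pixels
    where channel 2 is also above t2 (and symmetrically for M2).  With
    ``thresholded=False`` the denominators are the full channel sums over
    the region (the classic unthresholded variant).
    """
    ch1 = np.asarray(ch1, float)
    ch2 = np.asarray(ch2, float)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must have the same shape")
    if region is not None:
        if isinstance(region, RegionBox):
            region.validate_within(ch1.shape)
            sel = region.slices()
            ch1, ch2 = ch1[sel], ch2[sel]
        else:
            mask = np.asarray(region, bool)
            ch1, ch2 = ch1[mask], ch2[mask]
    above1 = ch1 > t1
    above2 = ch2 > t2
    denom1 = ch1[above1].sum() if thresholded else ch1.sum()
    denom2 = ch2[above2].sum() if thresholded else ch2.sum()
    if denom1 == 0 or denom2 == 0:
        raise AsymdivError("Manders coefficient undefined: zero denominator")
    m1 = float(ch1[above1 & above2].sum() / denom1)
    m2 = float(ch2[above1 & above2].sum() / denom2)
    return m1, m2


def costes_randomization(
    ch1: np.ndarray,
    ch2: np.ndarray,
    block_px: int = 5,
    n_iter: int = 200,
    seed: int | None = None,
) -> float:
    """Block-randomization p-value for the image correlation.

    Channel 2 is tiled into ``block_px`` squares (edge tiles narrower than
    a full block are excluded), the tiles are permuted uniformly at random
    ``n_iter`` times, and the Pearson correlation with channel 1 is
    recomputed each time.  The add-one estimator
    p = (1 + #{r_rand >= r_obs}) / (n_iter + 1) avoids p = 0.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1 (>= 100 recommended)")
    ch1 = np.asarray(ch1, float)
    ch2 = np.asarray(ch2, float)
    if ch1.shape != ch2.shape or ch1.ndim != 2:
        raise ValueError("channels must be 2-D arrays of the same shape")
    ny, nx = ch1.shape
    by, bx = ny // block_px, nx // block_px
    if by * bx < 2:
        raise ValueError("fewer than 2 complete tiles; reduce block_px")
    cy, cx = by * block_px, bx * block_px
    a = ch1[:cy, :cx]
    b = ch2[:cy, :cx]
    r_obs = _pearson(a.ravel(), b.ravel())
    # tiles as an array (n_tiles, block, block)
    tiles = (b.reshape(by, block_px, bx, block_px)
              .swapaxes(1, 2)
              .reshape(by * bx, block_px, block_px))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_iter):
        perm = rng.permutation(tiles.shape[0])
        shuffled = (tiles[perm]
                    .reshape(by, bx, block_px, block_px)
                    .swapaxes(1, 2)
                    .reshape(cy, cx))
        if _pearson(a.ravel(), shuffled.ravel()) >= r_obs:
            count += 1
    return (1 + count) / (n_iter + 1)
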