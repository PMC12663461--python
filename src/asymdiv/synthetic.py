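"""Synthetic dividing-cell movies and fixed-cell volumes with ground truth.

The division simulator emulates the imaging geometry of an apically
dividing neural progenitor: an elliptical cell with two centrosomes
separating along the anterior–posterior (A-P) axis, a cleavage furrow
appearing at anaphase onset, and point-like endosomes that first converge
toward the cell centre and then undergo a biased random walk toward the
posterior pole.  Rendering applies a Gaussian PSF followed by Poisson and
Gaussian read noise.  Every run records full ground truth (true positions,
centrosome labels, anaphase frame, asymmetry index) so that each analysis
stage can be validated against a known answer.

Anaphase onset is *defined* in the simulator as the first frame with
nonzero furrow signal, which gives the temporal-registration stage an
unambiguous detection target.

Dynamics are two-dimensional (in the imaging plane) with a thin z extent
by default, matching an analysis that operates on maximum-intensity
projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import default_rng

from .io_core import MovieStack

__all__ = [
    "DivisionSceneConfig",
    "DivisionGroundTruth",
    "simulate_division_truth",
    "simulate_division_movie",
    "FixedCellSpec",
    "FixedBlob",
    "FixedCellGroundTruth",
    "simulate_fixed_cell",
]

MEMBRANE, CENTROSOME, ENDOSOME = 0, 1, 2
DIVISION_CHANNELS = ["membrane", "centrosome", "endosome"]


@dataclass
class DivisionSceneConfig:
    """Parameters of one simulated dividing cell.

    Defaults describe the live-imaging regime the pipeline targets:
    12 s frame interval, ~8 min of imaging centred on anaphase onset,
    0.2 um pixels, a ~14 x 11 um cell, and endosome drift speeds on the
    um/min scale.
    """

    shape_zyx: tuple[int, int, int] = (3, 128, 128)
    voxel_size_um: tuple[float, float, float] = (1.0, 0.2, 0.2)
    n_frames: int = 41
    frame_interval_s: float = 12.0
    anaphase_frame: int = 20
    ap_direction: tuple[float, float] = (0.0, 1.0)  # (y, x); posterior = +x
    centrosome_sep_initial_um: float = 2.0
    centrosome_sep_final_um: float = 10.0
    cell_radii_um: tuple[float, float] = (7.0, 5.5)  # semi-axes (along axis, perp)
    n_endosomes: int = 12
    centripetal_rate_um_s: float = 0.02  # pre-anaphase drift toward the central zone
    central_zone_radius_um: float = 3.0  # convergence target; no drift inside
    posterior_drift_um_s: float = 0.02  # v_d, post-anaphase axial drift (1.2 um/min)
    p_bias: float = 0.8  # probability a post-anaphase step is posterior
    step_sigma_um: float = 0.05  # isotropic diffusion, um per frame
    furrow_frames: int = 10  # frames from furrow onset to abscission
    spot_amplitude: float = 150.0
    centrosome_amplitude: float = 300.0
    membrane_amplitude: float = 80.0
    psf_sigma_um: float = 0.2
    psf_sigma_z_um: float = 0.8
    poisson_noise: bool = True
    read_noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_bias <= 1.0:
            raise ValueError("p_bias must be in [0, 1]")
        for name in ("centripetal_rate_um_s", "posterior_drift_um_s", "step_sigma_um",
                     "psf_sigma_um", "read_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 1 <= self.anaphase_frame <= self.n_frames - 1:
            raise ValueError("anaphase_frame must lie within [1, n_frames - 1]")

    @property
    def axis_unit(self) -> np.ndarray:
        u = np.asarray(self.ap_direction, float)
        return u / np.linalg.norm(u)

    @property
    def center_um(self) -> np.ndarray:
        _, ny, nx = self.shape_zyx
        _, vy, vx = self.voxel_size_um
        return np.array([(ny - 1) / 2 * vy, (nx - 1) / 2 * vx])


@dataclass
class DivisionGroundTruth:
    """True object states of a simulated division, one row per frame."""

    endosome_positions_um: np.ndarray  # (n_frames, n_endosomes, 2) (y, x)
    centrosome_anterior_um: np.ndarray  # (n_frames, 2)
    centrosome_posterior_um: np.ndarray  # (n_frames, 2)
    anaphase_frame: int
    asymmetry_index: float
    label: str
    axis_unit: np.ndarray
    center_um: np.ndarray
    warnings: list[str] = field(default_factory=list)


def _reflect_ellipse(delta: np.ndarray, u: np.ndarray, v: np.ndarray,
                     a: float, b: float) -> np.ndarray:
    """Reflect a centre-relative position back inside the ellipse (a, b)."""
    qa, qp = float(delta @ u) / a, float(delta @ v) / b
    rho = np.hypot(qa, qp)
    if rho <= 1.0:
        return delta
    rho_new = max(2.0 - rho, 0.05)
    scale = rho_new / rho
    return (qa * scale * a) * u + (qp * scale * b) * v


def simulate_division_truth(config: DivisionSceneConfig) -> DivisionGroundTruth:
    """Generate ground-truth trajectories without rendering an image.

    Motion model: before anaphase each endosome drifts toward the cell
    centre at the centripetal rate plus isotropic Gaussian steps; from
    anaphase on, each step's axial component is +v_d*dt (posterior) with
    probability p_bias and -v_d*dt otherwise, plus noise.  Positions
    reflect at the cell boundary and, after abscission, at the cleavage
    midplane.
    """
    rng = default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    u = config.axis_unit
    v = np.array([-u[1], u[0]])
    a, b = config.cell_radii_um
    c = config.center_um
    t0 = config.anaphase_frame
    dt = config.frame_interval_s
    n, ne = config.n_frames, config.n_endosomes
    t_abs = t0 + config.furrow_frames

    # initial positions uniform in a shrunken ellipse
    r = np.sqrt(rng.uniform(0, 1, ne)) * 0.85
    th = rng.uniform(0, 2 * np.pi, ne)
    pos = np.empty((n, ne, 2))
    pos[0] = c + np.outer(r * np.cos(th) * a, u) + np.outer(r * np.sin(th) * b, v)

    for t in range(n - 1):
        cur = pos[t]
        noise = rng.normal(0.0, config.step_sigma_um, size=(ne, 2))
        if t >= t0:
            sign = np.where(rng.uniform(size=ne) < config.p_bias, 1.0, -1.0)
            drift = np.outer(sign * config.posterior_drift_um_s * dt, u)
        else:
            # drift toward the central zone; free diffusion once inside it
            to_center = c - cur
            dist = np.linalg.norm(to_center, axis=1)
            reach = np.clip(dist - config.central_zone_radius_um, 0.0, None)
            step = np.minimum(config.centripetal_rate_um_s * dt, reach)
            unit = np.where(dist[:, None] > 0,
                            to_center / np.maximum(dist, 1e-12)[:, None], 0.0)
            drift = step[:, None] * unit
        nxt = cur + drift + noise
        for i in range(ne):
            d = _reflect_ellipse(nxt[i] - c, u, v, a, b)
            if t >= t_abs:
                ax_prev = float((cur[i] - c) @ u)
                ax_new = float(d @ u)
                if ax_prev != 0 and np.sign(ax_new) != np.sign(ax_prev):
                    d = d - 2 * ax_new * u  # reflect at the cleavage midplane
            nxt[i] = c + d
        pos[t + 1] = nxt

    # centrosomes: symmetric about the cell centre, separating linearly
    sep = np.linspace(config.centrosome_sep_initial_um,
                      config.centrosome_sep_final_um, n)
    ant = c - np.outer(sep / 2, u)
    post = c + np.outer(sep / 2, u)

    axial_final = (pos[-1] - c) @ u
    n_post = int(np.sum(axial_final > 0))
    n_ant = ne - n_post
    from .kinematics import asymmetry_index, classify_asymmetry

    index = asymmetry_index(float(n_post), float(n_ant))
    warnings = []
    min_sep = 3.0 * config.psf_sigma_um
    crowded = 0
    for t in range(n):
        d2 = np.sum((pos[t][:, None, :] - pos[t][None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < min_sep ** 2:
            crowded += 1
    if crowded:
        warnings.append(
            f"endosomes closer than 3*PSF sigma in {crowded}/{n} frames; "
            "detectability is not guaranteed there"
        )
    return DivisionGroundTruth(
        endosome_positions_um=pos,
        centrosome_anterior_um=ant,
        centrosome_posterior_um=post,
        anaphase_frame=t0,
        asymmetry_index=index,
        label=classify_asymmetry(index),
        axis_unit=u,
        center_um=c,
        warnings=warnings,
    )


def _add_gaussian_spots(vol: np.ndarray, positions_um: np.ndarray,
                        amplitude: float, voxel: tuple[float, float, float],
                        sigma_um: float, sigma_z_um: float) -> None:
    """Render 3-D Gaussian spots (in place) centred at the mid z-plane."""
    nz, ny, nx = vol.shape
    vz, vy, vx = voxel
    sy, sx = sigma_um / vy, sigma_um / vx
    sz = max(sigma_z_um / vz, 1e-6)
    zc = (nz - 1) / 2
    gz = np.exp(-((np.arange(nz) - zc) ** 2) / (2 * sz ** 2))
    ry, rx = int(np.ceil(4 * sy)), int(np.ceil(4 * sx))
    for py, px in np.atleast_2d(positions_um):
        cy, cx = py / vy, px / vx
        y0, y1 = max(0, int(cy) - ry), min(ny, int(cy) + ry + 1)
        x0, x1 = max(0, int(cx) - rx), min(nx, int(cx) + rx + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        gy = np.exp(-((np.arange(y0, y1) - cy) ** 2) / (2 * sy ** 2))
        gx = np.exp(-((np.arange(x0, x1) - cx) ** 2) / (2 * sx ** 2))
        vol[:, y0:y1, x0:x1] += amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def _membrane_plane(config: DivisionSceneConfig, frame: int) -> np.ndarray:
    """2-D membrane photon image: boundary ring plus ingressing furrow."""
    _, ny, nx = config.shape_zyx
    _, vy, vx = config.voxel_size_um
    u, c = config.axis_unit, config.center_um
    v = np.array([-u[1], u[0]])
    a, b = config.cell_radii_um
    yy = np.arange(ny)[:, None] * vy - c[0]
    xx = np.arange(nx)[None, :] * vx - c[1]
    axial = yy * u[0] + xx * u[1]
    perp = yy * v[0] + xx * v[1]
    rho = np.hypot(axial / a, perp / b)
    thickness = 0.3  # um
    img = config.membrane_amplitude * np.exp(-(((rho - 1.0) * b) ** 2) / (2 * thickness ** 2))
    t0 = config.anaphase_frame
    if frame >= t0:
        amp_ramp = min(1.0, (frame - t0 + 1) / 3.0)
        band = np.exp(-(axial ** 2) / (2 * thickness ** 2)) * (rho < 1.0)
        img = img + config.membrane_amplitude * amp_ramp * band
    return img


def render_division_frame(config: DivisionSceneConfig,
                          truth: DivisionGroundTruth, frame: int,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one (c, z, y, x) frame; noise is applied iff ``rng`` is given."""
    nz, ny, nx = config.shape_zyx
    vol = np.zeros((3, nz, ny, nx), dtype=float)
    vol[MEMBRANE] = _membrane_plane(config, frame)[None, :, :]
    _add_gaussian_spots(vol[CENTROSOME],
                        np.stack([truth.centrosome_anterior_um[frame],
                                  truth.centrosome_posterior_um[frame]]),
                        config.centrosome_amplitude, config.voxel_size_um,
                        config.psf_sigma_um, config.psf_sigma_z_um)
    _add_gaussian_spots(vol[ENDOSOME], truth.endosome_positions_um[frame],
                        config.spot_amplitude, config.voxel_size_um,
                        config.psf_sigma_um, config.psf_sigma_z_um)
    if rng is not None:
        if config.poisson_noise:
            vol = rng.poisson(np.clip(vol, 0, None)).astype(float)
        if config.read_noise_sigma > 0:
            vol = vol + rng.normal(0.0, config.read_noise_sigma, size=vol.shape)
        vol = np.clip(vol, 0.0, None)
    return vol


def simulate_division_movie(config: DivisionSceneConfig
                            ) -> tuple[MovieStack, DivisionGroundTruth]:
    """Simulate and render a 3-channel division movie.

    Channels are (membrane, centrosome, endosome).  Identical config and
    seed produce bit-identical output.
    """
    truth = simulate_division_truth(config)
    rng_render = default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    noisy = config.poisson_noise or config.read_noise_sigma > 0
    frames = [
        render_division_frame(config, truth, t, rng_render if noisy else None)
        for t in range(config.n_frames)
    ]
    data = np.stack(frames).astype(np.float32)
    movie = MovieStack(
        data=data,
        voxel_size=config.voxel_size_um,
        frame_interval=config.frame_interval_s,
        channel_labels=list(DIVISION_CHANNELS),
    )
    return movie, truth


# ---------------------------------------------------------------------------
# Fixed-cell composition scenes
# ---------------------------------------------------------------------------

ZONES = ("central", "anterior_surround", "posterior_surround")


@dataclass
class FixedCellSpec:
    """Scene description for a fixed anaphase cell.

    ``zone_counts`` maps a zone name to ``{marker_combo: count}`` where a
    marker combo is a tuple of marker names carried by those endosomes
    (the empty tuple means reference-channel only).  Every endosome is
    rendered into the reference channel; markers add their own channels.
    """

    zone_counts: dict = field(default_factory=dict)
    markers: tuple[str, ...] = ("Par3", "Dlic1")
    reference: str = "Dld"
    shape_zyx: tuple[int, int, int] = (3, 160, 160)
    voxel_size_um: tuple[float, float, float] = (0.5, 0.126, 0.126)
    ap_direction: tuple[float, float] = (0.0, 1.0)
    nucleus_offset_um: float = 5.0  # nucleus centres at centre +/- offset along axis
    nucleus_radii_um: tuple[float, float] = (2.2, 1.9)  # (along axis, perp)
    blob_radius_um: float = 0.4
    blob_amplitude: float = 180.0
    dapi_amplitude: float = 150.0
    min_blob_separation_um: float = 1.2
    poisson_noise: bool = True
    read_noise_sigma: float = 2.0

    def __post_init__(self):
        for zone in self.zone_counts:
            if zone not in ZONES:
                raise ValueError(f"unknown zone {zone!r}; expected one of {ZONES}")
        for counts in self.zone_counts.values():
            for combo in counts:
                for m in combo:
                    if m not in self.markers:
                        raise ValueError(f"combo marker {m!r} not in markers {self.markers}")

    @property
    def channel_labels(self) -> list[str]:
        return ["DAPI", self.reference, *self.markers]


@dataclass
class FixedBlob:
    blob_id: int
    position_um: np.ndarray  # (y, x)
    zone: str
    combo: tuple[str, ...]
    area_um2: float


@dataclass
class FixedCellGroundTruth:
    blobs: list[FixedBlob]
    nucleus_centers_um: np.ndarray  # (2, 2): anterior, posterior
    nucleus_radii_um: tuple[float, float]
    axis_unit: np.ndarray
    center_um: np.ndarray

    def category_table(self) -> dict:
        """zone -> combo -> count, from ground truth."""
        out: dict = {}
        for blob in self.blobs:
            out.setdefault(blob.zone, {}).setdefault(blob.combo, 0)
            out[blob.zone][blob.combo] += 1
        return out


def _zone_region(spec: FixedCellSpec, zone: str) -> tuple[tuple[float, float], float]:
    """(axial range, max |perp|) in um relative to the cell centre."""
    a_nuc = spec.nucleus_radii_um[0]
    inner = spec.nucleus_offset_um - a_nuc  # inner nucleus edge
    if zone == "central":
        return (-(inner - 0.6), inner - 0.6), 3.5
    outer_lo, outer_hi = inner + 0.4, spec.nucleus_offset_um + a_nuc + 1.0
    if zone == "anterior_surround":
        return (-outer_hi, -outer_lo), 4.0
    return (outer_lo, outer_hi), 4.0


def simulate_fixed_cell(spec: FixedCellSpec, seed: int
                        ) -> tuple[MovieStack, FixedCellGroundTruth]:
    """Render a fixed anaphase cell: DAPI nuclei pair + endosome blobs.

    Blobs are soft-edged disks placed with a minimum mutual separation
    inside their requested zone; a zone that cannot accommodate its
    requested count raises ``ValueError``.
    """
    rng = default_rng(seed)
    nz, ny, nx = spec.shape_zyx
    vz, vy, vx = spec.voxel_size_um
    u = np.asarray(spec.ap_direction, float)
    u = u / np.linalg.norm(u)
    v = np.array([-u[1], u[0]])
    c = np.array([(ny - 1) / 2 * vy, (nx - 1) / 2 * vx])

    placed: list[FixedBlob] = []
    blob_id = 0
    for zone in ZONES:
        counts = spec.zone_counts.get(zone, {})
        for combo, count in counts.items():
            combo = tuple(combo)
            for _ in range(int(count)):
                (ax_lo, ax_hi), perp_max = _zone_region(spec, zone)
                for attempt in range(5000):
                    ax = rng.uniform(ax_lo, ax_hi)
                    pp = rng.uniform(-perp_max, perp_max)
                    p = c + ax * u + pp * v
                    if all(np.linalg.norm(p - b.position_um) >= spec.min_blob_separation_um
                           for b in placed):
                        break
                else:
                    raise ValueError(
                        f"requested counts exceed zone capacity in {zone!r} "
                        f"(separation {spec.min_blob_separation_um} um)"
                    )
                placed.append(FixedBlob(
                    blob_id=blob_id, position_um=p, zone=zone, combo=combo,
                    area_um2=float(np.pi * spec.blob_radius_um ** 2)))
                blob_id += 1

    yy = np.arange(ny)[:, None] * vy
    xx = np.arange(nx)[None, :] * vx
    py = yy - c[0]
    px = xx - c[1]
    axial = py * u[0] + px * u[1]
    perp = py * v[0] + px * v[1]

    def disk(center_ax: float, center_pp: float, radius: float, soft_um: float = 0.04):
        d = np.hypot(axial - center_ax, perp - center_pp)
        profile = 1.0 / (1.0 + np.exp(np.clip((d - radius) / soft_um, -50, 50)))
        return np.where(d <= radius + 6 * soft_um, profile, 0.0)  # compact support

    def nucleus(center_ax: float):
        rho = np.hypot((axial - center_ax) / spec.nucleus_radii_um[0],
                       perp / spec.nucleus_radii_um[1])
        return 1.0 / (1.0 + np.exp((rho - 1.0) * 14.0))

    channels = spec.channel_labels
    planes = {name: np.zeros((ny, nx)) for name in channels}
    planes["DAPI"] = spec.dapi_amplitude * (
        nucleus(-spec.nucleus_offset_um) + nucleus(spec.nucleus_offset_um))
    for blob in placed:
        d = blob.position_um - c
        bl = spec.blob_amplitude * disk(float(d @ u), float(d @ v), spec.blob_radius_um)
        planes[spec.reference] += bl
        for m in blob.combo:
            planes[m] += bl

    zc = (nz - 1) / 2
    zprofile = np.exp(-((np.arange(nz) - zc) ** 2) / (2 * 1.0 ** 2))
    data = np.zeros((1, len(channels), nz, ny, nx))
    for ci, name in enumerate(channels):
        data[0, ci] = zprofile[:, None, None] * planes[name][None, :, :]
    if spec.poisson_noise:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    if spec.read_noise_sigma > 0:
        data = data + rng.normal(0.0, spec.read_noise_sigma, size=data.shape)
    data = np.clip(data, 0.0, None).astype(np.float32)

    movie = MovieStack(data=data, voxel_size=spec.voxel_size_um,
                       frame_interval=0.0, channel_labels=channels)
    truth = FixedCellGroundTruth(
        blobs=placed,
        nucleus_centers_um=np.stack([c - spec.nucleus_offset_um * u,
                                     c + spec.nucleus_offset_um * u]),
        nucleus_radii_um=spec.nucleus_radii_um,
        axis_unit=u,
        center_um=c,
    )
    return movie, truth
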