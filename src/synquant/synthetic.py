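"""Synthetic ground-truth data emulating immunological-synapse imaging.

The generator renders the three kinds of raw data the analysis pipeline
consumes, each with an exact ground-truth record:

* A mature "bull's-eye" synapse as a 2D TIRF-like multi-channel image: a
  bright-field-style footprint disk, an adhesion (ICAM-1-like) ring — the
  pSMAC —, a receptor (TCR-like) channel with a central cSMAC disk plus
  diffraction-limited microclusters, and an adaptor (clathrin-like) channel
  whose colocalization with the receptor channel is controlled by a mixing
  parameter.
* Time-lapse movies of microclusters drifting centripetally toward the cSMAC.
* 3D confocal-like stacks of an ellipsoidal cell (membrane channel) with
  antigen-positive vesicles strictly inside it and released receptor-positive
  vesicles strictly outside it.
* Flow-cytometry-style event tables for the bead-supported-lipid-bilayer
  transfer assay.

Spots and spheres are evaluated analytically per pixel/voxel (no convolution)
so integrated intensities and volumes have closed forms usable as oracles.
Noise is optional: Poisson resampling of the noise-free image followed by
additive Gaussian read noise.  Each rendered object class draws from its own
RNG stream derived from the top-level seed, so e.g. adding vesicles never
perturbs microcluster placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .images import MultiChannelImage, VolumeStack

__all__ = [
    "SynapseSpec",
    "StackSpec",
    "GroundTruth",
    "render_synapse",
    "render_movie",
    "render_stack",
    "render_transfer_events",
]

# Fixed stream ids per object class: adding one class of objects must not
# change the draws of another.
_STREAMS = {
    "microclusters": 0,
    "puncta": 1,
    "noise2d": 2,
    "movie": 3,
    "vesicles": 4,
    "noise3d": 5,
    "transfer": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# specs


@dataclass
class SynapseSpec:
    """Geometry, intensities, and noise of one synthetic synapse.

    Default amplitudes follow the relative ligand densities used on the
    supported lipid bilayers (adhesion 200, receptor 20, adaptor 30 per um^2),
    used here purely as relative intensity scales in arbitrary units.
    Geometry is scaled to a ~13 um field holding one ~9 um synapse.
    """

    image_size_px: int = 128
    pixel_size_um: float = 0.1
    center_xy: tuple[float, float] | None = None  # px; None = image centre
    ring_radius_um: float = 3.5
    ring_width_um: float = 0.8
    csmac_radius_um: float = 1.2
    n_microclusters: int = 30
    microcluster_sigma_um: float = 0.2
    channel_amplitudes: dict[str, float] = field(
        default_factory=lambda: {
            "brightfield": 100.0,
            "adhesion": 200.0,
            "receptor": 20.0,
            "adaptor": 30.0,
        }
    )
    coloc_mixing: float = 0.7
    csmac_amplitude_scale: float = 1.0  # central-disk brightness relative to clusters
    background_level: float = 10.0
    gaussian_noise_sd: float = 0.0
    poisson_noise: bool = False
    seed: int = 0

    @property
    def footprint_radius_um(self) -> float:
        """Radius of the cell contact footprint: adhesion ring plus its width."""
        return self.ring_radius_um + self.ring_width_um

    @property
    def center_px(self) -> tuple[float, float]:
        if self.center_xy is not None:
            return (float(self.center_xy[0]), float(self.center_xy[1]))
        c = (self.image_size_px - 1) / 2.0
        return (c, c)

    def validate(self) -> None:
        half_extent_um = self.image_size_px * self.pixel_size_um / 2.0
        if not (0 < self.csmac_radius_um < self.ring_radius_um < half_extent_um):
            raise ValueError(
                "geometry must satisfy 0 < csmac_radius_um < ring_radius_um "
                f"< half extent ({half_extent_um:.2f} um)"
            )
        if self.ring_width_um <= 0 or self.microcluster_sigma_um <= 0:
            raise ValueError("widths and sigmas must be positive")
        if self.pixel_size_um <= 0 or self.image_size_px <= 0:
            raise ValueError("pixel size and image size must be positive")
        if any(a < 0 for a in self.channel_amplitudes.values()):
            raise ValueError("channel amplitudes must be nonnegative")
        if not 0.0 <= self.coloc_mixing <= 1.0:
            raise ValueError("coloc_mixing must lie in [0, 1]")
        if self.csmac_amplitude_scale < 0:
            raise ValueError("csmac_amplitude_scale must be nonnegative")
        if self.background_level < 0 or self.gaussian_noise_sd < 0:
            raise ValueError("background and noise sd must be nonnegative")
        if self.n_microclusters < 0:
            raise ValueError("n_microclusters must be nonnegative")


@dataclass
class StackSpec:
    """Geometry, intensities, and noise of one synthetic 3D cell stack.

    ``volume_size_px`` is (z, y, x); ``cell_center_um``/``cell_semiaxes_um``
    are (x, y, z) in physical units.  The default z step of 0.25 um mirrors
    typical confocal acquisition of whole T cells.  Default noise (Poisson
    shot noise plus Gaussian read noise, sd 2 on a vesicle amplitude of 150)
    defines the standard condition for count-recovery experiments.
    """

    volume_size_px: tuple[int, int, int] = (32, 96, 96)
    pixel_size_um: float = 0.15
    z_step_um: float = 0.25
    cell_center_um: tuple[float, float, float] | None = None
    cell_semiaxes_um: tuple[float, float, float] = (4.5, 4.5, 2.8)
    n_internal_vesicles: int = 7
    n_released_vesicles: int = 4
    vesicle_radius_um: float = 0.4
    vesicle_amplitude: float = 150.0
    membrane_amplitude: float = 100.0
    background_level: float = 5.0
    gaussian_noise_sd: float = 2.0
    poisson_noise: bool = True
    seed: int = 0

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent as (x, y, z)."""
        nz, ny, nx = self.volume_size_px
        return (nx * self.pixel_size_um, ny * self.pixel_size_um, nz * self.z_step_um)

    @property
    def center_um(self) -> tuple[float, float, float]:
        if self.cell_center_um is not None:
            return tuple(float(v) for v in self.cell_center_um)  # type: ignore[return-value]
        ex, ey, ez = self.extent_um
        return (ex / 2, ey / 2, ez / 2)

    def validate(self) -> None:
        if any(n < 3 for n in self.volume_size_px):
            raise ValueError("volume must have at least 3 planes per axis")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("voxel sizes must be positive")
        if any(a <= 0 for a in self.cell_semiaxes_um):
            raise ValueError("ellipsoid semi-axes must be positive")
        if self.vesicle_radius_um <= 0 or self.vesicle_amplitude <= 0:
            raise ValueError("vesicle radius and amplitude must be positive")
        if self.n_internal_vesicles < 0 or self.n_released_vesicles < 0:
            raise ValueError("vesicle counts must be nonnegative")
        if self.background_level < 0 or self.gaussian_noise_sd < 0:
            raise ValueError("background and noise sd must be nonnegative")
        ext = self.extent_um
        c = self.center_um
        for ax in range(3):
            if not 0 < c[ax] < ext[ax]:
                raise ValueError("cell centre must lie inside the volume")
            if c[ax] - self.cell_semiaxes_um[ax] < 0 or c[ax] + self.cell_semiaxes_um[ax] > ext[ax]:
                raise ValueError("cell ellipsoid must fit inside the volume")


@dataclass
class GroundTruth:
    """Exact record of every rendered object, for oracle-based testing.

    Only the fields relevant to the rendered artifact are populated.
    """

    cell_mask: np.ndarray | None = None
    microclusters: pd.DataFrame | None = None  # columns: cluster_id, x_px, y_px
    coloc_mixing: float | None = None
    tracks: pd.DataFrame | None = None  # columns: frame, track_id, x_px, y_px, radius_um
    vesicles: pd.DataFrame | None = None
    cell_center_um: tuple[float, float, float] | None = None
    cell_semiaxes_um: tuple[float, float, float] | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        if self.coloc_mixing is not None:
            out["coloc_mixing"] = self.coloc_mixing
        if self.microclusters is not None:
            out["microclusters"] = self.microclusters.to_dict(orient="records")
        if self.tracks is not None:
            out["tracks"] = self.tracks.to_dict(orient="records")
        if self.vesicles is not None:
            out["vesicles"] = self.vesicles.to_dict(orient="records")
        if self.cell_center_um is not None:
            out["cell_center_um"] = list(self.cell_center_um)
            out["cell_semiaxes_um"] = list(self.cell_semiaxes_um)  # type: ignore[arg-type]
        return out


# ---------------------------------------------------------------------------
# 2D rendering primitives (analytic, per pixel)


def _grid_um(spec: SynapseSpec) -> tuple[np.ndarray, np.ndarray]:
    """Radial distance from centre (um) and the pixel coordinate grids."""
    n = spec.image_size_px
    cy, cx = spec.center_px[1], spec.center_px[0]
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(xx - cx, yy - cy) * spec.pixel_size_um
    return r, np.stack([xx, yy])


def _soft_disk(r_um: np.ndarray, radius_um: float, edge_um: float) -> np.ndarray:
    """Unit-amplitude disk with a sigmoid edge of scale ``edge_um``."""
    return 1.0 / (1.0 + np.exp((r_um - radius_um) / edge_um))


def _gaussian_ring(r_um: np.ndarray, radius_um: float, width_um: float) -> np.ndarray:
    sigma = width_um / 2.355  # FWHM -> sigma
    return np.exp(-0.5 * ((r_um - radius_um) / sigma) ** 2)


def _gaussian_spots(
    shape: tuple[int, int],
    positions_px: np.ndarray,
    sigma_px: float,
    amplitude: float,
) -> np.ndarray:
    img = np.zeros(shape)
    if len(positions_px) == 0:
        return img
    half = int(math.ceil(4 * sigma_px))
    for x, y in positions_px:
        x0, y0 = int(round(x)), int(round(y))
        ys = slice(max(0, y0 - half), min(shape[0], y0 + half + 1))
        xs = slice(max(0, x0 - half), min(shape[1], x0 + half + 1))
        yy, xx = np.mgrid[ys, xs]
        img[ys, xs] += amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma_px**2)
        )
    return img


def _apply_noise(
    img: np.ndarray, poisson: bool, gaussian_sd: float, rng: np.random.Generator
) -> np.ndarray:
    out = img
    if poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape)
    return out


def _sample_annulus(
    rng: np.random.Generator, n: int, r_min_um: float, r_max_um: float
) -> np.ndarray:
    """Uniform-in-area positions (um, relative to centre) in an annulus."""
    u = rng.uniform(r_min_um**2, r_max_um**2, size=n)
    radii = np.sqrt(u)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])


# ---------------------------------------------------------------------------
# synapse image


def _render_synapse_channels(
    spec: SynapseSpec, cluster_xy_px: np.ndarray
) -> dict[str, np.ndarray]:
    """Noise-free signal channels (background included), given cluster positions."""
    r, _ = _grid_um(spec)
    amps = spec.channel_amplitudes
    edge = spec.pixel_size_um  # ~1 px soft edge: keeps profiles band-limited
    sigma_px = spec.microcluster_sigma_um / spec.pixel_size_um
    shape = (spec.image_size_px, spec.image_size_px)

    brightfield = amps.get("brightfield", 0.0) * _soft_disk(r, spec.footprint_radius_um, edge)
    adhesion = amps.get("adhesion", 0.0) * _gaussian_ring(r, spec.ring_radius_um, spec.ring_width_um)

    rec_amp = amps.get("receptor", 0.0)
    receptor = rec_amp * spec.csmac_amplitude_scale * _soft_disk(r, spec.csmac_radius_um, edge)
    receptor += _gaussian_spots(shape, cluster_xy_px, sigma_px, rec_amp)

    # Adaptor: a fraction ``coloc_mixing`` of its signal is a rescaled copy of
    # the receptor signal; the rest is an independent punctate pattern.
    ada_amp = amps.get("adaptor", 0.0)
    m = spec.coloc_mixing
    scaled_receptor = receptor * (ada_amp / rec_amp) if rec_amp > 0 else receptor
    puncta_rng = _rng(spec.seed, "puncta")
    n_puncta = spec.n_microclusters
    puncta_um = _sample_annulus(puncta_rng, n_puncta, 0.0, spec.ring_radius_um)
    cx, cy = spec.center_px
    puncta_px = puncta_um / spec.pixel_size_um + np.array([cx, cy])
    puncta = _gaussian_spots(shape, puncta_px, sigma_px, ada_amp) if n_puncta else np.zeros(shape)
    adaptor = m * scaled_receptor + (1.0 - m) * puncta

    bg = spec.background_level
    return {
        "brightfield": brightfield + bg,
        "adhesion": adhesion + bg,
        "receptor": receptor + bg,
        "adaptor": adaptor + bg,
    }


def render_synapse(spec: SynapseSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one bull's-eye synapse and its exact ground truth.

    Returns the four-channel image (brightfield, adhesion, receptor, adaptor)
    and a :class:`GroundTruth` holding the footprint mask, microcluster
    positions, and the colocalization mixing parameter.  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    mc_rng = _rng(spec.seed, "microclusters")
    rel_um = _sample_annulus(
        mc_rng, spec.n_microclusters, spec.csmac_radius_um, spec.ring_radius_um
    )
    cx, cy = spec.center_px
    cluster_px = rel_um / spec.pixel_size_um + np.array([cx, cy])

    channels = _render_synapse_channels(spec, cluster_px)
    noise_rng = _rng(spec.seed, "noise2d")
    channels = {
        name: _apply_noise(img, spec.poisson_noise, spec.gaussian_noise_sd, noise_rng)
        for name, img in channels.items()
    }

    r, _ = _grid_um(spec)
    gt = GroundTruth(
        cell_mask=r <= spec.footprint_radius_um,
        microclusters=pd.DataFrame(
            {
                "cluster_id": np.arange(len(cluster_px)),
                "x_px": cluster_px[:, 0] if len(cluster_px) else np.array([]),
                "y_px": cluster_px[:, 1] if len(cluster_px) else np.array([]),
            }
        ),
        coloc_mixing=spec.coloc_mixing,
    )
    return MultiChannelImage(channels, spec.pixel_size_um), gt


# ---------------------------------------------------------------------------
# movie


def render_movie(
    spec: SynapseSpec,
    n_frames: int,
    drift_per_frame_um: float,
    adaptor_scale_per_frame: Sequence[float] | None = None,
    initial_radii_um: Sequence[float] | None = None,
    angles_deg: Sequence[float] | None = None,
) -> tuple[list[MultiChannelImage], GroundTruth]:
    """Render a time-lapse of microclusters drifting centripetally.

    Each cluster starts in the pSMAC annulus and moves radially inward by
    ``drift_per_frame_um`` per frame until it reaches the cSMAC radius, where
    it stays.  ``adaptor_scale_per_frame`` optionally rescales the adaptor
    signal per frame (e.g. a linear recruitment ramp).  Initial radii and
    angles default to random placement; passing them explicitly gives full
    control over inter-cluster separations.  Track identities are recorded
    in the ground truth.
    """
    spec.validate()
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if drift_per_frame_um < 0:
        raise ValueError("drift must be nonnegative")
    if adaptor_scale_per_frame is not None and len(adaptor_scale_per_frame) != n_frames:
        raise ValueError("adaptor_scale_per_frame must have one entry per frame")

    mv_rng = _rng(spec.seed, "movie")
    n = spec.n_microclusters
    if initial_radii_um is not None:
        radii0 = np.asarray(initial_radii_um, dtype=float)
        if radii0.shape != (n,):
            raise ValueError("initial_radii_um must have one radius per cluster")
    else:
        u = mv_rng.uniform(spec.csmac_radius_um**2, spec.ring_radius_um**2, size=n)
        radii0 = np.sqrt(u)
    if angles_deg is not None:
        theta = np.deg2rad(np.asarray(angles_deg, dtype=float))
        if theta.shape != (n,):
            raise ValueError("angles_deg must have one angle per cluster")
    else:
        theta = mv_rng.uniform(0, 2 * np.pi, size=n)
    cx, cy = spec.center_px

    noise_rng = _rng(spec.seed, "noise2d")
    frames: list[MultiChannelImage] = []
    records = []
    for t in range(n_frames):
        radii = np.maximum(spec.csmac_radius_um, radii0 - t * drift_per_frame_um)
        rel_um = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
        pos_px = rel_um / spec.pixel_size_um + np.array([cx, cy])
        channels = _render_synapse_channels(spec, pos_px)
        if adaptor_scale_per_frame is not None:
            bg = spec.background_level
            channels["adaptor"] = (
                (channels["adaptor"] - bg) * float(adaptor_scale_per_frame[t]) + bg
            )
        channels = {
            name: _apply_noise(img, spec.poisson_noise, spec.gaussian_noise_sd, noise_rng)
            for name, img in channels.items()
        }
        frames.append(MultiChannelImage(channels, spec.pixel_size_um))
        for k in range(n):
            records.append(
                {
                    "frame": t,
                    "track_id": k,
                    "x_px": pos_px[k, 0],
                    "y_px": pos_px[k, 1],
                    "radius_um": radii[k],
                }
            )
    tracks = pd.DataFrame(
        records, columns=["frame", "track_id", "x_px", "y_px", "radius_um"]
    )
    return frames, GroundTruth(tracks=tracks, coloc_mixing=spec.coloc_mixing)


# ---------------------------------------------------------------------------
# 3D stack


def _voxel_centers_um(spec: StackSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nz, ny, nx = spec.volume_size_px
    z = (np.arange(nz) + 0.5) * spec.z_step_um
    y = (np.arange(ny) + 0.5) * spec.pixel_size_um
    x = (np.arange(nx) + 0.5) * spec.pixel_size_um
    return np.meshgrid(z, y, x, indexing="ij")


def _ellipsoid_norm(
    zz: np.ndarray, yy: np.ndarray, xx: np.ndarray, spec: StackSpec
) -> np.ndarray:
    cxu, cyu, czu = spec.center_um
    ax, ay, az = spec.cell_semiaxes_um
    return np.sqrt(((xx - cxu) / ax) ** 2 + ((yy - cyu) / ay) ** 2 + ((zz - czu) / az) ** 2)


def _place_vesicles(spec: StackSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Sample non-overlapping vesicle centres, internal strictly inside the
    cell ellipsoid and released strictly outside it (whole sphere on each
    side, with a half-radius safety margin).  Raises if a constraint cannot
    be satisfied within the retry budget.
    """
    r = spec.vesicle_radius_um
    margin = 1.5 * r
    # surface gap of two voxel layers so discretized balls never touch under
    # 26-connectivity: rendered objects must stay individually resolvable
    min_sep = 2 * r + 2 * max(spec.pixel_size_um, spec.z_step_um)
    ext = spec.extent_um
    c = np.array(spec.center_um)
    semi = np.array(spec.cell_semiaxes_um)
    placed: list[np.ndarray] = []
    rows = []

    def norm_at(p: np.ndarray, axes: np.ndarray) -> float:
        return float(np.sqrt(np.sum(((p - c) / axes) ** 2)))

    for location, count in (("internal", spec.n_internal_vesicles),
                            ("released", spec.n_released_vesicles)):
        for k in range(count):
            for _ in range(20000):
                p = np.array([rng.uniform(margin, e - margin) for e in ext])
                if location == "internal":
                    ok = norm_at(p, semi - margin) <= 1.0 if np.all(semi > margin) else False
                else:
                    ok = norm_at(p, semi + margin) > 1.0
                if ok and all(np.linalg.norm(p - q) > min_sep for q in placed):
                    placed.append(p)
                    rows.append(
                        {
                            "label": len(rows),
                            "x_um": p[0],
                            "y_um": p[1],
                            "z_um": p[2],
                            "radius_um": r,
                            "location": location,
                        }
                    )
                    break
            else:
                raise RuntimeError(
                    f"could not place {location} vesicle {k}: non-overlap and "
                    f"{'inside' if location == 'internal' else 'outside'}-ellipsoid "
                    "constraints unsatisfiable in the retry budget"
                )
    return pd.DataFrame(
        rows, columns=["label", "x_um", "y_um", "z_um", "radius_um", "location"]
    )


def _render_balls(
    spec: StackSpec, vesicles: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Render uniform-intensity balls; return (volume, true voxel counts)."""
    nz, ny, nx = spec.volume_size_px
    vol = np.zeros((nz, ny, nx))
    counts = np.zeros(len(vesicles), dtype=int)
    zz, yy, xx = _voxel_centers_um(spec)
    for i, v in vesicles.reset_index(drop=True).iterrows():
        d2 = (xx - v.x_um) ** 2 + (yy - v.y_um) ** 2 + (zz - v.z_um) ** 2
        inside = d2 <= v.radius_um**2
        vol[inside] += spec.vesicle_amplitude
        counts[i] = int(inside.sum())
    return vol, counts


def render_stack(spec: StackSpec) -> tuple[VolumeStack, GroundTruth]:
    """Render a 3D stack of one cell with internal and released vesicles.

    Channels: ``membrane`` (bright ellipsoid interior with an accentuated
    shell), ``antigen`` (internal vesicles only), ``receptor`` (internal and
    released vesicles).  The ground truth records each vesicle's centre,
    radius, rendered voxel count and integrated intensity, and side of the
    membrane.
    """
    spec.validate()
    rng = _rng(spec.seed, "vesicles")
    vesicles = _place_vesicles(spec, rng)

    zz, yy, xx = _voxel_centers_um(spec)
    norm = _ellipsoid_norm(zz, yy, xx, spec)
    # membrane stain: bright interior with a narrow shell accent; the soft
    # edge is centred on norm = 1 so a half-maximum threshold recovers the
    # true boundary
    mean_axis = float(np.mean(spec.cell_semiaxes_um))
    edge = 0.1 / mean_axis  # ~0.1 um sigmoid edge in normalised units
    shell_width = 0.1  # um
    membrane = spec.membrane_amplitude * (
        1.0 / (1.0 + np.exp((norm - 1.0) / edge))
        + 0.15 * np.exp(-0.5 * ((norm - 1.0) * mean_axis / shell_width) ** 2)
    )

    internal = vesicles[vesicles.location == "internal"]
    released = vesicles[vesicles.location == "released"]
    antigen, counts_int = _render_balls(spec, internal)
    receptor_balls, counts_all = _render_balls(spec, vesicles)

    bg = spec.background_level
    channels = {
        "membrane": membrane + bg,
        "antigen": antigen + bg,
        "receptor": receptor_balls + bg,
    }
    noise_rng = _rng(spec.seed, "noise3d")
    channels = {
        name: _apply_noise(img, spec.poisson_noise, spec.gaussian_noise_sd, noise_rng)
        for name, img in channels.items()
    }

    gt_ves = vesicles.copy()
    gt_ves["voxels"] = counts_all
    gt_ves["integrated_intensity"] = counts_all * spec.vesicle_amplitude
    gt_ves["volume_um3"] = (4.0 / 3.0) * np.pi * gt_ves["radius_um"] ** 3

    gt = GroundTruth(
        cell_mask=norm <= 1.0,
        vesicles=gt_ves,
        cell_center_um=spec.center_um,
        cell_semiaxes_um=spec.cell_semiaxes_um,
    )
    return VolumeStack(channels, spec.pixel_size_um, spec.z_step_um), gt


# ---------------------------------------------------------------------------
# transfer assay events


def render_transfer_events(
    n_beads: int,
    n_cells: int,
    bead_mu: float,
    cell_mu: float,
    noise_sd: float,
    seed: int,
    condition: str | None = None,
    ligand_density: float | None = None,
    experiment: str | None = None,
) -> pd.DataFrame:
    """Draw a flow-cytometry-style event table for the bead-transfer assay.

    Each event is a bead or a cell with fluorescence drawn as
    ``mu + N(0, noise_sd)``, clipped at zero.  Optional ``condition``,
    ``ligand_density`` and ``experiment`` labels are attached to every row so
    tables for dose-response experiments can be concatenated.
    """
    if n_beads < 1 or n_cells < 1:
        raise ValueError("need at least one bead and one cell event")
    if bead_mu < 0 or cell_mu < 0:
        raise ValueError("means must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = _rng(seed, "transfer")
    mus = np.concatenate([np.full(n_beads, bead_mu), np.full(n_cells, cell_mu)])
    vals = np.clip(mus + rng.normal(0.0, noise_sd, size=mus.size) if noise_sd > 0 else mus, 0, None)
    df = pd.DataFrame(
        {
            "event_id": np.arange(mus.size),
            "population": ["bead"] * n_beads + ["cell"] * n_cells,
            "fluorescence": vals,
        }
    )
    if condition is not None:
        df["condition"] = condition
    if ligand_density is not None:
        df["ligand_density"] = float(ligand_density)
    if experiment is not None:
        df["experiment"] = experiment
    return df
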