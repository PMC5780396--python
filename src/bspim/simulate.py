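"""Physics-based synthetic BSPIM acquisitions with ground truth.

The simulator replaces the microscope: it produces per-position time-lapse
speckle stacks with the statistical structure the GD index responds to,
together with an exact record of where every nematode is.

Speckle model
-------------
Fully developed polarized speckle is modelled as a per-pixel circular
complex Gaussian amplitude ``E`` whose intensity ``|E|^2`` is exponentially
distributed (speckle contrast sigma/mean = 1).  Temporal decorrelation is a
per-pixel AR(1) process on the amplitude,

    E' = rho * E + sqrt(1 - rho^2) * eta,

with ``eta`` a fresh circular complex Gaussian, so the lag-k amplitude
autocorrelation is ``rho**k`` and the marginal distribution is stationary.
Static material (background medium, soil particles, dead nematodes) has
``rho = 1``; live nematodes decorrelate the field (``rho < 1``) inside a
capsule-shaped footprint.  A finite speckle grain is imposed by low-pass
filtering the complex field.

Acquisition model
-----------------
A light sheet of configurable thickness is stepped through the scene; at
each position the sheet illuminates the slab of the scene it overlaps and a
stack of frames is recorded.  With 1 mm sheets stepped by 125 um a nematode
contributes activity to ~8 consecutive positions, the overlap later merged
by 3D connected components.  Frames are scaled to digital numbers, root
regions are driven into sensor saturation (so their strong biospeckle is
blotted out and they stay temporally constant), Gaussian read noise is
added, and the result is clipped and quantized to the sensor bit depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .biospeckle import FrameStack
from .errors import PlacementError

__all__ = [
    "Nematode",
    "RootSpec",
    "ClutterSpec",
    "GridGeometry",
    "SceneSpec",
    "AcquisitionConfig",
    "VolumeScan",
    "make_scene",
    "evolve_field",
    "render_frame",
    "simulate_scan",
    "slab_maps",
]

log = logging.getLogger(__name__)

# Size envelope of free-living nematodes: 40 um to 1.5 mm long, ~30 um wide.
MIN_LENGTH_UM = 40.0
MAX_LENGTH_UM = 1500.0
MAX_WIDTH_UM = 40.0


@dataclass(frozen=True)
class Nematode:
    """A capsule-shaped (cylinder + hemispherical caps) scatterer.

    ``decorrelation`` is the per-frame AR(1) coefficient rho of the complex
    field inside the body: live animals have rho < 1, heat-killed ones keep
    the background's rho and are temporally indistinguishable from it.
    ``brightness`` is a static scattering factor relative to the background
    mean intensity (dead nematodes remain slightly brighter than background,
    so they are visible in brightfield yet silent in GD).
    """

    centroid_um: Tuple[float, float, float]  # (x, y, z)
    length_um: float
    width_um: float
    orientation: Tuple[float, float, float]  # unit vector
    alive: bool
    decorrelation: float
    brightness: float = 2.5
    # optional locomotion between sheet positions (um per 6.8 s position
    # period); zero by default so ground-truth counts stay exact
    drift_um_per_position: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def centroid_at(self, position_index: int) -> Tuple[float, float, float]:
        dx, dy, dz = self.drift_um_per_position
        x, y, z = self.centroid_um
        k = position_index
        return (x + k * dx, y + k * dy, z + k * dz)

    def __post_init__(self) -> None:
        if not (MIN_LENGTH_UM <= self.length_um <= MAX_LENGTH_UM):
            raise ValueError(
                f"nematode length {self.length_um} um outside the "
                f"{MIN_LENGTH_UM}-{MAX_LENGTH_UM} um envelope"
            )
        if not (0.0 < self.width_um <= MAX_WIDTH_UM):
            raise ValueError(f"nematode width {self.width_um} um outside (0, {MAX_WIDTH_UM}]")
        if not (0.0 <= self.decorrelation <= 1.0):
            raise ValueError("decorrelation rho must lie in [0, 1]")
        norm = math.sqrt(sum(c * c for c in self.orientation))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError("orientation must be a unit vector")


@dataclass(frozen=True)
class RootSpec:
    """A plant-root cylinder, rendered saturated at the sensor."""

    p0_um: Tuple[float, float, float]
    p1_um: Tuple[float, float, float]
    radius_um: float = 250.0


@dataclass(frozen=True)
class ClutterSpec:
    """Static scatter heterogeneity of the medium.

    A log-normal smooth brightness field (refractive-index heterogeneity of
    the colloid) plus bright static grains (soil-particle glints).  All of it
    is temporally constant, so it raises brightfield noise without adding
    biospeckle activity.
    """

    amplitude_sd: float = 0.6  # log-sd of the smooth brightness field
    grain_um: float = 300.0  # correlation length of the smooth field
    n_bright_grains: int = 40  # static glints per optical section
    grain_brightness: float = 6.0  # glint brightness factor over background
    grain_radius_um: Tuple[float, float] = (60.0, 200.0)


@dataclass(frozen=True)
class GridGeometry:
    """Voxel grid of the simulated sample volume.

    The default in-plane sampling of 16 um/px corresponds to fitting the
    instrument's ~5 cm^2 field of view onto a 1392x1040 sensor; experiment
    drivers override it (e.g. a 1 cm cuvette mapped onto 256 px is
    ~39 um/px).  Voxel index ``i`` sits at physical coordinate
    ``i * voxel_size`` along each axis.
    """

    grid_shape: Tuple[int, int, int] = (256, 256, 80)  # (nx, ny, nz)
    voxel_size_xy: float = 16.0  # um / pixel in the image plane
    z_step: float = 125.0  # um between sheet positions

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if self.voxel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("physical voxel sizes must be positive")


@dataclass
class SceneSpec:
    """Ground-truth description of a synthetic sample.

    ``activity_halo_um`` is the radius by which the *decorrelating* region
    extends beyond a live animal's body: the coherent field at a pixel sums
    scattered amplitudes from a neighbourhood on the scale of the speckle
    grain and of the disturbed medium around the body, so speckle
    fluctuations reach somewhat beyond the anatomical outline.  The body's
    static brightness footprint is not widened.
    """

    geometry: GridGeometry
    nematodes: List[Nematode] = field(default_factory=list)
    root: Optional[RootSpec] = None
    background_decorrelation: float = 1.0
    clutter: Optional[ClutterSpec] = None
    activity_halo_um: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_decorrelation <= 1.0):
            raise ValueError("background decorrelation must lie in [0, 1]")

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.geometry.grid_shape

    @property
    def n_live(self) -> int:
        return sum(n.alive for n in self.nematodes)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scan protocol: 64 frames at 10 fps per position, 125 um steps.

    ``sheet_thickness_um`` is 1000 for fast automated detection scans
    (overlapping sections) or 30 for fine 3D rendering.  ``exposure_scale``
    maps unit mean speckle intensity to digital numbers; the default of 30 DN
    keeps the exponential intensity tail mostly below an 8-bit sensor's
    full well so speckle statistics survive quantization.
    """

    frames_per_position: int = 64
    frame_rate_hz: float = 10.0
    n_positions: int = 80
    z_increment_um: float = 125.0
    sheet_thickness_um: float = 1000.0
    settle_pause_s: float = 0.4
    exposure_scale: float = 30.0
    bit_depth: int = 8
    read_noise_sd: float = 1.0
    grain_px: float = 2.0  # speckle grain imposed on the complex field

    def __post_init__(self) -> None:
        if self.frames_per_position < 2:
            raise ValueError("need at least 2 frames per position")
        if self.z_increment_um <= 0:
            raise ValueError("z increment must be positive")
        if self.sheet_thickness_um <= 0:
            raise ValueError("sheet thickness must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def max_dn(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def position_period_s(self) -> float:
        """Time between starts of successive stacks (acquisition + settle)."""
        return self.frames_per_position / self.frame_rate_hz + self.settle_pause_s


@dataclass
class VolumeScan:
    """An ordered set of per-position frame stacks plus calibration."""

    stacks: List[FrameStack]
    acquisition: AcquisitionConfig
    pixel_size_um: float
    truth: Optional[SceneSpec] = None

    def __post_init__(self) -> None:
        if not self.stacks:
            raise ValueError("a scan needs at least one stack")
        shapes = {s.frames.shape for s in self.stacks}
        if len(shapes) != 1:
            raise ValueError(f"all stacks must share frame count and image shape, got {shapes}")
        zs = [s.z_position_um for s in self.stacks]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("stack order must be monotone in z")

    @property
    def n_positions(self) -> int:
        return len(self.stacks)


def _segment_distance_2d(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2D segments."""
    import numpy as _np

    def pt_seg(p, a, b):
        ab = b - a
        d = float(ab @ ab)
        if d == 0:
            return float(_np.linalg.norm(p - a))
        t = float(_np.clip((p - a) @ ab / d, 0.0, 1.0))
        return float(_np.linalg.norm(p - (a + t * ab)))

    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    d1, d2 = orient(a0, a1, b0), orient(a0, a1, b1)
    d3, d4 = orient(b0, b1, a0), orient(b0, b1, a1)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return 0.0
    return min(
        pt_seg(b0, a0, a1), pt_seg(b1, a0, a1), pt_seg(a0, b0, b1), pt_seg(a1, b0, b1)
    )


def _nematode_segment(nem: Nematode) -> Tuple[np.ndarray, np.ndarray]:
    c = np.asarray(nem.centroid_um, dtype=float)
    u = np.asarray(nem.orientation, dtype=float)
    half = (nem.length_um - nem.width_um) / 2.0  # axis of the capsule's cylinder
    half = max(half, 0.0)
    return c - half * u, c + half * u


def make_scene(
    n_nematodes: int,
    alive_fraction: float = 1.0,
    geometry: Optional[GridGeometry] = None,
    include_root: bool = False,
    seed: int = 0,
    *,
    medium: str = "clean",
    min_separation_um: float = 500.0,
    z_exclusion_um: float = 1400.0,
    length_range_um: Tuple[float, float] = (300.0, 1200.0),
    width_range_um: Tuple[float, float] = (20.0, 30.0),
    live_decorrelation: float = 0.5,
    live_brightness: float = 2.5,
    dead_brightness: float = 1.6,
    background_decorrelation: float = 1.0,
    clutter: Optional[ClutterSpec] = None,
    xy_margin_um: float = 150.0,
    z_margin_um: float = 1200.0,
    max_attempts_per_nematode: int = 500,
) -> SceneSpec:
    """Lay out a reproducible ground-truth scene.

    Nematodes are placed by rejection sampling with a pairwise separation
    constraint that keeps the ground-truth count well defined under the
    detection pipeline: two animals must either be at least
    ``min_separation_um`` apart in the image plane or have their sheet
    footprints separated in depth (centroids more than ``z_exclusion_um``
    apart, sized for a 1 mm sheet plus smoothing margin).  Dead animals get
    ``rho`` equal to the background's, making them statistically static.

    ``medium`` is ``"clean"`` (homogeneous colloid) or ``"soil"``
    (transparent soil: strong static refractive-index clutter); an explicit
    ``clutter`` spec overrides the medium preset.
    """
    if n_nematodes < 0:
        raise ValueError("n_nematodes must be >= 0")
    if not 0.0 <= alive_fraction <= 1.0:
        raise ValueError("alive_fraction must lie in [0, 1]")
    geometry = geometry or GridGeometry()
    rng = np.random.default_rng(seed)

    if clutter is None:
        if medium in ("soil", "soil-noise"):
            clutter = ClutterSpec()
        elif medium != "clean":
            raise ValueError(f"unknown medium {medium!r}; expected 'clean' or 'soil'")

    nx, ny, nz = geometry.grid_shape
    x_max = (nx - 1) * geometry.voxel_size_xy
    y_max = (ny - 1) * geometry.voxel_size_xy
    z_max = (nz - 1) * geometry.z_step

    n_live = int(round(alive_fraction * n_nematodes))
    alive_flags = np.zeros(n_nematodes, dtype=bool)
    alive_flags[:n_live] = True
    alive_flags = alive_flags[rng.permutation(n_nematodes)] if n_nematodes else alive_flags

    root = None
    if include_root:
        # Vertical root through the middle of the volume.
        xr, zr = 0.5 * x_max, 0.5 * z_max
        root = RootSpec(p0_um=(xr, 0.0, zr), p1_um=(xr, y_max, zr))

    placed: List[Nematode] = []
    for i in range(n_nematodes):
        length = float(rng.uniform(*length_range_um))
        width = float(rng.uniform(*width_range_um))
        margin = xy_margin_um + length / 2.0
        lo_z = min(z_margin_um, z_max / 2.0)
        hi_z = max(z_max - z_margin_um, z_max / 2.0)
        if 2 * margin >= x_max or 2 * margin >= y_max:
            raise PlacementError(
                f"grid {geometry.grid_shape} too small for a {length:.0f} um nematode "
                f"with {xy_margin_um} um margins"
            )
        for attempt in range(max_attempts_per_nematode):
            theta = rng.uniform(0.0, math.pi)
            u = (math.cos(theta), math.sin(theta), 0.0)
            c = (
                float(rng.uniform(margin, x_max - margin)),
                float(rng.uniform(margin, y_max - margin)),
                float(rng.uniform(lo_z, hi_z)),
            )
            cand = Nematode(
                centroid_um=c,
                length_um=length,
                width_um=width,
                orientation=u,
                alive=bool(alive_flags[i]),
                decorrelation=live_decorrelation if alive_flags[i] else background_decorrelation,
                brightness=live_brightness if alive_flags[i] else dead_brightness,
            )
            if root is not None:
                # keep animals clear of the saturated root band
                if abs(c[0] - root.p0_um[0]) < root.radius_um + width + min_separation_um / 2:
                    continue
            ok = True
            ca0, ca1 = _nematode_segment(cand)
            for other in placed:
                cb0, cb1 = _nematode_segment(other)
                dxy = _segment_distance_2d(ca0[:2], ca1[:2], cb0[:2], cb1[:2])
                dz = abs(cand.centroid_um[2] - other.centroid_um[2])
                if dxy < min_separation_um and dz < z_exclusion_um:
                    ok = False
                    break
            if ok:
                placed.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place nematode {i + 1}/{n_nematodes} after "
                f"{max_attempts_per_nematode} attempts: min_separation_um="
                f"{min_separation_um}, z_exclusion_um={z_exclusion_um} on grid "
                f"{geometry.grid_shape}"
            )

    return SceneSpec(
        geometry=geometry,
        nematodes=placed,
        root=root,
        background_decorrelation=background_decorrelation,
        clutter=clutter,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# coherent field machinery


def _filter_variance_scale(sigma: float) -> float:
    """Variance shrink factor of a gaussian_filter applied to white noise."""
    if sigma <= 0:
        return 1.0
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    s1 = float((k**2).sum())
    return s1 * s1  # separable 2D kernel


def coherent_noise(
    shape: Tuple[int, int], rng: np.random.Generator, grain_px: float = 0.0
) -> np.ndarray:
    """Unit-variance circular complex Gaussian field with optional grain.

    ``grain_px`` imposes a spatial speckle grain by low-pass filtering the
    amplitude (Gaussian, sigma = grain/2) and renormalizing to unit variance;
    per-pixel marginals stay circular Gaussian so intensities stay
    exponential.
    """
    re = rng.standard_normal(shape, dtype=np.float32)
    im = rng.standard_normal(shape, dtype=np.float32)
    if grain_px > 0:
        sigma = grain_px / 2.0
        re = gaussian_filter(re, sigma, mode="wrap")
        im = gaussian_filter(im, sigma, mode="wrap")
        scale = 1.0 / math.sqrt(_filter_variance_scale(sigma))
        re *= scale
        im *= scale
    return (re + 1j * im).astype(np.complex64) * np.float32(math.sqrt(0.5))


def evolve_field(
    field: np.ndarray,
    rho: float | np.ndarray,
    rng: np.random.Generator,
    grain_px: float = 0.0,
) -> np.ndarray:
    """Advance the complex speckle amplitude one frame interval.

    Applies the stationary AR(1) update ``E' = rho E + sqrt(1 - rho^2) eta``
    elementwise.  Where ``rho == 1`` the field is untouched and no noise is
    drawn, so large static backgrounds cost nothing; fresh grains are only
    synthesized over the bounding box of the decorrelating region.
    """
    field = np.asarray(field)
    rho_arr = np.asarray(rho, dtype=np.float32)
    if (rho_arr < 0).any() or (rho_arr > 1).any():
        raise ValueError("decorrelation rho must lie in [0, 1]")

    if rho_arr.ndim == 0:
        r = float(rho_arr)
        if r == 1.0:
            return field.copy()
        eta = coherent_noise(field.shape, rng, grain_px)
        return (r * field + math.sqrt(1.0 - r * r) * eta).astype(np.complex64)

    if rho_arr.shape != field.shape:
        raise ValueError("rho map must match the field shape")
    active = rho_arr < 1.0
    out = field.copy()
    if not active.any():
        return out
    rows = np.flatnonzero(active.any(axis=1))
    cols = np.flatnonzero(active.any(axis=0))
    pad = int(math.ceil(3.0 * grain_px)) if grain_px > 0 else 0
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + 1 + pad, field.shape[0])
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + 1 + pad, field.shape[1])
    sl = (slice(r0, r1), slice(c0, c1))
    eta = coherent_noise((r1 - r0, c1 - c0), rng, grain_px)
    r = rho_arr[sl]
    out[sl] = (r * field[sl] + np.sqrt(1.0 - r * r) * eta).astype(np.complex64)
    return out


@dataclass
class SlabMaps:
    """Per-position scene slice: what the sheet illuminates right now."""

    rho: np.ndarray | float  # AR(1) coefficient per pixel
    brightness: np.ndarray | float  # static scattering factor per pixel
    root_mask: Optional[np.ndarray]  # pixels driven into saturation
    z_um: float


def _capsule_footprint(
    nem: Nematode, shape: Tuple[int, int], voxel_xy: float, extra_radius_um: float = 0.0
) -> Optional[Tuple[slice, slice, np.ndarray]]:
    """Boolean in-plane footprint of a capsule, as (row slice, col slice, mask)."""
    a, b = _nematode_segment(nem)
    # effective rasterization radius: at least half a pixel so thin bodies
    # (30 um on a ~39 um grid) still cover their nearest pixel line
    rad = max(nem.width_um / 2.0 + extra_radius_um, 0.5 * voxel_xy)
    r_lo = int(math.floor(min(a[1], b[1]) / voxel_xy - rad / voxel_xy)) - 1
    r_hi = int(math.ceil(max(a[1], b[1]) / voxel_xy + rad / voxel_xy)) + 1
    c_lo = int(math.floor(min(a[0], b[0]) / voxel_xy - rad / voxel_xy)) - 1
    c_hi = int(math.ceil(max(a[0], b[0]) / voxel_xy + rad / voxel_xy)) + 1
    r_lo, r_hi = max(r_lo, 0), min(r_hi + 1, shape[0])
    c_lo, c_hi = max(c_lo, 0), min(c_hi + 1, shape[1])
    if r_lo >= r_hi or c_lo >= c_hi:
        return None
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
    px = cc * voxel_xy  # x coordinate of pixel centres
    py = rr * voxel_xy
    ab = b[:2] - a[:2]
    denom = float(ab @ ab)
    dx = px - a[0]
    dy = py - a[1]
    if denom == 0:
        ddx, ddy = dx, dy
    else:
        t = np.clip((dx * ab[0] + dy * ab[1]) / denom, 0.0, 1.0)
        ddx = dx - t * ab[0]
        ddy = dy - t * ab[1]
    mask = ddx * ddx + ddy * ddy <= rad * rad
    if not mask.any():
        return None
    return slice(r_lo, r_hi), slice(c_lo, c_hi), mask


def _clutter_brightness(
    scene: SceneSpec, shape: Tuple[int, int], position_index: int
) -> np.ndarray:
    """Static per-section brightness field for heterogeneous media.

    Seeded from the scene (not the scan) so the same sample re-imaged with a
    different scan seed keeps its static clutter.
    """
    spec = scene.clutter
    assert spec is not None
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(scene.seed) & 0x7FFFFFFF, spawn_key=(101, position_index))
    )
    g = rng.standard_normal(shape, dtype=np.float32)
    sigma_px = spec.grain_um / (2.0 * scene.geometry.voxel_size_xy)
    if sigma_px > 0:
        g = gaussian_filter(g, sigma_px, mode="reflect")
        g /= math.sqrt(_filter_variance_scale(sigma_px))
    b = np.exp(spec.amplitude_sd * g - 0.5 * spec.amplitude_sd**2).astype(np.float32)
    # bright static grains: soil-particle glints, some at or above saturation
    for _ in range(spec.n_bright_grains):
        r = rng.uniform(0, shape[0] - 1)
        c = rng.uniform(0, shape[1] - 1)
        rad = rng.uniform(*spec.grain_radius_um) / scene.geometry.voxel_size_xy
        factor = spec.grain_brightness * rng.uniform(0.5, 1.5)
        r0, r1 = max(int(r - rad) - 1, 0), min(int(r + rad) + 2, shape[0])
        c0, c1 = max(int(c - rad) - 1, 0), min(int(c + rad) + 2, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= rad * rad
        sub = b[r0:r1, c0:c1]
        sub[disk] = np.maximum(sub[disk], factor)
    return b


def slab_maps(scene: SceneSpec, acq: AcquisitionConfig, position_index: int) -> SlabMaps:
    """Resolve the scene into per-pixel rho/brightness maps for one position.

    The sheet at position ``k`` is centred at ``k * z_increment`` and spans
    half-open ``[z - t/2, z + t/2)``; any nematode whose body interval in z
    intersects it contributes its in-plane footprint, which is how a single
    animal shows up in ~(sheet/step) consecutive stacks.
    """
    nx, ny, _ = scene.grid_shape
    shape = (ny, nx)
    voxel = scene.geometry.voxel_size_xy
    z = position_index * acq.z_increment_um
    z_lo, z_hi = z - acq.sheet_thickness_um / 2.0, z + acq.sheet_thickness_um / 2.0

    rho: np.ndarray | float = float(scene.background_decorrelation)
    if scene.clutter is not None:
        brightness: np.ndarray | float = _clutter_brightness(scene, shape, position_index)
    else:
        brightness = 1.0

    for nem in scene.nematodes:
        if nem.drift_um_per_position != (0.0, 0.0, 0.0):
            nem = replace(nem, centroid_um=nem.centroid_at(position_index))
        zc = nem.centroid_um[2]
        half_z = nem.width_um / 2.0
        if zc + half_z < z_lo or zc - half_z >= z_hi:
            continue
        halo = scene.activity_halo_um if nem.decorrelation < scene.background_decorrelation else 0.0
        fp_rho = _capsule_footprint(nem, shape, voxel, extra_radius_um=halo)
        fp_body = _capsule_footprint(nem, shape, voxel)
        if fp_rho is None:
            continue
        rs, cs, mask = fp_rho
        if np.isscalar(rho):
            rho = np.full(shape, rho, dtype=np.float32)
        if np.isscalar(brightness):
            brightness = np.ones(shape, dtype=np.float32)
        rho[rs, cs][...] = np.where(mask, np.float32(nem.decorrelation), rho[rs, cs])
        if fp_body is not None:
            rs_b, cs_b, mask_b = fp_body
            brightness[rs_b, cs_b][...] = np.where(
                mask_b, np.float32(nem.brightness), brightness[rs_b, cs_b]
            )

    root_mask = None
    if scene.root is not None:
        rt = scene.root
        zr = rt.p0_um[2]
        if zr - rt.radius_um < z_hi and zr + rt.radius_um >= z_lo:
            xs = np.arange(nx) * voxel
            band = np.abs(xs - rt.p0_um[0]) <= rt.radius_um
            root_mask = np.zeros(shape, dtype=bool)
            root_mask[:, band] = True
    return SlabMaps(rho=rho, brightness=brightness, root_mask=root_mask, z_um=z)


def render_frame(
    field: np.ndarray,
    slab: SlabMaps,
    acq: AcquisitionConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Turn the complex amplitude into one quantized sensor frame.

    ``I = exposure * brightness * |E|^2``; root pixels are pushed above the
    sensor maximum (the deliberate over-exposure that blots out root
    biospeckle), Gaussian read noise is added, and the result is clipped to
    ``[0, 2^bit_depth - 1]`` and rounded to integers.  Saturated root pixels
    are therefore temporally constant at the maximum digital number.
    """
    intensity = (field.real**2 + field.imag**2) * np.float32(acq.exposure_scale)
    if not np.isscalar(slab.brightness) or slab.brightness != 1.0:
        intensity = intensity * slab.brightness
    if slab.root_mask is not None:
        # push well past full scale so read noise cannot un-saturate it
        intensity[slab.root_mask] = acq.max_dn + 10.0 * max(acq.read_noise_sd, 1.0)
    if acq.read_noise_sd > 0:
        intensity = intensity + acq.read_noise_sd * rng.standard_normal(
            intensity.shape, dtype=np.float32
        )
    np.clip(intensity, 0, acq.max_dn, out=intensity)
    dtype = np.uint8 if acq.bit_depth == 8 else np.uint16
    return np.rint(intensity).astype(dtype)


def simulate_scan(
    scene: SceneSpec,
    acq: Optional[AcquisitionConfig] = None,
    seed: Optional[int] = None,
) -> VolumeScan:
    """Simulate a full volume scan of a scene.

    Deterministic in ``(scene, acq, seed)``; ``seed`` defaults to the
    scene's own seed.  Each position gets an independently initialized
    coherent field advanced frame-by-frame with the scene's per-pixel rho
    (successive positions are 6.8 s apart in real time, far beyond the
    decorrelation time of a live animal, so independent fields per position
    are the stationary limit).
    """
    acq = acq or AcquisitionConfig()
    if seed is None:
        seed = scene.seed
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(7,))
    children = ss.spawn(acq.n_positions)

    nx, ny, _ = scene.grid_shape
    stacks: List[FrameStack] = []
    for k in range(acq.n_positions):
        rng = np.random.default_rng(children[k])
        slab = slab_maps(scene, acq, k)
        frames = np.empty((acq.frames_per_position, ny, nx), dtype=np.uint8 if acq.bit_depth == 8 else np.uint16)
        field = coherent_noise((ny, nx), rng, acq.grain_px)
        frames[0] = render_frame(field, slab, acq, rng)
        for i in range(1, acq.frames_per_position):
            field = evolve_field(field, slab.rho, rng, acq.grain_px)
            frames[i] = render_frame(field, slab, acq, rng)
        t0 = k * acq.position_period_s
        stamps = t0 + np.arange(acq.frames_per_position) / acq.frame_rate_hz
        stacks.append(
            FrameStack(frames=frames, timestamps=stamps, position_index=k, z_position_um=slab.z_um)
        )
    return VolumeScan(
        stacks=stacks,
        acquisition=acq,
        pixel_size_um=scene.geometry.voxel_size_xy,
        truth=scene,
    )
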