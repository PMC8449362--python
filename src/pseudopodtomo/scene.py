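"""Synthetic pseudopodium scene generator.

Builds tomogram-like volumes with fully known ground truth: helical actin
filaments of assigned barbed-end polarity bundled inside a membrane tube
resting on a support plane, receptor-shaped densities decorating the outer
leaflet, additive Gaussian noise and a single-axis missing wedge.

The default geometry is desk scale (1.1 nm voxels, 256 x 256 x 128 grid)
so that a full scene generates in seconds; the acquisition-scale pixel
sizes (0.34 / 0.22 nm) are ordinary parameter choices, not special cases.

Actin is modelled as a 1-start helix of Gaussian pseudo-subunits with a
rise of 27.6 Angstrom and a twist of 166.7 degrees per subunit; the twist
is left-handed by default (negative sign), the conventional handedness for
the actin 1-start (genetic) helix. The barbed end points along the +axis
of construction, which is what ties the synthetic ground truth to the
polarity labels recovered downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import TomogramVolume

__all__ = [
    "HelicalParams",
    "TubeSpec",
    "ReceptorSpec",
    "SceneSpec",
    "FilamentTrace",
    "SceneGroundTruth",
    "build_actin_density",
    "axial_autocorrelation_peak",
    "place_filaments",
    "place_membrane_and_receptors",
    "missing_wedge_filter",
    "apply_imaging_model",
    "generate_scene",
]

ACTIN_RISE_A = 27.6
ACTIN_TWIST_DEG = 166.7


class SceneError(ValueError):
    """Invalid scene specification or impossible placement request."""


@dataclass(frozen=True)
class HelicalParams:
    """Helical lattice of a filament.

    rise is in Angstrom (the unit resolutions and lattice spacings are
    conventionally quoted in); all other lengths in the package are nm.
    A negative twist is a left-handed 1-start helix.

    Each subunit is rendered as *two* Gaussian lobes: a main outer-domain
    lobe plus a smaller inner lobe displaced toward the barbed end. This
    matters: a helix of isotropic blobs has an exact 2-fold axis
    perpendicular to the filament (flipping it end-over-end reproduces
    the same helix at another phase), so polarity would be undetectable
    by construction. The asymmetric two-lobe subunit is what gives real
    filaments their arrowhead appearance, and what gives these synthetic
    ones a measurable polarity.
    """

    rise: float = ACTIN_RISE_A
    twist: float = -ACTIN_TWIST_DEG
    subunit_radius: float = 2.2   # nm, main lobe centre off the filament axis
    subunit_sigma: float = 0.9    # nm, main lobe Gaussian width
    lobe2_fraction: float = 0.9   # second-lobe amplitude relative to the main
    lobe2_radius: float = 3.0     # nm off-axis
    lobe2_sigma: float = 0.7      # nm
    lobe2_axial_offset: float = 1.4    # nm toward the barbed (+axis) end
    lobe2_azimuth_offset: float = -60.0  # deg relative to the main lobe

    def __post_init__(self) -> None:
        if not self.rise > 0:
            raise SceneError(f"rise must be positive, got {self.rise}")
        if not 0 < abs(self.twist) <= 180:
            raise SceneError(f"|twist| must lie in (0, 180], got {self.twist}")
        if self.subunit_radius < 0:
            raise SceneError("subunit_radius must be non-negative")
        if not self.subunit_sigma > 0:
            raise SceneError("subunit_sigma must be positive")

    @property
    def rise_nm(self) -> float:
        return self.rise / 10.0


@dataclass(frozen=True)
class TubeSpec:
    """Capped membrane cylinder resting above the support plane.

    The tube axis runs along x; the +x end carries a hemispherical cap
    (the protrusion tip), the -x end is left open (the continuation into
    the cell body).
    """

    radius: float = 50.0        # nm, outer leaflet radius
    length: float = 200.0       # nm, axis length excluding the cap
    bilayer_separation: float = 5.0   # nm between leaflet centres
    leaflet_sigma: float = 0.9  # nm, Gaussian radial profile per leaflet
    clearance: float = 3.0      # nm gap between tube bottom and support


@dataclass(frozen=True)
class ReceptorSpec:
    """Membrane-attached receptor decoration.

    ``height`` is the extent of the extracellular density above the outer
    leaflet measured at half of its peak -- the same convention the
    downstream height measurement uses.
    """

    count: int = 0
    height: float = 12.0              # nm
    placement_band: tuple[float, float] = (50.0, 70.0)  # nm above support
    min_separation: float = 9.0       # nm between placements
    amplitude: float = 1.3            # peak density relative to actin subunits


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to generate one synthetic pseudopodium tomogram."""

    volume_shape: tuple[int, int, int] = (256, 256, 128)  # (nx, ny, nz)
    pixel_size: float = 1.1          # nm / voxel
    n_filaments: tuple[int, int] = (15, 30)  # uniform draw [lo, hi]
    length_distribution: tuple[float, float] = (60.0, 170.0)  # nm
    tip_fraction: float = 0.74
    helical: HelicalParams = field(default_factory=HelicalParams)
    tube: TubeSpec = field(default_factory=TubeSpec)
    support_z: float = 5.0           # nm
    receptor_spec: ReceptorSpec = field(default_factory=ReceptorSpec)
    noise_sigma: float = 0.4         # x noise-free peak density
    tilt_range: float = 60.0         # degrees
    filament_angle_sigma: float = 4.0  # deg jitter of filament axes off the tube axis
    filament_separation: float = 9.0  # nm minimum distance between filament axes
    render_support: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tip_fraction <= 1:
            raise SceneError(f"tip_fraction must lie in [0,1], got {self.tip_fraction}")
        if not self.pixel_size > 0:
            raise SceneError("pixel_size must be positive")
        if not 0 < self.tilt_range <= 90:
            raise SceneError("tilt_range must lie in (0, 90]")
        if self.noise_sigma < 0:
            raise SceneError("noise_sigma must be non-negative")

    @property
    def tube_center_z(self) -> float:
        return self.support_z + self.tube.clearance + self.tube.radius


@dataclass
class FilamentTrace:
    """Centerline polyline of one filament.

    ``true_polarity`` is +1 if the barbed end points along increasing point
    order, -1 for the opposite, ``None`` when unknown (real data).
    """

    filament_id: int
    points: np.ndarray            # (N, 3) nm, [x, y, z]
    tangents: np.ndarray | None = None  # (N, 3) unit vectors
    true_polarity: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("trace needs an (N>=2, 3) point array")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0):
            raise ValueError("consecutive trace points must be distinct")
        if self.tangents is None:
            self.tangents = _polyline_tangents(self.points)

    @property
    def chord_direction(self) -> np.ndarray:
        d = self.points[-1] - self.points[0]
        return d / np.linalg.norm(d)

    def barbed_direction(self) -> np.ndarray:
        if self.true_polarity is None:
            raise ValueError("trace has no ground-truth polarity")
        return self.true_polarity * self.chord_direction

    def reversed(self) -> "FilamentTrace":
        pol = None if self.true_polarity is None else -self.true_polarity
        return FilamentTrace(self.filament_id, self.points[::-1].copy(),
                             None, pol)


@dataclass
class SceneGroundTruth:
    traces: list[FilamentTrace]
    receptor_placements: list[dict]
    tip_axis: np.ndarray
    membrane_mask: np.ndarray     # bool, [z, y, x]
    support_z: float
    tube_center: np.ndarray       # [x, y, z] of the tube axis midpoint


def _polyline_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents by central differences, one-sided at the ends."""
    tang = np.empty_like(points)
    tang[1:-1] = points[2:] - points[:-2]
    tang[0] = points[1] - points[0]
    tang[-1] = points[-1] - points[-2]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return tang


def _stamp_gaussians(grid: np.ndarray, origin: np.ndarray, pixel_size: float,
                     centers: np.ndarray, sigma: float | np.ndarray,
                     amplitude: float | np.ndarray = 1.0) -> None:
    """Add isotropic Gaussian blobs to ``grid`` in place (local stamping)."""
    centers = np.atleast_2d(centers)
    sigmas = np.broadcast_to(np.asarray(sigma, dtype=float), (len(centers),))
    amps = np.broadcast_to(np.asarray(amplitude, dtype=float), (len(centers),))
    nz, ny, nx = grid.shape
    for c, s, a in zip(centers, sigmas, amps):
        half = 3.5 * s
        lo = np.floor((c - half - origin) / pixel_size).astype(int)
        hi = np.ceil((c + half - origin) / pixel_size).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, [nx, ny, nz])
        if np.any(hi <= lo):
            continue
        ax = [origin[i] + pixel_size * np.arange(lo[i], hi[i]) - c[i] for i in range(3)]
        gx = np.exp(-0.5 * (ax[0] / s) ** 2)
        gy = np.exp(-0.5 * (ax[1] / s) ** 2)
        gz = np.exp(-0.5 * (ax[2] / s) ** 2)
        grid[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] += (
            a * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )


def helix_subunit_coords(params: HelicalParams, length_nm: float,
                         phase_deg: float = 0.0) -> np.ndarray:
    """Main-lobe subunit centres of a helix along +x starting at the origin.

    Subunit k sits at axial position k*rise, azimuth phase + k*twist,
    at ``subunit_radius`` off the axis. A filament shorter than one rise
    degenerates to a single subunit at the origin.
    """
    if length_nm < 0:
        raise SceneError("length must be non-negative")
    n = int(math.floor(length_nm / params.rise_nm)) + 1
    k = np.arange(n)
    ang = np.deg2rad(phase_deg + k * params.twist)
    return np.column_stack([
        k * params.rise_nm,
        params.subunit_radius * np.cos(ang),
        params.subunit_radius * np.sin(ang),
    ])


def helix_lobe_coords(params: HelicalParams, length_nm: float,
                      phase_deg: float = 0.0
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All rendered lobes of a helix along +x: main lattice plus the
    barbed-end-shifted second lobes.

    Returns ``(centers, sigmas, amplitudes)`` in the local frame
    (x = axis, barbed end toward +x).
    """
    main = helix_subunit_coords(params, length_nm, phase_deg)
    n = len(main)
    k = np.arange(n)
    ang2 = np.deg2rad(phase_deg + k * params.twist + params.lobe2_azimuth_offset)
    lobe2 = np.column_stack([
        k * params.rise_nm + params.lobe2_axial_offset,
        params.lobe2_radius * np.cos(ang2),
        params.lobe2_radius * np.sin(ang2),
    ])
    centers = np.concatenate([main, lobe2])
    sigmas = np.concatenate([np.full(n, params.subunit_sigma),
                             np.full(n, params.lobe2_sigma)])
    amps = np.concatenate([np.ones(n), np.full(n, params.lobe2_fraction)])
    return centers, sigmas, amps


def build_actin_density(params: HelicalParams, length_nm: float,
                        pixel_size: float, pad_nm: float = 6.0,
                        phase_deg: float = 0.0) -> tuple[TomogramVolume, np.ndarray]:
    """Rasterize a noise-free helical filament along +x.

    Returns the volume and the subunit centres (nm, volume frame). The
    barbed end points along +x by construction.
    """
    if not pixel_size > 0:
        raise SceneError(f"pixel_size must be positive, got {pixel_size}")
    coords = helix_subunit_coords(params, length_nm, phase_deg)
    lobes, sigmas, amps = helix_lobe_coords(params, length_nm, phase_deg)
    lateral = params.subunit_radius + 3.5 * params.subunit_sigma + pad_nm
    nx = int(math.ceil((coords[-1, 0] + 2 * pad_nm) / pixel_size)) + 1
    nyz = 2 * int(math.ceil(lateral / pixel_size)) + 1
    grid = np.zeros((nyz, nyz, nx), dtype=np.float32)
    origin = np.array([-pad_nm, -lateral, -lateral])
    _stamp_gaussians(grid, origin, pixel_size, lobes, sigmas, amps)
    vol = TomogramVolume(grid, pixel_size, origin=origin)
    return vol, coords


def axial_autocorrelation_peak(params: HelicalParams, length_nm: float = 100.0,
                               sample_a: float = 0.5,
                               pixel_size: float = 0.25,
                               detrend_sigma_nm: float = 2.0) -> float:
    """First off-origin peak (Angstrom) of the axial autocorrelation of a
    noise-free filament.

    The filament density is integrated over the two lateral axes to give
    an axial profile; the smooth envelope (the filament's finite length,
    Gaussian-filtered at ``detrend_sigma_nm``) is subtracted so the
    lattice ripple is not buried under the envelope's slope. The residual
    is upsampled by Fourier interpolation to ``sample_a`` Angstrom and
    autocorrelated; the first local maximum after the first local minimum
    is refined by quadratic interpolation.
    """
    vol, _ = build_actin_density(params, length_nm, pixel_size)
    profile = vol.grid.sum(axis=(0, 1)).astype(float)
    profile -= ndimage.gaussian_filter1d(profile, detrend_sigma_nm / pixel_size)
    # drop the end regions where detrending leaves edge residuals
    trim = int(round(4 * detrend_sigma_nm / pixel_size))
    if len(profile) > 4 * trim:
        profile = profile[trim:-trim]
    factor = max(1, int(round(pixel_size * 10.0 / sample_a)))
    n = len(profile)
    # Fourier zero-padding upsample
    spec = np.fft.rfft(profile)
    up = np.fft.irfft(spec, n=n * factor) * factor
    step_a = pixel_size * 10.0 / factor
    ac = np.correlate(up, up, mode="full")[len(up) - 1:]
    # first local minimum, then the following maximum
    d = np.diff(ac)
    rising = np.where(d > 0)[0]
    if len(rising) == 0:
        raise SceneError("no off-origin autocorrelation peak found")
    start = rising[0]
    seg = np.where(np.diff(ac[start:]) <= 0)[0]
    if len(seg) == 0:
        raise SceneError("no off-origin autocorrelation peak found")
    ipk = start + seg[0]
    # quadratic sub-sample refinement
    if 0 < ipk < len(ac) - 1:
        y0, y1, y2 = ac[ipk - 1:ipk + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            ipk = ipk + 0.5 * (y0 - y2) / denom
    return float(ipk * step_a)


def _random_unit_near(axis: np.ndarray, sigma_deg: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit vector drawn around ``axis`` with small angular jitter."""
    tilt = abs(rng.normal(0.0, np.deg2rad(sigma_deg)))
    az = rng.uniform(0, 2 * np.pi)
    # orthonormal frame around axis
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    helper = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    d = math.cos(tilt) * a + math.sin(tilt) * (math.cos(az) * u + math.sin(az) * v)
    return d / np.linalg.norm(d)


def _tube_interior_radius(spec: SceneSpec) -> float:
    t = spec.tube
    return t.radius - t.bilayer_separation - 3 * t.leaflet_sigma


def _tube_x_range(spec: SceneSpec) -> tuple[float, float]:
    """Axial span of the cylindrical part.

    The open (-x) end sits on the volume face -- the protrusion continues
    into the cell body outside the field of view -- and the +x cap needs
    a further ``radius`` of room inside it.
    """
    extent_x = spec.volume_shape[0] * spec.pixel_size
    total = spec.tube.length + spec.tube.radius
    if total > extent_x - 8.0:
        raise SceneError(
            f"tube ({spec.tube.length} nm) plus cap ({spec.tube.radius} nm) "
            f"does not fit the {extent_x:.0f} nm volume")
    return 0.0, spec.tube.length


def place_filaments(spec: SceneSpec,
                    rng: np.random.Generator | None = None,
                    max_retries: int = 500) -> list[FilamentTrace]:
    """Draw filament traces with ground-truth polarity inside the tube.

    Each filament is a near-straight polyline roughly parallel to the tube
    axis (+x, the tip direction), sampled every 4 nm, kept at least
    ``filament_separation`` nm from every previously placed filament (a
    bundle, not an interpenetrating tangle). Its barbed end points
    tip-ward with probability ``tip_fraction``. Point order is randomized
    independently of polarity so downstream code cannot cheat by reading
    the trace orientation.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    r_int = _tube_interior_radius(spec)
    lo, hi = spec.length_distribution
    if r_int <= 5.0 or spec.tube.length < lo:
        raise SceneError("tube too small to host filaments of the requested length")
    x0, x1 = _tube_x_range(spec)
    hi = min(hi, spec.tube.length - 17.0)  # must fit between the end margins
    if hi < lo:
        raise SceneError(
            f"tube length {spec.tube.length} nm cannot host filaments of "
            f"minimum length {lo} nm")
    cz = spec.tube_center_z
    cy = spec.volume_shape[1] * spec.pixel_size / 2.0
    n_lo, n_hi = spec.n_filaments
    n = int(rng.integers(n_lo, n_hi + 1))
    traces: list[FilamentTrace] = []
    placed_samples: list[np.ndarray] = []   # dense samples of accepted filaments
    for fid in range(n):
        for _ in range(max_retries):
            length = rng.uniform(lo, hi)
            direction = _random_unit_near([1.0, 0.0, 0.0], spec.filament_angle_sigma, rng)
            rad = (r_int - 5.0) * math.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            start_x = rng.uniform(x0 + 8.0, x1 - 8.0 - length)
            start = np.array([start_x,
                              cy + rad * math.cos(theta),
                              cz + rad * math.sin(theta)])
            end = start + length * direction
            mid = start + 0.5 * length * direction
            ok = all(
                np.hypot(p[1] - cy, p[2] - cz) < r_int - 2.0
                and x0 + 4.0 < p[0] < x1 - 4.0
                for p in (start, mid, end)
            )
            if ok and placed_samples:
                sample = start[None, :] + np.linspace(0, length, 32)[:, None] * direction
                others = np.concatenate(placed_samples)
                d2 = ((sample[:, None, :] - others[None, :, :]) ** 2).sum(axis=2)
                ok = d2.min() >= spec.filament_separation ** 2
            if ok:
                break
        else:
            if len(traces) >= n_lo:
                break   # bundle saturated; keep the filaments that fit
            raise SceneError(
                f"could not place filament {fid} inside the tube after "
                f"{max_retries} retries")
        placed_samples.append(
            start[None, :] + np.linspace(0, length, 32)[:, None] * direction)
        npts = max(2, int(length // 4.0) + 1)
        t = np.linspace(0, length, npts)
        points = start[None, :] + t[:, None] * direction[None, :]
        barbed_tipward = rng.uniform() < spec.tip_fraction
        # geometric order of the stored points, independent of polarity
        if rng.uniform() < 0.5:
            points = points[::-1]
        chord = points[-1] - points[0]
        tipward_sign = 1 if chord[0] > 0 else -1
        polarity = tipward_sign if barbed_tipward else -tipward_sign
        traces.append(FilamentTrace(fid, points, None, polarity))
    return traces


# ---------------------------------------------------------------------------
# membrane + receptors


def _receptor_blobs(spec: ReceptorSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Blob layout of the bent receptor in its local frame.

    Local frame: s = distance along the outward normal above the outer
    leaflet, t = lateral offset (the bend). Returns (offsets (N,2) [s, t],
    sigmas, amplitudes), calibrated numerically so that the half-peak
    extent of the rendered density along the normal equals spec.height.
    """
    h = spec.height
    base = np.array([
        #  s frac, lateral t (nm), sigma, amplitude
        [0.15, 0.0, 1.5, 1.0],    # membrane-proximal leg
        [0.42, 1.8, 1.5, 1.0],    # bend
        [0.68, 3.2, 2.0, 1.25],   # head lobe, lower
        [0.84, 2.4, 2.0, 1.25],   # head lobe, upper
    ])
    offsets = np.column_stack([base[:, 0] * h, base[:, 1]])
    sigmas = base[:, 2].copy()
    amps = base[:, 3] * spec.amplitude
    # calibrate: measure the half-peak extent of the 1D max-profile and
    # rescale the axial positions (two fixed-point passes are plenty)
    for _ in range(3):
        s_grid = np.linspace(-5, h + 12, 2000)
        prof = np.zeros_like(s_grid)
        for (s0, _t), sg, a in zip(offsets, sigmas, amps):
            prof = np.maximum(prof, a * np.exp(-0.5 * ((s_grid - s0) / sg) ** 2))
        peak = prof.max()
        above = np.where(prof >= 0.5 * peak)[0]
        extent = s_grid[above[-1]]
        if abs(extent - h) < 0.05:
            break
        offsets[:, 0] *= h / max(extent, 1e-6)
    return offsets, sigmas, amps


def _render_receptor(grid: np.ndarray, origin: np.ndarray, pixel_size: float,
                     anchor: np.ndarray, normal: np.ndarray,
                     spec: ReceptorSpec, rng: np.random.Generator) -> np.ndarray:
    """Stamp one bent receptor at ``anchor`` (on the outer leaflet) pointing
    along ``normal``. Returns the densest blob centre (the head position a
    density-based picker should find)."""
    offsets, sigmas, amps = _receptor_blobs(spec)
    n = np.asarray(normal) / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    # random azimuth of the bend around the normal
    az = rng.uniform(0, 2 * np.pi)
    v = np.cross(n, u)
    lat = math.cos(az) * u + math.sin(az) * v
    centers = anchor[None, :] + offsets[:, 0:1] * n[None, :] + offsets[:, 1:2] * lat[None, :]
    _stamp_gaussians(grid, origin, pixel_size, centers, sigmas, amps)
    # density at each blob centre from the blob set itself
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    dens = (amps[None, :] * np.exp(-0.5 * d2 / sigmas[None, :] ** 2)).sum(axis=1)
    return centers[int(np.argmax(dens))]


def place_membrane_and_receptors(
        spec: SceneSpec, rng: np.random.Generator | None = None,
        max_retries: int = 6000,
) -> tuple[TomogramVolume, np.ndarray, list[dict]]:
    """Render the capped bilayer tube and its receptor decorations.

    Returns (membrane+receptor density volume, boolean membrane mask,
    receptor placements). Each placement dict records ``position`` (nm, on
    the outer leaflet), ``normal`` (outward unit vector) and
    ``height_above_support`` (nm).
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    nx, ny, nz = spec.volume_shape
    px = spec.pixel_size
    grid = np.zeros((nz, ny, nx), dtype=np.float32)
    origin = np.zeros(3)
    t = spec.tube
    cy = ny * px / 2.0
    cz = spec.tube_center_z
    x0, x1 = _tube_x_range(spec)
    band_lo, band_hi = spec.receptor_spec.placement_band
    if spec.receptor_spec.count > 0 and not (
            spec.support_z + band_lo >= 0 and spec.support_z + band_hi <= nz * px):
        raise SceneError("receptor placement band extends outside the volume")

    xs = px * np.arange(nx)
    ys = px * np.arange(ny)
    zs = px * np.arange(nz)
    rho = np.hypot(ys[None, :] - cy, zs[:, None] - cz)  # (nz, ny)
    r_out, r_in = t.radius, t.radius - t.bilayer_separation
    shell = (np.exp(-0.5 * ((rho - r_out) / t.leaflet_sigma) ** 2)
             + np.exp(-0.5 * ((rho - r_in) / t.leaflet_sigma) ** 2))
    in_tube = (xs >= x0) & (xs <= x1)
    grid += shell[:, :, None] * in_tube[None, None, :].astype(np.float32)
    # hemispherical cap at the tip (+x end)
    cap_x = xs[None, None, :] - x1
    cap_r = np.sqrt(np.maximum(cap_x, 0.0) ** 2 + rho[:, :, None] ** 2)
    cap_zone = cap_x > 0
    cap = (np.exp(-0.5 * ((cap_r - r_out) / t.leaflet_sigma) ** 2)
           + np.exp(-0.5 * ((cap_r - r_in) / t.leaflet_sigma) ** 2))
    grid += np.where(cap_zone, cap, 0.0).astype(np.float32)
    mask = grid > 0.5

    placements: list[dict] = []
    n_rec = spec.receptor_spec.count
    if n_rec > 0:
        kept_pos: list[np.ndarray] = []
        tries = 0
        while len(placements) < n_rec:
            tries += 1
            if tries > max_retries:
                raise SceneError(
                    f"could not place {n_rec} receptors with "
                    f"{spec.receptor_spec.min_separation} nm separation in the band")
            z = rng.uniform(spec.support_z + band_lo, spec.support_z + band_hi)
            if abs(z - cz) >= r_out:
                continue
            side = 1 if rng.uniform() < 0.5 else -1
            y = cy + side * math.sqrt(r_out ** 2 - (z - cz) ** 2)
            x = rng.uniform(x0 + 10.0, x1 - 10.0)
            pos = np.array([x, y, z])
            if any(np.linalg.norm(pos - q) < spec.receptor_spec.min_separation
                   for q in kept_pos):
                continue
            normal = np.array([0.0, y - cy, z - cz])
            normal /= np.linalg.norm(normal)
            head = _render_receptor(grid, origin, px, pos, normal,
                                    spec.receptor_spec, rng)
            kept_pos.append(pos)
            placements.append({
                "position": pos,
                "head_position": head,
                "normal": normal,
                "height_above_support": z - spec.support_z,
            })
    vol = TomogramVolume(grid, px, origin=origin)
    return vol, mask, placements


# ---------------------------------------------------------------------------
# imaging model


def _wedge_keep_mask(shape_zyx: tuple[int, int, int], tilt_range: float,
                     rfft: bool = True) -> np.ndarray:
    """Boolean keep-mask of the sampled Fourier region for a single-axis
    tilt about y with half-range ``tilt_range`` degrees.

    A coefficient is *missing* when its (kx, kz) component makes an angle
    with the kx axis larger than the tilt range, i.e. |kz| > tan(range)|kx|.
    """
    nz, ny, nx = shape_zyx
    kz = np.fft.fftfreq(nz)
    kx = np.fft.rfftfreq(nx) if rfft else np.fft.fftfreq(nx)
    tan = math.tan(np.deg2rad(tilt_range))
    missing = np.abs(kz)[:, None] > tan * np.abs(kx)[None, :] + 1e-12
    missing[0, 0] = False  # origin always measured
    return ~missing[:, None, :] | np.zeros((1, ny, 1), dtype=bool)


def missing_wedge_filter(grid: np.ndarray, tilt_range: float) -> np.ndarray:
    """Zero Fourier coefficients inside the single-axis missing wedge."""
    if not 0 < tilt_range <= 90:
        raise SceneError(f"tilt_range must lie in (0, 90], got {tilt_range}")
    if tilt_range == 90:
        return np.asarray(grid, dtype=np.float32).copy()
    spec = np.fft.rfftn(grid)
    keep = _wedge_keep_mask(grid.shape, tilt_range, rfft=True)
    spec *= keep
    return np.fft.irfftn(spec, s=grid.shape, axes=(0, 1, 2)).astype(np.float32)


def apply_imaging_model(volume: TomogramVolume, tilt_range: float,
                        noise_sigma: float,
                        rng: np.random.Generator | None = None,
                        noise_reference: float | None = None) -> TomogramVolume:
    """Missing wedge plus additive Gaussian noise.

    ``noise_sigma`` is relative to the peak density of the noise-free
    input (override with ``noise_reference``). Noise is added after the
    wedge filter; with ``noise_sigma = 0`` the operation is a pure linear
    idempotent projection in Fourier space.
    """
    ref = float(volume.grid.max()) if noise_reference is None else noise_reference
    out = missing_wedge_filter(volume.grid, tilt_range)
    if noise_sigma > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        out = out + rng.normal(0.0, noise_sigma * ref, size=out.shape).astype(np.float32)
    return TomogramVolume(out, volume.pixel_size, tilt_range=tilt_range,
                          origin=volume.origin)


# ---------------------------------------------------------------------------
# full scene


def generate_scene(spec: SceneSpec) -> tuple[TomogramVolume, SceneGroundTruth]:
    """Generate one tomogram-like volume and its ground truth.

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    traces = place_filaments(spec, rng)
    mem_vol, mask, placements = place_membrane_and_receptors(spec, rng)
    grid = mem_vol.grid.copy()
    nx, ny, nz = spec.volume_shape
    px = spec.pixel_size
    for tr in traces:
        coords, sigmas, amps = _trace_subunits(tr, spec.helical, rng)
        _stamp_gaussians(grid, mem_vol.origin, px, coords, sigmas, amps)
    if spec.render_support:
        zs = px * np.arange(nz)
        grid += 0.3 * np.exp(-0.5 * ((zs - spec.support_z) / 1.5) ** 2)[:, None, None].astype(np.float32)
    clean = TomogramVolume(grid, px, origin=mem_vol.origin)
    noisy = apply_imaging_model(clean, spec.tilt_range, spec.noise_sigma, rng)
    gt = SceneGroundTruth(
        traces=traces,
        receptor_placements=placements,
        tip_axis=np.array([1.0, 0.0, 0.0]),
        membrane_mask=mask,
        support_z=spec.support_z,
        tube_center=np.array([nx * px / 2.0, ny * px / 2.0, spec.tube_center_z]),
    )
    return noisy, gt


def _trace_subunits(trace: FilamentTrace, params: HelicalParams,
                    rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Helical lobe coordinates along a (near-straight) trace.

    The helix axis follows the chord from the pointed end to the barbed
    end so that the rendered polarity matches ``true_polarity``. Returns
    ``(centers, sigmas, amplitudes)`` in the volume frame.
    """
    if trace.true_polarity is None:
        raise SceneError("synthetic traces need ground-truth polarity")
    if trace.true_polarity > 0:
        start, end = trace.points[0], trace.points[-1]
    else:
        start, end = trace.points[-1], trace.points[0]
    axis = end - start
    length = np.linalg.norm(axis)
    axis = axis / length
    local, sigmas, amps = helix_lobe_coords(params, length,
                                            phase_deg=rng.uniform(0, 360))
    helper = (np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9
              else np.array([0.0, 1.0, 0.0]))
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    frame = np.stack([axis, u, v], axis=1)  # columns: axis, u, v
    return start[None, :] + local @ frame.T, sigmas, amps
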