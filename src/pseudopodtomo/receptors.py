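"""Membrane-attached receptor picking, averaging, classification and
spatial statistics.

The picking emulates membrane-guided particle selection: local density
maxima inside a thin band outside the outer leaflet become candidates,
each inheriting the outward normal of its nearest membrane point. Picks
are filtered by height above the support plane (receptors are only
analysable where the membrane is resolved, 50-70 nm above the support by
default) and by the tilt of the normal out of the x-y plane (membranes
roughly parallel to the beam). Kept picks are boxed with the membrane at
the box centre, rotated normal-to-z, averaged, classified, and the height
of the selected class's extracellular density is measured at a fraction
of its peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .volume import TomogramVolume

ATTACH_BAND_NM = (2.0, 12.0)
HEIGHT_BAND_NM = (50.0, 70.0)
TILT_MAX_DEG = 20.0
MIN_SEPARATION_NM = 8.0


class ReceptorError(RuntimeError):
    pass


@dataclass
class MembraneModel:
    surface_points: np.ndarray      # (N, 3) nm, [x, y, z]
    outward_normals: np.ndarray     # (N, 3) unit vectors
    support_z: float
    solid: np.ndarray | None = None  # bool [z, y, x]: membrane + enclosed volume


@dataclass
class ReceptorPick:
    position: np.ndarray            # nm, density maximum
    surface_point: np.ndarray       # nm, nearest membrane point
    normal: np.ndarray              # outward unit vector
    height_above_support: float     # nm
    normal_tilt: float              # deg from the x-y plane
    density: float
    kept: bool = True
    reason: str | None = None       # exactly one machine-readable reason


@dataclass
class SubvolumeStack:
    boxes: list[np.ndarray]
    rotations: list[np.ndarray]     # 3x3, world -> box frame, normal -> +z
    box_edge: int
    pixel_size: float
    membrane_z_index: float         # box z index of the outer leaflet plane


# ---------------------------------------------------------------------------
# membrane geometry


def _fill_interior(mask: np.ndarray) -> np.ndarray:
    """Enclosed volume of a (possibly boundary-open) shell mask.

    Volume faces the shell touches are closed before hole filling, so a
    tube whose open end leaves the volume still gets an interior.
    """
    padded = np.pad(mask, 1, constant_values=False)
    capped = padded.copy()
    inner_faces = [np.s_[1, :, :], np.s_[-2, :, :], np.s_[:, 1, :],
                   np.s_[:, -2, :], np.s_[:, :, 1], np.s_[:, :, -2]]
    for inner in inner_faces:
        if np.any(padded[inner]):
            capped[inner] = True
    filled = ndimage.binary_fill_holes(capped)
    # the artificial caps themselves are not interior
    interior = filled & ~capped
    return interior[1:-1, 1:-1, 1:-1]


def estimate_normals(membrane_mask: np.ndarray, pixel_size: float,
                     support_z: float = 0.0, smooth_nm: float = 3.0,
                     subsample: int = 1) -> MembraneModel:
    """Outward surface normals from the gradient of a smoothed occupancy
    field.

    The enclosed side is found by hole-filling the (face-capped) shell;
    normals are the negative gradient of the smoothed solid indicator at
    the membrane voxels. Sheets with no enclosable interior fall back to
    ridge normals sign-aligned into one hemisphere (orientation is then
    consistent but globally arbitrary). Points where the gradient
    vanishes are dropped.
    """
    mask = np.asarray(membrane_mask, dtype=bool)
    if not np.any(mask):
        raise ReceptorError("membrane mask is empty")
    sigma_vox = smooth_nm / pixel_size
    interior = _fill_interior(mask)
    zz, yy, xx = np.nonzero(mask)
    if subsample > 1:
        zz, yy, xx = zz[::subsample], yy[::subsample], xx[::subsample]
    if np.any(interior):
        solid = mask | interior
        fld = ndimage.gaussian_filter(solid.astype(np.float32), sigma_vox)
        gz, gy, gx = np.gradient(fld)
        vecs = -np.column_stack([gx[zz, yy, xx], gy[zz, yy, xx], gz[zz, yy, xx]])
        norms = np.linalg.norm(vecs, axis=1)
        ok = norms > 1e-8
        if not np.any(ok):
            raise ReceptorError("no usable surface normals (degenerate mask)")
        vecs = vecs[ok] / norms[ok, None]
        pts = np.column_stack([xx, yy, zz])[ok].astype(float) * pixel_size
        return MembraneModel(pts, vecs, support_z, solid)
    # sheet without an enclosable interior: ridge normals from the Hessian
    # (the raw gradient vanishes on the ridge), sign-aligned into one
    # hemisphere -- orientation is consistent but globally arbitrary
    fld = ndimage.gaussian_filter(mask.astype(np.float32), sigma_vox)
    axes = {0: "z", 1: "y", 2: "x"}
    second = {}
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            second[(i, j)] = ndimage.gaussian_filter(fld, 1.0, order=order)
    n = len(zz)
    H = np.empty((n, 3, 3))
    for i in range(3):
        for j in range(3):
            key = (min(i, j), max(i, j))
            H[:, i, j] = second[key][zz, yy, xx]
    w, v = np.linalg.eigh(H)        # ascending eigenvalues
    vecs_zyx = v[:, :, 0]           # most negative curvature = ridge normal
    vecs = vecs_zyx[:, ::-1]        # -> [x, y, z]
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    # hemisphere consistency: align along the dominant axis
    dom = np.argmax(np.abs(vecs).mean(axis=0))
    flip = vecs[:, dom] < 0
    vecs[flip] *= -1
    pts = np.column_stack([xx, yy, zz]).astype(float) * pixel_size
    return MembraneModel(pts, vecs, support_z, mask)


# ---------------------------------------------------------------------------
# picking


def pick_densities(tomo: TomogramVolume, membrane: MembraneModel,
                   attach_band: tuple[float, float] = ATTACH_BAND_NM,
                   height_band: tuple[float, float] = HEIGHT_BAND_NM,
                   tilt_max: float = TILT_MAX_DEG,
                   min_separation: float = MIN_SEPARATION_NM,
                   smooth_nm: float = 1.2,
                   threshold_sigma: float = 3.5) -> list[ReceptorPick]:
    """Pick membrane-attached densities, filtered by height and tilt.

    Candidates are local maxima of the lightly smoothed tomogram lying
    ``attach_band`` nm outside the membrane solid, above a robust
    ``mean + threshold_sigma x SD`` density threshold of that band.
    Every rejected pick carries exactly one reason ("height", "tilt" or
    "proximity"); kept + rejected counts equal the candidate count.
    The height and tilt filters are decided per candidate before the
    proximity dedup, which only competes among filter-passing picks, so
    filter and dedup order commute.
    """
    if attach_band[0] >= attach_band[1] or height_band[0] >= height_band[1]:
        raise ValueError("bands must be well-ordered (lo < hi)")
    px = tomo.pixel_size
    if membrane.solid is None:
        raise ReceptorError("membrane model lacks the solid mask needed for picking")
    dist_out = ndimage.distance_transform_edt(~membrane.solid, sampling=px)
    band = (dist_out >= attach_band[0]) & (dist_out <= attach_band[1])
    sm = ndimage.gaussian_filter(tomo.grid.astype(np.float32), smooth_nm / px)
    footprint = int(max(3, round(min_separation / px / 2) * 2 + 1))
    local_max = sm == ndimage.maximum_filter(sm, size=footprint)
    vals = sm[band]
    thresh = float(vals.mean() + threshold_sigma * vals.std())
    cand = np.nonzero(band & local_max & (sm > thresh))
    if len(cand[0]) == 0:
        return []
    pos = np.column_stack([cand[2], cand[1], cand[0]]).astype(float) * px \
        + tomo.origin
    dens = sm[cand]
    tree = cKDTree(membrane.surface_points)
    _, nearest = tree.query(pos)
    picks: list[ReceptorPick] = []
    for p, d, ni in zip(pos, dens, nearest):
        n = membrane.outward_normals[ni]
        tilt = abs(math.degrees(math.asin(np.clip(n[2], -1.0, 1.0))))
        h = p[2] - membrane.support_z
        pick = ReceptorPick(p, membrane.surface_points[ni], n, h, tilt, float(d))
        if not height_band[0] <= h <= height_band[1]:
            pick.kept, pick.reason = False, "height"
        elif tilt > tilt_max:
            pick.kept, pick.reason = False, "tilt"
        picks.append(pick)
    # proximity dedup among filter-passing picks, highest density wins
    order = sorted((i for i, p in enumerate(picks) if p.kept),
                   key=lambda i: -picks[i].density)
    kept_pos: list[np.ndarray] = []
    for i in order:
        p = picks[i]
        if any(np.linalg.norm(p.position - q) < min_separation for q in kept_pos):
            p.kept, p.reason = False, "proximity"
        else:
            kept_pos.append(p.position)
    return picks


# ---------------------------------------------------------------------------
# stack extraction & averaging


def _rotation_normal_to_z(normal: np.ndarray) -> np.ndarray:
    """Rotation matrix (world -> box) taking ``normal`` onto +z, minimal
    rotation angle (in-plane orientation left free)."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(n, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return np.eye(3) if n[2] > 0 else Rotation.from_euler("x", 180, degrees=True).as_matrix()
    angle = math.atan2(s, float(n @ z))
    return Rotation.from_rotvec(axis / s * angle).as_matrix()


def extract_stack(tomo: TomogramVolume, picks: list[ReceptorPick],
                  box_edge: int = 32, pixel_size: float | None = None,
                  center_inset_nm: float = 1.0) -> SubvolumeStack:
    """Box kept picks with the membrane surface point at the box centre
    and rotate each box so its outward normal maps onto +z.

    The nearest-mask-voxel foot point lies on the outer *edge* of the
    segmented leaflet, about half the segmentation thickness outside its
    density centre, so the centre is inset by ``center_inset_nm`` along
    the inward normal. Boxes are extracted with a margin, rotated by
    resampling, then centre-cropped; picks whose padded box leaves the
    tomogram are skipped.
    """
    px = tomo.pixel_size if pixel_size is None else pixel_size
    margin = int(round(box_edge * 0.25))
    big = box_edge + 2 * margin
    boxes, rots = [], []
    for p in picks:
        if not p.kept:
            continue
        center = p.surface_point - center_inset_nm * p.normal
        if not tomo.contains_box(center, big):
            continue
        frac = tomo.world_to_voxel(center)
        idx = np.rint(frac).astype(int)
        half = big // 2
        lo = idx - half
        sub = tomo.grid[lo[2]:lo[2] + big, lo[1]:lo[1] + big, lo[0]:lo[0] + big]
        R = _rotation_normal_to_z(p.normal)
        rot = _rotate_box(sub, R)
        c0 = margin
        boxes.append(rot[c0:c0 + box_edge, c0:c0 + box_edge, c0:c0 + box_edge])
        rots.append(R)
    return SubvolumeStack(boxes, rots, box_edge, px,
                          membrane_z_index=(box_edge - 1) / 2.0)


def _rotate_box(box: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Resample ``box`` so that world direction v appears along R @ v.

    Grid axes are (z, y, x); the affine matrix therefore uses the
    axis-reversed rotation.
    """
    n = np.array(box.shape)
    center = (n - 1) / 2.0
    P = R[::-1, ::-1]      # act on (z, y, x) index vectors
    Minv = np.linalg.inv(P)
    offset = center - Minv @ center
    return ndimage.affine_transform(np.asarray(box, dtype=np.float64), Minv,
                                    offset=offset, order=1, mode="constant")


def align_average(stack: SubvolumeStack) -> np.ndarray:
    """Average the normal-aligned boxes (initial model).

    The in-plane angle about the normal is unconstrained and is
    marginalized by averaging, giving a cylindrically smeared model.
    """
    if len(stack.boxes) == 0:
        raise ReceptorError("empty subvolume stack")
    acc = np.zeros_like(np.asarray(stack.boxes[0], dtype=np.float64))
    for b in stack.boxes:
        acc += b
    return (acc / len(stack.boxes)).astype(np.float32)


# ---------------------------------------------------------------------------
# classification


def _standardize_flat(vols: np.ndarray, mask: np.ndarray) -> np.ndarray:
    flat = vols.reshape(len(vols), -1)[:, mask.ravel()]
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return flat / norms


def classify_3d(stack: SubvolumeStack, k: int = 2, n_iter: int = 10,
                seed: int = 0, member_floor: int | None = None
                ) -> tuple[np.ndarray, list[np.ndarray], int]:
    """Alignment-free k-partition of the normal-aligned boxes by NCC to
    class averages.

    The selected class is the one with the highest mean intra-class NCC
    among classes with at least ``member_floor`` members (default
    ``max(3, 10% of boxes)``). Empty classes are reseeded from the
    worst-fitting member. Deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(stack.boxes)
    if n < k:
        raise ReceptorError(f"need at least k={k} boxes, got {n}")
    if member_floor is None:
        member_floor = max(3, int(0.1 * n))
    vols = np.stack([np.asarray(b, dtype=np.float64) for b in stack.boxes])
    e = stack.box_edge
    zz, yy, xx = np.meshgrid(*([np.arange(e) - (e - 1) / 2] * 3), indexing="ij")
    mask = (np.hypot(xx, yy) < 0.45 * e) & (np.abs(zz) < 0.5 * e)
    flat = _standardize_flat(vols, mask)
    rng = np.random.default_rng(seed)
    # centroids bootstrapped from single boxes: the mean of a random
    # partition is a structureless fixed point
    cents = flat[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    scores = np.zeros(n)
    for _ in range(n_iter):
        sim = flat @ cents.T
        new_labels = sim.argmax(axis=1)
        scores = sim[np.arange(n), new_labels]
        for c in range(k):
            if not np.any(new_labels == c):
                counts = np.bincount(new_labels, minlength=k)
                cand = int(np.argmin(np.where(counts[new_labels] > 1,
                                              scores, np.inf)))
                new_labels[cand] = c
        converged = np.array_equal(new_labels, labels)
        labels = new_labels
        for c in range(k):
            m = labels == c
            if np.any(m):
                v = flat[m].sum(axis=0)
                nv = np.linalg.norm(v)
                cents[c] = v / nv if nv > 0 else v
        if converged:
            break
    class_vols = []
    mean_ncc = np.full(k, -np.inf)
    for c in range(k):
        m = labels == c
        avg = vols[m].mean(axis=0) if np.any(m) else np.zeros_like(vols[0])
        class_vols.append(avg.astype(np.float32))
        if np.sum(m) >= member_floor:
            cent = flat[m].mean(axis=0)
            ncent = np.linalg.norm(cent)
            if ncent > 0:
                mean_ncc[c] = float((flat[m] @ (cent / ncent)).mean())
    if not np.any(np.isfinite(mean_ncc)):
        raise ReceptorError("no class reached the member floor")
    selected = int(np.argmax(mean_ncc))
    return labels, class_vols, selected


# ---------------------------------------------------------------------------
# height measurement


def density_extent_above(volume: np.ndarray, leaflet_z_index: float,
                         pixel_size: float, level: float = 0.5,
                         lateral_radius_nm: float = 8.0,
                         clearance_nm: float = 3.0,
                         background_z_frac: float = 0.9,
                         min_peak_snr: float = 5.0,
                         smooth_vox: float = 0.8) -> tuple[float, bool]:
    """Extent (nm) of supra-threshold density above the outer leaflet.

    The volume is lightly smoothed (residual noise in a class average
    would otherwise inflate the per-plane maximum); the profile is the
    lateral maximum (within a central cylinder) per z-plane starting
    ``clearance_nm`` above the leaflet; the height is the furthest plane
    still at or above ``level`` x the extracellular peak. Returns
    ``(height_nm, flagged)`` where ``flagged`` marks the no-density case
    (peak indistinguishable from the background estimated in the top of
    the box): height 0.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if smooth_vox > 0:
        vol = ndimage.gaussian_filter(vol, smooth_vox)
    nz, ny, nx = vol.shape
    yy, xx = np.meshgrid(np.arange(ny) - (ny - 1) / 2,
                         np.arange(nx) - (nx - 1) / 2, indexing="ij")
    lat = np.hypot(xx, yy) * pixel_size <= lateral_radius_nm
    z0 = int(math.ceil(leaflet_z_index + clearance_nm / pixel_size))
    if z0 >= nz:
        return 0.0, True
    prof = np.array([vol[z][lat].max() for z in range(z0, nz)])
    bg_start = int(background_z_frac * len(prof))
    bg = prof[bg_start:] if bg_start < len(prof) else prof[-2:]
    bg_mean, bg_sd = float(np.mean(bg)), float(np.std(bg))
    peak = prof.max()
    # flagged when the extracellular peak is indistinguishable from the
    # box-top background or negligible against the membrane itself
    if peak <= bg_mean + min_peak_snr * max(bg_sd, 1e-12) \
            or peak < 0.1 * vol.max():
        return 0.0, True
    cut = level * peak
    above = np.where(prof >= cut)[0]
    top = above[-1]
    # sub-voxel edge: linear interpolation to the crossing
    if top + 1 < len(prof):
        p0, p1 = prof[top], prof[top + 1]
        frac = (p0 - cut) / (p0 - p1) if p0 != p1 else 0.0
        top_f = top + np.clip(frac, 0.0, 1.0)
    else:
        top_f = float(top)
    height = (z0 + top_f - leaflet_z_index) * pixel_size
    return float(max(height, 0.0)), False


def measure_height(class_volume: np.ndarray, membrane_z_index: float,
                   pixel_size: float, level: float = 0.5) -> tuple[float, bool]:
    """Height of the extracellular density above the outer leaflet of a
    normal-aligned class average, at ``level`` of the extracellular peak.

    ``membrane_z_index`` is the box z index of the outer leaflet plane
    (the surface point the boxes were centred on, i.e.
    ``stack.membrane_z_index`` for stacks from :func:`extract_stack`).
    Returns ``(height_nm, flagged)``; a bare-membrane class with no
    supra-threshold extracellular density reports 0 nm, flagged."""
    return density_extent_above(class_volume, membrane_z_index, pixel_size,
                                level=level)


# ---------------------------------------------------------------------------
# rigid fitting


def render_pseudo_atoms(coords_nm: np.ndarray, weights: np.ndarray | None,
                        shape_zyx: tuple[int, int, int], pixel_size: float,
                        resolution_nm: float,
                        origin: np.ndarray | None = None) -> np.ndarray:
    """Gaussian-per-atom density at a stated resolution (FWHM =
    resolution)."""
    from .scene import _stamp_gaussians  # shared rasterizer
    grid = np.zeros(shape_zyx, dtype=np.float32)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    sigma = resolution_nm / 2.355
    w = np.ones(len(coords_nm)) if weights is None else np.asarray(weights, float)
    _stamp_gaussians(grid, origin, pixel_size, np.asarray(coords_nm, float),
                     sigma, w)
    return grid


def _ncc_volumes(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float((a * b).sum() / (na * nb))


def _rotation_grid(step_deg: float) -> list[Rotation]:
    """Coarse deterministic SO(3) grid (Euler z-y-z, cos-uniform beta)."""
    alphas = np.arange(0, 360, step_deg)
    n_beta = max(2, int(round(180 / step_deg)) + 1)
    betas = np.degrees(np.arccos(np.linspace(1, -1, n_beta)))
    gammas = np.arange(0, 360, step_deg)
    rots = []
    for b in betas:
        for a in (alphas if 0 < b < 180 else [0.0]):
            for g in (gammas if 0 < b < 180 else alphas):
                rots.append(Rotation.from_euler("zyz", [a, b, g], degrees=True))
    return rots


def rigid_fit_score(map_volume: np.ndarray, coords_nm: np.ndarray,
                    resolution_nm: float, pixel_size: float,
                    weights: np.ndarray | None = None,
                    rot_step_deg: float = 15.0,
                    rotations: list[Rotation] | None = None,
                    refine: bool = True) -> tuple[dict, float]:
    """Exhaustive-rotation, FFT-translation rigid fit of a pseudo-atom
    model into a density map.

    For each rotation on a <= ``rot_step_deg`` grid the model is rendered
    at the map's resolution and the best translation found by FFT cross-
    correlation; the global best is locally refined over all six rigid
    parameters (Powell). Returns ``(transform, ncc)`` where the transform
    holds the fitted ``rotation`` (about the model centroid) and
    ``centroid_nm``, the fitted position of the model centroid in the
    map frame.
    """
    mapv = np.asarray(map_volume, dtype=np.float64)
    shape = mapv.shape
    coords = np.asarray(coords_nm, dtype=float)
    centroid = coords.mean(axis=0)
    coords0 = coords - centroid
    box_center = (np.array(shape[::-1]) - 1) / 2.0 * pixel_size  # [x, y, z]
    a = mapv - mapv.mean()
    fa = np.fft.rfftn(a)
    norm_a = np.linalg.norm(a)
    rot_list = rotations if rotations is not None else _rotation_grid(rot_step_deg)

    def render(rot: Rotation, shift_nm: np.ndarray) -> np.ndarray:
        pts = rot.apply(coords0) + box_center + shift_nm
        return render_pseudo_atoms(pts, weights, shape, pixel_size, resolution_nm)

    best = (-np.inf, None, None)
    for rot in rot_list:
        b = render(rot, np.zeros(3)).astype(np.float64)
        b -= b.mean()
        nb = np.linalg.norm(b)
        if nb == 0:
            continue
        corr = np.fft.irfftn(fa * np.conj(np.fft.rfftn(b)), s=shape,
                             axes=(0, 1, 2))
        idx = np.unravel_index(np.argmax(corr), shape)
        score = corr[idx] / (norm_a * nb)
        if score > best[0]:
            shift_vox = np.array([(i if i <= s // 2 else i - s)
                                  for i, s in zip(idx, shape)])
            best = (float(score), rot, shift_vox[::-1] * pixel_size)

    score, rot, shift = best
    if rot is None:
        raise ReceptorError("rigid fit failed: empty rendering")
    if refine:
        x0 = np.concatenate([rot.as_rotvec(), shift])

        def neg(x):
            r = Rotation.from_rotvec(x[:3])
            return -_ncc_volumes(mapv, render(r, x[3:]))

        res = minimize(neg, x0, method="Powell",
                       options={"maxiter": 200, "xtol": 1e-3})
        if -res.fun > score:
            score = float(-res.fun)
            rot = Rotation.from_rotvec(res.x[:3])
            shift = res.x[3:]
    return {"rotation": rot,
            "centroid_nm": box_center + np.asarray(shift, float)}, score


# ---------------------------------------------------------------------------
# spatial statistics


def _mean_nn_distance(points: np.ndarray) -> float:
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(d[:, 1].mean())


def spatial_randomness_test(pick_positions: np.ndarray,
                            surface_points: np.ndarray,
                            n_mc: int = 999, seed: int = 0) -> dict:
    """Monte-Carlo test of complete spatial randomness of picks on a
    membrane surface.

    The observed mean nearest-neighbour distance (surface-point Euclidean
    approximation to geodesic) is compared with ``n_mc`` uniform draws of
    the same size from the surface point set. Two-sided p-value with the
    +1 correction: ``p_tail = (1 + #{as or more extreme}) / (n_mc + 1)``,
    doubled and capped at 1.
    """
    pts = np.asarray(pick_positions, dtype=float)
    if len(pts) < 5:
        raise ReceptorError(f"insufficient picks for a CSR test: {len(pts)} < 5")
    if n_mc <= 0:
        raise ValueError("n_mc must be positive (null distribution undefined)")
    rng = np.random.default_rng(seed)
    obs = _mean_nn_distance(pts)
    null = np.empty(n_mc)
    surf = np.asarray(surface_points, dtype=float)
    for i in range(n_mc):
        idx = rng.choice(len(surf), size=len(pts), replace=False)
        null[i] = _mean_nn_distance(surf[idx])
    p_low = (1 + int(np.sum(null <= obs))) / (n_mc + 1)
    p_high = (1 + int(np.sum(null >= obs))) / (n_mc + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return {
        "p_value": p,
        "observed_mean_nn_nm": obs,
        "null_mean_nn_nm": float(null.mean()),
        "null_sd_nn_nm": float(null.std(ddof=1)),
        "n_picks": len(pts),
        "n_mc": n_mc,
    }
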