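"""Per-segment actin polarity from 2D class averages.

The chain mirrors classical filament-polarity analysis: each segment
subvolume is masked around its expected axis, its central slab projected
along z, rotated so the filament runs along +x, then the projections are
classified reference-free (translation + 180 degree in-plane rotation).
Each class average is labelled by normalized cross-correlation against
projections of the helical actin model in its two axial orientations,
maximized over a bank of helical phases (the screw symmetry links phase
to axial shift, but voxel-size shift steps sample it too coarsely at
desk scale, hence the explicit bank).

A segment's vote comes from its class label (times -1 if the segment
entered the class through the 180 degree in-plane rotation, which
reverses the apparent axis direction) when the class is confidently
labelled, and from the segment's own model-matching score otherwise.
Votes are signed along the segment tangent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .scene import HelicalParams, build_actin_density
from .segments import SegmentRecord

DEFAULT_SLAB_NM = 11.0
DEFAULT_MASK_RADIUS_NM = 6.0
DEFAULT_K = 20
DEFAULT_MARGIN = 0.05
DEFAULT_MIN_MEMBERS = 10
MAX_SHIFT_VOX = 5
STEEP_TANGENT_DEG = 5.0


class PolarityError(RuntimeError):
    pass


@dataclass
class ClassAverage2D:
    image: np.ndarray
    member_count: int
    polarity_label: int | None = None      # +1 / -1 / None (unassigned)
    score_plus: float = float("nan")
    score_minus: float = float("nan")
    selected: bool = False
    members: list[int] = field(default_factory=list)


def soft_cylinder_mask(box_shape_zyx: tuple[int, int, int], pixel_size: float,
                       tangent: np.ndarray, radius_nm: float = DEFAULT_MASK_RADIUS_NM,
                       taper_nm: float = 2.0) -> np.ndarray:
    """Raised-cosine cylindrical mask around the line through the box
    centre along ``tangent``."""
    nz, ny, nx = box_shape_zyx
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    c = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    vx = (xx - c[0]) * pixel_size
    vy = (yy - c[1]) * pixel_size
    vz = (zz - c[2]) * pixel_size
    proj = vx * t[0] + vy * t[1] + vz * t[2]
    d2 = vx * vx + vy * vy + vz * vz - proj * proj
    d = np.sqrt(np.maximum(d2, 0.0))
    m = np.clip((radius_nm + taper_nm - d) / taper_nm, 0.0, 1.0)
    return (0.5 - 0.5 * np.cos(np.pi * m)).astype(np.float32)


def project_slab(subvolume: np.ndarray, thickness_nm: float, pixel_size: float,
                 tangent: np.ndarray | None = None,
                 mask_radius_nm: float | None = DEFAULT_MASK_RADIUS_NM) -> np.ndarray:
    """Sum the central z-slab of a masked subvolume.

    ``thickness_nm`` selects round(thickness / pixel) central z-planes.
    With ``mask_radius_nm=None`` (or no tangent) the mask is skipped and
    a full-thickness call reduces to the plain z-sum.
    """
    if not thickness_nm > 0:
        raise ValueError(f"thickness must be positive, got {thickness_nm}")
    nz = subvolume.shape[0]
    if thickness_nm > nz * pixel_size + 1e-9:
        raise ValueError("slab thicker than the box")
    n_planes = min(nz, max(1, int(round(thickness_nm / pixel_size))))
    lo = (nz - n_planes) // 2
    vol = subvolume
    if mask_radius_nm is not None and tangent is not None:
        vol = vol * soft_cylinder_mask(vol.shape, pixel_size, tangent, mask_radius_nm)
    return vol[lo:lo + n_planes].sum(axis=0).astype(np.float32)


def rotate_to_axis(image: np.ndarray, tangent: np.ndarray,
                   residual_offset_nm: np.ndarray | None = None,
                   pixel_size: float = 1.0) -> tuple[np.ndarray, float]:
    """Rotate a projection so the in-plane tangent maps onto +x.

    Raises PolarityError when the tangent is within 5 degrees of the beam
    axis (the filament axis is then unresolvable in projection). The
    residual sub-voxel extraction offset, if given, is compensated before
    the rotation so segment centres land on the image centre.
    """
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    inplane = math.hypot(t[0], t[1])
    if math.degrees(math.atan2(inplane, abs(t[2]))) < STEEP_TANGENT_DEG:
        raise PolarityError("tangent within 5 degrees of the beam axis")
    angle = math.degrees(math.atan2(t[1], t[0]))
    out = image
    if residual_offset_nm is not None and np.any(residual_offset_nm[:2] != 0):
        # image axes are [y, x]; shift the content back onto the centre
        shift_vox = (-residual_offset_nm[1] / pixel_size,
                     -residual_offset_nm[0] / pixel_size)
        out = ndimage.shift(out, shift_vox, order=3, mode="constant")
    out = ndimage.rotate(out, angle, reshape=False, order=3, mode="constant")
    return out.astype(np.float32), -angle


# ---------------------------------------------------------------------------
# reference-free 2D classification


def _standardize(img: np.ndarray) -> np.ndarray:
    out = img - img.mean()
    n = np.linalg.norm(out)
    return out / n if n > 0 else out


def upsample_x(img: np.ndarray, factor: int) -> np.ndarray:
    """Fourier-interpolate an image along its x (column) axis.

    Alignment must lock the helical phase, and one desk-scale voxel is
    ~0.4 of a rise; sub-voxel x-shifts on the upsampled grid make the
    class averages phase-coherent instead of smearing the arrowhead.
    """
    if factor == 1:
        return np.asarray(img, dtype=np.float64)
    spec = np.fft.rfft(np.asarray(img, dtype=np.float64), axis=1)
    nx = img.shape[1]
    return np.fft.irfft(spec, n=nx * factor, axis=1) * factor


def _shift_window_mask(shape: tuple[int, int], max_shift_y: int,
                       max_shift_x: int | None = None) -> np.ndarray:
    if max_shift_x is None:
        max_shift_x = max_shift_y
    win = np.zeros(shape, dtype=bool)
    sy, sx = max_shift_y, max_shift_x
    win[:sy + 1, :sx + 1] = True
    win[:sy + 1, -sx:] = True
    win[-sy:, :sx + 1] = True
    win[-sy:, -sx:] = True
    return win


def _best_alignment(f_img: np.ndarray, f_img_rot: np.ndarray,
                    f_refs: np.ndarray, shape: tuple[int, int],
                    window: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best (score, shift index, flip) of one image against every reference.

    ``f_refs`` is a stacked rFFT of standardized references. Correlation
    maps are computed by batched inverse FFT; only shifts inside
    ``window`` compete.
    """
    corr = np.fft.irfft2(np.conj(f_img)[None] * f_refs, s=shape)
    corr_rot = np.fft.irfft2(np.conj(f_img_rot)[None] * f_refs, s=shape)
    both = np.stack([corr, corr_rot])           # (2, k, ny, nx)
    both = np.where(window[None, None], both, -np.inf)
    flat = both.reshape(2, both.shape[1], -1)
    idx = flat.argmax(axis=2)                   # (2, k)
    sc = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
    flip = sc[1] > sc[0]
    score = np.where(flip, sc[1], sc[0])
    shift_idx = np.where(flip, idx[1], idx[0])
    return score, shift_idx, flip


def _apply_alignment(img: np.ndarray, shift_idx: int, flip: bool,
                     shape: tuple[int, int]) -> np.ndarray:
    src = np.rot90(img, 2) if flip else img
    dy, dx = np.unravel_index(shift_idx, shape)
    # corr[s] = sum_r src(r) ref(r+s): rolling src by +s registers it on ref
    return np.roll(src, (dy, dx), axis=(0, 1))


def classify_2d(images: list[np.ndarray] | np.ndarray, k: int,
                n_iter: int = 12, seed: int = 0,
                max_shift: int = MAX_SHIFT_VOX,
                upsample: int = 4
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[ClassAverage2D]]:
    """Reference-free 2D classification with translation + 180 degree
    in-plane rotation alignment.

    Alternates (a) aligning every image to its class average and
    (b) reassigning each image to the best-correlating average. Images
    are Fourier-upsampled ``upsample``-fold along the filament axis so
    the translational search aligns the helical phase at sub-voxel
    precision (class averages are returned on that finer x grid). Empty
    classes are reseeded from the currently worst-fitting member.
    Deterministic for fixed ``(images, k, n_iter, seed)``.

    Returns ``(labels, flips, shift_indices, class_averages)``; ``flips``
    records whether each image entered its class through the 180 degree
    rotation (this reverses its apparent axis direction and must be
    folded into polarity votes).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(images)
    if n < k:
        raise ValueError(f"need at least k={k} images, got {n}")
    imgs = np.stack([upsample_x(im, upsample) for im in images])
    shape = imgs.shape[1:]
    std = np.stack([_standardize(im) for im in imgs])
    f_img = np.stack([np.fft.rfft2(im) for im in std])
    f_rot = np.stack([np.fft.rfft2(np.rot90(im, 2).copy()) for im in std])
    window = _shift_window_mask(shape, max_shift, max_shift * upsample)

    rng = np.random.default_rng(seed)
    # bootstrap references from single images: a featureless average is a
    # fixed point of align-and-average, so each class must start with the
    # phase structure of one member
    seed_idx = rng.choice(n, size=k, replace=False)
    refs = std[seed_idx].copy()
    labels = np.full(n, -1, dtype=int)
    flips = np.zeros(n, dtype=bool)
    shifts = np.zeros(n, dtype=int)
    scores = np.zeros(n)

    for _ in range(n_iter):
        f_refs = np.stack([np.fft.rfft2(r) for r in refs])
        new_labels = np.empty(n, dtype=int)
        for i in range(n):
            sc, sh, fl = _best_alignment(f_img[i], f_rot[i], f_refs, shape, window)
            c = int(np.argmax(sc))
            new_labels[i] = c
            scores[i] = sc[c]
            shifts[i] = sh[c]
            flips[i] = fl[c]
        # reseed empties deterministically from the worst-fitting members
        for c in range(k):
            if not np.any(new_labels == c):
                cand = int(np.argmin(np.where(
                    np.bincount(new_labels, minlength=k)[new_labels] > 1,
                    scores, np.inf)))
                new_labels[cand] = c
                shifts[cand] = 0
                flips[cand] = False
        converged = np.array_equal(new_labels, labels)
        labels = new_labels
        for c in range(k):
            members = np.where(labels == c)[0]
            acc = np.zeros(shape)
            for i in members:
                acc += _apply_alignment(std[i], shifts[i], flips[i], shape)
            refs[c] = _standardize(acc)
        if converged:
            break

    averages = []
    for c in range(k):
        members = np.where(labels == c)[0]
        acc = np.zeros(shape)
        for i in members:
            acc += _apply_alignment(imgs[i], shifts[i], flips[i], shape)
        avg = acc / max(1, len(members))
        averages.append(ClassAverage2D(avg.astype(np.float32), len(members),
                                       members=list(map(int, members))))
    return labels, flips, shifts, averages


# ---------------------------------------------------------------------------
# model projections and class labelling


def actin_model_projections(params: HelicalParams, box_edge: int,
                            pixel_size: float,
                            slab_nm: float = DEFAULT_SLAB_NM,
                            mask_radius_nm: float = DEFAULT_MASK_RADIUS_NM,
                            phase_deg: float = 0.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Reference projections of the helical actin model along +x.

    Returns ``(plus, minus)``: the masked central-slab projection of a
    noise-free filament with its barbed end along +x, and its axial flip
    (the 180 degree rotation about the in-plane y axis, an x-mirror of
    the projection since the z-sum is z-flip invariant).
    """
    length = box_edge * pixel_size * 1.5
    pad_nm = box_edge * pixel_size  # enough lateral room to cut a full box
    vol, _ = build_actin_density(params, length, pixel_size, pad_nm=pad_nm,
                                 phase_deg=phase_deg)
    # cut a box centred on the filament midpoint
    mid = np.array([length / 2.0, 0.0, 0.0])
    frac = vol.world_to_voxel(mid)
    idx = np.rint(frac).astype(int)
    half = box_edge // 2
    lo = idx - half
    sub = vol.grid[lo[2]:lo[2] + box_edge, lo[1]:lo[1] + box_edge,
                   lo[0]:lo[0] + box_edge]
    plus = project_slab(sub, slab_nm, pixel_size, tangent=[1.0, 0.0, 0.0],
                        mask_radius_nm=mask_radius_nm)
    minus = plus[:, ::-1].copy()
    return plus, minus


@lru_cache(maxsize=8)
def _cached_bank(params: HelicalParams, box_edge: int, pixel_size: float,
                 slab_nm: float, n_phases: int
                 ) -> tuple[tuple[np.ndarray, ...], tuple[np.ndarray, ...]]:
    plus, minus = [], []
    for ph in np.arange(0.0, 360.0, 360.0 / n_phases):
        p, m = actin_model_projections(params, box_edge, pixel_size, slab_nm,
                                       phase_deg=ph)
        plus.append(p)
        minus.append(m)
    return tuple(plus), tuple(minus)


def model_projection_bank(params: HelicalParams, box_edge: int,
                          pixel_size: float,
                          slab_nm: float = DEFAULT_SLAB_NM,
                          n_phases: int = 12
                          ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Model projections at ``n_phases`` helical phases per orientation.

    Integer-voxel shifts sample the screw phase too coarsely (one voxel
    is a third of a rise at desk scale), so orientation scores take the
    maximum over an explicit phase bank instead. Cached per parameter
    set.
    """
    plus, minus = _cached_bank(params, box_edge, float(pixel_size),
                               float(slab_nm), n_phases)
    return list(plus), list(minus)


def _ncc_over_shifts(image: np.ndarray, template: np.ndarray,
                     max_shift: int = MAX_SHIFT_VOX,
                     max_shift_x: int | None = None) -> float:
    """Max normalized cross-correlation of two images over a bounded
    integer shift window.

    A template with fewer columns than the image is Fourier-upsampled
    along x to match (images from :func:`classify_2d` live on a finer
    x grid)."""
    a = np.asarray(image, dtype=np.float64)
    b = np.asarray(template, dtype=np.float64)
    if b.shape != a.shape and a.shape[0] == b.shape[0] \
            and a.shape[1] % b.shape[1] == 0:
        ratio = a.shape[1] // b.shape[1]
        b = upsample_x(b, ratio)
        if max_shift_x is None:
            max_shift_x = max_shift * ratio
    a = _standardize(a)
    b = _standardize(b)
    corr = np.fft.irfft2(np.conj(np.fft.rfft2(a)) * np.fft.rfft2(b), s=a.shape)
    window = _shift_window_mask(a.shape, max_shift, max_shift_x)
    return float(corr[window].max())


def polarity_of_class(class_avg: ClassAverage2D | np.ndarray,
                      model_plus: np.ndarray | list[np.ndarray],
                      model_minus: np.ndarray | list[np.ndarray],
                      margin: float = DEFAULT_MARGIN,
                      max_shift: int = MAX_SHIFT_VOX
                      ) -> tuple[int | None, float, float]:
    """Label a class average by its better-matching axial orientation.

    Scores are max NCC over bounded shifts and, when a projection bank is
    given, over helical phases. Returns ``(label, score_plus,
    score_minus)`` with ``label`` None when the score difference is below
    ``margin``.
    """
    img = class_avg.image if isinstance(class_avg, ClassAverage2D) else class_avg
    bank_p = model_plus if isinstance(model_plus, (list, tuple)) else [model_plus]
    bank_m = model_minus if isinstance(model_minus, (list, tuple)) else [model_minus]
    sp = max(_ncc_over_shifts(img, t, max_shift) for t in bank_p)
    sm = max(_ncc_over_shifts(img, t, max_shift) for t in bank_m)
    if abs(sp - sm) < margin:
        label = None
    else:
        label = 1 if sp > sm else -1
    if isinstance(class_avg, ClassAverage2D):
        class_avg.polarity_label = label
        class_avg.score_plus = sp
        class_avg.score_minus = sm
    return label, sp, sm


def select_classes(classes: list[ClassAverage2D],
                   margin: float = DEFAULT_MARGIN,
                   min_members: int = DEFAULT_MIN_MEMBERS) -> list[ClassAverage2D]:
    """Retain confidently labelled, well-populated classes.

    Members of discarded classes get polarity vote 0 downstream. Raises
    when nothing survives (the pipeline cannot proceed).
    """
    selected = []
    for c in classes:
        ok = (c.polarity_label is not None
              and abs(c.score_plus - c.score_minus) >= margin
              and c.member_count >= min_members)
        c.selected = bool(ok)
        if ok:
            selected.append(c)
    if not selected:
        raise PolarityError(
            "no class passed selection (margin %.3f, min_members %d); "
            "inspect the class averages" % (margin, min_members))
    return selected


def assign_votes(records: list[SegmentRecord], labels: np.ndarray,
                 flips: np.ndarray, classes: list[ClassAverage2D],
                 usable_indices: list[int],
                 images: list[np.ndarray] | None = None,
                 model_plus: np.ndarray | list[np.ndarray] | None = None,
                 model_minus: np.ndarray | list[np.ndarray] | None = None,
                 segment_margin: float = 0.01) -> None:
    """Write per-segment polarity votes back into the segment records.

    ``labels``/``flips`` are indexed over the usable (classified) images;
    ``usable_indices[i]`` maps image i to its record. A vote of +1 means
    the barbed end points along +tangent of the segment.

    Members of selected, confidently labelled classes inherit the class
    label (times -1 when the member entered through the 180 degree
    rotation). When ``images`` and the model projections are given,
    members of discarded classes fall back to their own model-matching
    score and abstain only below ``segment_margin`` -- at coarse pixel
    sizes the class-average route alone abstains too often for the
    per-filament statistics to converge, while the per-image score
    against the clean helical model remains informative.
    """
    for img_i, rec_i in enumerate(usable_indices):
        rec = records[rec_i]
        c = classes[labels[img_i]]
        rec.class_id = int(labels[img_i])
        if c.selected and c.polarity_label is not None:
            vote = c.polarity_label * (-1 if flips[img_i] else 1)
            rec.polarity_vote = int(vote)
            rec.vote_score = float(abs(c.score_plus - c.score_minus))
            continue
        if images is None or model_plus is None or model_minus is None:
            rec.polarity_vote = 0
            rec.vote_score = 0.0
            continue
        label, sp, sm = polarity_of_class(np.asarray(images[img_i]),
                                          model_plus, model_minus,
                                          margin=segment_margin)
        rec.polarity_vote = 0 if label is None else int(label)
        rec.vote_score = float(abs(sp - sm))
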