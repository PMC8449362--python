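"""Simplified real-space subtomogram averaging and Fourier shell correlation.

Pre-oriented boxes (in-plane angle, polarity flip and residual shift from
the 2D classification) are transformed into a common frame and voxel-
averaged; an optional helical symmetrization applies the (rise, twist)
screw operators and re-averages. Resolution is read from a gold-standard
style half-set FSC at the 0.143 and 0.5 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .scene import HelicalParams


@dataclass
class BoxOrientation:
    """Transform taking one box into the common (filament along +x) frame."""
    inplane_angle: float = 0.0        # deg, rotation about z applied to the box
    flip: bool = False                # 180 deg rotation about y (polarity flip)
    shift_nm: np.ndarray | None = None  # residual [x, y] shift


@dataclass
class FSCCurve:
    shell_frequencies: np.ndarray     # 1/nm, strictly increasing to Nyquist
    correlations: np.ndarray
    resolution_at_0143: float | None  # Angstrom, None = beyond Nyquist
    resolution_at_05: float | None

    def resolution_at(self, threshold: float) -> float | None:
        return _resolution_at(self.shell_frequencies, self.correlations, threshold)


def _orient_box(box: np.ndarray, o: BoxOrientation, pixel_size: float) -> np.ndarray:
    out = np.asarray(box, dtype=np.float64)
    if o.shift_nm is not None and np.any(np.asarray(o.shift_nm) != 0):
        s = np.asarray(o.shift_nm, dtype=float) / pixel_size
        out = ndimage.shift(out, (0.0, -s[1], -s[0]), order=1, mode="constant")
    if o.inplane_angle:
        # rotate about z: acts on the (y, x) plane
        out = ndimage.rotate(out, o.inplane_angle, axes=(1, 2), reshape=False,
                             order=1, mode="constant")
    if o.flip:
        out = out[::-1, :, ::-1]      # 180 deg about y: x -> -x, z -> -z
    return out


def apply_helical_symmetry(volume: np.ndarray, params: HelicalParams,
                           pixel_size: float, n_ops: int = 4) -> np.ndarray:
    """Symmetrize a filament-along-x volume with the helical screw.

    Applies operators j = -n_ops .. +n_ops (translate j*rise along x,
    rotate j*twist about x) and averages.
    """
    acc = np.zeros_like(volume, dtype=np.float64)
    count = 0
    for j in range(-n_ops, n_ops + 1):
        v = np.asarray(volume, dtype=np.float64)
        if j != 0:
            v = ndimage.rotate(v, j * params.twist, axes=(0, 1), reshape=False,
                               order=1, mode="constant")
            v = ndimage.shift(v, (0.0, 0.0, -j * params.rise_nm / pixel_size),
                              order=1, mode="constant")
        acc += v
        count += 1
    return (acc / count).astype(np.float32)


def average_aligned(subvolumes: list[np.ndarray],
                    orientations: list[BoxOrientation],
                    pixel_size: float,
                    helical: HelicalParams | None = None,
                    n_sym_ops: int = 4) -> np.ndarray:
    """Average boxes after mapping each into the common frame."""
    if len(subvolumes) == 0:
        raise ValueError("cannot average an empty set of subvolumes")
    if len(subvolumes) != len(orientations):
        raise ValueError("one orientation per box required")
    acc = np.zeros_like(np.asarray(subvolumes[0], dtype=np.float64))
    for box, o in zip(subvolumes, orientations):
        acc += _orient_box(box, o, pixel_size)
    avg = (acc / len(subvolumes)).astype(np.float32)
    if helical is not None:
        avg = apply_helical_symmetry(avg, helical, pixel_size, n_sym_ops)
    return avg


# ---------------------------------------------------------------------------
# FSC


def soft_spherical_mask(shape: tuple[int, int, int],
                        radius_frac: float = 0.9,
                        taper_vox: float = 3.0) -> np.ndarray:
    """Raised-cosine spherical mask, radius ``radius_frac`` x box/2."""
    grids = np.meshgrid(*[np.arange(n) - (n - 1) / 2 for n in shape],
                        indexing="ij")
    r = np.sqrt(sum(g * g for g in grids))
    r0 = radius_frac * (min(shape) / 2.0) - taper_vox
    m = np.clip((r0 + taper_vox - r) / taper_vox, 0.0, 1.0)
    return (0.5 - 0.5 * np.cos(np.pi * m)).astype(np.float32)


def fsc(map1: np.ndarray, map2: np.ndarray, pixel_size: float,
        mask: np.ndarray | bool = True) -> FSCCurve:
    """Fourier shell correlation between two maps, shell width one voxel.

    Symmetric in its arguments and invariant to global intensity scaling.
    ``mask=True`` applies the default soft spherical mask (raised cosine
    at 0.9 x box/2) to both maps first.
    """
    a = np.asarray(map1, dtype=np.float64)
    b = np.asarray(map2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("half maps must share a shape")
    if mask is True:
        mask = soft_spherical_mask(a.shape)
    if mask is not False and mask is not None:
        a = a * mask
        b = b * mask
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    freqs = np.meshgrid(*[np.fft.fftfreq(n) for n in a.shape], indexing="ij")
    r = np.sqrt(sum(f * f for f in freqs))          # cycles / voxel
    n_shells = min(a.shape) // 2
    shell = np.minimum((r * min(a.shape)).astype(int), n_shells)
    num = np.real(fa * np.conj(fb))
    p1 = np.abs(fa) ** 2
    p2 = np.abs(fb) ** 2
    num_s = np.bincount(shell.ravel(), num.ravel(), minlength=n_shells + 1)
    p1_s = np.bincount(shell.ravel(), p1.ravel(), minlength=n_shells + 1)
    p2_s = np.bincount(shell.ravel(), p2.ravel(), minlength=n_shells + 1)
    denom = np.sqrt(p1_s * p2_s)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num_s / denom, 0.0)
    shells = np.arange(1, n_shells + 1)             # skip the DC shell
    freq_nm = shells / (min(a.shape) * pixel_size)  # 1 / nm
    corr = corr[1:n_shells + 1]
    return FSCCurve(freq_nm, corr,
                    _resolution_at(freq_nm, corr, 0.143),
                    _resolution_at(freq_nm, corr, 0.5))


def _resolution_at(freq_nm: np.ndarray, corr: np.ndarray,
                   threshold: float) -> float | None:
    """Resolution (Angstrom) where the curve first crosses ``threshold``
    (linear interpolation); None when it never does ("beyond Nyquist")."""
    below = np.where(corr < threshold)[0]
    if len(below) == 0:
        return None
    i = below[0]
    if i == 0:
        f = freq_nm[0]
    else:
        f0, f1 = freq_nm[i - 1], freq_nm[i]
        c0, c1 = corr[i - 1], corr[i]
        f = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0) if c0 != c1 else f1
    return float(10.0 / f)


def split_half_fsc(subvolumes: list[np.ndarray],
                   orientations: list[BoxOrientation],
                   pixel_size: float, seed: int = 0,
                   helical: HelicalParams | None = None) -> FSCCurve:
    """Gold-standard style FSC: random half split, independent averages,
    per-shell correlation."""
    n = len(subvolumes)
    if n < 2:
        raise ValueError("need at least two subvolumes for a half-set FSC")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half1, half2 = perm[: n // 2], perm[n // 2:]
    m1 = average_aligned([subvolumes[i] for i in half1],
                         [orientations[i] for i in half1], pixel_size, helical)
    m2 = average_aligned([subvolumes[i] for i in half2],
                         [orientations[i] for i in half2], pixel_size, helical)
    return fsc(m1, m2, pixel_size)
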