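"""Shared segmentation primitives.

Global and adaptive Otsu thresholding, single-pass voting (hole-filling)
filters, fraction-based cavity filling, binary morphology with anisotropic
ellipsoidal kernels, and connected-component volume filtering.

Connectivity convention: foreground objects are 26-connected, background
and cavities 6-connected (the standard complementary pairing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryMask, IntensityVolume, KernelSpec, xyz_to_zyx

CONN26 = np.ones((3, 3, 3), dtype=bool)
CONN6 = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# Thresholding


@dataclass
class ThresholdSpec:
    """Manual or adaptive-Otsu threshold.

    In adaptive mode, ``n_samples`` cuboidal regions of ``region_size``
    voxels (x, y, z) are placed on a uniform jittered grid (``seed`` fixes
    the jitter); each yields a local Otsu value at its centre and per-voxel
    thresholds are trilinearly interpolated (nearest beyond the hull).
    """

    mode: str = "adaptive_otsu"
    manual_value: int = 128
    region_size: tuple = (64, 64, 16)
    n_samples: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("manual", "adaptive_otsu"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if not (0 <= int(self.manual_value) <= 255):
            raise ValueError("manual threshold must be in 0..255")
        self.region_size = tuple(int(r) for r in self.region_size)
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def otsu_global(data) -> int:
    """Otsu threshold over the 256-bin histogram of an 8-bit volume.

    Returns the smallest ``t`` maximizing between-class variance for the
    split ``[< t]`` / ``[>= t]``.  A constant volume has no defined
    threshold and raises.
    """
    if isinstance(data, IntensityVolume):
        data = data.data
    data = np.asarray(data)
    hist = np.bincount(data.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold undefined for a constant volume")
    p = hist / hist.sum()
    levels = np.arange(256)
    omega0 = np.cumsum(p)  # weight of class [<= v]
    mu = np.cumsum(p * levels)
    mu_total = mu[-1]
    # split at t means class0 = [0, t-1]; index t-1 in the cumulatives
    w0 = omega0[:-1]
    w1 = 1.0 - w0
    m0 = mu[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * w0 - m0) ** 2 / (w0 * w1)
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    # the variance is flat across empty histogram gaps; tie-break at the
    # middle of the maximizing plateau
    best = sigma_b.max()
    ties = np.nonzero(sigma_b >= best - 1e-12 * max(best, 1.0))[0]
    return int(round(ties.mean())) + 1


def _grid_dims(n_samples, shape_zyx):
    """Factor n_samples into a (gz, gy, gx) grid matching the volume aspect."""
    best = None
    target = [max(n, 1) for n in shape_zyx]
    geo = math.prod(target) ** (1 / 3)
    ideal = [n_samples ** (1 / 3) * t / geo for t in target]
    for gz in range(1, n_samples + 1):
        if n_samples % gz:
            continue
        rem = n_samples // gz
        for gy in range(1, rem + 1):
            if rem % gy:
                continue
            gx = rem // gy
            score = sum(
                abs(math.log(g) - math.log(max(i, 1e-9)))
                for g, i in zip((gz, gy, gx), ideal)
            )
            if best is None or score < best[0]:
                best = (score, (gz, gy, gx))
    return best[1]


def otsu_adaptive(vol: IntensityVolume, spec: ThresholdSpec) -> np.ndarray:
    """Per-voxel threshold field from locally sampled Otsu values.

    With ``n_samples = 1`` and the region covering the whole volume this
    reduces exactly to a constant field at the global Otsu value.
    """
    if spec.mode != "adaptive_otsu":
        raise ValueError("otsu_adaptive requires adaptive_otsu mode")
    data = vol.data
    region = xyz_to_zyx(spec.region_size)
    if any(r > n for r, n in zip(region, data.shape)):
        raise ValueError(
            f"sample region {spec.region_size} larger than volume "
            f"{tuple(reversed(data.shape))} (x, y, z)"
        )
    dims = _grid_dims(spec.n_samples, data.shape)
    rng = np.random.default_rng(spec.seed)
    centers = []
    for axis, g in enumerate(dims):
        n = data.shape[axis]
        edges = np.linspace(0, n, g + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        cell = n / g
        jitter = rng.uniform(-0.25, 0.25, size=g) * cell
        half = region[axis] / 2
        c = np.clip(mids + jitter, half, n - half) if n > region[axis] else mids
        c = np.maximum.accumulate(np.round(c).astype(int))  # keep sorted
        centers.append(np.clip(c, 0, n - 1))

    fallback = None
    values = np.empty(dims, dtype=np.float64)
    for iz, cz in enumerate(centers[0]):
        for iy, cy in enumerate(centers[1]):
            for ix, cx in enumerate(centers[2]):
                sl = tuple(
                    _region_slice(c, r, n)
                    for c, r, n in zip((cz, cy, cx), region, data.shape)
                )
                block = data[sl]
                if block.min() == block.max():
                    if fallback is None:
                        fallback = otsu_global(data)
                    values[iz, iy, ix] = fallback
                else:
                    values[iz, iy, ix] = otsu_global(block)

    return _trilinear_field(centers, values, data.shape)


def _region_slice(center, size, n):
    lo = center - size // 2
    lo = min(max(lo, 0), max(n - size, 0))
    return slice(lo, min(lo + size, n))


def _trilinear_field(centers, values, shape):
    """Interpolate scattered-on-a-grid samples to a full voxel field."""
    out = np.zeros(shape, dtype=np.float64)
    idx, frac = [], []
    for axis, c in enumerate(centers):
        coords = np.arange(shape[axis], dtype=np.float64)
        if len(c) == 1:
            idx.append(np.zeros(shape[axis], dtype=np.intp))
            frac.append(np.zeros(shape[axis]))
            continue
        j = np.clip(np.searchsorted(c, coords, side="right") - 1, 0, len(c) - 2)
        denom = (c[j + 1] - c[j]).astype(float)
        denom[denom == 0] = 1.0
        f = np.clip((coords - c[j]) / denom, 0.0, 1.0)
        idx.append(j.astype(np.intp))
        frac.append(f)
    jz = idx[0][:, None, None]
    jy = idx[1][None, :, None]
    jx = idx[2][None, None, :]
    fz = frac[0][:, None, None]
    fy = frac[1][None, :, None]
    fx = frac[2][None, None, :]
    for dz in range(min(2, values.shape[0])):
        wz = (1 - fz) if dz == 0 else fz
        for dy in range(min(2, values.shape[1])):
            wy = (1 - fy) if dy == 0 else fy
            for dx in range(min(2, values.shape[2])):
                wx = (1 - fx) if dx == 0 else fx
                out += (wz * wy * wx) * values[
                    np.minimum(jz + dz, values.shape[0] - 1),
                    np.minimum(jy + dy, values.shape[1] - 1),
                    np.minimum(jx + dx, values.shape[2] - 1),
                ]
    return out


def apply_threshold(vol: IntensityVolume, spec: ThresholdSpec) -> BinaryMask:
    """Foreground = voxels with intensity >= threshold (manual or adaptive)."""
    if spec.mode == "manual":
        fg = vol.data >= spec.manual_value
        prov = f"threshold_manual_{spec.manual_value}"
    else:
        field = otsu_adaptive(vol, spec)
        fg = vol.data >= field
        prov = "threshold_adaptive_otsu"
    return BinaryMask(fg, vol.spacing, prov)


# ---------------------------------------------------------------------------
# Voting filters


@dataclass
class VotingParams:
    """Single-pass majority-voting hole filling.

    ``radius`` is a per-axis (x, y, z) box radius (guidance: <= 3);
    ``majority`` shifts the vote above the half-neighbourhood baseline and
    must lie in 0..10 — smaller values act more aggressively.
    """

    radius: tuple = (1, 1, 1)
    majority: int = 2

    def __post_init__(self):
        if np.isscalar(self.radius):
            self.radius = (int(self.radius),) * 3
        self.radius = tuple(int(r) for r in self.radius)
        if any(r < 0 for r in self.radius) or all(r == 0 for r in self.radius):
            raise ValueError("voting radius must be >= 0 per axis and nonzero overall")
        if not (0 <= int(self.majority) <= 10):
            raise ValueError("majority threshold values have to be within 0-10")


def _neighbour_counts(mask_data, radius_xyz):
    # separable box sum (running-sum implementation, outside counts as bg)
    size = tuple(2 * r + 1 for r in xyz_to_zyx(radius_xyz))
    counts = ndimage.uniform_filter(
        mask_data.astype(np.float64), size=size, mode="constant", cval=0.0
    ) * np.prod(size)
    counts -= mask_data  # exclude the centre voxel itself
    n_neigh = int(np.prod(size)) - 1
    return np.floor(counts + 0.5).astype(np.int64), n_neigh


def vote_fill(mask: BinaryMask, p: VotingParams, inverse=False, force=False) -> BinaryMask:
    """Majority-vote fill (direct) or despeckle (inverse), single pass.

    Direct: a background voxel turns foreground when its foreground
    neighbours number at least ``ceil(N/2) + majority`` (N = box
    neighbourhood size minus the centre).  Inverse: the symmetric rule
    removes foreground voxels dominated by background.  Direct mode never
    removes foreground; inverse mode never creates it.
    """
    if any(r > 3 for r in p.radius) and not force:
        raise ValueError(
            "voting radii should not exceed 3 voxels; pass force=True to override"
        )
    m = mask.data
    fg_counts, n_neigh = _neighbour_counts(m, p.radius)
    needed = -(-n_neigh // 2) + p.majority  # ceil(N/2) + majority
    if inverse:
        bg_counts = n_neigh - fg_counts
        out = m & ~(bg_counts >= needed)
        prov = f"vote_fill_inverse_m{p.majority}"
    else:
        out = m | (fg_counts >= needed)
        prov = f"vote_fill_direct_m{p.majority}"
    return mask.with_data(out, prov)


@dataclass
class CavityFillParams:
    """Surround-fraction cavity filling.

    A background voxel turns foreground when the fraction of the 26
    neighbourhood directions in which a foreground voxel occurs within the
    per-axis ``radius`` reaches ``min_foreground_fraction``; the sweep
    repeats until nothing changes, so a fully enclosed cavity floods from
    its most-surrounded voxels outward.  A completely enclosed hole is
    reachable at fractions up to 1; holes that are open on one side (a tube
    lumen, a cavity touching an unsegmented patch) need a lower fraction.
    The accelerated variant bounds each ray by the bounding box of the
    radius (slightly longer diagonal reach, cheapest bookkeeping); the
    precise variant bounds rays by the inscribed ellipsoid.
    """

    radius: tuple = (3, 3, 2)
    min_foreground_fraction: float = 0.8
    accelerated: bool = True

    def __post_init__(self):
        if np.isscalar(self.radius):
            self.radius = (int(self.radius),) * 3
        self.radius = tuple(int(r) for r in self.radius)
        if any(r < 1 for r in self.radius):
            raise ValueError("cavity-fill radius must be >= 1 per axis")
        if not (0.0 < self.min_foreground_fraction <= 1.0):
            raise ValueError("min_foreground_fraction must be in (0, 1]")


_DIRS26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _ray_reach(direction, radius_zyx, box: bool) -> int:
    """Number of unit steps along a 26-direction within the neighbourhood."""
    if box:
        return min(r for d, r in zip(direction, radius_zyx) if d != 0)
    s = sum((d / r) ** 2 for d, r in zip(direction, radius_zyx))
    return max(int(np.floor(1.0 / np.sqrt(s))), 1)


def _shift(arr, dz, dy, dx):
    """Shift with False padding: out[i] = arr[i + (dz, dy, dx)]."""
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, d in enumerate((dz, dy, dx)):
        n = arr.shape[axis]
        if abs(d) >= n:
            return out
        if d > 0:
            src[axis] = slice(d, n)
            dst[axis] = slice(0, n - d)
        elif d < 0:
            src[axis] = slice(0, n + d)
            dst[axis] = slice(-d, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def cavity_fill(mask: BinaryMask, p: CavityFillParams) -> BinaryMask:
    radius_zyx = xyz_to_zyx(p.radius)
    reaches = [_ray_reach(d, radius_zyx, p.accelerated) for d in _DIRS26]
    needed = int(np.ceil(p.min_foreground_fraction * len(_DIRS26) - 1e-9))
    m = mask.data.copy()
    while True:
        coverage = np.zeros(m.shape, dtype=np.uint8)
        for (dz, dy, dx), reach in zip(_DIRS26, reaches):
            hit = np.zeros(m.shape, dtype=bool)
            for t in range(1, reach + 1):
                hit |= _shift(m, t * dz, t * dy, t * dx)
            coverage += hit
        new = m | (~m & (coverage >= needed))
        if np.array_equal(new, m):
            break
        m = new
    return mask.with_data(m, f"cavity_fill_f{p.min_foreground_fraction}")


# ---------------------------------------------------------------------------
# Binary morphology


def open_close(mask: BinaryMask, k: KernelSpec, op: str) -> BinaryMask:
    """Binary erode/dilate/open/close with an (anisotropic) ellipsoidal kernel.

    A zero-radius kernel is the identity.  The outside of the stack counts
    as background for erosion, dilation and opening (border-touching
    structures shrink under erosion); the erosion half of a closing treats
    the outside as foreground so that closing never eats the stack faces.
    """
    if op not in ("open", "close", "erode", "dilate"):
        raise ValueError(f"unknown morphology op {op!r}")
    if k.is_identity:
        return mask.with_data(mask.data.copy(), f"{op}_identity")
    foot = k.footprint()

    def ero(m, border=0):
        return ndimage.binary_erosion(m, structure=foot, border_value=border)

    def dil(m):
        return ndimage.binary_dilation(m, structure=foot, border_value=0)

    if op == "erode":
        out = ero(mask.data)
    elif op == "dilate":
        out = dil(mask.data)
    elif op == "open":
        out = dil(ero(mask.data))
    else:
        out = ero(dil(mask.data), border=1)
    return mask.with_data(out, f"{op}_k{k.extents}")


def drop_small_objects(mask: BinaryMask, min_volume, units="voxels") -> BinaryMask:
    """Remove 26-connected components smaller than ``min_volume``.

    ``units='um3'`` interprets the threshold physically via the voxel
    spacing; components with volume >= the threshold survive.
    """
    if min_volume < 0:
        raise ValueError("min_volume must be >= 0")
    if units not in ("voxels", "um3"):
        raise ValueError("units must be 'voxels' or 'um3'")
    thr_vox = min_volume / mask.voxel_volume if units == "um3" else min_volume
    labels, n = ndimage.label(mask.data, structure=CONN26)
    if n == 0:
        return mask.with_data(mask.data.copy(), "drop_small")
    sizes = np.bincount(labels.ravel())
    keep = sizes >= thr_vox
    keep[0] = False
    return mask.with_data(keep[labels], f"drop_small_{min_volume}{units}")


def median_filter(vol: IntensityVolume, radius) -> IntensityVolume:
    """Median filter with an ellipsoidal (x, y, z)-radius footprint."""
    if np.isscalar(radius):
        radius = (int(radius),) * 3
    radius = tuple(int(r) for r in radius)
    if all(r == 0 for r in radius):
        return vol.with_data(vol.data.copy())
    foot = KernelSpec(radius, "ellipsoid").footprint()
    return vol.with_data(ndimage.median_filter(vol.data, footprint=foot))


def grey_open(vol: IntensityVolume, radius) -> IntensityVolume:
    """Greyscale opening with an ellipsoidal (x, y, z)-radius footprint."""
    if np.isscalar(radius):
        radius = (int(radius),) * 3
    radius = tuple(int(r) for r in radius)
    if all(r == 0 for r in radius):
        return vol.with_data(vol.data.copy())
    foot = KernelSpec(radius, "ellipsoid").footprint()
    return vol.with_data(ndimage.grey_opening(vol.data, footprint=foot))
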