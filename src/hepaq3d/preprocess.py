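"""Pre-processing: 3D contrast-limited adaptive histogram equalization and crop.

CLAHE here is fully volumetric: cuboidal histogram windows are sampled on a
regular grid (every ``step`` voxels per axis), each window yields a
clipped-histogram equalization mapping, and every voxel blends the mappings
of the surrounding sample centres trilinearly (nearest mapping beyond the
outermost centres).  ``clip = 1`` disables clipping and reduces to plain
adaptive histogram equalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IntensityVolume, xyz_to_zyx

N_BINS = 256


@dataclass
class ClaheParams:
    """CLAHE parameters.  ``window`` and ``step`` are (x, y, z) voxel triples."""

    window: tuple = (50, 50, 20)
    step: tuple = (25, 25, 10)
    clip: float = 0.1

    def __post_init__(self):
        self.window = tuple(int(w) for w in self.window)
        self.step = tuple(int(s) for s in self.step)
        if any(w < 1 for w in self.window):
            raise ValueError("window must be >= 1 per axis")
        if any(not (1 <= s <= w) for s, w in zip(self.step, self.window)):
            raise ValueError("step must satisfy 1 <= step <= window per axis")
        if not (0.0 < self.clip <= 1.0):
            raise ValueError("clip level must be in (0, 1]")


@dataclass
class CropBounds:
    """1-based inclusive crop bounds per axis."""

    x_start: int = 1
    x_end: int = 1
    y_start: int = 1
    y_end: int = 1
    z_start: int = 1
    z_end: int = 1

    def __post_init__(self):
        for a in "xyz":
            lo, hi = getattr(self, f"{a}_start"), getattr(self, f"{a}_end")
            if lo < 1 or lo > hi:
                raise ValueError(f"invalid {a} bounds: {lo}..{hi}")

    @classmethod
    def full(cls, vol: IntensityVolume):
        nz, ny, nx = vol.shape
        return cls(1, nx, 1, ny, 1, nz)

    def slices(self):
        """(z, y, x) slice objects (0-based, half-open)."""
        return (
            slice(self.z_start - 1, self.z_end),
            slice(self.y_start - 1, self.y_end),
            slice(self.x_start - 1, self.x_end),
        )


def _window_slice(center, size, n):
    lo = center - size // 2
    lo = min(max(lo, 0), max(n - size, 0))
    return slice(lo, min(lo + size, n))


def _grid_centers(n, step):
    centers = list(range(0, n, step))
    if centers[-1] != n - 1:
        centers.append(n - 1)
    return np.array(centers)


def _clipped_lut(hist, clip, n_window):
    """Equalization LUT from a (possibly clipped) 256-bin histogram."""
    if clip < 1.0:
        ceiling = max(clip * n_window, 1.0)
        excess = np.clip(hist - ceiling, 0, None).sum()
        hist = np.minimum(hist, ceiling) + excess / N_BINS
    cdf = np.cumsum(hist)
    total = cdf[-1]
    if total <= 0:
        return np.arange(N_BINS, dtype=np.float64)
    return 255.0 * cdf / total


def clahe(vol: IntensityVolume, p: ClaheParams) -> IntensityVolume:
    """Contrast-limited adaptive histogram equalization of a z-stack."""
    data = vol.data
    win = xyz_to_zyx(p.window)
    step = xyz_to_zyx(p.step)
    if any(w > n for w, n in zip(win, data.shape)):
        raise ValueError(
            f"histogram window {p.window} larger than volume "
            f"{tuple(reversed(data.shape))} (x, y, z)"
        )

    centers = [_grid_centers(n, s) for n, s in zip(data.shape, step)]
    gz, gy, gx = (len(c) for c in centers)
    luts = np.empty((gz, gy, gx, N_BINS), dtype=np.float64)
    n_window = int(np.prod(win))
    for iz, cz in enumerate(centers[0]):
        sz = _window_slice(cz, win[0], data.shape[0])
        for iy, cy in enumerate(centers[1]):
            sy = _window_slice(cy, win[1], data.shape[1])
            for ix, cx in enumerate(centers[2]):
                sx = _window_slice(cx, win[2], data.shape[2])
                block = data[sz, sy, sx]
                hist = np.bincount(block.ravel(), minlength=N_BINS).astype(np.float64)
                luts[iz, iy, ix] = _clipped_lut(hist, p.clip, n_window)

    # trilinear blend of the 8 surrounding sample mappings per voxel
    idx = []
    frac = []
    for axis, c in enumerate(centers):
        coords = np.arange(data.shape[axis], dtype=np.float64)
        j = np.searchsorted(c, coords, side="right") - 1
        j = np.clip(j, 0, len(c) - 2) if len(c) > 1 else np.zeros_like(j)
        if len(c) > 1:
            f = (coords - c[j]) / (c[j + 1] - c[j])
            f = np.clip(f, 0.0, 1.0)
        else:
            f = np.zeros_like(coords)
        idx.append(j.astype(np.intp))
        frac.append(f)

    jz = idx[0][:, None, None]
    jy = idx[1][None, :, None]
    jx = idx[2][None, None, :]
    fz = frac[0][:, None, None]
    fy = frac[1][None, :, None]
    fx = frac[2][None, None, :]
    out = np.zeros(data.shape, dtype=np.float64)
    for dz in (0, 1):
        wz = (1 - fz) if dz == 0 else fz
        if luts.shape[0] == 1 and dz == 1:
            continue
        for dy in (0, 1):
            wy = (1 - fy) if dy == 0 else fy
            if luts.shape[1] == 1 and dy == 1:
                continue
            for dx in (0, 1):
                wx = (1 - fx) if dx == 0 else fx
                if luts.shape[2] == 1 and dx == 1:
                    continue
                w = wz * wy * wx
                if np.all(w == 0):
                    continue
                vals = luts[
                    np.minimum(jz + dz, luts.shape[0] - 1),
                    np.minimum(jy + dy, luts.shape[1] - 1),
                    np.minimum(jx + dx, luts.shape[2] - 1),
                    data,
                ]
                out += w * vals
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return vol.with_data(out)


def crop(vol: IntensityVolume, b: CropBounds) -> IntensityVolume:
    """Crop a volume to 1-based inclusive bounds (same bounds for every channel)."""
    nz, ny, nx = vol.shape
    if b.x_end > nx or b.y_end > ny or b.z_end > nz:
        raise ValueError(
            f"crop bounds exceed volume: x<={nx}, y<={ny}, z<={nz}, got {b}"
        )
    return vol.with_data(vol.data[b.slices()].copy())
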