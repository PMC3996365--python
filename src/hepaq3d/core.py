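"""Core data model: intensity volumes, binary masks, kernels, TIFF stack I/O.

Conventions used throughout the package:

* Voxel grids are numpy arrays indexed ``(z, y, x)`` — page order of the
  TIFF stack first.
* All user-facing coordinate/size triples (spacing, kernel extents, seed
  points, crop bounds) are given in ``(x, y, z)`` order, matching the
  microscope convention; :func:`xyz_to_zyx` / :func:`zyx_to_xyz` centralize
  the conversion.
* Spacing is micrometres per voxel and may be anisotropic (a typical 60x
  confocal set-up is 0.207 x 0.207 x 0.54 um).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_SPACING_60X = (0.207, 0.207, 0.54)
DEFAULT_SPACING_20X = (0.621, 0.621, 0.54)


def xyz_to_zyx(t):
    """Reverse an (x, y, z) triple into array (z, y, x) order."""
    x, y, z = t
    return (z, y, x)


def zyx_to_xyz(t):
    z, y, x = t
    return (x, y, z)


def _check_spacing(spacing):
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing!r}")
    return spacing


@dataclass
class IntensityVolume:
    """A 3D 8-bit grayscale image stack with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx), dtype uint8
        Grey values in [0, 255].
    spacing : (sx, sy, sz)
        Voxel edge lengths in micrometres.
    channel_name : str
        Free-text channel identifier (e.g. ``"DPPIV"``).
    """

    data: np.ndarray
    spacing: tuple = DEFAULT_SPACING_60X
    channel_name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or any(d < 1 for d in self.data.shape):
            raise ValueError("volume data must be 3D with all dims >= 1")
        if self.data.dtype != np.uint8:
            raise ValueError(
                f"volumes are 8-bit; got dtype {self.data.dtype} "
                "(convert the raw data to 8 bit first)"
            )
        self.spacing = _check_spacing(self.spacing)

    @property
    def spacing_zyx(self):
        return xyz_to_zyx(self.spacing)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self):
        """Physical volume of one voxel in um^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_data(self, data, channel_name=None):
        return IntensityVolume(
            np.asarray(data, dtype=np.uint8),
            self.spacing,
            self.channel_name if channel_name is None else channel_name,
        )


@dataclass
class BinaryMask:
    """A boolean voxel grid sharing geometry with the volume it came from."""

    data: np.ndarray
    spacing: tuple = DEFAULT_SPACING_60X
    provenance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        self.spacing = _check_spacing(self.spacing)

    @property
    def spacing_zyx(self):
        return xyz_to_zyx(self.spacing)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self):
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_data(self, data, provenance=None):
        return BinaryMask(
            data, self.spacing, self.provenance if provenance is None else provenance
        )


@dataclass
class LabelVolume:
    """Integer object labels (0 = background) on a voxel grid."""

    data: np.ndarray
    spacing: tuple = DEFAULT_SPACING_60X
    provenance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer-typed")
        self.spacing = _check_spacing(self.spacing)

    @property
    def spacing_zyx(self):
        return xyz_to_zyx(self.spacing)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self):
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def labels(self):
        """Sorted nonzero labels present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]


@dataclass
class KernelSpec:
    """Morphological kernel given as per-axis radii in voxels.

    ``extents`` are radii ``(kx, ky, kz)``: the structuring element spans
    ``2*k + 1`` voxels along each axis.  A radius of 0 on every axis is the
    identity element (used to skip optional opening steps).
    """

    extents: tuple = (0, 0, 0)
    shape: str = "ellipsoid"

    def __post_init__(self):
        ext = tuple(int(e) for e in self.extents)
        if len(ext) != 3 or any(e < 0 for e in ext):
            raise ValueError(f"kernel extents must be three ints >= 0, got {ext!r}")
        if self.shape not in ("box", "ellipsoid"):
            raise ValueError(f"kernel shape must be 'box' or 'ellipsoid', got {self.shape!r}")
        self.extents = ext

    @property
    def is_identity(self):
        return all(e == 0 for e in self.extents)

    def footprint(self):
        """Boolean structuring element, array-ordered (z, y, x)."""
        kx, ky, kz = self.extents
        if self.shape == "box":
            return np.ones((2 * kz + 1, 2 * ky + 1, 2 * kx + 1), dtype=bool)
        zz, yy, xx = np.mgrid[-kz : kz + 1, -ky : ky + 1, -kx : kx + 1]
        # normalized ellipsoid in voxel units; zero radii collapse that axis
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (
                (xx / max(kx, 1)) ** 2
                + (yy / max(ky, 1)) ** 2
                + (zz / max(kz, 1)) ** 2
            )
        return r2 <= 1.0 + 1e-9


def rescale_kernel(k: KernelSpec, ref_spacing, new_spacing) -> KernelSpec:
    """Rescale kernel extents between image set-ups with different voxel sizes.

    Follows the tool's stated convention that a kernel of size (2, 2, 1) at
    0.207 um lateral spacing becomes (4, 4, 1) at 0.414 um: per axis,
    ``extent' = round(extent * new_spacing / ref_spacing)``.  Identical
    spacings leave the kernel unchanged.
    """
    ref = _check_spacing(ref_spacing)
    new = _check_spacing(new_spacing)
    out = []
    for e, r, n in zip(k.extents, ref, new):
        scaled = e * n / r
        out.append(max(int(np.floor(scaled + 0.5)), 0))
    return KernelSpec(tuple(out), k.shape)


# ---------------------------------------------------------------------------
# TIFF stack I/O


def read_stack(path, spacing=DEFAULT_SPACING_60X, channel_name=None) -> IntensityVolume:
    """Read a multi-page 8-bit grayscale TIFF as an intensity volume.

    Pages become z-slices in file order.  16-bit or colour input is
    rejected: channels must be converted to 8-bit grayscale beforehand.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF stack: {path}")
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected grayscale pages, got array of shape {data.shape}"
        )
    if data.dtype != np.uint8:
        raise ValueError(
            f"{path.name}: expected 8-bit grayscale pages, got {data.dtype}; "
            "convert the channel to 8 bit first"
        )
    if channel_name is None:
        channel_name = path.stem
    return IntensityVolume(data, spacing, channel_name)


def write_stack(vol: IntensityVolume, path) -> Path:
    """Write an intensity volume as a multi-page grayscale TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), vol.data, photometric="minisblack")
    return path


OVERLAY_COLOR = (255, 60, 60)


def write_mask(
    mask: BinaryMask,
    stem,
    suffix="_bin",
    reference: IntensityVolume | None = None,
    color=OVERLAY_COLOR,
) -> Path:
    """Write a mask as ``<stem>_bin.tif`` (0/255) or ``<stem>_overlay.tif``.

    The overlay paints masked voxels in ``color`` over the raw grayscale
    intensities of ``reference``; unmasked voxels keep their grey value in
    all three RGB planes.
    """
    if suffix not in ("_bin", "_overlay"):
        raise ValueError(f"suffix must be '_bin' or '_overlay', got {suffix!r}")
    stem = Path(stem)
    path = stem.with_name(stem.name + suffix + ".tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    if suffix == "_bin":
        tifffile.imwrite(
            str(path), mask.data.astype(np.uint8) * 255, photometric="minisblack"
        )
        return path
    if reference is None:
        raise ValueError("an overlay needs a reference intensity volume")
    if reference.shape != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match reference {reference.shape}"
        )
    rgb = np.repeat(reference.data[..., np.newaxis], 3, axis=-1)
    rgb[mask.data] = np.asarray(color, dtype=np.uint8)
    tifffile.imwrite(str(path), rgb, photometric="rgb")
    return path


def read_mask(path, spacing=DEFAULT_SPACING_60X, provenance="") -> BinaryMask:
    """Read a 0/255 binary-mask TIFF back into a :class:`BinaryMask`."""
    vol = read_stack(path, spacing)
    return BinaryMask(vol.data > 127, spacing, provenance or Path(path).stem)


def check_same_geometry(*objs):
    """Raise if the given volumes/masks differ in shape or spacing."""
    shapes = {o.shape for o in objs}
    spacings = {tuple(np.round(o.spacing, 9)) for o in objs}
    if len(shapes) > 1:
        raise ValueError(f"geometry mismatch: shapes {sorted(shapes)}")
    if len(spacings) > 1:
        raise ValueError(f"geometry mismatch: spacings {sorted(spacings)}")
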