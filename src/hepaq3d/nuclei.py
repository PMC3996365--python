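"""DAPI nuclei segmentation, watershed separation, and classification.

Nuclei come in two populations: large, nearly spherical hepatocyte nuclei
and smaller, often elongated non-hepatocyte (endothelial, stellate, ...)
nuclei.  Objects are separated by a distance-transform watershed whose
merge level ``alpha`` controls how aggressively touching nuclei are split,
then classified by equivalent spherical diameter, falling back to a
roundness measure where the two diameter ranges overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation

from .core import BinaryMask, IntensityVolume, KernelSpec, LabelVolume, check_same_geometry
from .morphops import (
    CONN26,
    CavityFillParams,
    ThresholdSpec,
    VotingParams,
    apply_threshold,
    cavity_fill,
    grey_open,
    median_filter,
    open_close,
    vote_fill,
)


@dataclass
class NucleiParams:
    median_radius: tuple = (1, 1, 1)
    grey_open_radius: tuple = (1, 1, 0)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    vote: VotingParams = field(default_factory=lambda: VotingParams((1, 1, 1), 2))
    cavity: CavityFillParams = field(
        default_factory=lambda: CavityFillParams((2, 2, 1), 0.8)
    )
    close_k: KernelSpec = field(default_factory=lambda: KernelSpec((2, 2, 1)))
    open_k: KernelSpec = field(default_factory=lambda: KernelSpec((1, 1, 0)))
    alpha: float = 1.0
    # diameter classification ranges (um); no silent defaults — required
    smallest_non_hep_diam: float = None
    biggest_non_hep_diam: float = None
    smallest_hep_diam: float = None
    biggest_hep_diam: float = None
    roundness_cutoff: float = 0.5

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0.0 <= self.roundness_cutoff <= 1.0):
            raise ValueError("roundness cutoff must be in [0, 1]")

    def require_class_ranges(self):
        vals = (
            self.smallest_non_hep_diam,
            self.biggest_non_hep_diam,
            self.smallest_hep_diam,
            self.biggest_hep_diam,
        )
        if any(v is None for v in vals):
            raise ValueError(
                "nuclei diameter class ranges must be given explicitly "
                "(smallest/biggest non-hepatocyte and hepatocyte diameters)"
            )
        s_nh, b_nh, s_h, b_h = (float(v) for v in vals)
        if not (s_nh <= b_nh and s_h <= b_h):
            raise ValueError("diameter ranges must be ordered (smallest <= biggest)")
        return s_nh, b_nh, s_h, b_h


@dataclass
class NucleusRecord:
    label: int
    centroid: tuple  # (x, y, z) um
    volume: float  # um^3
    equivalent_diameter: float  # um
    roundness: float
    cls: str  # 'hepatic' | 'non_hepatic'
    brdu_positive: bool | None = None


def _merge_shallow_watershed(labels, height, alpha):
    """Merge adjacent watershed basins separated by saddles shallower than alpha.

    ``height`` is the (distance) relief the watershed flooded; two basins
    merge when ``min(peak_a, peak_b) - saddle_ab < alpha``, i.e. the split
    is not supported by a deep enough valley.  Iterated until stable, so
    chains of shallow splits collapse into one object.
    """
    labels = labels.copy()
    while True:
        ids = np.unique(labels)
        ids = ids[ids > 0]
        if len(ids) < 2:
            return labels
        peaks = dict(zip(ids, ndimage.maximum(height, labels, ids)))
        saddle: dict = {}
        for axis in range(3):
            a = [slice(None)] * 3
            b = [slice(None)] * 3
            a[axis] = slice(None, -1)
            b[axis] = slice(1, None)
            la, lb = labels[tuple(a)], labels[tuple(b)]
            ha, hb = height[tuple(a)], height[tuple(b)]
            m = (la != lb) & (la > 0) & (lb > 0)
            if not m.any():
                continue
            lo = np.minimum(la[m], lb[m])
            hi = np.maximum(la[m], lb[m])
            s = np.minimum(ha[m], hb[m])
            for l1, l2, sv in zip(lo, hi, s):
                key = (int(l1), int(l2))
                if sv > saddle.get(key, -1.0):
                    saddle[key] = float(sv)
        parent = {int(i): int(i) for i in ids}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        merged = False
        for (l1, l2), s in saddle.items():
            if min(peaks[l1], peaks[l2]) - s < alpha and find(l1) != find(l2):
                parent[find(l1)] = find(l2)
                merged = True
        if not merged:
            return labels
        remap = np.arange(labels.max() + 1)
        for i in ids:
            remap[i] = find(int(i))
        labels = remap[labels]


def _separate(binary, distance, alpha):
    """Distance-transform watershed with basin merging at level ``alpha`` (um)."""
    peaks = morphology.local_maxima(distance, connectivity=3)
    peaks &= binary
    markers, _ = ndimage.label(peaks, structure=CONN26)
    labels = segmentation.watershed(-distance, markers, mask=binary)
    return _merge_shallow_watershed(labels, distance, alpha)


def segment_nuclei(
    dapi: IntensityVolume,
    p: NucleiParams,
    intermediates: dict | None = None,
) -> LabelVolume:
    """Segment and separate nuclei in a DAPI stack.

    Noise filtering (median + greyscale opening), threshold, inverse
    voting, cavity filling, closing, opening, then watershed separation on
    the negated anisotropic distance transform.  Smaller ``alpha`` splits
    more agglomerates; larger values split fewer.
    """
    steps = []
    v = median_filter(dapi, p.median_radius)
    steps.append(("median", v))
    v = grey_open(v, p.grey_open_radius)
    steps.append(("grey_open", v))
    m = apply_threshold(v, p.threshold)
    steps.append(("threshold", m))
    m = vote_fill(m, p.vote, inverse=True)
    steps.append(("inverse_vote", m))
    m = cavity_fill(m, p.cavity)
    steps.append(("cavity_fill", m))
    m = open_close(m, p.close_k, "close")
    steps.append(("closing", m))
    m = open_close(m, p.open_k, "open")
    steps.append(("opening", m))
    if intermediates is not None:
        intermediates.update(steps)

    binary = m.data
    if not binary.any():
        return LabelVolume(np.zeros(binary.shape, dtype=np.int32), dapi.spacing, "nuclei")
    distance = ndimage.distance_transform_edt(binary, sampling=m.spacing_zyx)
    labels = _separate(binary, distance, p.alpha)
    # compact label ids for stable downstream bookkeeping
    ids = np.unique(labels)
    remap = np.zeros(ids.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(len(ids))
    return LabelVolume(remap[labels], dapi.spacing, "nuclei")


# ---------------------------------------------------------------------------
# Shape


def roundness_from_geometry(volume: float, area: float) -> float:
    """Roundness from physical volume (um^3) and surface area (um^2).

    Isoperimetric quotient ``36 pi V^2 / A^3``: exactly 1 for a sphere,
    approaching 0 for infinitely elongated objects; clamped to [0, 1].
    """
    if volume <= 0 or area <= 0:
        raise ValueError("roundness needs positive volume and surface area")
    q = 36.0 * np.pi * volume**2 / area**3
    return float(min(max(q, 0.0), 1.0))


def surface_area(object_mask, spacing_xyz) -> float:
    """Physical surface area (um^2) of a voxel object via marching cubes.

    The binary object is lightly smoothed (one-voxel Gaussian support)
    before meshing to reduce the staircase over-estimate of voxelized
    surfaces.
    """
    obj = np.asarray(object_mask, dtype=bool)
    if not obj.any():
        raise ValueError("empty object")
    pad = np.pad(obj, 2).astype(np.float64)
    pad = ndimage.gaussian_filter(pad, sigma=0.8)
    sz, sy, sx = (spacing_xyz[2], spacing_xyz[1], spacing_xyz[0])
    verts, faces, _, _ = measure.marching_cubes(pad, level=0.5, spacing=(sz, sy, sx))
    return float(measure.mesh_surface_area(verts, faces))


def roundness(object_mask, spacing_xyz) -> float:
    """Roundness of a voxel object (1 = sphere, -> 0 with elongation)."""
    obj = np.asarray(object_mask, dtype=bool)
    n = int(obj.sum())
    if n == 0:
        raise ValueError("empty object")
    vol = n * spacing_xyz[0] * spacing_xyz[1] * spacing_xyz[2]
    return roundness_from_geometry(vol, surface_area(obj, spacing_xyz))


# ---------------------------------------------------------------------------
# Classification


def classify_nuclei(labels: LabelVolume, p: NucleiParams):
    """Classify labelled nuclei as hepatic / non-hepatic by diameter.

    Objects below the smallest non-hepatocyte diameter are dropped; in the
    overlap of the two diameter ranges the roundness measure decides
    (round objects are hepatocyte nuclei, elongated ones are not).

    Returns ``(hepatic_mask, non_hepatic_mask, records)``.
    """
    s_nh, b_nh, s_h, b_h = p.require_class_ranges()
    data = labels.data
    spacing = labels.spacing
    voxvol = labels.voxel_volume
    records: list[NucleusRecord] = []
    hep = np.zeros(data.shape, dtype=bool)
    non_hep = np.zeros(data.shape, dtype=bool)
    objects = ndimage.find_objects(data)
    for lab in labels.labels():
        sl = objects[lab - 1]
        obj = data[sl] == lab
        n_vox = int(obj.sum())
        vol = n_vox * voxvol
        diam = (6.0 * vol / np.pi) ** (1.0 / 3.0)
        if diam < s_nh:
            continue  # artificial object, dropped
        in_nh = s_nh <= diam <= b_nh
        in_h = s_h <= diam <= b_h
        rnd = roundness(obj, spacing)
        if in_h and in_nh:
            cls = "hepatic" if rnd >= p.roundness_cutoff else "non_hepatic"
        elif in_h:
            cls = "hepatic"
        elif in_nh:
            cls = "non_hepatic"
        elif diam > max(b_nh, b_h):
            continue  # beyond both ranges: unclassifiable agglomerate, dropped
        else:
            # gap between the two ranges: fall back to the roundness rule
            cls = "hepatic" if rnd >= p.roundness_cutoff else "non_hepatic"
        zz, yy, xx = np.nonzero(obj)
        off = [s.start for s in sl]
        centroid = (
            float((xx.mean() + off[2]) * spacing[0]),
            float((yy.mean() + off[1]) * spacing[1]),
            float((zz.mean() + off[0]) * spacing[2]),
        )
        records.append(NucleusRecord(int(lab), centroid, vol, diam, rnd, cls))
        target = hep if cls == "hepatic" else non_hep
        target[sl][obj] = True
    hep_mask = BinaryMask(hep, spacing, "hepNuclei")
    non_hep_mask = BinaryMask(non_hep, spacing, "non-HepNuclei")
    return hep_mask, non_hep_mask, records


def score_brdu(
    records: list,
    labels: LabelVolume,
    brdu: IntensityVolume,
    intensity_cutoff: float,
) -> list:
    """Flag each nucleus BrdU-positive iff its mean BrdU intensity >= cutoff."""
    check_same_geometry(labels, brdu)
    idx = [r.label for r in records]
    if not idx:
        return records
    means = ndimage.mean(brdu.data.astype(np.float64), labels=labels.data, index=idx)
    for r, m in zip(records, np.atleast_1d(means)):
        r.brdu_positive = bool(m >= intensity_cutoff)
    return records


def records_to_frame(records, dataset_name=""):
    """Tabulate nucleus records (one row per nucleus) for CSV export."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "dataset": dataset_name,
                "label": r.label,
                "centroid_x_um": r.centroid[0],
                "centroid_y_um": r.centroid[1],
                "centroid_z_um": r.centroid[2],
                "volume_um3": r.volume,
                "equivalent_diameter_um": r.equivalent_diameter,
                "roundness": r.roundness,
                "class": r.cls,
                "brdu_positive": r.brdu_positive,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "dataset",
            "label",
            "centroid_x_um",
            "centroid_y_um",
            "centroid_z_um",
            "volume_um3",
            "equivalent_diameter_um",
            "roundness",
            "class",
            "brdu_positive",
        ],
    )
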