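"""Region-level segmentation: necrotic areas and seeded central/portal veins.

The necrotic pipeline works on the DMs channel (the secondary antibody binds
dead-cell areas; the DPPIV channel is used for visualization only).  Vein
segmentation finds the unstained vessel lumina — voxels dark in *all*
provided channels — cleans them morphologically, and keeps only the
26-connected components selected by user-placed seed points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import BinaryMask, IntensityVolume, KernelSpec, check_same_geometry
from .morphops import (
    CONN26,
    ThresholdSpec,
    apply_threshold,
    drop_small_objects,
    open_close,
)


@dataclass
class NecroticParams:
    """Necrotic-region pipeline parameters.

    Guidance from the protocol: ``dilate1`` roughly twice ``erode1`` (noise
    removal plus closing of small cavities), ``erode2`` slightly larger than
    the sinusoid radius so the sinusoidal network is erased, ``dilate2``
    restoring the lesion extent, then a volume filter.
    """

    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    erode1: KernelSpec = field(default_factory=lambda: KernelSpec((1, 1, 1)))
    dilate1: KernelSpec = field(default_factory=lambda: KernelSpec((2, 2, 1)))
    erode2: KernelSpec = field(default_factory=lambda: KernelSpec((4, 4, 2)))
    dilate2: KernelSpec = field(default_factory=lambda: KernelSpec((4, 4, 2)))
    min_volume_um3: float = 500.0


def segment_necrotic(
    dms: IntensityVolume,
    dppiv: IntensityVolume | None,
    p: NecroticParams,
    intermediates: dict | None = None,
) -> BinaryMask:
    """Segment the necrotic region from the DMs channel.

    Holes inside the segmented lesion are tolerated; only its boundary is
    used downstream for distance measures.
    """
    if dppiv is not None:
        check_same_geometry(dms, dppiv)
    steps = []
    m = apply_threshold(dms, p.threshold)
    steps.append(("threshold", m))
    m = open_close(m, p.erode1, "erode")
    steps.append(("erode1", m))
    m = open_close(m, p.dilate1, "dilate")
    steps.append(("dilate1", m))
    m = open_close(m, p.erode2, "erode")
    steps.append(("erode2", m))
    m = open_close(m, p.dilate2, "dilate")
    steps.append(("dilate2", m))
    m = drop_small_objects(m, p.min_volume_um3, units="um3")
    steps.append(("drop_small", m))
    if intermediates is not None:
        intermediates.update(steps)
    return m.with_data(m.data, "necroticRegion")


# ---------------------------------------------------------------------------
# Veins


@dataclass
class SeedPoint:
    """A vein seed: 1-based (x, y, z) voxel position and its vein class."""

    position: tuple
    label: str

    def __post_init__(self):
        self.position = tuple(int(c) for c in self.position)
        if len(self.position) != 3 or any(c < 1 for c in self.position):
            raise ValueError(f"seed position must be 1-based (x, y, z), got {self.position}")
        if self.label not in ("central", "portal"):
            raise ValueError(f"seed label must be 'central' or 'portal', got {self.label!r}")

    @property
    def index_zyx(self):
        x, y, z = self.position
        return (z - 1, y - 1, x - 1)


def read_seeds(path) -> list[SeedPoint]:
    """Read a plain-text seed file: one ``x y z label`` per line, '#' comments."""
    seeds = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed seed line: {raw!r} (expected 'x y z label')")
        seeds.append(SeedPoint((int(parts[0]), int(parts[1]), int(parts[2])), parts[3]))
    return seeds


@dataclass
class VeinParams:
    """Seeded vein segmentation parameters.

    ``thresholds`` maps channel names to manual grey-value cut-offs that
    delimit the unstained lumen (a voxel is a lumen candidate when *below*
    the cut-off in every provided channel).  Opening removes attached
    vessels narrower than its radius; closing absorbs intraluminal cells.
    """

    thresholds: dict = field(default_factory=dict)
    opening: KernelSpec = field(default_factory=lambda: KernelSpec((0, 0, 0)))
    closing: KernelSpec = field(default_factory=lambda: KernelSpec((0, 0, 0)))
    seeds: list = field(default_factory=list)

    def __post_init__(self):
        if not self.thresholds:
            raise ValueError("vein segmentation needs at least one channel threshold")
        if not self.seeds:
            raise ValueError("vein segmentation needs at least one seed point")


def segment_veins(
    channels: dict,
    p: VeinParams,
    intermediates: dict | None = None,
):
    """Segment central and portal veins from seeds.

    Returns ``(central, portal)`` binary masks; each is the union of the
    26-connected lumen components selected by its seeds, and nothing else.
    """
    vols = [channels[name] for name in p.thresholds]
    check_same_geometry(*vols)
    ref = vols[0]
    cand = np.ones(ref.shape, dtype=bool)
    for name, thr in p.thresholds.items():
        cand &= channels[name].data < thr
    mask = BinaryMask(cand, ref.spacing, "vein_lumen_candidate")
    steps = [("lumen_candidate", mask)]
    mask = open_close(mask, p.opening, "open")
    steps.append(("opening", mask))
    mask = open_close(mask, p.closing, "close")
    steps.append(("closing", mask))
    if intermediates is not None:
        intermediates.update(steps)

    labels, _ = ndimage.label(mask.data, structure=CONN26)
    selected: dict[str, set] = {"central": set(), "portal": set()}
    comp_of_seed = {}
    for seed in p.seeds:
        idx = seed.index_zyx
        if any(i < 0 or i >= n for i, n in zip(idx, labels.shape)):
            raise ValueError(f"seed {seed.position} ({seed.label}) is outside the volume")
        comp = labels[idx]
        if comp == 0:
            raise ValueError(
                f"seed {seed.position} ({seed.label}) does not fall on a lumen "
                "candidate voxel; adjust thresholds or the seed position"
            )
        selected[seed.label].add(int(comp))
        comp_of_seed[tuple(seed.position)] = int(comp)
    shared = selected["central"] & selected["portal"]
    if shared:
        warnings.warn(
            f"component(s) {sorted(shared)} selected as both central and portal; "
            "they will appear in both masks",
            stacklevel=2,
        )
    central = BinaryMask(
        np.isin(labels, sorted(selected["central"])), ref.spacing, "vein_central"
    )
    portal = BinaryMask(
        np.isin(labels, sorted(selected["portal"])), ref.spacing, "vein_portal"
    )
    return central, portal
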