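"""Joint sinusoid and bile-canaliculi segmentation (60x mouse datasets).

In mouse, DPPIV/CD26 stains both the bile canaliculi (solid sub-micron
tubes) and the sinusoidal endothelium (vessel walls); the DMs secondary
stains the sinusoidal endothelium only.  A voxel must therefore pass the
threshold in *both* channels to count as sinusoidal, and the bile mask is
disambiguated afterwards by subtracting the sinusoid mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinaryMask, IntensityVolume, KernelSpec, check_same_geometry
from .morphops import (
    CavityFillParams,
    ThresholdSpec,
    VotingParams,
    apply_threshold,
    cavity_fill,
    drop_small_objects,
    grey_open,
    median_filter,
    open_close,
    vote_fill,
)


@dataclass
class SinusoidParams:
    threshold_dppiv: ThresholdSpec = field(default_factory=ThresholdSpec)
    threshold_dms: ThresholdSpec = field(default_factory=ThresholdSpec)
    vote: VotingParams = field(default_factory=lambda: VotingParams((1, 1, 1), 2))
    cavity: CavityFillParams = field(default_factory=CavityFillParams)
    close_k: KernelSpec = field(default_factory=lambda: KernelSpec((2, 2, 1)))
    open_k: KernelSpec = field(default_factory=lambda: KernelSpec((0, 0, 0)))
    min_volume_um3: float = 30.0
    necrotic_mask: BinaryMask | None = None


def segment_sinusoids(
    dppiv: IntensityVolume,
    dms: IntensityVolume,
    p: SinusoidParams,
    intermediates: dict | None = None,
) -> BinaryMask:
    """Segment the sinusoidal network.

    Pipeline: per-channel threshold AND -> inverse voting (salt-noise
    removal) -> cavity filling (the stained endothelium encloses an
    unstained lumen which must end up solid, otherwise network parameters
    would be distorted) -> closing + opening -> volume filter.  Voxels
    inside an optional necrotic mask are excluded.
    """
    check_same_geometry(dppiv, dms)
    steps = []
    a = apply_threshold(dppiv, p.threshold_dppiv)
    b = apply_threshold(dms, p.threshold_dms)
    m = a.with_data(a.data & b.data, "sinus_candidate")
    steps.append(("threshold_and", m))
    m = vote_fill(m, p.vote, inverse=True)
    steps.append(("inverse_vote", m))
    m = cavity_fill(m, p.cavity)
    steps.append(("cavity_fill", m))
    m = open_close(m, p.close_k, "close")
    steps.append(("closing", m))
    m = open_close(m, p.open_k, "open")
    steps.append(("opening", m))
    m = drop_small_objects(m, p.min_volume_um3, units="um3")
    steps.append(("drop_small", m))
    if p.necrotic_mask is not None:
        check_same_geometry(m, p.necrotic_mask)
        m = m.with_data(m.data & ~p.necrotic_mask.data, "sinus_minus_necrotic")
        steps.append(("exclude_necrotic", m))
    if intermediates is not None:
        intermediates.update(steps)
    return m.with_data(m.data, "sinus")


@dataclass
class BileParams:
    """Bile-canaliculi parameters.

    Protocol bounds: median/greyscale-opening radii at most 2; the
    gap-closing voting radius should not exceed 2 with a majority below 4;
    the optional opening defaults to radius 0 (skipped).
    """

    median_radius: tuple = (1, 1, 1)
    grey_open_radius: tuple = (1, 1, 0)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    fill_vote: VotingParams = field(default_factory=lambda: VotingParams((1, 1, 1), 2))
    open_k: KernelSpec = field(default_factory=lambda: KernelSpec((0, 0, 0)))
    vote: VotingParams = field(default_factory=lambda: VotingParams((1, 1, 1), 2))
    min_volume_um3: float = 5.0
    # the sinusoid wall's blurred halo also passes the bile threshold; the
    # subtraction therefore uses a slightly dilated sinusoid mask
    sinusoid_margin: KernelSpec = field(default_factory=lambda: KernelSpec((3, 3, 1)))

    def __post_init__(self):
        for name in ("median_radius", "grey_open_radius"):
            r = getattr(self, name)
            if np.isscalar(r):
                r = (int(r),) * 3
            r = tuple(int(v) for v in r)
            if any(v > 2 for v in r):
                raise ValueError(f"{name} must not exceed 2 voxels per axis")
            setattr(self, name, r)
        if any(r > 2 for r in self.fill_vote.radius):
            raise ValueError("gap-closing voting radii should not exceed 2")
        if self.fill_vote.majority >= 4:
            raise ValueError("gap-closing majority value should be smaller than 4")


def segment_bile(
    dppiv: IntensityVolume,
    sinusoid_mask: BinaryMask,
    p: BileParams,
    intermediates: dict | None = None,
) -> BinaryMask:
    """Segment the bile-canaliculi network from the DPPIV channel.

    Pipeline: median + greyscale opening (noise) -> threshold (may differ
    from the sinusoid threshold) -> direct voting (closes sub-voxel gaps so
    network connectivity is preserved) -> optional opening, inverse voting,
    volume filter.  Sinusoid-mask voxels are removed at the end, keeping
    the two networks disjoint.
    """
    check_same_geometry(dppiv, sinusoid_mask)
    steps = []
    v = median_filter(dppiv, p.median_radius)
    steps.append(("median", v))
    v = grey_open(v, p.grey_open_radius)
    steps.append(("grey_open", v))
    m = apply_threshold(v, p.threshold)
    steps.append(("threshold", m))
    m = vote_fill(m, p.fill_vote, inverse=False)
    steps.append(("direct_vote", m))
    m = open_close(m, p.open_k, "open")
    steps.append(("opening", m))
    m = vote_fill(m, p.vote, inverse=True)
    steps.append(("inverse_vote", m))
    m = drop_small_objects(m, p.min_volume_um3, units="um3")
    steps.append(("drop_small", m))
    sin_zone = open_close(sinusoid_mask, p.sinusoid_margin, "dilate")
    m = m.with_data(m.data & ~sin_zone.data, "bile")
    steps.append(("subtract_sinusoid", m))
    if intermediates is not None:
        intermediates.update(steps)
    return m
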