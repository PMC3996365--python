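"""Default parameterizations for the 60x mouse set-up emulated by the phantom.

These are the package's reference parameter tables (the counterpart of a
GUI's pre-filled pipeline forms), calibrated for the default acquisition
geometry (0.207 x 0.207 x 0.54 um voxels, walls ~0.7 um, sinusoid lumina
~1.6 um, bile canaliculi ~0.8 um, nuclei 4-8 um).  Real datasets need the
usual iterative tuning; every value can be overridden per run.

Notes on the choices:

* Thresholds use the adaptive Otsu with a whole-stack sample region, which
  reduces to the global Otsu value.  On a field this small (26 um), smaller
  sample regions can land in structure-free corners where Otsu splits pure
  background noise; a manual threshold is the documented fallback.
* The sinusoid cavity fill uses a radius slightly larger than the lumen
  radius; the closing radius then equals the largest remaining cavity.
* The bile threshold is manual, at roughly the half-maximum between the
  parenchymal background and the canalicular stain after median filtering
  (the bile step may use a different threshold than the sinusoid step).
"""

from __future__ import annotations

from .core import KernelSpec
from .graph import GraphFilterParams
from .morphops import CavityFillParams, ThresholdSpec, VotingParams
from .networks import BileParams, SinusoidParams
from .nuclei import NucleiParams
from .structures import VeinParams

WHOLE_STACK_OTSU = dict(
    mode="adaptive_otsu", region_size=(128, 128, 64), n_samples=4, seed=0
)


def default_sinusoid_params(necrotic_mask=None) -> SinusoidParams:
    return SinusoidParams(
        threshold_dppiv=ThresholdSpec(**WHOLE_STACK_OTSU),
        threshold_dms=ThresholdSpec(**WHOLE_STACK_OTSU),
        vote=VotingParams((1, 1, 1), 2),
        cavity=CavityFillParams((9, 9, 4), 0.7, accelerated=True),
        close_k=KernelSpec((4, 4, 2)),
        open_k=KernelSpec((0, 0, 0)),
        min_volume_um3=30.0,
        necrotic_mask=necrotic_mask,
    )


def default_bile_params() -> BileParams:
    return BileParams(
        median_radius=(1, 1, 0),
        grey_open_radius=(1, 1, 0),
        threshold=ThresholdSpec(mode="manual", manual_value=95),
        fill_vote=VotingParams((1, 1, 1), 2),
        open_k=KernelSpec((0, 0, 0)),
        vote=VotingParams((1, 1, 1), 2),
        min_volume_um3=3.0,
    )


def default_nuclei_params() -> NucleiParams:
    return NucleiParams(
        median_radius=(1, 1, 0),
        grey_open_radius=(0, 0, 0),
        threshold=ThresholdSpec(**WHOLE_STACK_OTSU),
        vote=VotingParams((1, 1, 1), 2),
        cavity=CavityFillParams((2, 2, 1), 0.8),
        close_k=KernelSpec((2, 2, 1)),
        open_k=KernelSpec((2, 2, 1)),
        alpha=1.5,
        smallest_non_hep_diam=3.0,
        biggest_non_hep_diam=5.8,
        smallest_hep_diam=6.1,
        biggest_hep_diam=10.0,
        roundness_cutoff=0.5,
    )


def default_vein_params(seeds) -> VeinParams:
    return VeinParams(
        thresholds={"DPPIV": 18, "DMs": 18},
        opening=KernelSpec((0, 0, 0)),
        closing=KernelSpec((2, 2, 1)),
        seeds=seeds,
    )


def default_graph_filters() -> GraphFilterParams:
    return GraphFilterParams(
        resampling_factor=0.5,
        deadend_min_length=3.0,
        collapse_distance=2.0,
        prune_angle=5.0,
    )


def default_skeleton_grid_um(network_type: str) -> float | None:
    """Isotropic thinning-grid pitch per network type.

    Wide vessels (sinusoids, ~4.6 um across) are thinned at a coarser cubic
    pitch (~a quarter of their diameter) to suppress medial-surface spurs;
    sub-micron bile canaliculi keep the native fine pitch.
    """
    return 0.54 if network_type == "sinusoid" else None
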