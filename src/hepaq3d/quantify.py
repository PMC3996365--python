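"""Lobule-level aggregation: distance fields, zonal profiles, summary table.

Distances are measured from landmark surfaces (central/portal vein or the
necrotic-lesion boundary); proliferating (BrdU-positive) nuclei can then be
profiled against that distance, and all upstream quantifications are
gathered into one tidy summary table per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask
from .graph import NetworkStats


@dataclass
class DistanceField:
    """Per-voxel Euclidean distance (um) to a reference mask; 0 inside it."""

    data: np.ndarray
    spacing: tuple
    reference: str = ""

    def at_position_um(self, pos_xyz):
        """Sample the field at a physical (x, y, z) position (nearest voxel)."""
        x, y, z = pos_xyz
        sx, sy, sz = self.spacing
        idx = (
            int(np.clip(round(z / sz), 0, self.data.shape[0] - 1)),
            int(np.clip(round(y / sy), 0, self.data.shape[1] - 1)),
            int(np.clip(round(x / sx), 0, self.data.shape[2] - 1)),
        )
        return float(self.data[idx])


@dataclass
class ZonalProfile:
    bin_edges: np.ndarray  # um
    totals: np.ndarray
    positives: np.ndarray

    @property
    def fractions(self):
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.totals > 0, self.positives / np.maximum(self.totals, 1), 0.0)
        return f


def distance_field(reference: BinaryMask) -> DistanceField:
    """Anisotropic-spacing-aware Euclidean distance to the mask surface."""
    if not reference.data.any():
        raise ValueError("distance field needs a non-empty reference mask")
    zyx = tuple(reversed(reference.spacing))
    d = ndimage.distance_transform_edt(~reference.data, sampling=zyx)
    return DistanceField(d, reference.spacing, reference.provenance)


def brdu_profile(records, field: DistanceField, bin_width: float) -> ZonalProfile:
    """Fraction of BrdU-positive nuclei per distance bin (centroid-based)."""
    if not records:
        raise ValueError("no nucleus records to profile")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    dists = np.array([field.at_position_um(r.centroid) for r in records])
    flags = np.array([bool(r.brdu_positive) for r in records])
    n_bins = max(int(np.ceil((dists.max() + 1e-9) / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    which = np.minimum((dists / bin_width).astype(int), n_bins - 1)
    totals = np.bincount(which, minlength=n_bins)
    positives = np.bincount(which, weights=flags, minlength=n_bins).astype(int)
    return ZonalProfile(edges, totals, positives)


def summarize_dataset(
    dataset_name: str,
    cell_table: pd.DataFrame | None = None,
    nucleus_records: list | None = None,
    network_stats: dict | None = None,
) -> pd.DataFrame:
    """One row per quantified parameter: mean, SD, n.

    Cells touching the dataset border are excluded from all cell
    statistics.  ``network_stats`` maps network names ('sinusoid', 'bile')
    to :class:`NetworkStats`; missing networks still produce rows with zero
    counts so downstream tables keep a fixed shape.
    """
    rows = []

    def add(parameter, mean, sd=np.nan, n=np.nan, unit=""):
        rows.append(
            {
                "dataset": dataset_name,
                "parameter": parameter,
                "mean": float(mean),
                "sd": float(sd) if np.isfinite(sd) else np.nan,
                "n": n,
                "unit": unit,
            }
        )

    if cell_table is not None and len(cell_table):
        inner = cell_table[~cell_table["touches_border"]]
        add("hepatocyte_count", len(inner), n=len(inner))
        for col, name, unit in [
            ("volume_um3", "hepatocyte_volume", "um^3"),
            ("equivalent_diameter_um", "hepatocyte_diameter", "um"),
            ("contact_frac_sinusoid", "hepatocyte_contact_sinusoid", "%"),
            ("contact_frac_bile", "hepatocyte_contact_bile", "%"),
            ("contact_frac_cell", "hepatocyte_contact_cell", "%"),
        ]:
            if len(inner):
                add(name, inner[col].mean(), inner[col].std(ddof=0), len(inner), unit)
            else:
                add(name, 0.0, 0.0, 0, unit)

    if nucleus_records is not None:
        hep = [r for r in nucleus_records if r.cls == "hepatic"]
        non = [r for r in nucleus_records if r.cls == "non_hepatic"]
        add("hepatic_nuclei_count", len(hep), n=len(hep))
        add("non_hepatic_nuclei_count", len(non), n=len(non))
        flagged = [r for r in nucleus_records if r.brdu_positive is not None]
        if flagged:
            pos = sum(bool(r.brdu_positive) for r in flagged)
            add("brdu_positive_fraction", pos / len(flagged), n=len(flagged))

    for net in ("sinusoid", "bile"):
        s = (network_stats or {}).get(net)
        if s is None:
            s = NetworkStats(network_type=net, dataset=dataset_name)
        add(f"{net}_intersection_nodes", s.n_intersection_nodes)
        add(f"{net}_deadend_branches", s.n_deadend_branches)
        add(f"{net}_first_order_branches", s.n_first_order_branches)
        add(f"{net}_second_order_branches", s.n_second_order_branches)
        add(f"{net}_branch_length", s.branch_length_mean, s.branch_length_sd, unit="um")
        add(f"{net}_radius", s.radius_mean, s.radius_sd, unit="um")
        add(f"{net}_volume_fraction", s.volume_fraction)

    return pd.DataFrame(rows, columns=["dataset", "parameter", "mean", "sd", "n", "unit"])
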