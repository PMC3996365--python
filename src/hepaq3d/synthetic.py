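"""Seeded synthetic phantoms of 3D confocal liver stacks with ground truth.

The generator emulates the staining set-up the analysis pipelines expect
(mouse, 60x): a dark-lumen central vein (plus portal corner veins), a
sinusoidal network stained at the vessel wall in both DPPIV and DMs, a
solid-stained bile-canaliculi network in DPPIV only, DAPI nuclei of two
diameter classes (large round hepatocyte nuclei, smaller elongated
non-hepatocyte nuclei), an optional necrotic blob in DMs, a pericentral GS
shell, and a BrdU channel marking a seeded fraction of nuclei.  Channels
are rendered with soft (partial-volume) edges, then anisotropically
blurred, then corrupted with Gaussian and salt-and-pepper noise.

Everything — geometry, noise — derives from one seeded RNG, and the
complete ground truth (masks, nucleus records, generating network trees)
is returned alongside the channels in the exact containers the pipelines
consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .core import BinaryMask, IntensityVolume, LabelVolume, xyz_to_zyx
from .graph import SpatialGraph
from .nuclei import NucleusRecord, roundness_from_geometry

EDGE_UM = 0.25  # soft-edge (partial volume) ramp width


@dataclass
class VeinSpec:
    central_radius: float = 3.5  # um, lumen radius of the central vein
    portal_radius: float = 2.5  # um, corner portal veins
    include_portal: bool = True


@dataclass
class TubeNetworkSpec:
    """A branching tube tree confined to the stack interior.

    ``wall`` > 0 renders a stained wall (unstained lumen) as for
    sinusoids; ``wall = 0`` renders a solid tube as for bile canaliculi.
    """

    radius: float = 1.6  # um, lumen radius
    wall: float = 0.7  # um, stained wall thickness (0 = solid staining)
    target_junctions: int = 3
    segment_length: tuple = (7.0, 11.0)  # um
    self_separation: float = 7.5  # um between non-adjacent centrelines
    branch_angle: tuple = (45.0, 70.0)  # deg off the parent direction
    sibling_angle: float = 95.0  # deg minimum between sibling branches
    leaf_extension: float = 5.0  # um added to terminal branches when space allows
    max_nodes: int = 40

    @property
    def outer_radius(self):
        return self.radius + self.wall


@dataclass
class NucleiSpec:
    n_hepatic: int = 12
    hepatic_diameter: tuple = (6.5, 8.0)  # um
    hepatic_axis_ratio: tuple = (1.0, 1.2)
    n_non_hepatic: int = 9
    non_hepatic_diameter: tuple = (4.0, 5.2)  # um
    non_hepatic_axis_ratio: tuple = (1.4, 1.8)
    brdu_rate: float = 0.3
    min_gap: float = 0.6  # um clearance between nuclei
    structure_gap: float = 0.4  # um clearance to tubes and veins


@dataclass
class NecrosisSpec:
    radius: float = 6.0  # um
    center: tuple | None = None  # (x, y, z) um; default: near the central vein


@dataclass
class NoiseSpec:
    gaussian_sigma: float = 6.0  # grey levels
    salt_pepper: float = 0.001  # voxel fraction per channel


@dataclass
class BlurSpec:
    sigma_um: tuple = (0.2, 0.2, 0.35)  # (x, y, z)


@dataclass
class PhantomSpec:
    shape: tuple = (128, 128, 64)  # (nx, ny, nz)
    spacing: tuple = (0.207, 0.207, 0.54)
    seed: int = 0
    vein: VeinSpec = field(default_factory=VeinSpec)
    sinusoid: TubeNetworkSpec = field(default_factory=TubeNetworkSpec)
    bile: TubeNetworkSpec = field(
        default_factory=lambda: TubeNetworkSpec(
            radius=0.8,
            wall=0.0,
            target_junctions=2,
            segment_length=(6.0, 9.0),
            self_separation=6.0,
            branch_angle=(40.0, 65.0),
            sibling_angle=70.0,
            leaf_extension=4.0,
            max_nodes=30,
        )
    )
    nuclei: NucleiSpec = field(default_factory=NucleiSpec)
    necrosis: NecrosisSpec | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    blur: BlurSpec | None = field(default_factory=BlurSpec)
    margin: float = 2.0  # um clearance from the stack faces

    @property
    def extent_um(self):
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass
class PhantomTruth:
    vein_central: BinaryMask
    vein_portal: BinaryMask
    sinusoid: BinaryMask
    bile: BinaryMask
    nuclei: LabelVolume
    records: list
    sinusoid_graph: SpatialGraph
    bile_graph: SpatialGraph
    gs: BinaryMask | None = None
    necrotic: BinaryMask | None = None


@dataclass
class Phantom:
    channels: dict  # name -> IntensityVolume (blurred + noisy)
    clean: dict  # name -> IntensityVolume (noise- and blur-free rendering)
    truth: PhantomTruth
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Geometry helpers (all in physical um coordinates, arrays in (z, y, x))


def _grids(spec: PhantomSpec):
    nx_, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    z, y, x = np.meshgrid(
        np.arange(nz) * sz,
        np.arange(ny) * sy,
        np.arange(nx_) * sx,
        indexing="ij",
    )
    return x.astype(np.float32), y.astype(np.float32), z.astype(np.float32)


def _segment_distance_field(X, Y, Z, p, q):
    """Distance from every voxel centre to the segment p-q (um)."""
    d = np.asarray(q, dtype=np.float64) - np.asarray(p, dtype=np.float64)
    L2 = float(np.dot(d, d))
    vx = X - p[0]
    vy = Y - p[1]
    vz = Z - p[2]
    if L2 == 0:
        return np.sqrt(vx**2 + vy**2 + vz**2)
    t = np.clip((vx * d[0] + vy * d[1] + vz * d[2]) / L2, 0.0, 1.0)
    return np.sqrt(
        (vx - t * d[0]) ** 2 + (vy - t * d[1]) ** 2 + (vz - t * d[2]) ** 2
    )


def _seg_seg_distance(p1, q1, p2, q2, n=12):
    """Approximate min distance between two segments (point sampling)."""
    t = np.linspace(0.0, 1.0, n)
    a = np.asarray(p1) + t[:, None] * (np.asarray(q1) - np.asarray(p1))
    b = np.asarray(p2) + t[:, None] * (np.asarray(q2) - np.asarray(p2))
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).min())


def _seg_point_distance_xy(p, q, cx, cy):
    """Min distance of segment p-q to the vertical line through (cx, cy)."""
    a = np.array([p[0], p[1]])
    b = np.array([q[0], q[1]])
    c = np.array([cx, cy])
    d = b - a
    L2 = float(np.dot(d, d))
    t = 0.0 if L2 == 0 else float(np.clip(np.dot(c - a, d) / L2, 0.0, 1.0))
    return float(np.linalg.norm(a + t * d - c))


def _rotate_towards(rng, direction, angle_deg):
    """Unit vector at the given angle from ``direction``, random azimuth."""
    d = direction / np.linalg.norm(direction)
    # random vector orthogonal to d
    while True:
        r = rng.normal(size=3)
        r -= np.dot(r, d) * d
        n = np.linalg.norm(r)
        if n > 1e-6:
            r /= n
            break
    ang = np.deg2rad(angle_deg)
    return np.cos(ang) * d + np.sin(ang) * r


def _grow_tree(rng, spec: TubeNetworkSpec, lo, hi, vein_axes, avoid_segs, avoid_sep):
    """Grow one branching tube tree; returns (nodes, edges, segments).

    Nodes are um positions; a node with two children (plus parent) is a
    junction.  Candidate segments are rejected if they leave the interior
    box, come closer than ``self_separation`` to a non-adjacent own
    segment, closer than ``avoid_sep`` to another network, or touch a vein.
    """
    lmin, lmax = spec.segment_length

    def ok(p, q, nid, nodes, edges):
        if np.any(q < lo) or np.any(q > hi):
            return False
        for cx, cy, r in vein_axes:
            if _seg_point_distance_xy(p, q, cx, cy) < r + spec.outer_radius + 0.8:
                return False
        ring = {nid} | {i for (i, j) in edges if j == nid} | {
            j for (i, j) in edges if i == nid
        }
        mid = 0.5 * (np.asarray(p) + np.asarray(q))
        for (i, j) in edges:
            if i == nid or j == nid:
                continue  # segments meeting at the growth node may touch
            if i in ring or j in ring:
                # one node away: only the far half of the candidate matters
                if _seg_seg_distance(mid, q, nodes[i], nodes[j]) < spec.self_separation:
                    return False
            elif _seg_seg_distance(p, q, nodes[i], nodes[j]) < spec.self_separation:
                return False
        for (a, b) in avoid_segs:
            if _seg_seg_distance(p, q, a, b) < avoid_sep:
                return False
        return True

    best = ([], [], -1)
    for attempt in range(80):
        root = rng.uniform(lo + 0.15 * (hi - lo), hi - 0.15 * (hi - lo))
        nodes = [root]
        edges = []
        junctions = 0
        trunk_dir = _rotate_towards(rng, rng.normal(size=3), 0.0)
        tips = [(0, trunk_dir, 0)]  # (node id, direction, depth)
        while tips and len(nodes) < spec.max_nodes:
            nid, dirn, depth = tips.pop(0)
            branch = junctions < spec.target_junctions and depth >= 1
            n_children = 2 if branch else 1
            if not branch and depth >= 3:
                continue  # terminate this path -> leaf
            placed = []
            for c in range(n_children):
                for _ in range(30):
                    if n_children == 2:
                        ang = rng.uniform(*spec.branch_angle)
                    else:
                        ang = rng.uniform(0.0, 25.0)
                    nd = _rotate_towards(rng, dirn, ang)
                    # siblings must diverge, or their tubes would fuse
                    if any(float(np.dot(nd, sd)) > np.cos(np.deg2rad(spec.sibling_angle))
                           for _, sd in placed):
                        continue
                    L = rng.uniform(lmin, lmax)
                    q = nodes[nid] + L * nd
                    if ok(nodes[nid], q, nid, nodes, edges):
                        nodes.append(q)
                        new_id = len(nodes) - 1
                        edges.append((nid, new_id))
                        placed.append((new_id, nd))
                        break
            if n_children == 2 and len(placed) == 2:
                junctions += 1
            for new_id, nd in placed:
                tips.append((new_id, nd, depth + 1))
        if junctions > best[2] or (junctions == best[2] and len(edges) > len(best[1])):
            best = (nodes, edges, junctions)
        if junctions >= spec.target_junctions:
            break
    else:
        nodes, edges, _ = best
    # extend terminal branches where space allows, so planted dead-ends sit
    # well above the skeleton tip-retraction scale (~tube radius)
    if spec.leaf_extension > 0 and edges:
        degree = {}
        for i, j in edges:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        for leaf, d in sorted(degree.items()):
            if d != 1:
                continue
            parent = next(i if j == leaf else j for i, j in edges if leaf in (i, j))
            dirn = nodes[leaf] - nodes[parent]
            dirn = dirn / np.linalg.norm(dirn)
            for frac in (1.0, 0.6, 0.3):
                q = nodes[leaf] + frac * spec.leaf_extension * dirn
                if ok(nodes[leaf], q, leaf, nodes, edges):
                    nodes[leaf] = q
                    break
    return nodes, edges


def _tree_to_graph(nodes, edges, radius, network_type, spacing):
    g = nx.Graph()
    for i, p in enumerate(nodes):
        g.add_node(i, pos=np.asarray(p, dtype=np.float64), radius=float(radius))
    g.add_edges_from(edges)
    return SpatialGraph(g, network_type, spacing)


def _soft_ge(d, r):
    """Soft indicator of d <= r with an EDGE_UM-wide ramp (1 inside)."""
    return np.clip((r + EDGE_UM / 2 - d) / EDGE_UM, 0.0, 1.0)


def _soft_shell(d, r_in, r_out):
    return _soft_ge(d, r_out) * np.clip((d - (r_in - EDGE_UM / 2)) / EDGE_UM, 0.0, 1.0)


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _ellipsoid_area(a, b, c):
    """Thomsen's approximation of the ellipsoid surface area (semi-axes)."""
    p = 1.6075
    return 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)


# ---------------------------------------------------------------------------


def generate(spec: PhantomSpec) -> Phantom:
    """Render a phantom and its complete ground truth (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    ex, ey, ez = spec.extent_um
    lo = np.array([spec.margin] * 3, dtype=np.float64)
    hi = np.array([ex - spec.margin, ey - spec.margin, ez - spec.margin])
    shape_zyx = xyz_to_zyx(spec.shape)
    X, Y, Z = _grids(spec)

    # --- veins (vertical cylinders; lumen is unstained in every channel)
    cx, cy = ex / 2.0, ey / 2.0
    vein_axes = [(cx, cy, spec.vein.central_radius)]
    cv_d = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    central = cv_d <= spec.vein.central_radius
    portal = np.zeros(shape_zyx, dtype=bool)
    if spec.vein.include_portal:
        for px, py in ((0.0, 0.0), (ex, 0.0), (0.0, ey), (ex, ey)):
            vein_axes.append((px, py, spec.vein.portal_radius))
            portal |= np.sqrt((X - px) ** 2 + (Y - py) ** 2) <= spec.vein.portal_radius
    lumen = central | portal
    lumen_soft = np.maximum(
        _soft_ge(cv_d, spec.vein.central_radius),
        np.zeros(shape_zyx, dtype=np.float32),
    )
    if spec.vein.include_portal:
        for px, py, in ((0.0, 0.0), (ex, 0.0), (0.0, ey), (ex, ey)):
            pv_d = np.sqrt((X - px) ** 2 + (Y - py) ** 2)
            lumen_soft = np.maximum(lumen_soft, _soft_ge(pv_d, spec.vein.portal_radius))

    # --- tube networks
    sin_nodes, sin_edges = _grow_tree(rng, spec.sinusoid, lo, hi, vein_axes, [], 0.0)
    sin_segs = [(sin_nodes[i], sin_nodes[j]) for i, j in sin_edges]
    bile_nodes, bile_edges = _grow_tree(
        rng, spec.bile, lo, hi, vein_axes, sin_segs,
        spec.sinusoid.outer_radius + spec.bile.outer_radius + 1.5,
    )
    bile_segs = [(bile_nodes[i], bile_nodes[j]) for i, j in bile_edges]

    big = np.float32(1e9)
    sin_d = np.full(shape_zyx, big, dtype=np.float32)
    for p, q in sin_segs:
        np.minimum(sin_d, _segment_distance_field(X, Y, Z, p, q), out=sin_d)
    bile_d = np.full(shape_zyx, big, dtype=np.float32)
    for p, q in bile_segs:
        np.minimum(bile_d, _segment_distance_field(X, Y, Z, p, q), out=bile_d)

    sin_mask = sin_d <= spec.sinusoid.outer_radius
    bile_mask = bile_d <= spec.bile.outer_radius

    # --- necrosis
    nec_mask = None
    nec_soft = None
    if spec.necrosis is not None:
        c = spec.necrosis.center
        if c is None:
            c = (cx + spec.vein.central_radius + spec.necrosis.radius + 1.0, cy, ez / 2)
        nd = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        nec_mask = nd <= spec.necrosis.radius
        nec_soft = _soft_ge(nd, spec.necrosis.radius)

    # --- nuclei (random ellipsoids, rejection-placed clear of everything)
    ns = spec.nuclei
    placed = []  # (center, semi_axes(3), R, cls, brdu)
    classes = ["hepatic"] * ns.n_hepatic + ["non_hepatic"] * ns.n_non_hepatic
    for cls in classes:
        dlo, dhi = ns.hepatic_diameter if cls == "hepatic" else ns.non_hepatic_diameter
        rlo, rhi = (
            ns.hepatic_axis_ratio if cls == "hepatic" else ns.non_hepatic_axis_ratio
        )
        for _ in range(1500):
            diam = rng.uniform(dlo, dhi)
            ratio = rng.uniform(rlo, rhi)
            # semi-axes (a, b, b) with a/b = ratio, preserving the volume
            b = (diam / 2.0) / ratio ** (1.0 / 3.0)
            a = b * ratio
            R = _random_rotation(rng)
            rmax = a
            c = rng.uniform(lo + rmax, hi - rmax)
            if any(
                np.linalg.norm(c - pc) < rmax + pax[0] + ns.min_gap
                for pc, pax, *_ in placed
            ):
                continue
            if any(
                _seg_seg_distance(c, c, p, q)
                < spec.sinusoid.outer_radius + rmax + ns.structure_gap
                for p, q in sin_segs
            ):
                continue
            if any(
                _seg_seg_distance(c, c, p, q)
                < spec.bile.outer_radius + rmax + ns.structure_gap
                for p, q in bile_segs
            ):
                continue
            if any(
                _seg_point_distance_xy(c, c, ax, ay) < r + rmax + ns.structure_gap
                for ax, ay, r in vein_axes
            ):
                continue
            if nec_mask is not None and spec.necrosis is not None:
                ncn = spec.necrosis.center or (
                    cx + spec.vein.central_radius + spec.necrosis.radius + 1.0,
                    cy,
                    ez / 2,
                )
                if (
                    np.linalg.norm(c - np.asarray(ncn))
                    < spec.necrosis.radius + rmax + ns.min_gap
                ):
                    continue
            brdu = bool(rng.uniform() < ns.brdu_rate)
            placed.append((c, np.array([a, b, b]), R, cls, brdu))
            break

    labels = np.zeros(shape_zyx, dtype=np.int32)
    dapi_soft = np.zeros(shape_zyx, dtype=np.float32)
    brdu_soft = np.zeros(shape_zyx, dtype=np.float32)
    records = []
    sx, sy, sz = spec.spacing
    for k, (c, ax, R, cls, brdu) in enumerate(placed, start=1):
        rmax = ax[0] + EDGE_UM
        zi = slice(
            max(int((c[2] - rmax) / sz), 0), min(int((c[2] + rmax) / sz) + 2, shape_zyx[0])
        )
        yi = slice(
            max(int((c[1] - rmax) / sy), 0), min(int((c[1] + rmax) / sy) + 2, shape_zyx[1])
        )
        xi = slice(
            max(int((c[0] - rmax) / sx), 0), min(int((c[0] + rmax) / sx) + 2, shape_zyx[2])
        )
        dx = X[zi, yi, xi] - c[0]
        dy = Y[zi, yi, xi] - c[1]
        dz = Z[zi, yi, xi] - c[2]
        u = R[0, 0] * dx + R[1, 0] * dy + R[2, 0] * dz
        v = R[0, 1] * dx + R[1, 1] * dy + R[2, 1] * dz
        w = R[0, 2] * dx + R[1, 2] * dy + R[2, 2] * dz
        # pseudo-distance to the ellipsoid surface for the soft edge
        rho = np.sqrt((u / ax[0]) ** 2 + (v / ax[1]) ** 2 + (w / ax[2]) ** 2)
        reff = (ax[0] * ax[1] * ax[2]) ** (1.0 / 3.0)
        pd = (rho - 1.0) * reff
        inside = pd <= 0
        labels[zi, yi, xi][inside] = k
        soft = np.clip((EDGE_UM / 2 - pd) / EDGE_UM, 0.0, 1.0).astype(np.float32)
        np.maximum(dapi_soft[zi, yi, xi], soft, out=dapi_soft[zi, yi, xi])
        if brdu:
            np.maximum(brdu_soft[zi, yi, xi], soft, out=brdu_soft[zi, yi, xi])
        vol = 4.0 / 3.0 * np.pi * ax[0] * ax[1] * ax[2]
        records.append(
            NucleusRecord(
                label=k,
                centroid=(float(c[0]), float(c[1]), float(c[2])),
                volume=float(vol),
                equivalent_diameter=float((6.0 * vol / np.pi) ** (1.0 / 3.0)),
                roundness=roundness_from_geometry(vol, _ellipsoid_area(*ax)),
                cls=cls,
                brdu_positive=brdu,
            )
        )

    # --- GS: pericentral shell (~two hepatocyte layers around the CV)
    gs_shell = (cv_d > spec.vein.central_radius) & (
        cv_d <= spec.vein.central_radius + 9.0
    )
    gs_soft = _soft_shell(cv_d, spec.vein.central_radius, spec.vein.central_radius + 9.0)

    # --- compose clean channels
    sin_wall = _soft_shell(sin_d, spec.sinusoid.radius, spec.sinusoid.outer_radius)
    if spec.bile.wall > 0:
        bile_stain = _soft_shell(bile_d, spec.bile.radius, spec.bile.outer_radius)
    else:
        bile_stain = _soft_ge(bile_d, spec.bile.outer_radius)
    sin_lumen = _soft_ge(sin_d, spec.sinusoid.radius)

    def compose(bg, layers, dark=None):
        out = np.full(shape_zyx, float(bg), dtype=np.float32)
        for soft, value in layers:
            np.maximum(out, soft * value, out=out)
        if dark is not None:
            for soft, value in dark:
                out = out * (1 - soft) + value * soft
        return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)

    dark_vein = [(lumen_soft, 3.0)]
    clean = {
        "DPPIV": compose(
            25, [(sin_wall, 200.0), (bile_stain, 190.0)],
            dark=[(sin_lumen * (1 - sin_wall), 8.0)] + dark_vein,
        ),
        "DMs": compose(
            25,
            [(sin_wall, 200.0)] + ([(nec_soft, 180.0)] if nec_soft is not None else []),
            dark=[(sin_lumen * (1 - sin_wall), 8.0)] + dark_vein,
        ),
        "DAPI": compose(8, [(dapi_soft, 200.0)], dark=dark_vein),
        "GS": compose(10, [(gs_soft, 150.0)], dark=dark_vein),
        "BrdU": compose(5, [(brdu_soft, 180.0)], dark=dark_vein),
    }

    # --- blur + noise
    channels = {}
    sigma_vox = (
        None
        if spec.blur is None
        else tuple(
            s / sp for s, sp in zip(xyz_to_zyx(spec.blur.sigma_um), xyz_to_zyx(spec.spacing))
        )
    )
    for name, img in clean.items():
        out = img.astype(np.float32)
        if sigma_vox is not None and any(s > 0 for s in sigma_vox):
            out = ndimage.gaussian_filter(out, sigma=sigma_vox)
        if spec.noise.gaussian_sigma > 0:
            out = out + rng.normal(0.0, spec.noise.gaussian_sigma, size=out.shape)
        out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
        if spec.noise.salt_pepper > 0:
            u = rng.uniform(size=out.shape)
            out[u < spec.noise.salt_pepper / 2] = 0
            out[u > 1 - spec.noise.salt_pepper / 2] = 255
        channels[name] = IntensityVolume(out, spec.spacing, name)

    clean_vols = {n: IntensityVolume(img, spec.spacing, n) for n, img in clean.items()}
    truth = PhantomTruth(
        vein_central=BinaryMask(central, spec.spacing, "vein_central_truth"),
        vein_portal=BinaryMask(portal, spec.spacing, "vein_portal_truth"),
        sinusoid=BinaryMask(sin_mask, spec.spacing, "sinus_truth"),
        bile=BinaryMask(bile_mask & ~sin_mask, spec.spacing, "bile_truth"),
        nuclei=LabelVolume(labels, spec.spacing, "nuclei_truth"),
        records=records,
        sinusoid_graph=_tree_to_graph(
            sin_nodes, sin_edges, spec.sinusoid.outer_radius, "sinusoid", spec.spacing
        ),
        bile_graph=_tree_to_graph(
            bile_nodes, bile_edges, spec.bile.outer_radius, "bile", spec.spacing
        ),
        gs=BinaryMask(gs_shell, spec.spacing, "gs_truth"),
        necrotic=(
            BinaryMask(nec_mask, spec.spacing, "necroticRegion_truth")
            if nec_mask is not None
            else None
        ),
    )
    return Phantom(channels=channels, clean=clean_vols, truth=truth, spec=spec)
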