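"""Pipeline configuration, the ``.ias`` dataset manifest, and the job runner.

A pipeline run is described by a small YAML file (the CLI counterpart of an
interactive parameter table): the pipeline name, its input files (directly
or through an ``.ias`` manifest mapping dataset roles to paths), an output
prefix, and the parameter map.  Unknown keys are rejected up front, every
filter stage writes an intermediate mask named after the filter, and a job
queue is simply an ordered list of config files executed sequentially.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import (
    DEFAULT_SPACING_60X,
    BinaryMask,
    KernelSpec,
    read_mask,
    read_stack,
    write_mask,
    write_stack,
)
from .cellshape import CellShapeParams, analyze_cells, approximate_cells
from .graph import (
    GraphFilterParams,
    analyze_network,
    apply_filters,
    skeleton_to_graph,
    skeletonize,
    write_graph,
)
from .morphops import CavityFillParams, ThresholdSpec, VotingParams
from .networks import BileParams, SinusoidParams, segment_bile, segment_sinusoids
from .nuclei import (
    NucleiParams,
    classify_nuclei,
    records_to_frame,
    score_brdu,
    segment_nuclei,
)
from .preprocess import ClaheParams, CropBounds, clahe, crop
from .structures import (
    NecroticParams,
    VeinParams,
    read_seeds,
    segment_necrotic,
    segment_veins,
)
from .synthetic import PhantomSpec, generate

PIPELINES = (
    "clahe",
    "crop",
    "segment_necrotic",
    "segment_veins",
    "segment_networks",
    "segment_nuclei",
    "extract_graph",
    "approximate_cells",
    "analyze_cells",
    "synth",
)

_COMMON_KEYS = {"pipeline", "inputs", "ias", "params", "output_prefix", "dataset_name", "spacing"}


@dataclass
class PipelineConfig:
    pipeline: str
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    output_prefix: str = "out"
    dataset_name: str = ""
    spacing: tuple = DEFAULT_SPACING_60X

    def __post_init__(self):
        if self.pipeline not in PIPELINES:
            raise ValueError(
                f"unknown pipeline {self.pipeline!r}; expected one of {PIPELINES}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)


def read_ias(path) -> dict:
    """Read an ``.ias`` dataset file list: ``role: path`` per line."""
    roles = {}
    base = Path(path).parent
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"malformed .ias line: {raw!r} (expected 'role: path')")
        role, p = (s.strip() for s in line.split(":", 1))
        roles[role] = str((base / p).resolve())
    return roles


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "pipeline" not in raw:
        raise ValueError(f"{path}: config must be a mapping with a 'pipeline' key")
    unknown = set(raw) - _COMMON_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    inputs = dict(raw.get("inputs") or {})
    if "ias" in raw:
        manifest = read_ias(Path(path).parent / raw["ias"])
        manifest.update(inputs)
        inputs = manifest
    return PipelineConfig(
        pipeline=raw["pipeline"],
        inputs=inputs,
        params=dict(raw.get("params") or {}),
        output_prefix=str(raw.get("output_prefix", "out")),
        dataset_name=str(raw.get("dataset_name", "")),
        spacing=tuple(raw.get("spacing", DEFAULT_SPACING_60X)),
    )


# --- parameter-map helpers -------------------------------------------------


def _threshold_from(d) -> ThresholdSpec:
    if d is None:
        return ThresholdSpec()
    if isinstance(d, (int, float)):
        return ThresholdSpec(mode="manual", manual_value=int(d))
    return ThresholdSpec(**d)


def _kernel_from(d) -> KernelSpec:
    if d is None:
        return KernelSpec((0, 0, 0))
    if isinstance(d, (list, tuple)):
        return KernelSpec(tuple(d))
    return KernelSpec(**d)


def _vote_from(d) -> VotingParams:
    return VotingParams() if d is None else VotingParams(**d)


def _cavity_from(d) -> CavityFillParams:
    return CavityFillParams() if d is None else CavityFillParams(**d)


def _build(params, spec_map, cls):
    """Instantiate a params dataclass from a config mapping with converters."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(params) - known
    if unknown:
        raise ValueError(f"unknown parameter(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in params.items():
        conv = spec_map.get(key)
        kwargs[key] = conv(value) if conv else value
    return cls(**kwargs)


def _write_intermediates(intermediates, prefix: Path):
    for name, obj in intermediates.items():
        if isinstance(obj, BinaryMask):
            write_mask(obj, prefix.with_name(prefix.name + f"_{name}"), "_bin")
        else:
            write_stack(obj, prefix.with_name(prefix.name + f"_{name}.tif"))


# --- runner ----------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig, out_dir, force=False) -> dict:
    """Execute one configured pipeline; returns a manifest of written files.

    Outputs land under ``out_dir`` with the configured prefix.  Existing
    outputs are only overwritten with ``force`` (move old results to a
    subdirectory instead of clobbering them).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = out_dir / cfg.output_prefix
    log_path = prefix.with_name(prefix.name + "_log.json")
    if log_path.exists() and not force:
        raise FileExistsError(
            f"{log_path} exists; re-running would overwrite previous results "
            "(pass force=True / --force, or move old results to a subdirectory)"
        )
    t0 = time.time()
    written = _dispatch(cfg, prefix)
    log = {
        "pipeline": cfg.pipeline,
        "dataset_name": cfg.dataset_name,
        "version": __version__,
        "params": _jsonable(cfg.params),
        "inputs": cfg.inputs,
        "spacing": list(cfg.spacing),
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": [str(p) for p in written],
    }
    log_path.write_text(json.dumps(log, indent=2))
    return {"log": log_path, "outputs": written}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _load_channel(cfg, role):
    if role not in cfg.inputs:
        raise ValueError(f"pipeline {cfg.pipeline!r} needs input {role!r}")
    return read_stack(cfg.inputs[role], cfg.spacing, role)


def _load_mask(cfg, role):
    if role not in cfg.inputs:
        raise ValueError(f"pipeline {cfg.pipeline!r} needs input {role!r}")
    return read_mask(cfg.inputs[role], cfg.spacing, role)


def _dispatch(cfg: PipelineConfig, prefix: Path) -> list:
    written = []
    p = dict(cfg.params)

    if cfg.pipeline == "synth":
        spec = PhantomSpec(**p) if p else PhantomSpec()
        phantom = generate(spec)
        for name, vol in phantom.channels.items():
            written.append(write_stack(vol, prefix.with_name(prefix.name + f"_{name}.tif")))
        for name, mask in (
            ("sinus_truth", phantom.truth.sinusoid),
            ("bile_truth", phantom.truth.bile),
            ("vein_central_truth", phantom.truth.vein_central),
            ("vein_portal_truth", phantom.truth.vein_portal),
        ):
            written.append(write_mask(mask, prefix.with_name(prefix.name + f"_{name}")))
        written.extend(
            write_graph(
                phantom.truth.sinusoid_graph, prefix.with_name(prefix.name + "_sinus_truth")
            )
        )
        return written

    if cfg.pipeline == "clahe":
        vol = _load_channel(cfg, "channel")
        params = _build(p, {}, ClaheParams)
        out = clahe(vol, params)
        path = prefix.with_name(prefix.name + "_clahe.tif")
        written.append(write_stack(out, path))
        return written

    if cfg.pipeline == "crop":
        vol = _load_channel(cfg, "channel")
        bounds = CropBounds(**p) if p else CropBounds.full(vol)
        out = crop(vol, bounds)
        written.append(write_stack(out, prefix.with_name(prefix.name + "_cut.tif")))
        return written

    if cfg.pipeline == "segment_necrotic":
        dms = _load_channel(cfg, "dms")
        dppiv = read_stack(cfg.inputs["dppiv"], cfg.spacing) if "dppiv" in cfg.inputs else None
        params = _build(
            p,
            {
                "threshold": _threshold_from,
                "erode1": _kernel_from,
                "dilate1": _kernel_from,
                "erode2": _kernel_from,
                "dilate2": _kernel_from,
            },
            NecroticParams,
        )
        inter = {}
        mask = segment_necrotic(dms, dppiv, params, intermediates=inter)
        _write_intermediates(inter, prefix)
        stem = prefix.with_name("necroticRegion")
        written.append(write_mask(mask, stem, "_bin"))
        written.append(write_mask(mask, stem.with_name("necroticRegion_dms"), "_overlay", dms))
        if dppiv is not None:
            written.append(
                write_mask(mask, stem.with_name("necroticRegion_dppiv"), "_overlay", dppiv)
            )
        return written

    if cfg.pipeline == "segment_veins":
        thresholds = p.get("thresholds")
        if not thresholds:
            raise ValueError("segment_veins needs a 'thresholds' channel->value map")
        channels = {name: _load_channel(cfg, name) for name in thresholds}
        seeds = read_seeds(cfg.inputs["seeds"]) if "seeds" in cfg.inputs else []
        params = VeinParams(
            thresholds=dict(thresholds),
            opening=_kernel_from(p.get("opening")),
            closing=_kernel_from(p.get("closing")),
            seeds=seeds,
        )
        unknown = set(p) - {"thresholds", "opening", "closing"}
        if unknown:
            raise ValueError(f"unknown parameter(s) for segment_veins: {sorted(unknown)}")
        central, portal = segment_veins(channels, params)
        ref = next(iter(channels.values()))
        for name, mask in (("vein_central", central), ("vein_portal", portal)):
            stem = prefix.with_name(name)
            written.append(write_mask(mask, stem, "_bin"))
            written.append(write_mask(mask, stem, "_overlay", ref))
        return written

    if cfg.pipeline == "segment_networks":
        dppiv = _load_channel(cfg, "dppiv")
        dms = _load_channel(cfg, "dms")
        necrotic = (
            _load_mask(cfg, "necroticRegion_bin") if "necroticRegion_bin" in cfg.inputs else None
        )
        sin_params = _build(
            p.get("sinusoid", {}),
            {
                "threshold_dppiv": _threshold_from,
                "threshold_dms": _threshold_from,
                "vote": _vote_from,
                "cavity": _cavity_from,
                "close_k": _kernel_from,
                "open_k": _kernel_from,
            },
            SinusoidParams,
        )
        sin_params.necrotic_mask = necrotic
        bile_params = _build(
            p.get("bile", {}),
            {
                "threshold": _threshold_from,
                "fill_vote": _vote_from,
                "open_k": _kernel_from,
                "vote": _vote_from,
            },
            BileParams,
        )
        unknown = set(p) - {"sinusoid", "bile"}
        if unknown:
            raise ValueError(f"unknown parameter(s) for segment_networks: {sorted(unknown)}")
        inter = {}
        sin = segment_sinusoids(dppiv, dms, sin_params, intermediates=inter)
        _write_intermediates({f"sinus_{k}": v for k, v in inter.items()}, prefix)
        inter = {}
        bile = segment_bile(dppiv, sin, bile_params, intermediates=inter)
        _write_intermediates({f"bile_{k}": v for k, v in inter.items()}, prefix)
        for name, mask in (("sinus", sin), ("bile", bile)):
            stem = prefix.with_name(name)
            written.append(write_mask(mask, stem, "_bin"))
            written.append(write_mask(mask, stem, "_overlay", dppiv))
        return written

    if cfg.pipeline == "segment_nuclei":
        dapi = _load_channel(cfg, "dapi")
        params = _build(
            p,
            {
                "threshold": _threshold_from,
                "vote": _vote_from,
                "cavity": _cavity_from,
                "close_k": _kernel_from,
                "open_k": _kernel_from,
            },
            NucleiParams,
        )
        inter = {}
        labels = segment_nuclei(dapi, params, intermediates=inter)
        _write_intermediates(inter, prefix)
        hep, non_hep, records = classify_nuclei(labels, params)
        if "brdu" in cfg.inputs:
            brdu = _load_channel(cfg, "brdu")
            cutoff = cfg.params.get("brdu_cutoff", 100)
            records = score_brdu(records, labels, brdu, cutoff)
        for name, mask in (("hepNuclei", hep), ("non-HepNuclei", non_hep)):
            stem = prefix.with_name(name)
            written.append(write_mask(mask, stem, "_bin"))
            written.append(write_mask(mask, stem, "_overlay", dapi))
        csv = prefix.with_name(prefix.name + "_nuclei.csv")
        records_to_frame(records, cfg.dataset_name).to_csv(csv, index=False)
        written.append(csv)
        return written

    if cfg.pipeline == "extract_graph":
        network_type = p.get("network_type", "sinusoid")
        mask = _load_mask(cfg, "mask")
        filt = _build(
            {k: v for k, v in p.items() if k != "network_type"}, {}, GraphFilterParams
        )
        skel = skeletonize(mask)
        sg = skeleton_to_graph(skel, mask, network_type)
        sg = apply_filters(sg, filt)
        written.extend(write_graph(sg, prefix.with_name(prefix.name + f"_{network_type}")))
        stats = analyze_network(sg, mask, cfg.dataset_name)
        csv = prefix.with_name(prefix.name + f"_{network_type}_network.csv")
        import pandas as pd

        pd.DataFrame([dataclasses.asdict(stats)]).to_csv(csv, index=False)
        written.append(csv)
        return written

    if cfg.pipeline == "approximate_cells":
        from scipy import ndimage as ndi

        hep = _load_mask(cfg, "hepNuclei_bin")
        markers, _ = ndi.label(hep.data, structure=np.ones((3, 3, 3), dtype=bool))
        from .core import LabelVolume

        nuclei_labels = LabelVolume(markers.astype(np.int32), cfg.spacing, "hepNuclei")
        sin = _load_mask(cfg, "sinus_bin") if "sinus_bin" in cfg.inputs else None
        bile = _load_mask(cfg, "bile_bin") if "bile_bin" in cfg.inputs else None
        necrotic = (
            _load_mask(cfg, "necroticRegion_bin") if "necroticRegion_bin" in cfg.inputs else None
        )
        params = _build(p, {}, CellShapeParams)
        cells = approximate_cells(nuclei_labels, sin, bile, params, necrotic=necrotic)
        stem = prefix.with_name("cellShape")
        cell_mask = BinaryMask(cells.data > 0, cells.spacing, "cellShape")
        written.append(write_mask(cell_mask, stem, "_bin"))
        if "dppiv" in cfg.inputs:
            written.append(write_mask(cell_mask, stem, "_overlay", _load_channel(cfg, "dppiv")))
        np.save(stem.with_name("cellShape_labels.npy"), cells.data)
        table = analyze_cells(cells, sin, bile, cfg.dataset_name)
        csv = prefix.with_name(prefix.name + "_cells.csv")
        table.to_csv(csv, index=False)
        written.append(csv)
        return written

    if cfg.pipeline == "analyze_cells":
        from .core import LabelVolume

        labels = np.load(cfg.inputs["cellShape_labels"])
        cells = LabelVolume(labels.astype(np.int32), cfg.spacing, "cellShape")
        sin = _load_mask(cfg, "sinus_bin") if "sinus_bin" in cfg.inputs else None
        bile = _load_mask(cfg, "bile_bin") if "bile_bin" in cfg.inputs else None
        table = analyze_cells(cells, sin, bile, cfg.dataset_name)
        csv = prefix.with_name(prefix.name + "_cells.csv")
        table.to_csv(csv, index=False)
        written.append(csv)
        return written

    raise ValueError(f"unhandled pipeline {cfg.pipeline!r}")


def run_queue(config_paths, out_dir, force=False, abort_on_error=False) -> list:
    """Run configs sequentially; per-job failures are captured, not raised."""
    statuses = []
    for path in config_paths:
        try:
            cfg = load_config(path)
            run_pipeline(cfg, out_dir, force=force)
            statuses.append({"config": str(path), "status": "ok", "error": ""})
        except Exception as exc:  # noqa: BLE001 - queue isolates job failures
            statuses.append({"config": str(path), "status": "failed", "error": str(exc)})
            if abort_on_error:
                break
    return statuses
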