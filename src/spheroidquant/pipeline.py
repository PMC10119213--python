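"""End-to-end orchestration: simulate/load → segment → zone → quantify →
SNR → report, driven by one config mapping and one global seed.

Per-stage seeds derive from the global seed by fixed offsets so each
stage is individually reproducible; every effective parameter lands in
``run_metadata.json`` and the returned manifest, which together suffice
to re-run the pipeline identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import ImageStack, PixelCalibration
from .events import (assign_event_zones, detect_apoptosis, ingest_mitoses,
                     mann_whitney, summarize, ComparisonResult)
from .image_io import (read_annotations, read_boundaries, read_stack,
                       write_results, write_stack)
from .segmentation import SegmentationParams, segment_stack
from .snr import BackgroundRegion, depth_profile, DEFAULT_SNR_THRESHOLD
from .synthetic import (TREATMENT_DEFAULTS, SimParams, preset,
                        simulate_spheroid, simulate_treatment_pair)
from .zones import (Ellipse, assign_zones, build_zone_map, estimate_boundaries,
                    fit_boundary_ellipse, select_quadrant)

logger = logging.getLogger("spheroidquant")

QUADRANT_SEED_OFFSET = 13
COMPARABLE_METRICS = ("invasion_count", "death_frequency", "max_distance")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """One pipeline run. Exactly one of ``tiff_paths`` / ``simulate_preset``
    must be set."""

    out_dir: Path
    seed: int = 0
    tiff_paths: list = field(default_factory=list)
    calibration: PixelCalibration | None = None
    depth_offset: float = 0.0
    simulate_preset: str | None = None
    sim_overrides: dict = field(default_factory=dict)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    roi_path: Path | None = None
    zone_radii: dict | None = None  # {'core_rim': µm, 'rim_invasion': µm}
    auto_boundaries: bool = False
    central_slice: int | None = None
    restrict_invasion_to_quadrant: bool = True
    annotations_path: Path | None = None
    snr_threshold: float = DEFAULT_SNR_THRESHOLD
    snr_background: tuple | None = None  # (row0, row1, col0, col1)
    time_label: str = ""

    def __post_init__(self) -> None:
        has_tiff = bool(self.tiff_paths)
        has_sim = self.simulate_preset is not None
        if has_tiff == has_sim:
            raise ConfigError("exactly one input mode required: "
                              "tiff_paths or simulate_preset")
        if has_tiff and self.calibration is None:
            raise ConfigError("tiff input requires explicit calibration")
        self.out_dir = Path(self.out_dir)
        if has_tiff and any(Path(p).parent == self.out_dir
                            for p in self.tiff_paths):
            raise ConfigError("output directory must be distinct from input")

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        cfg = dict(cfg)
        cal = cfg.pop("calibration", None)
        if cal is not None:
            cal = PixelCalibration(**cal)
        seg = cfg.pop("segmentation", None)
        seg = SegmentationParams(**seg) if seg else SegmentationParams()
        return cls(calibration=cal, segmentation=seg, **cfg)


def _load_input(config: RunConfig) -> tuple[ImageStack, object, SimParams | None]:
    if config.simulate_preset is not None:
        params = preset(config.simulate_preset, seed=config.seed)
        if config.sim_overrides:
            params = dataclasses.replace(params, **config.sim_overrides)
        if config.simulate_preset == "irradiated":
            # the treated member of a matched control/treated pair
            _, (stack, truth) = simulate_treatment_pair(params,
                                                        **TREATMENT_DEFAULTS)
        else:
            stack, truth = simulate_spheroid(params)
        return stack, truth, params
    volumes = [read_stack(p, config.calibration) for p in config.tiff_paths]
    vox = np.concatenate([v.voxels for v in volumes], axis=0)
    return (ImageStack(voxels=vox, calibration=config.calibration,
                       depth_offset=config.depth_offset), None, None)


def _zone_boundaries(config: RunConfig, stack: ImageStack,
                     params: SimParams | None) -> tuple[Ellipse, Ellipse]:
    if config.roi_path is not None:  # user ROIs always win
        polys = {p.label: p for p in read_boundaries(config.roi_path)}
        missing = {"core_rim", "rim_invasion"} - set(polys)
        if missing:
            raise ConfigError(f"ROI file lacks boundaries: {sorted(missing)}")
        return (fit_boundary_ellipse(polys["core_rim"]),
                fit_boundary_ellipse(polys["rim_invasion"]))
    if config.zone_radii is not None:
        return tuple(_circle_ellipse(stack, config.zone_radii[k])
                     for k in ("core_rim", "rim_invasion"))
    if params is not None and not config.auto_boundaries:
        # simulated scene: boundaries are known radii
        return (_circle_ellipse(stack, params.core_radius),
                _circle_ellipse(stack, params.rim_outer_radius))
    central = config.central_slice
    if central is None:
        central = stack.n_slices // 2
    polys = estimate_boundaries(stack, central)
    return fit_boundary_ellipse(polys[0]), fit_boundary_ellipse(polys[1])


def _circle_ellipse(stack: ImageStack, radius_um: float) -> Ellipse:
    _, h, w = stack.shape
    r_px = radius_um / stack.calibration.xy_size
    return Ellipse(center=((h - 1) / 2.0, (w - 1) / 2.0),
                   semi_major=r_px, semi_minor=r_px, orientation=0.0)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"software_version": __version__, "complete": False,
                      "seed": config.seed}
    try:
        stack, truth, params = _load_input(config)
        manifest["stage"] = "input"
        stack_path = out_dir / "stack.tif"
        write_stack(ImageStack(stack.voxels.astype(np.float32),
                               stack.calibration, stack.depth_offset),
                    stack_path)
        manifest["stack"] = str(stack_path)
        if truth is not None:
            truth.cells.to_csv(out_dir / "ground_truth_cells.csv", index=False)
            truth.fragments.to_csv(out_dir / "ground_truth_fragments.csv",
                                   index=False)
            manifest["ground_truth_cells"] = str(out_dir / "ground_truth_cells.csv")
            manifest["ground_truth_fragments"] = str(
                out_dir / "ground_truth_fragments.csv")

        manifest["stage"] = "segmentation"
        nuclei, fragments = segment_stack(stack, config.segmentation)

        manifest["stage"] = "zones"
        core_rim, rim_inv = _zone_boundaries(config, stack, params)
        zone_map = build_zone_map(core_rim, rim_inv, stack.shape)
        import tifffile

        tifffile.imwrite(out_dir / "zone_map.tif", zone_map.labels,
                         photometric="minisblack")
        manifest["zone_map"] = str(out_dir / "zone_map.tif")
        quadrant = select_quadrant(zone_map, config.seed + QUADRANT_SEED_OFFSET)
        assign_zones(nuclei, zone_map, quadrant,
                     restrict_invasion_to_quadrant=config.restrict_invasion_to_quadrant,
                     calibration=stack.calibration)

        manifest["stage"] = "events"
        events = detect_apoptosis(fragments, stack.calibration)
        assign_event_zones(events, zone_map, quadrant,
                           restrict_invasion_to_quadrant=config.restrict_invasion_to_quadrant)
        mitoses = None
        if config.annotations_path is not None:
            mitoses = ingest_mitoses(read_annotations(config.annotations_path),
                                     zone_map, nuclei, stack.calibration)

        manifest["stage"] = "snr"
        bg = (BackgroundRegion(*config.snr_background)
              if config.snr_background else None)
        profile = depth_profile(stack, bg, config.snr_threshold)

        manifest["stage"] = "summary"
        meta = {
            "seed": config.seed,
            "segmentation": dataclasses.asdict(config.segmentation),
            "quadrant_index": quadrant.index,
            "quadrant_seed": quadrant.seed,
            "restrict_invasion_to_quadrant": config.restrict_invasion_to_quadrant,
            "core_rim_ellipse": dataclasses.asdict(core_rim),
            "rim_invasion_ellipse": dataclasses.asdict(rim_inv),
            "snr_threshold": config.snr_threshold,
            "segmentable_depth_um": profile.segmentable_depth_um,
            "calibration": dataclasses.asdict(stack.calibration),
            "depth_offset": stack.depth_offset,
            "software_version": __version__,
            "input_mode": ("simulate" if config.simulate_preset else "tiff"),
            "preset": config.simulate_preset,
        }
        result = summarize(nuclei, events, mitoses, zone_map, quadrant,
                           stack.calibration, n_slices=stack.n_slices,
                           time_label=config.time_label, metadata=meta)
        result.snr_profile = profile
        manifest.update(write_results(result, out_dir))
        manifest["segmentable_depth_um"] = profile.segmentable_depth_um
        manifest["zone_totals"] = result.zone_totals
        manifest["invasion_max_distance_um"] = result.invasion_max_distance_um
        manifest["death_frequencies"] = result.death_frequencies
        manifest["complete"] = True
    except Exception as exc:
        stage = manifest.get("stage", "setup")
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        manifest["error"] = f"stage {stage}: {exc}"
        _write_manifest(manifest, out_dir)
        raise
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def extract_metric(manifest: dict, metric: str) -> float:
    if metric not in COMPARABLE_METRICS:
        raise ConfigError(f"unknown metric {metric!r}; available: "
                          f"{list(COMPARABLE_METRICS)}")
    try:
        if metric == "invasion_count":
            return float(manifest["zone_totals"]["invasion"])
        if metric == "death_frequency":
            return float(manifest["death_frequencies"]["invasion"])
        return float(manifest["invasion_max_distance_um"])
    except KeyError as exc:
        raise ConfigError(f"manifest lacks metric {metric!r} ({exc}); "
                          f"available metrics: {list(COMPARABLE_METRICS)}")


def compare(manifests_a: list[dict], manifests_b: list[dict], metric: str,
            labels: tuple = ("group_a", "group_b")) -> ComparisonResult:
    """Mann–Whitney comparison of one per-spheroid metric between groups."""
    va = [extract_metric(m, metric) for m in manifests_a]
    vb = [extract_metric(m, metric) for m in manifests_b]
    return mann_whitney(va, vb, labels=labels)
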