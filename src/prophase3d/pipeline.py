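"""End-to-end pipeline: simulate -> segment -> measure -> identify -> spatial."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .identification import assign_karyotype, validate_assignment
from .io import read_stack, write_config, write_labels, write_stack
from .morphometry import measure_all
from .phantom import PhantomConfig, generate_phantom
from .reference import load_reference
from .segmentation import segment_stack
from .spatial import build_spatial_report, plot_neighbor_heatmap

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("prophase3d")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration for a full run; every field has a sensible default.

    ``stack_path`` may point at an existing TIFF; if ``simulate`` is true a
    phantom is generated instead (and written to the output directory).
    """

    out_dir: str = "prophase3d_out"
    simulate: bool = True
    stack_path: str | None = None
    voxel_nm: tuple[float, float, float] | None = None
    seed: int = 0
    coarse: bool = True
    phantom: dict = field(default_factory=dict)
    band: str = "medium"
    connectivity: int = 26
    min_voxels: int | None = None
    denoise: bool = False
    spatial_radius: int = 2
    range_sd: float = 300.0
    strict: bool = False
    expected_count: int = 46
    reference_path: str | None = None
    weights: tuple[float, float, float] = (1.0, 1.0, 0.5)
    template: str = "XY"
    neighbor_cutoff_nm: float = 250.0
    heatmap: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for k, v in out.items():
            if isinstance(v, tuple):
                out[k] = list(v)
        return out


def _phantom_config(config: PipelineConfig) -> PhantomConfig:
    kwargs = dict(config.phantom)
    kwargs.setdefault("seed", config.seed)
    if config.voxel_nm is not None:
        kwargs.setdefault("voxel_nm", tuple(config.voxel_nm))
    if config.coarse:
        return PhantomConfig.coarse(**kwargs)
    return PhantomConfig(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; writes artifacts + a manifest, returns the bundle.

    Stages: simulate (or load) -> segment -> measure -> identify ->
    spatial.  Any stage error is re-raised as :class:`PipelineError` after
    the manifest (with the stages completed so far) is written, so partial
    outputs remain inspectable.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.stack_path is not None and not config.simulate:
        if not Path(config.stack_path).exists():
            raise FileNotFoundError(f"stack not found: {config.stack_path}")

    write_config(config.to_dict(), out / "config.yaml")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "timings_s": {},
        "warnings": [],
    }
    bundle: dict = {}
    reference = load_reference(config.reference_path)

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                manifest["error"] = {"stage": name, "message": str(exc)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise PipelineError(name, exc) from exc
            manifest["stages"].append(name)
            manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)

        return deco

    @stage("simulate")
    def _simulate():
        if config.simulate:
            pcfg = _phantom_config(config)
            stack, truth_labels, truth = generate_phantom(pcfg, reference)
            bundle["stack"] = stack
            bundle["truth_labels"] = truth_labels
            bundle["truth"] = truth
            write_stack(stack, out / "stack.tif")
            write_labels(truth_labels, out / "truth_labels.tif")
            truth.to_csv(out / "truth.csv", index=False)
        else:
            bundle["stack"] = read_stack(config.stack_path, config.voxel_nm)

    @stage("segment")
    def _segment():
        import warnings as _warnings

        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            labels = segment_stack(
                bundle["stack"],
                band=config.band,
                connectivity=config.connectivity,
                min_voxels=config.min_voxels,
                denoise=config.denoise,
                spatial_radius=config.spatial_radius,
                range_sd=config.range_sd,
                expected_count=config.expected_count,
            )
        for w in caught:
            manifest["warnings"].append(str(w.message))
            log.warning("%s", w.message)
        n = len(labels.object_ids())
        if config.strict and config.expected_count and n != config.expected_count:
            raise ValueError(
                f"strict mode: segmentation produced {n} objects, "
                f"expected {config.expected_count}"
            )
        bundle["labels"] = labels
        write_labels(labels, out / "labels.tif")

    @stage("measure")
    def _measure():
        morph = measure_all(bundle["labels"])
        bundle["morphometry"] = morph
        morph.to_csv(out / "morphometry.csv", index=False)

    @stage("identify")
    def _identify():
        assignment = assign_karyotype(
            bundle["morphometry"],
            reference,
            weights=tuple(config.weights),
            template=config.template,
        )
        bundle["assignment"] = assignment
        assignment.table.to_csv(out / "assignment.csv", index=False)
        report = validate_assignment(assignment, bundle["morphometry"], reference)
        bundle["validation"] = report
        (out / "validation.json").write_text(
            json.dumps(
                {
                    "slope_nm3_per_mbp": report.slope,
                    "intercept_nm3": report.intercept,
                    "r_squared": report.r_squared,
                    "relative_volume_error": report.relative_volume_error,
                    "outliers": report.outliers,
                },
                indent=2,
            )
        )

    @stage("spatial")
    def _spatial():
        report = build_spatial_report(
            bundle["labels"],
            bundle["morphometry"],
            assignment=bundle.get("assignment"),
            reference=reference,
            cutoff_nm=config.neighbor_cutoff_nm,
        )
        bundle["spatial"] = report
        report.per_chromosome.to_csv(out / "spatial.csv", index=False)
        report.neighbor_matrix.astype(int).to_csv(out / "neighbors.csv")
        (out / "regressions.json").write_text(
            json.dumps(
                {
                    "neighbor_cutoff_nm": report.neighbor_cutoff_nm,
                    "radius_vs_volume": dict(
                        zip(("slope", "intercept", "r_squared"), report.volume_regression)
                    ),
                    "radius_vs_gene_density": dict(
                        zip(
                            ("slope", "intercept", "r_squared"),
                            report.gene_density_regression,
                        )
                    ),
                },
                indent=2,
            )
        )
        if config.heatmap:
            plot_neighbor_heatmap(report, str(out / "neighbors.png"))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
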