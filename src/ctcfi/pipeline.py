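"""End-to-end pipeline orchestration with a reproducibility manifest.

One validated configuration drives: phantom generation (or volume
loading) -> optional low-dose simulation -> optional denoising -> colon
segmentation -> surface + centerline reconstruction -> filet ring sweep
with curvature fusion -> truth projection and blob detection -> metrics.
Every produced file is recorded in a manifest with its SHA-256 digest, so
a re-run with the same config and seed can be checked for bit-identical
outputs.  The global seed fans out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import detect as det
from . import filet as filet_mod
from . import ldct, segmentation as seg
from .phantom import GroundTruth, PhantomSpec, PolypSpec, make_colon_phantom
from .surface import (compute_vertex_curvature, extract_centerline,
                      reconstruct_surface, save_mesh)
from .volume import CTVolume, load_nifti, save_nifti

_STAGE_SEED_OFFSETS = {"phantom": 0, "ldct": 1000, "detect": 2000}


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    input_path: str | None = None           # load instead of generate
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lumen_radius_mm: float = 9.0
    straight: bool = False
    polyps: list[dict] = Field(default_factory=list)
    fluid_fill_fraction: float = 0.0
    fluid_segments: list[tuple[float, float]] = Field(default_factory=list)
    gravity_axis: str = "+y"


class DoseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    kvp: int = 60
    n_angles: int = 180
    filter_name: str = "hann"
    frequency_scaling: float = 0.641
    enhance: str = "none"                   # none | gaussian | tv


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lambda_pairwise: float = 1.0
    neighborhood: int = 6
    air_threshold_hu: float = -800.0
    fluid_threshold_hu: float = 300.0
    min_component_voxels: int = 100
    grow_fluid: bool = True


class SurfaceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    smooth_voxels: float = 1.0
    curvature_range: float = 0.5


class FiletConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ring_length_mm: float = 20.0
    step_mm: float = 10.0
    cameras: int = 8
    focal_length_mm: float = 10.0


class DetectConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    min_radius_px: float = 3.0
    curvature_cutoff: float = 0.15
    match_iou: float = 0.3


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    dose: DoseConfig = Field(default_factory=DoseConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    surface: SurfaceConfig = Field(default_factory=SurfaceConfig)
    filet: FiletConfig = Field(default_factory=FiletConfig)
    detect: DetectConfig = Field(default_factory=DetectConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")
    config: dict
    stages: list[str] = Field(default_factory=list)
    files: dict[str, str] = Field(default_factory=dict)   # relpath -> sha256
    metrics: dict = Field(default_factory=dict)

    def record(self, out_dir: Path, path: Path) -> None:
        self.files[str(path.relative_to(out_dir))] = _sha256(path)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(json.loads(self.model_dump_json()),
                                   indent=2, sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the configured stages, writing artifacts and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=json.loads(config.model_dump_json()))

    # --- phantom / input ---------------------------------------------------
    truth: GroundTruth | None = None
    try:
        pdir = out_dir / "phantom"
        pdir.mkdir(exist_ok=True)
        if config.phantom.input_path:
            volume = load_nifti(config.phantom.input_path)
        else:
            pc = config.phantom
            kwargs = dict(
                grid_shape=tuple(pc.grid_shape), spacing=tuple(pc.spacing),
                lumen_radius_mm=pc.lumen_radius_mm,
                polyps=[PolypSpec(**p) for p in pc.polyps],
                fluid_fill_fraction=pc.fluid_fill_fraction,
                fluid_segments=[tuple(s) for s in pc.fluid_segments],
                gravity_axis=pc.gravity_axis,
                seed=config.seed + _STAGE_SEED_OFFSETS["phantom"],
            )
            if pc.straight:
                from .phantom import straight_tube_spec
                kwargs.pop("grid_shape")
                kwargs.pop("spacing")
                spec = straight_tube_spec(tuple(pc.grid_shape), tuple(pc.spacing), **kwargs)
            else:
                spec = PhantomSpec(**kwargs)
            volume, truth = make_colon_phantom(spec)
            save_nifti(volume, pdir / "volume.nii")
            save_nifti(CTVolume(truth.colon_mask.astype(np.int16), volume.spacing),
                       pdir / "colon_mask.nii")
            save_nifti(CTVolume(truth.fluid_mask.astype(np.int16), volume.spacing),
                       pdir / "fluid_mask.nii")
            (pdir / "polyps.json").write_text(json.dumps(
                [a.to_json_dict() for a in truth.polyp_annotations], indent=2))
            for f in sorted(pdir.iterdir()):
                manifest.record(out_dir, f)
        manifest.stages.append("phantom")
    except Exception as e:                      # noqa: BLE001
        raise StageError("phantom", e) from e

    # --- dose simulation ---------------------------------------------------
    if config.dose.enabled:
        try:
            ddir = out_dir / "ldct"
            ddir.mkdir(exist_ok=True)
            model = ldct.DoseModel.preset(
                config.dose.kvp, seed=config.seed + _STAGE_SEED_OFFSETS["ldct"])
            volume = ldct.simulate_ldct(volume, model, n_angles=config.dose.n_angles,
                                        filter_name=config.dose.filter_name,
                                        frequency_scaling=config.dose.frequency_scaling)
            if config.dose.enhance != "none":
                volume = ldct.enhance(volume, config.dose.enhance)
            save_nifti(volume, ddir / "volume_ld.nii")
            manifest.record(out_dir, ddir / "volume_ld.nii")
            manifest.stages.append("ldct")
        except Exception as e:                  # noqa: BLE001
            raise StageError("ldct", e) from e

    # --- segmentation ------------------------------------------------------
    try:
        sdir = out_dir / "segment"
        sdir.mkdir(exist_ok=True)
        sc = config.segmentation
        mrf = seg.MRFConfig(lambda_pairwise=sc.lambda_pairwise,
                            neighborhood=sc.neighborhood,
                            air_threshold_hu=sc.air_threshold_hu,
                            fluid_threshold_hu=sc.fluid_threshold_hu,
                            min_component_voxels=sc.min_component_voxels)
        labels = seg.segment_colon(volume, mrf, gravity_axis=config.phantom.gravity_axis,
                                   grow_tagged_fluid=sc.grow_fluid)
        save_nifti(CTVolume(labels.labels.astype(np.int16), volume.spacing),
                   sdir / "labels.nii")
        report = {"air_voxels": int(labels.air_mask.sum()),
                  "fluid_voxels": int(labels.fluid_mask.sum())}
        if truth is not None:
            report["iou_vs_truth"] = seg.iou(truth.colon_mask | truth.fluid_mask,
                                             labels.colon_mask)
        (sdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest.record(out_dir, sdir / "labels.nii")
        manifest.record(out_dir, sdir / "report.json")
        manifest.metrics["segmentation"] = report
        manifest.stages.append("segment")
    except seg.SegmentationFailure as e:
        manifest.metrics["segmentation"] = {"failure": str(e)}
        manifest.stages.append("segment:failed")
        manifest.save(out_dir / "manifest.json")
        return manifest
    except Exception as e:                      # noqa: BLE001
        raise StageError("segment", e) from e

    # --- surface -----------------------------------------------------------
    try:
        udir = out_dir / "surface"
        udir.mkdir(exist_ok=True)
        mesh = reconstruct_surface(labels.colon_mask, volume.spacing,
                                   smooth_voxels=config.surface.smooth_voxels)
        mesh = compute_vertex_curvature(mesh)
        centerline = extract_centerline(labels.colon_mask, volume.spacing)
        save_mesh(mesh, udir / "mesh.ply")
        (udir / "centerline.json").write_text(
            json.dumps(centerline.to_json_dict(), indent=2))
        manifest.record(out_dir, udir / "mesh.ply")
        manifest.record(out_dir, udir / "centerline.json")
        manifest.stages.append("surface")
    except Exception as e:                      # noqa: BLE001
        raise StageError("surface", e) from e

    # --- filet sweep -------------------------------------------------------
    try:
        fdir = out_dir / "filet"
        fdir.mkdir(exist_ok=True)
        fc = config.filet
        frames = filet_mod.sweep_rings(
            mesh, centerline, step_mm=fc.step_mm, ring_length_mm=fc.ring_length_mm,
            k=fc.cameras, focal_length_mm=fc.focal_length_mm,
            truth=truth, curvature_range=config.surface.curvature_range)
        coco = {"images": [], "annotations": []}
        ann_id = 0
        for i, frame in enumerate(frames):
            filet_mod.save_filet_png(frame, fdir / f"frame_{i:03d}.png")
            manifest.record(out_dir, fdir / f"frame_{i:03d}.png")
            coco["images"].append({"id": i, "file_name": f"frame_{i:03d}.png",
                                   "ring_range_mm": list(frame.ring_range)})
            for pid, box in frame.boxes:
                coco["annotations"].append({"id": ann_id, "image_id": i,
                                            "category": "polyp", "polyp_id": pid,
                                            "bbox": list(box)})
                ann_id += 1
        (fdir / "boxes.json").write_text(json.dumps(coco, indent=2, sort_keys=True))
        manifest.record(out_dir, fdir / "boxes.json")
        manifest.stages.append("filet")
    except Exception as e:                      # noqa: BLE001
        raise StageError("filet", e) from e

    # --- detection + evaluation -------------------------------------------
    if config.detect.enabled:
        try:
            ddir2 = out_dir / "detect"
            ddir2.mkdir(exist_ok=True)
            dc = config.detect
            detections = []
            found_polyps: set[int] = set()
            n_fp = 0
            for i, frame in enumerate(frames):
                dets = det.detect_blobs(frame, min_radius_px=dc.min_radius_px,
                                        curvature_cutoff=dc.curvature_cutoff,
                                        frame_id=i)
                detections.extend(dets)
                tboxes = [b for _, b in frame.boxes]
                assignment, _ = det.match_detections(dets, tboxes, dc.match_iou,
                                                     wrap_width=frame.shape[1])
                for d, a in zip(dets, assignment):
                    if a is None:
                        n_fp += 1
                    else:
                        found_polyps.add(frame.boxes[a][0])
            n_truth = len(truth.polyp_annotations) if truth else 0
            report = {
                "n_detections": len(detections),
                "n_truth_polyps": n_truth,
                "polyps_found": sorted(found_polyps),
                "per_polyp_recall": (len(found_polyps) / n_truth) if n_truth else None,
                "false_positives_per_ring": n_fp / max(len(frames), 1),
            }
            (ddir2 / "detections.json").write_text(json.dumps(
                [d.to_json_dict() for d in detections], indent=2, sort_keys=True))
            (ddir2 / "eval.json").write_text(json.dumps(report, indent=2, sort_keys=True))
            manifest.record(out_dir, ddir2 / "detections.json")
            manifest.record(out_dir, ddir2 / "eval.json")
            manifest.metrics["detection"] = report
            manifest.stages.append("detect")
        except Exception as e:                  # noqa: BLE001
            raise StageError("detect", e) from e

    manifest.save(out_dir / "manifest.json")
    return manifest


def convert(in_path: str | Path, out_path: str | Path, kind: str) -> None:
    """Format conversions: dicom->nifti, mask->ply, boxes->csv."""
    in_path, out_path = Path(in_path), Path(out_path)
    if kind == "dicom->nifti":
        from .volume import load_dicom_series
        save_nifti(load_dicom_series(in_path), out_path, dtype=np.float32)
    elif kind == "mask->ply":
        vol = load_nifti(in_path)
        mesh = reconstruct_surface(vol.hu > 0.5, vol.spacing)
        save_mesh(mesh, out_path)
    elif kind == "boxes->csv":
        data = json.loads(in_path.read_text())
        anns = data["annotations"] if isinstance(data, dict) else data
        lines = ["image_id,category,x,y,w,h"]
        for a in anns:
            x, y, w, h = a["bbox"]
            lines.append(f"{a['image_id']},{a.get('category', 'polyp')},{x},{y},{w},{h}")
        out_path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown conversion kind {kind!r}")
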