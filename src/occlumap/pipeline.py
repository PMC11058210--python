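"""End-to-end orchestration: synthetic study from crowns to reconstruction.

``run_pipeline`` executes the full chain on synthetic data — generate a
crown population, normalize poses, project canonical depth maps, train the
desk-scale generator on the mirrored training split, carve a preparation
into a held-out tooth, extract its mask, reconstruct the removed area,
merge, back-project and score — writing every artifact with a JSON
provenance sidecar.  All randomness derives from the single master seed, so
a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import mask as mask_mod
from .evaluation import distance_distribution, relative_mask_area, rmse_vs_truth
from .generator import fit_linear_generator, mirror_augment, split_dataset
from .mask import BinaryMask, MaskThresholds, binarize, boundary_mask
from .normalization import normalize_orientation
from .projection import (
    DepthMap,
    ProjectionConfig,
    backproject,
    canonicalize_cloud_inplane,
    project_depth,
    sample_surface,
)
from .reconstruction import (
    FourierFeatureExtractor,
    LossWeights,
    OptimizerConfig,
    corrupt,
    optimize,
)
from .synthetic import (
    ToothShapeParams,
    carve_preparation,
    default_preparation,
    generate_dataset,
)

log = logging.getLogger("occlumap")

__all__ = ["PipelineConfig", "ToothFrame", "canonical_projection", "run_pipeline"]

_STAGES = ("synth", "project", "fit-generator", "mask", "reconstruct", "evaluate")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic reconstruction run."""

    seed: int = 0
    out_dir: str = "occlumap_run"
    prep_type: str = "a"
    n_dataset: int = 40
    n_test: int = 3
    latent_rank: int = 16
    projection: ProjectionConfig = field(
        default_factory=lambda: ProjectionConfig(resolution=128, n_sample=200_000)
    )
    weights: LossWeights = field(default_factory=LossWeights)
    optimizer: OptimizerConfig = field(
        default_factory=lambda: OptimizerConfig(n_steps=800, n_restarts=3)
    )
    mask_n_z_t: float = 0.25
    stop_after: str | None = None
    mask_override: str | None = None

    def __post_init__(self) -> None:
        if self.stop_after is not None and self.stop_after not in _STAGES:
            raise ValueError(f"stop_after must be one of {_STAGES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "projection" in raw:
            raw["projection"] = ProjectionConfig(**raw["projection"])
        if "weights" in raw:
            raw["weights"] = LossWeights(**raw["weights"])
        if "optimizer" in raw:
            raw["optimizer"] = OptimizerConfig(**raw["optimizer"])
        return cls(**raw)


@dataclass
class ToothFrame:
    """Shared alignment of a tooth and its preparation.

    Captures the normalization rotation, the depth-window shift and the
    in-plane canonicalization worked out on the intact tooth, so that the
    prepared tooth can be projected into exactly the same image frame.
    """

    rotation: np.ndarray
    z_shift: float
    inplane_deg: float
    inplane_center: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        out = np.asarray(points, dtype=float).copy()
        out[:, 2] += self.z_shift
        th = np.radians(self.inplane_deg)
        A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        out[:, :2] = (out[:, :2] - self.inplane_center) @ A.T
        return out


def canonical_projection(
    mesh: trimesh.Trimesh,
    config: ProjectionConfig,
    seed: int = 0,
    n_z_t: float = 0.9,
) -> tuple[DepthMap, trimesh.Trimesh, ToothFrame]:
    """Normalize a crown and project its canonical depth map.

    Returns the map, the normalized mesh, and the frame needed to project
    a derived (prepared) mesh into the same image coordinates.  The buccal
    hint is taken from the mesh's shape parameters when present.
    """
    res = normalize_orientation(mesh, n_z_t=n_z_t)
    hint = None
    bd = mesh.metadata.get("buccal_direction_3d")
    if bd is None:
        params = mesh.metadata.get("tooth_params")
        if isinstance(params, ToothShapeParams):
            bd = np.array([*params.buccal_direction, 0.0])
    if bd is not None:
        hint = tuple((res.rotation @ np.asarray(bd))[:2])
    cloud = sample_surface(res.mesh, config.n_sample, seed=seed)
    z_shift = config.z_norm - cloud.points[:, 2].max()
    pts = cloud.points.copy()
    pts[:, 2] += z_shift
    pts, rot_deg, center = canonicalize_cloud_inplane(pts, buccal_hint=hint)
    dmap = project_depth(pts, config, xy_offset=np.zeros(2))
    frame = ToothFrame(
        rotation=res.rotation,
        z_shift=z_shift,
        inplane_deg=rot_deg,
        inplane_center=center,
    )
    dmap.provenance.update({"seed": seed, "inplane_deg": rot_deg})
    return dmap, res.mesh, frame


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, (ProjectionConfig, LossWeights, OptimizerConfig)):
        return asdict(o)
    return str(o)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the artifact manifest."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.mask_override is not None and not Path(config.mask_override).exists():
        raise FileNotFoundError(
            f"mask override file not found: {config.mask_override}"
        )
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "prep_type": config.prep_type,
        "stages": [],
        "artifacts": [],
    }

    def record(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})
        log.info("stage %s done (%.1fs)", stage, time.time() - t_start)

    def done(stage: str) -> bool:
        return config.stop_after == stage

    # --- synth -----------------------------------------------------------
    meshes = generate_dataset(
        config.n_dataset, seed=int(rng.integers(2**31 - 1))
    )
    record("synth", n_meshes=len(meshes))
    if done("synth"):
        _write_json(out / "manifest.json", manifest)
        return manifest

    # --- normalize + project --------------------------------------------
    proj_seed = int(rng.integers(2**31 - 1))
    maps, norm_meshes, frames = [], [], []
    for i, mesh in enumerate(meshes):
        dmap, nmesh, frame = canonical_projection(
            mesh, config.projection, seed=proj_seed + i
        )
        maps.append(dmap)
        norm_meshes.append(nmesh)
        frames.append(frame)
    record("project", n_maps=len(maps))
    if done("project"):
        _write_json(out / "manifest.json", manifest)
        return manifest

    # --- split + train the generator ------------------------------------
    split_seed = int(rng.integers(2**31 - 1))
    idx_train, idx_test = split_dataset(
        list(range(len(maps))), config.n_test, seed=split_seed
    )
    train_maps = mirror_augment([maps[i] for i in idx_train])
    G = fit_linear_generator(train_maps, config.latent_rank)
    gen_path = out / "generator.npz"
    G.save(gen_path)
    manifest["artifacts"].append(str(gen_path))
    record(
        "fit-generator",
        n_train=len(train_maps),
        n_test=len(idx_test),
        rank=config.latent_rank,
    )
    if done("fit-generator"):
        _write_json(out / "manifest.json", manifest)
        return manifest

    # --- carve the target tooth and extract its mask ---------------------
    target = idx_test[0] if idx_test else 0
    x_true = maps[target]
    nmesh = norm_meshes[target]
    frame = frames[target]
    params = nmesh.metadata.get("tooth_params") or ToothShapeParams()
    # carve in the normalized frame; polygon rotated to follow the pose
    spec = default_preparation(config.prep_type, params)
    poly = np.asarray(spec.cavity_footprint, dtype=float)
    R2 = frame.rotation[:2, :2]
    # re-anchor the cavity in the normalized in-plane frame
    poly_rot = poly @ R2.T
    from dataclasses import replace as _replace

    spec = _replace(spec, cavity_footprint=tuple(map(tuple, poly_rot)))
    prep_mesh, region = carve_preparation(nmesh, spec)
    thresholds = MaskThresholds(
        n_z_t=config.mask_n_z_t, z_t=spec.cavity_floor_z + frame.z_shift + 0.2
    )
    mask_seed = int(rng.integers(2**31 - 1))
    cloud = sample_surface(
        prep_mesh, config.projection.n_sample, seed=mask_seed,
        interpolate_normals=False,
    )
    pts = frame.apply(cloud.points)
    x_prep = project_depth(pts, config.projection, xy_offset=np.zeros(2))
    if config.mask_override is not None:
        mask = BinaryMask.load_png(config.mask_override)
    else:
        from .normalization import OrientedPointCloud

        retained = mask_mod.extract_retained_points(
            OrientedPointCloud(pts, cloud.normals), thresholds
        )
        raw = binarize(
            project_depth(
                retained.points, config.projection, xy_offset=np.zeros(2)
            )
        )
        mask = mask_mod.finalize_mask(raw, footprint=binarize(x_prep))
    x_true.save_png(out / "x_true.png")
    x_prep.save_png(out / "x_prep.png")
    mask.save_png(out / "mask.png")
    manifest["artifacts"] += [
        str(out / "x_true.png"), str(out / "x_prep.png"), str(out / "mask.png")
    ]
    record("mask", removed_px=int(mask.black.sum()))
    if done("mask"):
        _write_json(out / "manifest.json", manifest)
        return manifest

    # --- reconstruct ------------------------------------------------------
    x_cor = corrupt(x_prep.quantized().astype(float), mask)
    M_B = boundary_mask(mask, footprint=binarize(x_prep))
    extractor = FourierFeatureExtractor(config.projection.resolution)
    opt = _replace(config.optimizer, seed=int(rng.integers(2**31 - 1)))
    result = optimize(x_cor, mask, M_B, G, config.weights, opt, extractor)
    x_clean = x_true.copy_with(result.x_clean)
    x_merge = x_true.copy_with(result.x_merged)
    x_clean.save_png(out / "x_clean.png")
    x_merge.save_png(out / "x_merge.png")
    np.savetxt(
        out / "loss_trace.csv",
        result.trace,
        header="loss_per_step",
        comments="",
    )
    merged_mesh = backproject(x_merge, config.projection)
    mesh_path = out / "x_merge_mesh.stl"
    merged_mesh.export(mesh_path)
    manifest["artifacts"] += [
        str(out / "x_clean.png"), str(out / "x_merge.png"),
        str(out / "loss_trace.csv"), str(mesh_path),
    ]
    record(
        "reconstruct",
        n_dr=result.n_dr,
        chosen_restart=result.chosen_restart,
        final_loss=result.final_loss,
    )
    if done("reconstruct"):
        _write_json(out / "manifest.json", manifest)
        return manifest

    # --- evaluate ---------------------------------------------------------
    rmse = rmse_vs_truth(x_merge, x_true)
    rel_area = relative_mask_area(mask, x_true)
    dist = distance_distribution(x_merge, x_true, mask)
    metrics = {
        "rmse_mm": rmse,
        "relative_mask_area": rel_area,
        "p95_distance_mm": dist.cutoff_mm,
        "n_dr": result.n_dr,
        "final_loss": result.final_loss,
        "config": {
            "projection": config.projection,
            "weights": config.weights,
            "optimizer": config.optimizer,
        },
    }
    _write_json(out / "metrics.json", metrics)
    manifest["artifacts"].append(str(out / "metrics.json"))
    record("evaluate", rmse_mm=rmse, relative_mask_area=rel_area)
    _write_json(out / "manifest.json", manifest)
    return manifest
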