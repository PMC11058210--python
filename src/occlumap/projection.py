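"""Calibrated depth-map projection of normalized crown meshes.

A pose-normalized mesh is sampled into an oriented point cloud and
rasterized orthographically onto a square plane parallel to xy.  Pixel
intensity encodes height linearly: 255 corresponds to the top of a global
depth window of ``z_norm`` mm, intensity 0 is background, and points more
than ``z_norm`` below the object's highest point fall out of the window.
The mm-per-intensity calibration ``c_pix_mm = z_norm / 255`` travels with
every map.

Internally depth maps are kept as continuous floats; quantization to 8 bits
happens on export (or explicitly via :meth:`DepthMap.quantized`), so that
downstream optimization does not accumulate double-quantization bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import trimesh

from .normalization import OrientedPointCloud

__all__ = [
    "ProjectionConfig",
    "DepthMap",
    "InPlanePose",
    "sample_surface",
    "normalize_z",
    "project_depth",
    "canonicalize_inplane",
    "canonicalize_cloud_inplane",
    "apply_pose_to_points",
    "downsample_max",
    "projection_rmse_mm",
    "repeatability_ci",
    "backproject",
]


def _check_power_of_two(width: int) -> None:
    if width < 4 or (width & (width - 1)) != 0:
        raise ValueError(
            f"resolution {width} is not a power of two >= 4; the generator "
            "latent layout requires log2(width) to be an integer"
        )


@dataclass
class ProjectionConfig:
    """Geometry of the projection: resolution, plane size and depth window.

    ``plane_size`` must exceed the dataset's maximal xy extent plus twice
    ``contour_offset`` so no crown touches the image border.  The defaults
    (16 mm plane, 8 mm window) comfortably hold a single molar crown.
    """

    resolution: int = 256
    plane_size: float = 16.0
    z_norm: float = 8.0
    n_sample: int = 3_300_000
    contour_offset: float = 1.0
    sampling_seed: int = 0

    def __post_init__(self) -> None:
        _check_power_of_two(self.resolution)
        if self.z_norm <= 0 or self.plane_size <= 0:
            raise ValueError("z_norm and plane_size must be positive")

    @property
    def pixel_size(self) -> float:
        """Side of one pixel in mm."""
        return self.plane_size / self.resolution

    @property
    def c_pix_mm(self) -> float:
        return self.z_norm / 255.0


@dataclass
class DepthMap:
    """Continuous-valued occlusal heightfield image with mm calibration."""

    pixels: np.ndarray  # float, (h, w), background exactly 0
    z_norm: float
    plane_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("depth map must be a square 2D array")
        self.pixels = px

    @property
    def resolution(self) -> int:
        return self.pixels.shape[0]

    @property
    def c_pix_mm(self) -> float:
        return self.z_norm / 255.0

    @property
    def pixel_size(self) -> float:
        return self.plane_size / self.resolution

    def quantized(self) -> np.ndarray:
        """8-bit export view (round half away from zero)."""
        return np.floor(np.clip(self.pixels, 0.0, 255.0) + 0.5).astype(np.uint8)

    def foreground(self) -> np.ndarray:
        return self.quantized() > 0

    def copy_with(self, pixels: np.ndarray) -> "DepthMap":
        return DepthMap(
            pixels=pixels, z_norm=self.z_norm, plane_size=self.plane_size,
            provenance=dict(self.provenance),
        )

    def save_png(self, path: str | Path) -> None:
        from PIL import Image

        path = Path(path)
        Image.fromarray(self.quantized(), mode="L").save(path)
        sidecar = {
            "z_norm_mm": self.z_norm,
            "plane_size_mm": self.plane_size,
            "c_pix_mm": self.c_pix_mm,
            "provenance": _jsonable(self.provenance),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load_png(cls, path: str | Path) -> "DepthMap":
        from PIL import Image

        path = Path(path)
        pixels = np.asarray(Image.open(path).convert("L"), dtype=float)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            pixels=pixels,
            z_norm=meta["z_norm_mm"],
            plane_size=meta["plane_size_mm"],
            provenance=meta.get("provenance", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class InPlanePose:
    """In-plane canonicalization: rotation (deg, image CCW) and shift (px)."""

    angle_deg: float
    translation_px: tuple[float, float]  # (d_col, d_row) moving rect -> center
    center_px: tuple[float, float]  # rotation pivot (col, row)


def sample_surface(
    mesh: trimesh.Trimesh,
    n_sample: int,
    seed: int = 0,
    interpolate_normals: bool = True,
) -> OrientedPointCloud:
    """Area-weighted uniform surface samples with normals.

    Normals are barycentrically interpolated vertex normals by default
    (smooth surfaces); with ``interpolate_normals=False`` each sample
    carries its triangle's face normal, which keeps creases sharp — the
    mask heuristic classifies points by per-triangle normals, so the
    preparation edge is not smeared across the wall/occlusal crease.
    """
    if n_sample <= 0:
        raise ValueError("n_sample must be positive")
    if len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    points, face_idx, bary = trimesh.sample.sample_surface(
        mesh, n_sample, seed=seed, return_barycentric=True
    )
    if interpolate_normals:
        vn = mesh.vertex_normals[mesh.faces[face_idx]]  # (n, 3 verts, 3)
        normals = np.einsum("ij,ijk->ik", bary, vn)
        lens = np.linalg.norm(normals, axis=1, keepdims=True)
        normals = np.divide(normals, np.maximum(lens, 1e-12))
    else:
        normals = mesh.face_normals[face_idx].copy()
    return OrientedPointCloud(np.asarray(points, dtype=float), normals)


def normalize_z(points: np.ndarray, z_norm: float) -> np.ndarray:
    """Shift the cloud so its maximal z equals ``z_norm``; xy untouched."""
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("empty point cloud")
    out = points.copy()
    out[:, 2] += z_norm - points[:, 2].max()
    return out


def project_depth(
    points: np.ndarray,
    config: ProjectionConfig,
    xy_offset: np.ndarray | None = None,
) -> DepthMap:
    """Rasterize a z-normalized cloud into a depth map.

    Each pixel takes the maximum sampled z in its footprint (top-surface
    capture); empty pixels and points at z <= 0 map to background 0.  The
    cloud is centered on the plane unless an explicit ``xy_offset`` is given
    (used to keep a prepared tooth aligned with its intact reference).
    Returns the offset used in the map's provenance.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("empty point cloud")
    w = config.resolution
    L = config.plane_size
    if xy_offset is None:
        lo = points[:, :2].min(axis=0)
        hi = points[:, :2].max(axis=0)
        xy_offset = -(lo + hi) / 2.0
    xy_offset = np.asarray(xy_offset, dtype=float)
    xy = points[:, :2] + xy_offset
    if np.any(np.abs(xy) > L / 2.0):
        raise ValueError(
            "points fall outside the projection plane; increase plane_size"
        )
    px = config.pixel_size
    col = np.clip(np.floor((xy[:, 0] + L / 2.0) / px).astype(int), 0, w - 1)
    row = np.clip(
        w - 1 - np.floor((xy[:, 1] + L / 2.0) / px).astype(int), 0, w - 1
    )
    top = np.zeros((w, w), dtype=float)
    np.maximum.at(top, (row, col), points[:, 2])
    pixels = np.where(top > 0, 255.0 * top / config.z_norm, 0.0)
    pixels = np.clip(pixels, 0.0, 255.0)
    return DepthMap(
        pixels=pixels,
        z_norm=config.z_norm,
        plane_size=L,
        provenance={"xy_offset_mm": xy_offset.tolist()},
    )


def _min_rect_pose(fg: np.ndarray) -> tuple[float, np.ndarray]:
    """Rotation (deg) and center (col, row) of the minimum-area rectangle."""
    rows, cols = np.nonzero(fg)
    if rows.size == 0:
        raise ValueError("empty foreground")
    # skimage convention: integer coordinates are pixel centers
    pts = shapely.multipoints(np.column_stack([cols, rows]).astype(float))
    rect = shapely.minimum_rotated_rectangle(pts)
    coords = shapely.get_coordinates(rect)
    if len(coords) < 4:  # degenerate (line/point) foreground
        return 0.0, np.array([cols.mean(), rows.mean()])
    corners = coords[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    long_edge = e1 if np.linalg.norm(e1) >= np.linalg.norm(e2) else e2
    angle = np.degrees(np.arctan2(long_edge[1], long_edge[0]))
    # wrap so the applied rotation is minimal: long axis -> horizontal
    angle = (angle + 90.0) % 180.0 - 90.0
    center = corners.mean(axis=0)
    return float(angle), center


def canonicalize_inplane(
    dmap: DepthMap,
    buccal_hint: tuple[float, float] | None = None,
) -> tuple[DepthMap, InPlanePose]:
    """Rotate/translate a depth map into the canonical image pose.

    The minimum-area bounding rectangle of the foreground is made
    axis-parallel with its long side horizontal and its center moved to the
    image center.  ``buccal_hint`` — the cheek-facing direction as an (x, y)
    vector in projection-plane mm coordinates — resolves the remaining
    180-degree ambiguity by pointing the buccal side to the bottom half of
    the image; without a hint the minimal rotation is used as is.
    """
    from skimage.transform import AffineTransform, warp

    fg = dmap.foreground()
    angle, rect_center = _min_rect_pose(fg)
    rot = -angle  # rotation applied to the image content
    if buccal_hint is not None:
        hint = np.asarray(buccal_hint, dtype=float)
        img_hint = np.array([hint[0], -hint[1]])  # row axis points down
        th = np.radians(rot)
        A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        if (A @ img_hint)[1] < 0:  # buccal would end up in the top half
            rot += 180.0
    w = dmap.resolution
    img_center = np.array([(w - 1) / 2.0, (w - 1) / 2.0])
    th = np.radians(rot)
    A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    # output = A (input - rect_center) + img_center; warp needs output->input
    tform = AffineTransform(matrix=_affine3(A, img_center - A @ rect_center))
    out = warp(
        dmap.pixels, tform.inverse, order=1, preserve_range=True, cval=0.0
    )
    pose = InPlanePose(
        angle_deg=rot,
        translation_px=tuple(img_center - rect_center),
        center_px=tuple(rect_center),
    )
    new = dmap.copy_with(out)
    new.provenance["inplane_pose"] = {
        "angle_deg": rot,
        "translation_px": list(pose.translation_px),
    }
    return new, pose


def _affine3(A: np.ndarray, t: np.ndarray) -> np.ndarray:
    M = np.eye(3)
    M[:2, :2] = A
    M[:2, 2] = t
    return M


def apply_pose_to_points(
    points: np.ndarray, pose: InPlanePose, dmap: DepthMap
) -> np.ndarray:
    """Apply an image-space canonicalization pose to 3D points.

    Equivalent to re-projecting after rotating the cloud about z, which
    avoids image interpolation: an image rotation by ``angle_deg`` (CCW on
    screen, row axis down) corresponds to a rotation by ``-angle_deg`` about
    +z in mm coordinates.  The xy offset recorded in the map's provenance is
    applied first so points and image live in the same frame; after this
    call, re-project with ``xy_offset=np.zeros(2)``.
    """
    px = dmap.pixel_size
    half = dmap.plane_size / 2.0
    center = np.asarray(pose.center_px, dtype=float)
    pivot = np.array([center[0] * px - half, half - center[1] * px])
    th = np.radians(-pose.angle_deg)
    A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    out = np.asarray(points, dtype=float).copy()
    offset = np.asarray(dmap.provenance.get("xy_offset_mm", (0.0, 0.0)))
    out[:, :2] = (out[:, :2] + offset - pivot) @ A.T
    return out


def downsample_max(dmap: DepthMap, factor: int = 2) -> DepthMap:
    """Reduce resolution by block maximum.

    Because rasterization keeps the maximal sampled height per pixel, the
    block maximum of a fine map equals the map the same point cloud would
    produce on the coarser grid (pixels nest exactly), so resolution
    pyramids stay consistent with the projection model.
    """
    w = dmap.resolution
    if factor < 1 or w % factor:
        raise ValueError("factor must divide the resolution")
    px = dmap.pixels.reshape(w // factor, factor, w // factor, factor)
    out = DepthMap(
        pixels=px.max(axis=(1, 3)),
        z_norm=dmap.z_norm,
        plane_size=dmap.plane_size,
        provenance=dict(dmap.provenance),
    )
    out.provenance["downsampled_by"] = factor
    return out


def canonicalize_cloud_inplane(
    points: np.ndarray,
    buccal_hint: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """In-plane canonicalization applied to the point cloud itself.

    Continuous-coordinate counterpart of :func:`canonicalize_inplane`: the
    minimum-area rectangle of the xy convex hull is rotated to axis-parallel
    (long side along x) about its center, which is moved to the origin.
    Working in mm space avoids image resampling entirely, so repeated runs
    of the same tooth under different initial poses align to sub-pixel
    accuracy.  Returns (points, applied rotation in degrees about +z,
    rect center in mm).  ``buccal_hint`` points the cheek side to -y.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("empty point cloud")
    hull = shapely.convex_hull(shapely.multipoints(points[:, :2]))
    rect = shapely.minimum_rotated_rectangle(hull)
    coords = shapely.get_coordinates(rect)
    if len(coords) < 4:
        raise ValueError("degenerate cloud: cannot fit a bounding rectangle")
    corners = coords[:4]
    e1, e2 = corners[1] - corners[0], corners[2] - corners[1]
    long_edge = e1 if np.linalg.norm(e1) >= np.linalg.norm(e2) else e2
    angle = np.degrees(np.arctan2(long_edge[1], long_edge[0]))
    rot = -((angle + 90.0) % 180.0 - 90.0)
    center = corners.mean(axis=0)
    if buccal_hint is not None:
        hint = np.asarray(buccal_hint, dtype=float)
        th = np.radians(rot)
        A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        if (A @ hint)[1] > 0:  # buccal side must face -y (image bottom)
            rot += 180.0
    th = np.radians(rot)
    A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    out = points.copy()
    out[:, :2] = (out[:, :2] - center) @ A.T
    return out, float(rot), center


def projection_rmse_mm(
    x0: DepthMap, xi: DepthMap, background: str = "include"
) -> float:
    """RMSE between two quantized maps converted to mm.

    ``background='include'`` averages over all pixels (the convention used
    for repeatability and reconstruction scoring); ``'exclude'`` averages
    only over pixels that are foreground in either map.
    """
    if x0.pixels.shape != xi.pixels.shape:
        raise ValueError("resolution mismatch")
    if not np.isclose(x0.z_norm, xi.z_norm):
        raise ValueError("calibration mismatch (different z_norm)")
    d = x0.quantized().astype(float) - xi.quantized().astype(float)
    if background == "include":
        mse = np.mean(d**2)
    elif background == "exclude":
        fg = x0.foreground() | xi.foreground()
        if not fg.any():
            return 0.0
        mse = np.mean(d[fg] ** 2)
    else:
        raise ValueError("background must be 'include' or 'exclude'")
    return float(np.sqrt(mse) * x0.c_pix_mm)


def repeatability_ci(
    mesh: trimesh.Trimesh,
    config: ProjectionConfig,
    n_rep: int = 100,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Confidence interval of the sampling-induced projection RMSE.

    The mesh is projected ``n_rep`` times with distinct sampling seeds; the
    first projection serves as the reference and the mean RMSE of the
    remaining ones against it is interval-estimated with a t distribution.
    """
    from scipy import stats

    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    maps = []
    offset = None
    for i in range(n_rep):
        cloud = sample_surface(mesh, config.n_sample, seed=config.sampling_seed + i)
        pts = normalize_z(cloud.points, config.z_norm)
        dm = project_depth(pts, config, xy_offset=offset)
        if offset is None:
            offset = np.asarray(dm.provenance["xy_offset_mm"])
        maps.append(dm)
    errs = np.array(
        [projection_rmse_mm(maps[0], m) for m in maps[1:]], dtype=float
    )
    mean = float(errs.mean())
    sem = float(errs.std(ddof=1) / np.sqrt(len(errs)))
    if sem == 0.0:
        return mean, mean
    lo, hi = stats.t.interval(confidence, df=len(errs) - 1, loc=mean, scale=sem)
    return float(max(lo, 0.0)), float(hi)


def backproject(dmap: DepthMap, config: ProjectionConfig) -> trimesh.Trimesh:
    """Lift a depth map back to a heightfield mesh.

    One vertex per nonzero pixel at z = intensity * c_pix_mm, triangulated
    over the 4-neighbor grid (two triangles per fully-occupied 2x2 block,
    one per three-quarter block).
    """
    q = dmap.quantized()
    nz = q > 0
    if not nz.any():
        raise ValueError("all-zero depth map cannot be back-projected")
    h, w = q.shape
    px = dmap.pixel_size
    half = dmap.plane_size / 2.0
    rows, cols = np.nonzero(nz)
    ids = -np.ones((h, w), dtype=int)
    ids[rows, cols] = np.arange(rows.size)
    verts = np.column_stack(
        [
            (cols + 0.5) * px - half,
            half - (rows + 0.5) * px,
            q[rows, cols] * dmap.c_pix_mm,
        ]
    )
    a = ids[:-1, :-1]
    b = ids[:-1, 1:]
    c = ids[1:, :-1]
    d = ids[1:, 1:]
    va, vb, vc, vd = (m >= 0 for m in (a, b, c, d))
    faces = []
    full = va & vb & vc & vd
    faces.append(np.column_stack([a[full], c[full], d[full]]))
    faces.append(np.column_stack([a[full], d[full], b[full]]))
    for missing, tri in (
        (~va, (b, c, d)),
        (~vb, (a, c, d)),
        (~vc, (a, d, b)),
        (~vd, (a, c, b)),
    ):
        m = missing & np.all([x >= 0 for x in tri], axis=0) & ~full
        faces.append(np.column_stack([t[m] for t in tri]))
    nonempty = [f for f in faces if len(f)]
    F = np.vstack(nonempty) if nonempty else np.zeros((0, 3), dtype=int)
    mesh = trimesh.Trimesh(vertices=verts, faces=F, process=False)
    mesh.metadata["backprojected_from"] = dict(dmap.provenance)
    return mesh
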