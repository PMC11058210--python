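"""Parametric molar-like test objects with known ground truth.

Real occlusal scans are proprietary, so every downstream stage of the
pipeline is exercised on synthetic crowns: a superellipse footprint carries a
dome-shaped occlusal table with four Gaussian cusps, a central fossa and a
small band-limited surface roughness, bounded by a cervical skirt that
descends to a low outer lip.  The top surface is a single-valued
heightfield, which guarantees a lossless orthographic depth-map projection;
a short wall and a flat base close the mesh into a watertight solid.

Cavity preparations are carved analytically: inside a given footprint
polygon the surface is lowered to a flat floor with near-vertical walls, and
the exact removed region is returned alongside the carved mesh, giving a
pixel-accurate oracle for mask extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import trimesh
from shapely.geometry import Polygon

__all__ = [
    "ToothShapeParams",
    "PreparationSpec",
    "RigidTransform",
    "occlusal_height",
    "generate_tooth_mesh",
    "apply_rigid_transform",
    "random_rigid_transform",
    "carve_preparation",
    "default_preparation",
    "generate_dataset",
]

#: superellipse exponent of the crown footprint
_FOOTPRINT_EXPONENT = 2.5
#: dome profile exponent; bounds the occlusal slope at the margin so the
#: margin ridge keeps an upward-facing normal (needed by the mask heuristic)
_DOME_EXPONENT = 2.5
#: fraction of base_height at the occlusal margin (rim of the occlusal table)
_MARGIN_FRACTION = 0.55
#: the occlusal table is bounded by a skirt descending to the cervical lip:
#: crown depth maps fade toward the outline, so silhouette pixels carry low
#: intensities rather than flipping between background and margin height
_SKIRT_SLOPE = 2.0  # mm height drop per mm radial run
_SKIRT_LIP_Z = 1.4  # mm height of the outermost (cervical) lip


@dataclass
class ToothShapeParams:
    """Shape parameters of a synthetic molar crown (all lengths in mm)."""

    footprint_radii: tuple[float, float] = (5.6, 4.9)
    base_height: float = 5.5
    cusp_centers: tuple[tuple[float, float], ...] = (
        (-2.4, -2.0),
        (2.4, -2.0),
        (-2.4, 2.0),
        (2.4, 2.0),
    )
    cusp_heights: tuple[float, ...] = (2.6, 2.4, 2.2, 2.0)
    cusp_widths: tuple[float, ...] = (1.9, 1.8, 1.9, 1.8)
    fossa_depth: float = 1.2
    fossa_width: float = 1.6
    noise_amp: float = 0.05
    #: cheek-facing direction in the xy plane; real scans carry no such
    #: label, so the synthetic ground truth records it explicitly
    buccal_direction: tuple[float, float] = (0.0, -1.0)

    def __post_init__(self) -> None:
        a, b = self.footprint_radii
        if a <= 0 or b <= 0 or self.base_height <= 0:
            raise ValueError("footprint radii and base height must be positive")
        if len(self.cusp_centers) != len(self.cusp_heights) or len(
            self.cusp_centers
        ) != len(self.cusp_widths):
            raise ValueError("cusp parameter lists must have equal length")
        if any(h <= 0 for h in self.cusp_heights) or any(
            w <= 0 for w in self.cusp_widths
        ):
            raise ValueError("cusp heights and widths must be positive")
        if self.fossa_depth < 0 or self.fossa_width <= 0:
            raise ValueError("fossa depth must be >= 0 and width > 0")
        if self.cusp_heights and self.fossa_depth >= min(self.cusp_heights):
            raise ValueError("fossa_depth must be smaller than the lowest cusp")
        if self.noise_amp < 0:
            raise ValueError("noise_amp must be >= 0")
        bd = np.asarray(self.buccal_direction, dtype=float)
        nrm = np.linalg.norm(bd)
        if nrm == 0:
            raise ValueError("buccal_direction must be a nonzero 2D vector")
        self.buccal_direction = tuple(bd / nrm)


@dataclass
class PreparationSpec:
    """A cavity preparation: footprint polygon, flat floor and wall slope.

    ``prep_type`` follows the clinical ladder "a" (small interior inlay)
    through "d" (large preparation); types "b"-"d" cut the outer crown
    contour while "a" stays strictly inside it.
    """

    prep_type: str
    cavity_footprint: tuple[tuple[float, float], ...]
    cavity_floor_z: float = 0.6
    wall_slope_deg: float = 6.0
    cuts_outer_contour: bool = False

    def __post_init__(self) -> None:
        if self.prep_type not in ("a", "b", "c", "d"):
            raise ValueError("prep_type must be one of 'a', 'b', 'c', 'd'")
        if not (0.0 <= self.wall_slope_deg < 45.0):
            raise ValueError("wall slope must be in [0, 45) degrees from vertical")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.cavity_footprint)


@dataclass
class RigidTransform:
    """Proper rigid motion p -> R p + t used as ground-truth pose."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-10):
            raise ValueError("rotation matrix must have determinant +1")
        self.rotation = R
        self.translation = t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: p -> R_self (R_other p + t_other) + t_self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def _superellipse_radius(theta: np.ndarray, a: float, b: float) -> np.ndarray:
    n = _FOOTPRINT_EXPONENT
    return (
        np.abs(np.cos(theta) / a) ** n + np.abs(np.sin(theta) / b) ** n
    ) ** (-1.0 / n)


def _noise_field(params: ToothShapeParams, seed: int):
    """Band-limited roughness: a fixed sum of random plane waves."""
    rng = np.random.default_rng(seed)
    k_mag = rng.uniform(0.4, 1.2, size=8)  # rad/mm
    k_dir = rng.uniform(0.0, 2.0 * np.pi, size=8)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=8)
    amp = rng.uniform(0.5, 1.0, size=8)
    # scale so the field std is noise_amp (sum of independent cosines)
    amp *= params.noise_amp / max(np.sqrt(np.sum(amp**2) / 2.0), 1e-12)
    kx = k_mag * np.cos(k_dir)
    ky = k_mag * np.sin(k_dir)

    def f(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        ph = np.multiply.outer(x, kx) + np.multiply.outer(y, ky) + phase
        return np.cos(ph) @ amp

    return f


def occlusal_height(
    params: ToothShapeParams,
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Evaluate the crown top-surface heightfield z(x, y) in mm.

    Inside the footprint (the occlusal table) the height is the dome plus
    cusps minus fossa plus roughness; outside it, the surface descends along
    the cervical skirt at ``_SKIRT_SLOPE`` down to the lip level (clamped
    there).  Deterministic for fixed (params, seed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a, b = params.footprint_radii
    n = _FOOTPRINT_EXPONENT
    rho = (np.abs(x / a) ** n + np.abs(y / b) ** n) ** (1.0 / n)
    z = _table_height(params, x, y, seed)
    outside = rho > 1.0
    if np.any(outside):
        # skirt: per direction, descend linearly from the rim height so the
        # slope stays exactly _SKIRT_SLOPE (no flat annulus that could leak
        # into the occlusal-plane point subset), clamped at the lip level
        r = np.hypot(x, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(rho > 0, 1.0 / rho, 0.0)
        xr = x * inv
        yr = y * inv
        h_rim = _table_height(params, xr, yr, seed)
        run = np.clip(r - r * inv, 0.0, None)
        z_skirt = np.maximum(h_rim - _SKIRT_SLOPE * run, _SKIRT_LIP_Z)
        z = np.where(outside, z_skirt, z)
    return z


def _table_height(
    params: ToothShapeParams, x: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Occlusal-table formula: dome + cusps - fossa + roughness."""
    a, b = params.footprint_radii
    n = _FOOTPRINT_EXPONENT
    rho = (np.abs(x / a) ** n + np.abs(y / b) ** n) ** (1.0 / n)
    z = params.base_height * (
        _MARGIN_FRACTION
        + (1.0 - _MARGIN_FRACTION)
        * np.clip(1.0 - rho**_DOME_EXPONENT, 0.0, None)
    )
    for (cx, cy), h, w in zip(
        params.cusp_centers, params.cusp_heights, params.cusp_widths
    ):
        z = z + h * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * w**2))
    z = z - params.fossa_depth * np.exp(
        -(x**2 + y**2) / (2.0 * params.fossa_width**2)
    )
    if params.noise_amp > 0:
        z = z + _noise_field(params, seed)(x, y)
    return z


def generate_tooth_mesh(
    params: ToothShapeParams,
    seed: int = 0,
    n_radial: int = 110,
    n_theta: int = 420,
    n_skirt: int = 24,
) -> trimesh.Trimesh:
    """Build a watertight crown mesh on a polar grid.

    The top surface samples :func:`occlusal_height` on ``n_radial`` rings
    across the occlusal table plus ``n_skirt`` rings across the cervical
    skirt, which descends to the flat lip at ``_SKIRT_LIP_Z``; a short
    vertical wall and a flat base close the solid.  Because the silhouette
    is the low-lying lip, projected crown outlines fade to low intensities
    the way real crown depth maps do.  Vertex indices
    0 .. (n_radial+n_skirt)*n_theta are the top surface (index 0 is the
    center), recorded in ``mesh.metadata`` for the carving step.
    """
    if n_radial < 4 or n_theta < 8 or n_skirt < 2:
        raise ValueError("grid resolution too low for a valid crown")
    a, b = params.footprint_radii
    if min(a, b) < 1e-6:
        raise ValueError("degenerate footprint")

    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    rim = _superellipse_radius(theta, a, b)
    n_rings = n_radial + n_skirt

    # ring radii: table out to the rim, then the skirt out past the lip
    rim_xy = np.column_stack([rim * np.cos(theta), rim * np.sin(theta)])
    h_rim = _table_height(params, rim_xy[:, 0], rim_xy[:, 1], seed)
    width = np.clip((h_rim - _SKIRT_LIP_Z) / _SKIRT_SLOPE, 0.2, None)
    rr = np.empty((n_rings, n_theta))
    table = np.linspace(0.0, 1.0, n_radial + 1)[1:]
    rr[:n_radial] = np.outer(table, rim)
    skirt = np.linspace(0.0, 1.0, n_skirt + 1)[1:]
    rr[n_radial:] = rim + np.outer(skirt, np.ones(n_theta)) * width

    xs = rr * np.cos(theta)
    ys = rr * np.sin(theta)
    zs = occlusal_height(params, xs, ys, seed=seed)
    zs[-1] = _SKIRT_LIP_Z  # outermost ring sits exactly on the lip
    z0 = float(occlusal_height(params, np.array(0.0), np.array(0.0), seed=seed))

    n_top = 1 + n_rings * n_theta
    base_start = n_top
    base_center = base_start + n_theta
    vertices = np.empty((base_center + 1, 3), dtype=float)
    vertices[0] = (0.0, 0.0, z0)
    vertices[1:n_top, 0] = xs.ravel()
    vertices[1:n_top, 1] = ys.ravel()
    vertices[1:n_top, 2] = zs.ravel()
    vertices[base_start:base_center, 0] = xs[-1]
    vertices[base_start:base_center, 1] = ys[-1]
    vertices[base_start:base_center, 2] = 0.0
    vertices[base_center] = (0.0, 0.0, 0.0)

    j = np.arange(n_theta)
    jn = (j + 1) % n_theta
    faces = []
    ring = lambda i: 1 + i * n_theta  # noqa: E731 - index of ring i start

    # center fan
    faces.append(np.column_stack([np.zeros_like(j), ring(0) + j, ring(0) + jn]))
    # quads between consecutive rings (table and skirt alike)
    for i in range(n_rings - 1):
        A = ring(i) + j
        B = ring(i) + jn
        C = ring(i + 1) + j
        D = ring(i + 1) + jn
        faces.append(np.column_stack([A, C, D]))
        faces.append(np.column_stack([A, D, B]))
    # vertical wall from the lip down to the base ring
    T = ring(n_rings - 1) + j
    Tn = ring(n_rings - 1) + jn
    G = base_start + j
    Gn = base_start + jn
    faces.append(np.column_stack([T, G, Gn]))
    faces.append(np.column_stack([T, Gn, Tn]))
    # base fan (downward normal)
    faces.append(np.column_stack([np.full_like(j, base_center), Gn, G]))

    mesh = trimesh.Trimesh(
        vertices=vertices, faces=np.vstack(faces), process=False
    )
    mesh.metadata["tooth_params"] = params
    mesh.metadata["tooth_seed"] = seed
    mesh.metadata["n_top_vertices"] = n_top
    # buccal direction expressed in the mesh's CURRENT frame; rotated along
    # with the vertices by apply_rigid_transform / normalize_orientation
    mesh.metadata["buccal_direction_3d"] = np.array(
        [*params.buccal_direction, 0.0]
    )
    # crown outline = outermost top ring (the cervical lip); vertex indices
    # survive rigid transforms where stored coordinates would go stale
    mesh.metadata["rim_vertex_indices"] = (n_top - n_theta, n_top)
    return mesh


def apply_rigid_transform(
    mesh: trimesh.Trimesh, t: RigidTransform
) -> trimesh.Trimesh:
    """Map all vertices by rotation then translation; connectivity unchanged."""
    out = trimesh.Trimesh(
        vertices=mesh.vertices @ t.rotation.T + t.translation,
        faces=mesh.faces.copy(),
        process=False,
    )
    out.metadata.update(mesh.metadata)
    bd = mesh.metadata.get("buccal_direction_3d")
    if bd is not None:
        out.metadata["buccal_direction_3d"] = t.rotation @ np.asarray(bd)
    return out


def random_rigid_transform(
    seed: int, max_translation: float = 20.0
) -> RigidTransform:
    """Uniform random rotation and bounded translation (test ground truth)."""
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(R, t)


def _top_vertex_data(mesh: trimesh.Trimesh):
    n_top = mesh.metadata.get("n_top_vertices")
    if n_top is not None:
        idx = np.arange(int(n_top))
    else:  # fall back to a normal/height heuristic for foreign meshes
        vn = mesh.vertex_normals
        z = mesh.vertices[:, 2]
        idx = np.flatnonzero((vn[:, 2] > 0.2) & (z > 0.25 * z.max()))
        if idx.size < 3:
            raise ValueError("cannot identify the occlusal surface of the mesh")
    return idx, mesh.vertices[idx]


def carve_preparation(
    mesh: trimesh.Trimesh, spec: PreparationSpec
) -> tuple[trimesh.Trimesh, Polygon]:
    """Carve a cavity into a crown mesh in normalized orientation.

    Inside the cavity footprint the surface is lowered to
    ``spec.cavity_floor_z``; the walls rise from the floor toward the rim at
    ``wall_slope_deg`` from vertical, anchored at the local occlusal height
    along the rim.  Returns the carved mesh and the exact occlusal-plane
    polygon of removed material (the footprint clipped to the crown).
    Material is only ever removed, never added.
    """
    from scipy.spatial import cKDTree

    poly = spec.polygon
    if poly.area == 0:
        return (
            trimesh.Trimesh(
                vertices=mesh.vertices.copy(), faces=mesh.faces.copy(),
                process=False, metadata=dict(mesh.metadata),
            ),
            Polygon(),
        )

    _, top_v = _top_vertex_data(mesh)
    tree = cKDTree(top_v[:, :2])

    V = mesh.vertices.copy()
    pts2d = shapely.points(V[:, :2])
    inside = shapely.contains(poly, pts2d)
    idx = np.flatnonzero(inside)
    if idx.size:
        boundary = poly.exterior
        seg = shapely.shortest_line(pts2d[idx], boundary)
        coords = shapely.get_coordinates(seg)
        nearest_rim = coords[1::2]  # second endpoint lies on the boundary
        s = np.linalg.norm(V[idx, :2] - nearest_rim, axis=1)
        _, rim_idx = tree.query(nearest_rim)
        h_rim = top_v[rim_idx, 2]
        slope = np.tan(np.radians(spec.wall_slope_deg))
        if slope > 0:
            wall = h_rim - s / slope
        else:
            wall = np.full_like(s, -np.inf)
        target = np.maximum(spec.cavity_floor_z, wall)
        if spec.cavity_floor_z >= float(np.max(V[idx, 2])):
            raise ValueError("cavity floor lies above the occlusal surface")
        V[idx, 2] = np.minimum(V[idx, 2], target)

    out = trimesh.Trimesh(vertices=V, faces=mesh.faces.copy(), process=False)
    out.metadata.update(mesh.metadata)
    out.metadata["preparation"] = spec

    rim_idx = mesh.metadata.get("rim_vertex_indices")
    if rim_idx is not None:
        rim_xy = mesh.vertices[rim_idx[0] : rim_idx[1], :2]
        region = poly.intersection(Polygon(rim_xy))
    else:
        region = poly
    return out, region


def default_preparation(
    prep_type: str, params: ToothShapeParams, cavity_floor_z: float = 0.6
) -> PreparationSpec:
    """Standard cavity footprints for the four inlay types.

    The removed occlusal-area fraction increases monotonically from roughly
    30% (type "a") to roughly 80% (type "d"); types "b"-"d" cut the outer
    crown contour.  Footprints scale with the crown radii.
    """
    a, b = params.footprint_radii
    big = 1.4  # polygon coordinates safely outside the crown
    if prep_type == "a":
        coords = _box(-0.77 * a, 0.77 * a, -0.50 * b, 0.50 * b)
        cuts = False
    elif prep_type == "b":
        coords = _box(-big * a, 0.58 * a, -0.64 * b, 0.64 * b)
        cuts = True
    elif prep_type == "c":
        coords = _box(-big * a, big * a, -0.65 * b, 0.65 * b)
        cuts = True
    elif prep_type == "d":
        coords = _box(-big * a, big * a, -big * b, 0.64 * b)
        cuts = True
    else:
        raise ValueError("prep_type must be one of 'a', 'b', 'c', 'd'")
    return PreparationSpec(
        prep_type=prep_type,
        cavity_footprint=coords,
        cavity_floor_z=cavity_floor_z,
        cuts_outer_contour=cuts,
    )


def _box(x0, x1, y0, y1):
    return ((x0, y0), (x1, y0), (x1, y1), (x0, y1))


def generate_dataset(
    n: int,
    base_params: ToothShapeParams | None = None,
    seed: int = 0,
    n_radial: int = 110,
    n_theta: int = 420,
) -> list[trimesh.Trimesh]:
    """Generate ``n`` crowns with parameters jittered around ``base_params``.

    Deterministic for fixed seed; jitter amplitudes emulate the anatomical
    spread of a small clinical collection (footprint +-5%, cusp heights
    +-15%, cusp positions +-0.4 mm, fossa depth +-15%).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_params or ToothShapeParams()
    rng = np.random.default_rng(seed)
    meshes = []
    for _ in range(n):
        a, b = base.footprint_radii
        radii = (
            a * rng.uniform(0.95, 1.05),
            b * rng.uniform(0.95, 1.05),
        )
        centers = tuple(
            (cx + rng.uniform(-0.4, 0.4), cy + rng.uniform(-0.4, 0.4))
            for cx, cy in base.cusp_centers
        )
        heights = tuple(
            h * rng.uniform(0.92, 1.08) for h in base.cusp_heights
        )
        widths = tuple(w * rng.uniform(0.9, 1.1) for w in base.cusp_widths)
        params = replace(
            base,
            footprint_radii=radii,
            cusp_centers=centers,
            cusp_heights=heights,
            cusp_widths=widths,
            fossa_depth=base.fossa_depth * rng.uniform(0.85, 1.15),
        )
        tooth_seed = int(rng.integers(0, 2**31 - 1))
        meshes.append(
            generate_tooth_mesh(
                params, seed=tooth_seed, n_radial=n_radial, n_theta=n_theta
            )
        )
    return meshes
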