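"""Extraction of the preparation-area binary mask.

A prepared crown differs from an intact one by a cavity whose walls are much
steeper than the occlusal surface and whose floor sits below it.  Both
properties are visible in the sampled point cloud: cavity points either have
a small normal z-component (walls) or a low height (floor).  Keeping only
points with ``n_z > n_z_t`` and ``z > z_t`` therefore removes the cavity;
projecting the retained points and binarizing yields a raw mask whose black
region is the preparation area plus small sampling artifacts.

The final cleanup (speckle removal, morphological closing, hole filling)
automates the manual post-processing step of the original workflow.  The
artifacts it removes never touch the preparation edge, so the cleanup cannot
move the mask boundary — which must coincide with the preparation edge for
the merged reconstruction to be seamless.

Masks use 1 for white (keep) and 0 for black (removed area) internally;
PNG serialization maps {0, 1} to {0, 255}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage import morphology

from .normalization import OrientedPointCloud
from .projection import (
    DepthMap,
    ProjectionConfig,
    normalize_z,
    project_depth,
    sample_surface,
)

__all__ = [
    "BinaryMask",
    "BoundaryMask",
    "MaskThresholds",
    "extract_retained_points",
    "binarize",
    "finalize_mask",
    "boundary_mask",
    "circle_mask",
    "boundary_cut_mask",
    "preparation_mask",
]


@dataclass
class MaskThresholds:
    """Cavity-removal thresholds: normal z-component and height floor.

    Empirical per preparation.  The normal threshold must lie between the
    steepest occlusal slope (below) and the cavity-wall slope (above): cusp
    flanks reach slopes near 2 (n_z ~ 0.45) while near-vertical walls stay
    under n_z ~ 0.15, so 0.25 separates the two with margin on both
    sides even after the occlusal plane has been leveled by a few degrees.
    ``z_t`` crops everything at or below the cavity floor.
    """

    n_z_t: float = 0.25
    z_t: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.n_z_t < 1.0):
            raise ValueError("n_z_t must lie strictly between 0 and 1")


@dataclass
class BinaryMask:
    """w x h mask, 1 = keep (white), 0 = removed area (black)."""

    m: np.ndarray
    source: str = "extracted"  # extracted | ground_truth | manual
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.m)
        if arr.ndim != 2:
            raise ValueError("mask must be a 2D array")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.m = arr.astype(np.uint8)

    @property
    def black(self) -> np.ndarray:
        return self.m == 0

    def save_png(self, path: str | Path) -> None:
        from PIL import Image

        path = Path(path)
        Image.fromarray((self.m * 255).astype(np.uint8), mode="L").save(path)
        path.with_suffix(".json").write_text(
            json.dumps({"source": self.source, "provenance": self.provenance})
        )

    @classmethod
    def load_png(cls, path: str | Path) -> "BinaryMask":
        from PIL import Image

        path = Path(path)
        arr = np.asarray(Image.open(path).convert("L"))
        meta = {}
        side = path.with_suffix(".json")
        if side.exists():
            meta = json.loads(side.read_text())
        return cls(
            m=(arr > 127).astype(np.uint8),
            source=meta.get("source", "manual"),
            provenance=meta.get("provenance", {}),
        )


@dataclass
class BoundaryMask:
    """Ring of white pixels adjacent (8-connectivity) to the black region."""

    m_b: np.ndarray
    ring_width: int = 1

    def __post_init__(self) -> None:
        self.m_b = np.asarray(self.m_b).astype(bool)


def extract_retained_points(
    cloud: OrientedPointCloud, th: MaskThresholds
) -> OrientedPointCloud:
    """Keep occlusal-remainder points: flat-enough normals above the floor."""
    keep = (cloud.normals[:, 2] > th.n_z_t) & (cloud.points[:, 2] > th.z_t)
    if not np.any(keep):
        raise ValueError(
            "no points retained; thresholds remove the whole surface"
        )
    return OrientedPointCloud(cloud.points[keep], cloud.normals[keep])


def binarize(dmap: DepthMap) -> BinaryMask:
    """Raw mask: white wherever the (quantized) depth map is nonzero."""
    return BinaryMask(
        m=(dmap.quantized() > 0).astype(np.uint8),
        source="extracted",
        provenance=dict(dmap.provenance),
    )


def finalize_mask(
    raw: BinaryMask,
    footprint: BinaryMask | None = None,
    min_speckle_px: int = 10,
    closing_radius_px: int = 1,
    opening_radius_px: int = 1,
) -> BinaryMask:
    """Clean a raw retained-points mask into the enclosed preparation mask.

    ``footprint`` is the crown silhouette (white = tooth), normally
    ``binarize(prepared depth map)``; it distinguishes true background from
    the cavity, which matters when a preparation cuts the outer contour.
    Without it the silhouette is estimated by closing and hole-filling the
    retained region, which is reliable only for interior preparations.

    The black output region is the filled preparation area; the white output
    covers the occlusal remainder and the background.  Idempotent.
    """
    white = raw.m.astype(bool)
    if footprint is not None:
        fg = footprint.m.astype(bool)
    else:
        fg = ndimage.binary_fill_holes(
            morphology.closing(white, morphology.disk(closing_radius_px))
        )
    black = fg & ~white
    # tiny dark islands on the occlusal remainder are sampling artifacts,
    # not cavity; drop them before closing can bridge them to the edge
    black = morphology.remove_small_objects(black, max_size=min_speckle_px - 1)
    if closing_radius_px > 0:
        # close white speckle inside the cavity without moving the edge;
        # the closing may only ADD pixels well inside the crown, where it
        # cannot bridge silhouette wall slivers into the cavity
        inner = ndimage.binary_erosion(fg, morphology.disk(2))
        grown = morphology.closing(black, morphology.disk(closing_radius_px))
        black = black | (grown & inner)
    if opening_radius_px > 0:
        # thin dark filaments (steep-flank bands, contour slivers) are
        # artifacts; a small opening removes them while displacing
        # wide-region corners by well under a pixel
        black = morphology.opening(black, morphology.disk(opening_radius_px))
    black = ndimage.binary_fill_holes(black)
    # the preparation is one enclosed region; residual excluded-surface
    # fragments elsewhere (steep patches, low-lying skirt arcs on tilted
    # crowns) are artifacts the reference workflow removed by hand
    labels, n_comp = ndimage.label(black)
    if n_comp > 1:
        sizes = ndimage.sum_labels(black, labels, index=np.arange(1, n_comp + 1))
        black = labels == (1 + int(np.argmax(sizes)))
    h, w = black.shape
    if (
        black[0, :].any()
        and black[-1, :].any()
        and black[:, 0].any()
        and black[:, -1].any()
    ):
        raise ValueError("preparation region touches all four image borders")
    return BinaryMask(
        m=(~black).astype(np.uint8),
        source="extracted",
        provenance=dict(raw.provenance),
    )


def boundary_mask(
    M: BinaryMask,
    ring_width: int = 1,
    footprint: BinaryMask | None = None,
) -> BoundaryMask:
    """White pixels within ``ring_width`` (8-connectivity) of the black area.

    With a crown silhouette given, ring pixels outside the tooth are
    dropped: where a preparation cuts the outer contour the adjacent
    background carries no boundary information.
    """
    black = M.black
    if not black.any():
        raise ValueError("mask has no black region")
    size = 2 * ring_width + 1
    ring = ndimage.binary_dilation(black, np.ones((size, size), bool)) & ~black
    if footprint is not None:
        ring &= footprint.m.astype(bool)
    return BoundaryMask(m_b=ring, ring_width=ring_width)


def _inscribed_circle_center(tooth: np.ndarray) -> tuple[np.ndarray, float]:
    dist = ndimage.distance_transform_edt(tooth)
    center = np.unravel_index(np.argmax(dist), dist.shape)
    return np.asarray(center, dtype=float), float(dist[center])


def circle_mask(dmap: DepthMap, area_fraction: float) -> BinaryMask:
    """Filled interior circle removing a given fraction of the tooth area.

    Centered at the largest inscribed circle of the crown silhouette; the
    radius is chosen by distance rank so the black pixel count matches the
    requested fraction exactly (up to ties).  Infeasible fractions — the
    disk would touch or cross the outer contour — are rejected.
    """
    tooth = dmap.foreground()
    n_tooth = int(tooth.sum())
    if n_tooth == 0:
        raise ValueError("empty tooth foreground")
    if not (0.0 <= area_fraction <= 1.0):
        raise ValueError("area_fraction must be in [0, 1]")
    k = int(round(area_fraction * n_tooth))
    m = np.ones_like(tooth, dtype=np.uint8)
    if k == 0:
        return BinaryMask(m=m, source="ground_truth")
    center, max_r = _inscribed_circle_center(tooth)
    rows, cols = np.nonzero(tooth)
    d = np.hypot(rows - center[0], cols - center[1])
    order = np.argsort(d, kind="stable")
    r_k = d[order[k - 1]]
    if r_k + 1.0 > max_r:
        raise ValueError(
            f"fraction {area_fraction} infeasible: circle of radius "
            f"{r_k:.1f}px would touch the outer contour (max {max_r:.1f}px)"
        )
    sel = order[:k]
    m[rows[sel], cols[sel]] = 0
    return BinaryMask(
        m=m,
        source="ground_truth",
        provenance={"kind": "circle", "area_fraction": area_fraction},
    )


def boundary_cut_mask(
    dmap: DepthMap, area_fraction: float, side: str = "top"
) -> BinaryMask:
    """Cap-shaped mask of equal area that intersects the outer contour.

    Removes the same number of pixels as :func:`circle_mask` at the same
    fraction but as a band clipped against the crown silhouette on the
    requested side, so the black region crosses the outer contour — the
    control condition for the interior-vs-contour-cut comparison.
    """
    if side not in ("top", "bottom", "left", "right"):
        raise ValueError("side must be top, bottom, left or right")
    tooth = dmap.foreground()
    n_tooth = int(tooth.sum())
    if n_tooth == 0:
        raise ValueError("empty tooth foreground")
    if not (0.0 <= area_fraction <= 1.0):
        raise ValueError("area_fraction must be in [0, 1]")
    k = int(round(area_fraction * n_tooth))
    m = np.ones_like(tooth, dtype=np.uint8)
    if k == 0:
        return BinaryMask(m=m, source="ground_truth")
    rows, cols = np.nonzero(tooth)
    if side == "top":
        primary = rows
    elif side == "bottom":
        primary = -rows
    elif side == "left":
        primary = cols
    else:
        primary = -cols
    secondary = np.hypot(rows - rows.mean(), cols - cols.mean())
    order = np.lexsort((secondary, primary))
    sel = order[:k]
    m[rows[sel], cols[sel]] = 0
    return BinaryMask(
        m=m,
        source="ground_truth",
        provenance={
            "kind": "boundary_cut",
            "area_fraction": area_fraction,
            "side": side,
        },
    )


def preparation_mask(
    prepared_mesh: trimesh.Trimesh,
    config: ProjectionConfig,
    thresholds: MaskThresholds,
    seed: int = 0,
    xy_offset: np.ndarray | None = None,
    z_shift: float | None = None,
    override: BinaryMask | None = None,
) -> tuple[BinaryMask, DepthMap]:
    """Full mask-extraction chain for a normalized prepared crown.

    Samples the mesh, projects the complete prepared-tooth depth map, then
    re-projects only the retained points and finalizes the binary mask
    against the crown silhouette.  ``xy_offset``/``z_shift`` align the
    preparation with its intact reference projection when given; a manual
    ``override`` mask is honored verbatim.
    Returns (mask, prepared-tooth depth map).
    """
    cloud = sample_surface(
        prepared_mesh, config.n_sample, seed=seed, interpolate_normals=False
    )
    pts = cloud.points
    if z_shift is None:
        pts = normalize_z(pts, config.z_norm)
    else:
        pts = pts.copy()
        pts[:, 2] += z_shift
    dmap = project_depth(pts, config, xy_offset=xy_offset)
    if override is not None:
        return override, dmap
    offset = np.asarray(dmap.provenance["xy_offset_mm"])
    retained = extract_retained_points(
        OrientedPointCloud(pts, cloud.normals), thresholds
    )
    raw_map = project_depth(retained.points, config, xy_offset=offset)
    raw = binarize(raw_map)
    mask = finalize_mask(raw, footprint=binarize(dmap))
    return mask, dmap
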