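"""Reconstruction quality metrics and the mask-size experiments.

All error metrics are computed in mm via the depth-map calibration
``c_pix_mm = z_norm / 255`` on the quantized 8-bit images.  The headline
metric is the full-image RMSE between the merged reconstruction and the
ground truth, background included; per-pixel error distributions over the
removed region (with a 95th-percentile cutoff against outliers) and
threshold overlays provide the spatial view.

The rising-circle-mask experiment measures how reconstruction error grows
with the removed area fraction, and the circle-vs-boundary-cut comparison
isolates the cost of losing the outer contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .generator import GeneratorContract
from .mask import (
    BinaryMask,
    binarize,
    boundary_cut_mask,
    boundary_mask,
    circle_mask,
)
from .projection import DepthMap
from .reconstruction import (
    FourierFeatureExtractor,
    LossWeights,
    OptimizerConfig,
    corrupt,
    optimize,
)

__all__ = [
    "DistanceDistribution",
    "AreaRmsePair",
    "rmse_vs_truth",
    "distance_distribution",
    "threshold_overlay",
    "relative_mask_area",
    "area_rmse_regression",
    "rising_mask_experiment",
    "reconstruct_masked",
    "plot_distance_distribution",
    "plot_area_rmse",
]


@dataclass
class DistanceDistribution:
    """Absolute mm errors over the removed region, percentile-truncated."""

    distances_mm: np.ndarray  # retained (below-cutoff) per-pixel errors
    cutoff_percentile: float
    cutoff_mm: float
    bin_edges_mm: np.ndarray
    ratios: np.ndarray  # histogram mass, sums to 1 over retained pixels
    n_total: int
    n_retained: int


@dataclass
class AreaRmsePair:
    area_fraction: float
    rmse_mm: float
    tooth_id: int
    mask_id: str


def _check_calibration(a: DepthMap, b: DepthMap) -> None:
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("resolution mismatch")
    if not np.isclose(a.z_norm, b.z_norm):
        raise ValueError("calibration mismatch (different z_norm)")


def rmse_vs_truth(x_merge: DepthMap, x_true: DepthMap) -> float:
    """Full-image RMSE in mm, background included."""
    _check_calibration(x_merge, x_true)
    d = x_merge.quantized().astype(float) - x_true.quantized().astype(float)
    return float(np.sqrt(np.mean(d**2)) * x_true.c_pix_mm)


def _abs_errors_mm(
    x_merge: DepthMap, x_true: DepthMap, M: BinaryMask
) -> np.ndarray:
    _check_calibration(x_merge, x_true)
    d = np.abs(
        x_merge.quantized().astype(float) - x_true.quantized().astype(float)
    )
    return d[M.black] * x_true.c_pix_mm


def distance_distribution(
    x_merge: DepthMap,
    x_true: DepthMap,
    M: BinaryMask,
    cutoff_percentile: float = 95.0,
    bin_width_mm: float = 0.01,
) -> DistanceDistribution:
    """Error-distance distribution over the removed (M=0) region.

    Values above the cutoff percentile are dropped: the extreme tail does
    not describe the continuous occlusal surface.
    """
    if not (0.0 < cutoff_percentile <= 100.0):
        raise ValueError("cutoff must lie in (0, 100]")
    errs = _abs_errors_mm(x_merge, x_true, M)
    if errs.size == 0:
        raise ValueError("mask has no removed region")
    cutoff_mm = float(np.percentile(errs, cutoff_percentile))
    kept = errs[errs <= cutoff_mm]
    hi = max(cutoff_mm, bin_width_mm)
    edges = np.arange(0.0, hi + bin_width_mm, bin_width_mm)
    hist, edges = np.histogram(kept, bins=edges)
    ratios = hist / max(kept.size, 1)
    return DistanceDistribution(
        distances_mm=kept,
        cutoff_percentile=cutoff_percentile,
        cutoff_mm=cutoff_mm,
        bin_edges_mm=edges,
        ratios=ratios,
        n_total=errs.size,
        n_retained=kept.size,
    )


def threshold_overlay(
    x_merge: DepthMap, x_true: DepthMap, threshold_mm: float = 0.1
) -> np.ndarray:
    """Boolean map of pixels whose |error| exceeds the threshold."""
    _check_calibration(x_merge, x_true)
    d = np.abs(
        x_merge.quantized().astype(float) - x_true.quantized().astype(float)
    )
    return d * x_true.c_pix_mm > threshold_mm


def relative_mask_area(M: BinaryMask, x_true: DepthMap) -> float:
    """Removed fraction of the tooth: |M=0 ∧ tooth| / |tooth|."""
    tooth = x_true.foreground()
    n = int(tooth.sum())
    if n == 0:
        raise ValueError("empty tooth foreground")
    return float((M.black & tooth).sum() / n)


def area_rmse_regression(
    pairs: list[AreaRmsePair],
) -> tuple[float, float, float, float]:
    """OLS of per-area mean RMSE on area: (slope, intercept, R^2, p).

    Pairs are grouped by area fraction and averaged first, mirroring a
    regression over mean values per mask size; the p-value is the two-sided
    test of zero slope.
    """
    from scipy import stats

    if not pairs:
        raise ValueError("no pairs")
    areas = np.array([p.area_fraction for p in pairs])
    rmses = np.array([p.rmse_mm for p in pairs])
    uniq = np.unique(np.round(areas, 6))
    if len(uniq) < 3:
        raise ValueError("need at least 3 distinct area levels")
    means = np.array(
        [rmses[np.isclose(areas, u)].mean() for u in uniq]
    )
    if np.allclose(means, means[0]):  # constant response: no trend
        return 0.0, float(means[0]), 0.0, 1.0
    fit = stats.linregress(uniq, means)
    return (
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        float(fit.pvalue),
    )


def plot_distance_distribution(dist: DistanceDistribution, path=None):
    """Bar plot of the error-distance ratios over the removed region."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    centers = (dist.bin_edges_mm[:-1] + dist.bin_edges_mm[1:]) / 2
    width = np.diff(dist.bin_edges_mm)
    ax.bar(centers, dist.ratios, width=width, align="center")
    ax.set_xlabel("error distance [mm]")
    ax.set_ylabel("ratio of removed-area pixels")
    ax.set_title(
        f"p{dist.cutoff_percentile:.0f} cutoff at {dist.cutoff_mm:.3f} mm"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_area_rmse(pairs: list[AreaRmsePair], path=None):
    """Scatter of RMSE vs removed-area fraction with the mean-value fit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    areas = np.array([p.area_fraction for p in pairs])
    rmses = np.array([p.rmse_mm for p in pairs])
    ax.scatter(areas, rmses, s=18, alpha=0.7, label="per tooth")
    slope, intercept, r2, pval = area_rmse_regression(pairs)
    xs = np.linspace(areas.min(), areas.max(), 50)
    ax.plot(
        xs, slope * xs + intercept, "k--",
        label=f"mean fit: R²={r2:.2f}, p={pval:.3g}",
    )
    ax.set_xlabel("relative removed area")
    ax.set_ylabel("RMSE [mm]")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def reconstruct_masked(
    x_true: DepthMap,
    M: BinaryMask,
    G: GeneratorContract,
    weights: LossWeights | None = None,
    opt: OptimizerConfig | None = None,
    extractor: FourierFeatureExtractor | None = None,
) -> tuple[DepthMap, float]:
    """Corrupt a ground-truth map with M, reconstruct, merge and score.

    Returns the merged reconstruction and its full-image RMSE in mm.
    """
    x_cor = corrupt(x_true.quantized().astype(float), M)
    M_B = boundary_mask(M, footprint=binarize(x_true))
    result = optimize(x_cor, M, M_B, G, weights, opt, extractor)
    merged = x_true.copy_with(result.x_merged)
    merged.provenance["n_dr"] = result.n_dr
    merged.provenance["chosen_restart"] = result.chosen_restart
    return merged, rmse_vs_truth(merged, x_true)


def rising_mask_experiment(
    teeth: list[DepthMap],
    fractions: list[float],
    G: GeneratorContract,
    weights: LossWeights | None = None,
    opt: OptimizerConfig | None = None,
    extractor: FourierFeatureExtractor | None = None,
    mask_kind: str = "circle",
) -> list[AreaRmsePair]:
    """Reconstruct every tooth under interior circle masks of rising area.

    Infeasible fractions (circle would touch the contour) are skipped with
    a warning.  ``mask_kind='boundary_cut'`` runs the contour-cutting
    control instead.  Deterministic given the optimizer seed.
    """
    extractor = extractor or FourierFeatureExtractor(G.resolution)
    pairs: list[AreaRmsePair] = []
    for tooth_id, x_true in enumerate(teeth):
        for frac in fractions:
            try:
                if mask_kind == "circle":
                    M = circle_mask(x_true, frac)
                elif mask_kind == "boundary_cut":
                    M = boundary_cut_mask(x_true, frac)
                else:
                    raise ValueError("mask_kind must be circle or boundary_cut")
            except ValueError as exc:
                warnings.warn(
                    f"tooth {tooth_id}, fraction {frac}: {exc}", stacklevel=2
                )
                continue
            _, rmse = reconstruct_masked(x_true, M, G, weights, opt, extractor)
            pairs.append(
                AreaRmsePair(
                    area_fraction=frac,
                    rmse_mm=rmse,
                    tooth_id=tooth_id,
                    mask_id=f"{mask_kind}_{frac:.2f}",
                )
            )
    return pairs
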