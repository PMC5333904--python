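"""Three-class fuzzy c-means tissue segmentation and tissue statistics.

A deterministic fuzzy c-means on voxel intensities stands in for adaptive
fuzzy segmenters: the input images are bias-field-free by construction
(MP2RAGE-like), so no gain-field estimation is needed.  Initial centroids
sit at the 10th/50th/90th intensity percentiles of the brain, which makes
the segmentation reproducible without any random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import (
    BACKGROUND, CSF, GM, WM, TISSUE_CODES, TISSUE_NAMES,
    IntensityVolume, ROIMask, TissueLabelMap, require_same_grid,
)

_CLASS_ORDER = ("CSF", "GM", "WM")  # ascending intensity


@dataclass
class FuzzyMembership:
    """Per-class membership grids (CSF, GM, WM) plus the class centroids."""

    memberships: dict[str, np.ndarray]
    class_centroids: tuple[float, float, float]  # CSF < GM < WM
    brain_mask: np.ndarray
    voxel_size: tuple[float, float, float]
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        c = self.class_centroids
        if not c[0] < c[1] < c[2]:
            raise ValueError("centroids must be strictly increasing CSF < GM < WM")
        stack = np.stack([self.memberships[t] for t in _CLASS_ORDER])
        sums = stack.sum(axis=0)[self.brain_mask]
        if sums.size and not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("memberships must sum to 1 at brain voxels")


@dataclass
class TissueStats:
    """Per-tissue intensity and volume summary."""

    mean: dict[str, float] = field(default_factory=dict)
    median: dict[str, float] = field(default_factory=dict)
    count: dict[str, int] = field(default_factory=dict)
    volume_mm3: dict[str, float] = field(default_factory=dict)
    absent: tuple[str, ...] = ()


def fuzzy_segment(
    vol: IntensityVolume,
    brain_mask: ROIMask | np.ndarray | None = None,
    fuzziness: float = 2.0,
    smoothing_weight: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-3,
) -> FuzzyMembership:
    """Three-class fuzzy c-means on intensities.

    Parameters
    ----------
    brain_mask
        Brain voxels; defaults to everything that is not exactly zero
        (skull-stripped convention).
    fuzziness
        The c-means exponent m (> 1); 2 is the conventional choice.
    smoothing_weight
        If positive, each membership map is blended per iteration with its
        6-neighbour local mean, ``u <- (u + w * mean) / (1 + w)``, a light
        spatial regularisation for noisy data.
    """
    if fuzziness <= 1:
        raise ValueError("fuzziness must be > 1")
    if brain_mask is None:
        mask = vol.data != 0
    elif isinstance(brain_mask, ROIMask):
        require_same_grid(vol, brain_mask, "volume and brain mask")
        mask = brain_mask.mask
    else:
        mask = np.asarray(brain_mask, dtype=bool)
    x = vol.data[mask]
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct intensity values in the brain")

    centroids = np.percentile(x, [10.0, 50.0, 90.0]).astype(float)
    if np.unique(centroids).size < 3:  # heavily discrete data: spread them
        lo, hi = x.min(), x.max()
        centroids = np.array([lo, 0.5 * (lo + hi), hi], dtype=float)
    expo = 2.0 / (fuzziness - 1.0)
    u = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = np.abs(x[:, None] - centroids[None, :])
        d = np.maximum(d, 1e-12)
        inv = d ** (-expo)
        u = inv / inv.sum(axis=1, keepdims=True)
        if smoothing_weight > 0:
            u = _smooth_memberships(u, mask, smoothing_weight)
        um = u ** fuzziness
        new = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        new = np.sort(new)
        shift = float(np.max(np.abs(new - centroids)))
        centroids = new
        if shift < tol:
            converged = True
            break
    if not converged:
        import logging
        logging.getLogger("mristand").warning(
            "fuzzy c-means did not converge in %d iterations (last shift %.3g); "
            "returning the partial result", max_iter, shift)
    # final memberships at the converged centroids
    d = np.maximum(np.abs(x[:, None] - centroids[None, :]), 1e-12)
    inv = d ** (-expo)
    u = inv / inv.sum(axis=1, keepdims=True)
    if smoothing_weight > 0:
        u = _smooth_memberships(u, mask, smoothing_weight)

    memberships = {}
    for j, t in enumerate(_CLASS_ORDER):
        grid = np.zeros(vol.grid_shape, dtype=np.float64)
        grid[mask] = u[:, j]
        memberships[t] = grid
    return FuzzyMembership(
        memberships, tuple(float(c) for c in centroids), mask,
        vol.voxel_size, converged=converged, n_iterations=it)


def _smooth_memberships(
    u: np.ndarray, mask: np.ndarray, weight: float
) -> np.ndarray:
    """Blend memberships with their 6-neighbour local mean inside the brain."""
    kernel = np.zeros((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    kernel[0, 1, 1] = kernel[2, 1, 1] = 1.0
    kernel[1, 0, 1] = kernel[1, 2, 1] = 1.0
    kernel[1, 1, 0] = kernel[1, 1, 2] = 1.0
    norm = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    out = np.empty_like(u)
    for j in range(u.shape[1]):
        grid = np.zeros(mask.shape)
        grid[mask] = u[:, j]
        neigh = ndimage.convolve(grid, kernel, mode="constant")
        mean = np.divide(neigh, norm, out=grid.copy(), where=norm > 0)
        out[:, j] = (u[:, j] + weight * mean[mask]) / (1.0 + weight)
    return out / out.sum(axis=1, keepdims=True)


def hard_labels(f: FuzzyMembership) -> TissueLabelMap:
    """Per-voxel class of maximal membership; ties go to the lower-intensity class."""
    stack = np.stack([f.memberships[t] for t in _CLASS_ORDER])
    # argmax returns the first maximal index, i.e. the lower-intensity class
    winner = np.argmax(stack, axis=0) + 1  # 1 CSF, 2 GM, 3 WM
    labels = np.where(f.brain_mask, winner, BACKGROUND).astype(np.int16)
    return TissueLabelMap(labels, voxel_size=f.voxel_size)


def tissue_stats(vol: IntensityVolume, labels: TissueLabelMap) -> TissueStats:
    """Mean/median intensity, voxel count, and volume (mm^3) per tissue class."""
    require_same_grid(vol, labels, "volume and label map")
    vox_mm3 = float(np.prod(labels.voxel_size))
    stats = TissueStats()
    absent = []
    for name, code in (("CSF", CSF), ("GM", GM), ("WM", WM)):
        sel = labels.labels == code
        n = int(sel.sum())
        stats.count[name] = n
        stats.volume_mm3[name] = n * vox_mm3
        if n == 0:
            absent.append(name)
            stats.mean[name] = float("nan")
            stats.median[name] = float("nan")
        else:
            vals = vol.data[sel]
            stats.mean[name] = float(vals.mean())
            stats.median[name] = float(np.median(vals))
    stats.absent = tuple(absent)
    return stats


def clean_roi(
    roi: ROIMask, labels: TissueLabelMap, min_voxels: int = 100
) -> ROIMask:
    """Drop ROI voxels whose hard label disagrees with the ROI's tissue tag.

    Mirrors the removal of CSF and vessel/WM voxels from hand-drawn masks.
    Errors when fewer than ``min_voxels`` survive — small ROIs give
    unreliable median estimates (a few thousand voxels is the comfortable
    lower limit for a GM ROI).
    """
    require_same_grid(roi, labels, "ROI and label map")
    keep = roi.mask & (labels.labels == TISSUE_CODES[roi.tissue])
    n = int(keep.sum())
    if n < min_voxels:
        raise ValueError(
            f"only {n} {roi.tissue} voxels survive cleaning (floor {min_voxels}); "
            "an ROI this small cannot support a reliable median — roughly 2000 "
            "voxels is the recommended lower limit for a GM ROI")
    return ROIMask(keep, tissue=roi.tissue, voxel_size=roi.voxel_size)
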