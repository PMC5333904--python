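"""Synthetic brain phantoms with known tissue geometry and intensity distortions.

The phantom is a nested-ellipsoid "brain" (CSF shell around a GM ribbon
around a WM core) with one small central GM sphere — a stand-in for the
hypothalamus — embedded in the WM and surrounded by a WM shell that serves
as the paired ROI.  Tissue intensities are drawn from per-class Gaussians
whose GM/WM means (1907, 3246) and SDs (75.9, 58.5; CSF 130.9) mirror the
sample statistics of skull-stripped T1-weighted MP2RAGE data, so histogram
modes fall inside the standard GM (1000, 2500) and WM (3000, 3500) search
windows.

Known monotone intensity distortions (offset, linear, tissue-piecewise,
smooth non-linear) model interscan variation and give every standardisation
method a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .volume_io import (
    BACKGROUND, CSF, GM, WM,
    I_MAX, I_MIN,
    IntensityVolume, ROIMask, TissueLabelMap,
)

# Geometry of the nested ellipsoids, as fractions of the smallest grid
# dimension, with mild per-axis anisotropy so the shells are true ellipsoids.
_BRAIN_FRAC = 0.45
_GM_OUTER_FRAC = 0.38
_WM_OUTER_FRAC = 0.28
_AXIS_RATIOS = (1.0, 0.95, 0.90)

#: Default tissue Gaussians.  GM/WM means are the MP2RAGE sample means of the
#: study population; the SDs are the between-subject SDs of the tissue means.
#: CSF has no published mean — 600 keeps it well below the GM mode window.
DEFAULT_TISSUE_MEANS = {"CSF": 600.0, "GM": 1907.0, "WM": 3246.0}
DEFAULT_TISSUE_SDS = {"CSF": 130.9, "GM": 75.9, "WM": 58.5}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic brain volume."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    tissue_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    tissue_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_SDS))
    hypothalamus_radius_vox: int = 8
    wm_shell_radius_vox: int = 12
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 0.7)
    intensity_min: float = I_MIN
    intensity_max: float = I_MAX
    gm_outer_frac: float = _GM_OUTER_FRAC
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.tissue_means
        if not m["CSF"] < m["GM"] < m["WM"]:
            raise ValueError("tissue means must satisfy CSF < GM < WM")
        if any(sd < 0 for sd in self.tissue_sds.values()):
            raise ValueError("tissue SDs must be non-negative")
        if self.wm_shell_radius_vox <= self.hypothalamus_radius_vox:
            raise ValueError("WM shell radius must exceed the GM sphere radius")
        s_min = min(self.grid_shape)
        wm_min_semiaxis = _WM_OUTER_FRAC * s_min * min(_AXIS_RATIOS)
        if self.wm_shell_radius_vox > wm_min_semiaxis:
            raise ValueError(
                f"wm_shell_radius_vox={self.wm_shell_radius_vox} does not fit "
                f"inside the WM core (semi-axis {wm_min_semiaxis:.1f} vox)")
        if not _WM_OUTER_FRAC < self.gm_outer_frac < _BRAIN_FRAC:
            raise ValueError("gm_outer_frac must lie between the WM and brain radii")


def _center(shape: Sequence[int]) -> np.ndarray:
    return np.array([s // 2 for s in shape], dtype=float)


def _radius_fields(shape: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean voxel distance from the centre, and per-axis offsets."""
    c = _center(shape)
    grids = np.indices(shape, dtype=float)
    offs = np.stack([grids[i] - c[i] for i in range(3)])
    return np.sqrt((offs ** 2).sum(axis=0)), offs


def _ellipsoid_rho(offs: np.ndarray, radius_vox: float) -> np.ndarray:
    """Normalised ellipsoid radius (<= 1 means inside)."""
    axes = np.array([radius_vox * r for r in _AXIS_RATIOS])
    return np.sqrt(sum((offs[i] / axes[i]) ** 2 for i in range(3)))


def phantom_labels(spec: PhantomSpec) -> TissueLabelMap:
    """Ground-truth tissue geometry of :func:`generate_phantom` (no noise)."""
    s_min = min(spec.grid_shape)
    dist, offs = _radius_fields(spec.grid_shape)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[_ellipsoid_rho(offs, _BRAIN_FRAC * s_min) <= 1.0] = CSF
    labels[_ellipsoid_rho(offs, spec.gm_outer_frac * s_min) <= 1.0] = GM
    labels[_ellipsoid_rho(offs, _WM_OUTER_FRAC * s_min) <= 1.0] = WM
    # Central GM sphere ("hypothalamus"); the surrounding WM is its shell.
    labels[dist <= spec.hypothalamus_radius_vox] = GM
    return TissueLabelMap(labels, voxel_size=spec.voxel_size)


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, TissueLabelMap]:
    """Draw a noisy phantom volume plus its ground-truth label map.

    Bit-reproducible for a given seed; the label map depends only on the
    geometry, never on the seed.
    """
    labels = phantom_labels(spec)
    rng = np.random.default_rng(spec.seed)
    data = np.zeros(spec.grid_shape, dtype=np.float64)
    for name, code in (("CSF", CSF), ("GM", GM), ("WM", WM)):
        m = labels.labels == code
        n = int(m.sum())
        data[m] = spec.tissue_means[name] + spec.tissue_sds[name] * rng.standard_normal(n)
    brain = labels.labels != BACKGROUND
    data[brain] = np.clip(data[brain], spec.intensity_min, spec.intensity_max)
    # keep brain voxels off the exact-zero background convention
    data[brain] = np.maximum(data[brain], spec.intensity_min + 1e-9)
    vol = IntensityVolume(
        data, voxel_size=spec.voxel_size,
        intensity_min=spec.intensity_min, intensity_max=spec.intensity_max)
    return vol, labels


def phantom_rois(
    labels: TissueLabelMap, spec: PhantomSpec | None = None
) -> tuple[ROIMask, ROIMask]:
    """GM ROI (central GM sphere) and the surrounding WM-shell ROI.

    When ``spec`` is given its radii are used directly; otherwise the GM
    sphere is recovered as the connected GM component containing the grid
    centre and the WM shell is taken 1.5x as wide.
    """
    from scipy import ndimage

    shape = labels.grid_shape
    dist, _ = _radius_fields(shape)
    if spec is not None:
        r_gm = float(spec.hypothalamus_radius_vox)
        r_wm = float(spec.wm_shell_radius_vox)
    else:
        c = tuple(int(s // 2) for s in shape)
        if labels.labels[c] != GM:
            raise ValueError("label map lacks the central GM structure")
        comp, _n = ndimage.label(labels.labels == GM)
        central = comp == comp[c]
        r_gm = float(dist[central].max())
        r_wm = 1.5 * r_gm
    if r_wm <= r_gm:
        raise ValueError("WM shell radius must exceed the GM sphere radius")
    gm_mask = (dist <= r_gm) & (labels.labels == GM)
    wm_mask = (dist > r_gm) & (dist <= r_wm) & (labels.labels == WM)
    if not gm_mask.any() or not wm_mask.any():
        raise ValueError("label map lacks the central GM sphere / WM shell")
    return (
        ROIMask(gm_mask, tissue="GM", voxel_size=labels.voxel_size),
        ROIMask(wm_mask, tissue="WM", voxel_size=labels.voxel_size),
    )


# ---------------------------------------------------------------------------
# Intensity distortions (models of interscan variation)
# ---------------------------------------------------------------------------

@dataclass
class DistortionSpec:
    """A known monotone intensity distortion.

    kinds
        ``identity`` —
        ``offset`` — global over/underexposure, params ``{"offset": n}``
        ``linear`` — exposure scaling with intensity, ``{"slope": m, "offset": n}``
        ``tissue_piecewise`` — per-tissue over/underexposure: piecewise-linear
        map anchored at (0, 0), each tissue mean scaled by its own slope,
        and the top of the range fixed; params
        ``{"slopes": {"CSF": ., "GM": ., "WM": .}, "tissue_means": {...}}``
        (means default to the phantom defaults)
        ``smooth_nonlinear`` — monotone cubic (PCHIP) through control points,
        params ``{"points": [(x0, y0), ...]}``
    """

    kind: str = "identity"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (
            "identity", "offset", "linear", "tissue_piecewise", "smooth_nonlinear"
        ):
            raise ValueError(f"unknown distortion kind {self.kind!r}")


def distortion_function(
    d: DistortionSpec,
    intensity_min: float = I_MIN,
    intensity_max: float = I_MAX,
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorised mapping for a distortion; raises on non-monotone parameters."""
    lo, hi = intensity_min, intensity_max
    if d.kind == "identity":
        f = lambda x: np.asarray(x, dtype=float)
    elif d.kind == "offset":
        n = float(d.params["offset"])
        f = lambda x: np.asarray(x, dtype=float) + n
    elif d.kind == "linear":
        m = float(d.params["slope"])
        n = float(d.params.get("offset", 0.0))
        if m <= 0:
            raise ValueError("linear distortion needs a positive slope")
        f = lambda x: m * np.asarray(x, dtype=float) + n
    elif d.kind == "tissue_piecewise":
        slopes = d.params["slopes"]
        means = d.params.get("tissue_means", DEFAULT_TISSUE_MEANS)
        xs = [lo] + [means[t] for t in ("CSF", "GM", "WM")] + [hi]
        ys = [lo] + [slopes[t] * means[t] for t in ("CSF", "GM", "WM")] + [hi]
        if np.any(np.diff(xs) <= 0) or np.any(np.diff(ys) < 0):
            raise ValueError("tissue_piecewise distortion is not monotone")
        f = lambda x: np.interp(np.asarray(x, dtype=float), xs, ys)
    elif d.kind == "smooth_nonlinear":
        pts = np.asarray(d.params["points"], dtype=float)
        xs, ys = pts[:, 0], pts[:, 1]
        if np.any(np.diff(xs) <= 0) or np.any(np.diff(ys) < 0):
            raise ValueError("smooth_nonlinear control points are not monotone")
        pchip = PchipInterpolator(xs, ys, extrapolate=True)
        f = lambda x: pchip(np.asarray(x, dtype=float))
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(d.kind)
    # monotonicity audit on a dense grid
    grid = np.linspace(lo, hi, 2049)
    if np.any(np.diff(f(grid)) < -1e-9):
        raise ValueError(f"distortion {d.kind!r} is not monotone on the range")
    return f


def apply_distortion(vol: IntensityVolume, d: DistortionSpec) -> IntensityVolume:
    """Remap voxel intensities by a distortion; a new volume is returned.

    Outputs are clamped to the declared range.  Exact-zero voxels (the
    skull-stripped background) are left at zero: interscan variation acts on
    tissue signal, not on air.
    """
    f = distortion_function(d, vol.intensity_min, vol.intensity_max)
    out = np.clip(f(vol.data), vol.intensity_min, vol.intensity_max)
    out[vol.data == 0] = 0.0
    return vol.copy_with(out)


# ---------------------------------------------------------------------------
# Age-linked cohorts (biological variation for the maintenance criterion)
# ---------------------------------------------------------------------------

@dataclass
class PhantomSubject:
    age: float
    spec: PhantomSpec
    volume: IntensityVolume
    labels: TissueLabelMap


def generate_cohort(
    n_subjects: int = 12,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (40, 40, 40),
    age_range: tuple[float, float] = (20.0, 70.0),
    gm_age_slope: float = 0.0012,
    gm_frac_jitter_sd: float = 0.002,
    noiseless: bool = False,
    hypothalamus_radius_vox: int = 5,
    wm_shell_radius_vox: int = 7,
) -> list[PhantomSubject]:
    """Cohort of phantoms whose GM ribbon thins with subject age.

    The outer GM radius shrinks by ``gm_age_slope`` (fraction of the grid per
    year) around age 45, with a small Gaussian jitter, so whole-brain GM
    volume carries a strong negative correlation with age — the biological
    signal the maintenance criterion requires standardisation to preserve.
    """
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(*age_range, size=n_subjects))
    sds = (
        {"CSF": 0.0, "GM": 0.0, "WM": 0.0}
        if noiseless else dict(DEFAULT_TISSUE_SDS)
    )
    subjects = []
    for i, age in enumerate(ages):
        frac = 0.40 - gm_age_slope * (age - 45.0)
        if not noiseless and gm_frac_jitter_sd > 0:
            frac += gm_frac_jitter_sd * rng.standard_normal()
        frac = float(np.clip(frac, _WM_OUTER_FRAC + 0.02, _BRAIN_FRAC - 0.02))
        spec = PhantomSpec(
            grid_shape=grid_shape,
            tissue_sds=sds,
            hypothalamus_radius_vox=hypothalamus_radius_vox,
            wm_shell_radius_vox=wm_shell_radius_vox,
            gm_outer_frac=frac,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, labels = generate_phantom(spec)
        subjects.append(PhantomSubject(float(age), spec, vol, labels))
    return subjects
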