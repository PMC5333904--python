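"""Volume and mask containers, NIfTI-1 I/O, and the global intensity conventions.

All images handled by this package live on one shared voxel grid: the
registration that would normally bring scans of different subjects into a
common space is an external concern.  Volumes are kept as floating point
internally; the nominal 12-bit scale (0-4095) of T1-weighted MP2RAGE data is
a per-dataset convention, configurable through :class:`IntensityRange` or a
TOML config file.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("mristand")

#: Default intensity conventions of skull-stripped T1-weighted MP2RAGE data.
I_MIN: float = 0.0
I_MAX: float = 4095.0

#: Integer tissue codes shared by every label map in the package.
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_NAMES = {BACKGROUND: "background", CSF: "CSF", GM: "GM", WM: "WM"}
TISSUE_CODES = {"background": BACKGROUND, "CSF": CSF, "GM": GM, "WM": WM}

#: Grid tolerance for voxel-size comparison, in mm.
GRID_ATOL_MM = 1e-6


@dataclass(frozen=True)
class IntensityRange:
    """Declared intensity range of a dataset (default 12-bit, 0-4095)."""

    minimum: float = I_MIN
    maximum: float = I_MAX

    def __post_init__(self) -> None:
        if not self.minimum < self.maximum:
            raise ValueError("intensity_min must be < intensity_max")

    @property
    def span(self) -> float:
        return self.maximum - self.minimum


def load_config(path: str | Path) -> IntensityRange:
    """Read the intensity-range declaration from a TOML config file.

    Recognised keys: ``intensity_min`` and ``intensity_max`` (either at top
    level or under an ``[intensity]`` table).
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    table = cfg.get("intensity", cfg)
    return IntensityRange(
        float(table.get("intensity_min", I_MIN)),
        float(table.get("intensity_max", I_MAX)),
    )


@dataclass
class IntensityVolume:
    """A 3D scalar image on a fixed voxel grid.

    Parameters
    ----------
    data
        3D float array of intensities.
    voxel_size
        Edge lengths of one voxel in mm.
    intensity_min, intensity_max
        Declared intensity range of the dataset; values may exceed it (they
        are reported, never silently clipped).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 0.7)
    intensity_min: float = I_MIN
    intensity_max: float = I_MAX

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if not self.intensity_min < self.intensity_max:
            raise ValueError("intensity_min must be < intensity_max")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def out_of_range_count(self) -> int:
        """Number of voxels outside the declared intensity range."""
        d = self.data
        return int(np.count_nonzero((d < self.intensity_min) | (d > self.intensity_max)))

    def copy_with(self, data: np.ndarray) -> "IntensityVolume":
        return IntensityVolume(
            data,
            voxel_size=self.voxel_size,
            intensity_min=self.intensity_min,
            intensity_max=self.intensity_max,
        )


@dataclass
class TissueLabelMap:
    """Hard tissue labels {0 background, 1 CSF, 2 GM, 3 WM} on a voxel grid."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 0.7)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.labels, 1), 0)):
                raise ValueError("label map must be integer valued")
            self.labels = self.labels.astype(np.int16)
        bad = np.setdiff1d(np.unique(self.labels), [BACKGROUND, CSF, GM, WM])
        if bad.size:
            raise ValueError(f"label map contains invalid codes {bad.tolist()}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def tissue_mask(self, tissue: int | str) -> np.ndarray:
        code = TISSUE_CODES[tissue] if isinstance(tissue, str) else int(tissue)
        return self.labels == code

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND


@dataclass
class ROIMask:
    """Boolean region-of-interest mask tagged with its tissue class."""

    mask: np.ndarray
    tissue: str  # "GM" or "WM"
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 0.7)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3D")
        if self.tissue not in ("GM", "WM"):
            raise ValueError("ROI tissue must be 'GM' or 'WM'")
        if self.voxel_count == 0:
            raise ValueError("ROI mask is empty")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape


Gridded = IntensityVolume | TissueLabelMap | ROIMask


def _grid_of(obj: Gridded) -> tuple[tuple[int, ...], tuple[float, ...]]:
    return obj.grid_shape, obj.voxel_size


def check_same_grid(a: Gridded, b: Gridded) -> bool:
    """True iff shapes match and voxel sizes agree within 1e-6 mm."""
    shape_a, vox_a = _grid_of(a)
    shape_b, vox_b = _grid_of(b)
    if shape_a != shape_b:
        return False
    return bool(np.allclose(vox_a, vox_b, rtol=0.0, atol=GRID_ATOL_MM))


def require_same_grid(a: Gridded, b: Gridded, what: str = "inputs") -> None:
    if not check_same_grid(a, b):
        raise ValueError(
            f"{what} are on different grids: "
            f"{_grid_of(a)[0]} @ {_grid_of(a)[1]} vs {_grid_of(b)[0]} @ {_grid_of(b)[1]}"
        )


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------

def read_volume(
    path: str | Path,
    intensity_range: IntensityRange | None = None,
) -> IntensityVolume:
    """Read a 3D scalar NIfTI-1 volume.

    Values outside the declared intensity range are counted and reported via
    a warning — never clipped: out-of-range voxels are a data-quality signal
    the caller may want to act on.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if data.dtype.kind not in "fiu":
        raise ValueError(f"{path}: non-scalar datatype {data.dtype}")
    rng = intensity_range or IntensityRange()
    # zooms are float32 in the header; round off the representation noise
    vox = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    vol = IntensityVolume(
        data.astype(np.float64),
        voxel_size=vox,
        intensity_min=rng.minimum,
        intensity_max=rng.maximum,
    )
    n_out = vol.out_of_range_count()
    if n_out:
        logger.warning(
            "%s: %d voxels outside declared range [%g, %g]",
            path, n_out, rng.minimum, rng.maximum,
        )
    return vol


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_volume(
    vol: IntensityVolume, path: str | Path, quantize: bool = False
) -> Path:
    """Write a volume as NIfTI-1.

    Float64 and lossless by default; with ``quantize`` values are rounded to
    the nearest integer, clamped to the declared range and stored as int16
    (the convention of the original 12-bit data).
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    if quantize:
        data = np.clip(
            np.rint(vol.data), vol.intensity_min, vol.intensity_max
        ).astype(np.int16)
    else:
        data = vol.data.astype(np.float64)
    nib.save(nib.Nifti1Image(data, _affine(vol.voxel_size)), str(path))
    return path


def read_label_map(path: str | Path) -> TissueLabelMap:
    """Read a tissue label map (NIfTI-1, integer codes 0-3)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label map, got shape {data.shape}")
    vox = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return TissueLabelMap(np.rint(data).astype(np.int16), voxel_size=vox)


def write_label_map(labels: TissueLabelMap, path: str | Path) -> Path:
    path = Path(path)
    nib.save(
        nib.Nifti1Image(labels.labels.astype(np.int16), _affine(labels.voxel_size)),
        str(path),
    )
    return path


def read_roi_mask(path: str | Path, tissue: str) -> ROIMask:
    """Read a boolean ROI mask (any nonzero voxel counts as in-mask)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    vox = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return ROIMask(data != 0, tissue=tissue, voxel_size=vox)


def write_roi_mask(roi: ROIMask, path: str | Path) -> Path:
    path = Path(path)
    nib.save(
        nib.Nifti1Image(roi.mask.astype(np.uint8), _affine(roi.voxel_size)), str(path)
    )
    return path
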