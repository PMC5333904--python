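"""The five intensity-standardisation transforms.

Every method produces a :class:`TransformFunction` — a serialisable monotone
mapping from target-image intensities to the reference scale:

PHM
    piecewise-linear interpolation between (I_min, I_min), the GM and WM
    histogram-mode anchors, and (I_max, I_max);
NHM
    a cubic spline through the same mode anchors plus near-diagonal guard
    points at intensities 1 and I_max - 1, avoiding PHM's contrast kinks;
CHM
    cumulative histogram matching at a fixed class resolution (1024 levels
    by default), i.e. matching every percentile at once;
RLS
    the global line fixed by the GM-ROI and WM-ROI median intensities of
    target and reference;
SPS
    piecewise-linear interpolation anchored at the CSF/GM/WM tissue-mean
    intensities from the segmentation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .histogram import CumulativeDistribution
from .volume_io import I_MAX, I_MIN, IntensityVolume

logger = logging.getLogger("mristand")

CHM_LEVELS = 1024  # class resolution of the cumulative matching

_METHODS = ("PHM", "NHM", "CHM", "RLS", "SPS", "identity")


@dataclass
class ROIMedians:
    """GM/WM ROI median intensities of target and reference images."""

    gm_target: float
    wm_target: float
    gm_reference: float
    wm_reference: float

    def __post_init__(self) -> None:
        if not (self.wm_target > self.gm_target and self.wm_reference > self.gm_reference):
            raise ValueError("WM medians must exceed GM medians")


@dataclass
class TransformFunction:
    """A monotone intensity mapping with a method tag.

    Anchor methods (PHM/NHM/RLS/SPS/identity) store ordered (input, output)
    anchors; CHM stores a per-class lookup table.  Evaluation clamps outputs
    to the domain and leaves exact-zero (background) voxels at zero.
    """

    method: str
    anchors: list[tuple[float, float]] | None = None
    lookup_table: np.ndarray | None = None
    levels: int | None = None
    domain: tuple[float, float] = (I_MIN, I_MAX)
    monotone: bool = True
    _spline: CubicSpline | None = field(default=None, repr=False, compare=False)
    _dense: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "CHM":
            if self.lookup_table is None or self.levels is None:
                raise ValueError("CHM transform needs a lookup table and levels")
            self.lookup_table = np.asarray(self.lookup_table, dtype=np.float64)
            if self.lookup_table.size != self.levels:
                raise ValueError(
                    f"CHM lookup has {self.lookup_table.size} entries, "
                    f"expected {self.levels}")
            if np.any(np.diff(self.lookup_table) < 0):
                raise ValueError("CHM lookup must be non-decreasing")
        else:
            if not self.anchors:
                raise ValueError(f"{self.method} transform needs anchors")
            xs = np.array([a[0] for a in self.anchors])
            if np.any(np.diff(xs) <= 0):
                raise ValueError("anchor inputs must be strictly increasing")
        if self.method == "NHM" and self._spline is None:
            xs = np.array([a[0] for a in self.anchors])
            ys = np.array([a[1] for a in self.anchors])
            self._spline = CubicSpline(xs, ys)  # not-a-knot ends

    # -- evaluation ---------------------------------------------------------

    def __call__(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        lo, hi = self.domain
        xc = np.clip(x, lo, hi)
        if self.method == "CHM":
            width = (hi + 1.0 - lo) / self.levels
            idx = np.clip(((xc - lo) / width).astype(np.int64), 0, self.levels - 1)
            out = self.lookup_table[idx]
        elif self.method == "RLS":
            (x0, y0), (x1, y1) = self.anchors
            m = (y1 - y0) / (x1 - x0)
            out = y0 + m * (xc - x0)
        elif self.method == "NHM":
            if self._dense is not None:  # monotonicity-repaired path
                out = np.interp(xc, *self._dense)
            else:
                out = self._spline(xc)
        else:  # PHM, SPS, identity: piecewise linear between anchors
            xs = np.array([a[0] for a in self.anchors])
            ys = np.array([a[1] for a in self.anchors])
            out = np.interp(xc, xs, ys)
        return np.clip(out, lo, hi)


def identity_transform(domain: tuple[float, float] = (I_MIN, I_MAX)) -> TransformFunction:
    return TransformFunction(
        "identity", anchors=[(domain[0], domain[0]), (domain[1], domain[1])],
        domain=domain)


def _check_modes(target: tuple[float, float], reference: tuple[float, float],
                 domain: tuple[float, float]) -> None:
    lo, hi = domain
    for name, (gm, wm) in (("target", target), ("reference", reference)):
        if not lo < gm < wm < hi:
            raise ValueError(
                f"{name} modes must satisfy {lo} < GM ({gm}) < WM ({wm}) < {hi}")


def build_phm(
    target_modes: tuple[float, float],
    reference_modes: tuple[float, float],
    domain: tuple[float, float] = (I_MIN, I_MAX),
) -> TransformFunction:
    """Piecewise-linear histogram matching anchored at the GM/WM modes."""
    _check_modes(target_modes, reference_modes, domain)
    lo, hi = domain
    anchors = [
        (lo, lo),
        (float(target_modes[0]), float(reference_modes[0])),
        (float(target_modes[1]), float(reference_modes[1])),
        (hi, hi),
    ]
    return TransformFunction("PHM", anchors=anchors, domain=domain)


def build_nhm(
    target_modes: tuple[float, float],
    reference_modes: tuple[float, float],
    domain: tuple[float, float] = (I_MIN, I_MAX),
) -> TransformFunction:
    """Cubic-spline histogram matching through the PHM anchors.

    Two near-diagonal guard points at intensities ``lo + 1`` and ``hi - 1``
    curb overshoot at the ends.  The spline is scanned for monotonicity on a
    dense grid; violations are logged and repaired by evaluating through a
    monotone (cumulative-maximum) envelope.
    """
    _check_modes(target_modes, reference_modes, domain)
    lo, hi = domain
    xs = [lo, lo + 1.0, float(target_modes[0]), float(target_modes[1]), hi - 1.0, hi]
    ys = [lo, lo + 1.0, float(reference_modes[0]), float(reference_modes[1]), hi - 1.0, hi]
    if np.any(np.diff(xs) <= 0):
        raise ValueError("NHM anchors coincide; spline is degenerate")
    t = TransformFunction("NHM", anchors=list(zip(xs, ys)), domain=domain)
    grid = np.linspace(lo, hi, 4097)
    vals = np.clip(t._spline(grid), lo, hi)
    if np.any(np.diff(vals) < -1e-9):
        n_bad = int(np.count_nonzero(np.diff(vals) < -1e-9))
        logger.warning(
            "NHM spline is non-monotone on %d grid intervals; "
            "outputs are clamped to a monotone envelope", n_bad)
        t.monotone = False
        t._dense = (grid, np.maximum.accumulate(vals))
    return t


def build_chm(
    target_cdf: CumulativeDistribution,
    reference_cdf: CumulativeDistribution,
    levels: int = CHM_LEVELS,
    domain: tuple[float, float] = (I_MIN, I_MAX),
) -> TransformFunction:
    """Cumulative histogram matching at a fixed class resolution.

    The intensity range is split into ``levels`` equal-width classes.  Each
    target class is assigned the reference class whose relative cumulative
    frequency is closest to its own (ties to the lowest level); the lookup
    is then forced non-decreasing so the black-to-white order is conserved.
    The lookup output is the lower edge of the chosen reference class, which
    keeps intensity 0 fixed.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    lo, hi = domain
    width = (hi + 1.0 - lo) / levels
    uppers = lo + width * np.arange(1, levels + 1) - 1.0  # top level per class
    p_t = target_cdf.at(uppers)
    p_r = reference_cdf.at(uppers)
    # per target class, reference class with minimal |P_R - P_T| (lowest wins)
    j = np.searchsorted(p_r, p_t, side="left")
    j = np.clip(j, 0, levels - 1)
    j_prev = np.clip(j - 1, 0, levels - 1)
    take_prev = np.abs(p_r[j_prev] - p_t) <= np.abs(p_r[j] - p_t)
    best = np.where(take_prev, j_prev, j)
    # searchsorted(left) already lands on the first of equal P_R values, and
    # take_prev uses <=, so ties resolve to the lowest qualifying class
    best = np.maximum.accumulate(best)  # enforce monotone lookup
    lut = lo + best * width
    return TransformFunction(
        "CHM", lookup_table=lut, levels=levels, domain=domain)


def build_rls(
    med: ROIMedians, domain: tuple[float, float] = (I_MIN, I_MAX)
) -> TransformFunction:
    """ROI-based linear standardisation: the line through the GM and WM
    ROI-median assignments, applied globally."""
    if med.wm_target == med.gm_target:
        raise ValueError("degenerate ROIs: target GM and WM medians coincide")
    anchors = [
        (float(med.gm_target), float(med.gm_reference)),
        (float(med.wm_target), float(med.wm_reference)),
    ]
    return TransformFunction("RLS", anchors=anchors, domain=domain)


def rls_coefficients(t: TransformFunction) -> tuple[float, float]:
    """(slope m, offset n) of an RLS transform."""
    (x0, y0), (x1, y1) = t.anchors
    m = (y1 - y0) / (x1 - x0)
    return m, y0 - m * x0


def build_sps(
    target_means: tuple[float, float, float],
    reference_means: tuple[float, float, float],
    domain: tuple[float, float] = (I_MIN, I_MAX),
) -> TransformFunction:
    """Segmentation-based piecewise-linear standardisation anchored at the
    CSF/GM/WM tissue means."""
    lo, hi = domain
    for name, (c, g, w) in (("target", target_means), ("reference", reference_means)):
        if not lo < c < g < w < hi:
            raise ValueError(f"{name} tissue means must be ordered CSF < GM < WM")
    anchors = [(lo, lo)] + [
        (float(t), float(r)) for t, r in zip(target_means, reference_means)
    ] + [(hi, hi)]
    return TransformFunction("SPS", anchors=anchors, domain=domain)


def apply_transform(vol: IntensityVolume, t: TransformFunction) -> IntensityVolume:
    """Voxelwise standardisation.  Exact-zero (background) voxels stay zero."""
    if (vol.intensity_min, vol.intensity_max) != tuple(t.domain):
        raise ValueError(
            f"volume range {(vol.intensity_min, vol.intensity_max)} does not "
            f"match transform domain {t.domain}")
    out = t(vol.data)
    out[vol.data == 0] = 0.0
    return vol.copy_with(out)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def serialize_transform(t: TransformFunction, path: str | Path | None = None) -> str:
    payload: dict = {
        "method": t.method,
        "domain": list(t.domain),
        "monotone": bool(t.monotone),
    }
    if t.method == "CHM":
        payload["levels"] = int(t.levels)
        payload["lookup_table"] = t.lookup_table.tolist()
    else:
        payload["anchors"] = [[float(a), float(b)] for a, b in t.anchors]
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def deserialize_transform(source: str | Path) -> TransformFunction:
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        source = Path(source).read_text()
    try:
        payload = json.loads(source)
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed transform JSON: {e}") from e
    if "method" not in payload:
        raise ValueError("transform JSON is missing the 'method' field")
    method = payload["method"]
    domain = tuple(payload.get("domain", (I_MIN, I_MAX)))
    if method == "CHM":
        t = TransformFunction(
            "CHM",
            lookup_table=np.asarray(payload["lookup_table"], dtype=float),
            levels=int(payload["levels"]),
            domain=domain,
            monotone=payload.get("monotone", True),
        )
    else:
        t = TransformFunction(
            method,
            anchors=[tuple(a) for a in payload["anchors"]],
            domain=domain,
            monotone=payload.get("monotone", True),
        )
        if method == "NHM" and not t.monotone:
            lo, hi = domain
            grid = np.linspace(lo, hi, 4097)
            t._dense = (grid, np.maximum.accumulate(np.clip(t._spline(grid), lo, hi)))
    return t
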