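"""Intensity histograms, robust smoothing, and GM/WM mode detection.

Unit-width histograms are the shared substrate of the mode-based transforms
(piecewise-linear and spline histogram matching), cumulative histogram
matching, and the CDF-based evaluation metrics.  Mode detection follows the
classic recipe for multimodal skull-stripped T1-weighted histograms: smooth
the histogram with robust locally weighted quadratic regression (robust
loess, 1% span), parameterise the smoothed curve with a cubic spline, and
take the highest local maximum inside the GM window (1000, 2500) and the WM
window (3000, 3500).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline

from .volume_io import (
    BACKGROUND, TISSUE_CODES,
    IntensityVolume, ROIMask, TissueLabelMap, require_same_grid,
)

GM_WINDOW = (1000.0, 2500.0)
WM_WINDOW = (3000.0, 3500.0)

_ROBUST_ITERATIONS = 5
_MIN_WINDOW = 6


@dataclass
class IntensityHistogram:
    """Counts over unit-width bins spanning [intensity_min, intensity_max + 1)."""

    bin_edges: np.ndarray  # length n_bins + 1, integer spacing 1
    counts: np.ndarray     # length n_bins, non-negative integers

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts/bin_edges size mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def levels(self) -> np.ndarray:
        """Left edge of each bin — the integer intensity level it represents."""
        return self.bin_edges[:-1]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count_at(self, level: float) -> int:
        idx = int(level - self.bin_edges[0])
        return int(self.counts[idx])

    @property
    def support(self) -> tuple[float, float]:
        """(lowest, highest) occupied intensity level."""
        occ = np.flatnonzero(self.counts)
        if occ.size == 0:
            raise ValueError("empty histogram")
        return float(self.levels[occ[0]]), float(self.levels[occ[-1]])


@dataclass
class SmoothedDensity:
    """Loess-smoothed relative frequencies with a cubic-spline parameterisation."""

    grid: np.ndarray
    values: np.ndarray
    spline: CubicSpline | None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.spline is not None:
            return self.spline(x)
        return np.interp(x, self.grid, self.values)


@dataclass
class ModeEstimate:
    tissue: str
    intensity: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo <= self.intensity <= hi:
            raise ValueError("mode estimate outside its window")


@dataclass
class CumulativeDistribution:
    """P(level) = fraction of voxels with intensity <= level, per integer level."""

    levels: np.ndarray
    P: np.ndarray
    total: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        self.P = np.asarray(self.P, dtype=np.float64)
        if np.any(np.diff(self.P) < -1e-12):
            raise ValueError("cumulative distribution must be non-decreasing")
        if abs(self.P[-1] - 1.0) > 1e-9:
            raise ValueError("cumulative distribution must end at 1")

    @property
    def support(self) -> tuple[float, float]:
        mass = np.diff(self.P, prepend=0.0)
        occ = np.flatnonzero(mass > 0)
        return float(self.levels[occ[0]]), float(self.levels[occ[-1]])

    def at(self, level: np.ndarray) -> np.ndarray:
        """P evaluated with a right-continuous step interpolation."""
        idx = np.clip(
            np.searchsorted(self.levels, level, side="right") - 1, -1,
            self.levels.size - 1)
        out = np.where(idx >= 0, self.P[np.maximum(idx, 0)], 0.0)
        return out


def compute_histogram(
    vol: IntensityVolume,
    mask: ROIMask | None = None,
    labels: TissueLabelMap | None = None,
    tissue: str | None = None,
) -> IntensityHistogram:
    """Unit-bin histogram of a volume, restricted to a mask or tissue class.

    With no mask and no labels, the whole brain is used with the exact-zero
    background excluded (skull-stripped convention).  With ``labels`` and a
    ``tissue`` name, only voxels of that tissue count; with ``labels`` alone
    all non-background voxels count.
    """
    if mask is not None:
        require_same_grid(vol, mask, "volume and ROI mask")
        sel = mask.mask
    elif labels is not None:
        require_same_grid(vol, labels, "volume and label map")
        if tissue is not None:
            sel = labels.labels == TISSUE_CODES[tissue]
        else:
            sel = labels.labels != BACKGROUND
    else:
        sel = vol.data != 0
    values = vol.data[sel]
    if values.size == 0:
        raise ValueError("selection contains no voxels")
    lo, hi = vol.intensity_min, vol.intensity_max
    n_bins = int(np.floor(hi) - np.floor(lo)) + 1
    idx = np.clip(np.floor(values - lo).astype(np.int64), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.floor(lo) + np.arange(n_bins + 1, dtype=np.float64)
    return IntensityHistogram(edges, counts)


# ---------------------------------------------------------------------------
# Robust loess smoothing (locally weighted quadratic regression)
# ---------------------------------------------------------------------------

def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _bisquare(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - u ** 2) ** 2


def _loess_quadratic(
    x: np.ndarray, y: np.ndarray, k: int, iterations: int = _ROBUST_ITERATIONS
) -> np.ndarray:
    """Robust loess with local quadratic fits over k-nearest contiguous windows.

    Vectorised: every point's window has exactly k points (edge windows are
    shifted inward), so the weighted normal equations are solved in batch.
    """
    n = x.size
    k = min(k, n)
    h = k // 2
    starts = np.clip(np.arange(n) - h, 0, n - k)
    xw = sliding_window_view(x, k)[starts]          # (n, k)
    yw = sliding_window_view(y, k)[starts]
    dx = xw - x[:, None]
    dmax = np.abs(dx).max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    w_kernel = _tricube(dx / dmax)
    X = np.stack([np.ones_like(dx), dx, dx ** 2], axis=-1)        # (n, k, 3)
    robust = np.ones(n)
    fitted = y.copy()
    for it in range(iterations + 1):
        w = w_kernel * sliding_window_view(robust, k)[starts]
        WX = X * w[..., None]
        A = np.einsum("nki,nkj->nij", WX, X)                      # (n, 3, 3)
        b = np.einsum("nki,nk->ni", WX, yw)                       # (n, 3)
        # ridge jitter keeps near-singular edge systems solvable
        A += 1e-12 * np.eye(3)
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        fitted = beta[:, 0]                                       # value at dx=0
        if it == iterations:
            break
        resid = y - fitted
        # Bisquare weights against a LOCAL residual scale: histogram counts
        # are heteroscedastic (Poisson), so a global median residual would
        # zero-weight entire peak regions rather than isolated outliers.
        rw = sliding_window_view(resid, k)[starts]                # (n, k)
        s_local = np.median(np.abs(rw), axis=1)
        s_local = np.maximum(s_local, 1e-300)
        robust = _bisquare(resid / (6.0 * s_local))
        robust[np.median(np.abs(rw), axis=1) == 0] = 1.0
    return fitted


def smooth_histogram(
    h: IntensityHistogram,
    span_fraction: float = 0.01,
    spline_break_spacing: float = 32.0,
) -> SmoothedDensity:
    """Robust-loess smoothing of the histogram plus spline parameterisation.

    The smoother runs over the contiguous occupied support; the window holds
    ``span_fraction`` of the histogram's data points (bins) — the classic 1%
    span.  The smoothed curve is then parameterised by a least-squares cubic
    spline with break points every ``spline_break_spacing`` intensity units
    (well below the tissue-peak widths, so peaks survive while bin-level
    noise does not); ``spline_break_spacing=0`` requests an interpolating
    spline instead.  Degenerate supports (fewer than 8 levels) skip the
    smoothing and are represented by the raw relative frequencies.
    """
    if h.total <= 0:
        raise ValueError("cannot smooth an empty histogram")
    if not 0 < span_fraction < 1:
        raise ValueError("span_fraction must be in (0, 1)")
    lo, hi = h.support
    i0 = int(lo - h.levels[0])
    i1 = int(hi - h.levels[0]) + 1
    grid = h.levels[i0:i1]
    freq = h.counts[i0:i1] / h.total
    if grid.size < 8:
        vals = freq.astype(float)
        spline = CubicSpline(grid, vals) if grid.size >= 2 else None
        return SmoothedDensity(grid.astype(float), vals, spline)
    # the span counts histogram data points, i.e. bins of the full vector
    k = int(round(span_fraction * h.counts.size))
    if k < _MIN_WINDOW:
        raise ValueError(
            f"span of {span_fraction:.3%} gives windows of {k} points; the "
            f"local quadratic fit needs at least {_MIN_WINDOW}")
    k += (k + 1) % 2  # odd windows centre on the fitted point
    grid = grid.astype(float)
    values = _loess_quadratic(grid, freq.astype(float), k)
    spline = _parameterise(grid, values, spline_break_spacing)
    return SmoothedDensity(grid, values, spline)


def _parameterise(grid: np.ndarray, values: np.ndarray, break_spacing: float):
    """Cubic-spline parameterisation of the smoothed curve.

    Least squares with evenly spaced interior break points when the support
    is long enough; plain interpolation otherwise (or when requested with
    ``break_spacing = 0``).
    """
    from scipy.interpolate import LSQUnivariateSpline

    if break_spacing and grid.size > 3 * break_spacing:
        step = int(break_spacing)
        knots = grid[step:-step:step]
        try:
            lsq = LSQUnivariateSpline(grid, values, knots, k=3)
            return CubicSpline(grid, lsq(grid))
        except Exception:  # Schoenberg-Whitney failures on odd supports
            pass
    return CubicSpline(grid, values)


def smooth_cumulative(
    h: IntensityHistogram, span_fraction: float = 0.01
) -> SmoothedDensity:
    """Loess-smoothed cumulative histogram (first-derivative view of the density).

    The second-derivative zero-crossings of this curve are the extrema of
    the density — the alternative reading of the mode-detection recipe,
    available behind :func:`detect_modes`'s ``on_cumulative`` flag.
    """
    if h.total <= 0:
        raise ValueError("cannot smooth an empty histogram")
    lo, hi = h.support
    i0 = int(lo - h.levels[0])
    i1 = int(hi - h.levels[0]) + 1
    grid = h.levels[i0:i1].astype(float)
    cum = np.cumsum(h.counts[i0:i1]) / h.total
    k = max(int(round(span_fraction * h.counts.size)), _MIN_WINDOW)
    k += (k + 1) % 2
    values = _loess_quadratic(grid, cum, k)
    return SmoothedDensity(grid, values, CubicSpline(grid, values))


# ---------------------------------------------------------------------------
# Mode detection
# ---------------------------------------------------------------------------

def _highest_local_max(
    d: SmoothedDensity, lo: float, hi: float
) -> float:
    """Intensity of the highest interior local maximum of d on [lo, hi]."""
    lo = max(lo, float(d.grid[0]))
    hi = min(hi, float(d.grid[-1]))
    if hi < lo:
        raise ValueError("mode window lies outside the histogram support")
    if hi == lo or d.grid.size < 4:
        # degenerate support: all mass effectively at one level
        sub = (d.grid >= lo) & (d.grid <= hi)
        if not sub.any() or not np.any(d.values[sub] > 0):
            raise ValueError("no mode in window")
        return float(d.grid[sub][int(np.argmax(d.values[sub]))])
    xs = np.arange(lo, hi + 0.25, 0.25)
    ys = d(xs)
    interior = np.zeros(xs.size, dtype=bool)
    interior[1:-1] = (ys[1:-1] >= ys[:-2]) & (ys[1:-1] >= ys[2:]) & (
        (ys[1:-1] > ys[:-2]) | (ys[1:-1] > ys[2:]))
    if not interior.any():
        raise ValueError(f"no mode in window ({lo:g}, {hi:g})")
    cand = np.flatnonzero(interior)
    best_y = ys[cand].max()
    # ties between equal-height maxima: lowest intensity wins (determinism)
    i = cand[np.flatnonzero(np.isclose(ys[cand], best_y, rtol=0, atol=1e-15))[0]]
    # parabolic refinement on the dense sample
    x0, x1, x2 = xs[i - 1], xs[i], xs[i + 1]
    y0, y1, y2 = ys[i - 1], ys[i], ys[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom < 0:
        x_hat = x1 + 0.5 * (y0 - y2) / denom * (x1 - x0)
    else:
        x_hat = x1
    return float(np.clip(x_hat, lo, hi))


def detect_modes(
    d: SmoothedDensity,
    gm_window: tuple[float, float] = GM_WINDOW,
    wm_window: tuple[float, float] = WM_WINDOW,
    histogram: IntensityHistogram | None = None,
    on_cumulative: bool = False,
) -> tuple[ModeEstimate, ModeEstimate]:
    """GM and WM histogram modes as spline local maxima inside fixed windows.

    With ``on_cumulative`` (requires ``histogram``) the modes are instead
    located as second-derivative zero-crossings of the smoothed *cumulative*
    histogram; on unimodal windows both routes agree.
    """
    if on_cumulative:
        if histogram is None:
            raise ValueError("on_cumulative mode detection needs the histogram")
        cum = smooth_cumulative(histogram)
        density = SmoothedDensity(
            cum.grid, cum.spline(cum.grid, 1), None)
        density = SmoothedDensity(
            cum.grid, density.values, CubicSpline(cum.grid, density.values))
        d = density
    gm = ModeEstimate("GM", _highest_local_max(d, *gm_window), tuple(gm_window))
    wm = ModeEstimate("WM", _highest_local_max(d, *wm_window), tuple(wm_window))
    return gm, wm


def cumulative_distribution(h: IntensityHistogram) -> CumulativeDistribution:
    """Relative cumulative frequencies P(level) = #{voxels <= level} / total."""
    if h.total <= 0:
        raise ValueError("empty histogram has no cumulative distribution")
    P = np.cumsum(h.counts) / h.total
    return CumulativeDistribution(h.levels, P, h.total)
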