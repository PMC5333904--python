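"""The four-level evaluation protocol and its statistical machinery.

Level 1 — histogram comparison: average and maximum absolute error between
tissue-specific cumulative probability distributions over the shared
intensity range, compared before/after standardisation with two-tailed
Wilcoxon signed-rank tests and the effect size r = Z / sqrt(N).

Level 2 — average image intensity: mean voxelwise |reference - target|
difference over voxels a tissue class claims in *both* label maps.

Level 3 — local image intensity: the intensity of the GM/WM boundary around
the hypothalamus, obtained through a three-colour transfer function whose
adjustable white point encodes the boundary; inter-individual variation of
that intensity is compared with the Pitman-Morgan test for correlated
variances (df = n - 2).

Level 4 — maintenance of biological variation: Pearson correlations between
whole-brain tissue volumes and age must survive standardisation; changes
are tested with Steiger's Z for dependent correlations and graded with
Cohen's q (0.10 / 0.30 / 0.50 = small / medium / large).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .histogram import CumulativeDistribution
from .volume_io import (
    GM, WM, TISSUE_CODES,
    IntensityVolume, ROIMask, TissueLabelMap, require_same_grid,
)

COHEN_R_BENCHMARKS = {"small": 0.10, "medium": 0.30, "large": 0.50}


# ---------------------------------------------------------------------------
# Level 1: histogram comparison
# ---------------------------------------------------------------------------

@dataclass
class CDFErrorResult:
    region: str
    average_abs_error: float
    maximum_abs_error: float
    shared_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 <= self.average_abs_error <= self.maximum_abs_error <= 1:
            raise ValueError("CDF errors must satisfy 0 <= average <= maximum <= 1")


def cdf_abs_error(
    target: CumulativeDistribution,
    reference: CumulativeDistribution,
    region: str = "",
) -> CDFErrorResult:
    """Average and maximum |P_T - P_R| over the shared occupied range."""
    lo_t, hi_t = target.support
    lo_r, hi_r = reference.support
    lo, hi = max(lo_t, lo_r), min(hi_t, hi_r)
    if hi < lo:
        raise ValueError("the occupied intensity supports do not overlap")
    grid = np.arange(lo, hi + 1.0)
    err = np.abs(target.at(grid) - reference.at(grid))
    return CDFErrorResult(region, float(err.mean()), float(err.max()), (lo, hi))


# ---------------------------------------------------------------------------
# Level 2: average image intensity
# ---------------------------------------------------------------------------

def voxelwise_intensity_difference(
    reference: IntensityVolume,
    target: IntensityVolume,
    ref_labels: TissueLabelMap,
    tgt_labels: TissueLabelMap,
    tissue: str,
    roi: ROIMask | None = None,
) -> float:
    """Mean |I_ref - I_tgt| over voxels the tissue claims in both label maps."""
    require_same_grid(reference, target, "reference and target volumes")
    require_same_grid(reference, ref_labels, "volume and reference labels")
    require_same_grid(reference, tgt_labels, "volume and target labels")
    code = TISSUE_CODES[tissue]
    sel = (ref_labels.labels == code) & (tgt_labels.labels == code)
    if roi is not None:
        require_same_grid(reference, roi, "volume and ROI")
        sel &= roi.mask
    if not sel.any():
        raise ValueError(f"no voxel is {tissue} in both label maps (and ROI)")
    return float(np.abs(reference.data[sel] - target.data[sel]).mean())


# ---------------------------------------------------------------------------
# Level 3: colour-coding and the hypothalamic boundary intensity
# ---------------------------------------------------------------------------

@dataclass
class ColourMap:
    """Three-colour piecewise-linear transfer function with adjustable middle."""

    lo: float
    hi: float
    colour_lo: tuple[int, int, int]
    colour_mid: tuple[int, int, int]
    colour_hi: tuple[int, int, int]
    mid_fraction: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("colour map needs lo < hi")
        if not 0 < self.mid_fraction < 1:
            raise ValueError("mid_fraction must be in (0, 1)")
        for c in (self.colour_lo, self.colour_mid, self.colour_hi):
            if any(not 0 <= v <= 255 for v in c):
                raise ValueError("colour channels must be 8-bit")


def t1w_colour_map(mid_fraction: float = 0.60) -> ColourMap:
    """T1-weighted preset: red at 0, adjustable white, blue at 4000.

    The default white point of 60% is the GM/WM boundary of the reference
    image around the hypothalamus.
    """
    return ColourMap(0.0, 4000.0, (255, 0, 0), (255, 255, 255), (0, 0, 255),
                     mid_fraction)


def t1map_colour_map(mid_fraction: float = 0.40) -> ColourMap:
    """Quantitative-T1 preset: blue at 950 ms, white at 40%, red at 3700 ms."""
    return ColourMap(950.0, 3700.0, (0, 0, 255), (255, 255, 255), (255, 0, 0),
                     mid_fraction)


def colorize(vol: IntensityVolume, cm: ColourMap) -> np.ndarray:
    """RGB volume (uint8, shape ``grid + (3,)``) from the transfer function."""
    t = np.clip((vol.data - cm.lo) / (cm.hi - cm.lo), 0.0, 1.0)
    out = np.empty(vol.grid_shape + (3,), dtype=np.uint8)
    lo = np.asarray(cm.colour_lo, dtype=float)
    mid = np.asarray(cm.colour_mid, dtype=float)
    hi = np.asarray(cm.colour_hi, dtype=float)
    mf = cm.mid_fraction
    below = t <= mf
    frac_lo = np.divide(t, mf, where=True)[..., None]
    frac_hi = ((t - mf) / (1.0 - mf))[..., None]
    rgb = np.where(
        below[..., None],
        lo + np.clip(frac_lo, 0, 1) * (mid - lo),
        mid + np.clip(frac_hi, 0, 1) * (hi - mid),
    )
    np.rint(rgb, out=rgb)
    out[:] = np.clip(rgb, 0, 255).astype(np.uint8)
    return out


def white_fraction_to_intensity(cm: ColourMap, fraction: float | None = None) -> float:
    """Intensity of the (adjustable) white point: lo + fraction * (hi - lo)."""
    f = cm.mid_fraction if fraction is None else float(fraction)
    if not 0 < f < 1:
        raise ValueError("fraction must be in (0, 1)")
    return cm.lo + f * (cm.hi - cm.lo)


def intensity_to_white_fraction(cm: ColourMap, intensity: float) -> float:
    """Inverse of :func:`white_fraction_to_intensity`."""
    f = (float(intensity) - cm.lo) / (cm.hi - cm.lo)
    if not 0 < f < 1:
        raise ValueError("intensity maps to a fraction outside (0, 1)")
    return f


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def interface_boundary_intensity(
    vol: IntensityVolume, labels: TissueLabelMap
) -> float:
    """Median intensity of the GM/WM interface voxels.

    An automated surrogate for a rater adjusting the white point until it
    highlights the boundary: the voxels considered are GM voxels with a
    face-adjacent WM neighbour and vice versa.
    """
    require_same_grid(vol, labels, "volume and label map")
    gm = labels.labels == GM
    wm = labels.labels == WM
    gm_touch = gm & ndimage.binary_dilation(wm, structure=_FACE_STRUCT)
    wm_touch = wm & ndimage.binary_dilation(gm, structure=_FACE_STRUCT)
    sel = gm_touch | wm_touch
    if not sel.any():
        raise ValueError("label map has no GM/WM interface")
    return float(np.median(vol.data[sel]))


# ---------------------------------------------------------------------------
# Paired statistics
# ---------------------------------------------------------------------------

@dataclass
class PairedTestResult:
    test: str
    statistic: float
    p_two_tailed: float
    n_pairs: int
    effect_size: float | None = None
    df: int | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_two_tailed <= 1:
            raise ValueError("p-value outside [0, 1]")


def wilcoxon_signed_rank(x, y) -> PairedTestResult:
    """Two-tailed Wilcoxon signed-rank test with the normal deviate Z.

    Convention: zero differences are dropped, the normal approximation is
    tie-corrected, no continuity correction is applied, and the effect size
    is r = Z / sqrt(N) with N = 2 * n_pairs — the convention under which 20
    pairs of one-signed differences saturate at |Z| = 3.92.  Positive Z
    means x tends to exceed y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        raise ValueError("need at least 5 nonzero paired differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    tie_sizes = np.unique(ranks, return_counts=True)[1]
    tie_term = float(((tie_sizes ** 3 - tie_sizes) / 48.0).sum())
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        raise ValueError("zero variance (all differences tied at one rank)")
    z = (w_plus - mu) / sigma
    p = 2.0 * stats.norm.sf(abs(z))
    r = z / np.sqrt(2 * n)
    return PairedTestResult("wilcoxon", float(z), float(min(p, 1.0)), n,
                            effect_size=float(r))


def pitman_morgan(x, y) -> PairedTestResult:
    """Pitman-Morgan two-tailed test for equal variances of correlated samples.

    t = r_sd * sqrt(n - 2) / sqrt(1 - r_sd^2) with r_sd the Pearson
    correlation of (x + y) with (x - y); df = n - 2.  Shapiro-Wilk normality
    p-values for both samples are attached for screening, not inference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    s, d = x + y, x - y
    if np.std(d) == 0 or np.std(s) == 0:
        r_sd = 0.0
    else:
        r_sd = float(np.corrcoef(s, d)[0, 1])
    r_sd = float(np.clip(r_sd, -1.0, 1.0))
    df = n - 2
    if abs(r_sd) >= 1.0:
        t = np.inf * np.sign(r_sd)
        p = 0.0
    else:
        t = r_sd * np.sqrt(df) / np.sqrt(1.0 - r_sd ** 2)
        p = 2.0 * stats.t.sf(abs(t), df)
    extra = None
    if 3 <= n <= 5000:
        extra = {
            "shapiro_p_x": float(stats.shapiro(x).pvalue),
            "shapiro_p_y": float(stats.shapiro(y).pvalue),
        }
    return PairedTestResult("pitman_morgan", float(t), float(min(p, 1.0)), n,
                            df=df, extra=extra)


def _fisher_z(r: float) -> float:
    return float(np.arctanh(r))


def cohens_q(r1: float, r2: float) -> float:
    """|z(r1) - z(r2)| with z the Fisher transform."""
    return abs(_fisher_z(r1) - _fisher_z(r2))


def grade_q(q: float) -> str:
    if q >= 0.50:
        return "large"
    if q >= 0.30:
        return "medium"
    if q >= 0.10:
        return "small"
    return "negligible"


def steiger_dependent_correlations(
    r_j1: float, r_j2: float, r_12: float, n: int
) -> PairedTestResult:
    """Steiger's Z for two dependent correlations sharing one variable.

    Common-index case with the pooled-r covariance (Steiger 1980, Z1*):
    H0: rho(j,1) = rho(j,2) given the correlation r_12 between variables 1
    and 2.  Effect size is Cohen's q.
    """
    for name, r in (("r_j1", r_j1), ("r_j2", r_j2), ("r_12", r_12)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z1, z2 = _fisher_z(r_j1), _fisher_z(r_j2)
    q = abs(z1 - z2)
    if z1 == z2:
        return PairedTestResult("steiger", 0.0, 1.0, n, effect_size=0.0)
    rbar = 0.5 * (r_j1 + r_j2)
    psi = r_12 * (1.0 - 2.0 * rbar ** 2) - 0.5 * rbar ** 2 * (
        1.0 - 2.0 * rbar ** 2 - r_12 ** 2)
    c = psi / (1.0 - rbar ** 2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    p = 2.0 * stats.norm.sf(abs(z))
    return PairedTestResult("steiger", float(z), float(min(p, 1.0)), n,
                            effect_size=float(q))


def icc_test_retest(run1, run2) -> float:
    """Test-retest ICC(3,1): two-way mixed, consistency, single measures."""
    import pingouin as pg

    run1 = np.asarray(run1, dtype=float)
    run2 = np.asarray(run2, dtype=float)
    if run1.shape != run2.shape or run1.size < 3:
        raise ValueError("need two equal-length runs of at least 3 subjects")
    between = run1 + run2
    if np.std(between) == 0 and np.std(run1 - run2) == 0:
        raise ValueError("zero variance across subjects")
    n = run1.size
    df = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["run1", "run2"], n),
        "score": np.concatenate([run1, run2]),
    })
    table = pg.intraclass_corr(
        data=df, targets="subject", raters="rater", ratings="score")
    sel = table["Type"].isin(["ICC3", "ICC(C,1)"])
    icc = float(table.loc[sel, "ICC"].iloc[0])
    if not np.isfinite(icc):
        raise ValueError("ICC undefined (zero variance across subjects)")
    return icc


@dataclass
class CorrelationMaintenance:
    r_age_before: float
    r_age_after: float
    r_before_after: float
    test: PairedTestResult
    changed: bool  # standardisation failure flag (p < 0.05)


def correlation_maintenance(
    volumes_before, volumes_after, age, alpha: float = 0.05
) -> CorrelationMaintenance:
    """Did standardisation preserve the age-volume correlation?

    Computes r(age, before), r(age, after), r(before, after) and Steiger's
    test for the change; a significant change flags the standardisation as
    having altered the biological signal.
    """
    vb = np.asarray(volumes_before, dtype=float)
    va = np.asarray(volumes_after, dtype=float)
    a = np.asarray(age, dtype=float)
    if not (vb.shape == va.shape == a.shape) or vb.size < 4:
        raise ValueError("need aligned subject vectors of length >= 4")
    for name, v in (("volumes_before", vb), ("volumes_after", va), ("age", a)):
        if np.std(v) == 0:
            raise ValueError(f"{name} is constant")
    r1 = float(np.corrcoef(a, vb)[0, 1])
    r2 = float(np.corrcoef(a, va)[0, 1])
    if np.allclose(vb, va):
        test = PairedTestResult("steiger", 0.0, 1.0, vb.size, effect_size=0.0)
        return CorrelationMaintenance(r1, r2, 1.0, test, False)
    r12 = float(np.corrcoef(vb, va)[0, 1])
    r12 = float(np.clip(r12, -0.999999, 0.999999))
    r1c = float(np.clip(r1, -0.999999, 0.999999))
    r2c = float(np.clip(r2, -0.999999, 0.999999))
    test = steiger_dependent_correlations(r1c, r2c, r12, vb.size)
    return CorrelationMaintenance(r1, r2, r12, test, test.p_two_tailed < alpha)
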