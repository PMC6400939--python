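"""Pixel-distribution features of a stitched biopsy image.

Lesion images often contain non-lesion tissue, so instead of spatial
features the pipeline characterises the *distribution* of pixel intensities.
Per biopsy it computes the empirical CDF of the pooled masked pixels and of
the brightest 1% of pixels, fits a three-parameter logistic

    F(x) = C / (1 + exp(-A (x - B)))

to each (A: slope, reflecting spread; B: horizontal shift, reflecting the
mean; C: upper asymptote, reflecting the bright tail), and adds the sample
mean, variance and max-to-min ratio of each pixel bin — 12 optical
predictors in total.

CDFs are evaluated on a fixed grid over max-normalised intensity so curves
from different biopsies share an abscissa and can be averaged within groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .imaging import StitchedImage

#: Canonical predictor order used everywhere a feature matrix is built.
FEATURE_NAMES = (
    "cdf_A_all",
    "cdf_B_all",
    "cdf_C_all",
    "cdf_A_top1",
    "cdf_B_top1",
    "cdf_C_top1",
    "mean_all",
    "var_all",
    "maxmin_all",
    "mean_top1",
    "var_top1",
    "maxmin_top1",
)

#: The four fixed predictor blocks evaluated as stand-alone classifiers.
FEATURE_BLOCKS = {
    "cdf_all": ("cdf_A_all", "cdf_B_all", "cdf_C_all"),
    "cdf_top1": ("cdf_A_top1", "cdf_B_top1", "cdf_C_top1"),
    "summary_all": ("mean_all", "var_all", "maxmin_all"),
    "summary_top1": ("mean_top1", "var_top1", "maxmin_top1"),
}

_A_CAP = 1e6  # slope cap for degenerate (step-function) CDFs


@dataclass(frozen=True)
class EmpiricalCDF:
    """Cumulative pixel-intensity distribution on an ascending grid."""

    grid: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.probs):
            raise ValueError("grid and probs must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if np.any(np.diff(self.probs) < 0):
            raise ValueError("probs must be nondecreasing")


@dataclass(frozen=True)
class LogisticFitParams:
    """Fitted logistic descriptors of one CDF."""

    A: float
    B: float
    C: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class FeatureVector:
    """The 12 optical predictors of one biopsy, in canonical order."""

    cdf_A_all: float
    cdf_B_all: float
    cdf_C_all: float
    cdf_A_top1: float
    cdf_B_top1: float
    cdf_C_top1: float
    mean_all: float
    var_all: float
    maxmin_all: float
    mean_top1: float
    var_top1: float
    maxmin_top1: float
    fits_converged: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def empirical_cdf(
    pixels: np.ndarray,
    n_grid: int = 1000,
    grid_range: tuple[float, float] | None = None,
) -> EmpiricalCDF:
    """Empirical CDF evaluated on a shared fixed grid.

    ``probs[i]`` is the fraction of pixels <= ``grid[i]``.  The grid spans
    ``grid_range`` (default: 0 to the sample maximum), so passing a common
    range makes curves from different samples averageable.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size < 2:
        raise ValueError("need at least 2 pixels")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    if grid_range is None:
        hi = float(pixels.max())
        lo = min(0.0, float(pixels.min()))
        if hi <= lo:
            hi = lo + 1.0
        grid_range = (lo, hi)
    grid = np.linspace(grid_range[0], grid_range[1], n_grid)
    sorted_px = np.sort(pixels)
    probs = np.searchsorted(sorted_px, grid, side="right") / pixels.size
    return EmpiricalCDF(grid=grid, probs=probs)


def top_fraction(pixels: np.ndarray, p: float) -> np.ndarray:
    """The ``ceil(p * n)`` brightest pixels (descending order)."""
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size == 0:
        raise ValueError("need at least 1 pixel")
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    k = math.ceil(p * pixels.size)
    return np.sort(pixels)[::-1][:k]


def _logistic(x: np.ndarray, A: float, B: float, C: float) -> np.ndarray:
    return C / (1.0 + np.exp(-np.clip(A * (x - B), -500.0, 500.0)))


def fit_logistic(
    cdf: EmpiricalCDF | tuple[np.ndarray, np.ndarray]
) -> LogisticFitParams:
    """Least-squares logistic fit to a (possibly noisy) cumulative curve.

    Accepts an :class:`EmpiricalCDF` or a raw ``(grid, probs)`` pair (noisy
    sampled curves need not be monotone).  Initialisation: slope from the
    interquartile rise, B at the median intensity, C at the final cumulative
    probability.  A degenerate CDF (all mass at one grid step) cannot
    constrain the slope; it returns a non-converged fit with A capped, B at
    the step and C = 1.
    """
    if isinstance(cdf, EmpiricalCDF):
        x, y = cdf.grid, cdf.probs
    else:
        x = np.asarray(cdf[0], dtype=float)
        y = np.asarray(cdf[1], dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 grid points")

    jumps = np.diff(y)
    if np.count_nonzero(jumps) <= 1:  # step function: slope unidentifiable
        step_idx = int(np.argmax(jumps)) if np.any(jumps > 0) else 0
        return LogisticFitParams(
            A=_A_CAP, B=float(x[step_idx]), C=1.0,
            rss=float(np.sum((y - _logistic(x, _A_CAP, x[step_idx], 1.0)) ** 2)),
            converged=False,
        )

    c0 = max(float(y[-1]), 1e-3)
    y_mono = np.maximum.accumulate(y)  # initialisation quantiles only
    q25 = float(np.interp(0.25 * c0, y_mono, x))
    q50 = float(np.interp(0.50 * c0, y_mono, x))
    q75 = float(np.interp(0.75 * c0, y_mono, x))
    iqr = max(q75 - q25, (x[-1] - x[0]) / len(x))
    # logistic rises from 0.25C to 0.75C over ~2.2/A
    a0 = 2.2 / iqr
    p0 = (a0, q50, min(c0, 1.0))
    bounds = ([1e-12, x[0] - (x[-1] - x[0]), 0.0], [_A_CAP, x[-1] + (x[-1] - x[0]), 1.05])
    try:
        popt, _ = curve_fit(_logistic, x, y, p0=p0, bounds=bounds, maxfev=20000)
        resid = y - _logistic(x, *popt)
        return LogisticFitParams(
            A=float(popt[0]), B=float(popt[1]), C=float(popt[2]),
            rss=float(np.sum(resid**2)), converged=True,
        )
    except RuntimeError:
        resid = y - _logistic(x, *p0)
        return LogisticFitParams(
            A=float(p0[0]), B=float(p0[1]), C=float(p0[2]),
            rss=float(np.sum(resid**2)), converged=False,
        )


def summary_stats(
    pixels: np.ndarray, eps: float | None = None
) -> tuple[float, float, float]:
    """Sample mean, variance (n-1 denominator) and max/min ratio.

    The ratio denominator is floored at ``eps`` (default: the smallest
    positive value in the sample) so near-zero dark pixels do not blow up the
    dynamic-range estimate.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size < 2:
        raise ValueError("need at least 2 pixels")
    mean = float(pixels.mean())
    var = float(pixels.var(ddof=1))
    mn, mx = float(pixels.min()), float(pixels.max())
    if mn <= 0:
        if eps is None:
            pos = pixels[pixels > 0]
            if pos.size == 0:
                raise ValueError("all pixels are zero and no eps floor configured")
            eps = float(pos.min())
        mn = max(mn, eps)
    ratio = mx / mn
    return mean, var, ratio


def extract_features(
    stitched: StitchedImage, n_grid: int = 1000, top_p: float = 0.01
) -> FeatureVector:
    """Assemble the 12 optical predictors of one stitched biopsy image.

    Logistic CDF fits use max-normalised intensity (shared [0, 1] grid) so
    the A/B/C parameters are comparable across biopsies; the summary
    statistics are computed on the calibrated intensities themselves.
    """
    pixels = np.asarray(stitched.pooled_pixels, dtype=float)
    if pixels.size == 0:
        raise ValueError("stitched image has no pooled pixels")

    top = top_fraction(pixels, top_p)
    scale = float(pixels.max())
    if scale <= 0:
        raise ValueError("image has no positive pixels")
    norm_all = pixels / scale
    norm_top = top / scale

    fit_all = fit_logistic(empirical_cdf(norm_all, n_grid, grid_range=(0.0, 1.0)))
    fit_top = fit_logistic(empirical_cdf(norm_top, n_grid, grid_range=(0.0, 1.0)))

    mean_all, var_all, mm_all = summary_stats(pixels)
    if top.size >= 2:
        mean_top, var_top, mm_top = summary_stats(top)
    else:  # a single brightest pixel: degenerate but well defined
        mean_top, var_top, mm_top = float(top[0]), 0.0, 1.0

    return FeatureVector(
        cdf_A_all=fit_all.A, cdf_B_all=fit_all.B, cdf_C_all=fit_all.C,
        cdf_A_top1=fit_top.A, cdf_B_top1=fit_top.B, cdf_C_top1=fit_top.C,
        mean_all=mean_all, var_all=var_all, maxmin_all=mm_all,
        mean_top1=mean_top, var_top1=var_top, maxmin_top1=mm_top,
        fits_converged=fit_all.converged and fit_top.converged,
    )
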