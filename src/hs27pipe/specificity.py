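"""Specific-vs-nonspecific probe optimisation analysis.

The imaging protocol (post-excision window, probe incubation time, probe
dose) was tuned in a pre-clinical biopsy model by comparing a binding probe
(HS-27) against a non-binding control analog (HS-217).  The unit of analysis
is the *specificity ratio*: each specific-probe image divided by the mean
control fluorescence of its experimental arm.  Per arm the module builds
per-biopsy survival curves (1 minus the cumulative probability) of those
ratios on a shared grid, averages them with a pointwise SEM, and compares
arms with two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import Biopsy

DEFAULT_KS_CAP = 2000  # pixels subsampled per arm before KS testing


@dataclass(frozen=True)
class SurvivalCurve:
    """Fraction of values exceeding each grid point (1 - CDF)."""

    grid: np.ndarray
    frac: np.ndarray

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.frac):
            raise ValueError("grid and frac must align")
        if np.any(np.diff(self.frac) > 1e-12):
            raise ValueError("frac must be nonincreasing")


@dataclass
class ArmResult:
    """Per-arm survival-curve summary for one optimisation condition."""

    arm_label: str
    curves: list[SurvivalCurve]
    grid: np.ndarray
    mean_frac: np.ndarray
    sem_frac: np.ndarray
    pooled_ratios: np.ndarray
    mean_ratio: float

    @property
    def n_biopsies(self) -> int:
        return len(self.curves)


def specificity_ratio(hs27_pixels: np.ndarray, hs217_group_mean: float) -> np.ndarray:
    """Per-pixel specific-probe intensity over the arm's control mean."""
    if hs217_group_mean <= 0:
        raise ValueError("nonspecific group mean must be positive")
    return np.asarray(hs27_pixels, dtype=float) / hs217_group_mean


def nonspecific_group_mean(hs217_pixel_vectors: list[np.ndarray]) -> float:
    """Pixel-weighted mean over all pooled control-probe pixels of an arm."""
    if not hs217_pixel_vectors:
        raise ValueError("need at least one control biopsy")
    pooled = np.concatenate([np.asarray(v, dtype=float).ravel() for v in hs217_pixel_vectors])
    if pooled.size == 0:
        raise ValueError("control biopsies contain no pixels")
    return float(pooled.mean())


def survival_curve(values: np.ndarray, grid: np.ndarray) -> SurvivalCurve:
    """1 minus the empirical CDF of ``values`` evaluated on ``grid``."""
    values = np.asarray(values, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("values must be nonempty")
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    sorted_v = np.sort(values)
    frac = 1.0 - np.searchsorted(sorted_v, grid, side="right") / values.size
    return SurvivalCurve(grid=grid, frac=frac)


def build_arm(
    arm_label: str,
    pairs: list[tuple[Biopsy, Biopsy]],
    grid: np.ndarray,
) -> ArmResult:
    """Specificity ratios, per-biopsy survival curves and mean +/- SEM.

    ``pairs`` holds (specific, control) biopsies; the control mean is pooled
    over the whole arm, mirroring the arm-wise normalisation of the assay.
    """
    if not pairs:
        raise ValueError("arm has no biopsy pairs")
    ctrl_mean = nonspecific_group_mean([c.pooled_pixels for _, c in pairs])
    per_biopsy_ratios = [specificity_ratio(s.pooled_pixels, ctrl_mean) for s, _ in pairs]
    curves = [survival_curve(r, grid) for r in per_biopsy_ratios]
    frac_mat = np.vstack([c.frac for c in curves])
    mean_frac = frac_mat.mean(axis=0)
    n = frac_mat.shape[0]
    sem_frac = frac_mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean_frac)
    pooled = np.concatenate(per_biopsy_ratios)
    return ArmResult(
        arm_label=arm_label,
        curves=curves,
        grid=grid,
        mean_frac=mean_frac,
        sem_frac=sem_frac,
        pooled_ratios=pooled,
        mean_ratio=float(pooled.mean()),
    )


def compare_arms(
    arm_a: ArmResult,
    arm_b: ArmResult,
    cap: int | None = DEFAULT_KS_CAP,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sample KS test between the pooled ratio samples of two arms.

    Millions of pixels make any difference 'significant', so each arm is
    subsampled (without replacement, seeded) to at most ``cap`` pixels before
    testing; pass ``cap=None`` to test the full pools.
    """
    a, b = arm_a.pooled_ratios, arm_b.pooled_ratios
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per arm")
    if cap is not None:
        rng = np.random.default_rng(seed)
        if a.size > cap:
            a = rng.choice(a, size=cap, replace=False)
        if b.size > cap:
            b = rng.choice(b, size=cap, replace=False)
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def run_optimization_experiment(
    arms: dict[str, list[tuple[Biopsy, Biopsy]]],
    n_grid: int = 1000,
    ks_cap: int | None = DEFAULT_KS_CAP,
    seed: int = 0,
) -> tuple[dict[str, ArmResult], pd.DataFrame, list[str]]:
    """Full optimisation analysis over named experimental arms.

    Returns per-arm results, a pairwise KS table (arm_a, arm_b, D, p,
    significant at alpha = 0.05), and the arm ranking by mean specificity
    ratio (largest — i.e. most specific — first).
    """
    if not arms:
        raise ValueError("no arms provided")
    for label, pairs in arms.items():
        if not pairs:
            raise ValueError(f"arm {label!r} has no biopsy pairs")
        for s, c in pairs:
            if s.agent != "specific" or c.agent != "nonspecific":
                raise ValueError(f"arm {label!r}: pairs must be (specific, nonspecific)")

    # Shared ratio grid across arms so mean +/- SEM curves are comparable.
    ratio_max = 0.0
    for label, pairs in arms.items():
        ctrl_mean = nonspecific_group_mean([c.pooled_pixels for _, c in pairs])
        for s, _ in pairs:
            ratio_max = max(ratio_max, float(s.pooled_pixels.max()) / ctrl_mean)
    grid = np.linspace(0.0, ratio_max * 1.05 + 1e-12, n_grid)

    results = {label: build_arm(label, pairs, grid) for label, pairs in arms.items()}

    rows = []
    for (la, ra), (lb, rb) in combinations(results.items(), 2):
        d, p = compare_arms(ra, rb, cap=ks_cap, seed=seed)
        rows.append({"arm_a": la, "arm_b": lb, "D": d, "p": p, "significant": p <= 0.05})
    ks_table = pd.DataFrame(rows, columns=["arm_a", "arm_b", "D", "p", "significant"])

    ranking = sorted(results, key=lambda l: results[l].mean_ratio, reverse=True)
    return results, ks_table, ranking
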