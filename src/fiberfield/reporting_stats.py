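"""Statistical comparisons, regression extrapolation, and report assembly.

Implant-vs-control location differences (nearest-neuron positions, local
densities, per-bin glial ratios) use two-sided pooled-variance two-sample
t-tests; distributional differences (CSSI, soma volume, dorsoventral
length) use the two-sample Kolmogorov–Smirnov test with the asymptotic
p-value by default.  Linear regression of a morphometric against distance
to the fiber is ordinary least squares, with the fitted line extrapolated
to the distance at which it crosses the contralateral mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "two_sample_location_test",
    "distribution_difference_test",
    "linear_fit_with_extrapolation",
    "build_report",
    "write_report",
]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r: float  # Pearson correlation
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs n >= 3")
        if not (-1.0 <= self.r <= 1.0):
            raise ValueError("correlation must lie in [-1, 1]")


def two_sample_location_test(
    x, y, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled variance by default.

    Degenerate input (zero variance in both samples with equal means) is
    reported as p = 1 by convention and logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
        logger.info("degenerate t-test input (identical constants): p = 1")
        return 0.0, 1.0
    t, p = sstats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def distribution_difference_test(
    x, y, method: str = "asymp"
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    Returns (D, p) with D = sup|F̂x − F̂y|.  ``method`` is "asymp"
    (default) or "exact" for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = sstats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def linear_fit_with_extrapolation(
    x, y, control_mean: float
) -> tuple[RegressionFit, float | None, str]:
    """OLS fit of y on x, extrapolated to where the line meets control_mean.

    Returns (fit, crossing, flag).  crossing = (control_mean − intercept) /
    slope; flag is "ok", or "no_crossing" when the slope is ~0 or the
    crossing lies at a non-positive distance (the line never reaches the
    control level in the physical direction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs n >= 3")
    if x.std() == 0:
        raise ValueError("zero-variance x")
    res = sstats.linregress(x, y)
    fit = RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=int(x.size),
    )
    scale = max(abs(y).max(), 1.0)
    if abs(fit.slope) < 1e-12 * scale:
        return fit, None, "no_crossing"
    crossing = (control_mean - fit.intercept) / fit.slope
    if crossing <= 0:
        return fit, float(crossing), "no_crossing"
    return fit, float(crossing), "ok"


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def build_report(
    position_summary: pd.DataFrame | None = None,
    density_summary: pd.DataFrame | None = None,
    morphometry_comparison: pd.DataFrame | None = None,
    discriminability_table: pd.DataFrame | None = None,
    glia_comparison: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the report bundle from upstream tables.

    Every provided section is passed through unchanged (deterministic:
    identical inputs give byte-identical CSV output).  Missing required
    sections are reported together in one error.
    """
    sections = {
        "position_summary": position_summary,
        "density_summary": density_summary,
        "morphometry_comparison": morphometry_comparison,
        "discriminability": discriminability_table,
        "glia_comparison": glia_comparison,
    }
    present = {k: v for k, v in sections.items() if v is not None}
    if not present:
        missing = ", ".join(sections)
        raise ValueError(f"no report inputs provided; expected any of: {missing}")
    return present


def write_report(report: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each section as CSV; returns the written paths.

    Note: no multiple-testing correction is applied across radial bins or
    positions; p-values are reported as computed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(report):
        path = out_dir / f"{name}.csv"
        report[name].to_csv(path, index=False)
        paths.append(path)
    return paths
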