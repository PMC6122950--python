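"""Detection of the intracapsid solid-to-fluid DNA transition temperature.

The ejection enthalpy per virion ΔH_ej(T) is essentially linear in
temperature on either side of the mechano-structural transition of the
packaged genome, with an abrupt slope inversion at T*.  T* is located by
exhaustive two-segment weighted least squares: two *independent* lines (the
data show a discontinuity, not a hinge) fitted on either side of a candidate
breakpoint scanned on a 0.1 °C grid, picking the breakpoint that minimizes
the total SSE.  The segment slopes are proxies for the heat capacity change
ΔCp of the ejection process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EnthalpySeries",
    "TransitionFit",
    "TstarMap",
    "InsufficientDataError",
    "fit_two_segment",
    "tstar_vs_mg",
]

BREAKPOINT_GRID_C = 0.1  # exhaustive-search resolution, °C


class InsufficientDataError(ValueError):
    """Too few temperature points for a two-segment fit."""


@dataclass(frozen=True)
class EnthalpySeries:
    """ΔH_ej per virion versus temperature at one Mg concentration."""

    temperatures: np.ndarray  # °C, strictly increasing
    dH_ej: np.ndarray  # J/virion
    se: np.ndarray  # J/virion, standard errors (0 = unweighted)
    mg_mM: float
    sparse_side_warning: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, float)
        h = np.asarray(self.dH_ej, float)
        s = np.asarray(self.se, float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if h.shape != t.shape or s.shape != t.shape:
            raise ValueError("dH_ej and se must match temperatures in length")
        if np.any(s < 0):
            raise ValueError("standard errors must be >= 0")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "dH_ej", h)
        object.__setattr__(self, "se", s)


@dataclass(frozen=True)
class TransitionFit:
    t_star: float  # °C
    slope_below: float  # J/virion/°C (ΔCp proxy)
    slope_above: float
    sse: float
    inversion: bool  # slope signs differ
    significant: bool  # inversion and both slope |t|-statistics > 2
    mg_mM: float


@dataclass(frozen=True)
class TstarMap:
    """T* versus Mg concentration with a saturation flag.

    ``saturation_mM`` is the lowest concentration from which consecutive T*
    values change by less than 1 °C (None if T* keeps moving, or with a
    single entry).
    """

    entries: tuple[tuple[float, float, bool], ...]  # (mg_mM, t_star, inversion)
    saturation_mM: float | None


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line; returns (slope, intercept, sse, slope_t)."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx == 0:
        return 0.0, ym, float(np.sum(w * (y - ym) ** 2)), 0.0
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    sse = float(np.sum(w * resid**2))
    dof = x.size - 2
    if dof > 0 and sse > 0:
        sigma2 = sse / dof
        slope_se = np.sqrt(sigma2 / sxx)
        t_stat = abs(slope) / slope_se
    else:
        t_stat = np.inf if x.size >= 2 else 0.0
    return float(slope), float(intercept), sse, float(t_stat)


def fit_two_segment(series: EnthalpySeries, *, connected: bool = False) -> TransitionFit:
    """Locate the ΔH_ej(T) breakpoint by exhaustive two-segment regression.

    Candidate breakpoints run on a 0.1 °C grid between the 2nd and (n−1)th
    temperature; each side is fitted by weighted least squares (weights
    1/SE² when all SEs are positive).  The default fits two unconnected
    lines; ``connected=True`` fits a continuous hinge instead.  When several
    breakpoints tie (a zero-SSE plateau between two sample points on exact
    data), the plateau midpoint is returned.

    The inversion flag records opposite slope signs; significance
    additionally requires each slope's |t|-statistic to exceed 2.
    """
    t, y, se = series.temperatures, series.dH_ej, series.se
    n = t.size
    if n < 5:
        raise InsufficientDataError("need at least 5 temperature points")
    w = 1.0 / se**2 if np.all(se > 0) else np.ones(n)

    grid = np.arange(t[1], t[-2] + BREAKPOINT_GRID_C / 2, BREAKPOINT_GRID_C)
    best: list[tuple[float, float]] = []  # (sse, breakpoint)
    results = {}
    for bp in grid:
        left = t <= bp
        right = ~left
        if left.sum() < 2 or right.sum() < 2:
            continue
        if connected:
            # continuous hinge: y = a + b1·(T−bp) + (b2−b1)·max(T−bp, 0)
            X = np.column_stack([np.ones(n), t - bp, np.maximum(t - bp, 0.0)])
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            resid = y - X @ coef
            sse = float(np.sum(w * resid**2))
            s1, s2 = float(coef[1]), float(coef[1] + coef[2])
            t1 = t2 = np.inf  # hinge t-stats not used for the default path
        else:
            s1, _, sse1, t1 = _wls_line(t[left], y[left], w[left])
            s2, _, sse2, t2 = _wls_line(t[right], y[right], w[right])
            sse = sse1 + sse2
        best.append((sse, float(bp)))
        results[float(bp)] = (s1, s2, sse, t1, t2)

    if not best:
        raise InsufficientDataError("no admissible breakpoint with >= 2 points per side")
    sses = np.array([s for s, _ in best])
    bps = np.array([b for _, b in best])
    min_sse = sses.min()
    scale = max(float(np.sum(w * (y - np.average(y, weights=w)) ** 2)), 1e-300)
    tol = min_sse + 1e-9 * scale
    plateau = bps[sses <= tol]
    # tie-break: midpoint of the contiguous optimal plateau containing argmin
    bp_star = float(plateau[np.argmin(np.abs(plateau - (plateau[0] + plateau[-1]) / 2))])
    s1, s2, sse, t1, t2 = results[bp_star]
    inversion = bool(np.sign(s1) != np.sign(s2) and s1 != 0 and s2 != 0)
    significant = inversion and t1 > 2 and t2 > 2
    return TransitionFit(
        t_star=bp_star,
        slope_below=s1,
        slope_above=s2,
        sse=sse,
        inversion=inversion,
        significant=significant,
        mg_mM=series.mg_mM,
    )


def tstar_vs_mg(series_list: Sequence[EnthalpySeries]) -> TstarMap:
    """Assemble the T* versus Mg-concentration map.

    Applies :func:`fit_two_segment` per concentration; failed series are
    skipped with a warning.  T* is flagged saturated from the concentration
    where consecutive values change by less than 1 °C (Mg screening of the
    DNA helices saturates).
    """
    entries = []
    for series in sorted(series_list, key=lambda s: s.mg_mM):
        try:
            fit = fit_two_segment(series)
        except InsufficientDataError as exc:
            warnings.warn(f"mg={series.mg_mM} mM: {exc}")
            continue
        entries.append((series.mg_mM, fit.t_star, fit.inversion))
    saturation = None
    for (mg0, t0, _), (mg1, t1, _) in zip(entries, entries[1:]):
        if abs(t1 - t0) < 1.0:
            saturation = mg0
            break
    return TstarMap(tuple(entries), saturation)
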