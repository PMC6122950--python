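"""Time-resolved SAXS reduction: DNA-peak areas, rates, activation energy.

The diffraction peak of capsid-ordered DNA (q ≈ 0.18–0.32 Å⁻¹) disappears as
genomes leave the capsid, so its area versus time counts the remaining
DNA-filled particles.  The reduction chain is

1. background construction — non-negative least squares mixture of the
   measured buffer / detergent (oPOE) / receptor (LamB) component profiles,
   fitted on the flanks of the DNA window,
2. Gaussian + linear-baseline fit of the background-subtracted peak; the
   area is amplitude·width·√(2π),
3. first-order rate constants from ln(area) slopes, split at t = 20 s into
   the fast (synchronized) and slow (desynchronized) regimes,
4. Arrhenius fit ln k = ln A − Ea/(k_B·T) across temperatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit, nnls
from scipy.stats import linregress

K_B = 1.380649e-23  # J/K
_T0_K = 273.15
DNA_WINDOW = (0.18, 0.32)  # Å⁻¹
#: flanks of the DNA window used for background coefficient fitting
BACKGROUND_FIT_REGION = ((0.10, 0.17), (0.33, 0.40))

__all__ = [
    "SAXSFrame",
    "BackgroundModel",
    "DNAPeakFit",
    "PeakAreaSeries",
    "RateFit",
    "ArrheniusResult",
    "construct_background",
    "subtract_background",
    "fit_dna_peak",
    "peak_area_series",
    "ejection_rates",
    "arrhenius_fit",
    "read_saxs_frame",
    "write_saxs_frame",
]


@dataclass(frozen=True)
class SAXSFrame:
    """One azimuthally averaged 1-D profile I(q) at a given time after mixing."""

    q: np.ndarray  # Å⁻¹, strictly increasing
    intensity: np.ndarray
    time: float  # s since mixing

    def __post_init__(self) -> None:
        q = np.asarray(self.q, float)
        i = np.asarray(self.intensity, float)
        if q.ndim != 1 or i.shape != q.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if not np.all(np.diff(q) > 0):
            raise ValueError("q must be strictly increasing")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)


@dataclass(frozen=True)
class BackgroundModel:
    """Mixture of component profiles plus a free constant offset."""

    component_names: tuple[str, ...]
    coefficients: np.ndarray  # ≥ 0, one per component
    offset: float
    profile: np.ndarray  # evaluated on the frame's q grid
    rank_deficient: bool = False


@dataclass(frozen=True)
class DNAPeakFit:
    area: float  # intensity·Å⁻¹
    center: float  # Å⁻¹
    width: float  # Å⁻¹ (Gaussian sigma)
    baseline_slope: float
    baseline_intercept: float
    window: tuple[float, float]
    peak_absent: bool = False


@dataclass(frozen=True)
class PeakAreaSeries:
    """DNA-peak area versus time at one temperature."""

    times: np.ndarray  # s, increasing
    areas: np.ndarray
    temperature_C: float
    peak_absent: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        a = np.asarray(self.areas, float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "areas", a)


@dataclass(frozen=True)
class RateFit:
    """First-order rate from an ln(area) vs t regression."""

    k: float  # 1/s
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class ArrheniusResult:
    k_by_temperature: tuple[tuple[float, float], ...]  # (°C, 1/s)
    activation_energy: float  # J/virion
    ln_prefactor: float
    ea_in_kT: float
    T_ref_C: float
    r_squared: float


# ---------------------------------------------------------------------------


def _region_mask(q: np.ndarray, region: Sequence[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(q.shape, bool)
    for lo, hi in region:
        mask |= (q >= lo) & (q <= hi)
    return mask


def construct_background(
    frame: SAXSFrame,
    components: Mapping[str, np.ndarray],
    *,
    component_q: np.ndarray | None = None,
    fit_region: Sequence[tuple[float, float]] = BACKGROUND_FIT_REGION,
) -> BackgroundModel:
    """Fit a non-negative mixture of component profiles to a frame.

    Coefficients are obtained by NNLS on the flanks of the DNA window (the
    peak itself is excluded so the DNA signal cannot leak into the
    background).  A free constant offset is included, so the residual has
    zero mean over the fit region.  Component profiles recorded on a
    different q grid are resampled linearly.
    """
    names = tuple(components)
    profiles = []
    for name in names:
        prof = np.asarray(components[name], float)
        if component_q is not None:
            prof = np.interp(frame.q, np.asarray(component_q, float), prof)
        elif prof.shape != frame.q.shape:
            raise ValueError(f"component {name!r} not on the frame q grid; pass component_q")
        profiles.append(prof)
    mask = _region_mask(frame.q, fit_region)
    if mask.sum() < len(names) + 1:
        raise ValueError("fit region contains too few points")
    # free offset via a +1/−1 column pair (keeps the problem in NNLS form)
    ones = np.ones(int(mask.sum()))
    design = np.column_stack([p[mask] for p in profiles] + [ones, -ones])
    rank = np.linalg.matrix_rank(design)
    deficient = rank < design.shape[1] - 1  # the ±1 pair is always collinear
    if deficient:
        warnings.warn("background component set is rank deficient; coefficients are not unique")
    coefs, _ = nnls(design, frame.intensity[mask])
    mix = coefs[: len(names)]
    offset = float(coefs[-2] - coefs[-1])
    profile = sum(c * p for c, p in zip(mix, profiles)) + offset
    return BackgroundModel(names, mix, offset, profile, rank_deficient=deficient)


def subtract_background(frame: SAXSFrame, background: BackgroundModel) -> SAXSFrame:
    return SAXSFrame(frame.q, frame.intensity - background.profile, frame.time)


def _gauss_line(q, amp, center, width, slope, intercept):
    return amp * np.exp(-0.5 * ((q - center) / width) ** 2) + slope * q + intercept


def fit_dna_peak(
    frame: SAXSFrame,
    window: tuple[float, float] = DNA_WINDOW,
    *,
    noise_sd: float | None = None,
) -> DNAPeakFit:
    """Gaussian + linear fit of the (background-subtracted) DNA peak.

    The fit is restricted to the DNA window; the reported area is the
    analytic Gaussian area amplitude·width·√(2π).  When the fitted amplitude
    falls below twice the noise level the peak is declared absent and the
    area set to zero.  ``noise_sd`` defaults to a robust estimate from the
    linear-detrended flanks of the window.
    """
    lo, hi = window
    mask = (frame.q >= lo) & (frame.q <= hi)
    if mask.sum() < 8:
        raise ValueError("DNA window not covered by the q grid")
    q, y = frame.q[mask], frame.intensity[mask]

    if noise_sd is None:
        edge = max(3, mask.sum() // 8)
        flank_q = np.concatenate([q[:edge], q[-edge:]])
        flank_y = np.concatenate([y[:edge], y[-edge:]])
        line = np.polyval(np.polyfit(flank_q, flank_y, 1), flank_q)
        resid = flank_y - line
        noise_sd = float(1.4826 * np.median(np.abs(resid - np.median(resid)))) or float(np.std(resid))

    slope0, icpt0 = np.polyfit(np.concatenate([q[:3], q[-3:]]), np.concatenate([y[:3], y[-3:]]), 1)
    detrended = y - (slope0 * q + icpt0)
    amp0 = max(float(detrended.max()), 1e-12)
    center0 = float(q[np.argmax(detrended)])
    p0 = (amp0, center0, 0.02, slope0, icpt0)
    bounds = ([0.0, lo, 1e-3, -np.inf, -np.inf], [np.inf, hi, 0.2, np.inf, np.inf])
    try:
        popt, _ = curve_fit(_gauss_line, q, y, p0=p0, bounds=bounds, maxfev=10000)
        amp, center, width, slope, icpt = (float(v) for v in popt)
    except RuntimeError:
        amp, center, width, slope, icpt = 0.0, center0, 0.02, float(slope0), float(icpt0)

    absent = amp < 2.0 * noise_sd
    area = 0.0 if absent else amp * width * np.sqrt(2 * np.pi)
    return DNAPeakFit(area, center, width, slope, icpt, window, peak_absent=absent)


def peak_area_series(
    frames: Sequence[SAXSFrame],
    components: Mapping[str, np.ndarray],
    temperature_C: float,
    *,
    component_q: np.ndarray | None = None,
) -> PeakAreaSeries:
    """Reduce a frame sequence to DNA-peak area versus time."""
    times, areas, absent = [], [], []
    for frame in frames:
        bg = construct_background(frame, components, component_q=component_q)
        fit = fit_dna_peak(subtract_background(frame, bg))
        times.append(frame.time)
        areas.append(fit.area)
        absent.append(fit.peak_absent)
    order = np.argsort(times)
    return PeakAreaSeries(
        np.asarray(times)[order],
        np.asarray(areas)[order],
        float(temperature_C),
        np.asarray(absent)[order],
    )


def ejection_rates(
    series: PeakAreaSeries, t_split: float = 20.0, *, min_area_fraction: float = 0.02
) -> tuple[RateFit | None, RateFit | None]:
    """Fast- and slow-regime first-order rate constants.

    k = −slope of the OLS line through (t, ln area), fitted separately for
    t < t_split (synchronized regime) and t > t_split (desynchronized
    regime).  Points with non-positive or absent peak area are excluded, as
    are areas below ``min_area_fraction`` of the series maximum — once the
    peak approaches the detection floor, ln(area) is dominated by noise (and
    by the non-negativity of the fitted amplitude) and would bias the slope.
    A regime with fewer than 3 usable points yields ``None``.
    """
    usable = series.areas > 0
    if series.peak_absent is not None:
        usable &= ~series.peak_absent
    if usable.any() and min_area_fraction > 0:
        usable &= series.areas > min_area_fraction * series.areas[usable].max()

    def regress(mask: np.ndarray) -> RateFit | None:
        mask = mask & usable
        if mask.sum() < 3:
            return None
        res = linregress(series.times[mask], np.log(series.areas[mask]))
        return RateFit(k=-float(res.slope), r_squared=float(res.rvalue) ** 2, n_points=int(mask.sum()))

    return regress(series.times < t_split), regress(series.times > t_split)


def arrhenius_fit(
    k_by_T: Sequence[tuple[float, float]],
    T_ref_C: float = 25.0,
) -> ArrheniusResult:
    """Activation energy from rate constants at several temperatures.

    Least squares on ln k = ln A − Ea/(k_B·T) with T in kelvin; Ea is
    −slope·k_B (J/virion), also reported in units of k_B·T_ref.  Points with
    k ≤ 0 are excluded with a warning; at least two usable temperatures are
    required.
    """
    pts = [(float(T), float(k)) for T, k in k_by_T]
    good = [(T, k) for T, k in pts if k > 0]
    if len(good) < len(pts):
        warnings.warn("non-positive rate constants excluded from the Arrhenius fit")
    if len(good) < 2:
        raise ValueError("need at least 2 temperatures with positive rates")
    inv_T = np.array([1.0 / (T + _T0_K) for T, _ in good])
    ln_k = np.array([np.log(k) for _, k in good])
    if len(good) == 2:
        slope = (ln_k[1] - ln_k[0]) / (inv_T[1] - inv_T[0])
        intercept = ln_k[0] - slope * inv_T[0]
        r2 = 1.0
    else:
        res = linregress(inv_T, ln_k)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue) ** 2
    ea = -slope * K_B
    return ArrheniusResult(
        k_by_temperature=tuple(good),
        activation_energy=float(ea),
        ln_prefactor=float(intercept),
        ea_in_kT=float(ea / (K_B * (T_ref_C + _T0_K))),
        T_ref_C=float(T_ref_C),
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# I/O: two-column whitespace text, one file per frame


def write_saxs_frame(frame: SAXSFrame, directory, prefix: str = "frame") -> Path:
    """Write ``frame_<t_s>.dat`` with columns ``q_invA intensity``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{prefix}_{frame.time:g}.dat"
    np.savetxt(path, np.column_stack([frame.q, frame.intensity]), header="q_invA intensity")
    return path


def read_saxs_frame(path) -> SAXSFrame:
    path = Path(path)
    data = np.loadtxt(path)
    stem = path.stem
    t = float(stem.rsplit("_", 1)[-1]) if "_" in stem else 0.0
    return SAXSFrame(data[:, 0], data[:, 1], t)
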