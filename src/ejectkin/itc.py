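"""Isothermal titration calorimetry trace handling.

The instrument readout is differential power (DP, heat flow) in µcal/s versus
time.  Traces carry run metadata (bath temperature, MgCl2 concentration,
titrant volume and phage titer) needed to convert integrated heat into an
ejection enthalpy per virion.  Conventions:

* time is in seconds, with t = 0 at the injection; samples at t < 0 are the
  pre-injection baseline used to estimate noise,
* exothermic deflections are stored as *positive* released heat flow after
  background subtraction (raw instrument polarity, if different, is the
  caller's concern and should be recorded in metadata),
* 1 cal = 4.184 J exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

J_PER_UCAL = 4.184e-6
#: metadata keys that must agree between a sample and its controls
_CONDITION_KEYS = ("temperature_C", "mg_mM")

__all__ = [
    "DPTrace",
    "ControlSet",
    "EnthalpyResult",
    "EquilibrationResult",
    "ConditionMismatchError",
    "UnitError",
    "subtract_backgrounds",
    "detect_equilibration",
    "integrate_ejection_enthalpy",
    "estimate_baseline",
    "read_dp_trace",
    "write_dp_trace",
]


class ConditionMismatchError(ValueError):
    """Sample and control traces were recorded under different conditions."""


class UnitError(ValueError):
    """Metadata required for a unit conversion is missing or invalid."""


@dataclass(frozen=True)
class DPTrace:
    """A differential-power time series.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing.  t = 0 marks the
        injection unless ``metadata['injection_time_s']`` says otherwise.
    power : array of float
        Heat flow in µcal/s (positive = exothermic, released heat).
    metadata : mapping
        Free-form run metadata.  Keys used by this package:
        ``temperature_C``, ``mg_mM``, ``titrant_uL``, ``titer_pfu_per_mL``,
        ``injection_time_s``, ``seed``.
    """

    time: np.ndarray
    power: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if t.ndim != 1 or p.shape != t.shape:
            raise ValueError("time and power must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise ValueError("DPTrace values must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "power", p)

    @property
    def injection_time(self) -> float:
        return float(self.metadata.get("injection_time_s", 0.0))

    def with_power(self, power: np.ndarray) -> "DPTrace":
        return DPTrace(self.time, np.asarray(power, float), dict(self.metadata))


@dataclass(frozen=True)
class ControlSet:
    """The three control titrations measured alongside each sample.

    The net background is phage-into-buffer + buffer-into-LamB minus
    buffer-into-buffer (the buffer-into-buffer mixing heat would otherwise be
    counted twice).
    """

    phage_into_buffer: DPTrace
    buffer_into_lamb: DPTrace
    buffer_into_buffer: DPTrace

    def traces(self) -> tuple[DPTrace, DPTrace, DPTrace]:
        return (self.phage_into_buffer, self.buffer_into_lamb, self.buffer_into_buffer)


@dataclass(frozen=True)
class EnthalpyResult:
    """Integrated ejection enthalpy."""

    dH_ej: float  # J per virion
    total_heat: float  # J
    n_virions: float
    temperature_C: float | None
    mg_mM: float | None


@dataclass(frozen=True)
class EquilibrationResult:
    """Return-to-baseline time.

    ``censored`` is True when the trace never satisfies the hold criterion and
    the end of the trace is reported instead; ``degenerate`` flags traces with
    no detectable signal (the first post-extremum sample is returned).
    """

    time: float
    censored: bool = False
    degenerate: bool = False

    def __float__(self) -> float:
        return self.time


# ---------------------------------------------------------------------------
# baseline statistics


def estimate_baseline(trace: DPTrace, window_s: float = 20.0) -> tuple[float, float]:
    """Median baseline level and robust noise sd from the pre-injection window.

    Uses samples in ``[t_inj − window_s, t_inj)``; falls back to the first
    ``window_s`` seconds of the trace when nothing precedes the injection.
    The noise sd is the scaled median absolute deviation (MAD × 1.4826).
    """
    t_inj = trace.injection_time
    mask = (trace.time >= t_inj - window_s) & (trace.time < t_inj)
    if not mask.any():
        mask = trace.time <= trace.time[0] + window_s
    vals = trace.power[mask]
    baseline = float(np.median(vals))
    mad = float(np.median(np.abs(vals - baseline)))
    return baseline, 1.4826 * mad


# ---------------------------------------------------------------------------
# operations


def _resample(control: DPTrace, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation onto the sample grid, constant extrapolation."""
    return np.interp(grid, control.time, control.power)


def subtract_backgrounds(sample: DPTrace, controls: ControlSet) -> DPTrace:
    """Remove mixing/dilution heats measured in separate control titrations.

    Returns ``sample − (phage_into_buffer + buffer_into_lamb −
    buffer_into_buffer)`` with every control linearly resampled onto the
    sample's time grid.  Controls must be recorded at the sample's temperature
    and Mg concentration (when both declare them).
    """
    for ctrl in controls.traces():
        for key in _CONDITION_KEYS:
            a, b = sample.metadata.get(key), ctrl.metadata.get(key)
            if a is not None and b is not None and not math.isclose(float(a), float(b), abs_tol=1e-9):
                raise ConditionMismatchError(
                    f"control {key}={b!r} does not match sample {key}={a!r}"
                )
    grid = sample.time
    background = (
        _resample(controls.phage_into_buffer, grid)
        + _resample(controls.buffer_into_lamb, grid)
        - _resample(controls.buffer_into_buffer, grid)
    )
    meta = dict(sample.metadata)
    meta["background_subtracted"] = True
    return DPTrace(grid, sample.power - background, meta)


def detect_equilibration(
    trace: DPTrace,
    noise_k: float = 2.0,
    hold_window: float = 10.0,
    *,
    sigma: float | None = None,
    baseline: float | None = None,
    after: float | None = None,
) -> EquilibrationResult:
    """Earliest post-peak time at which the trace stays within the noise band.

    The trace equilibrates at the first time after the global extremum where
    ``|power − baseline| < noise_k × σ`` holds continuously for
    ``hold_window`` seconds.  ``σ`` and the baseline default to robust
    pre-injection estimates; pass them explicitly when evaluating a noise-free
    model curve (e.g. a fitted peak component) against the noise level of the
    parent trace.  ``after`` overrides the extremum search start.

    Returns an :class:`EquilibrationResult`; censored results report the end
    of the trace.
    """
    if hold_window < 0:
        raise ValueError("hold_window must be >= 0")
    est_base, est_sigma = estimate_baseline(trace)
    if baseline is None:
        baseline = est_base
    if sigma is None:
        sigma = est_sigma
    dev = np.abs(trace.power - baseline)
    thresh = noise_k * sigma

    if after is None:
        i_ext = int(np.argmax(dev))
        if dev[i_ext] <= thresh:  # never leaves the noise band: no signal
            i0 = min(i_ext + 1, trace.time.size - 1)
            return EquilibrationResult(float(trace.time[i0] - trace.injection_time), degenerate=True)
        t_start = trace.time[i_ext]
    else:
        t_start = after

    inside = dev <= thresh
    candidates = np.flatnonzero((trace.time > t_start) & inside)
    for i in candidates:
        t_i = trace.time[i]
        span = (trace.time >= t_i) & (trace.time <= t_i + hold_window)
        if inside[span].all():
            return EquilibrationResult(float(t_i - trace.injection_time))
    return EquilibrationResult(float(trace.time[-1] - trace.injection_time), censored=True)


def n_virions_from_metadata(metadata: Mapping) -> float:
    """Titrated virion count = titrant volume (µL) × titer (pfu/mL)."""
    try:
        vol_uL = float(metadata["titrant_uL"])
        titer = float(metadata["titer_pfu_per_mL"])
    except (KeyError, TypeError, ValueError) as exc:
        raise UnitError("titrant_uL and titer_pfu_per_mL metadata are required") from exc
    if vol_uL <= 0 or titer <= 0:
        raise UnitError("titrant volume and titer must be positive")
    return vol_uL * 1e-3 * titer


def integrate_ejection_enthalpy(trace: DPTrace) -> EnthalpyResult:
    """Ejection enthalpy per virion from the area under the DP curve.

    Trapezoidal integration of the background-subtracted exothermic curve from
    the injection onward, converted µcal → J, divided by the number of
    titrated virions from the metadata.  Released heat is positive.
    """
    n = n_virions_from_metadata(trace.metadata)
    mask = trace.time >= trace.injection_time
    total_ucal = float(np.trapezoid(trace.power[mask], trace.time[mask]))
    total_heat = total_ucal * J_PER_UCAL
    return EnthalpyResult(
        dH_ej=total_heat / n,
        total_heat=total_heat,
        n_virions=n,
        temperature_C=trace.metadata.get("temperature_C"),
        mg_mM=trace.metadata.get("mg_mM"),
    )


# ---------------------------------------------------------------------------
# plain-text I/O: CSV trace + key=value sidecar

_CSV_HEADER = ["time_s", "power_ucal_per_s"]


def write_dp_trace(trace: DPTrace, path: str | Path) -> None:
    """Write ``time_s,power_ucal_per_s`` CSV plus a ``.meta`` sidecar."""
    path = Path(path)
    df = pd.DataFrame({_CSV_HEADER[0]: trace.time, _CSV_HEADER[1]: trace.power})
    df.to_csv(path, index=False, float_format="%.17g")
    lines = [f"{k}={v}" for k, v in sorted(trace.metadata.items(), key=lambda kv: str(kv[0]))]
    path.with_suffix(path.suffix + ".meta").write_text("\n".join(lines) + "\n")


def _parse_meta_value(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    if raw in ("True", "False"):
        return raw == "True"
    return raw


def read_dp_trace(path: str | Path) -> DPTrace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta")
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            line = line.strip()
            if line and "=" in line:
                k, _, v = line.partition("=")
                meta[k.strip()] = _parse_meta_value(v.strip())
    return DPTrace(df[_CSV_HEADER[0]].to_numpy(), df[_CSV_HEADER[1]].to_numpy(), meta)
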