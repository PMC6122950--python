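"""Light-scattering decays and their conversion to ITC-comparable heat flow.

Bulk light scattering tracks the number of DNA-filled capsids: the
normalized decay ΔI(t) = (I(t) − I_final) / (I_initial − I_final) runs from 1
to 0 as ejections proceed.  Its time derivative is the instantaneous number
of ejecting phages; scaled by the phage count and the per-virion ejection
enthalpy it overlays directly on an ITC DP curve — the cross-method check
that shows LS averages the two ejection populations into a single unimodal
decay and overestimates the ejection timescale (condensate relaxation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .itc import J_PER_UCAL, UnitError

__all__ = [
    "LSTrace",
    "NormalizedDecay",
    "DerivedHeatFlow",
    "FlatTraceError",
    "normalize_intensity",
    "differentiate_decay",
    "scale_to_itc",
    "read_ls_trace",
    "write_ls_trace",
]


class FlatTraceError(ValueError):
    """Initial and final intensities coincide; nothing to normalize."""


@dataclass(frozen=True)
class LSTrace:
    """Scattering intensity (arbitrary units) versus time (s)."""

    time: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        i = np.asarray(self.intensity, float)
        if t.ndim != 1 or i.shape != t.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise ValueError("intensity must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", i)


@dataclass(frozen=True)
class NormalizedDecay:
    """ΔI(t) in [≈0, ≈1] plus its single-exponential fit A·e^{−rt} + offset."""

    time: np.ndarray
    delta_i: np.ndarray
    amplitude: float
    rate: float
    offset: float
    metadata: dict = field(default_factory=dict)

    def fitted(self, t=None) -> np.ndarray:
        t = self.time if t is None else np.asarray(t, float)
        return self.amplitude * np.exp(-self.rate * t) + self.offset


@dataclass(frozen=True)
class DerivedHeatFlow:
    """−dΔI/dt scaled into µcal/s for overlay on a DP curve."""

    time: np.ndarray
    power_ucal_per_s: np.ndarray
    n_phage: float
    dH_per_virion: float


_ENDPOINT_WINDOW = 3  # samples averaged for I_initial / I_final


def normalize_intensity(trace: LSTrace) -> NormalizedDecay:
    """Normalize an LS trace to ΔI(t) = (I − I_final)/(I_initial − I_final).

    I_initial and I_final are means of the first and last three samples
    (robust to endpoint noise).  A single exponential with offset is fitted
    alongside and stored for analytic differentiation.
    """
    if trace.time.size < 10:
        raise ValueError("need at least 10 samples")
    i_init = float(trace.intensity[:_ENDPOINT_WINDOW].mean())
    i_final = float(trace.intensity[-_ENDPOINT_WINDOW:].mean())
    if i_init == i_final:
        raise FlatTraceError("I_initial equals I_final")
    delta = (trace.intensity - i_final) / (i_init - i_final)
    t = trace.time - trace.time[0]

    # log-linear start for the rate, then full nonlinear fit with offset
    pos = delta > 0.05
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(delta[pos]), 1)[0]
        r0 = max(-slope, 1e-6)
    else:
        r0 = 1.0 / max(t[-1], 1.0)
    try:
        popt, _ = curve_fit(
            lambda tt, A, r, off: A * np.exp(-r * tt) + off,
            t,
            delta,
            p0=(1.0, r0, 0.0),
            maxfev=10000,
        )
        amp, rate, off = (float(v) for v in popt)
    except RuntimeError:
        amp, rate, off = 1.0, r0, 0.0
    return NormalizedDecay(t, delta, amp, rate, off, dict(trace.metadata))


def differentiate_decay(norm: NormalizedDecay, method: str = "fit") -> tuple[np.ndarray, np.ndarray]:
    """Time derivative dΔI/dt of a normalized decay.

    ``fit`` differentiates the stored exponential analytically (default);
    ``numeric`` applies a Savitzky–Golay smooth (window 11, order 3) and
    central differences — the fallback when the decay is not single
    exponential.
    """
    t = norm.time
    if method == "fit":
        return t, -norm.amplitude * norm.rate * np.exp(-norm.rate * t)
    if method == "numeric":
        win = min(11, norm.delta_i.size - (1 - norm.delta_i.size % 2))
        smooth = savgol_filter(norm.delta_i, max(win, 5), 3)
        return t, np.gradient(smooth, t)
    raise ValueError("method must be 'fit' or 'numeric'")


def scale_to_itc(
    deriv: tuple[np.ndarray, np.ndarray],
    n_phage: float,
    dH_per_virion: float,
) -> DerivedHeatFlow:
    """Scale −dΔI/dt into an ITC-equivalent heat flow.

    output(t) = −dΔI/dt × n_phage × ΔH_per_virion, converted J/s → µcal/s.
    Its integral equals the total released heat n_phage × ΔH.
    """
    if not (n_phage > 0 and dH_per_virion > 0):
        raise UnitError("n_phage and dH_per_virion must be positive")
    t, d = deriv
    power = -np.asarray(d, float) * n_phage * dH_per_virion / J_PER_UCAL
    return DerivedHeatFlow(np.asarray(t, float), power, float(n_phage), float(dH_per_virion))


# ---------------------------------------------------------------------------
# I/O — two-column CSV


def write_ls_trace(trace: LSTrace, path) -> None:
    import pandas as pd

    pd.DataFrame({"time_s": trace.time, "intensity": trace.intensity}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_ls_trace(path, metadata: dict | None = None) -> LSTrace:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    return LSTrace(df["time_s"].to_numpy(), df["intensity"].to_numpy(), metadata or {})
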