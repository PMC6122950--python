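"""Locate the intracapsid DNA transition temperature T* versus [Mg2+].

ΔH_ej(T) is linear on both sides of the solid-to-fluid DNA transition with
an abrupt slope inversion at T*.  A two-segment weighted least-squares scan
finds the breakpoint; assembling T* across Mg concentrations shows the
counterion-screening saturation above ~20 mM.
"""

import numpy as np

from ejectkin import fit_two_segment, tstar_vs_mg
from ejectkin.simulate import synthesize_enthalpy_series

temps = np.arange(15.0, 46.0, 2.0)
series_list = [synthesize_enthalpy_series(temps, mg) for mg in (5.0, 10.0, 20.0, 50.0)]

fit = fit_two_segment(series_list[1])
print(f"10 mM: T* = {fit.t_star:.1f} C  (slopes {fit.slope_below:+.2e} / {fit.slope_above:+.2e} "
      f"J/virion/C, inversion={fit.inversion})")

tmap = tstar_vs_mg(series_list)
for mg, t_star, inversion in tmap.entries:
    print(f"  {mg:4.0f} mM -> T* = {t_star:5.1f} C")
print(f"T* saturates from {tmap.saturation_mM:.0f} mM upward")
# T* climbs from ~23 C at 5 mM to ~37 C at 20 mM and then stops moving:
# Mg screening of the packaged DNA helices is saturated.
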