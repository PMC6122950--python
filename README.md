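# ejectkin

Population kinetics of DNA ejection from bacteriophage λ, reconstructed from
three bulk measurements: isothermal titration calorimetry (ITC) heat flow,
time-resolved small-angle X-ray scattering (SAXS), and light scattering (LS).
The package is aimed at viral biophysicists who want to (a) separate
synchronized from desynchronized ejection populations in calorimetric
titration curves, (b) locate the solid-to-fluid mechano-structural transition
of intracapsid DNA from ejection enthalpies, and (c) extract the Arrhenius
activation energy of ejection initiation from diffraction-peak decays — plus
a ground-truthed instrument simulator so every stage of the pipeline can be
validated without instrument data.

## The science in brief

When phage λ meets its *E. coli* receptor LamB, each virion ejects its
48.5 kb genome through the tail. The packaged genome can be in two states:

* **fluid-like** (low interstrand sliding friction): ejection starts
  essentially immediately — synchronized across the population, finishing in
  ~10 s (the single-virion translocation time);
* **solid-like** (high friction): ejection initiation requires crossing an
  energy barrier, so start times are stochastic with an Arrhenius rate
  `k(T) = A·exp(−Ea / k_B·T)`, `Ea ≈ 1.2×10⁻¹⁹ J/virion ≈ 29 k_BT`.

Temperature and Mg²⁺ concentration switch DNA between the states; the
transition temperature `T*` rises from ~23 °C at 5 mM MgCl₂ to ~37 °C at
20 mM and then saturates.

**EMG deconvolution.** Each exothermic DP (differential power) peak is
modelled as an exponentially modified Gaussian

```
f(t) = a/(2b) · exp(c²/(2b²) + (d−t)/b) · [erf((t−d)/(c√2) − c/(b√2)) + 1]
```

with area `a`, damping (relaxation) time `b`, Gaussian width `c` and position
`d`. Moments follow `μ = d + b`, `s² = c² + b²`, `γ = 2b³/(c²+b²)^{3/2}`, and
each population's central ejection time is the Pearson median
`μ − s·γ/3`. A DP curve is fitted with one or two EMGs; AICc plus a
resolution rule decides whether two populations are genuinely present.

**Transition detection.** The ejection enthalpy per virion `ΔH_ej(T)`
(integrated DP area over the titrated virion count) is piecewise linear with
a slope inversion at `T*`; a two-segment weighted least-squares scan over a
0.1 °C breakpoint grid locates it.

**SAXS kinetics.** The DNA diffraction peak (q = 0.18–0.32 Å⁻¹) counts
DNA-filled capsids. Frames are reduced by NNLS background mixtures
(buffer / oPOE detergent / LamB) fitted on the window flanks, then a
Gaussian + line peak fit; `−d ln(area)/dt` at t > 20 s gives the slow
population's rate constant and an Arrhenius fit across temperatures gives
`Ea`.

## Worked example

```bash
python examples/02_deconvolve_dp_curve.py
```

```
--- 22 C / 10 mM MgCl2: bimodal
  fast median ejection time:  10.3 +- 2.0 s
  slow median ejection time:  30.1 +- 0.7 s
  fast-population fraction:  51 %
  slow peak returns to baseline at 255 s
--- 37 C / 10 mM MgCl2: unimodal
  fast median ejection time:  10.5 +- 2.1 s
```

Below the DNA transition (22 °C) the titration curve splits into a
synchronized ~10 s peak and a desynchronized ~30 s peak that takes ~250 s to
return to baseline; above the transition (37 °C) the fitted components
converge and a single synchronized population remains. The error bars are
the Gaussian widths `c` of the fitted components.

The other examples cover trace simulation and heat bookkeeping (`01`),
T* versus Mg²⁺ (`03`), the SAXS activation energy (`04`, prints
`Ea = 1.162e-19 J/virion = 28.2 kT at 25 C`), the LS cross-check and its
condensate bias (`05`), and the end-to-end scenario runner (`06`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes every headline quantity from scratch: it simulates the calibrated
default conditions (ITC curves at 22–42 °C / 5–20 mM, noise-free enthalpy
scans, SAXS decays at 25/30/37 °C), runs the full analysis pipeline on the
fresh data, and writes one JSON object mapping each quantity to its
recovered value and the problem size used. Runs in well under a minute on
one CPU.

## Layout

```
src/ejectkin/
  simulate.py    event-time simulator + ITC/LS/SAXS renderers (ground truth)
  itc.py         DP traces, background subtraction, equilibration, ΔH_ej
  emg.py         EMG model, moments, 1–2 component deconvolution, metrics
  transition.py  two-segment breakpoint detection, T* vs Mg map
  saxs.py        frame reduction, peak areas, rates, Arrhenius fit
  ls.py          normalized decays, differentiation, ITC-unit scaling
  report.py      scenario runner (simulate → analyse → report.json)
examples/        one narrative script per capability
docs/methods.md  model assumptions, calibration, numerical choices
```
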