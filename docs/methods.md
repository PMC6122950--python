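# Methods

## The generative model

One simulated experiment is a population of `n_virions` phage particles
titrated into receptor (LamB) solution at time zero. Each virion is
independently assigned the **fluid-like** DNA state with probability `φ`
(`phi_fast`) and otherwise the **solid-like** state.

* Fluid virions begin ejecting at `dead_time + U(0, jitter_max)` — the
  portal opens essentially as soon as receptor binding occurs; the jitter
  stands in for mixing and the small portal-opening barrier.
* Solid virions begin after `dead_time + Exp(1/k)`. The exponential is the
  minimal memoryless law consistent with the first-order ln(area) decays
  seen in the diffraction kinetics; nothing in the data motivates a heavier-
  or lighter-tailed delay. The rate is either taken from a per-condition
  table (ITC scenarios) or from the Arrhenius law
  `k(T) = A·exp(−Ea/k_B·T)` (SAXS scenarios) — see "Two parameterizations"
  below.
* Every ejection translocates the genome over `translocation_duration`
  (default 10 s) with a Beta(2, 3) speed profile: translocation speed rises
  at first (high packaged pressure, widening channel) and falls toward the
  end as the driving pressure drops.

### Instrument renderers

**ITC.** Each virion contributes a heat pulse of area `dH_per_virion`
(default 10⁻¹⁵ J — an order-of-magnitude choice that puts µcal-scale peaks
under a 2.69 µL × 10¹³ pfu/mL injection; absolute per-virion enthalpies are
not constrained by the reference data). The population sum is convolved with
a normalized exponential instrument response (`irf_tau` = 3.5 s, the
response time of an iTC200-class calorimeter) and i.i.d. Gaussian noise of
sd `noise_sd` is added. Rendering bins event times on the sampling grid
(default 0.25 s) and convolves with unit-area kernels, so the noise-free
integral equals `n × dH` to machine precision; the trace span is chosen
automatically (last event + translocation + 10 IRF time constants) so no
tail heat is lost. `n_virions` simulated events represent
`titer × volume` physical virions; each event carries the scaled heat share.

**Light scattering.** Intensity = filled-capsid fraction + `w` × condensate
term: each ejected genome initially remains a compact condensate scattering
with weight `w` (default 0.3) that relaxes away exponentially
(`ls_relax_tau`, default 200 s). Bookkeeping is binary (a capsid counts as
filled until its translocation completes), which makes the noise-free trace
exactly monotone for `w ≤ 1` and reproduces the known LS bias: the decay
outlasts the true event timescale and averages the two populations into one
unimodal curve.

**SAXS.** Frames every `frame_interval` (2 s by default; the instrument
records every 2–10 s) carry a Gaussian DNA diffraction peak at fixed center
q₀ = 0.25 Å⁻¹ (σ = 0.02 Å⁻¹) whose area is proportional to the
filled-capsid count, on top of a linear local background plus a fixed
mixture of three smooth component profiles standing in for TM buffer, 1 %
oPOE detergent and LamB. Because the per-virion loss is complete after the
10 s translocation, the solid population's peak area is exactly
`∝ e^{−kt}` for t > translocation — the rate extraction has an analytic
ground truth.

**Enthalpy series.** `ΔH_ej(T)` is piecewise linear with opposite-sign
slopes (+3×10⁻¹⁷ / −5×10⁻¹⁷ J/virion/°C around a 10⁻¹⁵ J base) meeting at
`T*(mg)` from the transition map {5 mM → 23 °C, 10 → 33, 20 → 37,
50 → 37 °C}, with optional Gaussian noise.

### Two parameterizations of the slow population

ITC median ejection times *lengthen* with temperature below the transition
(30 s at 22 °C → 45 s at 32 °C) while SAXS rate constants *speed up* with
temperature. A single Arrhenius law cannot produce both, so the simulator
supports (i) a direct per-condition delay-scale table — the default for ITC
scenarios — and (ii) Arrhenius mode — the default for SAXS scenarios
(`Ea = 1.2×10⁻¹⁹ J/virion`; the prefactor is anchored at `k(25 °C) =
0.01 s⁻¹` because the absolute attempt frequency is not observable and Ea
recovery is independent of it). This duality is deliberate and visible in
`default_config(..., mode=...)`, not hidden.

### Calibration of the default condition table

The defaults are calibrated, once and forward, so that the *analysis
pipeline's output* on rendered traces reproduces the reference landmark
numbers; they were then frozen:

| condition | φ | slow delay scale (s) |
|---|---|---|
| 22 °C / 10 mM | 0.50 | 55 |
| 32 °C / 10 mM | 0.50 | 100 |
| 37 °C / 10 mM | 0.93 | 25 |
| 42 °C / 10 mM | 0.97 | 20 |
| 37 °C / 5 mM | 1.00 | — |
| 37 °C / 20, 50 mM | 0.10 | 130 |

plus `dead_time` = 4 s (injection/mixing transit; a 2.69 µL injection takes
several seconds) and `noise_sd` = 4×10⁻⁴ µcal/s (realistic operating
baseline noise for this instrument class). Notes:

* The delay scales are larger than the naive "median − fast median" because
  the reported central time is the *Pearson* median of the fitted EMG
  (`μ − sγ/3`); for an exponential-dominated component (γ → 2) this sits
  near `d + b/3`, well below the true median. The table is calibrated
  against what the estimator actually reports.
* φ below the transition at 10 mM is not quantified by the reference data;
  0.5 is a modelling choice that renders two clearly resolved peaks.
* At 37 °C / 20 mM the fitted area fraction equals the true φ = 0.10 only
  because the delay scale (130 s) separates the populations enough for the
  fit to attribute early solid-state arrivals correctly; at shorter delays
  the fast component absorbs them and the recovered fraction biases high.
  This identifiability limit is intrinsic to two-EMG least squares, not to
  the data volume.

### What a green test does and does not establish

The generator emulates population-kinetic structure, instrument response,
additive Gaussian noise, and heat/area bookkeeping. It does **not** emulate
baseline drift, injection artifacts, detector nonlinearity, radiation
damage, capsid form-factor scattering at low q, or run-to-run titer
variability. Green recovery tests therefore establish that the estimators
are unbiased and stable under the stated stochastic model at realistic
signal-to-noise — not that they are robust to every instrumental pathology.

## Analysis: numerical choices

**EMG evaluation** rewrites the erf·exp product through the scaled
complementary error function (`erfcx`) and switches to the asymptotic
pure-exponential form deep in the right tail, so the model is finite and
non-negative for any parameters; `b ≤ 10⁻⁶ c` falls back to the analytic
Gaussian limit.

**Fitting** is bounded trust-region least squares (`b, c ∈ [0.1, 500] s`,
`d` within the trace span, `a ≥ 0`) from a deterministic start grid: peaks
picked on a Savitzky–Golay smoothed copy (window ≈ 2 s), two-peak geometry
when two maxima exist, a +2×FWHM offset otherwise, area shares {0.5, 0.15},
slow-damping multipliers {1, 5, 20}, plus two "overlapping shoulder" starts
(minor sharp component under a broad damped one at the same position). The
winning solution is re-polished so the returned parameters are a stationary
point (refitting is a no-op).

**Model selection** (auto mode): bimodal is reported only if it wins on
small-sample-corrected AIC *and* the components are resolved *and* the minor
component carries > 2 % of the area. Resolution is judged in median space —
`|median₂ − median₁| > 2·max(c₁, c₂)` — because at realistic
signal-to-noise an EMG pair can split a single skewed peak into two
near-coincident components that differ only in damping (Δmedian ≈ 2–3 s);
genuine slow populations sit 20–45 s later. Components are ordered by
Pearson median, which coincides with position order whenever the peaks are
resolved but stays meaningful when positions nearly coincide.

**Equilibration** (return to baseline): earliest time after the global
extremum at which |power − baseline| stays below `2σ` continuously for 10 s;
baseline and σ are the median and scaled MAD of the 20 s pre-injection
window. Component-wise equilibration evaluates the noise-free fitted
component against the parent trace's σ. Traces that never return are
reported censored at the trace end. A structural note: with the slow
population's damping pinned near 55 s by its 30 s Pearson median and the
noise floor pinned by the ~250 s slow-peak return, the isolated fast
component (damping ≈ the 3.5 s instrument response) crosses the 2σ band
only at ~35 s — a ~20 s fast-peak return is not simultaneously attainable
under this criterion; the figure an experimentalist reads off the trace is
the fast peak merging into the slow component's level, which happens near
17 s.

**Breakpoint search** scans candidate breakpoints on a 0.1 °C grid between
the 2nd and (n−1)th temperature, fitting two *independent* weighted
least-squares lines (the data show a discontinuity; a continuous hinge
variant is available via `connected=True`). Zero-SSE plateaus on exact data
are resolved to the plateau midpoint. Inversion = opposite slope signs;
significance additionally requires both slope |t|-statistics > 2.

**SAXS reduction**: NNLS over the component profiles plus a free offset
(implemented as a ±1 column pair, keeping the problem in NNLS form), fitted
on q ∈ [0.10, 0.17] ∪ [0.33, 0.40] Å⁻¹ so the DNA peak cannot leak into the
coefficients; Gaussian + line on the window with area = amplitude·σ·√(2π);
amplitude below 2× the noise level ⇒ peak absent, area 0. Rate regressions
exclude absent points and areas below 2 % of the series maximum — near the
detection floor ln(area) is dominated by noise and by the non-negativity of
the fitted amplitude, which would bias the slope. The fast/slow split time
is 20 s by default and exposed as a parameter.

**LS normalization** uses 3-sample window means for the initial and final
intensities (robust to endpoint noise); the single-exponential fit includes
an offset. Differentiation is analytic on the fitted exponential by default,
with a Savitzky–Golay + central-difference numeric fallback.

**Units**: 1 cal = 4.184 J exactly; T(K) = T(°C) + 273.15 exactly;
k_B = 1.380649×10⁻²³ J/K.

## Known limitations

* At most two EMG components; no Bayesian uncertainty on the deconvolution.
* The per-condition φ table interpolates crudely (0.5 below T*, 0.95 above)
  for conditions outside the calibrated set.
* The LS decay model is single-exponential; multi-exponential or stretched
  decays are out of scope.
* Median error bars follow the width-of-Gaussian convention (`c` at the
  median), not a propagated covariance.
* No vendor instrument-file parsing: traces enter as two-column CSV/text
  with a key=value metadata sidecar.
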