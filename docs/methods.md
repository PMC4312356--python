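# Methods

## The analysis calculus

All volumetric quantities are referenced to *total* cell volume
V = C_m / (SA:V), with C_m the measured membrane capacitance (pF) and SA:V
the capacitance-to-volume ratio (pF/pl). Free Ca is carried in nmol/l,
total-Ca amounts and fluxes in μmol/l of cell volume.

**Calibration.** Two inverse maps, both strictly monotone and exact
inverses of the simulator's emission models:

* Fura-2 (ratiometric): ca = K_eff (R − R_min)/(R_max − R). The constants
  are rig-specific configuration; the defaults (R_min 0.30, R_max 3.00,
  K_eff 1800 nmol/l) mirror the synthetic emission model and are
  placeholders, not measured values.
* Fluo-5F (single wavelength, self-ratio): when Ca-saturated fluorescence
  cannot be obtained in the cell, the trace is expressed as a pseudo-ratio
  R = F/F_rest and anchored to an independently measured resting free Ca:
  ca = K_d R / (K_d/ca_rest + 1 − R), K_d = 1035 nmol/l. R = 1 maps exactly
  to the anchor. Saturated samples (denominator ≤ 0) raise an error naming
  the first offending index; out-of-range ratiometric samples are returned
  as NaN with their indices, never clipped, and downstream fits ignore
  masked samples.

**Decay kinetics.** Transient decays are fitted with A·exp(−kt) + C by
least squares (scipy `curve_fit`, log-linear initialisation). A fit is
accepted only if k > 0, A > 0 and RMSE ≤ 10% of A (configurable); anything
else is flagged, not used. The fit window runs from where the signal has
fallen to 90% of its amplitude down to 10% (both configurable); for the
systolic transient the window additionally starts only after the
depolarising step ends, because the decay is contaminated by ongoing
L-type entry while the step is on. For the slow PMCA-only decay (caffeine
+ Ni²⁺) the window stops at 30% to keep its duration practical. The SR
removal rate is exact arithmetic k_SR = k_sys − k_caff per cell; negative
values are flagged, never clamped. APD is measured from the
maximum-upstroke-velocity sample to the first crossing of
peak − fraction·(peak − baseline), linearly interpolated.

**SR content from NCX charge.** NCX moves one net charge per extruded Ca²⁺
(3Na⁺:1Ca²⁺), so content = Q/(F·V), with Q the integral of the inward
current deflection during caffeine; L-type entry uses two charges per ion,
Q/(2F·V). Stoichiometries are fixed constants of the method. Two
methodological details matter:

* *Integration baseline.* Caffeine renders SERCA uptake futile, so the
  sarcolemmal current settles to a slightly different level than before
  caffeine (SERCA no longer removes its share of the background Ca
  influx). The charge integral therefore uses the **post-caffeine plateau**
  (median of the final 0.5 s of the window) as baseline; the pre-caffeine
  2 s median is reported alongside for QC. This makes the estimate exactly
  invariant to uniform baseline shifts. The residual error from the
  pre/post shift in diastolic free Ca is removed, when a calibrated Ca
  trace and a buffering estimate are available, by adding
  β·Δca_baseline/1000 (≈ 2 μmol/l for the default control cell). With both
  corrections the estimator closes the flux balance to well under 1% on
  noiseless data.
* *Non-NCX extrusion.* PMCA extrudes a share s of the sarcolemmal efflux
  without carrying the NCX charge; the NCX-derived content is multiplied
  by 1/(1 − s). The share is taken from configuration or derived per cell
  as k_PMCA/k_caff (both fitted rates). With the default s = 0.10 a 50%
  error in PMCA activity changes the content estimate by < 10%, so the
  correction is robust to PMCA uncertainty.

**Buffering power.** Over the caffeine decay, the total Ca still to be
extruded at time t is the outstanding (PMCA-corrected) extrusion-current
integral ∫ₜ^end. Regressing it on free Ca gives slope β (after nmol→μmol
unit conversion). The regression uses samples past the transient peak with
free Ca between end + 10% and peak − 10% of the excursion, avoiding the
release phase and the plateau; fits need ≥ 10 points and r² ≥ 0.90, else
flagged. β is interpreted strictly as ΔCa_total/Δ[Ca]ᵢ — no +1 adjustment
for the free fraction — matching the operational definition used with
such buffering curves.

**NCX–Ca relationship.** OLS slope of the extrusion-positive current
density (plateau-baseline-subtracted, divided by C_m) on free Ca over the
accepted decay window; under the simulator's linear NCX this recovers the
generating coefficient exactly.

**Economy.** total = β·Δ[Ca]ᵢ/1000; ΔSR_systole = total − ∫I_CaL;
fractional release = ΔSR/SR content; EC gain = ΔSR/∫I_CaL. The alternative
literal reading "content − (total − entry)" equals the post-release store,
not the released amount; it is exposed as `sr_content_after_release` and
the discrepancy is documented rather than resolved. Group summaries are
mean ± SEM over cells, with an animal-nested variant (mean of animal
means, each animal weighted once) and an optional log10 transform.
Percent contrasts are 100·(ref − comp)/ref, positive for reductions.
Full mixed-effects modelling is deliberately out of scope — users needing
REML inference should export the per-cell table to statsmodels/lme4.

## The synthetic myocyte

A deliberately minimal two-pool model chosen so that every estimator has a
closed-form target; it is a test-bench for the analysis, not a
biophysically detailed cell.

State: free cytosolic Ca (nmol/l) and SR content (μmol/l of cell volume),
with constant buffering power β linking free and total cytosolic changes
(d[Ca]_free = d[Ca]_total/β; a saturable buffer is intentionally absent
because the analysis regressions are linear).

Fluxes (all total-Ca, μmol/l/s):

* L-type current: during each 100 ms step, i_CaL = −g_CaL·C_m·e^(−k_inact·t)
  (inward negative); influx = −i_CaL/(2F·V).
* SR release: an instantaneous dump of frac_release·(g_CaL/2.27 pA·pF⁻¹)·SR
  at each stimulus onset — fractional, scaled linearly by the normalised
  trigger amplitude. The instantaneous dump makes the subsequent decay a
  clean single exponential, which is exactly what the fitting assumes.
* Removal: SERCA, NCX and PMCA are linear in (ca − ca_rest) with total-Ca
  rate constants k_serca, K_ncx = 10⁹·g_ncx·(SA:V)/F and k_pmca. NCX
  carries the corresponding current i_NCX = −g_ncx·C_m·(ca − ca_rest)
  (inward while extruding); PMCA is treated as electroneutral.
* A constant background influx j_leak (see below).

Caffeine switches instantaneously: the release channel is held open
(first-order SR dump at 50 s⁻¹, emptying in ~100 ms) and SERCA becomes
futile (net uptake zero); Ni²⁺ additionally zeroes NCX. Consequently the
free-Ca decay rates are exactly

    k_sys  = (k_serca + K_ncx + k_pmca)/β
    k_caff = (K_ncx + k_pmca)/β
    k_pmca_decay = k_pmca/β

which the kinetics tests target analytically.

**Why the background influx exists.** At a paced steady state the per-beat
balance forces sarcolemmal extrusion = L-type entry. With an ~83 nmol/l
transient, β ≈ 565 and k_caff/k_sys ≈ 8%, extrusion per beat is ≈ 3.9
μmol/l, yet integrated entry is only ≈ 0.74 μmol/l — a closed linear cell
cannot satisfy all three observables at once. A constant influx j_leak
(≈ 1.7 μmol/l/s for the control preset), balanced at rest by the linear
removal, closes the budget; it raises diastolic Ca by only ~0.3 nmol/l.
The preset builder solves j_leak, k_inact (from peak density and
integrated entry), g_ncx, k_serca and k_pmca in closed form from the
target observables.

**Presets.** Two parameter sets represent a healthy and a failing atrial
phenotype. Their targets (configuration, not hard-coded truth): control —
C_m 59.6 pF, SA:V 5.06 pF/pl, resting Ca 60.7 nmol/l, β 565, k_sys
8.99 s⁻¹, k_caff 0.745 s⁻¹, peak I_CaL 2.27 pA/pF, ∫I_CaL 0.74 μmol/l,
steady-state SR 84 μmol/l, fractional release 0.55; failing — 125.9 pF,
4.89 pF/pl, 37.3 nmol/l, β 318, 6.55 s⁻¹, 0.933 s⁻¹, 1.45 pA/pF,
0.86 μmol/l, SR 100.1 μmol/l, fractional release 0.18. PMCA is given 10%
of sarcolemmal extrusion in both. Emergent steady-state measurements land
within ~±10% of these targets (SR content sits a few μmol/l above its
target because SERCA keeps loading during the pre-caffeine pause). Note
two deliberate internal tensions inherited from the reference
measurements: the implied PMCA-only decay (k_pmca/β ≈ 0.075 s⁻¹) is much
slower than a directly measured Ni²⁺-protocol rate of ~1.17 s⁻¹ would
suggest, and matching both peak I_CaL and its integral forces an effective
inactivation rate (~80 s⁻¹ control) slower than the ~404 s⁻¹ a
peak-only reading would give; both are reported as measured, not forced
consistent.

**Conditions.** Dihydropyridine block (nicardipine) scales g_CaL by 0.70;
β-adrenergic stimulation (isoprenaline) scales g_CaL by 4.26/2.27 and
k_serca by 5.19/1.80. Scaling only the trigger reproduces the causal
signature of L-type reduction: a smaller steady-state transient *and* a
fuller SR store (less release per beat at a maintained uptake share).

**Numerics.** Fixed-step classical RK4 at 0.1 ms (numba-compiled, with a
pure-Python fallback); stimulus and caffeine events are aligned to the
step grid; recorded channels are decimated to 1 ms (5 ms for the long
Ni²⁺ recordings). The fastest model rate is ~80 s⁻¹, so k·h ≤ 0.008 and
the integrator error is far below the 1% tolerances used anywhere.
Integration aborts with a diagnostic on non-finite state or negative SR
content. The time base is built from the nominal record step so a CSV
write/read cycle is bit-identical.

**Noise and variability.** Measurement noise only (the state trajectory
stays deterministic): additive Gaussian noise per sample on each current
channel (default SD 5 pA) and on each optical channel (default SD 1% of
the resting emission). Cohorts draw multiplicative lognormal animal-level
then cell-level factors (default CV 8% and 5%) for the kinetic parameters,
β, resting Ca, capacitance and leak; SA:V is held fixed. All randomness is
seeded; identical seeds give bit-identical cohorts.

**What the simulator does not emulate** — and hence what passing recovery
tests do and do not show: no voltage dependence of NCX or of L-type
gating beyond step timing, no subsarcolemmal/central Ca gradients or
t-tubule geometry, no saturable buffering, no SR-dependent release
regulation, no spontaneous release or afterdepolarisations, no dye
bleaching, motion or background artefacts. Recovery within tolerance
demonstrates that the estimators are unbiased under the model's
assumptions (mono-exponential decays, linear NCX, linear buffering); on
real cells the same estimators inherit whatever bias those assumptions
carry.

## Sizes and seeds

Recovery tests and the acceptance script use a 6+6-animal × 4-cell cohort
(48 cells, three recordings each: 12-beat pacing, 12-beat + caffeine,
6-beat + caffeine/Ni²⁺) — large enough that per-cell noise averages to
< 1% SEM on the group means while the whole simulate-and-analyse cycle
stays in the tens of seconds. Limit-cycle checks use the documented
20-beat convergence (< 0.5% beat-to-beat SR difference from the preset
initial store); causal-sign comparisons use 30 beats to sit closer to each
parameter set's own steady state.

## Known limitations

* The self-ratio calibration inherits any error in the resting-Ca anchor
  multiplicatively; synthetic sidecars carry the true resting level, real
  data must supply a Fura-measured anchor.
* The PMCA correction assumes the fitted k_PMCA/k_caff share transfers
  from the Ni²⁺ protocol to the caffeine protocol.
* The plateau-baseline rule assumes the recording extends ≥ 6 caffeine
  decay time constants past onset; shorter windows truncate charge.
* Group contrasts are ratio-of-means; no delta-method error propagation
  through the economy ratios is attempted, matching per-cell reporting
  practice.
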