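# Methods

This note documents the models, estimators and numerical choices behind
osmoflux, what the synthetic-data generator does and does not emulate, and
the limitations a user should keep in mind.

## 1. Physical picture

A unilamellar lipid vesicle separates two aqueous compartments.  When the
external osmolality exceeds the internal one by Δπ (mOsm, numerically
equal to mol/m³ for dilute solutions), water leaves the vesicle.  The
membrane is described in the Helfrich continuum picture — energy per area
½κ_b(c₁+c₂−c₀)² + κ_G·c₁c₂ with bending rigidity κ_b, Gaussian modulus
κ_G and spontaneous curvature c₀ (`helfrich_energy_density`).  Passive
water (and, via a Grotthuss-type relay, proton) flow is carried by
transient water-filled lipid pores; nucleating one requires a membrane
reorganisation that takes a time t₀ after the osmotic challenge.  All the
analyses below are estimators of t₀, of the permeability P, of κ_b, or of
the couplings among them.

## 2. Shrinkage forward model (`shrinkage`)

Volume dynamics:

    V(t) = V₀                                           t < t₀
    dV/dt = −A(V)·V_w·P·(Δπ − k_mech·(V₀−V)/V₀)        t ≥ t₀

* `permeability` P (m/s): osmotic water permeability; default 2×10⁻⁵ m/s,
  a typical fluid-phase phosphatidylcholine value.
* `v_w` = 1.8×10⁻⁵ m³/mol (0.018 L/mol) is pinned: it is a physical
  constant of the flux law, not a tunable.
* `k_mech` (mOsm): linear elastic back-pressure, defined as the osmotic
  pressure balanced at 100% relative volume loss.  The drive is treated as
  constant (the interior osmolality is negligible) yet shrinkage visibly
  saturates, so the model closes the balance with membrane mechanics; a
  linear term is the simplest closure and yields exponential saturation at
  relative volume loss Δπ/k_mech.  Default 1500 mOsm makes the standard
  150 mOsm challenge shrink the vesicle by 10%, matching the ~10%
  hydrodynamic-radius decrease seen by light scattering.
* Geometry: a single representative sphere of radius 55 nm (the 110 nm
  mean extrusion diameter).  Area is updated with volume through the
  sphere law; a `frozen_area` option retains the exactly exponential
  variant used in closed-form tests.  Polydispersity is not modelled.
* Integration: explicit adaptive Runge–Kutta (scipy `solve_ivp`, RK45)
  with rtol 10⁻⁸, started exactly at t₀.  A deliberately naive fixed-step
  Euler oracle (dt = 10⁻⁵ s) lives in the test suite and agrees with the
  adaptive path to better than 0.1% over 1 s horizons.

Optical readout (`OpticsMap`): scattered intensity is dominated by the
state of the two membrane interfaces.  Stage I (t < t₀) is a cubic-ease
descent from the pre-mix level i_00 to the minimum i_0fin, chosen because
only the endpoints and the fact that the minimum marks t₀ are specified;
the ease has zero slope at t₀ so the minimum is exactly there.  For
t ≥ t₀ intensity is affine in relative volume loss, I = i_0fin +
γ·ΔV/V₀, per the experimental linearity between scattered intensity and
internal volume; no Lorenz–Mie computation is attempted.  Instrument
effects are a dead time (default 10 ms — samples before it are
unobservable) and additive Gaussian detector noise with a seeded
generator.

## 3. Trace parameterization (`tracefit`)

* **Deflection time.**  Savitzky–Golay smoothing (degree 2, default
  window 9 samples), global minimum after the dead time, re-localised on
  the raw trace inside the filter footprint (the filter spreads the kink
  and would otherwise bias the location by ~2 samples), then 3-point
  parabolic sub-grid refinement.  Outcomes are explicit: a minimum at the
  first retained sample means t₀ is below the dead time (`resolvable =
  False`); a trace whose post-minimum rise does not clear the
  extreme-value excursion of smoothed noise (σ_smooth·(√(2 ln n)+3)) has
  `no_deflection` — this is what the isosmotic control produces.
* **Plateaus.**  Medians (robust to noise): first 5 retained samples for
  i_00 (or a supplied pre-mix reference — after a long dead time the head
  of the trace underestimates the true pre-mix level), smoothed value at
  t₀ for i_0fin, median of the final 5% for i_fin,fin, with a drift flag
  when the tail is still climbing by more than 2% of the rise.
* **Stage-II slope and permeability.**  OLS over the window from t₀ to
  the first crossing of 50% of the stage-II/III rise.  Because that rise
  is a saturating relaxation, the window-average slope is a fixed,
  model-computable fraction of the initial slope: 12(3ln2/4 − ½)/ln³2 ≈
  0.7156 for the frozen-area exponential, and a slightly smaller value
  (0.701 at 10% volume loss) once area updating is included, computed by
  integrating the dimensionless trajectory (`stage2_window_factor`).
  `permeability_from_slope` divides by this factor before inverting
  P = slope·V₀/(γ·A₀·V_w·Δπ); without the correction the recovered P
  would be biased low by ~28%, which would defeat the 5% noiseless
  recovery this estimator achieves.  When the optics calibration γ is
  unknown the result is flagged `relative_units` (γ := 1), matching how
  fluxes are reported when only arbitrary-unit intensities exist.
* **Delay law and correlation.**  OLS of t₀ on 1/Δπ (`DelayLaw`), with R²
  defined as 1 for an exact fit (including the degenerate constant-t₀
  case); Pearson r plus an OLS line for t₀ against κ_b
  (`correlate_delay_rigidity`, ≥3 pairs).  The delay-law intercept is free
  in the fit although the generator default is zero.

Accuracy, measured by the suite and the acceptance script: noiseless, t₀
is recovered within one 1 ms grid step and P within 5% across the default
parameter box (Δπ ∈ [15, 150] mOsm, t₀ ∈ [13, 133] ms); at signal-to-noise
20 on the rise, RMS errors over 50 seeds are ≲ 9% for both.

## 4. Pore-delay law (`core`)

The delay is empirically proportional to 1/Δπ, grows with κ_b and falls
with temperature.  No functional form beyond these trends is established,
so the package uses the simplest separable law consistent with all three:

    t₀ = [k_scale + rigidity_coeff·(κ_b − κ_ref)] ·
         max(0, 1 − temp_coeff·(T − T_ref)) / Δπ

Defaults: k_scale = 2.0 mOsm·s (so t₀ < 10 ms — the dead time — whenever
Δπ > 200 mOsm, where the kinetics reduce to the plain flux law),
rigidity_coeff = 0.06 s·mOsm/k_BT (positive: cholesterol-stiffened
membranes open pores later), temp_coeff = 0.01 K⁻¹, κ_ref = 25 k_BT,
T_ref = 298.15 K.  Δπ = 0 returns an *infinite-delay* outcome rather than
an error: with no drive, no pore-driven flux is predicted.  The solute
label (KCl/NaCl/sucrose) is metadata only and never enters computation.
`barrier_to_delay` supplies the mechanistic reading — an Arrhenius/Kramers
waiting time τ_attempt·exp(E_pore/k_BT), with barriers of a few tens of
k_BT and microsecond attempt times spanning the observed delays.

## 5. Flicker spectroscopy (`flicker`)

Quasi-spherical Helfrich equipartition with equatorial projection
(Faucon/Méléard-type).  Spherical-harmonic amplitudes have variance
1/[κ_b(l−1)(l+2)(l(l+1)+σ̄)] with reduced tension σ̄ = σR²/κ_b; the
equatorial Fourier mode n of u = (r−R)/R collects all l ≥ n with weights
(2l+1)/(4π)·(l−n)!/(l+n)!·P_l^n(0)², summed to l_max (default 30).
Generator and estimator deliberately share this spectrum, so parameter
recovery is well-posed independent of formula-variant debates in the
literature.  Frames are statistically independent (the 33.4 fps temporal
correlation of a real acquisition is not modelled).  Modes n = 0
(dilation) and n = 1 (translation) are excluded everywhere — requesting
them is an error; normalising by the per-frame mean radius removes n = 0,
and centre errors land in the discarded n = 1.

Fitting: least squares of log⟨|u_n|²⟩ against log B_n over n = 2..20 by
default.  B_n factorises as b_n(σ̄)/κ_b, so κ_b is profiled out
analytically and a bounded 1-D search over log₁₀(σ̄+1) ∈ [0, 5] remains
(Brent, xatol 10⁻⁶).  95% CI by frame-level percentile bootstrap (1000
resamples, seeded; expanded to contain the point estimate).

Imaging path: frames are rendered as Gaussian-profile fluorescent rings
(default width 2 px, peak 200 counts on a 10-count background) with
Poisson shot noise at the 0.102 µm pixel size; extraction samples 128
radial profiles by bilinear interpolation, takes each profile maximum with
3-point parabolic refinement (subpixel; < 0.1 px noiseless), applies one
re-centring pass, and rejects frames whose profiles lack a peak 6 robust
sds above background or whose contour jumps > 3 px between neighbouring
rays.  A quarter of rendered frames are drawn strongly degraded (dim,
defocused) to emulate the out-of-focus and drifting frames a real
acquisition discards; under defaults the extraction pass rate is 70–80%,
mirroring the ~7500 usable of 10,000 recorded frames in a typical session.
With 7500 contour frames κ_b is recovered within 10% (typically ~1%); the
full generate→render→extract→fit path at 500 frames recovers it within
15% (typically ~4%).  Extraction noise adds a white floor to the measured
spectrum; at the default geometry it sits well below B₂₀ and does not
warrant truncating the mode range.

## 6. Proton flux (`proton`)

F(t) = f₀ + a_fast·(1−e^{−t/τ_fast})·(ΔpH/1.4) + m_slow·t, with
m_slow = s_ref·ΔpH·(g₀ + c_π·Δπ).  The fast phase is the outer-leaflet
dye (de)protonation (default τ_fast = 5 s, amplitude 10 a.u. at the
reference 1.4-unit gradient; the probe's titration curve is absorbed into
the linear ΔpH scaling, valid over the small gradients used).  The slow
linear drift is the transmembrane proton flux; its coupling to Δπ is
linear with a positive baseline g₀ = 1 (a nonzero flux exists at Δπ = 0)
and gain c_π = 0.02 mOsm⁻¹ — the data establish the monotone trend, not
the functional form, and the linear form is the minimal choice.  With a
pure osmotic drive (ΔpH = 0, Δπ > 0) a small interface artifact remains,
capped at 5% of the gradient-driven slope (default 3%).  Grotthuss
mechanics itself is not simulated; it is the rationale for coupling proton
flux to pore-opening, not a computed quantity.

The slope estimator is OLS inside the 80–150 s window: late enough that
the fast phase has decayed to e^{−16}, early enough that gradient
dissipation is negligible.  A drift whose extrapolated 3-hour change stays
below 3% of f₀ is classified negligible photobleaching.

## 7. Synthetic study designs (`synthetic`)

`StudyDesign.full()` is the study grid: 4 compositions × Δπ ∈
{15, 25, 50, 100, 150} mOsm × 298.15 K × KCl × 3 replicates (60 traces),
plus 10,000-frame flicker series per composition and the six canonical
proton conditions (ΔpH, Δπ, solute) = (0,0,—), (0,15,KCl), (0,15,sucrose),
(1.4,0), (1.4,15), (1.4,150).  `StudyDesign.ci()` trims this to 3 Δπ
values, 1 replicate and 500 flicker frames so the whole suite runs in
minutes on one CPU.  Detector noise defaults to 0.02 a.u. (scattering) and
0.3 a.u. (fluorescence).

Composition effects are *qualitative literature trends turned into default
multipliers*, labelled as such in every manifest: κ_b lookup PC 25,
PC/chol 7:3 50, PC/lysoPC 7:3 15, PC/PE 7:3 25 k_BT (cholesterol stiffens,
lysoPC softens, PE ≈ PC); PE multiplies P by 1.2; cholesterol multiplies
the stage-II/III optical rise by 10.  They reproduce orderings, not
measured values.  All per-condition seeds derive deterministically (CRC32)
from the master seed and condition labels — the solute label is excluded
so KCl/NaCl/sucrose runs are bit-identical, as they must be.  Regenerating
a bundle with the same master seed reproduces it byte-for-byte (trace and
contour files are written with 17 significant digits; TIFF stacks omit
timestamps).

What passing tests on these fixtures shows: the estimators are unbiased
and appropriately precise *under the stated noise and design*.  What they
do not show: robustness to multi-exponential vesicle-size heterogeneity,
baseline drift, flow artefacts, illumination gradients, focus drift or
temporally correlated frames, none of which the generator emulates.

## 8. Numerical and interface choices

* Times, volumes and permeabilities are SI; Δπ stays in mOsm and κ_b in
  k_BT, the field's working units; key names in files carry unit suffixes.
* Trace files are '#'-headed delimited text with a bit-exact round trip,
  so fixture bundles are hashable; unknown config keys are rejected
  loudly (`SchemaError` naming the key).
* Degenerate inputs are outcomes, not exceptions, wherever the experiment
  produces them: Δπ = 0 (infinite delay / flat trace), t₀ below dead time
  (unresolvable), blank or open contours (frame rejected), duplicate Δπ
  conditions (averaged with a flag).  Genuine misuse (negative
  concentrations, non-monotone time axes, modes n < 2) raises.
* Associated Legendre values come from `scipy.special.lpmv` with factorial
  ratios in log space (`gammaln`), stable to l_max ≈ 150.
* The statsmodels-style surface (`ShrinkageKinetics`, `DelayLaw`,
  `FlickerSpectroscopy`, `ProtonFlux` → results with `summary()` /
  `plot()`) wraps the plain functions; both layers are public.

## 9. Known limitations

Monodisperse single-vesicle optics (no population deconvolution or Mie
physics); a linear elastic closure for the shrinkage plateau (the real
balance may include water-activity equilibration); a phenomenological
delay law calibrated by defaults, not fitted to published figures (the
source figures are not tabulated); shared generator/estimator spectrum in
the flicker module (recovery tests validate the estimator's statistics,
not the spectrum's physical exactness); no buffer-capacity model behind
the pH gradients; no Gaussian-modulus estimation from fluctuations.
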