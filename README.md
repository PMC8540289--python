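# osmoflux

Analysis of passive **water and proton transport across lipid bilayers**,
for membrane biophysicists working with stopped-flow light-scattering
kinetics of extruded liposomes (LUVs) and flicker-noise microscopy of giant
unilamellar vesicles (GUVs).

At low osmotic pressure differences (tens of mOsm), osmotically driven
vesicle shrinkage does not start at flow stop: the scattered-light trace
first *drops* to a minimum and only then rises as water leaves the vesicle.
The package models this as **delayed pore opening** — the membrane needs a
time t₀ to reorganise and nucleate a water-filled lipid pore — and provides
estimators for every quantity in that story:

* **Shrinkage kinetics.** Volume follows the osmotic flux law with a delay,

  dV/dt = 0 for t < t₀,  dV/dt = −A·V_w·P·(Δπ − k_mech·ΔV/V₀) for t ≥ t₀,

  with permeability P, water molar volume V_w = 0.018 L/mol and a linear
  elastic back-pressure k_mech that halts shrinkage at a finite plateau.
  Traces are parameterised by t₀ (deflection minimum), the stage-II slope
  (∝ water flux), and the plateau levels I₀,₀, I₀,fin, I_fin,fin.
* **Delay law.** t₀ is proportional to 1/Δπ; the scale grows with membrane
  bending rigidity κ_b and shrinks with temperature.  `DelayLaw` fits
  t₀ = k/Δπ + b by OLS; `correlate_delay_rigidity` quantifies the t₀–κ_b
  correlation.
* **Flicker spectroscopy.** Equatorial GUV contours fluctuate with Helfrich
  equipartition mode variances B_n(κ_b, σ̄); `FlickerSpectroscopy` fits κ_b
  (with reduced tension σ̄ as nuisance and a bootstrap CI) from contour
  series, including contours re-extracted from rendered fluorescence
  frames at 0.102 µm pixel size.
* **Proton flux.** Two-phase fluorescence kinetics of a membrane-bound pH
  probe: fast outer-leaflet (de)protonation plus a slow linear drift whose
  80–150 s window slope measures the transmembrane proton flux riding on
  water-filled pores; the slope grows with Δπ.
* **Synthetic data.** A fixture factory emulates the full experimental
  design (composition × Δπ × temperature grid, 10,000-frame GUV movies,
  the six canonical proton-flux conditions) with per-file ground truth, so
  the entire pipeline runs and is testable without any instrument.

## Worked example

```python
import numpy as np
from osmoflux import (MembraneMechanics, OsmoticCondition, DelayCalibration,
                      pore_delay_time, ShrinkagePhysics, VesicleState,
                      OpticsMap, simulate_trace, ShrinkageKinetics)

mech = MembraneMechanics(kappa_b=25.0)      # plain egg-PC, k_BT units
cond = OsmoticCondition(delta_pi=50.0)      # mOsm, e.g. 1:1 mix with 100 mOsm stock
delay = pore_delay_time(cond, mech, DelayCalibration())   # t0 = 0.04 s

phys = ShrinkagePhysics(permeability=2e-5, t0=delay.t0)
trace = simulate_trace(VesicleState.from_radius(55e-9), phys, cond, OpticsMap(),
                       np.arange(0.0, 1.0005, 1e-3),
                       dead_time=0.01, noise_sd=0.02, seed=42)
print(ShrinkageKinetics(trace, optics_gamma=10.0).fit().summary())
```

```
Shrinkage kinetics fit
======================
composition        egg-PC
delta_pi           50 mOsm
temperature        298.15 K
n samples          991
----------------------
t0                 0.0413503 s
stage-II slope     6.33918 a.u./s
I_0,0              4.79392 a.u.
I_0,fin            4.01457 a.u.
I_fin,fin          4.33499 a.u.
stage-I drop       0.779349 a.u.
stage-II/III rise  0.32042 a.u.
permeability       1.81613e-05 m/s
```

The fitted deflection time (41.4 ms against a true 40 ms) is the
pore-opening delay; the stage-II slope, corrected for the curvature of the
saturating rise and inverted through the flux law, recovers the osmotic
water permeability (1.82×10⁻⁵ m/s against a true 2×10⁻⁵ m/s at this noise
level).  The stage-II/III rise (0.32 a.u.) reflects the 3.3% equilibrium
volume loss set by Δπ/k_mech.

The same analyses are scriptable from the shell:

```bash
osmoflux make-fixtures --out fixtures --profile ci --seed 1
osmoflux fit fixtures/shrinkage --out fits.tsv
osmoflux report fits.tsv          # delay-law fits + t0 vs kappa_b correlation
osmoflux flicker fit fixtures/flicker/PC_contours.tsv
```

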