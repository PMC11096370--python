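# cornekin

Spatial kinetic modelling of kallikrein (KLK) activation, LEKTI inhibition
and desquamation in the stratum corneum (SC), driven by its pH depth-profile.

## Scientific problem

The SC — the outermost, non-viable layer of the epidermis — must hold on to
corneocytes deep inside the tissue and shed them at the surface
(desquamation). Shedding is executed by kallikrein-related peptidases, which
are secreted at the bottom of the SC as inactive pro-KLK together with their
inhibitor LEKTI, and are carried toward the surface by corneocyte transit.
Whether and where KLKs become active is controlled by the pH along the depth
axis: activation of pro-KLK (by KLK autoactivation and by mesotrypsin),
KLK–LEKTI binding, mesotrypsin-mediated LEKTI elimination, and the catalytic
activity of free KLK are all pH-dependent.

Ratiometric fluorescence imaging of murine SC indicates the pH depth-profile
is not a monotone gradient but three zones — roughly pH 6.0 in the lower SC,
a strongly acidic pH 5.4 middle zone, and pH 6.7 near the surface, with
pH ≈ 7.0 at the secretion boundary. This package implements the kinetic
model used to ask: which pH depth-profiles allow KLKs to stay inhibited deep
in the SC yet become active exactly at the surface?

## Model

Normalized depth `x` runs from the secretion boundary (`x = 0`) to the skin
surface (`x = 1`). Corneocytes move at a constant transit rate
`v = 1/(5 days) ≈ 2.3e-6 /s`, so material at depth `x` has age `t = x/v` and
the time-domain mass balances become an initial value problem in `x`. With
`P` = pro-KLK, `K` = free active KLK, `L` = free LEKTI, `C` = KLK–LEKTI
complex (all molar), and pH-dependent coefficients evaluated at `pH(x)`:

```
v dP/dx = −P (k_auto a_KLK K + k_meso a_meso M)
v dK/dx = +P (k_auto a_KLK K + k_meso a_meso M) − (k_a K L − k_d C) + k_deg a_meso M C
v dL/dx = −(k_a K L − k_d C) − k_deg a_meso M L
v dC/dx = +(k_a K L − k_d C) − k_deg a_meso M C
```

where `M` is the mesotrypsin concentration, `a_KLK(pH)` and `a_meso(pH)` are
relative activities (sigmoids fitted to pH–activity assays and normalized to
1 at the assay optimum pH 7.8), and `k_a(pH)`, `k_d(pH)` are the binding and
dissociation rates interpolated from a measured table. Initial conditions:
`(P, K, L, C)(0) = (1e-10 M, 0, 1e-10 M, 0)`. The desquamation proxy is the
effective activity `E_KLK(x) = a_KLK(pH(x)) · K(x)`.

Parameters that cannot be measured directly are identified in two steps:

* `k_deg` is calibrated so total LEKTI (`L + C`) surviving at the surface
  hits a scenario target — 100 % (no degradation), 50 % (continuous
  decrease) or 0.01 % (complete depletion). Total LEKTI obeys a linear decay
  decoupled from activation, so this is a 1-D root find.
* `(k_auto, k_meso)` are screened over a 17×17 log-spaced grid on
  `[1e2, 1e6] /M/s`. A pair is accepted when total activated KLK (`K + C`)
  rises comparably (within ±50 %) in the upper and lower SC halves and
  exceeds 50 % of the secreted pro-KLK at the surface.

Accepted parameters are then simulated across candidate pH profiles
(three-zone stepwise, monotone and V-shaped gradients, uniform acidic or
neutral) to compare where `E_KLK` becomes large. The package also contains
the ratiometric-imaging side: fitting probe calibration sigmoids, inverting
background-subtracted intensity ratios to pH, and zone-wise summaries, plus
seeded synthetic generators for every input table.

## Worked example

```python
import cornekin as ck
from cornekin import synthetic as syn

# noiseless synthetic assay tables -> fitted pH-dependent rate functions
config = syn.GeneratorConfig(
    seed=1,
    activity=syn.ActivityAssayConfig(noise_sd=0.0),
    calibration=syn.RatioCalibrationConfig(noise_sd=0.0),
)
curves = ck.RateFunctions(
    a_klk=ck.fit_activity_curve(syn.gen_activity_assay(config, "klk5")),
    a_meso=ck.fit_activity_curve(syn.gen_activity_assay(config, "mesotrypsin")),
    binding=ck.fit_binding_rates(syn.gen_binding_table(config)),
)

# three-zone stepwise pH profile, 50 % LEKTI-survival scenario
profile = ck.make_named_profile("stepwise_7.0_6.0_5.4_6.7")
scenario = ck.ScenarioSpec.named("continuous_decrease")
base = ck.ModelParams(k_auto=1e4, k_meso=3e5)
k_deg = ck.calibrate_kdeg(scenario, base, profile, curves)
print(f"calibrated k_deg: {k_deg:.0f} /M/s")

traj = ck.simulate(base.replace(k_deg=k_deg), profile, curves)
print(f"total activated KLK at the surface: {traj.C_Ktotal[-1]:.3e} M")
print(f"LEKTI surviving at the surface: {100 * traj.C_Ltotal[-1] / traj.C_Ltotal[0]:.1f} %")
print(f"surface rise of E_KLK (relative): {ck.surface_rise(traj) / base.C_pKLK_boundary:.3f}")
```

Output:

```
calibrated k_deg: 54629 /M/s
total activated KLK at the surface: 9.797e-11 M
LEKTI surviving at the surface: 50.0 %
surface rise of E_KLK (relative): 0.187
```

## Repository layout

This is an analysis project: the library lives in `src/cornekin/`, and the
study itself is a sequence of thin numbered scripts:

```
analysis/01_generate_inputs.py        synthetic assay/calibration tables -> results/inputs/
analysis/02_fit_rate_curves.py        fitted activity sigmoids and binding interpolants
analysis/03_calibrate_kdeg.py         k_deg per LEKTI-survival scenario
analysis/04_screen_activation_rates.py  17x17 (k_auto, k_meso) feasibility screen
analysis/05_compare_ph_profiles.py    accepted pairs across the five named pH profiles
analysis/06_ratiometric_inference.py  probe calibration fit and zone-wise pH summary
```

Each script takes `--seed`/`--outdir` style flags (defaults: seed 1, output
under `results/`). Run them in order from the `analysis/` directory.

## Limitations

See `docs/methods.md`. In short: all quantitative inputs here are synthetic
stand-ins with round-number parameters, so fitted constants (e.g. the
calibrated `k_deg` values) are internally consistent but not measurements;
the model is one-dimensional, steady-state in the frame of a moving
corneocyte, and ignores diffusion.
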