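# Methods

## Model

The stratum corneum (SC) is modelled along a normalized depth coordinate
`x ∈ [0, 1]` from the stratum-granulosum/SC boundary (`x = 0`) to the skin
surface (`x = 1`). Corneocytes — and everything secreted with them — move
outward at a depth-independent transit rate `v` (units /s), so the material
found at depth `x` has spent time `t = x / v` in the SC. Substituting
`t = x/v` converts the well-mixed time-domain kinetics of one moving
corneocyte layer into a spatial initial value problem: each reaction term is
divided by `v` and integrated from `x = 0` to `1`.

State (molar concentrations):

| symbol | species |
| --- | --- |
| `C_pKLK` | inactive pro-kallikrein |
| `C_KLK` | free active kallikrein |
| `C_LEKTI` | free inhibitor |
| `C_KL` | KLK–LEKTI complex |

Processes, all modulated by the local pH `pH(x)`:

1. **Activation** of pro-KLK, by active KLK (`k_auto · a_KLK(pH)`) and by
   mesotrypsin (`k_meso · a_meso(pH) · C_meso`).
2. **Reversible inhibition**: `k_a(pH) · C_KLK · C_LEKTI − k_d(pH) · C_KL`.
3. **LEKTI elimination** by mesotrypsin at rate
   `k_deg · a_meso(pH) · C_meso`, acting on both free LEKTI and the complex;
   eliminating complexed LEKTI releases active KLK.
4. **Desquamation proxy**: `E_KLK(x) = a_KLK(pH(x)) · C_KLK(x)`, the
   activity-weighted free-KLK concentration. The quantity
   `surface_rise = E_KLK(1) − E_KLK(0.7)` summarizes whether activity turns
   on near the surface.

Initial conditions `(C0, 0, C0, 0)` with `C0 = 1e-10 M`. Two invariants
follow from the equations and anchor the test suite: the KLK moiety
`C_pKLK + C_KLK + C_KL` is exactly conserved, and total LEKTI
`C_LEKTI + C_KL` obeys the decoupled linear decay
`d(ln L_tot)/dx = −k_deg · a_meso(pH(x)) · C_meso / v`, whose solution is a
single exponential in `k_deg`.

## Parameters

| parameter | units | default | origin |
| --- | --- | --- | --- |
| `v` | /s | `1/(5·86400) ≈ 2.31e-6` | 5-day murine SC transit time |
| `C_pKLK(0)`, `C_LEKTI(0)`, `C_meso` | M | `1e-10` | order of epidermal protease abundance; only products `k·C_meso` matter |
| `k_auto`, `k_meso` | /M/s | screened over `[1e2, 1e6]` | not directly measurable; feasibility screen below |
| `k_deg` | /M/s | calibrated | scenario calibration below |
| `a_KLK`, `a_meso` | – | fitted sigmoids | pH–activity assays (synthetic) |
| `k_a`, `k_d` | /M/s, /s | fitted interpolants | binding-rate table (synthetic) |

**Activity curves.** Relative activity is modelled as a logistic in pH
normalized by its own value at the assay optimum `pH 7.8`, then clamped to
`[0, 1]`. The normalization makes `a(7.8) = 1` exactly, matching the assay
definition of “relative activity” (percent of the optimal-pH fluorescence);
a 4-parameter variant with free floor/ceiling is available behind a flag,
and constant data fall back to a flat curve.

**Binding rates.** `log k_a` and `log k_d` are interpolated with a monotone
piecewise-cubic (PCHIP) through the table knots — exact at the knots, no
overshoot — and extrapolated flat by clamping pH to the knot range.

**`k_deg` calibration.** Because total LEKTI decays as a single
exponential, the surviving fraction at `x = 1` is strictly decreasing in
`k_deg`; a bracketed root search on `log10 k_deg` over `[1, 1e7]` hits the
scenario target (1.0, 0.5 or 1e-4 of the secreted LEKTI) to better than
`1e-4` relative. With the default synthetic curves this gives
`k_deg ≈ 5.46e4 /M/s` (50 % survival) and `≈ 7.26e5 /M/s` (0.01 %).

**Activation-rate screen.** Each `(k_auto, k_meso)` pair on a 17×17
log-spaced grid is simulated on the stepwise profile and accepted when
(i) the upper-half and lower-half increases of total activated KLK agree
within ±50 % (`0.5 < half_ratio < 1.5`) and (ii) total activated KLK at the
surface exceeds 50 % of the secreted pro-KLK. Representative pairs (the four
log-extremes of the accepted region plus the point nearest its log-centroid)
feed the cross-profile comparison. Note that total activated KLK is
independent of `k_deg` (elimination only moves KLK from the complexed to the
free pool), so all three scenarios share one accepted region.

**pH profiles.** Five named profiles: the three-zone stepwise profile
`7.0 | 6.0, 5.4, 6.7` (boundary value 7.0 at `x = 0` only; zone steps at
thirds, right-continuous), a monotone gradient `7.0 → 5.4`, a V-shaped
gradient `7.0 → 5.4 → 6.7` (minimum at `x = 2/3`), and uniform 5.4 and 7.0.

**Ratiometric side.** Probe calibrations are 4-parameter logistics in pH,
fitted jointly across imaging conditions after normalizing each condition by
its ratio at the reference `pH 8.0`; this cancels multiplicative factors such
as laser power exactly. pH inference inverts the fitted curve by bracketed
root finding on the background-subtracted ROI ratio; ratios outside the
curve's dynamic range are censored (“below range” / “above range”), never
clamped. Zone summaries report per-zone n, mean and standard error.

## Synthetic data generators

Every input table has a seeded generator (`numpy.random.default_rng`), and
the generator defaults are the study conditions:

* **pH–activity assays**: logistic truth with midpoint 6.5 (slopes 4.0 for
  KLK5, 3.0 for mesotrypsin), sampled on the acetate (3.5 or 4.1–5.6) and
  phosphate (5.8–8.0) buffer grids, Gaussian noise sd 0.02.
* **Binding table**: `log10 k_a` rising 4 → 6 and `log10 k_d` falling
  −2 → −4 over pH 4.5–7.5.
* **Probe calibrations**: 4PL with pKa 5.8 (VmC) / 7.0 (VH148GmC), slope
  2.3, floor 0.1, ceiling 1.0, two laser-power conditions scaled ×1.0/×1.6.
* **ROI intensities**: four SC zones with mean pH 7.0/6.0/5.4/6.7
  (sd 0.08) and per-ROI intensity noise on two channels plus backgrounds.

These are stand-ins with round-number parameters, not re-measurements: they
reproduce the qualitative structure (sigmoidal activity, monotone binding
trends, three-tier zonation) but any constant fitted from them — notably the
calibrated `k_deg` magnitudes — is internally consistent rather than
empirical.

## Numerical choices

* `scipy.integrate.solve_ivp` with **LSODA** (stiff-capable) by default,
  `rtol = 1e-8`, `atol = 1e-16`; the binding terms can be orders of
  magnitude faster than transit, making the system stiff.
* **Segmented integration**: the solver is restarted at every profile
  breakpoint so it never steps across a pH discontinuity (stepwise) or kink
  (piecewise-linear); within a stepwise segment the pH is frozen to the
  segment value, which treats the piecewise problem exactly. This removes
  the order-reduction error a discontinuous right-hand side otherwise causes
  (observed ~1e-5 relative before segmentation).
* Negative undershoots beyond 10× the solver tolerance raise a warning;
  smaller ones are clipped to zero for reporting only.
* `k_deg` calibration integrates the scalar `d(ln L_tot)/dx` equation (no
  underflow even at the 1e-4 depletion target) and root-finds on
  `log10 k_deg` with `brentq`.
* Verification against independent oracles: a fixed-step classical RK4
  integrator at 1e5 steps (agreement < 1e-4 relative), a closed-form
  exponential-decay limit (< 1e-8 with DOP853; LSODA's own floor is ~1e-6),
  and Gauss quadrature of the LEKTI survival integral (< 1e-6 relative).

## Limitations

* One-dimensional, steady-state in the co-moving frame: no diffusion, no
  lateral heterogeneity, no feedback of desquamation on transit.
* The pH profile is prescribed, not emergent; the model evaluates candidate
  profiles rather than explaining zonation.
* Mesotrypsin concentration and activity profile are fixed inputs; only the
  products `k_meso·C_meso` and `k_deg·C_meso` are identified.
* Fitted activity curves are clamped at 1 above the assay optimum, so
  behaviour beyond pH 7.8 is not informative.
* All quantitative conclusions are conditional on the synthetic inputs; with
  real assay tables the same pipeline applies unchanged, but the accepted
  `(k_auto, k_meso)` region and calibrated `k_deg` values would shift.
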