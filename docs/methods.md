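# Methods

This document records the models implemented in `fiberlab`, the assumptions
behind them, the provenance of default parameter values, and known
limitations. All quantitative statements about accuracy below are verified
by the test suite on synthetic data generated by the package itself.

## Molecular-weight distribution (`distributions`)

Step-growth ligation of a subunit of mass M0 = 43 kDa is modelled by the
Flory most-probable distribution: the number fraction of i-mers is
n_i ∝ (1−p) p^(i−1) with extent of reaction p. Closed forms
Mn = M0/(1−p) and Mw = M0(1+p)/(1−p) hold for the untruncated distribution;
the implementation truncates at i_max and requires the retained mass
coverage p^i_max (1 + i_max(1−p)) complement to reach 99.99%, raising an
error naming a sufficient i_max otherwise. `flory_p_for_mw` inverts the Mw
closed form.

## SEC molecular weights (`sec`)

Calibration: retention volume maps to mass via mass = a·exp(b·Vr/V0), fitted
as a log-linear least-squares problem on ≥2 standards (duplicate volumes and
non-positive masses rejected). The default synthetic standards lie exactly
on a = 3.54e5 kDa, b = −4.26, V0 = 8 mL, spanning ~1 kDa–5 MDa between the
void and total volume.

Averages: each chromatogram sample i is treated as a species with mass
M_i = mass(V_i) and abundance N_i equal to its A280 signal, and
Mn = ΣM_iN_i/ΣN_i, Mw = ΣN_iM_i²/ΣN_iM_i as plain sums (no quadrature
weights, so the two-point hand example Mn = 75, Mw = 250/3 kDa is exact).
Sums are windowed to the column's usable range (default 1–5000 kDa); the
signal fraction eluting outside the calibrated standards is reported as
`extrapolated_fraction`.

Assumptions and limitations: A280 weighs mass concentration, so this
estimator is absorbance-weighted — it is biased upward relative to true
number-weighting, and the synthetic "study polymer" is therefore defined as
the Flory distribution whose *windowed absorbance-weighted* readout equals
the measured 2.4 MDa (p solved by Brent's method at runtime). Band
broadening is Gaussian in volume; species eluting outside the grid are
pooled at the grid edge and reported in `meta["pooled_fraction"]` (≈0.9% of
mass for the study polymer on the default grid, which starts near the void
volume). Recovery vs the species-level oracle is within 1% for
p ∈ {0.5, 0.9, 0.9648} on the default grid.

## Spectrum handling and baseline (`spectrum`)

The rubber-band baseline is the lower convex hull of the (x, y) points,
interpolated linearly between hull vertices. For a convex baseline it is
exact in peak-free regions; under a peak it follows the chord, so a small
fraction of peak-tail area at the range edges is removed with the baseline
(≤3% of peak area in the tested Lorentzian case, always one-sided: the
corrected area never exceeds the true peak area). The operation is
idempotent and returns a non-negative spectrum.

## FTIR amide-I deconvolution (`amide`)

The baseline-corrected amide-I region is fitted with 11 Lorentzians at
fixed centers (cm⁻¹): 1610, 1618.5, 1624.5, 1632.5, 1642, 1651, 1659,
1666.5, 1678, 1690.5, 1700, heights free and FWHMs bounded to [5, 40] cm⁻¹.
Component areas are analytic (π·h·FWHM/2). The default assignment maps
{1610, 1618.5, 1624.5, 1632.5, 1690.5, 1700} → β-sheet, {1642} → random
coil, {1651, 1659} → α-helix, {1666.5, 1678} → β-turn; class fractions are
assigned-area shares. A custom assignment must cover all 11 centers with
known classes.

Verified accuracy: a noiseless 4-class synthetic spectrum is recovered
within 3 percentage points per class (typically ≤0.7 pp); a pure 1624.5 cm⁻¹
component returns 100% β-sheet; the noiseless fit residual is below 1e-6 of
the signal norm. Limitations: fixed centers assume the calibration of the
band positions transfers; strongly overlapping structures with shifted bands
would alias between classes, and the Lorentzian shape ignores
instrument-resolution Gaussian broadening.

## Polarized Raman orientation ratio (`raman`)

Both polarized spectra (Y along the fiber axis, X perpendicular) are
normalised by their maximum in the conformation-insensitive 1450 ± 10 cm⁻¹
band; the ratio I = Y/X is evaluated at the amide-I peak of the normalised Y
spectrum within 1670 ± 10 cm⁻¹, with X read at the same wavenumber. The
estimator is exactly invariant to uniform rescaling of either spectrum and
recovers constructed ratios {0.5, 1, 2} within 1% (1.995 for a true 2.0 —
the small bias comes from overlapping band tails). A vanishing 1450 cm⁻¹
reference raises an error.

## WAXD geometry and integration (`waxd`)

Flat-detector geometry: wavelength 0.886 Å, sample–detector distance
200 mm, 0.172 mm pixels, 701×701 frame with the beam at the center.
Momentum transfer q = (4π/λ)·sin(arctan(r/L)/2); azimuth χ = 0 on the
equator (meridian vertical by default, rotatable). Background is either a
per-pixel map or a constant estimated from the corner medians; subtraction
clamps at zero. Sector integration averages background-corrected counts in
q-bins within ±sector_width/2 of the axis (both Friedel-symmetric sides);
azimuthal profiles average over a q-band on a χ grid.

## WAXD crystal statistics (`waxd_fit`)

Radial model: Gaussian components for the crystalline (200) and (120)
equatorial reflections plus two amorphous halos (centers 0.78 and
1.50 Å⁻¹). Crystallinity is the crystalline share of the total fitted area.
To break the strong overlap degeneracy between the broad (200) peak and the
first halo, the halo line shapes (center, FWHM, height) are first fitted in
an off-axis χ = 55° sector — where the oriented crystalline arcs are absent
but the isotropic halos are identical — and pinned in the equatorial fit,
leaving only the crystalline parameters free.

Scherrer size: D = Kλ/(β·cosθ) with K = 0.9, β = 2·arcsin(λ·FWHM_q/4π),
θ = arcsin(λ·q_peak/4π) (exact q-to-angle conversion, not the small-angle
approximation). Herman orientation from the azimuthal FWHMs of the two
equatorial reflections: f = (3⟨cos²⟩−1)/2 with
⟨cos²⟩ = 1 − 0.8·sin²(0.4·F200) − 1.2·sin²(0.4·F120) (arguments in degrees;
a guard rejects inputs outside [0, 90]° and results outside [−0.5, 1]).
Azimuthal fits use narrow (crystalline) plus broad (amorphous) Gaussian
pairs at χ = 0/180° over a floor, with optional (201) satellite components
whose positions are bounded away from the equator.

Verified round trip (synthetic truth 18% crystallinity, d = 1.08/0.46 nm,
D = 1.08/2.91 nm, f = 0.76, Poisson counting noise): d within 1% (measured
~0.1%), D within 5% (~0.4%/1.5%), crystallinity within 2 points (~0.4 pp),
f within 0.05 (≤0.005). Limitations: the forward model and the fit share
the Gaussian line-shape family, so the round trip validates the estimator
chain, not line-shape robustness; the Herman ⟨cos²⟩ expression is an
empirical mapping from FWHMs, exact only under its own orientation
distribution; overlapping meridional/equatorial intensity is not modelled
beyond the (002) option.

## Tensile and cyclic mechanics (`mechanics`)

Traces (time, displacement, force) convert to engineering stress/strain via
the initial cross-section π(d/2)² (diameter optionally averaged over
multi-point measurements) and gauge length (default 5 mm). Modulus is a
least-squares slope over the 0.2–1.5% strain window (≥4 samples required);
strength is the stress maximum; the break is the first post-peak sample
with >90% stress drop (otherwise the result is flagged censored); toughness
integrates stress to the break (MPa·strain ≡ MJ/m³).

Cycles split at the maximum-strain sample; damping capacity is the
hysteresis area over the loading area, damping energy the hysteresis area
itself. Negative stresses are clamped to zero for the area integrals, but
the permanent set (first zero crossing of the unloading stress) is
interpolated on the unclamped trace.

Forward model: linear-elastic to the yield strain 0.016, then power-law
hardening σ_y + h(ε−ε_y)^0.5; for the study polymer E = 4.2 GPa and h is
solved so the envelope reaches 378 MPa at break strain 0.47 (toughness then
emerges as ≈125 MJ/m³ from the closed-form envelope integral; replicate
sampling over n = 14 fibers gives means near 130 MJ/m³). Unloading is
linear at 4.0 GPa, floored at the loading secant so elastic cycles retrace
exactly (zero damping). The virgin loading branch follows the envelope;
reloads from a residual strain rise elastically until they intersect the
envelope. The low-molecular-weight (monomer) fiber applies relative
reductions of 38% (modulus), 60% (strength) and 57% (break strain).
Generated cycles reproduce their closed-form damping truths within 0.5%;
the triangle-loop hand example (DC = 50%, DE = 2.5 MJ/m³) is exact.
Limitations: engineering (not true) stress/strain throughout; the unload
path is idealised as linear; rate and humidity effects are not modelled —
`recovery_fraction` is only a stand-in for recovery treatment between
cycles.

## Pipeline (`pipeline`, `cli`)

`RunConfig` is a flat `key = value` file with module-prefixed keys; unknown
keys are rejected by name (with line number when parsed from text).
Per-stage seeds derive from SHA-256 of `"{seed}:{stage}"`, so stages are
decoupled and reproducible individually. Reports carry no timestamps: two
runs with identical config are byte-identical. `roundtrip_check` re-runs
the simulate→analyze loop and tabulates truth vs recovered against the
documented tolerances (relative comparisons fall back to absolute when the
truth is zero); `fiberlab check` exits non-zero on any violation.
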