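"""Synthetic instrument-data generators with attached ground truth.

Every downstream analysis stage (SEC molecular weights, amide-I
deconvolution, polarized-Raman ratio, WAXD crystal statistics, tensile
and cyclic mechanics) has a forward model here so the whole pipeline is
testable by parameter recovery, without any downloaded data.  Each
generator is a pure function of its parameters and seed: identical
inputs give bit-identical outputs.

Default parameter values are the study conditions of the fiber
characterisation the package models: a ~43 kDa four-domain titin subunit
chained by split-intein ligation into a megadalton polymer, spun into
~10 um fibers with ~28% beta-sheet, ~18% crystallinity, 1.08/0.46 nm
equatorial d-spacings, crystal orientation f ~ 0.76, modulus ~4.2 GPa,
strength ~378 MPa and break strain ~47%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .amide import AMIDE_I_CENTERS, DEFAULT_ASSIGNMENT, STRUCTURE_CLASSES, lorentzian
from .distributions import (DiscreteMWDistribution, gen_flory_distribution,
                            species_moments)
from .mechanics import MechanicalTrace
from .sec import CalibrationCurve, Chromatogram, fit_calibration
from .spectrum import Spectrum
from .waxd import DetectorGeometry, DiffractionImage, map_pixels
from .waxd_fit import GAUSS_AREA

__all__ = [
    "default_calibration", "study_polymer_distribution", "gen_sec_chromatogram",
    "gen_ftir_spectrum", "gen_raman_pair",
    "WAXDTruth", "gen_waxd_image", "orientation_fwhm_for_f",
    "MechanicalModelParams", "polymer_params", "monomer_params",
    "sample_tensile_params", "gen_tensile_trace", "gen_cyclic_traces",
    "MONOMER_MASS_KDA",
]

#: subunit (monomer) mass in kDa
MONOMER_MASS_KDA = 43.0


# ---------------------------------------------------------------------------
# SEC
# ---------------------------------------------------------------------------

#: synthetic gel-filtration standards (mass kDa, Vr mL) lying exactly on an
#: exponential calibration spanning ~1 kDa-5 MDa between void (8 mL) and
#: total volume (24 mL)
_CALIB_A = 3.54e5      # kDa
_CALIB_B = -4.26
_CALIB_V0 = 8.0        # mL


def default_calibration(noise_sd_rel: float = 0.0, seed: int = 0,
                        n_standards: int = 6) -> CalibrationCurve:
    """Calibration fitted to standards generated on an exponential curve.

    With ``noise_sd_rel`` > 0 each standard mass is perturbed by a
    relative Gaussian error before fitting (seeded).
    """
    vr = np.linspace(1.05 * _CALIB_V0, 2.9 * _CALIB_V0, n_standards)
    mass = _CALIB_A * np.exp(_CALIB_B * vr / _CALIB_V0)
    if noise_sd_rel > 0:
        rng = np.random.default_rng(seed)
        mass = mass * (1 + noise_sd_rel * rng.standard_normal(mass.size))
    return fit_calibration(list(zip(mass, vr)), _CALIB_V0)


def study_polymer_distribution(measured_mw_kda: float = 2.4e3,
                               monomer_mass: float = MONOMER_MASS_KDA,
                               mass_window: tuple[float, float] = (1.0, 5000.0),
                               i_max: int = 4000) -> DiscreteMWDistribution:
    """Flory polymer whose windowed, absorbance-weighted SEC readout
    matches the measured mass-average MW.

    The SEC estimator weighs species by A280 (i.e. by mass) and windows
    the sums to the column's usable range, so the extent of reaction is
    chosen by solving for the p whose species-level windowed
    absorbance-weighted Mw equals ``measured_mw_kda`` — the synthetic
    polymer then reproduces the measurement, not the (unobservable)
    untruncated moment.
    """

    def readout(p: float) -> float:
        d = gen_flory_distribution(p, monomer_mass, i_max)
        return species_moments(d, "absorbance", mass_window)[1]

    p = brentq(lambda pp: readout(pp) - measured_mw_kda, 0.5, 0.995, xtol=1e-10)
    return gen_flory_distribution(p, monomer_mass, i_max)


def gen_sec_chromatogram(dist: DiscreteMWDistribution, calib: CalibrationCurve,
                         broadening_sd: float = 0.15, noise_sd: float = 0.0,
                         seed: int = 0, grid_step: float = 0.01,
                         volume_range: tuple[float, float] | None = None
                         ) -> Chromatogram:
    """Forward SEC model: species bands on a uniform volume grid.

    Each species contributes signal proportional to its mass fraction
    (A280 weighs mass concentration) as a Gaussian band centered at the
    calibrated retention volume of its mass, with volume-domain sd
    ``broadening_sd`` (mL).  Species whose calibrated volume falls
    outside the grid are pooled at the nearest grid limit and counted in
    ``meta["pooled_fraction"]``.  Additive Gaussian noise is seeded.
    """
    if dist.masses.size == 0:
        raise ValueError("empty distribution")
    if broadening_sd < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if volume_range is None:
        volume_range = (0.95 * calib.void_volume, 3.05 * calib.void_volume)
    vlo, vhi = volume_range
    grid = vlo + grid_step * np.arange(int(round((vhi - vlo) / grid_step)) + 1)

    centers = np.asarray(calib.volume_at(dist.masses), float)
    pooled = (centers < grid[0]) | (centers > grid[-1])
    weights = dist.mass_fractions
    pooled_fraction = float(weights[pooled].sum())
    centers = np.clip(centers, grid[0], grid[-1])

    sd = max(broadening_sd, grid_step / 2.0)  # zero broadening -> one-bin band
    signal = np.zeros_like(grid)
    # vectorised: sum of Gaussians; chunk over species to bound memory
    for start in range(0, centers.size, 512):
        c = centers[start:start + 512, None]
        w = weights[start:start + 512, None]
        signal += (w * np.exp(-0.5 * ((grid[None, :] - c) / sd) ** 2)).sum(axis=0)
    signal /= sd * math.sqrt(2 * math.pi)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + noise_sd * rng.standard_normal(signal.size)
    return Chromatogram(grid, signal,
                        meta={"pooled_fraction": pooled_fraction,
                              "broadening_sd": broadening_sd, "seed": seed})


# ---------------------------------------------------------------------------
# FTIR
# ---------------------------------------------------------------------------

#: relative weights of the components within each structure class, used to
#: split a class area over its assigned centers
_CLASS_WEIGHTS: dict[str, dict[float, float]] = {
    "beta_sheet": {1610.0: 0.08, 1618.5: 0.20, 1624.5: 0.32, 1632.5: 0.25,
                   1690.5: 0.09, 1700.0: 0.06},
    "random_coil": {1642.0: 1.0},
    "alpha_helix": {1651.0: 0.6, 1659.0: 0.4},
    "beta_turn": {1666.5: 0.55, 1678.0: 0.45},
}

#: study-condition secondary structure: ~28% beta-sheet
DEFAULT_CLASS_FRACTIONS = {"beta_sheet": 0.28, "random_coil": 0.22,
                           "alpha_helix": 0.25, "beta_turn": 0.25}


def gen_ftir_spectrum(class_fractions: dict[str, float] | None = None,
                      widths: float | dict[float, float] = 14.0,
                      baseline_params: tuple[float, float, float] = (0.0, 0.0, 0.0),
                      noise_sd: float = 0.0, seed: int = 0,
                      total_area: float = 100.0,
                      x_range: tuple[float, float] = (1415.0, 1780.0),
                      step: float = 2.0) -> Spectrum:
    """Amide-I forward model: 11 Lorentzians plus a smooth baseline.

    ``class_fractions`` must sum to 1; each class area (fraction of
    ``total_area``) is split over its assigned centers with fixed
    within-class weights.  ``baseline_params`` (c0, c1, c2) add the
    convex curve c0 + c1*(x-x0) + c2*(x-xm)^2 (c2 >= 0 keeps it convex so
    a rubber-band baseline can recover it exactly in peak-free regions).
    The truth record (class fractions, per-component heights/areas) is
    attached to ``meta``.
    """
    fr = dict(DEFAULT_CLASS_FRACTIONS if class_fractions is None else class_fractions)
    unknown = set(fr) - set(STRUCTURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown structure class(es): {sorted(unknown)}")
    total = sum(fr.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"class fractions sum to {total}, not 1")
    if isinstance(widths, dict):
        width_of = lambda c: widths[c]  # noqa: E731
    else:
        width_of = lambda c: float(widths)  # noqa: E731

    x = np.arange(x_range[0], x_range[1] + step / 2, step)
    y = np.zeros_like(x)
    components = []
    for cls, weights in _CLASS_WEIGHTS.items():
        class_area = total_area * fr.get(cls, 0.0)
        for center, rel in weights.items():
            area = class_area * rel
            w = width_of(center)
            height = area / (math.pi * w / 2.0)
            y += lorentzian(x, height, center, w)
            components.append({"center": center, "height": height,
                               "fwhm": w, "area": area, "structure": cls})
    c0, c1, c2 = baseline_params
    if c2 < 0:
        raise ValueError("baseline curvature must be non-negative (convex)")
    xm = 0.5 * (x[0] + x[-1])
    y = y + c0 + c1 * (x - x[0]) + c2 * (x - xm) ** 2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * rng.standard_normal(y.size)
    return Spectrum(x, y, modality="ftir",
                    meta={"true_fractions": fr, "components": components,
                          "baseline_params": baseline_params, "seed": seed})


# ---------------------------------------------------------------------------
# Raman
# ---------------------------------------------------------------------------

def gen_raman_pair(true_ratio: float = 2.0, noise_sd: float = 0.0, seed: int = 0,
                   scale_x: float = 1.0, scale_y: float = 1.0,
                   x_range: tuple[float, float] = (1100.0, 1800.0),
                   step: float = 1.0) -> tuple[Spectrum, Spectrum]:
    """Polarized spectrum pair (Y, X) with a constructed orientation ratio.

    Both spectra carry an equal-height conformation-insensitive
    1450 cm^-1 reference band; the 1670 cm^-1 amide-I heights (after 1450
    normalisation) differ by exactly ``true_ratio``.  Independent global
    scale factors exercise the normalisation invariance.
    """
    if true_ratio <= 0:
        raise ValueError("true ratio must be positive")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    x = np.arange(x_range[0], x_range[1] + step / 2, step)
    ref_h, amide_x_h = 1.0, 0.6
    base = lorentzian(x, ref_h, 1450.0, 16.0) + lorentzian(x, 0.25, 1245.0, 24.0)
    yx = base + lorentzian(x, amide_x_h, 1670.0, 20.0)
    yy = base + lorentzian(x, amide_x_h * true_ratio, 1670.0, 20.0)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        yy = yy + noise_sd * rng.standard_normal(x.size)
        yx = yx + noise_sd * rng.standard_normal(x.size)
    meta = {"true_ratio": true_ratio, "seed": seed}
    spec_y = Spectrum(x, scale_y * yy, modality="raman", orientation="Y", meta=meta)
    spec_x = Spectrum(x, scale_x * yx, modality="raman", orientation="X", meta=meta)
    return spec_y, spec_x


# ---------------------------------------------------------------------------
# WAXD
# ---------------------------------------------------------------------------

def orientation_fwhm_for_f(f_true: float) -> float:
    """Azimuthal crystalline FWHM (degrees) whose Herman readout is ``f_true``.

    Inverts f = (3c-1)/2, c = 1 - 2 sin^2(0.4 w) (both reflections given
    the same azimuthal width).  Invertible for f in (-0.5, 1]; outside
    that range a ValueError reports the achievable interval.
    """
    if not -0.5 < f_true <= 1.0:
        raise ValueError(
            f"f_true={f_true} outside the invertible range (-0.5, 1] of the "
            "equal-width orientation model")
    c2 = (2 * f_true + 1) / 3
    s2 = (1 - c2) / 2
    return math.degrees(math.asin(math.sqrt(s2))) / 0.4


def _scherrer_fwhm_q(D_nm: float, d_nm: float, wavelength: float,
                     K: float = 0.9) -> float:
    """Radial FWHM (A^-1) implied by crystallite size D at spacing d."""
    pc = 2 * math.pi / (10.0 * d_nm)
    theta = math.asin(wavelength * pc / (4 * math.pi))
    beta = K * wavelength / (10.0 * D_nm * math.cos(theta))
    return (4 * math.pi / wavelength) * math.sin(beta / 2.0)


@dataclass(frozen=True)
class WAXDTruth:
    """Ground-truth parameters of a synthetic oriented fiber pattern."""

    d200_nm: float = 1.08
    d120_nm: float = 0.46
    crystallite_a_nm: float = 1.08
    crystallite_b_nm: float = 2.91
    crystallinity: float = 0.18
    f_true: float = 0.76
    amorphous_centers: tuple[float, float] = (0.78, 1.50)   # A^-1
    amorphous_fwhms: tuple[float, float] = (0.55, 0.70)     # A^-1
    amorphous_areas: tuple[float, float] = (40.0, 42.0)     # in-sector, au
    cryst_area_split: tuple[float, float] = (10.0, 8.0)     # (200):(120)
    orientation_weight: float = 1.0
    d002_nm: float | None = 0.35
    crystallite_c_nm: float = 2.0
    area_002: float = 3.0
    background: float = 2.0
    count_scale: float = 60.0
    sector_deg: float = 25.0
    scherrer_k: float = 0.9
    seed: int = 0

    def __post_init__(self):
        for name in ("d200_nm", "d120_nm", "crystallite_a_nm", "crystallite_b_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.crystallinity <= 1.0:
            raise ValueError("crystallinity must lie in [0, 1]")
        if not 0.0 <= self.orientation_weight <= 1.0:
            raise ValueError("orientation weight must lie in [0, 1]")


def _pair_gauss_deg(chi_deg: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    out = np.zeros_like(chi_deg)
    for c in (center, center + 180.0):
        for k in (-360.0, 0.0, 360.0):
            out += np.exp(-4 * math.log(2) * ((chi_deg - (c + k)) / fwhm) ** 2)
    return out


def gen_waxd_image(truth: WAXDTruth = WAXDTruth(),
                   geometry: DetectorGeometry | None = None,
                   shape: tuple[int, int] = (701, 701),
                   poisson: bool = True) -> DiffractionImage:
    """Render a synthetic oriented semi-crystalline fiber pattern.

    The analytic intensity surface is

        I(q, chi) = sum_cryst  A_k g(q; q_k, w_k) Phi(chi)
                  + sum_amorph B_j g(q; c_j, s_j)
                  + background,

    where the radial Gaussians carry FWHMs implied by the Scherrer chain
    for the stated crystallite sizes, and the crystalline azimuthal
    factor Phi mixes an equator-centered Gaussian pair (FWHM set by
    inverting Herman's function for ``f_true``) with a uniform term,
    normalised so its mean over the reference sector is one — making the
    in-sector component areas exactly the stated A_k/B_j.  Counts are
    Poisson-sampled at ``count_scale`` with the truth's seed
    (``poisson=False`` returns the noise-free surface for quadrature
    checks).  The truth record is attached to ``meta``.
    """
    geo = geometry or DetectorGeometry(center=((shape[0] - 1) / 2.0,
                                               (shape[1] - 1) / 2.0))
    q, chi = map_pixels(geo, shape)
    lam = geo.wavelength

    w_az = orientation_fwhm_for_f(truth.f_true)
    # azimuthal factor, normalised to unit mean over the reference sector
    fine = np.linspace(-truth.sector_deg / 2, truth.sector_deg / 2, 501)

    def phi_of(chi_deg, center):
        shape_part = _pair_gauss_deg(chi_deg, center, w_az)
        return truth.orientation_weight * shape_part + (1 - truth.orientation_weight)

    sector_mean = float(np.mean(phi_of(fine, 0.0)))
    phi_eq = phi_of(chi, 0.0) / sector_mean

    a_am1, a_am2 = truth.amorphous_areas
    total_am = a_am1 + a_am2
    if truth.crystallinity >= 1.0:
        raise ValueError("crystallinity of 1 needs zero amorphous area")
    total_cr = truth.crystallinity / (1 - truth.crystallinity) * total_am
    s200, s120 = truth.cryst_area_split
    a200 = total_cr * s200 / (s200 + s120)
    a120 = total_cr * s120 / (s200 + s120)

    def radial(area, d_nm, fwhm):
        q0 = 2 * math.pi / (10.0 * d_nm)
        h = area / (fwhm * GAUSS_AREA)
        return h * np.exp(-4 * math.log(2) * ((q - q0) / fwhm) ** 2)

    f200 = _scherrer_fwhm_q(truth.crystallite_a_nm, truth.d200_nm, lam,
                            truth.scherrer_k)
    f120 = _scherrer_fwhm_q(truth.crystallite_b_nm, truth.d120_nm, lam,
                            truth.scherrer_k)
    surface = radial(a200, truth.d200_nm, f200) * phi_eq
    surface += radial(a120, truth.d120_nm, f120) * phi_eq
    for c, w, a in zip(truth.amorphous_centers, truth.amorphous_fwhms,
                       truth.amorphous_areas):
        h = a / (w * GAUSS_AREA)
        surface += h * np.exp(-4 * math.log(2) * ((q - c) / w) ** 2)
    if truth.d002_nm is not None:
        f002 = _scherrer_fwhm_q(truth.crystallite_c_nm, truth.d002_nm, lam,
                                truth.scherrer_k)
        phi_mer = phi_of(chi, 90.0) / sector_mean
        surface += radial(truth.area_002, truth.d002_nm, f002) * phi_mer
    surface += truth.background

    expected = truth.count_scale * surface
    if poisson:
        rng = np.random.default_rng(truth.seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    meta = {"truth": truth, "azimuthal_fwhm_deg": w_az,
            "radial_fwhm_200": f200, "radial_fwhm_120": f120}
    return DiffractionImage(counts, geo, meta=meta)


# ---------------------------------------------------------------------------
# Mechanics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MechanicalModelParams:
    """Elastic-plastic fiber model: linear to the yield strain, power-law
    hardening beyond, linear unloading at the unload modulus."""

    modulus_gpa: float = 4.2
    yield_strain: float = 0.016
    hardening_coeff_mpa: float = 461.26
    hardening_exp: float = 0.5
    unload_modulus_gpa: float = 4.0
    break_strain: float = 0.47
    noise_sd_mpa: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.modulus_gpa <= 0 or self.unload_modulus_gpa <= 0:
            raise ValueError("moduli must be positive")
        if not 0 < self.yield_strain < self.break_strain:
            raise ValueError("need 0 < yield strain < break strain")
        if self.hardening_coeff_mpa < 0 or self.hardening_exp <= 0:
            raise ValueError("hardening parameters must be positive")

    # -- the loading envelope (virgin curve), stress in MPa ---------------
    def envelope(self, strain):
        e = np.asarray(strain, float)
        emod = self.modulus_gpa * 1e3
        sy = emod * self.yield_strain
        out = np.where(e <= self.yield_strain, emod * e,
                       sy + self.hardening_coeff_mpa
                       * np.abs(e - self.yield_strain) ** self.hardening_exp)
        return out if out.ndim else float(out)

    def envelope_area(self, a: float, b: float) -> float:
        """Closed-form integral of the envelope over [a, b] (MJ/m^3)."""
        emod = self.modulus_gpa * 1e3
        sy = emod * self.yield_strain
        h, m, ey = self.hardening_coeff_mpa, self.hardening_exp, self.yield_strain

        def cum(x: float) -> float:
            if x <= ey:
                return 0.5 * emod * x * x
            plastic = sy * (x - ey) + h * (x - ey) ** (m + 1) / (m + 1)
            return 0.5 * emod * ey * ey + plastic

        return cum(b) - cum(a)


def polymer_params(strength_mpa: float = 378.0, **overrides) -> MechanicalModelParams:
    """Study-condition polymer-fiber parameters; the hardening coefficient
    is solved so the envelope reaches ``strength_mpa`` at the break strain."""
    base = MechanicalModelParams(**overrides) if overrides else MechanicalModelParams()
    emod = base.modulus_gpa * 1e3
    sy = emod * base.yield_strain
    h = (strength_mpa - sy) / (base.break_strain - base.yield_strain) ** base.hardening_exp
    if h <= 0:
        raise ValueError("strength below the yield stress")
    return replace(base, hardening_coeff_mpa=float(h))


def monomer_params(**overrides) -> MechanicalModelParams:
    """Low-MW (monomer) fiber: the reported relative reductions versus the
    polymer fiber — modulus -38%, strength -60%, break strain -57% — with
    the same yield strain and hardening exponent."""
    defaults = dict(modulus_gpa=4.2 * (1 - 0.38),
                    unload_modulus_gpa=4.0 * (1 - 0.38),
                    break_strain=0.47 * (1 - 0.57))
    defaults.update(overrides)
    return polymer_params(strength_mpa=378.0 * (1 - 0.60), **defaults)


def sample_tensile_params(n: int, seed: int = 0,
                          mean_modulus_gpa: float = 4.2, sd_modulus_gpa: float = 0.6,
                          mean_strength_mpa: float = 378.0, sd_strength_mpa: float = 41.0,
                          mean_break_strain: float = 0.47, sd_break_strain: float = 0.07,
                          ) -> list[MechanicalModelParams]:
    """Per-fiber parameter sets reproducing replicate-to-replicate spread."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        e = max(float(rng.normal(mean_modulus_gpa, sd_modulus_gpa)), 0.5)
        s = max(float(rng.normal(mean_strength_mpa, sd_strength_mpa)), 50.0)
        eb = max(float(rng.normal(mean_break_strain, sd_break_strain)), 0.05)
        out.append(polymer_params(strength_mpa=s, modulus_gpa=e, break_strain=eb,
                                  unload_modulus_gpa=e * 0.95,
                                  seed=int(rng.integers(2 ** 31))))
    return out


CROSSHEAD_SPEED_MM_MIN = 10.0
SAMPLING_HZ = 50.0


def _strain_grid(params: MechanicalModelParams, gauge_mm: float,
                 start: float, stop: float) -> np.ndarray:
    rate = CROSSHEAD_SPEED_MM_MIN / 60.0 / gauge_mm       # strain per second
    step = rate / SAMPLING_HZ
    n = max(int(math.ceil((stop - start) / step)), 2)
    return start + (stop - start) * np.arange(n + 1) / n


def gen_tensile_trace(params: MechanicalModelParams = polymer_params(),
                      diameter_um: float = 10.0,
                      gauge_mm: float = 5.0) -> MechanicalTrace:
    """Pull-to-failure trace at constant crosshead speed.

    Loads along the elastic-plastic envelope to the break strain, then
    appends a >90% stress drop; seeded Gaussian stress noise is applied
    before conversion to force.  The closed-form truth (modulus, strength,
    break strain, toughness) is attached to ``meta``.
    """
    eps = _strain_grid(params, gauge_mm, 0.0, params.break_strain)
    sig = params.envelope(eps)
    peak = float(sig[-1])
    # post-break tail: stress collapses to 5% of the peak
    tail_eps = eps[-1] + np.array([0.002, 0.004])
    eps = np.concatenate([eps, tail_eps])
    sig = np.concatenate([sig, [0.05 * peak, 0.05 * peak]])
    if params.noise_sd_mpa > 0:
        rng = np.random.default_rng(params.seed)
        sig = sig + params.noise_sd_mpa * rng.standard_normal(sig.size)
    radius_m = diameter_um * 1e-6 / 2
    area = math.pi * radius_m ** 2
    rate = CROSSHEAD_SPEED_MM_MIN / 60.0 / gauge_mm
    time = eps / rate
    truth = {"modulus_gpa": params.modulus_gpa,
             "strength_mpa": peak,
             "breaking_strain": float(params.break_strain),
             "toughness_mj_m3": params.envelope_area(0.0, params.break_strain)}
    return MechanicalTrace(time, eps * gauge_mm, sig * 1e6 * area,
                           diameter_um, gauge_mm, meta={"truth": truth})


def _cycle_truth(params: MechanicalModelParams, start: float, peak: float
                 ) -> dict:
    """Closed-form loading/unloading areas for one cycle of the model."""
    emod = params.modulus_gpa * 1e3
    su_nominal = params.unload_modulus_gpa * 1e3

    def reload_line(e):
        return emod * (e - start)

    g = lambda e: reload_line(e) - params.envelope(e)  # noqa: E731
    if start == 0.0:
        # the reload line is the virgin elastic branch: follow the envelope
        cross = min(params.yield_strain, peak)
        sigma_peak = float(params.envelope(peak))
        a_load = params.envelope_area(0.0, peak)
    elif g(peak) < 0:
        # reload stays elastic to the peak (never reaches the envelope)
        cross = peak
        sigma_peak = reload_line(peak)
        a_load = 0.5 * sigma_peak * (peak - start)
    else:
        cross = brentq(g, start + 1e-12, peak)
        sigma_peak = float(params.envelope(peak))
        a_load = (0.5 * float(params.envelope(cross)) * (cross - start)
                  + params.envelope_area(cross, peak))
    # unload slope floored at the loading secant so the set never precedes
    # the cycle start (unload path must stay under the load path)
    secant = sigma_peak / (peak - start) if peak > start else su_nominal
    slope = max(su_nominal, secant)
    pset = peak - sigma_peak / slope
    a_unload = 0.5 * sigma_peak * (peak - pset)
    de = a_load - a_unload
    return {"peak_strain": peak, "start_strain": start,
            "sigma_peak": sigma_peak, "cross": cross, "unload_slope": slope,
            "permanent_set": pset, "a_load": a_load, "a_unload": a_unload,
            "damping_capacity_pct": 100.0 * de / a_load,
            "damping_energy_mj_m3": de}


def gen_cyclic_traces(params: MechanicalModelParams = polymer_params(),
                      peak_strains: tuple[float, ...] = (0.006, 0.016, 0.05,
                                                         0.10, 0.20, 0.30),
                      recovery_fraction: float = 1.0,
                      diameter_um: float = 10.0, gauge_mm: float = 5.0,
                      seed: int = 0) -> list[MechanicalTrace]:
    """Loading/unloading cycles at increasing peak strains.

    Each cycle loads along the model path from the current residual
    strain and unloads linearly at the unload modulus, leaving a
    permanent set; ``recovery_fraction`` rescales the set before the next
    cycle (the humid-air treatment stand-in: 1 = full length recovery).
    Closed-form truth damping capacity/energy per cycle are attached to
    each trace's ``meta["truth"]``.
    """
    if any(b < a for a, b in zip(peak_strains, peak_strains[1:])):
        raise ValueError("peak strains must be non-descending")
    if peak_strains and max(peak_strains) >= params.break_strain:
        raise ValueError("peak strains must stay below the break strain")
    if not 0.0 <= recovery_fraction <= 1.0:
        raise ValueError("recovery fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    radius_m = diameter_um * 1e-6 / 2
    area = math.pi * radius_m ** 2
    rate = CROSSHEAD_SPEED_MM_MIN / 60.0 / gauge_mm

    traces = []
    start = 0.0
    for peak in peak_strains:
        if peak <= start:
            raise ValueError(f"peak strain {peak} does not exceed the residual "
                             f"strain {start:.4g}")
        truth = _cycle_truth(params, start, peak)
        e_up = _strain_grid(params, gauge_mm, start, peak)
        if start == 0.0:
            # virgin branch: follow the envelope itself (just past yield the
            # sqrt-hardening envelope lies above the elastic line, so the
            # min() reload construction would wrongly clip it)
            s_up = params.envelope(e_up)
        else:
            s_up = np.minimum(params.modulus_gpa * 1e3 * (e_up - start),
                              params.envelope(e_up))
        e_dn = _strain_grid(params, gauge_mm, peak, truth["permanent_set"])[1:]
        s_dn = truth["sigma_peak"] - truth["unload_slope"] * (peak - e_dn)
        eps = np.concatenate([e_up, e_dn])
        sig = np.clip(np.concatenate([s_up, s_dn]), 0.0, None)
        if params.noise_sd_mpa > 0:
            sig = sig + params.noise_sd_mpa * rng.standard_normal(sig.size)
        # time advances with |strain change| at the constant crosshead rate
        dstrain = np.abs(np.diff(eps, prepend=eps[0]))
        time = dstrain.cumsum() / rate
        traces.append(MechanicalTrace(time, eps * gauge_mm, sig * 1e6 * area,
                                      diameter_um, gauge_mm,
                                      meta={"truth": truth}))
        start = (1.0 - recovery_fraction) * truth["permanent_set"]
    return traces
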