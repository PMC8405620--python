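"""Deconvolution of WAXD 1-D profiles and derived crystal statistics.

Radial sector profiles are fitted with Gaussian components: two equatorial
Bragg reflections indexed on an orthorhombic beta-sheet cell — (200),
the inter-sheet spacing along the a-axis, and (120), the inter-chain
spacing along the b-axis — plus two broad amorphous halos (the meridian
adds a freely-centered (002) reflection).  From the fitted peak centers
(PC) and widths (FWHM, both in A^-1):

* d-spacing           d = 2*pi / PC
* Bragg angle         theta = arcsin(lambda * PC / 4pi)
* width in radians    beta = 2 * arcsin(lambda * FWHM / 4pi)
* Scherrer size       D = K * lambda / (beta * cos(theta)),  K ~ 0.9
* crystallinity       sum of equatorial crystalline areas over the sum of
                      crystalline plus amorphous areas
* Herman's parameter  f = (3<cos^2 phi> - 1)/2 with
                      <cos^2 phi> = 1 - 0.8 sin^2(0.4 FWHM_200)
                                      - 1.2 sin^2(0.4 FWHM_120),
                      the azimuthal crystalline FWHMs entering in degrees.

"Intensity" of a component means its integrated area throughout (the
standard convention for crystallinity ratios), not its height.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .waxd import (AzimuthalProfile, DiffractionImage, RadialProfile,
                   azimuthal_profile, sector_integrate)

__all__ = [
    "PeakFit", "RadialProfileModel", "AzimuthalProfileModel",
    "crystallinity", "analyze_peak", "herman_orientation",
    "CrystalAnalysis", "analyze_image",
    "D200_NM", "D120_NM",
]

#: nominal equatorial d-spacings (nm) used to initialise the radial fit
D200_NM = 1.08
D120_NM = 0.46

GAUSS_AREA = math.sqrt(math.pi / (4 * math.log(2)))  # area = h * fwhm * this


def gaussian(x, height, center, fwhm):
    return height * np.exp(-4 * math.log(2) * ((x - center) / fwhm) ** 2)


@dataclass(frozen=True)
class PeakFit:
    """One fitted line-shape component of a 1-D profile."""

    label: str
    center: float        # A^-1 (radial) or degrees (azimuthal)
    fwhm: float
    height: float

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("FWHM must be positive")
        if self.height < 0:
            raise ValueError("height must be non-negative")

    @property
    def area(self) -> float:
        return self.height * self.fwhm * GAUSS_AREA

    @property
    def is_crystalline(self) -> bool:
        return not self.label.startswith("amorphous")


def _fit_table(fits) -> pd.DataFrame:
    return pd.DataFrame([{"label": f.label, "center": f.center,
                          "fwhm": f.fwhm, "height": f.height,
                          "area": f.area} for f in fits])


class RadialProfileModel:
    """Gaussian deconvolution of an equatorial or meridional radial profile.

    Components on the equator: (200), (120) and two amorphous halos; the
    meridian adds a freely-centered (002).  Crystalline centers are
    initialised at 2*pi/d for the nominal d-spacings and bounded +-15%;
    amorphous centers and widths are loosely bounded, with the amorphous
    width floor set above the crystalline floor so a width inversion
    (an "amorphous" component collapsing onto a Bragg peak) is detected
    and refit from a perturbed start.
    """

    CRYST_FWHM = (0.05, 0.9)
    AMORPH_FWHM = (0.10, 1.8)

    def __init__(self, profile: RadialProfile,
                 d200_nm: float = D200_NM, d120_nm: float = D120_NM,
                 amorphous_centers: tuple[float, float] = (0.78, 1.50),
                 amorphous_shape: tuple[tuple[float, float, float], ...] | None = None):
        self.profile = profile
        self.q200 = 2 * math.pi / (10.0 * d200_nm)
        self.q120 = 2 * math.pi / (10.0 * d120_nm)
        qmin, qmax = profile.q[0], profile.q[-1]
        if not (qmin < self.q200 < qmax and qmin < self.q120 < qmax):
            raise ValueError("profile does not cover both expected reflections")
        self.amorphous_centers = amorphous_centers
        # (center, fwhm, height) per halo pinned from an off-axis reference
        # sector; the halos are isotropic, so their sector-mean line shape is
        # identical on the equator.  Pinning them entirely breaks the
        # degeneracy between the broad (200) reflection and the first halo.
        self.amorphous_shape = amorphous_shape
        self.with_002 = profile.axis == "meridian"

    def _components(self) -> list[str]:
        names = ["c200", "c120", "am1", "am2"]
        if self.with_002:
            names.insert(2, "c002")
        return names

    def _make_params(self, rng: np.random.Generator | None) -> Parameters:
        prof = self.profile
        jitter = (lambda: rng.uniform(0.9, 1.1)) if rng is not None else (lambda: 1.0)
        p = Parameters()

        def amp_at(q0):
            return max(float(np.interp(q0, prof.q, prof.intensity)), 1e-6)

        specs = {
            "c200": (self.q200, 0.15, 0.45, self.CRYST_FWHM),
            "c120": (self.q120, 0.15, 0.18, self.CRYST_FWHM),
            "am1": (self.amorphous_centers[0], 0.30, 0.55, self.AMORPH_FWHM),
            "am2": (self.amorphous_centers[1], 0.30, 0.70, self.AMORPH_FWHM),
        }
        if self.with_002:
            specs["c002"] = (1.80, 0.20, 0.25, self.CRYST_FWHM)
        pinned_h = {}
        if self.amorphous_shape is not None:
            for name, (c0, w0, h0) in zip(("am1", "am2"), self.amorphous_shape):
                specs[name] = (c0, 0.0, w0, (w0, w0))
                pinned_h[name] = h0
        for name in self._components():
            c0, crel, w0, wb = specs[name]
            if crel == 0.0:   # shape pinned from the reference sector
                p.add(f"{name}_h", value=pinned_h[name], vary=False)
                p.add(f"{name}_c", value=c0, vary=False)
                p.add(f"{name}_w", value=w0, vary=False)
            else:
                p.add(f"{name}_h", value=0.5 * amp_at(c0) * jitter(), min=0.0)
                p.add(f"{name}_c", value=c0 * jitter(), min=c0 * (1 - crel),
                      max=c0 * (1 + crel))
                p.add(f"{name}_w", value=min(max(w0 * jitter(), wb[0]), wb[1]),
                      min=wb[0], max=wb[1])
        return p

    def _eval(self, params, q):
        out = np.zeros_like(q)
        for name in self._components():
            out += gaussian(q, params[f"{name}_h"].value,
                            params[f"{name}_c"].value, params[f"{name}_w"].value)
        return out

    def fit(self, max_restarts: int = 3, seed: int = 0) -> "RadialFitResult":
        q, y = self.profile.q, self.profile.intensity
        rng = np.random.default_rng(seed)
        best = None
        for attempt in range(max_restarts + 1):
            params = self._make_params(None if attempt == 0 else rng)
            res = minimize(lambda p: self._eval(p, q) - y, params,
                           method="least_squares")
            inverted = self._width_inversion(res.params)
            if best is None or (res.chisqr < best[0].chisqr and not inverted):
                best = (res, inverted)
            if res.success and not inverted:
                best = (res, False)
                break
        res, inverted = best
        if not np.isfinite(res.chisqr):
            raise RuntimeError(f"radial fit failed (residual {res.chisqr})")
        labels = {"c200": f"{self.profile.axis}(200)",
                  "c120": f"{self.profile.axis}(120)",
                  "c002": "(002)",
                  "am1": "amorphous1", "am2": "amorphous2"}
        fits = tuple(PeakFit(labels[name], res.params[f"{name}_c"].value,
                             res.params[f"{name}_w"].value,
                             res.params[f"{name}_h"].value)
                     for name in self._components())
        resid = float(np.linalg.norm(self._eval(res.params, q) - y))
        return RadialFitResult(fits, self.profile, resid, width_inversion=inverted)

    def _width_inversion(self, params) -> bool:
        if self.amorphous_shape is not None:
            return False
        # an amorphous halo should never be the narrowest component
        cw = [params["c120_w"].value]
        aw = [params["am1_w"].value, params["am2_w"].value]
        return min(aw) < 0.8 * min(cw)


@dataclass(frozen=True)
class RadialFitResult:
    """Fitted components of a radial sector profile."""

    peaks: tuple[PeakFit, ...]
    profile: RadialProfile
    residual_norm: float
    width_inversion: bool = False

    def __getitem__(self, label: str) -> PeakFit:
        for p in self.peaks:
            if p.label == label:
                return p
        raise KeyError(label)

    def table(self) -> pd.DataFrame:
        return _fit_table(self.peaks)

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write(f"Radial profile fit ({self.profile.axis}, "
                  f"sector {self.profile.sector_width:g} deg)\n")
        buf.write(self.table().to_string(index=False, float_format="%.4g"))
        buf.write(f"\n  residual norm = {self.residual_norm:.4g}\n")
        return buf.getvalue()


class AzimuthalProfileModel:
    """Orientation fit of an azimuthal profile around the equator.

    Per equatorial lobe (chi = 0 and 180 deg, Friedel-symmetric and
    sharing parameters): a narrow crystalline Gaussian and a broad
    component, over a constant floor from the isotropic amorphous halos.
    With ``include_subsidiary`` symmetric satellite Gaussians model
    residual off-axis (201) intensity.  The crystalline FWHM is reported
    in degrees and feeds Herman's orientation function.
    """

    def __init__(self, profile: AzimuthalProfile, include_subsidiary: bool = True):
        self.profile = profile
        span = profile.chi[-1] - profile.chi[0]
        if span < 180.0:
            raise ValueError("azimuthal profile must span at least 180 degrees")
        self.include_subsidiary = include_subsidiary

    @staticmethod
    def _pair(chi, height, center, fwhm):
        out = np.zeros_like(chi)
        for c in (center, center + 180.0):
            for k in (-360.0, 0.0, 360.0):
                out += gaussian(chi, height, c + k, fwhm)
        return out

    def _eval(self, p, chi):
        out = np.full_like(chi, p["floor"].value)
        out += self._pair(chi, p["n_h"].value, 0.0, p["n_w"].value)
        out += self._pair(chi, p["b_h"].value, 0.0, p["b_w"].value)
        if self.include_subsidiary:
            for sign in (-1.0, 1.0):
                out += self._pair(chi, p["s_h"].value, sign * p["s_c"].value,
                                  p["s_w"].value)
        return out

    def fit(self, max_restarts: int = 2, seed: int = 0) -> "AzimuthalFitResult":
        chi, y = self.profile.chi, self.profile.intensity
        rng = np.random.default_rng(seed)
        ymax = float(y.max()) or 1.0
        best = None
        for attempt in range(max_restarts + 1):
            j = 1.0 if attempt == 0 else float(rng.uniform(0.7, 1.3))
            p = Parameters()
            p.add("floor", value=float(np.percentile(y, 10)), min=0.0)
            p.add("n_h", value=0.6 * ymax * j, min=0.0)
            p.add("n_w", value=35.0 * j, min=5.0, max=80.0)
            p.add("b_h", value=0.05 * ymax, min=0.0)
            p.add("b_w", value=130.0, min=80.0, max=240.0)
            if self.include_subsidiary:
                p.add("s_h", value=0.02 * ymax, min=0.0)
                p.add("s_c", value=55.0, min=25.0, max=85.0)
                p.add("s_w", value=25.0 * j, min=5.0, max=60.0)
            res = minimize(lambda pp: self._eval(pp, chi) - y, p,
                           method="least_squares")
            inverted = res.params["b_w"].value < res.params["n_w"].value
            if best is None or (res.chisqr < best[0].chisqr and not inverted):
                best = (res, inverted)
            if res.success and not inverted:
                best = (res, False)
                break
        res, _ = best
        if not np.isfinite(res.chisqr):
            raise RuntimeError("azimuthal fit failed to converge")
        peaks = [
            PeakFit("crystalline-azimuthal", 0.0, res.params["n_w"].value,
                    res.params["n_h"].value),
            PeakFit("amorphous-azimuthal", 0.0, res.params["b_w"].value,
                    res.params["b_h"].value),
        ]
        if self.include_subsidiary:
            peaks.append(PeakFit("(201)", res.params["s_c"].value,
                                 res.params["s_w"].value, res.params["s_h"].value))
        resid = float(np.linalg.norm(self._eval(res.params, chi) - y))
        return AzimuthalFitResult(tuple(peaks), self.profile,
                                  float(res.params["floor"].value), resid)


@dataclass(frozen=True)
class AzimuthalFitResult:
    peaks: tuple[PeakFit, ...]
    profile: AzimuthalProfile
    floor: float
    residual_norm: float

    @property
    def crystalline_fwhm(self) -> float:
        """FWHM (degrees) of the narrow oriented component."""
        return self["crystalline-azimuthal"].fwhm

    def __getitem__(self, label: str) -> PeakFit:
        for p in self.peaks:
            if p.label == label:
                return p
        raise KeyError(label)

    def table(self) -> pd.DataFrame:
        return _fit_table(self.peaks)


def fit_amorphous_reference(profile: RadialProfile,
                            centers: tuple[float, float] = (0.78, 1.50)
                            ) -> tuple[tuple[float, float, float], ...]:
    """Halo line shapes (center, FWHM, height) from an off-axis sector.

    The amorphous halos are isotropic while the oriented Bragg arcs are
    confined to the equator, so a sector placed between equator and
    meridian sees (almost) pure halo, and the sector-mean halo profile
    there equals the halo contribution to any other sector.  Fitting two
    Gaussians to it pins the full halo line shapes for the equatorial
    deconvolution, leaving only the crystalline parameters free.
    """
    q, y = profile.q, profile.intensity
    p = Parameters()
    for i, c0 in enumerate(centers):
        h0 = max(float(np.interp(c0, q, y)), 1e-6)
        p.add(f"a{i}_h", value=0.8 * h0, min=0.0)
        p.add(f"a{i}_c", value=c0, min=0.75 * c0, max=1.25 * c0)
        p.add(f"a{i}_w", value=0.6, min=RadialProfileModel.AMORPH_FWHM[0],
              max=RadialProfileModel.AMORPH_FWHM[1])

    def model(pp):
        out = np.zeros_like(q)
        for i in range(len(centers)):
            out += gaussian(q, pp[f"a{i}_h"].value, pp[f"a{i}_c"].value,
                            pp[f"a{i}_w"].value)
        return out

    res = minimize(lambda pp: model(pp) - y, p, method="least_squares")
    if not np.isfinite(res.chisqr):
        raise RuntimeError("amorphous reference fit failed")
    return tuple((float(res.params[f"a{i}_c"].value),
                  float(res.params[f"a{i}_w"].value),
                  float(res.params[f"a{i}_h"].value))
                 for i in range(len(centers)))


def crystallinity(fits) -> float:
    """Crystalline area fraction from equatorial components.

    ``fits`` may be a :class:`RadialFitResult` or an iterable of
    :class:`PeakFit`; it must contain both equatorial Bragg peaks and
    both amorphous halos.
    """
    peaks = fits.peaks if isinstance(fits, RadialFitResult) else tuple(fits)
    by_label = {p.label: p for p in peaks}
    needed = []
    for suffix in ("(200)", "(120)"):
        match = [p for p in peaks if p.label.endswith(suffix)
                 and not p.label.startswith("amorphous")]
        if not match:
            raise ValueError(f"missing equatorial {suffix} component")
        needed.append(match[0])
    for name in ("amorphous1", "amorphous2"):
        if name not in by_label:
            raise ValueError(f"missing {name} component")
    cryst = sum(p.area for p in needed)
    total = cryst + by_label["amorphous1"].area + by_label["amorphous2"].area
    if total == 0:
        raise ValueError("all component areas are zero")
    return cryst / total


def analyze_peak(fit: PeakFit, wavelength: float, K: float = 0.9
                 ) -> tuple[float, float]:
    """d-spacing and Scherrer crystallite size from one radial peak.

    Parameters are the fitted peak center PC and FWHM in A^-1 and the
    X-ray wavelength in A.  Returns ``(d_nm, D_nm)`` where d = 2*pi/PC
    and D = K*lambda / (beta * cos(theta)) with beta and theta from the
    arcsin conversions above (all trigonometric work in radians; the
    degree form of the Bragg angle is only a reporting convention).
    """
    if fit.center <= 0:
        raise ValueError("peak center must be positive")
    if fit.fwhm <= 0:
        raise ValueError("zero peak width implies an unbounded crystallite size")
    s_theta = wavelength * fit.center / (4 * math.pi)
    s_beta = wavelength * fit.fwhm / (4 * math.pi)
    if s_theta > 1 or s_beta > 1:
        raise ValueError("wavelength * q / 4pi exceeds 1; check units")
    theta = math.asin(s_theta)
    beta = 2 * math.asin(s_beta)
    d_nm = 2 * math.pi / fit.center / 10.0
    D_nm = K * wavelength / (beta * math.cos(theta)) / 10.0
    return d_nm, D_nm


def herman_orientation(fwhm_200_deg: float, fwhm_120_deg: float) -> float:
    """Herman's orientation parameter from azimuthal crystalline FWHMs.

    f = (3<cos^2 phi> - 1)/2 with <cos^2 phi> = 1 - 0.8 sin^2(0.4 F200)
    - 1.2 sin^2(0.4 F120); the 0.4*FWHM arguments are interpreted in
    degrees (a radian reading drives <cos^2 phi> negative for typical
    widths).  f = 1 for perfect axial alignment, 0 for no preferred
    orientation; values outside [-0.5, 1] indicate a unit mistake and
    raise.
    """
    if fwhm_200_deg < 0 or fwhm_120_deg < 0:
        raise ValueError("FWHMs must be non-negative (degrees)")
    c2 = (1.0
          - 0.8 * math.sin(math.radians(0.4 * fwhm_200_deg)) ** 2
          - 1.2 * math.sin(math.radians(0.4 * fwhm_120_deg)) ** 2)
    f = (3 * c2 - 1) / 2
    if not -0.5 - 1e-12 <= f <= 1.0 + 1e-12:
        raise ValueError(f"orientation parameter {f:.3f} outside [-0.5, 1]; "
                         "check that FWHMs are in degrees")
    return min(max(f, -0.5), 1.0)


@dataclass(frozen=True)
class CrystalAnalysis:
    """Full crystal statistics extracted from one fiber-diffraction image."""

    crystallinity: float
    d200: float            # nm
    d120: float            # nm
    crystallite_a: float   # nm, along the inter-sheet a-axis, from (200)
    crystallite_b: float   # nm, along the inter-chain b-axis, from (120)
    f_crystal: float
    scherrer_k: float
    equatorial_fit: RadialFitResult = field(repr=False)
    meridional_fit: RadialFitResult | None = field(repr=False, default=None)
    azimuthal_fits: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.crystallinity <= 1.0:
            raise ValueError("crystallinity must lie in [0, 1]")
        if not -0.5 <= self.f_crystal <= 1.0:
            raise ValueError("f_crystal must lie in [-0.5, 1]")

    def summary(self) -> str:
        return (
            "WAXD crystal analysis\n"
            f"  crystallinity        = {100 * self.crystallinity:.1f} %\n"
            f"  d(200) inter-sheet   = {self.d200:.3f} nm\n"
            f"  d(120) inter-chain   = {self.d120:.3f} nm\n"
            f"  crystallite size a   = {self.crystallite_a:.2f} nm\n"
            f"  crystallite size b   = {self.crystallite_b:.2f} nm\n"
            f"  Herman f_crystal     = {self.f_crystal:.3f}\n"
            f"  (Scherrer K = {self.scherrer_k:g})\n"
        )


def analyze_image(image: DiffractionImage, sector_width: float = 25.0,
                  q_bin: float = 0.005, K: float = 0.9,
                  include_subsidiary: bool = True,
                  fit_meridian: bool = False) -> CrystalAnalysis:
    """End-to-end WAXD pipeline on one 2-D diffraction image.

    Sector-integrates the equator, deconvolves the radial profile
    (with the amorphous halo shapes pinned from an off-axis reference
    sector at chi = 55 deg, where the oriented Bragg arcs are absent),
    derives crystallinity, d-spacings and Scherrer sizes, then extracts
    azimuthal profiles in the radial bands of the two equatorial
    reflections and evaluates Herman's orientation function on their
    crystalline FWHMs.
    """
    ref_profile = sector_integrate(image, 55.0, sector_width, q_bin)
    halo_shape = fit_amorphous_reference(ref_profile)
    eq_profile = sector_integrate(image, "equator", sector_width, q_bin)
    eq_fit = RadialProfileModel(eq_profile, amorphous_shape=halo_shape).fit()
    xc = crystallinity(eq_fit)
    lam = image.geometry.wavelength
    p200 = eq_fit["equator(200)"]
    p120 = eq_fit["equator(120)"]
    d200, D_a = analyze_peak(p200, lam, K)
    d120, D_b = analyze_peak(p120, lam, K)

    az_fits = {}
    fwhms = {}
    for label, peak in (("(200)", p200), ("(120)", p120)):
        band = (peak.center - peak.fwhm / 2, peak.center + peak.fwhm / 2)
        prof = azimuthal_profile(image, band)
        fit = AzimuthalProfileModel(prof, include_subsidiary=include_subsidiary).fit()
        az_fits[label] = fit
        fwhms[label] = fit.crystalline_fwhm
    f = herman_orientation(fwhms["(200)"], fwhms["(120)"])

    mer_fit = None
    if fit_meridian:
        mer_profile = sector_integrate(image, "meridian", sector_width, q_bin)
        mer_fit = RadialProfileModel(mer_profile, amorphous_shape=halo_shape).fit()

    return CrystalAnalysis(xc, d200, d120, D_a, D_b, f, K,
                           eq_fit, mer_fit, az_fits)
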