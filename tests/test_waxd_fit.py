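import math

import numpy as np
import pytest

from fiberlab.waxd import AzimuthalProfile, RadialProfile
from fiberlab.waxd_fit import (AzimuthalProfileModel, GAUSS_AREA, PeakFit,
                               RadialProfileModel, analyze_peak, crystallinity,
                               gaussian, herman_orientation)

LAMBDA = 0.886


def test_gauss_area_constant():
    x = np.linspace(-50.0, 50.0, 200001)
    num = np.trapezoid(gaussian(x, 3.0, 0.0, 2.0), x)
    assert 3.0 * 2.0 * GAUSS_AREA == pytest.approx(num, rel=1e-9)


def test_peakfit_validation_and_area():
    with pytest.raises(ValueError):
        PeakFit("x", 1.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        PeakFit("x", 1.0, 1.0, -1.0)
    p = PeakFit("x", 1.0, 2.0, 3.0)
    assert p.area == pytest.approx(3.0 * 2.0 * GAUSS_AREA)


def test_analyze_peak_d_spacing():
    d, _ = analyze_peak(PeakFit("(200)", 0.582, 0.1, 1.0), LAMBDA)
    assert d == pytest.approx(1.080, abs=5e-4)


def test_analyze_peak_scherrer_chain():
    # independent numeric evaluation of D = K lambda / (beta cos theta)
    pc, fwhm, K = 0.582, 0.524, 0.9
    theta = math.asin(LAMBDA * pc / (4 * math.pi))
    beta = 2 * math.asin(LAMBDA * fwhm / (4 * math.pi))
    expected_nm = K * LAMBDA / (beta * math.cos(theta)) / 10.0
    _, D = analyze_peak(PeakFit("(200)", pc, fwhm, 1.0), LAMBDA, K=K)
    assert D == pytest.approx(expected_nm, rel=1e-12)
    assert D == pytest.approx(1.08, abs=0.01)


def test_analyze_peak_errors():
    from types import SimpleNamespace
    with pytest.raises(ValueError):
        analyze_peak(SimpleNamespace(center=-1.0, fwhm=0.1), LAMBDA)
    # FWHM -> 0 means an unbounded crystallite size and must error
    with pytest.raises(ValueError, match="unbounded"):
        analyze_peak(SimpleNamespace(center=0.582, fwhm=0.0), LAMBDA)


def test_analyze_peak_domain_error():
    with pytest.raises(ValueError, match="units"):
        analyze_peak(PeakFit("x", 20.0, 0.1, 1.0), LAMBDA)


def test_herman_closed_forms():
    assert herman_orientation(0.0, 0.0) == pytest.approx(1.0)
    # independent evaluation at 30/30 degrees
    c2 = 1 - 0.8 * math.sin(math.radians(12.0)) ** 2 \
           - 1.2 * math.sin(math.radians(12.0)) ** 2
    assert herman_orientation(30.0, 30.0) == pytest.approx((3 * c2 - 1) / 2,
                                                           rel=1e-12)
    assert herman_orientation(30.0, 30.0) == pytest.approx(0.870, abs=5e-3)


def test_herman_monotone_decreasing():
    f_vals = [herman_orientation(w, w) for w in np.linspace(0.0, 90.0, 19)]
    assert all(a > b for a, b in zip(f_vals, f_vals[1:]))
    fixed = [herman_orientation(w, 30.0) for w in np.linspace(0.0, 90.0, 19)]
    assert all(a > b for a, b in zip(fixed, fixed[1:]))


def test_herman_unit_guard():
    with pytest.raises(ValueError, match="degrees"):
        herman_orientation(150.0, 150.0)
    with pytest.raises(ValueError):
        herman_orientation(-1.0, 10.0)


def _peaks(a200=10.0, a120=8.0, am1=40.0, am2=42.0):
    def pk(label, center, fwhm, area):
        return PeakFit(label, center, fwhm, area / (fwhm * GAUSS_AREA))
    return [pk("equator(200)", 0.582, 0.52, a200),
            pk("equator(120)", 1.366, 0.195, a120),
            pk("amorphous1", 0.78, 0.55, am1),
            pk("amorphous2", 1.50, 0.70, am2)]


def test_crystallinity_hand_arithmetic():
    assert crystallinity(_peaks()) == pytest.approx(0.18, abs=1e-12)
    assert crystallinity(_peaks(a200=0.0, a120=0.0)) == 0.0
    assert crystallinity(_peaks(am1=0.0, am2=0.0)) == 1.0


def test_crystallinity_missing_component_errors():
    peaks = _peaks()
    with pytest.raises(ValueError, match=r"\(200\)"):
        crystallinity(peaks[1:])
    with pytest.raises(ValueError, match="amorphous1"):
        crystallinity(peaks[:2] + peaks[3:])


def _profile_from_peaks(peaks, qmax=2.0):
    q = np.arange(0.005, qmax, 0.005)
    y = np.zeros_like(q)
    for p in peaks:
        y += gaussian(q, p.height, p.center, p.fwhm)
    return RadialProfile(q, y, "equator", 25.0)


def test_radial_fit_exact_recovery_noiseless():
    truth = _peaks()
    prof = _profile_from_peaks(truth)
    fit = RadialProfileModel(prof).fit()
    for p in truth:
        rec = fit[p.label]
        assert rec.center == pytest.approx(p.center, rel=5e-3)
        assert rec.fwhm == pytest.approx(p.fwhm, rel=0.05)
    assert crystallinity(fit) == pytest.approx(0.18, abs=0.02)


def test_radial_fit_with_pinned_halos():
    truth = _peaks()
    prof = _profile_from_peaks(truth)
    shape = tuple((p.center, p.fwhm, p.height) for p in truth[2:])
    fit = RadialProfileModel(prof, amorphous_shape=shape).fit()
    for p in truth[:2]:
        rec = fit[p.label]
        assert rec.center == pytest.approx(p.center, rel=1e-3)
        assert rec.fwhm == pytest.approx(p.fwhm, rel=5e-3)
    assert crystallinity(fit) == pytest.approx(0.18, abs=0.005)


def test_radial_fit_requires_coverage():
    prof = _profile_from_peaks(_peaks(), qmax=1.0)   # misses (120)
    with pytest.raises(ValueError):
        RadialProfileModel(prof)


def _az_profile(n_h=1.0, n_w=25.0, b_h=0.2, b_w=120.0, floor=0.05,
                satellites=0.0):
    chi = np.arange(1.0, 360.0, 2.0)
    y = np.full_like(chi, floor)
    for c in (0.0, 180.0, 360.0):
        y += gaussian(chi, n_h, c, n_w) + gaussian(chi, b_h, c, b_w)
    y += gaussian(chi, b_h, -180.0, b_w)
    if satellites:
        for c in (55.0, 125.0, 235.0, 305.0):
            y += gaussian(chi, satellites, c, 20.0)
    return AzimuthalProfile(chi, y, (0.5, 0.6))


def test_azimuthal_fit_recovers_widths():
    fit = AzimuthalProfileModel(_az_profile(), include_subsidiary=False).fit()
    assert fit.crystalline_fwhm == pytest.approx(25.0, rel=0.05)
    assert fit["amorphous-azimuthal"].fwhm == pytest.approx(120.0, rel=0.05)


def test_azimuthal_fit_satellites_do_not_bias_main_width():
    fit = AzimuthalProfileModel(_az_profile(satellites=0.15),
                                include_subsidiary=True).fit()
    assert fit.crystalline_fwhm == pytest.approx(25.0, rel=0.05)


def test_azimuthal_fit_span_validation():
    chi = np.arange(0.0, 90.0, 2.0)
    prof = AzimuthalProfile(chi, np.ones_like(chi), (0.5, 0.6))
    with pytest.raises(ValueError):
        AzimuthalProfileModel(prof)
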