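import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fiberlab import simulate as sim
from fiberlab.distributions import gen_flory_distribution, species_moments
from fiberlab.sec import (Chromatogram, compute_mn_mw, fit_calibration)

A, B, V0 = 3.54e5, -4.26, 8.0


def _exact_standards(n=6):
    vr = np.linspace(1.05 * V0, 2.9 * V0, n)
    mass = A * np.exp(B * vr / V0)
    return list(zip(mass, vr))


def test_fit_calibration_exact_recovery():
    calib = fit_calibration(_exact_standards(), V0)
    assert calib.a == pytest.approx(A, rel=1e-9)
    assert calib.b == pytest.approx(B, rel=1e-9)
    assert np.abs(calib.residuals).max() < 1e-9


def test_two_standards_exact_interpolation():
    stds = _exact_standards(2)
    calib = fit_calibration(stds, V0)
    for mass, vr in stds:
        assert calib.mass_at(vr) == pytest.approx(mass, rel=1e-9)


def test_calibration_input_validation():
    with pytest.raises(ValueError):
        fit_calibration(_exact_standards(1), V0)
    with pytest.raises(ValueError):
        fit_calibration([(100.0, 10.0), (50.0, 10.0)], V0)
    with pytest.raises(ValueError):
        fit_calibration(_exact_standards(), 0.0)


def test_noisy_standards_within_three_sd():
    rel_sd = 0.02
    calib = sim.default_calibration(noise_sd_rel=rel_sd, seed=7)
    for mass, vr in _exact_standards():
        fitted = calib.mass_at(vr)
        assert abs(fitted - mass) < 3 * rel_sd * mass * np.sqrt(6)


def test_inverse_mapping_roundtrip():
    calib = fit_calibration(_exact_standards(), V0)
    masses = np.array([10.0, 1e3, 2.4e3])
    assert calib.mass_at(calib.volume_at(masses)) == pytest.approx(masses)


def test_single_narrow_peak_mn_equals_mw():
    calib = fit_calibration(_exact_standards(), V0)
    target = 500.0
    v0 = float(calib.volume_at(target))
    chrom = Chromatogram(np.array([v0 - 0.01, v0, v0 + 0.01]),
                         np.array([0.0, 1.0, 0.0]))
    res = compute_mn_mw(chrom, calib)
    assert res.mn == pytest.approx(target, rel=1e-6)
    assert res.mw == pytest.approx(target, rel=1e-6)
    assert res.dispersity == pytest.approx(1.0, rel=1e-9)


def test_two_point_hand_example():
    # equal signal at calibrated masses 50 and 100 kDa:
    # Mn = 75 kDa, Mw = (50^2+100^2)/150 = 83.333... kDa (plain sums)
    calib = fit_calibration(_exact_standards(), V0)
    vols = sorted(float(calib.volume_at(m)) for m in (50.0, 100.0))
    chrom = Chromatogram(np.array(vols), np.array([1.0, 1.0]))
    res = compute_mn_mw(chrom, calib)
    assert res.mn == pytest.approx(75.0, rel=1e-9)
    assert res.mw == pytest.approx(250.0 / 3.0, rel=1e-9)


def test_window_and_signal_errors():
    calib = fit_calibration(_exact_standards(), V0)
    v = float(calib.volume_at(500.0))
    chrom = Chromatogram(np.array([v, v + 0.01]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        compute_mn_mw(chrom, calib, mass_window=(1e6, 2e6))
    zero = Chromatogram(np.array([v, v + 0.01]), np.array([0.0, 0.0]))
    with pytest.raises(ValueError):
        compute_mn_mw(zero, calib)


def test_scaling_invariance():
    calib = sim.default_calibration()
    dist = gen_flory_distribution(0.9, 43.0, i_max=4000)
    chrom = sim.gen_sec_chromatogram(dist, calib)
    res1 = compute_mn_mw(chrom, calib)
    res2 = compute_mn_mw(Chromatogram(chrom.volume, 7.5 * chrom.absorbance),
                         calib)
    assert res2.mn == pytest.approx(res1.mn, rel=1e-12)
    assert res2.mw == pytest.approx(res1.mw, rel=1e-12)


def test_grid_refinement_invariance():
    calib = sim.default_calibration()
    dist = gen_flory_distribution(0.9, 43.0, i_max=4000)
    coarse = compute_mn_mw(sim.gen_sec_chromatogram(dist, calib,
                                                    grid_step=0.02), calib)
    fine = compute_mn_mw(sim.gen_sec_chromatogram(dist, calib,
                                                  grid_step=0.005), calib)
    assert fine.mw == pytest.approx(coarse.mw, rel=0.005)
    assert fine.mn == pytest.approx(coarse.mn, rel=0.005)


def test_estimator_matches_species_oracle():
    calib = sim.default_calibration()
    for p in (0.5, 0.9, 0.9648):
        dist = gen_flory_distribution(p, 43.0, i_max=4000)
        chrom = sim.gen_sec_chromatogram(dist, calib)
        res = compute_mn_mw(chrom, calib)
        omn, omw = species_moments(dist, "absorbance",
                                   mass_window=res.mass_window)
        assert res.mn == pytest.approx(omn, rel=0.01)
        assert res.mw == pytest.approx(omw, rel=0.01)


def test_extrapolated_fraction_flagged():
    calib = sim.default_calibration()
    dist = gen_flory_distribution(0.9648, 43.0, i_max=4000)
    chrom = sim.gen_sec_chromatogram(dist, calib)
    res = compute_mn_mw(chrom, calib)
    # the window reaches 5 MDa, above the largest standard
    assert res.extrapolated_fraction > 0.0


def test_chromatogram_csv_roundtrip(tmp_path):
    chrom = Chromatogram(np.array([1.0, 2.0, 3.0]), np.array([0.1, 0.5, 0.2]))
    path = tmp_path / "chrom.csv"
    chrom.to_csv(path)
    back = Chromatogram.from_csv(path)
    assert np.allclose(back.volume, chrom.volume)
    assert np.allclose(back.absorbance, chrom.absorbance)


def test_chromatogram_invariants():
    with pytest.raises(ValueError):
        Chromatogram(np.array([1.0, 1.0]), np.array([0.0, 0.0]))
    with pytest.raises(ValueError):
        Chromatogram(np.array([1.0, 2.0]), np.array([0.0, np.nan]))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=5.0), min_size=3,
                max_size=12))
def test_property_mw_ge_mn(signal):
    if sum(signal) <= 0:
        return
    calib = fit_calibration(_exact_standards(), V0)
    vols = np.linspace(1.2 * V0, 2.5 * V0, len(signal))
    res = compute_mn_mw(Chromatogram(vols, np.array(signal)), calib)
    assert res.mw >= res.mn * (1 - 1e-12)
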