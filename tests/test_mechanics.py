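import math

import numpy as np
import pytest

from fiberlab import simulate as sim
from fiberlab.mechanics import (MechanicalTrace, StressStrainCurve,
                                aggregate_replicates, cycle_damping,
                                tensile_summary, to_stress_strain)


def _curve(strain, stress, diameter_um=10.0, gauge_mm=5.0):
    r = diameter_um * 1e-6 / 2
    area = math.pi * r ** 2
    return StressStrainCurve(np.asarray(strain, float),
                             np.asarray(stress, float),
                             area, area * gauge_mm * 1e-3)


def test_to_stress_strain_arithmetic():
    # d = 10 um -> A = 7.854e-11 m^2; F = 7.854e-5 N -> 1.000 MPa
    t = np.array([0.0, 1.0])
    trace = MechanicalTrace(t, np.array([0.0, 0.5]),
                            np.array([0.0, 7.853981633974483e-05]), 10.0, 5.0)
    curve = to_stress_strain(trace)
    assert curve.strain[-1] == pytest.approx(0.10)
    assert curve.stress[-1] == pytest.approx(1.000, rel=1e-9)
    assert curve.area_m2 == pytest.approx(7.853981633974483e-11)


def test_diameter_averaging_and_validation():
    t = np.array([0.0, 1.0])
    trace = MechanicalTrace(t, t, t, (9.0, 10.0, 11.0))
    assert trace.mean_diameter_um == pytest.approx(10.0)
    with pytest.raises(ValueError):
        MechanicalTrace(t, t, t, 0.0)
    with pytest.raises(ValueError):
        MechanicalTrace(t, t, t, 10.0, gauge_mm=-1.0)


def test_trace_csv_roundtrip(tmp_path):
    trace = sim.gen_tensile_trace()
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    back = MechanicalTrace.from_csv(path, 10.0)
    assert np.allclose(back.force, trace.force)
    assert np.allclose(back.displacement, trace.displacement)


def test_linear_elastic_closed_form():
    # sigma = E eps to eb then instant drop: UTS = E eb, U = E eb^2 / 2
    emod, eb = 4200.0, 0.02   # MPa per strain, break strain
    eps = np.linspace(0.0, eb, 400)
    sig = emod * eps
    # near-vertical drop so the break segment adds negligible area
    eps = np.append(eps, [eb + 1e-9, eb + 2e-9])
    sig = np.append(sig, [1.0, 1.0])
    res = tensile_summary(_curve(eps, sig))
    assert res.strength_mpa == pytest.approx(emod * eb, rel=1e-9)
    assert res.modulus_gpa == pytest.approx(emod / 1e3, rel=1e-6)
    assert res.toughness_mj_m3 == pytest.approx(0.5 * emod * eb ** 2, rel=1e-4)
    assert not res.censored


def test_break_rule_90_percent_drop():
    eps = np.array([0.0, 0.002, 0.005, 0.008, 0.011, 0.014, 0.02,
                    0.021, 0.022])
    sig = np.array([0.0, 20.0, 50.0, 80.0, 110.0, 140.0, 200.0, 50.0, 10.0])
    res = tensile_summary(_curve(eps, sig))
    # first sample after the peak with stress < 10% of peak is 0.022
    assert res.breaking_strain == pytest.approx(0.022)


def test_censored_flag_and_error():
    eps = np.linspace(0.0, 0.02, 50)
    sig = 4200.0 * eps
    res = tensile_summary(_curve(eps, sig))
    assert res.censored
    with pytest.raises(ValueError):
        tensile_summary(_curve(eps, sig), allow_censored=False)


def test_elastic_window_needs_points():
    eps = np.array([0.0, 0.1, 0.2, 0.3])
    with pytest.raises(ValueError):
        tensile_summary(_curve(eps, eps))


def test_generated_trace_recovery():
    trace = sim.gen_tensile_trace()
    truth = trace.meta["truth"]
    res = tensile_summary(to_stress_strain(trace))
    assert res.modulus_gpa == pytest.approx(truth["modulus_gpa"], rel=0.02)
    assert res.strength_mpa == pytest.approx(truth["strength_mpa"], rel=0.02)
    assert res.breaking_strain == pytest.approx(truth["breaking_strain"],
                                                rel=0.02)
    assert res.toughness_mj_m3 == pytest.approx(truth["toughness_mj_m3"],
                                                rel=0.02)


def test_triangle_loop_damping():
    # load linearly to 100 MPa at eps 0.10, unload to zero stress at 0.05:
    # A_load = 5.0, A_unload = 2.5 -> DC = 50 %, DE = 2.5 MJ/m^3
    eps = np.array([0.0, 0.10, 0.05])
    sig = np.array([0.0, 100.0, 0.0])
    res = cycle_damping(_curve(eps, sig))
    assert res.damping_capacity_pct == pytest.approx(50.0, rel=1e-12)
    assert res.damping_energy_mj_m3 == pytest.approx(2.5, rel=1e-12)
    assert res.permanent_set == pytest.approx(0.05, rel=1e-12)
    assert not res.flagged


def test_retraced_loop_zero_damping():
    eps = np.concatenate([np.linspace(0.0, 0.01, 50),
                          np.linspace(0.01, 0.0, 50)[1:]])
    sig = 4200.0 * eps
    res = cycle_damping(_curve(eps, sig))
    assert res.damping_capacity_pct == pytest.approx(0.0, abs=1e-9)
    assert res.damping_energy_mj_m3 == pytest.approx(0.0, abs=1e-9)


def test_unload_above_load_flagged():
    eps = np.array([0.0, 0.10, 0.0])
    sig = np.array([0.0, 100.0, 50.0])   # unload ends above zero stress
    res = cycle_damping(_curve(eps, sig))
    # A_unload (7.5) > A_load (5.0): DC < 0 and flagged
    assert res.flagged
    assert res.damping_capacity_pct < 0


def test_cycle_needs_both_segments():
    with pytest.raises(ValueError):
        cycle_damping(_curve([0.0, 0.1], [0.0, 10.0]))


def test_permanent_set_interpolated():
    eps = np.array([0.0, 0.10, 0.08, 0.06])
    sig = np.array([0.0, 100.0, 40.0, -20.0])
    res = cycle_damping(_curve(eps, sig))
    # zero crossing between 0.08 (40 MPa) and 0.06 (-20 MPa)
    assert res.permanent_set == pytest.approx(0.08 - 0.02 * 40.0 / 60.0,
                                              rel=1e-9)


def test_damping_resampling_invariance():
    params = sim.polymer_params()
    for n in (200, 1000):
        eps_up = np.linspace(0.0, 0.3, n)
        sig_up = params.envelope(eps_up)
        truth = sim._cycle_truth(params, 0.0, 0.3)
        eps_dn = np.linspace(0.3, truth["permanent_set"], n)[1:]
        sig_dn = truth["sigma_peak"] - truth["unload_slope"] * (0.3 - eps_dn)
        res = cycle_damping(_curve(np.concatenate([eps_up, eps_dn]),
                                   np.concatenate([sig_up, sig_dn])))
        assert res.damping_capacity_pct == pytest.approx(
            truth["damping_capacity_pct"], rel=0.005)
        assert res.damping_energy_mj_m3 == pytest.approx(
            truth["damping_energy_mj_m3"], rel=0.005)


def test_cyclic_truth_oracle_agreement():
    traces = sim.gen_cyclic_traces()
    for trace in traces:
        truth = trace.meta["truth"]
        res = cycle_damping(to_stress_strain(trace))
        if truth["damping_capacity_pct"] == 0.0:
            assert res.damping_capacity_pct == pytest.approx(0.0, abs=0.5)
        else:
            assert res.damping_capacity_pct == pytest.approx(
                truth["damping_capacity_pct"], rel=0.005)
            assert res.damping_energy_mj_m3 == pytest.approx(
                truth["damping_energy_mj_m3"], rel=0.005)


def test_aggregate_replicates_hand_values():
    class R:
        def __init__(self, v):
            self.metric = v
    table = aggregate_replicates([R(1.0), R(2.0), R(3.0)])
    assert table.loc["metric", "mean"] == pytest.approx(2.0)
    assert table.loc["metric", "sd"] == pytest.approx(1.0)
    assert table.loc["metric", "n"] == 3


def test_aggregate_single_replicate_sd_not_available():
    class R:
        def __init__(self, v):
            self.metric = v
    table = aggregate_replicates([R(5.0)])
    assert math.isnan(table.loc["metric", "sd"])
    with pytest.raises(ValueError):
        aggregate_replicates([])


def test_identical_replicates_zero_sd():
    class R:
        def __init__(self, v):
            self.metric = v
    table = aggregate_replicates([R(4.0)] * 5)
    assert table.loc["metric", "sd"] == 0.0
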