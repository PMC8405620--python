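"""Fiber tensile and cyclic-loading analysis.

Force-displacement traces from a constant-crosshead-speed pull test are
converted to engineering stress and strain using the initial fiber
cross-section A = pi (d/2)^2 and gauge length (default 5 mm).  From the
stress-strain curve:

* modulus       slope of a linear least-squares fit over the initial
                elastic window (default 0.2-1.5% strain), reported in GPa
* strength      maximum stress (MPa)
* break strain  first strain after the peak where the stress has dropped
                by more than 90% of the peak (the break-detection rule)
* toughness     trapezoidal integral of stress over strain up to the
                break point; with stress in MPa and strain dimensionless
                the area is numerically identical to an energy density in
                MJ/m^3

For a load-unload cycle, the loop is split at the maximum-strain sample;
the damping capacity is the hysteresis area over the loading area (in %)
and the damping energy is the hysteresis area itself (MJ/m^3).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "MechanicalTrace", "StressStrainCurve", "TensileResult", "CycleResult",
    "to_stress_strain", "tensile_summary", "cycle_damping",
    "aggregate_replicates", "DEFAULT_ELASTIC_WINDOW",
]

DEFAULT_ELASTIC_WINDOW: tuple[float, float] = (0.002, 0.015)
DEFAULT_GAUGE_MM = 5.0


@dataclass(frozen=True)
class MechanicalTrace:
    """Raw instrument trace plus specimen geometry.

    ``diameter_um`` may be a scalar or a sequence of point measurements
    along the fiber (averaged, mirroring the three-point light-microscopy
    protocol).
    """

    time: np.ndarray          # s
    displacement: np.ndarray  # mm
    force: np.ndarray         # N
    diameter_um: float | tuple[float, ...]
    gauge_mm: float = DEFAULT_GAUGE_MM
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, float)
        d = np.asarray(self.displacement, float)
        f = np.asarray(self.force, float)
        for name, arr in (("time", t), ("displacement", d), ("force", f)):
            if arr.ndim != 1 or arr.size != t.size:
                raise ValueError(f"{name} must be 1-D and congruent")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)
        if self.mean_diameter_um <= 0:
            raise ValueError("fiber diameter must be positive")
        if self.gauge_mm <= 0:
            raise ValueError("gauge length must be positive")

    @property
    def mean_diameter_um(self) -> float:
        d = self.diameter_um
        if np.isscalar(d):
            return float(d)  # type: ignore[arg-type]
        return float(np.mean(d))

    @classmethod
    def from_csv(cls, path, diameter_um, gauge_mm: float = DEFAULT_GAUGE_MM
                 ) -> "MechanicalTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(float),
                   df["displacement_mm"].to_numpy(float),
                   df["force_N"].to_numpy(float),
                   diameter_um, gauge_mm)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "displacement_mm": self.displacement,
                      "force_N": self.force}).to_csv(path, index=False)


@dataclass(frozen=True)
class StressStrainCurve:
    """Engineering stress (MPa) vs strain with the specimen geometry."""

    strain: np.ndarray
    stress: np.ndarray        # MPa
    area_m2: float
    volume_m3: float

    def __post_init__(self):
        s = np.asarray(self.strain, float)
        t = np.asarray(self.stress, float)
        if s.size != t.size:
            raise ValueError("strain and stress must have equal length")
        object.__setattr__(self, "strain", s)
        object.__setattr__(self, "stress", t)


def to_stress_strain(trace: MechanicalTrace) -> StressStrainCurve:
    """Pointwise conversion: strain = displacement/gauge, stress = F/A.

    The raw sampling is retained (no monotone resampling).
    """
    radius_m = trace.mean_diameter_um * 1e-6 / 2.0
    area = math.pi * radius_m ** 2
    volume = area * trace.gauge_mm * 1e-3
    strain = trace.displacement / trace.gauge_mm
    stress = trace.force / area / 1e6   # Pa -> MPa
    return StressStrainCurve(strain, stress, area, volume)


@dataclass(frozen=True)
class TensileResult:
    """Summary statistics of one tensile test."""

    modulus_gpa: float
    strength_mpa: float
    breaking_strain: float
    toughness_mj_m3: float
    elastic_window: tuple[float, float]
    censored: bool = False   # True when the trace ended without a detected break

    def __post_init__(self):
        if self.toughness_mj_m3 < 0:
            raise ValueError("toughness must be non-negative")

    def summary(self) -> str:
        tail = "  (no break detected; censored at end of trace)\n" if self.censored else ""
        return (
            "Tensile summary\n"
            f"  modulus           = {self.modulus_gpa:.3g} GPa "
            f"(window {self.elastic_window[0]:.3%}-{self.elastic_window[1]:.3%} strain)\n"
            f"  ultimate strength = {self.strength_mpa:.4g} MPa\n"
            f"  breaking strain   = {self.breaking_strain:.3g} "
            f"({100 * self.breaking_strain:.1f} %)\n"
            f"  toughness         = {self.toughness_mj_m3:.4g} MJ/m^3\n" + tail
        )


def _clamped(stress: np.ndarray) -> np.ndarray:
    neg = stress < 0
    if neg.any():
        log.warning("clamping %d negative stress samples for area integrals",
                    int(neg.sum()))
        return np.where(neg, 0.0, stress)
    return stress


def tensile_summary(curve: StressStrainCurve,
                    elastic_window: tuple[float, float] = DEFAULT_ELASTIC_WINDOW,
                    allow_censored: bool = True) -> TensileResult:
    """Modulus, strength, break strain (90%-drop rule) and toughness.

    The break is the first sample after the stress peak where the stress
    falls below 10% of the peak; toughness integrates stress over strain
    from the start to that point (post-drop tail excluded).  If no break
    is found the result is flagged censored (or an error is raised when
    ``allow_censored`` is False).
    """
    eps, sig = curve.strain, curve.stress
    lo, hi = sorted(elastic_window)
    win = (eps >= lo) & (eps <= hi)
    if win.sum() < 4:
        raise ValueError("fewer than 4 samples in the elastic window")
    slope, _ = np.polyfit(eps[win], sig[win], 1)
    modulus_gpa = float(slope) / 1e3   # MPa per unit strain -> GPa

    ipeak = int(np.argmax(sig))
    strength = float(sig[ipeak])
    after = np.nonzero(sig[ipeak:] < 0.10 * strength)[0]
    if after.size:
        ibreak = ipeak + int(after[0])
        censored = False
    else:
        ibreak = eps.size - 1
        censored = True
        if not allow_censored:
            raise ValueError("no 90% stress drop detected and censoring disallowed")
    breaking_strain = float(eps[ibreak])
    toughness = float(np.trapezoid(_clamped(sig[:ibreak + 1]), eps[:ibreak + 1]))
    return TensileResult(modulus_gpa, strength, breaking_strain, toughness,
                         (lo, hi), censored)


@dataclass(frozen=True)
class CycleResult:
    """Damping statistics of one load-unload cycle."""

    peak_strain: float
    damping_capacity_pct: float
    damping_energy_mj_m3: float
    permanent_set: float
    flagged: bool = False   # unload exceeded load somewhere; bounds not guaranteed

    def summary(self) -> str:
        flag = "  (flagged: unload path exceeded load path)\n" if self.flagged else ""
        return (
            "Cycle damping\n"
            f"  peak strain      = {self.peak_strain:.3g}\n"
            f"  damping capacity = {self.damping_capacity_pct:.1f} %\n"
            f"  damping energy   = {self.damping_energy_mj_m3:.4g} MJ/m^3\n"
            f"  permanent set    = {self.permanent_set:.3g}\n" + flag
        )


def cycle_damping(curve: StressStrainCurve) -> CycleResult:
    """Damping capacity and energy of a single load-unload loop.

    The loop is split at the maximum-strain sample (first occurrence on
    ties).  Loading and unloading areas are trapezoidal integrals of
    stress over strain, both taken with positive orientation; negative
    stresses are clamped to zero first.  The permanent set is the strain
    at which the unloading stress first returns to zero (linear
    interpolation between samples).
    """
    eps, sig = curve.strain, np.asarray(_clamped(curve.stress))
    isplit = int(np.argmax(eps))
    if isplit == 0 or isplit == eps.size - 1:
        raise ValueError("curve must contain both a loading and an unloading segment")
    le, ls = eps[:isplit + 1], sig[:isplit + 1]
    ue, us = eps[isplit:], sig[isplit:]
    us_raw = np.asarray(curve.stress, float)[isplit:]  # for the zero crossing
    a_load = float(np.trapezoid(ls, le))
    a_unload = float(-np.trapezoid(us, ue))  # strain decreasing: flip sign
    if a_load <= 0:
        raise ValueError("loading area is non-positive")
    de = a_load - a_unload
    dc = 100.0 * de / a_load
    flagged = False
    if dc < -1e-9 or dc > 100.0 + 1e-9:
        flagged = True
        log.warning("damping capacity %.1f%% outside [0, 100]: unload path "
                    "exceeds load path", dc)
    # permanent set: first zero crossing of the (unclamped) unloading stress
    zero = np.nonzero(us_raw <= 0)[0]
    if zero.size:
        j = int(zero[0])
        if j == 0 or us_raw[j] == 0:
            pset = float(ue[j])
        else:
            f = us_raw[j - 1] / (us_raw[j - 1] - us_raw[j])
            pset = float(ue[j - 1] + f * (ue[j] - ue[j - 1]))
    else:
        pset = float(ue[-1])
    return CycleResult(float(eps[isplit]), dc, de, pset, flagged)


def aggregate_replicates(results, metrics: tuple[str, ...] | None = None
                         ) -> pd.DataFrame:
    """Per-metric mean and sample sd over replicate result objects.

    ``results`` is a sequence of dataclass results (e.g. TensileResult or
    CycleResult); ``metrics`` defaults to every numeric scalar field.
    With a single replicate the sd is reported as NaN (not available).
    """
    results = list(results)
    if not results:
        raise ValueError("at least one result is required")
    first = results[0]
    if metrics is None:
        metrics = tuple(k for k, v in vars(first).items()
                        if isinstance(v, (int, float)) and not isinstance(v, bool))
    rows = []
    for m in metrics:
        vals = np.array([float(getattr(r, m)) for r in results])
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
        rows.append({"metric": m, "mean": float(vals.mean()), "sd": sd,
                     "n": vals.size})
    return pd.DataFrame(rows).set_index("metric")


def replicate_summary_text(table: pd.DataFrame) -> str:
    buf = io.StringIO()
    buf.write("Replicate summary (mean +/- sample sd)\n")
    for m, row in table.iterrows():
        sd = "n/a" if np.isnan(row["sd"]) else f"{row['sd']:.3g}"
        buf.write(f"  {m:<22s} {row['mean']:.4g} +/- {sd}  (n={int(row['n'])})\n")
    return buf.getvalue()
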