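"""Size-exclusion chromatography: calibration and average molecular weights.

The column is calibrated by fitting an exponential, mass = a * exp(b * Vr/V0),
to standards of known mass (Vr the retention volume, V0 the void volume from
a blue-dextran run).  A chromatogram is then converted point-by-point to
calibrated masses and the number- and mass-average molecular weights are
computed as plain sums

    Mn = sum(Mi Ni) / sum(Ni),      Mw = sum(Ni Mi^2) / sum(Ni Mi)

with Ni the measured A280 absorbance at each grid point and the sums
restricted to a mass window (default 1 kDa - 5 MDa, the usable
fractionation range).  Note that an A280 detector weighs mass, not number,
so this Mn/Mw estimator inherits an upward bias relative to the
number-weighted moments; `fiberlab.distributions.species_moments` exposes
both weightings so the bias is visible on synthetic data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve", "Chromatogram", "MWResult",
    "fit_calibration", "compute_mn_mw",
    "DEFAULT_MASS_WINDOW",
]

#: default integration window in kDa (1 kDa to 5 MDa)
DEFAULT_MASS_WINDOW: tuple[float, float] = (1.0, 5000.0)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted exponential SEC calibration mass = a * exp(b * Vr / V0).

    ``b`` is negative for a size-exclusion column (larger species elute
    earlier).  ``residuals`` are log-mass residuals at the standards.
    """

    a: float
    b: float
    void_volume: float
    standards: pd.DataFrame = field(repr=False)
    residuals: np.ndarray = field(repr=False)

    def mass_at(self, vr) -> np.ndarray | float:
        """Calibrated mass (kDa) at retention volume(s) ``vr`` (mL)."""
        return self.a * np.exp(self.b * np.asarray(vr, float) / self.void_volume)

    def volume_at(self, mass) -> np.ndarray | float:
        """Inverse mapping: retention volume (mL) for mass(es) in kDa."""
        return np.log(np.asarray(mass, float) / self.a) * self.void_volume / self.b

    @property
    def standard_mass_range(self) -> tuple[float, float]:
        m = self.standards["mass_kDa"].to_numpy()
        return float(m.min()), float(m.max())

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("SEC calibration: mass = a * exp(b * Vr/V0)\n")
        buf.write(f"  a = {self.a:.6g} kDa\n  b = {self.b:.6g}\n")
        buf.write(f"  V0 = {self.void_volume:.4g} mL, n standards = {len(self.standards)}\n")
        buf.write(f"  rms log-mass residual = {np.sqrt(np.mean(self.residuals**2)):.3e}\n")
        return buf.getvalue()


@dataclass(frozen=True)
class Chromatogram:
    """Elution trace: retention-volume grid (mL) vs absorbance at 280 nm."""

    volume: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.volume, float)
        a = np.asarray(self.absorbance, float)
        object.__setattr__(self, "volume", v)
        object.__setattr__(self, "absorbance", a)
        if v.ndim != 1 or v.size != a.size:
            raise ValueError("volume and absorbance must be 1-D of equal length")
        if v.size and not np.all(np.diff(v) > 0):
            raise ValueError("volume grid must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance must be finite")

    @classmethod
    def from_csv(cls, path) -> "Chromatogram":
        df = pd.read_csv(path)
        return cls(df["volume_mL"].to_numpy(float), df["absorbance"].to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame({"volume_mL": self.volume,
                      "absorbance": self.absorbance}).to_csv(path, index=False)


@dataclass(frozen=True)
class MWResult:
    """Average molecular weights from one chromatogram."""

    mn: float            # kDa
    mw: float            # kDa
    mass_window: tuple[float, float]
    n_points: int
    extrapolated_fraction: float  # signal fraction beyond the standards' range

    def __post_init__(self):
        if self.mn > self.mw * (1 + 1e-9):
            raise ValueError("Mn must not exceed Mw")

    @property
    def dispersity(self) -> float:
        return self.mw / self.mn

    def summary(self) -> str:
        lo, hi = self.mass_window
        return (
            "SEC molecular-weight averages\n"
            f"  Mn = {self.mn:.4g} kDa\n"
            f"  Mw = {self.mw:.4g} kDa\n"
            f"  dispersity Mw/Mn = {self.dispersity:.4g}\n"
            f"  window = [{lo:g}, {hi:g}] kDa over {self.n_points} points\n"
            f"  signal beyond standards range = {100*self.extrapolated_fraction:.1f}%\n"
        )


def fit_calibration(standards, void_volume: float) -> CalibrationCurve:
    """Least-squares exponential fit of mass vs Vr/V0.

    Parameters
    ----------
    standards : DataFrame or sequence of (mass_kDa, Vr_mL)
        At least two standards with distinct retention volumes.
    void_volume : float
        V0 in mL (> 0), from the excluded-volume marker.

    The fit is linear least squares in log-mass, which is exact for data
    generated from the model and well-conditioned for typical standards
    whose masses span decades.
    """
    if void_volume <= 0:
        raise ValueError("void volume must be positive")
    if isinstance(standards, pd.DataFrame):
        df = standards.rename(columns=lambda c: c.strip())
        mass = df["mass_kDa"].to_numpy(float)
        vr = df["Vr_mL"].to_numpy(float)
    else:
        arr = np.asarray(list(standards), float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("standards must be (mass_kDa, Vr_mL) pairs")
        mass, vr = arr[:, 0], arr[:, 1]
    if mass.size < 2:
        raise ValueError("at least 2 standards are required")
    if np.unique(vr).size < mass.size:
        raise ValueError("standards must have distinct retention volumes")
    if np.any(mass <= 0):
        raise ValueError("standard masses must be positive")

    x = vr / void_volume
    slope, intercept = np.polyfit(x, np.log(mass), 1)
    a, b = float(np.exp(intercept)), float(slope)
    if b == 0:
        raise ValueError("fitted calibration is not monotone (b = 0)")
    resid = np.log(mass) - (intercept + slope * x)
    df = pd.DataFrame({"mass_kDa": mass, "Vr_mL": vr})
    return CalibrationCurve(a, b, float(void_volume), df, resid)


def compute_mn_mw(chrom: Chromatogram, calib: CalibrationCurve,
                  mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW,
                  subtract_baseline: bool = False) -> MWResult:
    """Number- and mass-average MW from a chromatogram (plain sums).

    Each grid point contributes Ni = absorbance (negative values clamped
    to zero) at the calibrated mass Mi; points whose Mi falls outside
    ``mass_window`` are excluded.  With ``subtract_baseline`` a straight
    line through the first and last in-window points is removed first
    (default off).
    """
    lo, hi = sorted(mass_window)
    masses = np.asarray(calib.mass_at(chrom.volume), float)
    sel = (masses >= lo) & (masses <= hi)
    if not sel.any():
        raise ValueError("chromatogram does not overlap the mass window")
    mi = masses[sel]
    ni = chrom.absorbance[sel].copy()
    if subtract_baseline and ni.size >= 2:
        base = np.interp(np.arange(ni.size), [0, ni.size - 1], [ni[0], ni[-1]])
        ni = ni - base
    np.clip(ni, 0.0, None, out=ni)
    if ni.sum() <= 0:
        raise ValueError("no positive signal inside the mass window")
    mn = float((mi * ni).sum() / ni.sum())
    mw = float((ni * mi ** 2).sum() / (ni * mi).sum())
    smin, smax = calib.standard_mass_range
    outside = (mi < smin) | (mi > smax)
    extr = float(ni[outside].sum() / ni.sum())
    return MWResult(mn, mw, (lo, hi), int(sel.sum()), extr)
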