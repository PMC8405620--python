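"""Sampled 1-D signals (wavenumber or scattering-vector vs intensity).

The :class:`Spectrum` container is shared by the FTIR, Raman and WAXD
profile stages.  The only non-trivial algorithm here is the rubber-band
(lower convex hull) baseline used to flatten vibrational spectra before
band deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "convex_hull_baseline"]


@dataclass(frozen=True)
class Spectrum:
    """A sampled 1-D signal with strictly increasing abscissa.

    Parameters
    ----------
    x : ndarray
        Abscissa (wavenumber in cm^-1 for vibrational spectra, q in
        inverse Angstrom for diffraction profiles), strictly increasing.
    y : ndarray
        Intensity in arbitrary units, finite.
    modality : str, optional
        Free-form tag, e.g. ``"ftir"``, ``"raman"``.
    orientation : str, optional
        Polarisation / fiber-orientation label (``"X"`` or ``"Y"``).
    """

    x: np.ndarray
    y: np.ndarray
    modality: Optional[str] = None
    orientation: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size and not np.all(np.diff(x) > 0):
            raise ValueError("abscissa must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.x.size

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to abscissa values in [lo, hi] (inclusive)."""
        if lo > hi:
            lo, hi = hi, lo
        mask = (self.x >= lo) & (self.x <= hi)
        if not mask.any():
            raise ValueError(f"no data in region [{lo}, {hi}]")
        return replace(self, x=self.x[mask], y=self.y[mask])

    def value_at(self, x0: float) -> float:
        """Linear interpolation of the intensity at x0."""
        return float(np.interp(x0, self.x, self.y))

    def peak_in(self, center: float, half_window: float) -> tuple[float, float]:
        """(abscissa, intensity) of the maximum within center +- half_window."""
        sub = self.crop(center - half_window, center + half_window)
        i = int(np.argmax(sub.y))
        return float(sub.x[i]), float(sub.y[i])

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, y=self.y * factor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y})

    @classmethod
    def from_csv(cls, path, modality: Optional[str] = None,
                 orientation: Optional[str] = None) -> "Spectrum":
        """Read a two-column CSV (first column abscissa, second intensity)."""
        df = pd.read_csv(path)
        x = df.iloc[:, 0].to_numpy(float)
        y = df.iloc[:, 1].to_numpy(float)
        order = np.argsort(x)
        return cls(x[order], y[order], modality=modality, orientation=orientation)

    def to_csv(self, path, x_label: str = "wavenumber_cm-1",
               y_label: str = "intensity") -> None:
        pd.DataFrame({x_label: self.x, y_label: self.y}).to_csv(path, index=False)


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # Andrew monotone chain, lower hull only; x already sorted ascending.
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # cross product of (p2-p1) x (p3-p1); keep right turns (convex down)
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def convex_hull_baseline(spec: Spectrum, region: Optional[tuple[float, float]] = None,
                         return_baseline: bool = False):
    """Rubber-band baseline subtraction.

    The baseline is the lower convex hull of the (x, y) points over
    ``region`` evaluated by linear interpolation between hull vertices;
    the returned spectrum is the original minus the baseline, which is
    non-negative up to floating-point rounding.  Applying the operation
    twice changes nothing: the hull of a hull-subtracted signal is zero.

    Parameters
    ----------
    spec : Spectrum
    region : (float, float), optional
        Sub-interval of the abscissa to operate on (default: full range).
    return_baseline : bool
        If True return ``(corrected, baseline)`` instead of just the
        corrected spectrum.
    """
    work = spec if region is None else spec.crop(*region)
    if len(work) < 3:
        raise ValueError("baseline region must contain at least 3 points")
    idx = _lower_hull_indices(work.x, work.y)
    baseline = np.interp(work.x, work.x[idx], work.y[idx])
    corrected = work.y - baseline
    # the hull lies on or below every point; clip rounding dust only
    corrected[corrected < 0] = 0.0
    out = replace(work, y=corrected)
    if return_baseline:
        return out, replace(work, y=baseline)
    return out
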