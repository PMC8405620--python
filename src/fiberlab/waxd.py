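"""Wide-angle fiber diffraction: detector geometry, q/azimuth mapping and
1-D profile extraction.

A flat detector normal to the beam records counts per pixel.  For a pixel
at radius r (mm) from the beam center, the scattering angle is
2*theta = arctan(r/L) and the scattering vector magnitude is
q = 4*pi*sin(theta)/lambda.  The azimuth chi is measured so that chi = 0
lies on the equator (perpendicular to the fiber axis) and chi = 90 deg on
the meridian (the fiber axis), with the meridian's direction on the
detector configurable.

Radial profiles are sector integrations (mean background-subtracted
intensity per q-bin over an azimuthal wedge around the equator or
meridian, Friedel pairs combined); azimuthal profiles are the mean
intensity versus chi within a radial band, typically placed on one of the
equatorial reflections to read off orientation spread.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "DetectorGeometry", "DiffractionImage",
    "RadialProfile", "AzimuthalProfile",
    "map_pixels", "sector_integrate", "azimuthal_profile",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector geometry for a fiber-diffraction experiment.

    Defaults follow a typical synchrotron fiber setup: 0.886 A beam,
    200 mm sample-detector distance, 172 um pixels, meridian vertical.
    """

    wavelength: float = 0.886          # Angstrom
    distance: float = 200.0            # mm, sample to detector
    center: tuple[float, float] = (350.0, 350.0)  # beam center, pixel (row, col)
    pixel_size: float = 0.172          # mm
    meridian_deg: float = 90.0         # detector azimuth of the fiber axis

    def __post_init__(self):
        if self.wavelength <= 0 or self.distance <= 0 or self.pixel_size <= 0:
            raise ValueError("wavelength, distance and pixel size must be positive")

    def q_of_radius(self, r_mm) -> np.ndarray | float:
        """q (A^-1) at radial distance r (mm) from the beam center."""
        two_theta = np.arctan(np.asarray(r_mm, float) / self.distance)
        return 4 * np.pi * np.sin(two_theta / 2) / self.wavelength

    def radius_of_q(self, q) -> np.ndarray | float:
        """Inverse of :meth:`q_of_radius` (mm)."""
        theta = np.arcsin(np.asarray(q, float) * self.wavelength / (4 * np.pi))
        return self.distance * np.tan(2 * theta)

    @property
    def max_q(self) -> float:
        # conservative: shortest center-to-edge distance is geometry-free here;
        # callers with an image should use map_pixels instead.
        return float("inf")

    # -- sidecar I/O ------------------------------------------------------
    def to_sidecar(self, path) -> None:
        lines = [
            f"wavelength_A = {self.wavelength!r}",
            f"distance_mm = {self.distance!r}",
            f"center_px = {self.center[0]!r}, {self.center[1]!r}",
            f"pixel_mm = {self.pixel_size!r}",
            f"meridian_deg = {self.meridian_deg!r}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_sidecar(cls, path) -> "DetectorGeometry":
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        center = tuple(float(v) for v in kv["center_px"].split(","))
        return cls(wavelength=float(kv["wavelength_A"]),
                   distance=float(kv["distance_mm"]),
                   center=center,  # type: ignore[arg-type]
                   pixel_size=float(kv["pixel_mm"]),
                   meridian_deg=float(kv.get("meridian_deg", 90.0)))


def map_pixels(geometry: DetectorGeometry, shape: tuple[int, int]
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (q, chi) arrays for an image of the given shape.

    q is in A^-1; chi in degrees in [0, 360) with chi = 0 on the equator
    (the detector direction ``meridian_deg - 90``).  Rows increase
    downward on the detector; the detector azimuth is measured from the
    +column direction toward +row, matching ``atan2(drow, dcol)``.
    """
    rows, cols = np.indices(shape)
    drow = (rows - geometry.center[0]) * geometry.pixel_size
    dcol = (cols - geometry.center[1]) * geometry.pixel_size
    r = np.hypot(drow, dcol)
    q = geometry.q_of_radius(r)
    phi = np.degrees(np.arctan2(drow, dcol))
    chi = np.mod(phi - (geometry.meridian_deg - 90.0), 360.0)
    return q, chi


@dataclass(frozen=True)
class DiffractionImage:
    """2-D counts grid plus detector geometry and optional air background."""

    counts: np.ndarray
    geometry: DetectorGeometry
    background: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.counts, float)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.background is not None:
            b = np.asarray(self.background, float)
            if b.shape != c.shape:
                raise ValueError("background shape must match counts")
            object.__setattr__(self, "background", b)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]

    def corrected(self) -> np.ndarray:
        """Background-subtracted counts, clamped at zero.

        With an air-background image supplied the subtraction is
        per-pixel; otherwise a constant offset estimated as the median of
        the four image corners (where the sample scattering is weakest)
        is removed.  Negative results are clamped and the clamped
        fraction logged.
        """
        if self.background is not None:
            out = self.counts - self.background
        else:
            k = max(4, min(self.shape) // 20)
            corners = np.concatenate([
                self.counts[:k, :k].ravel(), self.counts[:k, -k:].ravel(),
                self.counts[-k:, :k].ravel(), self.counts[-k:, -k:].ravel()])
            out = self.counts - float(np.median(corners))
        neg = out < 0
        if neg.any():
            log.warning("clamped %.2f%% negative pixels after background subtraction",
                        100.0 * neg.mean())
            out = np.where(neg, 0.0, out)
        return out

    # -- I/O --------------------------------------------------------------
    def save(self, path, sidecar=None, fmt: str = "auto") -> None:
        path = Path(path)
        if fmt == "auto":
            fmt = "tiff" if path.suffix.lower() in {".tif", ".tiff"} else "txt"
        if fmt == "tiff":
            import tifffile
            tifffile.imwrite(path, self.counts.astype(np.float32))
        else:
            np.savetxt(path, self.counts, fmt="%.6g")
        if sidecar is not None:
            self.geometry.to_sidecar(sidecar)

    @classmethod
    def load(cls, path, sidecar) -> "DiffractionImage":
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile
            counts = np.asarray(tifffile.imread(path), float)
        else:
            counts = np.loadtxt(path)
        return cls(counts, DetectorGeometry.from_sidecar(sidecar))


@dataclass(frozen=True)
class RadialProfile:
    """Mean intensity vs q over an azimuthal sector."""

    q: np.ndarray
    intensity: np.ndarray
    axis: str | float               # "equator", "meridian" or chi in degrees
    sector_width: float             # degrees, full width

    def __post_init__(self):
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q grid must be strictly increasing")


@dataclass(frozen=True)
class AzimuthalProfile:
    """Mean intensity vs azimuth chi (degrees, 0-360) over a radial band."""

    chi: np.ndarray
    intensity: np.ndarray
    q_band: tuple[float, float]

    def __post_init__(self):
        if not np.all(np.diff(self.chi) > 0):
            raise ValueError("chi grid must be strictly increasing")


_AXIS_CENTER = {"equator": 0.0, "meridian": 90.0}


def _axis_center(axis) -> float:
    if isinstance(axis, str):
        return _AXIS_CENTER[axis]
    return float(axis)


def _angular_distance(chi: np.ndarray, center: float) -> np.ndarray:
    """Distance to the axis at ``center`` combining Friedel pairs (mod 180)."""
    d = np.mod(chi - center, 180.0)
    return np.minimum(d, 180.0 - d)


def sector_integrate(image: DiffractionImage, axis: str = "equator",
                     sector_width: float = 25.0,
                     q_bin: float = 0.005,
                     q_range: tuple[float, float] | None = None) -> RadialProfile:
    """Radial 1-D profile from an azimuthal sector around an axis.

    Pixels whose azimuthal distance to the axis (on either side, Friedel
    pairs combined) is within ``sector_width / 2`` are averaged in q-bins
    of width ``q_bin`` (A^-1).  ``axis`` is ``"equator"``, ``"meridian"``
    or an azimuth in degrees (chi convention) for off-axis reference
    sectors.  Empty interior bins are flagged and linearly interpolated.
    """
    if isinstance(axis, str) and axis not in _AXIS_CENTER:
        raise ValueError("axis must be 'equator', 'meridian' or an angle")
    if not 5.0 <= sector_width <= 60.0:
        raise ValueError("sector width must lie in [5, 60] degrees")
    q, chi = map_pixels(image.geometry, image.shape)
    data = image.corrected()
    sel = _angular_distance(chi, _axis_center(axis)) <= sector_width / 2.0
    qs, vals = q[sel], data[sel]
    if q_range is None:
        lo = q_bin  # skip the beam-center bin
        hi = float(qs.max())
    else:
        lo, hi = q_range
    nbins = max(1, int(np.ceil((hi - lo) / q_bin)))
    edges = lo + q_bin * np.arange(nbins + 1)
    idx = np.digitize(qs, edges) - 1
    ok = (idx >= 0) & (idx < nbins)
    sums = np.bincount(idx[ok], weights=vals[ok], minlength=nbins)
    cnts = np.bincount(idx[ok], minlength=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        mean = sums / cnts
    empty = cnts == 0
    if empty.any():
        log.warning("interpolating %d empty q-bins in %s sector profile",
                    int(empty.sum()), axis)
        mean[empty] = np.interp(centers[empty], centers[~empty], mean[~empty])
    return RadialProfile(centers, mean, axis, sector_width)


def azimuthal_profile(image: DiffractionImage, q_band: tuple[float, float],
                      chi_bin: float = 2.0) -> AzimuthalProfile:
    """Mean intensity vs azimuth over the radial band ``q_band`` (A^-1)."""
    lo, hi = sorted(q_band)
    q, chi = map_pixels(image.geometry, image.shape)
    data = image.corrected()
    sel = (q >= lo) & (q <= hi)
    if not sel.any():
        raise ValueError(f"q-band [{lo}, {hi}] contains no pixels")
    nbins = int(round(360.0 / chi_bin))
    edges = np.linspace(0.0, 360.0, nbins + 1)
    idx = np.clip(np.digitize(chi[sel], edges) - 1, 0, nbins - 1)
    sums = np.bincount(idx, weights=data[sel], minlength=nbins)
    cnts = np.bincount(idx, minlength=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        mean = sums / cnts
    empty = cnts == 0
    if empty.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
        log.warning("interpolating %d empty chi-bins in azimuthal profile",
                    int(empty.sum()))
        mean[empty] = np.interp(centers[empty], centers[~empty], mean[~empty],
                                period=360.0)
    return AzimuthalProfile(centers, mean, (lo, hi))
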