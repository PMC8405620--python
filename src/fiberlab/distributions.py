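"""Discrete chain-length distributions for step-growth protein polymers.

The split-intein ligation that chains protein subunits head-to-tail is an
ideal step-growth polymerisation, so the canonical Flory most-probable
distribution is used as the ground-truth polymer model: at extent of
reaction ``p`` the number fraction of i-mers is (1-p) p**(i-1), giving the
closed forms Mn = M0/(1-p) and Mw = M0 (1+p)/(1-p) in the untruncated
limit.  The distribution carries its truncation-corrected truths so that
SEC estimators can be judged against an exact species-level oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DiscreteMWDistribution",
    "gen_flory_distribution",
    "flory_p_for_mw",
    "species_moments",
]

#: fraction of the untruncated mass that i_max must capture
MASS_COVERAGE = 0.9999


@dataclass(frozen=True)
class DiscreteMWDistribution:
    """Chain-length distribution with closed-form molecular-weight truths.

    Attributes
    ----------
    monomer_mass : float
        Subunit mass M0 in kDa.
    p : float
        Extent of reaction in [0, 1).
    masses : ndarray
        Per-species mass Mi = i * M0 (kDa), i = 1..i_max.
    number_fractions : ndarray
        Normalised number fractions, summing to 1.
    true_mn, true_mw : float
        Number- and mass-average MW (kDa) of the truncated distribution
        (direct summation; equal to the closed forms to the stated mass
        coverage).
    """

    monomer_mass: float
    p: float
    masses: np.ndarray
    number_fractions: np.ndarray
    true_mn: float
    true_mw: float

    def __post_init__(self):
        if abs(self.number_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("number fractions must sum to 1")
        if self.true_mn > self.true_mw * (1 + 1e-12):
            raise ValueError("Mn must not exceed Mw")

    @property
    def i_max(self) -> int:
        return int(self.masses.size)

    @property
    def mass_fractions(self) -> np.ndarray:
        w = self.number_fractions * self.masses
        return w / w.sum()

    @property
    def dispersity(self) -> float:
        return self.true_mw / self.true_mn


def gen_flory_distribution(p: float, monomer_mass: float,
                           i_max: int = 2000) -> DiscreteMWDistribution:
    """Flory most-probable distribution at extent of reaction ``p``.

    Raises
    ------
    ValueError
        If ``p`` is outside [0, 1) or if ``i_max`` truncates more than
        0.01% of the untruncated mass (the message names the required
        i_max).
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"extent of reaction must be in [0, 1), got {p}")
    if monomer_mass <= 0:
        raise ValueError("monomer mass must be positive")
    if p == 0.0:
        masses = np.array([monomer_mass])
        return DiscreteMWDistribution(monomer_mass, 0.0, masses,
                                      np.array([1.0]), monomer_mass, monomer_mass)

    i = np.arange(1, i_max + 1, dtype=float)
    n = (1 - p) * p ** (i - 1)
    masses = monomer_mass * i
    # untruncated weight distribution w_i = i (1-p)^2 p^(i-1);
    # tail mass beyond i_max has closed form p^i (1 + i (1-p))
    tail = p ** i_max * (1 + i_max * (1 - p))
    if tail > 1 - MASS_COVERAGE:
        # invert the tail expression for the needed i_max
        need = int(brentq(lambda m: m * np.log(p) + np.log1p(m * (1 - p))
                          - np.log(1 - MASS_COVERAGE), i_max, 10 * i_max / (1 - p)))
        raise ValueError(
            f"i_max={i_max} keeps only {100 * (1 - tail):.4f}% of the mass; "
            f"use i_max >= {need + 1}")
    nf = n / n.sum()
    mn = float((nf * masses).sum())
    mw = float((nf * masses ** 2).sum() / (nf * masses).sum())
    return DiscreteMWDistribution(monomer_mass, p, masses, nf, mn, mw)


def flory_p_for_mw(target_mw: float, monomer_mass: float) -> float:
    """Extent of reaction whose untruncated Mw equals ``target_mw`` (closed form)."""
    r = target_mw / monomer_mass
    if r < 1:
        raise ValueError("target Mw below monomer mass")
    return (r - 1) / (r + 1)


def species_moments(dist: DiscreteMWDistribution,
                    weighting: str = "number",
                    mass_window: tuple[float, float] | None = None
                    ) -> tuple[float, float]:
    """Species-level summation oracle for (Mn, Mw).

    Parameters
    ----------
    weighting : {"number", "absorbance"}
        How each species contributes to the sums' Ni.  ``"number"`` gives
        the textbook moments.  ``"absorbance"`` weighs species by mass
        concentration, mimicking an A280 detector read out through the
        Mn/Mw sum formulas; this is the quantity a chromatogram-based
        estimator with Ni = absorbance actually converges to, and it is
        biased upward relative to the number-weighted truth.
    mass_window : (lo, hi) in kDa, optional
        Restrict the sums to species inside the window (the integration
        window the chromatogram analysis applies).
    """
    m = dist.masses
    if weighting == "number":
        w = dist.number_fractions.copy()
    elif weighting == "absorbance":
        w = dist.number_fractions * m
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if mass_window is not None:
        lo, hi = mass_window
        sel = (m >= lo) & (m <= hi)
        if not sel.any():
            raise ValueError("mass window excludes every species")
        m, w = m[sel], w[sel]
    mn = float((w * m).sum() / w.sum())
    mw = float((w * m ** 2).sum() / (w * m).sum())
    return mn, mw
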